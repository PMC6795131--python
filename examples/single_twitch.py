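"""One isometric single-twitch experiment, start to finish.

Calibrates the fiber model (conduction velocity 3.5 m/s, twitch time-to-peak
71 ms), runs the baseline muscle-tendon system at two applied stretches, and
prints the electromechanical delay extracted from each reaction-stress trace.
"""

from emdsim.config import baseline_config
from emdsim.pipeline import compute_emd, get_calibration, run_twitch

cfg = baseline_config()
cal = get_calibration(cfg)
print(f"calibrated conduction velocity: {cal.cv_measured:.2f} m/s")
print(f"calibrated twitch time-to-peak: {cal.ttp_measured:.1f} ms "
      f"(rate multiplier {cal.rate_multiplier:.3f})\n")

for lam in (1.05, 1.25):
    trace = run_twitch(cfg, lam, calibration=cal)
    res = compute_emd(trace, cfg.cell.p_max)
    rise = trace.p.max() - trace.p[0]
    print(f"applied stretch {lam}: passive stress {trace.p[0]:6.3f} N/cm^2, "
          f"twitch rise {rise:5.3f} N/cm^2, EMD = {res.emd:6.2f} ms")

print("\nAt 1.05 the tendon is slack, so the muscle must first shorten"
      "\nagainst its own passive stiffness before stress reaches the distal"
      "\ntendon end; near the optimum (1.25) the stiff tendon transmits the"
      "\nactive stress almost immediately, giving a much shorter delay.")
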