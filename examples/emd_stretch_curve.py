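"""The EMD-stretch curve: the series tendon is what creates its shape.

Runs the seven-stretch grid for the baseline muscle-tendon system and for an
isolated muscle (no tendon) and prints both curves side by side.
"""

from emdsim.config import baseline_config, variant_config
from emdsim.study import emd_curve

base = baseline_config()
curve_mts = emd_curve(base)
curve_iso = emd_curve(variant_config("isolated_muscle"))

print(f"{'stretch':>8} {'muscle-tendon':>14} {'isolated muscle':>16}")
for lam, e_mts, e_iso in zip(base.stretches, curve_mts, curve_iso):
    print(f"{lam:8.2f} {e_mts:14.2f} {e_iso:16.2f}")

print("\nEMD in ms. The series system shows the characteristic steep decrease"
      "\ntoward its optimum followed by a plateau; the isolated muscle is"
      "\nnearly stretch-independent and minimal around its optimal length.")
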