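"""Passive stress-stretch behavior of muscle, tendon, and the series system.

Evaluates the incompressible uniaxial Ogden law for both tissues and solves
the passive series equilibrium of the baseline muscle-tendon rod, printing
how an applied stretch partitions between the stiff muscle and the
compliant-toe tendon.
"""

import numpy as np

from emdsim.config import baseline_config
from emdsim.mechanics import (
    OgdenMaterial,
    ogden_uniaxial_nominal_stress,
    solve_series_equilibrium,
)

cfg = baseline_config()
muscle = OgdenMaterial.muscle(cfg.materials)
tendon = OgdenMaterial.tendon(cfg.materials)

print("uniaxial nominal stress (N/cm^2)")
print(f"{'stretch':>8} {'muscle':>10} {'tendon':>10}")
for lam in (1.05, 1.15, 1.25, 1.35):
    pm = float(ogden_uniaxial_nominal_stress(lam, muscle))
    pt = float(ogden_uniaxial_nominal_stress(lam, tendon))
    print(f"{lam:8.2f} {pm:10.3f} {pt:10.3f}")

print("\npassive series equilibrium of the baseline system (MTR 0.33)")
print(f"{'applied':>8} {'lam_muscle':>11} {'lam_tendon':>11} {'stress':>9}")
for lam_bar in (1.05, 1.15, 1.25, 1.35):
    eq = solve_series_equilibrium(
        lam_bar, np.zeros(20), 0.0, cfg.geometry, cfg.materials, cfg.cell
    )
    print(f"{lam_bar:8.2f} {eq.lambda_m.mean():11.4f} "
          f"{eq.lambda_t:11.4f} {eq.p_nominal:9.3f}")

print("\nThe tendon, designed more compliant to offset its idealized 1 cm^2")
print("cross-section, absorbs most of the applied stretch while the muscle")
print("stays near its reference length - the key geometric fact behind the")
print("long electromechanical delay at small pre-stretch.")
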