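#!/usr/bin/env python
"""Re-derive the two calibration constants of the reference configuration.

The reference configuration has exactly two tuned surfaces:

1. the unit calibration ``mm_per_grid_unit``, fixed so the control run
   converts to 2.2 mm/min; and
2. the K-dimension scale factor lambda, fixed so the quiescent-to-
   propagating transition of the potassium-drive threshold kv* sits at 1.5.
   The model is exactly invariant under (every K-valued parameter x lambda,
   beta_v / lambda), so lambda moves the bifurcation point without changing
   any propagation speed.

This script recomputes both from the shipped configuration and reports the
residual against the frozen values; run after any change to the reference
parameters.

Usage:  python scripts/calibrate_reference.py
"""

from __future__ import annotations

import numpy as np

from csdwave import RunConfig, bifurcation_scan, calibrate, measure_speed


def main() -> None:
    cfg = RunConfig.reference()

    m = measure_speed(cfg)
    cal = calibrate(m.speed_model_units, 2.2)
    shipped = cfg.calibration()
    print(f"control speed: {m.speed_model_units:.6f} model units")
    print(f"mm_per_grid_unit derived {cal.mm_per_grid_unit:.6f} "
          f"shipped {shipped.mm_per_grid_unit:.6f}")

    kvs = np.round(np.arange(1.30, 1.701, 0.02), 3)
    diagram = bifurcation_scan(kvs, cfg)
    print(f"kv* transition: {diagram.transition}")
    lam_residual = 1.5 / diagram.transition
    print(f"residual K-scale factor to re-center at 1.5: {lam_residual:.4f} "
          "(1.0 means the shipped scale already places the transition at 1.5)")
    print("to apply a residual rescale: multiply k0, k1*, k2*, kv*, a and the "
          "stimulus amplitude by the factor and divide beta_ve, beta_vi by it")


if __name__ == "__main__":
    main()
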