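#!/usr/bin/env python
"""Extend itraconazole to repeated dosing (24-h interval).

Single-dose itraconazole never accumulates enough tissue drug to move the
Bottom term far; repeated administration does. Three routes are compared:
direct ODE integration of the repeated regimen, superposition of analytic
single-dose solutions (identical, by linearity), and the constant-Css
approximation. Writes results/multiple_dosing.csv.
"""

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

import pkpdcombo as pc

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    fx = pc.reference_fixtures()
    grid = pc.SimulationGrid(4400.0, 0.1)  # three daily doses plus tail
    base = pc.CombinationScenario(
        acd_params=fx["gemcitabine"], acd_regimen=fx["gemcitabine_regimen"],
        itz_params=fx["itraconazole"], itz_regimen=fx["itraconazole_regimen_100"],
        curve=fx["gem_combo_avg"], bottom_mod=fx["gem_bottom_mod"], grid=grid)

    rows = []
    single = pc.simulate_multiple_dosing(base, pc.MultipleDosingSpec("ode_repeat"))
    ode = pc.simulate_multiple_dosing(
        base, pc.MultipleDosingSpec("ode_repeat", n_doses=3, interval=1440.0))
    sup = pc.simulate_multiple_dosing(
        base, pc.MultipleDosingSpec("superposition", n_doses=3, interval=1440.0))
    css_low = pc.simulate_multiple_dosing(
        base, pc.MultipleDosingSpec("css_approximation", css=0.5))
    css_high = pc.simulate_multiple_dosing(
        base, pc.MultipleDosingSpec("css_approximation", css=2.0))

    for label, run in [("single_100mg", single), ("q24h_x3_ode", ode),
                       ("q24h_x3_superposition", sup),
                       ("css_0.5ug_per_ml", css_low),
                       ("css_2.0ug_per_ml", css_high)]:
        tail = run.effect.times > 4000.0
        rows.append({
            "mode": label,
            "itz_tissue_cmax": float(run.itz.tissue_conc.max()),
            "tail_bottom_percent": float(np.median(run.bottom[tail])),
            "auc_effect": run.effect.total_auc,
        })
        r = rows[-1]
        print(f"{label:22s} itz tissue Cmax {r['itz_tissue_cmax']:.3f} ug/mL  "
              f"tail Bottom {r['tail_bottom_percent']:+.2f}%  "
              f"AUC_effect {r['auc_effect']:9.0f}")

    agreement = float(np.max(np.abs(ode.itz.plasma_conc - sup.itz.plasma_conc))
                      / sup.itz.plasma_conc.max())
    print(f"\nODE-vs-superposition max plasma difference: {agreement:.2e} "
          "(relative to Cmax) - the two multiple-dosing routes agree.")
    print("Repeated 24-h dosing raises itraconazole tissue exposure, but at "
          "sub-0.4 ug/mL the Bottom quadratic is still on its descending "
          "branch, so the effect floor barely moves; holding plasma at a "
          "higher Css (2 ug/mL) pushes the tissue level onto the rising "
          "branch and lifts the post-collapse floor.")
    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "multiple_dosing.csv", index=False)


if __name__ == "__main__":
    main()
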