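#!/usr/bin/env python
"""Run the coupled ACD + itraconazole models at three itraconazole doses.

The anticancer drug and itraconazole each get their own two-compartment
model; the Hill Bottom follows the itraconazole tissue concentration
through the calibrated quadratic. Reports the effect plateau, the
collapse onset (tissue concentration falling through the published
threshold), the post-collapse tail level, and AUC_effect per dose.
Writes results/combination_summary.csv.
"""

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

import pkpdcombo as pc

OUT = Path(__file__).resolve().parents[1] / "results"

CASES = [
    ("gemcitabine", "gemcitabine_regimen", "gem_combo_avg", "gem_bottom_mod",
     400.0, (30.0, 120.0), 0.008),
    ("fluorouracil", "fluorouracil_regimen", "fu_combo_avg", "fu_bottom_mod",
     200.0, (5.0, 40.0), 0.5),
]


def main() -> None:
    fx = pc.reference_fixtures()
    rows = []
    for acd, regimen_name, curve_name, mod_name, t_end, window, threshold in CASES:
        base = pc.CombinationScenario(
            acd_params=fx[acd], acd_regimen=fx[regimen_name],
            itz_params=fx["itraconazole"],
            itz_regimen=fx["itraconazole_regimen_100"],
            curve=fx[curve_name], bottom_mod=fx[mod_name],
            grid=pc.SimulationGrid(t_end, 0.02))
        for dose in (100, 300, 500):
            scenario = dataclasses.replace(
                base, itz_regimen=fx[f"itraconazole_regimen_{dose}"],
                label=f"{acd}+itz{dose}")
            result = pc.simulate_combination(scenario)
            tail = result.effect.times > 0.95 * t_end
            rows.append({
                "scenario": scenario.label,
                "plateau_percent": result.effect.plateau(window),
                "drop_onset_min": pc.drop_onset_time(result.acd, threshold),
                "tail_effect_percent": float(np.median(result.effect.effect[tail])),
                "tail_bottom_percent": float(np.median(result.bottom[tail])),
                "itz_tissue_cmax": float(result.itz.tissue_conc.max()),
                "auc_effect": result.effect.total_auc,
            })
            r = rows[-1]
            print(f"{r['scenario']:22s} plateau {r['plateau_percent']:5.1f}%  "
                  f"collapse at {r['drop_onset_min']:6.1f} min  "
                  f"tail {r['tail_effect_percent']:5.2f}%  "
                  f"AUC_effect {r['auc_effect']:9.0f}")
    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "combination_summary.csv", index=False)
    print("\nThe plateau sits at the averaged Top (73% / 59%); after the ACD "
          "collapse the effect rides on Bottom(itraconazole tissue conc), so "
          "higher itraconazole doses lift the tail and AUC_effect. "
          f"Table written to {OUT / 'combination_summary.csv'}")


if __name__ == "__main__":
    main()
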