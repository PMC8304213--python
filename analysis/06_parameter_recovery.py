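#!/usr/bin/env python
"""Parameter-recovery study for the PK and Hill fitters.

Synthetic concentration-time profiles (multiplicative lognormal noise)
and MTT-style dose-response replicates (additive Gaussian noise) are
generated from the published parameter sets and refit. Noise-free data
must reproduce the truth to optimizer precision; noisy data shows which
parameters the sampling designs actually pin down.
Writes results/parameter_recovery.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import pkpdcombo as pc

OUT = Path(__file__).resolve().parents[1] / "results"

FU_TIMES = (1, 2, 4, 8, 12, 18, 25, 35, 45, 60, 75, 90)


def consistent(p: pc.PKParameters) -> pc.PKParameters:
    # plasma data cannot identify Vd2 independently of Vd1*k12/k21
    return pc.PKParameters(vd1=p.vd1, vd2=p.vd1 * p.k12 / p.k21, cl=p.cl,
                           k12=p.k12, k21=p.k21)


def main() -> None:
    fx = pc.reference_fixtures()
    rows = []
    for drug, regimen_name, times in [
        ("gemcitabine", "gemcitabine_regimen", pc.GEM_SAMPLE_TIMES),
        ("fluorouracil", "fluorouracil_regimen", FU_TIMES),
    ]:
        truth = consistent(fx[drug])
        regimen = fx[regimen_name]
        for sd, seed in [(0.0, 0), (0.05, 1), (0.05, 2), (0.05, 3)]:
            samples = pc.generate_cp_profile(truth, regimen, times,
                                             pc.NoiseModel(sd=sd, seed=seed))
            objectives = ["none"] if sd == 0.0 else ["none", "relative"]
            for weighting in objectives:
                fit = pc.fit_two_compartment(samples, regimen, seed=seed,
                                             weighting=weighting)
                for name, est in fit.estimates.items():
                    rows.append({"model": "pk2c", "drug": drug, "sd": sd,
                                 "seed": seed, "weighting": weighting,
                                 "parameter": name, "truth": getattr(truth, name),
                                 "estimate": est,
                                 "rel_error": est / getattr(truth, name) - 1.0,
                                 "cv_percent": fit.cv_percent[name]})
        noisefree = [r for r in rows if r["drug"] == drug and r["sd"] == 0.0]
        print(f"{drug}: noise-free max |rel error| "
              f"{max(abs(r['rel_error']) for r in noisefree):.2e}")
        for weighting in ("none", "relative"):
            errs = [r["rel_error"] for r in rows
                    if r["drug"] == drug and r["sd"] > 0
                    and r["parameter"] == "cl" and r["weighting"] == weighting]
            print(f"  5% noise CL error ({weighting:8s} weighting): "
                  + ", ".join(f"{e:+.1%}" for e in errs))

    truth_hill = fx["gem_I4"]
    concs = np.geomspace(2e-4, 0.05, 8)
    for sd, seed in [(0.0, 0), (3.0, 7), (3.0, 8)]:
        samples = pc.generate_dose_response(
            truth_hill, concs, 3, pc.NoiseModel("additive_gaussian", sd, seed))
        curve, fit = pc.fit_hill(samples, seed=seed)
        for name in ("bottom", "top", "steepness", "ec50"):
            truth_v = getattr(truth_hill, name)
            rows.append({"model": "hill", "drug": "gemcitabine", "sd": sd,
                         "seed": seed, "weighting": "none", "parameter": name,
                         "truth": truth_v, "estimate": getattr(curve, name),
                         "rel_error": getattr(curve, name) / truth_v - 1.0,
                         "cv_percent": fit.cv_percent[name]})
    hill_rows = [r for r in rows if r["model"] == "hill" and r["sd"] > 0
                 and r["parameter"] == "top"]
    print("hill: Top error under 3-point assay noise "
          + ", ".join(f"{r['estimate'] - r['truth']:+.1f} pts" for r in hill_rows))

    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "parameter_recovery.csv", index=False)
    print(f"\nRecovery table written to {OUT / 'parameter_recovery.csv'}. "
          "Clearance and Vd1 are well identified under the infusion design; "
          "for the bolus design without sub-minute samples the unweighted "
          "objective can land on a spiked profile (tiny Vd1), which the "
          "1/pred^2 relative weighting prevents. The gemcitabine transfer "
          "constants carry large CVs, mirroring the published fit.")


if __name__ == "__main__":
    main()
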