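"""Synthetic study data and the published parameter sets.

No raw clinical concentration-time tables or MTT plate readings are
deposited with the source study, so every estimation routine is exercised
against synthetic data that emulates their statistical shape:

* plasma concentration-time samples drawn from the analytic two-compartment
  solution with multiplicative lognormal noise (bioanalytical assays have
  roughly constant CV), and
* dose-response replicates drawn around a Hill curve with additive Gaussian
  noise on the % inhibition scale (plate-reader noise is absolute).

The published fitted parameter sets (PK tables, Hill curves, Bottom
quadratics, dose regimens) ship as a JSON resource and are exposed through
:func:`reference_fixtures`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

from .disposition import DoseRegimen, PKParameters, closed_form_concentration
from .effect import BottomModulation, HillCurve, hill_effect, micromolar_to_mass_conc

__all__ = [
    "NoiseModel",
    "ConcentrationSample",
    "DoseResponseSample",
    "generate_cp_profile",
    "generate_dose_response",
    "reference_fixtures",
    "GEM_SAMPLE_TIMES",
]

#: Literature-style gemcitabine sampling design: 14 draws across the 120-min
#: infusion and the 90 min that follow (samples were collected until 210 min
#: after infusion start in the source profile).
GEM_SAMPLE_TIMES = (5.0, 15.0, 30.0, 45.0, 60.0, 80.0, 100.0, 119.0,
                    125.0, 135.0, 150.0, 170.0, 190.0, 210.0)


@dataclass(frozen=True)
class ConcentrationSample:
    """One plasma measurement: time (min), concentration (ug/mL)."""

    time: float
    conc: float
    weight: float | None = None

    def __post_init__(self) -> None:
        if self.time < 0 or self.conc < 0:
            raise ValueError("time and concentration must be non-negative")


@dataclass(frozen=True)
class DoseResponseSample:
    """One assay well: concentration (tagged unit), % inhibition, replicate."""

    conc: float
    inhibition: float
    replicate: int = 0
    unit: str = "ug_per_ml"

    def __post_init__(self) -> None:
        if self.conc < 0:
            raise ValueError("concentration must be non-negative")
        if self.unit not in ("ug_per_ml", "uM"):
            raise ValueError(f"unknown concentration unit {self.unit!r}")


@dataclass(frozen=True)
class NoiseModel:
    """Reproducible measurement-noise specification.

    ``multiplicative_lognormal`` perturbs by exp(N(0, sd)); ``sd`` is then
    (approximately) the assay CV. ``additive_gaussian`` adds N(0, sd) on
    the measurement scale. The seed makes generation deterministic.
    """

    kind: str = "multiplicative_lognormal"
    sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("multiplicative_lognormal", "additive_gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    def apply(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.sd == 0.0:
            return values.copy()
        rng = np.random.default_rng(self.seed)
        draws = rng.standard_normal(values.shape)
        if self.kind == "multiplicative_lognormal":
            return values * np.exp(self.sd * draws)
        return values + self.sd * draws


def generate_cp_profile(params: PKParameters, regimen: DoseRegimen,
                        sample_times: Sequence[float], noise: NoiseModel
                        ) -> list[ConcentrationSample]:
    """Noisy concentration-time samples from the analytic PK solution."""
    if len(sample_times) == 0:
        raise ValueError("sample_times must be non-empty")
    times = np.asarray(sample_times, dtype=float)
    clean = np.atleast_1d(closed_form_concentration(params, regimen, times))
    noisy = noise.apply(clean)
    return [ConcentrationSample(time=float(t), conc=float(max(c, 0.0)))
            for t, c in zip(times, noisy)]


def generate_dose_response(curve: HillCurve, concentrations: Sequence[float],
                           replicates: int, noise: NoiseModel,
                           unit: str = "ug_per_ml") -> list[DoseResponseSample]:
    """MTT-style replicate responses around a Hill curve (additive noise)."""
    if len(concentrations) == 0:
        raise ValueError("concentrations must be non-empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    conc = np.asarray(concentrations, dtype=float)
    clean = np.tile(np.atleast_1d(hill_effect(conc, curve)), replicates)
    noisy = noise.apply(clean)
    samples = []
    for r in range(replicates):
        for j, c in enumerate(conc):
            samples.append(DoseResponseSample(conc=float(c),
                                              inhibition=float(noisy[r * conc.size + j]),
                                              replicate=r, unit=unit))
    return samples


def _load_raw() -> dict:
    text = resources.files("pkpdcombo").joinpath("data/reference_parameters.json").read_text()
    return json.loads(text)


def reference_fixtures(rounded_rates: bool = False) -> dict:
    """The published parameter sets as ready-to-use model objects.

    Returns a flat mapping containing, per drug, the :class:`PKParameters`
    (``gemcitabine``, ``fluorouracil``, ``itraconazole``), the eight
    :class:`HillCurve` rows (``gem_I0`` ... ``fu_I6``), the averaged
    combination curves (``gem_combo_avg``, ``fu_combo_avg``), the Bottom
    quadratics (``gem_bottom_mod``, ``fu_bottom_mod``), the dose regimens,
    and the raw reported table (under ``"tables"``) with CV%, AUC and Cmax.

    Itraconazole infusion regimens store rate = dose/duration exactly;
    pass ``rounded_rates=True`` for the rounded rates quoted alongside the
    published model diagrams (1.7 / 5 / 8.3 mg/min).
    """
    raw = _load_raw()
    mw = raw["molecular_weights"]["itraconazole"]
    x_max = micromolar_to_mass_conc(6.0, mw)

    out: dict = {"tables": raw, "itraconazole_mw": mw}
    for name, entry in raw["pk"].items():
        out[name] = PKParameters(vd1=entry["vd1"], vd2=entry["vd2"], cl=entry["cl"],
                                 k12=entry["k12"], k21=entry["k21"])
    for name, entry in raw["hill"].items():
        out[name] = HillCurve(bottom=entry["bottom"], top=entry["top"],
                              steepness=entry["steepness"], ec50=entry["ec50"])
    for name, entry in raw["hill_average"].items():
        # averaged curves carry the matching quadratic's zero-concentration
        # Bottom so they stand alone as single-drug curves
        c0 = raw["bottom_modulation"]["gem" if name.startswith("gem") else "fu"]["c"]
        out[name] = HillCurve(bottom=c0, top=entry["top"],
                              steepness=entry["steepness"], ec50=entry["ec50"])
    for name, entry in raw["bottom_modulation"].items():
        out[f"{name}_bottom_mod"] = BottomModulation(a=entry["a"], b=entry["b"],
                                                     c=entry["c"],
                                                     calibration_range=(0.0, x_max))
    for name, entry in raw["regimens"].items():
        entry = dict(entry)
        if rounded_rates and name in raw["rounded_infusion_rates"]:
            rate = raw["rounded_infusion_rates"][name]
            entry = {"route": "infusion", "rate": rate, "duration": entry["duration"],
                     "dose": rate * entry["duration"]}
        out[name] = DoseRegimen(**entry)
    return out
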