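"""Hill (four-parameter logistic) pharmacodynamics on tissue concentration.

% cell-growth inhibition as a function of drug tissue concentration:

    effect(c) = Bottom + (Top - Bottom) / (1 + (c / EC50)^(-n))

with Bottom/Top the lowest/highest inhibition, EC50 the half-maximal
concentration (ug/mL) and n the steepness factor. Effects are deliberately
NOT clamped to [0, 100]: fitted Bottom values can be negative (net growth
stimulation at low exposure) and clamping would bias the AUC_effect score;
negative intervals are flagged instead.

The Bottom parameter of the anticancer-drug curve is modulated by the
co-administered itraconazole tissue concentration through a calibrated
quadratic, Bottom(x) = a*x^2 + b*x + c.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .disposition import DispositionTrajectory, cumulative_auc

__all__ = [
    "HillCurve",
    "BottomModulation",
    "EffectTrajectory",
    "hill_effect",
    "bottom_from_itraconazole",
    "micromolar_to_mass_conc",
    "effect_trajectory",
    "collapse_diagnostic",
    "drop_onset_time",
    "ITRACONAZOLE_MW",
]

#: Itraconazole molecular weight (g/mol), used to convert the uM scale of
#: assay curves to the ug/mL scale of the tissue-concentration model.
ITRACONAZOLE_MW = 705.64


@dataclass(frozen=True)
class HillCurve:
    """Four-parameter dose-response constants (% inhibition vs ug/mL)."""

    bottom: float
    top: float
    steepness: float
    ec50: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ec50) and self.ec50 > 0):
            raise ValueError("ec50 must be positive and finite")
        if not (math.isfinite(self.steepness) and self.steepness > 0):
            raise ValueError("steepness must be positive and finite")
        if not self.top > self.bottom:
            raise ValueError("top must exceed bottom")


@dataclass(frozen=True)
class BottomModulation:
    """Quadratic dependence of the Hill Bottom on itraconazole tissue conc.

    Bottom(x) = a*x^2 + b*x + c with x in ug/mL. ``calibration_range`` is
    the concentration span of the underlying assay calibration; evaluation
    outside it is permitted but emits a warning.
    """

    a: float
    b: float
    c: float
    calibration_range: tuple[float, float] = (0.0, 4.2338)

    def __post_init__(self) -> None:
        lo, hi = self.calibration_range
        if not (0 <= lo < hi):
            raise ValueError("calibration_range must satisfy 0 <= lo < hi")

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        return bottom_from_itraconazole(x, self)


@dataclass(frozen=True)
class EffectTrajectory:
    """% cell-growth inhibition over time with its running AUC (% * min)."""

    times: np.ndarray
    effect: np.ndarray
    auc_effect: np.ndarray

    @property
    def total_auc(self) -> float:
        return float(self.auc_effect[-1])

    @property
    def has_negative_effect(self) -> bool:
        """True when the trajectory dips below zero inhibition."""
        return bool((self.effect < 0).any())

    @property
    def negative_fraction(self) -> float:
        return float(np.mean(self.effect < 0))

    @property
    def h(self) -> float:
        return float(self.times[1] - self.times[0])

    def auc_over(self, window: tuple[float, float]) -> float:
        """AUC_effect restricted to [start, stop) (rectangle accumulator)."""
        start, stop = window
        mask = (self.times >= start) & (self.times < stop)
        return float(np.sum(self.effect[mask]) * self.h)

    def plateau(self, window: tuple[float, float]) -> float:
        """Median effect over a time window; robust plateau estimator."""
        start, stop = window
        mask = (self.times >= start) & (self.times <= stop)
        if not mask.any():
            raise ValueError("plateau window contains no trajectory points")
        return float(np.median(self.effect[mask]))


def hill_effect(tissue_conc, curve: HillCurve):
    """Evaluate the Hill relation; the zero-concentration limit is Bottom.

    The literal expression contains (c/EC50)^(-n), which is singular at
    c = 0; the analytic limit (effect -> Bottom) is returned there instead.
    Overflow of the power for c << EC50 saturates harmlessly to Bottom.
    """
    c = np.asarray(tissue_conc, dtype=float)
    if (c < 0).any():
        raise ValueError("tissue concentration must be non-negative")
    with np.errstate(over="ignore", divide="ignore"):
        ratio = np.where(c > 0, (np.where(c > 0, c, 1.0) / curve.ec50) ** (-curve.steepness),
                         np.inf)
        out = curve.bottom + (curve.top - curve.bottom) / (1.0 + ratio)
    if np.isscalar(tissue_conc) or np.ndim(tissue_conc) == 0:
        return float(out)
    return out


def bottom_from_itraconazole(x, mod: BottomModulation):
    """Bottom(x) = a*x^2 + b*x + c, x = itraconazole tissue conc (ug/mL)."""
    x_arr = np.asarray(x, dtype=float)
    if (x_arr < 0).any():
        raise ValueError("itraconazole concentration must be non-negative")
    hi = mod.calibration_range[1]
    if float(x_arr.max(initial=0.0)) > hi:
        warnings.warn(
            f"Bottom modulation evaluated at {float(x_arr.max()):.3g} ug/mL, "
            f"outside its calibration range (0, {hi:g}]",
            stacklevel=2,
        )
    out = (mod.a * x_arr + mod.b) * x_arr + mod.c
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out


def micromolar_to_mass_conc(conc: float, molecular_weight: float) -> float:
    """Convert uM to ug/mL: conc * MW / 1000."""
    if molecular_weight <= 0:
        raise ValueError("molecular weight must be positive")
    if np.any(np.asarray(conc) < 0):
        raise ValueError("concentration must be non-negative")
    return conc * molecular_weight / 1000.0


def effect_trajectory(disposition: DispositionTrajectory, curve: HillCurve
                      ) -> EffectTrajectory:
    """Map a disposition trajectory to % effect over time.

    The effect at each node is the Hill response to the *tissue*
    concentration; AUC_effect accumulates with the same rectangle rule as
    the plasma AUC.
    """
    eff = hill_effect(disposition.tissue_conc, curve)
    return EffectTrajectory(
        times=disposition.times,
        effect=eff,
        auc_effect=cumulative_auc(eff, disposition.h),
    )


def collapse_diagnostic(x, ec50: float, steepness: float):
    """f(x) = (x/EC50)^(-steepness), the divisor term of the Hill relation.

    While the drug concentration is high f(x) is negligible and the effect
    sits at Top; once x falls below a threshold f(x) grows exponentially
    and the effect collapses toward Bottom. Singular at x = 0.
    """
    x_arr = np.asarray(x, dtype=float)
    if (x_arr <= 0).any():
        raise ValueError("x must be strictly positive (diagnostic is singular at 0)")
    if ec50 <= 0 or steepness <= 0:
        raise ValueError("ec50 and steepness must be positive")
    out = (x_arr / ec50) ** (-steepness)
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out


def drop_onset_time(disposition: DispositionTrajectory, threshold: float
                    ) -> float | None:
    """Earliest post-peak time at which tissue concentration < threshold.

    Only the falling limb counts: an infusion's rising phase also sits
    below the threshold but does not mark an effect collapse. Returns
    ``None`` when the concentration never falls below the threshold after
    its maximum.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    conc = disposition.tissue_conc
    peak = int(np.argmax(conc))
    below = np.nonzero(conc[peak + 1:] < threshold)[0]
    if below.size == 0:
        return None
    return float(disposition.times[peak + 1 + below[0]])
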