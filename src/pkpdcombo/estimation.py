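"""Parameter estimation: two-compartment PK fits, Hill fits, Bottom quadratic.

The PK fitter recovers (Vd1, Vd2, CL, k12, k21) from plasma
concentration-time samples by unweighted nonlinear least squares against
the analytic biexponential solution; positivity is enforced by optimizing
on the log scale. CV% is reported from the asymptotic (Jacobian-based)
covariance at the optimum, matching the Estimate / CV(%) presentation of
pharmacometric software output. The Hill fitter estimates the four
dose-response constants the same way. The Bottom quadratic is recovered
by exact interpolation through three calibration points (or least squares
for more).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .disposition import (
    DoseRegimen,
    PKParameters,
    auc_infinity,
    closed_form_concentration,
    derive_pk,
)
from .effect import BottomModulation, HillCurve, hill_effect
from .synthetic import ConcentrationSample, DoseResponseSample

__all__ = [
    "FitResult",
    "fit_two_compartment",
    "fit_hill",
    "fit_bottom_quadratic",
    "average_hill_parameters",
    "GEM_AVERAGING_EXCLUSIONS",
    "FU_AVERAGING_EXCLUSIONS",
]

#: Averaging exclusions for the gemcitabine combination table: the 2-uM
#: Bottom (out of line with the dose trend) and the 0-uM steepness (fitted
#: with an absurd standard error) are dropped from the averages.
GEM_AVERAGING_EXCLUSIONS = frozenset({("gem_I2", "bottom"), ("gem_I0", "steepness")})
#: For the 5-FU table only the 2-uM Bottom is excluded.
FU_AVERAGING_EXCLUSIONS = frozenset({("fu_I2", "bottom")})

_PK_NAMES = ("vd1", "vd2", "cl", "k12", "k21")
# Plasma concentration is fully determined by (Vd1, CL, k12, k21); the
# tissue volume never enters it and is not identifiable from plasma data.
# It is reported via the standard definition Vd2 = Vd1 * k12 / k21.
_PK_FREE = ("vd1", "cl", "k12", "k21")


@dataclass(frozen=True)
class FitResult:
    """Least-squares estimates with asymptotic uncertainty.

    ``cv_percent`` is 100 * SE / estimate per parameter (via the delta
    method for log-scale parameters). ``extras`` carries derived summaries
    (k10, Vss, AUC, Cmax for PK fits).
    """

    estimates: dict[str, float]
    cv_percent: dict[str, float]
    rss: float
    converged: bool
    n_obs: int
    extras: dict[str, float] | None = None


def _cv_from_jacobian(jac: np.ndarray, rss: float, n: int, log_scale: Sequence[bool]
                      ) -> np.ndarray:
    """CV% per parameter from the asymptotic covariance at the optimum.

    ``jac`` is with respect to the internal (possibly log) parameters; for
    a log parameter, SE(log theta) is already the relative standard error,
    so CV% = 100*SE directly. Rank-deficient designs yield inf CVs via the
    pseudo-inverse.
    """
    p = jac.shape[1]
    dof = max(n - p, 1)
    sigma2 = rss / dof
    jtj = jac.T @ jac
    try:
        cov = sigma2 * np.linalg.pinv(jtj)
    except np.linalg.LinAlgError:  # pragma: no cover - pinv rarely fails
        return np.full(p, np.inf)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return 100.0 * se  # caller rescales non-log entries


def fit_two_compartment(samples: Sequence[ConcentrationSample],
                        regimen: DoseRegimen,
                        init: PKParameters | None = None,
                        n_starts: int = 8, seed: int = 0,
                        weighting: str = "none") -> FitResult:
    """Fit the disposition constants to concentration-time samples.

    Multi-start least squares on log parameters: one data-driven start
    (clearance from the trapezoidal AUC, k10 from the terminal slope) plus
    ``n_starts - 1`` lognormal perturbations, keeping the best optimum.
    (Vd1, CL, k12, k21) are free; Vd2 is reported as Vd1*k12/k21 with its
    CV% propagated by the delta method. At least 5 distinct sampling times
    are required.

    ``weighting="none"`` (default) minimizes raw concentration residuals;
    ``weighting="relative"`` minimizes (pred - obs)/pred, the 1/pred^2
    scheme appropriate for constant-CV assay noise. Relative weighting
    also guards bolus designs without very early samples, where an
    unweighted fit can favor a spiked profile with an unobservably small
    central volume.
    """
    if weighting not in ("none", "relative"):
        raise ValueError(f"unknown weighting {weighting!r}")
    times = np.array([s.time for s in samples], dtype=float)
    concs = np.array([s.conc for s in samples], dtype=float)
    if np.unique(times).size < 5:
        raise ValueError("under-determined: need >= 5 distinct time points "
                         "to resolve a biexponential profile")
    order = np.argsort(times)
    times, concs = times[order], concs[order]

    def params_from(log_theta: np.ndarray) -> PKParameters:
        vd1, cl, k12, k21 = np.exp(np.clip(log_theta, -60.0, 60.0))
        return PKParameters(vd1=vd1, vd2=vd1 * k12 / k21, cl=cl, k12=k12, k21=k21)

    def residuals(log_theta: np.ndarray) -> np.ndarray:
        pred = np.asarray(closed_form_concentration(params_from(log_theta),
                                                    regimen, times))
        if weighting == "relative":
            return (pred - concs) / np.maximum(pred, 1e-12)
        return pred - concs

    data_guess = _initial_pk_guess(times, concs, regimen)
    x0_data = np.log([getattr(data_guess, name) for name in _PK_FREE])
    if init is None:
        x0 = x0_data
        starts = [x0]
    else:
        x0 = np.log([getattr(init, name) for name in _PK_FREE])
        # the data-driven start guards against shallow local minima far
        # from a user-supplied initialization
        starts = [x0, x0_data]

    rng = np.random.default_rng(seed)
    starts += [x0 + rng.normal(0.0, 0.35, size=4) for _ in range(n_starts - len(starts))]
    best = None
    for start in starts:
        res = least_squares(residuals, start, method="trf",
                            xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=4000)
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        return FitResult(estimates={}, cv_percent={}, rss=math.nan,
                         converged=False, n_obs=times.size)

    params = params_from(best.x)
    rss = float(2.0 * best.cost)
    cv_free = _cv_from_jacobian(best.jac, rss, times.size, [True] * 4)
    # delta method on log Vd2 = log Vd1 + log k12 - log k21
    dof = max(times.size - 4, 1)
    cov_log = (rss / dof) * np.linalg.pinv(best.jac.T @ best.jac)
    grad = np.array([1.0, 0.0, 1.0, -1.0])
    cv_vd2 = 100.0 * math.sqrt(max(float(grad @ cov_log @ grad), 0.0))
    cv = dict(zip(_PK_FREE, map(float, cv_free)))
    cv["vd2"] = cv_vd2
    estimates = {name: float(getattr(params, name)) for name in _PK_NAMES}
    derived = derive_pk(params)
    pred = np.asarray(closed_form_concentration(params, regimen, times))
    extras = {
        "k10": derived.k10,
        "vss": derived.vss,
        "auc": auc_infinity(params, regimen.total_dose),
        "cmax": float(pred.max()),
    }
    return FitResult(estimates=estimates,
                     cv_percent={name: cv[name] for name in _PK_NAMES},
                     rss=rss, converged=True, n_obs=times.size, extras=extras)


def _initial_pk_guess(times: np.ndarray, concs: np.ndarray,
                      regimen: DoseRegimen) -> PKParameters:
    """Crude moment-style starting values from the observed profile."""
    dose = regimen.total_dose
    auc_obs = float(np.trapezoid(concs, times))
    cl = dose / max(auc_obs, 1e-12) * 1000.0
    # terminal slope from the last third of positive samples
    tail = max(3, times.size // 3)
    t_tail, c_tail = times[-tail:], np.clip(concs[-tail:], 1e-12, None)
    slope = np.polyfit(t_tail, np.log(c_tail), 1)[0]
    k10 = max(-slope, 1e-4)
    vd1 = cl / k10
    return PKParameters(vd1=vd1, vd2=vd1 / 2.0, cl=cl, k12=k10 / 2.0, k21=k10)


def fit_hill(samples: Sequence[DoseResponseSample],
             n_starts: int = 5, seed: int = 0) -> tuple[HillCurve, FitResult]:
    """Fit the four Hill constants to dose-response replicates.

    Bottom and Top are fit on the natural scale, EC50 and steepness on the
    log scale. A flat response (no variance across wells) is rejected as
    unidentifiable; at least 4 distinct concentrations are required.
    """
    conc = np.array([s.conc for s in samples], dtype=float)
    resp = np.array([s.inhibition for s in samples], dtype=float)
    if np.unique(conc).size < 4:
        raise ValueError("need >= 4 distinct concentrations for a 4-parameter fit")
    if np.ptp(resp) == 0.0:
        raise ValueError("degenerate data: responses are identical (flat curve)")

    def unpack(x: np.ndarray) -> HillCurve:
        return HillCurve(bottom=min(x[0], x[1] - 1e-9), top=x[1],
                         steepness=float(np.exp(x[2])), ec50=float(np.exp(x[3])))

    def residuals(x: np.ndarray) -> np.ndarray:
        return np.asarray(hill_effect(conc, unpack(x))) - resp

    bottom0, top0 = float(resp.min()), float(resp.max())
    positive = conc[conc > 0]
    half = resp.mean()
    # concentration nearest the half response as EC50 seed
    ec50_seed = float(positive[np.argmin(np.abs(
        resp[conc > 0] - half))]) if positive.size else 1.0
    x0 = np.array([bottom0, top0, 0.0, np.log(max(ec50_seed, 1e-12))])

    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(n_starts - 1):
        jitter = np.array([rng.normal(0, 0.1 * max(np.ptp(resp), 1.0)),
                           rng.normal(0, 0.1 * max(np.ptp(resp), 1.0)),
                           rng.normal(0, 0.5), rng.normal(0, 0.5)])
        starts.append(x0 + jitter)
    best = None
    for start in starts:
        try:
            res = least_squares(residuals, start, method="trf",
                                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=4000)
        except (ValueError, FloatingPointError):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        return (HillCurve(bottom0, top0, 1.0, max(ec50_seed, 1e-12)),
                FitResult(estimates={}, cv_percent={}, rss=math.nan,
                          converged=False, n_obs=conc.size))

    curve = unpack(best.x)
    rss = float(2.0 * best.cost)
    cv_raw = _cv_from_jacobian(best.jac, rss, conc.size, [False, False, True, True])
    estimates = {"bottom": curve.bottom, "top": curve.top,
                 "steepness": curve.steepness, "ec50": curve.ec50}
    # natural-scale entries: convert SE to CV% (guard division by ~0)
    cv = {}
    for i, name in enumerate(("bottom", "top", "steepness", "ec50")):
        if i < 2:
            scale = abs(estimates[name])
            cv[name] = float(cv_raw[i] / scale) if scale > 1e-12 else math.inf
        else:
            cv[name] = float(cv_raw[i])
    return curve, FitResult(estimates=estimates, cv_percent=cv, rss=rss,
                            converged=True, n_obs=conc.size)


def fit_bottom_quadratic(points: Sequence[tuple[float, float]]) -> BottomModulation:
    """Quadratic Bottom(x) through (x, Bottom) calibration points.

    Exactly three points give exact interpolation (the default calibration
    path, which reproduces the published coefficient sets); more than
    three are fit by least squares. Duplicate abscissae are rejected.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (x, bottom) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size != x.size:
        raise ValueError("duplicate x values make the quadratic ill-posed")
    if pts.shape[0] == 3:
        vander = np.vander(x, 3)  # columns x^2, x, 1
        coeffs = np.linalg.solve(vander, y)
    else:
        coeffs = np.polyfit(x, y, 2)
    a, b, c = map(float, coeffs)
    return BottomModulation(a=a, b=b, c=c,
                            calibration_range=(0.0, float(x.max())))


def average_hill_parameters(rows: Mapping[str, HillCurve] | Iterable[tuple[str, HillCurve]],
                            exclusions: frozenset[tuple[str, str]] = frozenset()
                            ) -> dict[str, float]:
    """Arithmetic per-parameter mean of Hill rows, honoring exclusions.

    Only Top, steepness and EC50 are averaged — Bottom is never pooled
    because in combination scenarios it becomes the itraconazole-dependent
    quadratic. ``exclusions`` is a set of (row label, parameter) cells to
    drop, e.g. a steepness rendered meaningless by its standard error.
    """
    items = list(rows.items()) if isinstance(rows, Mapping) else list(rows)
    if not items:
        raise ValueError("no rows to average")
    out: dict[str, float] = {}
    for param in ("top", "steepness", "ec50"):
        values = [getattr(curve, param) for label, curve in items
                  if (label, param) not in exclusions]
        if not values:
            raise ValueError(f"all rows excluded for {param!r}")
        out[param] = float(np.mean(values))
    return out
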