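"""Two-compartment intravenous drug disposition.

Linear mammillary model: a central (plasma) compartment and a peripheral
(tissue) compartment exchange drug by first-order transfer (``k12``,
``k21``); elimination is first-order from the central compartment with rate
constant ``k10 = CL / Vd1``. The state is tracked as *amounts*:

    dA1/dt = r(t) - k12*A1 + k21*A2 - CL*(A1/Vd1)
    dA2/dt = k12*A1 - k21*A2
    dAe/dt = CL*(A1/Vd1)

where ``r(t)`` is the intravenous input (mg/min). Units are fixed
internally to mg, mL and min; concentrations are reported in ug/mL
(amount[mg] / volume[mL] * 1000), matching the scale on which clinical
plasma profiles are tabulated.

The fixed-step Euler / 4th-order Runge-Kutta integrator mirrors the
accumulator-and-flow construction of graphical system-dynamics tools, with
the infusion rate held constant over each step. An analytic biexponential
solution is provided as an independent oracle, and the running AUC follows
the rectangle accumulator AUC(t) = AUC(t-dt) + value(t-dt)*dt (a
trapezoidal variant is available for comparison with literature values
computed by the trapezoidal rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "PKParameters",
    "DerivedPK",
    "DoseRegimen",
    "SimulationGrid",
    "DispositionTrajectory",
    "derive_pk",
    "disposition_rhs",
    "integrate_disposition",
    "closed_form_amounts",
    "closed_form_concentration",
    "cumulative_auc",
    "auc_infinity",
]

_MG_PER_ML_TO_UG_PER_ML = 1000.0


@dataclass(frozen=True)
class PKParameters:
    """Fitted two-compartment disposition constants for one drug.

    Attributes
    ----------
    vd1, vd2 : float
        Central and tissue volumes of distribution (mL).
    cl : float
        Clearance (mL/min).
    k12, k21 : float
        Central->tissue and tissue->central transfer rate constants (1/min).
    """

    vd1: float
    vd2: float
    cl: float
    k12: float
    k21: float

    def __post_init__(self) -> None:
        for name in ("vd1", "vd2", "cl", "k12", "k21"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")

    @property
    def k10(self) -> float:
        """Elimination rate constant CL/Vd1 (1/min)."""
        return self.cl / self.vd1

    @property
    def vss(self) -> float:
        """Steady-state volume of distribution Vd1 + Vd2 (mL)."""
        return self.vd1 + self.vd2


@dataclass(frozen=True)
class DerivedPK:
    """Hybrid disposition constants derived from :class:`PKParameters`."""

    k10: float
    vss: float
    lambda1: float  # fast hybrid rate constant (1/min), the larger root
    lambda2: float  # slow (terminal) hybrid rate constant (1/min)

    @property
    def terminal_half_life(self) -> float:
        """ln(2)/lambda2 (min); infinite when elimination vanishes."""
        return math.inf if self.lambda2 == 0 else math.log(2.0) / self.lambda2


def derive_pk(params: PKParameters) -> DerivedPK:
    """Derive k10, Vss and the hybrid rate constants lambda1 >= lambda2.

    The lambdas are the roots of s^2 - (k10+k12+k21) s + k10*k21 = 0.
    lambda2 is computed as the product over lambda1 for numerical stability
    when the roots are widely separated.
    """
    k10 = params.k10
    s = k10 + params.k12 + params.k21
    p = k10 * params.k21
    disc = s * s - 4.0 * p
    # disc = (k10 + k12 - k21)^2 + 4 k12 k21 >= 0; clip rounding noise
    root = math.sqrt(max(disc, 0.0))
    lambda1 = 0.5 * (s + root)
    lambda2 = p / lambda1 if lambda1 > 0 else 0.0
    return DerivedPK(k10=k10, vss=params.vss, lambda1=lambda1, lambda2=lambda2)


@dataclass(frozen=True)
class DoseRegimen:
    """Intravenous dose regimen: the forcing function of the ODE system.

    ``route`` is ``"bolus"`` (instantaneous amount into the central
    compartment) or ``"infusion"`` (constant rate over ``duration``). For
    infusions any two of (dose, rate, duration) determine the third;
    supplying all three requires rate*duration == dose. Repeated dosing is
    expressed with ``n_doses`` administrations ``interval`` minutes apart.
    """

    route: str
    dose: float | None = None
    rate: float | None = None
    duration: float | None = None
    start_time: float = 0.0
    n_doses: int = 1
    interval: float | None = None

    def __post_init__(self) -> None:
        if self.route not in ("bolus", "infusion"):
            raise ValueError(f"route must be 'bolus' or 'infusion', got {self.route!r}")
        if self.start_time < 0:
            raise ValueError("start_time must be non-negative")
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")
        if self.n_doses > 1:
            if self.interval is None or self.interval <= 0:
                raise ValueError("interval required (and > 0) when n_doses > 1")
        if self.route == "bolus":
            if self.rate is not None or self.duration is not None:
                raise ValueError("bolus regimens take no rate/duration")
            if self.dose is None or self.dose < 0:
                raise ValueError("bolus dose must be a non-negative amount")
        else:
            dose, rate, duration = self.dose, self.rate, self.duration
            given = sum(v is not None for v in (dose, rate, duration))
            if given < 2:
                raise ValueError("infusion needs two of (dose, rate, duration)")
            if duration is None:
                duration = dose / rate
            elif rate is None:
                rate = dose / duration
            elif dose is None:
                dose = rate * duration
            if duration <= 0 or rate < 0 or dose < 0:
                raise ValueError("infusion quantities must be non-negative (duration > 0)")
            if abs(rate * duration - dose) > 1e-9 * max(dose, 1.0):
                raise ValueError(
                    f"inconsistent infusion: rate*duration={rate * duration!r} != dose={dose!r}"
                )
            if self.n_doses > 1 and self.interval < duration:
                raise ValueError("repeat interval must be >= infusion duration")
            object.__setattr__(self, "dose", dose)
            object.__setattr__(self, "rate", rate)
            object.__setattr__(self, "duration", duration)

    @classmethod
    def bolus(cls, dose: float, *, start_time: float = 0.0, n_doses: int = 1,
              interval: float | None = None) -> "DoseRegimen":
        return cls("bolus", dose=dose, start_time=start_time, n_doses=n_doses,
                   interval=interval)

    @classmethod
    def infusion(cls, *, dose: float | None = None, rate: float | None = None,
                 duration: float | None = None, start_time: float = 0.0,
                 n_doses: int = 1, interval: float | None = None) -> "DoseRegimen":
        return cls("infusion", dose=dose, rate=rate, duration=duration,
                   start_time=start_time, n_doses=n_doses, interval=interval)

    @property
    def dose_times(self) -> list[float]:
        """Start times of each administration (min)."""
        step = self.interval or 0.0
        return [self.start_time + i * step for i in range(self.n_doses)]

    @property
    def total_dose(self) -> float:
        return self.dose * self.n_doses

    def single_dose(self, index: int = 0) -> "DoseRegimen":
        """The ``index``-th administration as a stand-alone regimen."""
        return replace(self, start_time=self.dose_times[index], n_doses=1, interval=None)


@dataclass(frozen=True)
class SimulationGrid:
    """Fixed-step integration grid."""

    t_end: float
    h: float = 0.02
    method: str = "rk4"

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("step size h must be > 0")
        if self.t_end < self.h:
            raise ValueError("t_end must be >= h")
        if self.method not in ("euler", "rk4"):
            raise ValueError(f"method must be 'euler' or 'rk4', got {self.method!r}")
        n = round(self.t_end / self.h)
        if abs(n * self.h - self.t_end) > 1e-9 * max(self.t_end, 1.0):
            raise ValueError("t_end must be an integer multiple of h")

    @property
    def n_steps(self) -> int:
        return round(self.t_end / self.h)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_steps + 1) * self.h


@dataclass(frozen=True)
class DispositionTrajectory:
    """Time-indexed amounts, concentrations and running plasma AUC.

    Amounts in mg, concentrations in ug/mL, AUC in ug/mL*min. ``administered``
    is the cumulative dose delivered through each time point, so
    plasma + tissue + eliminated - administered ~ 0 (mass balance).
    """

    times: np.ndarray
    plasma_amount: np.ndarray
    tissue_amount: np.ndarray
    eliminated_amount: np.ndarray
    administered: np.ndarray
    plasma_conc: np.ndarray
    tissue_conc: np.ndarray
    auc_plasma: np.ndarray
    params: PKParameters
    h: float

    def mass_balance_error(self) -> float:
        """Max relative mass-balance defect over the trajectory."""
        defect = np.abs(self.plasma_amount + self.tissue_amount
                        + self.eliminated_amount - self.administered)
        scale = max(float(self.administered.max()), 1e-300)
        return float(defect.max() / scale)

    @property
    def auc_total(self) -> float:
        return float(self.auc_plasma[-1])

    def auc(self, rule: str = "rectangle") -> float:
        """Total plasma AUC under the given accumulation rule."""
        return float(cumulative_auc(self.plasma_conc, self.h, rule=rule)[-1])

    @property
    def cmax(self) -> float:
        return float(self.plasma_conc.max())

    @property
    def t_cmax(self) -> float:
        return float(self.times[int(np.argmax(self.plasma_conc))])


def disposition_rhs(plasma_amount: float, tissue_amount: float,
                    params: PKParameters, input_rate: float = 0.0
                    ) -> tuple[float, float, float]:
    """Instantaneous flows (dPlasma, dTissue, dEliminated) in mg/min.

    The three derivatives sum to ``input_rate`` exactly: every milligram
    entering the system is accounted for in one of the compartments.
    """
    if plasma_amount < 0 or tissue_amount < 0:
        raise ValueError("compartment amounts must be non-negative")
    k10 = params.k10
    elim = k10 * plasma_amount  # == CL * (A1/Vd1)
    transfer = params.k12 * plasma_amount - params.k21 * tissue_amount
    return (input_rate - transfer - elim, transfer, elim)


def _rate_and_bolus_schedules(regimen: DoseRegimen, grid: SimulationGrid
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Per-step infusion rate (length n) and per-node bolus jumps (n+1)."""
    n, h = grid.n_steps, grid.h
    rate = np.zeros(n)
    bolus = np.zeros(n + 1)
    for t0 in regimen.dose_times:
        if regimen.route == "bolus":
            j = int(round(t0 / h))
            if 0 <= j <= n:
                bolus[j] += regimen.dose
        else:
            i0 = int(round(t0 / h))
            i1 = int(round((t0 + regimen.duration) / h))
            rate[max(i0, 0):min(i1, n)] += regimen.rate
    return rate, bolus


def integrate_disposition(params: PKParameters, regimen: DoseRegimen,
                          grid: SimulationGrid) -> DispositionTrajectory:
    """Integrate the disposition system on a fixed grid.

    A bolus is an instantaneous jump of the central-compartment amount at
    its administration time (applied before the state is recorded, so the
    post-dose concentration appears at that node). Infusion rates are held
    constant over each step, which keeps the right-hand side smooth within
    steps; with RK4 the trajectory then matches the analytic solution to
    near machine precision.
    """
    n, h = grid.n_steps, grid.h
    rate, bolus = _rate_and_bolus_schedules(regimen, grid)

    a1_out = np.empty(n + 1)
    a2_out = np.empty(n + 1)
    el_out = np.empty(n + 1)

    k10 = params.k10
    k12 = params.k12
    k21 = params.k21
    ktot = k12 + k10
    a1 = a2 = el = 0.0
    use_rk4 = grid.method == "rk4"
    sixth = h / 6.0
    half = 0.5 * h

    for i in range(n):
        a1 += bolus[i]
        a1_out[i] = a1
        a2_out[i] = a2
        el_out[i] = el
        r = rate[i]
        d1a = r - ktot * a1 + k21 * a2
        d1b = k12 * a1 - k21 * a2
        d1e = k10 * a1
        if use_rk4:
            x1 = a1 + half * d1a
            x2 = a2 + half * d1b
            d2a = r - ktot * x1 + k21 * x2
            d2b = k12 * x1 - k21 * x2
            d2e = k10 * x1
            x1 = a1 + half * d2a
            x2 = a2 + half * d2b
            d3a = r - ktot * x1 + k21 * x2
            d3b = k12 * x1 - k21 * x2
            d3e = k10 * x1
            x1 = a1 + h * d3a
            x2 = a2 + h * d3b
            d4a = r - ktot * x1 + k21 * x2
            d4b = k12 * x1 - k21 * x2
            d4e = k10 * x1
            a1 += sixth * (d1a + 2.0 * (d2a + d3a) + d4a)
            a2 += sixth * (d1b + 2.0 * (d2b + d3b) + d4b)
            el += sixth * (d1e + 2.0 * (d2e + d3e) + d4e)
        else:
            a1 += h * d1a
            a2 += h * d1b
            el += h * d1e
    a1 += bolus[n]
    a1_out[n] = a1
    a2_out[n] = a2
    el_out[n] = el

    administered = np.cumsum(bolus)
    administered[1:] += np.cumsum(rate) * h
    plasma_conc = a1_out / params.vd1 * _MG_PER_ML_TO_UG_PER_ML
    tissue_conc = a2_out / params.vd2 * _MG_PER_ML_TO_UG_PER_ML
    return DispositionTrajectory(
        times=grid.times,
        plasma_amount=a1_out,
        tissue_amount=a2_out,
        eliminated_amount=el_out,
        administered=administered,
        plasma_conc=plasma_conc,
        tissue_conc=tissue_conc,
        auc_plasma=cumulative_auc(plasma_conc, h),
        params=params,
        h=h,
    )


def _expi(lam: float, tau: np.ndarray) -> np.ndarray:
    # integral of exp(-lam*u) du over [0, tau]; tau as lam -> 0
    if lam == 0.0:
        return tau.copy()
    return (1.0 - np.exp(-lam * tau)) / lam


def closed_form_amounts(params: PKParameters, regimen: DoseRegimen,
                        t: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
    """Analytic central/tissue amounts (mg) for a single IV dose.

    Biexponential solution of the two-compartment system; the repeated-root
    degeneracy (lambda1 == lambda2) is handled with the t*exp(-lambda*t)
    limit form. Serves as an integrator-independent oracle.
    """
    if regimen.n_doses != 1:
        raise ValueError("closed form supports single-dose regimens only; "
                         "use superposition for repeats")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    tau = np.clip(t_arr - regimen.start_time, 0.0, None)
    derived = derive_pk(params)
    l1, l2 = derived.lambda1, derived.lambda2
    k12, k21 = params.k12, params.k21
    delta = l1 - l2
    degenerate = delta <= 1e-12 * l1

    if regimen.route == "bolus":
        d = regimen.dose
        if degenerate:
            lam = 0.5 * (l1 + l2)
            e = np.exp(-lam * tau)
            a1 = d * e * (1.0 + (k21 - lam) * tau)
            a2 = d * k12 * tau * e
        else:
            e1 = np.exp(-l1 * tau)
            e2 = np.exp(-l2 * tau)
            a1 = d * ((l1 - k21) * e1 + (k21 - l2) * e2) / delta
            a2 = d * k12 * (e2 - e1) / delta
    else:
        rate, dur = regimen.rate, regimen.duration

        def step(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            # response to a unit-start infusion running since u=0
            if degenerate:
                lam = 0.5 * (l1 + l2)
                i0 = _expi(lam, u)
                if lam == 0.0:
                    i1 = 0.5 * u * u
                else:
                    i1 = (1.0 - np.exp(-lam * u) * (1.0 + lam * u)) / (lam * lam)
                return rate * (i0 + (k21 - lam) * i1), rate * k12 * i1
            f1 = _expi(l1, u)
            f2 = _expi(l2, u)
            s1 = rate * ((l1 - k21) * f1 + (k21 - l2) * f2) / delta
            s2 = rate * k12 * (f2 - f1) / delta
            return s1, s2

        a1_on, a2_on = step(tau)
        a1_off, a2_off = step(np.clip(tau - dur, 0.0, None))
        a1 = a1_on - a1_off
        a2 = a2_on - a2_off

    before = t_arr < regimen.start_time
    if before.any():
        a1 = np.where(before, 0.0, a1)
        a2 = np.where(before, 0.0, a2)
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(a1[0]), float(a2[0])
    return a1, a2


def closed_form_concentration(params: PKParameters, regimen: DoseRegimen,
                              t: np.ndarray | float) -> np.ndarray | float:
    """Analytic plasma concentration (ug/mL) for a single IV dose."""
    a1, _ = closed_form_amounts(params, regimen, t)
    return a1 / params.vd1 * _MG_PER_ML_TO_UG_PER_ML


def closed_form_tissue_concentration(params: PKParameters, regimen: DoseRegimen,
                                     t: np.ndarray | float) -> np.ndarray | float:
    """Analytic tissue concentration (ug/mL) for a single IV dose."""
    _, a2 = closed_form_amounts(params, regimen, t)
    return a2 / params.vd2 * _MG_PER_ML_TO_UG_PER_ML


def cumulative_auc(values: np.ndarray, h: float, rule: str = "rectangle") -> np.ndarray:
    """Running AUC of a uniformly sampled series.

    ``rectangle`` accumulates AUC(t) = AUC(t-dt) + value(t-dt)*dt, the
    accumulator-compartment rule of flow-based simulators; ``trapezoid``
    is the conventional trapezoidal rule used by most literature reports.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if rule == "rectangle":
        out = np.empty(values.shape)
        out[0] = 0.0
        np.cumsum(values[:-1] * h, out=out[1:])
        return out
    if rule == "trapezoid":
        return cumulative_trapezoid(values, dx=h, initial=0.0)
    raise ValueError(f"unknown rule {rule!r}")


def auc_infinity(params: PKParameters, dose: float) -> float:
    """Total plasma AUC to infinity, Dose/CL, in ug/mL*min.

    For any linear IV model the terminal AUC equals dose over clearance;
    used to check that simulated AUCs have converged.
    """
    if dose < 0:
        raise ValueError("dose must be non-negative")
    if params.cl <= 0:
        raise ValueError("clearance must be positive")
    return dose / params.cl * _MG_PER_ML_TO_UG_PER_ML


def elimination_grid(params: PKParameters, regimen: DoseRegimen,
                     n_half_lives: float = 25.0, h: float | None = None,
                     max_steps: int = 200_000, method: str = "rk4") -> SimulationGrid:
    """Grid long enough for the dose to be effectively eliminated.

    Extends ``n_half_lives`` terminal half-lives past the last input; the
    step defaults to 0.02 min but is coarsened as needed to keep the node
    count below ``max_steps`` (RK4 on this system is accurate to ~1e-10
    even at the coarsened steps).
    """
    derived = derive_pk(params)
    last_input = regimen.dose_times[-1] + (regimen.duration or 0.0)
    t_end = last_input + n_half_lives * derived.terminal_half_life
    if h is None:
        h = 0.02
        while t_end / h > max_steps:
            h *= 2.0
    n = math.ceil(t_end / h)
    return SimulationGrid(t_end=n * h, h=h, method=method)
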