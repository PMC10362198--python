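"""Semi-mechanistic transit-compartment model of haematopoiesis under cytotoxic therapy.

The model (Friberg et al.) describes neutrophil dynamics with five ODE
compartments: a proliferating pool ``Prol``, three maturation (transit)
compartments ``T1..T3`` and the circulating pool ``Circ`` observed in blood.
Chemotherapy suppresses proliferation by a factor ``1 - Edrug`` where
``Edrug`` is a Michaelis-Menten function of the drug concentration, and a
feedback term ``(Circ0/Circ)**gamma`` raises proliferation when circulating
counts fall below baseline.  Drug concentrations follow a one-compartment
pharmacokinetic model with a three-day zero-order infusion and first-order
elimination.

All cell counts are in 1e9 cells/L, times in days, doses in mg/m^2 and
concentrations in mg/L (the distribution volume is given per m^2 of body
surface area, so body size cancels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

#: half-maximal effect concentration (mg/L), fixed for the whole population
EC50_DEFAULT = 5.2
#: standard total etoposide dose per administration (mg/m^2)
STANDARD_DOSE = 375.0
#: duration of the continuous infusion (days)
INFUSION_DAYS = 3.0

# Neutropenia severity thresholds (CTCAE convention), 1e9 cells/L.  A count
# >= the first value is grade 0; below the last value is grade 4.
GRADE_THRESHOLDS = (2.0, 1.5, 1.0, 0.5)

N_TRANSIT = 3  # transit compartments between proliferation and circulation


@dataclass(frozen=True)
class PatientParameters:
    """Inter-individually variable parameters of one (virtual) patient.

    gamma : feedback strength (dimensionless)
    mtt : mean transit time from proliferation to circulation (days)
    circ0 : baseline circulating neutrophil count (1e9 cells/L)
    emax : maximal fractional suppression of proliferation (dimensionless)
    ec50 : concentration at half-maximal suppression (mg/L)
    """

    gamma: float
    mtt: float
    circ0: float = 5.0
    emax: float = 1.57
    ec50: float = EC50_DEFAULT

    def __post_init__(self) -> None:
        if not (self.gamma > 0 and self.mtt > 0 and self.circ0 > 0 and self.ec50 > 0):
            raise ValueError(f"patient parameters must be strictly positive, got {self}")
        if self.emax < 0:
            raise ValueError(f"emax must be non-negative, got {self.emax}")

    @property
    def ktr(self) -> float:
        """Transit rate constant: (n_transit + 1) / MTT = 4 / MTT per day."""
        return (N_TRANSIT + 1) / self.mtt


@dataclass(frozen=True)
class PkConfig:
    """One-compartment pharmacokinetics of the cytotoxic drug (etoposide-like)."""

    elimination_half_life: float = 7.0  # hours
    volume: float = 25.0  # L/m^2
    infusion_duration: float = INFUSION_DAYS  # days

    @property
    def ke(self) -> float:
        """First-order elimination rate constant, 1/day."""
        return np.log(2.0) / (self.elimination_half_life / 24.0)


@dataclass
class DrugExposure:
    """Daily-sampled concentration and drug-effect series for one scenario."""

    days: np.ndarray
    conc_series: np.ndarray  # mg/L
    edrug_series: np.ndarray  # dimensionless, in [0, emax]
    pk: PkConfig


@dataclass
class SimulatedSeries:
    """Daily neutrophil counts and drug effect for one (patient, scenario) pair."""

    days: np.ndarray
    neutrophils: np.ndarray  # 1e9 cells/L
    edrug: np.ndarray
    conc: np.ndarray
    patient: PatientParameters
    scenario_id: int = -1


def drug_effect(conc, params: PatientParameters):
    """Fractional suppression of proliferation at concentration ``conc`` (mg/L).

    Michaelis-Menten: emax * conc / (ec50 + conc); saturates below emax.
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("drug concentration must be non-negative")
    out = params.emax * conc / (params.ec50 + conc)
    return out if out.ndim else float(out)


_CIRC_FLOOR = 1e-6  # guard for the feedback term (Circ0/Circ)**gamma


def ode_rhs(state, edrug: float, params: PatientParameters) -> np.ndarray:
    """Time derivative of (Prol, T1, T2, T3, Circ) at a given drug effect."""
    prol, t1, t2, t3, circ = state
    ktr = params.ktr
    circ_safe = circ
    if circ < _CIRC_FLOOR:
        logger.warning("circulating count %.3g below floor; clipping feedback term", circ)
        circ_safe = _CIRC_FLOOR
    feedback = (params.circ0 / circ_safe) ** params.gamma
    dprol = ktr * prol * (1.0 - edrug) * feedback - ktr * prol
    dt1 = ktr * (prol - t1)
    dt2 = ktr * (t1 - t2)
    dt3 = ktr * (t2 - t3)
    dcirc = ktr * (t3 - circ)
    return np.array([dprol, dt1, dt2, dt3, dcirc])


def _concentration(t, administrations, pk: PkConfig):
    """Closed-form one-compartment concentration at times ``t`` (superposition).

    During a zero-order infusion of total dose D over ``tau`` days into
    volume V: C(s) = D/(tau*V*ke) * (1 - exp(-ke*s)); afterwards the
    accumulated concentration washes out as exp(-ke*(s - tau)).
    """
    t = np.asarray(t, dtype=float)
    conc = np.zeros_like(t)
    ke, tau = pk.ke, pk.infusion_duration
    for start, dose in administrations:
        s = t - start
        scale = dose / (tau * pk.volume * ke)
        during = (s > 0) & (s <= tau)
        after = s > tau
        conc[during] += scale * (1.0 - np.exp(-ke * s[during]))
        conc[after] += scale * (1.0 - np.exp(-ke * tau)) * np.exp(-ke * (s[after] - tau))
    return conc


def simulate_pk(scenario, pk: PkConfig | None = None, horizon: int = 300,
                params: PatientParameters | None = None) -> DrugExposure:
    """Daily-sampled drug concentration and effect for a therapy scenario.

    ``scenario`` is anything with an ``administrations`` attribute (or a bare
    list of ``(start_day, dose)`` pairs).  Overlapping infusions superpose.
    """
    pk = pk or PkConfig()
    admins = getattr(scenario, "administrations", scenario)
    admins = sorted(admins)
    if any(d <= 0 for _, d in admins):
        raise ValueError("doses must be positive")
    days = np.arange(horizon, dtype=float)
    conc = _concentration(days, admins, pk)
    if params is not None:
        edrug = drug_effect(conc, params)
    else:
        edrug = np.zeros_like(conc)
    return DrugExposure(days=days, conc_series=conc, edrug_series=edrug, pk=pk)


def simulate_patient(params: PatientParameters, scenario, horizon: int = 300,
                     pk: PkConfig | None = None, rtol: float = 1e-8,
                     atol: float = 1e-10) -> SimulatedSeries:
    """Integrate the five-compartment model from drug-free steady state.

    Returns daily circulating counts, drug effect and concentration on the
    integer-day grid 0..horizon-1.  Integration uses the adaptive
    stiff/non-stiff switching LSODA solver, split at infusion start/stop
    times where the right-hand side has kinks.
    """
    pk = pk or PkConfig()
    admins = sorted(getattr(scenario, "administrations", scenario))
    scenario_id = getattr(scenario, "id", -1)
    if admins and horizon < admins[-1][0] + pk.infusion_duration:
        raise ValueError("horizon must cover the last infusion")

    def conc_at(t: float) -> float:
        return float(_concentration(np.array([t]), admins, pk)[0])

    def rhs(t, y):
        return ode_rhs(y, drug_effect(conc_at(t), params), params)

    # breakpoints at infusion starts/ends keep LSODA away from the kinks
    t_end = float(horizon - 1)
    breaks = sorted({0.0, t_end}
                    | {float(s) for s, _ in admins if 0.0 < s < t_end}
                    | {float(s) + pk.infusion_duration for s, _ in admins
                       if 0.0 < s + pk.infusion_duration < t_end})
    days = np.arange(horizon, dtype=float)
    y0 = np.full(5, params.circ0)
    circ = np.empty(horizon)
    circ[0] = params.circ0
    for a, b in zip(breaks[:-1], breaks[1:]):
        day_mask = (days > a) & (days <= b)
        t_eval = np.union1d(days[day_mask], [b])
        sol = solve_ivp(rhs, (a, b), y0, method="LSODA", rtol=rtol, atol=atol,
                        t_eval=t_eval)
        if not sol.success:
            raise RuntimeError(
                f"ODE solver failed for patient {params} scenario {scenario_id}: {sol.message}")
        circ[day_mask] = sol.y[4][np.isin(sol.t, days[day_mask])]
        y0 = sol.y[:, -1]
    exposure = simulate_pk(admins, pk, horizon, params)
    return SimulatedSeries(days=days, neutrophils=circ, edrug=exposure.edrug_series,
                           conc=exposure.conc_series, patient=params, scenario_id=scenario_id)


def grade_neutropenia(count: float) -> int:
    """CTCAE severity grade 0-4 for a neutrophil count (1e9 cells/L)."""
    if count < 0:
        raise ValueError("count must be non-negative")
    for grade, threshold in enumerate(GRADE_THRESHOLDS):
        if count >= threshold:
            return grade
    return len(GRADE_THRESHOLDS)


class FribergCalibrator(BaseEstimator):
    """Least-squares calibration of the transit-compartment model.

    Fits (gamma, MTT, Emax, Circ0) to observed ``(day, log count)`` pairs by
    minimising squared error between log-simulated and log-observed counts,
    with multi-start bounded least squares.  EC50 stays fixed.

    Parameters
    ----------
    scenario : therapy scenario (administrations) under which the data arose
    pk : pharmacokinetic configuration
    init : starting parameters; also the centre of the multi-start cloud
    n_starts : number of seeded random restarts
    seed : RNG seed for the restarts
    """

    def __init__(self, scenario=None, pk: PkConfig | None = None,
                 init: PatientParameters | None = None, n_starts: int = 5,
                 seed: int = 0, bounds: dict | None = None):
        self.scenario = scenario
        self.pk = pk
        self.init = init
        self.n_starts = n_starts
        self.seed = seed
        self.bounds = bounds

    # physiological grid ranges widened by a factor of two on each side
    _DEFAULT_BOUNDS = {
        "gamma": (0.05, 0.5),
        "mtt": (1.5, 16.0),
        "emax": (0.39, 6.28),
        "circ0": (1.0, 20.0),
    }

    def fit(self, X, y):
        """Fit to observed data.

        X : array of observation days; y : log observed counts.
        """
        days = np.asarray(X, dtype=float).ravel()
        logobs = np.asarray(y, dtype=float).ravel()
        if len(days) < 4:
            raise ValueError("need at least 4 observations to calibrate")
        init = self.init or PatientParameters(gamma=0.2, mtt=5.0)
        pk = self.pk or PkConfig()
        bounds = dict(self._DEFAULT_BOUNDS, **(self.bounds or {}))
        names = ("gamma", "mtt", "emax", "circ0")
        lo = np.array([bounds[n][0] for n in names])
        hi = np.array([bounds[n][1] for n in names])
        horizon = int(np.ceil(days.max())) + 2
        admins = sorted(getattr(self.scenario, "administrations", self.scenario or []))
        # administrations after the observation window cannot inform the fit
        admins = [(s, d) for s, d in admins if s + pk.infusion_duration <= horizon]

        def residuals(theta):
            p = PatientParameters(gamma=theta[0], mtt=theta[1], circ0=theta[3],
                                  emax=theta[2], ec50=init.ec50)
            series = simulate_patient(p, admins, horizon=horizon, pk=pk,
                                      rtol=1e-6, atol=1e-8)
            sim = np.interp(days, series.days, series.neutrophils)
            return np.log(np.clip(sim, 1e-6, None)) - logobs

        rng = np.random.default_rng(self.seed)
        x0 = np.clip([init.gamma, init.mtt, init.emax, init.circ0], lo, hi)
        starts = [x0]
        for _ in range(self.n_starts - 1):
            starts.append(lo + rng.random(4) * (hi - lo))
        best = None
        for start in starts:
            try:
                res = least_squares(residuals, start, bounds=(lo, hi),
                                    xtol=1e-10, ftol=1e-10)
            except RuntimeError:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise RuntimeError("calibration failed from every start")
        self.converged_ = bool(best.success)
        if not self.converged_:
            logger.warning("calibration did not converge; returning best-so-far")
        self.cost_ = float(best.cost)
        self.params_ = PatientParameters(gamma=best.x[0], mtt=best.x[1],
                                         circ0=best.x[3], emax=best.x[2],
                                         ec50=init.ec50)
        return self


def fit_friberg(observed, scenario, init: PatientParameters,
                pk: PkConfig | None = None, n_starts: int = 5,
                seed: int = 0) -> PatientParameters:
    """Calibrate patient parameters to ``(day, log count)`` pairs.

    Thin functional wrapper over :class:`FribergCalibrator`.
    """
    observed = np.asarray(observed, dtype=float)
    cal = FribergCalibrator(scenario=scenario, pk=pk, init=init,
                            n_starts=n_starts, seed=seed)
    cal.fit(observed[:, 0], observed[:, 1])
    return cal.params_
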