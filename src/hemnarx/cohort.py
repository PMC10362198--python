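"""Virtual patient population and randomized therapy scenarios.

The population is a full factorial hypercube over the three heterogeneous
parameters: 8 equidistant feedback strengths (gamma), 8 equidistant mean
transit times (MTT) and 8 log-equidistant maximal drug effects (Emax) —
512 virtual patients in total.  Eighteen 300-day therapy scenarios of six
etoposide courses each (random start days at least a week apart, random
doses between 0.25x and 4x the 375 mg/m^2 standard dose) are shared by all
patients; scenarios 1-5 train, 6-7 validate and 8-18 test the networks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .friberg import (PatientParameters, PkConfig, SimulatedSeries,
                      STANDARD_DOSE, simulate_patient)

HORIZON = 300  # days per simulated series
N_ADMINISTRATIONS = 6
MIN_GAP = 7  # days between consecutive therapy starts
DOSE_RANGE = (0.25 * STANDARD_DOSE, 4.0 * STANDARD_DOSE)  # mg/m^2
FIRST_DOSE_WINDOW = (28, 60)  # keeps the network warm-up region dose-free
GAP_RANGE = (7, 35)
LAST_INFUSION_END = 290

GAMMA_RANGE = (0.1, 0.25)
MTT_RANGE = (3.0, 8.0)  # days; configurable, see docs
EMAX_RANGE = (0.785, 3.14)
POINTS_PER_AXIS = 8

#: deliberately extreme virtual patient used as the transfer-learning source;
#: gamma sits above the population range to produce strong dynamics
INDEX_PATIENT = PatientParameters(gamma=0.33, mtt=MTT_RANGE[1], emax=1.57)


@dataclass(frozen=True)
class TherapyScenario:
    """Six dose administrations over a 300-day horizon."""

    id: int  # 1..18
    administrations: tuple  # of (start_day, dose mg/m^2)
    role: str  # train | validation | test

    def __post_init__(self):
        if len(self.administrations) != N_ADMINISTRATIONS:
            raise ValueError("a scenario has exactly six administrations")
        starts = [s for s, _ in self.administrations]
        if any(b - a < MIN_GAP for a, b in zip(starts, starts[1:])):
            raise ValueError("consecutive therapy starts must be >= 7 days apart")


@dataclass
class PopulationGrid:
    """Full factorial grid of virtual patient parameters."""

    gamma_values: np.ndarray
    mtt_values: np.ndarray
    emax_values: np.ndarray
    patients: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"patient_id": i, "gamma": p.gamma, "mtt": p.mtt, "emax": p.emax,
              "circ0": p.circ0} for i, p in enumerate(self.patients)])


def build_grid(gamma_range=GAMMA_RANGE, mtt_range=MTT_RANGE,
               emax_range=EMAX_RANGE, points_per_axis: int = POINTS_PER_AXIS,
               circ0: float = 5.0) -> PopulationGrid:
    """Cartesian hypercube of patient parameters.

    gamma and MTT axes are linear, the Emax axis is geometric (equidistant
    on the log scale).
    """
    for lo, hi in (gamma_range, mtt_range, emax_range):
        if not (0 < lo < hi):
            raise ValueError("ranges must be positive with min < max")
    gammas = np.linspace(*gamma_range, points_per_axis)
    mtts = np.linspace(*mtt_range, points_per_axis)
    emaxs = np.geomspace(*emax_range, points_per_axis)
    patients = [PatientParameters(gamma=g, mtt=m, emax=e, circ0=circ0)
                for g, m, e in itertools.product(gammas, mtts, emaxs)]
    return PopulationGrid(gamma_values=gammas, mtt_values=mtts,
                          emax_values=emaxs, patients=patients)


def subgrid_indices(points_per_axis: int = POINTS_PER_AXIS, per_axis: int = 3):
    """Patient indices of a reduced sub-grid spanning each axis (min/../max)."""
    axis = np.unique(np.round(np.linspace(0, points_per_axis - 1, per_axis)).astype(int))
    n = points_per_axis
    return [int(g * n * n + m * n + e)
            for g, m, e in itertools.product(axis, axis, axis)]


def generate_scenarios(n_scenarios: int = 18, seed: int = 0,
                       horizon: int = HORIZON,
                       n_train: int = 5, n_val: int = 2) -> list:
    """Seeded random therapy scenarios with train/validation/test roles.

    Start days: first dose uniform in [28, 60], later gaps uniform in
    [7, 35] days, truncated so the last infusion ends by day 290.  Doses
    are continuous uniform in [0.25, 4] x 375 mg/m^2.
    """
    rng = np.random.default_rng(seed)
    scenarios = []
    for sid in range(1, n_scenarios + 1):
        for _attempt in range(100):
            starts = [int(rng.integers(FIRST_DOSE_WINDOW[0], FIRST_DOSE_WINDOW[1] + 1))]
            for _ in range(N_ADMINISTRATIONS - 1):
                starts.append(starts[-1] + int(rng.integers(GAP_RANGE[0], GAP_RANGE[1] + 1)))
            if starts[-1] + 3 <= LAST_INFUSION_END:
                break
        else:
            raise ValueError("dosing window too small for six gapped administrations")
        doses = rng.uniform(*DOSE_RANGE, size=N_ADMINISTRATIONS)
        if sid <= n_train:
            role = "train"
        elif sid <= n_train + n_val:
            role = "validation"
        else:
            role = "test"
        scenarios.append(TherapyScenario(
            id=sid, administrations=tuple(zip(starts, map(float, doses))), role=role))
    if horizon < HORIZON:
        raise ValueError("horizon must be at least 300 days")
    return scenarios


def scenarios_to_frame(scenarios) -> pd.DataFrame:
    rows = [{"scenario_id": s.id, "role": s.role, "dose_index": i,
             "start_day": start, "dose_mg_m2": dose}
            for s in scenarios for i, (start, dose) in enumerate(s.administrations)]
    return pd.DataFrame(rows)


def simulate_population(grid: PopulationGrid, scenarios, pk: PkConfig | None = None,
                        patient_ids=None, horizon: int = HORIZON) -> dict:
    """One simulated series per (patient, scenario) pair.

    Returns a dict keyed by ``(patient_id, scenario_id)``.  ``patient_ids``
    restricts the run to a subset (e.g. a 3x3x3 sub-grid) for scaled-down
    experiments.
    """
    ids = range(len(grid.patients)) if patient_ids is None else patient_ids
    out: dict[tuple, SimulatedSeries] = {}
    for pid in ids:
        patient = grid.patients[pid]
        for scenario in scenarios:
            out[(pid, scenario.id)] = simulate_patient(
                patient, scenario, horizon=horizon, pk=pk)
    return out
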