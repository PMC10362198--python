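"""Run configuration, seed derivation, pipeline glue and synthetic fixtures.

Everything here is plumbing around the scientific modules: a YAML-backed
run configuration whose defaults reproduce the study conditions, a
deterministic per-component seed derivation, end-to-end helpers that chain
simulation -> scaling -> training -> evaluation, and small synthetic
fixtures (including the sparse two-cycle patient that stands in for real
trial data, which are not distributable).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, fields
from pathlib import Path

import numpy as np
import yaml

from . import cohort, evaluation, friberg, training
from .cohort import (GAMMA_RANGE, MTT_RANGE, EMAX_RANGE, POINTS_PER_AXIS,
                     INDEX_PATIENT, build_grid, generate_scenarios,
                     subgrid_indices)
from .friberg import PatientParameters, PkConfig, simulate_patient
from .narx import NARXConfig, NARXModel
from .training import (TrainingConfig, prepare_patient_data,
                       train_index_patient, transfer_train)


def child_seed(global_seed: int, name: str) -> int:
    """Deterministic per-component seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class PopulationBlock:
    gamma_range: tuple = GAMMA_RANGE
    mtt_range: tuple = MTT_RANGE
    emax_range: tuple = EMAX_RANGE
    points_per_axis: int = POINTS_PER_AXIS
    circ0: float = 5.0


@dataclass
class ScenarioBlock:
    n_scenarios: int = 18
    n_train: int = 5
    n_val: int = 2
    horizon: int = cohort.HORIZON


@dataclass
class IndexBlock:
    gamma: float = INDEX_PATIENT.gamma
    mtt: float = INDEX_PATIENT.mtt
    emax: float = INDEX_PATIENT.emax


@dataclass
class RunConfig:
    population: PopulationBlock = field(default_factory=PopulationBlock)
    scenario: ScenarioBlock = field(default_factory=ScenarioBlock)
    pk: PkConfig = field(default_factory=PkConfig)
    index_patient: IndexBlock = field(default_factory=IndexBlock)
    narx: NARXConfig = field(default_factory=NARXConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    output_dir: str = "output"
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    _BLOCKS = {"population": PopulationBlock, "scenario": ScenarioBlock,
               "pk": PkConfig, "index_patient": IndexBlock,
               "narx": NARXConfig, "training": TrainingConfig}

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        known = {f.name for f in fields(cls)}
        bad = [k for k in data if k not in known]
        if bad:
            raise ValueError(f"unknown config keys: {bad}")
        kwargs = {}
        for name, value in data.items():
            block_cls = cls._BLOCKS.get(name)
            if block_cls is not None and isinstance(value, dict):
                block_fields = {bf.name for bf in fields(block_cls)}
                bad = [k for k in value if k not in block_fields]
                if bad:
                    raise ValueError(f"unknown keys in config block {name!r}: {bad}")
                value = block_cls(**{k: tuple(v) if isinstance(v, list) else v
                                     for k, v in value.items()})
            kwargs[name] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)


# ---------------------------------------------------------------------------
# pipeline glue


def simulate_patient_scenarios(params: PatientParameters, scenarios,
                               pk: PkConfig | None = None,
                               horizon: int = cohort.HORIZON) -> dict:
    """All 18 scenario series for one patient, keyed by scenario id."""
    return {s.id: simulate_patient(params, s, horizon=horizon, pk=pk)
            for s in scenarios}


def prepare_and_train_index(scenarios, config: RunConfig,
                            seed: int | None = None):
    """Simulate, scale and train the index patient; returns (model, report)."""
    ib = config.index_patient
    params = PatientParameters(gamma=ib.gamma, mtt=ib.mtt, emax=ib.emax,
                               circ0=config.population.circ0)
    series = simulate_patient_scenarios(params, scenarios, pk=config.pk)
    scaled, scaler = prepare_patient_data(series, scenarios, params.emax)
    tcfg = TrainingConfig(**{**asdict(config.training),
                             "seed": config.training.seed if seed is None else seed})
    return train_index_patient(scaled, config.narx, tcfg,
                               scaler=scaler, input_scale=params.emax)


def transfer_patient(index_model: NARXModel, params: PatientParameters,
                     scenarios, config: RunConfig, seed: int | None = None):
    """Simulate, scale and transfer-train one target patient."""
    series = simulate_patient_scenarios(params, scenarios, pk=config.pk)
    scaled, scaler = prepare_patient_data(series, scenarios, params.emax)
    tcfg = TrainingConfig(**{**asdict(config.training),
                             "seed": config.training.seed if seed is None else seed})
    return transfer_train(index_model, scaled, tcfg,
                          scaler=scaler, input_scale=params.emax)


def transfer_population(index_model: NARXModel, config: RunConfig,
                        patient_ids=None, scenarios=None) -> evaluation.PopulationReport:
    """Transfer-train a (sub-)population and collect the population report."""
    pop = config.population
    grid = build_grid(pop.gamma_range, pop.mtt_range, pop.emax_range,
                      pop.points_per_axis, pop.circ0)
    if scenarios is None:
        scenarios = generate_scenarios(config.scenario.n_scenarios,
                                       seed=child_seed(config.seed, "scenarios"),
                                       n_train=config.scenario.n_train,
                                       n_val=config.scenario.n_val)
    roles = {s.id: s.role for s in scenarios}
    ids = patient_ids if patient_ids is not None else range(len(grid.patients))
    records = []
    for pid in ids:
        params = grid.patients[pid]
        model, report = transfer_patient(index_model, params, scenarios, config,
                                         seed=child_seed(config.seed, f"patient-{pid}"))
        records.append(evaluation.PatientRecord(
            patient_id=pid, gamma=params.gamma, mtt=params.mtt, emax=params.emax,
            wf=model.wf, mse_by_scenario=dict(report.stats.mse_by_scenario),
            roles=roles))
    return evaluation.aggregate_population(records)


# ---------------------------------------------------------------------------
# synthetic fixtures

FIXTURE_KINDS = ("toy-narx-planted", "two-cycle-patient", "mini-population")


def _simulate_long_chain(params: PatientParameters, admins, n_transit: int = 5,
                         horizon: int = cohort.HORIZON,
                         pk: PkConfig | None = None) -> friberg.SimulatedSeries:
    """Transit-chain variant with extra maturation compartments.

    Used only to generate synthetic "real" patients whose dynamics the
    three-compartment calibration model cannot represent exactly.  The mean
    transit time is preserved: ktr = (n_transit + 1) / MTT.
    """
    from scipy.integrate import solve_ivp

    pk = pk or PkConfig()
    admins = sorted(admins)
    ktr = (n_transit + 1) / params.mtt

    def rhs(t, y):
        conc = friberg._concentration(np.array([t]), admins, pk)[0]
        edrug = friberg.drug_effect(conc, params)
        circ = max(y[-1], 1e-6)
        d = np.empty_like(y)
        d[0] = ktr * y[0] * (1.0 - edrug) * (params.circ0 / circ) ** params.gamma \
            - ktr * y[0]
        for i in range(1, len(y)):
            d[i] = ktr * (y[i - 1] - y[i])
        return d

    days = np.arange(horizon, dtype=float)
    # max_step keeps the adaptive solver from stepping over an infusion
    # while the system sits exactly at steady state
    sol = solve_ivp(rhs, (0.0, float(horizon - 1)), np.full(n_transit + 2, params.circ0),
                    method="LSODA", rtol=1e-8, atol=1e-10, t_eval=days, max_step=1.0)
    if not sol.success:
        raise RuntimeError(f"variant simulation failed: {sol.message}")
    exposure = friberg.simulate_pk(admins, pk, horizon, params)
    return friberg.SimulatedSeries(days=days, neutrophils=sol.y[-1],
                                   edrug=exposure.edrug_series,
                                   conc=exposure.conc_series, patient=params,
                                   scenario_id=99)


def make_fixture(kind: str, seed: int = 0) -> dict:
    """Small synthetic datasets for tests and the sparse-retraining mode.

    toy-narx-planted : series generated by a known sparse NARX network
    two-cycle-patient : a simulated patient on a 21-day cycle schedule,
        observed sparsely with lognormal noise (synthetic stand-in for real
        trial data)
    mini-population : 3x3x3 sub-grid of the parameter hypercube
    """
    rng = np.random.default_rng(seed)
    if kind == "toy-narx-planted":
        config = NARXConfig(n_hidden=2, ny=3, nu=4, hidden_activation="sigmoid")
        hidden = np.zeros((2, 7))
        hidden[0, 0] = 0.8    # one-day output memory
        hidden[0, 3] = -1.5   # one-day input lag
        hidden[1, 5] = 1.0    # three-day input lag
        output = np.array([1.2, -0.7])
        planted = NARXModel(config=config, hidden_weights=hidden,
                            output_weights=output)
        T = 120
        u = np.clip(np.convolve(rng.random(T) < 0.05, np.ones(5), mode="same"), 0, 1)
        u = u * rng.uniform(0.5, 1.0, T)
        y0 = np.zeros(config.ny)
        y = planted.simulate_closed_loop(u, y0)
        return {"model": planted, "u": u, "y": y, "wf_planted": planted.wf}
    if kind == "two-cycle-patient":
        params = PatientParameters(gamma=rng.uniform(0.12, 0.22),
                                   mtt=rng.uniform(4.0, 7.0),
                                   emax=rng.uniform(1.0, 2.5), circ0=5.0)
        start = 28
        admins = tuple((start + 21 * c, friberg.STANDARD_DOSE) for c in range(6))
        scenario = cohort.TherapyScenario(id=99, administrations=admins, role="test")
        # the "real" patient is structurally outside the calibration model
        # class (five maturation compartments instead of three), leaving a
        # cycle-stationary residual pattern as real patients do
        series = _simulate_long_chain(params, admins, n_transit=5)
        # sparse sampling: about twice a week over the six cycles
        obs_days = np.unique(rng.choice(np.arange(0, start + 21 * 6),
                                        size=60, replace=False))
        noise = rng.lognormal(mean=0.0, sigma=0.1, size=len(obs_days))
        observed = series.neutrophils[obs_days] * noise
        return {"params": params, "scenario": scenario, "series": series,
                "obs_days": obs_days, "obs_counts": observed,
                "cycle_days": [a for a, _ in admins]}
    if kind == "mini-population":
        grid = build_grid()
        ids = subgrid_indices(per_axis=3)
        scenarios = generate_scenarios(seed=child_seed(seed, "scenarios"))
        return {"grid": grid, "patient_ids": ids, "scenarios": scenarios}
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")


def sparse_retraining_experiment(fixture: dict, index_model: NARXModel,
                                 config: RunConfig, seed: int = 0,
                                 n_calibration_cycles: int = 2,
                                 n_starts: int = 3) -> dict:
    """Individualised prediction from sparse observations, end to end.

    Emulates the clinical workflow on the two-cycle-patient fixture: the
    mechanistic model is calibrated on the observations of the first two
    treatment cycles, the 18 therapy scenarios are simulated with the
    calibrated parameters to transfer-train an individual NARX network, and
    the network is finally retrained on the sparse observations themselves
    (low learning rate, single static prune).  Prediction error is measured
    on the held-out observations of cycles 3-6, before and after
    retraining.
    """
    obs_days = np.asarray(fixture["obs_days"], int)
    obs_counts = np.asarray(fixture["obs_counts"], float)
    cutoff = fixture["cycle_days"][n_calibration_cycles]
    early = obs_days < cutoff
    observed = np.column_stack([obs_days[early], np.log(obs_counts[early])])

    init = PatientParameters(gamma=0.2, mtt=5.0, emax=1.57,
                             circ0=float(np.exp(observed[0, 1])))
    fitted = friberg.fit_friberg(observed, fixture["scenario"], init,
                                 pk=config.pk, n_starts=n_starts, seed=seed)

    scenarios = generate_scenarios(config.scenario.n_scenarios,
                                   seed=child_seed(config.seed, "scenarios"),
                                   n_train=config.scenario.n_train,
                                   n_val=config.scenario.n_val)
    series = simulate_patient_scenarios(fitted, scenarios, pk=config.pk)
    scaled, scaler = prepare_patient_data(series, scenarios, fitted.emax)
    tcfg = TrainingConfig(**{**asdict(config.training), "seed": seed})
    model, _ = transfer_train(index_model, scaled, tcfg,
                              scaler=scaler, input_scale=fitted.emax)

    # the patient's actual therapy course as network input
    actual = simulate_patient(fitted, fixture["scenario"], pk=config.pk)
    from .narx import scale_drug_input
    u = scale_drug_input(actual.edrug, fitted.emax)
    y_obs_scaled = scaler.transform(np.log(obs_counts))
    ny = model.config.ny
    y_init = np.full(ny, y_obs_scaled[0])
    held_out = (obs_days >= cutoff) & (obs_days >= ny)

    def held_out_mse(m):
        pred = m.simulate_closed_loop(u, y_init)
        return float(np.mean((pred[obs_days[held_out]]
                              - y_obs_scaled[held_out]) ** 2))

    mse_before = held_out_mse(model)
    retrained = training.retrain_on_sparse(model, obs_days[early],
                                           y_obs_scaled[early], u, tcfg,
                                           y_init=y_init)
    mse_after = held_out_mse(retrained)
    return {"fitted_params": fitted, "model": model, "retrained": retrained,
            "mse_before": mse_before, "mse_after": mse_after,
            "n_held_out": int(held_out.sum())}


def write_run_meta(out_dir, config: RunConfig) -> Path:
    """Companion metadata (config hash + seed) for every file a run writes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash(), "seed": config.seed,
            "config": config.to_dict()}
    path = out_dir / "run_meta.json"
    path.write_text(json.dumps(meta, indent=2, default=str))
    return path
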