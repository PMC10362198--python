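"""Population-level analysis of the trained individual models.

Summarises prediction performance (per-scenario mean squared errors on the
standardized log scale, warm-up prefix excluded), model complexity (the
non-zero weight count wf) and the rank correlations between patient
parameters, complexity and generalisation performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


def mse(pred, target, eval_mask=None) -> float:
    """Mean squared error over the evaluated days."""
    pred = np.asarray(pred, float).ravel()
    target = np.asarray(target, float).ravel()
    if pred.shape != target.shape:
        raise ValueError("series must have equal lengths")
    if eval_mask is None:
        eval_mask = np.ones_like(pred, dtype=bool)
    eval_mask = np.asarray(eval_mask, bool)
    if not eval_mask.any():
        raise ValueError("empty evaluation set")
    return float(np.mean((pred[eval_mask] - target[eval_mask]) ** 2))


@dataclass
class PatientRecord:
    """Per-patient summary row of the population report."""

    patient_id: int
    gamma: float
    mtt: float
    emax: float
    wf: int
    mse_by_scenario: dict
    roles: dict  # scenario_id -> role

    def mean_mse(self, role: str) -> float:
        vals = [m for sid, m in self.mse_by_scenario.items()
                if self.roles.get(sid) == role]
        return float(np.mean(vals)) if vals else float("nan")


@dataclass
class PopulationReport:
    records: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "patient_id": r.patient_id, "gamma": r.gamma, "mtt": r.mtt,
            "emax": r.emax, "wf": r.wf,
            "mse_train_avg": r.mean_mse("train"),
            "mse_val_avg": r.mean_mse("validation"),
            "mse_test_avg": r.mean_mse("test")} for r in self.records])

    def summary(self) -> pd.DataFrame:
        """Mean, sd, min and max of the performance metrics across patients."""
        df = self.to_frame()
        cols = ["mse_test_avg", "mse_train_avg", "mse_val_avg", "wf"]
        return pd.DataFrame({
            "mean": df[cols].mean(),
            "sd": df[cols].std(ddof=1) if len(df) > 1 else 0.0,
            "max": df[cols].max(),
            "min": df[cols].min()})


def aggregate_population(records) -> PopulationReport:
    """Collect per-patient training outcomes into a population report."""
    if not records:
        raise ValueError("need at least one trained patient")
    return PopulationReport(records=list(records))


def parameter_correlations(report: PopulationReport) -> pd.DataFrame:
    """Rank correlations of complexity and performance with patient parameters.

    Spearman's rho of wf and of the average test MSE against each of gamma,
    MTT and Emax, plus Pearson's r between wf and the average test MSE.
    Constant columns yield NaN (correlation undefined).
    """
    df = report.to_frame()
    rows = []

    def spearman(a, b):
        if np.unique(a).size < 2 or np.unique(b).size < 2:
            return float("nan"), float("nan")
        rho, p = sps.spearmanr(a, b)
        return float(rho), float(p)

    for param in ("gamma", "mtt", "emax"):
        rho, p = spearman(df["wf"], df[param])
        rows.append({"x": "wf", "y": param, "stat": "spearman", "value": rho, "p": p})
        rho, p = spearman(df["mse_test_avg"], df[param])
        rows.append({"x": "mse_test_avg", "y": param, "stat": "spearman",
                     "value": rho, "p": p})
    if np.unique(df["wf"]).size < 2 or np.unique(df["mse_test_avg"]).size < 2:
        r, p = float("nan"), float("nan")
    else:
        r, p = sps.pearsonr(df["wf"], df["mse_test_avg"])
    rows.append({"x": "wf", "y": "mse_test_avg", "stat": "pearson",
                 "value": float(r), "p": float(p)})
    return pd.DataFrame(rows)


def scenario_boxplot_data(records, scenario_roles: dict | None = None) -> pd.DataFrame:
    """Per-scenario MSE distributions across patients (type-7 quartiles)."""
    sids = sorted({sid for r in records for sid in r.mse_by_scenario})
    rows = []
    for sid in sids:
        vals = np.array([r.mse_by_scenario[sid] for r in records
                         if sid in r.mse_by_scenario])
        q1, med, q3 = np.percentile(vals, [25, 50, 75])  # linear interpolation
        rows.append({"scenario_id": sid,
                     "role": (scenario_roles or {}).get(sid, ""),
                     "q1": q1, "median": med, "q3": q3,
                     "min": vals.min(), "max": vals.max(), "n": len(vals),
                     "values": vals})
    df = pd.DataFrame(rows)
    df.attrs["worst_scenario"] = int(df.loc[df["median"].idxmax(), "scenario_id"])
    return df
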