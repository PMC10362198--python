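"""NARX network architecture, closed-loop simulation and data scaling.

The individual patient model is a nonlinear auto-regressive network with
exogenous input: the next (scaled, log) neutrophil count is predicted from
tapped delay lines holding the last ``ny`` predicted counts and the last
``nu`` daily drug-effect inputs,

    y_t = w_out . act( W_hidden . [y_{t-1}..y_{t-ny}, u_{t-1}..u_{t-nu}] )

with a single hidden layer and a linear output neuron.  Layers carry no
bias terms, so the selected architecture (4 hidden neurons, ny=21, nu=28)
has exactly 4*(21+28) + 4 = 200 trainable weights.  Lag vectors are ordered
most-recent-first.  In closed-loop ("parallel") operation the network feeds
its own predictions back into the output delay line; the first ``ny`` values
come from data (or the scaled baseline when no observed prefix exists).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.preprocessing import StandardScaler

ACTIVATIONS = ("sigmoid", "tanh", "linear", "relu")


def _activate(a: np.ndarray, name: str) -> np.ndarray:
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-a))
    if name == "tanh":
        return np.tanh(a)
    if name == "linear":
        return a
    if name == "relu":
        return np.maximum(a, 0.0)
    raise ValueError(f"unknown activation {name!r}")


@dataclass(frozen=True)
class NARXConfig:
    """Architecture hyperparameters of the one-hidden-layer NARX network."""

    n_hidden: int = 4
    ny: int = 21  # output-memory length, days
    nu: int = 28  # therapy-input memory length, days
    hidden_activation: str = "sigmoid"

    def __post_init__(self):
        if self.hidden_activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")
        if self.n_hidden < 1 or self.ny < 1 or self.nu < 1:
            raise ValueError("n_hidden, ny and nu must be positive")

    @property
    def n_lags(self) -> int:
        return self.ny + self.nu


def count_weights(config: NARXConfig) -> int:
    """Total trainable weights: hidden matrix plus output vector, no biases."""
    return config.n_hidden * config.n_lags + config.n_hidden


class LogStandardScaler:
    """Per-patient output scaling: standardise log counts to zero mean, unit sd.

    Fitted on the concatenated log-count series of the training scenarios
    only, then applied unchanged to validation and test scenarios.
    """

    def __init__(self):
        self._scaler = StandardScaler()

    def fit(self, log_series_list) -> "LogStandardScaler":
        values = np.concatenate([np.asarray(s, float).ravel() for s in log_series_list])
        if len(np.unique(values)) < 2:
            raise ValueError("cannot standardise a series with fewer than 2 distinct values")
        self._scaler.fit(values.reshape(-1, 1))
        if self._scaler.scale_[0] == 0:
            raise ValueError("zero variance in training series")
        return self

    @property
    def mean_(self) -> float:
        return float(self._scaler.mean_[0])

    @property
    def scale_(self) -> float:
        return float(self._scaler.scale_[0])

    def transform(self, log_values):
        return (np.asarray(log_values, float) - self.mean_) / self.scale_

    def inverse_transform(self, scaled):
        return np.asarray(scaled, float) * self.scale_ + self.mean_


def fit_output_scaler(train_log_series) -> LogStandardScaler:
    """Fit the output scaler on the training scenarios' log-count series."""
    return LogStandardScaler().fit(train_log_series)


def scale_drug_input(edrug, emax_reference: float):
    """Scale the drug-effect input to [0, 1] by the patient's Emax.

    Emax is the analytic supremum of the Michaelis-Menten suppression, so
    u = 1 corresponds to full suppression; values are clipped to [0, 1]
    against numerical overshoot.
    """
    if emax_reference <= 0:
        raise ValueError("emax reference must be positive")
    edrug = np.asarray(edrug, float)
    if np.any(edrug < 0):
        raise ValueError("drug effect must be non-negative")
    return np.clip(edrug / emax_reference, 0.0, 1.0)


@dataclass
class NARXModel:
    """Weights, prune mask and fitted scalers of one individual patient model."""

    config: NARXConfig
    hidden_weights: np.ndarray  # (n_hidden, ny + nu)
    output_weights: np.ndarray  # (n_hidden,)
    hidden_mask: np.ndarray = None  # binary, same shape as hidden_weights
    output_mask: np.ndarray = None
    scaler: LogStandardScaler = None
    input_scale: float = None  # patient Emax used to scale the drug input

    def __post_init__(self):
        nh, nl = self.config.n_hidden, self.config.n_lags
        self.hidden_weights = np.asarray(self.hidden_weights, float).reshape(nh, nl)
        self.output_weights = np.asarray(self.output_weights, float).reshape(nh)
        if self.hidden_mask is None:
            self.hidden_mask = np.ones_like(self.hidden_weights, dtype=bool)
        if self.output_mask is None:
            self.output_mask = np.ones_like(self.output_weights, dtype=bool)
        self.hidden_mask = np.asarray(self.hidden_mask, bool)
        self.output_mask = np.asarray(self.output_mask, bool)
        self.apply_mask()

    @classmethod
    def random_init(cls, config: NARXConfig, init_sd: float = 0.5,
                    rng=None) -> "NARXModel":
        """Zero-mean Gaussian initialisation with the given standard deviation."""
        rng = np.random.default_rng(rng)
        return cls(config=config,
                   hidden_weights=rng.normal(0.0, init_sd, (config.n_hidden, config.n_lags)),
                   output_weights=rng.normal(0.0, init_sd, config.n_hidden))

    def apply_mask(self) -> None:
        self.hidden_weights[~self.hidden_mask] = 0.0
        self.output_weights[~self.output_mask] = 0.0

    @property
    def wf(self) -> int:
        """Number of free (non-zero, unmasked) weights."""
        return int(np.count_nonzero(self.hidden_weights[self.hidden_mask])
                   + np.count_nonzero(self.output_weights[self.output_mask]))

    def copy(self) -> "NARXModel":
        return NARXModel(config=self.config,
                         hidden_weights=self.hidden_weights.copy(),
                         output_weights=self.output_weights.copy(),
                         hidden_mask=self.hidden_mask.copy(),
                         output_mask=self.output_mask.copy(),
                         scaler=self.scaler, input_scale=self.input_scale)

    # -- forward computation ------------------------------------------------

    def forward_step(self, y_lags, u_lags) -> float:
        """One prediction from explicit lag vectors (most-recent-first)."""
        y_lags = np.asarray(y_lags, float)
        u_lags = np.asarray(u_lags, float)
        if len(y_lags) != self.config.ny or len(u_lags) != self.config.nu:
            raise ValueError(
                f"lag vectors must have lengths ny={self.config.ny}, nu={self.config.nu}")
        x = np.concatenate([y_lags, u_lags])
        a = (self.hidden_weights * self.hidden_mask) @ x
        h = _activate(a, self.config.hidden_activation)
        return float((self.output_weights * self.output_mask) @ h)

    def simulate_closed_loop(self, u, y_init) -> np.ndarray:
        """Parallel-configuration simulation over the full input series.

        The first ``ny`` outputs are ``y_init`` verbatim; afterwards each
        step feeds the model's own previous outputs back into the output
        delay line.  Input lags reaching before day 0 are zero (no drug
        exposure before the series starts).
        """
        ny, nu = self.config.ny, self.config.nu
        u = np.asarray(u, float)
        y_init = np.asarray(y_init, float)
        if len(y_init) != ny:
            raise ValueError(f"y_init must hold the first ny={ny} scaled data points")
        if len(u) < ny + 1:
            raise ValueError("input series must be longer than the output memory")
        T = len(u)
        u_padded = np.concatenate([np.zeros(nu), u])
        yhat = np.empty(T)
        yhat[:ny] = y_init
        for t in range(ny, T):
            y_lags = yhat[t - 1::-1][:ny]
            u_lags = u_padded[t + nu - 1:t - 1:-1][:nu]
            yhat[t] = self.forward_step(y_lags, u_lags)
            if not np.isfinite(yhat[t]):
                raise FloatingPointError(f"non-finite network output at day {t}")
        return yhat

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "config": asdict(self.config),
            "hidden_weights": self.hidden_weights.tolist(),
            "output_weights": self.output_weights.tolist(),
            "hidden_mask": self.hidden_mask.astype(int).tolist(),
            "output_mask": self.output_mask.astype(int).tolist(),
            "input_scale": self.input_scale,
        }
        if self.scaler is not None:
            d["scaler"] = {"mean": self.scaler.mean_, "scale": self.scaler.scale_}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NARXModel":
        scaler = None
        if "scaler" in d:
            scaler = LogStandardScaler()
            scaler._scaler.mean_ = np.array([d["scaler"]["mean"]])
            scaler._scaler.scale_ = np.array([d["scaler"]["scale"]])
        return cls(config=NARXConfig(**d["config"]),
                   hidden_weights=np.array(d["hidden_weights"], float),
                   output_weights=np.array(d["output_weights"], float),
                   hidden_mask=np.array(d["hidden_mask"], bool),
                   output_mask=np.array(d["output_mask"], bool),
                   scaler=scaler, input_scale=d.get("input_scale"))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "NARXModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
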