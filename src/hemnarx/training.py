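"""Learning machinery for individual NARX patient models.

Training minimises, in closed-loop (parallel) configuration,

    L = L_data + alpha * sum_i sqrt(|w_i|)

where ``L_data`` is the mean squared one-step error over the training
scenarios (warm-up prefix of ``ny`` days excluded) and the square-root
penalty drives small weights towards zero so magnitude pruning removes
them.  Optimisation uses Adam with early stopping on the validation
objective.  Model selection uses the Bayesian Information Criterion

    BIC = 2 nLL + k ln(Ntr + Nval),      k = number of non-zero weights,

with the residual error sigma estimated on the training set.  Pruning
iterates a geometric threshold schedule delta_{k+1} = 1.1 delta_k starting
at delta_0 = 0.001, retraining to plateau after each prune, and returns
the best-BIC model visited.  Transfer learning warm-starts a new patient's
model from the trained index patient's weights and mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from ._kernels import ACT_IDS, closed_loop_forward, closed_loop_backward
from .narx import NARXConfig, NARXModel, fit_output_scaler, scale_drug_input

logger = logging.getLogger(__name__)

#: |w| floor inside the square-root penalty gradient; the subgradient at 0 is 0
_SQRT_EPS = 1e-4


@dataclass
class TrainingConfig:
    """Hyperparameters of the training, pruning and retraining procedures."""

    alpha: float = 3e-4               # regularisation strength
    penalty: str = "sqrt"             # "sqrt" (default) or "l1"
    delta0: float = 1e-3              # initial prune threshold
    prune_growth: float = 1.1         # geometric threshold growth
    init_sd: float = 0.5              # weight init standard deviation
    learning_rate: float = 1e-2       # Adam step size for fresh training
    patience: int = 300               # early-stopping patience (epochs)
    max_epochs: int = 8000            # cap for the initial plateau training
    prune_patience: int = 100         # patience for warm-started prune retrains
    prune_max_epochs: int = 2000      # cap per prune-step retrain
    seed: int = 0
    retrain_learning_rate: float = 1e-4  # low rate for sparse-data retraining
    retrain_epochs: int = 300
    static_prune_delta: float = 0.003    # single static cut-off for retraining
    finetune_factor: float = 0.1      # lr decay for fine-tuning and prune retrains
    finetune_max_epochs: int = 3000


@dataclass
class FitStatistics:
    """Likelihood-based summary of one trained model state."""

    sigma: float
    nll: float
    bic: float
    k: int
    n_tr: int
    n_val: int
    mse_by_scenario: dict = field(default_factory=dict)


@dataclass
class FitReport:
    """Training outcome for one patient model."""

    stats: FitStatistics
    wf: int
    bic_trajectory: list = field(default_factory=list)
    delta_schedule: list = field(default_factory=list)
    n_epochs: int = 0
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stats"]["mse_by_scenario"] = {str(k): v for k, v in
                                         self.stats.mse_by_scenario.items()}
        return d


@dataclass
class ScaledSeries:
    """One scenario's scaled data: standardized log counts and [0,1] drug input."""

    id: int
    role: str
    u: np.ndarray
    y: np.ndarray


# ---------------------------------------------------------------------------
# objective components


def regularisation_penalty(weights, alpha: float, kind: str = "sqrt") -> float:
    """Sparsity penalty alpha * sum sqrt(|w|) (or alpha * sum |w|)."""
    w = np.abs(np.asarray(weights, float).ravel())
    if kind == "sqrt":
        return float(alpha * np.sum(np.sqrt(w)))
    if kind == "l1":
        return float(alpha * np.sum(w))
    raise ValueError(f"unknown penalty kind {kind!r}")


def _penalty_grad(weights: np.ndarray, alpha: float, kind: str) -> np.ndarray:
    w = np.asarray(weights, float)
    sign = np.sign(w)
    if kind == "sqrt":
        return alpha * sign / (2.0 * np.sqrt(np.maximum(np.abs(w), _SQRT_EPS)))
    return alpha * sign


def residual_sigma(predictions, targets) -> float:
    """Root-mean-square training residual (the residual error estimate)."""
    predictions = np.asarray(predictions, float).ravel()
    targets = np.asarray(targets, float).ravel()
    if predictions.size == 0:
        raise ValueError("cannot estimate sigma from an empty training set")
    return float(np.sqrt(np.mean((predictions - targets) ** 2)))


def negative_log_likelihood(train_residuals, val_residuals, sigma: float) -> float:
    """Gaussian negative log-likelihood with sigma profiled on the training set.

    nLL = Ntr/2 + (1/2) sum_val (res/sigma)^2 + (Ntr + Nval) ln(sigma).
    """
    train_residuals = np.asarray(train_residuals, float).ravel()
    val_residuals = np.asarray(val_residuals, float).ravel()
    if sigma <= 0:
        if np.any(val_residuals != 0):
            raise ValueError("degenerate likelihood: sigma is 0 with non-zero residuals")
        raise ValueError("sigma must be positive")
    n_tr, n_val = len(train_residuals), len(val_residuals)
    return float(n_tr / 2.0 + 0.5 * np.sum((val_residuals / sigma) ** 2)
                 + (n_tr + n_val) * np.log(sigma))


def bic(nll: float, k: int, n_tr: int, n_val: int) -> float:
    """Bayesian Information Criterion: 2 nLL + k ln(Ntr + Nval)."""
    if n_tr + n_val < 1:
        raise ValueError("need at least one time point")
    return float(2.0 * nll + k * np.log(n_tr + n_val))


def prune(model: NARXModel, delta: float) -> NARXModel:
    """Mask every weight with |w| < delta; already-masked weights stay masked."""
    if delta < 0:
        raise ValueError("prune threshold must be non-negative")
    model.hidden_mask &= np.abs(model.hidden_weights) >= delta
    model.output_mask &= np.abs(model.output_weights) >= delta
    model.apply_mask()
    return model


# ---------------------------------------------------------------------------
# data preparation


def prepare_patient_data(series_by_scenario: dict, scenarios, emax: float) -> tuple:
    """Scale one patient's simulated series for network training.

    Log counts are standardized with a scaler fitted on the training
    scenarios only; the drug-effect input is scaled to [0,1] by the
    patient's Emax.  Returns (scaled series list, fitted scaler).
    """
    train_logs = [np.log(series_by_scenario[s.id].neutrophils)
                  for s in scenarios if s.role == "train"]
    scaler = fit_output_scaler(train_logs)
    scaled = []
    for s in scenarios:
        series = series_by_scenario[s.id]
        scaled.append(ScaledSeries(
            id=s.id, role=s.role,
            u=scale_drug_input(series.edrug, emax),
            y=scaler.transform(np.log(series.neutrophils))))
    return scaled, scaler


def _split_roles(scaled):
    train = [s for s in scaled if s.role == "train"]
    val = [s for s in scaled if s.role == "validation"]
    test = [s for s in scaled if s.role == "test"]
    return train, val, test


# ---------------------------------------------------------------------------
# core optimisation


def _flatten(model: NARXModel):
    theta = np.concatenate([model.hidden_weights.ravel(), model.output_weights])
    mask = np.concatenate([model.hidden_mask.ravel(), model.output_mask])
    return theta, mask


def _unflatten(model: NARXModel, theta: np.ndarray) -> None:
    nh, nl = model.config.n_hidden, model.config.n_lags
    model.hidden_weights = theta[:nh * nl].reshape(nh, nl).copy()
    model.output_weights = theta[nh * nl:].copy()
    model.apply_mask()


def _forward(model: NARXModel, series: ScaledSeries):
    cfg = model.config
    yhat, H, bad = closed_loop_forward(
        model.hidden_weights, model.output_weights, series.u,
        series.y[:cfg.ny], cfg.ny, cfg.nu, ACT_IDS[cfg.hidden_activation])
    if bad >= 0:
        raise FloatingPointError(
            f"non-finite network output at day {bad} of scenario {series.id}")
    return yhat, H


def scenario_mse(model: NARXModel, series: ScaledSeries) -> float:
    """Closed-loop MSE on scaled data, warm-up prefix excluded."""
    yhat, _ = _forward(model, series)
    ny = model.config.ny
    return float(np.mean((yhat[ny:] - series.y[ny:]) ** 2))


def _data_objective(model: NARXModel, series_list) -> float:
    return float(np.mean([scenario_mse(model, s) for s in series_list]))


def _objective(model: NARXModel, series_list, cfg: TrainingConfig) -> float:
    theta, mask = _flatten(model)
    return _data_objective(model, series_list) + regularisation_penalty(
        theta[mask], cfg.alpha, cfg.penalty)


def _epoch_gradient(model: NARXModel, train, cfg: TrainingConfig):
    """Loss and gradient of the full objective over the training scenarios."""
    c = model.config
    act = ACT_IDS[c.hidden_activation]
    gWh = np.zeros_like(model.hidden_weights)
    gwo = np.zeros_like(model.output_weights)
    loss = 0.0
    n_scen = len(train)
    for s in train:
        yhat, H = _forward(model, s)
        n_eval = len(s.u) - c.ny
        res_scale = 1.0 / (n_scen * n_eval)
        loss += res_scale * np.sum((yhat[c.ny:] - s.y[c.ny:]) ** 2)
        gW, go = closed_loop_backward(model.hidden_weights, model.output_weights,
                                      s.u, s.y, yhat, H, c.ny, c.nu, act, res_scale,
                                      np.ones(len(s.u)))
        gWh += gW
        gwo += go
    theta, mask = _flatten(model)
    loss += regularisation_penalty(theta[mask], cfg.alpha, cfg.penalty)
    g = np.concatenate([gWh.ravel(), gwo])
    g += _penalty_grad(theta, cfg.alpha, cfg.penalty)
    g[~mask] = 0.0
    return loss, g


def train_until_plateau(model: NARXModel, train, val, cfg: TrainingConfig,
                        learning_rate: float | None = None,
                        max_epochs: int | None = None,
                        patience: int | None = None) -> tuple:
    """Adam optimisation until the validation objective stops improving.

    Returns ``(model, n_epochs)`` with the best-validation weights restored.
    Masked weights receive no updates.
    """
    lr = learning_rate if learning_rate is not None else cfg.learning_rate
    max_epochs = max_epochs if max_epochs is not None else cfg.max_epochs
    patience = patience if patience is not None else cfg.patience
    theta, mask = _flatten(model)
    m = np.zeros_like(theta)
    v = np.zeros_like(theta)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    monitor = val if val else train
    best_obj = _objective(model, monitor, cfg)
    best_theta = theta.copy()
    stale = 0
    epoch = 0
    for epoch in range(1, max_epochs + 1):
        _, g = _epoch_gradient(model, train, cfg)
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient at epoch {epoch}")
        m = beta1 * m + (1 - beta1) * g
        v = beta2 * v + (1 - beta2) * g * g
        mhat = m / (1 - beta1 ** epoch)
        vhat = v / (1 - beta2 ** epoch)
        theta = theta - lr * mhat / (np.sqrt(vhat) + eps)
        theta[~mask] = 0.0
        _unflatten(model, theta)
        obj = _objective(model, monitor, cfg)
        if obj < best_obj:
            best_obj, best_theta, stale = obj, theta.copy(), 0
        else:
            stale += 1
            if stale >= patience:
                break
    _unflatten(model, best_theta)
    return model, epoch


def fit_statistics(model: NARXModel, train, val) -> FitStatistics:
    """Sigma, likelihood and BIC of the current model state."""
    ny = model.config.ny
    tr_res, val_res = [], []
    mse_by_scenario = {}
    for s in train + val:
        yhat, _ = _forward(model, s)
        res = yhat[ny:] - s.y[ny:]
        mse_by_scenario[s.id] = float(np.mean(res ** 2))
        (tr_res if s.role == "train" else val_res).append(res)
    tr_res = np.concatenate(tr_res)
    val_res = np.concatenate(val_res) if val_res else np.empty(0)
    sigma = max(residual_sigma(tr_res, np.zeros_like(tr_res)), 1e-12)
    nll = negative_log_likelihood(tr_res, val_res, sigma)
    k = model.wf
    return FitStatistics(sigma=sigma, nll=nll,
                         bic=bic(nll, k, len(tr_res), len(val_res)),
                         k=k, n_tr=len(tr_res), n_val=len(val_res),
                         mse_by_scenario=mse_by_scenario)


def train_with_pruning(model: NARXModel, train, val, cfg: TrainingConfig) -> tuple:
    """Plateau training followed by the geometric pruning loop.

    Prunes at delta_k = delta0 * growth^k, retrains to plateau, evaluates
    the BIC, and stops at the first deterioration; the best-BIC model is
    returned together with a :class:`FitReport` recording the trajectory.

    The initial plateau training is followed by a fine-tuning phase at a
    decayed learning rate (and prune retrains use the decayed rate too):
    near a loss plateau Adam's normalised steps keep unimportant weights
    jittering at the order of the step size, so without decay they never
    shrink below the prune thresholds that the square-root penalty is
    meant to push them under.
    """
    model, n_epochs = train_until_plateau(model, train, val, cfg)
    fine_lr = cfg.learning_rate * cfg.finetune_factor
    model, ep = train_until_plateau(model, train, val, cfg, learning_rate=fine_lr,
                                    max_epochs=cfg.finetune_max_epochs,
                                    patience=2 * cfg.prune_patience)
    n_epochs += ep
    stats = fit_statistics(model, train, val)
    best_model, best_stats = model.copy(), stats
    trajectory = [stats.bic]
    deltas = []
    delta = cfg.delta0
    while True:
        wf_before = model.wf
        prune(model, delta)
        deltas.append(delta)
        if model.wf == 0:
            if len(trajectory) == 1:
                raise RuntimeError("all weights pruned before any BIC evaluation")
            logger.info("pruning emptied the network at delta=%.4g; stopping", delta)
            break
        if model.wf == wf_before:
            # threshold not yet reaching the next weight: the model is
            # unchanged, so grow delta instead of re-evaluating a tied BIC
            delta *= cfg.prune_growth
            continue
        model, ep = train_until_plateau(model, train, val, cfg,
                                        learning_rate=fine_lr,
                                        max_epochs=cfg.prune_max_epochs,
                                        patience=cfg.prune_patience)
        n_epochs += ep
        stats = fit_statistics(model, train, val)
        trajectory.append(stats.bic)
        logger.info("prune delta=%.4g wf=%d BIC=%.2f", delta, model.wf, stats.bic)
        if stats.bic < best_stats.bic:
            best_model, best_stats = model.copy(), stats
            delta *= cfg.prune_growth
        else:
            break
    report = FitReport(stats=best_stats, wf=best_model.wf,
                       bic_trajectory=trajectory, delta_schedule=deltas,
                       n_epochs=n_epochs, seed=cfg.seed)
    return best_model, report


# ---------------------------------------------------------------------------
# patient-level workflows


def train_index_patient(scaled_series, narx_config: NARXConfig,
                        cfg: TrainingConfig, scaler=None,
                        input_scale: float | None = None) -> tuple:
    """Train the transfer source from random initialisation.

    ``scaled_series`` holds the 18 prepared :class:`ScaledSeries` of the
    index patient (5 train / 2 validation / 11 test).
    """
    train, val, test = _split_roles(scaled_series)
    rng = np.random.default_rng(cfg.seed)
    model = NARXModel.random_init(narx_config, init_sd=cfg.init_sd, rng=rng)
    model.scaler = scaler
    model.input_scale = input_scale
    model, report = train_with_pruning(model, train, val, cfg)
    for s in test:
        report.stats.mse_by_scenario[s.id] = scenario_mse(model, s)
    return model, report


def transfer_train(index_model: NARXModel, scaled_series,
                   cfg: TrainingConfig, scaler=None,
                   input_scale: float | None = None) -> tuple:
    """Warm-start a new patient's model from the index patient's weights.

    The index weights and prune mask are inherited; training continues with
    BIC-controlled pruning from the inherited architecture, so the patient's
    wf can only shrink relative to the index model.
    """
    train, val, test = _split_roles(scaled_series)
    model = index_model.copy()
    model.scaler = scaler
    model.input_scale = input_scale
    model, report = train_with_pruning(model, train, val, cfg)
    for s in test:
        report.stats.mse_by_scenario[s.id] = scenario_mse(model, s)
    return model, report


def retrain_on_sparse(model: NARXModel, observed_days, observed_scaled,
                      u: np.ndarray, cfg: TrainingConfig,
                      y_init: np.ndarray | None = None) -> NARXModel:
    """Fine-tune a pre-trained model on sparse observed counts.

    The loss is evaluated only at the observed days (which must lie beyond
    the warm-up prefix); one static prune at ``static_prune_delta`` is
    applied up front and the mask is otherwise frozen.  Gradient steps use
    the low ``retrain_learning_rate``.
    """
    observed_days = np.asarray(observed_days, int)
    observed_scaled = np.asarray(observed_scaled, float)
    if len(observed_days) < 4:
        raise ValueError("need at least 4 observed points for retraining")
    c = model.config
    T = len(u)
    y = np.zeros(T)
    wmask = np.zeros(T)
    usable = observed_days >= c.ny
    y[observed_days[usable]] = observed_scaled[usable]
    wmask[observed_days[usable]] = 1.0
    if y_init is None:
        y_init = np.full(c.ny, observed_scaled[0])
    y[:c.ny] = y_init

    model = prune(model.copy(), cfg.static_prune_delta)
    series = ScaledSeries(id=0, role="train", u=np.asarray(u, float), y=y)
    act = ACT_IDS[c.hidden_activation]
    theta, mask = _flatten(model)
    m = np.zeros_like(theta)
    v = np.zeros_like(theta)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    n_obs = wmask.sum()

    def loss_and_grad():
        yhat, H = _forward(model, series)
        res = (yhat - y) * wmask
        loss = float(np.sum(res ** 2) / n_obs)
        gW, go = closed_loop_backward(model.hidden_weights, model.output_weights,
                                      series.u, y, yhat, H, c.ny, c.nu, act,
                                      1.0 / n_obs, wmask)
        g = np.concatenate([gW.ravel(), go])
        g[~mask] = 0.0
        return loss, g

    best_loss, _ = loss_and_grad()
    best_theta = theta.copy()
    stale = 0
    for epoch in range(1, cfg.retrain_epochs + 1):
        _, g = loss_and_grad()
        m = beta1 * m + (1 - beta1) * g
        v = beta2 * v + (1 - beta2) * g * g
        theta = theta - cfg.retrain_learning_rate * (m / (1 - beta1 ** epoch)) / (
            np.sqrt(v / (1 - beta2 ** epoch)) + eps)
        theta[~mask] = 0.0
        _unflatten(model, theta)
        loss, _ = loss_and_grad()
        if loss < best_loss:
            best_loss, best_theta, stale = loss, theta.copy(), 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    _unflatten(model, best_theta)
    return model


def hyperparameter_search(scaled_series, budget: int, seed: int,
                          cfg_base: TrainingConfig | None = None,
                          n_hidden_bounds=(2, 12), memory_bounds=(14, 42),
                          alpha_bounds=(1e-7, 1e-1),
                          activations=("sigmoid", "tanh", "linear", "relu"),
                          max_epochs: int | None = None) -> tuple:
    """Random search over architecture and regularisation strength.

    Each draw is scored by the BIC of a plateau-trained model on the index
    patient's data; the best configuration and its alpha are returned along
    with the full trial table.
    """
    if budget < 1:
        raise ValueError("budget must be at least 1")
    cfg_base = cfg_base or TrainingConfig()
    rng = np.random.default_rng(seed)
    train, val, _ = _split_roles(scaled_series)
    trials = []
    best = None
    for i in range(budget):
        config = NARXConfig(
            n_hidden=int(rng.integers(n_hidden_bounds[0], n_hidden_bounds[1] + 1)),
            ny=int(rng.integers(memory_bounds[0], memory_bounds[1] + 1)),
            nu=int(rng.integers(memory_bounds[0], memory_bounds[1] + 1)),
            hidden_activation=str(rng.choice(list(activations))))
        alpha = float(np.exp(rng.uniform(np.log(alpha_bounds[0]), np.log(alpha_bounds[1]))))
        cfg = TrainingConfig(**{**asdict(cfg_base), "alpha": alpha,
                                "seed": int(rng.integers(2 ** 31))})
        model = NARXModel.random_init(config, init_sd=cfg.init_sd,
                                      rng=np.random.default_rng(cfg.seed))
        model, _ = train_until_plateau(model, train, val, cfg, max_epochs=max_epochs)
        stats = fit_statistics(model, train, val)
        trials.append({"trial": i, "config": config, "alpha": alpha, "bic": stats.bic})
        if best is None or stats.bic < best[2]:
            best = (config, alpha, stats.bic)
    return best[0], best[1], trials


# ---------------------------------------------------------------------------
# sklearn-style estimator


class NARXRegressor(BaseEstimator, RegressorMixin):
    """Closed-loop NARX network regressor for daily time series.

    Expects already-scaled inputs: each row of ``X`` is one scenario's daily
    drug-effect input in [0, 1] and each row of ``y`` the matching
    standardized log count series.  Validation scenarios (for early
    stopping and BIC) are passed to :meth:`fit` as keyword arguments; when
    omitted, early stopping monitors the training objective.

    Parameters mirror :class:`NARXConfig` and :class:`TrainingConfig`.
    After fitting, ``model_`` holds the :class:`NARXModel`, ``wf_`` the
    non-zero weight count and ``report_`` the full pruning history.
    """

    def __init__(self, n_hidden: int = 4, ny: int = 21, nu: int = 28,
                 hidden_activation: str = "sigmoid", alpha: float = 3e-4,
                 penalty: str = "sqrt", delta0: float = 1e-3,
                 prune_growth: float = 1.1, init_sd: float = 0.5,
                 learning_rate: float = 1e-3, patience: int = 20,
                 max_epochs: int = 500, pruning: bool = True, seed: int = 0):
        self.n_hidden = n_hidden
        self.ny = ny
        self.nu = nu
        self.hidden_activation = hidden_activation
        self.alpha = alpha
        self.penalty = penalty
        self.delta0 = delta0
        self.prune_growth = prune_growth
        self.init_sd = init_sd
        self.learning_rate = learning_rate
        self.patience = patience
        self.max_epochs = max_epochs
        self.pruning = pruning
        self.seed = seed

    def _configs(self):
        narx_cfg = NARXConfig(n_hidden=self.n_hidden, ny=self.ny, nu=self.nu,
                              hidden_activation=self.hidden_activation)
        train_cfg = TrainingConfig(alpha=self.alpha, penalty=self.penalty,
                                   delta0=self.delta0, prune_growth=self.prune_growth,
                                   init_sd=self.init_sd, learning_rate=self.learning_rate,
                                   patience=self.patience, max_epochs=self.max_epochs,
                                   seed=self.seed)
        return narx_cfg, train_cfg

    @staticmethod
    def _as_series(X, y, role):
        X = np.atleast_2d(np.asarray(X, float))
        y = np.atleast_2d(np.asarray(y, float))
        if X.shape != y.shape:
            raise ValueError("X and y must have matching (n_scenarios, n_days) shapes")
        return [ScaledSeries(id=i, role=role, u=X[i], y=y[i]) for i in range(len(X))]

    def fit(self, X, y, X_val=None, y_val=None, init_model: NARXModel = None):
        narx_cfg, train_cfg = self._configs()
        train = self._as_series(X, y, "train")
        val = self._as_series(X_val, y_val, "validation") if X_val is not None else []
        if init_model is not None:
            model = init_model.copy()
        else:
            model = NARXModel.random_init(narx_cfg, init_sd=train_cfg.init_sd,
                                          rng=np.random.default_rng(train_cfg.seed))
        if self.pruning:
            model, report = train_with_pruning(model, train, val, train_cfg)
        else:
            model, n_epochs = train_until_plateau(model, train, val, train_cfg)
            stats = fit_statistics(model, train, val)
            report = FitReport(stats=stats, wf=model.wf, bic_trajectory=[stats.bic],
                               n_epochs=n_epochs, seed=train_cfg.seed)
        self.model_ = model
        self.hidden_weights_ = model.hidden_weights
        self.output_weights_ = model.output_weights
        self.wf_ = model.wf
        self.report_ = report
        return self

    def predict(self, X, y_init=None):
        """Closed-loop prediction for each input row.

        ``y_init`` supplies the first ``ny`` scaled values per row; a scalar
        is broadcast (the constant-baseline warm-up convention); default 0
        (the scaled training mean).
        """
        X = np.atleast_2d(np.asarray(X, float))
        ny = self.model_.config.ny
        if y_init is None:
            y_init = 0.0
        y_init = np.asarray(y_init, float)
        if y_init.ndim == 0:
            y_init = np.full((len(X), ny), float(y_init))
        y_init = np.atleast_2d(y_init)
        return np.vstack([self.model_.simulate_closed_loop(X[i], y_init[i])
                          for i in range(len(X))])
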