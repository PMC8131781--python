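"""Maximum-entropy presence/background model with linear+quadratic features.

The model estimates a Gibbs density over environmental space from presence
records and a background sample:

    q_λ(x) = w(x) · exp(λ · f(x)) / Z,   Z = Σ_background w(x) · exp(λ · f(x))

where f(x) expands each continuous covariate into a standardized linear
term z and its square z² (one-hot indicators for categoricals), and w(x)
are optional base-measure weights on the background (uniform by default;
the background-weighting module supplies non-uniform ones for invaded
ranges).  Fitting maximizes the mean presence log-likelihood under q_λ
minus an L1 penalty Σ_j ρ_j |λ_j| with ρ_j = β · s_j / √m (s_j the feature
sd over the background, m the presence count); β is the single
regularization knob, default 3.  The problem is convex; it is solved by
L-BFGS-B on the non-negative split λ = u − v, which handles the L1 term
exactly at the stationary point.

Predictions are reported on the cloglog scale by default
(1 − exp(−e^H · raw), H the entropy of the fitted background density),
with logistic and raw alternatives.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMap",
    "MaxentModel",
    "ReplicateEnsemble",
    "fit",
    "replicate_fit",
    "variable_contribution",
    "response_curve",
]


@dataclass
class FeatureMap:
    """Standardization, clamping and feature-expansion rules.

    All constants come from the training background sample.  Continuous
    variables are clamped to their background [min, max] before expansion
    (standard transfer behavior when projecting beyond the training
    range), then standardized; each contributes a linear and a quadratic
    feature.  Categorical variables are one-hot encoded over the declared
    levels; an unseen level encodes as all-zeros (the reference).
    """

    continuous: list[str]
    categorical: dict[str, list]
    mean: dict[str, float]
    sd: dict[str, float]
    clamp_min: dict[str, float]
    clamp_max: dict[str, float]
    dropped: list[str] = field(default_factory=list)

    @classmethod
    def from_background(
        cls, background: pd.DataFrame, categoricals: dict[str, list] | None = None
    ) -> "FeatureMap":
        categoricals = dict(categoricals or {})
        continuous, mean, sd, cmin, cmax, dropped = [], {}, {}, {}, {}, []
        for col in background.columns:
            if col in categoricals:
                continue
            vals = background[col].to_numpy(dtype=float)
            s = float(np.nanstd(vals))
            if s == 0.0:
                dropped.append(col)
                logger.info("dropping constant covariate %r", col)
                continue
            continuous.append(col)
            mean[col] = float(np.nanmean(vals))
            sd[col] = s
            cmin[col] = float(np.nanmin(vals))
            cmax[col] = float(np.nanmax(vals))
        return cls(continuous, categoricals, mean, sd, cmin, cmax, dropped)

    @property
    def variables(self) -> list[str]:
        return self.continuous + list(self.categorical)

    @property
    def feature_names(self) -> list[str]:
        names = []
        for v in self.continuous:
            names += [v, f"{v}^2"]
        for v, levels in self.categorical.items():
            names += [f"{v}={lvl}" for lvl in levels]
        return names

    @property
    def feature_variable(self) -> list[str]:
        """Parent variable of each expanded feature (for joint permutation)."""
        owners = []
        for v in self.continuous:
            owners += [v, v]
        for v, levels in self.categorical.items():
            owners += [v] * len(levels)
        return owners

    def transform(self, data: pd.DataFrame, clamp: bool = True) -> np.ndarray:
        missing = [v for v in self.variables if v not in data.columns]
        if missing:
            raise KeyError(f"covariates missing model variables: {missing}")
        cols = []
        for v in self.continuous:
            x = data[v].to_numpy(dtype=float)
            if not np.all(np.isfinite(x)):
                raise ValueError(f"non-finite values in covariate {v!r}")
            if clamp:
                x = np.clip(x, self.clamp_min[v], self.clamp_max[v])
            z = (x - self.mean[v]) / self.sd[v]
            cols += [z, z**2]
        for v, levels in self.categorical.items():
            x = data[v].to_numpy()
            for lvl in levels:
                cols.append((x == lvl).astype(float))
        return np.column_stack(cols)

    def to_dict(self) -> dict:
        return {
            "continuous": self.continuous,
            "categorical": {k: list(v) for k, v in self.categorical.items()},
            "mean": self.mean,
            "sd": self.sd,
            "clamp_min": self.clamp_min,
            "clamp_max": self.clamp_max,
            "dropped": self.dropped,
        }


@dataclass
class MaxentModel:
    """A fitted maximum-entropy model."""

    feature_map: FeatureMap
    coef: np.ndarray
    beta: float
    reg_scale: np.ndarray
    log_z: float  # log partition over training background, weights normalized
    entropy: float  # entropy of fitted background density (for transforms)
    gain: float  # mean presence log-likelihood improvement over λ=0
    log_n_background: float = 0.0  # log of positive-weight background count
    transform: str = "cloglog"
    meta: dict = field(default_factory=dict)

    @property
    def variables(self) -> list[str]:
        return self.feature_map.variables

    def linear_predictor(self, data: pd.DataFrame, clamp: bool = True) -> np.ndarray:
        return self.feature_map.transform(data, clamp=clamp) @ self.coef

    def predict(self, data: pd.DataFrame, output: str | None = None) -> np.ndarray:
        """Suitability per row. ``output``: cloglog (default), logistic, raw."""
        output = output or self.transform
        raw = np.exp(self.linear_predictor(data) - self.log_z)
        if output == "raw":
            return raw
        # per-point density scale: a flat model maps to 1 - 1/e on cloglog
        scaled = np.exp(self.entropy - self.log_n_background) * raw
        if output == "cloglog":
            return 1.0 - np.exp(-scaled)
        if output == "logistic":
            return scaled / (1.0 + scaled)
        raise ValueError(f"unknown output transform {output!r}")

    def to_dict(self) -> dict:
        return {
            "feature_map": self.feature_map.to_dict(),
            "coef": self.coef.tolist(),
            "beta": self.beta,
            "reg_scale": self.reg_scale.tolist(),
            "log_z": self.log_z,
            "entropy": self.entropy,
            "gain": self.gain,
            "log_n_background": self.log_n_background,
            "transform": self.transform,
            "meta": self.meta,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "MaxentModel":
        fm = FeatureMap(
            continuous=d["feature_map"]["continuous"],
            categorical=d["feature_map"]["categorical"],
            mean=d["feature_map"]["mean"],
            sd=d["feature_map"]["sd"],
            clamp_min=d["feature_map"]["clamp_min"],
            clamp_max=d["feature_map"]["clamp_max"],
            dropped=d["feature_map"].get("dropped", []),
        )
        return cls(
            feature_map=fm,
            coef=np.asarray(d["coef"], dtype=float),
            beta=d["beta"],
            reg_scale=np.asarray(d["reg_scale"], dtype=float),
            log_z=d["log_z"],
            entropy=d["entropy"],
            gain=d["gain"],
            log_n_background=d.get("log_n_background", 0.0),
            transform=d.get("transform", "cloglog"),
            meta=d.get("meta", {}),
        )

    @classmethod
    def load(cls, path) -> "MaxentModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def penalized_nll(
    lam: np.ndarray,
    f_presence: np.ndarray,
    f_background: np.ndarray,
    log_w: np.ndarray,
    rho: np.ndarray,
) -> float:
    """The convex objective the fit minimizes (exposed for audits/oracles).

    Mean negative presence log-likelihood of the weighted Gibbs density
    plus the L1 penalty; weights enter through ``log_w`` (log background
    base-measure weights, any positive scale).
    """
    eta_bg = f_background @ lam + log_w
    log_z = logsumexp(eta_bg) - logsumexp(log_w)
    return float(-np.mean(f_presence @ lam) + log_z + rho @ np.abs(lam))


def fit(
    presences: pd.DataFrame,
    background: pd.DataFrame,
    weights: np.ndarray | None = None,
    beta: float = 3.0,
    categoricals: dict[str, list] | None = None,
    feature_map: FeatureMap | None = None,
    transform: str = "cloglog",
    tol: float = 1e-10,
    max_iter: int = 5000,
    meta: dict | None = None,
) -> MaxentModel:
    """Fit the L1-penalized maximum-entropy model.

    ``presences`` and ``background`` are covariate tables with matching
    columns; ``weights`` are non-negative background base-measure weights
    (default uniform).  Raises on fewer than 10 presences, a background
    smaller than the presence set, or all-zero weights.
    """
    m = len(presences)
    if m < 10:
        raise ValueError(f"need at least 10 presences, got {m}")
    if len(background) < m:
        raise ValueError("background must be at least as large as the presence set")
    if weights is None:
        weights = np.ones(len(background))
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(background),):
        raise ValueError("weights length must match background")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    if not np.any(weights > 0):
        raise ValueError("all background weights are zero")

    fm = feature_map or FeatureMap.from_background(background, categoricals)
    f_bg = fm.transform(background, clamp=False)
    f_pr = fm.transform(presences, clamp=True)
    if not np.all(np.isfinite(f_pr)):
        raise ValueError("non-finite presence covariates after expansion")

    keep = weights > 0
    f_bg_w = f_bg[keep]
    log_w = np.log(weights[keep])
    log_w_norm = log_w - logsumexp(log_w)

    s_j = f_bg.std(axis=0)
    s_j[s_j == 0] = 1.0  # constant expanded feature: penalty scale moot
    rho = beta * s_j / np.sqrt(m)

    p = f_bg.shape[1]
    mean_pr = f_pr.mean(axis=0)

    def objective(theta: np.ndarray):
        lam = theta[:p] - theta[p:]
        eta = f_bg_w @ lam + log_w_norm
        log_z = logsumexp(eta)
        prob = np.exp(eta - log_z)
        val = -mean_pr @ lam + log_z + rho @ (theta[:p] + theta[p:])
        g = -mean_pr + f_bg_w.T @ prob
        grad = np.concatenate([g + rho, -g + rho])
        return val, grad

    theta0 = np.zeros(2 * p)
    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * (2 * p),
        options={"ftol": tol, "gtol": 1e-9, "maxiter": max_iter},
    )
    lam = res.x[:p] - res.x[p:]
    lam[np.abs(lam) < 1e-12] = 0.0

    eta = f_bg_w @ lam + log_w_norm
    log_z = float(logsumexp(eta))
    prob = np.exp(eta - log_z)
    entropy = float(-np.sum(prob * np.log(np.maximum(prob, 1e-300))))
    gain = float(mean_pr @ lam - log_z)  # objective at λ=0 is exactly 0

    return MaxentModel(
        feature_map=fm,
        coef=lam,
        beta=beta,
        reg_scale=rho,
        log_z=log_z,
        entropy=entropy,
        gain=gain,
        log_n_background=float(np.log(f_bg_w.shape[0])),
        transform=transform,
        meta=dict(meta or {}, n_presence=m, n_background=len(background),
                  converged=bool(res.success), n_iter=int(res.nit)),
    )


@dataclass
class ReplicateEnsemble:
    """Mean of several replicate fits; predicts as the arithmetic mean."""

    models: list[MaxentModel]

    @property
    def feature_map(self) -> FeatureMap:
        return self.models[0].feature_map

    @property
    def variables(self) -> list[str]:
        return self.models[0].variables

    @property
    def transform(self) -> str:
        return self.models[0].transform

    def predict(self, data: pd.DataFrame, output: str | None = None) -> np.ndarray:
        preds = [m.predict(data, output=output) for m in self.models]
        return np.mean(preds, axis=0)


def replicate_fit(
    presences: pd.DataFrame,
    background: pd.DataFrame,
    weights: np.ndarray | None = None,
    n_replicates: int = 10,
    train_fraction: float = 0.7,
    beta: float = 3.0,
    categoricals: dict[str, list] | None = None,
    seed: int = 0,
    transform: str = "cloglog",
):
    """Replicated 70/30 presence-split fitting with averaged predictions.

    Each replicate draws an independent random split of the presences; the
    background (and its weights) is shared.  Returns
    ``(ensemble, reports)`` where ``reports`` is a list of per-replicate
    :class:`~invaniche.evaluation.EvaluationReport` on the held-out 30%,
    or an empty list when ``train_fraction == 1``.
    """
    from .evaluation import evaluate_model  # local import avoids a cycle

    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    m = len(presences)
    if m < 4 and train_fraction < 1.0:
        raise ValueError("too few presences to split (need >= 4)")
    rng = np.random.default_rng(seed)
    models, reports = [], []
    for rep in range(n_replicates):
        if train_fraction >= 1.0:
            train_idx = np.arange(m)
            test_idx = np.array([], dtype=int)
        else:
            perm = rng.permutation(m)
            n_train = max(int(round(train_fraction * m)), 10)
            n_train = min(n_train, m - 1)
            train_idx, test_idx = perm[:n_train], perm[n_train:]
        model = fit(
            presences.iloc[train_idx],
            background,
            weights=weights,
            beta=beta,
            categoricals=categoricals,
            transform=transform,
            meta={"replicate": rep, "seed": seed},
        )
        models.append(model)
        if test_idx.size:
            reports.append(
                evaluate_model(model, presences.iloc[test_idx], background)
            )
    return ReplicateEnsemble(models), reports


def variable_contribution(
    model,
    presences: pd.DataFrame,
    background: pd.DataFrame,
    n_permutations: int = 10,
    seed: int = 0,
) -> pd.Series:
    """Permutation importance per variable, normalized to sum to 100.

    For each model variable, its values (both expanded features jointly)
    are permuted across the pooled presence+background evaluation rows and
    the drop in AUC from the unpermuted baseline is averaged over
    ``n_permutations`` shuffles, floored at zero, and rescaled so the
    contributions total 100%.
    """
    from .evaluation import auc

    variables = model.variables
    if len(variables) == 1:
        return pd.Series([100.0], index=variables)
    pooled = pd.concat(
        [presences[variables], background[variables]], ignore_index=True
    )
    n_pr = len(presences)
    base_scores = model.predict(pooled, output="raw")
    base_auc = auc(base_scores[:n_pr], base_scores[n_pr:])
    rng = np.random.default_rng(seed)
    drops = {}
    for v in variables:
        deltas = []
        for _ in range(n_permutations):
            shuffled = pooled.copy()
            perm = rng.permutation(len(pooled))
            shuffled[v] = pooled[v].to_numpy()[perm]
            scores = model.predict(shuffled, output="raw")
            deltas.append(base_auc - auc(scores[:n_pr], scores[n_pr:]))
        drops[v] = max(float(np.mean(deltas)), 0.0)
    total = sum(drops.values())
    if total == 0:
        return pd.Series({v: 100.0 / len(variables) for v in variables})
    return pd.Series({v: 100.0 * d / total for v, d in drops.items()})


def response_curve(
    model,
    variable: str,
    n_points: int = 100,
    output: str | None = None,
    sweep_range: tuple[float, float] | None = None,
):
    """Suitability as one covariate sweeps its range, others held at the
    background mean (categoricals at the reference level).

    Returns ``(values, suitability)`` arrays for continuous variables, or
    ``(levels, suitability)`` for categorical ones.  ``sweep_range``
    overrides the training range (values outside it are clamped by the
    model, flattening the curve there).
    """
    fm = model.feature_map
    if variable not in fm.variables:
        raise KeyError(f"variable {variable!r} not in model")

    def base_frame(n: int) -> pd.DataFrame:
        data = {}
        for v in fm.continuous:
            data[v] = np.full(n, fm.mean[v])
        for v in fm.categorical:
            data[v] = np.full(n, "__reference__", dtype=object)
        return pd.DataFrame(data)

    if variable in fm.categorical:
        levels = fm.categorical[variable]
        frame = base_frame(len(levels))
        frame[variable] = levels
        return np.asarray(levels, dtype=object), model.predict(frame, output=output)

    lo, hi = (sweep_range if sweep_range is not None
              else (fm.clamp_min[variable], fm.clamp_max[variable]))
    values = np.linspace(lo, hi, n_points)
    frame = base_frame(n_points)
    frame[variable] = values
    return values, model.predict(frame, output=output)
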