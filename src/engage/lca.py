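"""Latent class analysis for categorical indicators, written from scratch.

The model: each participant belongs to one of ``K`` unobserved classes
with prevalences ``gamma``; given the class, the ``J`` categorical
indicators are independent, item ``j`` responding at level ``k`` with
probability ``rho[j][c, k]``. The observed-data likelihood of response
vector ``y`` is ``sum_c gamma_c * prod_j rho[j][c, y_j]``.

Fitting is by expectation-maximization over the collapsed table of
unique response patterns, with multiple random starts to guard against
local maxima. Absolute fit is summarized by the likelihood-ratio
statistic G² against the saturated multinomial; relative fit by AIC and
BIC on the G² scale (``AIC = G² + 2p``, ``BIC = G² + ln(n)·p`` with
``p = (K-1) + K·sum_j (k_j - 1)`` free parameters), so lower is better
and differences match the usual −2·log-likelihood-scale criteria.

Class labels are arbitrary under the likelihood; :func:`align_classes`
resolves label switching by optimal assignment on the L1 distance
between item-response tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp

from engage import defaults

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IndicatorSpec:
    """Ordered categorical indicators and their level vocabularies."""

    items: tuple[str, ...]
    levels: Mapping[str, tuple[str, ...]]

    def __post_init__(self):
        if len(set(self.items)) != len(self.items):
            raise ValueError("item names must be unique")
        for item in self.items:
            if item not in self.levels:
                raise ValueError(f"no levels declared for item {item!r}")
            if len(self.levels[item]) < 2:
                raise ValueError(f"item {item!r} needs >= 2 levels")

    @property
    def n_levels(self) -> tuple[int, ...]:
        return tuple(len(self.levels[item]) for item in self.items)

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.n_levels))

    def encode(self, data: pd.DataFrame) -> np.ndarray:
        """Map level tokens to integer codes, one column per item."""
        codes = np.empty((len(data), len(self.items)), dtype=np.int64)
        for j, item in enumerate(self.items):
            if item not in data.columns:
                raise ValueError(f"data missing indicator column {item!r}")
            mapping = {lvl: k for k, lvl in enumerate(self.levels[item])}
            col = data[item].map(mapping)
            if col.isna().any():
                bad = sorted(set(data[item]) - set(mapping))
                raise ValueError(f"undeclared levels for {item!r}: {bad}")
            codes[:, j] = col.to_numpy()
        return codes


def engagement_spec() -> IndicatorSpec:
    """The seven engagement indicators (2 consistency + 5 quantity coded)."""
    levels = {f: tuple(defaults.CONSISTENCY_LEVELS) for f in defaults.CONSISTENCY_FEATURES}
    levels.update({f: tuple(defaults.QUANTITY_LEVELS) for f in defaults.QUANTITY_FEATURES})
    return IndicatorSpec(items=tuple(defaults.FEATURES), levels=levels)


def subgroup_spec() -> IndicatorSpec:
    """The five demographic/BMI indicators."""
    return IndicatorSpec(
        items=tuple(defaults.SUBGROUP_ITEMS),
        levels={k: tuple(v) for k, v in defaults.SUBGROUP_LEVELS.items()},
    )


@dataclass(frozen=True)
class LcaModel:
    """Fitted (or constructed) latent class model.

    ``rho[item]`` is a ``K x k_item`` array of class-conditional response
    probabilities; ``gamma`` the length-``K`` class prevalences.
    """

    gamma: np.ndarray
    rho: Mapping[str, np.ndarray]
    log_likelihood: float = float("nan")
    converged: bool = True
    n_iter: int = 0
    ll_history: tuple[float, ...] = field(default=(), repr=False)

    def __post_init__(self):
        gamma = np.asarray(self.gamma, dtype=float)
        object.__setattr__(self, "gamma", gamma)
        object.__setattr__(
            self, "rho", {k: np.asarray(v, dtype=float) for k, v in self.rho.items()}
        )
        if not np.isclose(gamma.sum(), 1.0, atol=1e-6):
            raise ValueError("gamma must sum to 1")
        if (gamma < 0).any():
            raise ValueError("gamma must be non-negative")
        for item, table in self.rho.items():
            if table.shape[0] != len(gamma):
                raise ValueError(f"rho[{item!r}] row count != K")
            if not np.allclose(table.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError(f"rho[{item!r}] rows must sum to 1")

    @property
    def n_classes(self) -> int:
        return len(self.gamma)

    def permute(self, perm: Sequence[int]) -> "LcaModel":
        """Reorder classes; ``perm[c]`` becomes the new class ``c``."""
        perm = np.asarray(perm, dtype=int)
        if sorted(perm.tolist()) != list(range(self.n_classes)):
            raise ValueError("perm must be a permutation of class indices")
        return replace(
            self,
            gamma=self.gamma[perm],
            rho={item: table[perm] for item, table in self.rho.items()},
        )

    def sorted_by_prevalence(self) -> "LcaModel":
        """Classes in descending prevalence order (reporting convention)."""
        order = np.argsort(-self.gamma, kind="stable")
        return self.permute(order)

    def to_dict(self) -> dict:
        return {
            "K": self.n_classes,
            "gamma": self.gamma.tolist(),
            "rho": {item: table.tolist() for item, table in self.rho.items()},
            "loglik": self.log_likelihood,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, payload: Mapping) -> "LcaModel":
        return cls(
            gamma=np.asarray(payload["gamma"], dtype=float),
            rho={k: np.asarray(v, dtype=float) for k, v in payload["rho"].items()},
            log_likelihood=float(payload.get("loglik", float("nan"))),
            converged=bool(payload.get("converged", True)),
            n_iter=int(payload.get("n_iter", 0)),
        )

    @classmethod
    def from_json(cls, path) -> "LcaModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class FitStats:
    """Absolute and relative fit of a latent class model."""

    G2: float
    df: int
    AIC: float
    BIC: float
    n_params: int
    df_unreliable: bool = False


@dataclass(frozen=True)
class FitConfig:
    """EM fitting configuration; identical config + data gives identical fits."""

    n_starts: int = 20
    max_iter: int = 5000
    tol: float = 1e-8
    seed: int = 0
    prob_floor: float = 1e-10

    def __post_init__(self):
        if self.n_starts < 1 or self.max_iter < 1:
            raise ValueError("n_starts and max_iter must be >= 1")
        if self.tol <= 0 or self.prob_floor <= 0:
            raise ValueError("tol and prob_floor must be positive")


@dataclass(frozen=True)
class PosteriorAssignment:
    """Posterior class-membership probabilities and modal assignment."""

    posterior: np.ndarray
    modal_class: np.ndarray

    def modal_shares(self, n_classes: int | None = None) -> np.ndarray:
        k = n_classes if n_classes is not None else self.posterior.shape[1]
        return np.bincount(self.modal_class, minlength=k) / len(self.modal_class)


# ---------------------------------------------------------------------------
# internals


def _check_dims(model: LcaModel, spec: IndicatorSpec) -> None:
    if set(model.rho) != set(spec.items):
        raise ValueError(
            f"model items {sorted(model.rho)} != spec items {sorted(spec.items)}"
        )
    for item, n_lvl in zip(spec.items, spec.n_levels):
        if model.rho[item].shape != (model.n_classes, n_lvl):
            raise ValueError(
                f"rho[{item!r}] shape {model.rho[item].shape} != "
                f"({model.n_classes}, {n_lvl})"
            )


def _collapse(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique response patterns and their observed counts."""
    patterns, counts = np.unique(codes, axis=0, return_counts=True)
    return patterns, counts.astype(float)


def _onehots(patterns: np.ndarray, n_levels: Sequence[int]) -> list[np.ndarray]:
    return [
        np.eye(n_lvl)[patterns[:, j]] for j, n_lvl in enumerate(n_levels)
    ]


def _pattern_loglik(
    onehots: list[np.ndarray], gamma: np.ndarray, rho_list: list[np.ndarray],
    prob_floor: float,
) -> np.ndarray:
    """log p(pattern, class) matrix of shape (n_patterns, K)."""
    log_joint = np.log(np.maximum(gamma, prob_floor))[None, :].copy()
    for X, rho_j in zip(onehots, rho_list):
        log_joint = log_joint + X @ np.log(np.maximum(rho_j, prob_floor)).T
    return log_joint


def _floor_renorm(p: np.ndarray, floor: float) -> np.ndarray:
    p = np.maximum(p, floor)
    return p / p.sum(axis=-1, keepdims=True)


def _em_run(
    onehots: list[np.ndarray],
    weights: np.ndarray,
    gamma: np.ndarray,
    rho_list: list[np.ndarray],
    config: FitConfig,
) -> tuple[np.ndarray, list[np.ndarray], float, list[float], bool]:
    """One EM run over the collapsed pattern table.

    Items are stacked into a single indicator matrix so both steps are
    one matrix product each; per-item tables are recovered by slicing.
    """
    n_levels = [X.shape[1] for X in onehots]
    edges = np.cumsum([0] + n_levels)
    X_all = np.concatenate(onehots, axis=1)  # (U, sum_j L_j)
    n = weights.sum()
    history: list[float] = []
    prev_ll = -np.inf
    converged = False
    for _ in range(config.max_iter):
        log_rho_all = np.log(
            np.concatenate([np.maximum(r, config.prob_floor) for r in rho_list], axis=1)
        )  # (K, sum L)
        log_joint = X_all @ log_rho_all.T
        log_joint += np.log(np.maximum(gamma, config.prob_floor))[None, :]
        m = log_joint.max(axis=1)
        shifted = np.exp(log_joint - m[:, None])
        marg = shifted.sum(axis=1)
        log_marginal = m + np.log(marg)
        ll = float(weights @ log_marginal)
        history.append(ll)
        post = shifted / marg[:, None]  # E-step posteriors
        w_post = weights[:, None] * post
        class_mass = w_post.sum(axis=0)
        gamma = _floor_renorm(class_mass / n, config.prob_floor)
        num_all = (X_all.T @ w_post).T / np.maximum(class_mass, config.prob_floor)[:, None]
        rho_list = [
            _floor_renorm(num_all[:, edges[j]:edges[j + 1]], config.prob_floor)
            for j in range(len(n_levels))
        ]
        if abs(ll - prev_ll) < config.tol:
            converged = True
            break
        prev_ll = ll
    return gamma, rho_list, history[-1], history, converged


# ---------------------------------------------------------------------------
# public operations


def lca_log_likelihood(
    profiles: pd.DataFrame, model: LcaModel, spec: IndicatorSpec,
    prob_floor: float = 1e-10,
) -> float:
    """Observed-data log-likelihood of ``profiles`` under ``model``."""
    _check_dims(model, spec)
    patterns, weights = _collapse(spec.encode(profiles))
    onehots = _onehots(patterns, spec.n_levels)
    rho_list = [model.rho[item] for item in spec.items]
    log_joint = _pattern_loglik(onehots, model.gamma, rho_list, prob_floor)
    return float(weights @ logsumexp(log_joint, axis=1))


def lca_fit(
    profiles: pd.DataFrame,
    K: int,
    spec: IndicatorSpec,
    config: FitConfig = FitConfig(),
) -> LcaModel:
    """Fit a ``K``-class model by multi-start EM; best start wins.

    Starting values are drawn per start: ``gamma`` uniform on the
    simplex and each ``rho`` row from a symmetric Dirichlet(1). Classes
    of the returned model are sorted by descending prevalence. A model
    whose best run hit ``max_iter`` without meeting ``tol`` is returned
    with ``converged=False`` rather than raising.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if len(profiles) < K:
        raise ValueError(f"need at least K={K} observations, got {len(profiles)}")
    patterns, weights = _collapse(spec.encode(profiles))
    onehots = _onehots(patterns, spec.n_levels)
    rng = np.random.default_rng(config.seed)

    best = None
    for _ in range(config.n_starts):
        gamma0 = rng.dirichlet(np.ones(K))
        rho0 = [rng.dirichlet(np.ones(n_lvl), size=K) for n_lvl in spec.n_levels]
        gamma, rho_list, ll, history, converged = _em_run(
            onehots, weights, gamma0, rho0, config
        )
        if best is None or ll > best[2]:
            best = (gamma, rho_list, ll, history, converged)

    gamma, rho_list, ll, history, converged = best
    if not converged:
        logger.warning("EM did not reach tol=%g within %d iterations",
                       config.tol, config.max_iter)
    model = LcaModel(
        gamma=gamma,
        rho=dict(zip(spec.items, rho_list)),
        log_likelihood=ll,
        converged=converged,
        n_iter=len(history),
        ll_history=tuple(history),
    )
    return model.sorted_by_prevalence()


def n_parameters(K: int, spec: IndicatorSpec) -> int:
    """Free parameters: (K-1) prevalences + K·sum_j (k_j - 1) responses."""
    return (K - 1) + K * sum(n_lvl - 1 for n_lvl in spec.n_levels)


def compute_fit_stats(
    model: LcaModel, profiles: pd.DataFrame, spec: IndicatorSpec
) -> FitStats:
    """G², degrees of freedom, AIC and BIC of ``model`` on ``profiles``.

    ``G² = 2·sum_cells O·ln(O/E)`` with expected counts from the model;
    unobserved cells contribute zero. ``df = (prod_j k_j - 1) - p`` and
    is flagged unreliable when negative (model not identified from the
    contingency table alone).
    """
    _check_dims(model, spec)
    n = len(profiles)
    patterns, observed = _collapse(spec.encode(profiles))
    onehots = _onehots(patterns, spec.n_levels)
    rho_list = [model.rho[item] for item in spec.items]
    log_joint = _pattern_loglik(onehots, model.gamma, rho_list, 1e-300)
    log_p = logsumexp(log_joint, axis=1)
    expected = n * np.exp(log_p)
    G2 = float(2.0 * observed @ np.log(observed / expected))
    G2 = max(G2, 0.0)
    p = n_parameters(model.n_classes, spec)
    df = spec.n_cells - 1 - p
    if spec.n_cells > n:
        logger.warning(
            "sparse table: %d cells for %d observations; G² reference "
            "distribution is unreliable", spec.n_cells, n,
        )
    return FitStats(
        G2=G2,
        df=df,
        AIC=G2 + 2 * p,
        BIC=G2 + np.log(n) * p,
        n_params=p,
        df_unreliable=df < 0,
    )


@dataclass(frozen=True)
class ModelSweep:
    """Result of a class-enumeration sweep."""

    table: pd.DataFrame
    selected_k: int
    models: Mapping[int, LcaModel]


def select_model(
    profiles: pd.DataFrame,
    spec: IndicatorSpec,
    k_range: Iterable[int],
    config: FitConfig = FitConfig(),
    criterion: str = "BIC",
) -> ModelSweep:
    """Fit each K in ``k_range`` and select the one minimizing ``criterion``.

    Each K gets its own deterministic seed stream (``config.seed + K``)
    so adding values to the range never perturbs existing fits.
    """
    if criterion not in ("BIC", "AIC"):
        raise ValueError("criterion must be 'BIC' or 'AIC'")
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 1 or ks[-1] > len(profiles):
        raise ValueError(f"k_range must lie within [1, n={len(profiles)}]")
    rows = []
    models = {}
    for K in ks:
        model = lca_fit(profiles, K, spec, replace(config, seed=config.seed + K))
        stats = compute_fit_stats(model, profiles, spec)
        models[K] = model
        rows.append(
            {
                "K": K,
                "log_likelihood": model.log_likelihood,
                "G2": stats.G2,
                "df": stats.df,
                "AIC": stats.AIC,
                "BIC": stats.BIC,
                "n_params": stats.n_params,
                "converged": model.converged,
                "identified": not stats.df_unreliable,
            }
        )
    table = pd.DataFrame(rows)
    selected_k = int(table.loc[table[criterion].idxmin(), "K"])
    return ModelSweep(table=table, selected_k=selected_k, models=models)


def posterior_classify(
    model: LcaModel, profiles: pd.DataFrame, spec: IndicatorSpec,
    prob_floor: float = 1e-10,
) -> PosteriorAssignment:
    """Bayes-rule posterior membership and modal class per participant.

    Ties in the posterior break toward the lowest class index.
    """
    _check_dims(model, spec)
    codes = spec.encode(profiles)
    onehots = _onehots(codes, spec.n_levels)
    rho_list = [model.rho[item] for item in spec.items]
    log_joint = _pattern_loglik(onehots, model.gamma, rho_list, prob_floor)
    log_marginal = logsumexp(log_joint, axis=1)
    posterior = np.exp(log_joint - log_marginal[:, None])
    posterior /= posterior.sum(axis=1, keepdims=True)
    return PosteriorAssignment(
        posterior=posterior, modal_class=np.argmax(posterior, axis=1)
    )


def align_classes(reference: LcaModel, candidate: LcaModel) -> np.ndarray:
    """Permutation resolving label switching between two fitted models.

    Returns ``perm`` such that ``candidate.permute(perm)`` puts the
    candidate class closest (total L1 distance over all item-response
    tables, optimal one-to-one assignment) to reference class ``c`` at
    position ``c``.
    """
    if reference.n_classes != candidate.n_classes:
        raise ValueError("models must have the same number of classes")
    if set(reference.rho) != set(candidate.rho):
        raise ValueError("models must share the same items")
    K = reference.n_classes
    cost = np.zeros((K, K))
    for item in reference.rho:
        ref_t, cand_t = reference.rho[item], candidate.rho[item]
        if ref_t.shape != cand_t.shape:
            raise ValueError(f"rho[{item!r}] shapes differ")
        cost += np.abs(ref_t[:, None, :] - cand_t[None, :, :]).sum(axis=2)
    row_ind, col_ind = linear_sum_assignment(cost)
    perm = np.empty(K, dtype=int)
    perm[row_ind] = col_ind
    return perm
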