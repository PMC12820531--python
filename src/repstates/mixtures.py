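"""Gaussian-mixture decomposition of corrected burst FRET efficiencies.

Free fits and BIC model selection are delegated to scikit-learn's
GaussianMixture; the globally constrained stage (shared centres across
conditions, per-condition sigmas/weights re-fitted with frozen means) and
the label-permutation test of state weights are implemented here, since
standard EM implementations cannot hold means fixed.

Conventions: E values are truncated to [-0.2, 1.2] before fitting to tame
shot-noise tails; components are reported sorted by mean (S1..S4 labels);
goodness of fit (R^2, reduced chi^2) is evaluated against a 50-bin
histogram of E on [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

E_TRUNCATION = (-0.2, 1.2)
_HIST_BINS = 50


@dataclass
class MixtureModel:
    """K-component Gaussian decomposition of a FRET-efficiency sample."""

    means: np.ndarray  # sorted ascending
    sigmas: np.ndarray
    weights: np.ndarray  # sum to 1
    log_likelihood: float
    bic: float
    r2: float
    chi2_reduced: float
    n: int

    def __post_init__(self) -> None:
        order = np.argsort(self.means)
        self.means = np.asarray(self.means, float)[order]
        self.sigmas = np.asarray(self.sigmas, float)[order]
        self.weights = np.asarray(self.weights, float)[order]

    @property
    def K(self) -> int:
        return self.means.size

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)[..., None]
        comp = np.exp(-0.5 * ((x - self.means) / self.sigmas) ** 2) \
            / (self.sigmas * np.sqrt(2 * np.pi))
        return (comp * self.weights).sum(axis=-1)

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)[..., None]
        comp = self.weights * np.exp(-0.5 * ((x - self.means) / self.sigmas) ** 2) \
            / (self.sigmas * np.sqrt(2 * np.pi))
        return comp / comp.sum(axis=-1, keepdims=True)


def _truncate(e_values: np.ndarray) -> np.ndarray:
    x = np.asarray(e_values, dtype=float)
    x = x[np.isfinite(x)]
    return x[(x >= E_TRUNCATION[0]) & (x <= E_TRUNCATION[1])]


def _hist_gof(x: np.ndarray, model: MixtureModel, n_params: int) -> tuple[float, float]:
    counts, edges = np.histogram(x, bins=_HIST_BINS, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    expected = model.pdf(centers) * x.size * width
    ss_res = float(np.sum((counts - expected) ** 2))
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    var = np.clip(expected, 1.0, None)  # Poisson bin variance
    dof = max(_HIST_BINS - n_params, 1)
    chi2 = float(np.sum((counts - expected) ** 2 / var) / dof)
    return r2, chi2


def fit_mixture(e_values: np.ndarray, K: int, n_restarts: int = 10,
                seed: int = 0) -> MixtureModel:
    """EM fit (best of ``n_restarts``, deterministic given ``seed``).

    Initialisation uses k-means refinement of quantile-spread starts, as
    provided by scikit-learn; degenerate solutions (any sigma below 1e-3)
    raise after all restarts.
    """
    x = _truncate(e_values)
    if x.size < 10 * K:
        raise ValueError(f"need >= {10 * K} values for K={K}")
    gm = GaussianMixture(n_components=K, covariance_type="full", tol=1e-8,
                         max_iter=500, n_init=n_restarts, init_params="k-means++",
                         random_state=seed, reg_covar=1e-6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm.fit(x[:, None])
    sigmas = np.sqrt(gm.covariances_.ravel())
    if np.any(sigmas <= 1.05e-3):  # at the variance floor: collapsed spike
        raise RuntimeError("all restarts converged on a degenerate component")
    logl = float(gm.score(x[:, None]) * x.size)
    n_params = 3 * K - 1
    model = MixtureModel(means=gm.means_.ravel(), sigmas=sigmas,
                         weights=gm.weights_, log_likelihood=logl,
                         bic=float(gm.bic(x[:, None])), r2=np.nan,
                         chi2_reduced=np.nan, n=x.size)
    model.r2, model.chi2_reduced = _hist_gof(x, model, n_params)
    return model


def select_k(e_values: np.ndarray, k_max: int = 6, n_restarts: int = 10,
             seed: int = 0) -> tuple[int, list[MixtureModel]]:
    """K* = argmin BIC over 1..k_max (BIC = -2 logL + (3K-1) ln n)."""
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    models = []
    for K in range(1, k_max + 1):
        try:
            models.append(fit_mixture(e_values, K, n_restarts, seed))
        except RuntimeError:
            # Over-parametrised K that only fits degenerately cannot win.
            models.append(None)
    bics = [m.bic if m is not None else np.inf for m in models]
    k_star = int(np.argmin(bics)) + 1
    return k_star, models


def _frozen_mean_em(x: np.ndarray, means: np.ndarray, sigmas0: np.ndarray,
                    weights0: np.ndarray, tol: float = 1e-8,
                    max_iter: int = 500, min_sigma: float = 5e-3) -> MixtureModel:
    """EM over (sigmas, weights) with component means held fixed."""
    mu = np.asarray(means, float)
    sig = np.asarray(sigmas0, float).copy()
    w = np.asarray(weights0, float).copy()
    x = np.asarray(x, float)
    prev = -np.inf
    for _ in range(max_iter):
        comp = w * np.exp(-0.5 * ((x[:, None] - mu) / sig) ** 2) / (sig * np.sqrt(2 * np.pi))
        tot = comp.sum(axis=1)
        tot = np.clip(tot, 1e-300, None)
        logl = float(np.log(tot).sum())
        r = comp / tot[:, None]
        nk = r.sum(axis=0)
        w = nk / x.size
        var = (r * (x[:, None] - mu) ** 2).sum(axis=0) / np.clip(nk, 1e-12, None)
        sig = np.sqrt(np.clip(var, min_sigma ** 2, None))
        if logl - prev < tol and logl >= prev:
            prev = logl
            break
        prev = logl
    n_params = 2 * mu.size - 1
    model = MixtureModel(means=mu, sigmas=sig, weights=w, log_likelihood=prev,
                         bic=-2 * prev + n_params * np.log(x.size),
                         r2=np.nan, chi2_reduced=np.nan, n=x.size)
    model.r2, model.chi2_reduced = _hist_gof(x, model, n_params)
    return model


def global_constrained_fit(datasets: list[np.ndarray], K: int = 4,
                           n_restarts: int = 10, seed: int = 0
                           ) -> tuple[MixtureModel, list[MixtureModel]]:
    """Two-stage constrained fit across conditions.

    Stage 1 fits the pooled data for shared centres; stage 2 re-fits each
    dataset with those centres frozen, optimising sigmas and weights.
    Returns (pooled model, per-dataset constrained models).
    """
    datasets = [np.asarray(d) for d in datasets]
    if len(datasets) < 2:
        raise ValueError("need at least two datasets for a global fit")
    keep = []
    for i, d in enumerate(datasets):
        if _truncate(d).size == 0:
            warnings.warn(f"dataset {i} is empty; skipped", stacklevel=2)
        else:
            keep.append(d)
    pooled = fit_mixture(np.concatenate(keep), K, n_restarts, seed)
    per_dataset = [
        _frozen_mean_em(_truncate(d), pooled.means, pooled.sigmas, pooled.weights)
        for d in keep
    ]
    return pooled, per_dataset


def constrained_fit(e_values: np.ndarray, means: np.ndarray,
                    sigmas0: np.ndarray | None = None,
                    weights0: np.ndarray | None = None) -> MixtureModel:
    """Fit one dataset with fixed component centres (sigmas/weights free)."""
    means = np.asarray(means, float)
    K = means.size
    sig0 = np.full(K, 0.05) if sigmas0 is None else np.asarray(sigmas0, float)
    w0 = np.full(K, 1.0 / K) if weights0 is None else np.asarray(weights0, float)
    return _frozen_mean_em(_truncate(e_values), means, sig0, w0)


def permutation_test_weights(dataset_a: np.ndarray, dataset_b: np.ndarray,
                             means: np.ndarray, n_perm: int = 999, seed: int = 0
                             ) -> tuple[np.ndarray, float, dict]:
    """Label-permutation test for per-state weight differences.

    Both datasets are fitted with frozen shared means; the per-state
    statistic is |dw_k| and the overall statistic is half the total
    variation distance sum_k |dw_k| / 2.  The null is built by permuting
    condition labels over bursts and re-fitting.  p-values use the
    add-one estimator (1 + #{null >= obs}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    a = _truncate(dataset_a)
    b = _truncate(dataset_b)
    means = np.asarray(means, float)

    def weights_of(x):
        return _frozen_mean_em(x, means, np.full(means.size, 0.05),
                               np.full(means.size, 1.0 / means.size)).weights

    wa, wb = weights_of(a), weights_of(b)
    obs_per_state = np.abs(wa - wb)
    obs_overall = obs_per_state.sum() / 2.0

    pooled = np.concatenate([a, b])
    na = a.size
    null_per_state = np.empty((n_perm, means.size))
    null_overall = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(pooled.size)
        w1 = weights_of(pooled[perm[:na]])
        w2 = weights_of(pooled[perm[na:]])
        d = np.abs(w1 - w2)
        null_per_state[i] = d
        null_overall[i] = d.sum() / 2.0
    p_state = (1 + (null_per_state >= obs_per_state).sum(axis=0)) / (n_perm + 1)
    p_overall = (1 + (null_overall >= obs_overall).sum()) / (n_perm + 1)
    detail = {"weights_a": wa, "weights_b": wb, "delta": wa - wb,
              "null_overall": null_overall}
    return p_state, float(p_overall), detail


def draw_from_fixture(fixture, n: int, seed: int) -> np.ndarray:
    """Draw burst-averaged E values from a fixture's mixture description."""
    rng = np.random.default_rng(seed)
    w = fixture.weights_normalised
    comp = rng.choice(w.size, size=n, p=w)
    mu = np.asarray(fixture.states.e_values)[comp]
    sig = np.asarray(fixture.mixture_sigmas)[comp]
    return rng.normal(mu, sig)
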