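"""Photon-by-photon hidden Markov modelling (H2MM) of within-burst kinetics.

The hidden conformational state evolves as a Markov chain on the 10 ns
timestamp clock with per-tick transition matrix A; a photon detected at a
given tick is emitted into one of the DD/DA/AA streams with a per-state
emission probability.  Between consecutive photons separated by an integer
gap dt the state distribution propagates by the matrix power A**dt, which is
evaluated through the eigendecomposition of A, so arbitrarily long gaps cost
O(K^3).  The Baum-Welch E-step uses the exact closed form for the expected
number of tick-level transitions accumulated across each gap:

    sum_{t=0}^{dt-1} lam_a^t lam_b^(dt-1-t)
        = (lam_a^dt - lam_b^dt) / (lam_a - lam_b)   (a != b)
        = dt * lam_a^(dt-1)                          (a == b)

so the M-step re-estimates the per-tick A from complete tick-level
statistics and the likelihood is non-decreasing over iterations.

Model selection fits K = 1..n+1 states, where n is the lowest state count
whose relative BIC improvement BIC'(K+1) = (BIC(K) - BIC(K+1))/|BIC(K)|
falls below 0.005; the integrated completed likelihood (ICL), computed from
the Viterbi complete-data likelihood, is reported as a cross-check.
Parameter uncertainties are profile-likelihood intervals at a log-likelihood
drop of 0.5 (one sigma).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.linalg import logm
from scipy.optimize import brentq

from .burst_core import Burst, CorrectionFactors
from .streams import AA, CLOCK_TICK_S, DA, DD, PhotonStream


# ---------------------------------------------------------------------------
# Data container
# ---------------------------------------------------------------------------

@dataclass
class BurstPhotons:
    """Flat photon-level observations for a set of bursts.

    The default alphabet is the two donor-excitation streams {DD, DA}.
    Acceptor-excitation (AA) photons are excluded by default: their arrival
    pattern is locked to the deterministic ALEX laser alternation, and an
    unconstrained photon HMM will otherwise learn a fast phase-tracking
    state instead of conformational kinetics.  The three-symbol alphabet
    remains available (``include_aa=True``) for gap-free or
    continuous-excitation data.
    """

    obs: np.ndarray  # uint8 symbol codes (0: DD, 1: DA[, 2: AA])
    gaps: np.ndarray  # int64 ticks since previous photon (first-of-burst: 0)
    burst_ptr: np.ndarray  # int64, len n_bursts+1
    n_symbols: int = 2
    aa_per_dex: float = np.nan  # AA / (DD+DA) count ratio of the source bursts

    @property
    def n_photons(self) -> int:
        return self.obs.size

    @property
    def n_bursts(self) -> int:
        return self.burst_ptr.size - 1

    @property
    def first_mask(self) -> np.ndarray:
        m = np.zeros(self.n_photons, dtype=bool)
        m[self.burst_ptr[:-1]] = True
        return m


def burst_photon_data(stream: PhotonStream, bursts: list[Burst],
                      include_aa: bool = False) -> BurstPhotons:
    """Extract each burst's photons with inter-photon tick gaps.

    By default only donor-excitation (DD/DA) photons enter the observation
    sequence (see BurstPhotons); the bursts' AA/(DD+DA) count ratio is
    recorded so state efficiencies can still be stoichiometry-corrected.
    """
    labels = stream.streams
    keep_codes = (DD, DA, AA) if include_aa else (DD, DA)
    obs_parts, gap_parts, ptr = [], [], [0]
    n_aa = n_dex = 0
    for b in bursts:
        idx = b.photon_index
        if idx is None:
            raise ValueError("bursts must carry photon indices")
        lab = labels[idx]
        n_aa += int((lab == AA).sum())
        n_dex += int(((lab == DD) | (lab == DA)).sum())
        keep = np.isin(lab, keep_codes)
        idx = idx[keep]
        if idx.size == 0:
            continue
        t = stream.timestamps[idx]
        g = np.diff(t, prepend=t[0])
        obs_parts.append(labels[idx].astype(np.uint8))
        gap_parts.append(g.astype(np.int64))
        ptr.append(ptr[-1] + idx.size)
    if not obs_parts:
        raise ValueError("no photons in bursts")
    return BurstPhotons(obs=np.concatenate(obs_parts),
                        gaps=np.concatenate(gap_parts),
                        burst_ptr=np.array(ptr, dtype=np.int64),
                        n_symbols=3 if include_aa else 2,
                        aa_per_dex=n_aa / max(n_dex, 1))


@dataclass
class H2MMModel:
    """K-state photon HMM: per-tick transitions, stream emissions, scores."""

    trans: np.ndarray  # (K, K) per-tick row-stochastic
    emission: np.ndarray  # (K, n_symbols) rows sum to 1
    initial: np.ndarray  # (K,)
    log_likelihood: float = np.nan
    bic: float = np.nan
    icl: float = np.nan
    n_photons: int = 0
    converged: bool = False
    n_iter: int = 0
    param_cis: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return self.trans.shape[0]

    @property
    def n_symbols(self) -> int:
        return self.emission.shape[1]

    @property
    def n_free_params(self) -> int:
        K = self.K
        return K * (K - 1) + K * (self.n_symbols - 1) + (K - 1)

    def state_e_raw(self) -> np.ndarray:
        """Per-state proximity ratio P(DA)/(P(DD)+P(DA))."""
        dd, da = self.emission[:, DD], self.emission[:, DA]
        return da / np.clip(dd + da, 1e-300, None)

    def state_e_background_corrected(self, f_bg: float, p_da_bg: float) -> np.ndarray:
        """Per-state proximity ratio with the in-burst background removed.

        A fraction ``f_bg`` of the donor-excitation photons inside bursts is
        background with DA probability ``p_da_bg``; the observed emission is
        the corresponding mixture, inverted here per state."""
        e_obs = self.state_e_raw()
        return np.clip((e_obs - f_bg * p_da_bg) / max(1.0 - f_bg, 1e-12), 0.0, 1.0)

    def state_e_corrected(self, cf: CorrectionFactors,
                          aa_per_dex: float | None = None) -> np.ndarray:
        """Per-state accurate FRET efficiency.

        The emission vector gives the state's expected stream composition
        (equal donor/acceptor excitation windows), so the burst correction
        formula applies directly.  On the two-symbol (DD/DA) alphabet the
        AA share needed for the direct-excitation term comes from
        ``aa_per_dex`` (AA/(DD+DA) ratio; AA emission is a labelling
        property, independent of the conformational state)."""
        out = np.empty(self.K)
        for k in range(self.K):
            if self.n_symbols >= 3:
                f_dd, f_da, f_aa = self.emission[k, :3]
            else:
                f_dd, f_da = self.emission[k]
                f_aa = (aa_per_dex or 0.0) * (f_dd + f_da)
            f_acc = f_da - cf.leakage_l * f_dd - cf.direct_excitation_d * f_aa
            den = cf.gamma * f_dd + f_acc
            out[k] = f_acc / den if den > 0 else np.nan
        return out


# ---------------------------------------------------------------------------
# Matrix powers via eigendecomposition
# ---------------------------------------------------------------------------

def _eig(A: np.ndarray):
    """Eigendecomposition of A with a real fast path.

    Per-tick transition matrices are diagonally dominant (off-diagonals are
    tiny rates), so their spectra are real and positive in practice; the
    complex path is kept for generality and near-defective matrices get a
    deterministic jitter to break the degeneracy."""
    lam, V = np.linalg.eig(A)
    cond = np.linalg.cond(V)
    if not np.isfinite(cond) or cond > 1e10:
        K = A.shape[0]
        jit = 1e-10 * (np.arange(K * K).reshape(K, K) % 7 + 1)
        Aj = A + jit
        Aj /= Aj.sum(axis=1, keepdims=True)
        lam, V = np.linalg.eig(Aj)
    if np.iscomplexobj(lam):
        if np.abs(lam.imag).max() < 1e-12 and lam.real.min() > 0:
            lam, V = lam.real.copy(), V.real.copy()
    elif lam.min() <= 0:
        lam, V = lam.astype(complex), V.astype(complex)
    W = np.linalg.inv(V)
    return lam, V, W


def matrix_power_eig(A: np.ndarray, dts: np.ndarray) -> np.ndarray:
    """A**dt for an array of integer exponents, via eigendecomposition."""
    lam, V, W = _eig(A)
    lp = lam[None, :] ** np.asarray(dts, dtype=float)[:, None]
    P = np.einsum("ka,na,al->nkl", V, lp, W)
    P = np.real(P)
    P = np.clip(P, 0.0, None)
    P /= np.clip(P.sum(axis=2, keepdims=True), 1e-300, None)
    return P


# ---------------------------------------------------------------------------
# Numba recursions
# ---------------------------------------------------------------------------

@njit(cache=True)
def _fb_kernel(P, b, pi, burst_ptr):
    N, K = b.shape
    alpha = np.zeros((N, K))
    beta = np.zeros((N, K))
    c = np.zeros(N)
    for bi in range(burst_ptr.size - 1):
        s, e = burst_ptr[bi], burst_ptr[bi + 1]
        tot = 0.0
        for k in range(K):
            alpha[s, k] = pi[k] * b[s, k]
            tot += alpha[s, k]
        if tot <= 0.0:
            tot = 1e-300
        c[s] = tot
        for k in range(K):
            alpha[s, k] /= tot
        for n in range(s + 1, e):
            tot = 0.0
            for j in range(K):
                acc = 0.0
                for i in range(K):
                    acc += alpha[n - 1, i] * P[n, i, j]
                acc *= b[n, j]
                alpha[n, j] = acc
                tot += acc
            if tot <= 0.0:
                tot = 1e-300
            c[n] = tot
            for j in range(K):
                alpha[n, j] /= tot
        for k in range(K):
            beta[e - 1, k] = 1.0
        for n in range(e - 2, s - 1, -1):
            for i in range(K):
                acc = 0.0
                for j in range(K):
                    acc += P[n + 1, i, j] * b[n + 1, j] * beta[n + 1, j]
                beta[n, i] = acc / c[n + 1]
    return alpha, beta, c


@njit(cache=True)
def _viterbi_kernel(logP, logb, logpi, burst_ptr):
    N, K = logb.shape
    path = np.zeros(N, dtype=np.int32)
    delta = np.zeros((N, K))
    psi = np.zeros((N, K), dtype=np.int32)
    score = 0.0
    for bi in range(burst_ptr.size - 1):
        s, e = burst_ptr[bi], burst_ptr[bi + 1]
        for k in range(K):
            delta[s, k] = logpi[k] + logb[s, k]
        for n in range(s + 1, e):
            for j in range(K):
                best = -1e300
                arg = 0
                for i in range(K):
                    v = delta[n - 1, i] + logP[n, i, j]
                    if v > best:
                        best = v
                        arg = i
                delta[n, j] = best + logb[n, j]
                psi[n, j] = arg
        best = -1e300
        arg = 0
        for k in range(K):
            if delta[e - 1, k] > best:
                best = delta[e - 1, k]
                arg = k
        score += best
        path[e - 1] = arg
        for n in range(e - 2, s - 1, -1):
            path[n] = psi[n + 1, path[n + 1]]
    return path, score


# ---------------------------------------------------------------------------
# Likelihood, EM
# ---------------------------------------------------------------------------

def _prepare(model: H2MMModel, data: BurstPhotons):
    K = model.K
    if not np.allclose(model.trans.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("transition matrix rows must sum to 1")
    b = model.emission[:, data.obs].T.copy()  # (N, K)
    if K == 1:
        P = np.ones((data.n_photons, 1, 1))
        eig_parts = None
    else:
        lam, V, W = _eig(model.trans)
        lp = lam[None, :] ** data.gaps.astype(float)[:, None]
        P = np.ascontiguousarray(np.real(np.einsum("ka,na,al->nkl", V, lp, W)))
        P = np.clip(P, 0.0, None)
        P /= np.clip(P.sum(axis=2, keepdims=True), 1e-300, None)
        eig_parts = (lam, V, W, lp)
    return P, b, eig_parts


def h2mm_loglik(model: H2MMModel, data: BurstPhotons) -> float:
    """Scaled-forward log likelihood of the photon data under the model."""
    P, b, _ = _prepare(model, data)
    _, _, c = _fb_kernel(P, b, model.initial.astype(float), data.burst_ptr)
    return float(np.log(np.clip(c, 1e-300, None)).sum())


def _em_step(model: H2MMModel, data: BurstPhotons):
    """One exact Baum-Welch step; returns (new model arrays, logL of input)."""
    K = model.K
    P, b, eig_parts = _prepare(model, data)
    alpha, beta, c = _fb_kernel(P, b, model.initial.astype(float), data.burst_ptr)
    logl = float(np.log(np.clip(c, 1e-300, None)).sum())
    gamma = alpha * beta
    gamma /= np.clip(gamma.sum(axis=1, keepdims=True), 1e-300, None)

    # Emission and initial-distribution updates.
    n_sym = model.n_symbols
    B_new = np.empty((K, n_sym))
    for s_code in range(n_sym):
        B_new[:, s_code] = gamma[data.obs == s_code].sum(axis=0)
    B_new = np.clip(B_new, 1e-12, None)
    B_new /= B_new.sum(axis=1, keepdims=True)
    pi_new = gamma[data.burst_ptr[:-1]].mean(axis=0)
    pi_new = np.clip(pi_new, 1e-12, None)
    pi_new /= pi_new.sum()

    if K == 1:
        return np.ones((1, 1)), B_new, pi_new, logl

    # Expected tick-level transition counts accumulated over each gap.
    lam, V, W, lp = eig_parts
    gaps = data.gaps.astype(float)
    first = data.first_mask
    f = np.roll(alpha, 1, axis=0)  # alpha at previous photon
    g = b * beta / np.clip(c, 1e-300, None)[:, None]
    f[first] = 0.0
    g[first] = 0.0
    p = f @ V  # (N, K) in eigenbasis
    q = g @ W.T
    denom = lam[:, None] - lam[None, :]
    eq = np.abs(denom) < 1e-12
    denom_safe = np.where(eq, 1.0, denom)
    S = (lp[:, :, None] - lp[:, None, :]) / denom_safe[None, :, :]
    lam_pm1 = lam[None, :] ** np.clip(gaps - 1.0, 0.0, None)[:, None]
    S_eq = gaps[:, None, None] * lam_pm1[:, :, None] * np.ones((1, 1, K))
    S = np.where(eq[None, :, :], S_eq, S)
    # Contract the photon axis first: T_ab = sum_n p_na q_nb S_nab.
    T = np.einsum("na,nb,nab->ab", p, q, S)
    xi_core = np.einsum("ai,ab,jb->ij", W, T, V)
    xi = model.trans * np.real(xi_core)
    xi = np.clip(xi, 0.0, None)
    row_sum = xi.sum(axis=1, keepdims=True)
    A_new = xi / np.clip(row_sum, 1e-300, None)
    empty = row_sum.ravel() <= 0  # unvisited states keep a self-loop row
    if empty.any():
        A_new[empty] = np.eye(K)[empty]
    return A_new, B_new, pi_new, logl


def default_init(K: int, n_symbols: int = 2) -> H2MMModel:
    """Spread emission proximity ratios evenly over [0.05, 0.95]; uniform A
    with 1e-4 off-diagonal mass per tick; uniform initial distribution."""
    e_init = np.linspace(0.05, 0.95, K) if K > 1 else np.array([0.5])
    B = np.empty((K, n_symbols))
    aa = 0.45 if n_symbols >= 3 else 0.0  # AA share under 50/50 ALEX duty
    if n_symbols >= 3:
        B[:, AA] = aa
    B[:, DD] = (1 - aa) * (1 - e_init)
    B[:, DA] = (1 - aa) * e_init
    A = np.full((K, K), 1e-4 / max(K - 1, 1))
    np.fill_diagonal(A, 0.0)
    np.fill_diagonal(A, 1.0 - A.sum(axis=1))
    pi = np.full(K, 1.0 / K)
    return H2MMModel(trans=A, emission=B, initial=pi)


def h2mm_em(data: BurstPhotons, K: int, init: H2MMModel | None = None,
            tol: float = 1e-6, max_iter: int = 3600) -> H2MMModel:
    """Baum-Welch adapted for inter-photon matrix powers.

    The log likelihood is non-decreasing across iterations; convergence is
    declared when the per-iteration gain falls below ``tol``.  If the
    iteration cap is reached the model is returned with ``converged=False``.
    """
    if data.n_bursts < 1:
        raise ValueError("need at least one burst")
    model = init if init is not None else default_init(K, data.n_symbols)
    if model.K != K:
        raise ValueError("init model has wrong state count")
    model = H2MMModel(trans=model.trans.copy(), emission=model.emission.copy(),
                      initial=model.initial.copy())
    prev = -np.inf
    logl = prev
    for it in range(max_iter):
        A, B, pi, logl = _em_step(model, data)
        if logl < prev - 1e-6 * max(1.0, abs(prev)):
            warnings.warn("log-likelihood decreased; stopping EM", stacklevel=2)
            break
        improved = logl - prev
        model.trans, model.emission, model.initial = A, B, pi
        if 0 <= improved < tol and it > 0:
            model.converged = True
            model.n_iter = it + 1
            break
        prev = logl
    else:
        model.n_iter = max_iter
    # Score the final parameter set.
    model.log_likelihood = h2mm_loglik(model, data)
    n = data.n_photons
    model.bic = -2.0 * model.log_likelihood + model.n_free_params * np.log(n)
    model.n_photons = n
    model.icl = integrated_complete_likelihood(model, data)
    return model


# ---------------------------------------------------------------------------
# Viterbi, dwells
# ---------------------------------------------------------------------------

@dataclass
class DwellPath:
    states: np.ndarray  # per-photon Viterbi state
    dwells: list  # (burst index, state, start tick offset idx, end idx)
    score: float


def viterbi_dwells(model: H2MMModel, data: BurstPhotons) -> DwellPath:
    """Most probable photon-state sequence (photon-level chain with A**dt
    inter-photon transitions) and its run-length-encoded dwells."""
    P, b, _ = _prepare(model, data)
    logP = np.log(np.clip(P, 1e-300, None))
    logb = np.log(np.clip(b, 1e-300, None))
    logpi = np.log(np.clip(model.initial.astype(float), 1e-300, None))
    path, score = _viterbi_kernel(logP, logb, logpi, data.burst_ptr)
    dwells = []
    for bi in range(data.n_bursts):
        s, e = data.burst_ptr[bi], data.burst_ptr[bi + 1]
        seg = path[s:e]
        change = np.flatnonzero(np.diff(seg)) + 1
        bounds = np.concatenate([[0], change, [seg.size]])
        for a, bnd in zip(bounds[:-1], bounds[1:]):
            dwells.append((bi, int(seg[a]), int(s + a), int(s + bnd)))
    return DwellPath(states=path, dwells=dwells, score=float(score))


def integrated_complete_likelihood(model: H2MMModel, data: BurstPhotons) -> float:
    """ICL-BIC: -2 * (complete-data logL along the Viterbi paths) + p ln n."""
    vp = viterbi_dwells(model, data)
    return -2.0 * vp.score + model.n_free_params * np.log(data.n_photons)


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

def bic_prime(bic_prev: float, bic_curr: float) -> float:
    """Relative BIC improvement of adding one state."""
    return (bic_prev - bic_curr) / abs(bic_prev)


def select_states(models: dict[int, H2MMModel], threshold: float = 0.005,
                  criterion: str = "icl") -> tuple[int, dict]:
    """Pick the state count from a fitted sweep.

    The relative BIC improvement BIC'(K) going from K-1 to K states defines
    how far the sweep needed to run (fit up to n+1 states, n being the last
    count whose addition still improved BIC' by >= ``threshold``); the
    optimal model is the ICL minimiser over the sweep (``criterion='icl'``,
    the default) or the BIC'-elbow count itself (``criterion='bic_prime'``).
    The two usually agree for well-separated states; disagreement is
    reported in the info dict and warned about.
    """
    ks = sorted(models)
    if len(ks) < 2:
        raise ValueError("need models for at least two state counts")
    scores = {k: models[k].bic for k in ks}
    bprimes = {}
    for k_prev, k in zip(ks[:-1], ks[1:]):
        bprimes[k] = bic_prime(scores[k_prev], scores[k])
    k_elbow = ks[-1]
    for k in ks[1:]:
        if bprimes[k] < threshold:
            k_elbow = k - 1
            break
    icl_k = min(ks, key=lambda k: models[k].icl)
    k_star = icl_k if criterion == "icl" else k_elbow
    info = {"bic": scores, "bic_prime": bprimes, "icl_k": icl_k,
            "bic_prime_k": k_elbow, "agreement": icl_k == k_elbow}
    if icl_k != k_elbow:
        warnings.warn(f"ICL selects K={icl_k} but the BIC' elbow is "
                      f"K={k_elbow}", stacklevel=2)
    return k_star, info


def fit_select(data: BurstPhotons, k_max: int = 5, tol: float = 1e-6,
               max_iter: int = 3600, threshold: float = 0.005
               ) -> tuple[int, dict[int, H2MMModel], dict]:
    """Optimise models for K = 1..n+1 and pick K* by the BIC' threshold."""
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    models: dict[int, H2MMModel] = {}
    for K in range(1, k_max + 2):
        models[K] = h2mm_em(data, K, tol=tol, max_iter=max_iter)
        if K >= 2 and bic_prime(models[K - 1].bic, models[K].bic) < threshold:
            break
    k_star, info = select_states(models, threshold)
    return k_star, models, info


# ---------------------------------------------------------------------------
# Profile-likelihood uncertainties
# ---------------------------------------------------------------------------

def _constrained_em(data: BurstPhotons, start: H2MMModel, fix: tuple,
                    tol: float = 1e-5, max_iter: int = 200) -> float:
    """EM with one parameter projected to a fixed value after each M-step.

    ``fix`` is ('E', k, value) for state k's emission proximity ratio, or
    ('A', i, j, value) for a per-tick transition probability.
    Returns the constrained log likelihood.
    """
    model = H2MMModel(trans=start.trans.copy(), emission=start.emission.copy(),
                      initial=start.initial.copy())
    _project(model, fix)
    prev = -np.inf
    for _ in range(max_iter):
        A, B, pi, logl = _em_step(model, data)
        model.trans, model.emission, model.initial = A, B, pi
        _project(model, fix)
        if abs(logl - prev) < tol:
            break
        prev = logl
    return h2mm_loglik(model, data)


def _project(model: H2MMModel, fix: tuple) -> None:
    if fix[0] == "E":
        _, k, value = fix
        p_aa = model.emission[k, AA] if model.n_symbols >= 3 else 0.0
        model.emission[k, DD] = (1.0 - value) * (1.0 - p_aa)
        model.emission[k, DA] = value * (1.0 - p_aa)
    elif fix[0] == "A":
        _, i, j, value = fix
        row = model.trans[i].copy()
        rest = 1.0 - row[j]
        if rest <= 0:
            row[:] = 0.0
        else:
            row *= (1.0 - value) / rest
        row[j] = value
        model.trans[i] = row / row.sum()
    else:
        raise ValueError(f"unknown parameter kind {fix[0]!r}")


def profile_ci(data: BurstPhotons, model: H2MMModel, fix_template: tuple,
               mle_value: float, bounds: tuple[float, float] = (1e-7, 1 - 1e-7),
               drop: float = 0.5) -> tuple[float, float, bool]:
    """One-sigma CI: parameter values where the profile log likelihood falls
    ``drop`` below the optimum.  Returns (lo, hi, bounded); an interval that
    runs into a parameter bound is flagged unbounded on that side."""
    l_max = model.log_likelihood

    def deficit(v):
        return (l_max - _constrained_em(data, model, fix_template + (v,))) - drop

    lo, hi = bounds
    bounded = True

    def search(direction):
        nonlocal bounded
        step = max(1e-4, abs(mle_value) * 0.05)
        x_prev, x = mle_value, mle_value
        for _ in range(60):
            x = x + direction * step
            x = min(max(x, lo), hi)
            d = deficit(x)
            if d > 0:
                return brentq(deficit, min(x_prev, x), max(x_prev, x), xtol=1e-5)
            x_prev = x
            step *= 1.8
            if x in (lo, hi):
                bounded = False
                return x
        bounded = False
        return x

    ci_lo = search(-1.0) if mle_value > lo else lo
    ci_hi = search(+1.0) if mle_value < hi else hi
    return float(ci_lo), float(ci_hi), bounded


def loglik_uncertainty(data: BurstPhotons, model: H2MMModel,
                       which: str = "E") -> dict:
    """Profile-likelihood one-sigma CIs (DeltaLogL = 0.5).

    ``which``: 'E' for the per-state FRET-equivalent emissions, 'A' for
    per-tick transition probabilities, 'all' for both.
    """
    cis: dict = {}
    if which in ("E", "all"):
        e = model.state_e_raw()
        cis["E"] = [profile_ci(data, model, ("E", k), float(e[k]))
                    for k in range(model.K)]
    if which in ("A", "all"):
        cis["A"] = {}
        for i in range(model.K):
            for j in range(model.K):
                if i != j:
                    cis["A"][(i, j)] = profile_ci(
                        data, model, ("A", i, j), float(model.trans[i, j]))
    model.param_cis.update(cis)
    return cis


# ---------------------------------------------------------------------------
# Rates, occupancy, state pruning
# ---------------------------------------------------------------------------

@dataclass
class RateMatrix:
    rates: np.ndarray  # (K, K) s^-1, off-diagonal
    occupancy: np.ndarray
    method: str = "linear"  # 'linear' (A_ij / dt) or 'logm'


def stationary_of(A: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(A.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    if pi.sum() < 0:
        pi = -pi
    pi = np.clip(pi, 0, None)
    return pi / pi.sum()


def rates_and_occupancy(model: H2MMModel, clock_tick_s: float = CLOCK_TICK_S
                        ) -> RateMatrix:
    """Interconversion rate constants k_ij = A_ij / dt (valid for A_ij << 1)
    and the stationary occupancy of A.  When any off-diagonal exceeds 0.01
    per tick the small-rate approximation degrades and the matrix-logarithm
    generator is used instead."""
    A = model.trans
    off = A - np.diag(np.diag(A))
    method = "linear"
    if np.any(off > 0.01):
        warnings.warn("transition probabilities exceed 0.01 per tick; using "
                      "matrix-logarithm generator", stacklevel=2)
        Q = np.real(logm(A)) / clock_tick_s
        rates = np.clip(Q - np.diag(np.diag(Q)), 0.0, None)
        method = "logm"
    else:
        rates = off / clock_tick_s
    return RateMatrix(rates=rates, occupancy=stationary_of(A), method=method)


def max_resolvable_rate(count_rate_per_s: float = 5.0e4,
                        photons_per_dwell: float = 20.0) -> float:
    """Fastest reliably distinguishable transition rate k_max given the
    detected photon rate and the photons needed per state dwell."""
    return count_rate_per_s / photons_per_dwell


def apply_corrections_to_e(e_raw, cf: CorrectionFactors,
                           aa_per_dex: float = 0.0) -> np.ndarray:
    """Accurate-FRET correction of proximity ratios: treats each value as a
    (1-e, e) donor-excitation split with an AA share of ``aa_per_dex``."""
    e_raw = np.asarray(e_raw, dtype=float)
    f_dd, f_da = 1.0 - e_raw, e_raw
    f_aa = aa_per_dex * np.ones_like(e_raw)
    f_acc = f_da - cf.leakage_l * f_dd - cf.direct_excitation_d * f_aa
    den = cf.gamma * f_dd + f_acc
    return np.where(den > 0, f_acc / den, np.nan)


def burst_background_fraction(bursts: list[Burst]) -> tuple[float, float]:
    """(fraction of in-burst donor-excitation photons that are background,
    DA probability of those background photons), from the bursts' expected
    background counts."""
    raw = np.array([b.raw_counts for b in bursts], dtype=float)
    bg = np.array([b.bg_counts for b in bursts], dtype=float)
    bg_dex = bg[:, :2].sum()
    raw_dex = max(raw[:, :2].sum(), 1.0)
    p_da = bg[:, 1].sum() / max(bg_dex, 1e-12)
    return float(min(bg_dex / raw_dex, 0.5)), float(p_da)


def exclude_dark_state(model: H2MMModel, e_open_pred: float,
                       cf: CorrectionFactors | None = None,
                       e_values: np.ndarray | None = None,
                       margin: float = 0.05,
                       occupancy_threshold: float = 0.10,
                       clock_tick_s: float = CLOCK_TICK_S) -> dict:
    """Flag sparsely populated states whose FRET efficiency falls below the
    open-structure prediction minus ``margin`` as acceptor-dark artefacts,
    and report rates/occupancies over the remaining states (renormalised).
    ``e_values`` overrides the per-state efficiencies (e.g. background- and
    distortion-corrected values)."""
    if e_values is not None:
        e = np.asarray(e_values, dtype=float)
    else:
        e = model.state_e_corrected(cf) if cf is not None else model.state_e_raw()
    rm = rates_and_occupancy(model, clock_tick_s)
    dark = (e < e_open_pred - margin) & (rm.occupancy < occupancy_threshold)
    if dark.all():
        raise ValueError("all states flagged dark")
    keep = ~dark
    occ = rm.occupancy[keep]
    return {
        "dark_states": np.flatnonzero(dark).tolist(),
        "kept_states": np.flatnonzero(keep).tolist(),
        "e_values": e[keep],
        "occupancy": occ / occ.sum(),
        "rates": rm.rates[np.ix_(keep, keep)],
    }
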