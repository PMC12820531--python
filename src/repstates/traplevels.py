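"""Offline analysis of long single-molecule (trapped) photon traces.

A trapped molecule yields seconds-long two-channel photon records.  The
pipeline: bin the photons (default 1 ms), identify background bins with an
AIC-optimised K-means clustering of bin brightness, segment the trace into
constant-brightness levels with a Poisson generalised-likelihood-ratio
changepoint test, correct each level's FRET efficiency for donor leakage,
polarisation G factor and emission-filter transmissions, and fit each
level's TCSPC micro-times with an IRF-convolved single-exponential maximum-
likelihood lifetime.  Only levels longer than 30 ms are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2
from sklearn.cluster import KMeans

from .decayfit import DecayHistogram
from .streams import ACCEPTOR_CH, DONOR_CH, PhotonStream


@dataclass
class TrapTrace:
    """Binned two-channel counts plus per-photon bookkeeping."""

    counts: np.ndarray  # (n_bins, 2): donor, acceptor
    bin_width_s: float
    photon_bin: np.ndarray  # bin index of each photon in the source stream
    stream: PhotonStream
    background: np.ndarray | None = None  # per-channel counts/bin

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def corrected(self) -> np.ndarray:
        if self.background is None:
            return self.counts.astype(float)
        return np.clip(self.counts - self.background, 0.0, None)


@dataclass
class Level:
    """A maximal constant-brightness interval between changepoints."""

    start_bin: int  # inclusive
    stop_bin: int  # exclusive
    mean_counts: np.ndarray  # per-channel background-subtracted counts/bin
    duration_s: float = 0.0
    E: float = np.nan
    tau_ns: float = np.nan
    tau_flagged: bool = False

    @property
    def n_bins(self) -> int:
        return self.stop_bin - self.start_bin


@dataclass(frozen=True)
class TrapCorrections:
    donor_leakage: float = 0.0
    g_factor: float = 1.0  # parallel/perpendicular detection ratio
    transmission_donor: float = 0.71  # emission-filter transmission
    transmission_acceptor: float = 0.55

    def __post_init__(self) -> None:
        if not (0 < self.transmission_donor <= 1 and 0 < self.transmission_acceptor <= 1):
            raise ValueError("transmissions must be in (0, 1]")
        if self.g_factor <= 0:
            raise ValueError("G factor must be > 0")


def bin_trace(stream: PhotonStream, bin_width_s: float = 1e-3) -> TrapTrace:
    from .streams import CLOCK_TICK_S
    bin_ticks = max(1, int(round(bin_width_s / CLOCK_TICK_S)))
    n_bins = int(np.ceil(stream.duration / bin_ticks))
    pb = (stream.timestamps // bin_ticks).astype(np.int64)
    counts = np.zeros((n_bins, 2), dtype=np.int64)
    for ch in (DONOR_CH, ACCEPTOR_CH):
        np.add.at(counts[:, ch], pb[stream.channels == ch], 1)
    return TrapTrace(counts=counts, bin_width_s=bin_ticks * CLOCK_TICK_S,
                     photon_bin=pb, stream=stream)


def identify_background(trace: TrapTrace, k_max: int = 5, seed: int = 0
                        ) -> np.ndarray:
    """AIC-optimised K-means over bin brightness; the lowest-mean cluster is
    background and its per-channel mean is subtracted from every bin.

    Returns the per-channel background (counts/bin); also stored on the
    trace.  If one cluster wins, the global minimum-decile mean is used
    (with a warning) — a constant trace has no resolvable background.
    """
    if trace.n_bins < 100:
        raise ValueError("need >= 100 bins")
    x = trace.total.astype(float)[:, None]
    best_k, best_aic, best_labels, best_centers = 1, np.inf, None, None
    for k in range(1, k_max + 1):
        if k == 1:
            mu = np.array([[x.mean()]])
            labels = np.zeros(x.size, dtype=int)
            var = max(x.var(), 1e-6)
            logl = -0.5 * x.size * (np.log(2 * np.pi * var) + 1.0)
        else:
            km = KMeans(n_clusters=k, n_init=5, random_state=seed).fit(x)
            labels, mu = km.labels_, km.cluster_centers_
            # Proper soft-mixture likelihood at the k-means parameters: a
            # hard-assignment score would always reward splitting noise.
            w = np.bincount(labels, minlength=k) / x.size
            sig = np.array([max(x[labels == c, 0].std(), 1e-3) for c in range(k)])
            comp = w * np.exp(-0.5 * ((x - mu[:, 0]) / sig) ** 2) \
                / (sig * np.sqrt(2 * np.pi))
            logl = float(np.log(np.clip(comp.sum(axis=1), 1e-300, None)).sum())
        aic = 2 * (3 * k - 1) - 2 * logl
        if aic < best_aic:
            best_k, best_aic = k, aic
            best_labels, best_centers = labels, mu
    if best_k == 1:
        warnings.warn("single brightness cluster; background set to the "
                      "trace mean", stacklevel=2)
        bg_mask = np.ones(trace.n_bins, dtype=bool)
    else:
        bg_cluster = int(np.argmin(best_centers[:, 0]))
        bg_mask = best_labels == bg_cluster
    bg = trace.counts[bg_mask].mean(axis=0)
    trace.background = bg
    return bg


def _poisson_loglik(counts_sum: float, n: int) -> float:
    if n == 0 or counts_sum == 0:
        return 0.0
    lam = counts_sum / n
    return counts_sum * np.log(lam) - n * lam


def _best_split(x: np.ndarray) -> tuple[int, float]:
    """Best Poisson-GLR split of a (n_bins, n_channels) counts array.

    The statistic sums the per-channel GLRs, so both brightness steps and
    pure FRET steps (anticorrelated channel changes at constant total) are
    detected.  Returns (index, statistic); df = n_channels under the null.
    """
    n, n_ch = x.shape
    idx = np.arange(1, n)
    glr = np.zeros(n - 1)
    for ch in range(n_ch):
        csum = np.cumsum(x[:, ch])
        total = csum[-1]
        left = csum[:-1]
        right = total - left
        # log-likelihoods at the MLE rates (data-factorial terms cancel)
        ll_left = np.where(left > 0, left * np.log(np.clip(left / idx, 1e-300, None)), 0.0) - left
        nr = n - idx
        ll_right = np.where(right > 0, right * np.log(np.clip(right / nr, 1e-300, None)), 0.0) - right
        ll_full = (total * np.log(np.clip(total / n, 1e-300, None)) if total > 0 else 0.0) - total
        glr += 2.0 * (ll_left + ll_right - ll_full)
    i = int(np.argmax(glr))
    return int(idx[i]), float(glr[i])


def changepoint_segment(trace: TrapTrace, alpha: float = 0.05,
                        min_level_bins: int = 2) -> list[Level]:
    """Recursive binary segmentation of per-channel bin counts with a
    Poisson GLR test (Bonferroni-corrected over candidate split positions),
    followed by a merge pass for adjacent levels with indistinguishable
    per-channel means."""
    x = trace.counts.astype(float)
    n, n_ch = x.shape
    boundaries = [0, n]

    def recurse(a: int, b: int) -> None:
        if b - a < 2 * min_level_bins:
            return
        seg = x[a:b]
        split, stat = _best_split(seg)
        n_cand = max(seg.shape[0] - 1, 1)
        crit = chi2.ppf(1.0 - alpha / n_cand, df=n_ch)
        if stat > crit and min_level_bins <= split <= seg.shape[0] - min_level_bins:
            boundaries.append(a + split)
            recurse(a, a + split)
            recurse(a + split, b)

    recurse(0, n)
    boundaries = sorted(set(boundaries))

    # Merge pass: adjacent levels whose pooled GLR is insignificant.
    merged = True
    while merged and len(boundaries) > 2:
        merged = False
        for i in range(1, len(boundaries) - 1):
            a, m, b = boundaries[i - 1], boundaries[i], boundaries[i + 1]
            stat = 0.0
            for ch in range(n_ch):
                l1 = _poisson_loglik(x[a:m, ch].sum(), m - a)
                l2 = _poisson_loglik(x[m:b, ch].sum(), b - m)
                l0 = _poisson_loglik(x[a:b, ch].sum(), b - a)
                stat += 2.0 * (l1 + l2 - l0)
            if stat < chi2.ppf(1.0 - alpha, df=n_ch):
                boundaries.pop(i)
                merged = True
                break

    corrected = trace.corrected()
    levels = []
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        levels.append(Level(start_bin=a, stop_bin=b,
                            mean_counts=corrected[a:b].mean(axis=0),
                            duration_s=(b - a) * trace.bin_width_s))
    return levels


def level_fret(level: Level, corrections: TrapCorrections) -> float:
    """Corrected level FRET: leakage removed, channels divided by their
    emission-filter transmissions; E = A' / (A' + D').

    (Polarisation channels are assumed already collapsed with the G factor;
    the stored per-channel means are the G-weighted sums.)"""
    d_raw, a_raw = level.mean_counts
    a_lk = a_raw - corrections.donor_leakage * d_raw
    if a_lk < 0:
        a_lk = 0.0
        level.tau_flagged = level.tau_flagged or False
    d = d_raw / corrections.transmission_donor
    a = a_lk / corrections.transmission_acceptor
    if d + a <= 0:
        level.E = np.nan
        return np.nan
    level.E = a / (d + a)
    return level.E


def combine_polarisations(parallel: np.ndarray, perpendicular: np.ndarray,
                          g_factor: float) -> np.ndarray:
    """Collapse parallel/perpendicular detection into one intensity,
    I = I_par + G * I_perp (anisotropy itself is out of scope here)."""
    return parallel + g_factor * perpendicular


def level_lifetime(delays_ns: np.ndarray, irf: DecayHistogram,
                   tau_bounds: tuple[float, float] = (0.05, 20.0)) -> tuple[float, bool]:
    """IRF-convolved single-exponential MLE lifetime of a level's photon
    micro-times; periodic wrap over the TCSPC window.  Returns (tau, at
    boundary flag)."""
    delays_ns = np.asarray(delays_ns, float)
    delays_ns = delays_ns[np.isfinite(delays_ns)]
    if delays_ns.size < 100:
        raise ValueError("need >= 100 photons in a level for a lifetime fit")
    edges = irf.bin_edges
    nb = edges.size - 1
    dt = irf.dt
    counts, _ = np.histogram(np.mod(delays_ns, irf.period_ns), bins=edges)
    irf_p = irf.irf_counts / max(irf.irf_counts.sum(), 1e-300)
    t = irf.bin_centers - edges[0]

    from .decayfit import wrapped_exp_kernel

    def nll(tau):
        decay = wrapped_exp_kernel(tau, dt, nb, irf.period_ns)
        model = np.real(np.fft.ifft(np.fft.fft(irf_p, nb) * np.fft.fft(decay, nb)))
        model = np.clip(model, 1e-300, None)
        model /= model.sum()
        return -float(np.dot(counts, np.log(model)))

    res = minimize_scalar(nll, bounds=tau_bounds, method="bounded",
                          options={"xatol": 1e-4})
    tau = float(res.x)
    at_bound = tau <= tau_bounds[0] * 1.02 or tau >= tau_bounds[1] * 0.98
    if at_bound:
        warnings.warn("lifetime optimum at the fit boundary", stacklevel=2)
    return tau, at_bound


def filter_levels(levels: list[Level], min_duration_s: float = 30e-3) -> list[Level]:
    """Keep levels strictly longer than ``min_duration_s`` (default 30 ms)."""
    return [lv for lv in levels if lv.duration_s > min_duration_s]


def analyse_trap_trace(stream: PhotonStream, corrections: TrapCorrections,
                       irf: DecayHistogram | None = None,
                       bin_width_s: float = 1e-3, alpha: float = 0.05,
                       min_duration_s: float = 30e-3,
                       min_photons_lifetime: int = 100) -> list[Level]:
    """Full offline pipeline: bin, background, changepoints, E and tau per
    retained level."""
    trace = bin_trace(stream, bin_width_s)
    identify_background(trace)
    levels = changepoint_segment(trace, alpha=alpha)
    levels = filter_levels(levels, min_duration_s)
    for lv in levels:
        level_fret(lv, corrections)
        if irf is not None and stream.microtimes is not None:
            in_level = ((trace.photon_bin >= lv.start_bin)
                        & (trace.photon_bin < lv.stop_bin)
                        & (stream.channels == DONOR_CH))
            delays = stream.microtimes[in_level]
            delays = delays[np.isfinite(delays)]
            if delays.size >= min_photons_lifetime:
                lv.tau_ns, lv.tau_flagged = level_lifetime(delays, irf)
    return levels
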