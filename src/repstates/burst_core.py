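"""Background estimation, burst search, FRET/stoichiometry correction, and
population filtering for diffusing-molecule ALEX data.

Background is fitted per 5-minute segment as the maximum-likelihood rate of
an exponential tail of the interphoton-delay distribution (delays shorter
than ``min_delay`` — dominated by molecule transits — are ignored; by
memorylessness the truncated fit stays unbiased).  Bursts are maximal runs
of photons whose local rate over a sliding window of m photons exceeds
F times the background rate; the dual-channel variant demands the criterion
in the donor-excitation and acceptor-excitation streams independently,
which rejects singly-labelled transits.

Counts are corrected with the standard accurate-FRET factors: leakage l,
direct excitation d, detection factor gamma, excitation factor beta:

    F_acc  = F_DA - l*F_DD - d*F_AA
    E_corr = F_acc / (gamma*F_DD + F_acc)
    S_corr = (gamma*F_DD + F_acc) / (gamma*F_DD + F_acc + F_AA/beta)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .streams import AA, CLOCK_TICK_S, DA, DD, PhotonStream


@dataclass(frozen=True)
class CorrectionFactors:
    leakage_l: float = 0.0
    direct_excitation_d: float = 0.0
    gamma: float = 1.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.leakage_l < 0 or self.direct_excitation_d < 0:
            raise ValueError("l and d must be >= 0")
        if self.gamma <= 0 or self.beta <= 0:
            raise ValueError("gamma and beta must be > 0")


@dataclass
class BackgroundModel:
    """Per-segment, per-stream background rates (counts/s)."""

    segment_edges_s: np.ndarray  # len n_seg+1, tiling the acquisition
    rates: dict[int, np.ndarray]  # stream code -> rate per segment
    total: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.total is None:
            self.total = sum(self.rates.values())

    @property
    def n_segments(self) -> int:
        return len(self.segment_edges_s) - 1

    def segment_of(self, ticks: np.ndarray) -> np.ndarray:
        s = np.searchsorted(self.segment_edges_s, np.asarray(ticks) * CLOCK_TICK_S,
                            side="right") - 1
        return np.clip(s, 0, self.n_segments - 1)

    def rate_at(self, stream: int | str, ticks: np.ndarray) -> np.ndarray:
        key = stream if isinstance(stream, int) else {"DD": DD, "DA": DA, "AA": AA,
                                                      "total": -1}[stream]
        arr = self.total if key == -1 else self.rates[key]
        return arr[self.segment_of(ticks)]


@dataclass
class Burst:
    """One detected single-molecule transit."""

    start: int  # tick, inclusive
    stop: int  # tick, exclusive
    raw_counts: tuple[int, int, int]  # (DD, DA, AA) photons inside
    counts: tuple[float, float, float]  # background-subtracted, floored at 0
    bg_counts: tuple[float, float, float] = (0.0, 0.0, 0.0)  # expected background
    E_raw: float = np.nan
    S_raw: float = np.nan
    E_corr: float = np.nan
    S_corr: float = np.nan
    valid: bool = True
    photon_index: np.ndarray | None = None  # indices into the parent stream

    @property
    def size(self) -> int:
        return int(sum(self.raw_counts))

    @property
    def duration_s(self) -> float:
        return (self.stop - self.start) * CLOCK_TICK_S


def _truncated_exponential_rate(delays_s: np.ndarray, min_delay_s: float) -> tuple[float, int]:
    kept = delays_s[delays_s > min_delay_s]
    if kept.size == 0:
        return np.nan, 0
    return 1.0 / float(np.mean(kept - min_delay_s)), kept.size


def estimate_background(stream: PhotonStream, segment_length_s: float = 300.0,
                        min_delay_s: float | None = None) -> BackgroundModel:
    """MLE exponential fit to interphoton delays, per stream and segment.

    ``min_delay_s`` defaults to 10x the mean interphoton delay of the whole
    record (crude total rate), which pushes the fit onto the background-
    dominated tail; segments with fewer than 10 retained delays inherit the
    previous segment's rate (warning).
    """
    if len(stream) == 0:
        raise ValueError("empty photon stream")
    T = stream.duration_s
    if min_delay_s is None:
        crude = len(stream) / T
        min_delay_s = 10.0 / crude
    n_seg = max(1, int(np.ceil(T / segment_length_s)))
    edges = np.minimum(np.arange(n_seg + 1) * segment_length_s, T)
    edges[-1] = T
    labels = stream.streams
    t_s = stream.timestamps * CLOCK_TICK_S
    rates: dict[int, np.ndarray] = {}
    for code in (DD, DA, AA):
        tt = t_s[labels == code]
        out = np.empty(n_seg)
        prev = np.nan
        for i in range(n_seg):
            seg = tt[(tt >= edges[i]) & (tt < edges[i + 1])]
            rate, n_kept = _truncated_exponential_rate(np.diff(seg), min_delay_s)
            if n_kept < 10:
                if np.isnan(prev):
                    # First segment: fall back to the crude segment rate.
                    rate = seg.size / max(edges[i + 1] - edges[i], 1e-12)
                    warnings.warn(f"segment {i}: <10 retained delays; using crude rate",
                                  stacklevel=2)
                else:
                    rate = prev
                    warnings.warn(f"segment {i}: <10 retained delays; inheriting "
                                  "previous segment", stacklevel=2)
            out[i] = rate
            prev = rate
        rates[code] = out
    return BackgroundModel(segment_edges_s=edges, rates=rates)


def _sliding_inburst_mask(t: np.ndarray, rate_threshold: np.ndarray, m: int) -> np.ndarray:
    """Mark photons belonging to any m-photon window whose local rate
    m / (t[i+m-1] - t[i]) exceeds the per-photon threshold (counts/s)."""
    n = t.size
    mask = np.zeros(n, dtype=bool)
    if n < m:
        return mask
    span = (t[m - 1:] - t[: n - m + 1]) * CLOCK_TICK_S
    ok = m / np.maximum(span, CLOCK_TICK_S) > rate_threshold[: n - m + 1]
    # A qualifying window marks all m of its photons (ties resolved toward
    # inclusion: bursts extend to the last photon satisfying the criterion).
    idx = np.flatnonzero(ok)
    delta = np.zeros(n + 1, dtype=np.int64)
    np.add.at(delta, idx, 1)
    np.add.at(delta, idx + m, -1)
    mask = np.cumsum(delta[:-1]) > 0
    return mask


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask.size and mask[0]:
        starts = [0] + starts
    if mask.size and mask[-1]:
        ends = ends + [mask.size]
    return list(zip(starts, ends))


def _make_burst(stream: PhotonStream, background: BackgroundModel,
                idx: np.ndarray) -> Burst:
    labels = stream.streams[idx]
    t0, t1 = int(stream.timestamps[idx[0]]), int(stream.timestamps[idx[-1]]) + 1
    raw = tuple(int(np.sum(labels == c)) for c in (DD, DA, AA))
    dur = (t1 - t0) * CLOCK_TICK_S
    mid = np.array([t0])
    # Expected background inside a photon-delimited interval: rate*duration
    # plus one extra count (inspection paradox of photon-bounded windows),
    # shared across streams in proportion to their background rates.
    rates = np.array([float(background.rate_at(c, mid)[0]) for c in (DD, DA, AA)])
    tot = max(rates.sum(), 1e-12)
    bg = tuple(r * dur + r / tot for r in rates)
    # Background subtraction per stream, floored at 0.
    counts = tuple(max(r - b, 0.0) for r, b in zip(raw, bg))
    f_dd, f_da, f_aa = counts
    tot_dex = f_dd + f_da
    e_raw = f_da / tot_dex if tot_dex > 0 else np.nan
    s_raw = tot_dex / (tot_dex + f_aa) if tot_dex + f_aa > 0 else np.nan
    return Burst(start=t0, stop=t1, raw_counts=raw, counts=counts, bg_counts=bg,
                 E_raw=e_raw, S_raw=s_raw, photon_index=idx)


def all_photon_burst_search(stream: PhotonStream, background: BackgroundModel,
                            F: float = 6.0, m: int = 10,
                            min_size: int = 50) -> list[Burst]:
    """All-photon burst search: local rate over m consecutive photons must
    exceed F times the total background rate; runs with >= min_size photons
    become bursts."""
    if F <= 1:
        raise ValueError("F must exceed 1 (threshold below background)")
    labels = stream.streams
    sel = np.flatnonzero(labels != 3)  # DD/DA/AA photons only
    t = stream.timestamps[sel]
    thr = F * background.rate_at("total", t)
    mask = _sliding_inburst_mask(t, thr, m)
    bursts = []
    for a, b in _runs(mask):
        if b - a >= min_size:
            bursts.append(_make_burst(stream, background, sel[a:b]))
    return bursts


def dual_channel_burst_search(stream: PhotonStream, background: BackgroundModel,
                              F: float = 6.0, m: int = 10,
                              min_per_channel: int = 50) -> list[Burst]:
    """Dual-channel burst search: the rate criterion must hold simultaneously
    in the donor-excitation (DD+DA) and acceptor-excitation (AA) streams,
    and a burst needs >= min_per_channel photons in each — this retains only
    doubly-labelled transits."""
    if F <= 1:
        raise ValueError("F must exceed 1 (threshold below background)")
    labels = stream.streams
    sel_dex = np.flatnonzero((labels == DD) | (labels == DA))
    sel_aex = np.flatnonzero(labels == AA)
    t_dex = stream.timestamps[sel_dex]
    t_aex = stream.timestamps[sel_aex]
    bg_dex = background.rate_at(DD, t_dex) + background.rate_at(DA, t_dex)
    bg_aex = background.rate_at(AA, t_aex)
    mask_dex = _sliding_inburst_mask(t_dex, F * bg_dex, m)
    mask_aex = _sliding_inburst_mask(t_aex, F * bg_aex, m)
    spans_dex = [(t_dex[a], t_dex[b - 1]) for a, b in _runs(mask_dex)]
    spans_aex = [(t_aex[a], t_aex[b - 1]) for a, b in _runs(mask_aex)]
    spans = _intersect_spans(spans_dex, spans_aex)
    sel_all = np.flatnonzero(labels != 3)
    t_all = stream.timestamps[sel_all]
    bursts = []
    for lo, hi in spans:
        a, b = np.searchsorted(t_all, [lo, hi + 1])
        idx = sel_all[a:b]
        if idx.size == 0:
            continue
        burst = _make_burst(stream, background, idx)
        n_dex = burst.raw_counts[0] + burst.raw_counts[1]
        n_aex = burst.raw_counts[2]
        if n_dex >= min_per_channel and n_aex >= min_per_channel:
            bursts.append(burst)
    return bursts


def _intersect_spans(a: list[tuple[int, int]], b: list[tuple[int, int]]):
    out, i, j = [], 0, 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo <= hi:
            out.append((lo, hi))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def correct_e_s(burst: Burst, cf: CorrectionFactors) -> tuple[float, float]:
    """Accurate FRET efficiency and stoichiometry from background-subtracted
    counts; flags the burst invalid when a denominator is not positive."""
    f_dd, f_da, f_aa = burst.counts
    f_acc = f_da - cf.leakage_l * f_dd - cf.direct_excitation_d * f_aa
    den_e = cf.gamma * f_dd + f_acc
    den_s = den_e + f_aa / cf.beta
    if den_e <= 0 or den_s <= 0:
        burst.valid = False
        burst.E_corr, burst.S_corr = np.nan, np.nan
        return np.nan, np.nan
    burst.E_corr = f_acc / den_e
    burst.S_corr = den_e / den_s
    return burst.E_corr, burst.S_corr


def apply_corrections(bursts: list[Burst], cf: CorrectionFactors) -> list[Burst]:
    for b in bursts:
        correct_e_s(b, cf)
    return bursts


def derive_corrections(bursts: list[Burst], background: BackgroundModel | None = None,
                       s_donor_only: float = 0.9,
                       s_acceptor_only: float = 0.15,
                       s_fret_range: tuple[float, float] = (0.3, 0.8),
                       k_max_populations: int = 5) -> CorrectionFactors:
    """Estimate (l, d, gamma, beta) from the burst populations themselves.

    l comes from the pooled raw E of the donor-only population (S_raw ~ 1,
    guarded against doubly-labelled contaminants by an absolute AA-count
    ceiling) and d from the pooled raw S of the acceptor-only population
    (S_raw ~ 0, DD-count guarded).  gamma and beta come from the linear
    relation 1/S = Omega + Sigma*E across FRET populations after leakage/
    direct-excitation correction: beta = Omega + Sigma - 1, gamma =
    (Omega - 1)/(Omega + Sigma - 1).  Populations are identified by a
    BIC-selected 1-D Gaussian mixture over burst E and each population's
    coordinates are computed from its summed photon counts — per-burst
    regression is avoided because the shared-denominator shot noise of
    (E, 1/S) is correlated and tilts a naive line fit.
    """
    e_raw = np.array([b.E_raw for b in bursts])
    s_raw = np.array([b.S_raw for b in bursts])
    raw = np.array([b.raw_counts for b in bursts], dtype=float)
    # Unfloored subtraction: pooled calibration sums must stay unbiased even
    # when a stream's per-burst signal is comparable to its background.
    f = raw - np.array([b.bg_counts for b in bursts], dtype=float)
    dur = np.array([b.duration_s for b in bursts])
    ok = np.isfinite(e_raw) & np.isfinite(s_raw)

    # Absolute contamination guards: a genuinely singly-labelled burst has
    # only background counts in the missing channel.
    if background is not None:
        t0 = np.array([b.start for b in bursts])
        exp_aa = background.rate_at(AA, t0) * dur
        exp_dd = background.rate_at(DD, t0) * dur
    else:
        exp_aa = np.full(len(bursts), 1.0)
        exp_dd = np.full(len(bursts), 1.0)
    aa_ceiling = exp_aa + 4.0 * np.sqrt(np.clip(exp_aa, 1.0, None)) + 2.0
    dd_ceiling = exp_dd + 4.0 * np.sqrt(np.clip(exp_dd, 1.0, None)) + 2.0

    donly = ok & (s_raw > s_donor_only) & (raw[:, 2] <= aa_ceiling)
    aonly = ok & (s_raw < s_acceptor_only) & (raw[:, 0] <= dd_ceiling)
    if donly.sum() < 5 or aonly.sum() < 5:
        raise ValueError("need donor-only and acceptor-only populations "
                         "(>=5 bursts each) to derive corrections")
    e_do = float(f[donly, 1].sum() / (f[donly, 0].sum() + f[donly, 1].sum()))
    s_ao = float((f[aonly, 0] + f[aonly, 1]).sum()
                 / (f[aonly, 0] + f[aonly, 1] + f[aonly, 2]).sum())
    l = e_do / (1.0 - e_do)
    d = s_ao / (1.0 - s_ao)

    fret = ok & (s_raw >= s_fret_range[0]) & (s_raw <= s_fret_range[1])
    f_acc = f[:, 1] - l * f[:, 0] - d * f[:, 2]
    den = f[:, 0] + f_acc
    usable = fret & (den > 0)
    E_ld = f_acc[usable] / den[usable]
    if E_ld.size < 20 or np.std(E_ld) < 0.05:
        warnings.warn("fewer than two FRET populations resolvable; "
                      "returning gamma = beta = 1", stacklevel=2)
        return CorrectionFactors(l, d, 1.0, 1.0)

    from sklearn.mixture import GaussianMixture
    best, best_bic = None, np.inf
    for K in range(2, k_max_populations + 1):
        if E_ld.size < 10 * K:
            break
        gm = GaussianMixture(K, random_state=0, n_init=3).fit(E_ld[:, None])
        if gm.bic(E_ld[:, None]) < best_bic:
            best, best_bic = gm, gm.bic(E_ld[:, None])
    labels = best.predict(E_ld[:, None])
    xs, ys, ws = [], [], []
    fu, f_accu = f[usable], f_acc[usable]
    for k in range(best.n_components):
        m = labels == k
        if m.sum() < 5:
            continue
        D = fu[m, 0].sum() + f_accu[m].sum()
        if D <= 0:
            continue
        xs.append(f_accu[m].sum() / D)
        ys.append((D + fu[m, 2].sum()) / D)
        ws.append(D)
    if len(xs) < 2:
        warnings.warn("fewer than two FRET populations resolvable; "
                      "returning gamma = beta = 1", stacklevel=2)
        return CorrectionFactors(l, d, 1.0, 1.0)
    slope, intercept = np.polyfit(xs, ys, 1, w=np.sqrt(ws))
    beta = intercept + slope - 1.0
    gamma = (intercept - 1.0) / (intercept + slope - 1.0)
    if beta <= 0 or gamma <= 0:
        warnings.warn("gamma/beta fit degenerate; returning 1", stacklevel=2)
        return CorrectionFactors(l, d, 1.0, 1.0)
    return CorrectionFactors(l, d, float(gamma), float(beta))


def filter_population(bursts: list[Burst], s_range: tuple[float, float] = (0.2, 0.8),
                      min_AA: int = 50, min_size: int = 50) -> list[Burst]:
    """Keep doubly-labelled FRET bursts: AA photons >= min_AA, total size >=
    min_size, corrected stoichiometry inside s_range.  Order preserved."""
    out = []
    for b in bursts:
        if not b.valid or not np.isfinite(b.S_corr):
            continue
        if b.raw_counts[2] >= min_AA and b.size >= min_size \
                and s_range[0] <= b.S_corr <= s_range[1]:
            out.append(b)
    return out


def bursts_to_frame(bursts: list[Burst]) -> pd.DataFrame:
    """Burst table with documented column names (CSV/Parquet friendly)."""
    return pd.DataFrame({
        "start_tick": [b.start for b in bursts],
        "stop_tick": [b.stop for b in bursts],
        "duration_ms": [b.duration_s * 1e3 for b in bursts],
        "n_dd": [b.raw_counts[0] for b in bursts],
        "n_da": [b.raw_counts[1] for b in bursts],
        "n_aa": [b.raw_counts[2] for b in bursts],
        "f_dd": [b.counts[0] for b in bursts],
        "f_da": [b.counts[1] for b in bursts],
        "f_aa": [b.counts[2] for b in bursts],
        "e_raw": [b.E_raw for b in bursts],
        "s_raw": [b.S_raw for b in bursts],
        "e_corr": [b.E_corr for b in bursts],
        "s_corr": [b.S_corr for b in bursts],
        "valid": [b.valid for b in bursts],
    })
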