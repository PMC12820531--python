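"""Synthetic ALEX photon streams, trapped-molecule traces, and TCSPC decays.

Every downstream stage of the pipeline is testable against this generator's
stored ground truth.  Diffusion bursts are modelled as rate gates: a burst is
an exponential-length interval (mean ~1 ms) during which the molecule emits
at its in-burst brightness, separated by background-only gaps (mean ~50 ms,
the ~pM occupancy regime).  Within a burst the conformational state follows
Gillespie sampling of the fixture's rate matrix, and photons are placed as
Poisson arrivals whose channel split encodes the state's FRET efficiency
plus the fixture's leakage / direct-excitation / gamma / beta distortions.

The emission split is constructed by inverting the burst-correction
formulas, so that fully corrected E equals the state's nominal efficiency
and corrected S is exactly 0.5 for doubly-labelled molecules; this makes the
distortion/correction round trip exactly testable.  Acceptor-excitation
(AA) photons are generated at a state-independent rate — stoichiometry is a
labelling property, not a conformational one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .decayfit import DecayHistogram
from .fixtures import Fixture
from .streams import (ACCEPTOR_CH, CLOCK_TICK_S, DONOR_CH, ALEXScheme,
                      PhotonStream)

SPECIES_DA, SPECIES_DONOR_ONLY, SPECIES_ACCEPTOR_ONLY = 0, 1, 2


def _stream_rates(e: float, N: float, l: float, d: float, gamma: float, beta: float,
                  species: int) -> tuple[float, float, float]:
    """Instantaneous in-window detected rates (DD, DA, AA) for one state.

    N is the donor-excitation signal rate; the split inverts the accurate-
    correction formulas so corrected (E, S) come out at (e, 0.5).
    """
    r_aa = beta * gamma * N
    if species == SPECIES_DONOR_ONLY:
        return N, l * N, 0.0
    if species == SPECIES_ACCEPTOR_ONLY:
        return 0.0, d * r_aa, r_aa
    r_dd = N * (1.0 - e)
    r_da = N * gamma * e + l * r_dd + d * r_aa
    return r_dd, r_da, r_aa


def _poisson_times(rng: np.random.Generator, rate_per_s: float, t0: int, t1: int) -> np.ndarray:
    """Homogeneous Poisson arrival ticks in [t0, t1)."""
    if rate_per_s <= 0 or t1 <= t0:
        return np.empty(0, dtype=np.int64)
    mean = rate_per_s * (t1 - t0) * CLOCK_TICK_S
    n = rng.poisson(mean)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    return t0 + (rng.random(n) * (t1 - t0)).astype(np.int64)


def _phase_mask(alex: ALEXScheme, t: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    ph = t % alex.cycle
    return (ph >= window[0]) & (ph < window[1])


def simulate_burst_stream(
    fixture: Fixture,
    n_bursts: int,
    seed: int,
    alex: ALEXScheme | None = None,
    species_fractions: tuple[float, float, float] = (1.0, 0.0, 0.0),
) -> PhotonStream:
    """Simulate a diffusing-molecule ALEX acquisition with known truth.

    ``species_fractions`` gives the probability that a transit is doubly
    labelled, donor-only, or acceptor-only (the experiment's labelling is
    far from complete, which is what the stoichiometry filter exploits).

    Ground truth (per photon): hidden state (-1 for background), burst id,
    species; plus burst intervals and the Gillespie dwell list.
    """
    if n_bursts < 1:
        raise ValueError("n_bursts must be >= 1")
    alex = alex or ALEXScheme()
    rng = np.random.default_rng(seed)
    st = fixture.states
    dp = fixture.distortions
    duty = alex.donor_duty + alex.acceptor_duty
    pi0 = (st.initial_distribution if st.initial_distribution is not None
           else st.stationary())
    sf = np.asarray(species_fractions, dtype=float)
    sf = sf / sf.sum()

    ts_parts, ch_parts = [], []
    state_parts, burst_parts, species_parts = [], [], []
    bursts_truth, dwell_truth = [], []

    tick = 0
    for b in range(n_bursts):
        tick += max(1, int(rng.exponential(fixture.mean_gap_s) / CLOCK_TICK_S))
        dur = max(1, int(rng.exponential(fixture.mean_burst_duration_s) / CLOCK_TICK_S))
        start, stop = tick, tick + dur
        species = int(rng.choice(3, p=sf))
        # Gillespie trajectory over the burst (single 'state 0' for singly
        # labelled transits — their photon split does not depend on it).
        segs: list[tuple[int, int, int]] = []
        if species == SPECIES_DA:
            s = int(rng.choice(st.n_states, p=pi0))
            t0 = start
            while t0 < stop:
                exit_rate = -st.rate_matrix[s, s]
                if exit_rate <= 0:
                    t1 = stop
                else:
                    t1 = min(stop, t0 + max(1, int(rng.exponential(1.0 / exit_rate) / CLOCK_TICK_S)))
                segs.append((s, t0, t1))
                if t1 < stop:
                    p = st.rate_matrix[s].copy()
                    p[s] = 0.0
                    p /= p.sum()
                    s = int(rng.choice(st.n_states, p=p))
                t0 = t1
        else:
            segs.append((0, start, stop))

        for s, t0, t1 in segs:
            e = st.e_values[s]
            N = st.brightness[s] / duty
            r_dd, r_da, r_aa = _stream_rates(e, N, dp.leakage_l, dp.direct_excitation_d,
                                             dp.gamma, dp.beta, species)
            # Donor-excitation photons: generated over the dwell, thinned to
            # donor windows (lasers gate the fluorescence).
            t_dex = _poisson_times(rng, r_dd + r_da, t0, t1)
            t_dex = t_dex[_phase_mask(alex, t_dex, alex.donor_window)]
            ch_dex = np.where(rng.random(t_dex.size) < (r_da / max(r_dd + r_da, 1e-300)),
                              ACCEPTOR_CH, DONOR_CH).astype(np.uint8)
            t_aex = _poisson_times(rng, r_aa, t0, t1)
            t_aex = t_aex[_phase_mask(alex, t_aex, alex.acceptor_window)]
            n_new = t_dex.size + t_aex.size
            ts_parts += [t_dex, t_aex]
            ch_parts += [ch_dex, np.full(t_aex.size, ACCEPTOR_CH, dtype=np.uint8)]
            state_parts.append(np.full(n_new, s if species == SPECIES_DA else -1, dtype=np.int8))
            burst_parts.append(np.full(n_new, b, dtype=np.int32))
            species_parts.append(np.full(n_new, species, dtype=np.int8))
            if species == SPECIES_DA:
                dwell_truth.append((b, s, t0, t1))
        bursts_truth.append({"start": start, "stop": stop, "species": species})
        tick = stop
    duration = tick + max(1, int(rng.exponential(fixture.mean_gap_s) / CLOCK_TICK_S))

    # Background photons over the whole record, per stream, confined to the
    # stream's excitation window (off-window background lands in OFF).
    bg_dd, bg_da, bg_aa = dp.background_rates
    t_bg_dd = _poisson_times(rng, bg_dd / alex.donor_duty, 0, duration)
    t_bg_dd = t_bg_dd[_phase_mask(alex, t_bg_dd, alex.donor_window)]
    t_bg_da = _poisson_times(rng, bg_da / alex.donor_duty, 0, duration)
    t_bg_da = t_bg_da[_phase_mask(alex, t_bg_da, alex.donor_window)]
    t_bg_aa = _poisson_times(rng, bg_aa / alex.acceptor_duty, 0, duration)
    t_bg_aa = t_bg_aa[_phase_mask(alex, t_bg_aa, alex.acceptor_window)]
    # Off-window dark counts at the same instantaneous channel rates.
    off_duty = 1.0 - duty
    t_off_d = _poisson_times(rng, bg_dd / alex.donor_duty * off_duty, 0, duration)
    t_off_d = t_off_d[~(_phase_mask(alex, t_off_d, alex.donor_window)
                        | _phase_mask(alex, t_off_d, alex.acceptor_window))]
    n_bg = t_bg_dd.size + t_bg_da.size + t_bg_aa.size + t_off_d.size
    ts_parts += [t_bg_dd, t_bg_da, t_bg_aa, t_off_d]
    ch_parts += [np.full(t_bg_dd.size, DONOR_CH, np.uint8),
                 np.full(t_bg_da.size, ACCEPTOR_CH, np.uint8),
                 np.full(t_bg_aa.size, ACCEPTOR_CH, np.uint8),
                 np.full(t_off_d.size, DONOR_CH, np.uint8)]
    state_parts.append(np.full(n_bg, -1, dtype=np.int8))
    burst_parts.append(np.full(n_bg, -1, dtype=np.int32))
    species_parts.append(np.full(n_bg, -1, dtype=np.int8))

    t = np.concatenate(ts_parts)
    ch = np.concatenate(ch_parts)
    state = np.concatenate(state_parts)
    burst_id = np.concatenate(burst_parts)
    species_arr = np.concatenate(species_parts)
    n_burst_photons = int(np.sum(burst_id >= 0))

    t, ch, state, burst_id, species_arr, n_shifted = _sort_resolve(
        t, ch, state, burst_id, species_arr)
    if t.size and n_shifted / t.size > 1e-3:
        warnings.warn(f"{n_shifted} of {t.size} photons shifted to resolve "
                      "timestamp collisions (>0.1%)", stacklevel=2)

    truth = {
        "state": state,
        "burst_id": burst_id,
        "species": species_arr,
        "bursts": bursts_truth,
        "dwells": dwell_truth,
        "n_burst_photons": n_burst_photons,
        "n_background_photons": int(n_bg),
        "n_collisions_shifted": int(n_shifted),
    }
    return PhotonStream(timestamps=t, channels=ch, alex=alex, duration=duration,
                        ground_truth=truth)


def _sort_resolve(t, *arrays):
    """Jointly sort photon arrays by time and push timestamp collisions to
    the next free tick (stable, preserving arrival order of collided photons)."""
    order = np.argsort(t, kind="stable")
    t = t[order]
    arrays = [a[order] for a in arrays]
    n_shifted = 0
    while True:
        dup = np.flatnonzero(np.diff(t) <= 0) + 1
        if dup.size == 0:
            break
        t[dup] = t[dup - 1] + 1
        n_shifted += dup.size
        order = np.argsort(t, kind="stable")
        t = t[order]
        arrays = [a[order] for a in arrays]
    return (t, *arrays, n_shifted)


# ---------------------------------------------------------------------------
# Trapped-molecule traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LevelSpec:
    """One constant-brightness level of a trapped-molecule trace."""

    duration_s: float
    rate_donor: float  # counts/s
    rate_acceptor: float  # counts/s
    tau_ns: float | None = None  # donor lifetime for micro-time generation


def simulate_trap_trace(
    level_spec: list[LevelSpec],
    background: float,
    seed: int,
    tcspc_period_ns: float = 16.7,
    irf_sigma_ns: float = 0.0,
) -> PhotonStream:
    """Piecewise-constant Poisson photon record with exact level boundaries
    stored as ground truth.  ``background`` (counts/s) is split equally
    between the two channels.  Donor-channel photons carry TCSPC micro-times
    drawn from the level's exponential lifetime (optionally blurred by a
    Gaussian IRF), wrapped into the excitation period."""
    if not level_spec:
        raise ValueError("empty level specification")
    if any(lv.duration_s <= 0 for lv in level_spec):
        raise ValueError("level durations must be > 0")
    rng = np.random.default_rng(seed)
    ts, chs, mts, levels = [], [], [], []
    boundaries_s = [0.0]
    tick = 0
    for i, lv in enumerate(level_spec):
        dur = max(1, int(lv.duration_s / CLOCK_TICK_S))
        for ch, rate in ((DONOR_CH, lv.rate_donor + background / 2),
                         (ACCEPTOR_CH, lv.rate_acceptor + background / 2)):
            tt = _poisson_times(rng, rate, tick, tick + dur)
            ts.append(tt)
            chs.append(np.full(tt.size, ch, np.uint8))
            if ch == DONOR_CH:
                tau = lv.tau_ns if lv.tau_ns is not None else 2.0
                mt = rng.exponential(tau, tt.size)
                if irf_sigma_ns > 0:
                    mt += rng.normal(0.0, irf_sigma_ns, tt.size)
                mts.append(np.mod(mt, tcspc_period_ns))
            else:
                mts.append(np.full(tt.size, np.nan))
            levels.append(np.full(tt.size, i, np.int16))
        tick += dur
        boundaries_s.append(tick * CLOCK_TICK_S)
    t = np.concatenate(ts)
    ch = np.concatenate(chs)
    mt = np.concatenate(mts)
    lvl = np.concatenate(levels)
    t, ch, mt, lvl, _ = _sort_resolve(t, ch, mt, lvl)
    truth = {
        "boundaries_s": boundaries_s,
        "level_of_photon": lvl,
        "levels": [{"duration_s": lv.duration_s, "rate_donor": lv.rate_donor,
                    "rate_acceptor": lv.rate_acceptor, "tau_ns": lv.tau_ns}
                   for lv in level_spec],
    }
    return PhotonStream(timestamps=t, channels=ch, duration=tick,
                        microtimes=mt, ground_truth=truth)


# ---------------------------------------------------------------------------
# TCSPC decays
# ---------------------------------------------------------------------------

def delta_irf(n_bins: int = 512, period_ns: float = 50.0) -> DecayHistogram:
    """An idealised instantaneous IRF on a uniform grid (testing aid)."""
    edges = np.linspace(0.0, period_ns, n_bins + 1)
    irf = np.zeros(n_bins)
    irf[0] = 1.0
    return DecayHistogram(bin_edges=edges, counts=np.zeros(n_bins),
                          irf_counts=irf, period_ns=period_ns)


def gaussian_irf(sigma_ns: float, center_ns: float = 2.0, n_bins: int = 512,
                 period_ns: float = 50.0) -> DecayHistogram:
    edges = np.linspace(0.0, period_ns, n_bins + 1)
    c = 0.5 * (edges[:-1] + edges[1:])
    irf = np.exp(-0.5 * ((c - center_ns) / sigma_ns) ** 2)
    return DecayHistogram(bin_edges=edges, counts=np.zeros(n_bins),
                          irf_counts=irf, period_ns=period_ns)


def simulate_decay(components: list[tuple[float, float]], irf: DecayHistogram,
                   n_photons: int, seed: int) -> DecayHistogram:
    """Draw photon delays from a mixture of exponentials, add an IRF-distributed
    offset, wrap into the excitation period, and histogram on the IRF grid."""
    alphas = np.array([a for a, _ in components], dtype=float)
    taus = np.array([tau for _, tau in components], dtype=float)
    if alphas.sum() <= 0:
        raise ValueError("total amplitude must be > 0")
    if np.any(taus <= 0):
        raise ValueError("lifetimes must be > 0")
    irf_sum = irf.irf_counts.sum()
    if irf_sum <= 0:
        raise ValueError("IRF is not normalisable")
    rng = np.random.default_rng(seed)
    p = alphas / alphas.sum()
    comp = rng.choice(len(p), size=n_photons, p=p)
    delays = rng.exponential(taus[comp])
    # IRF offset: sample a bin by weight, uniform within the bin.
    bins = rng.choice(irf.irf_counts.size, size=n_photons, p=irf.irf_counts / irf_sum)
    offset = irf.bin_edges[bins] + rng.random(n_photons) * irf.dt
    t = np.mod(delays + offset, irf.period_ns)
    counts, _ = np.histogram(t, bins=irf.bin_edges)
    return DecayHistogram(bin_edges=irf.bin_edges, counts=counts.astype(float),
                          irf_counts=irf.irf_counts, period_ns=irf.period_ns)
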