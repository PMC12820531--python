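"""Photon streams and the alternating-laser-excitation (ALEX) timing scheme.

A confocal ALEX measurement interleaves donor and acceptor excitation on a
microsecond cycle.  Each detected photon carries an integer timestamp (one
tick = 10 ns by default) and a detector channel; combining the channel with
the excitation phase of ``timestamp mod cycle`` yields the canonical photon
streams:

* ``DD`` — donor excitation, donor detector
* ``DA`` — donor excitation, acceptor detector (FRET-sensitised)
* ``AA`` — acceptor excitation, acceptor detector (stoichiometry probe)

Photons falling in laser-off windows, or on the donor detector during
acceptor excitation, carry no FRET information and are labelled ``OFF``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

CLOCK_TICK_S = 1e-8  # 10 ns timestamp resolution

# Stream codes (kept small so they can live in a uint8 array).
DD, DA, AA, OFF = 0, 1, 2, 3
STREAM_NAMES = {DD: "DD", DA: "DA", AA: "AA", OFF: "OFF"}

DONOR_CH, ACCEPTOR_CH = 0, 1


@dataclass(frozen=True)
class ALEXScheme:
    """Timing of one excitation cycle, in clock ticks.

    The default mirrors a nominal 100 µs cycle: 45 µs donor excitation,
    5 µs off, 45 µs acceptor excitation, 5 µs off.
    """

    cycle: int = 10_000  # ticks (100 µs at 10 ns/tick)
    donor_window: tuple[int, int] = (0, 4_500)
    acceptor_window: tuple[int, int] = (5_000, 9_500)

    def __post_init__(self) -> None:
        d0, d1 = self.donor_window
        a0, a1 = self.acceptor_window
        if not (0 <= d0 < d1 <= self.cycle and 0 <= a0 < a1 <= self.cycle):
            raise ValueError("excitation windows must lie inside the cycle")
        if max(d0, a0) < min(d1, a1):
            raise ValueError("donor and acceptor windows overlap")

    @property
    def donor_duty(self) -> float:
        return (self.donor_window[1] - self.donor_window[0]) / self.cycle

    @property
    def acceptor_duty(self) -> float:
        return (self.acceptor_window[1] - self.acceptor_window[0]) / self.cycle

    def phase(self, timestamps: np.ndarray) -> np.ndarray:
        return np.asarray(timestamps) % self.cycle

    def stream_labels(self, timestamps: np.ndarray, channels: np.ndarray) -> np.ndarray:
        """Derive DD/DA/AA/OFF labels from timestamps and detector channels."""
        ph = self.phase(timestamps)
        in_d = (ph >= self.donor_window[0]) & (ph < self.donor_window[1])
        in_a = (ph >= self.acceptor_window[0]) & (ph < self.acceptor_window[1])
        ch = np.asarray(channels)
        out = np.full(ph.shape, OFF, dtype=np.uint8)
        out[in_d & (ch == DONOR_CH)] = DD
        out[in_d & (ch == ACCEPTOR_CH)] = DA
        out[in_a & (ch == ACCEPTOR_CH)] = AA
        return out


@dataclass
class PhotonStream:
    """Time-stamped, channel-labelled photon record for one acquisition.

    ``ground_truth`` (optional, simulation only) may hold per-photon hidden
    state labels, burst intervals, species labels, or level boundaries —
    whatever the generator knows that an instrument would not.
    """

    timestamps: np.ndarray  # int64 ticks, strictly increasing
    channels: np.ndarray  # uint8, DONOR_CH / ACCEPTOR_CH
    alex: ALEXScheme = field(default_factory=ALEXScheme)
    duration: int = 0  # total ticks in the record
    microtimes: np.ndarray | None = None  # TCSPC micro-times (ns), if recorded
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.channels = np.asarray(self.channels, dtype=np.uint8)
        if self.timestamps.size and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.duration == 0 and self.timestamps.size:
            self.duration = int(self.timestamps[-1]) + 1

    def __len__(self) -> int:
        return self.timestamps.size

    @property
    def duration_s(self) -> float:
        return self.duration * CLOCK_TICK_S

    @property
    def streams(self) -> np.ndarray:
        """Per-photon DD/DA/AA/OFF labels (derived, cached)."""
        if not hasattr(self, "_streams"):
            self._streams = self.alex.stream_labels(self.timestamps, self.channels)
        return self._streams

    def select(self, mask: np.ndarray) -> "PhotonStream":
        """Photon subset (keeps the full-record duration and scheme)."""
        sub = PhotonStream(
            timestamps=self.timestamps[mask],
            channels=self.channels[mask],
            alex=self.alex,
            duration=self.duration,
            microtimes=None if self.microtimes is None else self.microtimes[mask],
        )
        return sub


def resolve_collisions(timestamps: np.ndarray) -> tuple[np.ndarray, int]:
    """Make sorted timestamps strictly increasing by shifting collided photons
    to the next free tick.  Returns (fixed timestamps, number shifted)."""
    t = np.asarray(timestamps, dtype=np.int64).copy()
    shifted = 0
    # Iterate: each pass pushes duplicates forward by one tick.
    while True:
        dup = np.flatnonzero(np.diff(t) <= 0) + 1
        if dup.size == 0:
            break
        t[dup] = t[dup - 1] + 1
        shifted += dup.size
        t.sort(kind="stable")
    return t, shifted


# ---------------------------------------------------------------------------
# Photon-HDF5-style persistence (subset of the format's field layout)
# ---------------------------------------------------------------------------

def write_photon_h5(path: str | Path, stream: PhotonStream) -> None:
    """Write a Photon-HDF5-conformant subset plus a ground-truth sidecar JSON."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        pd_grp = f.create_group("photon_data")
        pd_grp.create_dataset("timestamps", data=stream.timestamps)
        pd_grp.create_dataset("detectors", data=stream.channels)
        if stream.microtimes is not None:
            pd_grp.create_dataset("nanotimes", data=stream.microtimes)
        ms = pd_grp.create_group("measurement_specs")
        ms.attrs["measurement_type"] = "smFRET-usALEX"
        ms.create_dataset("alex_period", data=stream.alex.cycle)
        ms.create_dataset("alex_excitation_period1", data=np.array(stream.alex.donor_window))
        ms.create_dataset("alex_excitation_period2", data=np.array(stream.alex.acceptor_window))
        f.create_dataset("acquisition_duration", data=stream.duration * CLOCK_TICK_S)
        f.attrs["timestamps_unit"] = CLOCK_TICK_S
        f.attrs["duration_ticks"] = stream.duration
    if stream.ground_truth is not None:
        sidecar = path.with_suffix(path.suffix + ".truth.json")
        sidecar.write_text(json.dumps(_jsonable(stream.ground_truth)))


def read_photon_h5(path: str | Path) -> PhotonStream:
    path = Path(path)
    with h5py.File(path, "r") as f:
        ts = f["photon_data/timestamps"][:]
        det = f["photon_data/detectors"][:]
        nanot = None
        if "nanotimes" in f["photon_data"]:
            nanot = f["photon_data/nanotimes"][:]
        ms = f["photon_data/measurement_specs"]
        alex = ALEXScheme(
            cycle=int(ms["alex_period"][()]),
            donor_window=tuple(int(x) for x in ms["alex_excitation_period1"][:]),
            acceptor_window=tuple(int(x) for x in ms["alex_excitation_period2"][:]),
        )
        duration = int(f.attrs["duration_ticks"])
    truth = None
    sidecar = path.with_suffix(path.suffix + ".truth.json")
    if sidecar.exists():
        truth = json.loads(sidecar.read_text())
    return PhotonStream(timestamps=ts, channels=det, alex=alex, duration=duration,
                        microtimes=nanot, ground_truth=truth)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
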