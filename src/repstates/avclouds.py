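"""Accessible-volume (AV) dye modelling on structure coordinates.

A fluorophore tethered to a residue by a flexible linker explores the set
of positions reachable without steric clash.  The dye is modelled as a
sphere of radius r whose centre is connected to the attachment atom by a
linker of given length and width; a grid point is accessible if (i) a
clash-free path of clearance >= width/2 leads from the attachment atom
(flood-fill geodesic over the grid, path length <= linker length) and
(ii) the dye sphere itself does not clash with any structure heavy atom.
Following the AV3 convention this is repeated for three dye radii and the
clouds are pooled with equal weight.

Distances between the mean dye positions (Rmp) and Monte-Carlo averaged
FRET efficiencies <E> = <1 / (1 + (r/R0)^6)> over position pairs sampled
from the two clouds predict the measurable FRET observables for a given
structure.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

# Bondi-style van der Waals radii for common heavy elements (Angstrom).
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
             "H": 1.20, "SE": 1.90, "FE": 1.80, "ZN": 1.39, "MG": 1.73}
DEFAULT_VDW = 1.70


@dataclass(frozen=True)
class DyeParams:
    """Dye/linker geometry (AV3): all lengths in Angstrom."""

    linker_length: float = 20.5
    linker_width: float = 4.5
    dye_radii: tuple[float, float, float] = (9.5, 3.0, 1.5)
    r0: float = 70.0  # Foerster radius of the dye pair
    grid_spacing: float = 1.0

    def __post_init__(self) -> None:
        if min(self.linker_length, self.linker_width, self.r0,
               self.grid_spacing, *self.dye_radii) <= 0:
            raise ValueError("all dye parameters must be > 0")


@dataclass
class Structure:
    """Heavy-atom coordinates with chain/residue/atom addressing."""

    coords: np.ndarray  # (n, 3) Angstrom
    elements: np.ndarray  # str
    chain_ids: np.ndarray
    res_ids: np.ndarray  # 1-based PDB residue numbering
    atom_names: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([VDW_RADII.get(str(e).upper(), DEFAULT_VDW)
                         for e in self.elements])

    def atom_index(self, chain: str, res_id: int, atom_name: str) -> int:
        hit = np.flatnonzero((self.chain_ids == chain) & (self.res_ids == res_id)
                             & (self.atom_names == atom_name))
        if hit.size == 0:
            raise KeyError(f"attachment atom {chain}:{res_id}:{atom_name} "
                           "not found in structure")
        return int(hit[0])

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Structure":
        c = self.coords
        if rotation is not None:
            c = c @ np.asarray(rotation).T
        if translation is not None:
            c = c + np.asarray(translation)
        return Structure(c, self.elements, self.chain_ids, self.res_ids,
                         self.atom_names)


def read_structure(path: str) -> Structure:
    """Parse a PDB file into heavy-atom coordinates (hydrogens dropped,
    highest-occupancy alternate conformers kept)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1, altloc="occupancy")
    heavy = atoms[atoms.element != "H"]
    return Structure(
        coords=np.asarray(heavy.coord, dtype=float),
        elements=np.asarray(heavy.element),
        chain_ids=np.asarray(heavy.chain_id),
        res_ids=np.asarray(heavy.res_id),
        atom_names=np.asarray(heavy.atom_name),
    )


@dataclass
class AVCloud:
    """Clash-free dye positions around one attachment atom."""

    attachment: np.ndarray  # (3,)
    positions: np.ndarray  # (n, 3)
    weights: np.ndarray  # per-position
    grid_spacing: float

    def __post_init__(self) -> None:
        if self.positions.shape[0] == 0:
            raise ValueError("empty accessible volume (buried attachment?)")
        self.weights = np.asarray(self.weights, float)
        self.weights = self.weights / self.weights.sum()

    @property
    def mean_position(self) -> np.ndarray:
        return (self.positions * self.weights[:, None]).sum(axis=0)

    def translated(self, shift) -> "AVCloud":
        return AVCloud(self.attachment + np.asarray(shift),
                       self.positions + np.asarray(shift),
                       self.weights.copy(), self.grid_spacing)


def compute_av(structure: Structure, attachment: tuple[str, int, str] | int,
               dye: DyeParams) -> AVCloud:
    """Grid flood fill of dye positions reachable from the attachment atom.

    ``attachment`` is (chain, residue id, atom name) or a direct atom index.
    The attachment atom itself is excluded from the obstacle set (the linker
    is bonded to it).
    """
    if isinstance(attachment, tuple):
        ai = structure.atom_index(*attachment)
    else:
        ai = int(attachment)
    origin = structure.coords[ai]
    obstacles = np.delete(structure.coords, ai, axis=0)
    radii = np.delete(structure.radii, ai)

    L = dye.linker_length
    h = dye.grid_spacing
    max_r = max(dye.dye_radii)
    half = int(np.ceil(L / h)) + 1
    axis = np.arange(-half, half + 1) * h
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3) + origin
    shape = (axis.size,) * 3

    # Clearance: distance to the nearest obstacle surface.
    clearance = np.full(pts.shape[0], np.inf)
    if obstacles.shape[0]:
        tree = cKDTree(obstacles)
        reach = float(radii.max() + max(max_r, dye.linker_width / 2) + 2 * h)
        pairs = tree.query_ball_point(pts, r=reach, workers=-1)
        for i, nb in enumerate(pairs):
            if nb:
                d = np.linalg.norm(obstacles[nb] - pts[i], axis=1) - radii[nb]
                clearance[i] = d.min()
    clearance = clearance.reshape(shape)

    geod = _grid_geodesic(clearance >= dye.linker_width / 2.0, shape, h,
                          start=(half, half, half))
    reachable = geod <= L

    flat_clear = clearance.ravel()
    flat_reach = reachable.ravel()
    weight = np.zeros(pts.shape[0])
    for r in dye.dye_radii:
        weight += (flat_reach & (flat_clear >= r)).astype(float)
    sel = weight > 0
    return AVCloud(attachment=origin, positions=pts[sel], weights=weight[sel],
                   grid_spacing=h)


def _grid_geodesic(free: np.ndarray, shape: tuple[int, int, int], h: float,
                   start: tuple[int, int, int]) -> np.ndarray:
    """Dijkstra path lengths over the free-cell grid (26-connectivity with
    metric step costs), seeded at the attachment cell.  The seed connects to
    its immediate neighbourhood even if the seed cell itself is blocked (the
    linker starts at a bonded atom inside the structure surface)."""
    nx, ny, nz = shape
    dist = np.full(shape, np.inf)
    steps = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
             for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)]
    costs = [h * np.sqrt(dx * dx + dy * dy + dz * dz) for dx, dy, dz in steps]
    sx, sy, sz = start
    heap: list[tuple[float, int, int, int]] = []
    # Seed: the attachment cell at distance 0 regardless of clearance.
    dist[sx, sy, sz] = 0.0
    heapq.heappush(heap, (0.0, sx, sy, sz))
    while heap:
        d, x, y, z = heapq.heappop(heap)
        if d > dist[x, y, z]:
            continue
        for (dx, dy, dz), c in zip(steps, costs):
            x2, y2, z2 = x + dx, y + dy, z + dz
            if not (0 <= x2 < nx and 0 <= y2 < ny and 0 <= z2 < nz):
                continue
            if not free[x2, y2, z2]:
                continue
            nd = d + c
            if nd < dist[x2, y2, z2]:
                dist[x2, y2, z2] = nd
                heapq.heappush(heap, (nd, x2, y2, z2))
    return dist


def rmp(a: AVCloud, b: AVCloud) -> float:
    """Distance between the mean dye positions of two accessible volumes."""
    return float(np.linalg.norm(a.mean_position - b.mean_position))


def av_fret_efficiency(a: AVCloud, b: AVCloud, r0: float,
                       n_samples: int = 1_000_000, seed: int = 0) -> float:
    """<E> over position pairs sampled independently from the two clouds:
    E(r) = 1 / (1 + (r/R0)^6)."""
    if r0 <= 0:
        raise ValueError("R0 must be > 0")
    rng = np.random.default_rng(seed)
    ia = rng.choice(a.positions.shape[0], size=n_samples, p=a.weights)
    ib = rng.choice(b.positions.shape[0], size=n_samples, p=b.weights)
    r = np.linalg.norm(a.positions[ia] - b.positions[ib], axis=1)
    e = 1.0 / (1.0 + (r / r0) ** 6)
    return float(e.mean())


def state_agreement(e_predictions, mixture) -> float:
    """Fraction of predicted efficiencies lying within one sigma of their
    nearest identified FRET state."""
    e = np.asarray(e_predictions, float)
    mu = np.asarray(mixture.means, float)
    sig = np.asarray(mixture.sigmas, float)
    nearest = np.argmin(np.abs(e[:, None] - mu[None, :]), axis=1)
    within = np.abs(e - mu[nearest]) <= sig[nearest]
    return float(within.mean())
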