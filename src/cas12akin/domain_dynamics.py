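"""Inter-domain geometry from coordinate trajectories.

Single-molecule FRET and simulation work associate target-strand cleavage
by Cas12a with an inward "clamping" motion that closes the gap between the
REC2 and Nuc domains.  This module quantifies that motion from multi-model
PDB trajectories: the per-frame mass-weighted centre-of-mass (COM)
separation of two residue-range selections, the per-frame count of
inter-domain heavy-atom contacts (pair distance < 3.5 Å), the residue
pairs ranked by contact occupancy, and Gaussian kernel-density summaries
of any per-frame series.

Residue numbering is taken verbatim from the input file (1-based,
inclusive ranges); built-in REC2/Nuc ranges are provided for the three
commonly compared orthologues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.spatial import cKDTree
from scipy.stats import gaussian_kde

import biotite.structure as struc
import biotite.structure.io.pdb as pdb
from biotite.structure.info import mass as element_mass

__all__ = [
    "Trajectory",
    "DomainSelection",
    "BUILTIN_DOMAINS",
    "SeriesSummary",
    "com_distance",
    "contact_count",
    "contact_residues",
    "kde_summary",
]

#: Heavy-atom contact cutoff in Å (strict less-than).
CONTACT_CUTOFF_A = 3.5

#: REC2 and Nuc residue ranges (1-based, inclusive) per orthologue.
BUILTIN_DOMAINS = {
    "FnCas12a": {"REC2": (340, 591), "Nuc": (1079, 1254)},
    "LbCas12a": {"REC2": (283, 521), "Nuc": (998, 1179)},
    "AsCas12a": {"REC2": (321, 526), "Nuc": (1067, 1262)},
}


@dataclass(frozen=True)
class DomainSelection:
    """Named inclusive residue-range selection, e.g. REC2 (340-591)."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.name}: start {self.start} > end {self.end}")

    @classmethod
    def builtin(cls, orthologue: str, domain: str) -> "DomainSelection":
        try:
            start, end = BUILTIN_DOMAINS[orthologue][domain]
        except KeyError:
            raise KeyError(
                f"unknown orthologue/domain {orthologue!r}/{domain!r}; "
                f"built-ins: {sorted(BUILTIN_DOMAINS)}"
            ) from None
        return cls(name=f"{orthologue}:{domain}", start=start, end=end)


class Trajectory:
    """Fixed-roster coordinate trajectory.

    Thin wrapper around per-atom metadata arrays and an
    ``(n_frames, n_atoms, 3)`` coordinate block, with multi-model PDB I/O.
    """

    def __init__(self, coords, res_id, element, atom_name=None, chain_id=None):
        self.coords = np.asarray(coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        n_atoms = self.coords.shape[1]
        self.res_id = np.asarray(res_id, dtype=int)
        self.element = np.asarray(element, dtype="U2")
        if self.res_id.shape != (n_atoms,) or self.element.shape != (n_atoms,):
            raise ValueError("per-atom arrays must match the atom count")
        self.atom_name = (
            np.asarray(atom_name, dtype="U4")
            if atom_name is not None
            else np.array(["CA"] * n_atoms, dtype="U4")
        )
        self.chain_id = (
            np.asarray(chain_id, dtype="U4")
            if chain_id is not None
            else np.array(["A"] * n_atoms, dtype="U4")
        )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def masses(self) -> np.ndarray:
        return np.array([element_mass(e) for e in self.element], dtype=float)

    def select(self, sel: DomainSelection) -> np.ndarray:
        """Atom indices whose residue id lies in the inclusive range."""
        idx = np.flatnonzero((self.res_id >= sel.start) & (self.res_id <= sel.end))
        if idx.size == 0:
            raise ValueError(
                f"selection {sel.name!r} ({sel.start}-{sel.end}) matches no atoms"
            )
        return idx

    @classmethod
    def from_pdb(cls, path) -> "Trajectory":
        """Read a multi-model PDB (MODEL/ENDMDL records per frame).

        The element column is used when present, falling back to the first
        alphabetic character of the atom name.
        """
        stack = pdb.PDBFile.read(str(path)).get_structure(model=None)
        element = np.array(
            [
                e if e else _element_from_name(n)
                for e, n in zip(stack.element, stack.atom_name)
            ],
            dtype="U2",
        )
        return cls(
            coords=stack.coord,
            res_id=stack.res_id,
            element=element,
            atom_name=stack.atom_name,
            chain_id=stack.chain_id,
        )

    def to_pdb(self, path) -> None:
        n = self.n_atoms
        arr = struc.AtomArray(n)
        arr.res_id = self.res_id
        arr.res_name = np.array(["GLY"] * n)
        arr.atom_name = self.atom_name
        arr.element = np.char.upper(self.element)
        arr.chain_id = self.chain_id
        frames = []
        for k in range(self.n_frames):
            frame = arr.copy()
            frame.coord = self.coords[k]
            frames.append(frame)
        f = pdb.PDBFile()
        f.set_structure(struc.stack(frames))
        f.write(str(path))


def _element_from_name(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def _check_pair(traj: Trajectory, a: DomainSelection, b: DomainSelection):
    ia, ib = traj.select(a), traj.select(b)
    if np.intersect1d(ia, ib).size:
        raise ValueError(f"selections {a.name!r} and {b.name!r} overlap")
    return ia, ib


def com_distance(
    traj: Trajectory,
    a: DomainSelection,
    b: DomainSelection,
    mass_weighted: bool = True,
) -> np.ndarray:
    """Per-frame Euclidean distance between the two selections' COMs (Å).

    The centre of mass is weighted by standard atomic masses over *all*
    atoms of the selection (hydrogens included when present); pass
    ``mass_weighted=False`` for the geometric centroid as a sensitivity
    check.
    """
    ia, ib = _check_pair(traj, a, b)
    if mass_weighted:
        m = traj.masses
        wa, wb = m[ia], m[ib]
    else:
        wa = np.ones(ia.size)
        wb = np.ones(ib.size)
    com_a = np.einsum("fij,i->fj", traj.coords[:, ia], wa) / wa.sum()
    com_b = np.einsum("fij,i->fj", traj.coords[:, ib], wb) / wb.sum()
    return np.linalg.norm(com_a - com_b, axis=1)


def _heavy(traj: Trajectory, idx: np.ndarray) -> np.ndarray:
    return idx[np.char.upper(traj.element[idx]) != "H"]


def _contact_pairs_frame(xa, xb, cutoff):
    """Index pairs (into xa, xb) closer than cutoff, via KD-tree."""
    tree = cKDTree(xb)
    pairs = []
    for i, neigh in enumerate(tree.query_ball_point(xa, cutoff)):
        for j in neigh:
            if np.linalg.norm(xa[i] - xb[j]) < cutoff:  # strict <
                pairs.append((i, j))
    return pairs


def contact_count(
    traj: Trajectory,
    a: DomainSelection,
    b: DomainSelection,
    cutoff: float = CONTACT_CUTOFF_A,
    unit: str = "atom_pairs",
) -> np.ndarray:
    """Per-frame count of inter-domain heavy-atom contacts.

    A contact is a pair (one heavy atom from each selection) at distance
    strictly below ``cutoff``.  ``unit="residue_pairs"`` instead counts
    distinct residue pairs with at least one qualifying atom pair.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if unit not in ("atom_pairs", "residue_pairs"):
        raise ValueError(f"unknown contact unit {unit!r}")
    ia, ib = _check_pair(traj, a, b)
    ia, ib = _heavy(traj, ia), _heavy(traj, ib)
    counts = np.zeros(traj.n_frames, dtype=int)
    for k in range(traj.n_frames):
        pairs = _contact_pairs_frame(traj.coords[k, ia], traj.coords[k, ib], cutoff)
        if unit == "atom_pairs":
            counts[k] = len(pairs)
        else:
            res_pairs = {(traj.res_id[ia[i]], traj.res_id[ib[j]]) for i, j in pairs}
            counts[k] = len(res_pairs)
    return counts


def contact_residues(
    traj: Trajectory,
    a: DomainSelection,
    b: DomainSelection,
    cutoff: float = CONTACT_CUTOFF_A,
) -> pd.DataFrame:
    """Residue pairs in contact, ranked by per-frame occupancy.

    Returns columns ``res_a, res_b, occupancy`` sorted by occupancy
    descending, then residue numbers ascending.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ia, ib = _check_pair(traj, a, b)
    ia, ib = _heavy(traj, ia), _heavy(traj, ib)
    hits: dict[tuple, int] = {}
    for k in range(traj.n_frames):
        pairs = _contact_pairs_frame(traj.coords[k, ia], traj.coords[k, ib], cutoff)
        for rp in {(traj.res_id[ia[i]], traj.res_id[ib[j]]) for i, j in pairs}:
            hits[rp] = hits.get(rp, 0) + 1
    rows = [
        {"res_a": ra, "res_b": rb, "occupancy": n / traj.n_frames}
        for (ra, rb), n in hits.items()
    ]
    df = pd.DataFrame(rows, columns=["res_a", "res_b", "occupancy"])
    return df.sort_values(
        ["occupancy", "res_a", "res_b"], ascending=[False, True, True]
    ).reset_index(drop=True)


@dataclass
class SeriesSummary:
    """Gaussian-KDE summary of a per-frame series (distances or contacts)."""

    grid: np.ndarray
    density: np.ndarray
    mode: float
    modes: list = field(default_factory=list)
    bandwidth: float = float("nan")
    degenerate: bool = False

    @property
    def multimodal(self) -> bool:
        return len(self.modes) > 1


def kde_summary(series, bandwidth="auto", grid_size: int = 512) -> SeriesSummary:
    """Kernel-density summary of a per-frame series.

    Gaussian kernels with Scott's-rule bandwidth (or a fixed value),
    evaluated on a ``grid_size``-point grid spanning [min-3h, max+3h].
    The mode is the grid argmax; secondary local maxima above 50% of the
    main peak are reported as additional modes.  A zero-variance series
    returns a degenerate point-mass summary.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 10:
        raise ValueError(f"need >= 10 values for a KDE summary, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if np.ptp(x) == 0:
        v = float(x[0])
        return SeriesSummary(
            grid=np.array([v]),
            density=np.array([np.inf]),
            mode=v,
            modes=[v],
            degenerate=True,
        )
    kde = gaussian_kde(x, bw_method="scott" if bandwidth == "auto" else None)
    if bandwidth != "auto":
        kde.set_bandwidth(float(bandwidth) / x.std(ddof=1))
    h = float(kde.factor * x.std(ddof=1))
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, grid_size)
    density = kde(grid)
    main = int(np.argmax(density))
    peaks, _ = find_peaks(density, height=0.5 * density[main])
    modes = sorted(float(grid[p]) for p in set(peaks) | {main})
    return SeriesSummary(
        grid=grid,
        density=density,
        mode=float(grid[main]),
        modes=modes,
        bandwidth=h,
    )
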