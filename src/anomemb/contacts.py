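"""Coordinate-level protein-lipid contact analytics.

A lipid molecule is counted as contacting the protein when any of its
particles lies strictly within the cutoff distance of any protein particle
under orthorhombic minimum-image convention (0.7 nm is the conventional
cutoff for coarse-grained particles, 0.4 nm for atomistic).  Binding to
the bilayer is declared when the protein/bilayer COM distance drops below
4 length units, and the first 100 time units after each binding event are
discarded as non-equilibrium.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "FrameCoordinates",
    "ContactSeries",
    "count_contacts",
    "count_contacts_bruteforce",
    "contact_series",
    "residue_contact_profile",
    "com_distance_series",
    "detect_binding",
]


@dataclass
class FrameCoordinates:
    """One frame: protein particles grouped by residue, lipid particles
    grouped by molecule and species, orthorhombic box."""

    protein_xyz: np.ndarray
    residue_ids: np.ndarray
    lipid_xyz: np.ndarray
    lipid_mol_ids: np.ndarray
    lipid_species: np.ndarray
    box: np.ndarray
    time: float = 0.0
    protein_masses: np.ndarray | None = None
    lipid_masses: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.protein_xyz = np.asarray(self.protein_xyz, dtype=float)
        self.lipid_xyz = np.asarray(self.lipid_xyz, dtype=float)
        self.residue_ids = np.asarray(self.residue_ids)
        self.lipid_mol_ids = np.asarray(self.lipid_mol_ids)
        self.lipid_species = np.asarray(self.lipid_species)
        self.box = np.asarray(self.box, dtype=float)
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive edge lengths")
        if len(self.protein_xyz) != len(self.residue_ids):
            raise ValueError("every protein particle needs a residue id")
        if not (len(self.lipid_xyz) == len(self.lipid_mol_ids)
                == len(self.lipid_species)):
            raise ValueError("every lipid particle needs a molecule id and species")


@dataclass
class ContactSeries:
    """Per-frame lipid-molecule contact counts per species."""

    times: np.ndarray
    counts: dict
    cutoff: float

    def species_counts(self, species: str) -> np.ndarray:
        return self.counts[species]

    def summary(self) -> dict:
        return {
            sp: {"mean": float(np.mean(c)), "sd": float(np.std(c, ddof=0))}
            for sp, c in self.counts.items()
        }


def _min_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    return delta - box * np.round(delta / box)


def count_contacts_bruteforce(frame: FrameCoordinates, species: str,
                              cutoff: float) -> int:
    """O(N*M) minimum-image double loop; the reference implementation."""
    sel = frame.lipid_species == species
    mols = frame.lipid_mol_ids[sel]
    lip = frame.lipid_xyz[sel]
    touched = set()
    for i, p in enumerate(lip):
        if mols[i] in touched:
            continue
        d = _min_image(frame.protein_xyz - p, frame.box)
        if np.any(np.einsum("ij,ij->i", d, d) < cutoff**2):
            touched.add(mols[i])
    return len(touched)


def _contact_pairs(frame: FrameCoordinates, species: str, cutoff: float):
    """(lipid molecule id, residue id) pairs with any particle-particle
    distance strictly below cutoff; periodic KD-tree accelerated."""
    if cutoff >= frame.box.min() / 2:
        raise ValueError("cutoff must be below half the smallest box edge")
    sel = frame.lipid_species == species
    lip = np.mod(frame.lipid_xyz[sel], frame.box)
    mols = frame.lipid_mol_ids[sel]
    if len(lip) == 0:
        return set()
    prot = np.mod(frame.protein_xyz, frame.box)
    tree = cKDTree(prot, boxsize=frame.box)
    pairs = set()
    neighbors = tree.query_ball_point(lip, r=cutoff)
    for i, idxs in enumerate(neighbors):
        for j in idxs:
            d = _min_image(prot[j] - lip[i], frame.box)
            if d @ d < cutoff**2:  # enforce the strict inequality
                pairs.add((mols[i], frame.residue_ids[j]))
    return pairs


def count_contacts(frame: FrameCoordinates, species: str, cutoff: float) -> int:
    """Number of lipid molecules of ``species`` with any particle strictly
    within ``cutoff`` of any protein particle (minimum image)."""
    return len({m for m, _ in _contact_pairs(frame, species, cutoff)})


def contact_series(frames, species_list, cutoff: float) -> ContactSeries:
    """Per-frame contact counts for each species across a frame sequence."""
    if not frames:
        raise ValueError("no frames supplied")
    n_prot = len(frames[0].protein_xyz)
    n_lip = len(frames[0].lipid_xyz)
    counts = {sp: np.empty(len(frames), dtype=int) for sp in species_list}
    times = np.empty(len(frames))
    for i, fr in enumerate(frames):
        if len(fr.protein_xyz) != n_prot or len(fr.lipid_xyz) != n_lip:
            raise ValueError(f"topology drift at frame {i}")
        times[i] = fr.time
        for sp in species_list:
            counts[sp][i] = count_contacts(fr, sp, cutoff)
    return ContactSeries(times=times, counts=counts, cutoff=cutoff)


def residue_contact_profile(frames, species: str, cutoff: float) -> np.ndarray:
    """Normalized per-residue contact frequency with one lipid species.

    Residue-lipid-molecule contact events are summed over frames and
    divided by the maximum across residues, so the most-contacted residue
    scores 1 and untouched residues score 0.
    """
    if not frames:
        raise ValueError("no frames supplied")
    residues = np.unique(frames[0].residue_ids)
    raw = {int(r): 0 for r in residues}
    for fr in frames:
        for _, res in _contact_pairs(fr, species, cutoff):
            raw[int(res)] += 1
    values = np.array([raw[int(r)] for r in residues], dtype=float)
    peak = values.max()
    if peak == 0:
        warnings.warn(f"no {species} contacts in any frame", RuntimeWarning)
        return values
    return values / peak


def com_distance_series(frames, axis: str = "z") -> np.ndarray:
    """Per-frame distance between the protein COM and the lipid (bilayer)
    COM, mass-weighted when masses are present.

    Measured along the membrane normal (z) by default; ``axis='3d'`` gives
    the full Euclidean distance.
    """
    if not frames:
        raise ValueError("no frames supplied")
    out = np.empty(len(frames))
    for i, fr in enumerate(frames):
        if len(fr.protein_xyz) == 0 or len(fr.lipid_xyz) == 0:
            raise ValueError("empty protein or lipid group")
        pm = fr.protein_masses if fr.protein_masses is not None else None
        lm = fr.lipid_masses if fr.lipid_masses is not None else None
        pcom = np.average(fr.protein_xyz, axis=0, weights=pm)
        lcom = np.average(fr.lipid_xyz, axis=0, weights=lm)
        if axis == "z":
            out[i] = abs(pcom[2] - lcom[2])
        elif axis == "3d":
            out[i] = float(np.linalg.norm(pcom - lcom))
        else:
            raise ValueError("axis must be 'z' or '3d'")
    return out


def detect_binding(distances, dt: float = 1.0, threshold: float = 4.0,
                   discard: float = 100.0) -> list[tuple[int, int]]:
    """Maximal windows where the COM distance stays below ``threshold``.

    The first ``discard`` time units of each window are trimmed (initial
    non-equilibrium relaxation); windows shorter than ``discard`` are
    dropped.  Returns [start, end) index pairs on the frame grid.
    """
    d = np.asarray(distances, dtype=float)
    below = d < threshold
    if not below.any():
        return []
    edges = np.diff(below.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)
    if below[0]:
        starts = [0] + starts
    if below[-1]:
        ends = ends + [len(d)]
    skip = int(np.ceil(discard / dt))
    windows = []
    for s, e in zip(starts, ends):
        if e - s > skip:
            windows.append((s + skip, e))
    return windows
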