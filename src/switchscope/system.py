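"""Core containers: parameterized structures and trajectories.

A :class:`ParamStructure` couples atom/residue metadata with the per-atom
energy parameters (partial charge, Lennard-Jones r_min/2 and well depth,
Born radius) and the interaction-typing flags that the fingerprint rules
consume.  A :class:`Trajectory` is a plain frames x atoms x 3 coordinate
block in Å with a frame interval in ps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._constants import ELEMENT_MASSES

ROLES = ("protein", "ligand", "nucleotide", "ion")


class StructureError(ValueError):
    """Raised when a structure violates its invariants."""


@dataclass
class ParamStructure:
    """Atoms with residue/region annotation plus energy parameters.

    Parameters
    ----------
    names, elements, resids, resnames, chains, roles
        Per-atom metadata arrays.  ``resids`` are 1-based; ``roles`` are one
        of ``protein``, ``ligand``, ``nucleotide``, ``ion``.
    charges, rmin2, epsilon, born
        Per-atom energy parameters: partial charge (e), LJ r_min/2 (Å),
        LJ well depth (kcal/mol), effective Born radius (Å).
    regions
        Mapping region name -> inclusive 1-based residue range.
    bonds
        (n_bonds, 2) integer atom-index pairs, each bond stored once.
    donor, acceptor, cation, anion, hydrophobic
        Boolean typing flags per atom used by the fingerprint rules.
    ring_ids
        Integer per atom; atoms sharing a non-negative id form an aromatic
        ring.  -1 means "not in a ring".
    """

    names: np.ndarray
    elements: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    chains: np.ndarray
    roles: np.ndarray
    charges: np.ndarray
    rmin2: np.ndarray
    epsilon: np.ndarray
    born: np.ndarray
    regions: dict = field(default_factory=dict)
    bonds: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    donor: np.ndarray | None = None
    acceptor: np.ndarray | None = None
    cation: np.ndarray | None = None
    anion: np.ndarray | None = None
    hydrophobic: np.ndarray | None = None
    ring_ids: np.ndarray | None = None

    def __post_init__(self):
        n = self.n_atoms
        for attr in ("names", "elements", "resids", "resnames", "chains", "roles"):
            setattr(self, attr, np.asarray(getattr(self, attr)))
        for attr in ("charges", "rmin2", "epsilon", "born"):
            arr = np.asarray(getattr(self, attr), dtype=float)
            if arr.shape != (n,):
                raise StructureError(f"{attr} must have one value per atom")
            if not np.all(np.isfinite(arr)):
                raise StructureError(f"{attr} contains non-finite values")
            setattr(self, attr, arr)
        for attr in ("donor", "acceptor", "cation", "anion", "hydrophobic"):
            val = getattr(self, attr)
            if val is None:
                val = np.zeros(n, dtype=bool)
            setattr(self, attr, np.asarray(val, dtype=bool))
        if self.ring_ids is None:
            self.ring_ids = np.full(n, -1, dtype=int)
        self.ring_ids = np.asarray(self.ring_ids, dtype=int)
        self.resids = np.asarray(self.resids, dtype=int)
        if np.any(self.resids <= 0):
            raise StructureError("residue indices must be strictly positive")
        bad = set(np.unique(self.roles)) - set(ROLES)
        if bad:
            raise StructureError(f"unknown atom roles: {sorted(bad)}")
        self.bonds = np.asarray(self.bonds, dtype=int).reshape(-1, 2)
        if np.any(self.bonds[:, 0] == self.bonds[:, 1]):
            raise StructureError("bond list must be irreflexive")
        protein_resids = set(self.resids[self.roles == "protein"].tolist())
        for name, (lo, hi) in self.regions.items():
            if lo > hi:
                raise StructureError(f"region {name!r} has inverted range ({lo}, {hi})")
            if not set(range(lo, hi + 1)) <= protein_resids:
                raise StructureError(
                    f"region {name!r} range ({lo}, {hi}) lies outside existing residues"
                )

    # -- basic properties -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def masses(self) -> np.ndarray:
        return np.array([ELEMENT_MASSES[e.upper()] for e in self.elements])

    @property
    def heavy(self) -> np.ndarray:
        """Boolean mask of heavy (non-hydrogen) atoms."""
        return np.array([e.upper() != "H" for e in self.elements])

    # -- selections --------------------------------------------------------

    def atoms_by_role(self, role: str) -> np.ndarray:
        return np.flatnonzero(self.roles == role)

    def residue_atoms(self, resid: int, role: str = "protein") -> np.ndarray:
        return np.flatnonzero((self.resids == resid) & (self.roles == role))

    def protein_resids(self) -> np.ndarray:
        return np.unique(self.resids[self.roles == "protein"])

    def region_resids(self, name: str) -> np.ndarray:
        lo, hi = self.regions[name]
        return np.arange(lo, hi + 1)

    def region_atoms(self, name: str) -> np.ndarray:
        lo, hi = self.regions[name]
        return np.flatnonzero(
            (self.roles == "protein") & (self.resids >= lo) & (self.resids <= hi)
        )

    def beads(self) -> np.ndarray:
        """One representative atom per protein residue (the Cα-equivalent)."""
        idx = []
        for resid in self.protein_resids():
            atoms = self.residue_atoms(resid)
            ca = atoms[np.char.equal(self.names[atoms].astype(str), "CA")]
            idx.append(ca[0] if len(ca) else atoms[0])
        return np.array(idx, dtype=int)

    def bonded_hydrogens(self, atom: int) -> np.ndarray:
        """Hydrogen atoms bonded to ``atom``."""
        partners = np.concatenate(
            [self.bonds[self.bonds[:, 0] == atom, 1], self.bonds[self.bonds[:, 1] == atom, 0]]
        )
        return partners[~self.heavy[partners]] if len(partners) else partners

    def rings(self) -> dict[int, np.ndarray]:
        """Aromatic rings: ring id -> member atom indices."""
        out = {}
        for rid in np.unique(self.ring_ids):
            if rid >= 0:
                out[int(rid)] = np.flatnonzero(self.ring_ids == rid)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.names,
                "element": self.elements,
                "resid": self.resids,
                "resname": self.resnames,
                "chain": self.chains,
                "role": self.roles,
                "charge": self.charges,
                "rmin2": self.rmin2,
                "epsilon": self.epsilon,
                "born": self.born,
                "donor": self.donor,
                "acceptor": self.acceptor,
                "cation": self.cation,
                "anion": self.anion,
                "hydrophobic": self.hydrophobic,
                "ring_id": self.ring_ids,
            }
        )


class TrajectoryError(ValueError):
    """Raised when trajectory data violates its invariants."""


@dataclass
class Trajectory:
    """Frames x atoms x 3 coordinates (Å) with time metadata."""

    coords: np.ndarray
    dt_ps: float = 100.0
    ref_frame: int = 0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryError("coordinates must have shape (frames, atoms, 3)")
        if self.coords.shape[0] < 1:
            raise TrajectoryError("a trajectory needs at least one frame")
        if not np.all(np.isfinite(self.coords)):
            raise TrajectoryError("coordinates contain non-finite values")
        if not 0 <= self.ref_frame < self.n_frames:
            raise TrajectoryError("reference frame index out of range")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def check_structure(self, structure: ParamStructure) -> None:
        if self.n_atoms != structure.n_atoms:
            raise TrajectoryError(
                f"trajectory has {self.n_atoms} atoms, structure has {structure.n_atoms}"
            )
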