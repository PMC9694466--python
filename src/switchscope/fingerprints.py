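"""Protein–ligand interaction fingerprints.

Interactions are typed per frame from geometry alone, using the typing
flags carried on the structure (donor/acceptor/charge/hydrophobic/aromatic).
Type labels follow the ligand-centric convention of standard fingerprinting
tools: ``HBDonor`` means the *ligand* donates the hydrogen bond, ``Cationic``
means the ligand carries the positive charge, and so on.  Frequencies are
reported as percentages of frames, and report tables keep only rows whose
frequency exceeds the configured threshold in at least one system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .system import ParamStructure, Trajectory

INTERACTION_TYPES = (
    "Hydrophobic",
    "HBAcceptor",
    "HBDonor",
    "PiStacking",
    "Cationic",
    "Anionic",
    "CationPi",
)

HYDROPHOBIC_ELEMENTS = {"C", "S"}


class FingerprintError(ValueError):
    pass


@dataclass(frozen=True)
class InteractionRules:
    """Geometric thresholds for each interaction type.

    Defaults are the community-standard values; every threshold is
    configuration so planted test geometries can sit far from boundaries.
    """

    pocket_cutoff: float = 6.0           # Å, residue inclusion zone
    hydrophobic_cutoff: float = 4.5      # Å, C/S–C/S
    hbond_cutoff: float = 3.5            # Å, donor–acceptor heavy atoms
    hbond_angle: float = 130.0           # degrees, D–H...A minimum
    pistack_centroid: float = 5.5        # Å, face-to-face centroid distance
    pistack_angle: float = 30.0          # degrees, max plane tilt face-to-face
    tshape_centroid: float = 6.5         # Å, edge-to-face centroid distance
    tshape_angle_lo: float = 60.0        # degrees, edge-to-face tilt window
    ionic_cutoff: float = 4.5            # Å, opposite formal charges
    cationpi_cutoff: float = 4.5         # Å, cation–ring centroid


def define_pocket(frame, structure: ParamStructure, ligand_sel=None, cutoff: float = 6.0):
    """Protein residues with >=1 heavy atom within ``cutoff`` of any ligand heavy atom."""
    frame = np.asarray(frame)
    if ligand_sel is None:
        ligand_sel = structure.atoms_by_role("ligand")
    ligand_sel = np.asarray(ligand_sel, dtype=int)
    if ligand_sel.size == 0:
        raise FingerprintError("empty ligand selection")
    lig_heavy = ligand_sel[structure.heavy[ligand_sel]]
    prot = np.flatnonzero((structure.roles == "protein") & structure.heavy)
    d = np.linalg.norm(frame[prot, None, :] - frame[None, lig_heavy, :], axis=2)
    close = prot[(d <= cutoff).any(axis=1)]
    return set(structure.resids[close].tolist())


def _ring_geometry(frame, atoms):
    pts = frame[atoms]
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # plane normal = smallest principal axis
    _, _, vt = np.linalg.svd(centered)
    return centroid, vt[2]


def _plane_angle(n1, n2):
    c = abs(float(np.dot(n1, n2)) / (np.linalg.norm(n1) * np.linalg.norm(n2)))
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


def _hbond_pairs(frame, structure, donors, acceptors, rules):
    """(donor_heavy, acceptor) pairs satisfying distance and, when the donor
    carries an explicit hydrogen, the D–H...A angle."""
    out = []
    for d_idx in donors:
        hyds = structure.bonded_hydrogens(int(d_idx))
        for a_idx in acceptors:
            r = np.linalg.norm(frame[d_idx] - frame[a_idx])
            if r > rules.hbond_cutoff or r < 1e-6:
                continue
            if len(hyds):
                ok = False
                for h in hyds:
                    v1 = frame[d_idx] - frame[h]
                    v2 = frame[a_idx] - frame[h]
                    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                    if ang >= rules.hbond_angle:
                        ok = True
                if not ok:
                    continue
            out.append((int(d_idx), int(a_idx)))
    return out


def detect_frame_interactions(
    frame,
    structure: ParamStructure,
    ligand_sel=None,
    rules: InteractionRules = InteractionRules(),
):
    """Set of ``(residue, interaction_type)`` pairs firing in one frame."""
    frame = np.asarray(frame)
    if ligand_sel is None:
        ligand_sel = structure.atoms_by_role("ligand")
    ligand_sel = np.asarray(ligand_sel, dtype=int)
    heavy = structure.heavy
    prot = np.flatnonzero((structure.roles == "protein") & heavy)
    lig_heavy = ligand_sel[heavy[ligand_sel]]
    resid = structure.resids
    hits: set[tuple[int, str]] = set()

    dmat = np.linalg.norm(frame[prot, None, :] - frame[None, lig_heavy, :], axis=2)

    # Hydrophobic: C/S vs C/S within cutoff, both flagged hydrophobic
    p_hyd = np.array(
        [structure.hydrophobic[i] and structure.elements[i].upper() in HYDROPHOBIC_ELEMENTS for i in prot]
    )
    l_hyd = np.array(
        [structure.hydrophobic[i] and structure.elements[i].upper() in HYDROPHOBIC_ELEMENTS for i in lig_heavy]
    )
    mask = p_hyd[:, None] & l_hyd[None, :] & (dmat <= rules.hydrophobic_cutoff)
    for pi in np.flatnonzero(mask.any(axis=1)):
        hits.add((int(resid[prot[pi]]), "Hydrophobic"))

    # Hydrogen bonds (ligand-centric labels)
    p_don = prot[structure.donor[prot]]
    p_acc = prot[structure.acceptor[prot]]
    l_don = lig_heavy[structure.donor[lig_heavy]]
    l_acc = lig_heavy[structure.acceptor[lig_heavy]]
    for d_idx, a_idx in _hbond_pairs(frame, structure, p_don, l_acc, rules):
        hits.add((int(resid[d_idx]), "HBAcceptor"))  # ligand accepts
    for d_idx, a_idx in _hbond_pairs(frame, structure, l_don, p_acc, rules):
        hits.add((int(resid[a_idx]), "HBDonor"))  # ligand donates

    # Ionic (ligand-centric: Cationic = ligand +, Anionic = ligand -)
    for p_flag, l_flag, label in (
        (structure.anion, structure.cation, "Cationic"),
        (structure.cation, structure.anion, "Anionic"),
    ):
        pi_set = prot[p_flag[prot]]
        li_set = lig_heavy[l_flag[lig_heavy]]
        if len(pi_set) and len(li_set):
            d = np.linalg.norm(frame[pi_set, None, :] - frame[None, li_set, :], axis=2)
            for k in np.flatnonzero((d <= rules.ionic_cutoff).any(axis=1)):
                hits.add((int(resid[pi_set[k]]), label))

    # Rings
    rings = structure.rings()
    prot_rings = {rid: a for rid, a in rings.items() if structure.roles[a[0]] == "protein"}
    lig_rings = {rid: a for rid, a in rings.items() if structure.roles[a[0]] == "ligand"}
    lig_ring_geo = {rid: _ring_geometry(frame, a) for rid, a in lig_rings.items()}
    for rid, atoms in prot_rings.items():
        c1, n1 = _ring_geometry(frame, atoms)
        for lrid, (c2, n2) in lig_ring_geo.items():
            dist = np.linalg.norm(c1 - c2)
            ang = _plane_angle(n1, n2)
            face = dist <= rules.pistack_centroid and ang <= rules.pistack_angle
            edge = (
                dist <= rules.tshape_centroid
                and rules.tshape_angle_lo <= ang <= 90.0
            )
            if face or edge:
                hits.add((int(resid[atoms[0]]), "PiStacking"))

    # Cation-pi: protein cation vs ligand ring, and ligand cation vs protein ring
    p_cat = prot[structure.cation[prot]]
    for rid, (c2, n2) in lig_ring_geo.items():
        for pi_idx in p_cat:
            if np.linalg.norm(frame[pi_idx] - c2) <= rules.cationpi_cutoff:
                hits.add((int(resid[pi_idx]), "CationPi"))
    l_cat = lig_heavy[structure.cation[lig_heavy]]
    for rid, atoms in prot_rings.items():
        c1, _ = _ring_geometry(frame, atoms)
        for li in l_cat:
            if np.linalg.norm(frame[li] - c1) <= rules.cationpi_cutoff:
                hits.add((int(resid[atoms[0]]), "CationPi"))

    # restrict to pocket residues
    pocket = define_pocket(frame, structure, ligand_sel, rules.pocket_cutoff)
    return {(r, t) for r, t in hits if r in pocket}


@dataclass
class FingerprintTable:
    """Frequency (%) of each (residue, type) row, per system."""

    frequencies: pd.DataFrame  # index (resid, type), columns = systems
    pocket_cutoff: float = 6.0
    report_threshold: float = 30.0

    def report(self) -> pd.DataFrame:
        """Rows whose best frequency across systems strictly exceeds the threshold."""
        keep = self.frequencies.max(axis=1) > self.report_threshold
        return self.frequencies[keep]


def interaction_frequencies(
    traj: Trajectory,
    structure: ParamStructure,
    ligand_sel=None,
    rules: InteractionRules = InteractionRules(),
    report_threshold: float = 30.0,
    system: str = "system",
    stride: int = 1,
) -> FingerprintTable:
    """Percent of frames in which each (residue, type) interaction fires."""
    traj.check_structure(structure)
    counts: dict[tuple[int, str], int] = {}
    frames = range(0, traj.n_frames, stride)
    n = 0
    for f in frames:
        n += 1
        for key in detect_frame_interactions(traj.coords[f], structure, ligand_sel, rules):
            counts[key] = counts.get(key, 0) + 1
    idx = pd.MultiIndex.from_tuples(sorted(counts), names=["resid", "type"])
    freqs = pd.DataFrame(
        {system: [100.0 * counts[k] / n for k in sorted(counts)]}, index=idx
    )
    return FingerprintTable(freqs, rules.pocket_cutoff, report_threshold)


def compare_fingerprints(table_a: FingerprintTable, table_b: FingerprintTable) -> pd.Series:
    """Per-row frequency delta (B - A) over the union of rows, sorted by |delta|."""
    fa = table_a.frequencies.iloc[:, 0]
    fb = table_b.frequencies.iloc[:, 0]
    union = fa.index.union(fb.index)
    delta = fb.reindex(union, fill_value=0.0) - fa.reindex(union, fill_value=0.0)
    return delta.iloc[np.argsort(-np.abs(delta.values), kind="stable")]
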