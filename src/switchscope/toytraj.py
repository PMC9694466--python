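"""Synthetic coarse-grained protein–ligand–nucleotide–ion systems.

The generator emulates, at toy scale, a small GTPase-like protein with two
flexible loop regions that interconvert between metastable "closed" and
"open" conformations, a pocket-bound multi-atom inhibitor, a bound
nucleotide analogue, and a divalent ion.  Hidden-state dynamics are
discrete-time Markov (not Langevin), so the generator's transition matrix
is exact ground truth for Markov-model recovery tests; every planted
protein–ligand interaction geometry is recorded in a
:class:`TruthManifest` so fingerprint and network recovery can be checked
against design rather than against another implementation.

Protein residues are single beads (the bead is both the Cα and the
residue's only heavy atom); special pocket residues additionally carry an
aromatic six-membered ring or a polar hydrogen so the geometric
interaction rules fire by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .system import ParamStructure, Trajectory

CONTACT_CUTOFF = 4.5  # Å, used for the designed contact-frequency table


class GeneratorError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Settings for the toy system.

    The default is a 60-residue chain with two metastable loops
    (``LoopI`` residues 30–42, ``LoopII`` residues 57–63), a 12-atom
    ligand bound in a pocket formed against loop II, a 5-atom nucleotide
    analogue near the nucleotide site, and one divalent ion.
    """

    n_residues: int = 72
    regions: dict = field(default_factory=lambda: {"LoopI": (30, 42), "LoopII": (57, 63)})
    with_ligand: bool = True
    ligand_style: str = "full"      # "full" 12-atom inhibitor or "single" probe atom
    with_nucleotide: bool = True
    with_ion: bool = True
    covalent_link: bool = True
    covalent_resid: int = 56
    noise_sd: float = 0.15          # Å, isotropic per coordinate
    open_shift: float = 8.0         # Å, loop displacement in the open state
    hidden_T: tuple = ((0.95, 0.05), (0.2, 0.8))  # closed/open, stationary (0.8, 0.2)
    frame_interval_ps: float = 100.0

    def __post_init__(self):
        if self.ligand_style not in ("full", "single"):
            raise GeneratorError(f"unknown ligand style {self.ligand_style!r}")
        if self.with_ligand and self.ligand_style == "full" and self.n_residues < 68:
            raise GeneratorError("the full pocket layout needs at least 68 residues")
        names = list(self.regions)
        for i, a in enumerate(names):
            lo_a, hi_a = self.regions[a]
            if hi_a > self.n_residues:
                raise GeneratorError(
                    f"region {a!r} upper bound {hi_a} exceeds residue count {self.n_residues}"
                )
            for b in names[i + 1 :]:
                lo_b, hi_b = self.regions[b]
                if lo_a <= hi_b and lo_b <= hi_a:
                    raise GeneratorError(f"regions {a!r} and {b!r} overlap")


@dataclass
class TruthManifest:
    """Ground truth recorded by the generator for parameter-recovery tests."""

    states: np.ndarray                 # frame -> hidden state label
    hidden_T: np.ndarray               # generator transition matrix
    state_refs: np.ndarray             # (n_states, n_atoms, 3) reference coordinates
    contact_freqs: dict                # (atom_i, atom_j) -> designed fraction
    interaction_freqs: dict            # (resid, type) -> designed fraction
    pocket_resids: set                 # designed pocket (reference/closed state)
    seed: int = 0

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=int)
        self.hidden_T = np.asarray(self.hidden_T, dtype=float)
        rows = self.hidden_T.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-10):
            raise GeneratorError("manifest transition matrix rows must sum to 1")

    def occupancy(self) -> np.ndarray:
        """Realized hidden-state occupancy over the generated frames."""
        n_states = self.hidden_T.shape[0]
        return np.bincount(self.states, minlength=n_states) / len(self.states)

    def stationary(self) -> np.ndarray:
        """Stationary distribution of the generator transition matrix."""
        vals, vecs = np.linalg.eig(self.hidden_T.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        return pi / pi.sum()

    def to_json(self) -> str:
        return json.dumps(
            {
                "states": self.states.tolist(),
                "hidden_T": self.hidden_T.tolist(),
                "state_refs": self.state_refs.tolist(),
                "contact_freqs": {f"{i}-{j}": v for (i, j), v in self.contact_freqs.items()},
                "interaction_freqs": {f"{r}:{t}": v for (r, t), v in self.interaction_freqs.items()},
                "pocket_resids": sorted(self.pocket_resids),
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        d = json.loads(text)
        return cls(
            states=np.array(d["states"]),
            hidden_T=np.array(d["hidden_T"]),
            state_refs=np.array(d["state_refs"]),
            contact_freqs={
                tuple(int(x) for x in k.split("-")): v for k, v in d["contact_freqs"].items()
            },
            interaction_freqs={
                (int(k.split(":")[0]), k.split(":")[1]): v
                for k, v in d["interaction_freqs"].items()
            },
            pocket_resids=set(d["pocket_resids"]),
            seed=d["seed"],
        )


# ---------------------------------------------------------------------------
# topology construction
# ---------------------------------------------------------------------------

_PARAMS = {  # element -> (rmin/2 Å, epsilon kcal/mol, Born radius Å)
    "C": (1.9, 0.086, 1.7),
    "N": (1.8, 0.17, 1.55),
    "O": (1.7, 0.21, 1.5),
    "H": (0.6, 0.015, 1.2),
    "MG": (0.79, 0.875, 1.45),
    "BEAD": (2.0, 0.1, 2.0),
}

# Pocket layout constants (Å), all relative to the ligand ring centroid.
_RING_CENTER = np.array([66.0, 8.2, 0.0])

# Planted protein–ligand interactions: (resid, ligand-centric type,
# hidden states in which the geometry satisfies the rule).
PLANTED_INTERACTIONS = (
    (55, "Anionic", (0, 1)),
    (56, "Hydrophobic", (0, 1)),
    (58, "Hydrophobic", (0,)),
    (59, "HBAcceptor", (0,)),
    (60, "PiStacking", (0,)),
    (62, "Cationic", (0,)),
    (65, "HBDonor", (0, 1)),
)


def _base_bead(i: int) -> np.ndarray:
    """Backbone helix position of residue ``i`` (1-based).

    A compact idealized helix (rise 1.2 Å, radius 1.9 Å, 120° per residue)
    whose i/i+2 (4.07 Å) and i/i+3 (3.6 Å) bead distances fall inside the
    4.5 Å network contact cutoff, giving a connected backbone network once
    sequence-adjacent pairs are excluded."""
    w = 2.0 * np.pi / 3.0
    return np.array([1.2 * i, 1.9 * np.cos(w * i), 1.9 * np.sin(w * i)])


def _hexagon(center, radius=1.39, normal_z=True, phase=np.pi / 2):
    """Six ring-atom positions in a plane of constant z."""
    ang = phase + np.arange(6) * np.pi / 3
    pts = np.stack(
        [center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang), np.full(6, center[2])],
        axis=1,
    )
    return pts


def generate_topology(config: GeneratorConfig | None = None) -> ParamStructure:
    """Build the toy :class:`ParamStructure` (deterministic for a config)."""
    if config is None:
        config = GeneratorConfig()
    rows = []  # (name, element, resid, resname, chain, role, charge, flags..., ring)
    coords = []

    def add(name, element, resid, resname, chain, role, charge, pos, *,
            donor=False, acceptor=False, cation=False, anion=False,
            hydrophobic=False, ring=-1):
        rows.append(
            dict(name=name, element=element, resid=resid, resname=resname,
                 chain=chain, role=role, charge=charge, donor=donor,
                 acceptor=acceptor, cation=cation, anion=anion,
                 hydrophobic=hydrophobic, ring=ring)
        )
        coords.append(np.asarray(pos, dtype=float))
        return len(rows) - 1

    n = config.n_residues
    full_ligand = config.with_ligand and config.ligand_style == "full"
    pocket = _pocket_positions() if full_ligand else {}
    bead_idx = {}
    for i in range(1, n + 1):
        pos = pocket.get(i, _base_bead(i))
        flags = {}
        if full_ligand:
            if i == 59:
                flags = dict(donor=True)
            elif i == 65:
                flags = dict(acceptor=True)
            elif i == 62:
                flags = dict(anion=True)
            elif i == 55:
                flags = dict(cation=True)
            elif i in (58, 56):
                flags = dict(hydrophobic=True)
        charge = {62: -1.0, 55: 1.0}.get(i, 0.05 * (-1) ** i) if full_ligand else 0.05 * (-1) ** i
        element = {59: "N", 65: "O", 62: "O", 55: "N"}.get(i, "C") if full_ligand else "C"
        bead_idx[i] = add("CA", element, i, "RES", "A", "protein", charge, pos, **flags)

    bonds = [(bead_idx[i], bead_idx[i + 1]) for i in range(1, n)]
    ring_counter = 0

    if config.with_ligand and config.ligand_style == "single":
        # a lone probe atom hovering above the middle of the chain
        mid = _base_bead((n + 1) // 2) + np.array([0.0, 6.0, 0.0])
        add("C1", "C", n + 1, "LIG", "B", "ligand", 0.0, mid, hydrophobic=True)

    if full_ligand:
        # donor hydrogen of residue 59, pointing at the ligand acceptor
        h59 = add("HD1", "H", 59, "RES", "A", "protein", 0.2,
                  pocket[59] + np.array([0.0, -1.0, 0.0]))
        bonds.append((bead_idx[59], h59))
        # aromatic ring of residue 60, stacked parallel above the ligand ring
        ring60 = _hexagon(_RING_CENTER + np.array([0.0, 0.0, 3.6]))
        ring_atoms = [
            add(f"CZ{k}", "C", 60, "RES", "A", "protein", -0.05, ring60[k], ring=ring_counter)
            for k in range(6)
        ]
        bonds += [(ring_atoms[k], ring_atoms[(k + 1) % 6]) for k in range(6)]
        bonds.append((bead_idx[60], ring_atoms[0]))
        ring_counter += 1

        lig_resid = n + 1
        ringL = _hexagon(_RING_CENTER)
        lring = [
            add(f"C{k + 1}", "C", lig_resid, "LIG", "B", "ligand", -0.05, ringL[k],
                hydrophobic=True, ring=ring_counter)
            for k in range(6)
        ]
        bonds += [(lring[k], lring[(k + 1) % 6]) for k in range(6)]
        ring_counter += 1
        la = add("O1", "O", lig_resid, "LIG", "B", "ligand", -0.4,
                 _RING_CENTER + np.array([-4.5, 0.0, 0.0]), acceptor=True)
        nd = add("N1", "N", lig_resid, "LIG", "B", "ligand", -0.3,
                 _RING_CENTER + np.array([4.5, 0.0, 0.0]), donor=True)
        hd = add("H1", "H", lig_resid, "LIG", "B", "ligand", 0.3,
                 _RING_CENTER + np.array([4.5, -1.0, 0.0]))
        lc = add("N2", "N", lig_resid, "LIG", "B", "ligand", 1.0,
                 _RING_CENTER + np.array([-2.5, 0.0, -3.5]), cation=True)
        ln = add("O2", "O", lig_resid, "LIG", "B", "ligand", -1.0,
                 _RING_CENTER + np.array([2.5, 0.0, -3.5]), anion=True)
        lw = add("CW", "C", lig_resid, "LIG", "B", "ligand", 0.0,
                 _RING_CENTER + np.array([7.5, -1.5, 0.0]), hydrophobic=True)
        bonds += [(la, lring[2]), (nd, lring[0]), (nd, hd), (lc, la), (ln, nd), (lw, nd)]
        if config.covalent_link:
            bonds.append((lw, bead_idx[config.covalent_resid]))

    if config.with_nucleotide:
        nuc_resid = n + 2
        anchor = _base_bead(28) + np.array([0.0, 3.5, 0.0])
        c1p = add("C1'", "C", nuc_resid, "GDP", "C", "nucleotide", 0.1, anchor)
        prev = c1p
        # zigzag chain: collinear fragments would be zero-stiffness
        # mechanisms in the elastic-network entropy model
        offsets = ((1.4, 0.5, 0.0), (2.8, -0.5, 0.4), (4.2, 0.5, -0.4))
        for (nm, el), off in zip((("N1", "N"), ("O2'", "O"), ("P1", "O")), offsets):
            a = add(nm, el, nuc_resid, "GDP", "C", "nucleotide",
                    -0.4, anchor + np.array(off))
            bonds.append((prev, a))
            prev = a
        o5 = add("O5'", "O", nuc_resid, "GDP", "C", "nucleotide", -0.6,
                 anchor + np.array([-1.4, 0.3, 0.3]))
        bonds.append((c1p, o5))

    if config.with_ion:
        anchor = _base_bead(28) + np.array([0.0, 3.5, 0.0])
        add("MG", "MG", n + 3, "MG", "D", "ion", 2.0, anchor + np.array([-3.4, 0.0, 0.0]))

    names = np.array([r["name"] for r in rows])
    elements = np.array([r["element"] for r in rows])
    params = np.array(
        [
            _PARAMS["BEAD"] if (r["role"] == "protein" and r["name"] == "CA")
            else _PARAMS[r["element"].upper()]
            for r in rows
        ]
    )
    structure = ParamStructure(
        names=names,
        elements=elements,
        resids=np.array([r["resid"] for r in rows]),
        resnames=np.array([r["resname"] for r in rows]),
        chains=np.array([r["chain"] for r in rows]),
        roles=np.array([r["role"] for r in rows]),
        charges=np.array([r["charge"] for r in rows], dtype=float),
        rmin2=params[:, 0],
        epsilon=params[:, 1],
        born=params[:, 2],
        regions=dict(config.regions),
        bonds=np.array(bonds, dtype=int),
        donor=np.array([r["donor"] for r in rows]),
        acceptor=np.array([r["acceptor"] for r in rows]),
        cation=np.array([r["cation"] for r in rows]),
        anion=np.array([r["anion"] for r in rows]),
        hydrophobic=np.array([r["hydrophobic"] for r in rows]),
        ring_ids=np.array([r["ring"] for r in rows]),
    )
    structure.ref_coords = np.array(coords)
    return structure


def _pocket_positions() -> dict:
    """Hand-placed pocket bead positions (closed state).

    Distances are chosen well inside (or outside) every geometric rule
    threshold so that thermal noise cannot flip an interaction on or off.
    """
    c = _RING_CENTER
    return {
        55: c + np.array([2.5, 0.0, -6.5]),    # cation bead 3.0 Å from the ligand anion
        56: c + np.array([7.5, -1.5, 1.9]),    # covalent-link partner, 1.9 Å from warhead
        58: c + np.array([0.0, -4.8, 0.0]),    # hydrophobic bead under the ring edge
        59: c + np.array([-4.5, 2.8, 0.0]),    # donor bead 2.8 Å above the acceptor O1
        60: c + np.array([0.0, 1.5, 3.6]),     # ring-carrier bead; ring centroid at +3.6 z
        62: c + np.array([-2.5, 0.0, -6.5]),   # anion bead 3.0 Å from the ligand cation
        65: c + np.array([4.5, -2.9, 0.0]),    # acceptor bead 2.9 Å below the donor N1
        # bridge beads stepping from the pocket cluster back to the helix
        # surface (56 -> 64 -> 66 -> helix bead 69, each hop <= 4.2 Å and
        # never between sequence-adjacent residues)
        64: c + np.array([9.5, -4.3, 3.5]),
        66: c + np.array([13.15, -5.3, 1.75]),
    }


def state_references(config: GeneratorConfig, structure: ParamStructure) -> np.ndarray:
    """Per-hidden-state reference coordinates (state 0 closed, state 1 open).

    In the open state every atom belonging to a loop region (bead plus any
    decorating ring/hydrogen atoms) is rigidly displaced by ``open_shift``
    along y, alternating sign between consecutive regions so the net
    center-of-mass drift between states is small and the displacement is
    not absorbed by the global superposition fit.  Loop II moves away from
    the ligand (-y), breaking the closed-state pocket contacts.
    """
    closed = structure.ref_coords.copy()
    open_ = closed.copy()
    for k, name in enumerate(config.regions):
        sign = 1.0 if k % 2 == 0 else -1.0
        shift = np.array([0.0, sign * config.open_shift, 2.0])
        lo, hi = config.regions[name]
        mask = (structure.roles == "protein") & (structure.resids >= lo) & (structure.resids <= hi)
        open_[mask] += shift
    return np.stack([closed, open_])


# ---------------------------------------------------------------------------
# trajectory generation
# ---------------------------------------------------------------------------

def _rng_for(seed: int, stage: int):
    """Counter-based seed splitting: one integer controls every stage."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


def generate_trajectory(
    structure: ParamStructure,
    hidden_T,
    state_refs,
    noise_sd: float,
    n_frames: int,
    seed: int,
    frame_interval_ps: float = 100.0,
) -> tuple[Trajectory, TruthManifest]:
    """Sample a discrete-time Markov chain over hidden states and emit frames.

    Each frame is the current state's reference coordinates plus isotropic
    Gaussian displacement of standard deviation ``noise_sd`` per coordinate.
    ``noise_sd`` may be a scalar or a per-atom array.
    """
    hidden_T = np.asarray(hidden_T, dtype=float)
    if hidden_T.ndim != 2 or hidden_T.shape[0] != hidden_T.shape[1]:
        raise GeneratorError("hidden transition matrix must be square")
    if np.any(hidden_T < 0) or not np.allclose(hidden_T.sum(axis=1), 1.0, atol=1e-10):
        raise GeneratorError("hidden transition matrix must be row-stochastic")
    state_refs = np.asarray(state_refs, dtype=float)
    if state_refs.shape[0] != hidden_T.shape[0] or state_refs.shape[1] != structure.n_atoms:
        raise GeneratorError("state references incongruent with structure/transition matrix")
    sd = np.asarray(noise_sd, dtype=float)
    if np.any(sd < 0):
        raise GeneratorError("noise_sd must be non-negative")
    if sd.ndim == 0:
        sd = np.full(structure.n_atoms, float(sd))

    n_states = hidden_T.shape[0]
    rng_chain = _rng_for(seed, 0)
    rng_noise = _rng_for(seed, 1)
    pi = _stationary(hidden_T)
    states = np.empty(n_frames, dtype=int)
    states[0] = rng_chain.choice(n_states, p=pi)
    u = rng_chain.random(n_frames - 1)
    cum = np.cumsum(hidden_T, axis=1)
    for f in range(1, n_frames):
        states[f] = np.searchsorted(cum[states[f - 1]], u[f - 1], side="right")
    coords = state_refs[states] + rng_noise.standard_normal((n_frames, structure.n_atoms, 3)) * sd[None, :, None]
    # anchor the reference at the first frame of the most probable state so
    # RMSD reaction coordinates start from the dominant basin
    top_state = int(np.argmax(pi))
    hits = np.flatnonzero(states == top_state)
    ref_frame = int(hits[0]) if hits.size else 0
    traj = Trajectory(coords, dt_ps=frame_interval_ps, ref_frame=ref_frame)

    occ = np.bincount(states, minlength=n_states) / n_frames
    manifest = TruthManifest(
        states=states,
        hidden_T=hidden_T,
        state_refs=state_refs,
        contact_freqs=_designed_contacts(structure, state_refs, occ, noise_sd=sd),
        interaction_freqs=_designed_interactions(structure, occ),
        pocket_resids=_designed_pocket(structure, state_refs[0]),
        seed=seed,
    )
    return traj, manifest


def _stationary(T):
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.abs(np.real(vecs[:, i]))
    return pi / pi.sum()


def _designed_contacts(structure, state_refs, occupancy, noise_sd=0.0):
    """Protein-bead x ligand-heavy-atom contact fractions from noise-free geometry.

    Pairs whose noise-free distance falls within a 3-sigma guard band of
    the cutoff in any state are omitted: thermal noise makes their contact
    status genuinely ambiguous, so the generator does not vouch for them.
    """
    lig = structure.atoms_by_role("ligand")
    lig = lig[structure.heavy[lig]]
    if lig.size == 0:
        return {}
    guard = 3.0 * np.sqrt(2.0) * float(np.max(noise_sd))
    beads = structure.beads()
    out = {}
    dists = []
    for s in range(state_refs.shape[0]):
        dists.append(np.linalg.norm(
            state_refs[s][beads][:, None, :] - state_refs[s][lig][None, :, :], axis=2
        ))
    per_state = [d <= CONTACT_CUTOFF for d in dists]
    ambiguous = np.any(
        [np.abs(d - CONTACT_CUTOFF) < guard for d in dists], axis=0
    )
    anystate = np.any(per_state, axis=0) & ~ambiguous
    for bi, li in zip(*np.nonzero(anystate)):
        frac = float(sum(occupancy[s] * per_state[s][bi, li] for s in range(len(per_state))))
        out[(int(beads[bi]), int(lig[li]))] = frac
    return out


def _designed_interactions(structure, occupancy):
    """Planted-interaction fractions; only meaningful for the full pocket
    layout, and only over the hidden states the run actually has."""
    prot = structure.resids[structure.roles == "protein"]
    if structure.atoms_by_role("ligand").size < 6 or prot.max() < 65:
        return {}
    return {
        (resid, itype): float(sum(occupancy[s] for s in states if s < len(occupancy)))
        for resid, itype, states in PLANTED_INTERACTIONS
    }


def _designed_pocket(structure, closed_ref):
    lig = structure.atoms_by_role("ligand")
    lig = lig[structure.heavy[lig]]
    if lig.size == 0:
        return set()
    prot = np.flatnonzero((structure.roles == "protein") & structure.heavy)
    d = np.linalg.norm(closed_ref[prot][:, None, :] - closed_ref[lig][None, :, :], axis=2)
    return set(structure.resids[prot[(d <= 6.0).any(axis=1)]].tolist())


def generate_system(
    config: GeneratorConfig | None = None, n_frames: int = 2000, seed: int = 0
) -> tuple[ParamStructure, Trajectory, TruthManifest]:
    """Convenience: topology + state references + trajectory in one call."""
    if config is None:
        config = GeneratorConfig()
    structure = generate_topology(config)
    refs = state_references(config, structure)
    traj, manifest = generate_trajectory(
        structure, np.array(config.hidden_T), refs, config.noise_sd, n_frames, seed,
        frame_interval_ps=config.frame_interval_ps,
    )
    return structure, traj, manifest


# ---------------------------------------------------------------------------
# standard-format IO (PDB topology, DCD trajectory, JSON parameter sidecar)
# ---------------------------------------------------------------------------

class TrajectoryIOError(IOError):
    pass


def write_system(structure: ParamStructure, traj: Trajectory, outdir) -> dict:
    """Write PDB (topology + reference frame), DCD (all frames) and the
    parameter sidecar.  Returns the paths written."""
    import MDAnalysis as mda

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traj.check_structure(structure)
    n_res_total = len(np.unique(structure.resids))
    resid_order = {r: k for k, r in enumerate(np.unique(structure.resids))}
    u = mda.Universe.empty(
        structure.n_atoms,
        n_residues=n_res_total,
        atom_resindex=np.array([resid_order[r] for r in structure.resids]),
        trajectory=True,
    )
    u.add_TopologyAttr("names", structure.names.astype(str))
    u.add_TopologyAttr("elements", structure.elements.astype(str))
    uniq = np.unique(structure.resids)
    u.add_TopologyAttr("resids", uniq)
    u.add_TopologyAttr(
        "resnames",
        [structure.resnames[structure.resids == r][0] for r in uniq],
    )
    u.add_TopologyAttr(
        "chainIDs",
        structure.chains.astype(str),
    )
    u.atoms.positions = traj.coords[traj.ref_frame]
    pdb_path = outdir / "system.pdb"
    dcd_path = outdir / "traj.dcd"
    with mda.Writer(str(pdb_path)) as w:
        w.write(u.atoms)
    with mda.Writer(str(dcd_path), n_atoms=structure.n_atoms) as w:
        for f in range(traj.n_frames):
            u.atoms.positions = traj.coords[f]
            w.write(u.atoms)
    sidecar = {
        "dt_ps": traj.dt_ps,
        "ref_frame": traj.ref_frame,
        "n_frames": traj.n_frames,
        "regions": {k: list(v) for k, v in structure.regions.items()},
        "bonds": structure.bonds.tolist(),
        "atoms": {
            "name": structure.names.tolist(),
            "element": structure.elements.tolist(),
            "resid": structure.resids.tolist(),
            "resname": structure.resnames.tolist(),
            "chain": structure.chains.tolist(),
            "role": structure.roles.tolist(),
            "charge": structure.charges.tolist(),
            "rmin2": structure.rmin2.tolist(),
            "epsilon": structure.epsilon.tolist(),
            "born": structure.born.tolist(),
            "donor": structure.donor.tolist(),
            "acceptor": structure.acceptor.tolist(),
            "cation": structure.cation.tolist(),
            "anion": structure.anion.tolist(),
            "hydrophobic": structure.hydrophobic.tolist(),
            "ring_id": structure.ring_ids.tolist(),
        },
    }
    sidecar_path = outdir / "params.json"
    sidecar_path.write_text(json.dumps(sidecar))
    return {"pdb": pdb_path, "dcd": dcd_path, "params": sidecar_path}


def read_system(indir) -> tuple[ParamStructure, Trajectory]:
    """Read back a system written by :func:`write_system`."""
    import MDAnalysis as mda

    indir = Path(indir)
    pdb_path = indir / "system.pdb"
    dcd_path = indir / "traj.dcd"
    sidecar_path = indir / "params.json"
    for p in (pdb_path, dcd_path, sidecar_path):
        if not p.exists():
            raise TrajectoryIOError(f"missing file: {p}")
    d = json.loads(sidecar_path.read_text())
    a = d["atoms"]
    structure = ParamStructure(
        names=np.array(a["name"]),
        elements=np.array(a["element"]),
        resids=np.array(a["resid"]),
        resnames=np.array(a["resname"]),
        chains=np.array(a["chain"]),
        roles=np.array(a["role"]),
        charges=np.array(a["charge"]),
        rmin2=np.array(a["rmin2"]),
        epsilon=np.array(a["epsilon"]),
        born=np.array(a["born"]),
        regions={k: tuple(v) for k, v in d["regions"].items()},
        bonds=np.array(d["bonds"], dtype=int).reshape(-1, 2),
        donor=np.array(a["donor"]),
        acceptor=np.array(a["acceptor"]),
        cation=np.array(a["cation"]),
        anion=np.array(a["anion"]),
        hydrophobic=np.array(a["hydrophobic"]),
        ring_ids=np.array(a["ring_id"]),
    )
    try:
        u = mda.Universe(str(pdb_path), str(dcd_path))
    except (OSError, ValueError, EOFError) as exc:
        raise TrajectoryIOError(
            f"failed to read trajectory {dcd_path} "
            f"({dcd_path.stat().st_size} bytes on disk): {exc}"
        ) from exc
    if len(u.atoms) != structure.n_atoms:
        raise TrajectoryIOError(
            f"atom-count mismatch: sidecar has {structure.n_atoms}, files have {len(u.atoms)}"
        )
    expected = d.get("n_frames")
    if expected is not None and len(u.trajectory) != expected:
        raise TrajectoryIOError(
            f"truncated trajectory {dcd_path}: expected {expected} frames, "
            f"found {len(u.trajectory)} ({dcd_path.stat().st_size} bytes on disk)"
        )
    coords = np.empty((len(u.trajectory), structure.n_atoms, 3))
    try:
        for f, ts in enumerate(u.trajectory):
            coords[f] = ts.positions
    except (OSError, EOFError, RuntimeError) as exc:
        raise TrajectoryIOError(
            f"truncated or corrupt trajectory {dcd_path} at frame {f} "
            f"({dcd_path.stat().st_size} bytes on disk): {exc}"
        ) from exc
    traj = Trajectory(coords, dt_ps=d["dt_ps"], ref_frame=d["ref_frame"])
    return structure, traj


def roundtrip_io(structure: ParamStructure, traj: Trajectory, path):
    """Write then immediately re-read a system; coordinates agree to the
    single-precision limit of the DCD format (<=1e-3 Å)."""
    write_system(structure, traj, path)
    return read_system(path)
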