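"""MM/GBSA-style binding energetics with per-residue decomposition.

The calculated binding free energy is assembled as

    ΔG_cal = ΔE_elec + ΔE_vdW + ΔE_covalent + ΔG_solv − TΔS = ΔE_bind − TΔS

with molecular-mechanics electrostatics and Lennard-Jones terms, a
generalized-Born (Still) polar solvation term, a surface-area nonpolar
term (Shrake–Rupley SASA times a surface-tension coefficient), and a
normal-mode vibrational entropy.  The single-trajectory protocol is used:
complex, receptor and ligand are scored on identical frames and the
binding terms are the per-frame differences, averaged.

Conventions: interior dielectric 1, exterior 78.5, Coulomb constant
332.0637, GB prefactor 166.03, probe radius 1.4 Å, surface tension
0.0072 kcal/(mol Å²), temperature 310 K; no distance cutoffs.  Nonbonded
terms skip 1-2 and 1-3 connected pairs (their energy belongs to the
covalent term), so a covalent protein–ligand link does not leak a clash
into ΔE_vdW.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from ._constants import (
    COULOMB_KCAL,
    EPS_SOLVENT,
    GB_PREFACTOR,
    H_PLANCK,
    KB_J,
    OMEGA2_PER_EIGVAL,
    PROBE_RADIUS,
    R_KCAL,
    SURFACE_TENSION,
    T_DEFAULT,
)
from .system import ParamStructure, Trajectory


class EnergeticsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# molecular-mechanics cross terms
# ---------------------------------------------------------------------------

def _excluded_pairs(structure: ParamStructure) -> set:
    """1-2 and 1-3 connected pairs (as frozensets of atom indices)."""
    adj: dict[int, set] = {}
    for i, j in structure.bonds:
        adj.setdefault(int(i), set()).add(int(j))
        adj.setdefault(int(j), set()).add(int(i))
    excl = {frozenset((int(i), int(j))) for i, j in structure.bonds}
    for mid, nbrs in adj.items():
        nbrs = sorted(nbrs)
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                excl.add(frozenset((nbrs[a], nbrs[b])))
    return excl


def mm_interaction_energy(
    frame,
    structure: ParamStructure,
    group_a,
    group_b,
    dielectric: float = 1.0,
) -> tuple[float, float]:
    """Electrostatic and van der Waals cross energies between two groups.

    elec = 332.0637 Σ q_i q_j / (ε r_ij); vdW from Lennard-Jones 12-6 with
    Lorentz–Berthelot combination, minimum −ε_ij at r = r_min,ij.
    """
    frame = np.asarray(frame)
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    if np.intersect1d(a, b).size:
        raise EnergeticsError("groups must be disjoint")
    d = np.linalg.norm(frame[a][:, None, :] - frame[b][None, :, :], axis=2)
    if np.any(d < 1e-6):
        ii, jj = np.unravel_index(int(np.argmin(d)), d.shape)
        raise EnergeticsError(f"overlapping atoms {int(a[ii])} and {int(b[jj])}")
    mask = np.ones_like(d, dtype=bool)
    excl = _excluded_pairs(structure)
    if excl:
        for ii, ai in enumerate(a):
            for jj, bj in enumerate(b):
                if frozenset((int(ai), int(bj))) in excl:
                    mask[ii, jj] = False
    qq = np.outer(structure.charges[a], structure.charges[b])
    elec = COULOMB_KCAL * float((qq[mask] / (dielectric * d[mask])).sum())
    rmin = structure.rmin2[a][:, None] + structure.rmin2[b][None, :]
    epsij = np.sqrt(np.outer(structure.epsilon[a], structure.epsilon[b]))
    ratio6 = (rmin / d) ** 6
    vdw = float((epsij[mask] * (ratio6[mask] ** 2 - 2.0 * ratio6[mask])).sum())
    return elec, vdw


def covalent_energy(frame, structure: ParamStructure, group_a, group_b,
                    k_bond: float = 100.0, r0: dict | None = None) -> float:
    """Bonded (harmonic) energy across bonds that connect the two groups.

    Zero when the groups share no bonds (noncovalent split).  ``r0`` maps
    bond (i, j) tuples to reference lengths; by default the observed length
    is taken as the reference, making the term a strain energy of zero at
    the reference geometry.
    """
    frame = np.asarray(frame)
    a = set(int(x) for x in np.asarray(group_a).ravel())
    b = set(int(x) for x in np.asarray(group_b).ravel())
    e = 0.0
    for i, j in structure.bonds:
        i, j = int(i), int(j)
        if (i in a and j in b) or (j in a and i in b):
            r = float(np.linalg.norm(frame[i] - frame[j]))
            ref = (r0 or {}).get((i, j), (r0 or {}).get((j, i), r))
            e += k_bond * (r - ref) ** 2
    return e


# ---------------------------------------------------------------------------
# solvation: GB polar + SASA nonpolar
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5**0.5) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def shrake_rupley_sasa(
    frame, radii, probe: float = PROBE_RADIUS, n_points: int = 960
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²) by sphere sampling."""
    frame = np.asarray(frame, dtype=float)
    radii = np.asarray(radii, dtype=float) + probe
    n = len(frame)
    pts = _sphere_points(n_points)
    sasa = np.zeros(n)
    d2 = ((frame[:, None, :] - frame[None, :, :]) ** 2).sum(axis=2)
    for i in range(n):
        nbrs = np.flatnonzero((d2[i] < (radii[i] + radii) ** 2) & (np.arange(n) != i))
        surface = frame[i] + radii[i] * pts
        if len(nbrs):
            dd = ((surface[:, None, :] - frame[nbrs][None, :, :]) ** 2).sum(axis=2)
            buried = (dd < (radii[nbrs] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        sasa[i] = 4.0 * np.pi * radii[i] ** 2 * frac
    return sasa


def gb_polar_energy(frame, charges, born_radii, eps_solvent: float = EPS_SOLVENT) -> float:
    """Still's generalized-Born polar solvation energy, self terms included.

    E = -166.03 (1 - 1/ε) Σ_ij q_i q_j / f_GB(r_ij) over all ordered pairs,
    with f_GB = sqrt(r² + R_i R_j exp(-r²/(4 R_i R_j))).  Reduces to the
    Born ion formula for a single charge and to per-atom self terms at
    infinite separation.
    """
    frame = np.asarray(frame, dtype=float)
    q = np.asarray(charges, dtype=float)
    R = np.asarray(born_radii, dtype=float)
    if np.any(R <= 0):
        raise EnergeticsError("Born radii must be positive")
    r2 = ((frame[:, None, :] - frame[None, :, :]) ** 2).sum(axis=2)
    RR = np.outer(R, R)
    fgb = np.sqrt(r2 + RR * np.exp(-r2 / (4.0 * RR)))
    return float(-GB_PREFACTOR * (1.0 - 1.0 / eps_solvent) * (np.outer(q, q) / fgb).sum())


def solvation_energy(
    frame,
    structure: ParamStructure,
    group,
    eps_solvent: float = EPS_SOLVENT,
    probe: float = PROBE_RADIUS,
    gamma: float = SURFACE_TENSION,
    n_points: int = 960,
) -> tuple[float, float, float]:
    """(polar, nonpolar, sasa) solvation terms for one atom group."""
    group = np.asarray(group, dtype=int)
    frame = np.asarray(frame)[group]
    polar = gb_polar_energy(frame, structure.charges[group], structure.born[group], eps_solvent)
    sasa = float(shrake_rupley_sasa(frame, structure.rmin2[group], probe, n_points).sum())
    return polar, gamma * sasa, sasa


# ---------------------------------------------------------------------------
# normal-mode entropy
# ---------------------------------------------------------------------------

class ElasticNetworkModel:
    """Harmonic springs between all atom pairs within a cutoff.

    A deliberately simple surrogate potential for the vibrational-entropy
    stage: any frame is its own energy minimum, so normal modes are well
    defined at every snapshot without a separate minimization.
    """

    def __init__(self, ref_coords, cutoff: float = 12.0, k: float = 1.0):
        self.ref = np.asarray(ref_coords, dtype=float)
        n = len(self.ref)
        d = np.linalg.norm(self.ref[:, None, :] - self.ref[None, :, :], axis=2)
        iu = np.triu_indices(n, k=1)
        keep = d[iu] <= cutoff
        self.pairs = np.stack([iu[0][keep], iu[1][keep]], axis=1)
        self.r0 = d[iu][keep]
        self.k = k

    def energy(self, coords) -> float:
        coords = np.asarray(coords, dtype=float).reshape(self.ref.shape)
        d = np.linalg.norm(coords[self.pairs[:, 0]] - coords[self.pairs[:, 1]], axis=1)
        return float(0.5 * self.k * ((d - self.r0) ** 2).sum())

    def hessian(self, coords=None) -> np.ndarray:
        """Analytic Hessian at the network's equilibrium geometry.

        At r = r0 each spring contributes k r̂r̂ᵀ along the bond direction
        and nothing perpendicular (the anisotropic-network-model form).
        """
        x = self.ref if coords is None else np.asarray(coords, float).reshape(self.ref.shape)
        n = len(x)
        h = np.zeros((3 * n, 3 * n))
        for (i, j) in self.pairs:
            rij = x[j] - x[i]
            rhat = rij / np.linalg.norm(rij)
            block = self.k * np.outer(rhat, rhat)
            si, sj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
            h[si, si] += block
            h[sj, sj] += block
            h[si, sj] -= block
            h[sj, si] -= block
        return h


def numerical_hessian(energy_fn, coords, h: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian of a scalar energy function."""
    x0 = np.asarray(coords, dtype=float).ravel()
    n = x0.size
    hess = np.empty((n, n))
    e0 = energy_fn(x0)
    # diagonal and upper triangle via function evaluations
    ei = np.empty((n, 2))
    for i in range(n):
        for s, sign in enumerate((1.0, -1.0)):
            x = x0.copy()
            x[i] += sign * h
            ei[i, s] = energy_fn(x)
        hess[i, i] = (ei[i, 0] - 2.0 * e0 + ei[i, 1]) / h**2
    for i in range(n):
        for j in range(i + 1, n):
            x = x0.copy()
            x[[i, j]] += h
            epp = energy_fn(x)
            x = x0.copy()
            x[i] += h
            x[j] -= h
            epm = energy_fn(x)
            x = x0.copy()
            x[i] -= h
            x[j] += h
            emp = energy_fn(x)
            x = x0.copy()
            x[[i, j]] -= h
            emm = energy_fn(x)
            hess[i, j] = hess[j, i] = (epp - epm - emp + emm) / (4.0 * h**2)
    return hess


def harmonic_entropy(nu_hz: np.ndarray, T: float) -> float:
    """Vibrational entropy, kcal/(mol K), of harmonic modes at frequencies nu."""
    x = H_PLANCK * np.asarray(nu_hz) / (KB_J * T)
    return float(R_KCAL * (x / np.expm1(x) - np.log1p(-np.exp(-x))).sum())


def vibrational_entropy(
    structure: ParamStructure,
    energy_model,
    coords,
    T: float = T_DEFAULT,
    sel=None,
    zero_tol: float = 1e-9,
) -> float:
    """Entropy (kcal/(mol K)) from mass-weighted normal modes at a minimum.

    Near-zero rigid-body modes (at most 6) are removed; a strongly negative
    eigenvalue or more than 6 near-zero modes means the coordinates are not
    a minimum and raises.
    """
    coords = np.asarray(coords, dtype=float)
    if sel is None:
        masses = structure.masses
    else:
        masses = structure.masses[np.asarray(sel, dtype=int)]
    if hasattr(energy_model, "hessian"):
        hess = energy_model.hessian(coords)
    else:
        hess = numerical_hessian(energy_model.energy, coords)
    m = np.repeat(masses, 3)
    mw = hess / np.sqrt(np.outer(m, m))
    evals = np.linalg.eigvalsh(mw)
    scale = max(abs(evals).max(), 1.0)
    near_zero = np.abs(evals) < zero_tol * scale
    if near_zero.sum() > 6:
        raise EnergeticsError(
            f"not a minimum: {int(near_zero.sum())} near-zero modes (max 6 allowed)"
        )
    vib = evals[~near_zero]
    if np.any(vib < -zero_tol * scale):
        raise EnergeticsError("not a minimum: negative Hessian eigenvalue")
    vib = vib[vib > 0]
    if vib.size == 0:
        return 0.0
    nu = np.sqrt(vib * OMEGA2_PER_EIGVAL) / (2.0 * np.pi)
    return harmonic_entropy(nu, T)


def nma_entropy(
    structure: ParamStructure,
    frame,
    receptor_sel,
    ligand_sel,
    T: float = T_DEFAULT,
    cutoff: float = 12.0,
    k: float = 1.0,
    minimize: bool = False,
) -> float:
    """-TΔS (kcal/mol) for binding: -T (S_complex - S_receptor - S_ligand).

    Each species' normal modes come from an elastic-network surrogate built
    at the frame coordinates; ``minimize=True`` first relaxes the frame
    under that model (a no-op for the elastic network, whose minimum is the
    construction geometry).
    """
    frame = np.asarray(frame, dtype=float)
    receptor_sel = np.asarray(receptor_sel, dtype=int)
    ligand_sel = np.asarray(ligand_sel, dtype=int)
    complex_sel = np.concatenate([receptor_sel, ligand_sel])
    entropies = []
    for sel in (complex_sel, receptor_sel, ligand_sel):
        x = frame[sel]
        model = ElasticNetworkModel(x, cutoff=cutoff, k=k)
        if minimize:
            res = scipy.optimize.minimize(model.energy, x.ravel(), method="L-BFGS-B")
            x = res.x.reshape(x.shape)
        entropies.append(vibrational_entropy(structure, model, x, T=T, sel=sel))
    s_complex, s_receptor, s_ligand = entropies
    return -T * (s_complex - s_receptor - s_ligand)


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

@dataclass
class EnergyReport:
    """The per-system energy ledger (kcal/mol) with standard errors."""

    e_elec: float
    e_vdw: float
    e_covalent: float
    g_solv: float
    g_solv_polar: float
    g_solv_nonpolar: float
    minus_t_ds: float
    stderr: dict = field(default_factory=dict)
    n_frames: int = 0

    @property
    def e_bind(self) -> float:
        return self.e_elec + self.e_vdw + self.e_covalent + self.g_solv

    @property
    def g_cal(self) -> float:
        return self.e_bind + self.minus_t_ds

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "dE_vdW": self.e_vdw,
                "dE_elec": self.e_elec,
                "dE_covalent": self.e_covalent,
                "dG_solv": self.g_solv,
                "dE_bind": self.e_bind,
                "-TdS": self.minus_t_ds,
                "dG_cal": self.g_cal,
            }
        )


def mmgbsa_binding(
    traj: Trajectory,
    structure: ParamStructure,
    receptor_sel,
    ligand_sel,
    stride: int = 1,
    T: float = T_DEFAULT,
    entropy_frames: int = 0,
    sasa_points: int = 480,
) -> EnergyReport:
    """Single-trajectory MM/GBSA over ``traj`` frames taken every ``stride``.

    ΔX = X_complex − X_receptor − X_ligand per frame, averaged.  For the
    pairwise MM terms this difference is exactly the receptor–ligand cross
    term, which is what is computed.  ``entropy_frames`` > 0 additionally
    averages the normal-mode −TΔS over that many evenly spaced frames.
    """
    traj.check_structure(structure)
    receptor_sel = np.asarray(receptor_sel, dtype=int)
    ligand_sel = np.asarray(ligand_sel, dtype=int)
    if stride < 1:
        raise EnergeticsError("frame stride must be >= 1")
    frames = list(range(0, traj.n_frames, stride))
    if not frames:
        raise EnergeticsError("frame stride yields no frames")
    complex_sel = np.concatenate([receptor_sel, ligand_sel])
    per = {k: [] for k in ("elec", "vdw", "cov", "polar", "nonpolar")}
    # strain-free covalent reference from the trajectory's reference frame
    ref_lengths = {
        (int(i), int(j)): float(
            np.linalg.norm(traj.coords[traj.ref_frame, int(i)] - traj.coords[traj.ref_frame, int(j)])
        )
        for i, j in structure.bonds
    }
    for f in frames:
        x = traj.coords[f]
        elec, vdw = mm_interaction_energy(x, structure, receptor_sel, ligand_sel)
        per["elec"].append(elec)
        per["vdw"].append(vdw)
        per["cov"].append(covalent_energy(x, structure, receptor_sel, ligand_sel, r0=ref_lengths))
        pol_c, np_c, _ = solvation_energy(x, structure, complex_sel, n_points=sasa_points)
        pol_r, np_r, _ = solvation_energy(x, structure, receptor_sel, n_points=sasa_points)
        pol_l, np_l, _ = solvation_energy(x, structure, ligand_sel, n_points=sasa_points)
        per["polar"].append(pol_c - pol_r - pol_l)
        per["nonpolar"].append(np_c - np_r - np_l)

    def mean_se(v):
        v = np.asarray(v)
        return float(v.mean()), float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0

    e_elec, se_elec = mean_se(per["elec"])
    e_vdw, se_vdw = mean_se(per["vdw"])
    e_cov, se_cov = mean_se(per["cov"])
    polar, se_pol = mean_se(per["polar"])
    nonpolar, se_np = mean_se(per["nonpolar"])

    minus_t_ds = 0.0
    if entropy_frames > 0:
        picks = np.unique(np.linspace(0, len(frames) - 1, entropy_frames).astype(int))
        vals = [
            nma_entropy(structure, traj.coords[frames[p]], receptor_sel, ligand_sel, T=T)
            for p in picks
        ]
        minus_t_ds = float(np.mean(vals))

    return EnergyReport(
        e_elec=e_elec,
        e_vdw=e_vdw,
        e_covalent=e_cov,
        g_solv=polar + nonpolar,
        g_solv_polar=polar,
        g_solv_nonpolar=nonpolar,
        minus_t_ds=minus_t_ds,
        stderr={
            "dE_elec": se_elec,
            "dE_vdW": se_vdw,
            "dE_covalent": se_cov,
            "dG_solv": float(np.hypot(se_pol, se_np)),
        },
        n_frames=len(frames),
    )


def per_residue_decomposition(
    traj: Trajectory,
    structure: ParamStructure,
    ligand_sel,
    stride: int = 1,
    sasa_points: int = 480,
) -> pd.DataFrame:
    """Assign receptor–ligand cross terms to individual protein residues.

    Pairwise electrostatic, vdW and GB-polar cross terms go to the protein
    residue of each pair; the nonpolar column is the residue's SASA burial
    upon complexation times the surface tension.  Residue totals sum to the
    whole-system cross terms computed the same way.
    """
    traj.check_structure(structure)
    ligand_sel = np.asarray(ligand_sel, dtype=int)
    frames = list(range(0, traj.n_frames, stride))
    if not frames:
        raise EnergeticsError("frame stride yields no frames")
    resids = structure.protein_resids()
    acc = pd.DataFrame(
        0.0, index=resids, columns=["vdW", "elec", "polar", "nonpolar", "total"]
    )
    protein = np.flatnonzero(structure.roles == "protein")
    excl = _excluded_pairs(structure)
    ql = structure.charges[ligand_sel]
    Rl = structure.born[ligand_sel]
    for f in frames:
        x = traj.coords[f]
        receptor_all = np.flatnonzero(structure.roles != "ligand")
        sasa_complex = shrake_rupley_sasa(
            x[np.concatenate([receptor_all, ligand_sel])],
            structure.rmin2[np.concatenate([receptor_all, ligand_sel])],
            n_points=sasa_points,
        )[: len(receptor_all)]
        sasa_receptor = shrake_rupley_sasa(
            x[receptor_all], structure.rmin2[receptor_all], n_points=sasa_points
        )
        burial = {int(a): sasa_complex[k] - sasa_receptor[k] for k, a in enumerate(receptor_all)}
        for resid in resids:
            atoms = structure.residue_atoms(int(resid))
            d = np.linalg.norm(x[atoms][:, None, :] - x[ligand_sel][None, :, :], axis=2)
            mask = np.ones_like(d, dtype=bool)
            for ii, ai in enumerate(atoms):
                for jj, bj in enumerate(ligand_sel):
                    if frozenset((int(ai), int(bj))) in excl:
                        mask[ii, jj] = False
            qq = np.outer(structure.charges[atoms], ql)
            elec = COULOMB_KCAL * float((qq[mask] / d[mask]).sum())
            rmin = structure.rmin2[atoms][:, None] + structure.rmin2[ligand_sel][None, :]
            epsij = np.sqrt(np.outer(structure.epsilon[atoms], structure.epsilon[ligand_sel]))
            r6 = (rmin / d) ** 6
            vdw = float((epsij[mask] * (r6[mask] ** 2 - 2 * r6[mask])).sum())
            RR = np.outer(structure.born[atoms], Rl)
            fgb = np.sqrt(d**2 + RR * np.exp(-(d**2) / (4 * RR)))
            polar = float(-2.0 * GB_PREFACTOR * (1 - 1 / EPS_SOLVENT) * (qq / fgb).sum())
            nonpolar = SURFACE_TENSION * float(sum(burial[int(a)] for a in atoms))
            acc.loc[resid, ["vdW", "elec", "polar", "nonpolar"]] += [vdw, elec, polar, nonpolar]
    acc /= len(frames)
    acc["total"] = acc[["vdW", "elec", "polar", "nonpolar"]].sum(axis=1)
    return acc


# ---------------------------------------------------------------------------
# experimental conversion and affinity tables
# ---------------------------------------------------------------------------

def dg_from_ic50(ic50_nM: float, T: float = T_DEFAULT) -> float:
    """Experimental binding free energy ΔG_exp = RT ln(IC50), kcal/mol."""
    if ic50_nM <= 0:
        raise EnergeticsError("IC50 must be positive")
    return R_KCAL * T * float(np.log(ic50_nM * 1e-9))


@dataclass
class AffinityRecord:
    system: str
    ic50_nM: float | None
    dg_exp: float | None
    dg_cal: float
    ddg_cal: float | None  # None for the reference system


def assemble_affinity_table(
    reports: dict[str, EnergyReport],
    ic50s: dict[str, float],
    reference: str,
    T: float = T_DEFAULT,
    require_ic50: bool = True,
) -> list[AffinityRecord]:
    """Per-system ΔG_cal/ΔG_exp/ΔΔG_cal records, ΔΔG relative to ``reference``."""
    if reference not in reports:
        raise EnergeticsError(f"reference system {reference!r} missing from reports")
    dg_ref = reports[reference].g_cal
    records = []
    for name, rep in reports.items():
        ic50 = ic50s.get(name)
        if ic50 is None and require_ic50:
            raise EnergeticsError(f"missing IC50 for system {name!r}")
        records.append(
            AffinityRecord(
                system=name,
                ic50_nM=ic50,
                dg_exp=dg_from_ic50(ic50, T) if ic50 else None,
                dg_cal=rep.g_cal,
                ddg_cal=None if name == reference else rep.g_cal - dg_ref,
            )
        )
    return records


def r_squared(x, y) -> float:
    """Squared Pearson correlation between two equal-length value lists."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise EnergeticsError("need equal-length inputs with at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise EnergeticsError("zero variance input")
    return float(np.corrcoef(x, y)[0, 1] ** 2)
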