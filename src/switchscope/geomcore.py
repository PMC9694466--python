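"""Geometric primitives: superposition, RMSD/RMSF, flexibility selection,
and switch-state classification.

All downstream stages (featurization, PMF coordinates, network correlations)
route their structural alignment through :func:`kabsch_superpose`, which
returns a proper rotation (reflections rejected) minimizing the weighted
RMSD between two point sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .system import Trajectory


class GeometryError(ValueError):
    pass


def kabsch_superpose(mobile, target, weights=None):
    """Optimal rigid superposition of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``target`` in the
    (weighted) least-squares sense.  The rotation is proper
    (determinant +1).

    Raises
    ------
    GeometryError
        For fewer than 3 points or (near-)collinear point sets, where the
        rotation is not uniquely determined.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise GeometryError("point sets must have identical shapes")
    n = mobile.shape[0]
    if n < 3:
        raise GeometryError("superposition needs at least 3 points")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise GeometryError("weights must be non-negative with positive sum")
    w = w / w.sum()
    mc = mobile - (w[:, None] * mobile).sum(axis=0)
    tc = target - (w[:, None] * target).sum(axis=0)
    for pts, label in ((mc, "mobile"), (tc, "target")):
        s = np.linalg.svd(pts * np.sqrt(w)[:, None], compute_uv=False)
        if s[0] > 0 and s[1] / s[0] < 1e-9:
            raise GeometryError(f"{label} points are collinear; rotation is degenerate")
    h = (mc * w[:, None]).T @ tc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = (w[:, None] * target).sum(axis=0) - rotation @ (
        (w[:, None] * mobile).sum(axis=0)
    )
    fitted = mobile @ rotation.T + translation
    rmsd = float(np.sqrt((w[:, None] * (fitted - target) ** 2).sum()))
    return rotation, translation, rmsd


def apply_transform(coords, rotation, translation):
    return np.asarray(coords) @ rotation.T + translation


def superpose_frames(traj_coords, reference, fit_sel):
    """Superpose every frame onto ``reference`` using the fit selection.

    Returns a new (frames, atoms, 3) array with the transform from the fit
    selection applied to all atoms of each frame.
    """
    fit_sel = np.asarray(fit_sel, dtype=int)
    out = np.empty_like(traj_coords)
    ref = reference[fit_sel]
    for f in range(traj_coords.shape[0]):
        rot, trans, _ = kabsch_superpose(traj_coords[f, fit_sel], ref)
        out[f] = apply_transform(traj_coords[f], rot, trans)
    return out


def rmsd_series(traj: Trajectory, reference, measure_sel, fit_sel=None) -> np.ndarray:
    """Per-frame RMSD (Å) of ``measure_sel`` after fitting on ``fit_sel``.

    ``reference`` is a frame index or an (atoms, 3) coordinate array.
    """
    measure_sel = np.asarray(measure_sel, dtype=int)
    if measure_sel.size == 0:
        raise GeometryError("empty measure selection")
    ref = traj.coords[reference] if np.isscalar(reference) else np.asarray(reference)
    if fit_sel is None:
        fit_sel = np.arange(traj.n_atoms)
    fit_sel = np.asarray(fit_sel, dtype=int)
    if fit_sel.size == 0:
        raise GeometryError("empty fit selection")
    fitted = superpose_frames(traj.coords, ref, fit_sel)
    diff = fitted[:, measure_sel] - ref[measure_sel]
    return np.sqrt((diff**2).sum(axis=2).mean(axis=1))


def rmsf_profile(traj: Trajectory, sel=None, fit_sel=None) -> np.ndarray:
    """Per-atom RMSF (Å) about the mean structure.

    Frames are first superposed onto frame 0, the mean is formed, frames are
    re-superposed onto that mean (one iteration), and the fluctuation is
    measured about the final mean.
    """
    if traj.n_frames < 2:
        raise GeometryError("RMSF needs at least 2 frames")
    if sel is None:
        sel = np.arange(traj.n_atoms)
    sel = np.asarray(sel, dtype=int)
    if fit_sel is None:
        fit_sel = sel
    fitted = superpose_frames(traj.coords, traj.coords[0], fit_sel)
    mean1 = fitted.mean(axis=0)
    fitted = superpose_frames(traj.coords, mean1, fit_sel)
    mean2 = fitted.mean(axis=0)
    dev = fitted[:, sel] - mean2[sel]
    return np.sqrt((dev**2).sum(axis=2).mean(axis=0))


def select_flexible_residues(rmsf_by_resid: dict, threshold: float = 2.0) -> list:
    """Residues whose RMSF strictly exceeds ``threshold`` Å, in index order.

    The 2 Å default is the gate used to pick metastable-loop residues as
    the Markov-model metric.
    """
    if not rmsf_by_resid:
        raise GeometryError("empty RMSF profile")
    return sorted(r for r, v in rmsf_by_resid.items() if v > threshold)


@dataclass(frozen=True)
class RectZone:
    """Axis-aligned rectangle in the (loop I RMSD, loop II RMSD) plane."""

    x_lo: float
    x_hi: float
    y_lo: float
    y_hi: float

    def contains(self, x, y):
        return (self.x_lo <= x) & (x < self.x_hi) & (self.y_lo <= y) & (y < self.y_hi)

    def overlaps(self, other: "RectZone") -> bool:
        return (
            self.x_lo < other.x_hi
            and other.x_lo < self.x_hi
            and self.y_lo < other.y_hi
            and other.y_lo < self.y_hi
        )


def classify_switch_state(loop1_rmsd, loop2_rmsd, zones: dict):
    """Label conformations by rectangular zones in the loop-RMSD plane.

    ``zones`` maps labels (e.g. ``typeA``, ``typeB``, ``open``) to
    :class:`RectZone` instances (or ``(x_lo, x_hi, y_lo, y_hi)`` tuples);
    zones must be pairwise disjoint.  Points falling in no zone are labelled
    ``other``.  Scalar inputs return a single label; array inputs return an
    array of labels.
    """
    zones = {k: z if isinstance(z, RectZone) else RectZone(*z) for k, z in zones.items()}
    keys = list(zones)
    for i, a in enumerate(keys):
        for b in keys[i + 1 :]:
            if zones[a].overlaps(zones[b]):
                raise GeometryError(f"zones {a!r} and {b!r} overlap")
    x = np.atleast_1d(np.asarray(loop1_rmsd, dtype=float))
    y = np.atleast_1d(np.asarray(loop2_rmsd, dtype=float))
    labels = np.full(x.shape, "other", dtype=object)
    for name, zone in zones.items():
        labels[zone.contains(x, y)] = name
    if np.isscalar(loop1_rmsd):
        return labels[0]
    return labels


def state_fractions(labels) -> dict:
    """Fraction of frames per conformational label."""
    labels = np.asarray(labels, dtype=object)
    vals, counts = np.unique(labels.astype(str), return_counts=True)
    return {v: c / len(labels) for v, c in zip(vals, counts)}
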