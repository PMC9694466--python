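"""2D potential-of-mean-force surfaces over loop RMSD coordinates.

The free energy per bin is obtained by Boltzmann inversion of the bin
occupancy, F = −k_B T ln(count / max_count), so the best-populated bin
sits at F = 0 and empty bins are masked rather than set to 0 or ∞.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._constants import KB_KCAL, T_DEFAULT


class PmfError(ValueError):
    pass


@dataclass
class PmfGrid:
    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ma.MaskedArray  # kcal/mol, min-shifted to 0, empty bins masked
    counts: np.ndarray
    temperature: float

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0

    def display_surface(self, pad: float = 1.0) -> np.ndarray:
        """Dense surface for plotting: empty bins shown at max occupied F + pad."""
        out = self.free_energy.filled(float(self.free_energy.max()) + pad)
        return out


def compute_pmf2d(x, y, bins: int = 50, T: float = T_DEFAULT,
                  ranges=None, pad_frac: float = 0.05) -> PmfGrid:
    """Boltzmann-inverted 2D free-energy surface on loop-RMSD coordinates.

    Bins are half-open [lo, hi) with the right-most bin closed (numpy
    convention); by default the grid spans the data range padded by 5%.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise PmfError("coordinate arrays must have equal length")
    nbins = bins if np.iterable(bins) else (bins, bins)
    if len(x) < max(np.atleast_1d(nbins)):
        raise PmfError("fewer frames than bins")
    if ranges is None:
        ranges = []
        for v in (x, y):
            lo, hi = float(v.min()), float(v.max())
            span = (hi - lo) or 1.0
            ranges.append((lo - pad_frac * span, hi + pad_frac * span))
    counts, x_edges, y_edges = np.histogram2d(x, y, bins=nbins, range=ranges)
    if (counts > 0).sum() == 1:
        warnings.warn("all frames fall into a single bin", stacklevel=2)
    kbt = KB_KCAL * T
    with np.errstate(divide="ignore"):
        f = -kbt * np.log(counts / counts.max())
    fe = np.ma.MaskedArray(f, mask=counts == 0)
    return PmfGrid(x_edges=x_edges, y_edges=y_edges, free_energy=fe,
                   counts=counts, temperature=T)


@dataclass
class Basin:
    bin_idx: tuple
    free_energy: float
    x: float
    y: float
    member_frames: np.ndarray


def locate_basins(grid: PmfGrid, depth_threshold: float = 1.0,
                  x=None, y=None) -> list[Basin]:
    """Local minima of the surface over 8-neighborhoods, kept if below
    (global minimum + depth_threshold).  The global minimum is always a
    basin.  If the original coordinates are given, each basin reports the
    frames falling into its bin."""
    f = grid.free_energy
    if not grid.occupied.any():
        raise PmfError("grid has no occupied bins")
    nx, ny = f.shape
    fmin = float(f.min())
    minima = set()
    for i in range(nx):
        for j in range(ny):
            if f.mask[i, j]:
                continue
            v = f[i, j]
            is_min = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == dj == 0:
                        continue
                    a, b = i + di, j + dj
                    if 0 <= a < nx and 0 <= b < ny and not f.mask[a, b] and f[a, b] < v:
                        is_min = False
            if is_min and (v <= fmin + depth_threshold):
                minima.add((i, j))
    # merge 8-connected tied plateaus into single basins
    basins = []
    seen: set = set()
    for start in sorted(minima):
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            (i, j) = stack.pop()
            comp.append((i, j))
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    nb = (i + di, j + dj)
                    if nb in minima and nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
        i, j = min(comp, key=lambda b: (f[b], b))
        frames = np.empty(0, dtype=int)
        if x is not None and y is not None:
            frames = np.concatenate([_bin_members(grid, a, b, x, y) for a, b in sorted(comp)])
        basins.append(
            Basin(
                bin_idx=(i, j),
                free_energy=float(f[i, j]),
                x=0.5 * (grid.x_edges[i] + grid.x_edges[i + 1]),
                y=0.5 * (grid.y_edges[j] + grid.y_edges[j + 1]),
                member_frames=frames,
            )
        )
    basins.sort(key=lambda b: (b.free_energy, b.bin_idx))
    return basins


def _bin_index(edges, value):
    """Half-open binning [lo, hi); right-most bin closed; clamped with warning."""
    idx = int(np.searchsorted(edges, value, side="right")) - 1
    if value == edges[-1]:
        idx = len(edges) - 2
    if idx < 0 or idx > len(edges) - 2:
        warnings.warn(f"value {value} outside grid range; clamped", stacklevel=3)
        idx = int(np.clip(idx, 0, len(edges) - 2))
    return idx


def _bin_members(grid, i, j, x, y):
    x = np.asarray(x)
    y = np.asarray(y)
    in_x = (x >= grid.x_edges[i]) & ((x < grid.x_edges[i + 1]) | ((i == len(grid.x_edges) - 2) & (x == grid.x_edges[i + 1])))
    in_y = (y >= grid.y_edges[j]) & ((y < grid.y_edges[j + 1]) | ((j == len(grid.y_edges) - 2) & (y == grid.y_edges[j + 1])))
    return np.flatnonzero(in_x & in_y)


def project_states_on_pmf(grid: PmfGrid, labels: dict) -> dict:
    """Map each metastate's (loop I, loop II) RMSD label onto its PMF bin.

    ``labels`` maps metastate id -> (x, y).  Returns metastate ->
    dict(x, y, bin, F); F is None for an empty bin.
    """
    out = {}
    for meta, (lx, ly) in labels.items():
        i = _bin_index(grid.x_edges, float(lx))
        j = _bin_index(grid.y_edges, float(ly))
        fe = None if grid.free_energy.mask[i, j] else float(grid.free_energy[i, j])
        out[meta] = {"x": float(lx), "y": float(ly), "bin": (i, j), "F": fe}
    return out
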