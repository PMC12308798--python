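"""Membrane geometry: area per lipid, density profiles, thickness.

Area per lipid comes in two flavours: the box estimate APL_xy
(``Lx*Ly / n_per_leaflet``, assuming a flat membrane) and the per-lipid
Voronoi estimate APL_vor from a 2D tessellation of headgroup centres of
mass, computed only for leaflets in contact with water.  Thickness is
read off electron-density profile peaks (outer-peak separation for the
whole membrane; outer-to-central peak for individual bilayers in stacked
configurations) with five-block averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.spatial import Voronoi, QhullError

from .core import LeafletAssignment, TrajectoryData, atomic_masses, atomic_numbers

__all__ = [
    "TessellationError",
    "PeakDetectionError",
    "AreaResult",
    "DensityProfile",
    "ThicknessResult",
    "apl_xy",
    "apl_voronoi",
    "density_profile",
    "thickness_from_profile",
]

#: histogram bin width used to report the mode of APL_vor distributions
APL_MODE_BIN = 0.5  # A^2


class TessellationError(RuntimeError):
    """Voronoi tessellation failed (degenerate/collinear sites)."""


class PeakDetectionError(RuntimeError):
    """Density profile does not contain the required number of peaks."""


@dataclass
class AreaResult:
    """Box and/or Voronoi area-per-lipid summary (areas in A^2)."""

    apl_xy_series: np.ndarray | None = None  # per frame
    apl_xy_mean: float | None = None
    apl_xy_sd: float | None = None
    apl_vor_values: np.ndarray | None = None  # pooled per-lipid areas
    apl_vor_mean: float | None = None
    apl_vor_median: float | None = None
    apl_vor_mode: float | None = None


@dataclass
class DensityProfile:
    """Density along z, optionally with per-block profiles for block averaging."""

    z: np.ndarray  # bin centres, A
    values: np.ndarray  # (n_bins,) density per A^3
    weighting: str = "number"
    block_values: np.ndarray | None = None  # (n_blocks, n_bins)
    peaks: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def bin_width(self) -> float:
        return float(self.z[1] - self.z[0])


@dataclass
class ThicknessResult:
    membrane_thickness: float  # A, outer peak to outer peak
    membrane_thickness_sd: float
    bilayer_thickness: float | None = None  # A, outer peak to central peak
    bilayer_thickness_sd: float | None = None


def apl_xy(traj: TrajectoryData, n_per_leaflet: int) -> AreaResult:
    """Box-based area per lipid: Lx*Ly / n_per_leaflet, per frame."""
    if n_per_leaflet <= 0:
        raise ValueError("n_per_leaflet must be positive")
    series = traj.box[:, 0] * traj.box[:, 1] / n_per_leaflet
    return AreaResult(
        apl_xy_series=series,
        apl_xy_mean=float(series.mean()),
        apl_xy_sd=float(series.std(ddof=0)),
    )


def _voronoi_cell_areas(sites: np.ndarray, Lx: float, Ly: float) -> np.ndarray:
    """Per-site Voronoi cell areas in a periodic Lx x Ly box.

    Periodicity is handled by explicit replication of all 8 neighbouring
    images before tessellating; only central-image cells are returned,
    which makes every kept region bounded.
    """
    n = len(sites)
    if n < 3:
        raise TessellationError("need at least 3 sites per leaflet")
    spread = np.linalg.eigvalsh(np.cov(sites.T))
    if spread[0] < 1e-9:
        raise TessellationError("degenerate site geometry: sites are collinear")
    shifts = np.array([(i, j) for i in (-1, 0, 1) for j in (-1, 0, 1)], dtype=float)
    tiled = (sites[None, :, :] + shifts[:, None, :] * (Lx, Ly)).reshape(-1, 2)
    central_offset = 4 * n  # shifts order puts (0,0) at index 4
    try:
        vor = Voronoi(tiled)
    except QhullError as exc:
        raise TessellationError(f"degenerate site geometry: {exc}") from exc
    areas = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[central_offset + i]]
        if -1 in region or len(region) == 0:
            raise TessellationError(f"unbounded Voronoi cell for site {i}")
        poly = vor.vertices[region]
        x, y = poly[:, 0], poly[:, 1]
        areas[i] = 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))
    return areas


def apl_voronoi(
    traj: TrajectoryData,
    leaflets: LeafletAssignment,
    site_atoms: tuple[str, ...] | None = None,
) -> AreaResult:
    """Per-lipid areas from 2D Voronoi tessellation of headgroup COMs.

    Only outer leaflets (in contact with water) are tessellated; sites are
    the mass-weighted centres of ``site_atoms`` (default: the topology's
    headgroup atoms) projected onto the xy plane, with full periodic image
    replication.  Per-leaflet areas sum to the box area by construction.
    """
    names = site_atoms or traj.topology.headgroup_atoms
    masses = atomic_masses(names)
    com = np.einsum(
        "flaj,a->flj", traj.lipid_coords(names).astype(float), masses
    ) / masses.sum()  # (F, n_lipids, 3)
    all_areas = []
    for f in range(traj.n_frames):
        Lx, Ly = traj.box[f, 0], traj.box[f, 1]
        for li in range(leaflets.n_leaflets):
            if not leaflets.outer_flag[li]:
                continue
            mask = leaflets.leaflet_id[f] == li
            sites = np.mod(com[f, mask, :2], (Lx, Ly))
            all_areas.append(_voronoi_cell_areas(sites, Lx, Ly))
    values = np.concatenate(all_areas)
    edges = np.arange(0.0, values.max() + APL_MODE_BIN, APL_MODE_BIN)
    hist, _ = np.histogram(values, bins=edges)
    mode = float(edges[np.argmax(hist)] + APL_MODE_BIN / 2.0)
    return AreaResult(
        apl_vor_values=values,
        apl_vor_mean=float(values.mean()),
        apl_vor_median=float(np.median(values)),
        apl_vor_mode=mode,
    )


def density_profile(
    traj: TrajectoryData,
    selection: np.ndarray | None = None,
    weighting: str = "electron",
    n_bins: int = 100,
    n_blocks: int | None = None,
    partial_charges: np.ndarray | None = None,
) -> DensityProfile:
    """Density along z assuming a planar membrane perpendicular to z.

    ``selection`` is an array of global atom indices (default: all atoms).
    Weighting is 'number' (1 per atom), 'mass' (amu) or 'electron' (atomic
    number, minus force-field partial charges when supplied).  Profiles are
    averaged over frames and normalised per bin volume; ``n_blocks``
    additionally stores per-block profiles for block-averaged thickness.
    """
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(selection)
    if sel.size == 0:
        raise ValueError("empty selection")
    names = traj.atom_names[sel]
    if weighting == "number":
        w = np.ones(sel.size)
    elif weighting == "mass":
        w = atomic_masses(names)
    elif weighting == "electron":
        w = atomic_numbers(names)
        if partial_charges is not None:
            w = w - np.asarray(partial_charges)[sel]
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    Lz = float(traj.box[:, 2].mean())
    edges = np.linspace(0.0, Lz, n_bins + 1)
    xy_area = float((traj.box[:, 0] * traj.box[:, 1]).mean())
    bin_volume = xy_area * (Lz / n_bins)

    def hist_of(frames) -> np.ndarray:
        acc = np.zeros(n_bins)
        for f in frames:
            z = np.mod(traj.coords[f, sel, 2].astype(float), traj.box[f, 2])
            h, _ = np.histogram(z, bins=edges, weights=w)
            acc += h
        return acc / (len(frames) * bin_volume)

    values = hist_of(range(traj.n_frames))
    block_values = None
    if n_blocks:
        bounds = np.linspace(0, traj.n_frames, n_blocks + 1).astype(int)
        block_values = np.array(
            [
                hist_of(range(bounds[i], bounds[i + 1]))
                for i in range(n_blocks)
                if bounds[i + 1] > bounds[i]  # skip empty blocks of short runs
            ]
        )
    centres = 0.5 * (edges[:-1] + edges[1:])
    peaks, _ = find_peaks(values, prominence=0.05 * values.max())
    return DensityProfile(
        z=centres,
        values=values,
        weighting=weighting,
        block_values=block_values,
        peaks=centres[peaks],
    )


def _refined_peaks(z: np.ndarray, y: np.ndarray, prominence_frac: float = 0.05) -> np.ndarray:
    """Local maxima with quadratic sub-bin refinement, sorted by position."""
    idx, _ = find_peaks(y, prominence=prominence_frac * y.max())
    dz = z[1] - z[0]
    out = []
    for i in idx:
        if 0 < i < len(y) - 1:
            denom = y[i - 1] - 2 * y[i] + y[i + 1]
            shift = 0.0 if denom == 0 else 0.5 * (y[i - 1] - y[i + 1]) / denom
            out.append(z[i] + shift * dz)
        else:
            out.append(z[i])
    return np.array(sorted(out))


def thickness_from_profile(
    profile: DensityProfile,
    mode: str = "overall",
    prominence_frac: float = 0.05,
) -> ThicknessResult:
    """Peak-to-peak thickness from a density profile.

    ``mode='overall'`` measures the outermost peak separation (whole
    membrane, all lamellar layers); ``mode='per_bilayer'`` the distance
    from the outer peaks to the peak nearest the membrane centre, averaged
    over the two sides (stacked-bilayer configurations).  When the profile
    carries per-block values (five blocks by convention) the result is the
    block mean +- sd.
    """
    if mode not in ("overall", "per_bilayer"):
        raise ValueError(f"unknown mode {mode!r}")
    blocks = profile.block_values if profile.block_values is not None else profile.values[None, :]
    mem, bil = [], []
    for b, y in enumerate(blocks):
        peaks = _refined_peaks(profile.z, y, prominence_frac)
        need = 3 if mode == "per_bilayer" else 2
        if len(peaks) < need:
            raise PeakDetectionError(
                f"block {b}: found {len(peaks)} peaks at {np.round(peaks, 2)}, "
                f"need >= {need} for mode {mode!r}"
            )
        mem.append(peaks[-1] - peaks[0])
        if mode == "per_bilayer":
            centre = 0.5 * (peaks[0] + peaks[-1])
            central = peaks[np.argmin(np.abs(peaks - centre))]
            bil.append(0.5 * ((central - peaks[0]) + (peaks[-1] - central)))
    mem = np.array(mem)
    res = ThicknessResult(
        membrane_thickness=float(mem.mean()),
        membrane_thickness_sd=float(mem.std(ddof=0)),
    )
    if mode == "per_bilayer":
        bil = np.array(bil)
        res.bilayer_thickness = float(bil.mean())
        res.bilayer_thickness_sd = float(bil.std(ddof=0))
    else:
        res.bilayer_thickness = res.membrane_thickness
        res.bilayer_thickness_sd = res.membrane_thickness_sd
    return res
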