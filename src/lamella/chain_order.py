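"""Hydrocarbon-tail order, orientation, splay, dynamics and lateral packing.

The deuterium order parameter S_CD = (3<cos^2 theta_CD> - 1)/2 is taken
against the bilayer normal (the z axis for planar membranes), with the
deuterium/hydrogen directions reconstructed from the neighbouring carbon
positions assuming ideal tetrahedral methylene geometry.  Orientational
autocorrelation functions follow C_f(t) = <f(tau) f(tau+t)>_tau with all
frames used as time origins and lags up to half the analysis window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import LeafletAssignment, TrajectoryData, atomic_masses
from .series import ProfileSeries

__all__ = [
    "OrderProfile",
    "AngleDistribution",
    "ACFSeries",
    "RDF2D",
    "scd_profile",
    "reconstruct_ch_vectors",
    "tilt_distribution",
    "splay_distribution",
    "head_tail_angle",
    "vector_acf",
    "orientation_acf",
    "rdf_2d",
]

# half the ideal H-C-H tetrahedral angle
_HALF_HCH = math.radians(109.47 / 2.0)


@dataclass
class OrderProfile:
    """Per-carbon S_CD with block mean and sd (five equal blocks by default)."""

    carbons: tuple[str, ...]
    scd: np.ndarray  # block means, (n_carbons,)
    scd_sd: np.ndarray
    n_blocks: int = 5
    block_scd: np.ndarray | None = None  # (n_blocks, n_carbons)

    @property
    def mean_abs(self) -> float:
        return float(np.mean(np.abs(self.scd)))


@dataclass
class AngleDistribution:
    """Binned angle distribution (degrees); probabilities sum to 1."""

    bin_edges: np.ndarray
    prob: np.ndarray
    tag: str = ""

    @property
    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def mode(self) -> float:
        return float(self.bin_centres[np.argmax(self.prob)])


@dataclass
class ACFSeries:
    """Normalised autocorrelation series: C(0) = 1, lags in ps."""

    lags: np.ndarray  # ps
    values: np.ndarray
    normalization: str = "P1"
    meta: dict = field(default_factory=dict)

    def to_profile(self) -> ProfileSeries:
        return ProfileSeries(self.lags, self.values, label="acf", meta=dict(self.meta))


@dataclass
class RDF2D:
    r: np.ndarray  # bin centres, A
    g: np.ndarray
    tag: str = ""


def reconstruct_ch_vectors(prev: np.ndarray, this: np.ndarray, nxt: np.ndarray):
    """Two unit C-H directions of a methylene from its carbon neighbours.

    Ideal tetrahedral construction: both hydrogens lie in the plane spanned
    by the inverse bisector of the two C-C bonds and the normal of the
    C(i-1)-C(i)-C(i+1) plane, at half the H-C-H angle either side.
    Inputs are (..., 3) stacks.
    """
    b1 = prev - this
    b2 = nxt - this
    b1 = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    b2 = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    bis = b1 + b2
    bis_n = np.linalg.norm(bis, axis=-1, keepdims=True)
    nrm = np.cross(b1, b2)
    nrm_n = np.linalg.norm(nrm, axis=-1, keepdims=True)
    bad = (bis_n[..., 0] < 1e-8) | (nrm_n[..., 0] < 1e-8)
    bis = np.divide(bis, bis_n, out=np.zeros_like(bis), where=bis_n > 1e-8)
    nrm = np.divide(nrm, nrm_n, out=np.zeros_like(nrm), where=nrm_n > 1e-8)
    c, s = math.cos(_HALF_HCH), math.sin(_HALF_HCH)
    h1 = -bis * c + nrm * s
    h2 = -bis * c - nrm * s
    if np.any(bad):
        # collinear neighbours: the H plane is undefined.  Use an orthonormal
        # pair perpendicular to the local chain axis; their cos^2 average over
        # the two directions equals the azimuth-averaged value.
        axis = b2[bad]
        helper = np.zeros_like(axis)
        helper[..., 0] = 1.0
        parallel = np.abs(axis[..., 0]) > 0.9
        helper[parallel] = [0.0, 1.0, 0.0]
        n1 = np.cross(axis, helper)
        n1 /= np.linalg.norm(n1, axis=-1, keepdims=True)
        n2 = np.cross(axis, n1)
        h1[bad] = n1
        h2[bad] = n2
    return h1, h2


def scd_profile(
    traj: TrajectoryData,
    tail_atoms: tuple[str, ...],
    n_blocks: int = 5,
) -> OrderProfile:
    """Deuterium order parameter profile of one tail.

    For each methylene carbon (terminal carbons excluded: reconstruction
    needs both neighbours and terminal methyls are not methylenes),
    S_CD = (3<cos^2 theta> - 1)/2 averaged over both reconstructed C-H
    vectors, all lipids and the frames of each block; reported as the
    block mean +- sd per carbon.
    """
    if len(tail_atoms) < 3:
        raise ValueError("tail must have at least 3 carbons")
    pos = traj.lipid_coords(tail_atoms).astype(float)  # (F, n_lip, n_c, 3)
    h1, h2 = reconstruct_ch_vectors(pos[:, :, :-2], pos[:, :, 1:-1], pos[:, :, 2:])
    cos2 = 0.5 * (h1[..., 2] ** 2 + h2[..., 2] ** 2)  # (F, n_lip, n_mid)
    F = traj.n_frames
    bounds = np.linspace(0, F, n_blocks + 1).astype(int)
    blocks = np.array(
        [
            1.5 * cos2[bounds[i] : bounds[i + 1]].mean(axis=(0, 1)) - 0.5
            for i in range(n_blocks)
            if bounds[i + 1] > bounds[i]
        ]
    )
    return OrderProfile(
        carbons=tuple(tail_atoms[1:-1]),
        scd=blocks.mean(axis=0),
        scd_sd=blocks.std(axis=0, ddof=0),
        n_blocks=len(blocks),
        block_scd=blocks,
    )


def _angle_histogram(angles_deg: np.ndarray, lo: float, hi: float, n_bins: int, tag: str):
    edges = np.linspace(lo, hi, n_bins + 1)
    hist, _ = np.histogram(angles_deg.ravel(), bins=edges)
    prob = hist / hist.sum()
    return AngleDistribution(bin_edges=edges, prob=prob, tag=tag)


def _lipid_orientation_sign(traj: TrajectoryData) -> np.ndarray:
    """+1 for lipids whose headgroup (O1) sits above the branching carbon C5.

    Serves as the per-lipid outward leaflet normal sign; robust for all
    planar arrangements including interdigitated slabs.
    """
    o1 = traj.coords[:, traj.lipid_atom_indices("O1"), 2]
    c5 = traj.coords[:, traj.lipid_atom_indices(traj.topology.splay_vertex), 2]
    return np.where(o1 >= c5, 1.0, -1.0)  # (F, n_lipids)


def tilt_distribution(
    traj: TrajectoryData,
    vector_spec: tuple[str, str],
    n_bins: int = 180,
) -> AngleDistribution:
    """Angle between a tail vector and its leaflet's outward normal.

    ``vector_spec=(from, to)`` e.g. ('C20', 'C7'): terminal-to-first tail
    vector.  The outward normal is +-z depending on lipid orientation, and
    angles are folded to [0, 90] deg.
    """
    a, b = vector_spec
    v = (
        traj.coords[:, traj.lipid_atom_indices(b)] - traj.coords[:, traj.lipid_atom_indices(a)]
    ).astype(float)
    nrm = np.linalg.norm(v, axis=-1)
    if np.any(nrm < 1e-10):
        raise ValueError("zero-length tail vector")
    cosang = v[..., 2] / nrm * _lipid_orientation_sign(traj)
    ang = np.degrees(np.arccos(np.clip(np.abs(cosang), -1.0, 1.0)))
    return _angle_histogram(ang, 0.0, 90.0, n_bins, tag=f"tilt:{a}->{b}")


def splay_distribution(
    traj: TrajectoryData,
    triple_spec: tuple[str, str, str] = ("C9", "C5", "C22"),
    n_bins: int = 180,
) -> AngleDistribution:
    """Vertex angle at the central atom between the two tail-side atoms.

    Splay 1 uses the second tail carbons (C9, C5, C22); splay 2 the
    terminal carbons (C20, C5, C35).
    """
    a, vertex, b = triple_spec
    pa = traj.coords[:, traj.lipid_atom_indices(a)].astype(float)
    pv = traj.coords[:, traj.lipid_atom_indices(vertex)].astype(float)
    pb = traj.coords[:, traj.lipid_atom_indices(b)].astype(float)
    v1, v2 = pa - pv, pb - pv
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    if np.any(n1 < 1e-10) or np.any(n2 < 1e-10):
        raise ValueError("coincident atoms in splay triple")
    cosang = np.einsum("...j,...j->...", v1, v2) / (n1 * n2)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return _angle_histogram(ang, 0.0, 180.0, n_bins, tag=f"splay:{a}-{vertex}-{b}")


def head_tail_angle(
    traj: TrajectoryData,
    head_vector: tuple[str, str] = ("C1", "C3"),
    tail_vector: tuple[str, str] = ("C5", "C20"),
    n_bins: int = 180,
) -> AngleDistribution:
    """Unfolded [0, 180] angle between the headgroup vector and a tail vector."""
    def vec(spec):
        a, b = spec
        v = (
            traj.coords[:, traj.lipid_atom_indices(b)]
            - traj.coords[:, traj.lipid_atom_indices(a)]
        ).astype(float)
        n = np.linalg.norm(v, axis=-1, keepdims=True)
        if np.any(n < 1e-10):
            raise ValueError("zero-length vector")
        return v / n

    u, w = vec(head_vector), vec(tail_vector)
    cosang = np.einsum("...j,...j->...", u, w)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return _angle_histogram(
        ang, 0.0, 180.0, n_bins, tag=f"head-tail:{head_vector}->{tail_vector}"
    )


def orientation_acf(vectors: np.ndarray, dt: float, max_lag: int | None = None) -> ACFSeries:
    """P1 orientational ACF of per-lipid vectors, shape (F, n, 3).

    C(t) = <u(tau).u(tau+t)> over all lipids and time origins, normalised
    to C(0) = 1.  Lags default to half the window.
    """
    F = vectors.shape[0]
    if F < 2:
        raise ValueError("need at least 2 frames")
    u = vectors / np.linalg.norm(vectors, axis=-1, keepdims=True)
    u = u.astype(np.float64)
    if max_lag is None:
        max_lag = max(F // 2, 1)
    lags = np.arange(max_lag + 1)
    c = np.empty(len(lags))
    for i, l in enumerate(lags):
        c[i] = np.einsum("fnk,fnk->", u[: F - l], u[l:]) / ((F - l) * u.shape[1])
    c = c / c[0]
    return ACFSeries(lags=lags * dt, values=c, normalization="P1")


def vector_acf(
    traj: TrajectoryData,
    vector_spec: tuple[str, str],
    max_lag: int | None = None,
) -> ACFSeries:
    """P1 rotational ACF of the atom-to-atom vector given by ``vector_spec``."""
    a, b = vector_spec
    v = (
        traj.coords[:, traj.lipid_atom_indices(b)] - traj.coords[:, traj.lipid_atom_indices(a)]
    ).astype(float)
    acf = orientation_acf(v, traj.frame_dt, max_lag=max_lag)
    acf.meta["vector"] = f"{a}->{b}"
    return acf


def rdf_2d(
    traj: TrajectoryData,
    reference_atoms: tuple[str, ...],
    selection_atoms: tuple[str, ...],
    leaflets: LeafletAssignment,
    r_max: float,
    n_bins: int = 100,
    outer_only: bool = True,
) -> RDF2D:
    """In-plane radial distribution function of selection COMs around
    reference COMs, computed per leaflet (minimum image in x and y) and
    averaged over leaflets and frames."""
    if r_max > min(traj.box[:, 0].min(), traj.box[:, 1].min()) / 2.0:
        raise ValueError("r_max must be <= half the smallest lateral box edge")
    m_ref = atomic_masses(reference_atoms)
    m_sel = atomic_masses(selection_atoms)
    ref = np.einsum(
        "flaj,a->flj", traj.lipid_coords(reference_atoms).astype(float), m_ref
    ) / m_ref.sum()
    sel = np.einsum(
        "flaj,a->flj", traj.lipid_coords(selection_atoms).astype(float), m_sel
    ) / m_sel.sum()
    same = tuple(reference_atoms) == tuple(selection_atoms)

    edges = np.linspace(0.0, r_max, n_bins + 1)
    hist = np.zeros(n_bins)
    norm = 0.0
    for f in range(traj.n_frames):
        Lx, Ly = traj.box[f, 0], traj.box[f, 1]
        area = Lx * Ly
        for li in range(leaflets.n_leaflets):
            if outer_only and not leaflets.outer_flag[li]:
                continue
            mask = leaflets.leaflet_id[f] == li
            R = ref[f, mask, :2]
            S = sel[f, mask, :2]
            if len(R) == 0 or len(S) == 0:
                continue
            d = R[:, None, :] - S[None, :, :]
            d[..., 0] -= Lx * np.round(d[..., 0] / Lx)
            d[..., 1] -= Ly * np.round(d[..., 1] / Ly)
            r = np.hypot(d[..., 0], d[..., 1])
            if same:
                r[np.diag_indices(len(R))] = np.inf
            h, _ = np.histogram(r, bins=edges)
            hist += h
            density = (len(S) - (1 if same else 0)) / area
            norm += len(R) * density
    annulus = math.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    g = np.divide(hist, norm * annulus, out=np.zeros(n_bins), where=norm * annulus > 0)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return RDF2D(r=centres, g=g, tag=f"{reference_atoms[0]}..:{selection_atoms[0]}..")
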