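"""Synthetic planar lamellar membranes with controllable ground truth.

Generates toy systems of two-tailed glycerolipids on a jittered lattice so
that every analysis stage (geometry, chain order, conformational-motif
clustering, interfacial hydrogen bonding and dynamics) can be exercised
against planted labels without multi-microsecond trajectories.

The generator emulates *statistical structure*, not physics: alkyl tails
are pure rotamer chains (fixed 1.53 A bonds, 111 deg angles, trans/gauche
dihedrals drawn independently), lipids do not interact, and headgroup
dynamics act directly on the glycerol C1->C3 vector as a two-timescale
rotational diffusion whose orientational autocorrelation is
``a1*exp(-t/tau1) + a2*exp(-t/tau2) + b`` by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import LipidTopology, TrajectoryData, mmg_topology
from .series import ProfileSeries

__all__ = [
    "PackingError",
    "MotifSpec",
    "SyntheticSystemSpec",
    "MOTIF_LIBRARY",
    "BOND_LENGTH",
    "BOND_ANGLE",
    "generate_chain",
    "generate_lipid",
    "generate_membrane_trajectory",
    "generate_decay_curve",
    "write_system",
    "dihedral_angles",
]

BOND_LENGTH = 1.53  # A, C-C
BOND_ANGLE = 111.0  # deg, C-C-C
_ZIGZAG_RISE = BOND_LENGTH * math.sin(math.radians(BOND_ANGLE / 2.0))  # per-bond axial rise


class PackingError(ValueError):
    """Requested area per lipid too small for the excluded volume of the tails."""


@dataclass(frozen=True)
class MotifSpec:
    """One of the four tail-conformation motifs.

    ids: 0 closed-ordered, 1 closed-tight-ordered, 2 splayed-disordered,
    3 splayed-ordered.  ``splay1_target`` is the vertex angle at the
    branching carbon C5 between the directions to the second tail carbons
    (C9, C22); ``tail_separation`` the lateral distance the two chain
    continuations aim for at depth.
    """

    motif_id: int
    gauche_prob: float
    splay1_target: float  # deg
    tail_separation: float  # A
    tilt_mean: float  # deg
    tilt_sd: float  # deg

    def __post_init__(self):
        if not 0.0 <= self.gauche_prob <= 1.0:
            raise ValueError("gauche_prob must be in [0, 1]")
        if not 0.0 < self.splay1_target < 180.0:
            raise ValueError("splay1_target must be in (0, 180) degrees")


#: Default motif taxonomy: closed vs splayed tails x ordered vs disordered chains.
MOTIF_LIBRARY: dict[int, MotifSpec] = {
    0: MotifSpec(0, gauche_prob=0.12, splay1_target=95.0, tail_separation=5.5, tilt_mean=8.0, tilt_sd=3.0),
    1: MotifSpec(1, gauche_prob=0.02, splay1_target=95.0, tail_separation=4.2, tilt_mean=5.0, tilt_sd=2.0),
    2: MotifSpec(2, gauche_prob=0.40, splay1_target=135.0, tail_separation=13.0, tilt_mean=12.0, tilt_sd=4.0),
    3: MotifSpec(3, gauche_prob=0.05, splay1_target=135.0, tail_separation=13.0, tilt_mean=8.0, tilt_sd=3.0),
}


@dataclass
class SyntheticSystemSpec:
    """Recipe for a synthetic lamellar system.

    ``arrangement``: 'single_bilayer' (2 leaflets), 'double_bilayer'
    (4 leaflets, water gap between the bilayers) or 'interdigitated'
    (4 leaflets, each pair sharing one tail slab).  Headgroup rotational
    timescales default to the literature-reported fast/slow glycerol
    rotation modes of a single-bilayer gel membrane (2.1 / 57.3 ns with
    amplitudes 0.23 / 0.12).
    """

    arrangement: str = "single_bilayer"
    n_per_leaflet: int = 100
    motif_fractions: tuple[float, float, float, float] = (1.0, 0.0, 0.0, 0.0)
    apl_target: float = 40.0  # A^2
    headgroup_tau1: float = 2100.0  # ps
    headgroup_tau2: float = 57300.0  # ps
    headgroup_a1: float = 0.23
    headgroup_a2: float = 0.12
    hbond_fraction: float = 0.0
    water_per_outer_lipid: float = 0.0
    water_hbond_counts: dict | None = None  # e.g. {"O5-H": 3, "O4": 2}
    n_frames: int = 5
    frame_dt: float = 500.0  # ps
    tail_dynamics: bool = True  # re-draw rotamer continuations every frame
    seed: int = 0
    lipid_name: str = "MMG"
    stereo_label: str = "2R3S"
    lattice_jitter: float = 0.3  # A
    water_gap: float = 6.0  # A between stacked units
    water_pad: float = 10.0  # A of water above/below the stack

    def __post_init__(self):
        if self.arrangement not in ("single_bilayer", "double_bilayer", "interdigitated"):
            raise ValueError(f"unknown arrangement {self.arrangement!r}")
        if abs(sum(self.motif_fractions) - 1.0) > 1e-9:
            raise ValueError("motif_fractions must sum to 1")
        if self.apl_target <= 0:
            raise ValueError("apl_target must be positive")
        if math.sqrt(self.apl_target) < 4.6:
            raise PackingError(
                f"apl_target={self.apl_target} A^2 gives lattice spacing below the "
                "~4.6 A excluded diameter of a lipid"
            )
        if self.headgroup_a1 + self.headgroup_a2 > 1.0 + 1e-9:
            raise ValueError("headgroup amplitudes must sum to <= 1")

    @property
    def n_leaflets(self) -> int:
        return 2 if self.arrangement == "single_bilayer" else 4

    @property
    def n_lipids(self) -> int:
        return self.n_per_leaflet * self.n_leaflets


# ---------------------------------------------------------------------------
# rotamer chain construction
# ---------------------------------------------------------------------------

def _place_atom(p1, p2, p3, bond: float, angle_deg: float, dihedral_deg: float):
    """NeRF placement of the next atom given three predecessors."""
    theta = math.radians(angle_deg)
    chi = math.radians(dihedral_deg)
    b1 = p2 - p1
    b2 = p3 - p2
    b2u = b2 / np.linalg.norm(b2)
    n = np.cross(b1, b2)
    n /= np.linalg.norm(n)
    m = np.cross(n, b2u)
    d = np.array(
        [
            -bond * math.cos(theta),
            bond * math.sin(theta) * math.cos(chi),
            bond * math.sin(theta) * math.sin(chi),
        ]
    )
    return p3 + d[0] * b2u + d[1] * m + d[2] * n


def generate_chain(
    n_carbons: int,
    gauche_prob: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Rotameric alkyl chain: 1.53 A bonds, 111 deg angles, trans/gauche dihedrals.

    Each internal dihedral is drawn trans (180 deg) with probability
    ``1 - gauche_prob``, else gauche (+60 or -60 deg equiprobably).
    Reproducible for a fixed seed.  Returns (n_carbons, 3) coordinates
    starting at the origin.
    """
    if n_carbons < 3:
        raise ValueError("n_carbons must be >= 3")
    if not 0.0 <= gauche_prob <= 1.0:
        raise ValueError("gauche_prob must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coords = np.zeros((n_carbons, 3))
    coords[1] = (BOND_LENGTH, 0.0, 0.0)
    phi = math.radians(180.0 - BOND_ANGLE)
    coords[2] = coords[1] + BOND_LENGTH * np.array([math.cos(phi), math.sin(phi), 0.0])
    n_dihedrals = n_carbons - 3
    if n_dihedrals > 0:
        is_gauche = rng.random(n_dihedrals) < gauche_prob
        signs = np.where(rng.random(n_dihedrals) < 0.5, 1.0, -1.0)
        chis = np.where(is_gauche, signs * 60.0, 180.0)
        for i in range(3, n_carbons):
            coords[i] = _place_atom(
                coords[i - 3], coords[i - 2], coords[i - 1], BOND_LENGTH, BOND_ANGLE, chis[i - 3]
            )
    return coords


def dihedral_angles(chain: np.ndarray) -> np.ndarray:
    """Signed dihedral angles (deg, in (-180, 180]) along a chain of atoms."""
    b0 = chain[1:-2] - chain[:-3]
    b1 = chain[2:-1] - chain[1:-2]
    b2 = chain[3:] - chain[2:-1]
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1u = b1 / np.linalg.norm(b1, axis=1, keepdims=True)
    m1 = np.cross(n1, b1u)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    ang = np.degrees(np.arctan2(y, x))
    return np.where(ang <= -180.0 + 1e-12, ang + 360.0, ang)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a onto unit vector b (Rodrigues)."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any perpendicular axis
        p = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            p = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, p)
        axis /= np.linalg.norm(axis)
        return _axis_angle_matrix(axis, math.pi)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _axis_angle_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


def _oriented_chain(
    n_carbons: int, gauche_prob: float, axis: np.ndarray, start: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rotamer chain whose end-to-end axis points along ``axis``; first atom at start."""
    chain = generate_chain(n_carbons, gauche_prob, rng)
    ee = chain[-1] - chain[0]
    R = _rotation_between(ee, np.asarray(axis, dtype=float))
    chain = chain @ R.T
    spin = _axis_angle_matrix(np.asarray(axis, dtype=float), rng.uniform(0, 2 * math.pi))
    chain = chain @ spin.T
    return chain - chain[0] + start


# ---------------------------------------------------------------------------
# single lipid
# ---------------------------------------------------------------------------

# Stylized headgroup template relative to the branching carbon C5 (+z = water
# side).  Hydroxyl hydrogens point toward the water (+z) so that, with the
# 30 deg acceptor-donor-hydrogen criterion, no intra- or inter-lipid hydrogen
# bond forms unless planted explicitly.
_HEAD_TEMPLATE = {
    "C6": (1.45, 0.00, 0.50),
    "O5": (2.55, -0.90, 1.10),
    "C4": (-1.30, 0.20, 1.00),
    "O4": (-2.45, 0.40, 0.60),
    "O2": (-1.15, 0.20, 2.75),
    "C3": (0.05, 0.40, 3.55),
    "C2": (0.00, -0.35, 4.85),
    "O3": (1.30, -1.00, 5.15),
    "C1": (-0.60, 0.30, 6.00),
    "O1": (-0.55, 0.15, 7.40),
}
_OH_LENGTH = 0.97

#: atoms rigidly attached to the rotating glycerol C1->C3 vector (pivot C1).
#: Only the carbons rotate: the oxygens stay at their template positions so
#: the rotor sweep cannot create accidental hydrogen-bond geometries.
_GLYCEROL_ROTOR = ("C2", "C3")

_STEM_SPACING = (1.53, 2.80, 4.07)  # radial positions of the first stem carbons


#: tail continuation chains (beyond the stem carbons), re-drawn per frame
#: when tail conformational dynamics are enabled
_TAIL_CONTINUATIONS = (
    ("C9", tuple(f"C{i}" for i in range(10, 21)), +1),
    ("C22", tuple(f"C{i}" for i in range(23, 36)), -1),
)


def _generate_lipid_full(
    motif: MotifSpec,
    leaflet_direction: int,
    rng: np.random.Generator,
    topo: LipidTopology,
):
    """Build one lipid; returns (coords, tail_info).

    ``tail_info`` lists (continuation atom indices, axis, start) in the
    final (tilted/mirrored) local frame so the rotamer continuations can
    be re-drawn per frame for conformational dynamics.
    """
    coords = np.zeros((topo.atoms_per_lipid, 3))

    def put(name, xyz):
        coords[topo.index_of(name)] = xyz

    # headgroup template + upward hydroxyl hydrogens
    for name, xyz in _HEAD_TEMPLATE.items():
        put(name, xyz)
    for oname, hname in (("O1", "HO1"), ("O3", "HO3"), ("O5", "HO5")):
        put(hname, np.array(_HEAD_TEMPLATE[oname]) + (0.0, 0.0, _OH_LENGTH))

    beta = math.radians(motif.splay1_target / 2.0)
    u1 = np.array([math.sin(beta), 0.0, -math.cos(beta)])
    u2 = np.array([-math.sin(beta), 0.0, -math.cos(beta)])

    # stems: tail 1 C7-C8-C9 on the u1 ray, tail 2 C21-C22 on the u2 ray
    for name, r in zip(("C7", "C8", "C9"), _STEM_SPACING):
        put(name, r * u1)
    for name, r in zip(("C21", "C22"), _STEM_SPACING[:2]):
        put(name, r * u2)

    tail_depth = 14.0 * _ZIGZAG_RISE  # nominal chain extent below the stems
    tail_geo = []
    for anchor_name, names, side in _TAIL_CONTINUATIONS:
        anchor = coords[topo.index_of(anchor_name)]
        target = np.array([side * motif.tail_separation / 2.0, 0.0, anchor[2] - tail_depth])
        axis = target - anchor
        axis /= np.linalg.norm(axis)
        start = anchor + BOND_LENGTH * axis
        chain = _oriented_chain(len(names), motif.gauche_prob, axis, start, rng)
        for name, xyz in zip(names, chain):
            put(name, xyz)
        tail_geo.append((topo.indices_of(names), axis, start))

    # rigid tilt about a random horizontal axis through C5
    tilt = math.radians(rng.normal(motif.tilt_mean, motif.tilt_sd))
    az = rng.uniform(0, 2 * math.pi)
    axis = np.array([math.cos(az), math.sin(az), 0.0])
    R = _axis_angle_matrix(axis, tilt)
    coords = coords @ R.T
    mirror = np.array([1.0, 1.0, -1.0 if leaflet_direction < 0 else 1.0])
    coords = coords * mirror
    tail_info = [
        (idx, (R @ ax) * mirror, (R @ st) * mirror) for idx, ax, st in tail_geo
    ]
    return coords, tail_info


def generate_lipid(
    motif: MotifSpec,
    leaflet_direction: int = 1,
    seed: int | np.random.Generator = 0,
    topology: LipidTopology | None = None,
) -> np.ndarray:
    """One lipid in a local frame: C5 at the origin, water side along +-z.

    The two tails leave C5 along directions separated by the splay-1 target
    (so the C9-C5-C22 vertex angle echoes it exactly); beyond the second
    stem carbon each tail continues as a rotamer chain aimed to reach a
    lateral separation of ``tail_separation`` at depth.  The whole lipid is
    then tilted by a draw from N(tilt_mean, tilt_sd) about a random
    horizontal axis.  ``leaflet_direction=-1`` mirrors the lipid so O1
    faces -z.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    topo = topology or mmg_topology()
    coords, _ = _generate_lipid_full(motif, leaflet_direction, rng, topo)
    return coords


# ---------------------------------------------------------------------------
# full membranes
# ---------------------------------------------------------------------------

_HEAD_EXTENT = 8.5  # A above C5 (O1 + H)
_WATER_GEOM = np.array(  # OW, HW1, HW2 in a local frame
    [[0.0, 0.0, 0.0], [0.9572, 0.0, 0.0], [-0.2399, 0.9266, 0.0]]
)


def _tail_extent() -> float:
    """Nominal distance from C5 to the lowest tail atom (all-trans)."""
    return _STEM_SPACING[1] + BOND_LENGTH + 13.0 * _ZIGZAG_RISE + 2.0


def _lattice(n: int, apl: float, jitter: float, rng) -> tuple[np.ndarray, float, float]:
    """n jittered sites with total area n*apl; returns (sites, Lx, Ly)."""
    nx = math.ceil(math.sqrt(n))
    ny = math.ceil(n / nx)
    Lx = nx * math.sqrt(apl)
    Ly = n * apl / Lx
    dx, dy = Lx / nx, Ly / ny
    ix, iy = np.divmod(np.arange(n), ny)
    sites = np.stack([(ix + 0.5) * dx, (iy + 0.5) * dy], axis=1)
    sites += rng.uniform(-jitter, jitter, size=sites.shape)
    return sites, Lx, Ly


def generate_membrane_trajectory(spec: SyntheticSystemSpec):
    """Build a full synthetic system.

    Returns ``(traj, ground_truth)`` where ``ground_truth`` is a DataFrame
    with one row per lipid: lipid id, planted motif, leaflet id (numbered
    bottom-to-top as in :func:`lamella.core.assign_leaflets`), and the
    headgroup dynamic class (0 fast / 1 slow / 2 static).
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    topo = mmg_topology(stereo_label=spec.stereo_label, lipid_name=spec.lipid_name)
    apl_atoms = topo.atoms_per_lipid
    n_leaflets = spec.n_leaflets
    n = spec.n_per_leaflet
    L_t = _tail_extent()

    # leaflet descriptors, bottom to top: (pivot z of C5 plane, direction)
    if spec.arrangement == "single_bilayer":
        leaflet_geo = [(-L_t, -1), (+L_t, +1)]
    elif spec.arrangement == "double_bilayer":
        half = L_t + _HEAD_EXTENT
        c = half + spec.water_gap / 2.0
        leaflet_geo = [(-c - L_t, -1), (-c + L_t, +1), (c - L_t, -1), (c + L_t, +1)]
    else:  # interdigitated: two slabs, each pair of leaflets sharing one tail slab
        slab = L_t + _HEAD_EXTENT  # C5-to-C5 span is L_t; heads stick out both sides
        c = L_t / 2.0 + _HEAD_EXTENT + spec.water_gap / 2.0
        leaflet_geo = [(-c - L_t / 2.0, -1), (c - L_t / 2.0, -1), (-c + L_t / 2.0, +1), (c + L_t / 2.0, +1)]
        # note: leaflets are listed here in construction order; ground-truth
        # leaflet ids are re-derived from head z below so numbering is
        # bottom-to-top regardless of arrangement.

    motif_ids = rng.choice(4, size=spec.n_lipids, p=np.asarray(spec.motif_fractions))
    lipid_coords = np.zeros((spec.n_lipids, apl_atoms, 3))
    leaflet_of = np.zeros(spec.n_lipids, dtype=int)
    tail_infos: list = [None] * spec.n_lipids

    Lx = Ly = None
    lid = 0
    for li, (zpivot, direction) in enumerate(leaflet_geo):
        sites, Lx, Ly = _lattice(n, spec.apl_target, spec.lattice_jitter, rng)
        if spec.arrangement == "interdigitated":
            # interleave opposing leaflets within the shared slab
            sites = sites + (0.25 * math.sqrt(spec.apl_target) * (1 if direction > 0 else -1))
        for s in sites:
            motif = MOTIF_LIBRARY[int(motif_ids[lid])]
            xyz, tinfo = _generate_lipid_full(motif, direction, rng, topo)
            offset = np.array([s[0], s[1], zpivot])
            lipid_coords[lid] = xyz + offset
            tail_infos[lid] = [(idx, ax, st + offset) for idx, ax, st in tinfo]
            leaflet_of[lid] = li
            lid += 1

    # re-number leaflets bottom-to-top by mean O1 z
    o1 = topo.index_of("O1")
    head_z = lipid_coords[:, o1, 2]
    means = np.array([head_z[leaflet_of == li].mean() for li in range(n_leaflets)])
    order = np.argsort(means)
    renum = np.empty(n_leaflets, dtype=int)
    renum[order] = np.arange(n_leaflets)
    leaflet_of = renum[leaflet_of]

    # Planted lipid-lipid hydrogen bonds: the donor's O5-H and the lattice
    # successor's carbonyl O4 are relocated to a vertical dumbbell in the
    # solvent region above the midpoint of the pair (stylized geometry that
    # keeps every planted bond isolated: dumbbells of adjacent pairs are at
    # least one lattice spacing apart and 4 A clear of the lipids below).
    n_planted_inter = 0
    if spec.hbond_fraction > 0:
        o5, ho5, o4 = topo.index_of("O5"), topo.index_of("HO5"), topo.index_of("O4")
        c5 = topo.index_of("C5")
        for li in range(n_leaflets):
            members = np.nonzero(leaflet_of == li)[0]
            n_bonds = int(round(spec.hbond_fraction * len(members)))
            chosen = rng.permutation(members)[:n_bonds]
            s = 1.0 if head_z[np.nonzero(leaflet_of == li)[0][0]] > lipid_coords[
                np.nonzero(leaflet_of == li)[0][0], c5, 2
            ] else -1.0
            apex = head_z[members].max() if s > 0 else head_z[members].min()
            for k, i in enumerate(chosen):
                j = members[(np.nonzero(members == i)[0][0] + 1) % len(members)]
                mid = 0.5 * (lipid_coords[i, c5, :2] + lipid_coords[j, c5, :2])
                zb = apex + s * (4.0 + 1.5 * (k % 2))
                lipid_coords[j, o4] = (mid[0], mid[1], zb)
                lipid_coords[i, o5] = (mid[0], mid[1], zb + s * 2.9)
                lipid_coords[i, ho5] = (mid[0], mid[1], zb + s * (2.9 - _OH_LENGTH))
                n_planted_inter += 1

    # stack extent and box
    z_top = max(zp for zp, _ in leaflet_geo) + _HEAD_EXTENT
    z_bot = min(zp for zp, _ in leaflet_geo) - _HEAD_EXTENT
    Lz = (z_top - z_bot) + 2.0 * spec.water_pad
    z_shift = -z_bot + spec.water_pad  # membrane sits inside [0, Lz]
    lipid_coords[:, :, 2] += z_shift
    tail_infos = [
        [(idx, ax, st + np.array([0.0, 0.0, z_shift])) for idx, ax, st in ti]
        for ti in tail_infos
    ]

    # water: random in the two outer slabs, plus planted hydrogen-bond partners
    water = []
    n_rand = int(round(spec.water_per_outer_lipid * 2 * n))
    for _ in range(n_rand):
        top = rng.random() < 0.5
        z0 = rng.uniform(z_top + z_shift + 2.0, Lz - 1.5) if top else rng.uniform(
            1.5, z_bot + z_shift - 2.0
        )
        pos = np.array([rng.uniform(0, Lx), rng.uniform(0, Ly), z0])
        spin = _axis_angle_matrix(rng.normal(size=3), rng.uniform(0, 2 * math.pi))
        water.append(_WATER_GEOM @ spin.T + pos)
    if spec.water_hbond_counts:
        water += _plant_water_bonds(spec, topo, lipid_coords, leaflet_of, n_leaflets, rng)
    water = np.array(water).reshape(-1, 3, 3) if water else np.zeros((0, 3, 3))

    # assemble atoms: lipids first, then the water block
    n_water = len(water)
    coords0 = np.concatenate(
        [lipid_coords.reshape(-1, 3), water.reshape(-1, 3)], axis=0
    )
    order_names = sorted(topo.name_map, key=topo.name_map.get)
    atom_names = np.array(
        list(np.tile(order_names, spec.n_lipids)) + ["OW", "HW1", "HW2"] * n_water
    )
    mol = np.concatenate(
        [
            np.repeat(np.arange(spec.n_lipids), apl_atoms),
            spec.n_lipids + np.repeat(np.arange(n_water), 3),
        ]
    ).astype(np.intp)

    # frames: glycerol rotor dynamics on the C1->C3 vector
    # deterministic class counts (shuffled) so the planted ACF amplitudes are
    # exactly a1/a2/b rather than multinomially noisy
    n1 = int(round(spec.headgroup_a1 * spec.n_lipids))
    n2 = int(round(spec.headgroup_a2 * spec.n_lipids))
    head_class = np.concatenate(
        [np.zeros(n1, int), np.ones(n2, int), np.full(spec.n_lipids - n1 - n2, 2)]
    )
    rng.shuffle(head_class)
    gauche_of = np.array([MOTIF_LIBRARY[int(m)].gauche_prob for m in motif_ids])
    frames = _evolve_frames(spec, topo, coords0, head_class, tail_infos, gauche_of, rng)

    times = np.arange(spec.n_frames) * spec.frame_dt
    box = np.tile([Lx, Ly, Lz], (spec.n_frames, 1))
    traj = TrajectoryData(
        times=times,
        box=box,
        coords=frames,
        topology=topo,
        n_lipids=spec.n_lipids,
        molecule_index=mol,
        atom_names=atom_names,
    )
    gt = pd.DataFrame(
        {
            "lipid": np.arange(spec.n_lipids),
            "motif": motif_ids,
            "leaflet": leaflet_of,
            "head_class": head_class,
        }
    )
    gt.attrs["n_planted_inter_hbonds"] = n_planted_inter
    gt.attrs["spec"] = spec
    return traj, gt


def _plant_water_bonds(spec, topo, lipid_coords, leaflet_of, n_leaflets, rng):
    """Waters placed in hydrogen-bond geometry with requested lipid groups.

    The target group's oxygen (plus hydrogen for hydroxyls) is relocated to
    the solvent apex above its own lipid and the water is stacked
    vertically on top: hydroxyl groups ('O1-H', 'O3-H', 'O5-H') receive a
    water *acceptor* on the O-H axis, acceptor-only groups ('O2', 'O4') a
    water *donor* with one O-H aimed straight at the lipid oxygen.  Each
    outer-leaflet lipid is used for at most one planted bond, which keeps
    dumbbells a full lattice spacing apart.
    """
    out = []
    outer = (leaflet_of == 0) | (leaflet_of == n_leaflets - 1)
    members = rng.permutation(np.nonzero(outer)[0])
    total = sum(int(c) for c in spec.water_hbond_counts.values())
    if total > len(members):
        raise ValueError(
            f"cannot plant {total} water bonds with only {len(members)} outer lipids"
        )
    c5, o1 = topo.index_of("C5"), topo.index_of("O1")
    cos_h, sin_h = math.cos(math.radians(52.25)), math.sin(math.radians(52.25))
    used = 0
    for group, count in spec.water_hbond_counts.items():
        for i in members[used : used + int(count)]:
            s = 1.0 if lipid_coords[i, o1, 2] > lipid_coords[i, c5, 2] else -1.0
            base = np.array(
                [lipid_coords[i, c5, 0], lipid_coords[i, c5, 1],
                 lipid_coords[i, o1, 2] + s * 4.0]
            )
            up = np.array([0.0, 0.0, s])
            if group.endswith("-H"):
                oname = group[:-2]
                lipid_coords[i, topo.index_of(oname)] = base
                lipid_coords[i, topo.index_of("H" + oname)] = base + _OH_LENGTH * up
                ow = base + 2.9 * up
                perp = np.array([1.0, 0.0, 0.0])
                w = np.array(
                    [ow,
                     ow + _OH_LENGTH * (cos_h * up + sin_h * perp),
                     ow + _OH_LENGTH * (cos_h * up - sin_h * perp)]
                )
            else:
                lipid_coords[i, topo.index_of(group)] = base
                ow = base + 2.9 * up
                w = np.empty((3, 3))
                w[0] = ow
                w[1] = ow - _OH_LENGTH * up  # H aimed straight at the acceptor
                perp = np.array([1.0, 0.0, 0.0])
                ch, sh = math.cos(math.radians(104.5)), math.sin(math.radians(104.5))
                w[2] = ow + _OH_LENGTH * (-ch * up + sh * perp)
            out.append(w)
        used += int(count)
    return out


def _evolve_frames(spec, topo, coords0, head_class, tail_infos, gauche_of, rng):
    """Propagate headgroup and tail dynamics over the frames.

    Glycerol rotor: each step rotates the C1->C3 rotor by a fixed angle
    alpha_c = arccos(exp(-dt/tau)) about a random axis perpendicular to the
    current direction, which makes the per-lag expectation of u(0).u(t)
    exactly exp(-t/tau) for each dynamic class; the class mixture supplies
    the a1/a2/b amplitudes of the planted double exponential.

    Tail dynamics: when enabled, the rotamer continuations of both tails
    are re-drawn independently every frame (memoryless trans/gauche
    hopping), so frame-averaged conformational statistics converge to the
    motif's expected distribution.
    """
    F = spec.n_frames
    n_lip = spec.n_lipids
    apl_atoms = topo.atoms_per_lipid
    frames = np.empty((F, len(coords0), 3), dtype=np.float32)
    frames[0] = coords0

    c1 = topo.index_of("C1")
    rotor_idx = topo.indices_of(_GLYCEROL_ROTOR)
    lip = coords0[: n_lip * apl_atoms].reshape(n_lip, apl_atoms, 3).copy()

    alphas = np.zeros(n_lip)
    for cls, tau in ((0, spec.headgroup_tau1), (1, spec.headgroup_tau2)):
        mask = head_class == cls
        alphas[mask] = math.acos(math.exp(-spec.frame_dt / tau))
    moving = head_class != 2

    cur = lip.copy()
    for f in range(1, F):
        u = cur[:, topo.index_of("C3")] - cur[:, c1]
        u = u / np.linalg.norm(u, axis=1, keepdims=True)
        # random axis perpendicular to u
        r = rng.normal(size=(n_lip, 3))
        axis = np.cross(u, r)
        nrm = np.linalg.norm(axis, axis=1, keepdims=True)
        bad = nrm[:, 0] < 1e-12
        if bad.any():
            axis[bad] = np.cross(u[bad], [[0.12, 0.93, 0.35]])
            nrm = np.linalg.norm(axis, axis=1, keepdims=True)
        axis = axis / nrm
        ca = np.cos(alphas)[:, None]
        sa = np.sin(alphas)[:, None]
        pivot = cur[:, c1][:, None, :]
        v = cur[:, rotor_idx] - pivot  # (n_lip, rotor, 3)
        k = axis[:, None, :]
        rotated = (
            v * ca[:, None]
            + np.cross(np.broadcast_to(k, v.shape), v) * sa[:, None]
            + k * np.einsum("nrj,nrj->nr", np.broadcast_to(k, v.shape), v)[..., None] * (1 - ca[:, None])
        )
        new = cur.copy()
        new[np.ix_(np.nonzero(moving)[0], rotor_idx)] = (pivot + rotated)[moving]
        cur = new
        if spec.tail_dynamics:
            for lid in range(n_lip):
                for idx, ax, st in tail_infos[lid]:
                    cur[lid, idx] = _oriented_chain(len(idx), gauche_of[lid], ax, st, rng)
        frame = frames[0].astype(np.float64).copy()
        frame[: n_lip * apl_atoms] = cur.reshape(-1, 3)
        frames[f] = frame
    return frames


def generate_decay_curve(
    a1: float,
    tau1: float,
    a2: float,
    tau2: float,
    b: float,
    noise_sd: float,
    lags: np.ndarray,
    seed: int = 0,
) -> ProfileSeries:
    """Double-exponential decay ``a1*exp(-t/tau1) + a2*exp(-t/tau2) + b``
    with optional additive Gaussian noise, sampled at ``lags``."""
    if tau1 <= 0 or tau2 <= 0:
        raise ValueError("time constants must be positive")
    lags = np.asarray(lags, dtype=float)
    rng = np.random.default_rng(seed)
    y = a1 * np.exp(-lags / tau1) + a2 * np.exp(-lags / tau2) + b
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=lags.shape)
    return ProfileSeries(
        x=lags,
        y=y,
        label="decay",
        meta={"a1": a1, "tau1": tau1, "a2": a2, "tau2": tau2, "b": b, "noise_sd": noise_sd},
    )


# ---------------------------------------------------------------------------
# on-disk output
# ---------------------------------------------------------------------------

def write_system(traj: TrajectoryData, ground_truth, outdir, prefix: str = "system"):
    """Write GRO (first frame) + XTC (all frames) + ground-truth TSV."""
    import os

    import MDAnalysis as mda

    os.makedirs(outdir, exist_ok=True)
    apl_atoms = traj.topology.atoms_per_lipid
    n_water = (traj.n_atoms - traj.n_lipid_atoms) // 3
    n_res = traj.n_lipids + n_water
    resindex = np.concatenate(
        [
            np.repeat(np.arange(traj.n_lipids), apl_atoms),
            traj.n_lipids + np.repeat(np.arange(n_water), 3),
        ]
    )
    u = mda.Universe.empty(
        traj.n_atoms, n_residues=n_res, atom_resindex=resindex, trajectory=True
    )
    u.add_TopologyAttr("names", list(traj.atom_names))
    u.add_TopologyAttr(
        "resnames", [traj.topology.lipid_name] * traj.n_lipids + ["SOL"] * n_water
    )
    u.add_TopologyAttr("resids", list(range(1, n_res + 1)))
    gro = os.path.join(outdir, f"{prefix}.gro")
    xtc = os.path.join(outdir, f"{prefix}.xtc")
    tsv = os.path.join(outdir, f"{prefix}_ground_truth.tsv")
    u.atoms.positions = traj.coords[0]
    u.dimensions = [*traj.box[0], 90.0, 90.0, 90.0]
    u.atoms.write(gro)
    with mda.Writer(xtc, traj.n_atoms) as w:
        for f in range(traj.n_frames):
            u.atoms.positions = traj.coords[f]
            u.dimensions = [*traj.box[f], 90.0, 90.0, 90.0]
            u.trajectory.ts.time = traj.times[f]
            u.trajectory.ts.frame = f
            w.write(u.atoms)
    ground_truth.to_csv(tsv, sep="\t", index=False)
    return gro, xtc, tsv
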