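"""Core data model for lamellar membrane trajectory analysis.

Holds the lipid name-map topology, the in-memory trajectory container,
analysis-window selection and per-frame leaflet assignment shared by all
analysis stages.  Internal units are fixed to angstrom (coordinates, box)
and picosecond (times) regardless of the on-disk dialect; MDAnalysis
already reports both natively.

Coordinates are *not* wrapped on load: each analysis declares its own
periodic-image policy (minimum image, explicit replication, or none for
intramolecular work).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "TopologyError",
    "TruncationError",
    "DegenerateGeometryError",
    "EmptyWindowError",
    "LipidTopology",
    "TrajectoryData",
    "LeafletAssignment",
    "mmg_topology",
    "load_trajectory",
    "select_window",
    "assign_leaflets",
    "atomic_masses",
    "atomic_numbers",
]


class TopologyError(ValueError):
    """Atom naming / count inconsistent with the declared lipid topology."""


class TruncationError(RuntimeError):
    """Trajectory stream unreadable past some frame; names the last valid frame."""

    def __init__(self, last_valid_frame: int, message: str | None = None):
        self.last_valid_frame = last_valid_frame
        super().__init__(
            message
            or f"trajectory unreadable after frame {last_valid_frame} "
            f"(last valid frame index: {last_valid_frame})"
        )


class DegenerateGeometryError(ValueError):
    """Marker geometry does not resolve into the requested number of leaflets."""


class EmptyWindowError(ValueError):
    """Requested time window contains no frames."""


# Masses / atomic numbers for the elements that occur in these systems.
_ELEMENT_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974}
_ELEMENT_Z = {"H": 1, "C": 6, "N": 7, "O": 8, "P": 15}


def _element_of(name: str) -> str:
    """Leading-letter element guess; 'HO5' -> H, 'OW' -> O, 'C35' -> C."""
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise TopologyError(f"cannot infer element from atom name {name!r}")


def atomic_masses(names: Sequence[str]) -> np.ndarray:
    return np.array([_ELEMENT_MASS[_element_of(n)] for n in names])


def atomic_numbers(names: Sequence[str]) -> np.ndarray:
    return np.array([_ELEMENT_Z[_element_of(n)] for n in names], dtype=float)


@dataclass(frozen=True)
class LipidTopology:
    """Name map of a two-tailed glycerolipid following the O1–O5 / C1–C35 scheme.

    ``name_map`` maps atom name -> index within one lipid.  Tail 1 runs
    C7…C20 and tail 2 C21…C35; the headgroup is the glycerol moiety plus
    the hydrophilic part of the lipid acid (C1–C6, O1–O5).  ``g3_selection``
    is the lipid-acid carbon set used for conformational fingerprints and
    excludes the carbonyl carbon C4.
    """

    lipid_name: str
    name_map: Mapping[str, int]
    tail1_atoms: tuple[str, ...]
    tail2_atoms: tuple[str, ...]
    headgroup_atoms: tuple[str, ...]
    glycerol_vector_atoms: tuple[str, str] = ("C1", "C3")
    splay_vertex: str = "C5"
    g3_selection: tuple[str, ...] = ()
    stereo_label: str = "2R3S"
    # hydrogen-bond chemistry: hydroxyls donate and accept, ester/carbonyl
    # oxygens (O2, O4) accept only
    donor_pairs: tuple[tuple[str, str], ...] = (("O1", "HO1"), ("O3", "HO3"), ("O5", "HO5"))
    acceptor_atoms: tuple[str, ...] = ("O1", "O2", "O3", "O4", "O5")

    @property
    def atoms_per_lipid(self) -> int:
        return len(self.name_map)

    def __post_init__(self):
        idx = list(self.name_map.values())
        if sorted(idx) != list(range(len(idx))):
            raise TopologyError("name_map indices must be 0..n-1 without gaps")
        for group in (
            self.tail1_atoms,
            self.tail2_atoms,
            self.headgroup_atoms,
            self.g3_selection,
            self.glycerol_vector_atoms,
            (self.splay_vertex,),
            self.acceptor_atoms,
        ):
            for name in group:
                if name not in self.name_map:
                    raise TopologyError(f"atom {name!r} not present in name_map")
        for d, h in self.donor_pairs:
            if d not in self.name_map or h not in self.name_map:
                raise TopologyError(f"donor pair ({d}, {h}) not present in name_map")
        if set(self.tail1_atoms) & set(self.tail2_atoms):
            raise TopologyError("tail1 and tail2 atom sets must be disjoint")
        if "C4" in self.g3_selection:
            raise TopologyError("g3_selection must exclude the carbonyl carbon C4")
        if self.stereo_label not in {"2R3S", "2S3R", "2R3R", "2S3S"}:
            raise TopologyError(f"unknown stereo label {self.stereo_label!r}")

    def index_of(self, name: str) -> int:
        try:
            return self.name_map[name]
        except KeyError:
            raise TopologyError(f"atom {name!r} not in lipid {self.lipid_name!r}") from None

    def indices_of(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.index_of(n) for n in names], dtype=np.intp)


def mmg_topology(stereo_label: str = "2R3S", lipid_name: str = "MMG") -> LipidTopology:
    """Standard 43-atom name map of the monomycoloyl-glycerol analogs.

    Glycerol carbons C1–C3 with the primary hydroxyl O1 on C1, ester
    linkage O2/carbonyl C4=O4 to the corynomycolic acid, branching
    alpha-carbon C5, hydroxyl-bearing beta-carbon C6 (O5–H), and the two
    alkyl tails C7–C20 / C21–C35.  Hydroxyl hydrogens HO1/HO3/HO5 are the
    only hydrogens carried explicitly (hydrogen-bond donors).
    """
    names = (
        ["C1", "C2", "C3", "O1", "O2", "O3", "C4", "O4", "C5", "C6", "O5"]
        + [f"C{i}" for i in range(7, 21)]
        + [f"C{i}" for i in range(21, 36)]
        + ["HO1", "HO3", "HO5"]
    )
    name_map = {n: i for i, n in enumerate(names)}
    return LipidTopology(
        lipid_name=lipid_name,
        name_map=name_map,
        tail1_atoms=tuple(f"C{i}" for i in range(7, 21)),
        tail2_atoms=tuple(f"C{i}" for i in range(21, 36)),
        headgroup_atoms=("C1", "C2", "C3", "C4", "C5", "C6", "O1", "O2", "O3", "O4", "O5"),
        g3_selection=("C5", "C6") + tuple(f"C{i}" for i in range(7, 36)),
        stereo_label=stereo_label,
    )


@dataclass
class TrajectoryData:
    """Frames of coordinates plus periodic box and the lipid name-map topology.

    ``coords`` has shape (n_frames, n_atoms, 3) in angstrom; lipid atoms
    come first, ordered lipid-by-lipid following the topology name map,
    followed by an optional contiguous solvent block.  ``molecule_index``
    assigns every atom a molecule id (lipids 0..n_lipids-1, then solvent
    molecules).
    """

    times: np.ndarray  # (F,) ps, strictly increasing
    box: np.ndarray  # (F, 3) angstrom
    coords: np.ndarray  # (F, N, 3) angstrom
    topology: LipidTopology
    n_lipids: int
    molecule_index: np.ndarray  # (N,) int
    atom_names: np.ndarray  # (N,) str

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.coords = np.asarray(self.coords)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.diff(self.times) > 0) and len(self.times) > 1:
            raise ValueError("frame times must be strictly increasing")
        if not np.all(self.box > 0):
            raise ValueError("box edges must be positive")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        apl_atoms = self.topology.atoms_per_lipid
        if self.n_atoms < self.n_lipids * apl_atoms:
            raise TopologyError(
                f"{self.n_atoms} atoms cannot hold {self.n_lipids} lipids "
                f"of {apl_atoms} atoms"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def n_lipid_atoms(self) -> int:
        return self.n_lipids * self.topology.atoms_per_lipid

    @property
    def frame_dt(self) -> float:
        if self.n_frames < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    def lipid_atom_indices(self, name: str) -> np.ndarray:
        """Global atom indices of atom ``name`` in every lipid, shape (n_lipids,)."""
        off = self.topology.index_of(name)
        apl = self.topology.atoms_per_lipid
        return np.arange(self.n_lipids, dtype=np.intp) * apl + off

    def lipid_coords(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Coordinates reshaped per lipid: (F, n_lipids, n_sel, 3).

        ``names=None`` returns all atoms of every lipid in name-map order.
        """
        apl = self.topology.atoms_per_lipid
        block = self.coords[:, : self.n_lipid_atoms].reshape(
            self.n_frames, self.n_lipids, apl, 3
        )
        if names is None:
            return block
        return block[:, :, self.topology.indices_of(names), :]

    def solvent_coords(self) -> np.ndarray:
        return self.coords[:, self.n_lipid_atoms :]


@dataclass
class LeafletAssignment:
    """Per-frame leaflet id for every lipid plus which leaflets touch water.

    Leaflets are numbered 0..n_leaflets-1 from low to high mean marker z;
    ``outer_flag`` marks the two extreme-z leaflets (for a single bilayer
    both leaflets are outer).
    """

    leaflet_id: np.ndarray  # (F, n_lipids) small ints
    outer_flag: np.ndarray  # (n_leaflets,) bool
    marker_atom: str = "O1"

    @property
    def n_leaflets(self) -> int:
        return len(self.outer_flag)

    def populations(self, frame: int = 0) -> np.ndarray:
        return np.bincount(self.leaflet_id[frame], minlength=self.n_leaflets)

    def outer_mask(self, frame: int) -> np.ndarray:
        """Boolean per-lipid mask of outer-leaflet membership in ``frame``."""
        return self.outer_flag[self.leaflet_id[frame]]


def load_trajectory(
    topology_path,
    trajectory_path,
    lipid_spec: LipidTopology,
) -> TrajectoryData:
    """Read a coordinate file (PDB/GRO) plus trajectory (XTC/TRR/DCD) into memory.

    Lipid residues are recognised by ``lipid_spec.lipid_name``; every such
    residue must contain exactly the atoms of the name map, in map order.
    Remaining atoms are treated as a contiguous solvent block.  Raises
    :class:`TopologyError` on naming/count mismatch and
    :class:`TruncationError` (naming the last valid frame) if the stream
    breaks mid-read.
    """
    import MDAnalysis as mda

    u = mda.Universe(str(topology_path), str(trajectory_path))
    names = u.atoms.names.astype(str)
    resnames = u.atoms.resnames.astype(str)
    lipid_mask = resnames == lipid_spec.lipid_name
    apl = lipid_spec.atoms_per_lipid
    n_lipid_atoms = int(lipid_mask.sum())
    if n_lipid_atoms == 0 or n_lipid_atoms % apl != 0:
        raise TopologyError(
            f"{n_lipid_atoms} atoms with resname {lipid_spec.lipid_name!r} "
            f"is not a multiple of atoms_per_lipid={apl}"
        )
    if not lipid_mask[:n_lipid_atoms].all():
        raise TopologyError("lipid atoms must form a leading contiguous block")
    n_lipids = n_lipid_atoms // apl
    order = sorted(lipid_spec.name_map, key=lipid_spec.name_map.get)
    expected = np.tile(np.array(order, dtype=object), n_lipids)
    if not np.array_equal(names[:n_lipid_atoms].astype(object), expected):
        bad = np.nonzero(names[:n_lipid_atoms].astype(object) != expected)[0]
        raise TopologyError(
            f"atom name mismatch at index {bad[0]}: found "
            f"{names[bad[0]]!r}, expected {expected[bad[0]]!r}"
        )

    mol = np.empty(len(names), dtype=np.intp)
    mol[:n_lipid_atoms] = np.repeat(np.arange(n_lipids), apl)
    # solvent molecules follow the residue numbering of the file
    if len(names) > n_lipid_atoms:
        sol_res = u.atoms.resindices[n_lipid_atoms:]
        _, sol_mol = np.unique(sol_res, return_inverse=True)
        mol[n_lipid_atoms:] = n_lipids + sol_mol

    times, boxes, frames = [], [], []
    last_valid = -1
    try:
        for ts in u.trajectory:
            frames.append(u.atoms.positions.astype(np.float32).copy())
            boxes.append(ts.dimensions[:3].astype(float).copy())
            times.append(float(ts.time))
            last_valid += 1
    except Exception as exc:  # unreadable / corrupt tail frame
        if last_valid < 0:
            raise TruncationError(-1, f"no readable frames: {exc}") from exc
        raise TruncationError(last_valid) from exc

    return TrajectoryData(
        times=np.array(times),
        box=np.array(boxes),
        coords=np.array(frames),
        topology=lipid_spec,
        n_lipids=n_lipids,
        molecule_index=mol,
        atom_names=names,
    )


def select_window(traj: TrajectoryData, start_time: float, end_time: float) -> TrajectoryData:
    """Frames with ``start_time <= t <= end_time``, order preserved.

    The conventional production choice is the final stretch of the run
    (e.g. the last 500 ns of a 2.5 us trajectory).
    """
    if start_time >= end_time:
        raise ValueError("start_time must be < end_time")
    mask = (traj.times >= start_time) & (traj.times <= end_time)
    if not mask.any():
        raise EmptyWindowError(
            f"no frames in window [{start_time}, {end_time}] ps "
            f"(trajectory spans [{traj.times[0]}, {traj.times[-1]}] ps)"
        )
    return replace(
        traj,
        times=traj.times[mask],
        box=traj.box[mask],
        coords=traj.coords[mask],
    )


def _kmeans_1d(z: np.ndarray, k: int, max_iter: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic 1D k-means: quantile init, Lloyd iterations."""
    qs = (np.arange(k) + 0.5) / k
    centers = np.quantile(z, qs)
    labels = np.zeros(len(z), dtype=np.intp)
    for _ in range(max_iter):
        labels = np.argmin(np.abs(z[:, None] - centers[None, :]), axis=1)
        new = np.array(
            [z[labels == j].mean() if np.any(labels == j) else centers[j] for j in range(k)]
        )
        if np.allclose(new, centers):
            centers = new
            break
        centers = new
    return labels, centers


def assign_leaflets(
    traj: TrajectoryData,
    n_leaflets: int,
    marker_atom: str = "O1",
    min_gap: float = 2.0,
) -> LeafletAssignment:
    """Partition lipids into leaflets by 1D clustering of marker-atom z.

    The marker is conventionally the primary hydroxyl oxygen O1.  Each
    frame is clustered independently with a fixed cluster count (2 for a
    single bilayer, 4 for stacked/interdigitated double configurations);
    clusters are relabelled bottom-to-top so ids are stable.  Raises
    :class:`DegenerateGeometryError` when the marker z values do not
    resolve into ``n_leaflets`` bands separated by at least ``min_gap``
    angstrom (center-to-center).
    """
    if n_leaflets not in (2, 4):
        raise ValueError("n_leaflets must be 2 or 4")
    idx = traj.lipid_atom_indices(marker_atom)
    out = np.empty((traj.n_frames, traj.n_lipids), dtype=np.int8)
    for f in range(traj.n_frames):
        z = traj.coords[f, idx, 2].astype(float)
        if len(np.unique(np.round(z, 6))) < n_leaflets:
            raise DegenerateGeometryError(
                f"frame {f}: fewer than {n_leaflets} distinct marker z bands"
            )
        labels, centers = _kmeans_1d(z, n_leaflets)
        order = np.argsort(centers)
        centers_sorted = centers[order]
        if np.min(np.diff(centers_sorted)) < min_gap:
            raise DegenerateGeometryError(
                f"frame {f}: leaflet bands closer than {min_gap} A "
                f"(centers {np.round(centers_sorted, 2)})"
            )
        rank = np.empty(n_leaflets, dtype=np.int8)
        rank[order] = np.arange(n_leaflets, dtype=np.int8)
        out[f] = rank[labels]
    outer = np.zeros(n_leaflets, dtype=bool)
    outer[0] = outer[-1] = True
    return LeafletAssignment(leaflet_id=out, outer_flag=outer, marker_atom=marker_atom)
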