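"""Interfacial hydrogen bonding and headgroup dynamics.

A hydrogen bond exists when the donor and acceptor oxygens are within
3.5 A and the acceptor-donor-hydrogen angle is at most 30 deg.  Bonds are
classified intramolecular, intermolecular (lipid-lipid) or lipid-water.
Bond stability is assessed with the intermittent-indicator autocorrelation
C(t) = <h(tau) h(tau+t)> / <h>, optionally tail-corrected by subtracting
the long-lag plateau and renormalising.  Orientational decay curves are
fitted with a double exponential a1*exp(-t/tau1) + a2*exp(-t/tau2) + b
(fast and slow rotational modes) using multi-start nonlinear least
squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .chain_order import ACFSeries, vector_acf
from .core import TrajectoryData

__all__ = [
    "HBOND_DISTANCE_CUTOFF",
    "HBOND_ANGLE_CUTOFF",
    "HBondRecord",
    "DoubleExpFit",
    "detect_hbonds",
    "hbond_statistics",
    "hbond_acf",
    "fit_double_exponential",
    "glycerol_acf",
]

HBOND_DISTANCE_CUTOFF = 3.5  # A, donor-acceptor
HBOND_ANGLE_CUTOFF = 30.0  # deg, acceptor-donor-hydrogen

#: hydrogen-bond bookkeeping groups: hydroxyls donate and accept,
#: ester/carbonyl oxygens accept only
DONOR_GROUPS = {"O1": "O1-H", "O3": "O3-H", "O5": "O5-H"}
ACCEPTOR_GROUPS = ("O1", "O2", "O3", "O4", "O5")


@dataclass(frozen=True)
class HBondRecord:
    frame: int
    donor_atom: int
    hydrogen_atom: int
    acceptor_atom: int
    donor_mol: int
    acceptor_mol: int
    kind: str  # 'intra' | 'inter' | 'lipid-water'
    donor_group: str  # 'O1-H' | 'O3-H' | 'O5-H' | 'water'
    acceptor_group: str  # 'O1'..'O5' | 'water'


@dataclass
class DoubleExpFit:
    """Double-exponential fit; reported with tau1 <= tau2 (fast/slow)."""

    a1: float
    tau1: float
    a2: float
    tau2: float
    b: float
    residual: float
    degenerate: bool = False

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        return (
            self.a1 * np.exp(-np.asarray(t) / self.tau1)
            + self.a2 * np.exp(-np.asarray(t) / self.tau2)
            + self.b
        )


def _hbond_sites(traj: TrajectoryData):
    """Donor (D, H), acceptor and water site index arrays for the system."""
    topo = traj.topology
    donors, hydrogens, d_groups = [], [], []
    for oname, hname in topo.donor_pairs:
        donors.append(traj.lipid_atom_indices(oname))
        hydrogens.append(traj.lipid_atom_indices(hname))
        d_groups += [DONOR_GROUPS.get(oname, oname + "-H")] * traj.n_lipids
    acceptors, a_groups = [], []
    for oname in topo.acceptor_atoms:
        acceptors.append(traj.lipid_atom_indices(oname))
        a_groups += [oname] * traj.n_lipids
    donors = np.concatenate(donors)
    hydrogens = np.concatenate(hydrogens)
    acceptors = np.concatenate(acceptors)

    # water block: OW followed by two hydrogens per molecule
    wmask = traj.atom_names == "OW"
    w_ox = np.nonzero(wmask)[0]
    if len(w_ox):
        donors = np.concatenate([donors, w_ox, w_ox])
        hydrogens = np.concatenate([hydrogens, w_ox + 1, w_ox + 2])
        d_groups += ["water"] * (2 * len(w_ox))
        acceptors = np.concatenate([acceptors, w_ox])
        a_groups += ["water"] * len(w_ox)
    return donors, hydrogens, np.array(d_groups), acceptors, np.array(a_groups)


def detect_hbonds(
    traj: TrajectoryData,
    frame: int,
    d_cut: float = HBOND_DISTANCE_CUTOFF,
    angle_cut: float = HBOND_ANGLE_CUTOFF,
) -> list[HBondRecord]:
    """All hydrogen bonds in one frame under the (3.5 A, 30 deg) criterion.

    Donor-hydrogen pairing comes from the topology (hydroxyl hydrogens and
    water hydrogens); acceptors are the lipid oxygens and water oxygens.
    Distances use the minimum-image convention.  Water-water bonds are not
    reported.
    """
    from scipy.spatial import cKDTree

    donors, hydrogens, d_groups, acceptors, a_groups = _hbond_sites(traj)
    if len(donors) == 0 or len(acceptors) == 0:
        return []
    box = traj.box[frame]
    pos = traj.coords[frame].astype(float)
    dpos = np.mod(pos[donors], box)
    apos = np.mod(pos[acceptors], box)
    tree = cKDTree(apos, boxsize=box)
    pairs = tree.query_ball_point(dpos, r=d_cut)
    cos_cut = math.cos(math.radians(angle_cut))
    mol = traj.molecule_index
    out = []
    for di, acc_list in enumerate(pairs):
        d_atom = donors[di]
        h_atom = hydrogens[di]
        dh = pos[h_atom] - pos[d_atom]
        dh = dh - box * np.round(dh / box)
        dh_u = dh / np.linalg.norm(dh)
        for ai in acc_list:
            a_atom = acceptors[ai]
            if a_atom == d_atom:
                continue
            if d_groups[di] == "water" and a_groups[ai] == "water":
                continue
            da = pos[a_atom] - pos[d_atom]
            da = da - box * np.round(da / box)
            r = np.linalg.norm(da)
            if r < 1e-6 or r > d_cut:
                continue
            if float(da @ dh_u) / r < cos_cut:
                continue
            dm, am = int(mol[d_atom]), int(mol[a_atom])
            if dm == am:
                kind = "intra"
            elif dm < traj.n_lipids and am < traj.n_lipids:
                kind = "inter"
            else:
                kind = "lipid-water"
            out.append(
                HBondRecord(
                    frame=frame,
                    donor_atom=int(d_atom),
                    hydrogen_atom=int(h_atom),
                    acceptor_atom=int(a_atom),
                    donor_mol=dm,
                    acceptor_mol=am,
                    kind=kind,
                    donor_group=str(d_groups[di]),
                    acceptor_group=str(a_groups[ai]),
                )
            )
    return out


def hbond_statistics(
    traj: TrajectoryData,
    d_cut: float = HBOND_DISTANCE_CUTOFF,
    angle_cut: float = HBOND_ANGLE_CUTOFF,
):
    """Per-molecule hydrogen-bond counts, frame-averaged.

    Returns a dict with 'intra'/'inter' mean +- sd of bonds per lipid, and
    a per-group breakdown of lipid-water bonds over {O1-H, O2, O3-H, O4,
    O5-H} (hydroxyls counted via their donor role plus their acceptor
    role toward water donors; O2/O4 as acceptors only).
    """
    n = traj.n_lipids
    per_frame = {"intra": [], "inter": [], "water": []}
    group_cols = ["O1-H", "O2", "O3-H", "O4", "O5-H"]
    group_frames = {g: [] for g in group_cols}
    records = []
    for f in range(traj.n_frames):
        bonds = detect_hbonds(traj, f, d_cut, angle_cut)
        records.append(bonds)
        per_frame["intra"].append(sum(b.kind == "intra" for b in bonds) / n)
        per_frame["inter"].append(sum(b.kind == "inter" for b in bonds) / n)
        per_frame["water"].append(sum(b.kind == "lipid-water" for b in bonds) / n)
        counts = dict.fromkeys(group_cols, 0)
        for b in bonds:
            if b.kind != "lipid-water":
                continue
            if b.donor_group != "water":  # lipid hydroxyl donating to water
                counts[b.donor_group] += 1
            else:  # water donating to a lipid oxygen
                grp = DONOR_GROUPS.get(b.acceptor_group, b.acceptor_group)
                counts[grp] += 1
        for g in group_cols:
            group_frames[g].append(counts[g] / n)
    out = {"records": records}
    for k in ("intra", "inter", "water"):
        arr = np.array(per_frame[k])
        out[k] = (float(arr.mean()), float(arr.std(ddof=0)))
    out["groups"] = {
        g: (float(np.mean(v)), float(np.std(v, ddof=0))) for g, v in group_frames.items()
    }
    return out


def hbond_acf(
    traj: TrajectoryData,
    d_cut: float = HBOND_DISTANCE_CUTOFF,
    angle_cut: float = HBOND_ANGLE_CUTOFF,
    kinds: tuple[str, ...] = ("intra", "inter"),
    tail_correct: bool = True,
    max_lag: int | None = None,
) -> ACFSeries:
    """Intermittent hydrogen-bond autocorrelation.

    The indicator h(t) of every donor-acceptor pair ever bonded is
    correlated as C(t) = <h(tau) h(tau+t)> / <h>, so C(0) = 1.  With
    ``tail_correct`` the long-lag plateau (mean of the last fifth of the
    lags) is subtracted and the curve renormalised; the plateau value is
    logged in the series metadata.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    pair_index: dict[tuple[int, int], int] = {}
    frames_bonds = []
    for f in range(traj.n_frames):
        bonds = {
            (b.donor_atom, b.acceptor_atom)
            for b in detect_hbonds(traj, f, d_cut, angle_cut)
            if b.kind in kinds
        }
        frames_bonds.append(bonds)
        for p in bonds:
            pair_index.setdefault(p, len(pair_index))
    if not pair_index:
        raise ValueError("no hydrogen bonds of the requested kinds found in any frame")
    F = traj.n_frames
    h = np.zeros((F, len(pair_index)), dtype=np.float64)
    for f, bonds in enumerate(frames_bonds):
        for p in bonds:
            h[f, pair_index[p]] = 1.0
    if max_lag is None:
        max_lag = max(F // 2, 1)
    lags = np.arange(max_lag + 1)
    c = np.empty(len(lags))
    for i, l in enumerate(lags):
        c[i] = (h[: F - l] * h[l:]).sum() / ((F - l) * h.shape[1])
    c = c / c[0]
    meta = {"n_pairs": len(pair_index), "kinds": kinds}
    if tail_correct:
        tail = c[-max(len(c) // 5, 1) :].mean()
        meta["plateau"] = float(tail)
        if tail < 1.0:
            c = (c - tail) / (1.0 - tail)
    return ACFSeries(lags=lags * traj.frame_dt, values=c, normalization="intermittent", meta=meta)


def _double_exp(t, a1, tau1, a2, tau2, b):
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + b


def fit_double_exponential(acf: ACFSeries, n_starts: int = 8) -> DoubleExpFit:
    """Nonlinear least-squares fit of a1*exp(-t/tau1) + a2*exp(-t/tau2) + b.

    Initialisation is multi-start over a log-spaced tau grid spanning the
    lag range (two-exponential fits are initialisation-sensitive); the
    best-residual solution is reported with tau1 <= tau2.  A fit is
    flagged degenerate when the two timescales coincide (ratio < 1.05) or
    an amplitude vanishes (< 1e-6).
    """
    t = np.asarray(acf.lags, dtype=float)
    y = np.asarray(acf.values, dtype=float)
    if len(t) < 10:
        raise ValueError("need at least 10 lag points")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in ACF")
    pos = t[t > 0]
    t_lo, t_hi = pos.min(), t.max()
    grid = np.geomspace(t_lo, 2 * t_hi, n_starts)
    amp0 = max(y[0] - y[-1], 0.1)
    best = None
    for k in range(n_starts - 1):
        x0 = [amp0 / 2, grid[k], amp0 / 2, grid[min(k + n_starts // 2, n_starts - 1)], y[-1]]
        try:
            sol = least_squares(
                lambda p: _double_exp(t, *p) - y,
                x0,
                bounds=([-np.inf, t_lo * 1e-3, -np.inf, t_lo * 1e-3, -np.inf], np.inf),
                method="trf",
                max_nfev=5000,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success and best.cost > 1e6:
        raise RuntimeError("double-exponential fit failed from all starts")
    a1, tau1, a2, tau2, b = best.x
    if tau1 > tau2:
        a1, tau1, a2, tau2 = a2, tau2, a1, tau1
    degenerate = (tau2 / max(tau1, 1e-300) < 1.05) or min(abs(a1), abs(a2)) < 1e-6
    return DoubleExpFit(
        a1=float(a1),
        tau1=float(tau1),
        a2=float(a2),
        tau2=float(tau2),
        b=float(b),
        residual=float(np.sqrt(2 * best.cost)),
        degenerate=bool(degenerate),
    )


def glycerol_acf(traj: TrajectoryData, max_lag: int | None = None) -> ACFSeries:
    """Rotational ACF of the glycerol C1->C3 vector (headgroup dynamics)."""
    a, b = traj.topology.glycerol_vector_atoms
    acf = vector_acf(traj, (a, b), max_lag=max_lag)
    acf.meta["vector"] = f"{a}->{b} (glycerol)"
    return acf
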