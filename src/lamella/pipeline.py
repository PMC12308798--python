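"""Config-driven orchestration of the full analysis battery.

Runs geometry -> chain order -> conformational ML -> interface analysis on
a real (topology + trajectory file) or synthetic system, writing TSV
tables with JSON metadata sidecars.  A single master seed fans out to
per-stage seeds by fixed offsets so stages stay individually reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import chain_order, conformation, geometry, interface
from .core import assign_leaflets, load_trajectory, mmg_topology, select_window
from .synthetic import SyntheticSystemSpec, generate_membrane_trajectory, write_system

__all__ = [
    "AnalysisConfig",
    "StageError",
    "run_pipeline",
    "generate_fixtures",
    "FIXTURE_SPECS",
]

log = logging.getLogger("lamella.pipeline")

# seed offsets per stage
_SEED_OFFSETS = {"synthesis": 11, "motifs": 23}


class StageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage {stage!r} failed: {original}")


@dataclass
class AnalysisConfig:
    """Pipeline configuration; hyperparameters default to the standard
    protocol values (g3 cutoff 15 A on a 201x101 grid, t-SNE perplexity
    100 with early exaggeration 4, HDBSCAN minimum cluster size 50,
    hydrogen-bond criterion 3.5 A / 30 deg)."""

    name: str = "system"
    arrangement: str = "single_bilayer"
    topology_path: str | None = None
    trajectory_path: str | None = None
    synthetic: dict | None = None  # SyntheticSystemSpec fields
    window: tuple[float, float] | None = None  # ps
    n_blocks: int = 5
    n_per_leaflet: int | None = None
    g3_cutoff: float = 15.0
    perplexity: float = 100.0
    early_exaggeration: float = 4.0
    min_cluster_size: int = 50
    hbond_distance: float = 3.5
    hbond_angle: float = 30.0
    out_dir: str = "lamella_out"
    seed: int = 0
    run_motifs: bool = True
    stages: tuple[str, ...] = ("geometry", "order", "motifs", "interface")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self):
        if self.synthetic is None:
            if not self.topology_path or not self.trajectory_path:
                raise ValueError(
                    "config needs either a synthetic spec or topology_path + trajectory_path"
                )
            for p in (self.topology_path, self.trajectory_path):
                if not Path(p).exists():
                    raise FileNotFoundError(f"input file not found: {p}")
        if self.window is not None and self.window[0] >= self.window[1]:
            raise ValueError("window start must be before window end")


def _load(config: AnalysisConfig, seed: int):
    if config.synthetic is not None:
        spec = SyntheticSystemSpec(
            arrangement=config.arrangement,
            seed=seed + _SEED_OFFSETS["synthesis"],
            **config.synthetic,
        )
        traj, gt = generate_membrane_trajectory(spec)
        return traj, gt, spec.n_per_leaflet
    topo = mmg_topology()
    traj = load_trajectory(config.topology_path, config.trajectory_path, topo)
    return traj, None, config.n_per_leaflet


def _write_tsv(path: Path, frame, meta: dict):
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
    side = path.with_suffix(path.suffix + ".json")
    side.write_text(json.dumps(meta, indent=2, default=str))


def _stage_geometry(config, traj, leaflets, n_per_leaflet, out, summary):
    import pandas as pd

    area = geometry.apl_xy(traj, n_per_leaflet)
    vor = geometry.apl_voronoi(traj, leaflets)
    prof = geometry.density_profile(
        traj,
        np.arange(traj.n_lipid_atoms),
        weighting="electron",
        n_bins=max(100, traj.n_atoms // 500),
        n_blocks=min(config.n_blocks, traj.n_frames),
    )
    mode = "overall" if config.arrangement == "single_bilayer" else "per_bilayer"
    thick = geometry.thickness_from_profile(prof, mode=mode)
    _write_tsv(
        out / "membrane_properties.tsv",
        pd.DataFrame(
            [
                {
                    "system": config.name,
                    "apl_xy": area.apl_xy_mean,
                    "apl_xy_sd": area.apl_xy_sd,
                    "apl_vor_mean": vor.apl_vor_mean,
                    "apl_vor_median": vor.apl_vor_median,
                    "apl_vor_mode": vor.apl_vor_mode,
                    "membrane_thickness": thick.membrane_thickness,
                    "membrane_thickness_sd": thick.membrane_thickness_sd,
                    "bilayer_thickness": thick.bilayer_thickness,
                    "bilayer_thickness_sd": thick.bilayer_thickness_sd,
                }
            ]
        ),
        {"stage": "geometry", "n_frames": traj.n_frames},
    )
    summary["apl_xy"] = area.apl_xy_mean
    summary["apl_vor_mean"] = vor.apl_vor_mean
    summary["membrane_thickness"] = thick.membrane_thickness
    summary["bilayer_thickness"] = thick.bilayer_thickness


def _stage_order(config, traj, leaflets, n_per_leaflet, out, summary):
    import pandas as pd

    rows = []
    for tail_name, tail in (
        ("tail1", traj.topology.tail1_atoms),
        ("tail2", traj.topology.tail2_atoms),
    ):
        prof = chain_order.scd_profile(traj, tail, n_blocks=config.n_blocks)
        rows += [
            {"tail": tail_name, "carbon": c, "scd": s, "scd_sd": sd}
            for c, s, sd in zip(prof.carbons, prof.scd, prof.scd_sd)
        ]
        summary[f"mean_abs_scd_{tail_name}"] = prof.mean_abs
    _write_tsv(out / "order_parameters.tsv", pd.DataFrame(rows), {"stage": "order"})

    angle_rows = []
    for tag, dist in (
        ("tilt_tail1", chain_order.tilt_distribution(traj, ("C20", "C7"))),
        ("tilt_tail2", chain_order.tilt_distribution(traj, ("C35", "C21"))),
        ("splay1", chain_order.splay_distribution(traj, ("C9", "C5", "C22"))),
        ("splay2", chain_order.splay_distribution(traj, ("C20", "C5", "C35"))),
    ):
        angle_rows.append({"angle": tag, "mode_deg": dist.mode})
        summary[f"{tag}_mode"] = dist.mode
    _write_tsv(out / "angles.tsv", pd.DataFrame(angle_rows), {"stage": "order"})

    if traj.n_frames >= 4:
        acf = chain_order.vector_acf(traj, ("C7", "C20"))
        _write_tsv(out / "tail_acf.tsv", acf.to_profile().to_frame(), {"stage": "order"})
    r_max = float(min(traj.box[:, 0].min(), traj.box[:, 1].min()) / 2.0) - 1e-9
    rdf = chain_order.rdf_2d(
        traj,
        tuple(f"C{i}" for i in range(7, 36)),
        tuple(f"C{i}" for i in range(7, 36)),
        leaflets,
        r_max=min(r_max, 15.0),
    )
    _write_tsv(out / "tail_rdf.tsv", pd.DataFrame({"r": rdf.r, "g": rdf.g}), {"stage": "order"})


def _stage_motifs(config, traj, leaflets, n_per_leaflet, out, summary):
    import pandas as pd

    H = conformation.compute_g3_all(traj, cutoff=config.g3_cutoff)
    sim = conformation.build_similarity_matrix(H)
    res = conformation.embed_and_cluster(
        sim,
        perplexity=config.perplexity,
        early_exaggeration=config.early_exaggeration,
        min_cluster_size=config.min_cluster_size,
        seed=config.seed + _SEED_OFFSETS["motifs"],
    )
    conformation.characterize_clusters(res, H)
    emb = pd.DataFrame(
        {
            "lipid": np.arange(traj.n_lipids),
            "tsne_x": res.embedding[:, 0],
            "tsne_y": res.embedding[:, 1],
            "pca_x": res.pca_embedding[:, 0],
            "pca_y": res.pca_embedding[:, 1],
            "cluster": res.labels,
            "motif": res.motif_labels(),
        }
    )
    _write_tsv(
        out / "motif_labels.tsv",
        emb,
        {
            "stage": "motifs",
            "motif_map": {str(k): int(v) for k, v in res.motif_map.items()},
            "fractions": res.fractions,
        },
    )
    summary["n_clusters"] = res.n_clusters
    summary["motif_fractions"] = res.fractions


def _stage_interface(config, traj, leaflets, n_per_leaflet, out, summary):
    import pandas as pd

    st = interface.hbond_statistics(traj, config.hbond_distance, config.hbond_angle)
    _write_tsv(
        out / "hbonds.tsv",
        pd.DataFrame(
            [
                {
                    "inter_per_mol": st["inter"][0],
                    "inter_sd": st["inter"][1],
                    "intra_per_mol": st["intra"][0],
                    "intra_sd": st["intra"][1],
                    **{f"water_{g}": v[0] for g, v in st["groups"].items()},
                }
            ]
        ),
        {"stage": "interface"},
    )
    summary["hbond_inter_per_mol"] = st["inter"][0]
    summary["hbond_intra_per_mol"] = st["intra"][0]
    if traj.n_frames >= 20:
        acf = interface.glycerol_acf(traj)
        _write_tsv(out / "glycerol_acf.tsv", acf.to_profile().to_frame(), {"stage": "interface"})
        try:
            fit = interface.fit_double_exponential(acf)
            summary["glycerol_tau1_ps"] = fit.tau1
            summary["glycerol_tau2_ps"] = fit.tau2
            summary["glycerol_a1"] = fit.a1
            summary["glycerol_a2"] = fit.a2
        except (RuntimeError, ValueError):
            log.warning("glycerol ACF fit did not converge; skipping summary entry")


_STAGES = {
    "geometry": _stage_geometry,
    "order": _stage_order,
    "motifs": _stage_motifs,
    "interface": _stage_interface,
}


def run_pipeline(config: AnalysisConfig) -> dict:
    """Execute the configured stages in order (geometry -> order -> motifs ->
    interface), writing tables under ``config.out_dir``.

    Returns a summary dict of headline numbers.  On stage failure the run
    aborts with :class:`StageError` naming the stage; outputs of completed
    stages are preserved on disk.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    summary: dict = {"name": config.name, "seed": config.seed}
    logging.basicConfig(level=logging.INFO, format="%(asctime)s %(message)s")

    traj, gt, n_per_leaflet = _load(config, config.seed)
    if config.window is not None:
        traj = select_window(traj, *config.window)
    n_leaflets = 2 if config.arrangement == "single_bilayer" else 4
    leaflets = assign_leaflets(traj, n_leaflets)
    if n_per_leaflet is None:
        n_per_leaflet = traj.n_lipids // n_leaflets

    wanted = [s for s in _STAGES if s in config.stages]
    if not config.run_motifs and "motifs" in wanted:
        wanted.remove("motifs")
    for stage in wanted:
        log.info("stage: %s", stage)
        try:
            _STAGES[stage](config, traj, leaflets, n_per_leaflet, out, summary)
        except Exception as exc:
            raise StageError(stage, exc) from exc

    summary["runtime_s"] = round(time.time() - t_start, 2)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary


#: named synthetic fixtures
FIXTURE_SPECS = {
    "motif4": dict(
        arrangement="single_bilayer",
        n_per_leaflet=500,
        motif_fractions=(0.25, 0.25, 0.25, 0.25),
        apl_target=40.0,
        n_frames=8,
        frame_dt=500.0,
    ),
    "bilayer_small": dict(
        arrangement="single_bilayer",
        n_per_leaflet=100,
        motif_fractions=(0.6, 0.2, 0.1, 0.1),
        apl_target=39.8,
        n_frames=100,
        frame_dt=500.0,
        water_per_outer_lipid=1.0,
        hbond_fraction=0.3,
    ),
    "double_small": dict(
        arrangement="double_bilayer",
        n_per_leaflet=64,
        motif_fractions=(0.7, 0.2, 0.05, 0.05),
        apl_target=41.2,
        n_frames=10,
        frame_dt=500.0,
    ),
    "interdigitated_small": dict(
        arrangement="interdigitated",
        n_per_leaflet=64,
        motif_fractions=(0.7, 0.2, 0.05, 0.05),
        apl_target=72.0,
        n_frames=10,
        frame_dt=500.0,
    ),
}


def generate_fixtures(spec_name: str, out_dir, seed: int = 0):
    """Write a named synthetic dataset (GRO + XTC + ground-truth TSV).

    Known names: motif4 (4 planted conformational families, 250 lipids
    each), bilayer_small, double_small, interdigitated_small.
    """
    if spec_name not in FIXTURE_SPECS:
        raise ValueError(
            f"unknown fixture {spec_name!r}; available: {sorted(FIXTURE_SPECS)}"
        )
    spec = SyntheticSystemSpec(seed=seed, **FIXTURE_SPECS[spec_name])
    traj, gt = generate_membrane_trajectory(spec)
    return write_system(traj, gt, out_dir, prefix=spec_name)
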