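"""End-to-end pipeline: simulate/ingest -> profiles -> gaps -> normalization ->
functional regression -> dissimilarity clustering, with file outputs and a
reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import cluster_speakers, dendrogram_newick, pca_dissim
from .dissim import pair_dissim, subject_average, subject_distance_matrix
from .errors import ConfigurationError
from .extract import extract_trajectories
from .fosr import FosrSpec, fit_all_sites, predict_curves
from .grid import regrid_per_trial
from .io import read_image_stack
from .prep import assemble
from .synth import CohortDesign, GestureArchetype, PhantomSpec, gen_trajectories, \
    phantom_grid, render_phantom

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run."""

    mode: str = "synthetic"  # or "ingest"
    out_dir: str = "artikin_out"
    seed: int = 0
    # synthetic mode
    synth: dict = field(default_factory=dict)  # CohortDesign overrides
    render: bool = False  # render phantom images and re-extract (synthetic)
    phantom: dict = field(default_factory=dict)  # PhantomSpec overrides
    # ingest mode
    images: list[str] = field(default_factory=list)
    landmarks_csv: str | None = None
    metadata_csv: str | None = None
    overrides_csv: str | None = None
    # analysis settings
    gmm: dict = field(default_factory=dict)
    prep: dict = field(default_factory=dict)  # min_reps / max_reps / drop_training
    fosr: dict = field(default_factory=dict)  # FosrSpec overrides + test settings
    clustering: dict = field(default_factory=dict)  # linkage / k_range / energy mode
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.mode not in ("synthetic", "ingest"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.mode == "ingest":
            if not self.images:
                raise ConfigurationError("ingest mode requires 'images'")
            if not self.landmarks_csv:
                raise ConfigurationError("ingest mode requires 'landmarks_csv'")
            for p in list(self.images) + [self.landmarks_csv]:
                if p and not Path(p).exists():
                    raise ConfigurationError(f"input path does not exist: {p}")

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output location and
        log level excluded, so reruns into different directories compare
        equal)."""
        payload = asdict(self)
        payload.pop("out_dir", None)
        payload.pop("log_level", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _build_design(cfg: PipelineConfig, seed: int) -> CohortDesign:
    kwargs = dict(cfg.synth)
    kwargs.setdefault("seed", seed)
    if "group_archetypes" in kwargs:
        kwargs["group_archetypes"] = {
            g: tuple(GestureArchetype(**a) for a in archs)
            for g, archs in kwargs["group_archetypes"].items()
        }
    return CohortDesign(**kwargs)


def _acquire_trajectories(cfg: PipelineConfig, seed: int, out: Path) -> pd.DataFrame:
    """simulate or ingest + extract; returns the raw long trajectory table."""
    if cfg.mode == "synthetic":
        design = _build_design(cfg, seed)
        bundle = gen_trajectories(design)
        bundle.trials.to_csv(out / "trials.csv", index=False)
        if not cfg.render:
            df = bundle.data.copy()
            df["width_mm"] = df["width_px"] * PhantomSpec(**cfg.phantom).spacing_mm
            return df
        spec = PhantomSpec(**cfg.phantom)
        seqs, truth = render_phantom(bundle, spec, seed=seed)
        truth.to_csv(out / "ground_truth.csv", index=False)
        grid = phantom_grid(spec)
        return extract_trajectories(seqs, grid, gmm_kwargs=cfg.gmm)

    landmarks = pd.read_csv(cfg.landmarks_csv)
    overrides = pd.read_csv(cfg.overrides_csv) if cfg.overrides_csv else None
    seqs = [read_image_stack(p) for p in cfg.images]

    def per_trial_grid(seq):
        return regrid_per_trial(landmarks, f"{seq.subject}_{seq.repetition}")

    return extract_trajectories(seqs, per_trial_grid, gmm_kwargs=cfg.gmm,
                                overrides=overrides)


def run_pipeline(cfg: PipelineConfig, seed: int | None = None,
                 stages: tuple[str, ...] = ("extract", "regress", "cluster")) -> dict:
    """Execute the pipeline and write all outputs; returns the run report."""
    cfg.validate()
    seed = cfg.seed if seed is None else int(seed)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"mode": cfg.mode, "seed": seed}

    raw = _acquire_trajectories(cfg, seed, out)
    raw.to_csv(out / "trajectories_raw.csv", index=False)

    metadata = pd.read_csv(cfg.metadata_csv) if cfg.metadata_csv else None
    ts = assemble(raw, metadata=metadata, **cfg.prep)
    ts.data.to_csv(out / "trajectories_normalized.csv", index=False)
    ts.exclusion_log.to_csv(out / "exclusions.csv", index=False)
    report["t_star"] = ts.t_star
    report["n_subjects"] = len(ts.subjects)
    report["n_excluded_trials"] = int(len(ts.exclusion_log))

    if "regress" in stages:
        fspec_kwargs = dict(cfg.fosr)
        test = fspec_kwargs.pop("test", "wald")
        n_perm = int(fspec_kwargs.pop("n_perm", 199))
        fits = fit_all_sites(ts, FosrSpec(**fspec_kwargs), test=test, n_perm=n_perm,
                             seed=seed)
        summary = {
            site: {k: v for k, v in d.items() if k != "fit"} for site, d in fits.items()
        }
        (out / "fosr_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        curves = pd.concat(
            [predict_curves(d["fit"], "group") for d in fits.values()]
            + [predict_curves(d["fit"], "subject") for d in fits.values()],
            ignore_index=True,
        )
        curves.to_csv(out / "predicted_curves.csv", index=False)
        report["fosr"] = {s: {"edf_group": d["edf_group"], "p": d["p"]}
                          for s, d in summary.items()}

    if "cluster" in stages:
        ccfg = dict(cfg.clustering)
        linkage = ccfg.get("linkage", "ward")
        k_range = tuple(ccfg.get("k_range", (2, 6)))
        mode = ccfg.get("energy_mode", "repetition")
        tab = pair_dissim(ts)
        tab.to_csv(out / "pair_dissimilarities.csv")
        subj = subject_average(tab)
        subj.to_csv(out / "subject_dissimilarities.csv")
        D, subjects, groups = subject_distance_matrix(tab, mode=mode)
        pd.DataFrame(D, index=subjects, columns=subjects).to_csv(out / "distance_matrix.csv")
        res = cluster_speakers(D, subjects, groups, linkage=linkage, k_range=k_range,
                               fisher_seed=seed)
        pca = pca_dissim(subj.droplevel("group") if "group" in subj.index.names else subj)
        cluster_report = res.report()
        cluster_report["pca_explained_ratio"] = pca.explained_ratio.tolist()
        cluster_report["pca_loadings_pc1"] = dict(
            zip(pca.feature_names, pca.loadings[0].tolist())
        )
        (out / "cluster_report.json").write_text(
            json.dumps(cluster_report, indent=2, sort_keys=True)
        )
        pd.DataFrame(res.merge_tree,
                     columns=["node_a", "node_b", "height", "n_members"]).to_csv(
            out / "dendrogram_merges.csv", index=False)
        (out / "dendrogram.newick").write_text(dendrogram_newick(res.merge_tree, subjects))
        report["cluster"] = {
            "k": int(res.k),
            "fisher_p": res.fisher_p,
            "allocation_fraction": res.allocation.fraction,
            "pc1_share": float(pca.explained_ratio[0]),
            "linkage": linkage,
        }

    manifest = {
        "package_version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": seed,
        "stages": list(stages),
        "report": report,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return report
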