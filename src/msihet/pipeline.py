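"""End-to-end pipeline: simulate/load → normalize → segment → grid → report.

A run is described by a :class:`RunConfig` (usually loaded from YAML),
executed into an output directory, and sealed with a ``manifest.json``
recording the config hash, seed, package version and a SHA-256 checksum of
every output file.  Re-running an identical config reproduces identical
checksums.  A stage failure raises a stage-named error; outputs written
before the failure are retained.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import pooled_segment_and_compare
from .dataio import (
    read_clinical_table,
    read_feature_catalog,
    read_pixel_table,
    rms_normalize,
)
from .differential import (
    drug_pathway_association,
    heatmap_matrix,
    pathway_enrichment,
    patient_feature_means,
    subpop_correlation,
    volcano,
)
from .diversity import diversity_table, optimal_cutoff, stage_association
from .segmentation import kmeans_segment, pixel_distribution, presence_matrix
from .survgrid import (
    andersen_gill_fit,
    assign_patients,
    default_tau_grid,
    grid_search,
    multivariate_cox,
    pairwise_subpopulation_tests,
    select_model,
)
from .synthdata import SyntheticConfig, generate_cohort

log = logging.getLogger("msihet")

__all__ = ["RunConfig", "run_pipeline", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    outdir: str = "msihet_run"
    seed: int = 0
    # either simulate (kwargs of SyntheticConfig) or explicit input paths
    simulate: dict | None = None
    pixels: str | None = None
    clinical: str | None = None
    features: str | None = None
    pixels_second_cohort: str | None = None  # enables the compare stage
    stages: dict = field(
        default_factory=lambda: {
            "segment": True,
            "grid": True,
            "diversity": True,
            "survival": True,
            "differential": True,
            "compare": False,
        }
    )
    k_min: int = 2
    k_max: int = 15
    tau_min: float = 0.02
    tau_max: float = 0.50
    tau_step: float = 0.01
    alpha: float = 0.05
    fc_threshold: float = 1.5
    min_group_frac: float = 0.1
    n_init: int = 10
    max_iter: int = 300
    chosen_k: int | None = None  # override grid selection
    chosen_tau: float | None = None
    stage_coding: str = "dummy"
    tau_presence: float = 0.05  # compare-stage presence rule
    min_patients: int = 1
    plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.simulate is None and not (self.pixels and self.clinical):
            raise ValueError("config needs either 'simulate' or input paths")
        for p in (self.pixels, self.clinical, self.features, self.pixels_second_cohort):
            if p is not None and not Path(p).exists():
                raise ValueError(f"input file does not exist: {p}")
        if not (2 <= self.k_min <= self.k_max):
            raise ValueError("need 2 <= k_min <= k_max")
        if not (0 < self.tau_min <= self.tau_max < 1):
            raise ValueError("tau grid must lie in (0, 1)")

    def canonical(self) -> str:
        """Canonical YAML of the analysis-relevant parameters (the output
        location does not change what is computed and is excluded)."""
        d = dataclasses.asdict(self)
        d.pop("outdir")
        return yaml.safe_dump(d, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; return the manifest (also written)."""
    cfg = config
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    outputs: dict[str, Path] = {}
    try:
        _run_stages(cfg, outdir, outputs)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"pipeline failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    manifest = {
        "msihet_version": __version__,
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(cfg.canonical().encode()).hexdigest(),
        "outputs": {name: _sha256(p) for name, p in sorted(outputs.items())},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            log.info("stage %s: start", name)
            try:
                return fn(*a, **kw)
            except Exception as exc:
                raise StageError(f"stage '{name}' failed: {exc}") from exc
        return wrapper
    return deco


def _run_stages(cfg: RunConfig, outdir: Path, outputs: dict) -> None:
    # --- inputs -----------------------------------------------------------
    if cfg.simulate is not None:
        sim = SyntheticConfig(**{**cfg.simulate, "seed": cfg.simulate.get("seed", cfg.seed)})
        pixels, clinical, catalog, _truth = generate_cohort(sim)
        log.info("simulated cohort: %d patients, %d pixels", sim.n_patients, pixels.n_pixels)
        from .dataio import write_clinical_table, write_feature_catalog, write_pixel_table

        outputs["pixels"] = write_pixel_table(pixels, outdir / "pixels.tsv")
        outputs["clinical"] = write_clinical_table(clinical, outdir / "clinical.tsv")
        outputs["features"] = write_feature_catalog(catalog, outdir / "features.tsv")
    else:
        pixels = read_pixel_table(cfg.pixels)
        clinical = read_clinical_table(cfg.clinical)
        catalog = read_feature_catalog(cfg.features) if cfg.features else None

    norm = rms_normalize(pixels)

    presences = {}
    segs = {}
    if cfg.stages.get("segment", True):
        run_segment = _stage("segment")(_segment_all)
        segs, presences = run_segment(cfg, norm)
        sel_k = cfg.chosen_k or max(segs)
        seg = segs[sel_k]
        outputs["segmentation"] = _write(
            seg.labels.rename_axis("pixel_id").reset_index(), outdir / "segmentation.tsv"
        )
        cent = pd.DataFrame(seg.centroids, index=range(1, seg.k + 1), columns=norm.feature_cols)
        outputs["centroids"] = _write(cent.rename_axis("cluster"), outdir / "centroids.tsv", index=True)
        outputs["pixel_distribution"] = _write(
            pixel_distribution(seg), outdir / "pixel_distribution.tsv"
        )

    selection = None
    if cfg.stages.get("grid", True) and presences:
        run_grid = _stage("grid")(_grid)
        grid, selection = run_grid(cfg, presences, clinical)
        outputs["grid"] = _write(grid.frame, outdir / "grid.tsv")
        best = grid.best_per_k()
        if len(best):
            outputs["grid_best_per_k"] = _write(best, outdir / "grid_best_per_k.tsv")
        if cfg.plots:
            from .plots import grid_heatmap

            outputs["grid_heatmap"] = grid_heatmap(grid, outdir / "grid_heatmap.png")

    k_star = cfg.chosen_k or (selection.selected[0] if selection and selection.selected else None)
    tau_star = cfg.chosen_tau or (
        selection.selected[1] if selection and selection.selected else None
    )
    if k_star is None and presences:
        k_star = max(presences)  # fall back: largest segmented k
    presence = presences.get(k_star) if presences else None

    cutoff = None
    if cfg.stages.get("diversity", True) and presence is not None:
        run_div = _stage("diversity")(_diversity)
        div, assoc, cutoff = run_div(cfg, presence, norm, clinical)
        outputs["diversity"] = _write(div.frame, outdir / "diversity.tsv")
        outputs["stage_association"] = _write(assoc.pairwise, outdir / "stage_association.tsv")
        payload = {
            "spearman_rho": assoc.rho,
            "spearman_p": assoc.p,
            "notes": assoc.notes,
        }
        if cutoff is not None:
            payload.update(
                cutoff=cutoff.cutoff,
                logrank_p=cutoff.logrank_p,
                group_sizes=list(cutoff.group_sizes),
                n_candidates=len(cutoff.candidates),
                optimism_warning=cutoff.optimism_warning,
            )
        (outdir / "cutoff.json").write_text(json.dumps(payload, indent=2))
        outputs["cutoff"] = outdir / "cutoff.json"

    assignment = None
    if cfg.stages.get("survival", True) and presence is not None and tau_star is not None:
        run_surv = _stage("survival")(_survival)
        assignment, ag, mv, pw = run_surv(cfg, presence, clinical, tau_star)
        outputs["membership"] = _write(assignment.members, outdir / "membership.tsv")
        if ag is not None:
            outputs["cox_andersen_gill"] = _write(
                ag.summary.rename_axis("term"), outdir / "cox_andersen_gill.tsv", index=True
            )
            outputs["pairwise_subpop"] = _write(pw, outdir / "pairwise_subpop.tsv")
        outputs["cox_multivariate"] = _write(
            mv.summary.rename_axis("term"), outdir / "cox_multivariate.tsv", index=True
        )

    if cfg.stages.get("differential", True) and presence is not None and cutoff is not None:
        run_diff = _stage("differential")(_differential)
        vol, heat, corr, enr, drug = run_diff(cfg, norm, cutoff, presence, catalog)
        outputs["volcano"] = _write(vol, outdir / "volcano.tsv")
        if heat is not None:
            outputs["heatmap_matrix"] = _write(
                heat.matrix.rename_axis("feature"), outdir / "heatmap_matrix.tsv", index=True
            )
        outputs["subpop_correlation"] = _write(corr, outdir / "subpop_correlation.tsv")
        if enr is not None:
            outputs["enrichment"] = _write(enr, outdir / "enrichment.tsv")
        if drug is not None:
            outputs["drug_assoc"] = _write(drug[0], outdir / "drug_assoc.tsv")
            outputs["drug_edges"] = _write(drug[1], outdir / "drug_edges.tsv")

    if cfg.stages.get("compare", False) and cfg.pixels_second_cohort:
        run_cmp = _stage("compare")(_compare)
        comparison = run_cmp(cfg, pixels, k_star or cfg.k_max)
        outputs["comparison"] = _write(comparison.table, outdir / "comparison.tsv")
        if cfg.plots:
            from .plots import comparison_bars

            outputs["comparison_bars"] = comparison_bars(
                comparison, outdir / "comparison_bars.png"
            )


def _segment_all(cfg: RunConfig, norm):
    segs, presences = {}, {}
    ks = [cfg.chosen_k] if (cfg.chosen_k and not cfg.stages.get("grid", True)) else range(
        cfg.k_min, cfg.k_max + 1
    )
    for k in ks:
        seg = kmeans_segment(norm, k, seed=cfg.seed, n_init=cfg.n_init, max_iter=cfg.max_iter)
        segs[k] = seg
        presences[k] = presence_matrix(seg, norm)
        log.info("segmented k=%d wcss=%.4g", k, seg.wcss)
    return segs, presences


def _grid(cfg: RunConfig, presences, clinical):
    taus = default_tau_grid(cfg.tau_min, cfg.tau_max, cfg.tau_step)
    grid = grid_search(presences, clinical, taus)
    selection = select_model(grid, alpha=cfg.alpha)
    log.info("grid: %d rows; selection: %s", len(grid.frame), selection.selected or selection.reason)
    return grid, selection


def _diversity(cfg: RunConfig, presence, norm, clinical):
    div = diversity_table(presence, norm)
    assoc = stage_association(div, clinical)
    try:
        cutoff = optimal_cutoff(div, clinical, min_group_frac=cfg.min_group_frac)
    except ValueError as exc:
        log.warning("no heterogeneity cutoff: %s", exc)
        cutoff = None
    return div, assoc, cutoff


def _survival(cfg: RunConfig, presence, clinical, tau_star):
    assignment = assign_patients(presence, tau_star, clinical)
    ag = pw = None
    if assignment.counts().ge(2).sum() >= 2:
        ag = andersen_gill_fit(assignment, clinical)
        pw = pairwise_subpopulation_tests(ag)
    mv = multivariate_cox(assignment, clinical, stage_coding=cfg.stage_coding)
    return assignment, ag, mv, pw


def _differential(cfg: RunConfig, norm, cutoff, presence, catalog):
    means = patient_feature_means(norm)
    vol = volcano(means, cutoff.group_labels, cfg.fc_threshold, cfg.alpha)
    heat = heatmap_matrix(means, vol, top_n=min(50, vol["p"].notna().sum())) if len(
        means.columns
    ) >= 2 else None
    corr = subpop_correlation(means, presence)
    enr = drug = None
    if catalog is not None:
        enr = pathway_enrichment(corr, catalog, alpha=cfg.alpha)
        drug = drug_pathway_association(corr, catalog, alpha=cfg.alpha)
    return vol, heat, corr, enr, drug


def _compare(cfg: RunConfig, pixels, k):
    second = read_pixel_table(cfg.pixels_second_cohort)
    return pooled_segment_and_compare(
        pixels,
        second,
        k,
        tau_presence=cfg.tau_presence,
        min_patients=cfg.min_patients,
        seed=cfg.seed,
        n_init=cfg.n_init,
    )
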