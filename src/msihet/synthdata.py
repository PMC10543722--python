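"""Synthetic TMA-style MSI cohorts with planted metabolic subpopulations.

The generator emulates the measurement design the pipeline targets: a tissue
microarray of ~70 patients, three 1 mm cores per patient, on the order of a
thousand ROI pixels per patient, and a few hundred abstract intensity
channels tagged with synthetic m/z values.  Ground truth is planted at every
level so downstream stages can be tested for recovery:

* each core is a disc of lattice pixels partitioned into contiguous patches
  (nearest-seed / Voronoi partition of random seed points), and each patch
  carries one true metabolic subpopulation sampled from a patient-specific
  Dirichlet composition — this mimics the patchy, spatially coherent but not
  contiguous cluster maps seen in real segmentations;
* pixel spectra are the subpopulation centroid plus i.i.d. Gaussian noise,
  truncated at zero (intensities are non-negative);
* survival is exponential with a log-hazard that jumps by ``beta_c`` when the
  patient's *realized* pixel fraction of a prognostic subpopulation reaches
  the planted presence threshold ``tau_true``; censoring is independent
  exponential;
* ordinal stage 1-4 is drawn from a proportional-odds model whose linear
  predictor increases with the patient's true Gini-Simpson diversity.

Identical config (including seed) reproduces the cohort bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataio import (
    ClinicalTable,
    FeatureCatalog,
    PixelTable,
    feature_columns,
    write_clinical_table,
    write_feature_catalog,
    write_pixel_table,
)

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_cohort", "write_cohort", "disc_grid"]

# Proportional-odds cutpoints putting stages at 25/25/25/25 % when the
# diversity link is zero: logit(0.25), logit(0.5), logit(0.75).
_STAGE_CUTPOINTS = np.array([-1.0986122886681098, 0.0, 1.0986122886681098])


@dataclass
class SyntheticConfig:
    """Parameters of the generating model.

    ``centroid_separation`` is the pairwise Euclidean distance between
    subpopulation centroids in units of the noise SD (an absolute distance
    in the noise-free limit ``noise_sd = 0``).  ``composition_concentration``
    are the Dirichlet parameters of the per-patient subpopulation mix;
    ``None`` means symmetric Dirichlet(1).  Hazard-related fields are rates
    per month; at the defaults roughly 40 % of patients are censored.
    """

    n_patients: int = 72
    cores_per_patient: int = 3
    pixels_per_core: int = 333
    n_features: int = 100
    n_clusters_true: int = 5
    centroid_separation: float = 6.0
    noise_sd: float = 1.0
    composition_concentration: tuple | None = None
    patches_per_core: int = 12
    prognostic_clusters: frozenset = frozenset({1})
    log_hazard_effects: dict = field(default_factory=lambda: {1: 1.5})
    presence_threshold_true: float = 0.20
    baseline_hazard_rate: float = 0.02
    censoring_rate: float = 0.023
    stage_diversity_link: float = 2.0
    log_hazard_age: float = 0.0
    seed: int = 0

    def __post_init__(self):
        counts = {
            "n_patients": self.n_patients,
            "cores_per_patient": self.cores_per_patient,
            "pixels_per_core": self.pixels_per_core,
            "n_features": self.n_features,
            "patches_per_core": self.patches_per_core,
        }
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v}")
        if self.n_clusters_true < 2:
            raise ValueError("n_clusters_true must be >= 2")
        if self.n_features < self.n_clusters_true:
            raise ValueError("need n_features >= n_clusters_true to separate centroids")
        if not (0 < self.presence_threshold_true < 1):
            raise ValueError("presence_threshold_true must lie in (0, 1)")
        if self.noise_sd < 0 or self.centroid_separation < 0:
            raise ValueError("noise_sd and centroid_separation must be non-negative")
        for name in ("baseline_hazard_rate", "censoring_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.prognostic_clusters = frozenset(int(c) for c in self.prognostic_clusters)
        if not self.prognostic_clusters <= set(range(1, self.n_clusters_true + 1)):
            raise ValueError("prognostic_clusters must be subset of {1..n_clusters_true}")
        if self.composition_concentration is not None:
            conc = np.asarray(self.composition_concentration, dtype=float)
            if conc.shape != (self.n_clusters_true,) or (conc <= 0).any():
                raise ValueError(
                    "composition_concentration must be a positive vector of length n_clusters_true"
                )

    @property
    def concentration(self) -> np.ndarray:
        if self.composition_concentration is None:
            return np.ones(self.n_clusters_true)
        return np.asarray(self.composition_concentration, dtype=float)

    @property
    def centroid_spacing(self) -> float:
        """Absolute pairwise centroid distance implied by the config."""
        return self.centroid_separation * (self.noise_sd if self.noise_sd > 0 else 1.0)


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a generated cohort.

    ``patient_compositions`` are the *realized* per-patient pixel fractions
    of each true subpopulation (rows sum to 1) — the quantity the survival
    model thresholds and the quantity a perfect segmentation would recover.
    ``dirichlet_draws`` are the underlying sampling weights.
    """

    centroids: np.ndarray
    patient_compositions: pd.DataFrame
    dirichlet_draws: pd.DataFrame
    pixel_true_labels: pd.Series
    prognostic_indicator: pd.Series
    true_log_hazards: dict
    presence_threshold_true: float
    true_diversity: pd.Series


def disc_grid(n: int) -> np.ndarray:
    """The ``n`` integer lattice points closest to the origin (a disc).

    Deterministic: points ordered by (squared radius, x, y), the first ``n``
    retained.  Used as the pixel grid of one 1 mm TMA core.
    """
    r = int(np.ceil(np.sqrt(n / np.pi))) + 2
    xs, ys = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    d2 = (pts**2).sum(axis=1)
    order = np.lexsort((pts[:, 1], pts[:, 0], d2))
    return pts[order][:n]


def _make_centroids(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Equidistant non-negative centroids.

    Centroids sit at ``base + s/sqrt(2) * q_c`` where the ``q_c`` are
    orthonormal directions, giving exact pairwise distance ``s`` (the
    configured spacing).  The baseline is lifted far enough that centroid
    entries stay non-negative.
    """
    s = cfg.centroid_spacing
    g = rng.standard_normal((cfg.n_features, cfg.n_clusters_true))
    q, _ = np.linalg.qr(g)
    base = rng.uniform(1.0, 2.0, size=cfg.n_features) + s / np.sqrt(2.0)
    return (base[:, None] + (s / np.sqrt(2.0)) * q).T  # clusters × features


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[PixelTable, ClinicalTable, FeatureCatalog, SyntheticTruth]:
    """Draw one full synthetic cohort (pixels, clinical data, catalog, truth)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    k = cfg.n_clusters_true
    centroids = _make_centroids(cfg, rng)

    grid = disc_grid(cfg.pixels_per_core)
    n_core_px = cfg.pixels_per_core

    dirichlet = rng.dirichlet(cfg.concentration, size=cfg.n_patients)
    patient_ids = [f"P{i:03d}" for i in range(1, cfg.n_patients + 1)]

    rows_meta = []
    labels_all = np.empty(cfg.n_patients * cfg.cores_per_patient * n_core_px, dtype=int)
    pos = 0
    for pi, pid in enumerate(patient_ids):
        for ci in range(1, cfg.cores_per_patient + 1):
            n_seed = min(cfg.patches_per_core, n_core_px)
            seed_idx = rng.choice(n_core_px, size=n_seed, replace=False)
            seeds = grid[seed_idx]
            # nearest-seed partition; ties resolved toward the lowest seed index
            d2 = ((grid[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
            patch_of_pixel = np.argmin(d2, axis=1)
            patch_cluster = rng.choice(np.arange(1, k + 1), size=n_seed, p=dirichlet[pi])
            labels_all[pos : pos + n_core_px] = patch_cluster[patch_of_pixel]
            for (x, y) in grid:
                rows_meta.append((pid, f"{pid}-c{ci}", int(x), int(y)))
            pos += n_core_px

    n_total = pos
    intens = centroids[labels_all - 1].astype(float)
    if cfg.noise_sd > 0:
        intens = intens + rng.normal(0.0, cfg.noise_sd, size=intens.shape)
        np.maximum(intens, 0.0, out=intens)  # truncate: intensities are non-negative

    fcols = feature_columns(cfg.n_features)
    meta = pd.DataFrame(rows_meta, columns=["patient_id", "core_id", "x", "y"])
    meta.insert(0, "pixel_id", [f"px{i:07d}" for i in range(1, n_total + 1)])
    meta.insert(3, "cohort", "tumor")
    pixel_frame = pd.concat(
        [meta, pd.DataFrame(intens, columns=fcols)], axis=1
    )
    pixels = PixelTable(pixel_frame)

    # realized compositions
    comp = np.zeros((cfg.n_patients, k))
    per_patient = cfg.cores_per_patient * n_core_px
    for pi in range(cfg.n_patients):
        lab = labels_all[pi * per_patient : (pi + 1) * per_patient]
        comp[pi] = np.bincount(lab, minlength=k + 1)[1:] / per_patient
    comp_df = pd.DataFrame(comp, index=patient_ids, columns=range(1, k + 1))

    tau = cfg.presence_threshold_true
    betas = {int(c): float(b) for c, b in cfg.log_hazard_effects.items()}
    log_hr = np.zeros(cfg.n_patients)
    for c, b in betas.items():
        log_hr += b * (comp[:, c - 1] >= tau)
    prognostic = np.zeros(cfg.n_patients, dtype=int)
    for c in cfg.prognostic_clusters:
        prognostic |= (comp[:, c - 1] >= tau).astype(int)

    age = np.clip(rng.normal(55.0, 12.0, size=cfg.n_patients), 18.0, 95.0)
    if cfg.log_hazard_age:
        log_hr = log_hr + cfg.log_hazard_age * (age - 55.0)
    rate = cfg.baseline_hazard_rate * np.exp(log_hr)
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.exponential(1.0 / cfg.censoring_rate, size=cfg.n_patients)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    diversity = 1.0 - (comp**2).sum(axis=1)
    eta = cfg.stage_diversity_link * (diversity - diversity.mean())
    u = rng.uniform(size=cfg.n_patients)
    cum = 1.0 / (1.0 + np.exp(-(_STAGE_CUTPOINTS[None, :] - eta[:, None])))
    stage = 1 + (u[:, None] > cum).sum(axis=1)
    sex = rng.choice(["F", "M"], size=cfg.n_patients)

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "patient_id": patient_ids,
                "time": time,
                "event": event,
                "stage": stage,
                "age": age,
                "sex": sex,
            }
        )
    )

    mz = np.sort(rng.uniform(50.0, 1000.0, size=cfg.n_features))
    catalog = FeatureCatalog(
        pd.DataFrame(
            {
                "feature_index": np.arange(1, cfg.n_features + 1),
                "mz": mz,
                "metabolite_name": [None] * cfg.n_features,
                "pathway_ids": [frozenset() for _ in range(cfg.n_features)],
                "drug_pathway_ids": [frozenset() for _ in range(cfg.n_features)],
            }
        )
    )

    truth = SyntheticTruth(
        centroids=centroids,
        patient_compositions=comp_df,
        dirichlet_draws=pd.DataFrame(dirichlet, index=patient_ids, columns=range(1, k + 1)),
        pixel_true_labels=pd.Series(labels_all, index=meta["pixel_id"], name="true_cluster"),
        prognostic_indicator=pd.Series(prognostic, index=patient_ids, name="prognostic"),
        true_log_hazards=betas,
        presence_threshold_true=tau,
        true_diversity=pd.Series(diversity, index=patient_ids, name="true_diversity"),
    )
    return pixels, clinical, catalog, truth


def write_cohort(config: SyntheticConfig, outdir) -> dict:
    """Generate and write a cohort plus truth sidecar and config YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pixels, clinical, catalog, truth = generate_cohort(config)
    paths = {
        "pixels": write_pixel_table(pixels, outdir / "pixels.tsv"),
        "clinical": write_clinical_table(clinical, outdir / "clinical.tsv"),
        "features": write_feature_catalog(catalog, outdir / "features.tsv"),
    }
    truth_df = truth.patient_compositions.copy()
    truth_df.columns = [f"comp_{c}" for c in truth_df.columns]
    truth_df["prognostic"] = truth.prognostic_indicator
    truth_df["true_diversity"] = truth.true_diversity
    truth_df.to_csv(outdir / "truth_patients.tsv", sep="\t", float_format="%.17g")
    truth.pixel_true_labels.to_csv(outdir / "truth_pixels.tsv", sep="\t")
    cfg = asdict(config)
    cfg["prognostic_clusters"] = sorted(cfg["prognostic_clusters"])
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    paths["truth_patients"] = outdir / "truth_patients.tsv"
    paths["truth_pixels"] = outdir / "truth_pixels.tsv"
    paths["config"] = outdir / "config.yaml"
    return paths
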