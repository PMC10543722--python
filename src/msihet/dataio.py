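"""Interchange tables and spectrum normalization.

Three plain-text tables move between pipeline stages:

``pixels.tsv``
    One row per ROI pixel: ``pixel_id, patient_id, core_id, cohort, x, y,
    f0001..fNNNN``.  The ``f``-columns are non-negative intensities of the
    resolved m/z feature channels; all rows share one feature count.
``clinical.tsv``
    One row per patient: ``patient_id, time, event, stage, age, sex``.
    ``time`` is follow-up in months, ``event`` 1 for death, ``stage`` the
    ordinal tumor stage 1-4.
``features.tsv``
    One row per feature channel: ``feature_index, mz, metabolite_name,
    pathway_ids, drug_pathway_ids`` with the id sets semicolon-separated.

Everything is UTF-8, tab-delimited by default and round-trips through
:func:`write_pixel_table` / :func:`read_pixel_table` at full double
precision.  Vendor formats (imzML, SCiLS) are deliberately out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "IntegrityError",
    "PixelTable",
    "ClinicalTable",
    "FeatureCatalog",
    "feature_columns",
    "read_pixel_table",
    "write_pixel_table",
    "read_clinical_table",
    "write_clinical_table",
    "read_feature_catalog",
    "write_feature_catalog",
    "rms_normalize",
]

PIXEL_KEY = ["patient_id", "core_id", "x", "y"]
PIXEL_META = ["pixel_id", "patient_id", "core_id", "cohort", "x", "y"]
_FEATURE_RE = re.compile(r"^f(\d{4,})$")


class FormatError(ValueError):
    """A file or frame does not match the documented schema."""


class IntegrityError(ValueError):
    """Schema-conformant data violating a table invariant (duplicates, NaN, ...)."""


def feature_columns(n_features: int) -> list[str]:
    """Column names ``f0001..f{n}`` used for intensity channels."""
    width = max(4, len(str(n_features)))
    return [f"f{i:0{width}d}" for i in range(1, n_features + 1)]


@dataclass
class PixelTable:
    """ROI pixels with spatial coordinates and an intensity vector each.

    Wraps a :class:`pandas.DataFrame` whose columns are the metadata columns
    followed by the intensity channels.  Validated on construction:
    ``(patient_id, core_id, x, y)`` must be unique and intensities finite and
    non-negative.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PIXEL_META if c not in self.frame.columns]
        if missing:
            raise FormatError(f"pixel table missing columns: {missing}")
        fcols = self.feature_cols
        if not fcols:
            raise FormatError("pixel table has no intensity columns (f0001...)")
        dup = self.frame.duplicated(subset=PIXEL_KEY)
        if dup.any():
            first = self.frame.loc[dup, PIXEL_KEY].iloc[0].tolist()
            raise IntegrityError(
                f"duplicate pixel coordinates (patient_id, core_id, x, y) = {tuple(first)}"
            )
        if self.frame["pixel_id"].duplicated().any():
            raise IntegrityError("duplicate pixel_id values")
        vals = self.frame[fcols].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise IntegrityError("missing intensity values are not allowed")
        if not np.isfinite(vals).all():
            raise IntegrityError("non-finite intensity values")
        if (vals < 0).any():
            raise IntegrityError("negative intensity values")

    @property
    def feature_cols(self) -> list[str]:
        return [c for c in self.frame.columns if _FEATURE_RE.match(c)]

    @property
    def n_features(self) -> int:
        return len(self.feature_cols)

    @property
    def n_pixels(self) -> int:
        return len(self.frame)

    @property
    def pixel_ids(self) -> pd.Series:
        return self.frame["pixel_id"]

    def intensities(self) -> np.ndarray:
        """Pixel × feature intensity matrix (float64 copy)."""
        return self.frame[self.feature_cols].to_numpy(dtype=float)

    def patients(self) -> list:
        return list(pd.unique(self.frame["patient_id"]))

    def subset(self, mask) -> "PixelTable":
        return PixelTable(self.frame.loc[mask].reset_index(drop=True))


@dataclass
class ClinicalTable:
    """Per-patient survival and covariate table."""

    frame: pd.DataFrame

    REQUIRED = ("patient_id", "time", "event", "stage", "age", "sex")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise FormatError(f"clinical table missing columns: {missing}")
        if self.frame["patient_id"].duplicated().any():
            raise IntegrityError("clinical table must have one row per patient")
        if (self.frame["time"].to_numpy(dtype=float) <= 0).any():
            raise IntegrityError("survival times must be positive")
        if not set(self.frame["event"].unique()) <= {0, 1}:
            raise IntegrityError("event must be binary 0/1")
        if not set(self.frame["stage"].unique()) <= {1, 2, 3, 4}:
            raise IntegrityError("stage must be ordinal 1-4")

    def indexed(self) -> pd.DataFrame:
        return self.frame.set_index("patient_id")


@dataclass
class FeatureCatalog:
    """m/z values and optional annotation for each feature channel.

    ``pathway_ids`` and ``drug_pathway_ids`` hold frozensets of labels; empty
    sets mean "no annotation", which excludes the feature from the
    enrichment universe.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        for c in ("feature_index", "mz"):
            if c not in self.frame.columns:
                raise FormatError(f"feature catalog missing column {c}")
        idx = self.frame["feature_index"].to_numpy()
        if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            raise IntegrityError("feature_index must be contiguous starting at 1")
        mz = self.frame["mz"].to_numpy(dtype=float)
        if not (np.diff(mz) > 0).all():
            raise IntegrityError("mz must be strictly increasing with feature_index")
        for c in ("metabolite_name", "pathway_ids", "drug_pathway_ids"):
            if c not in self.frame.columns:
                self.frame[c] = [None] * len(self.frame) if c == "metabolite_name" else [
                    frozenset() for _ in range(len(self.frame))
                ]

    def pathway_sets(self, kind: str = "pathway_ids") -> dict[int, frozenset]:
        """Map feature_index -> set of pathway labels (possibly empty)."""
        out = {}
        for fi, ids in zip(self.frame["feature_index"], self.frame[kind]):
            out[int(fi)] = frozenset(ids) if ids else frozenset()
        return out


# ---------------------------------------------------------------------------
# readers / writers


def _sep(dialect: str) -> str:
    if dialect in ("tsv", "\t", "tab"):
        return "\t"
    if dialect in ("csv", ","):
        return ","
    raise ValueError(f"unknown dialect {dialect!r}")


def read_pixel_table(path, dialect: str = "tsv") -> PixelTable:
    df = pd.read_csv(path, sep=_sep(dialect))
    df.columns = [c.lower() for c in df.columns]
    fcols = [c for c in df.columns if _FEATURE_RE.match(c)]
    if df[fcols].isna().any().any():
        raise FormatError(f"{path}: ragged or missing intensity values")
    df[fcols] = df[fcols].astype(float)
    return PixelTable(df)


def write_pixel_table(table: PixelTable, path, dialect: str = "tsv"):
    cols = PIXEL_META + table.feature_cols
    table.frame[cols].to_csv(path, sep=_sep(dialect), index=False, float_format="%.17g")
    return path


def read_clinical_table(path, dialect: str = "tsv") -> ClinicalTable:
    df = pd.read_csv(path, sep=_sep(dialect))
    df.columns = [c.lower() for c in df.columns]
    return ClinicalTable(df)


def write_clinical_table(table: ClinicalTable, path, dialect: str = "tsv"):
    table.frame.to_csv(path, sep=_sep(dialect), index=False, float_format="%.17g")
    return path


def _join_ids(ids) -> str:
    return ";".join(sorted(ids)) if ids else ""


def _split_ids(text) -> frozenset:
    if text is None or (isinstance(text, float) and np.isnan(text)) or text == "":
        return frozenset()
    return frozenset(str(text).split(";"))


def read_feature_catalog(path, dialect: str = "tsv") -> FeatureCatalog:
    df = pd.read_csv(path, sep=_sep(dialect))
    df.columns = [c.lower() for c in df.columns]
    for c in ("pathway_ids", "drug_pathway_ids"):
        if c in df.columns:
            df[c] = df[c].map(_split_ids)
    return FeatureCatalog(df)


def write_feature_catalog(catalog: FeatureCatalog, path, dialect: str = "tsv"):
    df = catalog.frame.copy()
    for c in ("pathway_ids", "drug_pathway_ids"):
        df[c] = df[c].map(_join_ids)
    df.to_csv(path, sep=_sep(dialect), index=False, float_format="%.17g")
    return path


# ---------------------------------------------------------------------------
# normalization


def rms_normalize(table: PixelTable) -> PixelTable:
    """Scale every pixel spectrum to unit root-mean-square intensity.

    Each pixel's intensity vector ``s`` is divided by
    ``sqrt(mean(s_f^2))`` computed over all F feature channels (zero
    channels included).  After normalization the RMS of every pixel is 1, so
    pixels are compared by spectral shape rather than total signal; the
    operation is idempotent.

    Raises
    ------
    IntegrityError
        If any pixel has an all-zero spectrum (its RMS is 0 and the pixel
        carries no spectral shape to compare).
    """
    vals = table.intensities()
    rms = np.sqrt(np.mean(vals**2, axis=1))
    bad = rms == 0
    if bad.any():
        ids = table.frame.loc[bad, "pixel_id"].tolist()
        raise IntegrityError(f"all-zero spectra for pixel_ids {ids[:20]}")
    out = table.frame.copy()
    out[table.feature_cols] = vals / rms[:, None]
    return PixelTable(out)
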