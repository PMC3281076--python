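"""Core in-memory containers shared by all pipeline stages.

All tabular data travels as thin, validated wrappers around
:class:`pandas.DataFrame`:

* :class:`SampleTable` — sample metadata (case/control group, blood
  fraction, technical-replicate structure).
* :class:`ProbeMatrix` — probe-level linear-scale intensities with probe
  annotation (feature assignment, GC count, anti-genomic flag).
* :class:`ExprMatrix` — the log2 feature-by-sample matrix that is the
  common currency of every analysis stage.
* :class:`GenomicLocus` — 0-based half-open genomic interval of a feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GROUPS = ("case", "control")
FRACTIONS = ("platelet", "microvesicle", "pbmc")

#: conventional short prefixes used when fractions are concatenated
FRACTION_PREFIX = {"platelet": "pl", "microvesicle": "mv", "pbmc": "pb"}


class ValidationError(ValueError):
    """Raised when a container violates one of its structural invariants."""


@dataclass
class SampleTable:
    """Sample metadata: one row per hybridized sample.

    Columns: ``sample_id``, ``group`` (case/control), ``fraction``
    (platelet/microvesicle/pbmc) and optional ``replicate_of`` naming the
    parent sample of a technical replicate (empty/NaN for primary samples).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        required = {"sample_id", "group", "fraction"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"sample table missing columns: {sorted(missing)}")
        if "replicate_of" not in df.columns:
            df["replicate_of"] = ""
        df["replicate_of"] = df["replicate_of"].fillna("").astype(str)
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        bad_group = set(df["group"]) - set(GROUPS)
        if bad_group:
            raise ValidationError(f"unknown group labels: {sorted(bad_group)}")
        bad_frac = set(df["fraction"]) - set(FRACTIONS)
        if bad_frac:
            raise ValidationError(f"unknown fraction labels: {sorted(bad_frac)}")
        known = set(df["sample_id"])
        orphans = [r for r in df["replicate_of"] if r and r not in known]
        if orphans:
            raise ValidationError(f"replicate_of refers to unknown samples: {orphans}")
        self.table = df.reset_index(drop=True)

    # -- accessors -----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def primary(self) -> "SampleTable":
        """Metadata restricted to primary (non-replicate) samples."""
        return SampleTable(self.table[self.table["replicate_of"] == ""].copy())

    def subset(self, sample_ids: Sequence[str]) -> "SampleTable":
        keep = self.table[self.table["sample_id"].isin(set(sample_ids))]
        return SampleTable(keep.copy())

    def for_fraction(self, fraction: str) -> "SampleTable":
        if fraction not in FRACTIONS:
            raise ValidationError(f"unknown fraction: {fraction!r}")
        return SampleTable(self.table[self.table["fraction"] == fraction].copy())

    def groups_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Boolean case mask aligned to ``sample_ids``."""
        lookup = dict(zip(self.table["sample_id"], self.table["group"]))
        try:
            return np.array([lookup[s] == "case" for s in sample_ids], dtype=bool)
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValidationError(f"sample not in metadata: {exc}") from exc

    def replicate_groups(self) -> dict[str, list[str]]:
        """Map parent sample id -> [parent and its technical replicates]."""
        groups: dict[str, list[str]] = {}
        for _, row in self.table.iterrows():
            parent = row["replicate_of"] or row["sample_id"]
            groups.setdefault(parent, []).append(row["sample_id"])
        return groups

    def require_two_per_class(self) -> None:
        counts = self.primary().table["group"].value_counts()
        if counts.get("case", 0) < 2 or counts.get("control", 0) < 2:
            raise ValidationError(
                "analysis requires at least 2 cases and 2 controls; got "
                f"{counts.to_dict()}"
            )


@dataclass
class ExprMatrix:
    """Log2 feature-by-sample expression matrix (no missing values)."""

    data: pd.DataFrame  # index: feature_id, columns: sample_id, float values
    scale: str = "log2"

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].tolist()
            raise ValidationError(f"duplicate feature ids: {dups}")
        if df.isna().to_numpy().any():
            raise ValidationError("expression matrix contains missing values")
        if self.scale != "log2":
            raise ValidationError(f"unsupported scale: {self.scale!r}")
        self.data = df.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return [str(f) for f in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExprMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing}")
        return ExprMatrix(self.data.loc[:, list(sample_ids)].copy())

    def subset_features(self, feature_ids: Sequence[str]) -> "ExprMatrix":
        missing = [f for f in feature_ids if f not in self.data.index]
        if missing:
            raise ValidationError(f"features not in matrix: {missing}")
        return ExprMatrix(self.data.loc[list(feature_ids)].copy())


ANNOT_COLUMNS = ["feature_id", "gc_count", "is_antigenomic"]


@dataclass
class ProbeMatrix:
    """Probe-level linear-scale intensities plus probe annotation.

    ``probes`` is indexed by ``probe_id`` and carries the annotation columns
    ``feature_id`` (empty for anti-genomic background probes), ``gc_count``
    and ``is_antigenomic``, followed by one float column per sample.
    """

    probes: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.probes
        missing = [c for c in ANNOT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"probe matrix missing columns: {missing}")
        if df.index.has_duplicates:
            raise ValidationError("duplicate probe ids")
        df = df.copy()
        df["feature_id"] = df["feature_id"].fillna("").astype(str)
        df["gc_count"] = df["gc_count"].astype(int)
        df["is_antigenomic"] = df["is_antigenomic"].astype(bool)
        if (df["gc_count"] < 0).any():
            raise ValidationError("gc_count must be nonnegative")
        inten = df[self.sample_columns(df)].astype(float)
        if (inten.to_numpy() < 0).any():
            raise ValidationError("probe intensities must be nonnegative")
        df[inten.columns] = inten
        self.probes = df

    @staticmethod
    def sample_columns(df: pd.DataFrame) -> list[str]:
        return [c for c in df.columns if c not in ANNOT_COLUMNS]

    @property
    def sample_ids(self) -> list[str]:
        return self.sample_columns(self.probes)

    @property
    def intensities(self) -> pd.DataFrame:
        return self.probes[self.sample_ids]

    @property
    def annotation(self) -> pd.DataFrame:
        return self.probes[ANNOT_COLUMNS]

    def genomic(self) -> pd.DataFrame:
        return self.probes[~self.probes["is_antigenomic"]]

    def antigenomic(self) -> pd.DataFrame:
        return self.probes[self.probes["is_antigenomic"]]


@dataclass(frozen=True)
class GenomicLocus:
    """0-based half-open genomic interval of a feature (BED convention)."""

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval for {self.feature_id}: [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "unknown"):
            raise ValidationError(f"invalid strand: {self.strand!r}")


def as_case_mask(meta: SampleTable, sample_ids: Sequence[str]) -> np.ndarray:
    """Boolean vector marking case samples, aligned to ``sample_ids``."""
    return meta.groups_for(sample_ids)
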