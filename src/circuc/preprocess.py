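"""Probe-level preprocessing: GC background correction, log transform,
quantile normalization, and median summarization.

The chain runs in a fixed order: per-sample GC-matched background
subtraction on the linear scale (using anti-genomic control probes),
clamping at a floor, a +offset/log2 transform (default offset 16), quantile
normalization of the log2 probe values within each blood fraction, median
summarization of each feature's probe set, and finally technical-replicate
averaging (handled in :mod:`circuc.io`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from circuc.datatypes import (
    ExprMatrix,
    ProbeMatrix,
    SampleTable,
    ValidationError,
)
from circuc.io import average_replicates

logger = logging.getLogger("circuc")


@dataclass
class PreprocessParams:
    """Tunables of the preprocessing chain.

    offset : additive constant applied before log2 (must be > 0).
    gc_stat : background statistic over anti-genomic probes per GC class,
        ``median`` (default) or ``mean``.
    clamp_floor : lower clamp applied after background subtraction.
    """

    offset: float = 16.0
    gc_stat: str = "median"
    clamp_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.offset <= 0:
            raise ValidationError("offset must be > 0")
        if self.gc_stat not in ("median", "mean"):
            raise ValidationError(f"gc_stat must be median or mean, got {self.gc_stat!r}")
        if self.clamp_floor < 0:
            raise ValidationError("clamp_floor must be >= 0")


def gc_background_correct(p: ProbeMatrix, params: PreprocessParams | None = None) -> ProbeMatrix:
    """Subtract GC-class background estimated from anti-genomic probes.

    Per sample and per GC class the background is the ``gc_stat`` of the
    anti-genomic probe intensities in that class; it is subtracted from
    every genomic probe of the class and the result clamped at
    ``clamp_floor``.  Anti-genomic probes are dropped from the output.
    """
    params = params or PreprocessParams()
    genomic = p.genomic()
    anti = p.antigenomic()
    sample_cols = p.sample_ids
    needed = sorted(set(genomic["gc_count"]))
    have = set(anti["gc_count"])
    missing = [gc for gc in needed if gc not in have]
    if missing:
        raise ValidationError(
            f"no anti-genomic probes for gc_count classes: {missing}"
        )
    agg = "median" if params.gc_stat == "median" else "mean"
    bg = anti.groupby("gc_count")[sample_cols].agg(agg)
    corrected = genomic.copy()
    bg_rows = bg.loc[genomic["gc_count"].to_numpy()].to_numpy()
    vals = genomic[sample_cols].to_numpy() - bg_rows
    corrected[sample_cols] = np.clip(vals, params.clamp_floor, None)
    return ProbeMatrix(corrected)


def log_transform(p: ProbeMatrix, params: PreprocessParams | None = None) -> ProbeMatrix:
    """value -> log2(value + offset); input must be nonnegative."""
    params = params or PreprocessParams()
    out = p.probes.copy()
    cols = p.sample_ids
    vals = out[cols].to_numpy()
    if (vals < 0).any():
        raise ValidationError("negative intensities: clamp before log transform")
    out[cols] = np.log2(vals + params.offset)
    return _probe_like(out)


def _probe_like(df: pd.DataFrame) -> ProbeMatrix:
    # bypass the nonnegativity check (log2 values may be any real)
    pm = object.__new__(ProbeMatrix)
    pm.probes = df
    return pm


def quantile_normalize(values: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Classical quantile normalization of a (rows x columns) matrix.

    Every column is mapped onto the shared reference distribution obtained
    by averaging the sorted columns rank by rank.  Tied values within a
    column receive the mean of the reference values at their tied ranks
    (implemented via mid-ranks and linear interpolation), which makes the
    result deterministic and invariant to row order.  A single-column
    matrix is returned unchanged.
    """
    df = isinstance(values, pd.DataFrame)
    X = values.to_numpy() if df else np.asarray(values, dtype=float)
    if X.ndim != 2:
        raise ValidationError("quantile_normalize expects a 2-D matrix")
    n, k = X.shape
    if k == 1:
        return values
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X, dtype=float)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(k):
        ranks = rankdata(X[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, reference)
    if df:
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def median_summarize(p: ProbeMatrix) -> ExprMatrix:
    """Per feature and sample, the median over the feature's probes."""
    genomic = p.genomic()
    if (genomic["feature_id"] == "").any():
        raise ValidationError("genomic probe without feature assignment")
    if genomic.empty:
        raise ValidationError("no genomic probes to summarize")
    med = genomic.groupby("feature_id", sort=True)[p.sample_ids].median()
    med.index.name = "feature_id"
    return ExprMatrix(med)


def preprocess_probes(p: ProbeMatrix, meta: SampleTable,
                      params: PreprocessParams | None = None) -> ExprMatrix:
    """Full chain: GC correction -> clamp -> +offset/log2 -> per-fraction
    quantile normalization -> median summarization -> replicate averaging."""
    params = params or PreprocessParams()
    corrected = gc_background_correct(p, params)
    logged = log_transform(corrected, params)
    df = logged.probes.copy()
    fractions = meta.table.groupby("fraction")["sample_id"].apply(list)
    for fraction, samples in fractions.items():
        cols = [s for s in samples if s in df.columns]
        missing = [s for s in samples if s not in df.columns]
        if missing:
            raise ValidationError(f"samples missing from probe matrix: {missing}")
        if cols:
            df[cols] = quantile_normalize(df[cols].to_numpy())
    summarized = median_summarize(_probe_like(df[["feature_id", "gc_count",
                                                  "is_antigenomic"] + meta.sample_ids]))
    return average_replicates(summarized, meta)
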