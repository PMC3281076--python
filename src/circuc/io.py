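"""Readers and writers for the package's tabular formats.

One tabular dialect is used throughout: tab-separated UTF-8 text with a
header row; lines starting with ``#`` are comments.  Expression matrices
have ``feature_id`` as the first column and one column per sample.  Genomic
loci are read from BED (0-based half-open).  miRNA target maps are
two-column TSV (mirna_id, gene_id).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from circuc.datatypes import (
    ANNOT_COLUMNS,
    ExprMatrix,
    GenomicLocus,
    ProbeMatrix,
    SampleTable,
    ValidationError,
)

logger = logging.getLogger("circuc")

_TSV_KW = dict(sep="\t", comment="#", dtype=str)


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, **_TSV_KW)
    return SampleTable(df)


def write_sample_table(meta: SampleTable, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


def read_expr_matrix(path: str | Path, meta: SampleTable | None = None) -> ExprMatrix:
    """Read a log2 feature-by-sample TSV matrix.

    When ``meta`` is given the columns are restricted to, and ordered by,
    the metadata sample order; dropped columns are logged.  A metadata
    sample absent from the file, or a non-numeric cell, is a hard error
    naming the offender.
    """
    raw = pd.read_csv(path, **_TSV_KW)
    first = raw.columns[0]
    raw = raw.set_index(first)
    raw.index.name = "feature_id"
    numeric = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna() | raw[col].isna()
        if bad.any():
            row = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise ValidationError(
                f"non-numeric value at feature {row!r}, sample {col!r} in {path}"
            )
        numeric[col] = converted
    if meta is not None:
        wanted = meta.sample_ids
        missing = [s for s in wanted if s not in numeric.columns]
        if missing:
            raise ValidationError(f"metadata samples missing from {path}: {missing}")
        dropped = [c for c in numeric.columns if c not in set(wanted)]
        if dropped:
            logger.info("dropping %d columns not in metadata: %s", len(dropped), dropped)
        numeric = numeric[wanted]
    return ExprMatrix(numeric)


def write_expr_matrix(m: ExprMatrix, path: str | Path) -> None:
    # 12 significant digits keeps the round trip lossless for doubles we emit
    m.data.to_csv(path, sep="\t", index=True, index_label="feature_id",
                  float_format="%.12g")


def read_probe_matrix(path: str | Path, meta: SampleTable | None = None) -> ProbeMatrix:
    raw = pd.read_csv(path, sep="\t", comment="#")
    if "probe_id" not in raw.columns:
        raise ValidationError(f"probe matrix {path} lacks a probe_id column")
    raw = raw.set_index("probe_id")
    pm = ProbeMatrix(raw)
    if meta is not None:
        wanted = meta.sample_ids
        missing = [s for s in wanted if s not in pm.sample_ids]
        if missing:
            raise ValidationError(f"metadata samples missing from {path}: {missing}")
        pm = ProbeMatrix(pm.probes[ANNOT_COLUMNS + wanted])
    return pm


def write_probe_matrix(p: ProbeMatrix, path: str | Path) -> None:
    p.probes.to_csv(path, sep="\t", index=True, index_label="probe_id",
                    float_format="%.12g")


def read_bed(path: str | Path) -> list[GenomicLocus]:
    """Read feature loci from BED: chrom, start, end, name[, score, strand]."""
    loci: list[GenomicLocus] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValidationError(f"BED line needs >=4 fields: {line!r}")
        chrom, start, end, name = parts[:4]
        strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "unknown"
        loci.append(GenomicLocus(name, chrom, int(start), int(end), strand))
    return loci


def read_target_map(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (mirna_id, gene_id) -> mapping to non-empty gene sets.

    miRNAs that end up with no targets are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["mirna_id", "gene_id"], dtype=str)
    df = df.dropna()
    targets: dict[str, set[str]] = {}
    for mirna, genes in df.groupby("mirna_id")["gene_id"]:
        gene_set = set(genes)
        if gene_set:
            targets[str(mirna)] = gene_set
        else:  # pragma: no cover - groupby never yields empty groups
            logger.warning("miRNA %s has no targets; dropped", mirna)
    return targets


def write_target_map(targets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for mirna in sorted(targets):
            for gene in sorted(targets[mirna]):
                fh.write(f"{mirna}\t{gene}\n")


def average_replicates(m: ExprMatrix, meta: SampleTable) -> ExprMatrix:
    """Collapse technical replicates to their parent sample.

    Each replicate group (a parent sample plus the samples whose
    ``replicate_of`` names it) is replaced by one column holding the
    arithmetic mean of the members' log2 values; singleton groups pass
    through unchanged.
    """
    groups = meta.replicate_groups()
    cols = {}
    for parent, members in groups.items():
        present = [s for s in members if s in m.data.columns]
        if not present:
            raise ValidationError(f"replicate group {parent!r} absent from matrix")
        cols[parent] = m.data[present].mean(axis=1)
    out = pd.DataFrame(cols, index=m.data.index)
    # preserve metadata parent order
    order = [s for s in meta.primary().sample_ids if s in out.columns]
    return ExprMatrix(out[order])
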