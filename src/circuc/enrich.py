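"""Exact 2x2 tests, term enrichment, and miRNA-target anti-correlation.

Because miRNAs repress their targets, up-regulated biomarker miRNAs should
be accompanied by down-regulated target mRNAs in the affected tissue.
:func:`target_downregulation_test` formalizes this: differentially
expressed mRNAs are found by SAM, filtered by fold change, and the
fraction of down-regulated genes among predicted targets is compared with
the fraction among non-targets by a one-sided Fisher exact test and a
binomial tail test.  :func:`term_enrichment` is a generic hypergeometric
over-representation test for ontology/pathway categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom, hypergeom
from statsmodels.stats.multitest import multipletests

from circuc.datatypes import ExprMatrix, ValidationError
from circuc.sam import SamParams, sam_calibrate

logger = logging.getLogger("circuc")


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Returns P(X >= a) where X is the top-left cell under fixed margins
    (alternative: greater).
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValidationError("counts must be nonnegative")
    total = a + b + c + d
    # hypergeometric: draw (a+b) from a population of `total` with (a+c) marked
    return float(hypergeom.sf(a - 1, total, a + c, a + b))


def binomial_tail(k: int, n: int, p0: float) -> float:
    """Upper binomial tail P(X >= k) for X ~ Binomial(n, p0)."""
    if not (0 <= k <= n):
        raise ValidationError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 <= p0 <= 1.0):
        raise ValidationError(f"p0 must be in [0, 1], got {p0}")
    if k == 0:
        return 1.0
    return float(binom.sf(k - 1, n, p0))


@dataclass
class DownregulationResult:
    table: pd.DataFrame       # 2x2 counts (target vs non-target x down vs not)
    p_binomial: float
    p_fisher: float
    n_down_targets: int
    n_targets: int
    n_down_nontargets: int
    n_nontargets: int


def target_downregulation_test(mrna_expr: ExprMatrix, case_mask: np.ndarray,
                               targets: dict[str, set[str]],
                               panel: set[str] | list[str],
                               fdr: float = 0.001, fc_min: float = 2.0,
                               sam_params: SamParams | None = None) -> DownregulationResult:
    """Test whether targets of the biomarker panel are enriched for
    down-regulated mRNAs.

    SAM runs on the mRNA matrix at the given FDR; down-regulated genes are
    calls with fold change <= 1/fc_min (patient over control).  The 2x2
    contrast is (target of any panel miRNA vs not) x (down-regulated vs
    not); the binomial tail uses the non-target down-regulation rate as
    the null success probability.
    """
    panel = set(panel)
    extras = panel - set(targets)
    if extras:
        logger.warning("panel members without target sets are ignored: %s",
                       sorted(extras))
    target_genes = set().union(*(targets[m] for m in panel & set(targets))) \
        if panel & set(targets) else set()
    universe = set(mrna_expr.feature_ids)
    target_genes &= universe
    nontargets = universe - target_genes
    if not nontargets:
        raise ValidationError("no non-target genes: background undefined")

    params = sam_params or SamParams(fdr_target=fdr, n_permutations=500)
    if params.fdr_target != fdr:
        params = SamParams(fdr_target=fdr, n_permutations=params.n_permutations,
                           s0_mode=params.s0_mode, s0_value=params.s0_value,
                           seed=params.seed)
    res = sam_calibrate(mrna_expr, case_mask, params)
    called = res.table["called"]
    down = called & (res.table["fold_change"] <= 1.0 / fc_min)
    down_genes = set(res.table.index[down])

    a = len(down_genes & target_genes)
    b = len(target_genes - down_genes)
    c = len(down_genes & nontargets)
    d = len(nontargets - down_genes)
    p_fisher = fisher_one_sided(a, b, c, d)
    p0 = c / len(nontargets)
    p_binom = binomial_tail(a, len(target_genes), p0) if target_genes else 1.0

    table = pd.DataFrame([[a, b], [c, d]],
                         index=["target", "non_target"],
                         columns=["down", "not_down"])
    return DownregulationResult(table=table, p_binomial=p_binom, p_fisher=p_fisher,
                                n_down_targets=a, n_targets=len(target_genes),
                                n_down_nontargets=c, n_nontargets=len(nontargets))


def term_enrichment(gene_set: set[str], categories: dict[str, set[str]],
                    universe: set[str]) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_set`` in each category.

    Categories are trimmed to the universe; per term the overlap count,
    percent overlap (overlap / category size) and one-sided hypergeometric
    p-value for drawing ``|gene_set|`` genes from the universe are
    reported, sorted ascending by p with a Benjamini-Hochberg column.
    """
    if not universe:
        raise ValidationError("empty universe")
    stray = set(gene_set) - set(universe)
    if stray:
        raise ValidationError(f"gene_set members outside universe: {sorted(stray)[:5]}")
    N = len(universe)
    n_draw = len(gene_set)
    rows = []
    for term, genes in categories.items():
        cat = set(genes) & universe
        if not cat:
            continue
        overlap = len(cat & gene_set)
        p = float(hypergeom.sf(overlap - 1, N, len(cat), n_draw))
        rows.append({
            "category_id": term,
            "category_size": len(cat),
            "overlap": overlap,
            "percent_overlap": overlap / len(cat),
            "p_value": p,
        })
    df = pd.DataFrame(rows, columns=["category_id", "category_size", "overlap",
                                     "percent_overlap", "p_value"])
    if len(df):
        df = df.sort_values(["p_value", "category_id"], kind="stable").reset_index(drop=True)
        df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    else:
        df["p_adjusted"] = pd.Series(dtype=float)
    return df


def read_gmt(path) -> dict[str, set[str]]:
    """GMT-style TSV: term, description, gene, gene, ..."""
    categories: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"GMT line needs term, description, genes: {line!r}")
            categories[parts[0]] = set(g for g in parts[2:] if g)
    return categories
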