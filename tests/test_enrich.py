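from fractions import Fraction
from itertools import product
from math import comb

import numpy as np
import pandas as pd
import pytest

from circuc.datatypes import ExprMatrix, ValidationError
from circuc.enrich import (
    binomial_tail,
    fisher_one_sided,
    target_downregulation_test,
    term_enrichment,
)
from circuc.sam import SamParams


def _fisher_oracle(a, b, c, d):
    """Exact enumeration of all 2x2 tables with fixed margins."""
    r1, c1, n = a + b, a + c, a + b + c + d
    def prob(x):
        return Fraction(comb(c1, x) * comb(n - c1, r1 - x), comb(n, r1))
    return float(sum(prob(x) for x in range(a, min(r1, c1) + 1)))


def _binom_oracle(k, n, p0):
    """Arbitrary-precision rational binomial upper tail."""
    p = Fraction(p0).limit_denominator(10**9)
    return float(sum(comb(n, x) * p**x * (1 - p)**(n - x) for x in range(k, n + 1)))


class TestFisher:
    def test_printed_demographics_contrast(self):
        # 8/20 cases vs 0/20 controls with a GI history
        assert fisher_one_sided(8, 12, 0, 20) == pytest.approx(0.0016, abs=5e-5)

    def test_least_extreme_table_is_one(self):
        assert fisher_one_sided(0, 20, 0, 20) == 1.0

    def test_small_table_by_enumeration(self):
        assert fisher_one_sided(2, 1, 1, 2) == pytest.approx(0.5, abs=1e-12)

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 15, size=4)
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            assert fisher_one_sided(a, b, c, d) == pytest.approx(
                _fisher_oracle(a, b, c, d), abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            fisher_one_sided(-1, 2, 3, 4)


class TestBinomialTail:
    def test_closed_forms(self):
        assert binomial_tail(0, 10, 0.3) == 1.0
        assert binomial_tail(5, 5, 0.5) == pytest.approx(0.03125, abs=1e-12)
        assert binomial_tail(5, 10, 0.2) == pytest.approx(
            _binom_oracle(5, 10, 0.2), abs=1e-12)

    def test_matches_rational_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = int(rng.integers(1, 50))
            k = int(rng.integers(0, n + 1))
            p0 = float(rng.uniform(0.05, 0.95))
            assert binomial_tail(k, n, p0) == pytest.approx(
                _binom_oracle(k, n, p0), abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            binomial_tail(5, 3, 0.5)
        with pytest.raises(ValidationError):
            binomial_tail(1, 3, 1.5)


class TestTermEnrichment:
    def test_exact_category_ranks_first(self):
        universe = {f"g{i}" for i in range(100)}
        gene_set = {f"g{i}" for i in range(10)}
        cats = {"hit": set(gene_set), "other": {f"g{i}" for i in range(50, 80)}}
        out = term_enrichment(gene_set, cats, universe)
        assert out.iloc[0]["category_id"] == "hit"
        assert out.iloc[0]["percent_overlap"] == 1.0

    def test_disjoint_category_probability_from_oracle(self):
        from scipy.stats import hypergeom
        universe = {f"g{i}" for i in range(40)}
        gene_set = {f"g{i}" for i in range(5)}
        cats = {"far": {f"g{i}" for i in range(30, 40)}}
        out = term_enrichment(gene_set, cats, universe)
        assert out.iloc[0]["overlap"] == 0
        assert out.iloc[0]["p_value"] == pytest.approx(
            float(hypergeom.sf(-1, 40, 10, 5)), abs=1e-12)
        assert out.iloc[0]["p_value"] == 1.0

    def test_invariant_to_gene_renaming(self):
        rng = np.random.default_rng(2)
        universe = {f"g{i}" for i in range(60)}
        gene_set = set(rng.choice(sorted(universe), 12, replace=False))
        cats = {f"t{j}": set(rng.choice(sorted(universe), 15, replace=False))
                for j in range(4)}
        rename = {g: f"x_{g}" for g in universe}
        out_a = term_enrichment(gene_set, cats, universe)
        out_b = term_enrichment({rename[g] for g in gene_set},
                                {t: {rename[g] for g in gs} for t, gs in cats.items()},
                                {rename[g] for g in universe})
        pd.testing.assert_frame_equal(out_a, out_b)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            term_enrichment(set(), {}, set())


def _mrna_dataset(seed, n_genes=300, n_down=50, fc_range=(1.2, 2.0)):
    """Synthetic mRNA case/control matrix with planted down-regulation."""
    from circuc.synth import SimulationDesign, sample_table, simulate_feature_matrix
    design = SimulationDesign(
        n_cases=10, n_controls=10, n_features=n_genes, n_de=n_down,
        de_direction="down", log2_fc_range=fc_range,
        noise_sd_range=(0.4, 0.4), corr_blocks=(), seed=seed)
    expr, truth = simulate_feature_matrix(design)
    mask = sample_table(design).groups_for(expr.sample_ids)
    genes = [f"gene{i}" for i in range(n_genes)]
    expr = ExprMatrix(pd.DataFrame(expr.values, index=genes,
                                   columns=expr.sample_ids))
    down = [g for g, d in zip(genes, truth["is_de"]) if d]
    return expr, mask, genes, down


class TestTargetDownregulation:
    def test_enriched_targets_detected(self):
        hits = 0
        runs = 10
        for s in range(runs):
            expr, mask, genes, down = _mrna_dataset(800 + s)
            rng = np.random.default_rng(s)
            # targets 3x enriched for planted down-regulated genes
            n_pick = 60
            weights = np.array([3.0 if g in set(down) else 1.0 for g in genes])
            chosen = rng.choice(genes, size=n_pick, replace=False,
                                p=weights / weights.sum())
            targets = {"mirA": set(chosen)}
            res = target_downregulation_test(
                expr, mask, targets, {"mirA"}, fdr=0.001, fc_min=2.0,
                sam_params=SamParams(fdr_target=0.001, n_permutations=300, seed=s))
            hits += (res.p_fisher < 0.05)
        assert hits >= 0.7 * runs

    def test_null_targets_rarely_significant(self):
        rejections = 0
        runs = 40
        for s in range(runs):
            expr, mask, genes, _ = _mrna_dataset(900 + s)
            rng = np.random.default_rng(10_000 + s)
            targets = {"mirA": set(rng.choice(genes, size=60, replace=False))}
            res = target_downregulation_test(
                expr, mask, targets, {"mirA"}, fdr=0.001, fc_min=2.0,
                sam_params=SamParams(fdr_target=0.001, n_permutations=200, seed=s))
            rejections += (res.p_fisher < 0.05)
        assert rejections <= 0.15 * runs

    def test_all_genes_targets_is_error(self):
        expr, mask, genes, _ = _mrna_dataset(950)
        with pytest.raises(ValidationError, match="non-target"):
            target_downregulation_test(expr, mask, {"mirA": set(genes)}, {"mirA"})

    def test_counts_partition_the_universe(self):
        expr, mask, genes, _ = _mrna_dataset(960)
        targets = {"mirA": set(genes[:80])}
        res = target_downregulation_test(
            expr, mask, targets, {"mirA"},
            sam_params=SamParams(fdr_target=0.001, n_permutations=200, seed=0))
        assert res.table.to_numpy().sum() == len(genes)
        assert res.n_targets == 80
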