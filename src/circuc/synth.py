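"""Synthetic case/control microarray data with known ground truth.

The generator emulates the statistical structure of a two-arm circulating
miRNA study: a 20-case / 20-control cohort profiled over ~847 features on a
log2 intensity scale, with a small panel of planted up-regulated features,
latent-factor correlation blocks (mimicking co-regulated miRNA clusters),
and independent Gaussian noise elsewhere.  A probe-level layer adds
per-probe affinity offsets, GC-dependent additive background, and
anti-genomic background probes so the preprocessing chain can be exercised
end to end.

Model
-----
For feature *i* and sample *j* the log2 value is

    x_ij = mu_i + delta_i * case_j + sigma_i * (sqrt(rho_b) * F_bj
                                                + sqrt(1 - rho_b) * e_ij)

with baseline ``mu_i ~ U(baseline_mean_range)``, planted log2 fold change
``delta_i`` (zero for null features), per-feature noise scale ``sigma_i ~
U(noise_sd_range)``, a shared standard-normal latent factor ``F_bj`` per
correlation block *b*, and iid standard-normal ``e_ij``.  The single-factor
construction gives pairwise within-block correlation exactly ``rho_b`` in
expectation.

Probe intensities (linear scale) are

    y_pj = 2 ** (x_ij + a_p) + bg(gc_p) + noise,

where ``a_p`` is a per-probe affinity offset and ``bg`` an additive
background that depends only on probe GC count; anti-genomic probes carry
background only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from circuc.datatypes import ExprMatrix, ProbeMatrix, SampleTable, ValidationError


@dataclass
class SimulationDesign:
    """Parameters of a synthetic two-class study.

    Defaults mirror the reference study conditions: 20 cases vs 20
    controls, 847 features, 31 planted up-regulated features with log2
    fold changes in [0.5, 1.0] (linear fold changes ~1.4-2.0), baselines
    spanning log2 4-14, noise sd 0.5, and four latent correlation blocks
    at pairwise r = 0.75 covering 28 of the planted features.
    """

    n_cases: int = 20
    n_controls: int = 20
    n_features: int = 847
    n_de: int = 31
    de_direction: str = "up"
    log2_fc_range: tuple[float, float] = (0.5, 1.0)
    baseline_mean_range: tuple[float, float] = (4.0, 14.0)
    noise_sd_range: tuple[float, float] = (0.5, 0.5)
    corr_blocks: tuple[tuple[int, float], ...] = ((8, 0.75), (8, 0.75), (6, 0.75), (6, 0.75))
    probes_per_feature: int = 4
    n_antigenomic_per_gc: int = 20
    probe_affinity_sd: float = 0.25
    probe_noise_sd: float = 5.0
    gc_range: tuple[int, int] = (6, 14)
    gc_background_base: float = 40.0
    gc_background_slope: float = 8.0
    fraction: str = "platelet"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de > self.n_features:
            raise ValidationError("n_de exceeds n_features")
        if self.de_direction not in ("up", "down", "mixed"):
            raise ValidationError(f"bad de_direction: {self.de_direction!r}")
        for lo, hi in (self.log2_fc_range, self.baseline_mean_range, self.noise_sd_range):
            if lo > hi:
                raise ValidationError(f"range not ordered: ({lo}, {hi})")
        if sum(b for b, _ in self.corr_blocks) > self.n_features:
            raise ValidationError("correlation blocks exceed feature count")
        for size, rho in self.corr_blocks:
            if not (0.0 <= rho < 1.0):
                raise ValidationError(f"latent_r out of [0,1): {rho}")
            if size < 1:
                raise ValidationError("block size must be >= 1")
        if self.probes_per_feature < 1:
            raise ValidationError("probes_per_feature must be >= 1")


def _sample_ids(design: SimulationDesign) -> tuple[list[str], list[str]]:
    cases = [f"p{i + 1:02d}" for i in range(design.n_cases)]
    controls = [f"c{i + 1:02d}" for i in range(design.n_controls)]
    return cases, controls


def sample_table(design: SimulationDesign) -> SampleTable:
    """Metadata matching the simulated matrix (cases first, then controls)."""
    cases, controls = _sample_ids(design)
    df = pd.DataFrame({
        "sample_id": cases + controls,
        "group": ["case"] * len(cases) + ["control"] * len(controls),
        "fraction": design.fraction,
        "replicate_of": "",
    })
    return SampleTable(df)


def simulate_feature_matrix(design: SimulationDesign) -> tuple[ExprMatrix, pd.DataFrame]:
    """Simulate a log2 feature-by-sample matrix and its ground-truth table.

    Returns the matrix and a truth table with one row per feature:
    ``feature_id``, ``is_de``, ``log2_fc`` (0 for null features),
    ``fold_change`` (2**log2_fc; exactly 1 for nulls) and ``block_id``
    (-1 for features outside every correlation block).
    """
    rng = np.random.default_rng(design.seed)
    m, n = design.n_features, design.n_cases + design.n_controls
    cases, controls = _sample_ids(design)
    samples = cases + controls
    case_mask = np.array([1.0] * design.n_cases + [0.0] * design.n_controls)

    features = [f"mir-{i + 1:04d}" for i in range(m)]
    baseline = rng.uniform(*design.baseline_mean_range, size=m)
    sigma = rng.uniform(*design.noise_sd_range, size=m)

    # planted effects on the first n_de features (identity recorded in truth)
    log2_fc = np.zeros(m)
    if design.n_de:
        fc = rng.uniform(*design.log2_fc_range, size=design.n_de)
        if design.de_direction == "down":
            fc = -fc
        elif design.de_direction == "mixed":
            fc *= rng.choice([-1.0, 1.0], size=design.n_de)
        log2_fc[: design.n_de] = fc

    # correlation blocks assigned to leading features (DE features first,
    # emulating clusters among the planted biomarker panel)
    block_id = np.full(m, -1, dtype=int)
    pos = 0
    rho = np.zeros(m)
    for b, (size, r) in enumerate(design.corr_blocks):
        block_id[pos: pos + size] = b
        rho[pos: pos + size] = r
        pos += size

    noise = rng.standard_normal((m, n))
    factors = rng.standard_normal((max(len(design.corr_blocks), 1), n))
    latent = np.where(block_id[:, None] >= 0, factors[np.clip(block_id, 0, None)], 0.0)
    mix = np.sqrt(rho)[:, None] * latent + np.sqrt(1.0 - rho)[:, None] * noise
    values = baseline[:, None] + log2_fc[:, None] * case_mask[None, :] + sigma[:, None] * mix

    matrix = ExprMatrix(pd.DataFrame(values, index=features, columns=samples))
    truth = pd.DataFrame({
        "feature_id": features,
        "is_de": log2_fc != 0.0,
        "log2_fc": log2_fc,
        "fold_change": np.exp2(log2_fc),
        "block_id": block_id,
    })
    return matrix, truth


def simulate_probe_matrix(design: SimulationDesign) -> ProbeMatrix:
    """Simulate linear-scale probe intensities consistent with the design.

    The underlying feature matrix is the one :func:`simulate_feature_matrix`
    returns for the same design (same seed), so preprocessing output can be
    compared against known feature-level values.
    """
    feat, _ = simulate_feature_matrix(design)
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 0x9E3779B9]))
    gc_lo, gc_hi = design.gc_range
    gc_classes = np.arange(gc_lo, gc_hi + 1)

    def background(gc: np.ndarray) -> np.ndarray:
        return design.gc_background_base + design.gc_background_slope * (gc - gc_lo)

    rows = []
    k = design.probes_per_feature
    affinity = rng.normal(0.0, design.probe_affinity_sd, size=(feat.shape[0], k))
    gc_counts = rng.integers(gc_lo, gc_hi + 1, size=(feat.shape[0], k))
    n = feat.shape[1]
    X = feat.values
    for i, fid in enumerate(feat.feature_ids):
        for p in range(k):
            signal = np.exp2(X[i] + affinity[i, p])
            vals = signal + background(gc_counts[i, p])
            if design.probe_noise_sd > 0:
                vals = vals + rng.normal(0.0, design.probe_noise_sd, size=n)
            rows.append((f"{fid}_p{p + 1}", fid, int(gc_counts[i, p]), False,
                         np.clip(vals, 0.0, None)))
    for gc in gc_classes:
        for a in range(design.n_antigenomic_per_gc):
            vals = np.full(n, background(np.array(gc, dtype=float)))
            if design.probe_noise_sd > 0:
                vals = vals + rng.normal(0.0, design.probe_noise_sd, size=n)
            rows.append((f"antigen_gc{gc}_{a + 1}", "", int(gc), True,
                         np.clip(vals, 0.0, None)))

    index = [r[0] for r in rows]
    df = pd.DataFrame(
        {"feature_id": [r[1] for r in rows],
         "gc_count": [r[2] for r in rows],
         "is_antigenomic": [r[3] for r in rows]},
        index=pd.Index(index, name="probe_id"),
    )
    inten = pd.DataFrame([r[4] for r in rows], index=df.index, columns=feat.sample_ids)
    return ProbeMatrix(pd.concat([df, inten], axis=1))


def simulate_target_map(n_mirnas: int, n_genes: int, targets_per_mirna: int,
                        seed: int = 0) -> dict[str, set[str]]:
    """Uniform random miRNA -> gene-set map, reproducible by seed."""
    if targets_per_mirna > n_genes:
        raise ValidationError("targets_per_mirna exceeds n_genes")
    rng = np.random.default_rng(seed)
    genes = np.array([f"gene-{g + 1:05d}" for g in range(n_genes)])
    targets: dict[str, set[str]] = {}
    for i in range(n_mirnas):
        chosen = rng.choice(n_genes, size=targets_per_mirna, replace=False)
        targets[f"mir-{i + 1:04d}"] = set(genes[chosen])
    return targets
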