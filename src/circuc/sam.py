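"""Two-class unpaired Significance Analysis of Microarrays (SAM).

SAM scores each feature with a variance-stabilized t-like statistic

    d_i = (mean_case_i - mean_control_i) / (s_i + s0),

where ``s_i`` is the pooled standard error and ``s0`` a small "fudge
factor" that prevents low-variance features from dominating.  The null
distribution of the ordered scores is obtained by permuting the class
labels; for a given threshold ``delta`` features whose ordered score
departs from its permutation expectation by more than ``delta`` are
called, and the false discovery rate is estimated as

    FDR(delta) = pi0 * median_over_permutations(#permuted scores beyond
                 the calling cut points) / #called,

with ``pi0`` (the null-feature proportion) estimated from the fraction of
permuted scores falling inside the interquartile range of the observed
scores.  The smallest ``delta`` achieving the target FDR defines the call
set; per-feature q-values are the smallest estimated FDR at which the
feature is called.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from circuc.datatypes import ExprMatrix, ValidationError

logger = logging.getLogger("circuc")

_MAX_DELTA_GRID = 512


@dataclass
class SamParams:
    """SAM configuration.

    fdr_target : FDR threshold for calling features (default 1%).
    n_permutations : cap on label permutations; when the space of distinct
        case/control assignments is no larger, the exact null is used.
    s0_mode : ``auto_percentile`` tunes s0 over percentiles of the s_i
        distribution; ``fixed`` uses ``s0_value`` directly.
    """

    fdr_target: float = 0.01
    n_permutations: int = 1000
    s0_mode: str = "auto_percentile"
    s0_value: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr_target < 1.0):
            raise ValidationError("fdr_target must be in (0, 1)")
        if self.s0_mode not in ("auto_percentile", "fixed"):
            raise ValidationError(f"bad s0_mode: {self.s0_mode!r}")
        if self.s0_mode == "fixed" and self.s0_value is None:
            raise ValidationError("s0_mode=fixed requires s0_value")
        if self.s0_value is not None and self.s0_value < 0:
            raise ValidationError("s0_value must be >= 0")
        if self.n_permutations < 50:
            logger.warning("n_permutations=%d < 50: FDR estimates will be unstable",
                           self.n_permutations)


@dataclass
class SamResult:
    """Per-feature SAM table plus the global permutation/FDR state.

    ``table`` has one row per feature: score, fold_change, q_value, called,
    direction (up/down/none), q_zero_flag (q-value of exactly 0, i.e. the
    statistic was more extreme than every permuted score at the chosen
    delta — an estimate floor, not a true zero).
    """

    table: pd.DataFrame
    s0: float
    delta: float
    pi0: float
    expected_order_scores: np.ndarray
    n_permutations_used: int
    fdr_target: float

    @property
    def called_features(self) -> list[str]:
        return self.table.index[self.table["called"]].tolist()


# ----------------------------------------------------------------- scores

def _class_stats(values: np.ndarray, case_mask: np.ndarray):
    n1 = int(case_mask.sum())
    n2 = int((~case_mask).sum())
    if n1 < 2 or n2 < 2:
        raise ValidationError(f"each class needs >=2 samples (got {n1} cases, {n2} controls)")
    mc = values[:, case_mask].mean(axis=1)
    mn = values[:, ~case_mask].mean(axis=1)
    ss1 = ((values[:, case_mask] - mc[:, None]) ** 2).sum(axis=1)
    ss2 = ((values[:, ~case_mask] - mn[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * (ss1 + ss2) / (n1 + n2 - 2))
    return mc, mn, s, n1, n2


def sam_scores(m: ExprMatrix | np.ndarray, case_mask: np.ndarray, s0: float) -> np.ndarray:
    """Modified t-scores d_i = (mean_case - mean_control) / (s_i + s0)."""
    values = m.values if isinstance(m, ExprMatrix) else np.asarray(m, dtype=float)
    mc, mn, s, _, _ = _class_stats(values, np.asarray(case_mask, dtype=bool))
    return (mc - mn) / (s + s0)


def pooled_se(m: ExprMatrix | np.ndarray, case_mask: np.ndarray) -> np.ndarray:
    """Per-feature pooled standard errors s_i."""
    values = m.values if isinstance(m, ExprMatrix) else np.asarray(m, dtype=float)
    _, _, s, _, _ = _class_stats(values, np.asarray(case_mask, dtype=bool))
    return s


def fold_change(m: ExprMatrix | np.ndarray, case_mask: np.ndarray) -> np.ndarray:
    """Linear fold change 2**(mean_case - mean_control) from log2 values."""
    values = m.values if isinstance(m, ExprMatrix) else np.asarray(m, dtype=float)
    case_mask = np.asarray(case_mask, dtype=bool)
    return np.exp2(values[:, case_mask].mean(axis=1) - values[:, ~case_mask].mean(axis=1))


def choose_s0(m: ExprMatrix | np.ndarray, case_mask: np.ndarray,
              n_windows: int = 100) -> float:
    """Standard SAM fudge-factor tuning.

    Candidates are the percentiles {0, 5, ..., 95} of the s_i distribution;
    the winner minimizes the coefficient of variation of the median
    absolute deviation of d_i across s_i-quantile windows.  Ties break
    toward the smallest percentile.
    """
    values = m.values if isinstance(m, ExprMatrix) else np.asarray(m, dtype=float)
    case_mask = np.asarray(case_mask, dtype=bool)
    mc, mn, s, _, _ = _class_stats(values, case_mask)
    r = mc - mn
    if np.all(s == 0):
        logger.warning("all pooled standard errors are zero; using s0=1e-8")
        return 1e-8
    percentiles = np.arange(0, 100, 5)
    candidates = np.percentile(s, percentiles)
    order = np.argsort(s, kind="stable")
    nw = max(1, min(n_windows, len(s)))
    windows = np.array_split(order, nw)
    mads = np.empty((len(candidates), nw))
    for w_idx, w in enumerate(windows):
        d_w = r[w][None, :] / (s[w][None, :] + candidates[:, None])
        med = np.median(d_w, axis=1, keepdims=True)
        mads[:, w_idx] = np.median(np.abs(d_w - med), axis=1)
    means = mads.mean(axis=1)
    stds = mads.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(means > 0, stds / means,
                      np.where(stds == 0, 0.0, np.inf))
    return float(candidates[int(np.argmin(cv))])


# ----------------------------------------------------- permutation machinery

def _permutation_masks(n: int, n1: int, n_permutations: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Distinct case-label assignments as a boolean (B x n) matrix.

    Enumerates the full space when it is no larger than ``n_permutations``;
    otherwise samples uniformly without replacement.
    """
    total = math.comb(n, n1)
    masks = np.zeros((min(total, n_permutations), n), dtype=bool)
    if total <= n_permutations:
        for b, idx in enumerate(combinations(range(n), n1)):
            masks[b, list(idx)] = True
        return masks
    seen: set[tuple[int, ...]] = set()
    b = 0
    while b < n_permutations:
        idx = tuple(sorted(rng.choice(n, size=n1, replace=False).tolist()))
        if idx in seen:
            continue
        seen.add(idx)
        masks[b, list(idx)] = True
        b += 1
    return masks


def _batch_scores(values: np.ndarray, masks: np.ndarray, s0: float) -> np.ndarray:
    """Scores for every label assignment in ``masks`` (features x B)."""
    n = values.shape[1]
    n1 = int(masks[0].sum())
    n2 = n - n1
    Z = masks.T.astype(float)  # n x B
    row_sum = values.sum(axis=1, keepdims=True)
    row_sq = (values ** 2).sum(axis=1, keepdims=True)
    S1 = values @ Z
    Q1 = (values ** 2) @ Z
    mc = S1 / n1
    mn = (row_sum - S1) / n2
    ss1 = Q1 - n1 * mc ** 2
    ss2 = (row_sq - Q1) - n2 * mn ** 2
    ss = np.clip(ss1 + ss2, 0.0, None)  # guard tiny negatives from rounding
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    return (mc - mn) / (s + s0)


def _cut_points(d_sorted: np.ndarray, dbar: np.ndarray, delta: float) -> tuple[float, float]:
    """Calling thresholds for a given delta.

    Scanning outward from where the expected order scores cross zero, the
    first ordered score whose departure from expectation reaches delta
    fixes the cut; everything beyond it is called.
    """
    diff = d_sorted - dbar
    start = int(np.searchsorted(dbar, 0.0))
    up = np.nonzero(diff[start:] >= delta)[0]
    cut_up = d_sorted[start + up[0]] if len(up) else np.inf
    low = np.nonzero(diff[:start] <= -delta)[0]
    cut_low = d_sorted[low[-1]] if len(low) else -np.inf
    return float(cut_up), float(cut_low)


def sam_calibrate(m: ExprMatrix, case_mask: np.ndarray,
                  params: SamParams | None = None) -> SamResult:
    """Full SAM run: scores, permutation null, delta/FDR calibration, q-values."""
    params = params or SamParams()
    case_mask = np.asarray(case_mask, dtype=bool)
    values = m.values
    n = values.shape[1]
    n1 = int(case_mask.sum())

    if params.s0_mode == "fixed":
        s0 = float(params.s0_value)
    else:
        s0 = choose_s0(values, case_mask)

    d = sam_scores(values, case_mask, s0)
    fc = fold_change(values, case_mask)
    order = np.argsort(d, kind="stable")
    d_sorted = d[order]

    rng = np.random.default_rng(params.seed)
    masks = _permutation_masks(n, n1, params.n_permutations, rng)
    perm = _batch_scores(values, masks, s0)           # m x B
    perm_sorted = np.sort(perm, axis=0)               # order scores per perm
    dbar = perm_sorted.mean(axis=1)

    # pi0 from the fraction of permuted scores inside the observed IQR
    q25, q75 = np.percentile(d, [25, 75])
    inside = np.count_nonzero((perm >= q25) & (perm <= q75))
    pi0 = min(1.0, inside / (0.5 * perm.size))

    # delta grid from the observed departures; always includes the extremes
    diffs = np.abs(d_sorted - dbar)
    grid = np.unique(diffs)
    if len(grid) > _MAX_DELTA_GRID:
        take = np.unique(np.quantile(grid, np.linspace(0, 1, _MAX_DELTA_GRID)))
        grid = np.unique(np.concatenate([take, grid[-3:], [0.0]]))
    else:
        grid = np.unique(np.concatenate([grid, [0.0]]))

    n_features = len(d)
    cuts = np.array([_cut_points(d_sorted, dbar, float(delta)) for delta in grid])
    cuts_up, cuts_low = cuts[:, 0], cuts[:, 1]

    # per-permutation false-call counts via sorted-array searches
    B = perm_sorted.shape[1]
    counts = np.empty((B, len(grid)))
    for b in range(B):
        col = perm_sorted[:, b]
        n_up = n_features - np.searchsorted(col, cuts_up, side="left")
        n_low = np.searchsorted(col, cuts_low, side="right")
        counts[b] = n_up + n_low
    med_false = np.median(counts, axis=0)

    called_mat = (d[None, :] >= cuts_up[:, None]) | (d[None, :] <= cuts_low[:, None])
    n_called = called_mat.sum(axis=1)
    fdr_arr = np.minimum(pi0 * med_false / np.maximum(1, n_called), 1.0)

    ok = np.nonzero(fdr_arr <= params.fdr_target)[0]
    if len(ok):
        chosen = int(ok[0])
        delta = float(grid[chosen])
        called = called_mat[chosen]
    else:
        delta = float("inf")
        called = np.zeros(n_features, dtype=bool)

    # q-value: smallest estimated FDR over deltas at which the feature is called
    q = np.where(called_mat, fdr_arr[:, None], np.inf).min(axis=0)
    q = np.clip(np.where(np.isfinite(q), q, 1.0), 0.0, 1.0)

    direction = np.where(called & (d > 0), "up",
                         np.where(called & (d < 0), "down", "none"))
    table = pd.DataFrame(
        {
            "score": d,
            "fold_change": fc,
            "q_value": q,
            "called": called,
            "direction": direction,
            "q_zero_flag": called & (q == 0.0),
        },
        index=pd.Index(m.feature_ids, name="feature_id"),
    )
    return SamResult(
        table=table,
        s0=s0,
        delta=delta,
        pi0=pi0,
        expected_order_scores=dbar,
        n_permutations_used=masks.shape[0],
        fdr_target=params.fdr_target,
    )
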