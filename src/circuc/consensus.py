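"""Resampling consensus biomarker selection.

Differential calls from a single SAM run depend on the particular cohort;
to stabilize the panel, SAM is re-run on many random case/control subsets
(by default 100 draws of 18-of-20 per arm, a 9:1 subsampling without
replacement) and each feature's selection frequency across runs is
recorded.  Features whose frequency reaches the threshold (default 90%)
form the consensus panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from circuc._seeds import stage_seed
from circuc.datatypes import ExprMatrix, FRACTION_PREFIX, SampleTable, ValidationError
from circuc.sam import SamParams, sam_calibrate

logger = logging.getLogger("circuc")


@dataclass
class ConsensusParams:
    n_iterations: int = 100
    subset_cases: int = 18
    subset_controls: int = 18
    frequency_threshold: float = 0.9
    threshold_comparator: str = "ge"  # "ge" (frequency >= t) or "gt"
    sam_params: SamParams = field(default_factory=lambda: SamParams(n_permutations=200))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")
        if not (0.0 < self.frequency_threshold <= 1.0):
            raise ValidationError("frequency_threshold must be in (0, 1]")
        if self.threshold_comparator not in ("ge", "gt"):
            raise ValidationError("threshold_comparator must be 'ge' or 'gt'")


@dataclass
class ConsensusPanel:
    """Selection frequencies and the thresholded consensus decision.

    ``table``: per feature — frequency (fraction of iterations called),
    mean_score and mean_fold_change over iterations where called (NaN if
    never called), direction (up/down/mixed/none), selected.
    """

    table: pd.DataFrame
    n_iterations: int
    threshold: float

    @property
    def selected_features(self) -> list[str]:
        return self.table.index[self.table["selected"]].tolist()


def derive_consensus(m: ExprMatrix, meta: SampleTable,
                     params: ConsensusParams | None = None) -> ConsensusPanel:
    """Run SAM on repeated class-balanced subsamples and tally call frequency."""
    params = params or ConsensusParams()
    meta = meta.subset(m.sample_ids)
    groups = meta.table.set_index("sample_id")["group"]
    # sorted so that the resampling stream is invariant to column order
    cases = sorted(s for s in m.sample_ids if groups.get(s) == "case")
    controls = sorted(s for s in m.sample_ids if groups.get(s) == "control")
    if len(cases) < params.subset_cases or len(controls) < params.subset_controls:
        raise ValidationError(
            f"need >= {params.subset_cases} cases and {params.subset_controls} controls; "
            f"have {len(cases)}/{len(controls)}"
        )

    rng = np.random.default_rng(stage_seed(params.seed, "consensus-resampling"))
    n_feat = m.shape[0]
    call_count = np.zeros(n_feat, dtype=int)
    up_count = np.zeros(n_feat, dtype=int)
    down_count = np.zeros(n_feat, dtype=int)
    score_sum = np.zeros(n_feat)
    fc_sum = np.zeros(n_feat)

    for it in range(params.n_iterations):
        sub_cases = list(rng.choice(cases, size=params.subset_cases, replace=False))
        sub_controls = list(rng.choice(controls, size=params.subset_controls, replace=False))
        sub = m.subset_samples(sub_cases + sub_controls)
        mask = np.array([True] * len(sub_cases) + [False] * len(sub_controls))
        it_params = replace(params.sam_params,
                            seed=stage_seed(params.seed, f"consensus-sam-{it}"))
        res = sam_calibrate(sub, mask, it_params)
        called = res.table["called"].to_numpy()
        call_count += called
        up_count += called & (res.table["direction"].to_numpy() == "up")
        down_count += called & (res.table["direction"].to_numpy() == "down")
        score_sum += np.where(called, res.table["score"].to_numpy(), 0.0)
        fc_sum += np.where(called, res.table["fold_change"].to_numpy(), 0.0)

    freq = call_count / params.n_iterations
    with np.errstate(invalid="ignore"):
        mean_score = np.where(call_count > 0, score_sum / np.maximum(call_count, 1), np.nan)
        mean_fc = np.where(call_count > 0, fc_sum / np.maximum(call_count, 1), np.nan)
    direction = np.full(n_feat, "none", dtype=object)
    direction[(up_count > 0) & (down_count == 0)] = "up"
    direction[(down_count > 0) & (up_count == 0)] = "down"
    mixed = (up_count > 0) & (down_count > 0)
    direction[mixed] = "mixed"
    if mixed.any():
        logger.warning("features called in both directions across iterations: %s",
                       [m.feature_ids[i] for i in np.nonzero(mixed)[0]])
    if params.threshold_comparator == "ge":
        selected = freq >= params.frequency_threshold
    else:
        selected = freq > params.frequency_threshold

    table = pd.DataFrame(
        {
            "frequency": freq,
            "mean_score": mean_score,
            "mean_fold_change": mean_fc,
            "direction": direction,
            "selected": selected,
        },
        index=pd.Index(m.feature_ids, name="feature_id"),
    )
    return ConsensusPanel(table=table, n_iterations=params.n_iterations,
                          threshold=params.frequency_threshold)


def combine_fractions(m_by_fraction: dict[str, ExprMatrix]) -> ExprMatrix:
    """Row-concatenate per-fraction matrices with fraction-prefixed ids.

    All fractions must cover the same samples (per-subject pairing);
    feature ids become e.g. ``pl:mir-0001`` so the same miRNA measured in
    two fractions never collides.
    """
    if not m_by_fraction:
        raise ValidationError("no fractions supplied")
    sample_sets = {f: tuple(m.sample_ids) for f, m in m_by_fraction.items()}
    reference = next(iter(sample_sets.values()))
    offenders = {f: sorted(set(s) ^ set(reference))
                 for f, s in sample_sets.items() if set(s) != set(reference)}
    if offenders:
        raise ValidationError(f"sample sets differ between fractions: {offenders}")
    parts = []
    for fraction, m in m_by_fraction.items():
        prefix = FRACTION_PREFIX.get(fraction, fraction)
        df = m.data.loc[:, list(reference)].copy()
        df.index = [f"{prefix}:{fid}" for fid in m.feature_ids]
        parts.append(df)
    return ExprMatrix(pd.concat(parts, axis=0))


def strip_fraction_prefix(feature_id: str) -> str:
    return feature_id.split(":", 1)[1] if ":" in feature_id else feature_id


def panel_overlap(panels: dict[str, ConsensusPanel | list[str]]) -> pd.DataFrame:
    """Pairwise intersection/difference counts and Jaccard indices.

    Fraction prefixes are stripped before comparison so a miRNA selected
    in two fraction-specific panels counts as shared.
    """
    if len(panels) < 2:
        raise ValidationError("panel_overlap needs >= 2 panels")
    sets = {}
    for name, panel in panels.items():
        features = panel.selected_features if isinstance(panel, ConsensusPanel) else panel
        sets[name] = {strip_fraction_prefix(f) for f in features}
    rows = []
    names = sorted(sets)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            inter = sets[a] & sets[b]
            union = sets[a] | sets[b]
            rows.append({
                "panel_a": a, "panel_b": b,
                "size_a": len(sets[a]), "size_b": len(sets[b]),
                "intersection": len(inter),
                "only_a": len(sets[a] - sets[b]),
                "only_b": len(sets[b] - sets[a]),
                "jaccard": len(inter) / len(union) if union else 1.0,
            })
    return pd.DataFrame(rows)
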