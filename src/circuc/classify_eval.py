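"""Nested Monte-Carlo cross-validated evaluation of an RBF-kernel SVM.

Each repetition draws a training cohort (default 18 cases + 18 controls)
and holds out the remainder (2 + 2) for testing.  Biomarker selection is
redone *inside* the training cohort — the consensus selector runs on inner
16 + 16 subsamples — so the held-out samples never inform the panel.  A
soft-margin SVM with radial-basis-function kernel is trained on the
standardized selected features and applied to the test samples; confusion
counts are aggregated over all repetitions and the performance measures
(accuracy, sensitivity, specificity, PPV, NPV, FPR, FNR) derived from the
aggregate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from circuc._seeds import stage_seed
from circuc.consensus import ConsensusParams, derive_consensus
from circuc.datatypes import ExprMatrix, SampleTable, ValidationError
from circuc.sam import SamParams, sam_calibrate

logger = logging.getLogger("circuc")


def _default_inner_consensus() -> ConsensusParams:
    return ConsensusParams(
        n_iterations=20,
        subset_cases=16,
        subset_controls=16,
        frequency_threshold=0.9,
        sam_params=SamParams(fdr_target=0.01, n_permutations=100),
    )


@dataclass
class EvalParams:
    """Nested evaluation configuration.

    ``kernel_gamma`` is either a positive float or the string
    ``"reciprocal-of-feature-count"`` (RBF width 1/k for k selected
    features, the e1071/libsvm default).
    """

    n_repetitions: int = 100
    train_cases: int = 18
    train_controls: int = 18
    inner_consensus: ConsensusParams = field(default_factory=_default_inner_consensus)
    kernel_gamma: float | str = "reciprocal-of-feature-count"
    cost: float = 1.0
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repetitions < 1:
            raise ValidationError("n_repetitions must be >= 1")
        if self.inner_consensus.subset_cases >= self.train_cases or \
           self.inner_consensus.subset_controls >= self.train_controls:
            raise ValidationError("inner subset sizes must be < training sizes")
        if isinstance(self.kernel_gamma, str) and \
           self.kernel_gamma != "reciprocal-of-feature-count":
            raise ValidationError(f"bad kernel_gamma: {self.kernel_gamma!r}")


@dataclass
class ConfusionAggregate:
    tp: int
    fp: int
    tn: int
    fn: int
    n_repetitions: int
    misclassified_sample_counts: dict[str, int]
    test_appearance_counts: dict[str, int]

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class PerfMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    fpr: float
    fnr: float

    @classmethod
    def from_confusion(cls, c: ConfusionAggregate) -> "PerfMetrics":
        def ratio(num: int, den: int) -> float:
            return num / den if den else float("nan")

        sens = ratio(c.tp, c.tp + c.fn)
        spec = ratio(c.tn, c.tn + c.fp)
        return cls(
            accuracy=ratio(c.tp + c.tn, c.total),
            sensitivity=sens,
            specificity=spec,
            ppv=ratio(c.tp, c.tp + c.fp),
            npv=ratio(c.tn, c.tn + c.fn),
            fpr=1.0 - spec if spec == spec else float("nan"),
            fnr=1.0 - sens if sens == sens else float("nan"),
        )


def _select_in_fold(train: ExprMatrix, meta: SampleTable, params: EvalParams,
                    rep_seed: int) -> tuple[list[str], str]:
    """In-fold feature selection; returns (features, how-they-were-chosen)."""
    inner = replace(params.inner_consensus, seed=rep_seed)
    panel = derive_consensus(train, meta, inner)
    features = panel.selected_features
    if features:
        return features, "consensus"
    # degenerate fold: fall back to a single SAM run on the full training split
    mask = meta.groups_for(train.sample_ids)
    sam = sam_calibrate(train, mask,
                        replace(inner.sam_params, seed=rep_seed))
    features = sam.called_features
    if features:
        return features, "single-sam"
    return [], "majority"


def evaluate(m: ExprMatrix, meta: SampleTable,
             params: EvalParams | None = None) -> tuple[ConfusionAggregate, PerfMetrics]:
    """Nested Monte-Carlo cross-validation with in-fold consensus selection."""
    params = params or EvalParams()
    meta = meta.subset(m.sample_ids)
    groups = meta.table.set_index("sample_id")["group"]
    cases = sorted(s for s in m.sample_ids if groups.get(s) == "case")
    controls = sorted(s for s in m.sample_ids if groups.get(s) == "control")
    if len(cases) <= params.train_cases - 1 or len(controls) <= params.train_controls - 1:
        raise ValidationError("not enough samples for the train/test split scheme")
    if len(cases) == params.train_cases or len(controls) == params.train_controls:
        raise ValidationError("split scheme leaves an empty test class")

    rng = np.random.default_rng(stage_seed(params.seed, "eval-splits"))
    tp = fp = tn = fn = 0
    miscls: dict[str, int] = {s: 0 for s in cases + controls}
    appearances: dict[str, int] = {s: 0 for s in cases + controls}
    X_all = m.data.T  # samples x features

    for rep in range(params.n_repetitions):
        train_cases = list(rng.choice(cases, size=params.train_cases, replace=False))
        train_controls = list(rng.choice(controls, size=params.train_controls, replace=False))
        test_samples = sorted(set(cases) - set(train_cases)) + \
            sorted(set(controls) - set(train_controls))
        train_samples = train_cases + train_controls
        assert not set(train_samples) & set(test_samples)

        train = m.subset_samples(train_samples)
        rep_seed = stage_seed(params.seed, f"eval-rep-{rep}")
        features, mode = _select_in_fold(train, meta, params, rep_seed)

        y_test_true = np.array([groups[s] == "case" for s in test_samples])
        if not features:
            logger.warning("repetition %d: empty feature panel, majority fallback", rep)
            n_case = len(train_cases)
            n_ctrl = len(train_controls)
            majority_case = n_case > n_ctrl  # control wins ties
            y_pred = np.full(len(test_samples), majority_case)
        else:
            if mode == "single-sam":
                logger.info("repetition %d: consensus empty, single-SAM fallback "
                            "selected %d features", rep, len(features))
            Xtr = X_all.loc[train_samples, features].to_numpy()
            Xte = X_all.loc[test_samples, features].to_numpy()
            if params.standardize:
                mu = Xtr.mean(axis=0)
                sd = Xtr.std(axis=0, ddof=0)
                sd[sd == 0] = 1.0
                Xtr = (Xtr - mu) / sd
                Xte = (Xte - mu) / sd
            gamma = (1.0 / len(features)
                     if params.kernel_gamma == "reciprocal-of-feature-count"
                     else float(params.kernel_gamma))
            y_train = np.array([groups[s] == "case" for s in train_samples])
            clf = SVC(kernel="rbf", gamma=gamma, C=params.cost)
            clf.fit(Xtr, y_train)
            y_pred = clf.predict(Xte).astype(bool)

        for s, truth, pred in zip(test_samples, y_test_true, y_pred):
            appearances[s] += 1
            if truth and pred:
                tp += 1
            elif truth and not pred:
                fn += 1
                miscls[s] += 1
            elif not truth and pred:
                fp += 1
                miscls[s] += 1
            else:
                tn += 1

    agg = ConfusionAggregate(tp=tp, fp=fp, tn=tn, fn=fn,
                             n_repetitions=params.n_repetitions,
                             misclassified_sample_counts=miscls,
                             test_appearance_counts=appearances)
    return agg, PerfMetrics.from_confusion(agg)


def misclassification_report(c: ConfusionAggregate, meta: SampleTable) -> pd.DataFrame:
    """Per-sample test appearances, misclassification counts and rates."""
    groups = meta.table.set_index("sample_id")["group"]
    rows = []
    for s, n_test in c.test_appearance_counts.items():
        n_mis = c.misclassified_sample_counts.get(s, 0)
        rows.append({
            "sample_id": s,
            "group": groups.get(s, "unknown"),
            "times_in_test": n_test,
            "times_misclassified": n_mis,
            "rate": n_mis / n_test if n_test else 0.0,
        })
    df = pd.DataFrame(rows)
    return df.sort_values(["rate", "sample_id"], ascending=[False, True],
                          kind="stable").reset_index(drop=True)
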