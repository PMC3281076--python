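"""qPCR validation arithmetic: delta-Ct normalization, 2^(-dCt) replicate
statistics, group t-tests and cross-platform concordance.

A qPCR table holds cycle-threshold (Ct) measurements for target miRNAs and
for normalizer assays, per biological group (case/control) and replicate.
Each replicate's delta-Ct is the target Ct minus the mean normalizer Ct of
that (group, replicate); relative abundance is 2**(-dCt).  Fold change is
the ratio of case to control mean abundances, and significance comes from
a pooled-variance (classic Student) two-sample t-test on the replicate
abundances; Welch's correction is available by flag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from circuc.datatypes import ValidationError

logger = logging.getLogger("circuc")

_QPCR_COLUMNS = ["mirna_id", "group", "replicate_id", "ct", "is_normalizer"]


def validate_qpcr_table(q: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _QPCR_COLUMNS if c not in q.columns]
    if missing:
        raise ValidationError(f"qPCR table missing columns: {missing}")
    q = q.copy()
    q["ct"] = q["ct"].astype(float)
    if not np.isfinite(q["ct"]).all():
        raise ValidationError("non-finite Ct values")
    q["is_normalizer"] = q["is_normalizer"].astype(bool)
    bad = set(q["group"]) - {"case", "control"}
    if bad:
        raise ValidationError(f"unknown groups in qPCR table: {sorted(bad)}")
    return q


def _normalizer_means(q: pd.DataFrame) -> pd.Series:
    norms = q[q["is_normalizer"]]
    if norms.empty:
        raise ValidationError("qPCR table has no normalizer measurements")
    return norms.groupby(["group", "replicate_id"])["ct"].mean()


@dataclass
class QpcrResult:
    mirna_id: str
    fold_change: float
    p_value: float
    case_values: np.ndarray
    control_values: np.ndarray


def delta_ct_fold_change(q: pd.DataFrame, mirna: str,
                         welch: bool = False) -> QpcrResult:
    """Fold change and t-test p for one miRNA from its replicate 2^(-dCt).

    Every (group, replicate) of the target must carry at least one
    normalizer measurement; at least two replicates per group are needed.
    """
    q = validate_qpcr_table(q)
    norm_mean = _normalizer_means(q)
    target = q[(q["mirna_id"] == mirna) & (~q["is_normalizer"])]
    if target.empty:
        raise ValidationError(f"no measurements for miRNA {mirna!r}")
    values: dict[str, list[float]] = {"case": [], "control": []}
    for _, row in target.iterrows():
        key = (row["group"], row["replicate_id"])
        if key not in norm_mean.index:
            raise ValidationError(f"missing normalizer for group={key[0]!r}, "
                                  f"replicate={key[1]!r}")
        dct = row["ct"] - norm_mean[key]
        values[row["group"]].append(2.0 ** (-dct))
    case = np.array(values["case"])
    control = np.array(values["control"])
    if len(case) < 2 or len(control) < 2:
        raise ValidationError(f"{mirna}: need >=2 replicates per group, got "
                              f"{len(case)}/{len(control)}")
    fc = case.mean() / control.mean()
    if case.std(ddof=1) == 0 and control.std(ddof=1) == 0:
        if case.mean() == control.mean():
            p = 1.0
        else:
            logger.warning("%s: zero variance with unequal means; p below machine eps",
                           mirna)
            p = float(np.finfo(float).tiny)
    else:
        p = float(stats.ttest_ind(case, control, equal_var=not welch).pvalue)
    return QpcrResult(mirna_id=mirna, fold_change=float(fc), p_value=p,
                      case_values=case, control_values=control)


def qpcr_summary(q: pd.DataFrame, welch: bool = False) -> pd.DataFrame:
    """delta_ct_fold_change for every non-normalizer miRNA in the table."""
    q = validate_qpcr_table(q)
    mirnas = sorted(q.loc[~q["is_normalizer"], "mirna_id"].unique())
    rows = []
    for mirna in mirnas:
        res = delta_ct_fold_change(q, mirna, welch=welch)
        rows.append({"mirna_id": mirna, "fold_change": res.fold_change,
                     "p_value": res.p_value,
                     "n_case": len(res.case_values),
                     "n_control": len(res.control_values)})
    return pd.DataFrame(rows)


def platform_concordance(array_fc: pd.Series | dict, qpcr_fc: pd.Series | dict) -> float:
    """Paired two-sided t-test on per-miRNA log2 fold-change differences.

    Agreement between platforms (e.g. microarray vs qPCR) is assessed on
    the log2 scale so up- and down-regulation are symmetric.  Returns the
    p-value; a large p means no detectable systematic difference.
    """
    a = pd.Series(array_fc).astype(float)
    b = pd.Series(qpcr_fc).astype(float)
    if set(a.index) != set(b.index):
        raise ValidationError("platform comparison requires the same miRNA set")
    if len(a) < 2:
        raise ValidationError("paired t-test needs >= 2 miRNAs")
    diff = np.log2(a.sort_index().to_numpy()) - np.log2(b.sort_index().to_numpy())
    if np.allclose(diff, diff[0]):
        if np.allclose(diff, 0.0):
            return 1.0
        logger.warning("constant nonzero log2 difference between platforms; "
                       "p below machine eps")
        return float(np.finfo(float).tiny)
    return float(stats.ttest_rel(np.log2(a.sort_index().to_numpy()),
                                 np.log2(b.sort_index().to_numpy())).pvalue)
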