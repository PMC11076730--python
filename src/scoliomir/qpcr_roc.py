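"""qPCR relative quantification and ROC diagnostic evaluation.

Relative expression follows the 2^-ddCt convention: per subject,
dCt = mean target Ct - mean reference Ct over triplicates; ddCt
subtracts the calibrator group's mean dCt (here the control group, so
the control group's geometric-mean relative quantity is exactly 1); the
relative quantity is RQ = 2^-ddCt.  Because dCt is a within-subject
difference, any constant plate offset added to all of a subject's wells
cancels exactly.

Diagnostic evaluation is rank-based: AUC by concordant-pair counting
(ties count 1/2, so AUC equals the Mann-Whitney U statistic divided by
n_case * n_control), a DeLong placement-value confidence interval with
a percentile-bootstrap cross-check, and a Youden-optimal operating
cutoff scanned over the midpoints between adjacent distinct scores.
Markers down-regulated in cases are scored with the
``low_predicts_case`` orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import QpcrSample

__all__ = [
    "RelativeExpression",
    "RocResult",
    "delta_delta_ct",
    "compare_groups",
    "roc_auc",
    "auc_confidence_interval",
    "youden_cutoff",
    "evaluate_marker",
]

ORIENTATIONS = ("low_predicts_case", "high_predicts_case")


@dataclass(frozen=True)
class RocResult:
    """AUC with confidence interval and Youden operating point."""

    auc: float
    ci_low: float
    ci_high: float
    threshold: float
    sensitivity: float
    specificity: float
    orientation: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.auc <= self.ci_high <= 1.0):
            raise ValueError("need 0 <= ci_low <= auc <= ci_high <= 1")


def delta_delta_ct(samples: Sequence[QpcrSample],
                   calibrator_group: str = "control") -> pd.DataFrame:
    """2^-ddCt relative expression per subject and target.

    Returns a tidy frame (subject_id, group, target, delta_ct,
    delta_delta_ct, rq).  The calibrator is the mean dCt of the
    calibrator group per target, so that group's log-scale mean RQ is 0
    (geometric mean RQ = 1).
    """
    if not samples:
        raise ValueError("no qPCR samples")
    targets = list(samples[0].targets)
    rows = []
    for s in samples:
        if set(s.targets) != set(targets):
            raise ValueError(f"sample {s.subject_id} has a different target panel")
        ref = float(np.mean(s.reference))
        for t in targets:
            rows.append({"subject_id": s.subject_id, "group": s.group, "target": t,
                         "delta_ct": float(np.mean(s.targets[t])) - ref})
    df = pd.DataFrame(rows)
    calib = (df[df["group"] == calibrator_group]
             .groupby("target")["delta_ct"].mean())
    if calib.empty:
        raise ValueError(f"no samples in calibrator group {calibrator_group!r}")
    df["delta_delta_ct"] = df["delta_ct"] - df["target"].map(calib)
    df["rq"] = np.exp2(-df["delta_delta_ct"])
    return df


def compare_groups(case_values: Sequence[float], control_values: Sequence[float],
                   test: str = "welch_t") -> tuple[float, float]:
    """Two-group comparison: Welch t on log2 values, or Wilcoxon rank-sum.

    ``welch_t`` runs on log2 of the (positive) values, matching how
    relative quantities are compared.  ``rank_sum`` is exact for
    combined n <= 20 without ties and uses the tie-corrected normal
    approximation otherwise.  Identical degenerate samples give p = 1.
    """
    a = np.asarray(case_values, dtype=float)
    b = np.asarray(control_values, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    if test == "welch_t":
        if (a <= 0).any() or (b <= 0).any():
            raise ValueError("welch_t on relative quantities needs positive values")
        res = stats.ttest_ind(np.log2(a), np.log2(b), equal_var=False)
        return float(res.statistic), float(res.pvalue)
    if test == "rank_sum":
        if np.ptp(np.concatenate([a, b])) == 0:
            return 0.0, 1.0
        has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if (len(a) + len(b) <= 20 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(min(res.pvalue, 1.0))
    raise ValueError("test must be 'welch_t' or 'rank_sum'")


def _split(scores: Sequence[float], labels: Sequence) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    lab = np.asarray([_is_case(l) for l in labels])
    if len(scores) != len(lab):
        raise ValueError("scores and labels must align")
    case, control = scores[lab], scores[~lab]
    if len(case) == 0 or len(control) == 0:
        raise ValueError("both groups must be non-empty")
    return case, control


def _is_case(label) -> bool:
    if isinstance(label, str):
        return label.lower() in ("case", "ais", "1", "true", "positive")
    return bool(label)


def _oriented(case: np.ndarray, control: np.ndarray, orientation: str):
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    if orientation == "low_predicts_case":
        return -case, -control
    return case, control


def roc_auc(scores: Sequence[float], labels: Sequence, orientation: str) -> float:
    """AUC by concordant-pair counting (ties count one half).

    Under ``high_predicts_case`` a (case, control) pair is concordant
    when the case scores higher; ``low_predicts_case`` flips the
    comparison.  Equals Mann-Whitney U / (n_case * n_control).
    """
    case, control = _oriented(*_split(scores, labels), orientation)
    diff = case[:, None] - control[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def _delong_variance(case: np.ndarray, control: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from placement values."""
    m, n = len(case), len(control)
    # placement of each case among controls, and vice versa
    v10 = np.array([((c > control).sum() + 0.5 * (c == control).sum()) / n for c in case])
    v01 = np.array([((case > c).sum() + 0.5 * (case == c).sum()) / m for c in control])
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def auc_confidence_interval(scores: Sequence[float], labels: Sequence,
                            orientation: str = "high_predicts_case",
                            level: float = 0.95, method: str = "delong",
                            n_boot: int = 2000,
                            seed: int | None = 0) -> tuple[float, float]:
    """Confidence interval for the AUC.

    ``delong`` is the placement-value Wald interval clipped to [0,1];
    perfect separation (zero variance) degenerates to [auc, auc].
    ``bootstrap`` is the stratified percentile interval, provided as an
    independent cross-check.
    """
    case, control = _oriented(*_split(scores, labels), orientation)
    if len(case) < 2 or len(control) < 2:
        raise ValueError("need at least 2 subjects per group for a CI")
    if method == "delong":
        auc, var = _delong_variance(case, control)
        if var <= 0:
            return auc, auc
        z = stats.norm.ppf(0.5 + level / 2)
        half = z * np.sqrt(var)
        return float(max(0.0, auc - half)), float(min(1.0, auc + half))
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        aucs = np.empty(n_boot)
        for i in range(n_boot):
            cs = rng.choice(case, size=len(case), replace=True)
            ct = rng.choice(control, size=len(control), replace=True)
            diff = cs[:, None] - ct[None, :]
            aucs[i] = ((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size
        lo, hi = np.quantile(aucs, [(1 - level) / 2, 0.5 + level / 2])
        return float(lo), float(hi)
    raise ValueError("method must be 'delong' or 'bootstrap'")


def youden_cutoff(scores: Sequence[float], labels: Sequence,
                  orientation: str) -> tuple[float, float, float]:
    """Operating cutoff maximizing Youden's J = sens + spec - 1.

    Thresholds scan the midpoints between adjacent distinct scores
    (plus open ends).  Under ``high_predicts_case`` a subject is called
    a case when its score exceeds the threshold; ``low_predicts_case``
    calls cases below it.  Ties in J break toward higher sensitivity,
    then toward the less extreme threshold.  The returned threshold is
    on the original score scale.
    """
    case, control = _split(scores, labels)
    ocase, ocontrol = _oriented(case, control, orientation)
    pooled = np.unique(np.concatenate([ocase, ocontrol]))
    mids = (pooled[:-1] + pooled[1:]) / 2 if len(pooled) > 1 else np.array([])
    cuts = np.concatenate([[pooled[0] - 1.0], mids, [pooled[-1] + 1.0]])
    best = None
    for cut in cuts:
        sens = float((ocase > cut).mean())
        spec = float((ocontrol <= cut).mean())
        key = (sens + spec - 1.0, sens, -cut)
        if best is None or key > best[0]:
            best = (key, cut, sens, spec)
    _, cut, sens, spec = best
    threshold = -cut if orientation == "low_predicts_case" else cut
    return float(threshold), sens, spec


def evaluate_marker(scores: Sequence[float], labels: Sequence,
                    orientation: str | None = None, level: float = 0.95) -> RocResult:
    """Full diagnostic summary for one marker.

    When ``orientation`` is None it is derived from the data: if cases
    score lower on average the marker is scored ``low_predicts_case``
    (the convention for down-regulated markers).
    """
    case, control = _split(scores, labels)
    if orientation is None:
        orientation = ("low_predicts_case" if case.mean() < control.mean()
                       else "high_predicts_case")
    auc = roc_auc(scores, labels, orientation)
    lo, hi = auc_confidence_interval(scores, labels, orientation, level=level)
    thr, sens, spec = youden_cutoff(scores, labels, orientation)
    return RocResult(auc=auc, ci_low=min(lo, auc), ci_high=max(hi, auc),
                     threshold=thr, sensitivity=sens, specificity=spec,
                     orientation=orientation)
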