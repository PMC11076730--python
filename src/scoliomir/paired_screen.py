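"""Matched-pair differential screen and candidate selection.

The sequencing arm has one case and one control per matched pair and no
biological replicates, so per-pair differential calls use Fisher's exact
test on raw counts against the library remainder, gated by a fold-change
threshold on counts-per-million: a miRNA is differential in a pair iff
p < alpha AND |log2 FC| >= min_abs_log2fc.  Candidates are the miRNAs
differential in *every* pair; a direction-consistency filter then keeps
only those moving the same way in all pairs.  A sequencing-based
reference-miRNA selector picks the most abundant miRNA that is detected
everywhere, stable (low CV of CPM) and not group-shifted.

No multiple-testing correction is applied anywhere in this screen: the
published selection rule is per-pair p < 0.05 with a 2-fold change, and
the cross-pair intersection is itself the stringency mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_matching import MatchedPair
from .smallrna_quant import CountMatrix

__all__ = [
    "PairDEResult",
    "CandidateSet",
    "pair_differential",
    "shared_candidates",
    "direction_consistency_filter",
    "select_reference_mirna",
    "group_differential",
]


@dataclass
class PairDEResult:
    """Per-pair differential table (one row per miRNA).

    Columns: case_count, control_count, case_cpm, control_cpm, log2fc,
    p_value, is_differential, direction ('up'/'down'/'none').
    """

    pair_id: str
    case_sample: str
    control_sample: str
    table: pd.DataFrame
    alpha: float
    min_abs_log2fc: float

    @property
    def differential_ids(self) -> set[str]:
        return set(self.table.index[self.table["is_differential"]])


@dataclass
class CandidateSet:
    """Cross-pair intersection of differential calls.

    ``shared_ids`` are differential in all pairs; ``directions`` is the
    miRNA x pair direction table for those ids; ``consistent_ids`` moved
    the same way in every pair; ``upset_counts`` holds the exclusive
    intersection size for every non-empty subset of pairs.
    """

    pair_ids: list[str]
    shared_ids: list[str]
    directions: pd.DataFrame
    consistent_ids: list[str]
    consistent_directions: dict[str, str] = field(default_factory=dict)
    upset_counts: pd.DataFrame | None = None


def pair_differential(matrix: CountMatrix, pair: MatchedPair | tuple[str, str],
                      alpha: float = 0.05, min_abs_log2fc: float = 1.0,
                      pseudocount: float = 0.5, p_mode: str = "all") -> PairDEResult:
    """Differential call for one matched pair, no replicates.

    For every miRNA the p-value is two-sided Fisher's exact on
    [[case_count, case_lib - case_count], [control_count, control_lib -
    control_count]]; the fold change is log2((case_cpm + pseudocount) /
    (control_cpm + pseudocount)).  ``p_mode='gated'`` computes p-values
    only where the fold-change gate already passes (the differential set
    is unchanged: a call needs both conditions); elsewhere p is NaN.
    """
    if isinstance(pair, MatchedPair):
        case_s, control_s = pair.case_id, pair.control_id
    else:
        case_s, control_s = pair
    for s in (case_s, control_s):
        if s not in matrix.sample_ids:
            raise ValueError(f"sample {s} not in count matrix")
    if p_mode not in ("all", "gated"):
        raise ValueError("p_mode must be 'all' or 'gated'")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")

    case = matrix.raw[case_s].to_numpy()
    control = matrix.raw[control_s].to_numpy()
    case_lib = int(matrix.library_sizes[case_s])
    control_lib = int(matrix.library_sizes[control_s])
    if case.max(initial=0) > case_lib or control.max(initial=0) > control_lib:
        raise ValueError("count exceeds library size")
    case_cpm = case * 1e6 / case_lib
    control_cpm = control * 1e6 / control_lib
    log2fc = np.log2((case_cpm + pseudocount) / (control_cpm + pseudocount))
    gate = np.abs(log2fc) >= min_abs_log2fc

    pvals = np.full(len(case), np.nan)
    todo = np.arange(len(case)) if p_mode == "all" else np.flatnonzero(gate)
    for i in todo:
        tbl = [[int(case[i]), case_lib - int(case[i])],
               [int(control[i]), control_lib - int(control[i])]]
        pvals[i] = stats.fisher_exact(tbl).pvalue
    is_diff = gate & (pvals < alpha)
    direction = np.where(is_diff, np.where(log2fc > 0, "up", "down"), "none")

    table = pd.DataFrame({
        "case_count": case, "control_count": control,
        "case_cpm": case_cpm, "control_cpm": control_cpm,
        "log2fc": log2fc, "p_value": pvals,
        "is_differential": is_diff, "direction": direction,
    }, index=matrix.mirna_ids)
    table.index.name = "mirna_id"
    return PairDEResult(pair_id=f"{case_s}|{control_s}", case_sample=case_s,
                        control_sample=control_s, table=table,
                        alpha=alpha, min_abs_log2fc=min_abs_log2fc)


def shared_candidates(results: Sequence[PairDEResult],
                      with_upset: bool = True) -> CandidateSet:
    """Intersect differential sets across pairs; tabulate UpSet counts.

    ``upset_counts`` has one row per non-empty pair subset with the
    number of miRNAs differential in exactly that subset (exclusive
    intersections); the row for the full subset is the shared set size.
    """
    if not results:
        raise ValueError("at least one pair result is required")
    pair_ids = [r.pair_id for r in results]
    diff_sets = [r.differential_ids for r in results]
    shared = set.intersection(*diff_sets)

    membership: dict[str, tuple[bool, ...]] = {}
    for mid in set.union(*diff_sets):
        membership[mid] = tuple(mid in s for s in diff_sets)

    upset = None
    if with_upset:
        rows = []
        n = len(results)
        for k in range(1, n + 1):
            for subset in combinations(range(n), k):
                mask = tuple(i in subset for i in range(n))
                count = sum(1 for m in membership.values() if m == mask)
                rows.append({"subset": "".join("1" if b else "0" for b in mask),
                             "n_pairs": k, "count": count})
        upset = pd.DataFrame(rows)

    shared_sorted = sorted(shared)
    directions = pd.DataFrame(
        {r.pair_id: r.table.loc[shared_sorted, "direction"] for r in results},
        index=shared_sorted)
    directions.index.name = "mirna_id"
    consistent, cdir = [], {}
    for mid in shared_sorted:
        dirs = set(directions.loc[mid])
        if len(dirs) == 1:
            consistent.append(mid)
            cdir[mid] = next(iter(dirs))
    return CandidateSet(pair_ids=pair_ids, shared_ids=shared_sorted,
                        directions=directions, consistent_ids=consistent,
                        consistent_directions=cdir, upset_counts=upset)


def direction_consistency_filter(candidates: CandidateSet) -> dict[str, str]:
    """Shared candidates moving the same way in every pair (id -> direction)."""
    return dict(candidates.consistent_directions)


def select_reference_mirna(matrix: CountMatrix, case_ids: Sequence[str],
                           control_ids: Sequence[str], cv_quantile: float = 0.25,
                           min_abs_log2fc: float = 1.0) -> tuple[str, pd.DataFrame]:
    """Pick an internal-reference miRNA from the sequencing data.

    Eligible miRNAs are detected (count > 0) in every sample, sit below
    the ``cv_quantile`` quantile of CPM coefficient of variation among
    the detected miRNAs, and show |log2 mean case/control CPM ratio|
    below ``min_abs_log2fc``.  Among the eligible, the one with the
    highest mean CPM is returned, with a ranked stability report.
    """
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise ValueError("need at least 2 samples per group")
    samples = list(case_ids) + list(control_ids)
    cpm = matrix.cpm()[samples]
    detected = (matrix.raw[samples] > 0).all(axis=1)
    report = pd.DataFrame({
        "mean_cpm": cpm.mean(axis=1),
        "cv": cpm.std(axis=1, ddof=1) / cpm.mean(axis=1),
        "log2_group_ratio": np.log2(cpm[list(case_ids)].mean(axis=1)
                                    / cpm[list(control_ids)].mean(axis=1)),
        "detected_all": detected,
    })
    pool = report[detected]
    if pool.empty:
        raise ValueError("no miRNA detected in all samples; relax the criteria")
    cv_cut = pool["cv"].quantile(cv_quantile)
    eligible = pool[(pool["cv"] <= cv_cut)
                    & (pool["log2_group_ratio"].abs() < min_abs_log2fc)]
    if eligible.empty:
        raise ValueError("no stable reference miRNA; relax cv_quantile")
    eligible = eligible.sort_values("mean_cpm", ascending=False)
    report = report.sort_values(["detected_all", "mean_cpm"], ascending=False)
    return str(eligible.index[0]), eligible


def group_differential(matrix: CountMatrix, case_ids: Sequence[str],
                       control_ids: Sequence[str], alpha: float = 0.05,
                       min_abs_log2fc: float = 1.0,
                       pseudocount: float = 0.5) -> pd.DataFrame:
    """Pooled case-vs-control screen (Welch t on log2(CPM + pseudocount)).

    A volcano-style stand-in for the pooled 6-vs-6 comparison; per-pair
    calls, not this table, drive candidate selection.
    """
    cpm = matrix.cpm()
    logs = np.log2(cpm + pseudocount)
    case = logs[list(case_ids)]
    control = logs[list(control_ids)]
    t, p = stats.ttest_ind(case, control, axis=1, equal_var=False)
    log2fc = case.mean(axis=1) - control.mean(axis=1)
    sig = (p < alpha) & (np.abs(log2fc) >= min_abs_log2fc)
    out = pd.DataFrame({"log2fc": log2fc, "t": t, "p_value": p,
                        "is_differential": sig,
                        "direction": np.where(sig, np.where(log2fc > 0, "up", "down"),
                                              "none")},
                       index=matrix.mirna_ids)
    out.index.name = "mirna_id"
    return out
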