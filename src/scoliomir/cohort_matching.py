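"""1:1 case-control matching on age, sex and ethnicity.

With only three matching covariates, two of them categorical, exact
matching on the categoricals plus a nearest-age caliper dominates a
fitted propensity model: controls are matched exactly on sex and
ethnicity and greedily to the nearest age within the caliper.  Cases
are processed in sorted-id order, ties go to the smaller control id,
and no control is reused, so the matching is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Protocol, Sequence

__all__ = ["MatchedPair", "match_pairs"]


class _CovariateRecord(Protocol):
    subject_id: str
    age: int
    sex: str
    ethnicity: str


@dataclass(frozen=True)
class MatchedPair:
    """One matched case-control pair (identical sex and ethnicity)."""

    case_id: str
    control_id: str
    age_difference: float

    def __post_init__(self) -> None:
        if self.age_difference < 0:
            raise ValueError("age_difference cannot be negative")


def match_pairs(
    cases: Iterable[_CovariateRecord],
    controls: Iterable[_CovariateRecord],
    age_caliper: float = 1.0,
) -> tuple[list[MatchedPair], list[str]]:
    """Greedy 1:1 matching: exact on sex/ethnicity, nearest age in caliper.

    Returns the matched pairs and the ids of cases left unmatched.  Each
    control is used at most once.
    """
    if age_caliper < 0:
        raise ValueError("age caliper cannot be negative")
    case_list = sorted(cases, key=lambda r: str(r.subject_id))
    pool: dict[tuple[str, str], list[_CovariateRecord]] = {}
    for ctl in controls:
        pool.setdefault((ctl.sex, ctl.ethnicity), []).append(ctl)
    for group in pool.values():
        group.sort(key=lambda r: str(r.subject_id))

    pairs: list[MatchedPair] = []
    unmatched: list[str] = []
    for case in case_list:
        group = pool.get((case.sex, case.ethnicity), [])
        best = None
        best_key = None
        for ctl in group:
            diff = abs(float(ctl.age) - float(case.age))
            if diff > age_caliper:
                continue
            key = (diff, str(ctl.subject_id))
            if best_key is None or key < best_key:
                best, best_key = ctl, key
        if best is None:
            unmatched.append(str(case.subject_id))
        else:
            group.remove(best)
            pairs.append(MatchedPair(case_id=str(case.subject_id),
                                     control_id=str(best.subject_id),
                                     age_difference=best_key[0]))
    return pairs, unmatched
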