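"""Bundled published summary tables from the screening program.

These are the printed age x sex screening counts, the anthropometric
group summaries (n, mean, SD) and the screening-flow / categorical
counts the phase-1 statistics are recomputed from.  No patient-level
data is bundled; everything here is an aggregate a report would print.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .epi_screen import GroupSummary

__all__ = [
    "load_prevalence_by_age_sex",
    "load_anthropometric_summaries",
    "load_screening_flow",
    "bmi_contingency",
    "education_contingency",
]


def _data(name: str):
    return resources.files("scoliomir.data").joinpath(name)


def load_prevalence_by_age_sex() -> pd.DataFrame:
    """Age x sex stratum counts: columns age, sex, n_screened, n_positive."""
    with resources.as_file(_data("prevalence_by_age_sex.csv")) as path:
        return pd.read_csv(path)


def load_anthropometric_summaries() -> dict[str, dict[str, GroupSummary]]:
    """(variable -> group -> GroupSummary) for height/sitting height/weight."""
    with resources.as_file(_data("anthropometric_summaries.csv")) as path:
        df = pd.read_csv(path)
    out: dict[str, dict[str, GroupSummary]] = {}
    for row in df.itertuples():
        out.setdefault(row.variable, {})[row.group] = GroupSummary(
            n=int(row.n), mean=float(row.mean), sd=float(row.sd))
    return out


def load_screening_flow() -> dict:
    """Top-line screening counts (screened, referred, diagnosed, managed)."""
    with resources.as_file(_data("screening_flow.json")) as path:
        return json.loads(path.read_text())


def bmi_contingency(flow: dict | None = None) -> list[list[int]]:
    """2x2 BMI (>=18.5 vs <18.5) x group (IS vs normal) counts."""
    flow = flow or load_screening_flow()
    b = flow["bmi_counts"]
    return [[b["is"]["ge_18_5"], b["normal"]["ge_18_5"]],
            [b["is"]["lt_18_5"], b["normal"]["lt_18_5"]]]


def education_contingency(flow: dict | None = None) -> list[list[int]]:
    """2x3 group x education-stage counts (primary/junior/senior)."""
    flow = flow or load_screening_flow()
    e = flow["education_counts"]
    return [[e["is"]["primary"], e["is"]["junior"], e["is"]["senior"]],
            [e["normal"]["primary"], e["normal"]["junior"], e["normal"]["senior"]]]
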