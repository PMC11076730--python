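"""Synthetic screening population and case-control matching.

Simulates a scaled-down screening population under the published
stratum rates (10% of the published strata keeps this quick), checks
that the realized prevalence tracks the design, classifies positives
into management classes, tabulates curve morphology, and matches the
surgical-class cases 1:1 to healthy controls on age, sex and ethnicity.

Run: python analysis/02_synthetic_screening.py [seed]
"""

import sys
from pathlib import Path

from scoliomir.cohort_matching import match_pairs
from scoliomir.epi_screen import classify_management, curve_profile_table, prevalence_table
from scoliomir.io import write_pairs_csv, write_records_csv
from scoliomir.synthetic_data import default_population_spec, simulate_screening_population

OUT = Path("results/synthetic_screening")


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = default_population_spec(seed=seed, scale=0.1)
    records = simulate_screening_population(spec)
    write_records_csv(records, OUT / "screening_records.csv")
    table = prevalence_table(records)
    table.to_csv(OUT / "prevalence_table.tsv", sep="\t", index=False)
    total = table[table["stratum"] == "total"].iloc[0]
    print(f"simulated {len(records):,} students (seed {seed}); realized prevalence "
          f"{total['rate']:.2f}% (design 1.10%), male {total['male_rate']:.2f}%, "
          f"female {total['female_rate']:.2f}%")

    positives = [r for r in records if r.is_positive]
    classes = {c: 0 for c in ("observation", "rehabilitation_or_brace", "surgery")}
    for r in positives:
        classes[classify_management(r.cobb)] += 1
    n = len(positives)
    print("management mix:", {k: f"{v} ({100*v/n:.1f}%)" for k, v in classes.items()})
    profile = curve_profile_table(positives)
    for name in ("severity_by_pattern", "severity_by_region", "severity_by_convexity"):
        profile[name].to_csv(OUT / f"{name}.tsv", sep="\t")
    print("severity counts:", profile["severity_counts"].to_dict())

    cases = [r for r in positives if classify_management(r.cobb) == "surgery"]
    controls = [r for r in records if r.cobb is None]
    pairs, unmatched = match_pairs(cases, controls, age_caliper=1.0)
    write_pairs_csv(pairs, OUT / "matched_pairs.csv")
    print(f"matched {len(pairs)}/{len(cases)} surgical cases to controls "
          f"({len(unmatched)} unmatched); max age gap "
          f"{max((p.age_difference for p in pairs), default=0):.0f} y")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
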