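"""Matched-pair differential screen and candidate selection.

Runs the per-pair Fisher + fold-change screen on 6 simulated matched
pairs at the full design depth (300 miRNAs, 10^6 reads/sample, count
level), intersects the per-pair differential sets, applies the
direction-consistency filter, selects the sequencing reference miRNA,
and quantifies recovery of the planted biomarker set over 100 seeds.

Run: python analysis/04_paired_biomarker_screen.py [seed]
"""

import json
import sys
from pathlib import Path

from scoliomir.paired_screen import (group_differential, pair_differential,
                                     select_reference_mirna, shared_candidates)
from scoliomir.synthetic_data import default_mirna_spec, simulate_pair_counts

OUT = Path("results/paired_screen")
N_REPLICATES = 100


def screen_once(seed: int, n_planted: int = 5, p_mode: str = "gated"):
    spec = default_mirna_spec(seed=seed, n_planted=n_planted)
    matrix, truth = simulate_pair_counts(spec)
    results = [pair_differential(matrix, (f"AIS_{k}", f"CTRL_{k}"), p_mode=p_mode)
               for k in range(1, spec.n_pairs + 1)]
    return spec, matrix, truth, results


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec, matrix, truth, results = screen_once(seed, p_mode="all")
    candidates = shared_candidates(results)
    planted = sorted(truth.index[truth.planted])
    print(f"seed {seed}: planted {planted}")
    print(f"shared across all 6 pairs: {candidates.shared_ids}")
    print(f"direction-consistent:      {candidates.consistent_ids}")
    candidates.upset_counts.to_csv(OUT / "upset_counts.tsv", sep="\t", index=False)
    candidates.directions.to_csv(OUT / "shared_directions.tsv", sep="\t")

    case_ids = [f"AIS_{k}" for k in range(1, 7)]
    control_ids = [f"CTRL_{k}" for k in range(1, 7)]
    ref, report = select_reference_mirna(matrix, case_ids, control_ids)
    report.to_csv(OUT / "reference_report.tsv", sep="\t")
    print(f"selected reference miRNA: {ref} "
          f"(designated stable reference: {spec.reference_mirna_id})")
    pooled = group_differential(matrix, case_ids, control_ids)
    n_up = int((pooled["direction"] == "up").sum())
    n_down = int((pooled["direction"] == "down").sum())
    print(f"pooled 6-vs-6 screen (volcano stand-in): {n_up} up, {n_down} down")

    exact = misses = extras = 0
    for rep in range(N_REPLICATES):
        _, _, truth_r, results_r = screen_once(seed + rep)
        shared = set(shared_candidates(results_r, with_upset=False).shared_ids)
        truth_set = set(truth_r.index[truth_r.planted])
        exact += shared == truth_set
        misses += len(truth_set - shared)
        extras += len(shared - truth_set)
    null_empty = 0
    for rep in range(N_REPLICATES):
        _, _, _, results_r = screen_once(10_000 + seed + rep, n_planted=0)
        null_empty += not shared_candidates(results_r, with_upset=False).shared_ids
    summary = {
        "planted": planted, "shared": candidates.shared_ids,
        "consistent": candidates.consistent_ids, "reference": ref,
        "pooled_up": n_up, "pooled_down": n_down,
        "exact_recovery": exact, "n_replicates": N_REPLICATES,
        "missed_calls": misses, "extra_calls": extras, "null_empty": null_empty,
    }
    (OUT / "summary.json").write_text(json.dumps(summary, indent=2))
    print(f"exact planted-set recovery: {exact}/{N_REPLICATES} replicates "
          f"({misses} missed and {extras} extra calls in total); the per-pair "
          f"log2FC noise floor at dispersion 0.05 is ~0.46, so a 4-fold effect "
          f"clears the 2-fold call threshold by only ~2.2 SD per pair")
    print(f"null design: shared set empty in {null_empty}/{N_REPLICATES} replicates")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
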