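"""Phase-1 epidemiology from the published summary tables.

Recomputes, from the bundled age x sex stratum counts and printed group
summaries, the prevalence table with per-age sex-difference chi-squares,
the anthropometric Welch t statistics, the BMI and education-stage
chi-squares, and the screening-flow shares (referral rate, management
mix).  Writes results/epidemiology/ as TSV + JSON.

Run: python analysis/01_published_epidemiology.py
"""

import json
from pathlib import Path

from scoliomir.datasets import (bmi_contingency, education_contingency,
                                load_anthropometric_summaries,
                                load_prevalence_by_age_sex, load_screening_flow)
from scoliomir.epi_screen import pearson_chi_square, prevalence_table, welch_t_from_summary

OUT = Path("results/epidemiology")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = prevalence_table(load_prevalence_by_age_sex())
    table.to_csv(OUT / "prevalence_by_age_sex.tsv", sep="\t", index=False)
    total = table[table["stratum"] == "total"].iloc[0]
    print(f"screened {int(total['n_screened']):,}: overall IS prevalence "
          f"{total['rate']:.2f}% (male {total['male_rate']:.2f}%, "
          f"female {total['female_rate']:.2f}%), "
          f"sex chi2 {total['chi_square']:.2f}")
    peak = table.iloc[:-1].sort_values("rate").iloc[-1]
    print(f"peak prevalence at age {peak['stratum']}: {peak['rate']:.2f}% "
          f"(chi2 {peak['chi_square']:.3f})")

    report = {}
    for variable, groups in load_anthropometric_summaries().items():
        res = welch_t_from_summary(groups["is"], groups["normal"])
        report[variable] = {"t": res.t, "abs_t": abs(res.t), "df": res.df,
                            "p_value": res.p_value}
        print(f"{variable}: |t| = {abs(res.t):.3f}, p = {res.p_value:.4f}")
    for name, tab in (("bmi", bmi_contingency()), ("education", education_contingency())):
        res = pearson_chi_square(tab)
        report[name] = {"chi_square": res.statistic, "df": res.df, "p_value": res.p_value}
        print(f"{name}: chi2 = {res.statistic:.4f} (df {res.df}), p = {res.p_value:.4g}")

    flow = load_screening_flow()
    shares = {
        "referral_rate_pct": 100 * flow["n_referred"] / flow["n_screened"],
        "is_prevalence_pct": 100 * flow["n_is_diagnosed"] / flow["n_screened"],
        "observation_share_pct": 100 * flow["n_observation"] / flow["n_is_diagnosed"],
        "rehabilitation_share_pct": 100 * flow["n_rehabilitation_or_brace"] / flow["n_is_diagnosed"],
        "surgery_share_pct": 100 * flow["n_surgery"] / flow["n_is_diagnosed"],
    }
    report["screening_flow"] = shares
    print(f"referral rate {shares['referral_rate_pct']:.2f}%; management mix "
          f"observation {shares['observation_share_pct']:.2f}% / rehab "
          f"{shares['rehabilitation_share_pct']:.2f}% / surgery "
          f"{shares['surgery_share_pct']:.2f}%")
    (OUT / "summary_statistics.json").write_text(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
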