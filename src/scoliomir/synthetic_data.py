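"""Synthetic-data backbone for the screening and biomarker pipeline.

Three generators, all driven by a single integer seed each:

* an age/sex-structured school screening population with a specified
  per-stratum scoliosis prevalence, a referral false-positive stream
  (ATR >= 5 but Cobb < 10), Cobb angles for confirmed positives, curve
  morphology descriptors and group-specific anthropometrics;
* matched case-control pairs of negative-binomial miRNA counts with
  planted >= 2-fold biomarkers and, on top of the counts, error-free
  FASTQ reads carrying a 3' adapter and a contaminant read stream;
* qPCR Ct tables in triplicate with a group-stable reference miRNA and
  case-shifted targets.

The defaults encode the study conditions the downstream stages assume:
the default screening strata reproduce the published age x sex counts
and rates; the default molecular design is 6 matched pairs, 300 miRNAs,
10^6 reads per sample, negative-binomial dispersion 0.05 and 5 planted
biomarkers at |log2 effect| = 2; the default qPCR design is 23 cases
vs 23 controls in triplicate.  Distributional forms (negative binomial
for counts, log-normal Cobb excess, normal Ct noise) are documented
stand-ins: the screening program published only observed frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import load_prevalence_by_age_sex
from .epi_screen import (CONVEXITIES, CURVE_REGIONS, ScreeningRecord)
from .smallrna_quant import CountMatrix, ReadRecord, ReferenceCatalog, trim_adapter

__all__ = [
    "PopulationSpec",
    "MiRNASimSpec",
    "QpcrSimSpec",
    "QpcrSample",
    "default_population_spec",
    "default_mirna_spec",
    "default_qpcr_spec",
    "simulate_screening_population",
    "simulate_pair_counts",
    "random_catalog",
    "simulate_reads",
    "simulate_qpcr",
    "TRUSEQ_SMALL_RNA_ADAPTER",
]

#: Illumina TruSeq small-RNA 3' adapter prefix (the library chemistry the
#: sequenced cohort used).
TRUSEQ_SMALL_RNA_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

_ETHNICITIES = ("han", "yi", "bai", "dai", "hani", "other")
_ETHNICITY_PROBS = (0.62, 0.12, 0.08, 0.06, 0.06, 0.06)


def _education_stage(age: int) -> str:
    if age <= 12:
        return "primary"
    if age <= 15:
        return "junior"
    return "senior"


@dataclass
class PopulationSpec:
    """Design of a synthetic screening population.

    ``stratum_counts``/``prevalence`` map (age, sex) to the number
    screened and the scoliosis probability.  ``cobb_log_location`` /
    ``cobb_log_scale`` parameterize the Cobb angle of positives as
    10 + LogNormal(location, scale) degrees; the defaults put ~49% of
    positives in [10,20) and ~13% at >= 40, matching the published
    management-class mix.  Curve morphology is categorical: probability
    of a double major curve, region probabilities for single curves, and
    the probability of right convexity.
    """

    stratum_counts: dict[tuple[int, str], int]
    prevalence: dict[tuple[int, str], float]
    referral_false_positive_rate: float = 0.0449
    cobb_log_location: float = 2.317
    cobb_log_scale: float = 0.963
    p_double_curve: float = 0.55
    region_probs: dict[str, float] = field(
        default_factory=lambda: {"thoracic": 0.30, "thoracolumbar": 0.55, "lumbar": 0.15})
    p_right_convex: float = 0.55
    anthropometrics: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            "is": {"height_cm": (156.53, 14.45), "sitting_height_cm": (82.48, 7.78),
                   "weight_kg": (46.69, 10.91)},
            "normal": {"height_cm": (156.84, 14.95), "sitting_height_cm": (83.23, 7.57),
                       "weight_kg": (47.35, 10.33)},
        })
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.stratum_counts:
            raise ValueError("at least one stratum is required")
        for key, n in self.stratum_counts.items():
            if n <= 0:
                raise ValueError(f"stratum {key} must have a positive count")
            if key not in self.prevalence:
                raise ValueError(f"stratum {key} has no prevalence")
        for key, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {key} outside [0,1]")
        if not 0.0 <= self.referral_false_positive_rate <= 1.0:
            raise ValueError("referral false-positive rate outside [0,1]")
        if not 0.0 <= self.p_double_curve <= 1.0 or not 0.0 <= self.p_right_convex <= 1.0:
            raise ValueError("curve-pattern probabilities outside [0,1]")
        if set(self.region_probs) != set(CURVE_REGIONS):
            raise ValueError(f"region_probs must cover {CURVE_REGIONS}")
        if any(p < 0 for p in self.region_probs.values()):
            raise ValueError("region probabilities must be non-negative")
        if not math.isclose(sum(self.region_probs.values()), 1.0, abs_tol=1e-9):
            raise ValueError("region probabilities must sum to 1")
        if self.cobb_log_scale <= 0:
            raise ValueError("Cobb log-scale must be positive")


def default_population_spec(seed: int = 0, scale: float = 1.0) -> PopulationSpec:
    """Published age x sex strata (optionally scaled down) and rates."""
    table = load_prevalence_by_age_sex()
    counts: dict[tuple[int, str], int] = {}
    prev: dict[tuple[int, str], float] = {}
    for row in table.itertuples():
        key = (int(row.age), row.sex)
        counts[key] = max(1, int(round(row.n_screened * scale)))
        prev[key] = row.n_positive / row.n_screened
    return PopulationSpec(stratum_counts=counts, prevalence=prev, seed=seed)


def simulate_screening_population(spec: PopulationSpec) -> list[ScreeningRecord]:
    """Draw a full screening population under the spec.

    Per stratum the number of true positives is Binomial(n, p); positives
    carry Cobb >= 10 and curve descriptors; a referral false-positive
    stream carries ATR >= 5 with Cobb < 10; everyone else is a negative
    screen with no Cobb.  Total record count equals the summed strata.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[ScreeningRecord] = []
    serial = 0
    regions = list(spec.region_probs)
    region_p = np.array([spec.region_probs[r] for r in regions])
    for (age, sex), n in sorted(spec.stratum_counts.items()):
        p = spec.prevalence[(age, sex)]
        n_pos = rng.binomial(n, p)
        n_fp = rng.binomial(n - n_pos, spec.referral_false_positive_rate)
        status = (["positive"] * n_pos + ["false_positive"] * n_fp
                  + ["negative"] * (n - n_pos - n_fp))
        for st in status:
            serial += 1
            sid = f"S{serial:07d}"
            ethnicity = _ETHNICITIES[rng.choice(len(_ETHNICITIES), p=_ETHNICITY_PROBS)]
            group = "is" if st == "positive" else "normal"
            anthro = spec.anthropometrics[group]
            height = rng.normal(*anthro["height_cm"])
            sitting = rng.normal(*anthro["sitting_height_cm"])
            weight = rng.normal(*anthro["weight_kg"])
            height = max(height, 100.0)
            weight = max(weight, 15.0)
            bmi = weight / (height / 100.0) ** 2
            kwargs = dict(
                subject_id=sid, age=age, sex=sex, ethnicity=ethnicity,
                region="yunnan", education_stage=_education_stage(age),
                height_cm=round(height, 1), sitting_height_cm=round(sitting, 1),
                weight_kg=round(weight, 1), bmi=round(bmi, 2),
            )
            if st == "negative":
                records.append(ScreeningRecord(atr=None, cobb=None, **kwargs))
                continue
            atr = 5.0 + rng.exponential(2.0)
            if st == "false_positive":
                records.append(ScreeningRecord(atr=round(atr, 1),
                                               cobb=round(rng.uniform(0.0, 9.9), 1),
                                               **kwargs))
                continue
            cobb = 10.0 + rng.lognormal(spec.cobb_log_location, spec.cobb_log_scale)
            pattern = "double" if rng.random() < spec.p_double_curve else "single"
            region = regions[rng.choice(len(regions), p=region_p)] if pattern == "single" else None
            convexity = "right" if rng.random() < spec.p_right_convex else "left"
            records.append(ScreeningRecord(
                atr=round(atr, 1), cobb=round(cobb, 1), curve_pattern=pattern,
                curve_region=region, convexity=convexity, **kwargs))
    return records


@dataclass
class MiRNASimSpec:
    """Design of the matched-pair miRNA count/read simulation.

    Counts are negative binomial in the mean/dispersion parameterization
    (variance = m + dispersion * m^2).  ``planted`` maps miRNA ids to
    log2 effects (|effect| >= 1, i.e. at least 2-fold) applied to the
    case member of every pair; the reference miRNA carries effect 0 by
    construction and a smaller dispersion (``reference_dispersion``),
    emulating a biologically stable housekeeping-like species.
    ``baseline_abundance`` gives per-miRNA relative abundances (any
    positive scale; normalized internally).
    """

    mirna_ids: list[str]
    baseline_abundance: np.ndarray
    planted: dict[str, float] = field(default_factory=dict)
    reference_mirna_id: str | None = None
    n_pairs: int = 6
    library_size: int = 1_000_000
    nb_dispersion: float = 0.05
    reference_dispersion: float = 0.005
    adapter: str = TRUSEQ_SMALL_RNA_ADAPTER
    contaminant_fraction: float = 0.1
    read_length: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        self.baseline_abundance = np.asarray(self.baseline_abundance, dtype=float)
        if len(self.mirna_ids) != len(self.baseline_abundance):
            raise ValueError("one baseline abundance per miRNA id is required")
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise ValueError("miRNA ids must be unique")
        if (self.baseline_abundance <= 0).any():
            raise ValueError("baseline abundances must be positive")
        if self.n_pairs <= 0 or self.library_size <= 0:
            raise ValueError("n_pairs and library_size must be positive")
        if self.nb_dispersion <= 0 or self.reference_dispersion <= 0:
            raise ValueError("negative-binomial dispersion must be positive")
        if not 0.0 <= self.contaminant_fraction < 1.0:
            raise ValueError("contaminant fraction must be in [0,1)")
        known = set(self.mirna_ids)
        for mid, eff in self.planted.items():
            if mid not in known:
                raise ValueError(f"planted id {mid} not in catalog")
            if abs(eff) < 1.0:
                raise ValueError(f"planted effect for {mid} below the 2-fold floor")
        if self.reference_mirna_id is not None:
            if self.reference_mirna_id not in known:
                raise ValueError("reference miRNA id not in catalog")
            if self.reference_mirna_id in self.planted:
                raise ValueError("reference miRNA cannot carry a planted effect")

    @property
    def n_mirna(self) -> int:
        return len(self.mirna_ids)


def default_mirna_spec(seed: int = 0, n_mirna: int = 300, n_pairs: int = 6,
                       library_size: int = 1_000_000, nb_dispersion: float = 0.05,
                       n_planted: int = 5, planted_abs_log2fc: float = 2.0,
                       contaminant_fraction: float = 0.1) -> MiRNASimSpec:
    """Default molecular design: 6 pairs, 300 miRNAs, 5 planted at 4-fold.

    Baselines are log-normal across the catalog.  The most abundant
    miRNA is designated the reference (effect 0); the planted biomarkers
    take the next abundance ranks with alternating effect signs, which
    keeps each per-miRNA direction identical across pairs.
    """
    if n_mirna <= n_planted:
        raise ValueError("need n_mirna > n_planted (plus one reference)")
    rng = np.random.default_rng(seed)
    ids = [f"syn-mir-{i + 1:04d}" for i in range(n_mirna)]
    baseline = rng.lognormal(mean=4.0, sigma=1.5, size=n_mirna)
    order = np.argsort(baseline)[::-1]
    reference = ids[order[0]]
    planted: dict[str, float] = {}
    for k in range(n_planted):
        sign = 1.0 if k % 2 == 0 else -1.0
        planted[ids[order[1 + k]]] = sign * planted_abs_log2fc
    return MiRNASimSpec(mirna_ids=ids, baseline_abundance=baseline, planted=planted,
                        reference_mirna_id=reference, n_pairs=n_pairs,
                        library_size=library_size, nb_dispersion=nb_dispersion,
                        contaminant_fraction=contaminant_fraction, seed=seed)


def simulate_pair_counts(spec: MiRNASimSpec) -> tuple[CountMatrix, pd.DataFrame]:
    """Negative-binomial counts for every pair, plus the planted truth.

    Control counts are NB with mean = baseline share x library size;
    case counts use baseline x 2^effect for planted miRNAs.  Sample ids
    are ``AIS_k`` / ``CTRL_k`` for pair k.  The truth table has one row
    per miRNA with its planted log2 effect (0 when unplanted).
    """
    rng = np.random.default_rng(spec.seed)
    share = spec.baseline_abundance / spec.baseline_abundance.sum()
    base_mean = share * spec.library_size
    effect = np.array([spec.planted.get(mid, 0.0) for mid in spec.mirna_ids])
    case_mean = base_mean * np.exp2(effect)
    # the reference miRNA is biologically stable: smaller dispersion
    disp = np.full(spec.n_mirna, spec.nb_dispersion)
    if spec.reference_mirna_id is not None:
        disp[spec.mirna_ids.index(spec.reference_mirna_id)] = spec.reference_dispersion
    r = 1.0 / disp

    def draw(mean: np.ndarray) -> np.ndarray:
        return rng.negative_binomial(r, r / (r + mean))

    columns: dict[str, np.ndarray] = {}
    for k in range(1, spec.n_pairs + 1):
        columns[f"AIS_{k}"] = draw(case_mean)
        columns[f"CTRL_{k}"] = draw(base_mean)
    raw = pd.DataFrame(columns, index=spec.mirna_ids)
    matrix = CountMatrix(raw, raw.sum(axis=0))
    truth = pd.DataFrame({"mirna_id": spec.mirna_ids, "log2_effect": effect,
                          "planted": effect != 0.0}).set_index("mirna_id")
    return matrix, truth


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def random_catalog(spec: MiRNASimSpec, n_contaminants_per_set: int = 20,
                   catalog_seed: int | None = None) -> ReferenceCatalog:
    """Random mature sequences (mode 22 nt) plus contaminant sets.

    Sequences are rejection-sampled so that a synthetic read (mature +
    adapter) trims back to exactly the mature sequence and no mature
    sequence collides with a contaminant: this guarantees the exact
    count round trip through the cascade at mismatch tolerance 0.
    """
    rng = np.random.default_rng(spec.seed if catalog_seed is None else catalog_seed)
    lengths = (20, 21, 22, 23, 24)
    length_p = np.array([0.10, 0.25, 0.35, 0.20, 0.10])

    def _clean_smallrna(existing: set[str]) -> str:
        while True:
            seq = _random_dna(rng, int(rng.choice(lengths, p=length_p)))
            if seq in existing:
                continue
            probe = ReadRecord("probe", seq + spec.adapter, "I" * (len(seq) + len(spec.adapter)))
            trimmed = trim_adapter(probe, spec.adapter) if spec.adapter else probe
            if trimmed is not None and trimmed.sequence == seq:
                return seq

    seen: set[str] = set()
    mature: dict[str, str] = {}
    for mid in spec.mirna_ids:
        seq = _clean_smallrna(seen)
        seen.add(seq)
        mature[mid] = seq
    mature_seqs = list(mature.values())
    contaminants: dict[str, list[str]] = {}
    for name in ("mrna", "rfam", "repbase"):
        seqs = []
        while len(seqs) < n_contaminants_per_set:
            seq = _clean_smallrna(seen)
            # a mature sequence inside a contaminant would be filtered away
            # and break the exact count round trip
            if any(m in seq for m in mature_seqs):
                continue
            seen.add(seq)
            seqs.append(seq)
        contaminants[name] = seqs
    return ReferenceCatalog(mature_mirnas=mature, contaminant_sets=contaminants)


def simulate_reads(spec: MiRNASimSpec, counts: CountMatrix,
                   catalog: ReferenceCatalog) -> dict[str, list[ReadRecord]]:
    """Error-free FASTQ-style reads realizing a count matrix.

    Every counted miRNA copy emits mature sequence + 3' adapter, padded
    with A to the platform read length; contaminant reads are mixed in
    so they make up ``contaminant_fraction`` of each sample's raw reads.
    Running the cascade at mismatch 0 reproduces ``counts`` exactly.
    """
    for mid in counts.mirna_ids:
        if mid not in catalog.mature_mirnas:
            raise ValueError(f"counted miRNA {mid} missing from catalog")
        if not 18 <= len(catalog.mature_mirnas[mid]) <= 26:
            raise ValueError(f"catalog sequence for {mid} outside 18-26 nt")
    rng = np.random.default_rng(spec.seed + 1)
    cont_pool = [s for _, seqs in catalog.ordered_contaminant_sets() for s in seqs]
    if spec.contaminant_fraction > 0 and not cont_pool:
        raise ValueError("contaminant_fraction > 0 needs contaminant sequences")

    def synth(seq: str) -> tuple[str, str]:
        full = seq + spec.adapter
        if spec.adapter and spec.read_length > 0:
            full = (full + "A" * spec.read_length)[:max(spec.read_length, len(seq))]
        return full, "I" * len(full)

    out: dict[str, list[ReadRecord]] = {}
    for sample in counts.sample_ids:
        col = counts.raw[sample]
        n_mirna_reads = int(col.sum())
        f = spec.contaminant_fraction
        n_cont = int(round(n_mirna_reads * f / (1.0 - f))) if f > 0 else 0
        reads: list[ReadRecord] = []
        serial = 0
        for mid, k in col.items():
            seq = catalog.mature_mirnas[mid]
            for _ in range(int(k)):
                serial += 1
                s, q = synth(seq)
                reads.append(ReadRecord(f"{sample}:{serial:08d}", s, q))
        for _ in range(n_cont):
            serial += 1
            seq = cont_pool[rng.integers(0, len(cont_pool))]
            s, q = synth(seq)
            reads.append(ReadRecord(f"{sample}:{serial:08d}", s, q))
        perm = rng.permutation(len(reads))
        out[sample] = [reads[i] for i in perm]
    return out


@dataclass
class QpcrSample:
    """One subject's qPCR plate: Ct triplicates per target + reference."""

    subject_id: str
    group: str
    targets: dict[str, tuple[float, float, float]]
    reference: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.group not in ("case", "control"):
            raise ValueError("group must be 'case' or 'control'")
        for name, trip in list(self.targets.items()) + [("reference", self.reference)]:
            if len(trip) != 3:
                raise ValueError(f"{name}: Ct measurements must be triplicates")
            if any(ct <= 0 for ct in trip):
                raise ValueError(f"{name}: Ct values must be positive")


@dataclass
class QpcrSimSpec:
    """Design of the qPCR validation simulation.

    ``delta_ct_effects`` maps target name to the Ct shift applied to
    cases (negative = higher case Ct = lower expression).  Between-
    subject biology enters as N(0, between_subject_sd) on each subject's
    target delta-Ct; triplicate wells jitter with triplicate_sd; a
    per-subject plate offset shifts target and reference Ct together
    (and cancels in delta-Ct).
    """

    delta_ct_effects: dict[str, float]
    n_per_group: int = 23
    triplicate_sd: float = 0.15
    between_subject_sd: float = 1.0
    reference_ct_mean: float = 20.0
    target_ct_mean: float = 25.0
    subject_offset_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.triplicate_sd <= 0 or self.between_subject_sd <= 0:
            raise ValueError("noise SDs must be positive")
        if not self.delta_ct_effects:
            raise ValueError("at least one target is required")


def default_qpcr_spec(seed: int = 0) -> QpcrSimSpec:
    """Validation-arm defaults: 23 + 23 subjects, six candidate targets.

    Three targets are down-regulated in cases (negative effects sized to
    put the resulting AUCs in the high-0.7/low-0.8 range at 1-cycle
    between-subject SD); three are null.
    """
    return QpcrSimSpec(
        delta_ct_effects={
            "hsa-miR-27a-5p": -1.05,
            "hsa-miR-539-5p": -1.40,
            "hsa-miR-1246": -1.04,
            "hsa-miR-20a-5p": 0.0,
            "hsa-miR-20b-5p": 0.0,
            "hsa-miR-454-3p": 0.0,
        },
        seed=seed,
    )


def simulate_qpcr(spec: QpcrSimSpec) -> list[QpcrSample]:
    """Draw triplicate Ct tables for both groups under the spec."""
    rng = np.random.default_rng(spec.seed)
    samples: list[QpcrSample] = []
    for group, prefix in (("case", "AIS"), ("control", "CTRL")):
        for j in range(1, spec.n_per_group + 1):
            offset = rng.normal(0.0, spec.subject_offset_sd)
            ref_mean = spec.reference_ct_mean + offset
            reference = tuple(ref_mean + rng.normal(0.0, spec.triplicate_sd, 3))
            targets: dict[str, tuple[float, float, float]] = {}
            for name, eff in spec.delta_ct_effects.items():
                mean = (spec.target_ct_mean + offset
                        + rng.normal(0.0, spec.between_subject_sd)
                        - (eff if group == "case" else 0.0))
                targets[name] = tuple(mean + rng.normal(0.0, spec.triplicate_sd, 3))
            samples.append(QpcrSample(subject_id=f"{prefix}_{j:02d}", group=group,
                                      targets=targets, reference=reference))
    return samples
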