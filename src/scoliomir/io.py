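"""Readers and writers for the pipeline's on-disk formats.

FASTQ (4-line, Phred+33) and FASTA go through Biopython; tabular data
(count matrices, Ct tables, screening records, pair lists) are plain
CSV/TSV via pandas.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cohort_matching import MatchedPair
from .epi_screen import ScreeningRecord
from .smallrna_quant import ReadRecord, ReferenceCatalog
from .synthetic_data import QpcrSample

__all__ = [
    "write_fastq", "read_fastq", "write_fasta", "read_fasta",
    "write_catalog", "read_catalog",
    "write_records_csv", "read_records_csv",
    "write_pairs_csv", "read_pairs_csv",
    "write_ct_csv", "read_ct_csv",
]


def write_fastq(reads: Iterable[ReadRecord], path) -> int:
    n = 0
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{read.quality}\n")
            n += 1
    return n


def read_fastq(path) -> list[ReadRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append(ReadRecord(rec.id, str(rec.seq).upper(), qual))
    return out


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_catalog(catalog: ReferenceCatalog, directory) -> dict[str, Path]:
    """Write mature + contaminant FASTA files; returns name -> path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {"mature": directory / "mature_mirnas.fa"}
    write_fasta(catalog.mature_mirnas, paths["mature"])
    for name, seqs in catalog.contaminant_sets.items():
        paths[name] = directory / f"contaminants_{name}.fa"
        write_fasta({f"{name}_{i + 1:04d}": s for i, s in enumerate(seqs)}, paths[name])
    return paths


def read_catalog(mature_path, contaminant_paths: dict[str, str] | None = None) -> ReferenceCatalog:
    contaminants = {name: list(read_fasta(p).values())
                    for name, p in (contaminant_paths or {}).items()}
    return ReferenceCatalog(mature_mirnas=read_fasta(mature_path),
                            contaminant_sets=contaminants)


def write_records_csv(records: Sequence[ScreeningRecord], path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(path, index=False)


def read_records_csv(path) -> list[ScreeningRecord]:
    df = pd.read_csv(path)
    fields = {f.name for f in dataclasses.fields(ScreeningRecord)}
    out = []
    for row in df.to_dict("records"):
        clean = {k: (None if pd.isna(v) else v) for k, v in row.items() if k in fields}
        clean["age"] = int(clean["age"])
        out.append(ScreeningRecord(**clean))
    return out


def write_pairs_csv(pairs: Sequence[MatchedPair], path) -> None:
    pd.DataFrame([dataclasses.asdict(p) for p in pairs]).to_csv(path, index=False)


def read_pairs_csv(path) -> list[MatchedPair]:
    df = pd.read_csv(path)
    return [MatchedPair(str(r.case_id), str(r.control_id), float(r.age_difference))
            for r in df.itertuples()]


def write_ct_csv(samples: Sequence[QpcrSample], path) -> None:
    """Tidy Ct table: subject_id, group, target, ct1..ct3, ref_ct1..ref_ct3."""
    rows = []
    for s in samples:
        for target, trip in s.targets.items():
            rows.append({"subject_id": s.subject_id, "group": s.group, "target": target,
                         "ct1": trip[0], "ct2": trip[1], "ct3": trip[2],
                         "ref_ct1": s.reference[0], "ref_ct2": s.reference[1],
                         "ref_ct3": s.reference[2]})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ct_csv(path) -> list[QpcrSample]:
    df = pd.read_csv(path)
    samples = []
    for (sid, group), grp in df.groupby(["subject_id", "group"], sort=False):
        targets = {r.target: (r.ct1, r.ct2, r.ct3) for r in grp.itertuples()}
        first = grp.iloc[0]
        samples.append(QpcrSample(subject_id=str(sid), group=str(group), targets=targets,
                                  reference=(first.ref_ct1, first.ref_ct2, first.ref_ct3)))
    return samples
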