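"""Per-intron PSI and the gene-level ISOR splicing statistic.

PSI (per cent spliced in) for one intron is the fraction of junction-spanning
reads among junction plus intron-retention reads.  ISOR (isoform spliced-out
ratio) summarizes splicing at the gene level: the spliced-out length —
each intron's length weighted by its observed spliced fraction — divided by
the exonic length.  A fully spliced two-intron gene with long introns can
have ISOR > 1; that is by construction (spliced-out length is not bounded by
exon length).  A full-length-read estimator provides an independent route to
the same quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import GeneModel


@dataclass
class JunctionEvidence:
    gene_id: str
    intron_id: str
    intron_length: int
    junction_reads: int
    retention_reads: int

    def __post_init__(self) -> None:
        if self.intron_length <= 0:
            raise ValueError("intron_length must be positive")
        if self.junction_reads < 0 or self.retention_reads < 0:
            raise ValueError("read counts must be non-negative")


@dataclass
class IsorRecord:
    gene_id: str
    isor: float
    exonic_length: int
    covered: bool


def compute_psi(ev: JunctionEvidence) -> float | None:
    """Fraction spliced; None when the intron has no evidence at all."""
    total = ev.junction_reads + ev.retention_reads
    if total == 0:
        return None
    return ev.junction_reads / total


def compute_isor(model: GeneModel, evidence: list[JunctionEvidence]) -> IsorRecord:
    """Length-weighted PSI over covered introns, per exonic kilobase of gene.

    Introns with zero evidence are skipped (never imputed as unspliced);
    a gene with no covered intron gets covered=False and ISOR 0.
    """
    exonic_length = model.exonic_length
    by_id = {ev.intron_id: ev for ev in evidence if ev.gene_id == model.gene_id}
    spliced_out = 0.0
    any_covered = False
    for iid in model.intron_ids():
        ev = by_id.get(iid)
        if ev is None:
            continue
        psi = compute_psi(ev)
        if psi is None:
            continue
        any_covered = True
        spliced_out += ev.intron_length * psi
    if not any_covered:
        return IsorRecord(model.gene_id, 0.0, exonic_length, False)
    return IsorRecord(model.gene_id, spliced_out / exonic_length, exonic_length, True)


def isor_from_fulllength(transcript_reads: pd.DataFrame, model: GeneModel) -> IsorRecord:
    """ISOR estimated directly from full-length transcript structures.

    ``transcript_reads`` needs columns read_id, gene_id, retained_introns
    (comma-separated intron ids; empty string = fully spliced).  Each read
    contributes the total length of the introns it spliced out; ISOR is the
    mean over reads divided by exonic length.  Equals the junction-read
    estimator when per-intron retention is independent and noise-free.
    """
    intron_len = {
        iid: e - s
        for iid, (s, e) in zip(model.intron_ids(), model.introns_transcript_order())
    }
    total_intron = sum(intron_len.values())
    reads = transcript_reads[transcript_reads["gene_id"] == model.gene_id]
    if len(reads) == 0:
        return IsorRecord(model.gene_id, 0.0, model.exonic_length, False)
    spliced = []
    for retained in reads["retained_introns"]:
        ids = [r for r in str(retained).split(",") if r] if not pd.isna(retained) else []
        kept = sum(intron_len[i] for i in ids)
        spliced.append(total_intron - kept)
    isor = (sum(spliced) / len(spliced)) / model.exonic_length
    return IsorRecord(model.gene_id, isor, model.exonic_length, True)


def isor_table(models: list[GeneModel], junctions: pd.DataFrame) -> pd.DataFrame:
    """ISOR per gene from a junction table (gene_id, intron_id,
    intron_length, junction_reads, retention_reads)."""
    evidence = [
        JunctionEvidence(
            r.gene_id, r.intron_id, int(r.intron_length),
            int(r.junction_reads), int(r.retention_reads),
        )
        for r in junctions.itertuples()
    ]
    rows = []
    for m in models:
        rec = compute_isor(m, evidence)
        rows.append(
            {"gene_id": rec.gene_id, "isor": rec.isor,
             "exonic_length": rec.exonic_length, "covered": rec.covered}
        )
    return pd.DataFrame(rows)
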