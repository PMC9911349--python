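"""Readers and writers for the standard formats the pipeline touches.

One coordinate convention rules the package: 0-based, half-open intervals,
everywhere in memory.  GTF (1-based, inclusive) and VCF (1-based) are
converted at the I/O boundary and nowhere else.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, TextIO

import pysam

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class GtfParseError(ValueError):
    pass


@dataclass
class GeneModel:
    """Stranded multi-exon gene structure.

    ``exons`` are 0-based half-open intervals on the genome, sorted by start
    and non-overlapping.  Multi-transcript genes are collapsed to the union
    of their exons: every gene-level metric in the package (N/C ratio, ISOR,
    U1 density) is defined on that union.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    biotype: str = "coding"
    species: str = ""

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        exons = sorted((int(s), int(e)) for s, e in self.exons)
        for s, e in exons:
            if e <= s:
                raise ValueError(f"empty exon ({s}, {e}) in {self.gene_id}")
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in {self.gene_id}")
        self.exons = exons

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def genic_length(self) -> int:
        s, e = self.span
        return e - s

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, genomic order, 0-based half-open."""
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    @property
    def intronic_length(self) -> int:
        return sum(e - s for s, e in self.introns)

    def intron_ids(self) -> list[str]:
        """Stable intron identifiers in transcript (5'->3') order."""
        n = len(self.introns)
        order = range(n) if self.strand == "+" else range(n - 1, -1, -1)
        return [f"{self.gene_id}.i{k}" for k, _ in enumerate(order)]

    def introns_transcript_order(self) -> list[tuple[int, int]]:
        ivs = self.introns
        return ivs if self.strand == "+" else ivs[::-1]


@dataclass
class PolymorphicSiteRaw:
    chrom: str
    position: int  # 0-based
    ref: str
    alt: str
    derived_allele: str
    derived_freq: float
    lineage: str = "A"
    site_class: str = ""

    def __post_init__(self) -> None:
        if self.derived_allele not in {self.ref, self.alt}:
            raise ValueError(
                f"derived allele {self.derived_allele!r} is neither ref nor alt "
                f"at {self.chrom}:{self.position}"
            )


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(sequences: Mapping[str, str], handle: TextIO | str | Path, width: int = 60) -> None:
    close = False
    if isinstance(handle, (str, Path)):
        handle, close = open(handle, "w"), True
    try:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
    finally:
        if close:
            handle.close()


def load_fasta(handle: TextIO | str | Path) -> dict[str, str]:
    close = False
    if isinstance(handle, (str, Path)):
        handle, close = open(handle), True
    try:
        out: dict[str, str] = {}
        name, chunks = None, []
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
        if name is not None:
            out[name] = "".join(chunks)
        return out
    finally:
        if close:
            handle.close()


def get_spliced_sequence(model: GeneModel, genome: Mapping[str, str]) -> str:
    """Concatenated exon sequence, 5'->3' in transcript orientation."""
    if model.chrom not in genome:
        raise KeyError(f"chromosome {model.chrom!r} not in sequence store")
    chrom_seq = genome[model.chrom]
    if model.span[1] > len(chrom_seq):
        raise IndexError(
            f"gene {model.gene_id} extends past end of {model.chrom} "
            f"({model.span[1]} > {len(chrom_seq)})"
        )
    seq = "".join(chrom_seq[s:e] for s, e in model.exons)
    return reverse_complement(seq) if model.strand == "-" else seq


def get_genic_sequence(model: GeneModel, genome: Mapping[str, str]) -> str:
    """Unspliced (genic span) sequence in transcript orientation."""
    if model.chrom not in genome:
        raise KeyError(f"chromosome {model.chrom!r} not in sequence store")
    s, e = model.span
    seq = genome[model.chrom][s:e]
    return reverse_complement(seq) if model.strand == "-" else seq


# ---------------------------------------------------------------------------
# GTF (2.2; 1-based inclusive on disk)


def write_gtf(models: Iterable[GeneModel], handle: TextIO | str | Path) -> None:
    close = False
    if isinstance(handle, (str, Path)):
        handle, close = open(handle, "w"), True
    try:
        for m in models:
            attrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.gene_id}.t1"; '
                f'gene_biotype "{m.biotype}"; species "{m.species}";'
            )
            gs, ge = m.span
            handle.write(
                f"{m.chrom}\tlncexport\tgene\t{gs + 1}\t{ge}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            handle.write(
                f"{m.chrom}\tlncexport\ttranscript\t{gs + 1}\t{ge}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            for s, e in m.exons:
                handle.write(
                    f"{m.chrom}\tlncexport\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )
    finally:
        if close:
            handle.close()


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def load_gene_models(handle: TextIO | str | Path) -> list[GeneModel]:
    """Parse a GTF stream into collapsed (union-of-exons) gene models."""
    close = False
    if isinstance(handle, (str, Path)):
        handle, close = open(handle), True
    try:
        per_gene: dict[str, dict] = {}
        for lineno, line in enumerate(handle, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"line {lineno}: expected 9 fields, got {len(fields)}")
            chrom, _, feature, start, end, _, strand, _, attr_text = fields
            if feature != "exon":
                continue
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise GtfParseError(f"line {lineno}: end < start ({end_i} < {start_i})")
            if strand not in {"+", "-"}:
                raise GtfParseError(f"line {lineno}: unknown strand {strand!r}")
            attrs = _parse_gtf_attributes(attr_text)
            gid = attrs.get("gene_id")
            if gid is None:
                raise GtfParseError(f"line {lineno}: missing gene_id attribute")
            rec = per_gene.setdefault(
                gid,
                {
                    "chrom": chrom,
                    "strand": strand,
                    "exons": [],
                    "biotype": attrs.get("gene_biotype", "coding"),
                    "species": attrs.get("species", ""),
                },
            )
            if rec["chrom"] != chrom or rec["strand"] != strand:
                raise GtfParseError(f"line {lineno}: gene {gid} changes chrom/strand")
            # on-disk 1-based inclusive -> internal 0-based half-open
            rec["exons"].append((start_i - 1, end_i))
        models = []
        for gid, rec in per_gene.items():
            models.append(
                GeneModel(
                    gene_id=gid,
                    chrom=rec["chrom"],
                    strand=rec["strand"],
                    exons=merge_intervals(rec["exons"]),
                    biotype=rec["biotype"],
                    species=rec["species"],
                )
            )
        return models
    finally:
        if close:
            handle.close()


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals (adjacent intervals are merged)."""
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


# ---------------------------------------------------------------------------
# VCF (4.2; INFO keys AA, AF and optional LINEAGE / SCLASS)

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">
##INFO=<ID=LINEAGE,Number=1,Type=String,Description="Lineage label">
##INFO=<ID=SCLASS,Number=1,Type=String,Description="Site class">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(sites: Iterable[PolymorphicSiteRaw], handle: TextIO | str | Path) -> None:
    close = False
    if isinstance(handle, (str, Path)):
        handle, close = open(handle, "w"), True
    try:
        handle.write(_VCF_HEADER)
        for s in sites:
            af = s.derived_freq if s.derived_allele == s.alt else 1.0 - s.derived_freq
            aa = s.ref if s.derived_allele == s.alt else s.alt
            info = f"AA={aa};AF={af:.6g}"
            if s.lineage:
                info += f";LINEAGE={s.lineage}"
            if s.site_class:
                info += f";SCLASS={s.site_class}"
            handle.write(
                f"{s.chrom}\t{s.position + 1}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t{info}\n"
            )
    finally:
        if close:
            handle.close()


def load_variants(path: str | Path) -> tuple[list[PolymorphicSiteRaw], int]:
    """Load polarized biallelic SNVs from a VCF file.

    Derived-allele frequency is AF when the ancestral allele (AA) equals the
    reference, and 1 - AF when it equals the alternate.  Sites whose AA is
    missing or matches neither allele cannot be polarized; they are excluded
    and counted in the returned tally.
    """
    sites: list[PolymorphicSiteRaw] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                skipped += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            info = dict(rec.info)
            aa = info.get("AA")
            af = info.get("AF")
            if isinstance(af, tuple):
                af = af[0]
            if aa not in (ref, alt) or af is None:
                skipped += 1
                continue
            derived = alt if aa == ref else ref
            dfreq = float(af) if derived == alt else 1.0 - float(af)
            sites.append(
                PolymorphicSiteRaw(
                    chrom=rec.chrom,
                    position=rec.pos - 1,
                    ref=ref,
                    alt=alt,
                    derived_allele=derived,
                    derived_freq=dfreq,
                    lineage=str(info.get("LINEAGE", "A")),
                    site_class=str(info.get("SCLASS", "")),
                )
            )
    return sites, skipped
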