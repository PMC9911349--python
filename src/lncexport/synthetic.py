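"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the shape of a nuclear/cytoplasmic fractionation
study of spliced genes: multi-exon gene models carrying planted U1 (5'
splice-like) motifs and donor sites of controlled strength; fraction read
counts whose cytoplasmic share follows a logistic export model in exonic
U1 density and true splicing (ISOR); junction and full-length reads for the
splicing statistics; allele-resolved mutation-assay reads with injected
effect sizes; derived-allele frequencies under neutral and constrained
regimes; and two-species expression panels with shared and lineage-specific
co-expression blocks.

Export model: the probability that a transcript copy is cytoplasmic is

    p_cyt = sigmoid(b0 + b_u1 * exonic_U1_density + b_isor * ISOR)

with b_u1 < 0 (exonic U1 retains transcripts in the nucleus) and
b_isor > 0 (splicing promotes export) by default, so lncRNA-like genes
(weak donors, U1-rich exons) end up nuclear and mRNA-like genes cytosolic.
Read counts are Poisson at the gene level and binomial/multinomial across
fractions and alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .io import GeneModel, PolymorphicSiteRaw, reverse_complement
from .maxent import DONOR_CONSENSUS, U1_CORE, ALPHABET

STRONG_DONOR = DONOR_CONSENSUS  # CAGGTAAGT
WEAK_DONOR = "AAGGTCTGA"  # GT core kept, consensus degraded elsewhere

_FLANK = 100


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Knobs of the generative model; the seed fully determines all output."""

    n_genes: int = 100
    exons_per_gene: tuple[int, int] = (2, 4)
    exon_len: tuple[int, int] = (200, 700)
    intron_len: tuple[int, int] = (200, 1200)
    gc_content: float = 0.5
    planted_u1_rate_exonic: float = 2.0  # motifs per kb
    planted_u1_rate_intronic: float = 2.0
    u1_mutation_rate: float = 0.1  # per-base divergence of planted 7-mers
    splice_strength_mix: dict = field(default_factory=lambda: {"strong": 0.5, "weak": 0.5})
    psi_strong: float = 0.92
    psi_weak: float = 0.40
    # (intercept, beta on exonic U1 density [/kb], beta on true ISOR)
    export_model_coefficients: tuple[float, float, float] = (0.5, -0.8, 2.0)
    seq_depth: float = 100.0  # expected reads per gene (both fractions)
    junction_depth: float = 50.0  # expected reads per intron junction
    fulllength_depth: int = 30  # full-length reads per gene
    # mutation assay
    assay_depth: int = 2000  # reads per mutation
    assay_junction_depth: int = 500  # junction-region reads per allele
    multi_mutation_fraction: float = 0.0
    # population
    n_chromosomes_population: int = 100
    selection_classes: dict = field(
        default_factory=lambda: {
            "synonymous": {"n_sites": 300, "sfs_exponent": 1.0, "lineage": "A"},
            "u1_weaken": {"n_sites": 300, "sfs_exponent": 2.5, "lineage": "A"},
        }
    )
    # expression panels
    panel_blocks: list = field(default_factory=list)
    n_background_genes: int = 50
    n_individuals_a: int = 134
    n_individuals_b: int = 35
    panel_block_r: float = 0.8
    # optional two-class gene structure (mRNA-like vs lncRNA-like)
    lnc_fraction: float = 0.0
    lnc_u1_rate_exonic: float | None = None
    lnc_u1_rate_intronic: float | None = None
    lnc_splice_strength_mix: dict | None = None
    # optional per-gene heterogeneity of the exonic U1 planting rate
    exonic_u1_rate_range: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ConfigurationError("n_genes must be >= 0")
        for name in ("exons_per_gene", "exon_len", "intron_len"):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0:
                raise ConfigurationError(f"invalid range for {name}: ({lo}, {hi})")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ConfigurationError("gc_content must be in [0, 1]")
        for name in ("planted_u1_rate_exonic", "planted_u1_rate_intronic"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.seq_depth < 0 or self.junction_depth < 0:
            raise ConfigurationError("depths must be >= 0")
        if not 0 <= self.multi_mutation_fraction <= 1:
            raise ConfigurationError("multi_mutation_fraction must be in [0, 1]")
        total = sum(self.splice_strength_mix.values())
        if total <= 0:
            raise ConfigurationError("splice_strength_mix must have positive mass")


@dataclass
class GeneTruth:
    gene_id: str
    biotype: str
    exonic_u1: int
    intronic_u1: int
    exonic_length: int
    intronic_length: int
    psi: list[float]  # per intron, transcript order
    true_isor: float
    exonic_u1_density: float  # per kb
    p_cyt: float


@dataclass
class SimTruth:
    genes: dict[str, GeneTruth] = field(default_factory=dict)
    mutations: pd.DataFrame | None = None
    sites: pd.DataFrame | None = None

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.genes.values():
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "biotype": g.biotype,
                    "exonic_u1": g.exonic_u1,
                    "intronic_u1": g.intronic_u1,
                    "exonic_length": g.exonic_length,
                    "intronic_length": g.intronic_length,
                    "true_isor": g.true_isor,
                    "exonic_u1_density": g.exonic_u1_density,
                    "p_cyt": g.p_cyt,
                }
            )
        return pd.DataFrame(rows)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def _mutate_motif(rng: np.random.Generator, motif: str, rate: float) -> str:
    out = []
    for b in motif:
        if rng.random() < rate:
            out.append(ALPHABET[rng.integers(0, 4)])
        else:
            out.append(b)
    return "".join(out)


def _plant_motifs(
    rng: np.random.Generator,
    seq: np.ndarray,
    start: int,
    end: int,
    rate_per_kb: float,
    mutation_rate: float,
) -> int:
    """Plant Poisson(rate x length) copies of the U1 7-mer in seq[start:end]."""
    length = end - start
    if length < len(U1_CORE) or rate_per_kb <= 0:
        return 0
    n = rng.poisson(rate_per_kb * length / 1_000)
    planted = 0
    occupied: list[tuple[int, int]] = []
    for _ in range(n):
        for _attempt in range(20):
            pos = int(rng.integers(start, end - len(U1_CORE) + 1))
            if all(pos + 7 <= s or pos >= e for s, e in occupied):
                motif = _mutate_motif(rng, U1_CORE, mutation_rate)
                seq[pos : pos + 7] = [ALPHABET.index(b) for b in motif]
                occupied.append((pos, pos + 7))
                planted += 1
                break
    return planted


def simulate_genome(
    config: SimConfig,
) -> tuple[dict[str, str], list[GeneModel], SimTruth]:
    """Generate chromosome sequences, gene models and ground truth.

    Each gene sits on its own chromosome with 100-nt flanks; donor 9-mers
    (3 exonic + 6 intronic nt) are written at every exon/intron boundary
    with strength drawn from ``splice_strength_mix``, and U1 7-mers are
    planted at the configured per-kb rates.
    """
    rng = np.random.default_rng(config.seed)
    b0, b_u1, b_isor = config.export_model_coefficients
    strengths = sorted(config.splice_strength_mix)
    weights = np.array([config.splice_strength_mix[s] for s in strengths], dtype=float)
    weights /= weights.sum()

    sequences: dict[str, str] = {}
    models: list[GeneModel] = []
    truth = SimTruth()

    for i in range(config.n_genes):
        gid = f"g{i:05d}"
        is_lnc = rng.random() < config.lnc_fraction
        biotype = "lncRNA" if is_lnc else "coding"
        if is_lnc:
            rate_ex = (
                config.lnc_u1_rate_exonic
                if config.lnc_u1_rate_exonic is not None
                else config.planted_u1_rate_exonic
            )
            rate_in = (
                config.lnc_u1_rate_intronic
                if config.lnc_u1_rate_intronic is not None
                else config.planted_u1_rate_intronic
            )
            mix = config.lnc_splice_strength_mix or config.splice_strength_mix
        else:
            rate_ex = config.planted_u1_rate_exonic
            rate_in = config.planted_u1_rate_intronic
            mix = config.splice_strength_mix
        if config.exonic_u1_rate_range is not None:
            lo, hi = config.exonic_u1_rate_range
            rate_ex = float(rng.uniform(lo, hi))
        mix_names = sorted(mix)
        mix_w = np.array([mix[s] for s in mix_names], dtype=float)
        mix_w /= mix_w.sum()

        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(config.exon_len[0], config.exon_len[1] + 1, size=n_exons)
        intron_lens = rng.integers(
            config.intron_len[0], config.intron_len[1] + 1, size=max(n_exons - 1, 0)
        )

        # transcript-direction layout
        parts: list[np.ndarray] = []
        exon_bounds: list[tuple[int, int]] = []
        pos = 0
        for k, el in enumerate(exon_lens):
            parts.append(_random_bases(rng, int(el), config.gc_content))
            exon_bounds.append((pos, pos + int(el)))
            pos += int(el)
            if k < len(intron_lens):
                parts.append(_random_bases(rng, int(intron_lens[k]), config.gc_content))
                pos += int(intron_lens[k])
        seq = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)

        # donor sites at each exon/intron boundary
        psis: list[float] = []
        for k in range(len(intron_lens)):
            boundary = exon_bounds[k][1]
            strength = mix_names[int(rng.choice(len(mix_names), p=mix_w))]
            donor = STRONG_DONOR if strength == "strong" else WEAK_DONOR
            seq[boundary - 3 : boundary + 6] = [ALPHABET.index(b) for b in donor]
            psis.append(config.psi_strong if strength == "strong" else config.psi_weak)

        # plant U1 motifs (keeping clear of donor 9-mers)
        n_ex_u1 = 0
        for k, (s, e) in enumerate(exon_bounds):
            hi = e - 3 if k < len(intron_lens) else e
            lo = s + 6 if k > 0 else s
            n_ex_u1 += _plant_motifs(rng, seq, lo, hi, rate_ex, config.u1_mutation_rate)
        n_in_u1 = 0
        for k in range(len(intron_lens)):
            s = exon_bounds[k][1] + 6
            e = exon_bounds[k + 1][0] - 3
            n_in_u1 += _plant_motifs(rng, seq, s, e, rate_in, config.u1_mutation_rate)

        exonic_len = int(exon_lens.sum())
        intronic_len = int(intron_lens.sum()) if len(intron_lens) else 0
        true_isor = (
            sum(il * p for il, p in zip(intron_lens, psis)) / exonic_len
            if len(intron_lens)
            else 0.0
        )
        density = n_ex_u1 / (exonic_len / 1_000)
        p_cyt = float(_sigmoid(b0 + b_u1 * density + b_isor * true_isor))

        strand = "+" if rng.random() < 0.5 else "-"
        gene_len = len(seq)
        flanks = _random_bases(rng, 2 * _FLANK, config.gc_content)
        chrom_codes = np.concatenate([flanks[:_FLANK], seq, flanks[_FLANK:]])
        chrom_seq = "".join(ALPHABET[c] for c in chrom_codes)
        if strand == "-":
            chrom_seq = reverse_complement(chrom_seq)
            exons = [
                (_FLANK + gene_len - e, _FLANK + gene_len - s) for s, e in exon_bounds
            ][::-1]
        else:
            exons = [(_FLANK + s, _FLANK + e) for s, e in exon_bounds]

        chrom = f"chr_{gid}"
        sequences[chrom] = chrom_seq
        models.append(GeneModel(gid, chrom, strand, exons, biotype=biotype, species="sim"))
        truth.genes[gid] = GeneTruth(
            gene_id=gid,
            biotype=biotype,
            exonic_u1=n_ex_u1,
            intronic_u1=n_in_u1,
            exonic_length=exonic_len,
            intronic_length=intronic_len,
            psi=psis,
            true_isor=true_isor,
            exonic_u1_density=density,
            p_cyt=p_cyt,
        )
    return sequences, models, truth


def simulate_fraction_counts(
    models: list[GeneModel],
    truth: SimTruth,
    config: SimConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Nuclear/cytoplasmic counts, junction evidence and full-length reads."""
    if config.seq_depth < 0:
        raise ConfigurationError("seq_depth must be >= 0")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    count_rows, junction_rows, fl_rows = [], [], []
    for m in models:
        g = truth.genes[m.gene_id]
        weight = float(rng.lognormal(0.0, 0.4))
        n_total = int(rng.poisson(config.seq_depth * weight))
        n_cyt = int(rng.binomial(n_total, g.p_cyt)) if n_total else 0
        count_rows.append(
            {
                "gene_id": m.gene_id,
                "n_nuc": n_total - n_cyt,
                "n_cyt": n_cyt,
                "exonic_length": m.exonic_length,
            }
        )
        intron_ids = m.intron_ids()
        intron_lens = [e - s for s, e in m.introns_transcript_order()]
        for iid, ilen, psi in zip(intron_ids, intron_lens, g.psi):
            n_j = int(rng.poisson(config.junction_depth))
            spliced = int(rng.binomial(n_j, psi)) if n_j else 0
            junction_rows.append(
                {
                    "gene_id": m.gene_id,
                    "intron_id": iid,
                    "intron_length": ilen,
                    "junction_reads": spliced,
                    "retention_reads": n_j - spliced,
                }
            )
        for r in range(config.fulllength_depth):
            retained = [
                iid for iid, psi in zip(intron_ids, g.psi) if rng.random() > psi
            ]
            fl_rows.append(
                {
                    "read_id": f"{m.gene_id}.fl{r}",
                    "gene_id": m.gene_id,
                    "retained_introns": ",".join(retained),
                }
            )
    return (
        pd.DataFrame(count_rows, columns=["gene_id", "n_nuc", "n_cyt", "exonic_length"]),
        pd.DataFrame(
            junction_rows,
            columns=["gene_id", "intron_id", "intron_length", "junction_reads", "retention_reads"],
        ),
        pd.DataFrame(fl_rows, columns=["read_id", "gene_id", "retained_introns"]),
    )


# ---------------------------------------------------------------------------
# Mutation assay


@dataclass
class InjectedEffect:
    mutation_id: str
    gene_id: str
    position: int  # 0-based, within the gene span
    ref: str
    alt: str
    export_odds_multiplier: float = 1.0  # nuclear-odds multiplier of the mutant allele
    psi_delta: float = 0.0


def simulate_mutation_assay(
    models: list[GeneModel],
    injected_effects: list[InjectedEffect],
    config: SimConfig,
    truth: SimTruth | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Allele-resolved fraction reads for CRISPR-style mutation tests.

    Returns (read_calls, allele_junctions, assay_truth).  ``read_calls`` has
    one row per retained amplicon read: read_id, fraction (nuc/cyt),
    gene_id, overlapped_mutations and carried_mutations (comma lists).  A
    configured fraction of mutant reads carries a second mutation of the
    same gene, to exercise the downstream discard rule; their ids are
    recorded in the truth table.
    """
    by_gene = {m.gene_id: m for m in models}
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    gene_p_cyt = (
        {g.gene_id: g.p_cyt for g in truth.genes.values()} if truth else {}
    )
    gene_psi = (
        {g.gene_id: (g.psi[0] if g.psi else 0.8) for g in truth.genes.values()}
        if truth
        else {}
    )
    effects_by_gene: dict[str, list[InjectedEffect]] = {}
    for eff in injected_effects:
        model = by_gene.get(eff.gene_id)
        if model is None:
            raise ValueError(f"unknown gene {eff.gene_id} for {eff.mutation_id}")
        span = model.span
        if not (span[0] <= eff.position < span[1]):
            raise ValueError(
                f"position {eff.position} outside gene {eff.gene_id} span {span}"
            )
        effects_by_gene.setdefault(eff.gene_id, []).append(eff)

    read_rows, junction_rows, truth_rows = [], [], []
    for eff in injected_effects:
        p_cyt = gene_p_cyt.get(eff.gene_id, 0.5)
        o_ref = (1 - p_cyt) / p_cyt  # nuclear odds
        o_mut = o_ref * eff.export_odds_multiplier
        siblings = [e.mutation_id for e in effects_by_gene[eff.gene_id] if e is not eff]
        multi_ids = []
        for r in range(config.assay_depth):
            carries_mut = rng.random() < 0.5
            odds = o_mut if carries_mut else o_ref
            fraction = "nuc" if rng.random() < odds / (1 + odds) else "cyt"
            carried = [eff.mutation_id] if carries_mut else []
            overlapped = [eff.mutation_id]
            if (
                carries_mut
                and siblings
                and rng.random() < config.multi_mutation_fraction
            ):
                other = siblings[int(rng.integers(0, len(siblings)))]
                carried.append(other)
                overlapped.append(other)
                multi_ids.append(f"{eff.mutation_id}.r{r}")
            read_rows.append(
                {
                    "read_id": f"{eff.mutation_id}.r{r}",
                    "fraction": fraction,
                    "gene_id": eff.gene_id,
                    "overlapped_mutations": ",".join(overlapped),
                    "carried_mutations": ",".join(carried),
                }
            )
        psi_ref = gene_psi.get(eff.gene_id, 0.8)
        psi_mut = float(np.clip(psi_ref + eff.psi_delta, 0.0, 1.0))
        ilen = 500
        model = by_gene[eff.gene_id]
        if model.introns:
            s, e = model.introns_transcript_order()[0]
            ilen = e - s
        for allele, psi in (("ref", psi_ref), ("mut", psi_mut)):
            n = config.assay_junction_depth
            spliced = int(rng.binomial(n, psi)) if n else 0
            junction_rows.append(
                {
                    "mutation_id": eff.mutation_id,
                    "allele": allele,
                    "intron_length": ilen,
                    "junction_reads": spliced,
                    "retention_reads": n - spliced,
                }
            )
        truth_rows.append(
            {
                "mutation_id": eff.mutation_id,
                "gene_id": eff.gene_id,
                "export_odds_multiplier": eff.export_odds_multiplier,
                "psi_delta": eff.psi_delta,
                "multi_mutation_reads": ",".join(multi_ids),
            }
        )
    return (
        pd.DataFrame(
            read_rows,
            columns=["read_id", "fraction", "gene_id", "overlapped_mutations", "carried_mutations"],
        ),
        pd.DataFrame(
            junction_rows,
            columns=["mutation_id", "allele", "intron_length", "junction_reads", "retention_reads"],
        ),
        pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# Population


def _sfs_frequencies(
    rng: np.random.Generator, n_sites: int, n_chrom: int, exponent: float
) -> np.ndarray:
    """Derived-allele counts k in 1..n-1 with P(k) proportional to k^-exponent."""
    k = np.arange(1, n_chrom)
    w = 1.0 / k.astype(float) ** exponent
    w /= w.sum()
    counts = rng.choice(k, size=n_sites, p=w)
    return counts / n_chrom


def simulate_population(
    config: SimConfig, seed: int | None = None
) -> list[PolymorphicSiteRaw]:
    """Polymorphic sites with derived-allele frequencies drawn per class.

    Each entry of ``selection_classes`` maps a class name to
    ``{"n_sites", "sfs_exponent", "lineage"}``; exponent 1 is the standard
    neutral spectrum, larger exponents give the excess of rare derived
    alleles expected under purifying selection.
    """
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    sites: list[PolymorphicSiteRaw] = []
    pos = 0
    for cls in sorted(config.selection_classes):
        spec = config.selection_classes[cls]
        freqs = _sfs_frequencies(
            rng, int(spec["n_sites"]), config.n_chromosomes_population,
            float(spec.get("sfs_exponent", 1.0)),
        )
        for f in freqs:
            pos += int(rng.integers(5, 50))
            ref, alt = rng.choice(4, size=2, replace=False)
            derived_is_alt = rng.random() < 0.5
            sites.append(
                PolymorphicSiteRaw(
                    chrom="chrPop",
                    position=pos,
                    ref=ALPHABET[ref],
                    alt=ALPHABET[alt],
                    derived_allele=ALPHABET[alt] if derived_is_alt else ALPHABET[ref],
                    derived_freq=float(f),
                    lineage=str(spec.get("lineage", "A")),
                    site_class=cls,
                )
            )
    return sites


# ---------------------------------------------------------------------------
# Expression panels


def simulate_expression_panel(
    config: SimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Two-species expression matrices with block co-expression structure.

    ``panel_blocks`` entries: {"n_genes", "r", "shared"}.  Within a block,
    genes load on one latent factor so that pairwise Pearson correlation is
    approximately r; "shared" blocks are correlated in both species,
    lineage-specific blocks only in species A.  Values are FPKM-like
    (location 10, scale 2, clipped at 0).
    """
    rng = np.random.default_rng(config.seed + 4 if seed is None else seed)
    blocks = config.panel_blocks or []

    def one_species(n_ind: int, active: list[bool]) -> tuple[list[str], np.ndarray]:
        names, rows = [], []
        for b, blk in enumerate(blocks):
            r = float(blk.get("r", config.panel_block_r))
            factor = rng.standard_normal(n_ind)
            for gidx in range(int(blk["n_genes"])):
                noise = rng.standard_normal(n_ind)
                if active[b]:
                    x = np.sqrt(r) * factor + np.sqrt(1 - r) * noise
                else:
                    x = noise
                names.append(f"blk{b}_g{gidx}")
                rows.append(x)
        for gidx in range(config.n_background_genes):
            names.append(f"bg_g{gidx}")
            rows.append(rng.standard_normal(n_ind))
        mat = np.clip(10.0 + 2.0 * np.array(rows), 0.0, None)
        return names, mat

    active_a = [True] * len(blocks)
    active_b = [bool(blk.get("shared", True)) for blk in blocks]
    names_a, mat_a = one_species(config.n_individuals_a, active_a)
    names_b, mat_b = one_species(config.n_individuals_b, active_b)
    panel_a = pd.DataFrame(
        mat_a, index=[f"hsa_{n}" for n in names_a],
        columns=[f"indA{i}" for i in range(config.n_individuals_a)],
    )
    panel_b = pd.DataFrame(
        mat_b, index=[f"mml_{n}" for n in names_b],
        columns=[f"indB{i}" for i in range(config.n_individuals_b)],
    )
    orthology = pd.DataFrame(
        {"gene_a": [f"hsa_{n}" for n in names_a], "gene_b": [f"mml_{n}" for n in names_b]}
    )
    return panel_a, panel_b, orthology


# ---------------------------------------------------------------------------
# Classifier task


def make_classification_dataset(
    n_sequences: int = 2000,
    seed: int = 1,
    u1_rate_range: tuple[float, float] = (0.3, 8.0),
    extreme_fraction: float = 0.25,
    depth: float = 300.0,
):
    """End-to-end labeled-sequence task for the export classifier.

    Generates ``2 * n_sequences`` two/three-exon genes whose exonic U1
    planting rate varies per gene, simulates fraction counts under the
    logistic export model, computes N/C ratios, and labels the extreme
    tails (top/bottom quarter) nuclear/cytosolic — the synthetic analogue
    of labeling the top and bottom 5% of a transcriptome-wide N/C table.
    Labels of the extremes are essentially Bayes-separable because the
    tails differ strongly in planted exonic U1 density.

    Returns (labeled, planted_pwm) where ``labeled`` is a list of
    LabeledSequence and ``planted_pwm`` the 7x4 probability matrix of the
    planted U1 motif.
    """
    from .classifier import LabeledSequence, label_extremes
    from . import io as _io
    from .localization import nc_table

    config = SimConfig(
        n_genes=2 * n_sequences,
        exons_per_gene=(2, 3),
        exon_len=(250, 650),
        intron_len=(150, 500),
        planted_u1_rate_exonic=2.0,
        exonic_u1_rate_range=u1_rate_range,
        export_model_coefficients=(2.0, -1.0, 2.0),
        seq_depth=depth,
        fulllength_depth=0,
        seed=seed,
    )
    sequences, models, truth = simulate_genome(config)
    counts, _, _ = simulate_fraction_counts(models, truth, config)
    nc = nc_table(counts)
    spliced = {
        m.gene_id: _io.get_spliced_sequence(m, sequences) for m in models
    }
    labeled = label_extremes(nc, spliced, fraction=extreme_fraction, max_len=5_000)
    mu = config.u1_mutation_rate
    pwm = np.full((len(U1_CORE), 4), mu / 4)
    for i, b in enumerate(U1_CORE):
        pwm[i, ALPHABET.index(b)] += 1 - mu
    return labeled, pwm
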