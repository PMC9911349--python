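"""Selection tests: pN/pS with site counting, DAF spectra, skewness tests,
and segregating-site effect summaries.

pN/pS compares nonsynonymous and synonymous polymorphism densities, with
mutational opportunities counted per codon by equal-rate enumeration of
all nine single-nucleotide changes (Nei-Gojobori-style, no ts/tv
weighting); changes creating a stop codon count as nonsynonymous.  For
non-coding orthologues, a codon-level alignment projects the coding frame
onto the orthologue, defining pseudo-nonsynonymous and pseudo-synonymous
sites.

Derived-allele-frequency (DAF) spectra get bootstrap standard deviations
(1,000 replicates); purifying selection shows as a left-skewed spectrum —
an excess of rare derived alleles — and is tested by comparing the sample
skewness of a focal class against a Monte-Carlo null built by resampling
matched-size sets from the synonymous (neutral) sites 10,000 times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .io import PolymorphicSiteRaw
from .maxent import variant_delta

_CODON_TO_AA = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)
_BASES = "ACGT"


def _translate(codon: str) -> str:
    if codon in _STOPS:
        return "*"
    return _CODON_TO_AA[codon]


def count_ng_sites(coding_sequence: str) -> tuple[float, float]:
    """Expected nonsynonymous and synonymous site counts of an in-frame CDS.

    Every codon contributes 3 sites split by the synonymous fraction of its
    nine possible single-nucleotide changes; the two counts sum to the
    sequence length.
    """
    cds = coding_sequence.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    nonsyn = syn = 0.0
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if any(b not in _BASES for b in codon):
            raise ValueError(f"non-ACGT base in codon {codon!r} at position {i}")
        if codon in _STOPS and i < len(cds) - 3:
            raise ValueError(f"internal stop codon {codon} at position {i}")
        aa = _translate(codon)
        n_syn_changes = 0
        for j in range(3):
            for b in _BASES:
                if b == codon[j]:
                    continue
                alt = codon[:j] + b + codon[j + 1 :]
                # stop-producing changes count as nonsynonymous
                if alt not in _STOPS and _translate(alt) == aa:
                    n_syn_changes += 1
        syn += n_syn_changes / 3.0
        nonsyn += (9 - n_syn_changes) / 3.0
    return nonsyn, syn


def classify_coding_change(cds: str, position: int, alt: str) -> str:
    """"synonymous" or "nonsynonymous" for a single CDS substitution."""
    codon_idx = position // 3
    codon = cds[3 * codon_idx : 3 * codon_idx + 3].upper()
    offset = position % 3
    alt_codon = codon[:offset] + alt.upper() + codon[offset + 1 :]
    if alt_codon in _STOPS:
        return "nonsynonymous"
    return "synonymous" if _translate(alt_codon) == _translate(codon) else "nonsynonymous"


def project_frame(aligned_cds: str, aligned_ortholog: str) -> dict[int, int]:
    """Map ungapped ortholog positions to CDS positions via an alignment.

    Both sequences come from one pairwise alignment (equal length, '-' for
    gaps).  Only columns ungapped in both sequences are mapped; variants
    falling outside the map are skipped by ``pnps``.
    """
    if len(aligned_cds) != len(aligned_ortholog):
        raise ValueError("aligned sequences must have equal length")
    mapping: dict[int, int] = {}
    i_cds = i_orth = 0
    for a, b in zip(aligned_cds, aligned_ortholog):
        if a != "-" and b != "-":
            mapping[i_orth] = i_cds
        if a != "-":
            i_cds += 1
        if b != "-":
            i_orth += 1
    return mapping


@dataclass
class PnpsResult:
    n_nonsyn_poly: int
    n_syn_poly: int
    nonsyn_sites: float
    syn_sites: float
    pnps: float | None  # None when no synonymous polymorphism (undefined)
    n_skipped: int = 0


def pnps(
    cds: str,
    variants: list[tuple[int, str]],
    frame_projection: dict[int, int] | None = None,
) -> PnpsResult:
    """pN/pS from a CDS and a list of (position, alt_base) polymorphisms.

    Positions are CDS coordinates, or ortholog coordinates when
    ``frame_projection`` maps them into the CDS frame (pseudo-site mode);
    unmapped positions are skipped and tallied.
    """
    nonsyn_sites, syn_sites = count_ng_sites(cds)
    n_non = n_syn = skipped = 0
    for pos, alt in variants:
        if frame_projection is not None:
            if pos not in frame_projection:
                skipped += 1
                continue
            pos = frame_projection[pos]
        if not 0 <= pos < len(cds):
            skipped += 1
            continue
        if classify_coding_change(cds, pos, alt) == "synonymous":
            n_syn += 1
        else:
            n_non += 1
    if n_syn == 0 or syn_sites == 0 or nonsyn_sites == 0:
        ratio = None
    else:
        ratio = (n_non / nonsyn_sites) / (n_syn / syn_sites)
    return PnpsResult(n_non, n_syn, nonsyn_sites, syn_sites, ratio, skipped)


# ---------------------------------------------------------------------------
# DAF spectra and skewness


@dataclass
class DafSpectrum:
    bin_edges: np.ndarray
    proportions: np.ndarray
    bootstrap_sd: np.ndarray
    n_sites: int


def daf_spectrum(
    freqs, n_bins: int = 10, n_boot: int = 1_000, seed: int = 0
) -> DafSpectrum:
    """Binned derived-allele-frequency spectrum with bootstrap SDs."""
    freqs = np.asarray(freqs, dtype=float)
    if len(freqs) == 0:
        raise ValueError("no frequencies given")
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("segregating-site frequencies must lie in (0, 1)")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(freqs, bins=edges)
    props = counts / len(freqs)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, n_bins))
    for b in range(n_boot):
        resampled = rng.choice(freqs, size=len(freqs), replace=True)
        boots[b] = np.histogram(resampled, bins=edges)[0] / len(freqs)
    return DafSpectrum(edges, props, boots.std(axis=0, ddof=1), len(freqs))


def skewness(values) -> float:
    """Sample skewness g1 = m3 / m2^(3/2) (biased moment estimator)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("skewness needs at least 3 values")
    d = x - x.mean()
    m2 = np.mean(d**2)
    if m2 == 0:
        raise ValueError("zero variance")
    return float(np.mean(d**3) / m2**1.5)


def mc_skew_test(
    focal_freqs,
    neutral_freqs,
    n_boot: int = 10_000,
    seed: int = 0,
    alternative: str = "left",
) -> tuple[float, float]:
    """Monte-Carlo test of DAF-spectrum skewness against a neutral background.

    The null distribution is the skewness of ``len(focal)`` sites resampled
    with replacement from the neutral set, ``n_boot`` times.  For the
    default left-skew alternative (excess of rare derived alleles) the
    p-value is the add-one-smoothed fraction of null skewness values at or
    below the observed one.  Returns (observed_skewness, p).
    """
    focal = np.asarray(focal_freqs, dtype=float)
    neutral = np.asarray(neutral_freqs, dtype=float)
    if len(focal) == 0 or len(neutral) == 0:
        raise ValueError("both site sets must be non-empty")
    if np.var(focal) == 0:
        # degenerate spectrum (e.g. all singletons): maximal concentration
        obs = np.inf
    else:
        obs = skewness(focal)
    rng = np.random.default_rng(seed)
    samples = rng.choice(neutral, size=(n_boot, len(focal)), replace=True)
    d = samples - samples.mean(axis=1, keepdims=True)
    m2 = np.mean(d**2, axis=1)
    m3 = np.mean(d**3, axis=1)
    ok = m2 > 0
    null = np.where(ok, m3 / np.where(ok, m2, 1.0) ** 1.5, np.inf)
    # A spectrum leaning left (mass piled on rare derived alleles, the
    # purifying-selection signature) has *larger* sample skewness of the
    # frequency values, so the "left" alternative rejects for large g1.
    if alternative == "left":
        p = (1 + int(np.sum(null >= obs))) / (n_boot + 1)
    elif alternative == "right":
        p = (1 + int(np.sum(null <= obs))) / (n_boot + 1)
    elif alternative == "two-sided":
        p_hi = (1 + int(np.sum(null >= obs))) / (n_boot + 1)
        p_lo = (1 + int(np.sum(null <= obs))) / (n_boot + 1)
        p = min(1.0, 2 * min(p_hi, p_lo))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return obs, float(p)


# ---------------------------------------------------------------------------
# Segregating-site effect classification


@dataclass
class ClassifiedSite:
    site: PolymorphicSiteRaw
    effect_channel: str  # "splice" / "U1"
    effect_call: str  # "strengthen" / "weaken" / "neutral"
    delta: float | None
    flag: str = ""


def classify_segregating_sites(
    sites: list[PolymorphicSiteRaw],
    motif_model,
    sequences: dict[str, str],
    channel: str,
) -> list[ClassifiedSite]:
    """Delta-score each site's derived change under a motif model.

    The substitution is oriented ancestral -> derived, so "strengthen"
    means the derived allele improves the site.  Sequences must be
    strand-resolved; sites whose variant cannot be placed in any clean
    scoring window are classified neutral and flagged.
    """
    out = []
    for s in sites:
        seq = sequences.get(s.chrom)
        if seq is None:
            out.append(ClassifiedSite(s, channel, "neutral", None, "no_sequence"))
            continue
        anc = s.ref if s.derived_allele == s.alt else s.alt
        delta, call = variant_delta(motif_model, seq, s.position, anc, s.derived_allele)
        if delta is None:
            out.append(ClassifiedSite(s, channel, "neutral", None, "out_of_window"))
        else:
            out.append(ClassifiedSite(s, channel, call, delta))
    return out


def summarize_lineage_effects(classified: list[ClassifiedSite]) -> pd.DataFrame:
    """Counts and percentages of strengthen/weaken per lineage and channel.

    Neutral sites are excluded from denominators; empty cells are NA, never
    0%.  Percentages are rounded to one decimal.
    """
    rows = []
    keys = sorted({(c.site.lineage, c.effect_channel) for c in classified})
    for lineage, channel in keys:
        sub = [
            c
            for c in classified
            if c.site.lineage == lineage and c.effect_channel == channel
        ]
        n_str = sum(1 for c in sub if c.effect_call == "strengthen")
        n_weak = sum(1 for c in sub if c.effect_call == "weaken")
        total = n_str + n_weak
        rows.append(
            {
                "lineage": lineage,
                "channel": channel,
                "n_strengthen": n_str,
                "n_weaken": n_weak,
                "n_effect": total,
                "pct_strengthen": round(100.0 * n_str / total, 1) if total else np.nan,
                "pct_weaken": round(100.0 * n_weak / total, 1) if total else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "lineage", "channel", "n_strengthen", "n_weaken", "n_effect",
            "pct_strengthen", "pct_weaken",
        ],
    )
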