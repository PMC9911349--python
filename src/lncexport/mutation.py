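"""Per-mutation tests of nuclear-export and splicing shifts.

From pooled amplicon sequencing of nuclear and cytoplasmic fractions, each
mutation yields a 2x2 table — (mutant, reference) alleles x (nuclear,
cytoplasmic) fractions.  A two-sided Fisher exact test with
Benjamini-Hochberg correction across all mutations calls the export shift;
the odds ratio is the nuclear odds of the mutant over the reference allele,
so OR > 1 means the mutant is nuclear-retained (decreased export).  Reads
carrying more than one mutation are discarded before tabulation to avoid
compound effects.  Splicing shifts are tested the same way on junction
versus retention reads per allele, and called only when the PSI difference
also exceeds 5 percentage points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln


@dataclass
class AlleleFractionCounts:
    mutation_id: str
    gene_id: str = ""
    n_mut_nuc: int = 0
    n_ref_nuc: int = 0
    n_mut_cyt: int = 0
    n_ref_cyt: int = 0


def count_alleles(read_calls: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Tabulate allele x fraction counts from per-read calls.

    ``read_calls`` columns: read_id, fraction ("nuc"/"cyt"), gene_id,
    overlapped_mutations, carried_mutations (comma-separated ids).  Reads
    carrying two or more mutations are discarded and tallied; every
    retained read increments, for each mutation it overlaps, the mutant
    cell if it carries that mutation and the reference cell otherwise.
    """
    counts: dict[str, AlleleFractionCounts] = {}
    discarded = 0
    for row in read_calls.itertuples():
        carried = [m for m in str(row.carried_mutations).split(",") if m and m != "nan"]
        if len(carried) >= 2:
            discarded += 1
            continue
        overlapped = [m for m in str(row.overlapped_mutations).split(",") if m and m != "nan"]
        for mid in overlapped:
            rec = counts.setdefault(
                mid, AlleleFractionCounts(mid, getattr(row, "gene_id", ""))
            )
            is_mut = mid in carried
            if row.fraction == "nuc":
                if is_mut:
                    rec.n_mut_nuc += 1
                else:
                    rec.n_ref_nuc += 1
            else:
                if is_mut:
                    rec.n_mut_cyt += 1
                else:
                    rec.n_ref_cyt += 1
    df = pd.DataFrame(
        [
            {
                "mutation_id": r.mutation_id,
                "gene_id": r.gene_id,
                "n_mut_nuc": r.n_mut_nuc,
                "n_ref_nuc": r.n_ref_nuc,
                "n_mut_cyt": r.n_mut_cyt,
                "n_ref_cyt": r.n_ref_cyt,
            }
            for r in counts.values()
        ],
        columns=["mutation_id", "gene_id", "n_mut_nuc", "n_ref_nuc", "n_mut_cyt", "n_ref_cyt"],
    )
    return df, discarded


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float | None, float]:
    """Two-sided Fisher exact test for [[a, b], [c, d]].

    p sums hypergeometric probabilities no larger than the observed table's
    (with a 1+1e-7 tolerance against roundoff).  The odds ratio a*d/(b*c)
    is None when undefined (0/0 or a zero margin).
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return None, 1.0
    if b * c == 0:
        odds = None if a * d == 0 else np.inf
    else:
        odds = (a * d) / (b * c)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    # hypergeometric log-pmf over the whole support via log-gamma
    lg = gammaln(np.arange(n + 2))

    def lcomb(nn, kk):
        return lg[nn + 1] - lg[kk + 1] - lg[nn - kk + 1]

    logp = lcomb(r1, support) + lcomb(n - r1, c1 - support) - lcomb(n, c1)
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[a - lo]
    p = float(probs[probs <= p_obs * (1 + 1e-7)].sum())
    return odds, min(p, 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def test_export_shift(counts: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-mutation Fisher test of the nuclear/cytoplasmic allele table.

    OR = nuclear odds of mutant over reference.  increased_export is called
    at q < alpha with OR < 1 (mutant relatively cytoplasm-enriched),
    decreased_export at q < alpha with OR > 1.  Mutations with a zero
    margin are untestable: excluded from the BH family and left uncalled.
    """
    rows = []
    for r in counts.itertuples():
        odds, p = fisher_exact_2x2(r.n_mut_nuc, r.n_ref_nuc, r.n_mut_cyt, r.n_ref_cyt)
        testable = (
            (r.n_mut_nuc + r.n_mut_cyt) > 0
            and (r.n_ref_nuc + r.n_ref_cyt) > 0
            and (r.n_mut_nuc + r.n_ref_nuc) > 0
            and (r.n_mut_cyt + r.n_ref_cyt) > 0
        )
        rows.append(
            {
                "mutation_id": r.mutation_id,
                "odds_ratio": np.nan if odds is None else odds,
                "p_raw": p,
                "testable": testable,
            }
        )
    df = pd.DataFrame(rows)
    df["q_bh"] = np.nan
    mask = df["testable"].to_numpy()
    if mask.any():
        df.loc[mask, "q_bh"] = bh_adjust(df.loc[mask, "p_raw"])
    calls = []
    for r in df.itertuples():
        if not r.testable or not r.q_bh < alpha or not np.isfinite(r.odds_ratio):
            calls.append("none")
        elif r.odds_ratio < 1:
            calls.append("increased_export")
        elif r.odds_ratio > 1:
            calls.append("decreased_export")
        else:
            calls.append("none")
    df["export_call"] = calls
    return df


def test_splice_shift(
    junctions: pd.DataFrame, alpha: float = 0.05, min_delta: float = 0.05
) -> pd.DataFrame:
    """Per-mutation Fisher test of junction vs retention reads by allele.

    ``junctions``: mutation_id, allele ("ref"/"mut"), junction_reads,
    retention_reads.  A call requires q < alpha AND |PSI_mut - PSI_ref|
    greater than ``min_delta`` (the 5-percentage-point rule).
    """
    rows = []
    for mid, grp in junctions.groupby("mutation_id", sort=True):
        by_allele = {r.allele: r for r in grp.itertuples()}
        if "ref" not in by_allele or "mut" not in by_allele:
            continue
        ref, mut = by_allele["ref"], by_allele["mut"]
        _, p = fisher_exact_2x2(
            ref.junction_reads, ref.retention_reads, mut.junction_reads, mut.retention_reads
        )
        tot_ref = ref.junction_reads + ref.retention_reads
        tot_mut = mut.junction_reads + mut.retention_reads
        psi_ref = ref.junction_reads / tot_ref if tot_ref else np.nan
        psi_mut = mut.junction_reads / tot_mut if tot_mut else np.nan
        rows.append(
            {
                "mutation_id": mid,
                "psi_ref": psi_ref,
                "psi_mut": psi_mut,
                "delta_psi": psi_mut - psi_ref,
                "p_raw_splice": p,
            }
        )
    df = pd.DataFrame(
        rows, columns=["mutation_id", "psi_ref", "psi_mut", "delta_psi", "p_raw_splice"]
    )
    if len(df):
        df["q_bh_splice"] = bh_adjust(df["p_raw_splice"])
    else:
        df["q_bh_splice"] = np.array([])
    calls = []
    for r in df.itertuples():
        if r.q_bh_splice < alpha and abs(r.delta_psi) > min_delta:
            calls.append("increased_splicing" if r.delta_psi > 0 else "decreased_splicing")
        else:
            calls.append("none")
    df["splice_call"] = calls
    return df


def filter_u1_effects(effects: pd.DataFrame, keep_fraction: float = 0.5) -> pd.DataFrame:
    """Keep the mutations with the most dramatic U1-score changes.

    Ranks by |du1_score| (ties broken by mutation_id) and keeps the top
    ``keep_fraction`` — the top-50% rule by default.
    """
    df = effects.copy()
    df["_absdu1"] = df["du1_score"].abs()
    df = df.sort_values(["_absdu1", "mutation_id"], ascending=[False, True])
    k = int(round(keep_fraction * len(df)))
    kept = df.head(k).drop(columns="_absdu1")
    return kept.sort_values("mutation_id").reset_index(drop=True)


def concordance_summary(effects: pd.DataFrame) -> tuple[int, int, float]:
    """Concordance between splicing and export calls.

    Eligible mutations have both a splice call and an export call;
    concordant ones couple stronger splicing with increased export or
    weaker splicing with decreased export.  Returns (n_eligible,
    n_concordant, percent to one decimal).
    """
    eligible = effects[
        (effects["splice_call"] != "none") & (effects["export_call"] != "none")
    ]
    n_eligible = len(eligible)
    concordant = (
        (eligible["splice_call"] == "increased_splicing")
        & (eligible["export_call"] == "increased_export")
    ) | (
        (eligible["splice_call"] == "decreased_splicing")
        & (eligible["export_call"] == "decreased_export")
    )
    n_concordant = int(concordant.sum())
    percent = round(100.0 * n_concordant / n_eligible, 1) if n_eligible else float("nan")
    return n_eligible, n_concordant, percent
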