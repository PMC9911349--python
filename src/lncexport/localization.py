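"""Nuclear-export quantification from fractionated RNA-seq.

The nuclear/cytoplasmic (N/C) ratio is the workhorse statistic: for a gene
with nuclear and cytoplasmic FPKM, weakly expressed genes
(FPKM_nuc + FPKM_cyt < 0.2) are discarded and the remainder scored as

    nc_ratio = log2((FPKM_nuc + 0.1) / (FPKM_cyt + 0.1))

with the 0.1 pseudocount keeping the ratio finite.  High values mean
nuclear retention; lncRNA-like transcripts sit above mRNA-like ones.
For cross-dataset comparison the ratios are z-scored within each dataset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PSEUDOCOUNT = 0.1
MIN_TOTAL_FPKM = 0.2


def compute_fpkm(read_count: float, exonic_length: int, mapped_reads: int) -> float:
    """Fragments per kilobase of exon per million mapped reads."""
    if exonic_length <= 0:
        raise ValueError("exonic_length must be positive")
    if mapped_reads <= 0:
        raise ValueError("mapped_reads must be positive")
    return read_count / (exonic_length / 1_000 * mapped_reads / 1_000_000)


def nc_ratio(
    fpkm_nuc: float,
    fpkm_cyt: float,
    pseudocount: float = PSEUDOCOUNT,
    min_total: float = MIN_TOTAL_FPKM,
) -> tuple[float | None, bool]:
    """log2 N/C ratio with expression filter.

    Returns ``(ratio, passed_filter)``; the ratio is None when the gene is
    filtered out for weak expression.
    """
    if fpkm_nuc < 0 or fpkm_cyt < 0:
        raise ValueError("FPKM values must be non-negative")
    if fpkm_nuc + fpkm_cyt < min_total:
        return None, False
    return float(np.log2((fpkm_nuc + pseudocount) / (fpkm_cyt + pseudocount))), True


def cyto_total_ratio(fpkm_nuc: float, fpkm_cyt: float) -> float:
    """Proportion of transcripts located in the cytoplasm."""
    total = fpkm_nuc + fpkm_cyt
    if total <= 0:
        raise ValueError("at least one fraction must be non-zero")
    return fpkm_cyt / total


def zscore_normalize(values, groups=None) -> np.ndarray:
    """z-score (sample SD, ddof=1), optionally within groups.

    A group with fewer than two values or zero variance is an error: silent
    zeros would corrupt cross-dataset comparisons.
    """
    values = np.asarray(values, dtype=float)
    if groups is None:
        groups = np.zeros(len(values), dtype=int)
    groups = np.asarray(groups)
    out = np.empty_like(values)
    for g in np.unique(groups):
        mask = groups == g
        vals = values[mask]
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
        sd = vals.std(ddof=1)
        if sd == 0:
            raise ValueError(f"group {g!r} has zero variance")
        out[mask] = (vals - vals.mean()) / sd
    return out


def nc_table(
    counts: pd.DataFrame,
    mapped_nuc: int | None = None,
    mapped_cyt: int | None = None,
    zscore_group: str | None = None,
) -> pd.DataFrame:
    """Per-gene N/C table from a count table.

    ``counts`` needs columns gene_id, n_nuc, n_cyt, exonic_length (and the
    optional z-score grouping column).  Library sizes default to the column
    totals — each fraction is normalized by its own library, never pooled.
    """
    mapped_nuc = int(counts["n_nuc"].sum()) if mapped_nuc is None else mapped_nuc
    mapped_cyt = int(counts["n_cyt"].sum()) if mapped_cyt is None else mapped_cyt
    df = counts.copy()
    df["fpkm_nuc"] = [
        compute_fpkm(c, l, mapped_nuc) for c, l in zip(df["n_nuc"], df["exonic_length"])
    ]
    df["fpkm_cyt"] = [
        compute_fpkm(c, l, mapped_cyt) for c, l in zip(df["n_cyt"], df["exonic_length"])
    ]
    ratios, passed = [], []
    for fn, fc in zip(df["fpkm_nuc"], df["fpkm_cyt"]):
        r, ok = nc_ratio(fn, fc)
        ratios.append(np.nan if r is None else r)
        passed.append(ok)
    df["nc_ratio"] = ratios
    df["passed_filter"] = passed
    df["nc_z"] = np.nan
    mask = df["passed_filter"].to_numpy()
    if mask.sum() >= 2:
        grp = df.loc[mask, zscore_group] if zscore_group else None
        df.loc[mask, "nc_z"] = zscore_normalize(df.loc[mask, "nc_ratio"], grp)
    return df
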