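"""Co-expression partner sets and their cross-species conservation.

For each focal gene, partners are the genes whose expression across
individuals correlates with it (Pearson, exact t-transform p-value, BH
correction within the focal gene's family, q < 0.05).  The conservation
fraction of a focal gene is the proportion of its partners in species A
whose orthologous pair is also a significant partner pair in species B.
Lineage-specific regulatory modules show up as low conservation fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mutation import bh_adjust


def filter_expressed(panel: pd.DataFrame, min_fpkm: float = 0.2) -> pd.DataFrame:
    """Drop genes whose panel-mean FPKM is below the cutoff (0.2)."""
    if panel.empty:
        return panel
    return panel[panel.mean(axis=1) >= min_fpkm]


@dataclass
class PartnerSet:
    focal_gene: str
    partners: dict[str, tuple[float, float]] = field(default_factory=dict)  # gene -> (r, q)
    n_tested: int = 0
    n_excluded_constant: int = 0


def _pearson_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the exact t transform, t = r sqrt((n-2)/(1-r^2))."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(t)] = 1.0
    p[np.isinf(t)] = 0.0
    return p


def partner_sets(
    panel: pd.DataFrame, focal_genes: list[str], alpha: float = 0.05
) -> list[PartnerSet]:
    """Significant co-expression partners of each focal gene.

    BH correction is applied within each focal gene's set of tests.
    Constant-expression genes have undefined correlation and are excluded
    (tallied per focal gene).
    """
    n = panel.shape[1]
    if n < 3:
        raise ValueError("at least 3 individuals required")
    X = panel.to_numpy(dtype=float)
    sd = X.std(axis=1)
    centered = X - X.mean(axis=1, keepdims=True)
    out = []
    gene_index = {g: i for i, g in enumerate(panel.index)}
    for focal in focal_genes:
        if focal not in gene_index:
            out.append(PartnerSet(focal))
            continue
        fi = gene_index[focal]
        if sd[fi] == 0:
            out.append(PartnerSet(focal, n_excluded_constant=1))
            continue
        usable = np.array(
            [i for i in range(len(panel)) if i != fi and sd[i] > 0], dtype=int
        )
        n_constant = int((sd == 0).sum() - (0 if sd[fi] > 0 else 1))
        r = centered[usable] @ centered[fi] / (n * sd[usable] * sd[fi])
        p = _pearson_pvalues(r, n)
        q = bh_adjust(p)
        partners = {
            panel.index[i]: (float(ri), float(qi))
            for i, ri, qi in zip(usable, r, q)
            if qi < alpha
        }
        out.append(
            PartnerSet(focal, partners, n_tested=len(usable), n_excluded_constant=n_constant)
        )
    return out


def conservation_fraction(
    ps: PartnerSet,
    panel_b: pd.DataFrame,
    orthology: dict[str, str],
    alpha: float = 0.05,
) -> tuple[float | None, int]:
    """Fraction of a focal gene's partners conserved in the other species.

    The focal gene's orthologue is re-tested against the whole of panel B
    with the same procedure; a partner counts as conserved when its
    orthologue is significant there.  Partners without an orthologue in
    panel B are excluded from the denominator (returned as the tally).
    Returns (fraction or None when nothing is mappable, n_unmappable).
    """
    focal_b = orthology.get(ps.focal_gene)
    if focal_b is None or focal_b not in panel_b.index:
        return None, len(ps.partners)
    partners_b = partner_sets(panel_b, [focal_b], alpha=alpha)[0].partners
    mappable = 0
    conserved = 0
    unmappable = 0
    for partner in ps.partners:
        partner_b = orthology.get(partner)
        if partner_b is None or partner_b not in panel_b.index:
            unmappable += 1
            continue
        mappable += 1
        if partner_b in partners_b:
            conserved += 1
    if mappable == 0:
        return None, unmappable
    return conserved / mappable, unmappable


def compare_groups(
    fractions_focal, fractions_background, paired: bool = False
) -> tuple[float, float]:
    """Rank test of conservation fractions between two gene groups.

    Wilcoxon rank-sum (Mann-Whitney) for independent groups; the
    signed-rank procedure when paired.  Returns (statistic, two-sided p).
    """
    x = np.asarray(fractions_focal, dtype=float)
    y = np.asarray(fractions_background, dtype=float)
    if paired:
        res = stats.wilcoxon(x, y)
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
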