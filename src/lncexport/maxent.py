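"""Maximum-entropy models of fixed-width sequence sites.

One scorer serves both the U1-recognition score and the 5' splice-site
score: the U1 snRNP recognizes the 5'-splice consensus, a 9-mer with three
exonic and six intronic positions.  The model is the maximum-entropy
distribution over the 4^w site space subject to the low-order positional
marginal constraints of a training set:

* order 1 — all single-position marginals; the solution is the product of
  positional marginals (closed form).
* order 2 — all pairwise marginals; fitted by iterative proportional
  fitting (IPF) on the full joint table, run until the largest constrained
  marginal deviates by < 1e-4 or 500 sweeps.

A site's score is log2 P_model(site) / P_background(site); a "strong" site
exceeds a threshold calibrated to a chosen quantile (default 95th) of
scores of background-sampled sites.  A position-weight-matrix scorer with
the same interface is provided as a simpler alternative.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

# canonical 5'-splice/U1 consensus: 3 exonic + 6 intronic positions
DONOR_CONSENSUS = "CAGGTAAGT"
U1_CORE = "GGTAAGT"


def encode_sites(sites: list[str], width: int) -> np.ndarray:
    arr = np.empty((len(sites), width), dtype=np.int64)
    for i, s in enumerate(sites):
        if len(s) != width:
            raise ValueError(f"site {s!r} is not {width} nt")
        for j, b in enumerate(s):
            try:
                arr[i, j] = BASE_INDEX[b]
            except KeyError:
                raise ValueError(f"non-ACGT symbol {b!r} in site {s!r}") from None
    return arr


def _single_marginals(codes: np.ndarray, width: int, alpha: float = 0.0) -> np.ndarray:
    m = np.zeros((width, 4))
    for j in range(width):
        counts = np.bincount(codes[:, j], minlength=4).astype(float) + alpha
        m[j] = counts / counts.sum()
    return m


def _pair_marginals(
    codes: np.ndarray, width: int, alpha: float = 0.0
) -> dict[tuple[int, int], np.ndarray]:
    # alpha/4 per pair cell keeps pair marginals consistent with the
    # alpha-smoothed single marginals (row sums match)
    out = {}
    for i, j in itertools.combinations(range(width), 2):
        m = np.zeros((4, 4))
        np.add.at(m, (codes[:, i], codes[:, j]), 1.0)
        m += alpha / 4.0
        out[(i, j)] = m / m.sum()
    return out


def _ipf(
    width: int,
    pair_targets: dict[tuple[int, int], np.ndarray],
    tol: float = 1e-4,
    max_sweeps: int = 500,
) -> np.ndarray:
    """Iterative proportional fitting of the joint table to pairwise targets."""
    shape = (4,) * width
    p = np.full(shape, 1.0 / 4**width)
    axes = set(range(width))
    for _ in range(max_sweeps):
        max_dev = 0.0
        for (i, j), target in pair_targets.items():
            other = tuple(sorted(axes - {i, j}))
            cur = p.sum(axis=other)
            if i > j:  # sum() keeps remaining axes in order; align to (i, j)
                cur = cur.T
            max_dev = max(max_dev, float(np.abs(cur - target).max()))
            ratio = np.divide(target, cur, out=np.ones_like(cur), where=cur > 0)
            bshape = [1] * width
            bshape[i], bshape[j] = 4, 4
            if i < j:
                p = p * ratio.reshape(bshape)
            else:
                p = p * ratio.T.reshape(bshape)
        if max_dev < tol:
            break
    return p / p.sum()


@dataclass
class MotifModel:
    """Maximum-entropy site model with log2-odds scoring."""

    width: int
    constraint_order: int
    background: np.ndarray  # (width, 4) per-position probabilities
    joint: np.ndarray = field(repr=False)  # (4,)*width
    single_targets: np.ndarray = field(repr=False)
    pair_targets: dict = field(default_factory=dict, repr=False)
    strong_threshold: float | None = None

    # -- fitting -----------------------------------------------------------

    @classmethod
    def fit(
        cls,
        training_sites: list[str],
        constraint_order: int = 2,
        background: np.ndarray | None = None,
        width: int | None = None,
        pseudocount: float = 0.0,
    ) -> "MotifModel":
        """Fit to the training marginals; ``pseudocount`` adds Laplace mass
        so that unseen sites keep finite scores (0 = exact marginals)."""
        if not training_sites:
            raise ValueError("empty training set")
        width = width or len(training_sites[0])
        if constraint_order not in (1, 2):
            raise ValueError("constraint_order must be 1 or 2")
        codes = encode_sites(training_sites, width)
        singles = _single_marginals(codes, width, pseudocount)
        pairs = {}
        if constraint_order == 1:
            joint = singles[0]
            for j in range(1, width):
                joint = np.multiply.outer(joint, singles[j])
        else:
            pairs = _pair_marginals(codes, width, pseudocount)
            joint = _ipf(width, pairs)
        if background is None:
            background = np.full((width, 4), 0.25)
        background = np.asarray(background, dtype=float)
        if background.shape == (4,):
            background = np.tile(background, (width, 1))
        return cls(
            width=width,
            constraint_order=constraint_order,
            background=background,
            joint=joint,
            single_targets=singles,
            pair_targets=pairs,
        )

    # -- scoring -----------------------------------------------------------

    def site_probability(self, site: str) -> float:
        idx = tuple(encode_sites([site], self.width)[0])
        return float(self.joint[idx])

    def background_probability(self, site: str) -> float:
        codes = encode_sites([site], self.width)[0]
        return float(np.prod(self.background[np.arange(self.width), codes]))

    def score_site(self, site: str) -> float:
        """log2 odds of the site under the model versus background."""
        with np.errstate(divide="ignore"):
            return float(
                np.log2(self.site_probability(site))
                - np.log2(self.background_probability(site))
            )

    def score_codes(self, codes: np.ndarray) -> np.ndarray:
        """Vectorized scores for an (n, width) array of base codes."""
        p = self.joint[tuple(codes.T)]
        bg = self.background[np.arange(self.width)[None, :], codes].prod(axis=1)
        with np.errstate(divide="ignore"):
            return np.log2(p) - np.log2(bg)

    def normalization(self) -> float:
        return float(self.joint.sum())

    def calibrate_strong_threshold(
        self, rng: np.random.Generator, n: int = 10_000, quantile: float = 0.95
    ) -> float:
        """Set the 'strong' cutoff at a quantile of background-site scores."""
        codes = np.stack(
            [rng.choice(4, size=n, p=self.background[j]) for j in range(self.width)],
            axis=1,
        )
        scores = self.score_codes(codes)
        finite = scores[np.isfinite(scores)]
        self.strong_threshold = float(np.quantile(finite, quantile))
        return self.strong_threshold

    # -- serialization (marginals + background; order-2 refit on load) -----

    def to_json(self, path: str | Path) -> None:
        payload = {
            "width": self.width,
            "constraint_order": self.constraint_order,
            "background": self.background.tolist(),
            "single_targets": self.single_targets.tolist(),
            "pair_targets": {f"{i},{j}": m.tolist() for (i, j), m in self.pair_targets.items()},
            "strong_threshold": self.strong_threshold,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "MotifModel":
        payload = json.loads(Path(path).read_text())
        width = payload["width"]
        singles = np.array(payload["single_targets"])
        pairs = {
            tuple(map(int, k.split(","))): np.array(v)
            for k, v in payload["pair_targets"].items()
        }
        if payload["constraint_order"] == 1:
            joint = singles[0]
            for j in range(1, width):
                joint = np.multiply.outer(joint, singles[j])
        else:
            joint = _ipf(width, pairs)
        return cls(
            width=width,
            constraint_order=payload["constraint_order"],
            background=np.array(payload["background"]),
            joint=joint,
            single_targets=singles,
            pair_targets=pairs,
            strong_threshold=payload["strong_threshold"],
        )


@dataclass
class PWMModel:
    """Position-weight-matrix log2-odds scorer (same interface as MotifModel)."""

    width: int
    log_odds: np.ndarray  # (width, 4)
    strong_threshold: float | None = None

    @classmethod
    def fit(
        cls,
        training_sites: list[str],
        pseudocount: float = 0.5,
        background: np.ndarray | None = None,
    ) -> "PWMModel":
        if not training_sites:
            raise ValueError("empty training set")
        width = len(training_sites[0])
        codes = encode_sites(training_sites, width)
        counts = np.zeros((width, 4))
        for j in range(width):
            counts[j] = np.bincount(codes[:, j], minlength=4)
        probs = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True) + 4 * pseudocount)
        if background is None:
            background = np.full((width, 4), 0.25)
        return cls(width=width, log_odds=np.log2(probs) - np.log2(background))

    def score_site(self, site: str) -> float:
        codes = encode_sites([site], self.width)[0]
        return float(self.log_odds[np.arange(self.width), codes].sum())

    def score_codes(self, codes: np.ndarray) -> np.ndarray:
        return self.log_odds[np.arange(self.width)[None, :], codes].sum(axis=1)

    def calibrate_strong_threshold(
        self, rng: np.random.Generator, n: int = 10_000, quantile: float = 0.95
    ) -> float:
        codes = rng.integers(0, 4, size=(n, self.width))
        scores = self.log_odds[np.arange(self.width)[None, :], codes].sum(axis=1)
        self.strong_threshold = float(np.quantile(scores, quantile))
        return self.strong_threshold


# ---------------------------------------------------------------------------
# Scanning and densities


@dataclass
class MotifHit:
    gene_id: str
    position: int  # offset of the window start in the scanned sequence
    score: float
    region: str  # "exonic" / "intronic" / ""
    strong: bool


def scan_sequence(
    model,
    sequence: str,
    region_mask: list[str] | None = None,
    gene_id: str = "",
) -> tuple[list[MotifHit], int]:
    """Score every window of the (strand-resolved) sequence.

    ``region_mask`` labels each position (e.g. "exonic"/"intronic"); a hit
    takes the label at its window start.  Windows containing ambiguous
    bases are skipped and tallied in the second return value.
    """
    w = model.width
    hits: list[MotifHit] = []
    thr = model.strong_threshold
    if len(sequence) < w:
        return hits, 0
    codes = np.array([BASE_INDEX.get(b, -1) for b in sequence], dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    valid = (windows >= 0).all(axis=1)
    skipped = int((~valid).sum())
    positions = np.nonzero(valid)[0]
    scores = model.score_codes(windows[positions])
    for pos, score in zip(positions, scores):
        region = region_mask[pos] if region_mask is not None else ""
        strong = bool(thr is not None and score >= thr)
        hits.append(MotifHit(gene_id, int(pos), float(score), region, strong))
    return hits, skipped


def u1_density(hits: list[MotifHit], region_length: int, strong_only: bool = True) -> float:
    """Qualifying sites per kilobase of region."""
    if region_length <= 0:
        raise ValueError("region_length must be positive")
    n = sum(1 for h in hits if h.strong or not strong_only)
    return n / (region_length / 1_000)


# ---------------------------------------------------------------------------
# Variant effect scores


def delta_score(model, ref_context: str, alt_context: str) -> tuple[float, str]:
    """Score change of a single-nucleotide substitution within one window."""
    if len(ref_context) != len(alt_context):
        raise ValueError("contexts must have equal length")
    n_diff = sum(a != b for a, b in zip(ref_context, alt_context))
    if n_diff > 1:
        raise ValueError("contexts differ at more than one position")
    delta = model.score_site(alt_context) - model.score_site(ref_context)
    call = "strengthen" if delta > 0 else ("weaken" if delta < 0 else "neutral")
    return delta, call


def variant_delta(
    model, sequence: str, position: int, ref: str, alt: str
) -> tuple[float | None, str]:
    """Delta score for a variant inside a scanned sequence.

    Among all full-width windows overlapping the variant, the one with the
    maximal score (under either allele) is scored for both alleles.  Returns
    (None, "out_of_window") when no clean window covers the variant.
    """
    w = model.width
    if sequence[position] != ref:
        raise ValueError(
            f"reference mismatch at {position}: sequence has {sequence[position]!r}"
        )
    best: tuple[float, float] | None = None
    lo = max(0, position - w + 1)
    hi = min(position, len(sequence) - w)
    for start in range(lo, hi + 1):
        ref_win = sequence[start : start + w]
        if any(b not in BASE_INDEX for b in ref_win):
            continue
        alt_win = ref_win[: position - start] + alt + ref_win[position - start + 1 :]
        s_ref = model.score_site(ref_win)
        s_alt = model.score_site(alt_win)
        key = max(s_ref, s_alt)
        if best is None or key > best[0]:
            best = (key, s_alt - s_ref)
    if best is None:
        return None, "out_of_window"
    delta = best[1]
    call = "strengthen" if delta > 0 else ("weaken" if delta < 0 else "neutral")
    return delta, call


# ---------------------------------------------------------------------------
# Exports


def write_bed(hits: list[MotifHit], chrom: str, handle) -> None:
    """BED6; score column = log2-odds x 100, rounded."""
    close = False
    if isinstance(handle, (str, Path)):
        handle, close = open(handle, "w"), True
    try:
        for h in hits:
            score = int(round(h.score * 100)) if np.isfinite(h.score) else -9999
            handle.write(
                f"{chrom}\t{h.position}\t{h.position + 9}\t{h.gene_id}\t{score}\t+\n"
            )
    finally:
        if close:
            handle.close()


def write_meme(pfms: dict[str, np.ndarray], handle) -> None:
    """Minimal MEME-format export of probability matrices (columns ACGT)."""
    close = False
    if isinstance(handle, (str, Path)):
        handle, close = open(handle, "w"), True
    try:
        handle.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        handle.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for name, pfm in pfms.items():
            probs = pfm / pfm.sum(axis=1, keepdims=True)
            handle.write(f"MOTIF {name}\n")
            handle.write(f"letter-probability matrix: alength= 4 w= {len(probs)}\n")
            for row in probs:
                handle.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            handle.write("\n")
    finally:
        if close:
            handle.close()
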