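"""CNN classifier of nuclear- versus cytosol-enriched transcripts.

Sequences from the extreme tails of the N/C distribution (top 5% nuclear,
bottom 5% cytosolic by default, length < 5,000 nt) are one-hot encoded and
classified by a compact convolutional network whose first layer slides
11-nt filters along the transcript — the receptive field that makes the
learned filters directly interpretable as sequence motifs.  After training,
position-frequency matrices are extracted from the first-layer filters by
collecting the windows that activate each filter most strongly.

The network is implemented directly in numpy (im2col convolutions, ReLU,
local max pooling, masked global mean pooling, one logistic output unit,
Adam, early stopping on validation loss).  Global mean pooling makes the
penultimate representation a per-filter motif *density*, which is the
quantity the export model of the synthetic data operates on.  Everything is
seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_BASE_TO_COL = {b: i for i, b in enumerate(BASES)}


@dataclass
class LabeledSequence:
    gene_id: str
    sequence: str
    label: str  # "nuclear" / "cytosolic"
    split: str = ""  # "train" / "valid" / "test"


def label_extremes(
    nc_table, sequences: dict[str, str], fraction: float = 0.05, max_len: int = 5_000
) -> list[LabeledSequence]:
    """Label the N/C extremes: highest tail nuclear, lowest cytosolic.

    Only filter-passing genes shorter than ``max_len`` are eligible;
    floor(fraction x n) genes per class, boundary ties broken by gene_id.
    """
    df = nc_table[nc_table["passed_filter"]].copy()
    df = df[df["gene_id"].map(lambda g: g in sequences and len(sequences[g]) < max_len)]
    df = df.sort_values(["nc_ratio", "gene_id"], ascending=[False, True])
    k = int(fraction * len(df))
    nuclear = df.head(k)["gene_id"].tolist()
    cytosolic = df.tail(k)["gene_id"].tolist()
    out = [LabeledSequence(g, sequences[g], "nuclear") for g in nuclear]
    out += [LabeledSequence(g, sequences[g], "cytosolic") for g in cytosolic]
    return out


def encode_onehot(sequence: str) -> np.ndarray:
    """(L, 4) one-hot; N (or any ambiguity) encodes as an all-zero row."""
    mat = np.zeros((len(sequence), 4), dtype=np.float32)
    for i, b in enumerate(sequence):
        j = _BASE_TO_COL.get(b)
        if j is not None:
            mat[i, j] = 1.0
    return mat


def decode_onehot(matrix: np.ndarray) -> str:
    out = []
    for row in matrix:
        j = int(np.argmax(row))
        out.append(BASES[j] if row[j] > 0 else "N")
    return "".join(out)


def split_dataset(
    labeled: list[LabeledSequence], ratios: tuple[int, int, int] = (8, 1, 1), seed: int = 0
) -> list[LabeledSequence]:
    """Class-stratified train/valid/test assignment (8:1:1 by default)."""
    rng = np.random.default_rng(seed)
    total = sum(ratios)
    for label in sorted({s.label for s in labeled}):
        members = [s for s in labeled if s.label == label]
        order = rng.permutation(len(members))
        n = len(members)
        n_train = int(round(n * ratios[0] / total))
        n_valid = int(round(n * ratios[1] / total))
        for rank, idx in enumerate(order):
            if rank < n_train:
                members[idx].split = "train"
            elif rank < n_train + n_valid:
                members[idx].split = "valid"
            else:
                members[idx].split = "test"
    return labeled


@dataclass
class ClassifierSpec:
    """Architecture and optimization settings.

    ``conv_blocks`` is a list of (n_filters, filter_width, pool_width);
    pool_width 1 means no local pooling after that block.  The first
    filter width is 11 by construction of the motif-extraction stage.
    """

    conv_blocks: list[tuple[int, int, int]] = field(
        default_factory=lambda: [(24, 11, 6), (32, 5, 1)]
    )
    learning_rate: float = 1e-2
    batch_size: int = 32
    max_epochs: int = 20
    patience: int = 4
    seed: int = 0


def evaluate_auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC; ties get average ranks."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for AUC")
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(len(scores), dtype=float)
    sorted_scores = scores[order]
    i = 0
    while i < len(scores):
        j = i
        while j + 1 < len(scores) and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _windows(x: np.ndarray, width: int) -> np.ndarray:
    """im2col: (B, L, C) -> (B, L-width+1, width*C)."""
    B, L, C = x.shape
    w = np.lib.stride_tricks.sliding_window_view(x, width, axis=1)  # (B, L-w+1, C, w)
    return np.ascontiguousarray(w.transpose(0, 1, 3, 2)).reshape(B, L - width + 1, width * C)


class ExportCNN:
    """Sequence classifier; probability of the 'nuclear' class."""

    def __init__(self, spec: ClassifierSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        in_ch = 4
        for n_filters, width, _pool in spec.conv_blocks:
            fan_in = width * in_ch
            self.W.append(
                (rng.standard_normal((fan_in, n_filters)) * np.sqrt(2.0 / fan_in)).astype(
                    np.float32
                )
            )
            self.b.append(np.zeros(n_filters, dtype=np.float32))
            in_ch = n_filters
        self.w_out = (rng.standard_normal(in_ch) * np.sqrt(1.0 / in_ch)).astype(np.float32)
        self.b_out = np.float32(0.0)
        self.history: list[dict] = []

    # -- forward ------------------------------------------------------------

    def _params(self):
        return self.W + self.b + [self.w_out, np.atleast_1d(self.b_out)]

    def _forward(self, X: np.ndarray, lengths: np.ndarray, keep: bool = False):
        """X: (B, L, 4) zero-padded; lengths: valid nt per sequence."""
        cache = []
        h = X
        valid = lengths.copy()
        for layer, (n_filters, width, pool) in enumerate(self.spec.conv_blocks):
            in_len = h.shape[1]
            if in_len < width:  # zero-pad so at least one window exists
                h = np.pad(h, ((0, 0), (0, width - in_len), (0, 0)))
            cols = _windows(h, width)
            z = cols @ self.W[layer] + self.b[layer]
            # a sequence shorter than the filter keeps its one (zero-padded)
            # window; empty sequences stay fully masked
            conv_valid = np.minimum(valid, in_len) - width + 1
            valid = np.where(valid > 0, np.maximum(conv_valid, 1), 0)
            # mask activations of windows that run past each sequence's end
            pos = np.arange(z.shape[1])[None, :]
            mask = pos < valid[:, None]
            a = np.maximum(z, 0.0) * mask[:, :, None]
            if pool > 1:
                n_out = a.shape[1] // pool
                ar = a[:, : n_out * pool].reshape(a.shape[0], n_out, pool, -1)
                idx = ar.argmax(axis=2)
                a_p = np.take_along_axis(ar, idx[:, :, None, :], axis=2)[:, :, 0, :]
                valid = np.where(valid > 0, np.maximum(valid // pool, 1), 0)
            else:
                a_p, idx, ar = a, None, None
            if keep:
                cache.append((cols, z, mask, a, idx, ar, pool, in_len))
            h = a_p
        pos = np.arange(h.shape[1])[None, :]
        final_mask = pos < np.maximum(valid, 1)[:, None]
        denom = final_mask.sum(axis=1, keepdims=True).astype(np.float32)
        pooled = (h * final_mask[:, :, None]).sum(axis=1) / denom
        logits = pooled @ self.w_out + self.b_out
        probs = 1.0 / (1.0 + np.exp(-logits))
        if keep:
            return probs, (cache, h, final_mask, denom, pooled)
        return probs

    # -- backward + fit -------------------------------------------------------

    def _backward(self, X, lengths, y, probs, fwd):
        cache, h, final_mask, denom, pooled = fwd
        B = len(y)
        dlogits = (probs - y) / B  # BCE w.r.t. logits
        gw_out = pooled.T @ dlogits
        gb_out = dlogits.sum()
        dh = (
            dlogits[:, None, None]
            * self.w_out[None, None, :]
            * final_mask[:, :, None]
            / denom[:, :, None]
        )
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        for layer in range(len(self.spec.conv_blocks) - 1, -1, -1):
            cols, z, mask, a, idx, ar, pool, in_len = cache[layer]
            if pool > 1:
                da = np.zeros_like(a)
                n_out = idx.shape[1]
                dar = da[:, : n_out * pool].reshape(a.shape[0], n_out, pool, -1)
                np.put_along_axis(dar, idx[:, :, None, :], dh[:, :, None, :], axis=2)
                da[:, : n_out * pool] = dar.reshape(a.shape[0], n_out * pool, -1)
            else:
                da = dh
            dz = da * (z > 0) * mask[:, :, None]
            gW[layer] = np.einsum("bpf,bpk->fk", cols, dz, optimize=True)
            gb[layer] = dz.sum(axis=(0, 1))
            if layer > 0:
                # col2im back into the previous layer's pooled output
                width = self.spec.conv_blocks[layer][1]
                dcols = dz @ self.W[layer].T  # (B, P, width*C)
                C = self.W[layer].shape[0] // width
                dcols = dcols.reshape(dz.shape[0], dz.shape[1], width, C)
                dh = np.zeros(
                    (dz.shape[0], dz.shape[1] + width - 1, C), dtype=np.float32
                )
                for k in range(width):
                    dh[:, k : k + dz.shape[1]] += dcols[:, :, k]
                dh = dh[:, :in_len]  # drop gradient on zero-padding
        return gW + gb + [gw_out, np.atleast_1d(np.float32(gb_out))]

    @staticmethod
    def _pack(seqs: list[LabeledSequence]):
        X = [encode_onehot(s.sequence) for s in seqs]
        y = np.array([1.0 if s.label == "nuclear" else 0.0 for s in seqs], dtype=np.float32)
        return X, y

    @staticmethod
    def _pad(mats: list[np.ndarray]):
        lengths = np.array([len(m) for m in mats])
        L = lengths.max()
        X = np.zeros((len(mats), L, 4), dtype=np.float32)
        for i, m in enumerate(mats):
            X[i, : len(m)] = m
        return X, lengths

    def predict_proba(self, seqs: list[LabeledSequence], batch_size: int = 64) -> np.ndarray:
        mats = [encode_onehot(s.sequence) for s in seqs]
        order = np.argsort([len(m) for m in mats], kind="mergesort")
        probs = np.empty(len(mats))
        for i in range(0, len(order), batch_size):
            idx = order[i : i + batch_size]
            X, lengths = self._pad([mats[j] for j in idx])
            probs[idx] = self._forward(X, lengths)
        return probs

    def fit(self, train: list[LabeledSequence], valid: list[LabeledSequence]) -> "ExportCNN":
        if not train or not valid:
            raise ValueError("train and valid sets must be non-empty")
        labels = {s.label for s in train}
        if len(labels) < 2:
            raise ValueError("training set contains a single class")
        rng = np.random.default_rng(self.spec.seed + 1)
        mats, y = self._pack(train)
        opt = _Adam(self._params(), self.spec.learning_rate)
        best_loss, best_state, bad_epochs = np.inf, None, 0
        for epoch in range(self.spec.max_epochs):
            order = rng.permutation(len(mats))
            # length-bucketed batches keep padding (and wasted FLOPs) small
            bs = self.spec.batch_size
            chunks = [order[i : i + 8 * bs] for i in range(0, len(order), 8 * bs)]
            batches = []
            for chunk in chunks:
                by_len = sorted(chunk, key=lambda j: len(mats[j]))
                batches += [by_len[i : i + bs] for i in range(0, len(by_len), bs)]
            train_loss = 0.0
            for batch in batches:
                X, lengths = self._pad([mats[j] for j in batch])
                yb = y[list(batch)]
                probs, fwd = self._forward(X, lengths, keep=True)
                eps = 1e-7
                train_loss -= float(
                    np.sum(yb * np.log(probs + eps) + (1 - yb) * np.log(1 - probs + eps))
                )
                grads = self._backward(X, lengths, yb, probs, fwd)
                params = self._params()
                opt.step(params, grads)
                self.W = params[: len(self.W)]
                self.b = params[len(self.W) : 2 * len(self.W)]
                self.w_out, self.b_out = params[-2], np.float32(params[-1][0])
            val_probs = self.predict_proba(valid)
            yv = np.array([1.0 if s.label == "nuclear" else 0.0 for s in valid])
            eps = 1e-7
            val_loss = float(
                -np.mean(yv * np.log(val_probs + eps) + (1 - yv) * np.log(1 - val_probs + eps))
            )
            self.history.append(
                {"epoch": epoch, "train_loss": train_loss / len(mats), "valid_loss": val_loss}
            )
            if val_loss < best_loss - 1e-5:
                best_loss = val_loss
                best_state = [p.copy() for p in self._params()]
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= self.spec.patience:
                    break
        if best_state is not None:
            self.W = best_state[: len(self.W)]
            self.b = best_state[len(self.W) : 2 * len(self.W)]
            self.w_out, self.b_out = best_state[-2], np.float32(best_state[-1][0])
        return self


def train(
    spec: ClassifierSpec, train_set: list[LabeledSequence], valid_set: list[LabeledSequence]
) -> ExportCNN:
    """Train a fresh classifier under the given spec."""
    return ExportCNN(spec).fit(train_set, valid_set)


# ---------------------------------------------------------------------------
# Motif extraction


@dataclass
class ExtractedMotif:
    filter_id: int
    rank: int
    activation_score: float
    pfm: np.ndarray  # (width, 4) counts
    n_contributing_windows: int

    def pfm_probabilities(self) -> np.ndarray:
        return self.pfm / self.pfm.sum(axis=1, keepdims=True)


def extract_motifs(
    model: ExportCNN,
    sequences: list[LabeledSequence],
    top_k: int = 5,
    activation_quantile: float = 0.5,
    max_windows_per_filter: int = 5_000,
) -> list[ExtractedMotif]:
    """Turn first-layer filters into position-frequency matrices.

    For each filter, the windows whose first-layer activation reaches at
    least ``activation_quantile`` of that filter's maximum are stacked into
    an (11 x 4) count matrix; filters are ranked by the mean activation of
    their contributing windows and the top_k returned.
    """
    if not sequences:
        raise ValueError("no sequences to extract motifs from")
    width = model.spec.conv_blocks[0][1]
    n_filters = model.spec.conv_blocks[0][0]
    acts: list[np.ndarray] = []
    wins: list[np.ndarray] = []
    for s in sequences:
        oh = encode_onehot(s.sequence)
        if len(oh) < width:
            continue
        cols = _windows(oh[None], width)[0]  # (P, width*4)
        z = cols @ model.W[0] + model.b[0]
        acts.append(z)
        wins.append(cols)
    A = np.concatenate(acts, axis=0)  # (n_windows, n_filters)
    Wn = np.concatenate(wins, axis=0)
    motifs = []
    for f in range(n_filters):
        a = A[:, f]
        peak = a.max()
        if peak <= 0:
            continue
        sel = np.nonzero(a >= activation_quantile * peak)[0]
        if len(sel) > max_windows_per_filter:
            sel = sel[np.argsort(a[sel])[::-1][:max_windows_per_filter]]
        pfm = Wn[sel].reshape(len(sel), width, 4).sum(axis=0)
        motifs.append(
            ExtractedMotif(
                filter_id=f,
                rank=-1,
                activation_score=float(a[sel].mean()),
                pfm=pfm,
                n_contributing_windows=len(sel),
            )
        )
    motifs.sort(key=lambda m: -m.activation_score)
    for rank, m in enumerate(motifs):
        m.rank = rank
    return motifs[:top_k]


def pfm_match_correlation(pfm: np.ndarray, planted_pwm: np.ndarray) -> float:
    """Best Pearson correlation of a planted PWM slid along an extracted PFM.

    Both matrices are column-normalized to probabilities; the shorter
    planted motif is compared at every offset of the wider PFM and the
    maximum correlation returned.
    """
    p = pfm / pfm.sum(axis=1, keepdims=True)
    q = planted_pwm / planted_pwm.sum(axis=1, keepdims=True)
    w_p, w_q = len(p), len(q)
    if w_q > w_p:
        p, q = q, p
        w_p, w_q = w_q, w_p
    best = -1.0
    for off in range(w_p - w_q + 1):
        a = p[off : off + w_q].ravel()
        b = q.ravel()
        if a.std() == 0 or b.std() == 0:
            continue
        best = max(best, float(np.corrcoef(a, b)[0, 1]))
    return best
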