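"""PWM construction, sensitivity-calibrated scanning and exact hit-count P-values.

The binding model is a position weight matrix (PWM) with log-odds weights

    w(i, b) = ln( (n(i, b) + a * p_b) / ((N + a) * p_b) )

built from an alignment of equal-length sites with pseudocount ``a``
distributed by the background composition ``p``.  The scan threshold is
calibrated so that a chosen fraction (default 90%) of the training sites
score above it.

For a sequence of length ``L_seq`` the P-value of observing at least ``k``
(possibly overlapping) hits scoring >= T in an i.i.d. (or first-order Markov)
random sequence with the same composition is computed exactly: the set of
above-threshold words (and, in double-strand mode, words whose reverse
complement scores above threshold) is compiled into an Aho-Corasick automaton
and a dynamic program over (state, hit count capped at k) propagates
probability mass position by position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "PWM",
    "ScanResult",
    "MotifPValue",
    "build_pwm",
    "calibrate_threshold",
    "scan",
    "pvalue_at_least_k",
    "enrichment_curve",
    "cumulative_curve",
    "make_control",
    "sequence_background",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = np.array([3, 2, 1, 0])  # A<->T, C<->G


def _encode(seq: str) -> np.ndarray:
    out = np.full(len(seq), -1, dtype=np.int8)
    for i, ch in enumerate(seq.upper()):
        out[i] = _BASE_INDEX.get(ch, -1)
    return out


@dataclass(frozen=True)
class PWM:
    """Position weight matrix with provenance count matrix and background."""

    weights: np.ndarray  #: (L, 4) log-odds weights, base order A,C,G,T
    background: np.ndarray  #: (4,) background probabilities, sum 1
    counts: np.ndarray | None = None  #: (L, 4) training counts
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[1] != 4 or w.shape[0] < 1:
            raise ValueError("weights must be (L, 4) with L >= 1")
        if not np.isfinite(w).all():
            raise ValueError("weights must be finite")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be 4 probabilities summing to 1")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "background", bg)

    @property
    def length(self) -> int:
        return self.weights.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.weights.min(axis=1).sum())

    def score_word(self, word: str) -> float:
        code = _encode(word)
        if len(code) != self.length or (code < 0).any():
            raise ValueError("word length/alphabet mismatch")
        return float(self.weights[np.arange(self.length), code].sum())

    def frequency_table(self) -> pd.DataFrame:
        """Per-position base frequencies of the training sites (text logo)."""
        if self.counts is None:
            raise ValueError("PWM carries no count matrix")
        freq = self.counts / self.counts.sum(axis=1, keepdims=True)
        return pd.DataFrame(freq, columns=list(BASES)).rename_axis("position")

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.weights.argmax(axis=1))


def build_pwm(
    aligned_sites: Sequence[str],
    pseudocount: float = 1.0,
    background: Sequence[float] | None = None,
) -> PWM:
    """Build a PWM from equal-length gapless aligned sites."""
    if not aligned_sites:
        raise ValueError("no sites given")
    length = len(aligned_sites[0])
    if any(len(s) != length for s in aligned_sites):
        raise ValueError("sites differ in length")
    bg = (
        np.full(4, 0.25)
        if background is None
        else np.asarray(background, dtype=float)
    )
    counts = np.zeros((length, 4))
    for s in aligned_sites:
        code = _encode(s)
        if (code < 0).any():
            raise ValueError(f"site {s!r} contains non-ACGT characters")
        counts[np.arange(length), code] += 1
    n = len(aligned_sites)
    weights = np.log((counts + pseudocount * bg) / ((n + pseudocount) * bg))
    return PWM(weights, bg, counts=counts, pseudocount=pseudocount)


def _window_scores(code: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Scores of all windows; windows containing non-ACGT get -inf."""
    L = weights.shape[0]
    n = len(code)
    if n < L:
        return np.empty(0)
    valid = code >= 0
    safe = np.where(valid, code, 0)
    mat = np.lib.stride_tricks.sliding_window_view(safe, L)
    ok = np.lib.stride_tricks.sliding_window_view(valid, L).all(axis=1)
    scores = weights[np.arange(L), mat].sum(axis=1)
    return np.where(ok, scores, -np.inf)


def best_hit_score(seq: str, pwm: PWM, *, both_strands: bool = True) -> float:
    """Best window score of a sequence (both strands by default)."""
    code = _encode(seq)
    scores = _window_scores(code, pwm.weights)
    if both_strands:
        rc_scores = _window_scores(_encode(_revcomp(seq)), pwm.weights)
        scores = np.concatenate([scores, rc_scores])
    if not len(scores):
        return -np.inf
    return float(scores.max())


def _revcomp(seq: str) -> str:
    table = str.maketrans("ACGTN", "TGCAN")
    return seq.upper().translate(table)[::-1]


def calibrate_threshold(
    pwm: PWM,
    training_sites: Sequence[str],
    sensitivity: float = 0.90,
    *,
    both_strands: bool = True,
) -> float:
    """Threshold recovering at least ``sensitivity`` of training sites.

    Returns the largest score T such that at least a ``sensitivity`` fraction
    of the training sites have best-hit score >= T: the empirical
    (1 - sensitivity) quantile of per-site best scores.
    """
    if not (0.0 < sensitivity <= 1.0):
        raise ValueError("sensitivity must be in (0, 1]")
    scores = np.array(
        [best_hit_score(s, pwm, both_strands=both_strands) for s in training_sites]
    )
    if not len(scores):
        raise ValueError("no training sites")
    k = int(np.ceil(sensitivity * len(scores)))
    return float(np.sort(scores)[::-1][k - 1])


@dataclass
class ScanResult:
    """Hits of a PWM scan: positions, strands and scores of windows >= T."""

    seq_id: str
    threshold: float
    hits: list[tuple[int, str, float]] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.hits)


def scan(
    seq: str,
    pwm: PWM,
    threshold: float,
    *,
    seq_id: str = "seq",
    both_strands: bool = True,
) -> ScanResult:
    """Record every window scoring >= threshold; overlapping hits all count.

    A sequence shorter than the motif yields k = 0.
    """
    code = _encode(seq)
    hits: list[tuple[int, str, float]] = []
    fwd = _window_scores(code, pwm.weights)
    for pos in np.flatnonzero(fwd >= threshold):
        hits.append((int(pos), "+", float(fwd[pos])))
    if both_strands:
        # score the reverse complement of each window in place; the recorded
        # score is recomputed on the reverse-complement word so that
        # re-scoring reported hits reproduces scores bit-exactly
        rc_weights = pwm.weights[::-1, ::-1]
        rev = _window_scores(code, rc_weights)
        for pos in np.flatnonzero(rev >= threshold):
            word = _revcomp(seq[pos : pos + pwm.length])
            hits.append((int(pos), "-", pwm.score_word(word)))
    hits.sort(key=lambda h: (h[0], h[1]))
    return ScanResult(seq_id=seq_id, threshold=threshold, hits=hits)


@dataclass(frozen=True)
class MotifPValue:
    """P(#hits >= k) for a random sequence of given length and composition."""

    p: float
    length: int
    k: int
    background_order: int
    n_words: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 + 1e-12):
            raise ValueError("p outside [0, 1]")


def _all_word_scores(pwm: PWM) -> np.ndarray:
    """Scores of all 4^L words, word index base-4 big-endian."""
    L = pwm.length
    scores = np.zeros(1)
    for i in range(L):
        scores = (scores[:, None] + pwm.weights[i][None, :]).ravel()
    return scores


def _word_occurrence_weights(
    pwm: PWM, threshold: float, both_strands: bool
) -> np.ndarray:
    """occ[word] = number of strand-hits the word contributes (0, 1 or 2)."""
    L = pwm.length
    scores = _all_word_scores(pwm)
    occ = (scores >= threshold).astype(np.int8)
    if both_strands:
        idx = np.arange(4 ** L)
        rc = np.zeros_like(idx)
        x = idx.copy()
        for _ in range(L):
            rc = rc * 4 + _COMPLEMENT[x % 4]
            x //= 4
        occ = occ + (scores[rc] >= threshold).astype(np.int8)
    return occ


class _Automaton:
    """Aho-Corasick automaton over the above-threshold word set.

    All words share one length, so occurrences fire exactly on depth-L
    states; ``inc`` carries the per-word strand multiplicity (1 or 2).
    """

    def __init__(self, words: np.ndarray, incs: np.ndarray, length: int) -> None:
        # trie construction; all four depth-1 nodes are materialised so every
        # non-initial state knows its last character (needed for order-1
        # backgrounds: the automaton state then determines the previous base)
        goto: list[list[int]] = [[-1] * 4]
        depth = [0]
        self.inc_state = [0]
        for c in range(4):
            goto.append([-1] * 4)
            depth.append(1)
            self.inc_state.append(0)
            goto[0][c] = len(goto) - 1
        for w, inc in zip(words, incs):
            digits = [(int(w) >> (2 * (length - 1 - i))) & 3 for i in range(length)]
            s = 0
            for d in digits:
                if goto[s][d] == -1:
                    goto.append([-1] * 4)
                    depth.append(depth[s] + 1)
                    self.inc_state.append(0)
                    goto[s][d] = len(goto) - 1
                s = goto[s][d]
            self.inc_state[s] = int(inc)
        n = len(goto)
        fail = [0] * n
        # BFS to complete transitions
        from collections import deque

        queue = deque()
        delta = np.zeros((n, 4), dtype=np.int32)
        for c in range(4):
            t = goto[0][c]
            if t == -1:
                delta[0, c] = 0
            else:
                delta[0, c] = t
                fail[t] = 0
                queue.append(t)
        while queue:
            s = queue.popleft()
            for c in range(4):
                t = goto[s][c]
                if t == -1:
                    delta[s, c] = delta[fail[s], c]
                else:
                    delta[s, c] = t
                    fail[t] = delta[fail[s], c]
                    queue.append(t)
        self.delta = delta
        self.n_states = n
        self.inc = np.asarray(self.inc_state, dtype=np.int8)
        # occurrences only fire on full-length words (deepest states)
        self.inc[np.asarray(depth) < length] = 0


def pvalue_at_least_k(
    length: int,
    background: Sequence[float] | np.ndarray | Mapping[str, float],
    pwm: PWM,
    threshold: float,
    k: int,
    *,
    both_strands: bool = True,
    background_order: int = 0,
    transition: np.ndarray | None = None,
) -> MotifPValue:
    """Exact P(at least k possibly-overlapping hits) in a random sequence.

    ``background`` is the i.i.d. base distribution (order 0); with
    ``background_order=1`` a first-order chain is used, ``transition`` being
    the (4, 4) matrix of P(next | current) and ``background`` its initial
    distribution.  The DP tracks (automaton state, hit count capped at k), so
    the result is exact to floating precision.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return MotifPValue(1.0, length, 0, background_order, 0)
    if isinstance(background, Mapping):
        bg = np.array([background.get(b, 0.0) for b in BASES], dtype=float)
    else:
        bg = np.asarray(background, dtype=float)
    bg = bg / bg.sum()
    if background_order == 1 and transition is None:
        raise ValueError("order-1 background needs a transition matrix")

    occ = _word_occurrence_weights(pwm, threshold, both_strands)
    words = np.flatnonzero(occ)
    if not len(words) or length < pwm.length:
        return MotifPValue(0.0, length, k, background_order, int(len(words)))
    auto = _Automaton(words, occ[words], pwm.length)
    S = auto.n_states

    # sparse transition operators per occurrence increment; in order-1 mode
    # emission probabilities condition on the state's last character
    last_char = np.full(S, -1, dtype=np.int8)
    for s in range(S):
        for c in range(4):
            t = auto.delta[s, c]
            if t != 0:
                last_char[t] = c
    mats = {}
    for inc in (0, 1, 2):
        rows, cols, vals = [], [], []
        for s in range(S):
            for c in range(4):
                t = auto.delta[s, c]
                if auto.inc[t] != inc:
                    continue
                if background_order == 1 and last_char[s] >= 0:
                    p = transition[last_char[s], c]
                else:
                    p = bg[c]
                rows.append(s)
                cols.append(t)
                vals.append(p)
        mats[inc] = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(S, S), dtype=float
        )

    kk = k  # cap
    x = np.zeros((kk + 1, S))
    x[0, 0] = 1.0
    m0t = mats[0].T.tocsr()
    m1t = mats[1].T.tocsr()
    m2t = mats[2].T.tocsr()
    has1, has2 = mats[1].nnz > 0, mats[2].nnz > 0
    for _ in range(length):
        new = np.zeros_like(x)
        for j in range(kk + 1):
            acc = m0t @ x[j]
            if has1:
                src = x[j - 1] if j >= 1 else None
                if j == kk:
                    src = x[kk - 1] + x[kk] if kk >= 1 else x[kk]
                if src is not None:
                    acc = acc + m1t @ src
            if has2:
                if j == kk:
                    src2 = x[max(kk - 2, 0) : kk + 1].sum(axis=0) if kk >= 2 else x[: kk + 1].sum(axis=0)
                    acc = acc + m2t @ src2
                elif j >= 2:
                    acc = acc + m2t @ x[j - 2]
            new[j] = acc
        x = new
    p_lt = float(x[:kk].sum())
    p = max(0.0, min(1.0, 1.0 - p_lt))
    return MotifPValue(p, length, k, background_order, int(len(words)))


def sequence_background(seq: str, order: int = 0):
    """Composition of a sequence: base frequencies, plus transitions if order 1."""
    code = _encode(seq)
    code = code[code >= 0]
    counts = np.bincount(code, minlength=4).astype(float)
    if counts.sum() == 0:
        raise ValueError("sequence has no unambiguous bases")
    bg = counts / counts.sum()
    if order == 0:
        return bg
    trans = np.zeros((4, 4))
    np.add.at(trans, (code[:-1], code[1:]), 1.0)
    rowsum = trans.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        trans = np.where(rowsum > 0, trans / rowsum, 0.25)
    return bg, trans


def enrichment_curve(
    seq_sets: Mapping[str, Sequence[str]],
    pwm: PWM,
    threshold: float,
    *,
    both_strands: bool = True,
    background_order: int = 0,
    max_k: int = 50,
) -> pd.DataFrame:
    """Per-sequence motif-occurrence significance across sequence sets.

    For each sequence the background is estimated from its own composition,
    the hit count k comes from scanning at ``threshold``, and the exact
    P(>= k) is computed.  Returns one row per sequence with columns
    ``set_name, seq_index, length, k, p, neg_log10_p``.
    """
    rows = []
    for name, seqs in seq_sets.items():
        for i, seq in enumerate(seqs):
            res = scan(seq, pwm, threshold, both_strands=both_strands)
            k = min(res.k, max_k)
            if background_order == 1:
                bg, trans = sequence_background(seq, order=1)
            else:
                bg, trans = sequence_background(seq, order=0), None
            pv = pvalue_at_least_k(
                len(seq),
                bg,
                pwm,
                threshold,
                k,
                both_strands=both_strands,
                background_order=background_order,
                transition=trans,
            )
            p = max(pv.p, 1e-300)
            rows.append(
                {
                    "set_name": name,
                    "seq_index": i,
                    "length": len(seq),
                    "k": res.k,
                    "p": pv.p,
                    "neg_log10_p": -np.log10(p),
                }
            )
    return pd.DataFrame(rows)


def cumulative_curve(
    per_seq: pd.DataFrame, grid: np.ndarray | None = None
) -> pd.DataFrame:
    """Cumulative fraction of sequences at least as significant as each grid point."""
    if grid is None:
        grid = np.linspace(0.0, 20.0, 81)
    rows = []
    for name, sub in per_seq.groupby("set_name"):
        vals = sub["neg_log10_p"].to_numpy()
        for g in grid:
            rows.append(
                {
                    "set_name": name,
                    "neg_log10_p": float(g),
                    "fraction": float((vals >= g).mean()),
                }
            )
    return pd.DataFrame(rows)


def make_control(
    seq: str,
    rng: np.random.Generator,
    mode: str = "dinucleotide_shuffle",
    *,
    max_tries: int = 200,
) -> str:
    """Composition-preserving control sequence.

    ``dinucleotide_shuffle`` preserves the dinucleotide count vector exactly
    (random Eulerian path with the same start and end); ``markov1`` samples a
    fresh sequence from a first-order chain fitted to the input.
    """
    seq = seq.upper()
    if len(seq) < 2:
        return seq
    if mode == "markov1":
        bg, trans = sequence_background(seq, order=1)
        out = [rng.choice(4, p=bg)]
        for _ in range(len(seq) - 1):
            out.append(rng.choice(4, p=trans[out[-1]]))
        return "".join(BASES[i] for i in out)
    if mode != "dinucleotide_shuffle":
        raise ValueError(f"unknown control mode {mode!r}")

    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    start, end = seq[0], seq[-1]
    vertices = [v for v in edges if v != end]

    for _ in range(max_tries):
        # pick candidate "last edges" forming paths to the end vertex
        last_edge = {}
        for v in vertices:
            last_edge[v] = edges[v][rng.integers(0, len(edges[v]))]
        # check connectivity of the last-edge graph toward `end`
        ok = True
        for v in vertices:
            seen = set()
            cur = v
            while cur != end:
                if cur in seen or cur not in last_edge:
                    ok = False
                    break
                seen.add(cur)
                cur = last_edge[cur]
            if not ok:
                break
        if not ok:
            continue
        # shuffle the remaining edges, append the reserved last edge
        pools: dict[str, list[str]] = {}
        for v, targets in edges.items():
            rest = list(targets)
            if v in last_edge:
                rest.remove(last_edge[v])
            order = rng.permutation(len(rest))
            pools[v] = [rest[i] for i in order]
            if v in last_edge:
                pools[v].append(last_edge[v])
        out = [start]
        ptr = {v: 0 for v in pools}
        cur = start
        for _ in range(len(seq) - 1):
            nxt = pools[cur][ptr[cur]]
            ptr[cur] += 1
            out.append(nxt)
            cur = nxt
        if len(out) == len(seq):
            return "".join(out)
    raise RuntimeError("dinucleotide shuffle failed to converge")
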