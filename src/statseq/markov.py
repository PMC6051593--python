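"""Order-k Markov stimulus models, sequence generation and KL-based selection.

The stimulus streams of the prediction task are drawn from Markov models of
order k = 0, 1 or 2 over four abstract items A-D.  The three levels are
matched in context-conditional uncertainty:

* level-0 (memoryless): one frequent item (p = 0.72), one intermediate
  (p = 0.18) and two rare ones (p = 0.05 each);
* level-1 / level-2: given the context (the previous one or two items),
  exactly two items may follow, one with probability 0.80 and one with 0.20.

Candidate sequences are scored by the Kullback-Leibler divergence between
their empirical (conditional) statistics and the generating model, and the
closest-matching sequences are retained for presentation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import N_ITEMS, ITEM_LETTERS, ConditionalTable, Context, context_label, smooth_row

__all__ = [
    "Alphabet",
    "MarkovModel",
    "SequenceSet",
    "Trial",
    "build_model",
    "stationary_context_distribution",
    "generate_sequence",
    "generate_sequences",
    "empirical_distribution",
    "kl_to_ideal",
    "select_sequences",
    "make_training_block",
    "make_test_run",
    "make_random_sequence",
    "encode_items",
    "decode_items",
]

#: canonical cyclic successor design for the context-based levels:
#: the first successor of each item is the high-probability target at level-1.
CANONICAL_SUCCESSORS: dict[int, tuple[int, int]] = {
    0: (1, 2),  # A -> B (high), C (low)
    1: (2, 3),  # B -> C (high), D (low)
    2: (3, 0),  # C -> D (high), A (low)
    3: (0, 1),  # D -> A (high), B (low)
}

DEFAULT_LEVEL0_PROBS = (0.18, 0.72, 0.05, 0.05)  # P(A), P(B), P(C), P(D)


def encode_items(text: str) -> np.ndarray:
    """Convert an item-letter string (``'ABCA...'``) to an index array."""
    try:
        return np.array([ITEM_LETTERS.index(ch) for ch in text], dtype=np.int8)
    except ValueError as err:
        raise ValueError(f"unknown item letter in {text!r}") from err


def decode_items(items) -> str:
    return "".join(ITEM_LETTERS[int(i)] for i in np.asarray(items).ravel())


def _as_items(sequence) -> np.ndarray:
    if isinstance(sequence, str):
        return encode_items(sequence)
    seq = np.asarray(sequence, dtype=np.int8)
    if seq.ndim != 1:
        raise ValueError("sequence must be one-dimensional")
    if seq.size and (seq.min() < 0 or seq.max() >= N_ITEMS):
        raise ValueError("item indices must lie in 0..3")
    return seq


@dataclass(frozen=True)
class Alphabet:
    """Four abstract items and their assignment to concrete glyphs.

    The correspondence between the abstract items A-D and the glyphs shown
    on screen is a counterbalanced permutation; internally everything is
    0-based item indices and glyphs only matter at the I/O boundary.
    """

    items: tuple[str, ...] = tuple(ITEM_LETTERS)
    symbol_map: tuple[int, ...] = (0, 1, 2, 3)

    def __post_init__(self) -> None:
        if len(self.items) != N_ITEMS:
            raise ValueError("alphabet must have exactly 4 items")
        if sorted(self.symbol_map) != list(range(N_ITEMS)):
            raise ValueError("symbol_map must be a permutation of 0..3")


class MarkovModel:
    """An order-k Markov source over the four items.

    Parameters
    ----------
    order : int
        Context length k (0, 1 or 2 in the standard designs; any k >= 0
        is accepted).
    table : dict
        Mapping ``context (k-tuple) -> length-4 probability vector``.
        The context set must be closed under the induced context chain and
        that chain must be ergodic.
    model_id : str
        Free-form identifier carried into outputs.
    """

    def __init__(self, order: int, table: dict[Context, np.ndarray],
                 model_id: str = "model"):
        self.order = int(order)
        self.model_id = model_id
        tbl: dict[Context, np.ndarray] = {}
        for ctx, row in table.items():
            ctx = tuple(int(i) for i in ctx)
            if len(ctx) != self.order:
                raise ValueError(f"context {ctx!r} does not have length {self.order}")
            row = np.asarray(row, dtype=float)
            if row.shape != (N_ITEMS,):
                raise ValueError("each row must have 4 entries")
            if np.any(row < 0):
                raise ValueError("negative transition probability")
            if abs(row.sum() - 1.0) > 1e-12:
                raise ValueError(
                    f"row for context {context_label(ctx)} sums to {row.sum()!r}, not 1"
                )
            if self.order >= 1 and np.count_nonzero(row) != 2:
                raise ValueError(
                    f"order-{self.order} rows must have exactly two allowed targets "
                    f"(context {context_label(ctx)})"
                )
            tbl[ctx] = row
        if not tbl:
            raise ValueError("empty transition table")
        self.contexts: list[Context] = sorted(tbl)
        self.table = {c: tbl[c] for c in self.contexts}

        self._ctx_index = {c: i for i, c in enumerate(self.contexts)}
        n = len(self.contexts)
        self._rows = np.array([self.table[c] for c in self.contexts])
        # successor context per (context, emitted item); -1 marks an illegal draw
        self._succ = np.full((n, N_ITEMS), -1, dtype=np.int64)
        for i, ctx in enumerate(self.contexts):
            for t in np.flatnonzero(self._rows[i] > 0):
                nxt = (ctx + (int(t),))[-self.order:] if self.order else ()
                j = self._ctx_index.get(nxt)
                if j is None:
                    raise ValueError(
                        f"context chain not closed: {context_label(ctx)} can emit "
                        f"{ITEM_LETTERS[t]} but context {context_label(nxt)} is missing"
                    )
                self._succ[i, t] = j
        self._cum_rows = np.cumsum(self._rows, axis=1)
        self.context_weights = stationary_context_distribution(self)

    # -- convenience -----------------------------------------------------
    @property
    def n_contexts(self) -> int:
        return len(self.contexts)

    def row(self, context) -> np.ndarray:
        return self.table[tuple(int(i) for i in context)]

    def as_conditional_table(self) -> ConditionalTable:
        return ConditionalTable(self.order, dict(self.table))

    def context_weight(self, context) -> float:
        return float(self.context_weights[self._ctx_index[tuple(context)]])

    def weights_dict(self) -> dict[Context, float]:
        return {c: float(self.context_weights[i]) for i, c in enumerate(self.contexts)}

    def __repr__(self) -> str:  # pragma: no cover
        return (f"MarkovModel(order={self.order}, contexts={self.n_contexts}, "
                f"id={self.model_id!r})")


def _strongly_connected(adj: np.ndarray) -> np.ndarray:
    """Boolean mask of nodes in the strongly connected component of node 0."""

    def reach(mat):
        seen = np.zeros(mat.shape[0], dtype=bool)
        stack = [0]
        seen[0] = True
        while stack:
            i = stack.pop()
            for j in np.flatnonzero(mat[i]):
                if not seen[j]:
                    seen[j] = True
                    stack.append(j)
        return seen

    return reach(adj) & reach(adj.T)


def stationary_context_distribution(model: MarkovModel) -> np.ndarray:
    """Stationary distribution of the induced context chain.

    Solves pi = pi T for the context-transition operator T; raises if the
    chain is not ergodic, naming the contexts outside the recurrent class.
    """
    n = model.n_contexts
    if n == 1:
        return np.ones(1)
    T = np.zeros((n, n))
    for i in range(n):
        for t in np.flatnonzero(model._rows[i] > 0):
            T[i, model._succ[i, t]] += model._rows[i, t]
    core = _strongly_connected(T > 0)
    if not core.all():
        bad = [context_label(model.contexts[i]) for i in np.flatnonzero(~core)]
        raise ValueError(f"context chain is not ergodic; unreachable contexts: {bad}")
    # left eigenvector for eigenvalue 1: solve (T' - I) pi = 0 with sum(pi) = 1
    A = np.vstack([T.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def build_model(level: int,
                permutation: tuple[int, ...] | None = None,
                level0_probs=DEFAULT_LEVEL0_PROBS,
                high_p: float = 0.80,
                low_p: float | None = None,
                model_id: str | None = None) -> MarkovModel:
    """Construct the canonical level-0/1/2 stimulus model.

    ``permutation`` remaps the canonical items (counterbalancing which
    glyph plays which structural role): canonical item ``i`` becomes
    ``permutation[i]``.

    Level-1 follows the cyclic successor design A->{B:.8, C:.2},
    B->{C:.8, D:.2}, C->{D:.8, A:.2}, D->{A:.8, B:.2}.  Level-2 uses the
    same allowed-successor *sets*, determined by the most recent item,
    while the 0.80/0.20 assignment depends on the item two back — the
    smallest ergodic design in which the target probabilities genuinely
    depend on both context items (8 reachable two-item contexts).
    """
    if level not in (0, 1, 2):
        raise ValueError(f"level must be 0, 1 or 2, got {level!r}")
    if low_p is None:
        low_p = 1.0 - high_p
    if not (0 < high_p < 1) or abs(high_p + low_p - 1.0) > 1e-12:
        raise ValueError("high_p and low_p must be in (0,1) and sum to 1")
    perm = tuple(range(N_ITEMS)) if permutation is None else tuple(int(i) for i in permutation)
    if sorted(perm) != list(range(N_ITEMS)):
        raise ValueError("permutation must be a permutation of 0..3")

    table: dict[Context, np.ndarray] = {}
    if level == 0:
        probs = np.asarray(level0_probs, dtype=float)
        if probs.shape != (N_ITEMS,) or np.any(probs < 0) or abs(probs.sum() - 1) > 1e-12:
            raise ValueError("level0_probs must be 4 nonnegative values summing to 1")
        row = np.zeros(N_ITEMS)
        row[list(perm)] = probs
        table[()] = row
    elif level == 1:
        for a, (hi, lo) in CANONICAL_SUCCESSORS.items():
            row = np.zeros(N_ITEMS)
            row[perm[hi]], row[perm[lo]] = high_p, low_p
            table[(perm[a],)] = row
    else:
        # predecessors of b in the canonical successor graph, in canonical order
        preds = {b: tuple(a for a in range(N_ITEMS) if b in CANONICAL_SUCCESSORS[a])
                 for b in range(N_ITEMS)}
        for b in range(N_ITEMS):
            s1, s2 = CANONICAL_SUCCESSORS[b]
            for rank, a in enumerate(preds[b]):
                row = np.zeros(N_ITEMS)
                # the item two back decides which allowed target is likely
                hi, lo = (s1, s2) if rank == 0 else (s2, s1)
                row[perm[hi]], row[perm[lo]] = high_p, low_p
                table[(perm[a], perm[b])] = row
    return MarkovModel(level, table, model_id=model_id or f"level{level}")


def make_random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. uniform draws over the four items (the 'random' condition)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return rng.integers(0, N_ITEMS, size=length).astype(np.int8)


def generate_sequences(model: MarkovModel, n: int, length: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Generate ``n`` sequences of ``length`` items as an (n, length) array.

    The first k items of each sequence are a context drawn from the
    stationary context distribution, so empirical statistics carry no
    burn-in bias; every subsequent item is drawn from the row of the
    current context.
    """
    k = model.order
    if length < k + 1:
        raise ValueError(f"length must be >= order + 1 = {k + 1}")
    out = np.empty((n, length), dtype=np.int8)
    ctx_idx = rng.choice(model.n_contexts, size=n, p=model.context_weights)
    if k:
        starts = np.array([model.contexts[i] for i in ctx_idx], dtype=np.int8)
        out[:, :k] = starts
    cum = model._cum_rows
    for pos in range(k, length):
        u = rng.random(n)
        nxt = (u[:, None] > cum[ctx_idx]).sum(axis=1)
        out[:, pos] = nxt
        ctx_idx = model._succ[ctx_idx, nxt]
    return out


def generate_sequence(model: MarkovModel, length: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Single stochastic Markov sequence (see :func:`generate_sequences`)."""
    return generate_sequences(model, 1, length, rng)[0]


def _context_codes(seqs: np.ndarray, k: int) -> np.ndarray:
    """Integer code of the k-context preceding each position >= k."""
    n, length = seqs.shape
    codes = np.zeros((n, length - k), dtype=np.int64)
    for j in range(k):
        codes = codes * N_ITEMS + seqs[:, j:length - k + j]
    return codes


def _transition_counts(seqs: np.ndarray, k: int) -> np.ndarray:
    """(n, 4**k, 4) counts of context -> next-item transitions per sequence."""
    seqs = np.atleast_2d(seqs)
    n, length = seqs.shape
    if length <= k:
        raise ValueError("sequence shorter than order + 1")
    ctx = _context_codes(seqs, k)
    tgt = seqs[:, k:].astype(np.int64)
    flat = (np.arange(n)[:, None] * (N_ITEMS ** k * N_ITEMS)
            + ctx * N_ITEMS + tgt)
    counts = np.bincount(flat.ravel(), minlength=n * N_ITEMS ** k * N_ITEMS)
    return counts.reshape(n, N_ITEMS ** k, N_ITEMS).astype(float)


def _code_of(ctx: Context) -> int:
    code = 0
    for i in ctx:
        code = code * N_ITEMS + int(i)
    return code


def empirical_distribution(sequence, order: int) -> ConditionalTable:
    """Relative frequency of the item following each observed context.

    Contexts that never occur in the sequence are absent from the result.
    """
    seq = _as_items(sequence)
    if seq.size == 0:
        raise ValueError("empty sequence")
    if seq.size <= order:
        raise ValueError("sequence must be longer than the order")
    counts = _transition_counts(seq[None, :], order)[0]
    probs: dict[Context, np.ndarray] = {}
    raw: dict[Context, np.ndarray] = {}
    for ctx in itertools.product(range(N_ITEMS), repeat=order):
        row = counts[_code_of(ctx)]
        tot = row.sum()
        if tot > 0:
            probs[ctx] = row / tot
            raw[ctx] = row
    return ConditionalTable(order, probs, counts=raw)


def _kl_rows(Q: np.ndarray, P: np.ndarray, weights: np.ndarray,
             log_base: float | None = None) -> float:
    """Sum_c w_c Sum_t Q[c,t] log(Q[c,t]/P[c,t]) over entries with Q > 0."""
    mask = Q > 0
    terms = np.zeros_like(Q)
    terms[mask] = Q[mask] * np.log(Q[mask] / P[mask])
    kl = float(weights @ terms.sum(axis=1))
    if log_base is not None:
        kl /= np.log(log_base)
    return kl


def kl_to_ideal(sequence, model: MarkovModel, epsilon: float = 1e-6,
                log_base: float | None = None) -> float:
    """KL divergence from a sequence's empirical statistics to the model.

    For k = 0 this is ``sum_t Q(t) log(Q(t)/P(t))``; for k >= 1 the
    context-conditional divergences are weighted by the model's stationary
    context probabilities.  Q is the ideal model, P the epsilon-smoothed
    empirical table (unobserved contexts contribute via the smoothed,
    uniform floor).  Natural log by default; pass ``log_base=2`` for bits.
    """
    seq = _as_items(sequence)
    if seq.size <= model.order:
        raise ValueError("sequence must be longer than the model order")
    emp = empirical_distribution(seq, model.order)
    P = np.array([
        smooth_row(emp.get_row(c, np.zeros(N_ITEMS)), epsilon)
        for c in model.contexts
    ])
    Q = model._rows
    return _kl_rows(Q, P, model.context_weights, log_base)


@dataclass
class SequenceSet:
    """Sequences selected for presentation, with their KL scores.

    ``sequences`` is an (n_select, length) item array sorted by
    non-decreasing ``kl_scores``.
    """

    sequences: np.ndarray
    kl_scores: np.ndarray
    model_id: str
    seed: int | None = None

    def __post_init__(self) -> None:
        self.sequences = np.atleast_2d(np.asarray(self.sequences, dtype=np.int8))
        self.kl_scores = np.asarray(self.kl_scores, dtype=float)
        if self.sequences.shape[0] != self.kl_scores.shape[0]:
            raise ValueError("kl_scores must align 1:1 with sequences")

    def __len__(self) -> int:
        return self.sequences.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sequence_id": np.arange(len(self)),
            "kl_score": self.kl_scores,
            "sequence": [decode_items(s) for s in self.sequences],
        })


def select_sequences(model: MarkovModel, n_generate: int = 10_000,
                     length: int = 672, n_select: int = 50,
                     rng: np.random.Generator | None = None,
                     epsilon: float = 1e-6,
                     log_base: float | None = None) -> SequenceSet:
    """Generate candidates and keep those closest to the ideal model.

    Scores every candidate with :func:`kl_to_ideal` (vectorized) and
    returns the ``n_select`` lowest-KL sequences sorted ascending, ties
    broken by generation index (stable sort).
    """
    if n_select > n_generate:
        raise ValueError("n_select must not exceed n_generate")
    if rng is None:
        rng = np.random.default_rng()
    seqs = generate_sequences(model, n_generate, length, rng)
    if n_select == 0:
        return SequenceSet(np.empty((0, length), dtype=np.int8), np.empty(0),
                           model.model_id)
    k = model.order
    counts = _transition_counts(seqs, k)            # (n, 4**k, 4)
    codes = [_code_of(c) for c in model.contexts]
    counts = counts[:, codes, :]                    # (n, n_ctx, 4)
    totals = counts.sum(axis=2, keepdims=True)
    with np.errstate(invalid="ignore"):
        P = np.where(totals > 0, counts / totals, 0.0)
    P = (P + epsilon) / (1.0 + N_ITEMS * epsilon)
    Q = model._rows[None, :, :]
    mask = Q > 0
    terms = np.zeros_like(P)
    np.log(np.broadcast_to(Q, P.shape), out=terms, where=np.broadcast_to(mask, P.shape))
    terms -= np.where(mask, np.log(P), 0.0)
    terms *= np.where(mask, Q, 0.0)
    scores = terms.sum(axis=2) @ model.context_weights
    if log_base is not None:
        scores = scores / np.log(log_base)
    order_idx = np.argsort(scores, kind="stable")[:n_select]
    return SequenceSet(seqs[order_idx], scores[order_idx], model.model_id)


@dataclass
class Trial:
    """One presented symbol stream within a block."""

    trial_id: int
    presented: np.ndarray
    condition: str = "structured"   # structured | random
    block_id: int = 0
    session_id: int = 0
    level: int | None = None

    def __post_init__(self) -> None:
        self.presented = _as_items(self.presented)

    def context(self, order: int) -> Context:
        """The final k items of the stream — what the prediction conditions on."""
        if order == 0:
            return ()
        return tuple(int(i) for i in self.presented[-order:])


def make_training_block(seqset: SequenceSet, n_trials: int = 56,
                        length_range: tuple[int, int] = (8, 14),
                        rng: np.random.Generator | None = None,
                        block_id: int = 0, session_id: int = 0,
                        level: int | None = None) -> list[Trial]:
    """Cut one training block of trials from a selected sequence set.

    Each of the lengths in ``length_range`` (inclusive) appears equally
    often; trial streams are contiguous windows cut from the selected
    long sequences at random offsets, and trial order is shuffled.
    """
    if rng is None:
        rng = np.random.default_rng()
    if len(seqset) == 0:
        raise ValueError("empty sequence set")
    lengths = list(range(length_range[0], length_range[1] + 1))
    if n_trials % len(lengths):
        raise ValueError(
            f"n_trials={n_trials} is not divisible by {len(lengths)} trial lengths"
        )
    per_length = n_trials // len(lengths)
    seq_len = seqset.sequences.shape[1]
    streams = []
    for L in lengths:
        for _ in range(per_length):
            s = rng.integers(0, len(seqset))
            off = rng.integers(0, seq_len - L + 1)
            streams.append(seqset.sequences[s, off:off + L])
    order_idx = rng.permutation(n_trials)
    return [
        Trial(trial_id=i, presented=streams[j], condition="structured",
              block_id=block_id, session_id=session_id, level=level)
        for i, j in enumerate(order_idx)
    ]


def make_test_run(model: MarkovModel, rng: np.random.Generator | None = None,
                  session_id: int = 0, trial_length: int = 10,
                  n_blocks: int = 10, trials_per_block: int = 2) -> list[Trial]:
    """One test run: structured and random blocks in counterbalanced order.

    Ten blocks of two length-10 trials each — five blocks structured
    (streams drawn from the model), five random (uniform i.i.d. items) —
    giving 10 structured and 10 random trials per run.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_blocks % 2:
        raise ValueError("n_blocks must be even (half structured, half random)")
    conditions = ["structured"] * (n_blocks // 2) + ["random"] * (n_blocks // 2)
    conditions = [conditions[i] for i in rng.permutation(n_blocks)]
    trials: list[Trial] = []
    tid = 0
    for block_id, cond in enumerate(conditions):
        for _ in range(trials_per_block):
            if cond == "structured":
                stream = generate_sequence(model, trial_length, rng)
            else:
                stream = make_random_sequence(trial_length, rng)
            trials.append(Trial(trial_id=tid, presented=stream, condition=cond,
                                block_id=block_id, session_id=session_id,
                                level=model.order))
            tid += 1
    return trials
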