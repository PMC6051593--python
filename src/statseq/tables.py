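"""Conditional probability tables over a four-item alphabet.

A :class:`ConditionalTable` maps a temporal context (a k-tuple of item
indices) to a probability vector over the four items that can follow it.
It is the common currency of the package: Markov models, empirical
sequence statistics, response distributions and the matching /
maximization baselines are all expressed as conditional tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_ITEMS = 4
ITEM_LETTERS = "ABCD"

Context = tuple[int, ...]


def context_label(context: Context) -> str:
    """Render a context tuple as item letters; the empty context is ``'-'``."""
    return "".join(ITEM_LETTERS[i] for i in context) if context else "-"


@dataclass
class ConditionalTable:
    """Distribution over next items per context.

    Parameters
    ----------
    order : int
        Context length k; every key must be a k-tuple of item indices.
    probs : dict
        Mapping ``context -> length-4 probability vector``.  Contexts that
        were never observed are simply absent (not zero-filled).
    counts : dict, optional
        Raw counts backing ``probs`` when the table is empirical.
    """

    order: int
    probs: dict[Context, np.ndarray]
    counts: dict[Context, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[Context, np.ndarray] = {}
        for ctx, row in self.probs.items():
            ctx = tuple(int(i) for i in ctx)
            if len(ctx) != self.order:
                raise ValueError(
                    f"context {ctx!r} has length {len(ctx)}, expected order {self.order}"
                )
            row = np.asarray(row, dtype=float)
            if row.shape != (N_ITEMS,):
                raise ValueError(f"row for context {ctx!r} must have {N_ITEMS} entries")
            if np.any(row < 0):
                raise ValueError(f"negative probability in row for context {ctx!r}")
            if abs(row.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"row for context {ctx!r} sums to {row.sum():.12f}, expected 1"
                )
            clean[ctx] = row
        self.probs = clean

    @property
    def contexts(self) -> list[Context]:
        return sorted(self.probs)

    def row(self, context: Context) -> np.ndarray:
        return self.probs[tuple(context)]

    def get_row(self, context: Context, default: np.ndarray | None = None):
        return self.probs.get(tuple(context), default)

    def __contains__(self, context) -> bool:
        return tuple(context) in self.probs

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with one row per context, columns A..D."""
        rows = {context_label(c): self.probs[c] for c in self.contexts}
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=list(ITEM_LETTERS)
        ).rename_axis("context")

    def allclose(self, other: "ConditionalTable", atol: float = 1e-12) -> bool:
        if self.order != other.order or set(self.probs) != set(other.probs):
            return False
        return all(
            np.allclose(self.probs[c], other.probs[c], atol=atol) for c in self.probs
        )


def smooth_row(row: np.ndarray, epsilon: float) -> np.ndarray:
    """Add-epsilon smoothing followed by renormalization.

    An all-zero row (a context with no observations) smooths to the
    uniform distribution, which is the floor through which unobserved
    contexts enter KL divergences.
    """
    row = np.asarray(row, dtype=float)
    sm = row + epsilon
    return sm / sm.sum()
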