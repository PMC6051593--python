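"""Matching-vs-maximization strategy metrics.

Given a stochastic stimulus source, an observer may *match* — respond so
as to reproduce the conditional target distribution — or *maximize* —
always pick the most probable target in the current context.  The
response distribution R is compared by KL divergence with two baselines
derived from the generating model M: the matching model (the model rows
themselves) and the maximization model (all mass on the arg-max target).

    KL(M ‖ R) = sum_c M(c) sum_t M(t|c) log( M(t|c) / R(t|c) )

The strategy-choice statistic is dKL = KL(matching ‖ R) − KL(maximization ‖ R),
oriented so that larger values mean closer to maximization.  Computed in
consecutive trial windows it yields a strategy curve; the integral curve
difference (ICD) between that curve and the exact-matching reference is
the scalar strategy index (0 = matching, > 0 toward maximization).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import MarkovModel
from .performance import ResponseRecord, build_response_and_presented_tables
from .tables import N_ITEMS, ConditionalTable, Context, smooth_row

__all__ = [
    "BaselineModels",
    "StrategyCurve",
    "StrategyIndex",
    "baseline_models",
    "kl_model_to_response",
    "strategy_choice",
    "strategy_curve",
    "strategy_curve_from_tables",
    "strategy_index",
    "pooled_context_index",
    "StrategyModel",
    "StrategyResults",
]


@dataclass
class BaselineModels:
    """The two response baselines derived from a stimulus model."""

    matching: ConditionalTable
    maximization: ConditionalTable
    context_weights: dict[Context, float]


def baseline_models(model: MarkovModel) -> BaselineModels:
    """Matching = the model rows; maximization = arg-max rows.

    Ties among maxima split the mass equally (cannot occur in the
    standard 0.80/0.20 designs but keeps configurable models well
    defined).
    """
    matching = model.as_conditional_table()
    max_rows: dict[Context, np.ndarray] = {}
    for c in model.contexts:
        row = model.row(c)
        top = row == row.max()
        max_rows[c] = top / top.sum()
    return BaselineModels(matching, ConditionalTable(model.order, max_rows),
                          model.weights_dict())


def kl_model_to_response(M: ConditionalTable, R: ConditionalTable,
                         context_weights: dict[Context, float],
                         epsilon: float = 1e-6,
                         log_base: float | None = None,
                         direction: str = "model_to_response") -> float:
    """Context-weighted KL divergence between a baseline model and responses.

    The response table is epsilon-smoothed (contexts without responses
    enter via the uniform smoothed floor).  ``direction='response_to_model'``
    reverses the divergence (both tables smoothed) for sensitivity
    analysis; the default places the model in the numerator, as the
    defining formula does.
    """
    kl = 0.0
    for c, w in context_weights.items():
        m = np.asarray(M.row(c), dtype=float)
        r = smooth_row(R.get_row(c, np.zeros(N_ITEMS)), epsilon)
        if direction == "model_to_response":
            mask = m > 0
            kl += w * float(np.sum(m[mask] * np.log(m[mask] / r[mask])))
        elif direction == "response_to_model":
            m_sm = smooth_row(m, epsilon)
            kl += w * float(np.sum(r * np.log(r / m_sm)))
        else:
            raise ValueError(f"unknown direction {direction!r}")
    if log_base is not None:
        kl /= np.log(log_base)
    return kl


def strategy_choice(R: ConditionalTable, model: MarkovModel,
                    epsilon: float = 1e-6,
                    log_base: float | None = None,
                    direction: str = "model_to_response") -> float:
    """dKL = KL(matching ‖ R) − KL(maximization ‖ R).

    Negative for a matcher, increasingly positive toward maximization.
    """
    bm = baseline_models(model)
    kl_match = kl_model_to_response(bm.matching, R, bm.context_weights,
                                    epsilon, log_base, direction)
    kl_max = kl_model_to_response(bm.maximization, R, bm.context_weights,
                                  epsilon, log_base, direction)
    return kl_match - kl_max


@dataclass
class StrategyCurve:
    """Windowed dKL values plus the exact-matcher reference level."""

    window_ids: np.ndarray
    delta_kl: np.ndarray
    reference_value: float
    level: int | None = None

    def __post_init__(self) -> None:
        self.window_ids = np.asarray(self.window_ids)
        self.delta_kl = np.asarray(self.delta_kl, dtype=float)
        if self.window_ids.shape != self.delta_kl.shape:
            raise ValueError("window_ids and delta_kl must align")
        if self.delta_kl.size == 0:
            raise ValueError("strategy curve needs at least one window")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "window_id": self.window_ids,
            "delta_kl": self.delta_kl,
            "reference": self.reference_value,
        })


@dataclass
class StrategyIndex:
    """The ICD scalar; 0 = exact matching, > 0 toward maximization."""

    icd: float
    level: int | str | None = None


def strategy_curve(records: list[ResponseRecord], model: MarkovModel,
                   window: int = 56, epsilon: float = 1e-6,
                   log_base: float | None = None) -> StrategyCurve:
    """dKL in consecutive non-overlapping windows of ``window`` trials.

    The response table of each window is estimated exactly as in the
    performance analysis (responses grouped by trial context); trailing
    trials that do not fill a window are dropped.
    """
    n_windows = len(records) // window
    if n_windows == 0:
        raise ValueError(
            f"need at least {window} trials for one window, got {len(records)}")
    tables = []
    for w in range(n_windows):
        chunk = records[w * window:(w + 1) * window]
        p_resp, _, _, _ = build_response_and_presented_tables(chunk, model.order)
        tables.append(p_resp)
    curve = strategy_curve_from_tables(tables, model, epsilon, log_base)
    return curve


def strategy_curve_from_tables(response_tables: list[ConditionalTable],
                               model: MarkovModel, epsilon: float = 1e-6,
                               log_base: float | None = None) -> StrategyCurve:
    """Strategy curve from per-window response tables given directly.

    Useful for noise-free (distributional) response profiles where no
    trial sampling is involved.
    """
    if not response_tables:
        raise ValueError("need at least one window table")
    delta = np.array([
        strategy_choice(R, model, epsilon, log_base) for R in response_tables
    ])
    reference = strategy_choice(model.as_conditional_table(), model,
                                epsilon, log_base)
    return StrategyCurve(np.arange(len(delta)), delta, reference,
                         level=model.order)


def strategy_index(curve: StrategyCurve) -> StrategyIndex:
    """Integral curve difference between a strategy curve and its reference.

    The curve is integrated by the trapezoidal rule over a normalized
    window axis (so the integral of a constant curve is that constant);
    a single-window curve degenerates to ``delta_kl − reference``.
    """
    d = curve.delta_kl - curve.reference_value
    if d.size == 1:
        icd = float(d[0])
    else:
        x = np.linspace(0.0, 1.0, d.size)
        icd = float(np.trapezoid(d, x))
    return StrategyIndex(icd=icd, level=curve.level)


def pooled_context_index(index_l1: StrategyIndex,
                         index_l2: StrategyIndex) -> StrategyIndex:
    """Mean of the level-1 and level-2 indices (context-based statistics)."""
    return StrategyIndex(icd=0.5 * (index_l1.icd + index_l2.icd),
                         level="pooled")


class StrategyModel:
    """Windowed strategy analysis of a trial log.

    Parameters
    ----------
    records : list of ResponseRecord
        Training-trial log, in presentation order.
    model : MarkovModel
        The generating stimulus model supplying both baselines.
    window : int
        Trials per strategy-curve window (default one 56-trial block).
    epsilon : float
        Smoothing constant applied to response tables inside KL terms.

    Examples
    --------
    >>> res = StrategyModel(records, model).fit()
    >>> res.icd                  # doctest: +SKIP
    >>> print(res.summary())     # doctest: +SKIP
    """

    def __init__(self, records: list[ResponseRecord], model: MarkovModel,
                 window: int = 56, epsilon: float = 1e-6,
                 log_base: float | None = None):
        self.records = list(records)
        self.model = model
        self.window = window
        self.epsilon = epsilon
        self.log_base = log_base

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, model: MarkovModel, **kwargs):
        from .session_io import records_from_frame
        return cls(records_from_frame(df), model, **kwargs)

    @classmethod
    def from_window_tables(cls, tables: list[ConditionalTable],
                           model: MarkovModel, epsilon: float = 1e-6,
                           log_base: float | None = None) -> "StrategyResults":
        """Fit directly from noise-free per-window response tables."""
        self = cls([], model, epsilon=epsilon, log_base=log_base)
        curve = strategy_curve_from_tables(tables, model, epsilon, log_base)
        return StrategyResults(self, curve, strategy_index(curve))

    def fit(self) -> "StrategyResults":
        curve = strategy_curve(self.records, self.model, self.window,
                               self.epsilon, self.log_base)
        return StrategyResults(self, curve, strategy_index(curve))


class StrategyResults:
    """Results of :meth:`StrategyModel.fit`."""

    def __init__(self, model: StrategyModel, curve: StrategyCurve,
                 index: StrategyIndex):
        self.model = model
        self.curve = curve
        self.index = index

    icd = property(lambda self: self.index.icd)
    delta_kl = property(lambda self: self.curve.delta_kl)
    reference_value = property(lambda self: self.curve.reference_value)

    @property
    def delta_kl_se(self) -> float:
        d = self.curve.delta_kl
        if d.size < 2:
            return float("nan")
        return float(np.std(d, ddof=1) / np.sqrt(d.size))

    def to_frame(self) -> pd.DataFrame:
        return self.curve.to_frame()

    def summary(self) -> str:
        mm = self.model.model
        d = self.curve.delta_kl
        lines = [
            "Strategy analysis (matching vs maximization)",
            "=" * 46,
            f"model: {mm.model_id}  (order {mm.order})",
            f"windows:              {d.size}  x {self.model.window} trials",
            "-" * 46,
            f"mean dKL:             {d.mean():8.4f}  (SE {self.delta_kl_se:.4f})",
            f"matcher reference:    {self.reference_value:8.4f}",
            f"strategy index (ICD): {self.icd:8.4f}",
            "  (0 = matching, > 0 toward maximization)",
            "=" * 46,
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Strategy curve with the matcher reference line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.curve.window_ids, self.curve.delta_kl, marker="o",
                label="observed dKL")
        ax.axhline(self.reference_value, color="k", ls="--",
                   label="exact matching")
        ax.set_xlabel("window")
        ax.set_ylabel("dKL (matching vs maximization)")
        ax.legend()
        return ax
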