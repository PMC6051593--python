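"""Synthetic observers on the matching-to-maximization continuum.

No real trial logs ship with the package; instead, configurable agents
emulate observers with the statistical structure the analysis assumes.
An agent keeps decayed Dirichlet counts of context-to-target transitions,
updates them from every transition in each presented stream, and responds
with a blend of the two strategies: with probability ``lambda_max`` it
picks the arg-max of its posterior-mean row (maximization), otherwise it
samples from the posterior mean (matching); lapses produce uniform
random responses.  The blend parameter is the ground truth that the
strategy-index pipeline is expected to recover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .markov import (MarkovModel, SequenceSet, Trial, build_model,
                     make_training_block, select_sequences)
from .performance import ResponseRecord
from .strategy import StrategyModel
from .tables import N_ITEMS

__all__ = [
    "AgentConfig",
    "CohortSpec",
    "simulate_agent",
    "make_training_trials",
    "simulate_cohort",
    "recovery_experiment",
    "recovery_summary",
    "agent_seed",
]


@dataclass
class AgentConfig:
    """Parameters of one synthetic observer.

    lambda_max
        Blend toward maximization: probability of responding with the
        arg-max of the learned row rather than sampling from it.
    prior_count
        Dirichlet pseudo-count per (context, target) pair; the agent's
        initial belief is uniform with this concentration.
    decay
        Per-trial forgetting factor on accumulated evidence (1 = none).
    lapse
        Probability of a uniform random response regardless of beliefs.
    seed
        Mandatory; the agent is deterministic given it.
    """

    lambda_max: float
    seed: int
    prior_count: float = 1.0
    decay: float = 1.0
    lapse: float = 0.0

    def __post_init__(self) -> None:
        for name in ("lambda_max", "decay", "lapse"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.prior_count <= 0:
            raise ValueError("prior_count must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def simulate_agent(model: MarkovModel, trials: list[Trial],
                   config: AgentConfig) -> list[ResponseRecord]:
    """Run one agent over a list of trials, returning its response log.

    The agent learns from every within-stream transition of each trial
    (not only the final prediction outcome), then predicts the item
    following the trial's final context.
    """
    rng = np.random.default_rng(config.seed)
    k = model.order
    n_ctx = model.n_contexts
    ctx_index = model._ctx_index
    evidence = np.zeros((n_ctx, N_ITEMS))
    prior = config.prior_count

    records: list[ResponseRecord] = []
    for trial in trials:
        if config.decay < 1.0:
            evidence *= config.decay
        stream = trial.presented
        # learn from the stream the agent just watched
        for pos in range(k, stream.size):
            c = ctx_index.get(tuple(int(i) for i in stream[pos - k:pos]))
            if c is not None:
                evidence[c, stream[pos]] += 1.0
        ctx = trial.context(k)
        ci = ctx_index.get(ctx)
        if ci is None:
            row = np.full(N_ITEMS, 1.0 / N_ITEMS)
        else:
            counts = evidence[ci] + prior
            row = counts / counts.sum()
        u = rng.random()
        if u < config.lapse:
            response = int(rng.integers(0, N_ITEMS))
        elif rng.random() < config.lambda_max:
            top = np.flatnonzero(row == row.max())
            response = int(top[0] if top.size == 1 else rng.choice(top))
        else:
            response = int(rng.choice(N_ITEMS, p=row))
        records.append(ResponseRecord(
            trial_id=trial.trial_id, presented=stream, response=response,
            condition=trial.condition, block_id=trial.block_id,
            session_id=trial.session_id, level=trial.level))
    return records


def agent_seed(master_seed: int, *key: int) -> int:
    """Derive a child seed from a master seed and an index path.

    Uses :class:`numpy.random.SeedSequence` entropy splitting so cohorts
    are reproducible piecewise; the result is kept below 2**31.
    """
    ss = np.random.SeedSequence([int(master_seed), *map(int, key)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def make_training_trials(model: MarkovModel, n_trials: int,
                         rng: np.random.Generator,
                         seqset: SequenceSet | None = None,
                         trials_per_block: int = 56,
                         length_range: tuple[int, int] = (8, 14),
                         session_id: int = 0,
                         n_generate: int = 200, n_select: int = 50,
                         seq_length: int = 672) -> list[Trial]:
    """Assemble consecutive training blocks totalling ``n_trials`` trials."""
    if n_trials % trials_per_block:
        raise ValueError("n_trials must be a multiple of trials_per_block")
    if seqset is None:
        seqset = select_sequences(model, n_generate, seq_length, n_select, rng)
    trials: list[Trial] = []
    for b in range(n_trials // trials_per_block):
        block = make_training_block(seqset, trials_per_block, length_range,
                                    rng, block_id=b, session_id=session_id,
                                    level=model.order)
        for t in block:
            t.trial_id = len(trials)
            trials.append(t)
    return trials


@dataclass
class CohortSpec:
    """A cohort of synthetic observers and their session plan.

    The default plan mirrors the study's training regime: sequential
    phases of frequency statistics (level-0), first-order context
    statistics (level-1) and variable-order statistics (alternating
    level-1 / level-2 blocks), four 280-trial sessions per phase
    (1120 trials, within the study's 840-1400 range).
    """

    n_agents: int = 21
    lambdas: list[float] | None = None
    sessions_per_level: int = 4
    blocks_per_session: int = 5
    trials_per_block: int = 56
    prior_count: float = 1.0
    decay: float = 1.0
    lapse: float = 0.0

    def __post_init__(self) -> None:
        n_trials = (self.sessions_per_level * self.blocks_per_session
                    * self.trials_per_block)
        if not 840 <= n_trials <= 1400:
            raise ValueError(
                f"session plan gives {n_trials} trials per level, "
                "outside the 840-1400 training range")
        if self.lambdas is None:
            self.lambdas = list(np.linspace(0.0, 1.0, self.n_agents))
        if len(self.lambdas) != self.n_agents:
            raise ValueError("need one lambda per agent")


def simulate_cohort(spec: CohortSpec, models: dict[int, MarkovModel] | None = None,
                    master_seed: int = 0):
    """Simulate a cohort of agents through the full training curriculum.

    Returns ``(logs, manifest)``: ``logs`` maps agent_id to its list of
    :class:`ResponseRecord` (levels in curriculum order, ``session_id``
    increasing across phases), ``manifest`` is a DataFrame with one row
    per agent (agent_id, lambda, seed, sessions).
    """
    if models is None:
        models = {lvl: build_model(lvl) for lvl in (0, 1, 2)}
    trials_per_session = spec.blocks_per_session * spec.trials_per_block

    # shared presentation material per level
    seq_rng = np.random.default_rng(agent_seed(master_seed, 10_000))
    seqsets = {lvl: select_sequences(m, 200, 672, 50, seq_rng)
               for lvl, m in models.items()}

    logs: dict[int, list[ResponseRecord]] = {}
    rows = []
    for a in range(spec.n_agents):
        lam = float(spec.lambdas[a])
        seed = agent_seed(master_seed, a)
        trial_rng = np.random.default_rng(agent_seed(master_seed, a, 1))
        records: list[ResponseRecord] = []
        session = 0
        # phase 1: level-0, phase 2: level-1, phase 3: variable order (1 & 2)
        for phase, levels in ((0, (0,)), (1, (1,)), (2, (1, 2))):
            trials: list[Trial] = []
            for _ in range(spec.sessions_per_level):
                for b in range(spec.blocks_per_session):
                    lvl = levels[b % len(levels)]
                    block = make_training_block(
                        seqsets[lvl], spec.trials_per_block, (8, 14),
                        trial_rng, block_id=b, session_id=session, level=lvl)
                    for t in block:
                        t.trial_id = len(trials)
                        trials.append(t)
                session += 1
            # one learner per level within the phase: beliefs accumulate
            # across the phase's sessions, separately per model order
            for lvl in levels:
                lvl_trials = [t for t in trials if t.level == lvl]
                cfg = AgentConfig(lambda_max=lam, seed=agent_seed(
                    master_seed, a, 2, phase, lvl),
                    prior_count=spec.prior_count, decay=spec.decay,
                    lapse=spec.lapse)
                records.extend(simulate_agent(models[lvl], lvl_trials, cfg))
        logs[a] = records
        rows.append({"agent_id": a, "lambda": lam, "seed": seed,
                     "sessions": session})
    manifest = pd.DataFrame(rows)
    return logs, manifest


def recovery_experiment(lambda_grid=(0.0, 0.25, 0.5, 0.75, 1.0),
                        n_replicates: int = 20, n_trials: int = 1120,
                        levels=(1,), master_seed: int = 0,
                        window: int = 56, epsilon: float = 1e-6,
                        models: dict[int, MarkovModel] | None = None,
                        agent_kwargs: dict | None = None) -> pd.DataFrame:
    """End-to-end parameter recovery: true lambda vs estimated strategy index.

    For each level and each lambda on the grid, ``n_replicates`` agents
    are trained for ``n_trials`` trials and pushed through the windowed
    strategy pipeline.  Returns a tidy DataFrame with columns
    ``level, lam, replicate, icd``.
    """
    if not len(lambda_grid):
        raise ValueError("empty lambda grid")
    if models is None:
        models = {lvl: build_model(lvl) for lvl in levels}
    agent_kwargs = agent_kwargs or {}
    rows = []
    for lvl in levels:
        model = models[lvl]
        seq_rng = np.random.default_rng(agent_seed(master_seed, 20_000, lvl))
        seqset = select_sequences(model, 200, 672, 50, seq_rng)
        for li, lam in enumerate(lambda_grid):
            for rep in range(n_replicates):
                trial_rng = np.random.default_rng(
                    agent_seed(master_seed, lvl, li, rep, 0))
                trials = make_training_trials(model, n_trials, trial_rng,
                                              seqset=seqset)
                cfg = AgentConfig(lambda_max=float(lam),
                                  seed=agent_seed(master_seed, lvl, li, rep, 1),
                                  **agent_kwargs)
                records = simulate_agent(model, trials, cfg)
                res = StrategyModel(records, model, window=window,
                                    epsilon=epsilon).fit()
                rows.append({"level": lvl, "lam": float(lam),
                             "replicate": rep, "icd": res.icd})
    return pd.DataFrame(rows)


def recovery_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean/sd of the recovered index per (level, lambda), plus Spearman rho.

    The rank correlation between true lambda and recovered index is
    attached as ``table.attrs['spearman_rho']`` per level.
    """
    out = (table.groupby(["level", "lam"])["icd"]
           .agg(["mean", "std", "count"]).reset_index())
    rhos = {}
    for lvl, sub in table.groupby("level"):
        rho = stats.spearmanr(sub["lam"], sub["icd"]).statistic
        rhos[int(lvl)] = float(rho)
    out.attrs["spearman_rho"] = rhos
    return out
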