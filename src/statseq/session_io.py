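"""File formats, configuration and the full analysis pipeline.

All interchange formats are plain text: trial logs, sequence sets, score
and strategy tables are comma-separated UTF-8 with a mandatory header
row; configuration is YAML.  Every output produced by the pipeline
carries the seed and a configuration hash sufficient to regenerate it.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .markov import (MarkovModel, SequenceSet, build_model, decode_items,
                     encode_items)
from .performance import PerformanceModel, ResponseRecord
from .strategy import StrategyModel
from .tables import ITEM_LETTERS

__all__ = [
    "RunConfig",
    "TRIAL_LOG_COLUMNS",
    "read_trial_log",
    "write_trial_log",
    "records_from_frame",
    "records_to_frame",
    "write_sequence_set",
    "read_sequence_set",
    "load_config",
    "save_config",
    "config_hash",
    "run_full_pipeline",
]

TRIAL_LOG_COLUMNS = ["session_id", "block_id", "trial_id", "condition",
                     "level", "presented", "response", "rt_ms"]


# ---------------------------------------------------------------------------
# trial logs

def records_to_frame(records: list[ResponseRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "session_id": r.session_id,
            "block_id": r.block_id,
            "trial_id": r.trial_id,
            "condition": r.condition,
            "level": "" if r.level is None else r.level,
            "presented": decode_items(r.presented),
            "response": "" if r.response is None else ITEM_LETTERS[r.response],
            "rt_ms": "" if r.rt_ms is None else r.rt_ms,
        })
    return pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS)


def records_from_frame(df: pd.DataFrame) -> list[ResponseRecord]:
    missing = [c for c in TRIAL_LOG_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"trial log is missing columns: {missing}")
    records: list[ResponseRecord] = []
    seen: set[tuple] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            presented = encode_items(str(row.presented))
        except ValueError as err:
            raise ValueError(f"row {i}: {err}") from err
        resp_field = "" if pd.isna(row.response) else str(row.response).strip()
        if resp_field == "":
            response = None
        elif resp_field in ITEM_LETTERS:
            response = ITEM_LETTERS.index(resp_field)
        else:
            raise ValueError(f"row {i}: unknown response item {resp_field!r}")
        key = (row.session_id, row.block_id, row.trial_id)
        if key in seen:
            raise ValueError(
                f"row {i}: duplicate trial id {row.trial_id} in block "
                f"{row.block_id} (session {row.session_id})")
        seen.add(key)
        level = None
        if "level" in df.columns and not pd.isna(row.level) and str(row.level) != "":
            level = int(row.level)
        rt = None
        if hasattr(row, "rt_ms") and not pd.isna(row.rt_ms) and str(row.rt_ms) != "":
            rt = float(row.rt_ms)
        records.append(ResponseRecord(
            trial_id=int(row.trial_id), presented=presented, response=response,
            condition=str(row.condition), block_id=int(row.block_id),
            session_id=int(row.session_id), level=level, rt_ms=rt))
    return records


def write_trial_log(records: list[ResponseRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_trial_log(path) -> list[ResponseRecord]:
    df = pd.read_csv(path, dtype={"presented": str, "response": str},
                     keep_default_na=False, na_values=[])
    return records_from_frame(df)


# ---------------------------------------------------------------------------
# sequence sets

def write_sequence_set(seqset: SequenceSet, path, fmt: str = "text",
                       seed: int | None = None) -> None:
    """Write selected sequences: one per line with a header comment, or CSV."""
    path = Path(path)
    if fmt == "csv":
        seqset.to_frame().to_csv(path, index=False)
        return
    if fmt != "text":
        raise ValueError(f"unknown format {fmt!r}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# model={seqset.model_id} seed={seed if seed is not None else seqset.seed} "
                 f"n={len(seqset)}\n")
        for score, seq in zip(seqset.kl_scores, seqset.sequences):
            fh.write(f"# kl={score:.10g}\n{decode_items(seq)}\n")


def read_sequence_set(path) -> SequenceSet:
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path, dtype={"sequence": str})
        seqs = np.array([encode_items(s) for s in df["sequence"]])
        return SequenceSet(seqs, df["kl_score"].to_numpy(), model_id="file")
    model_id, seed = "file", None
    scores, seqs = [], []
    pending_kl = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("model="):
                        model_id = tok[6:]
                    elif tok.startswith("seed=") and tok[5:] != "None":
                        seed = int(tok[5:])
                    elif tok.startswith("kl="):
                        pending_kl = float(tok[3:])
            else:
                seqs.append(encode_items(line))
                scores.append(pending_kl if pending_kl is not None else np.nan)
                pending_kl = None
    return SequenceSet(np.array(seqs), np.array(scores), model_id, seed=seed)


# ---------------------------------------------------------------------------
# configuration

@dataclass
class RunConfig:
    """Resolved parameters of a full run; defaults are the study's values."""

    levels: tuple[int, ...] = (0, 1, 2)
    level0_probs: tuple[float, ...] = (0.18, 0.72, 0.05, 0.05)
    high_p: float = 0.80
    low_p: float = 0.20
    n_generate: int = 10_000
    sequence_length: int = 672
    n_select: int = 50
    trials_per_block: int = 56
    blocks_per_session: int = 5
    sessions_per_level: int = 4
    length_range: tuple[int, int] = (8, 14)
    window: int = 56
    epsilon: float = 1e-6
    log_base: str = "e"
    seed: int = 0
    n_agents: int = 21
    recovery_grid: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    recovery_replicates: int = 20
    recovery_trials: int = 1120

    def __post_init__(self) -> None:
        probs = np.asarray(self.level0_probs, dtype=float)
        if probs.shape != (4,) or np.any(probs < 0) or abs(probs.sum() - 1) > 1e-9:
            raise ValueError("level0_probs must be 4 nonnegative values summing to 1")
        if abs(self.high_p + self.low_p - 1.0) > 1e-9:
            raise ValueError("high_p + low_p must equal 1")
        if self.n_select > self.n_generate:
            raise ValueError("n_select cannot exceed n_generate")
        if self.log_base not in ("e", "2"):
            raise ValueError("log_base must be 'e' or '2'")

    @property
    def log_base_value(self) -> float | None:
        return None if self.log_base == "e" else 2.0

    def build_models(self) -> dict[int, MarkovModel]:
        return {lvl: build_model(lvl, level0_probs=self.level0_probs,
                                 high_p=self.high_p, low_p=self.low_p)
                for lvl in self.levels}


def save_config(config: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_plain(asdict(config)), fh, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    known = RunConfig.__dataclass_fields__
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("levels", "level0_probs", "length_range", "recovery_grid"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return RunConfig(**data)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def config_hash(config: RunConfig) -> str:
    blob = yaml.safe_dump(_plain(asdict(config)), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# pipeline

def run_full_pipeline(config: RunConfig, outdir) -> dict[str, Path]:
    """Simulate a cohort, score it, run the strategy and recovery analyses.

    Writes ``scores.csv``, ``strategy.csv``, ``recovery.csv``,
    ``manifest.csv`` and ``run.log`` under ``outdir`` and returns their
    paths.  Deterministic given the config seed.
    """
    from . import __version__
    from .agents import CohortSpec, recovery_experiment, recovery_summary, simulate_cohort

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    models = config.build_models()

    def _stage(name, fn):
        try:
            return fn()
        except Exception as err:
            raise RuntimeError(f"pipeline stage '{name}' failed: {err}") from err

    spec = CohortSpec(n_agents=config.n_agents,
                      sessions_per_level=config.sessions_per_level,
                      blocks_per_session=config.blocks_per_session,
                      trials_per_block=config.trials_per_block)
    logs, manifest = _stage("simulate", lambda: simulate_cohort(
        spec, models, master_seed=config.seed))

    score_rows, strat_rows = [], []
    for agent_id, records in logs.items():
        for lvl in config.levels:
            lvl_records = [r for r in records if r.level == lvl]
            if not lvl_records:
                continue
            perf = _stage("score", lambda r=lvl_records, m=models[lvl]:
                          PerformanceModel(r, m).fit())
            for rep in perf.block_reports:
                row = rep.to_row()
                row.update(agent_id=agent_id, level=lvl)
                score_rows.append(row)
            if len(lvl_records) >= config.window:
                strat = _stage("strategy", lambda r=lvl_records, m=models[lvl]:
                               StrategyModel(r, m, window=config.window,
                                             epsilon=config.epsilon,
                                             log_base=config.log_base_value).fit())
                for wid, dkl in zip(strat.curve.window_ids, strat.curve.delta_kl):
                    strat_rows.append({
                        "agent_id": agent_id, "level": lvl, "window_id": wid,
                        "delta_kl": dkl, "reference": strat.reference_value,
                        "icd": "",
                    })
                strat_rows.append({
                    "agent_id": agent_id, "level": lvl, "window_id": "summary",
                    "delta_kl": "", "reference": strat.reference_value,
                    "icd": strat.icd,
                })

    scores = pd.DataFrame(score_rows)
    strategy = pd.DataFrame(strat_rows)
    recovery = _stage("recover", lambda: recovery_experiment(
        config.recovery_grid, config.recovery_replicates,
        config.recovery_trials, levels=(1,), master_seed=config.seed,
        window=config.window, epsilon=config.epsilon))
    summary = recovery_summary(recovery)

    paths = {}
    header = (f"# statseq {__version__} config_hash={chash} seed={config.seed}\n")
    for name, df in (("scores", scores), ("strategy", strategy),
                     ("recovery", recovery), ("manifest", manifest)):
        p = outdir / f"{name}.csv"
        with open(p, "w", encoding="utf-8") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
        paths[name] = p

    log_path = outdir / "run.log"
    with open(log_path, "w", encoding="utf-8") as fh:
        fh.write(f"statseq version: {__version__}\n")
        fh.write(f"config hash:     {chash}\n")
        fh.write(f"master seed:     {config.seed}\n")
        fh.write("resolved configuration:\n")
        fh.write(yaml.safe_dump(_plain(asdict(config)), sort_keys=True))
        fh.write("recovery summary (mean icd per lambda):\n")
        fh.write(summary.to_string(index=False))
        fh.write(f"\nspearman rho: {summary.attrs['spearman_rho']}\n")
    paths["log"] = log_path
    return paths
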