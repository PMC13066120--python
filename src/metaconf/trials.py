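"""Trial-level confidence-judgement data: schema, I/O, validation, aggregation.

The canonical exchange format is long: one row per (agent, condition, item)
with a binary correctness flag and a confidence rating on the 0-100 scale.
Three answering conditions are admitted, named after their response format:
two-alternative choice (``2C``, guess rate 0.5), four-alternative choice
(``4C``, 0.25) and open-ended (``OP``, practically 0).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

CONDITIONS: tuple[str, ...] = ("2C", "4C", "OP")
POOLED_CONDITION = "All"

#: Guess-success probability of each answering format.
DEFAULT_CHANCE_MAP: dict[str, float] = {"2C": 0.5, "4C": 0.25, "OP": 0.0}

#: Canonical column order of the long trial format.
TRIAL_COLUMNS = ("agent_id", "agent_group", "condition", "item_id", "correct", "confidence")


class SchemaError(ValueError):
    """A required column is missing or has an unusable dtype."""


class TrialValidationError(ValueError):
    """A row violates a trial invariant (range, label, uniqueness)."""


@dataclass
class TrialTable:
    """An ordered collection of trials plus the per-condition chance levels.

    Parameters
    ----------
    trials
        Long-format DataFrame with columns ``agent_id``, ``agent_group``,
        ``condition``, ``item_id``, ``correct`` (0/1) and ``confidence``
        ([0, 100], real-valued; integer inputs are not rounded).
    chance_map
        Mapping condition label -> chance level in [0, 1). Defaults to
        {2C: 0.5, 4C: 0.25, OP: 0.0}.
    """

    trials: pd.DataFrame
    chance_map: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CHANCE_MAP))

    def __post_init__(self) -> None:
        self.trials = _coerce_frame(self.trials)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        df = self.trials
        if df["confidence"].lt(0).any() or df["confidence"].gt(100).any():
            bad = df.index[(df["confidence"] < 0) | (df["confidence"] > 100)][0]
            raise TrialValidationError(
                f"confidence outside [0, 100] at row {bad}: {df.loc[bad, 'confidence']!r}"
            )
        if not df["correct"].isin((0, 1)).all():
            bad = df.index[~df["correct"].isin((0, 1))][0]
            raise TrialValidationError(f"correct must be 0 or 1 at row {bad}: {df.loc[bad, 'correct']!r}")
        unknown = set(df["condition"].unique()) - set(self.chance_map)
        if unknown:
            raise TrialValidationError(
                f"condition labels without a chance level: {sorted(unknown)}; "
                f"admitted: {sorted(self.chance_map)}"
            )
        for cond, g in self.chance_map.items():
            if not 0.0 <= g < 1.0:
                raise TrialValidationError(f"chance level for {cond!r} must lie in [0, 1): {g}")
        dup = df.duplicated(subset=["agent_id", "condition", "item_id"])
        if dup.any():
            row = df.index[dup][0]
            key = tuple(df.loc[row, ["agent_id", "condition", "item_id"]])
            raise TrialValidationError(f"duplicate (agent, condition, item) triple {key} at row {row}")

    # -- conveniences -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.trials)

    @property
    def agent_groups(self) -> list[str]:
        return sorted(self.trials["agent_group"].unique())

    @property
    def conditions(self) -> list[str]:
        return sorted(self.trials["condition"].unique())

    def equals(self, other: "TrialTable") -> bool:
        return self.chance_map == other.chance_map and self.trials.reset_index(drop=True).equals(
            other.trials.reset_index(drop=True)
        )


def _coerce_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    out = df.loc[:, list(TRIAL_COLUMNS)].copy()
    if out[["correct", "confidence"]].isna().any().any():
        row = out.index[out[["correct", "confidence"]].isna().any(axis=1)][0]
        raise TrialValidationError(f"missing response value at row {row}; missing data are rejected")
    out["agent_id"] = out["agent_id"].astype(str)
    out["agent_group"] = out["agent_group"].astype(str)
    out["condition"] = out["condition"].astype(str)
    out["item_id"] = out["item_id"].astype(str)
    try:
        out["correct"] = pd.to_numeric(out["correct"]).astype(int)
        out["confidence"] = pd.to_numeric(out["confidence"]).astype(float)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"non-numeric correct/confidence value: {exc}") from exc
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_trials(
    path: str | Path | io.IOBase,
    *,
    sep: str = ",",
    column_map: Mapping[str, str] | None = None,
    chance_map: Mapping[str, float] | None = None,
) -> TrialTable:
    """Read a delimited long-format trial file into a validated :class:`TrialTable`.

    ``column_map`` renames source columns to the canonical six names, e.g.
    ``{"participant": "agent_id"}`` — it absorbs foreign layouts such as the
    deposited study repository's. Row order is preserved.
    """
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns={src: dst for src, dst in column_map.items()})
    return TrialTable(df, dict(chance_map) if chance_map else dict(DEFAULT_CHANCE_MAP))


def write_trials(table: TrialTable, path: str | Path, *, sep: str = ",") -> Path:
    """Write ``table`` as delimited text; inverse of :func:`read_trials`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.trials.to_csv(path, sep=sep, index=False)
    return path


def load_table_config(path: str | Path) -> dict:
    """Load a YAML config holding ``column_map`` and/or ``chance_map`` entries."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    out: dict = {}
    if "column_map" in cfg:
        out["column_map"] = {str(k): str(v) for k, v in cfg["column_map"].items()}
    if "chance_map" in cfg:
        out["chance_map"] = {str(k): float(v) for k, v in cfg["chance_map"].items()}
    return out


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def summarize_by_agent(table: TrialTable, include_pooled: bool = True) -> pd.DataFrame:
    """Per-agent, per-condition correct rate and mean confidence.

    With ``include_pooled`` a pseudo-condition ``"All"`` row aggregating every
    trial of the agent is appended, matching the pooled rows of the group
    summary tables downstream.
    """
    if len(table) == 0:
        raise TrialValidationError("cannot summarize an empty trial table")
    df = table.trials

    def _agg(g: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "n_trials": len(g),
                "correct_rate": g["correct"].mean(),
                "mean_confidence": g["confidence"].mean(),
            }
        )

    per_cond = (
        df.groupby(["agent_id", "agent_group", "condition"], sort=True)[["correct", "confidence"]]
        .apply(_agg)
        .reset_index()
    )
    frames = [per_cond]
    if include_pooled:
        pooled = (
            df.groupby(["agent_id", "agent_group"], sort=True)[["correct", "confidence"]]
            .apply(_agg)
            .reset_index()
        )
        pooled.insert(2, "condition", POOLED_CONDITION)
        frames.append(pooled)
    out = pd.concat(frames, ignore_index=True)
    out["n_trials"] = out["n_trials"].astype(int)
    return out


def summarize_by_item(table: TrialTable) -> pd.DataFrame:
    """Per-item, per-agent-group correct rate and mean confidence (across agents)."""
    if len(table) == 0:
        raise TrialValidationError("cannot summarize an empty trial table")
    df = table.trials
    out = (
        df.groupby(["item_id", "condition", "agent_group"], sort=True)
        .agg(
            n_agents=("agent_id", "nunique"),
            correct_rate=("correct", "mean"),
            mean_confidence=("confidence", "mean"),
        )
        .reset_index()
    )
    return out
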