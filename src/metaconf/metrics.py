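"""Metacognitive sensitivity and efficiency measures.

Type-2 ROC/AUROC treats the confidence rating as a classifier of the agent's
own correctness: a type-2 hit is high confidence on a correct trial, a type-2
false alarm is high confidence on an error. meta-J is the plug-in mutual
information (bits) between accuracy and confidence binarized at the
meta-J-maximizing threshold; meta-J2r normalizes it by the Shannon entropy of
accuracy, its upper bound, yielding an efficiency measure in [0, 1]. Both are
invariant to metacognitive bias (any strictly increasing relabelling of the
confidence scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trials import POOLED_CONDITION, TrialTable


class UndefinedMetricError(ValueError):
    """The metric is undefined for this input (e.g. no errors to rank against).

    Distinct from a malformed-input error: the data are valid, the quantity
    simply does not exist (an agent with all answers correct has no type-2
    false-alarm distribution).
    """


@dataclass
class Type2ROC:
    """Type-2 ROC curve of one agent/condition.

    ``thresholds`` are the criterion values swept from above the maximum
    rating downward; ``hr2[i]`` = P(conf >= thresholds[i] | correct) and
    ``far2[i]`` = P(conf >= thresholds[i] | incorrect). ``auroc`` is the
    trapezoidal area, identical to the tie-aware rank statistic
    P(conf_correct > conf_incorrect) + 0.5 P(tie).
    """

    thresholds: np.ndarray
    hr2: np.ndarray
    far2: np.ndarray
    auroc: float
    n_correct: int
    n_incorrect: int


def type2_roc(confidence, correct) -> Type2ROC:
    """Compute the nonparametric type-2 ROC and its area.

    Raises
    ------
    UndefinedMetricError
        If all trials are correct or all incorrect.
    ValueError
        If the sequences are malformed (length mismatch, empty, non-binary).
    """
    conf = np.asarray(confidence, dtype=float)
    corr = np.asarray(correct)
    if conf.ndim != 1 or conf.shape != corr.shape:
        raise ValueError("confidence and correct must be parallel 1-d sequences")
    if conf.size == 0:
        raise ValueError("empty input")
    if not np.isin(corr, (0, 1)).all():
        raise ValueError("correct must be binary 0/1")
    corr = corr.astype(bool)
    n_c = int(corr.sum())
    n_i = int(conf.size - n_c)
    if n_c == 0 or n_i == 0:
        raise UndefinedMetricError(
            f"type-2 sensitivity undefined: {n_c} correct, {n_i} incorrect trials"
        )

    distinct = np.unique(conf)[::-1]  # descending
    thresholds = np.concatenate(([distinct[0] + 1.0], distinct))
    hr2 = np.array([(conf[corr] >= t).mean() for t in thresholds])
    far2 = np.array([(conf[~corr] >= t).mean() for t in thresholds])
    auroc = float(np.trapezoid(hr2, far2))
    return Type2ROC(thresholds, hr2, far2, auroc, n_c, n_i)


def shannon_entropy(p: float) -> float:
    """Binary Shannon entropy in bits, with 0*log(0) = 0."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    h = 0.0
    for q in (p, 1.0 - p):
        if q > 0.0:
            h -= q * math.log2(q)
    return h


def meta_j(confidence, correct, threshold: float) -> float:
    """Plug-in mutual information (bits) between accuracy and confidence
    binarized as high = (confidence >= threshold)."""
    conf = np.asarray(confidence, dtype=float)
    corr = np.asarray(correct).astype(int)
    if conf.shape != corr.shape or conf.ndim != 1:
        raise ValueError("confidence and correct must be parallel 1-d sequences")
    n = conf.size
    if n < 2:
        raise ValueError("need at least 2 trials")
    high = (conf >= threshold).astype(int)
    mi = 0.0
    for a in (0, 1):
        p_a = float((corr == a).mean())
        for c in (0, 1):
            p_c = float((high == c).mean())
            p_ac = float(((corr == a) & (high == c)).mean())
            if p_ac > 0.0:
                mi += p_ac * math.log2(p_ac / (p_a * p_c))
    return max(0.0, mi)


@dataclass
class MetaJResult:
    """meta-J at its maximizing binarization threshold, plus the entropy bound.

    ``meta_j2r`` is ``meta_j / accuracy_entropy`` when the entropy is
    positive and NaN (undefined) otherwise.
    """

    meta_j: float
    threshold: float
    accuracy_entropy: float
    meta_j2r: float
    n_trials: int


def meta_j_max(confidence, correct) -> MetaJResult:
    """Maximize meta-J over every distinct binarization of the ratings.

    Candidate thresholds are the midpoints between consecutive distinct
    confidence values plus one sentinel below the minimum and one above the
    maximum; ties on meta-J break toward the lowest threshold.
    """
    conf = np.asarray(confidence, dtype=float)
    corr = np.asarray(correct).astype(int)
    if conf.shape != corr.shape or conf.ndim != 1:
        raise ValueError("confidence and correct must be parallel 1-d sequences")
    n = conf.size
    if n < 2:
        raise ValueError("need at least 2 trials")
    p_correct = float(corr.mean())
    h_a = shannon_entropy(p_correct)
    distinct = np.unique(conf)
    candidates = np.concatenate(
        ([distinct[0] - 1.0], (distinct[:-1] + distinct[1:]) / 2.0, [distinct[-1] + 1.0])
    )
    if h_a == 0.0:
        return MetaJResult(0.0, float(candidates[0]), 0.0, float("nan"), n)
    best_j, best_t = -1.0, candidates[0]
    for t in candidates:  # ascending; strict > keeps the lowest tied threshold
        j = meta_j(conf, corr, t)
        if j > best_j + 1e-15:
            best_j, best_t = j, t
    return MetaJResult(float(best_j), float(best_t), h_a, float(best_j / h_a), n)


def normalized_discriminability(correct_rate: float, chance: float):
    """(correct_rate - chance) / (1 - chance); below-chance values stay signed."""
    chance = np.asarray(chance, dtype=float)
    if np.any(chance >= 1.0):
        raise ValueError("chance level must be < 1")
    return (np.asarray(correct_rate, dtype=float) - chance) / (1.0 - chance)


# ---------------------------------------------------------------------------
# Folded X-pattern
# ---------------------------------------------------------------------------

def folded_x_table(table: TrialTable, n_bins: int = 4) -> pd.DataFrame:
    """Mean confidence by (group, condition, discriminability bin, correctness).

    Per agent group and condition, item-level correct rates across the
    group's agents are mapped to normalized discriminability and binned into
    ``n_bins`` equal-probability bins by within-condition empirical quantiles
    (items exactly on an edge fall to the lower bin). Trials of binned items
    are pooled and mean confidence is reported separately for the correct and
    incorrect branches; an empty branch yields a missing (NaN) cell. When all
    items of a condition share one discriminability value the binning is
    degenerate and collapses to a single flagged bin.
    """
    df = table.trials
    rows = []
    for (group, cond), sub in df.groupby(["agent_group", "condition"], sort=True):
        item_rate = sub.groupby("item_id")["correct"].mean()
        if len(item_rate) < n_bins:
            raise ValueError(
                f"group {group!r} condition {cond!r} has {len(item_rate)} items; "
                f"need >= {n_bins} for {n_bins}-bin folding"
            )
        disc = normalized_discriminability(item_rate.to_numpy(), table.chance_map[cond])
        disc = pd.Series(disc, index=item_rate.index)
        degenerate = bool(np.isclose(disc.max(), disc.min()))
        if degenerate:
            bin_of = pd.Series(0, index=disc.index)
            edges = np.array([disc.min(), disc.max()])
            nb = 1
        else:
            inner = np.quantile(disc.to_numpy(), np.linspace(0, 1, n_bins + 1)[1:-1])
            bin_of = pd.Series(np.searchsorted(inner, disc.to_numpy(), side="left"), index=disc.index)
            edges = np.concatenate(([disc.min()], inner, [disc.max()]))
            nb = n_bins
        for b in range(nb):
            in_bin = bin_of.index[bin_of == b]
            trials = sub[sub["item_id"].isin(in_bin)]
            for branch, flag in (("correct", 1), ("incorrect", 0)):
                cell = trials[trials["correct"] == flag]
                rows.append(
                    {
                        "agent_group": group,
                        "condition": cond,
                        "quartile": b + 1,
                        "disc_low": float(edges[b]),
                        "disc_high": float(edges[b + 1]),
                        "mean_discriminability": float(disc.loc[in_bin].mean()),
                        "correctness": branch,
                        "mean_confidence": float(cell["confidence"].mean()) if len(cell) else float("nan"),
                        "n_trials": int(len(cell)),
                        "degenerate": degenerate,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Per-agent metric tables (Table 1 / Table 2 analogs)
# ---------------------------------------------------------------------------

def agent_metric_table(table: TrialTable) -> pd.DataFrame:
    """Type-2 AUROC and meta-J per (agent, condition) and pooled ``"All"``.

    Undefined cells (an agent with all trials correct or all incorrect in a
    condition has no type-2 ROC, and a zero accuracy entropy leaves meta-J2r
    undefined) propagate as NaN; group summaries exclude and count them.
    The binarization threshold is re-optimized on the pooled trials for the
    ``"All"`` row rather than averaged over conditions.
    """
    df = table.trials
    rows = []
    for (agent, group), sub in df.groupby(["agent_id", "agent_group"], sort=True):
        blocks = [(cond, blk) for cond, blk in sub.groupby("condition", sort=True)]
        blocks.append((POOLED_CONDITION, sub))
        for cond, blk in blocks:
            conf = blk["confidence"].to_numpy()
            corr = blk["correct"].to_numpy()
            try:
                auroc = type2_roc(conf, corr).auroc
            except UndefinedMetricError:
                auroc = float("nan")
            if len(blk) >= 2:
                mj = meta_j_max(conf, corr)
                mj_val, mj_thr, h_a, mj2r = mj.meta_j, mj.threshold, mj.accuracy_entropy, mj.meta_j2r
            else:
                mj_val = mj_thr = h_a = mj2r = float("nan")
            rows.append(
                {
                    "agent_id": agent,
                    "agent_group": group,
                    "condition": cond,
                    "n_trials": len(blk),
                    "auroc": auroc,
                    "meta_j": mj_val,
                    "threshold": mj_thr,
                    "accuracy_entropy": h_a,
                    "meta_j2r": mj2r,
                }
            )
    return pd.DataFrame(rows)


def group_metric_summary(metric_table: pd.DataFrame,
                         metrics: tuple[str, ...] = ("auroc", "meta_j", "meta_j2r")) -> pd.DataFrame:
    """Group x condition means/SDs over agents with defined values.

    ``n_excluded`` counts agents whose value is undefined in that cell — the
    auditable analog of the varying ANOVA denominators in study-style
    reports.
    """
    rows = []
    for (group, cond), sub in metric_table.groupby(["agent_group", "condition"], sort=True):
        for m in metrics:
            vals = sub[m].dropna()
            rows.append(
                {
                    "agent_group": group,
                    "condition": cond,
                    "metric": m,
                    "mean": float(vals.mean()) if len(vals) else float("nan"),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                    "n": int(len(vals)),
                    "n_excluded": int(sub[m].isna().sum()),
                }
            )
    return pd.DataFrame(rows)
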