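"""Confidence-accuracy association at the stimulus and agent levels.

Two aggregation levels are analyzed: stimulus-level points average each
item's correct rate and confidence across the agents of a group (item
difficulty axis); agent-level points average across items for each agent
(individual-differences axis). Group differences are tested two ways — a
Fisher r-to-z comparison of Pearson correlations and an OLS interaction test
on the regression slope of confidence on correct rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .trials import TrialTable, summarize_by_agent, summarize_by_item


class UndefinedCorrelationError(ValueError):
    """Pearson r is undefined (constant input)."""


def level_means(table: TrialTable, level: str, agent_aggregation: str = "pooled") -> pd.DataFrame:
    """Aggregate a trial table into per-point (x = correct rate, y = confidence) means.

    ``level`` is ``"stimulus"`` (one point per item per group) or ``"agent"``.
    At the agent level, ``agent_aggregation`` selects ``"pooled"`` (one point
    per agent, all conditions merged) or ``"per_condition"`` (one point per
    agent per condition); both readings of study-style layouts are supported
    because published analyses are not always consistent about which was used.
    """
    if level == "stimulus":
        s = summarize_by_item(table)
        out = s.rename(columns={"item_id": "unit"})[
            ["unit", "condition", "agent_group", "correct_rate", "mean_confidence"]
        ]
    elif level == "agent":
        if agent_aggregation == "pooled":
            s = summarize_by_agent(table, include_pooled=True)
            s = s[s["condition"] == "All"]
        elif agent_aggregation == "per_condition":
            s = summarize_by_agent(table, include_pooled=False)
        else:
            raise ValueError(f"unknown agent_aggregation {agent_aggregation!r}")
        out = s.rename(columns={"agent_id": "unit"})[
            ["unit", "condition", "agent_group", "correct_rate", "mean_confidence"]
        ]
    else:
        raise ValueError(f"level must be 'stimulus' or 'agent', got {level!r}")
    return out.reset_index(drop=True)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need parallel sequences with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class CorrelationComparison:
    """Two-sample comparison of independent Pearson correlations via Fisher z."""

    r1: float
    r2: float
    n1: int
    n2: int
    z: float
    p: float


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> CorrelationComparison:
    """z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided normal p."""
    if not (abs(r1) < 1 and abs(r2) < 1):
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("both samples must have n > 3")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return CorrelationComparison(r1, r2, n1, n2, float(z), float(p))


@dataclass
class SlopeComparison:
    """OLS slope-difference (interaction) test between two groups.

    ``delta_beta`` is slope(group2) - slope(group1) with groups in the label
    order of ``groups``; ``degenerate`` flags an exact fit (zero residual
    variance), where t is unbounded.
    """

    groups: tuple[str, str]
    beta_per_group: dict[str, float]
    delta_beta: float
    se: float
    t: float
    df: int
    p: float
    degenerate: bool


def slope_difference(points: pd.DataFrame,
                     x: str = "correct_rate",
                     y: str = "mean_confidence",
                     group: str = "agent_group") -> SlopeComparison:
    """Test the group difference in the regression slope of ``y`` on ``x``.

    Fits ``y ~ x + group + x:group`` by OLS over the pooled points of exactly
    two groups; the interaction coefficient is the slope difference and its
    t-test (df = n - 4) is the reported comparison.
    """
    groups = sorted(points[group].unique())
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    g1, g2 = groups
    for g in groups:
        sub = points[points[group] == g]
        if len(sub) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 points")
        if np.ptp(sub[x].to_numpy()) == 0:
            raise ValueError(f"group {g!r} has constant x; slope undefined")
    xv = points[x].to_numpy(dtype=float)
    yv = points[y].to_numpy(dtype=float)
    ind = (points[group] == g2).to_numpy(dtype=float)
    X = sm.add_constant(np.column_stack([xv, ind, xv * ind]))
    fit = sm.OLS(yv, X).fit()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design for slope comparison")
    beta1 = float(fit.params[1])
    delta = float(fit.params[3])
    se = float(fit.bse[3])
    degenerate = bool(fit.ssr <= max(1e-12, 1e-12 * float(np.square(yv).sum())))
    tval = float(fit.tvalues[3]) if not degenerate else math.inf * np.sign(delta) if delta else 0.0
    pval = float(fit.pvalues[3]) if not degenerate else 0.0 if delta else 1.0
    return SlopeComparison(
        groups=(g1, g2),
        beta_per_group={g1: beta1, g2: beta1 + delta},
        delta_beta=delta,
        se=se,
        t=tval,
        df=int(fit.df_resid),
        p=pval,
        degenerate=degenerate,
    )


def correlation_table(points: pd.DataFrame,
                      x: str = "correct_rate",
                      y: str = "mean_confidence",
                      group: str = "agent_group") -> pd.DataFrame:
    """Per-group Pearson r and the between-group Fisher-z comparison."""
    rows = []
    per_group = {}
    for g, sub in points.groupby(group, sort=True):
        r, p = pearson_r(sub[x], sub[y])
        per_group[g] = (r, len(sub))
        rows.append({"agent_group": g, "r": r, "p": p, "n": len(sub)})
    out = pd.DataFrame(rows)
    if len(per_group) == 2:
        (g1, (r1, n1)), (g2, (r2, n2)) = sorted(per_group.items())
        cmpz = fisher_z_compare(r1, n1, r2, n2)
        out.attrs["fisher_z"] = {"z": cmpz.z, "p": cmpz.p, "order": f"{g1} vs {g2}"}
    return out
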