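"""Mixed-design (split-plot) ANOVA with Greenhouse-Geisser correction.

One between-subjects factor (e.g. agent group) crossed with one or two
within-subject factors (answering condition, correctness), balanced within
subjects: every subject contributes exactly one value per within-cell. The
machinery follows the multivariate-regression formulation: the within-cell
response matrix is regressed on the (sum-coded, Type III) between design, and
each effect is evaluated through an orthonormal contrast of the within cells.
Univariate F statistics, Box/Greenhouse-Geisser epsilon, Mauchly's sphericity
test and generalized eta squared all derive from the resulting hypothesis and
error cross-product matrices.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class DesignError(ValueError):
    """The data do not form a balanced within-subject design."""


def _orthonormal_contrast(k: int) -> np.ndarray:
    """Orthonormal basis (k x (k-1)) of the subspace orthogonal to the constant."""
    if k < 2:
        raise ValueError("need at least 2 levels")
    q, _ = np.linalg.qr(np.column_stack([np.ones(k), np.eye(k)[:, :-1]]))
    return q[:, 1:]


def gg_epsilon(within_covariance: np.ndarray) -> float:
    """Box's epsilon-hat from a k x k within-subject covariance matrix.

    Computed on the double-centered covariance; bounded in [1/(k-1), 1].
    Equals 1 exactly under compound symmetry and always for k = 2.
    """
    s = np.asarray(within_covariance, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(s, s.T, atol=1e-8):
        raise ValueError("covariance must be symmetric")
    k = s.shape[0]
    if k == 2:
        return 1.0
    c = np.eye(k) - np.ones((k, k)) / k
    sc = c @ s @ c
    num = np.trace(sc) ** 2
    den = (k - 1) * np.trace(sc @ sc)
    if den <= 0:
        return 1.0
    return float(min(1.0, max(1.0 / (k - 1), num / den)))


def _contrast_epsilon(sigma: np.ndarray) -> float:
    """Epsilon from an already-contrast-projected covariance (q x q)."""
    q = sigma.shape[0]
    if q == 1:
        return 1.0
    num = np.trace(sigma) ** 2
    den = q * np.trace(sigma @ sigma)
    if den <= 0:
        return 1.0
    return float(min(1.0, max(1.0 / q, num / den)))


def _mauchly_p(sigma: np.ndarray, df_error: int) -> float:
    """Mauchly's sphericity test on the contrast-projected covariance."""
    q = sigma.shape[0]
    if q == 1:
        return 1.0
    det = np.linalg.det(sigma)
    mean_tr = np.trace(sigma) / q
    if det <= 0 or mean_tr <= 0:
        return 0.0
    w = det / mean_tr**q
    d = 1.0 - (2.0 * q**2 + q + 2.0) / (6.0 * q * df_error)
    chi2 = -df_error * d * math.log(w)
    ddof = q * (q + 1) // 2 - 1
    # second-order Box series correction for the chi-square approximation
    w2 = (
        (q + 2) * (q - 1) * (q - 2) * (2 * q**3 + 6 * q**2 + 3 * (q + 1) + 2)
        / (288.0 * (df_error * q * d) ** 2)
    )
    p1 = stats.chi2.sf(chi2, ddof)
    p2 = stats.chi2.sf(chi2, ddof + 4)
    return float(p1 + w2 * (p2 - p1))


@dataclass
class _Effect:
    name: str
    ss: float
    ss_err: float
    df1: float
    df2: float
    eps: float
    mauchly_p: float
    is_within: bool


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    between: str | None = None,
    within: list[str] | None = None,
    gg: str = "auto",
    alpha: float = 0.05,
    drop_incomplete: bool = False,
) -> pd.DataFrame:
    """Type III mixed-design ANOVA on a long-format table.

    Parameters
    ----------
    data : long table with one row per (subject, within-cell) observation.
    dv, subject, between, within : column names; ``within`` may hold one or
        two factors. With no within factor the model reduces to a one-way
        between-subjects ANOVA.
    gg : Greenhouse-Geisser policy — ``"auto"`` corrects a within effect when
        Mauchly's test rejects at ``alpha``, ``"always"``/``"never"`` force
        the choice (useful for exact-reproduction runs).
    drop_incomplete : drop subjects missing any within-cell instead of
        raising; the exclusion count is recorded in ``attrs['n_dropped']``.
        This is how study-style reports end up with reduced error
        denominators when some agents have no value in a cell.

    Returns
    -------
    DataFrame with one row per effect: sums of squares, (possibly corrected)
    degrees of freedom, F, uncorrected and GG-corrected p, the selected ``p``,
    epsilon, Mauchly p, and generalized eta squared (``ges``).
    """
    if gg not in ("auto", "always", "never"):
        raise ValueError("gg must be 'auto', 'always' or 'never'")
    within = list(within or [])
    cols = [subject, dv] + ([between] if between else []) + within
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise DesignError(f"missing column(s): {missing}")
    df = data.loc[:, cols].dropna()

    # subject -> between level must be unique
    if between:
        per_subj = df.groupby(subject)[between].nunique()
        if (per_subj > 1).any():
            raise DesignError("a subject appears under more than one between level")
        glevels = sorted(df[between].unique())
        if len(glevels) < 2:
            between = None

    if not within:
        return _between_only_anova(df, dv, subject, between)

    wlevels = [sorted(df[w].unique()) for w in within]
    if any(len(l) < 2 for l in wlevels):
        raise DesignError("every within factor needs >= 2 levels")
    cells = list(itertools.product(*wlevels))
    p = len(cells)

    pivot = df.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    if len(within) == 1:
        pivot = pivot.reindex(columns=wlevels[0])
    else:
        pivot = pivot.reindex(columns=pd.MultiIndex.from_tuples(cells, names=within))
    n_dropped = 0
    if pivot.isna().any().any():
        if drop_incomplete:
            n_dropped = int(pivot.isna().any(axis=1).sum())
            pivot = pivot.dropna()
            if len(pivot) < 3:
                raise DesignError("fewer than 3 complete subjects after dropping incomplete ones")
        else:
            bad = pivot.index[pivot.isna().any(axis=1)][:3].tolist()
            raise DesignError(f"missing within-cells for subject(s) {bad}; designs must be complete")
    subjects = pivot.index.to_numpy()
    y = pivot.to_numpy(dtype=float)
    n = y.shape[0]

    # Between design: intercept + sum-coded group columns (Type III).
    if between:
        gmap = df.drop_duplicates(subject).set_index(subject)[between]
        groups = gmap.loc[subjects].to_numpy()
        glevels = sorted(set(groups))
        G = len(glevels)
        if min(np.sum(groups == g) for g in glevels) < 2:
            raise DesignError("need >= 2 subjects per between level")
        X = np.ones((n, G))
        for j, g in enumerate(glevels[:-1]):
            X[:, j + 1] = np.where(groups == g, 1.0, np.where(groups == glevels[-1], -1.0, 0.0))
    else:
        G = 1
        X = np.ones((n, 1))
    if n - G < 1:
        raise DesignError("not enough subjects for the residual")

    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    b = xtx_inv @ X.T @ y
    resid = y - X @ b
    e_full = resid.T @ resid
    df_e = n - G

    # Contrast (or unit) vector per within factor, kron-combined per effect.
    units = [np.ones((len(l), 1)) / math.sqrt(len(l)) for l in wlevels]
    contrasts = [_orthonormal_contrast(len(l)) for l in wlevels]

    def _m_for(effect_factors: tuple[int, ...]) -> np.ndarray:
        mats = [contrasts[i] if i in effect_factors else units[i] for i in range(len(within))]
        m = mats[0]
        for mm in mats[1:]:
            m = np.kron(m, mm)
        return m

    m0 = _m_for(())
    ss_subj = float((m0.T @ e_full @ m0).item())

    between_rows = list(range(1, G))  # sum-coded group coefficients
    effects: list[_Effect] = []

    def _add(name: str, L_rows: list[int], M: np.ndarray, is_within: bool) -> None:
        q = M.shape[1]
        L = np.eye(G)[L_rows, :]
        bm = L @ b @ M
        h = bm.T @ np.linalg.inv(L @ xtx_inv @ L.T) @ bm
        em = M.T @ e_full @ M
        sigma = em / df_e
        eps = _contrast_epsilon(sigma) if is_within else 1.0
        mp = _mauchly_p(sigma, df_e) if is_within else 1.0
        effects.append(
            _Effect(name, float(np.trace(h)), float(np.trace(em)),
                    len(L_rows) * q, df_e * q, eps, mp, is_within)
        )

    if between:
        _add(between, between_rows, m0, is_within=False)
    n_w = len(within)
    effect_spaces = []
    for r in range(1, n_w + 1):
        effect_spaces.extend(itertools.combinations(range(n_w), r))
    for idx in effect_spaces:
        name = " * ".join(within[i] for i in idx)
        M = _m_for(idx)
        _add(name, [0], M, is_within=True)
        if between:
            _add(f"{between} * {name}", between_rows, M, is_within=True)

    tr_e = float(np.trace(e_full))  # total error SS across all strata
    rows = []
    for ef in effects:
        f = (ef.ss / ef.df1) / (ef.ss_err / ef.df2)
        p_unc = float(stats.f.sf(f, ef.df1, ef.df2))
        p_gg = float(stats.f.sf(f, ef.df1 * ef.eps, ef.df2 * ef.eps))
        use_gg = ef.is_within and ef.eps < 1.0 and (
            gg == "always" or (gg == "auto" and ef.mauchly_p < alpha)
        )
        rows.append(
            {
                "effect": ef.name,
                "ss": ef.ss,
                "ss_error": ef.ss_err,
                "df1": ef.df1 * ef.eps if use_gg else ef.df1,
                "df2": ef.df2 * ef.eps if use_gg else ef.df2,
                "F": f,
                "p_uncorrected": p_unc,
                "p_gg": p_gg,
                "p": p_gg if use_gg else p_unc,
                "eps": ef.eps,
                "mauchly_p": ef.mauchly_p,
                "gg_applied": use_gg,
                "ges": ef.ss / (ef.ss + tr_e) if (ef.ss + tr_e) > 0 else 0.0,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["ss_subjects"] = ss_subj
    out.attrs["df_error_between"] = df_e
    out.attrs["n_subjects"] = n
    out.attrs["n_dropped"] = n_dropped
    return out


def _between_only_anova(df: pd.DataFrame, dv: str, subject: str, between: str | None) -> pd.DataFrame:
    """Degenerate path: no within factor -> one-way between-subjects ANOVA."""
    means = df.groupby(subject).agg({dv: "mean", **({between: "first"} if between else {})})
    if between is None:
        raise DesignError("no factors to analyze")
    groups = [g[dv].to_numpy() for _, g in means.groupby(between)]
    if len(groups) < 2:
        raise DesignError("need >= 2 between levels")
    f, p = stats.f_oneway(*groups)
    grand = means[dv].mean()
    ss_b = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_w = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return pd.DataFrame(
        [{
            "effect": between, "ss": ss_b, "ss_error": ss_w,
            "df1": len(groups) - 1, "df2": len(means) - len(groups),
            "F": float(f), "p_uncorrected": float(p), "p_gg": float(p), "p": float(p),
            "eps": 1.0, "mauchly_p": 1.0, "gg_applied": False,
            "ges": ss_b / (ss_b + ss_w) if (ss_b + ss_w) > 0 else 0.0,
        }]
    )


# ---------------------------------------------------------------------------
# Bonferroni pairwise post hocs
# ---------------------------------------------------------------------------

def bonferroni_pairwise(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    comparisons: list[tuple[dict, dict]],
) -> pd.DataFrame:
    """Bonferroni-corrected pairwise t-tests over an explicit comparison family.

    Each comparison is a pair of cell filters ``({factor: level, ...},
    {factor: level, ...})``. Values are averaged to one number per subject
    within each cell; a paired t-test is used when the two cells share the
    same subjects (within comparison), an independent two-sample t-test
    otherwise. The family size ``m`` is the number of comparisons passed, and
    adjusted p = min(1, m * raw p).
    """
    m = len(comparisons)
    if m == 0:
        raise ValueError("comparison family must not be empty")

    def _cell(filt: dict) -> pd.Series:
        sub = data
        for k, v in filt.items():
            sub = sub[sub[k] == v]
        if len(sub) == 0:
            raise ValueError(f"cell filter {filt} selects no rows")
        return sub.groupby(subject)[dv].mean()

    rows = []
    for filt_a, filt_b in comparisons:
        a, bvals = _cell(filt_a), _cell(filt_b)
        shared = a.index.intersection(bvals.index)
        paired = len(shared) == len(a) == len(bvals)
        if paired:
            t, p = stats.ttest_rel(a.loc[shared], bvals.loc[shared])
            dof = len(shared) - 1
        else:
            t, p = stats.ttest_ind(a, bvals, equal_var=True)
            dof = len(a) + len(bvals) - 2
        rows.append(
            {
                "cell_a": str(filt_a),
                "cell_b": str(filt_b),
                "mean_diff": float(a.mean() - bvals.mean()),
                "t": float(t),
                "df": int(dof),
                "paired": paired,
                "p_raw": float(p),
                "p_bonf": float(min(1.0, m * p)),
                "m": m,
            }
        )
    return pd.DataFrame(rows)


def condition_pairs(factor: str, levels: list[str], fixed: dict | None = None) -> list[tuple[dict, dict]]:
    """All pairwise comparisons of ``levels`` of one factor, optionally within
    fixed levels of other factors (a simple-effects family)."""
    fixed = fixed or {}
    out = []
    for a, b in itertools.combinations(levels, 2):
        out.append(({**fixed, factor: a}, {**fixed, factor: b}))
    return out
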