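"""Cognitive-association statistics.

One ordinary-least-squares model per cognitive outcome, with demographic
covariates (age, sex, years of education, systolic and diastolic blood
pressure) plus either the log-adjusted total WMH volume or the four
log-adjusted sub-class volumes.  Per-term significance uses Type III
sums of squares: the full model is compared against the model with that
term removed, which with continuous covariates plus a single two-level
factor coincides with the drop-one-term F test.  Pearson correlations
and Bonferroni correction round out the battery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .volumes_io import CohortTable

__all__ = [
    "COVARIATES",
    "COGNITIVE_OUTCOMES",
    "TOTAL_PREDICTOR",
    "SUBCLASS_PREDICTORS",
    "TermResult",
    "RegressionResult",
    "PearsonResult",
    "CollinearityError",
    "DegenerateOutcomeError",
    "fit_glm_type3",
    "run_model_family",
    "pearson_correlations",
    "bonferroni_adjust",
]

COVARIATES = ("age", "sex", "education", "systolic", "diastolic")

#: default cognitive battery (column names)
COGNITIVE_OUTCOMES = (
    "moca",
    "tmt_a",
    "tmt_b",
    "tmt_b_minus_a",
    "digit_span_forward",
    "digit_span_backwards",
    "digit_span_sequence",
    "digit_symbol",
    "digit_coding",
    "bnt_60",
    "letter_fluency",
    "category_fluency",
)

TOTAL_PREDICTOR = "log_total"
SUBCLASS_PREDICTORS = (
    "log_peri_hypo",
    "log_peri_nonhypo",
    "log_deep_hypo",
    "log_deep_nonhypo",
)

ALPHA = 0.05


class CollinearityError(ValueError):
    """The design matrix is rank deficient."""


class DegenerateOutcomeError(ValueError):
    """The outcome has no variance in the complete cases."""


@dataclass
class TermResult:
    beta: float
    se: float
    f_type3: float
    p: float


@dataclass
class RegressionResult:
    outcome: str
    terms: dict[str, TermResult]
    model_f: float
    model_p: float
    r2: float
    adj_r2: float
    n_used: int
    alpha: float = ALPHA
    m_bonferroni: int = 1
    p_bonferroni: dict[str, float] = field(default_factory=dict)


@dataclass
class PearsonResult:
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    flagged: pd.DataFrame  # True where a cell could not be computed


def _as_dataframe(table: CohortTable | pd.DataFrame) -> pd.DataFrame:
    return table.df if isinstance(table, CohortTable) else table


def _encode_sex(col: pd.Series) -> np.ndarray:
    """0/1 indicator; for string/categorical input, female-like level -> 0."""
    if pd.api.types.is_numeric_dtype(col):
        vals = col.to_numpy(dtype=float)
        if not np.isin(vals[np.isfinite(vals)], (0.0, 1.0)).all():
            raise ValueError("numeric sex column must be coded 0/1")
        return vals
    levels = sorted(set(col.dropna().astype(str)))
    if len(levels) > 2:
        raise ValueError(f"sex must have at most 2 levels, got {levels}")
    for ref in ("F", "f", "female", "Female"):
        if ref in levels:
            levels = [ref] + [l for l in levels if l != ref]
            break
    mapping = {lvl: float(i) for i, lvl in enumerate(levels)}
    return col.astype(str).map(mapping).to_numpy(dtype=float)


def _build_design(
    df: pd.DataFrame, outcome: str, predictors: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, list[str], int]:
    """Listwise-complete design matrix (with intercept) and outcome."""
    cols: dict[str, np.ndarray] = {}
    for term in predictors:
        if term not in df.columns:
            raise ValueError(f"predictor column '{term}' absent from table")
        if term == "sex":
            cols[term] = _encode_sex(df[term])
        else:
            cols[term] = pd.to_numeric(df[term], errors="coerce").to_numpy(dtype=float)
    if outcome not in df.columns:
        raise ValueError(f"outcome column '{outcome}' absent from table")
    y = pd.to_numeric(df[outcome], errors="coerce").to_numpy(dtype=float)

    keep = np.isfinite(y)
    for arr in cols.values():
        keep &= np.isfinite(arr)
    n_used = int(keep.sum())
    names = list(predictors)
    X = np.column_stack([np.ones(n_used)] + [cols[t][keep] for t in names])
    return X, y[keep], names, n_used


def _type3_drop_term_ss(X: np.ndarray, y: np.ndarray, j: int) -> float:
    """SSR(reduced) - SSR(full) for dropping column j (0-based, excl. intercept).

    Computed through a QR factorisation with the dropped column permuted
    last, so the sum-of-squares difference is obtained as a single
    projection instead of a cancellation-prone subtraction of two large
    residual sums.
    """
    p = X.shape[1]
    order = [c for c in range(p) if c != j + 1] + [j + 1]
    q, _ = np.linalg.qr(X[:, order])
    c = q[:, -1] @ y
    return float(c * c)


def fit_glm_type3(
    table: CohortTable | pd.DataFrame,
    outcome: str,
    predictors: Sequence[str],
    alpha: float = ALPHA,
    m_bonferroni: int = 1,
) -> RegressionResult:
    """Univariate multiple linear regression with Type III per-term tests.

    Incomplete rows are dropped listwise for this model and the n used is
    reported.  Each term's Type III F is the full-vs-reduced comparison
    dropping that term (numerator df 1: all terms are single columns —
    continuous covariates, volumes, or the 0/1 sex indicator).

    Raises
    ------
    CollinearityError
        If the design is rank deficient (dependent terms are named).
    DegenerateOutcomeError
        If the outcome is constant over the complete cases.
    """
    df = _as_dataframe(table)
    X, y, names, n_used = _build_design(df, outcome, predictors)
    p = X.shape[1]
    if n_used < p + 1:
        raise ValueError(
            f"only {n_used} complete cases for {p - 1} terms; need >= {p + 1}"
        )
    if np.ptp(y) == 0.0:
        raise DegenerateOutcomeError(f"outcome '{outcome}' is constant over complete cases")
    r_diag = np.abs(np.diag(np.linalg.qr(X, mode="r")))
    rank_tol = X.shape[0] * np.finfo(float).eps * r_diag.max()
    if (r_diag < rank_tol).any():
        dep = [names[k - 1] for k in np.flatnonzero(r_diag < rank_tol) if k > 0]
        raise CollinearityError(f"design is rank deficient; dependent terms: {dep}")

    ols = sm.OLS(y, X).fit()
    df_resid = n_used - p
    # residual variation below float round-off of the outcome's total
    # variation counts as a perfect (degenerate) fit
    perfect = float(ols.ssr) <= 1e-12 * float(ols.centered_tss)
    mse = 0.0 if perfect else float(ols.ssr) / df_resid

    terms: dict[str, TermResult] = {}
    for j, name in enumerate(names):
        ss = _type3_drop_term_ss(X, y, j)
        if mse > 0:
            f_val = ss / mse
            p_val = float(stats.f.sf(f_val, 1, df_resid))
        else:  # perfect fit
            f_val = float("inf") if ss > 0 else 0.0
            p_val = 0.0 if ss > 0 else 1.0
        terms[name] = TermResult(
            beta=float(ols.params[j + 1]),
            se=float(ols.bse[j + 1]),
            f_type3=f_val,
            p=p_val,
        )

    if perfect:
        model_f, model_p = float("inf"), 0.0
    else:
        model_f, model_p = float(ols.fvalue), float(ols.f_pvalue)
    result = RegressionResult(
        outcome=outcome,
        terms=terms,
        model_f=model_f,
        model_p=model_p,
        r2=float(ols.rsquared),
        adj_r2=float(ols.rsquared_adj),
        n_used=n_used,
        alpha=alpha,
        m_bonferroni=m_bonferroni,
    )
    result.p_bonferroni = {
        name: bonferroni_adjust([tr.p], m_bonferroni)[0] for name, tr in terms.items()
    }
    return result


def run_model_family(
    table: CohortTable | pd.DataFrame,
    mode: str,
    outcomes: Iterable[str] | None = None,
    covariates: Sequence[str] = COVARIATES,
    m_bonferroni: int | None = None,
    alpha: float = ALPHA,
) -> dict[str, RegressionResult]:
    """One GLM per cognitive outcome for one of the two model families.

    ``mode="total"`` adds the log-adjusted total WMH volume to the
    demographic covariates; ``mode="subclass"`` adds the four
    log-adjusted sub-class volumes simultaneously.  The Bonferroni family
    size defaults to the number of outcomes actually modelled.
    """
    if mode == "total":
        wmh_terms: tuple[str, ...] = (TOTAL_PREDICTOR,)
    elif mode == "subclass":
        wmh_terms = SUBCLASS_PREDICTORS
    else:
        raise ValueError(f"mode must be 'total' or 'subclass', got '{mode}'")
    df = _as_dataframe(table)
    if outcomes is None:
        outcomes = [c for c in COGNITIVE_OUTCOMES if c in df.columns]
    outcomes = list(outcomes)
    for col in list(covariates) + list(wmh_terms):
        if col not in df.columns:
            raise ValueError(f"required predictor column '{col}' absent from table")
    m = m_bonferroni if m_bonferroni is not None else max(1, len(outcomes))
    predictors = list(covariates) + list(wmh_terms)
    return {
        outcome: fit_glm_type3(df, outcome, predictors, alpha=alpha, m_bonferroni=m)
        for outcome in outcomes
    }


def pearson_correlations(
    table: CohortTable | pd.DataFrame, variables: Sequence[str]
) -> PearsonResult:
    """Pairwise-complete Pearson correlations with two-sided t-based p.

    Cells with fewer than 3 complete pairs or zero variance are flagged
    (NaN r) rather than propagating NaNs through the matrix.
    """
    df = _as_dataframe(table)
    k = len(variables)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    flagged = np.zeros((k, k), dtype=bool)
    arrays = {
        v: pd.to_numeric(df[v], errors="coerce").to_numpy(dtype=float) for v in variables
    }
    for i, vi in enumerate(variables):
        for j, vj in enumerate(variables):
            if j < i:
                continue
            a, b = arrays[vi], arrays[vj]
            keep = np.isfinite(a) & np.isfinite(b)
            nij = int(keep.sum())
            n[i, j] = n[j, i] = nij
            if nij < 3 or a[keep].std() == 0.0 or b[keep].std() == 0.0:
                flagged[i, j] = flagged[j, i] = True
                continue
            if i == j:
                r[i, j], p[i, j] = 1.0, 0.0
                continue
            res = stats.pearsonr(a[keep], b[keep])
            r[i, j] = r[j, i] = float(res.statistic)
            p[i, j] = p[j, i] = float(res.pvalue)
    idx = list(variables)
    return PearsonResult(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
        flagged=pd.DataFrame(flagged, index=idx, columns=idx),
    )


def bonferroni_adjust(p: Sequence[float] | Mapping[str, float], m: int) -> list[float] | dict[str, float]:
    """Bonferroni-adjusted p-values: min(1, p*m) for family size m >= 1."""
    if m < 1:
        raise ValueError(f"Bonferroni family size must be >= 1, got {m}")
    if isinstance(p, Mapping):
        return {k: min(1.0, float(v) * m) for k, v in p.items()}
    vals = [float(v) for v in p]
    if any(not 0.0 <= v <= 1.0 for v in vals):
        raise ValueError("p-values must lie in [0, 1]")
    return [min(1.0, v * m) for v in vals]
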