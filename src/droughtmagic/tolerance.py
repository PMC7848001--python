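"""Drought tolerance indices and their descriptive / association statistics.

The tolerance index for a trait is ``100 * (value under restricted
irrigation / value under full irrigation)``: values below 100 mean the
trait was reduced by drought.  Growth habit is compared between regimes
and coded 1 (no change) / 9 (change); for modeling the coding is mapped
to 0/1.  The association between habit change and each quantitative
index is assessed with a univariate logistic regression reporting Wald
Z statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .simulate import N_HABIT_LEVELS, QUANT_TRAITS

TI_COLUMNS = {
    "maturity": "TI_maturity",
    "flowering_time": "TI_flowering",
    "seed_weight": "TI_seedweight",
    "grain_yield": "TI_yield",
}

HABIT_NO_CHANGE, HABIT_CHANGE = 1, 9


class DomainError(ValueError):
    pass


class EmptySummaryError(ValueError):
    pass


def tolerance_index(y_restricted, y_full):
    """100 * restricted / full; NaN if either input is missing or full <= 0."""
    y_restricted = np.asarray(y_restricted, dtype=float)
    y_full = np.asarray(y_full, dtype=float)
    if np.nanmin(y_restricted, initial=0.0) < 0 or np.nanmin(y_full, initial=0.0) < 0:
        raise DomainError("trait values must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        ti = 100.0 * y_restricted / y_full
    ti = np.where((y_full <= 0) | np.isnan(y_full) | np.isnan(y_restricted), np.nan, ti)
    return ti if ti.ndim else float(ti) if not np.isnan(ti) else np.nan


def habit_change(gh_full, gh_restricted):
    """1 if the ordinal habit score is unchanged between regimes, 9 otherwise."""
    gh_full = np.asarray(gh_full, dtype=float)
    gh_restricted = np.asarray(gh_restricted, dtype=float)
    for a in (gh_full, gh_restricted):
        vals = a[~np.isnan(a)]
        if ((vals < 1) | (vals > N_HABIT_LEVELS) | (vals != np.round(vals))).any():
            raise DomainError(f"growth habit scores must be integers 1..{N_HABIT_LEVELS}")
    out = np.where(gh_full == gh_restricted, HABIT_NO_CHANGE, HABIT_CHANGE).astype(float)
    out = np.where(np.isnan(gh_full) | np.isnan(gh_restricted), np.nan, out)
    return out if out.ndim else float(out) if not np.isnan(out) else np.nan


def habit_change_binary(coded) -> np.ndarray:
    """Map the 1/9 I/O coding to a 0/1 modeling view (NaN preserved)."""
    coded = np.asarray(coded, dtype=float)
    ok = np.isin(coded, (HABIT_NO_CHANGE, HABIT_CHANGE)) | np.isnan(coded)
    if not ok.all():
        raise DomainError("habit change must be coded 1 or 9")
    return np.where(np.isnan(coded), np.nan, (coded == HABIT_CHANGE).astype(float))


def tolerance_table(pheno: pd.DataFrame) -> pd.DataFrame:
    """Per-RIL tolerance indices and habit-change coding from a long table.

    ``pheno`` has one row per RIL x regime with trait columns; if several
    replicate rows exist per (ril, regime) they are averaged per regime
    before the ratio is taken.
    """
    agg = {t: "mean" for t in QUANT_TRAITS}
    agg["growth_habit"] = lambda s: s.iloc[0] if s.notna().any() else np.nan
    wide = pheno.groupby(["ril", "regime"], sort=False).agg(agg).unstack("regime")
    out = pd.DataFrame(index=wide.index)
    for trait, col in TI_COLUMNS.items():
        out[col] = tolerance_index(
            wide[(trait, "restricted")].to_numpy(), wide[(trait, "full")].to_numpy()
        )
    out["habit_change"] = habit_change(
        wide[("growth_habit", "full")].to_numpy(),
        wide[("growth_habit", "restricted")].to_numpy(),
    )
    return out.reset_index()


def summarize(values) -> dict:
    """min / max / mean / sd (n-1) / skewness over non-missing values."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise EmptySummaryError("no non-missing values to summarize")
    sd = float(np.std(v, ddof=1)) if v.size >= 2 else np.nan
    skew = float(stats.skew(v, bias=False)) if v.size >= 3 and sd > 0 else np.nan
    return {
        "n": int(v.size),
        "min": float(v.min()),
        "max": float(v.max()),
        "mean": float(v.mean()),
        "sd": sd,
        "skewness": skew,
    }


def correlation_matrix(ti_table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between tolerance indices."""
    columns = list(columns) if columns is not None else list(TI_COLUMNS.values())
    sub = ti_table[columns]
    constant = [c for c in columns if sub[c].dropna().nunique() <= 1]
    if constant:
        warnings.warn(f"constant columns give undefined correlations: {constant}")
    return sub.corr(method="pearson", min_periods=3)


@dataclass
class LogisticFit:
    """Univariate logistic fit log[pi/(1-pi)] = b0 + b1 x."""

    intercept: float
    slope: float
    z_value: float
    p_value: float
    converged: bool
    n: int
    deviance_path: list


def univariate_logistic(binary_response, covariate) -> LogisticFit:
    """ML logistic regression of a 0/1 (or 1/9-coded) response on one covariate.

    Fitted by iteratively reweighted least squares (statsmodels GLM with a
    binomial family); Wald Z = slope / SE and a two-sided normal p-value.
    Single-class responses and separated fits are flagged non-converged
    with the Z and p suppressed.
    """
    y = np.asarray(binary_response, dtype=float)
    if set(np.unique(y[~np.isnan(y)])) <= {HABIT_NO_CHANGE, HABIT_CHANGE}:
        y = habit_change_binary(y)
    x = np.asarray(covariate, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(x))
    y, x = y[keep], x[keep]
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise DomainError("response must be binary (0/1 or 1/9 coded)")
    n = int(y.size)
    if n == 0 or len(np.unique(y)) < 2:
        return LogisticFit(np.nan, np.nan, np.nan, np.nan, False, n, [])
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        except Exception:
            return LogisticFit(np.nan, np.nan, np.nan, np.nan, False, n, [])
    # the first two history entries are initialization values (inf and the
    # deviance at the mean-based starting mu), not model-fit deviances
    deviance_path = list(res.fit_history.get("deviance", []))[2:]
    # huge standard errors signal (quasi-)separation: ML estimate diverges
    converged = bool(res.converged) and np.all(np.isfinite(res.bse)) and res.bse[1] < 1e4
    if not converged:
        return LogisticFit(
            float(res.params[0]), float(res.params[1]), np.nan, np.nan, False, n,
            deviance_path,
        )
    z = float(res.params[1] / res.bse[1])
    p = float(2.0 * stats.norm.sf(abs(z)))
    return LogisticFit(
        float(res.params[0]), float(res.params[1]), z, p, True, n, deviance_path
    )


def habit_logistic_screen(ti_table: pd.DataFrame) -> pd.DataFrame:
    """Univariate logistic fit of habit change on each tolerance index."""
    rows = []
    for col in TI_COLUMNS.values():
        fit = univariate_logistic(
            ti_table["habit_change"].to_numpy(), ti_table[col].to_numpy()
        )
        rows.append(
            {
                "index": col,
                "slope": fit.slope,
                "z_value": fit.z_value,
                "p_value": fit.p_value,
                "converged": fit.converged,
                "n": fit.n,
            }
        )
    return pd.DataFrame(rows)
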