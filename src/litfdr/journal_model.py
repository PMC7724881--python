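"""Random-intercept linear models of journal-level empirical FDR.

The response is the per-journal-year empirical false discovery rate; the
predictors are centred year, an Open Access indicator, natural-log
impact factor and (in the global model) an oncology indicator, with a
random intercept per journal.  This module builds the model frame,
applies the sensitivity-dataset filters, fits the models by REML, runs
the hierarchical interaction screen, and computes the derived effects
(change per twofold impact-factor move, adjusted group means, percent
excess, cluster-bootstrap prediction bands).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)

DATASET_IDS = ("all", "oa_stable", "nonzero_fdr", "oa_stable_and_nonzero")

#: Default fixed-effect terms of the global model.
GLOBAL_TERMS = ("year_c", "oa", "log_jif", "oncology")
STRATIFIED_TERMS = ("year_c", "oa", "log_jif")


@dataclass
class LmmResult:
    """Fixed-effect table plus variance components of one fitted model."""

    table: pd.DataFrame  # index: term; estimate, se, tvalue, pvalue, ci_low, ci_high
    re_var: float
    resid_var: float
    n_obs: int
    n_groups: int
    method: dict = field(default_factory=dict)


class FitError(RuntimeError):
    pass


def build_model_frame(
    estimates: pd.DataFrame, meta: pd.DataFrame, base_year: Optional[int] = None
) -> pd.DataFrame:
    """Merge FDR estimates with journal metadata into a modelling frame.

    Columns: journal, year, fdr, year_c (centred at the first study
    year), oa, log_jif, oncology.  Impact factor is matched per
    journal-year from the metadata (a static per-journal value simply
    repeats across years).
    """
    df = estimates.merge(meta, on=["journal", "year"], how="inner")
    if (df["jif"] <= 0).any():
        raise ValueError("impact factors must be positive")
    if base_year is None:
        base_year = int(df["year"].min())
    df = df.assign(
        year_c=df["year"] - base_year,
        log_jif=np.log(df["jif"]),
        oncology=(df["subject"] == "oncology").astype(int)
        if "oncology" not in df.columns else df["oncology"].astype(int),
    )
    return df[["journal", "year", "fdr", "year_c", "oa", "log_jif", "oncology"]].copy()


def apply_dataset_filter(
    estimates: pd.DataFrame,
    meta: pd.DataFrame,
    which: str = "all",
    zero_tol: float = 1e-4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sensitivity-dataset filters on (estimates, meta), by journal.

    ``oa_stable`` drops journals whose Open Access status changed within
    the window; ``nonzero_fdr`` drops journals with any year's estimate
    below ``zero_tol``; the combined filter is the intersection.
    """
    if which not in DATASET_IDS:
        raise ValueError(f"unknown dataset id {which!r}; expected one of {DATASET_IDS}")
    keep = set(estimates["journal"])
    if which in ("oa_stable", "oa_stable_and_nonzero"):
        oa_n = meta.groupby("journal")["oa"].nunique()
        keep &= set(oa_n[oa_n == 1].index)
    if which in ("nonzero_fdr", "oa_stable_and_nonzero"):
        min_fdr = estimates.groupby("journal")["fdr"].min()
        keep &= set(min_fdr[min_fdr >= zero_tol].index)
    est_f = estimates[estimates["journal"].isin(keep)].reset_index(drop=True)
    meta_f = meta[meta["journal"].isin(keep)].reset_index(drop=True)
    return est_f, meta_f


def _design(frame: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    X = pd.DataFrame({"Intercept": np.ones(len(frame))}, index=frame.index)
    for t in terms:
        v = None
        for factor in t.split(":"):
            col = frame[factor].astype(float)
            v = col if v is None else v * col
        X[t] = v
    return X


def fit_lmm(frame: pd.DataFrame, terms: Sequence[str]) -> LmmResult:
    """REML fit of fdr ~ terms with a random intercept per journal.

    Inference on the fixed effects uses the large-sample normal
    approximation (recorded as ``method["df_method"]``).  Degenerate
    frames with (numerically) zero between- and within-journal variance
    fall back to ordinary least squares with the random-intercept
    variance reported as zero.
    """
    if frame["journal"].nunique() < 2 or len(frame) < 2:
        raise FitError("need at least 2 observations from at least 2 journals")
    y = frame["fdr"].astype(float)
    X = _design(frame, terms)
    if np.linalg.matrix_rank(X.values) < X.shape[1]:
        raise FitError("design matrix is rank deficient for these terms")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            res = MixedLM(y, X, groups=frame["journal"]).fit(reml=True)
            fe = res.fe_params
            se = res.bse_fe
        if not np.all(np.isfinite(se)) or np.any(se <= 0):
            raise FitError("non-finite standard errors")
        re_var = float(np.asarray(res.cov_re)[0, 0])
        resid_var = float(res.scale)
        df_method = "normal"
        dist = stats.norm
        converged = bool(res.converged)
    except (FitError, np.linalg.LinAlgError, ValueError, ZeroDivisionError):
        # zero-variance / singular frames: plain least squares
        ols = sm.OLS(y, X).fit()
        fe = ols.params
        se = ols.bse
        re_var = 0.0
        resid_var = float(ols.scale)
        dof = max(int(ols.df_resid), 1)
        df_method = f"residual t ({dof} df, OLS fallback)"
        dist = stats.t(dof)
        converged = True
    tval = fe / se.replace(0.0, np.nan) if isinstance(se, pd.Series) else fe / se
    pval = 2.0 * dist.sf(np.abs(tval.fillna(np.inf)))
    crit = dist.ppf(0.975)
    table = pd.DataFrame({
        "estimate": fe,
        "se": se,
        "tvalue": tval,
        "pvalue": pval,
        "ci_low": fe - crit * se,
        "ci_high": fe + crit * se,
    })
    return LmmResult(
        table=table,
        re_var=re_var,
        resid_var=resid_var,
        n_obs=len(frame),
        n_groups=int(frame["journal"].nunique()),
        method={"df_method": df_method, "reml": True, "converged": converged,
                "terms": list(terms)},
    )


# -- interaction screening --------------------------------------------------


def _factors(term: str) -> frozenset:
    return frozenset(term.split(":"))


def prune_collinear_terms(
    frame: pd.DataFrame, terms: Sequence[str], base: Sequence[str] = ()
) -> tuple[list[str], list[str]]:
    """Drop terms whose columns add no rank to the design (given ``base``).

    Small or stratified frames can make a covariate constant (e.g. no
    Open Access journal in a stratum); such terms are unestimable and
    are removed before fitting.
    """
    X = _design(frame, list(base)).values
    kept, dropped = [], []
    for t in terms:
        Xc = np.column_stack([X, _design(frame, [t])[t].values])
        if np.linalg.matrix_rank(Xc) > np.linalg.matrix_rank(X):
            kept.append(t)
            X = Xc
        else:
            dropped.append(t)
    return kept, dropped


def screen_interactions(
    frame: pd.DataFrame,
    main_terms: Sequence[str],
    candidates: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> tuple[list[str], list[dict]]:
    """Hierarchical backward screen of interaction terms.

    The three-way subject x OA x log-JIF term (when applicable) is
    assessed first; a two-way term becomes testable only once no
    retained higher-order term contains it.  Terms with p > alpha are
    removed one at a time (largest p first); main effects are always
    retained.  Returns the final term list and a log of every
    intermediate fit.
    """
    if candidates is None:
        if "oncology" in main_terms:
            candidates = ["oncology:oa", "oncology:log_jif", "oa:log_jif",
                          "oncology:oa:log_jif"]
        else:
            candidates = ["oa:log_jif"]
    main_terms, dropped_main = prune_collinear_terms(frame, main_terms)
    current, dropped_cand = prune_collinear_terms(frame, candidates, base=main_terms)
    log: list[dict] = []
    if dropped_main or dropped_cand:
        logger.warning("screen_interactions: unestimable terms dropped: %s",
                       dropped_main + dropped_cand)
        log.append({"step": "prune", "terms": list(main_terms) + current,
                    "testable_pvalues": {}, "removed": dropped_main + dropped_cand})
    step = 0
    while True:
        terms = list(main_terms) + current
        fit = fit_lmm(frame, terms)
        testable = [
            t for t in current
            if not any(_factors(t) < _factors(u) for u in current)
        ]
        pvals = {t: float(fit.table.loc[t, "pvalue"]) for t in testable}
        worst = max(pvals, key=pvals.get) if pvals else None
        remove = worst if worst is not None and pvals[worst] > alpha else None
        log.append({
            "step": step, "terms": terms, "testable_pvalues": pvals,
            "removed": remove,
        })
        if remove is None:
            return terms, log
        current.remove(remove)
        step += 1


# -- derived effects --------------------------------------------------------


def twofold_jif_effect(beta_logjif: float) -> float:
    """Change in FDR when impact factor halves: -beta * ln 2.

    Positive when the log-JIF slope is negative (lower-impact journals
    have higher FDR).
    """
    return -beta_logjif * float(np.log(2.0))


def adjusted_means(
    result: LmmResult, frame: pd.DataFrame, group_term: str
) -> dict[int, float]:
    """Model-predicted mean FDR per level of a 0/1 group term.

    Other fixed covariates are held at their sample means and the random
    intercept at zero, so the difference between the two levels equals
    the group coefficient exactly.
    """
    terms = [t for t in result.table.index if t != "Intercept"]
    if group_term not in terms:
        raise ValueError(f"group term {group_term!r} not in the fitted model")
    if any(group_term in _factors(t) for t in terms if t != group_term):
        raise ValueError(f"{group_term!r} appears in interaction terms; adjusted "
                         "means at covariate means are not defined")
    beta = result.table["estimate"]
    out = {}
    for level in (0, 1):
        pred = float(beta["Intercept"])
        for t in terms:
            if t == group_term:
                pred += float(beta[t]) * level
            else:
                v = None
                for f in t.split(":"):
                    col = frame[f].astype(float)
                    v = col if v is None else v * col
                pred += float(beta[t]) * float(v.mean())
        out[level] = pred
    return out


def percent_excess(mean_high: float, mean_low: float) -> float:
    """Relative excess of one adjusted mean over another, in percent."""
    if mean_low == 0:
        raise ValueError("reference mean must be non-zero")
    return 100.0 * (mean_high - mean_low) / mean_low


def bootstrap_bands(
    frame: pd.DataFrame,
    terms: Sequence[str],
    grid: Sequence[float],
    B: int = 200,
    seed: int = 0,
    jif_term: str = "log_jif",
    at: Optional[dict[str, float]] = None,
) -> pd.DataFrame:
    """Cluster-bootstrap 95% bands for predicted FDR over a log-JIF grid.

    Journals (whole clusters) are resampled with replacement B times and
    the model refit; predictions hold the other covariates at their
    sample means (or the values in ``at``).  Failed refits are logged
    and skipped.  Returns columns log_jif, point, lower, upper.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    fixed = {
        t: float(_design(frame, [t])[t].mean())
        for t in terms if jif_term not in _factors(t)
    }
    if at:
        fixed.update(at)

    def predict(res: LmmResult) -> np.ndarray:
        beta = res.table["estimate"]
        pred = np.full(grid.shape, float(beta["Intercept"]))
        for t in terms:
            if jif_term in _factors(t):
                contrib = np.ones_like(grid) * float(beta[t])
                for f in t.split(":"):
                    contrib = contrib * (grid if f == jif_term else fixed.get(f, fixed[f]))
                pred = pred + contrib
            else:
                pred = pred + float(beta[t]) * fixed[t]
        return pred

    base = fit_lmm(frame, terms)
    journals = np.sort(frame["journal"].unique())
    preds = []
    n_failed = 0
    for _ in range(B):
        ids = rng.choice(journals, size=journals.size, replace=True)
        parts = [
            frame[frame["journal"] == j].assign(journal=f"{j}~{k}")
            for k, j in enumerate(ids)
        ]
        bframe = pd.concat(parts, ignore_index=True)
        try:
            preds.append(predict(fit_lmm(bframe, terms)))
        except (FitError, np.linalg.LinAlgError, ValueError):
            n_failed += 1
    if n_failed:
        logger.info("bootstrap_bands: %d/%d refits failed and were skipped", n_failed, B)
    if len(preds) < 2:
        raise FitError("too few successful bootstrap refits for bands")
    arr = np.vstack(preds)
    lo, hi = np.percentile(arr, [2.5, 97.5], axis=0)
    return pd.DataFrame({
        "log_jif": grid, "point": predict(base), "lower": lo, "upper": hi,
    })


def subject_access_table(meta: pd.DataFrame) -> pd.DataFrame:
    """Journal counts by subject area and (window-stable) access status,
    with row/column margins — the descriptive journal-types table."""
    per_journal = meta.sort_values("year").groupby("journal").agg(
        subject=("subject", "first"), oa=("oa", "max")
    )
    tab = pd.crosstab(
        per_journal["oa"].map({1: "open_access", 0: "closed_access"}),
        per_journal["subject"],
        margins=True, margins_name="total",
    )
    return tab
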