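"""Synthetic abstract corpora and journal panels with known ground truth.

The generator emulates the study conditions end to end: per-journal-year
sets of significant p values drawn from the pi0*U(0, alpha) +
(1 - pi0)*tBeta(a, b) mixture; a reporting process that renders each
value as an exact, rounded, or truncated string inside abstract-like
text; and a journal panel in which the true pi0 depends linearly on
centred year, Open Access status, log impact factor and subject area,
with a journal-level random intercept.  Everything returns the ground
truth needed for recovery tests (component labels, true pi0 per cell,
true coefficients).
"""

from __future__ import annotations

import io
import logging
import textwrap
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .estimator import MixtureParams
from .records import ReportedPValue

logger = logging.getLogger(__name__)

#: Conventional thresholds for truncated reporting ("p < t"), ascending.
STANDARD_THRESHOLDS: tuple[float, ...] = (0.0001, 0.001, 0.01, 0.05)


@dataclass
class ReportingPolicy:
    """How an exact p value becomes a published report.

    With probability ``p_exact`` the value is reported to 3-4 decimal
    places (scientific notation below 5e-4); with ``p_round`` it is
    rounded to 1-2 decimals; with ``p_truncate`` it is reported as
    "< t" at the smallest standard threshold above it.
    """

    p_exact: float = 0.3
    p_round: float = 0.4
    p_truncate: float = 0.3
    thresholds: tuple[float, ...] = STANDARD_THRESHOLDS

    def __post_init__(self) -> None:
        probs = (self.p_exact, self.p_round, self.p_truncate)
        if any(p < 0 for p in probs):
            raise ValueError("reporting probabilities must be non-negative")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("reporting probabilities must sum to 1")


EXACT_ONLY = ReportingPolicy(1.0, 0.0, 0.0)


@dataclass
class PanelConfig:
    """Journal panel with a linear true-pi0 model and random intercepts.

    Defaults mirror a two-subject medical-journal panel over 2011-2015:
    57 oncology and 37 general-medicine journals, about a quarter Open
    Access, right-skewed impact factors, and fixed effects at the scale
    reported for such panels (oncology +0.071, log JIF -0.029 per unit).
    """

    n_oncology: int = 57
    n_medicine: int = 37
    years: tuple[int, int] = (2011, 2015)
    intercept: float = 0.23
    beta_year: float = -0.002
    beta_oa: float = 0.015
    beta_logjif: float = -0.029
    beta_oncology: float = 0.071
    random_intercept_sd: float = 0.06
    residual_sd: float = 0.04
    jif_meanlog: float = 1.0
    jif_sdlog: float = 0.7
    oa_prevalence: float = 0.24
    oa_switch_prob: float = 0.0
    pvalues_per_journal_year: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_oncology < 0 or self.n_medicine < 0:
            raise ValueError("journal counts must be non-negative")
        if self.years[1] < self.years[0]:
            raise ValueError("year range must be non-decreasing")
        for name in ("random_intercept_sd", "residual_sd", "jif_sdlog"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.oa_prevalence <= 1.0:
            raise ValueError("oa_prevalence must be a probability")


def sample_mixture_pvalues(
    params: MixtureParams,
    n: int,
    alpha: float = 0.05,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n significant p values from the uniform + truncated-Beta mixture.

    Returns ``(values, is_null)`` where ``is_null`` marks draws from the
    uniform (false discovery) component — the ground-truth labels.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    rng = np.random.default_rng(seed) if rng is None else rng
    is_null = rng.random(n) < params.pi0
    values = np.empty(n)
    k = int(is_null.sum())
    values[is_null] = rng.uniform(0.0, alpha, k)
    m = n - k
    if m:
        fa = special.betainc(params.a, params.b, alpha)
        if fa <= 1e-300:
            raise ValueError("Beta component has no numeric mass below alpha")
        u = rng.uniform(0.0, fa, m)
        values[~is_null] = stats.beta.ppf(u, params.a, params.b)
    tiny = np.finfo(float).tiny
    np.clip(values, tiny, np.nextafter(alpha, 0.0), out=values)
    return values, is_null


def _smallest_threshold_above(p: float, ladder: Sequence[float]) -> Optional[float]:
    for t in sorted(ladder):
        if t > p:
            return t
    return None


def apply_reporting(
    p: float,
    policy: ReportingPolicy,
    rng: np.random.Generator,
    forced: Optional[str] = None,
    round_decimals: Optional[int] = None,
) -> ReportedPValue:
    """Turn an exact p value into a reported one under the policy.

    ``forced`` pins the report kind ("exact"/"round"/"truncate") and
    ``round_decimals`` the rounding precision, for tests.  Rounding that
    would print 0 (or >= 1) falls back to truncation so every emitted
    report parses back to a value in (0, 1).
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    kind = forced or rng.choice(
        ["exact", "round", "truncate"],
        p=[policy.p_exact, policy.p_round, policy.p_truncate],
    )
    if kind == "round":
        d = round_decimals if round_decimals is not None else (2 if rng.random() < 0.9 else 1)
        v = round(p, d)
        if 0.0 < v < 1.0:
            return ReportedPValue(value=v, comparator="=", decimals=d)
        kind = "truncate"  # e.g. p < 0.005 rounds to 0.00
    if kind == "truncate":
        t = _smallest_threshold_above(p, policy.thresholds)
        if t is None:  # above the ladder; report to 2 decimals instead
            v = round(p, 2)
            if 0.0 < v < 1.0:
                return ReportedPValue(value=v, comparator="=", decimals=2)
            raise ValueError(f"cannot report p={p} under this policy")
        comp = "<" if rng.random() < 0.8 else "≤"
        return ReportedPValue(value=t, comparator=comp, decimals=None)
    # exact
    if p >= 5e-4:
        d = int(rng.integers(3, 5))  # 3 or 4 decimals
        v = round(p, d)
        if v > 0.0:
            return ReportedPValue(value=v, comparator="=", decimals=d)
    v = float(f"{p:.2e}")  # scientific notation, 3 significant digits
    return ReportedPValue(value=v, comparator="=", decimals=None)


# -- rendering --------------------------------------------------------------

_TEMPLATES = (
    "The primary endpoint differed significantly between arms ({span}).",
    "Treatment was associated with improved response ({span}).",
    "We observed a significant association {span}.",
    "Risk was lower in the intervention group ({span}) after adjustment.",
    "The difference remained significant in sensitivity analyses, {span}.",
)

_FILLER = (
    "A total of 248 patients were enrolled across 12 centres.",
    "Baseline characteristics were balanced between groups.",
    "Median follow-up was 3.2 years.",
    "Secondary outcomes showed consistent trends.",
)


def _format_sci(value: float, rng: np.random.Generator) -> str:
    mant_s, exp_s = f"{value:.2e}".split("e")
    mant = mant_s.rstrip("0").rstrip(".")
    exp = int(exp_s)
    style = rng.integers(0, 4)
    if style == 0:
        return f"{mant} × 10−{-exp}"  # 1.2 × 10−4, unicode signs
    if style == 1:
        return f"{mant}E-{-exp}"
    if style == 2:
        return f"{mant} x 10^-{-exp}"
    return f"{mant}e-{-exp:02d}"


def _format_span(rec: ReportedPValue, rng: np.random.Generator) -> str:
    if rec.decimals is None and rec.comparator == "=":
        val = _format_sci(rec.value, rng)
    elif rec.decimals is None:  # truncation threshold
        s = f"{rec.value:.10f}".rstrip("0")
        val = s if rng.random() < 0.8 else _format_sci(rec.value, rng)
    else:
        val = f"{rec.value:.{rec.decimals}f}"
        if rng.random() < 0.15:
            val = val[1:]  # no leading zero: ".01"
    p_tok = rng.choice(["p", "P", "p-value", "P value"], p=[0.45, 0.35, 0.1, 0.1])
    comp = rec.comparator
    if comp == "≤" and rng.random() < 0.5:
        comp = "≤"  # already the unicode char; kept for clarity
    spaces = rng.choice(["", " "], size=2)
    return f"{p_tok}{spaces[0]}{comp}{spaces[1]}{val}"


def render_abstract(
    records: Sequence[ReportedPValue],
    journal: str,
    year: int,
    rng: np.random.Generator,
) -> str:
    """Abstract-like text embedding each report in a scraper-target phrase."""
    if not records:
        raise ValueError("records must be non-empty")
    sentences = [str(rng.choice(_FILLER))]
    for rec in records:
        tpl = str(rng.choice(_TEMPLATES))
        sentences.append(tpl.format(span=_format_span(rec, rng)))
    if rng.random() < 0.5:
        sentences.append(str(rng.choice(_FILLER)))
    return " ".join(sentences)


# -- journal panel ----------------------------------------------------------


def generate_journal_panel(config: PanelConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Journal metadata, per-journal-year true pi0, and the true coefficients.

    True pi0 for journal j in year t is
    ``intercept + beta_year*(t - t0) + beta_oa*OA_jt + beta_logjif*ln(JIF_j)
    + beta_onc*ONC_j + b_j + eps_jt`` clamped to [0.01, 0.99]; the clamp
    rate is reported (and logged) so configs that clip heavily are visible.
    """
    rng = np.random.default_rng(config.seed)
    y0, y1 = config.years
    years = np.arange(y0, y1 + 1)
    journals, subjects = [], []
    for i in range(config.n_oncology):
        journals.append(f"ONC{i + 1:03d}")
        subjects.append("oncology")
    for i in range(config.n_medicine):
        journals.append(f"MED{i + 1:03d}")
        subjects.append("medicine")
    nj = len(journals)
    jif = np.exp(rng.normal(config.jif_meanlog, config.jif_sdlog, nj))
    oa_base = rng.random(nj) < config.oa_prevalence
    switch = rng.random(nj) < config.oa_switch_prob
    switch_year = rng.integers(y0 + 1, y1 + 1, nj)  # "Open Access since <year>"
    b_j = rng.normal(0.0, config.random_intercept_sd, nj)

    meta_rows, truth_rows = [], []
    n_clamped = 0
    for j in range(nj):
        onc = 1 if subjects[j] == "oncology" else 0
        for year in years:
            if switch[j]:
                oa = 1 if year >= switch_year[j] else 0
            else:
                oa = int(oa_base[j])
            eps = rng.normal(0.0, config.residual_sd)
            lin = (
                config.intercept
                + config.beta_year * (year - y0)
                + config.beta_oa * oa
                + config.beta_logjif * np.log(jif[j])
                + config.beta_oncology * onc
                + b_j[j]
                + eps
            )
            pi0 = float(np.clip(lin, 0.01, 0.99))
            clamped = pi0 != lin
            n_clamped += clamped
            meta_rows.append({
                "journal": journals[j], "year": int(year), "subject": subjects[j],
                "oncology": onc, "oa": oa, "jif": float(jif[j]),
            })
            truth_rows.append({
                "journal": journals[j], "year": int(year),
                "true_pi0": pi0, "clamped": bool(clamped),
            })
    meta = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(truth_rows)
    clamp_rate = n_clamped / max(len(truth), 1)
    if clamp_rate > 0:
        logger.warning("generate_journal_panel: %.1f%% of true pi0 values clamped",
                       100 * clamp_rate)
    coefs = {
        "intercept": config.intercept,
        "beta_year": config.beta_year,
        "beta_oa": config.beta_oa,
        "beta_logjif": config.beta_logjif,
        "beta_oncology": config.beta_oncology,
        "random_intercept_sd": config.random_intercept_sd,
        "residual_sd": config.residual_sd,
        "clamp_rate": clamp_rate,
    }
    return meta, truth, coefs


# -- corpus -----------------------------------------------------------------


def _write_medline_entry(fh, pmid: str, journal: str, year: int, text: str) -> None:
    fh.write(f"PMID- {pmid}\n")
    fh.write(f"TI  - Synthetic abstract {pmid}.\n")
    fh.write(f"TA  - {journal}\n")
    fh.write(f"DP  - {year} Jan\n")
    lines = textwrap.wrap(text, width=80) or [""]
    fh.write(f"AB  - {lines[0]}\n")
    for line in lines[1:]:
        fh.write(f"      {line}\n")
    fh.write("\n")


def generate_corpus(
    meta: pd.DataFrame,
    truth: pd.DataFrame,
    path: str,
    policy: Optional[ReportingPolicy] = None,
    mixture_shapes: tuple[float, float] = (0.7, 30.0),
    alpha: float = 0.05,
    pvalues_per_cell: int = 150,
    abstract_size: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Write a MEDLINE flat file of synthetic abstracts; return ground truth.

    Each journal-year's embedded significant p values are drawn from the
    mixture at that cell's true pi0 (from ``truth``) with the given Beta
    shapes, then passed through the reporting policy and rendered into
    abstracts of about ``abstract_size`` reports each.  A master seed
    derives one independent substream per journal-year, so regenerating
    any subset reproduces the same draws.
    """
    policy = policy or ReportingPolicy()
    cells = truth.merge(
        meta[["journal", "year"]].drop_duplicates(), on=["journal", "year"]
    ).sort_values(["journal", "year"]).reset_index(drop=True)
    gt_rows = []
    pmid = 10_000_000
    with open(path, "w", encoding="utf-8") as fh:
        for idx, cell in enumerate(cells.itertuples(index=False)):
            rng = np.random.default_rng([seed, idx])
            pi0 = min(max(float(cell.true_pi0), 1e-6), 1 - 1e-6)
            params = MixtureParams(pi0, *mixture_shapes)
            values, is_null = sample_mixture_pvalues(
                params, pvalues_per_cell, alpha=alpha, rng=rng
            )
            reports = [apply_reporting(float(p), policy, rng) for p in values]
            for start in range(0, len(reports), abstract_size):
                chunk = reports[start:start + abstract_size]
                pmid += 1
                text = render_abstract(chunk, cell.journal, int(cell.year), rng)
                _write_medline_entry(fh, str(pmid), cell.journal, int(cell.year), text)
                for k, rec in enumerate(chunk):
                    i = start + k
                    gt_rows.append({
                        "pmid": str(pmid), "journal": cell.journal,
                        "year": int(cell.year), "true_p": float(values[i]),
                        "is_null": bool(is_null[i]),
                        "reported_value": rec.value,
                        "comparator": rec.comparator,
                        "decimals": rec.decimals if rec.decimals is not None else np.nan,
                        "cls": rec.cls,
                    })
    return pd.DataFrame(gt_rows)
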