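"""Extract, normalise and classify p values reported in abstract text.

The scraper targets the non-case-sensitive phrases "p = ", "p < " and
"p ≤ " (with optional "value", flexible spacing and common notation
variants), cleans the trailing string, and parses it to a numeric
report.  Text is standardised first — unicode comparators, minus and
multiplication signs, spacing, and scientific-notation variants are
mapped to canonical ASCII forms — which removes most misread-character
failures.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable, Optional

import pandas as pd
from Bio import Medline

from .records import AbstractRecord, ReportedPValue, classify

logger = logging.getLogger(__name__)


def read_medline(path: str) -> list[AbstractRecord]:
    """Parse a MEDLINE flat file into abstract records.

    Journal comes from TA, year from the first four characters of DP,
    text from AB.  Entries without an abstract are skipped and counted
    in a log message.
    """
    records: list[AbstractRecord] = []
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for entry in Medline.parse(fh):
            pmid = entry.get("PMID", "")
            ab = entry.get("AB")
            if not ab:
                skipped += 1
                continue
            ta = entry.get("TA", "")
            dp = entry.get("DP", "")
            try:
                year = int(str(dp)[:4])
            except ValueError as exc:
                raise ValueError(f"malformed DP field in entry PMID={pmid!r}: {dp!r}") from exc
            records.append(AbstractRecord(abstract_id=pmid, journal=ta, year=year, text=ab))
    logger.info("read_medline: %d abstracts read, %d entries skipped (no AB)",
                len(records), skipped)
    return records


# -- normalisation ----------------------------------------------------------

_UNICODE_MAP = {
    "≤": "<=",   # ≤
    "⩽": "<=",   # ⩽
    "≦": "<=",   # ≦
    "＜": "<",    # fullwidth <
    "＝": "=",    # fullwidth =
    "−": "-",    # unicode minus
    "–": "-",    # en dash
    "—": "-",    # em dash
    "·": ".",    # middle dot decimal
    "⋅": ".",
    "×": "x",    # multiplication sign
    "✕": "x",
    " ": " ",
    " ": " ",
    " ": " ",
    " ": " ",
}

_P_PREFIX = r"(?:p|P)(?:[\s-]*[Vv]alue)?"

_RE_MANTISSA_SCI = re.compile(r"(\d+(?:\.\d+)?)\s*x\s*10\s*(?:\^|\*\*)?\s*-\s*(\d+)")
_RE_E_NOTATION = re.compile(r"(\d+(?:\.\d+)?)\s*[eE]\s*-\s*0*(\d+)")
_RE_BARE_POWER = re.compile(rf"({_P_PREFIX}\s*(?:<=|<|=)\s*)10\s*(?:\^|\*\*)?\s*-\s*(\d+)")
_RE_COMMA_DECIMAL = re.compile(rf"({_P_PREFIX}\s*(?:<=|<|=)\s*\d*),(\d+)")


def normalize_text(text: str) -> str:
    """Canonicalise comparators, signs, spacing and scientific notation.

    Idempotent: applying it twice gives the same string.
    """
    for src, dst in _UNICODE_MAP.items():
        text = text.replace(src, dst)
    text = re.sub(r"\s+", " ", text).strip()
    text = _RE_MANTISSA_SCI.sub(lambda m: f"{m.group(1)}e-{int(m.group(2))}", text)
    text = _RE_E_NOTATION.sub(lambda m: f"{m.group(1)}e-{int(m.group(2))}", text)
    text = _RE_BARE_POWER.sub(lambda m: f"{m.group(1)}1e-{int(m.group(2))}", text)
    text = _RE_COMMA_DECIMAL.sub(lambda m: f"{m.group(1)}.{m.group(2)}", text)
    return text


# -- extraction -------------------------------------------------------------

_RE_PVALUE = re.compile(
    rf"(?<![A-Za-z0-9]){_P_PREFIX}\s*(<=|<|=)\s*"
    r"((?:\d+(?:\.\d+)?e-\d+)|(?:\d*\.\d+)|(?:\d+))"
)

_COMPARATOR_CANON = {"<=": "≤", "<": "<", "=": "="}


def _parse_candidate(token: str) -> tuple[Optional[float], Optional[int]]:
    """(value, decimal places) from a cleaned candidate; decimals None for
    scientific notation."""
    token = token.strip().rstrip(".,;:)")
    if "e-" in token:
        try:
            return float(token), None
        except ValueError:
            return None, None
    try:
        value = float(token)
    except ValueError:
        return None, None
    decimals = len(token.split(".", 1)[1]) if "." in token else 0
    return value, decimals


def extract_pvalues(record: AbstractRecord) -> list[ReportedPValue]:
    """All p-value reports in one abstract (text is normalised first).

    Unparseable candidates and values outside (0, 1) are dropped with a
    logged reason; duplicates within an abstract are all retained.
    """
    text = normalize_text(record.text)
    out: list[ReportedPValue] = []
    for m in _RE_PVALUE.finditer(text):
        comp = _COMPARATOR_CANON[m.group(1)]
        value, decimals = _parse_candidate(m.group(2))
        if value is None:
            logger.debug("drop span %r: unparseable", m.group(0))
            continue
        if not 0.0 < value < 1.0:
            logger.debug("drop span %r: value %s outside (0, 1)", m.group(0), value)
            continue
        out.append(
            ReportedPValue(
                value=value,
                comparator=comp,
                decimals=decimals,
                cls=classify(comp, decimals),
                span=m.group(0),
                abstract_id=record.abstract_id,
                journal=record.journal,
                year=record.year,
            )
        )
    return out


def filter_significant(
    records: Iterable[ReportedPValue], alpha: float = 0.05
) -> list[ReportedPValue]:
    """Keep reports counting as positive results at threshold alpha.

    A report is kept when its value is below alpha; a report exactly at
    alpha is kept when it is truncated ("< alpha" / "≤ alpha") or when
    its rounding interval intersects (0, alpha).  Exact reports at or
    above alpha are dropped.
    """
    kept: list[ReportedPValue] = []
    dropped = 0
    for r in records:
        if r.value < alpha:
            kept.append(r)
        elif r.value == alpha:
            if r.comparator in ("<", "≤"):
                kept.append(r)
            elif r.cls == "rounded" and r.value - 0.5 * 10.0 ** (-r.decimals) < alpha:
                kept.append(r)
            else:
                dropped += 1
        else:
            dropped += 1
    if dropped:
        logger.info("filter_significant: dropped %d reports at alpha=%s", dropped, alpha)
    return kept


def scrape_file(path: str) -> pd.DataFrame:
    """MEDLINE file -> tidy table of every extracted p-value report."""
    rows = []
    for rec in read_medline(path):
        for pv in extract_pvalues(rec):
            rows.append({
                "abstract_id": pv.abstract_id, "journal": pv.journal,
                "year": pv.year, "value": pv.value, "comparator": pv.comparator,
                "decimals": pv.decimals, "cls": pv.cls, "span": pv.span,
            })
    return pd.DataFrame(
        rows,
        columns=["abstract_id", "journal", "year", "value",
                 "comparator", "decimals", "cls", "span"],
    )
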