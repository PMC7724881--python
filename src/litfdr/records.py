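"""Shared record types for abstracts and reported p values.

A *reported* p value is what appears in an abstract: a numeric value, a
comparator ("=", "<" or "≤"), and for decimal notation the number of
decimal places shown.  The report class follows from those two pieces
alone:

* ``truncated`` — comparator is "<" or "≤" (e.g. ``p < 0.05``);
* ``rounded``   — comparator is "=" and at most two decimal places are
  shown (e.g. ``p = 0.01``);
* ``exact``     — everything else, including scientific notation.

Downstream likelihoods treat rounded and truncated reports as interval
observations and exact reports as point observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: Conventional reporting ladder for truncated p values, ascending.
TRUNCATION_LADDER: tuple[float, ...] = (0.0001, 0.001, 0.01, 0.05)

COMPARATORS = ("=", "<", "≤")

CLASS_EXACT = "exact"
CLASS_ROUNDED = "rounded"
CLASS_TRUNCATED = "truncated"


def classify(comparator: str, decimals: Optional[int]) -> str:
    """Report class as a pure function of (comparator, decimal places).

    ``decimals`` is ``None`` for scientific notation, which is always
    classed as exact: a mantissa is not a rounding of the probability
    scale to two decimals.
    """
    if comparator in ("<", "≤"):
        return CLASS_TRUNCATED
    if comparator == "=" and decimals is not None and decimals <= 2:
        return CLASS_ROUNDED
    return CLASS_EXACT


@dataclass
class ReportedPValue:
    """One p-value report scraped from (or embedded into) an abstract."""

    value: float
    comparator: str
    decimals: Optional[int] = None
    cls: str = ""
    span: str = ""
    abstract_id: str = ""
    journal: str = ""
    year: int = 0

    def __post_init__(self) -> None:
        if self.comparator not in COMPARATORS:
            raise ValueError(f"unknown comparator {self.comparator!r}")
        if not 0.0 < self.value < 1.0:
            raise ValueError(f"reported p value {self.value} outside (0, 1)")
        if not self.cls:
            self.cls = classify(self.comparator, self.decimals)


@dataclass
class AbstractRecord:
    """One abstract with its provenance (journal and publication year)."""

    abstract_id: str
    journal: str
    year: int
    text: str

    def __post_init__(self) -> None:
        if self.text is None:
            raise ValueError("abstract text must not be None")
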