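"""Rule-based classification of first-cleavage patterns.

The taxonomy follows standard time-lapse morphokinetics for in-vitro
embryos. The first division of the zygote decides the top-level class:

* **normal** — division into two equal-sized blastomeres;
* **abnormal** — *direct* (one cell dividing straight into three or more
  blastomeres), *unequal* (two markedly different-sized blastomeres) or
  *reverse* (blastomere number dropping from two back to one through the
  first division). An embryo may show more than one abnormal pattern
  within the first-division window (e.g. unequal followed by reverse).

Normally cleaved embryos are subtyped by their subsequent divisions:
**synchronous** embryos pass only through the 4-, 8- and 16-cell states;
**asynchronous** embryos pass through at least one intermediate count
(3, 5, 6, 7, 10 or 12 blastomeres). Asynchronous embryos are further
binned by their number of asynchronous events into classes 1, 2, 3, 4 or
5–6 (five and six events are merged — both are rare).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from morphokin.events import Cohort, EmbryoRecord, Symmetry

#: Cell counts reached by purely synchronous rounds of division.
SYNCHRONOUS_COUNTS = frozenset({4, 8, 16})

#: Intermediate cell counts that mark one asynchronous cleavage event.
ASYNCHRONOUS_COUNTS = frozenset({3, 5, 6, 7, 10, 12})

#: Default size-ratio threshold for the optional ratio-based symmetry
#: helper (larger/smaller blastomere diameter). An extension, not a rule
#: from any annotation guideline: the primary input is the annotated flag.
UNEQUAL_RATIO_THRESHOLD = 1.33


@dataclass(frozen=True)
class PatternCall:
    """The classifier's verdict for one embryo.

    ``top`` partitions embryos into normal / abnormal / unclassified.
    ``abnormal_subtypes`` preserves observation order within the
    first-division window. ``async_class`` is ``"1"``–``"4"``, ``"5_6"``
    or ``"none"``. ``later_direct`` / ``later_reverse`` flag suspicious
    events after the first-division window; they do not change ``top``.
    ``unclassified_events`` lists post-first-division cell counts outside
    the recognized synchronous and asynchronous sets (excluded from the
    asynchrony tally).
    """

    top: str = "unclassified"
    normal_subtype: str = "none"
    abnormal_subtypes: tuple[str, ...] = ()
    multiple_abnormal: bool = False
    n_async_events: int = 0
    async_class: str = "none"
    later_direct: bool = False
    later_reverse: bool = False
    unclassified_events: tuple[int, ...] = ()
    diagnostic: str | None = None

    def __post_init__(self) -> None:
        assert self.top in ("normal", "abnormal", "unclassified")
        if self.top == "normal":
            assert not self.abnormal_subtypes and self.normal_subtype != "none"
        if self.top == "abnormal":
            assert self.abnormal_subtypes
        assert self.multiple_abnormal == (len(self.abnormal_subtypes) > 1)
        if self.normal_subtype == "synchronous":
            assert self.n_async_events == 0

    @property
    def category(self) -> str:
        """Single reporting label used in cohort-composition tallies."""
        if self.top == "unclassified":
            return "unclassified"
        if self.top == "normal":
            return self.normal_subtype
        if self.multiple_abnormal:
            return "multiple_abnormal"
        return self.abnormal_subtypes[0]


def size_ratio_symmetry(larger: float, smaller: float,
                        threshold: float = UNEQUAL_RATIO_THRESHOLD) -> Symmetry:
    """Map a blastomere diameter ratio to a symmetry flag.

    Helper for annotation pipelines that measure sizes rather than flag
    symmetry directly; ratio > ``threshold`` is called unequal.
    """
    if larger <= 0 or smaller <= 0:
        raise ValueError("blastomere sizes must be positive")
    if larger < smaller:
        larger, smaller = smaller, larger
    return Symmetry.UNEQUAL if larger / smaller > threshold else Symmetry.EQUAL


def _first_division_scan(counts: Sequence[int], syms: Sequence[Symmetry]) -> tuple[tuple[str, ...], int]:
    """Abnormal subtypes within the first-division window.

    Returns the ordered subtypes and the index of the first event after
    the window (the first event with count > 2, i.e. a later division).
    """
    subtypes: list[str] = []
    c1, s1 = counts[0], syms[0]
    if c1 >= 3:
        subtypes.append("direct")
        if s1 is Symmetry.UNEQUAL:
            subtypes.append("unequal")
        return tuple(subtypes), 1
    # c1 == 2: the window covers consequent events at counts <= 2 before a
    # second division takes the embryo beyond 2 cells.
    if s1 is Symmetry.UNEQUAL:
        subtypes.append("unequal")
    i = 1
    while i < len(counts) and counts[i] <= 2:
        if counts[i] == 1 and "reverse" not in subtypes:
            subtypes.append("reverse")
        elif counts[i] == 2 and syms[i] is Symmetry.UNEQUAL and "unequal" not in subtypes:
            subtypes.append("unequal")
        i += 1
    return tuple(subtypes), i


def classify_trajectory(counts: Sequence[int],
                        symmetries: Sequence[Symmetry] | None = None) -> PatternCall:
    """Classify an ordered cell-count trajectory (counts after each event).

    The trajectory starts from an implicit 1-cell zygote. ``symmetries``
    defaults to equal for 2-cell events and not-applicable otherwise.
    """
    counts = list(counts)
    if symmetries is None:
        syms = [Symmetry.EQUAL if c == 2 else Symmetry.NOT_APPLICABLE for c in counts]
    else:
        syms = list(symmetries)
        if len(syms) != len(counts):
            raise ValueError("symmetries must match counts in length")
    if not counts:
        return PatternCall(diagnostic="no cleavage event")

    subtypes, after = _first_division_scan(counts, syms)
    later = counts[after:]
    later_reverse = any(b < a for a, b in zip([counts[after - 1]] + later, later))
    later_direct = any(b > 2 * a for a, b in zip([counts[after - 1]] + later, later))

    if subtypes:
        return PatternCall(
            top="abnormal",
            abnormal_subtypes=subtypes,
            multiple_abnormal=len(subtypes) > 1,
            later_direct=later_direct,
            later_reverse=later_reverse,
        )

    # normal first cleavage: subtype from post-first-division counts
    n_async = sum(1 for c in later if c in ASYNCHRONOUS_COUNTS)
    odd = tuple(c for c in later if c not in ASYNCHRONOUS_COUNTS and c not in SYNCHRONOUS_COUNTS)
    synchronous = all(c in SYNCHRONOUS_COUNTS for c in later)
    subtype = "synchronous" if synchronous else "asynchronous"
    return PatternCall(
        top="normal",
        normal_subtype=subtype,
        n_async_events=n_async,
        async_class=_async_class(n_async) if subtype == "asynchronous" else "none",
        later_direct=later_direct,
        later_reverse=later_reverse,
        unclassified_events=odd,
    )


def _async_class(n: int) -> str:
    if n <= 0:
        return "none"
    if n <= 4:
        return str(n)
    return "5_6"


def _cleavage_arrays(record: EmbryoRecord) -> tuple[list[int], list[Symmetry]]:
    evs = record.cleavage_events
    return [e.cell_count for e in evs], [e.symmetry for e in evs]


def classify_record(record: EmbryoRecord) -> PatternCall:
    """Full pattern call for one (complete) embryo record."""
    counts, syms = _cleavage_arrays(record)
    return classify_trajectory(counts, syms)


def classify_first_cleavage(record: EmbryoRecord) -> PatternCall:
    """Top-level class and abnormal subtypes (first-division window).

    Assigns exactly one of normal/abnormal (or unclassified with a
    diagnostic when no cleavage event exists); abnormal subtypes are
    recorded in observation order. The asynchrony fields of the returned
    call are already populated as a convenience — the contract only
    guarantees ``top`` and ``abnormal_subtypes`` here, with
    :func:`classify_normal_subtype` as the dedicated accessor.
    """
    return classify_record(record)


def classify_normal_subtype(record: EmbryoRecord) -> PatternCall:
    """Synchronous/asynchronous subtype for a normally cleaved record.

    Raises ``ValueError`` if the record's first cleavage is not normal
    (contract: call :func:`classify_first_cleavage` first).
    """
    full = classify_record(record)
    if full.top != "normal":
        raise ValueError(
            f"classify_normal_subtype called on a {full.top} record "
            f"({record.embryo_id!r})"
        )
    return full


def classify_cohort(cohort: Cohort) -> pd.DataFrame:
    """Classify every record; returns one row per embryo.

    Columns: embryo_id, run_id, top, normal_subtype, abnormal_subtypes
    (semicolon-joined, observation order), multiple_abnormal,
    n_async_events, async_class, category, later_direct, later_reverse.
    Deterministic: identical cohorts give identical tables.
    """
    rows = []
    for rec in cohort.records:
        call = classify_record(rec)
        rows.append(
            {
                "embryo_id": rec.embryo_id,
                "run_id": rec.run_id,
                "top": call.top,
                "normal_subtype": call.normal_subtype,
                "abnormal_subtypes": ";".join(call.abnormal_subtypes),
                "multiple_abnormal": call.multiple_abnormal,
                "n_async_events": call.n_async_events,
                "async_class": call.async_class,
                "category": call.category,
                "later_direct": call.later_direct,
                "later_reverse": call.later_reverse,
            }
        )
    columns = [
        "embryo_id", "run_id", "top", "normal_subtype", "abnormal_subtypes",
        "multiple_abnormal", "n_async_events", "async_class", "category",
        "later_direct", "later_reverse",
    ]
    return pd.DataFrame(rows, columns=columns)


def tally_categories(calls: pd.DataFrame) -> dict[str, int]:
    """Category counts (synchronous, asynchronous, direct, unequal,
    reverse, multiple_abnormal, unclassified) from a call table."""
    return calls["category"].value_counts().to_dict()
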