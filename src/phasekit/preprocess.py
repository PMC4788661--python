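"""Read trimming, size selection, collapsing to distinct sequences, and RPM.

Distinct sequences ("clusters") are the unit of all downstream analysis: one
row per unique 18-28-nt sequence with per-library read counts and
reads-per-million abundances.  The table columns are listed in
``DISTINCT_COLUMNS``; annotation columns are filled later by
:mod:`phasekit.annotate`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import pandas as pd

LIBRARIES = ("A", "B")

DISTINCT_COLUMNS = [
    "sequence", "length", "count_A", "count_B", "rpm_A", "rpm_B",
    "annotation_class", "annotation_subclass", "genome_hits",
]


class SmallRNARead(NamedTuple):
    id: str
    sequence: str
    qualities: str | None
    library: str


@dataclass
class TrimStats:
    total: int = 0
    kept: int = 0
    dropped_quality: int = 0
    dropped_empty: int = 0


def _mean_phred(qual: str) -> float:
    return sum(ord(c) - 33 for c in qual) / len(qual)


def trim_reads(
    reads: Iterable[SmallRNARead],
    adapter: str | None,
    min_quality: float = 20.0,
    min_overlap: int = 5,
) -> tuple[list[SmallRNARead], TrimStats]:
    """Remove 3' adapter and low-quality reads.

    The adapter is removed at its first full occurrence in the read; otherwise
    the longest read suffix exactly matching an adapter prefix of at least
    ``min_overlap`` nt is cut.  Reads whose mean Phred quality (over the
    retained bases) falls below ``min_quality`` are dropped, as are reads left
    empty after trimming.  ``adapter=None`` disables trimming; an empty
    adapter string is a parameter error.
    """
    if adapter is not None and adapter == "":
        raise ValueError("adapter must be a non-empty sequence (or None to disable)")
    if adapter is not None and min_overlap < 5:
        raise ValueError("min_overlap must be >= 5")
    stats = TrimStats()
    kept: list[SmallRNARead] = []
    for read in reads:
        stats.total += 1
        seq, qual = read.sequence, read.qualities
        if adapter:
            cut = seq.find(adapter)
            if cut < 0:
                cut = len(seq)
                for k in range(min(len(adapter), len(seq)), min_overlap - 1, -1):
                    if seq.endswith(adapter[:k]):
                        cut = len(seq) - k
                        break
            seq = seq[:cut]
            qual = qual[:cut] if qual is not None else None
        if not seq:
            stats.dropped_empty += 1
            continue
        if qual is not None and _mean_phred(qual) < min_quality:
            stats.dropped_quality += 1
            continue
        stats.kept += 1
        kept.append(SmallRNARead(read.id, seq, qual, read.library))
    return kept, stats


def collapse(
    reads: Iterable[SmallRNARead],
    min_len: int = 18,
    max_len: int = 28,
) -> tuple[pd.DataFrame, int]:
    """Collapse trimmed reads into the distinct-sequence table.

    Returns ``(distincts, n_discarded)`` where reads outside ``[min_len,
    max_len]`` are excluded and counted.  The table is sorted by sequence, so
    the result is independent of input read order.
    """
    counters = {lib: Counter() for lib in LIBRARIES}
    discarded = 0
    for read in reads:
        if not (min_len <= len(read.sequence) <= max_len):
            discarded += 1
            continue
        counters[read.library][read.sequence] += 1
    sequences = sorted(set().union(*[set(c) for c in counters.values()]))
    df = pd.DataFrame(
        {
            "sequence": sequences,
            "length": [len(s) for s in sequences],
            "count_A": [counters["A"][s] for s in sequences],
            "count_B": [counters["B"][s] for s in sequences],
        }
    )
    df["rpm_A"] = 0.0
    df["rpm_B"] = 0.0
    df["annotation_class"] = ""
    df["annotation_subclass"] = ""
    df["genome_hits"] = 0
    return df[DISTINCT_COLUMNS], discarded


def normalize(distincts: pd.DataFrame, totals: dict[str, int] | None = None) -> pd.DataFrame:
    """Fill reads-per-million columns: ``rpm = count * 1e6 / library_total``.

    By default the totals are the per-library sums of the table itself (reads
    retained after size selection).  Explicit totals must be positive for any
    library with nonzero counts.
    """
    out = distincts.copy()
    for lib in LIBRARIES:
        col = f"count_{lib}"
        total = (totals or {}).get(lib, int(out[col].sum()))
        if total <= 0:
            if out[col].sum() > 0:
                raise ValueError(f"library {lib}: zero total with nonzero counts")
            out[f"rpm_{lib}"] = 0.0
        else:
            out[f"rpm_{lib}"] = out[col] * 1e6 / total
    return out
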