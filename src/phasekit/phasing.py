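"""Detection of 21-nt phased siRNA loci and trigger-site scanning.

The phasing statistic is a hypergeometric upper tail computed in a sliding
window: in a window of ``cycles`` 21-nt cycles there are ``N = 2 * 21 *
cycles`` possible 5'-start positions (both strands) of which ``K = 2 *
cycles`` are in phase with a given register; given ``n`` observed distinct
start positions of which ``k`` are in phase, the locus p-value is
``P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``.  Minus-strand reads are
considered in phase when offset by 2 nt from the plus-strand register,
reflecting the 2-nt 3' overhang of Dicer duplex products.

Detected loci are post-filtered (multi-mapping members, blacklisted regions),
extended by two recruitment passes over sequences not detected as phased, and
their flanks scanned for the 22-nt trigger-miRNA recognition site with a
position-weighted complementarity penalty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from phasekit.annotate import GenomeAlignment, MatchParams, SeqDatabase
from phasekit.seq import PHASE, encode, revcomp


@lru_cache(maxsize=None)
def hypergeom_tail(N: int, K: int, n: int, k: int) -> Fraction:
    """Exact upper tail ``P(X >= k)`` of ``Hypergeometric(N, K, n)``.

    Computed as a rational number from binomial coefficients, so the result
    is exact for any population size.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require 0 <= K <= N and 0 <= n <= N")
    if k <= max(0, n + K - N):
        return Fraction(1)
    hi = min(n, K)
    if k > hi:
        return Fraction(0)
    num = sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, hi + 1))
    return Fraction(num, math.comb(N, n))


@lru_cache(maxsize=None)
def _tail_float(N: int, K: int, n: int, k: int) -> float:
    return float(hypergeom_tail(N, K, n, k))


@dataclass
class PhasingWindowScore:
    chrom: str
    window_start: int
    window_len: int
    register: int
    N: int  # eligible start positions (both strands)
    K: int  # in-phase positions among them
    n: int  # observed distinct start positions
    k: int  # observed in-phase start positions
    p_value: float


@dataclass
class TriggerHit:
    trigger_name: str
    position: int  # genomic start of the 22-nt recognition site
    strand: str
    score: float  # complementarity penalty, 0 = perfect
    distance_to_locus_end: int
    side: str  # "5p" (left flank) or "3p" (right flank)
    cleavage_position: int  # genomic boundary coordinate of the cleavage point


@dataclass
class PhasedLocus:
    id: str
    chrom: str
    start: int
    end: int
    register: int
    core_members: list[str]
    member_positions: dict[str, list[tuple[str, int]]]
    both_strands: bool
    min_p: float
    recruited_pass1: list[str] = field(default_factory=list)
    recruited_pass2: list[str] = field(default_factory=list)
    count_A: int = 0
    count_B: int = 0
    rpm_A: float = 0.0
    rpm_B: float = 0.0
    trigger_hit: TriggerHit | None = None

    @property
    def n_distinct(self) -> int:
        return len(self.core_members) + len(self.recruited_pass1) + len(self.recruited_pass2)


def in_phase(alignment: GenomeAlignment, register: int, origin: int = 0) -> bool:
    """True when a 21-nt alignment starts in the given register.

    Plus-strand reads are in phase when ``(start - register) % 21 == 0``;
    minus-strand reads when their leftmost coordinate is 2 nt behind the
    register (duplex 2-nt 3' overhang).  ``origin`` shifts the coordinate
    frame (registers are defined relative to it).
    """
    if alignment.end - alignment.start != PHASE:
        raise ValueError("in_phase is defined for 21-nt alignments only")
    pos = alignment.start - origin
    if alignment.strand == "+":
        return (pos - register) % PHASE == 0
    return (pos + 2 - register) % PHASE == 0


def _phase_of(strand: str, leftmost: int) -> int:
    return leftmost % PHASE if strand == "+" else (leftmost + 2) % PHASE


def score_window(
    positions: Iterable[tuple[str, int]],
    chrom: str,
    window_start: int,
    register: int,
    cycles: int = 11,
) -> PhasingWindowScore:
    """Hypergeometric phasing score for one window and register.

    ``positions`` are (strand, leftmost coordinate) pairs of 21-nt
    alignments; duplicates are collapsed and positions outside
    ``[window_start, window_start + 21 * cycles)`` ignored.
    """
    window_len = PHASE * cycles
    N, K = 2 * window_len, 2 * cycles
    inside = {
        (s, p) for s, p in positions if window_start <= p < window_start + window_len
    }
    n = len(inside)
    if n > N:
        raise ValueError("more distinct start positions than eligible positions")
    k = sum(1 for s, p in inside if _phase_of(s, p) == register)
    return PhasingWindowScore(
        chrom=chrom, window_start=window_start, window_len=window_len,
        register=register, N=N, K=K, n=n, k=k, p_value=_tail_float(N, K, n, k),
    )


def detect_loci(
    alignments: Iterable[GenomeAlignment],
    cycles: int = 11,
    step: int = PHASE,
    alpha: float = 1e-4,
    min_members: int = 3,
) -> list[PhasedLocus]:
    """Scan sliding windows over each chromosome and call phased loci.

    Windows advance by ``step`` on a grid anchored at coordinate 0; all 21
    registers are tested in every window holding at least ``min_members``
    distinct start positions.  Overlapping significant windows with the same
    register are merged; the locus span is the extent of its in-phase member
    alignments.
    """
    window_len = PHASE * cycles
    N, K = 2 * window_len, 2 * cycles

    by_chrom: dict[str, dict[tuple[str, int], set[str]]] = {}
    for a in alignments:
        if a.end - a.start != PHASE:
            continue
        by_chrom.setdefault(a.chrom, {}).setdefault((a.strand, a.start), set()).add(
            a.sequence
        )

    loci: list[PhasedLocus] = []
    for chrom in sorted(by_chrom):
        entries = sorted(by_chrom[chrom], key=lambda sp: (sp[1], sp[0]))
        pos = np.array([p for _, p in entries])
        phase = np.array([_phase_of(s, p) for s, p in entries])
        lo = max(0, (int(pos.min()) - window_len + step) // step * step)
        hi = int(pos.max())
        significant: list[tuple[int, int, float]] = []  # (window_start, register, p)
        for w in range(lo, hi + 1, step):
            i0, i1 = np.searchsorted(pos, [w, w + window_len])
            n = int(i1 - i0)
            if n < min_members:
                continue
            counts = np.bincount(phase[i0:i1], minlength=PHASE)
            for r in range(PHASE):
                if counts[r] < min_members:
                    continue
                p = _tail_float(N, K, n, int(counts[r]))
                if p <= alpha:
                    significant.append((w, r, p))

        by_register: dict[int, list[tuple[int, float]]] = {}
        for w, r, p in significant:
            by_register.setdefault(r, []).append((w, p))
        for r in sorted(by_register):
            wins = sorted(by_register[r])
            cluster = [wins[0]]
            for w, p in wins[1:]:
                if w >= cluster[-1][0] + window_len:  # gap: windows no longer overlap
                    loci.append(
                        _make_locus(chrom, r, cluster, entries, by_chrom[chrom],
                                    window_len)
                    )
                    cluster = []
                cluster.append((w, p))
            loci.append(
                _make_locus(chrom, r, cluster, entries, by_chrom[chrom], window_len)
            )

    loci.sort(key=lambda lc: (lc.chrom, lc.start, lc.register))
    for i, lc in enumerate(loci):
        lc.id = f"PL{i + 1:04d}"
    return loci


def _make_locus(
    chrom: str,
    register: int,
    cluster: list[tuple[int, float]],
    entries: list[tuple[str, int]],
    seq_map: dict[tuple[str, int], set[str]],
    window_len: int,
) -> PhasedLocus:
    span_lo = min(w for w, _ in cluster)
    span_hi = max(w for w, _ in cluster) + window_len
    members: dict[str, list[tuple[str, int]]] = {}
    strands = set()
    coords = []
    for s, p in entries:
        if span_lo <= p < span_hi and _phase_of(s, p) == register:
            for seq in sorted(seq_map[(s, p)]):
                members.setdefault(seq, []).append((s, p))
            strands.add(s)
            coords.append(p)
    return PhasedLocus(
        id="", chrom=chrom, start=min(coords), end=max(coords) + PHASE,
        register=register, core_members=sorted(members),
        member_positions=members, both_strands=len(strands) == 2,
        min_p=min(p for _, p in cluster),
    )


def postfilter_loci(
    loci: Sequence[PhasedLocus],
    blacklist: Iterable[tuple[str, int, int]],
    genome_hits: Mapping[str, int],
    max_genome_hits: int = 10,
    min_members: int = 3,
) -> tuple[list[PhasedLocus], int]:
    """Apply the post-detection filters; returns (kept loci, n removed).

    Member sequences aligning to more than ``max_genome_hits`` genomic
    positions are removed; loci overlapping a blacklist interval (e.g.
    telomere-associated regions) or left with fewer than ``min_members``
    members are dropped.  Spans are recomputed from the surviving members.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, s, e in blacklist:
        if e <= s:
            raise ValueError(f"malformed blacklist interval {chrom}:{s}-{e}")
        trees.setdefault(chrom, IntervalTree()).addi(s, e)

    kept: list[PhasedLocus] = []
    removed = 0
    for lc in loci:
        members = {
            seq: ps for seq, ps in lc.member_positions.items()
            if genome_hits.get(seq, 1) <= max_genome_hits
        }
        if len(members) < min_members:
            removed += 1
            continue
        coords = [p for ps in members.values() for _, p in ps]
        start, end = min(coords), max(coords) + PHASE
        if chrom_tree := trees.get(lc.chrom):
            if chrom_tree.overlap(start, end):
                removed += 1
                continue
        strands = {s for ps in members.values() for s, _ in ps}
        kept.append(
            PhasedLocus(
                id=lc.id, chrom=lc.chrom, start=start, end=end,
                register=lc.register, core_members=sorted(members),
                member_positions=members, both_strands=len(strands) == 2,
                min_p=lc.min_p, trigger_hit=lc.trigger_hit,
            )
        )
    return kept, removed


#: recruitment passes: exact identity first, then relaxed to 85 %
RECRUIT_PASS1 = MatchParams(min_identity_frac=1.0, min_coverage_frac=0.85, min_match_len=16)
RECRUIT_PASS2 = MatchParams(min_identity_frac=0.85, min_coverage_frac=0.85, min_match_len=16)


def recruit_members(
    loci: Sequence[PhasedLocus],
    candidates: Iterable[str],
    pass1: MatchParams = RECRUIT_PASS1,
    pass2: MatchParams = RECRUIT_PASS2,
) -> pd.DataFrame:
    """Recruit additional 21-nt sequences into detected loci in two passes.

    The loci's core members form the match database.  Pass 1 requires an
    exact (100 % identity) match over at least 85 % of the candidate length
    (minimum 16 nt); pass 2 relaxes identity to 85 %.  A sequence recruited
    in pass 1 is not reconsidered in pass 2; a sequence matching members of
    several loci is recruited into all of them and flagged ambiguous.

    Mutates ``loci`` (filling ``recruited_pass1/2``) and returns a table
    ``(sequence, locus_id, recruitment_pass, ambiguous)``.
    """
    core = {seq for lc in loci for seq in lc.core_members}
    member_records = {
        f"{lc.id}|{i}": seq for lc in loci for i, seq in enumerate(lc.core_members)
    }
    by_id = {lc.id: lc for lc in loci}
    rows = []
    remaining = [c for c in dict.fromkeys(candidates) if c not in core]
    for pass_no, params in ((1, pass1), (2, pass2)):
        if not member_records or not remaining:
            break
        db = SeqDatabase(member_records, params)
        next_remaining = []
        for seq in remaining:
            hits = db.search(seq)
            locus_ids = sorted({m.subject_id.split("|")[0] for m in hits})
            if not locus_ids:
                next_remaining.append(seq)
                continue
            ambiguous = len(locus_ids) > 1
            for lid in locus_ids:
                target = (by_id[lid].recruited_pass1 if pass_no == 1
                          else by_id[lid].recruited_pass2)
                target.append(seq)
                rows.append(dict(sequence=seq, locus_id=lid,
                                 recruitment_pass=pass_no, ambiguous=ambiguous))
        remaining = next_remaining
    return pd.DataFrame(rows, columns=["sequence", "locus_id", "recruitment_pass",
                                       "ambiguous"])


def fill_locus_counts(
    loci: Sequence[PhasedLocus],
    distincts: pd.DataFrame,
    include_recruited: bool = True,
) -> None:
    """Sum member counts and RPM per locus into the locus records."""
    table = distincts.set_index("sequence")
    for lc in loci:
        seqs = list(lc.core_members)
        if include_recruited:
            seqs += lc.recruited_pass1 + lc.recruited_pass2
        present = [s for s in seqs if s in table.index]
        sub = table.loc[present]
        lc.count_A = int(sub["count_A"].sum())
        lc.count_B = int(sub["count_B"].sum())
        lc.rpm_A = float(sub["rpm_A"].sum())
        lc.rpm_B = float(sub["rpm_B"].sum())


# --- trigger-site scanning -------------------------------------------------

#: trigger positions (1-based, from the trigger 5' end) with doubled penalty
CORE_REGION = (2, 13)
WOBBLE_PENALTY = 0.5
MISMATCH_PENALTY = 1.0
#: the precursor is cleaved between the bases pairing trigger positions 10/11
CLEAVAGE_RULE = 10

_PAIR = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_WOBBLE = {("G", "T"), ("T", "G")}  # trigger G : target U and trigger U : target G


def _pair_penalty(trigger_base: str, target_base: str) -> float:
    if (trigger_base, target_base) in _PAIR:
        return 0.0
    if (trigger_base, target_base) in _WOBBLE:
        return WOBBLE_PENALTY
    return MISMATCH_PENALTY


def complementarity_score(trigger: str, site: str) -> float:
    """Penalty of an antiparallel trigger / target-site duplex.

    ``site`` is the target in sense orientation, same length as the trigger;
    trigger position ``i`` (1-based from its 5' end) pairs the site base at
    position ``len - i + 1``.  Mismatches cost 1, G:U wobbles 0.5, both
    doubled within trigger positions 2-13; 0 is a perfect duplex.
    """
    if len(site) != len(trigger):
        raise ValueError("site and trigger must have equal length")
    total = 0.0
    L = len(trigger)
    for i0, t in enumerate(trigger):
        weight = 2.0 if CORE_REGION[0] <= i0 + 1 <= CORE_REGION[1] else 1.0
        total += weight * _pair_penalty(t, site[L - 1 - i0])
    return total


def _scan_profile(trigger: str, target_sense: np.ndarray) -> np.ndarray:
    """Vectorised duplex penalties for every site start in ``target_sense``."""
    L = len(trigger)
    n = len(target_sense) - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    for i0, t in enumerate(trigger):
        weight = 2.0 if CORE_REGION[0] <= i0 + 1 <= CORE_REGION[1] else 1.0
        pen = np.full(256, MISMATCH_PENALTY)
        for b in "ACGT":
            pen[ord(b)] = _pair_penalty(t, b)
        scores += weight * pen[target_sense[L - 1 - i0: L - 1 - i0 + n]]
    return scores


def scan_trigger_site(
    locus: PhasedLocus,
    genome: Mapping[str, str],
    trigger_db: Mapping[str, str],
    flank: int = 500,
    threshold: float = 4.5,
) -> TriggerHit | None:
    """Scan the locus +/- ``flank`` bp for the best trigger recognition site.

    Both strands are scanned with :func:`complementarity_score`; the best
    site with penalty <= ``threshold`` is reported together with its distance
    to the nearest locus end and the inferred cleavage position (the boundary
    between the target bases pairing trigger positions 10 and 11).  Returns
    None when no site passes.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    chrom_seq = genome.get(locus.chrom)
    if chrom_seq is None or locus.start < 0 or locus.end > len(chrom_seq):
        raise ValueError(f"locus {locus.id} outside the genome")
    win_start = max(0, locus.start - flank)
    win_end = min(len(chrom_seq), locus.end + flank)
    window = chrom_seq[win_start:win_end]

    best: tuple[tuple, TriggerHit] | None = None
    for name in sorted(trigger_db):
        trigger = trigger_db[name]
        if not (20 <= len(trigger) <= 24):
            raise ValueError(f"trigger {name} must be 20-24 nt")
        L = len(trigger)
        for strand in ("+", "-"):
            sense = window if strand == "+" else revcomp(window)
            scores = _scan_profile(trigger, encode(sense))
            for p in np.nonzero(scores <= threshold)[0]:
                if strand == "+":
                    gs = win_start + int(p)
                else:
                    gs = win_start + len(window) - (int(p) + L)
                ge = gs + L
                if ge <= locus.start:
                    dist, side = locus.start - ge, "5p"
                elif gs >= locus.end:
                    dist, side = gs - locus.end, "3p"
                else:
                    dist = 0
                    side = "5p" if gs - locus.start < locus.end - ge else "3p"
                cleavage = gs + (L - CLEAVAGE_RULE) if strand == "+" else gs + CLEAVAGE_RULE
                hit = TriggerHit(
                    trigger_name=name, position=gs, strand=strand,
                    score=float(scores[p]), distance_to_locus_end=dist, side=side,
                    cleavage_position=cleavage,
                )
                key = (hit.score, dist, 0 if strand == "+" else 1, gs)
                if best is None or key < best[0]:
                    best = (key, hit)
    return None if best is None else best[1]
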