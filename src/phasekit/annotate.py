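"""Hierarchical annotation of distinct small-RNA sequences.

Sequences are classified first-hit-wins against an ordered series of tiers
(mature miRNAs, ncRNAs, repeats, then CDS / intron / UTR features via genome
mapping, then the genome itself); a sequence matching only the genome is
"unannotated" and one matching nothing is "unmapped".

Matching is an ungapped all-offsets local alignment: for every strand and
every diagonal the best window satisfying the identity / coverage / minimum
length thresholds is reported.  For 18-28-nt queries this is the operative
part of a BLASTN-style search; gapped alignment and e-values are deliberately
out of scope (the identity/coverage/length thresholds are the filter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from phasekit.seq import DNA, check_dna, encode, revcomp
from phasekit.synthgen import ReferenceBundle


@dataclass(frozen=True)
class MatchParams:
    """Acceptance thresholds for an ungapped local match.

    A window of aligned length ``w`` (against a query of length ``L``) is
    accepted when ``w >= max(min_match_len, ceil(min_coverage_frac * L))`` and
    ``identities / w >= min_identity_frac``.
    """

    min_identity_frac: float = 0.85
    min_coverage_frac: float = 0.85
    min_match_len: int = 16

    def __post_init__(self) -> None:
        if not (0.0 < self.min_identity_frac <= 1.0):
            raise ValueError("min_identity_frac must be in (0, 1]")
        if not (0.0 < self.min_coverage_frac <= 1.0):
            raise ValueError("min_coverage_frac must be in (0, 1]")
        if self.min_match_len < 1:
            raise ValueError("min_match_len must be >= 1")

    def min_window(self, query_len: int) -> int:
        return max(self.min_match_len, math.ceil(self.min_coverage_frac * query_len))


class SequenceMatch(NamedTuple):
    query: str
    subject_id: str
    subject_start: int  # leftmost subject coordinate of the aligned window
    strand: str
    aligned_len: int
    identities: int
    identity_frac: float
    coverage_frac: float
    query_start: int  # on the original (plus) query orientation


class GenomeAlignment(NamedTuple):
    sequence: str
    chrom: str
    start: int  # leftmost, 0-based
    end: int  # half-open
    strand: str
    mismatches: int


_EPS = 1e-9


def _best_on_diagonal(
    q: np.ndarray, s: np.ndarray, diag: int, wmin: int, min_id: float
) -> tuple[int, int, int, int] | None:
    """Best admissible window on one diagonal.

    Returns ``(identities, aligned_len, q_start, s_start)`` maximising
    identities, then aligned length, then the leftmost start; None if no
    window passes.  ``diag`` is ``s_index - q_index``.
    """
    qi0, si0 = max(0, -diag), max(0, diag)
    ov = min(len(q) - qi0, len(s) - si0)
    if ov < wmin:
        return None
    eq = q[qi0:qi0 + ov] == s[si0:si0 + ov]
    cs = np.concatenate(([0], np.cumsum(eq)))
    best = None
    for w in range(wmin, ov + 1):
        ident = cs[w:] - cs[:-w]
        ok = ident + _EPS >= min_id * w
        if not ok.any():
            continue
        idx = np.nonzero(ok)[0]
        j = int(idx[np.argmax(ident[idx])])  # first maximum -> leftmost start
        key = (int(ident[j]), w, -j)
        if best is None or key > best[0]:
            best = (key, (int(ident[j]), w, qi0 + j, si0 + j))
    return None if best is None else best[1]


def _match_one_strand(
    query: str,
    q: np.ndarray,
    s: np.ndarray,
    subject_id: str,
    strand: str,
    params: MatchParams,
    diagonals: Sequence[int] | None = None,
) -> list[SequenceMatch]:
    L = len(q)
    wmin = params.min_window(L)
    if diagonals is None:
        diagonals = range(-(L - 1), len(s))
    out = []
    for d in diagonals:
        hit = _best_on_diagonal(q, s, d, wmin, params.min_identity_frac)
        if hit is None:
            continue
        ident, w, qs, ss = hit
        q_start = qs if strand == "+" else L - (qs + w)
        out.append(
            SequenceMatch(
                query=query, subject_id=subject_id, subject_start=ss, strand=strand,
                aligned_len=w, identities=ident, identity_frac=ident / w,
                coverage_frac=w / L, query_start=q_start,
            )
        )
    return out


def local_match(
    query: str,
    subject: str,
    params: MatchParams | None = None,
    subject_id: str = "subject",
) -> list[SequenceMatch]:
    """All ungapped local matches of *query* against both strands of *subject*.

    One match (the best admissible window) is reported per strand and
    diagonal; minus-strand hits are reported with plus-strand subject
    coordinates.  Returns an empty list when nothing passes the thresholds.
    """
    params = params or MatchParams()
    check_dna(query, what="query")
    if len(query) < params.min_match_len:
        raise ValueError("query shorter than min_match_len")
    s = encode(subject)
    matches = _match_one_strand(query, encode(query), s, subject_id, "+", params)
    matches += _match_one_strand(query, encode(revcomp(query)), s, subject_id, "-", params)
    matches.sort(key=lambda m: (m.strand, m.subject_start - m.query_start, m.subject_start))
    return matches


def _safe_seed_k(params: MatchParams, max_query_len: int = 28) -> int:
    """Longest exact seed guaranteed inside any admissible window (pigeonhole)."""
    k = max_query_len
    for w in range(params.min_match_len, max_query_len + 1):
        mm = math.floor((1.0 - params.min_identity_frac) * w + _EPS)
        k = min(k, math.ceil((w - mm) / (mm + 1)))
    return k


class SeqDatabase:
    """Seed-indexed search over a set of subject records.

    Produces exactly the matches :func:`local_match` would report against
    each record, using exact k-mer seeds (pigeonhole-safe for the configured
    thresholds) to restrict the diagonals evaluated.  Falls back to the full
    diagonal scan when the safe seed length is too short to index.
    """

    def __init__(
        self,
        records: Mapping[str, str],
        params: MatchParams | None = None,
        max_query_len: int = 28,
    ):
        self.params = params or MatchParams()
        self.records = dict(records)
        self._encoded = {rid: encode(seq) for rid, seq in self.records.items()}
        self.k = _safe_seed_k(self.params, max_query_len)
        self._index: dict[str, list[tuple[str, int]]] = {}
        if self.k >= 3:
            for rid in sorted(self.records):
                seq = self.records[rid]
                for i in range(len(seq) - self.k + 1):
                    self._index.setdefault(seq[i:i + self.k], []).append((rid, i))

    def search(self, query: str) -> list[SequenceMatch]:
        check_dna(query, what="query")
        out: list[SequenceMatch] = []
        for strand, oriented in (("+", query), ("-", revcomp(query))):
            q = encode(oriented)
            if self.k < 3:
                for rid in sorted(self.records):
                    out += _match_one_strand(
                        query, q, self._encoded[rid], rid, strand, self.params
                    )
                continue
            diags: dict[str, set[int]] = {}
            for i in range(len(oriented) - self.k + 1):
                for rid, pos in self._index.get(oriented[i:i + self.k], ()):
                    diags.setdefault(rid, set()).add(pos - i)
            for rid in sorted(diags):
                out += _match_one_strand(
                    query, q, self._encoded[rid], rid, strand, self.params,
                    diagonals=sorted(diags[rid]),
                )
        out.sort(key=lambda m: (m.subject_id, m.strand,
                                m.subject_start - m.query_start, m.subject_start))
        return out

    def best(self, query: str) -> SequenceMatch | None:
        """Best match by (identities, aligned length), ties broken by id."""
        hits = self.search(query)
        if not hits:
            return None
        return min(hits, key=lambda m: (-m.identities, -m.aligned_len, m.subject_id))


def map_to_genome(
    sequences: Sequence[str],
    genome: Mapping[str, str],
    max_mismatches: int = 0,
) -> dict[str, list[GenomeAlignment]]:
    """End-to-end genomic alignments of each sequence on both strands.

    With ``max_mismatches=0`` (the default for short-read mapping here) this
    is an exact substring search; larger values use a vectorised full-length
    mismatch scan.  Alignments are reported with plus-strand leftmost
    coordinates; ``end - start`` equals the query length.
    """
    chroms = sorted(genome)
    enc = {c: encode(genome[c]) for c in chroms} if max_mismatches > 0 else {}
    result: dict[str, list[GenomeAlignment]] = {}
    for seq in sequences:
        alns: list[GenomeAlignment] = []
        for chrom in chroms:
            g = genome[chrom]
            for strand, probe in (("+", seq), ("-", revcomp(seq))):
                if max_mismatches == 0:
                    i = g.find(probe)
                    while i >= 0:
                        alns.append(GenomeAlignment(seq, chrom, i, i + len(seq), strand, 0))
                        i = g.find(probe, i + 1)
                else:
                    garr, parr = enc[chrom], encode(probe)
                    n = len(garr) - len(parr) + 1
                    if n <= 0:
                        continue
                    mm = np.zeros(n, dtype=np.int32)
                    for j in range(len(parr)):
                        mm += garr[j:j + n] != parr[j]
                    for i in np.nonzero(mm <= max_mismatches)[0]:
                        alns.append(
                            GenomeAlignment(seq, chrom, int(i), int(i) + len(seq),
                                            strand, int(mm[i]))
                        )
        alns.sort(key=lambda a: (a.chrom, a.start, a.strand))
        result[seq] = alns
    return result


#: Tier order of the hierarchical classification.
TIER_ORDER = ("miRNA", "ncRNA", "repeat", "CDS", "intron/UTR", "genome")


def classify_hierarchical(
    distincts: pd.DataFrame,
    bundle: ReferenceBundle,
    params: MatchParams | None = None,
    max_mismatches: int = 0,
) -> tuple[pd.DataFrame, dict[str, list[GenomeAlignment]]]:
    """Assign each distinct sequence its annotation class (first hit wins).

    Tier order: miRNA -> ncRNA -> repeat -> CDS -> intron/UTR -> genome.
    CDS and intron/UTR hits are genome alignments overlapping the respective
    feature intervals and are reported as class ``gene`` with the subclass
    recorded; genome-only hits are ``unannotated``; everything else is
    ``unmapped``.  Also fills ``genome_hits`` and returns the genome
    alignments for downstream phasing analysis.
    """
    params = params or MatchParams()
    dbs = []
    for tier, records in (("miRNA", bundle.mirna_db), ("ncRNA", bundle.ncrna_db),
                          ("repeat", bundle.repeat_db)):
        if records is None:
            raise ValueError(f"missing database for tier {tier!r}")
        dbs.append((tier, SeqDatabase(records, params)))

    trees: dict[str, dict[str, IntervalTree]] = {}
    for cls in ("CDS", "intron", "UTR"):
        trees[cls] = {c: IntervalTree() for c in bundle.genome}
        for f in bundle.feature_intervals.get(cls, []):
            trees[cls][f.chrom].addi(f.start, f.end)

    sequences = distincts["sequence"].tolist()
    alignments = map_to_genome(sequences, bundle.genome, max_mismatches=max_mismatches)

    classes, subclasses, subjects, hits = [], [], [], []
    for seq in sequences:
        alns = alignments[seq]
        hits.append(len(alns))
        cls, sub, subj = "", "", ""
        for tier, db in dbs:
            m = db.best(seq)
            if m is not None:
                cls, subj = tier, m.subject_id
                break
        if not cls:
            for feature_cls, label, sublabel in (
                ("CDS", "gene", "CDS"), ("intron", "gene", "intron"),
                ("UTR", "gene", "UTR"),
            ):
                if any(
                    trees[feature_cls][a.chrom].overlap(a.start, a.end) for a in alns
                ):
                    cls, sub = label, sublabel
                    break
        if not cls:
            cls = "unannotated" if alns else "unmapped"
        classes.append(cls)
        subclasses.append(sub)
        subjects.append(subj)

    out = distincts.copy()
    out["annotation_class"] = classes
    out["annotation_subclass"] = subclasses
    out["annotation_subject"] = subjects
    out["genome_hits"] = hits
    return out, alignments


def class_composition(distincts: pd.DataFrame) -> pd.Series:
    """Per-class proportions over distinct sequences (not reads); sums to 1."""
    if len(distincts) == 0:
        raise ValueError("class composition undefined for an empty table")
    counts = distincts["annotation_class"].value_counts()
    return counts / counts.sum()
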