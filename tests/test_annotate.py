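"""Local matcher correctness and hierarchical classification."""

from __future__ import annotations

import numpy as np
import pytest

from phasekit.annotate import (
    MatchParams,
    SeqDatabase,
    class_composition,
    classify_hierarchical,
    local_match,
    map_to_genome,
)
from phasekit.preprocess import collapse, SmallRNARead
from phasekit.seq import DNA, revcomp
from phasekit.synthgen import Feature, ReferenceBundle

from oracles import brute_local_match

RNG = np.random.default_rng(2024)


def _rand(n, rng=RNG):
    return "".join(np.array(list(DNA))[rng.integers(0, 4, size=n)])


def _as_tuples(matches):
    return sorted((m.strand, m.subject_start, m.aligned_len, m.identities,
                   m.query_start) for m in matches)


def test_exact_substring_gives_full_identity_match():
    query = _rand(21)
    subject = _rand(40) + query + _rand(40)
    hits = [m for m in local_match(query, subject) if m.strand == "+"]
    best = max(hits, key=lambda m: m.identities)
    assert best.identity_frac == 1.0
    assert best.coverage_frac == 1.0
    assert best.subject_start == 40


def test_four_spread_mismatches_fail_default_thresholds():
    # identity 17/21 = 0.81 overall and every >=18-nt window holds >=3 mismatches
    rng = np.random.default_rng(5)
    query = _rand(21, rng)
    corrupted = list(query)
    for pos in (2, 7, 12, 17):
        corrupted[pos] = DNA[(DNA.index(corrupted[pos]) + 1) % 4]
    subject = "".join(corrupted)
    assert local_match(query, subject) == []


def test_reverse_complement_match_reports_minus_strand():
    query = _rand(21)
    subject = _rand(30) + revcomp(query) + _rand(30)
    strands = {m.strand for m in local_match(query, subject)}
    assert "-" in strands
    best = max((m for m in local_match(query, subject) if m.strand == "-"),
               key=lambda m: m.identities)
    assert best.subject_start == 30 and best.identity_frac == 1.0


def test_non_dna_query_is_rejected():
    with pytest.raises(ValueError, match="query"):
        local_match("ACGTNACGTACGTACGTACGT", "ACGT" * 20)


def test_local_match_equals_brute_force_enumeration():
    params = MatchParams()
    rng = np.random.default_rng(77)
    for _ in range(60):
        qlen = int(rng.integers(18, 29))
        query = _rand(qlen, rng)
        subject = _rand(int(rng.integers(30, 200)), rng)
        if rng.random() < 0.5:  # plant a mutated copy to exercise near-matches
            copy = list(query)
            for pos in rng.choice(qlen, size=int(rng.integers(0, 4)), replace=False):
                copy[pos] = DNA[(DNA.index(copy[pos]) + 1) % 4]
            ins = int(rng.integers(0, len(subject)))
            subject = subject[:ins] + "".join(copy) + subject[ins:]
        assert _as_tuples(local_match(query, subject)) == brute_local_match(
            query, subject, params
        )


def test_seed_indexed_database_agrees_with_per_record_matching():
    rng = np.random.default_rng(99)
    records = {f"rec{i:02d}": _rand(int(rng.integers(50, 300)), rng) for i in range(12)}
    db = SeqDatabase(records, MatchParams())
    for _ in range(40):
        query = _rand(21, rng)
        if rng.random() < 0.5:
            rid = f"rec{int(rng.integers(0, 12)):02d}"
            src = records[rid]
            off = int(rng.integers(0, len(src) - 21))
            query = src[off:off + 21]
            if rng.random() < 0.5:
                q = list(query)
                q[int(rng.integers(0, 21))] = DNA[(DNA.index(q[0]) + 1) % 4]
                query = "".join(q)
        expected = []
        for rid in sorted(records):
            expected += local_match(query, records[rid], subject_id=rid)
        assert _as_tuples(db.search(query)) == _as_tuples(expected)


def test_map_to_genome_counts_all_positions(bundle):
    fam_seq = bundle.repeat_db["repfam-001"]
    probe = fam_seq[100:121]
    hits = map_to_genome([probe], bundle.genome)[probe]
    assert len(hits) == 12  # the planted multi-copy repeat family
    absent = "A" * 21
    assert map_to_genome([absent], bundle.genome)[absent] == []


def test_planted_members_map_back_to_their_positions(bundle, planted):
    lc = planted[0]
    m = lc.members[0]
    hits = map_to_genome([m.sequence], bundle.genome)[m.sequence]
    assert any(h.chrom == lc.chrom and h.start == m.position and h.strand == m.strand
               for h in hits)


def _tiny_bundle():
    """Handmade bundle with one sequence plantable per tier."""
    rng = np.random.default_rng(31)
    mir = _rand(21, rng)
    nc = _rand(21, rng)
    rep = _rand(21, rng)
    cds_region = _rand(60, rng)
    unique = _rand(40, rng)
    genome = {"chrT": _rand(50, rng) + mir + nc + rep + cds_region + unique + _rand(50, rng)}
    cds_start = 50 + 63
    return ReferenceBundle(
        genome=genome,
        feature_intervals={"CDS": [Feature("chrT", 113, 173, "+", "cds-1")],
                           "intron": [], "UTR": [], "miRNA": []},
        mirna_db={"mir-1": mir},
        mirna_families={"mir-1": "miRFAM"},
        family_types={"miRFAM": "canonical"},
        ncrna_db={"nc-1": nc, "shared": rep},
        repeat_db={"rep-1": rep},
        blacklist=[],
        trigger_db={"trig": _rand(22, rng)},
    ), mir, nc, rep, cds_region, unique


def test_first_hit_wins_across_the_annotation_hierarchy():
    bundle, mir, nc, rep, cds_region, unique = _tiny_bundle()
    reads = []
    probes = {
        mir: "miRNA",  # matches miRNA db AND genome -> miRNA wins
        nc: "ncRNA",
        rep: "ncRNA",  # present in ncRNA and repeat db: earlier tier wins
        cds_region[10:31]: "gene",
        unique[5:26]: "unannotated",
        "A" * 21: "unmapped",
    }
    for i, seq in enumerate(probes):
        reads.append(SmallRNARead(f"r{i}", seq, None, "A"))
    table, _ = collapse(reads)
    annotated, alignments = classify_hierarchical(table, bundle)
    got = dict(zip(annotated["sequence"], annotated["annotation_class"]))
    for seq, expected in probes.items():
        assert got[seq] == expected, (seq, expected, got[seq])
    row = annotated[annotated["sequence"] == cds_region[10:31]].iloc[0]
    assert row["annotation_subclass"] == "CDS"
    assert annotated.set_index("sequence").loc["A" * 21, "genome_hits"] == 0


def test_classification_ignores_database_record_order():
    bundle, mir, *_ = _tiny_bundle()
    reads = [SmallRNARead("r", mir, None, "A")]
    table, _ = collapse(reads)
    first, _ = classify_hierarchical(table, bundle)
    bundle.mirna_db = dict(reversed(list(bundle.mirna_db.items())))
    second, _ = classify_hierarchical(table, bundle)
    assert first["annotation_class"].tolist() == second["annotation_class"].tolist()


def test_class_composition_sums_to_one():
    import pandas as pd

    df = pd.DataFrame({"annotation_class": ["miRNA", "ncRNA", "repeat", "gene"]})
    comp = class_composition(df)
    assert comp.sum() == pytest.approx(1.0)
    assert (comp == 0.25).all()
    with pytest.raises(ValueError):
        class_composition(df.iloc[:0])


def test_recovered_composition_tracks_planted_class_mix(distincts, bundle, simulation):
    _, _, truth = simulation
    annotated, _ = classify_hierarchical(distincts, bundle)
    merged = annotated.merge(
        truth.background[["sequence", "cls"]], on="sequence", how="inner"
    )
    # miRNA reads are exact database copies: tier 1 must catch nearly all
    mir = merged[merged["cls"] == "mirna"]
    assert (mir["annotation_class"] == "miRNA").mean() > 0.95
    rep = merged[merged["cls"] == "repeat"]
    assert (rep["annotation_class"] == "repeat").mean() > 0.9
    un = merged[merged["cls"] == "unmapped"]
    assert (un["annotation_class"] == "unmapped").mean() > 0.9
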