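"""Synthetic reference and small-RNA library generator with planted phased loci.

The generator emulates the design of a two-library (two bulked genotype pools)
small RNA-seq experiment over a plant genome: a random reference genome with
planted miRNA / ncRNA / repeat / gene features, a set of 21-nt phased siRNA
loci whose register is anchored to a planted 22-nt trigger-miRNA recognition
site, and two read libraries in which a configurable fraction of phased loci
over-accumulates in library A by a planted fold ratio.  Every emitted read is
traceable to a truth row, so downstream detection, annotation and differential
statistics can be validated exactly.

Coordinates are 0-based half-open throughout; BED output is 0-based, GFF3
output 1-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml
from intervaltree import IntervalTree

from phasekit.seq import DNA, PHASE, revcomp

TRIGGER_LEN = 22  #: trigger miRNAs are 22 nt
#: distance (bp) from the trigger-site start to the cleavage point: the
#: precursor is cut between the bases pairing trigger positions 10 and 11.
CLEAVAGE_OFFSET = 12

#: Illumina small-RNA 3' adapter used as the default simulated adapter.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

TELOMERE_PAD = 5_000  # chromosome-end blacklist span emulating telomeric loci


class CapacityError(ValueError):
    """Requested feature density does not fit in the genome."""


class PlacementError(ValueError):
    """No free genomic space left to place a phased locus."""


class Feature(NamedTuple):
    chrom: str
    start: int
    end: int
    strand: str
    name: str


class MemberSpec(NamedTuple):
    """One planted phasiRNA: strand, leftmost genomic coordinate, relative
    abundance weight within its locus, and the 21-nt sequence."""

    strand: str
    position: int
    weight: float
    sequence: str


@dataclass
class SyntheticLocusSpec:
    """Ground truth for one planted phased locus."""

    locus_id: str
    chrom: str
    start: int
    end: int
    register: int
    orientation: str  # strand of the precursor transcript
    strands_used: str  # "both" | "plus_only"
    n_members: int
    members: list[MemberSpec]
    fold_ratio: float  # expected library-A / library-B abundance ratio
    weight: float  # relative locus expression level
    trigger_name: str | None = None
    trigger_offset: int | None = None  # bp from locus span edge to site edge
    trigger_site_start: int | None = None


@dataclass
class ReferenceBundle:
    """In-memory reference: genome, planted features, and annotation databases.

    Database sequences are copies of the planted feature intervals, so a read
    sampled from a feature is guaranteed to match its database tier.
    """

    genome: dict[str, str]
    feature_intervals: dict[str, list[Feature]]
    mirna_db: dict[str, str]
    mirna_families: dict[str, str]  # db record id -> family name
    family_types: dict[str, str]  # family -> canonical | variant | siRNA-like
    ncrna_db: dict[str, str]
    repeat_db: dict[str, str]
    blacklist: list[tuple[str, int, int]]
    trigger_db: dict[str, str]

    def occupancy(self) -> dict[str, IntervalTree]:
        """Interval trees of all planted features plus the blacklist."""
        trees: dict[str, IntervalTree] = {c: IntervalTree() for c in self.genome}
        for feats in self.feature_intervals.values():
            for f in feats:
                trees[f.chrom].addi(f.start, f.end)
        for chrom, start, end in self.blacklist:
            trees[chrom].addi(start, end)
        return trees


@dataclass
class SyntheticTruth:
    """Machine-readable ground truth for one simulated two-library run."""

    loci: list[SyntheticLocusSpec]
    member_counts: pd.DataFrame
    background: pd.DataFrame
    seed: int
    library_sizes: tuple[int, int]


DEFAULT_FEATURE_COUNTS = {
    "miRNA": 15,
    "ncRNA": 10,
    "repeat": 10,
    "CDS": 18,
    "intron": 12,
    "UTR": 12,
}
FEATURE_LENGTH_RANGES = {
    "miRNA": (21, 21),
    "ncRNA": (80, 200),
    "repeat": (250, 600),
    "CDS": (300, 1200),
    "intron": (100, 500),
    "UTR": (100, 400),
}
FAMILY_NAMES = [
    "miR159", "miR319", "miR156", "miR166", "miR396", "miR528", "miR827", "miR444",
]
FAMILY_TYPES = {
    "miR159": "canonical",
    "miR319": "canonical",
    "miR156": "canonical",
    "miR166": "canonical",
    "miR396": "canonical",
    "miR528": "variant",
    "miR827": "variant",
    "miR444": "siRNA-like",
}


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(DNA))[rng.integers(0, 4, size=n)])


def _place_interval(
    rng: np.random.Generator,
    tree: IntervalTree,
    chrom_len: int,
    length: int,
    *,
    margin: int = 30,
    lo: int | None = None,
    hi: int | None = None,
    tries: int = 300,
) -> int | None:
    """Sample a non-overlapping start for an interval of *length*; None if stuck."""
    lo = TELOMERE_PAD if lo is None else lo
    hi = (chrom_len - TELOMERE_PAD - length) if hi is None else hi
    if hi <= lo:
        return None
    for _ in range(tries):
        s = int(rng.integers(lo, hi))
        if not tree.overlap(s - margin, s + length + margin):
            return s
    return None


def generate_reference(
    chromosome_length: int = 500_000,
    n_chromosomes: int = 2,
    feature_counts: dict[str, int] | None = None,
    repeat_family_copies: int = 12,
    seed: int = 0,
) -> ReferenceBundle:
    """Generate a random genome with planted annotation features and databases.

    One repeat record is planted as a multi-copy family (``repeat_family_copies``
    identical copies spread over the genome) so that reads derived from it are
    genuine multi-mappers.  The trigger database holds a single 22-nt trigger
    miRNA ("miR2118"-like); its recognition sites are planted later, by
    :func:`plant_phased_loci`.

    Parameters
    ----------
    chromosome_length:
        Length of every chromosome (>= 100 kb).
    feature_counts:
        Features to plant per chromosome and class; defaults to
        ``DEFAULT_FEATURE_COUNTS``.
    """
    if chromosome_length < 100_000:
        raise ValueError("chromosome_length must be >= 100 kb")
    counts = dict(DEFAULT_FEATURE_COUNTS, **(feature_counts or {}))
    rng = np.random.default_rng(seed)

    for cls, n in counts.items():
        need = n * n_chromosomes * FEATURE_LENGTH_RANGES[cls][1]
        if need > 0.5 * chromosome_length * n_chromosomes:
            raise CapacityError(
                f"feature class {cls!r} requires ~{need} bp, exceeding half the genome"
            )

    genome = {
        f"chr{i + 1}": _random_dna(rng, chromosome_length) for i in range(n_chromosomes)
    }
    trees = {c: IntervalTree() for c in genome}
    features: dict[str, list[Feature]] = {c: [] for c in counts}
    serial = {c: 0 for c in counts}

    def plant(cls: str, chrom: str, length: int) -> Feature | None:
        s = _place_interval(rng, trees[chrom], chromosome_length, length)
        if s is None:
            return None
        trees[chrom].addi(s, s + length)
        serial[cls] += 1
        strand = "+" if rng.random() < 0.5 else "-"
        name = f"{cls.lower()}-{serial[cls]:03d}"
        feat = Feature(chrom, s, s + length, strand, name)
        features[cls].append(feat)
        return feat

    # multi-copy repeat family: identical sequence at several genomic positions
    repeat_db: dict[str, str] = {}
    family_copy_names: set[str] = set()
    if counts.get("repeat", 0) > 0 and repeat_family_copies > 1:
        fam_seq = _random_dna(rng, 400)
        chroms = sorted(genome)
        for _ in range(repeat_family_copies):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            s = _place_interval(rng, trees[chrom], chromosome_length, len(fam_seq))
            if s is None:
                raise CapacityError("feature class 'repeat' (multi-copy family): no space")
            trees[chrom].addi(s, s + len(fam_seq))
            g = genome[chrom]
            genome[chrom] = g[:s] + fam_seq + g[s + len(fam_seq):]
            serial["repeat"] += 1
            name = f"repeat-{serial['repeat']:03d}"
            family_copy_names.add(name)
            features["repeat"].append(Feature(chrom, s, s + len(fam_seq), "+", name))
        repeat_db["repfam-001"] = fam_seq

    for cls in sorted(counts):
        lo, hi = FEATURE_LENGTH_RANGES[cls]
        for chrom in sorted(genome):
            for _ in range(counts[cls]):
                length = int(rng.integers(lo, hi + 1))
                if plant(cls, chrom, length) is None:
                    raise CapacityError(f"feature class {cls!r}: no space on {chrom}")

    def extract(f: Feature) -> str:
        s = genome[f.chrom][f.start:f.end]
        return s if f.strand == "+" else revcomp(s)

    mirna_db = {f.name: extract(f) for f in features.get("miRNA", [])}
    mirna_families = {
        f.name: FAMILY_NAMES[i % len(FAMILY_NAMES)]
        for i, f in enumerate(features.get("miRNA", []))
    }
    ncrna_db = {f.name: extract(f) for f in features.get("ncRNA", [])}
    repeat_db.update({f.name: extract(f) for f in features.get("repeat", [])
                      if f.name not in family_copy_names})

    blacklist = []
    for chrom in sorted(genome):
        blacklist.append((chrom, 0, TELOMERE_PAD))
        blacklist.append((chrom, chromosome_length - TELOMERE_PAD, chromosome_length))

    trigger_db = {"miR2118": _random_dna(rng, TRIGGER_LEN)}
    return ReferenceBundle(
        genome=genome,
        feature_intervals=features,
        mirna_db=mirna_db,
        mirna_families=mirna_families,
        family_types=dict(FAMILY_TYPES),
        ncrna_db=ncrna_db,
        repeat_db=repeat_db,
        blacklist=blacklist,
        trigger_db=trigger_db,
    )


def _zipf_weights(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Zipf-like member weights (1-2 dominant members), randomly permuted."""
    w = (np.arange(1, n + 1, dtype=float)) ** (-exponent)
    w /= w.sum()
    return rng.permutation(w)


def plant_phased_loci(
    bundle: ReferenceBundle,
    n_loci: int = 60,
    *,
    member_range: tuple[int, int] = (3, 10),
    fold_range: tuple[float, float] = (5.0, 10.0),
    fold_fraction: float = 0.7,
    trigger_fraction: float = 0.6,
    trigger_offset_range: tuple[int, int] = (2, 452),
    both_strand_fraction: float = 0.925,
    zipf_exponent: float = 1.5,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> list[SyntheticLocusSpec]:
    """Plant phased loci into the bundle's genome and return their truth specs.

    Each locus is a run of in-register 21-nt members on a precursor strand
    (``orientation``), with duplex partners on the opposite strand offset by
    the 2-nt 3' overhang.  For loci carrying a trigger site, the reverse
    complement of the trigger miRNA is written into the genome in the 5' flank
    of the precursor and the phase register is anchored to the cleavage point
    between trigger positions 10 and 11, so realised trigger offsets are
    quantised to ``21*j - 10`` within ``trigger_offset_range``.

    Mutates ``bundle.genome`` (trigger sites) and returns the locus specs;
    loci never overlap features, the blacklist, or each other.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_loci == 0:
        return []
    if not (0 < fold_range[0] <= fold_range[1]):
        raise ValueError("fold_range must be positive and ordered")
    lo_m, hi_m = member_range
    if not (2 <= lo_m <= hi_m <= 91):
        raise ValueError("member_range must lie within [2, 91]")

    trees = bundle.occupancy()
    trigger_name = sorted(bundle.trigger_db)[0]
    trigger_seq = bundle.trigger_db[trigger_name]
    off_lo, off_hi = trigger_offset_range
    j0_lo = max(1, math.ceil((off_lo + 10) / PHASE))
    j0_hi = (off_hi + 10) // PHASE
    if j0_hi < j0_lo:
        raise ValueError("trigger_offset_range admits no cleavage-anchored offset")

    chroms = sorted(bundle.genome)
    loci: list[SyntheticLocusSpec] = []
    failures = 0
    while len(loci) < n_loci:
        if failures > 30:
            raise PlacementError(
                f"could only place {len(loci)} of {n_loci} loci without overlap"
            )
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        chrom_len = len(bundle.genome[chrom])
        strands_used = "both" if rng.random() < both_strand_fraction else "plus_only"
        orientation = "+" if strands_used == "plus_only" or rng.random() < 0.5 else "-"
        has_trigger = rng.random() < trigger_fraction
        n_members = int(rng.integers(lo_m, hi_m + 1))
        n_cycles = n_members + int(rng.integers(0, 3))
        j0 = int(rng.integers(j0_lo, j0_hi + 1)) if has_trigger else 0
        gap = PHASE * j0 - 10 if has_trigger else 0
        span = PHASE * n_cycles
        region_len = (TRIGGER_LEN + gap if has_trigger else 0) + span

        s = _place_interval(
            rng, trees[chrom], chrom_len, region_len, margin=40,
        )
        if s is None:
            failures += 1
            continue
        failures = 0

        if orientation == "+":
            site_start = s if has_trigger else None
            first = s + (CLEAVAGE_OFFSET + PHASE * j0 if has_trigger else 0)
            register = first % PHASE
        else:
            # precursor on the minus strand: site sits to the right of the locus;
            # `first` is the leftmost coordinate of the rightmost (sense) member
            site_start = s + region_len - TRIGGER_LEN if has_trigger else None
            if has_trigger:
                first = site_start - PHASE * j0 - 11
            else:
                first = s + span - PHASE
            register = (first + 2) % PHASE

        if has_trigger:
            g = bundle.genome[chrom]
            planted = revcomp(trigger_seq) if orientation == "+" else trigger_seq
            bundle.genome[chrom] = (
                g[:site_start] + planted + g[site_start + TRIGGER_LEN:]
            )

        cycles = {0, n_cycles - 1}
        free = [j for j in range(1, n_cycles - 1)]
        extra = n_members - len(cycles)
        if extra > 0:
            cycles.update(rng.choice(free, size=extra, replace=False).tolist())
        cycle_list = sorted(cycles)

        weights = _zipf_weights(rng, n_members, zipf_exponent)
        members: list[MemberSpec] = []
        sense = orientation
        anti = "-" if sense == "+" else "+"
        strands = []
        for idx, j in enumerate(cycle_list):
            if strands_used == "plus_only":
                strands.append("+")
            elif idx == 0:
                strands.append(sense)  # first duplex after cleavage: sense read
            else:
                strands.append(sense if rng.random() < 0.65 else anti)
        if strands_used == "both" and anti not in strands and len(strands) > 1:
            strands[int(rng.integers(1, len(strands)))] = anti

        genome_seq = bundle.genome[chrom]
        for idx, j in enumerate(cycle_list):
            if orientation == "+":
                pos = first + PHASE * j
                if strands[idx] == "-":
                    pos -= 2  # duplex partner: 2-nt 3' overhang
            else:
                pos = first - PHASE * j
                if strands[idx] == "+":
                    pos += 2
            seq = genome_seq[pos:pos + PHASE]
            if strands[idx] == "-":
                seq = revcomp(seq)
            members.append(MemberSpec(strands[idx], pos, float(weights[idx]), seq))

        start = min(m.position for m in members)
        end = max(m.position for m in members) + PHASE
        trigger_offset = None
        if has_trigger:
            site_end = site_start + TRIGGER_LEN
            trigger_offset = start - site_end if orientation == "+" else site_start - end
        if rng.random() < fold_fraction:
            fold = float(rng.uniform(fold_range[0], fold_range[1]))
        else:
            fold = 1.0
        trees[chrom].addi(s - 40, s + region_len + 40)
        loci.append(
            SyntheticLocusSpec(
                locus_id=f"TL{len(loci) + 1:04d}",
                chrom=chrom,
                start=start,
                end=end,
                register=register,
                orientation=orientation,
                strands_used=strands_used,
                n_members=n_members,
                members=members,
                fold_ratio=fold,
                weight=float(rng.lognormal(0.0, 0.5)),
                trigger_name=trigger_name if has_trigger else None,
                trigger_offset=trigger_offset,
                trigger_site_start=site_start,
            )
        )
    return loci


DEFAULT_CLASS_MIX = {
    "phased": 0.33,
    "mirna": 0.22,
    "ncrna": 0.08,
    "repeat": 0.12,
    "gene": 0.14,
    "noise": 0.08,
    "unmapped": 0.03,
}


class _Species(NamedTuple):
    species_id: str
    cls: str
    sequence: str
    wa: float
    wb: float


def _background_species(
    bundle: ReferenceBundle,
    loci: list[SyntheticLocusSpec],
    rng: np.random.Generator,
    mix: dict[str, float],
    dominant_family: str,
    dominant_weight: float,
    n_species: dict[str, int],
) -> list[_Species]:
    species: list[_Species] = []

    # miRNA reads: mature database sequences; one family dominates abundance
    fam_of = bundle.mirna_families
    dom_members = [m for m in sorted(bundle.mirna_db) if fam_of[m] == dominant_family]
    other = [m for m in sorted(bundle.mirna_db) if fam_of[m] != dominant_family]
    if dom_members and other:
        per_dom = dominant_weight / len(dom_members)
        per_other = (1.0 - dominant_weight) / len(other)
        fam_w = {m: per_dom for m in dom_members}
        fam_w.update({m: per_other for m in other})
    else:
        fam_w = {m: 1.0 / max(1, len(bundle.mirna_db)) for m in sorted(bundle.mirna_db)}
    for m in sorted(bundle.mirna_db):
        w = mix["mirna"] * fam_w[m]
        species.append(_Species(f"mir:{m}", "mirna", bundle.mirna_db[m], w, w))

    # keep random noise out of the planted precursor regions (phased span,
    # trigger site and gap) plus a margin: 21-mers inside an active precursor
    # would be processed in phase, not be unphased background
    margin = 250
    locus_trees: dict[str, IntervalTree] = {c: IntervalTree() for c in bundle.genome}
    for lc in loci:
        lo = min([lc.start] + ([lc.trigger_site_start] if lc.trigger_site_start is not None else []))
        hi = max([lc.end] + ([lc.trigger_site_start + TRIGGER_LEN]
                             if lc.trigger_site_start is not None else []))
        locus_trees[lc.chrom].addi(lo - margin, hi + margin)

    def windows(cls: str, sources: list[tuple[str, str]], n: int,
                lengths: tuple[int, int]) -> None:
        if not sources or n == 0:
            return
        raw = rng.lognormal(0.0, 1.0, size=n)
        raw /= raw.sum()
        for i in range(n):
            sid, seq_src = sources[int(rng.integers(0, len(sources)))]
            length = int(rng.integers(lengths[0], lengths[1] + 1))
            if len(seq_src) < length:
                length = len(seq_src)
            off = int(rng.integers(0, len(seq_src) - length + 1))
            seq = seq_src[off:off + length]
            if rng.random() < 0.5:
                seq = revcomp(seq)
            w = mix[cls] * float(raw[i])
            species.append(_Species(f"{cls}:{i:05d}:{sid}", cls, seq, w, w))

    windows("ncrna", [(k, v) for k, v in sorted(bundle.ncrna_db.items())],
            n_species["ncrna"], (20, 26))
    windows("repeat", [(k, v) for k, v in sorted(bundle.repeat_db.items())],
            n_species["repeat"], (24, 24))
    gene_feats = [
        (f.name, bundle.genome[f.chrom][f.start:f.end])
        for cls in ("CDS", "intron", "UTR")
        for f in bundle.feature_intervals.get(cls, [])
    ]
    windows("gene", gene_feats, n_species["gene"], (18, 28))

    # unphased 21-nt noise from anywhere in the genome except planted loci
    chroms = sorted(bundle.genome)
    raw = rng.lognormal(0.0, 1.0, size=n_species["noise"])
    raw /= raw.sum()
    placed = 0
    while placed < n_species["noise"]:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        pos = int(rng.integers(0, len(bundle.genome[chrom]) - PHASE))
        if locus_trees[chrom].overlap(pos, pos + PHASE):
            continue
        seq = bundle.genome[chrom][pos:pos + PHASE]
        if rng.random() < 0.5:
            seq = revcomp(seq)
        w = mix["noise"] * float(raw[placed])
        species.append(_Species(f"noise:{placed:05d}", "noise", seq, w, w))
        placed += 1

    raw = rng.lognormal(0.0, 1.0, size=n_species["unmapped"])
    raw /= raw.sum()
    for i in range(n_species["unmapped"]):
        seq = _random_dna(rng, PHASE)
        w = mix["unmapped"] * float(raw[i])
        species.append(_Species(f"unmapped:{i:05d}", "unmapped", seq, w, w))
    return species


def simulate_libraries(
    loci: list[SyntheticLocusSpec],
    bundle: ReferenceBundle,
    *,
    library_sizes: tuple[int, int] = (50_000, 50_000),
    class_mix: dict[str, float] | None = None,
    error_rate: float = 0.001,
    adapter: str | None = DEFAULT_ADAPTER,
    read_length: int = 36,
    dominant_family: str = "miR159",
    dominant_weight: float = 0.64,
    n_species: dict[str, int] | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]], SyntheticTruth]:
    """Draw two read libraries from the planted loci plus background classes.

    Per-library counts are a single multinomial draw of exactly
    ``library_sizes`` reads over all species, so read conservation is exact.
    Phased-locus species keep their planted A/B abundance ratio in the
    per-library probability vectors (background classes absorb the
    compositional compensation, as RPM normalisation does on real data).
    Sequencing errors are i.i.d. substitutions at ``error_rate`` per base.

    Returns ``(reads_A, reads_B, truth)`` where reads are ``(id, seq, qual)``
    triples; if *outdir* is given also writes ``library_A.fastq``,
    ``library_B.fastq`` and the truth TSVs there.
    """
    if not (0.0 <= error_rate <= 0.1):
        raise ValueError("error_rate must be within [0, 0.1]")
    if min(library_sizes) <= 0:
        raise ValueError("library sizes must be positive")
    rng = np.random.default_rng(seed)
    mix = dict(DEFAULT_CLASS_MIX, **(class_mix or {}))
    if loci:
        total = sum(mix.values())
    else:
        mix = {k: v for k, v in mix.items() if k != "phased"}
        total = sum(mix.values())
    mix = {k: v / total for k, v in mix.items()}
    n_species = dict(
        {"ncrna": 150, "repeat": 300, "gene": 350, "noise": 1500, "unmapped": 120},
        **(n_species or {}),
    )

    species: list[_Species] = []
    if loci:
        raw_a, raw_b, entries = [], [], []
        for lc in loci:
            f = lc.fold_ratio
            fa, fb = 2.0 * f / (1.0 + f), 2.0 / (1.0 + f)
            for mi, m in enumerate(lc.members):
                w = lc.weight * m.weight
                entries.append((f"phased:{lc.locus_id}:{mi}", m.sequence))
                raw_a.append(w * fa)
                raw_b.append(w * fb)
        sa, sb = sum(raw_a), sum(raw_b)
        scale = 2.0 * mix["phased"] / (sa + sb)
        phased_a, phased_b = scale * sa, scale * sb
        bg_scale_a = (1.0 - phased_a) / (1.0 - mix["phased"])
        bg_scale_b = (1.0 - phased_b) / (1.0 - mix["phased"])
        for (sid, seq), wa, wb in zip(entries, raw_a, raw_b):
            species.append(_Species(sid, "phased", seq, scale * wa, scale * wb))
    else:
        bg_scale_a = bg_scale_b = 1.0

    bg = _background_species(
        bundle, loci, rng, mix, dominant_family, dominant_weight, n_species
    )
    for sp in bg:
        species.append(sp._replace(wa=sp.wa * bg_scale_a, wb=sp.wb * bg_scale_b))

    pa = np.array([sp.wa for sp in species])
    pb = np.array([sp.wb for sp in species])
    counts_a = rng.multinomial(library_sizes[0], pa / pa.sum())
    counts_b = rng.multinomial(library_sizes[1], pb / pb.sum())

    def emit(lib: str, counts: np.ndarray) -> list[tuple[str, str, str]]:
        reads: list[tuple[str, str, str]] = []
        serial = 0
        for sp, c in zip(species, counts):
            if c == 0:
                continue
            insert = sp.sequence
            base = insert + (adapter or "")
            base = base[:read_length] if adapter else base
            n_err = rng.binomial(len(base), error_rate, size=int(c))
            for k in n_err:
                serial += 1
                seq = base
                if k > 0:
                    arr = list(seq)
                    for p in rng.choice(len(arr), size=int(k), replace=False):
                        arr[p] = DNA[(DNA.index(arr[p]) + int(rng.integers(1, 4))) % 4]
                    seq = "".join(arr)
                reads.append((f"{lib}:{serial:07d}:{sp.species_id}", seq, "I" * len(seq)))
        return reads

    reads_a = emit("A", counts_a)
    reads_b = emit("B", counts_b)

    member_rows, bg_rows = [], []
    by_id = {sp.species_id: i for i, sp in enumerate(species)}
    for lc in loci:
        for mi, m in enumerate(lc.members):
            i = by_id[f"phased:{lc.locus_id}:{mi}"]
            member_rows.append(
                dict(locus_id=lc.locus_id, member_index=mi, strand=m.strand,
                     position=m.position, sequence=m.sequence,
                     count_A=int(counts_a[i]), count_B=int(counts_b[i]))
            )
    for sp in bg:
        i = by_id[sp.species_id]
        bg_rows.append(
            dict(species_id=sp.species_id, cls=sp.cls, sequence=sp.sequence,
                 count_A=int(counts_a[i]), count_B=int(counts_b[i]))
        )
    truth = SyntheticTruth(
        loci=loci,
        member_counts=pd.DataFrame(
            member_rows,
            columns=["locus_id", "member_index", "strand", "position", "sequence",
                     "count_A", "count_B"],
        ),
        background=pd.DataFrame(
            bg_rows, columns=["species_id", "cls", "sequence", "count_A", "count_B"]
        ),
        seed=seed,
        library_sizes=tuple(library_sizes),
    )
    if outdir is not None:
        from phasekit import io as pio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pio.write_fastq(outdir / "library_A.fastq", reads_a)
        pio.write_fastq(outdir / "library_B.fastq", reads_b)
        write_truth(truth, outdir)
    return reads_a, reads_b, truth


def write_truth(truth: SyntheticTruth, outdir: str | Path) -> None:
    """Write truth tables (loci, members, background) as TSV."""
    outdir = Path(outdir)
    rows = []
    realized = truth.member_counts.groupby("locus_id")[["count_A", "count_B"]].sum()
    for lc in truth.loci:
        ca, cb = (realized.loc[lc.locus_id] if lc.locus_id in realized.index else (0, 0))
        rows.append(
            dict(locus_id=lc.locus_id, chrom=lc.chrom, start=lc.start, end=lc.end,
                 register=lc.register, orientation=lc.orientation,
                 strands_used=lc.strands_used, n_members=lc.n_members,
                 fold_ratio=lc.fold_ratio,
                 trigger_name=lc.trigger_name if lc.trigger_name else "",
                 trigger_offset="" if lc.trigger_offset is None else lc.trigger_offset,
                 trigger_site_start=(
                     "" if lc.trigger_site_start is None else lc.trigger_site_start),
                 count_A=int(ca), count_B=int(cb))
        )
    pd.DataFrame(rows).to_csv(outdir / "truth_loci.tsv", sep="\t", index=False)
    truth.member_counts.to_csv(outdir / "truth_members.tsv", sep="\t", index=False)
    truth.background.to_csv(outdir / "truth_background.tsv", sep="\t", index=False)


def write_bundle(bundle: ReferenceBundle, outdir: str | Path) -> None:
    """Write the bundle as genome FASTA, features GFF3, database FASTAs, BED."""
    from phasekit import io as pio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pio.write_fasta(outdir / "genome.fasta", sorted(bundle.genome.items()))
    with open(outdir / "features.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for cls in sorted(bundle.feature_intervals):
            for f in sorted(bundle.feature_intervals[cls]):
                attrs = f"ID={f.name};feature_class={cls}"
                if cls == "miRNA":
                    attrs += f";family={bundle.mirna_families[f.name]}"
                fh.write(
                    f"{f.chrom}\tphasekit_sim\t{cls}\t{f.start + 1}\t{f.end}\t.\t"
                    f"{f.strand}\t.\t{attrs}\n"
                )
    pio.write_fasta(
        outdir / "mirna.fasta",
        [(f"{k} family={bundle.mirna_families[k]}"
          f" type={bundle.family_types.get(bundle.mirna_families[k], 'canonical')}", v)
         for k, v in sorted(bundle.mirna_db.items())],
    )
    pio.write_fasta(outdir / "ncrna.fasta", sorted(bundle.ncrna_db.items()))
    pio.write_fasta(outdir / "repeat.fasta", sorted(bundle.repeat_db.items()))
    pio.write_fasta(outdir / "triggers.fasta", sorted(bundle.trigger_db.items()))
    with open(outdir / "blacklist.bed", "w") as fh:
        for chrom, s, e in sorted(bundle.blacklist):
            fh.write(f"{chrom}\t{s}\t{e}\ttelomere\n")


def write_config_echo(config: dict, path: str | Path) -> None:
    """Echo the effective simulation configuration as YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
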