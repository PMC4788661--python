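"""End-to-end pipeline: preprocess -> annotate -> phasing -> differential.

The stages communicate through TSV/BED files with documented schemas, so each
can be re-run independently; a :class:`RunReport` records per-stage record
counts, the effective parameters, and wall-clock times.  Given the same
configuration and seed, repeated runs produce byte-identical tables.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

import phasekit
from phasekit import io as pio
from phasekit.annotate import MatchParams, class_composition, classify_hierarchical
from phasekit.diffexpr import (
    class_enrichment,
    mirna_family_profile,
    unit_differential,
)
from phasekit.phasing import (
    PhasedLocus,
    detect_loci,
    fill_locus_counts,
    postfilter_loci,
    recruit_members,
    scan_trigger_site,
)
from phasekit.preprocess import SmallRNARead, collapse, normalize, trim_reads
from phasekit.seq import PHASE


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 42,
    "simulate": {
        "n_chromosomes": 2,
        "chromosome_length": 500_000,
        "n_loci": 60,
        "library_size": 50_000,
        "error_rate": 0.001,
        "member_range": [3, 10],
        "fold_range": [5.0, 10.0],
        "fold_fraction": 0.7,
        "trigger_fraction": 0.6,
        "both_strand_fraction": 0.925,
    },
    "preprocess": {
        "adapter": "TGGAATTCTCGGGTGCCAAGG",
        "min_quality": 20.0,
        "min_overlap": 5,
        "min_len": 18,
        "max_len": 28,
    },
    "match": {
        "min_identity_frac": 0.85,
        "min_coverage_frac": 0.85,
        "min_match_len": 16,
    },
    "phasing": {
        "cycles": 11,
        "step": 21,
        "alpha": 1e-4,
        "min_members": 3,
        "max_genome_hits": 10,
        "flank": 500,
        "trigger_threshold": 4.5,
    },
    "differential": {
        "alpha": 1e-3,
        "fold": 5.0,
        "pseudocount": 0.5,
    },
}


def default_config() -> dict[str, Any]:
    return json.loads(json.dumps(DEFAULT_CONFIG))


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML config, overlaying it on the defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    for section, values in user.items():
        if isinstance(values, dict) and isinstance(cfg.get(section), dict):
            cfg[section].update(values)
        else:
            cfg[section] = values
    return cfg


@dataclass
class RunReport:
    version: str = phasekit.__version__
    parameters: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, *, seconds: float, **counts: Any) -> None:
        self.stages[stage] = {"wall_seconds": round(seconds, 3), **counts}

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def simulate(config: dict[str, Any], outdir: str | Path) -> Path:
    """Generate the synthetic bundle, libraries and truth under ``outdir/sim``."""
    from phasekit import synthgen

    sim = config["simulate"]
    seed = int(config.get("seed", 0))
    simdir = Path(outdir) / "sim"
    bundle = synthgen.generate_reference(
        chromosome_length=int(sim["chromosome_length"]),
        n_chromosomes=int(sim["n_chromosomes"]),
        seed=seed,
    )
    loci = synthgen.plant_phased_loci(
        bundle,
        n_loci=int(sim["n_loci"]),
        member_range=tuple(sim["member_range"]),
        fold_range=tuple(sim["fold_range"]),
        fold_fraction=float(sim["fold_fraction"]),
        trigger_fraction=float(sim["trigger_fraction"]),
        both_strand_fraction=float(sim["both_strand_fraction"]),
        seed=seed + 1,
    )
    synthgen.simulate_libraries(
        loci,
        bundle,
        library_sizes=(int(sim["library_size"]), int(sim["library_size"])),
        error_rate=float(sim["error_rate"]),
        adapter=config["preprocess"]["adapter"],
        seed=seed + 2,
        outdir=simdir,
    )
    synthgen.write_bundle(bundle, simdir / "bundle")
    synthgen.write_config_echo(config, simdir / "config_echo.yaml")
    return simdir


def run_pipeline(
    config: dict[str, Any],
    outdir: str | Path,
    library_a: str | Path,
    library_b: str | Path,
    bundle_dir: str | Path,
) -> RunReport:
    """Execute all pipeline stages and write the outputs under ``outdir``.

    Raises :class:`StageError` naming the failing stage on any error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(parameters=json.loads(json.dumps(config)))
    pp, ph, dd = config["preprocess"], config["phasing"], config["differential"]
    params = MatchParams(**config["match"])

    # --- preprocess ---------------------------------------------------------
    t0 = time.monotonic()
    try:
        reads: list[SmallRNARead] = []
        n_in = {"A": 0, "B": 0}
        for lib, path in (("A", library_a), ("B", library_b)):
            for rid, seq, qual in pio.read_reads(path):
                n_in[lib] += 1
                reads.append(SmallRNARead(rid, seq, qual, lib))
        trimmed, tstats = trim_reads(
            reads, pp["adapter"], min_quality=float(pp["min_quality"]),
            min_overlap=int(pp["min_overlap"]),
        )
        distincts, discarded = collapse(
            trimmed, min_len=int(pp["min_len"]), max_len=int(pp["max_len"])
        )
        distincts = normalize(distincts)
        pio.write_tsv(distincts, outdir / "distincts.tsv")
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(f"stage 'preprocess' failed: {exc}") from exc
    report.record(
        "preprocess", seconds=time.monotonic() - t0,
        reads_in=n_in, reads_kept=tstats.kept,
        dropped_quality=tstats.dropped_quality, dropped_empty=tstats.dropped_empty,
        size_discarded=discarded, n_distinct=int(len(distincts)),
    )

    # --- annotate -----------------------------------------------------------
    t0 = time.monotonic()
    try:
        bundle = pio.load_bundle(bundle_dir)
        distincts, alignments = classify_hierarchical(distincts, bundle, params)
        pio.write_tsv(distincts, outdir / "distincts.tsv")
        aln_rows = [
            dict(sequence=a.sequence, chrom=a.chrom, start=a.start, end=a.end,
                 strand=a.strand, mismatches=a.mismatches)
            for seq in sorted(alignments)
            for a in alignments[seq]
        ]
        pio.write_tsv(
            pd.DataFrame(aln_rows, columns=["sequence", "chrom", "start", "end",
                                            "strand", "mismatches"]),
            outdir / "alignments.tsv",
        )
        composition = (
            class_composition(distincts).to_dict() if len(distincts) else {}
        )
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'annotate' failed: {exc}") from exc
    n_mapped = int((distincts["genome_hits"] > 0).sum()) if len(distincts) else 0
    report.record(
        "annotate", seconds=time.monotonic() - t0,
        n_distinct=int(len(distincts)), n_mapped=n_mapped,
        class_composition={k: round(v, 4) for k, v in composition.items()},
    )

    # --- phasing ------------------------------------------------------------
    t0 = time.monotonic()
    try:
        all_21 = [
            a for seq in sorted(alignments) for a in alignments[seq]
            if a.end - a.start == PHASE
        ]
        initial = detect_loci(
            all_21, cycles=int(ph["cycles"]), step=int(ph["step"]),
            alpha=float(ph["alpha"]), min_members=int(ph["min_members"]),
        )
        hits = dict(zip(distincts["sequence"], distincts["genome_hits"]))
        loci, n_removed = postfilter_loci(
            initial, bundle.blacklist, hits,
            max_genome_hits=int(ph["max_genome_hits"]),
            min_members=int(ph["min_members"]),
        )
        core = {seq for lc in loci for seq in lc.core_members}
        candidates = [
            s for s, L in zip(distincts["sequence"], distincts["length"])
            if L == PHASE and s not in core
        ]
        recruited = recruit_members(loci, candidates)
        fill_locus_counts(loci, distincts)
        for lc in loci:
            lc.trigger_hit = scan_trigger_site(
                lc, bundle.genome, bundle.trigger_db,
                flank=int(ph["flank"]), threshold=float(ph["trigger_threshold"]),
            )
        _write_loci(loci, recruited, outdir)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'phasing' failed: {exc}") from exc
    report.record(
        "phasing", seconds=time.monotonic() - t0,
        loci_initial=len(initial), loci_removed=n_removed, loci_final=len(loci),
        n_recruited=int(len(recruited)),
        n_with_trigger=sum(1 for lc in loci if lc.trigger_hit is not None),
    )

    # --- differential -------------------------------------------------------
    t0 = time.monotonic()
    try:
        totals = {
            "A": max(1, int(distincts["count_A"].sum())),
            "B": max(1, int(distincts["count_B"].sum())),
        }
        seq_units = distincts.rename(columns={"sequence": "unit_id"})[
            ["unit_id", "count_A", "count_B", "rpm_A", "rpm_B"]
        ]
        diff_seq = unit_differential(
            seq_units, totals, alpha=float(dd["alpha"]), fold=float(dd["fold"]),
            pseudocount=float(dd["pseudocount"]),
        )
        pio.write_tsv(diff_seq, outdir / "diff_sequences.tsv")

        locus_units = pd.DataFrame(
            [dict(unit_id=lc.id, count_A=lc.count_A, count_B=lc.count_B,
                  rpm_A=lc.rpm_A, rpm_B=lc.rpm_B) for lc in loci],
            columns=["unit_id", "count_A", "count_B", "rpm_A", "rpm_B"],
        )
        diff_loci = unit_differential(
            locus_units, totals, alpha=float(dd["alpha"]), fold=float(dd["fold"]),
            pseudocount=float(dd["pseudocount"]),
        )
        pio.write_tsv(diff_loci, outdir / "diff_loci.tsv")

        if len(distincts):
            over = diff_seq[(diff_seq["fold5_flag"]) & (diff_seq["category"] == "over_A")]
            over_seqs = set(over["unit_id"])
            sub = distincts[distincts["sequence"].isin(over_seqs)]
            subset = sub["annotation_class"].value_counts().to_dict()
            background = distincts["annotation_class"].value_counts().to_dict()
            enrich = class_enrichment(subset, background, alpha=float(dd["alpha"]))
        else:
            enrich = pd.DataFrame(
                columns=["annotation_class", "subset_n", "subset_frac", "background_n",
                         "background_frac", "G", "p_value", "direction"]
            )
        pio.write_tsv(enrich, outdir / "class_enrichment.tsv")

        families = mirna_family_profile(distincts, bundle, loci)
        pio.write_tsv(families, outdir / "mirna_families.tsv")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'differential' failed: {exc}") from exc
    n_sig = int((diff_loci["category"] != "ns").sum()) if len(diff_loci) else 0
    n_fold5 = int(diff_loci["fold5_flag"].sum()) if len(diff_loci) else 0
    report.record(
        "differential", seconds=time.monotonic() - t0,
        loci_tested=len(diff_loci), loci_significant=n_sig, loci_fold5=n_fold5,
        sequences_tested=len(diff_seq), n_families=len(families),
    )

    report.write(outdir / "run_report.json")
    return report


LOCI_COLUMNS = [
    "locus_id", "chrom", "start", "end", "register", "n_core", "n_recruited_pass1",
    "n_recruited_pass2", "n_distinct", "both_strands", "min_p", "count_A", "count_B",
    "rpm_A", "rpm_B", "trigger_name", "trigger_position", "trigger_strand",
    "trigger_score", "trigger_distance", "trigger_side",
]


def _write_loci(loci: list[PhasedLocus], recruited: pd.DataFrame, outdir: Path) -> None:
    rows = []
    for lc in loci:
        th = lc.trigger_hit
        rows.append(
            dict(locus_id=lc.id, chrom=lc.chrom, start=lc.start, end=lc.end,
                 register=lc.register, n_core=len(lc.core_members),
                 n_recruited_pass1=len(lc.recruited_pass1),
                 n_recruited_pass2=len(lc.recruited_pass2),
                 n_distinct=lc.n_distinct, both_strands=lc.both_strands,
                 min_p=lc.min_p, count_A=lc.count_A, count_B=lc.count_B,
                 rpm_A=lc.rpm_A, rpm_B=lc.rpm_B,
                 trigger_name=th.trigger_name if th else "",
                 trigger_position=th.position if th else "",
                 trigger_strand=th.strand if th else "",
                 trigger_score=th.score if th else "",
                 trigger_distance=th.distance_to_locus_end if th else "",
                 trigger_side=th.side if th else "")
        )
    pio.write_tsv(pd.DataFrame(rows, columns=LOCI_COLUMNS), outdir / "loci.tsv")
    with open(outdir / "loci.bed", "w") as fh:
        for lc in sorted(loci, key=lambda x: (x.chrom, x.start, x.end)):
            fh.write(f"{lc.chrom}\t{lc.start}\t{lc.end}\t{lc.id}\t0\t.\n")
    member_rows = [
        dict(locus_id=lc.id, sequence=seq, origin="core", ambiguous=False)
        for lc in loci for seq in lc.core_members
    ]
    amb = set()
    if len(recruited):
        dup = recruited.groupby(["sequence", "recruitment_pass"])["locus_id"].nunique()
        amb = {s for (s, _), n in dup.items() if n > 1}
        for rec in recruited.itertuples(index=False):
            member_rows.append(
                dict(locus_id=rec.locus_id, sequence=rec.sequence,
                     origin=f"recruited{rec.recruitment_pass}",
                     ambiguous=rec.sequence in amb)
            )
    pio.write_tsv(
        pd.DataFrame(member_rows, columns=["locus_id", "sequence", "origin",
                                           "ambiguous"]),
        outdir / "members.tsv",
    )


def validate_outputs(outdir: str | Path) -> list[str]:
    """Check output files for schema and cross-file consistency violations."""
    outdir = Path(outdir)
    violations: list[str] = []

    bed = outdir / "loci.bed"
    if bed.exists():
        last: dict[str, int] = {}
        with open(bed) as fh:
            for ln, line in enumerate(fh, 1):
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    violations.append(f"loci.bed:{ln}: fewer than 3 columns")
                    continue
                try:
                    start, end = int(parts[1]), int(parts[2])
                except ValueError:
                    violations.append(f"loci.bed:{ln}: non-integer coordinates")
                    continue
                if start < 0 or end <= start:
                    violations.append(f"loci.bed:{ln}: invalid interval {start}-{end}")
                if parts[0] in last and start < last[parts[0]]:
                    violations.append(f"loci.bed:{ln}: not sorted within {parts[0]}")
                last[parts[0]] = start

    schemas = {
        "loci.tsv": LOCI_COLUMNS,
        "members.tsv": ["locus_id", "sequence", "origin", "ambiguous"],
        "distincts.tsv": ["sequence", "length", "count_A", "count_B"],
    }
    tables: dict[str, pd.DataFrame] = {}
    for fname, cols in schemas.items():
        path = outdir / fname
        if not path.exists():
            continue
        df = pio.read_tsv(path)
        tables[fname] = df
        missing = [c for c in cols if c not in df.columns]
        if missing:
            violations.append(f"{fname}: missing columns {missing}")

    if "members.tsv" in tables and "loci.tsv" in tables:
        known = set(tables["loci.tsv"]["locus_id"])
        for i, lid in enumerate(tables["members.tsv"]["locus_id"], 2):
            if lid not in known:
                violations.append(f"members.tsv:{i}: unknown locus_id {lid!r}")
    if "members.tsv" in tables and "distincts.tsv" in tables:
        known = set(tables["distincts.tsv"]["sequence"])
        for i, seq in enumerate(tables["members.tsv"]["sequence"], 2):
            if seq not in known:
                violations.append(f"members.tsv:{i}: sequence absent from distincts")

    for gff in outdir.glob("**/features.gff3"):
        with open(gff) as fh:
            for ln, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) != 9:
                    violations.append(f"{gff.name}:{ln}: expected 9 columns")
                    continue
                try:
                    s, e = int(cols[3]), int(cols[4])
                except ValueError:
                    violations.append(f"{gff.name}:{ln}: non-integer coordinates")
                    continue
                if s < 1 or e < s:
                    violations.append(f"{gff.name}:{ln}: invalid 1-based interval")
    return violations


def full_run(config: dict[str, Any], outdir: str | Path) -> RunReport:
    """Simulate (when configured) and run the pipeline end to end."""
    outdir = Path(outdir)
    if "libraries" in config:
        lib_a = config["libraries"]["A"]
        lib_b = config["libraries"]["B"]
        bundle_dir = config["libraries"]["bundle"]
    else:
        simdir = simulate(config, outdir)
        lib_a = simdir / "library_A.fastq"
        lib_b = simdir / "library_B.fastq"
        bundle_dir = simdir / "bundle"
    return run_pipeline(config, outdir, lib_a, lib_b, bundle_dir)
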