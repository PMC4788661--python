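"""File I/O helpers: FASTA/FASTQ (via Biopython), BED, GFF3 and TSV tables."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from phasekit.synthgen import Feature, ReferenceBundle


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ``{id: sequence}`` dict (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield ``(id, sequence, quality)`` from a FASTQ file."""
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield title, seq.upper(), qual


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_reads(path: str | Path) -> Iterator[tuple[str, str, str | None]]:
    """Read FASTQ or FASTA (by extension); FASTA reads have no qualities."""
    path = Path(path)
    if path.suffix.lower() in {".fa", ".fasta", ".fna"}:
        for rec in SeqIO.parse(str(path), "fasta"):
            yield rec.id, str(rec.seq).upper(), None
    else:
        for rid, seq, qual in read_fastq(path):
            yield rid, seq, qual


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read the first three BED columns (0-based half-open intervals)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED line has fewer than 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{ln}: BED end <= start")
            out.append((chrom, start, end))
    return out


def read_gff3_features(path: str | Path) -> dict[str, list[Feature]]:
    """Read GFF3 into per-type :class:`Feature` lists (0-based half-open)."""
    feats: dict[str, list[Feature]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line in {path}: {line!r}")
            chrom, _, ftype, start, end, _, strand, _, attrs = cols
            name = ftype
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    name = kv[3:]
            feats.setdefault(ftype, []).append(
                Feature(chrom, int(start) - 1, int(end), strand, name)
            )
    return feats


def _parse_fasta_meta(path: Path) -> tuple[dict[str, str], dict[str, str], dict[str, str]]:
    """Parse a miRNA FASTA whose descriptions carry family/type metadata."""
    seqs, families, ftypes = {}, {}, {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
        fam, ftype = rec.id, "canonical"
        for token in rec.description.split():
            if token.startswith("family="):
                fam = token[7:]
            elif token.startswith("type="):
                ftype = token[5:]
        families[rec.id] = fam
        ftypes[fam] = ftype
    return seqs, families, ftypes


def load_bundle(bundle_dir: str | Path) -> ReferenceBundle:
    """Load a reference bundle from the directory layout written by
    :func:`phasekit.synthgen.write_bundle`."""
    d = Path(bundle_dir)
    mirna_db, families, ftypes = _parse_fasta_meta(d / "mirna.fasta")
    return ReferenceBundle(
        genome=read_fasta(d / "genome.fasta"),
        feature_intervals=read_gff3_features(d / "features.gff3"),
        mirna_db=mirna_db,
        mirna_families=families,
        family_types=ftypes,
        ncrna_db=read_fasta(d / "ncrna.fasta"),
        repeat_db=read_fasta(d / "repeat.fasta"),
        blacklist=read_bed(d / "blacklist.bed"),
        trigger_db=read_fasta(d / "triggers.fasta"),
    )


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
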