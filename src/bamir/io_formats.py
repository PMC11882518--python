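"""Readers and writers for the external formats the pipeline touches.

Coordinate convention: every interval held in memory is 0-based half-open.
GTF (1-based inclusive) is converted at the parse boundary and converted
back on write, so a round trip reproduces the original integers.

Sequences are normalised to the RNA alphabet (uppercase, T→U) on read;
strandedness is resolved when sequence is extracted, not at parse time.

Tabular formats are tab-separated UTF-8 with a header row; lines starting
with ``#`` are comments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

_RNA_ALPHABET = frozenset("ACGU")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def normalise_rna(sequence: str) -> str:
    """Uppercase a nucleotide string and transcribe T to U.

    Raises :class:`FormatError` on characters outside {A,C,G,U,T}.
    """
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - _RNA_ALPHABET
    if bad:
        raise FormatError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return seq


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SequenceRecord:
    """A named RNA sequence (inputs in DNA alphabet are transcribed on read)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - _RNA_ALPHABET
        if bad:
            raise ValueError(f"record {self.id!r} not RNA after normalisation: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class StructureRecord:
    """An RNA sequence with dot-bracket secondary structure and its MFE."""

    id: str
    sequence: str
    dot_bracket: str
    mfe_kcal_mol: float

    def __post_init__(self) -> None:
        if len(self.dot_bracket) != len(self.sequence):
            raise ValueError(
                f"{self.id!r}: structure length {len(self.dot_bracket)} != "
                f"sequence length {len(self.sequence)}"
            )
        depth = 0
        for ch in self.dot_bracket:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise ValueError(f"{self.id!r}: unbalanced brackets")
            elif ch != ".":
                raise ValueError(f"{self.id!r}: illegal structure character {ch!r}")
        if depth != 0:
            raise ValueError(f"{self.id!r}: unbalanced brackets")


def parse_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into normalised RNA records.

    One record per header, uppercase, T→U. Empty files and duplicate ids
    are format errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        try:
            records.append(SequenceRecord(rec.id, normalise_rna(str(rec.seq))))
        except (FormatError, ValueError) as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def parse_structure_file(path: str | Path) -> list[StructureRecord]:
    """Read an RNAfold-style structure file.

    Three lines per record: ``>id``, the sequence, then the dot-bracket
    with the MFE appended in parentheses, e.g. ``(((...))) (-1.20)``.
    """
    lines = [ln.rstrip("\n") for ln in Path(path).read_text(encoding="utf-8").splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise FormatError(f"empty structure file: {path}")
    if len(lines) % 3 != 0:
        raise FormatError(f"{path}: expected 3-line records, got {len(lines)} lines")
    records: list[StructureRecord] = []
    seen: set[str] = set()
    for i in range(0, len(lines), 3):
        header, seq_line, struct_line = lines[i : i + 3]
        if not header.startswith(">"):
            raise FormatError(f"{path}: record {i // 3} does not start with '>'")
        rec_id = header[1:].split()[0]
        if rec_id in seen:
            raise FormatError(f"duplicate structure id {rec_id!r} in {path}")
        seen.add(rec_id)
        # split off trailing "(mfe)" — the dot-bracket itself never contains spaces
        parts = struct_line.rsplit(None, 1)
        if len(parts) != 2 or not (parts[1].startswith("(") and parts[1].endswith(")")):
            raise FormatError(f"{path}: {rec_id!r}: missing '(mfe)' suffix on structure line")
        dot_bracket = parts[0]
        try:
            mfe = float(parts[1][1:-1])
        except ValueError as exc:
            raise FormatError(f"{path}: {rec_id!r}: unparsable MFE {parts[1]!r}") from exc
        try:
            records.append(
                StructureRecord(rec_id, normalise_rna(seq_line), dot_bracket, mfe)
            )
        except (FormatError, ValueError) as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return records


def write_structure_file(records: Iterable[StructureRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n{rec.dot_bracket} ({rec.mfe_kcal_mol:.2f})\n")


def parse_gtf_features(
    path: str | Path, feature_types: Sequence[str]
) -> list[tuple[str, str, str, GenomicInterval]]:
    """Extract (gene_id, transcript_id, feature, interval) tuples from a GTF.

    GTF is 1-based inclusive; the returned intervals are 0-based half-open.
    Rows whose feature is not in ``feature_types`` are omitted; rows missing
    the gene_id or transcript_id attribute are skipped with a warning.
    """
    wanted = set(feature_types)
    out: list[tuple[str, str, str, GenomicInterval]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feat = feature_from_line(line)
            if feat.featuretype not in wanted:
                continue
            try:
                gene_id = feat.attributes["gene_id"][0]
                transcript_id = feat.attributes["transcript_id"][0]
            except KeyError as exc:
                logger.warning("%s line %d: missing attribute %s; row skipped", path, lineno, exc)
                continue
            strand = feat.strand if feat.strand in ("+", "-") else "+"
            interval = GenomicInterval(feat.seqid, feat.start - 1, feat.end, strand)
            out.append((gene_id, transcript_id, feat.featuretype, interval))
    return out


def interval_to_gtf_coords(interval: GenomicInterval) -> tuple[int, int]:
    """Back-convert a half-open interval to GTF's 1-based inclusive pair."""
    return interval.start + 1, interval.end


# ---------------------------------------------------------------------------
# Tab-separated tables.  Each reader validates its schema and key uniqueness.

COUNTS_KEY = "gene_id"
DE_COLUMNS = ["gene_id", "log2fc", "padj"]
INTERACTION_COLUMNS = ["mirna_id", "gene_id", "n_sites", "best_class", "min_energy"]
READ_STACK_COLUMNS = ["precursor_id", "start", "end", "mismatches", "count"]
ARM_COLUMNS = ["precursor_id", "mature_start", "mature_end", "star_start", "star_end"]
LIBRARY_META_COLUMNS = ["library_id", "domain", "stage", "replicate"]


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={c: str for c in ("gene_id", "mirna_id", "precursor_id", "library_id")})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


def _check_unique(df: pd.DataFrame, keys: Sequence[str], path: str | Path) -> None:
    if df.duplicated(subset=list(keys)).any():
        raise FormatError(f"{path}: duplicate rows for key {list(keys)}")


def read_counts_table(path: str | Path) -> pd.DataFrame:
    """Gene × library count matrix; gene_id column becomes the index."""
    df = _read_tsv(path, [COUNTS_KEY])
    _check_unique(df, [COUNTS_KEY], path)
    return df.set_index(COUNTS_KEY)


def write_counts_table(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label=COUNTS_KEY)


def read_library_metadata(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, LIBRARY_META_COLUMNS)
    _check_unique(df, ["library_id"], path)
    return df.set_index("library_id")


def read_de_table(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, DE_COLUMNS)
    _check_unique(df, ["gene_id"], path)
    return df


def write_de_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_interactions_table(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, INTERACTION_COLUMNS)
    _check_unique(df, ["mirna_id", "gene_id"], path)
    return df


def write_interactions_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_read_stacks(path: str | Path) -> pd.DataFrame:
    """Collapsed read alignments: one row per distinct (start, end, mismatches)."""
    return _read_tsv(path, READ_STACK_COLUMNS)


def write_read_stacks(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_arm_table(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, ARM_COLUMNS)
    _check_unique(df, ["precursor_id"], path)
    return df.set_index("precursor_id")


def write_arm_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="precursor_id")
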