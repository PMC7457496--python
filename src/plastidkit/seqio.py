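"""Sequence and annotation data model plus readers/writers.

Coordinates are 0-based half-open internally; every human-facing report
converts to 1-based inclusive. Circular molecules are stored linearly with an
explicit ``circular`` flag; intervals crossing the origin are split into two
sub-intervals sharing a label.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

IUPAC_ALPHABET = frozenset("ACGTNRYSWKMBDHV")

_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHVacgtnryswkmbdhv",
    "TGCANYRSWMKVHDBtgcanyrswmkvhdb",
)


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


class ValidationError(ValueError):
    """Raised when parsed content violates a model invariant."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A named nucleotide sequence, optionally circular."""

    id: str
    residues: str
    circular: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        residues = self.residues.upper()
        if not residues:
            raise ValidationError(f"sequence {self.id!r} is empty")
        bad = set(residues) - IUPAC_ALPHABET
        if bad:
            raise ValidationError(
                f"sequence {self.id!r} contains invalid characters: {sorted(bad)}"
            )
        object.__setattr__(self, "residues", residues)

    def __len__(self) -> int:
        return len(self.residues)

    def slice(self, start: int, end: int) -> str:
        """Residues of [start, end); wraps across the origin when circular."""
        n = len(self.residues)
        if 0 <= start <= end <= n:
            return self.residues[start:end]
        if not self.circular:
            raise IndexError(f"[{start}, {end}) outside linear sequence of length {n}")
        start %= n
        end %= n
        if start < end:
            return self.residues[start:end]
        return self.residues[start:] + self.residues[:end]


@dataclass(frozen=True)
class GenomeRegion:
    """Half-open interval [start, end) on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"
    label: str = "other"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"bad interval [{self.start}, {self.end}) for {self.seq_id!r}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Feature:
    """An annotated gene feature, possibly multi-exon."""

    gene: str
    kind: str  # CDS, tRNA, rRNA, other
    intervals: tuple[GenomeRegion, ...]
    strand: str
    codon_start: int = 1

    def __post_init__(self) -> None:
        if self.kind == "CDS" and self.codon_start not in (1, 2, 3):
            raise ValidationError(f"CDS {self.gene!r}: codon_start must be 1..3")
        if not self.intervals:
            raise ValidationError(f"feature {self.gene!r} has no intervals")

    @property
    def span(self) -> tuple[int, int]:
        return (min(r.start for r in self.intervals), max(r.end for r in self.intervals))


@dataclass
class FeatureTable:
    seq_id: str
    features: list[Feature] = field(default_factory=list)

    def validate_against(self, seq: NucleotideSequence) -> None:
        n = len(seq)
        for f in self.features:
            for r in f.intervals:
                if r.end > n:
                    raise ValidationError(
                        f"feature {f.gene!r} interval [{r.start}, {r.end}) exceeds "
                        f"sequence length {n}"
                    )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a (multi-)FASTA file into NucleotideSequence records.

    Residues are upper-cased on ingest; record order is preserved. An empty
    file yields an empty list.
    """
    path = Path(path)
    records: list[NucleotideSequence] = []
    with open(path) as handle:
        for lineno, rec in _iter_fasta(handle):
            rec_id, desc, seq = rec
            if not seq:
                raise ParseError(f"{path}:{lineno}: record {rec_id!r} has no residues")
            try:
                records.append(
                    NucleotideSequence(id=rec_id, residues=seq, description=desc)
                )
            except ValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return records


def _iter_fasta(handle: io.TextIOBase):
    header_line = None
    rec_id = desc = None
    chunks: list[str] = []
    for lineno, line in enumerate(handle, 1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith(">"):
            if rec_id is not None:
                yield header_line, (rec_id, desc, "".join(chunks))
            header = line[1:].strip()
            if not header:
                raise ParseError(f"line {lineno}: empty FASTA header")
            parts = header.split(None, 1)
            rec_id, desc = parts[0], parts[1] if len(parts) > 1 else ""
            header_line = lineno
            chunks = []
        else:
            if rec_id is None:
                raise ParseError(f"line {lineno}: sequence data before first header")
            chunks.append(line.strip())
    if rec_id is not None:
        yield header_line, (rec_id, desc, "".join(chunks))


def write_fasta(seqs: Iterable[NucleotideSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as out:
        for s in seqs:
            header = f">{s.id}" + (f" {s.description}" if s.description else "")
            out.write(header + "\n")
            for i in range(0, len(s.residues), width):
                out.write(s.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Feature tables

def read_feature_table(path: str | Path, seq_length: int | None = None) -> FeatureTable:
    """Read gene features from a GenBank flat file or a 5-column TSV dialect.

    GenBank ``join()`` coordinates are decomposed into ordered intervals,
    ``complement()`` maps to strand '-', and all coordinates are converted to
    0-based half-open. The TSV dialect is
    ``gene<TAB>kind<TAB>strand<TAB>codon_start<TAB>intervals`` with intervals
    as comma-separated 1-based inclusive ``start..end`` pairs.
    """
    path = Path(path)
    with open(path) as fh:
        head = fh.read(256)
    if head.startswith("LOCUS") or "FEATURES" in head:
        table = _read_genbank_features(path)
    else:
        table = _read_tsv_features(path)
    if seq_length is not None:
        for f in table.features:
            for r in f.intervals:
                if r.end > seq_length:
                    raise ValidationError(
                        f"feature {f.gene!r}: interval [{r.start}, {r.end}) outside "
                        f"sequence of length {seq_length}"
                    )
    return table


_FEATURE_KINDS = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


def _read_genbank_features(path: Path) -> FeatureTable:
    record = next(SeqIO.parse(str(path), "genbank"))
    features: list[Feature] = []
    for feat in record.features:
        kind = _FEATURE_KINDS.get(feat.type)
        if kind is None:
            continue
        gene = feat.qualifiers.get("gene", feat.qualifiers.get("locus_tag", ["?"]))[0]
        strand = "-" if feat.location.strand == -1 else "+"
        intervals = []
        for part in sorted(feat.location.parts, key=lambda p: int(p.start)):
            intervals.append(
                GenomeRegion(record.id, int(part.start), int(part.end), strand)
            )
        if strand == "-":
            intervals = intervals[::-1]
        codon_start = int(feat.qualifiers.get("codon_start", ["1"])[0])
        features.append(
            Feature(gene=gene, kind=kind, intervals=tuple(intervals), strand=strand,
                    codon_start=codon_start)
        )
    return FeatureTable(seq_id=record.id, features=features)


def _read_tsv_features(path: Path) -> FeatureTable:
    features: list[Feature] = []
    seq_id = path.stem
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("#seq_id"):
                    seq_id = line.split("\t")[1] if "\t" in line else seq_id
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ParseError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            gene, kind, strand, codon_start, ivtext = parts
            intervals = []
            for chunk in ivtext.split(","):
                try:
                    a, b = chunk.split("..")
                    start, end = int(a) - 1, int(b)
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad interval {chunk!r}") from exc
                intervals.append(GenomeRegion(seq_id, start, end, strand))
            features.append(
                Feature(gene=gene, kind=kind, intervals=tuple(intervals),
                        strand=strand, codon_start=int(codon_start))
            )
    return FeatureTable(seq_id=seq_id, features=features)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write the 5-column TSV feature dialect (1-based inclusive intervals)."""
    with open(path, "w") as out:
        out.write(f"#seq_id\t{table.seq_id}\n")
        for f in table.features:
            ivtext = ",".join(f"{r.start + 1}..{r.end}" for r in f.intervals)
            out.write(f"{f.gene}\t{f.kind}\t{f.strand}\t{f.codon_start}\t{ivtext}\n")


# ---------------------------------------------------------------------------
# Elementary sequence operations

def revcomp(residues: str) -> str:
    """Reverse complement of a residue string (IUPAC-aware)."""
    return residues.translate(_COMPLEMENT)[::-1]


def complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)


def reverse_complement(seq: NucleotideSequence) -> NucleotideSequence:
    return replace(seq, residues=revcomp(seq.residues))


def gc_content(target: NucleotideSequence | str) -> float:
    """GC fraction over unambiguous bases only (N/ambiguity codes excluded)."""
    residues = target.residues if isinstance(target, NucleotideSequence) else target.upper()
    gc = residues.count("G") + residues.count("C")
    at = residues.count("A") + residues.count("T")
    if gc + at == 0:
        raise ValidationError("gc_content undefined: no unambiguous bases")
    return gc / (gc + at)


def translate_cds(residues: str, codon_start: int = 1) -> str:
    """Translate with the bacterial/plastid genetic code (table 11)."""
    coding = residues[codon_start - 1 :]
    coding = coding[: len(coding) - len(coding) % 3]
    return str(Seq(coding).translate(table=11))


# ---------------------------------------------------------------------------
# BED

def write_region_bed(regions: Sequence[GenomeRegion], path: str | Path) -> None:
    """Write regions as BED6 (0-based half-open, label in the name column)."""
    with open(path, "w") as out:
        for r in regions:
            out.write(f"{r.seq_id}\t{r.start}\t{r.end}\t{r.label}\t.\t{r.strand}\n")


def read_region_bed(path: str | Path) -> list[GenomeRegion]:
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: expected BED6")
            regions.append(
                GenomeRegion(parts[0], int(parts[1]), int(parts[2]),
                             strand=parts[5], label=parts[3])
            )
    return regions
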