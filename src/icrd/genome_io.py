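"""Genome assemblies, genomic intervals, and standard-format I/O.

All coordinates are 0-based half-open internally.  GFF3 (1-based inclusive)
is converted at the file boundary only; BED is already 0-based half-open.
Rendering for human-readable reports uses 1-based inclusive coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class GenomeIOError(ValueError):
    """Malformed input file or coordinate violation."""


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet (involution)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Chromosome:
    """A named chromosome-scale sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise GenomeIOError("chromosome id must be nonempty")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GenomeAssembly:
    """Named, ordered collection of chromosomes; the unit of all scanning."""

    name: str
    chromosomes: list[Chromosome] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.chromosomes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise GenomeIOError(f"duplicate chromosome ids: {dupes}")

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    def __getitem__(self, chrom_id: str) -> Chromosome:
        for c in self.chromosomes:
            if c.id == chrom_id:
                return c
        raise GenomeIOError(f"unknown chromosome {chrom_id!r} in assembly {self.name!r}")

    def __contains__(self, chrom_id: str) -> bool:
        return any(c.id == chrom_id for c in self.chromosomes)

    def ids(self) -> list[str]:
        return [c.id for c in self.chromosomes]

    def lengths(self) -> dict[str, int]:
        return {c.id: c.length for c in self.chromosomes}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named chromosome with strand.

    ``start`` is inclusive, ``end`` exclusive; ``0 <= start < end`` always
    (empty intervals are rejected).
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenomeIOError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0:
            raise GenomeIOError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise GenomeIOError(
                f"interval must be non-empty: start={self.start}, end={self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)

    def render_1based(self) -> str:
        """Human-readable 1-based inclusive form, e.g. ``Chr05:50639971-50641791``."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"


@dataclass
class Feature:
    """A genomic interval plus annotation attributes (BED/GFF3 payload)."""

    interval: GenomicInterval
    name: str = "."
    score: float | None = None
    type: str = "region"
    source: str = "icrd"
    attributes: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> GenomeAssembly:
    """Read a multi-record FASTA into a :class:`GenomeAssembly`.

    Sequences are uppercased and U is normalized to T.  Record order is
    preserved.  Raises :class:`GenomeIOError` on an empty file, duplicate
    record ids, or characters outside {A,C,G,T,N,U}.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise GenomeIOError(f"no records in FASTA file {path}")
    chroms = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise GenomeIOError(f"duplicate chromosome id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - VALID_BASES
        if bad:
            raise GenomeIOError(
                f"non-nucleotide characters {sorted(bad)} in record {rec.id!r}"
            )
        chroms.append(Chromosome(id=rec.id, sequence=seq))
    return GenomeAssembly(name=path.stem, chromosomes=chroms)


def write_fasta(assembly: GenomeAssembly, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.id, description="")
        for c in assembly.chromosomes
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Subsequence extraction
# ---------------------------------------------------------------------------

def extract_interval(assembly: GenomeAssembly, iv: GenomicInterval) -> str:
    """Extract the sequence of ``iv``; minus strand returns the reverse complement.

    Raises :class:`GenomeIOError` for an unknown chromosome or an interval
    exceeding the chromosome bounds, naming the bound violated.
    """
    chrom = assembly[iv.chrom]
    if iv.end > chrom.length:
        raise GenomeIOError(
            f"interval end {iv.end} exceeds length {chrom.length} of {iv.chrom!r}"
        )
    seq = chrom.sequence[iv.start : iv.end]
    return reverse_complement(seq) if iv.strand == "-" else seq


def extract_many(assembly: GenomeAssembly, ivs: Iterable[GenomicInterval]) -> list[str]:
    """Batch extraction (the classic extract-from-genome helper script)."""
    return [extract_interval(assembly, iv) for iv in ivs]


# ---------------------------------------------------------------------------
# Feature files: BED6 and GFF3
# ---------------------------------------------------------------------------

def read_features(path: str | Path, format: str | None = None) -> list[Feature]:
    """Read BED6 or GFF3 features; coordinates converted to 0-based half-open.

    ``format`` is inferred from the file suffix when omitted.  Malformed lines
    are reported with their line number.
    """
    path = Path(path)
    fmt = (format or _infer_format(path)).upper()
    if fmt == "BED":
        return _read_bed(path)
    if fmt == "GFF3":
        return _read_gff3(path)
    raise GenomeIOError(f"unsupported feature format {fmt!r}")


def write_features(features: Sequence[Feature], path: str | Path,
                   format: str | None = None) -> None:
    """Write features as BED6 or GFF3, exactly inverting :func:`read_features`."""
    path = Path(path)
    fmt = (format or _infer_format(path)).upper()
    if fmt == "BED":
        _write_bed(features, path)
    elif fmt == "GFF3":
        _write_gff3(features, path)
    else:
        raise GenomeIOError(f"unsupported feature format {fmt!r}")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".bed":
        return "BED"
    if suffix in (".gff", ".gff3"):
        return "GFF3"
    raise GenomeIOError(f"cannot infer feature format from suffix {suffix!r}")


def _read_bed(path: Path) -> list[Feature]:
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GenomeIOError(f"{path}:{lineno}: BED line has <3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise GenomeIOError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = parts[3] if len(parts) > 3 else "."
            score = None
            if len(parts) > 4 and parts[4] not in (".", ""):
                score = float(parts[4])
            strand = parts[5] if len(parts) > 5 else "+"
            try:
                iv = GenomicInterval(parts[0], start, end, strand)
            except GenomeIOError as exc:
                raise GenomeIOError(f"{path}:{lineno}: {exc}") from exc
            feats.append(Feature(interval=iv, name=name, score=score))
    return feats


def _write_bed(features: Sequence[Feature], path: Path) -> None:
    with open(path, "w") as fh:
        for f in features:
            iv = f.interval
            score = "." if f.score is None else f"{f.score:g}"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{f.name}\t{score}\t{iv.strand}\n"
            )


def _read_gff3(path: Path) -> list[Feature]:
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise GenomeIOError(f"{path}:{lineno}: GFF3 line has {len(parts)} columns, expected 9")
            chrom, source, ftype, start1, end1, score, strand, _phase, attrs = parts
            try:
                # GFF3 is 1-based inclusive; internal form is 0-based half-open.
                iv = GenomicInterval(chrom, int(start1) - 1, int(end1),
                                     strand if strand in "+-" else "+")
            except (ValueError, GenomeIOError) as exc:
                raise GenomeIOError(f"{path}:{lineno}: {exc}") from exc
            attributes = {}
            for kv in attrs.split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    attributes[k] = v
            feats.append(Feature(
                interval=iv,
                name=attributes.get("ID", attributes.get("Name", ".")),
                score=None if score == "." else float(score),
                type=ftype,
                source=source,
                attributes=attributes,
            ))
    return feats


def _write_gff3(features: Sequence[Feature], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            iv = f.interval
            attrs = dict(f.attributes)
            if f.name != "." and "ID" not in attrs:
                attrs["ID"] = f.name
            attr_str = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
            score = "." if f.score is None else f"{f.score:g}"
            fh.write(
                f"{iv.chrom}\t{f.source}\t{f.type}\t{iv.start + 1}\t{iv.end}\t"
                f"{score}\t{iv.strand}\t.\t{attr_str}\n"
            )
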