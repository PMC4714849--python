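"""Transcript/interval data model and readers/writers for GTF, GFF3, BED and FASTA.

All coordinates are 0-based half-open internally; the 1-based inclusive
conventions of GTF/GFF3 are converted at the I/O boundary and nowhere else.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

__all__ = [
    "GenomeScaffold",
    "TranscriptModel",
    "IntervalSet",
    "SequenceStore",
    "read_gtf",
    "write_gtf",
    "read_intervals",
    "read_fasta",
    "write_fasta",
    "read_scaffold_lengths",
    "spliced_sequence",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeScaffold:
    """A named scaffold with a known length in base pairs."""

    name: str
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"scaffold {self.name!r}: length must be > 0")


@dataclass
class TranscriptModel:
    """A stranded, (usually multi-)exon transcript on one scaffold.

    ``exons`` are (start, end) pairs in 0-based half-open genomic coordinates,
    sorted and non-overlapping.  ``attributes`` may carry ``coverage`` (per-base
    read coverage), ``fpkm`` and ``class_code``.  ``support`` records the
    (assembler, tissue) pairs in which this intron chain was observed.
    """

    transcript_id: str
    locus_id: str
    scaffold: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    attributes: dict = field(default_factory=dict)
    support: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"transcript {self.transcript_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        for s, e in exons:
            if e <= s:
                raise ValueError(
                    f"transcript {self.transcript_id!r}: exon ({s},{e}) has end <= start"
                )
        for (_, e0), (s1, _) in zip(exons, exons[1:]):
            if s1 < e0:
                raise ValueError(
                    f"transcript {self.transcript_id!r}: overlapping exons near {s1}"
                )
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "support", frozenset(self.support))

    # -- geometry -----------------------------------------------------------
    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Genomic intron intervals, in genomic order."""
        return tuple((e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]))

    def with_attributes(self, **kwargs) -> "TranscriptModel":
        attrs = dict(self.attributes)
        attrs.update(kwargs)
        return replace(self, attributes=attrs)


class IntervalSet:
    """Scaffold-keyed intervals with overlap queries (0-based half-open)."""

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}

    def add(self, scaffold: str, start: int, end: int, strand: str | None = None,
            name: str | None = None) -> None:
        if end <= start:
            raise ValueError(f"interval ({start},{end}) on {scaffold}: end must be > start")
        self._trees.setdefault(scaffold, IntervalTree()).addi(start, end, (strand, name))

    def overlaps(self, scaffold: str, start: int, end: int,
                 strand: str | None = None) -> list[tuple[int, int, str | None, str | None]]:
        tree = self._trees.get(scaffold)
        if tree is None:
            return []
        out = []
        for iv in sorted(tree.overlap(start, end)):
            s, n = iv.data
            if strand is None or s is None or s == strand:
                out.append((iv.begin, iv.end, s, n))
        return out

    def __iter__(self) -> Iterator[tuple[str, int, int, str | None, str | None]]:
        for scaffold in sorted(self._trees):
            for iv in sorted(self._trees[scaffold]):
                s, n = iv.data
                yield scaffold, iv.begin, iv.end, s, n

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())


class SequenceStore(dict):
    """Mapping scaffold name -> uppercase DNA string over {A,C,G,T,N}."""

    def __setitem__(self, name: str, seq: str) -> None:
        seq = seq.upper()
        if re.search(r"[^ACGTN]", seq):
            bad = re.search(r"[^ACGTN]", seq).group()
            raise ValueError(f"scaffold {name!r}: non-ACGTN character {bad!r}")
        super().__setitem__(name, seq)

    def scaffolds(self) -> list[GenomeScaffold]:
        return [GenomeScaffold(n, len(s)) for n, s in self.items()]


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(path, strand_policy: str = "error") -> list[TranscriptModel]:
    """Read exon features of a GTF file into TranscriptModels.

    GTF 1-based inclusive coordinates are converted to 0-based half-open.
    ``locus_id`` falls back to ``gene_id`` then ``transcript_id``.  Transcripts
    without strand information ('.') are rejected (``strand_policy='error'``)
    or dropped with a warning (``'drop'``).
    """
    if strand_policy not in ("error", "drop"):
        raise ValueError(f"unknown strand_policy {strand_policy!r}")
    per_tx: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: malformed GTF line {lineno}: expected 9 fields")
            scaffold, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed GTF line {lineno}: non-integer coordinate") from exc
            attributes = _parse_attributes(attrs)
            tid = attributes.get("transcript_id")
            if not tid:
                raise ValueError(f"{path}: malformed GTF line {lineno}: missing transcript_id")
            rec = per_tx.get(tid)
            if rec is None:
                rec = {"scaffold": scaffold, "strand": strand, "exons": [],
                       "attrs": attributes, "lineno": lineno}
                per_tx[tid] = rec
                order.append(tid)
            else:
                if rec["scaffold"] != scaffold:
                    raise ValueError(
                        f"{path}: line {lineno}: inconsistent scaffold for transcript {tid!r}"
                    )
                if rec["strand"] != strand:
                    raise ValueError(
                        f"{path}: line {lineno}: inconsistent strand for transcript {tid!r}"
                    )
            rec["exons"].append((start_i - 1, end_i))

    out: list[TranscriptModel] = []
    dropped = []
    for tid in order:
        rec = per_tx[tid]
        if rec["strand"] not in ("+", "-"):
            if strand_policy == "drop":
                dropped.append(tid)
                continue
            raise ValueError(
                f"{path}: transcript {tid!r} (line {rec['lineno']}): unoriented strand {rec['strand']!r}"
            )
        attrs = rec["attrs"]
        model_attrs: dict = {}
        if "cov" in attrs:
            model_attrs["coverage"] = float(attrs["cov"])
        if "coverage" in attrs:
            model_attrs["coverage"] = float(attrs["coverage"])
        if "FPKM" in attrs:
            model_attrs["fpkm"] = float(attrs["FPKM"])
        if "class_code" in attrs:
            model_attrs["class_code"] = attrs["class_code"]
        locus = attrs.get("gene_id") or tid
        out.append(TranscriptModel(
            transcript_id=tid, locus_id=locus, scaffold=rec["scaffold"],
            strand=rec["strand"], exons=tuple(rec["exons"]), attributes=model_attrs,
        ))
    if dropped:
        import warnings

        warnings.warn(f"{path}: dropped {len(dropped)} unoriented transcript(s)")
    return out


def write_gtf(transcripts: Iterable[TranscriptModel], path, source: str = "lncforge") -> None:
    """Write exon lines (1-based inclusive) such that read_gtf round-trips."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = [f'gene_id "{t.locus_id}"', f'transcript_id "{t.transcript_id}"']
            if "coverage" in t.attributes:
                attrs.append(f'cov "{t.attributes["coverage"]:.6g}"')
            if "fpkm" in t.attributes:
                attrs.append(f'FPKM "{t.attributes["fpkm"]:.6g}"')
            if "class_code" in t.attributes:
                attrs.append(f'class_code "{t.attributes["class_code"]}"')
            if "category" in t.attributes:
                attrs.append(f'category "{t.attributes["category"]}"')
            attr_str = "; ".join(attrs) + ";"
            for s, e in t.exons:
                fh.write("\t".join([
                    t.scaffold, source, "exon", str(s + 1), str(e), ".",
                    t.strand, ".", attr_str,
                ]) + "\n")


# ---------------------------------------------------------------------------
# BED / GFF3 intervals
# ---------------------------------------------------------------------------

def read_intervals(path, format: str) -> IntervalSet:
    """Read BED (0-based half-open) or GFF3 (1-based inclusive) intervals."""
    ivs = IntervalSet()
    if format == "bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}: malformed BED line {lineno}")
                name = fields[3] if len(fields) > 3 else None
                strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else None
                try:
                    ivs.add(fields[0], int(fields[1]), int(fields[2]), strand, name)
                except ValueError as exc:
                    raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    elif format == "gff3":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 9:
                    raise ValueError(f"{path}: malformed GFF3 line {lineno}")
                strand = fields[6] if fields[6] in "+-" else None
                attrs = dict(
                    kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                )
                name = attrs.get("Name") or attrs.get("ID")
                try:
                    ivs.add(fields[0], int(fields[3]) - 1, int(fields[4]), strand, name)
                except ValueError as exc:
                    raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    else:
        raise ValueError(f"unknown interval format {format!r} (expected 'bed' or 'gff3')")
    return ivs


# ---------------------------------------------------------------------------
# FASTA and scaffold tables
# ---------------------------------------------------------------------------

def read_fasta(path) -> SequenceStore:
    store = SequenceStore()
    for rec in SeqIO.parse(str(path), "fasta"):
        store[rec.id] = str(rec.seq)
    return store


def write_fasta(store: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in store:
            fh.write(f">{name}\n")
            seq = store[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_scaffold_lengths(path) -> dict[str, int]:
    """Two-column TSV (name, length) -> mapping."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: malformed scaffold-length line {lineno}")
            length = int(fields[1])
            if length <= 0:
                raise ValueError(f"{path}: line {lineno}: non-positive length")
            if fields[0] in out:
                raise ValueError(f"{path}: line {lineno}: duplicate scaffold {fields[0]!r}")
            out[fields[0]] = length
    return out


def spliced_sequence(t: TranscriptModel, genome: Mapping[str, str]) -> str:
    """5'->3' spliced sequence of ``t`` (minus strand reverse-complemented)."""
    try:
        scaffold_seq = genome[t.scaffold]
    except KeyError as exc:
        raise KeyError(f"transcript {t.transcript_id!r}: scaffold {t.scaffold!r} not in genome") from exc
    if t.end > len(scaffold_seq):
        raise ValueError(
            f"transcript {t.transcript_id!r}: exon end {t.end} beyond scaffold "
            f"{t.scaffold!r} length {len(scaffold_seq)}"
        )
    seq = "".join(scaffold_seq[s:e] for s, e in t.exons)
    if t.strand == "-":
        seq = reverse_complement(seq)
    return seq
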