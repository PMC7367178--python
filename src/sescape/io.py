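"""Readers and writers for the on-disk formats the pipeline consumes.

Dialects handled: narrowPeak (BED6+4), broadPeak (BED6+3), 4-column
bedGraph, BED6 gene tables, 4-column chromatin-state segmentation BED,
fragment BED, and the tab-separated expression table.  Parsing is strict:
malformed column counts, ``.`` score placeholders, inverted coordinates
and records that leave the declared chromosome all raise with the
offending line number rather than being silently coerced.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeSpec
from .intervals import FragmentIndex, SignalTrack


class ParseError(ValueError):
    """Malformed record in an input file; message names the line."""


@dataclass(frozen=True)
class PeakRecord:
    """One peak call with MACS2-style statistics.

    ``summit_offset`` is bp from ``start`` (narrowPeak only; ``None`` for
    broadPeak records and for narrowPeak records with summit -1).
    """

    chrom: str
    start: int
    end: int
    name: str
    neg_log10_p: float
    fold_enrichment: float
    summit_offset: int | None = None
    score: int = 0
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.name}: start >= end")
        if self.neg_log10_p < 0 or self.fold_enrichment < 0:
            raise ValueError(f"peak {self.name}: negative statistic")

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SegmentationRecord:
    chrom: str
    start: int
    end: int
    state_label: str


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its transcription start site.

    TSS is the leftmost base for + strand genes and the rightmost covered
    base (end - 1) for - strand genes.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    fpkm_a: float
    fpkm_b: float
    q_value: float

    def __post_init__(self) -> None:
        if self.fpkm_a < 0 or self.fpkm_b < 0:
            raise ValueError(f"{self.gene_id}: negative FPKM")
        if not (0.0 <= self.q_value <= 1.0):
            raise ValueError(f"{self.gene_id}: q-value outside [0, 1]")


_NARROWPEAK_COLS = 10
_BROADPEAK_COLS = 9


def _read_lines(path) -> list[list[str]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            rows.append((lineno, line.split("\t")))
    return rows


def _float_field(value: str, lineno: int, what: str) -> float:
    if value == ".":
        raise ParseError(f"line {lineno}: missing {what} ('.')")
    try:
        return float(value)
    except ValueError:
        raise ParseError(f"line {lineno}: bad {what} {value!r}") from None


def read_peaks(
    path, dialect: str = "narrowPeak", genome: GenomeSpec | None = None
) -> list[PeakRecord]:
    """Read a narrowPeak or broadPeak file.

    narrowPeak is BED6+4 (signal/fold-enrichment, -log10 P, -log10 q,
    summit); broadPeak is BED6+3 (no summit column).
    """
    if dialect not in ("narrowPeak", "broadPeak"):
        raise ValueError(f"unknown peak dialect {dialect!r}")
    want = _NARROWPEAK_COLS if dialect == "narrowPeak" else _BROADPEAK_COLS
    peaks = []
    for lineno, fields in _read_lines(path):
        if len(fields) != want:
            raise ParseError(
                f"line {lineno}: expected {want} columns for {dialect}, "
                f"got {len(fields)}"
            )
        chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
        if start >= end:
            raise ParseError(f"line {lineno}: start >= end")
        if genome is not None:
            try:
                genome.validate_interval(chrom, start, end)
            except (ValueError, KeyError) as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
        fe = _float_field(fields[6], lineno, "fold enrichment")
        nlp = _float_field(fields[7], lineno, "-log10 P")
        summit = None
        if dialect == "narrowPeak":
            s = int(fields[9])
            summit = None if s < 0 else s
        peaks.append(
            PeakRecord(
                chrom=chrom,
                start=start,
                end=end,
                name=name,
                neg_log10_p=nlp,
                fold_enrichment=fe,
                summit_offset=summit,
                score=int(fields[4]),
                strand=fields[5],
            )
        )
    return peaks


def write_peaks(peaks: Sequence[PeakRecord], path, dialect: str = "narrowPeak") -> None:
    with open(path, "w") as fh:
        for p in peaks:
            base = (
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score}\t{p.strand}"
                f"\t{p.fold_enrichment:.5f}\t{p.neg_log10_p:.5f}\t-1"
            )
            if dialect == "narrowPeak":
                summit = -1 if p.summit_offset is None else p.summit_offset
                fh.write(f"{base}\t{summit}\n")
            elif dialect == "broadPeak":
                fh.write(base + "\n")
            else:
                raise ValueError(f"unknown peak dialect {dialect!r}")


def read_bedgraph(path, genome: GenomeSpec, library_size: int | None = None) -> SignalTrack:
    """Read a 4-column bedGraph into a :class:`SignalTrack`.

    Steps must be non-overlapping within each chromosome; overlap raises,
    because a silently summed track would hide upstream double-counting.
    """
    records = []
    for lineno, fields in _read_lines(path):
        if len(fields) != 4:
            raise ParseError(f"line {lineno}: bedGraph needs 4 columns, got {len(fields)}")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        if start >= end:
            raise ParseError(f"line {lineno}: start >= end")
        try:
            genome.validate_interval(chrom, start, end)
        except (ValueError, KeyError) as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
        records.append((chrom, start, end, _float_field(fields[3], lineno, "value")))
    return SignalTrack.from_steps(records, genome, library_size=library_size)


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.genome.chrom_names:
            if chrom not in track.steps:
                continue
            starts, ends, values = track.steps[chrom]
            for s, e, v in zip(starts.tolist(), ends.tolist(), values.tolist()):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def read_gene_table(path, genome: GenomeSpec | None = None) -> list[GeneRecord]:
    """Read a BED6-like gene table; strand must be + or -."""
    genes = []
    for lineno, fields in _read_lines(path):
        if len(fields) < 6:
            raise ParseError(f"line {lineno}: gene table needs 6 columns")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        strand = fields[5]
        if strand not in ("+", "-"):
            raise ParseError(f"line {lineno}: unknown strand {strand!r}")
        if start >= end:
            raise ParseError(f"line {lineno}: start >= end")
        if genome is not None:
            try:
                genome.validate_interval(chrom, start, end)
            except (ValueError, KeyError) as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
        genes.append(GeneRecord(fields[3], chrom, start, end, strand))
    return genes


def write_gene_table(genes: Sequence[GeneRecord], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_segmentation(
    path, genome: GenomeSpec | None = None, states: Sequence[str] | None = None
) -> list[SegmentationRecord]:
    """Read a 4-column chromatin-state BED; segments must be sorted and
    non-overlapping within each chromosome."""
    segs = []
    last: dict[str, int] = {}
    for lineno, fields in _read_lines(path):
        if len(fields) != 4:
            raise ParseError(f"line {lineno}: segmentation needs 4 columns")
        chrom, start, end, label = fields[0], int(fields[1]), int(fields[2]), fields[3]
        if start >= end:
            raise ParseError(f"line {lineno}: start >= end")
        if states is not None and label not in states:
            raise ParseError(f"line {lineno}: unknown state label {label!r}")
        if genome is not None:
            try:
                genome.validate_interval(chrom, start, end)
            except (ValueError, KeyError) as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
        if chrom in last and start < last[chrom]:
            raise ParseError(f"line {lineno}: segments overlap or are unsorted")
        last[chrom] = end
        segs.append(SegmentationRecord(chrom, start, end, label))
    return segs


def write_segmentation(segs: Sequence[SegmentationRecord], path) -> None:
    with open(path, "w") as fh:
        for s in segs:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.state_label}\n")


def read_fragments(path, genome: GenomeSpec | None = None) -> FragmentIndex:
    """Read a fragment BED (first three columns used) into a FragmentIndex."""
    frags = []
    for lineno, fields in _read_lines(path):
        if len(fields) < 3:
            raise ParseError(f"line {lineno}: fragment BED needs >= 3 columns")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        if start >= end:
            raise ParseError(f"line {lineno}: start >= end")
        frags.append((chrom, start, end))
    return FragmentIndex(frags, genome=genome)


def write_fragments(fragments: Iterable[tuple[str, int, int]], path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in fragments:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_expression(path) -> list[ExpressionRecord]:
    """Read the expression TSV: gene_id, fpkm_<A>, fpkm_<B>, q_value header.

    A missing q_value column is an error: differential calls need
    externally supplied adjusted significance — this package does not fit
    an expression model.
    """
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if "q_value" not in cols:
        raise ParseError(
            "expression table lacks a q_value column; supply adjusted "
            "significance from your expression-model fit"
        )
    fpkm_cols = [c for c in cols if c.startswith("fpkm_")]
    if len(fpkm_cols) != 2 or "gene_id" not in cols:
        raise ParseError(
            "expression table needs columns: gene_id, fpkm_<A>, fpkm_<B>, q_value"
        )
    return [
        ExpressionRecord(
            gene_id=str(r["gene_id"]),
            fpkm_a=float(r[fpkm_cols[0]]),
            fpkm_b=float(r[fpkm_cols[1]]),
            q_value=float(r["q_value"]),
        )
        for r in df.to_dict("records")
    ]


def write_expression(
    records: Sequence[ExpressionRecord], path, cond_a: str = "wt", cond_b: str = "ko"
) -> None:
    with open(path, "w") as fh:
        fh.write(f"gene_id\tfpkm_{cond_a}\tfpkm_{cond_b}\tq_value\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.fpkm_a:.4f}\t{r.fpkm_b:.4f}\t{r.q_value:.6g}\n")
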