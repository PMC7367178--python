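"""Genome coordinate frame.

All coordinates in this package are 0-based, half-open (BED convention).
A :class:`GenomeSpec` names the chromosomes and fixes their lengths; every
reader validates records against it and every enrichment computation uses
its total length as the background universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered chromosome names and lengths (bp).

    Parameters
    ----------
    chrom_names:
        Chromosome identifiers, in the order they are written to disk.
    chrom_lengths:
        Length of each chromosome in base pairs; must be positive.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    _lengths: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        object.__setattr__(
            self, "_lengths", dict(zip(self.chrom_names, self.chrom_lengths))
        )

    @property
    def total_bp(self) -> int:
        return sum(self.chrom_lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def length_of(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def validate_interval(self, chrom: str, start: int, end: int) -> None:
        """Raise ValueError unless ``[start, end)`` is a valid span on ``chrom``."""
        length = self.length_of(chrom)
        if not (0 <= start < end <= length):
            raise ValueError(
                f"invalid interval {chrom}:{start}-{end} "
                f"(chromosome length {length})"
            )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"chrom": self.chrom_names, "length": self.chrom_lengths}
        ).to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_tsv(cls, path) -> "GenomeSpec":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
        return cls(tuple(df["chrom"].astype(str)), tuple(int(x) for x in df["length"]))
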