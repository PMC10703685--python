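"""Genomic region handling.

Truth sites and calls use 1-based VCF coordinates; region intervals use
0-based half-open BED coordinates throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree


@dataclass(frozen=True)
class RegionSet:
    """A set of genomic intervals (0-based, half-open), e.g. a high-confidence mask."""

    intervals: tuple[tuple[str, int, int], ...]
    _trees: dict = field(default=None, compare=False, repr=False)

    def __post_init__(self):
        trees: dict[str, IntervalTree] = {}
        for chrom, start, end in self.intervals:
            if end <= start:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
        for t in trees.values():
            t.merge_overlaps()
        object.__setattr__(self, "_trees", trees)

    @classmethod
    def single(cls, chrom: str, length: int, start: int = 0) -> "RegionSet":
        return cls(((chrom, start, start + length),))

    @classmethod
    def from_bed(cls, path) -> "RegionSet":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2], names=["chrom", "start", "end"],
            dtype={"chrom": str, "start": int, "end": int},
        )
        return cls(tuple(df.itertuples(index=False, name=None)))

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in sorted(self.intervals):
                fh.write(f"{chrom}\t{start}\t{end}\n")

    @property
    def total_bp(self) -> int:
        return sum(iv.end - iv.begin for t in self._trees.values() for iv in t)

    @property
    def mbp(self) -> float:
        return self.total_bp / 1e6

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps(pos - 1))

    def contains_many(self, chroms, positions) -> pd.Series:
        return pd.Series(
            [self.contains(c, p) for c, p in zip(chroms, positions)], dtype=bool
        )
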