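"""Called genomic intervals and curve peaks."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Region:
    """A directed genomic interval called significant.

    ``direction`` is ``"gain"``/``"loss"`` for within-group calls, or a
    contrast label such as ``"A>B"`` for differential calls. Coordinates are
    0-based half-open base pairs; ``peak_pos``/``peak_height`` locate the
    extreme smoothed value inside the interval.
    """

    chrom: str
    start: float
    end: float
    direction: str
    peak_pos: float
    peak_height: float
    group: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"region must have start < end, got [{self.start}, {self.end})")

    def overlaps(self, chrom: str, start: float, end: float) -> bool:
        """Any-overlap (>= 1 bp) against a half-open interval."""
        return self.chrom == chrom and self.start < end and start < self.end


@dataclass(frozen=True)
class Peak:
    """A local extremum of a smoothed curve on its evaluation grid."""

    chrom: str
    pos: float
    height: float
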