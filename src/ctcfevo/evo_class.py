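"""Evolutionary classification of binding sites between two subspecies.

A peak in subspecies A is projected through a pairwise orthology block map
onto subspecies B.  Peaks whose sequence has no alignment in the other
subspecies are *subspecies-specific*; peaks that project onto an orthologous
location carrying a B peak are *musculus-common*; peaks that project but find
no B peak are kept as a distinct *aligned-unbound* class (the binary wording
of the common/specific dichotomy leaves their fate open, so both groupings
are supported downstream).

Orthology is consumed as gapless pairwise blocks: each block maps an
A-interval onto an equal-length B-interval, forward (+) or reverse-
complemented (-).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .intervals import GenomicInterval, merge
from .peaks import Peak

__all__ = [
    "EvoClass",
    "OrthologyBlock",
    "OrthologyMap",
    "map_to_other",
    "classify",
    "read_orthology_tsv",
    "write_orthology_tsv",
]


class EvoClass(str, Enum):
    MUSCULUS_COMMON = "musculus_common"
    SPECIES_SPECIFIC_UNALIGNED = "species_specific_unaligned"
    ALIGNED_UNBOUND = "aligned_unbound"


@dataclass(frozen=True)
class OrthologyBlock:
    """A gapless alignment block A[startA, endA) <-> B[startB, endB)."""

    chromA: str
    startA: int
    endA: int
    chromB: str
    startB: int
    endB: int
    orientation: str  # '+' or '-'

    def __post_init__(self):
        if self.endA - self.startA != self.endB - self.startB:
            raise ValueError("gapless block requires equal lengths on A and B")
        if self.endA <= self.startA:
            raise ValueError("empty block")
        if self.orientation not in ("+", "-"):
            raise ValueError(f"invalid orientation {self.orientation!r}")

    def project(self, start: int, end: int) -> tuple[str, int, int]:
        """Project an A-subinterval (must lie within the block) onto B."""
        if not (self.startA <= start < end <= self.endA):
            raise ValueError("subinterval outside block")
        if self.orientation == "+":
            off = self.startB - self.startA
            return self.chromB, start + off, end + off
        # mirror projection: A's right edge maps to B's left edge
        return (
            self.chromB,
            self.startB + (self.endA - end),
            self.startB + (self.endA - start),
        )


class OrthologyMap:
    """Ordered, A-nonoverlapping collection of orthology blocks."""

    def __init__(self, blocks: Iterable[OrthologyBlock]):
        self.blocks = sorted(blocks, key=lambda b: (b.chromA, b.startA))
        self._by_chrom: dict[str, list[OrthologyBlock]] = {}
        for b in self.blocks:
            self._by_chrom.setdefault(b.chromA, []).append(b)
        for bs in self._by_chrom.values():
            for prev, cur in zip(bs, bs[1:]):
                if cur.startA < prev.endA:
                    raise ValueError(
                        f"blocks overlap on A: {prev} vs {cur}"
                    )

    def overlapping(self, chrom: str, start: int, end: int) -> list[OrthologyBlock]:
        return [
            b
            for b in self._by_chrom.get(chrom, ())
            if b.startA < end and start < b.endA
        ]


def map_to_other(
    peak: Peak | GenomicInterval,
    omap: OrthologyMap,
    min_mapped_fraction: float = 0.5,
) -> Optional[GenomicInterval]:
    """Project a peak onto the other genome, or None if coverage is too low.

    The peak maps when at least ``min_mapped_fraction`` of its length lies
    inside alignment blocks.  The returned interval spans the projected
    covered portion on the B chromosome carrying the most coverage.
    """
    if not (0 < min_mapped_fraction <= 1):
        raise ValueError("min_mapped_fraction must be in (0, 1]")
    iv = peak.interval if isinstance(peak, Peak) else peak
    pieces: list[tuple[str, int, int, int]] = []  # chromB, startB, endB, covered
    covered = 0
    for block in omap.overlapping(iv.chrom, iv.start, iv.end):
        s = max(iv.start, block.startA)
        e = min(iv.end, block.endA)
        covered += e - s
        chromB, bs, be = block.project(s, e)
        pieces.append((chromB, bs, be, e - s))
    if covered < min_mapped_fraction * iv.length or not pieces:
        return None
    per_chrom: dict[str, int] = {}
    for chromB, _, _, cov in pieces:
        per_chrom[chromB] = per_chrom.get(chromB, 0) + cov
    best_chrom = max(per_chrom, key=lambda c: (per_chrom[c], c))
    sel = [p for p in pieces if p[0] == best_chrom]
    return GenomicInterval(
        best_chrom, min(p[1] for p in sel), max(p[2] for p in sel), name=iv.name
    )


def classify(
    peaksA: Sequence[Peak],
    peaksB: Sequence[Peak],
    omap: OrthologyMap,
    min_mapped_fraction: float = 0.5,
) -> dict[str, EvoClass]:
    """Per-peak evolutionary class for every subspecies-A peak, keyed by name.

    No projection -> species_specific_unaligned; projection overlapping a
    B peak (>= 1 bp) -> musculus_common; projection without a B peak ->
    aligned_unbound.
    """
    b_union = merge([p.interval for p in peaksB], max_gap=0)
    b_by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in b_union:
        b_by_chrom.setdefault(r.chrom, []).append(r)
    labels: dict[str, EvoClass] = {}
    for p in peaksA:
        proj = map_to_other(p, omap, min_mapped_fraction)
        if proj is None:
            labels[p.name] = EvoClass.SPECIES_SPECIFIC_UNALIGNED
        elif any(
            r.start < proj.end and proj.start < r.end
            for r in b_by_chrom.get(proj.chrom, ())
        ):
            labels[p.name] = EvoClass.MUSCULUS_COMMON
        else:
            labels[p.name] = EvoClass.ALIGNED_UNBOUND
    return labels


def read_orthology_tsv(path: str | Path) -> OrthologyMap:
    """Read the 7-column block TSV (header required)."""
    blocks = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:7] != ["chromA", "startA", "endA", "chromB", "startB", "endB", "orientation"]:
            raise ValueError(f"{path}: unexpected orthology header {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            cA, sA, eA, cB, sB, eB, ori = line.split("\t")[:7]
            blocks.append(
                OrthologyBlock(cA, int(sA), int(eA), cB, int(sB), int(eB), ori)
            )
    return OrthologyMap(blocks)


def write_orthology_tsv(path: str | Path, omap: OrthologyMap) -> None:
    with open(path, "w") as fh:
        fh.write("chromA\tstartA\tendA\tchromB\tstartB\tendB\torientation\n")
        for b in omap.blocks:
            fh.write(
                f"{b.chromA}\t{b.startA}\t{b.endA}\t{b.chromB}\t{b.startB}\t"
                f"{b.endB}\t{b.orientation}\n"
            )
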