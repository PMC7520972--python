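"""Genomic-interval data model and exact set operations.

Coordinates are 0-based, half-open (BED convention) throughout.  Abutting
intervals (``end_a == start_b``) do *not* overlap for :func:`intersect` but
*are* joined by :func:`merge` at ``max_gap=0``, matching the behaviour of the
BEDTools/BEDOPS pairing these operations emulate.  Strand is carried on every
interval but ignored by all set operations; orientation logic lives in
:mod:`ctcfevo.tad_cohesin`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "Karyotype",
    "intersect",
    "closest",
    "merge",
    "shuffle",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "UnknownChromosomeError",
    "ShufflePlacementError",
]


class UnknownChromosomeError(ValueError):
    """An interval references a chromosome absent from the karyotype."""


class ShufflePlacementError(RuntimeError):
    """Random placement failed after the bounded retry budget."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    ``strand`` is one of ``+``, ``-`` or ``.`` and is ignored by the set
    operations in this module.
    """

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)
    name: str = field(default=".", compare=False)
    score: float = field(default=0.0, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def shifted(self, new_start: int) -> "GenomicInterval":
        return replace(self, start=new_start, end=new_start + self.length)

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.chrom}:{self.start}-{self.end}"


class Karyotype:
    """Ordered mapping of chromosome name to length in bp."""

    def __init__(self, sizes: Mapping[str, int]):
        for chrom, size in sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {size}")
        self._sizes = dict(sizes)

    def __getitem__(self, chrom: str) -> int:
        try:
            return self._sizes[chrom]
        except KeyError:
            raise UnknownChromosomeError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __iter__(self):
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def items(self):
        return self._sizes.items()

    def validate(self, intervals: Iterable[GenomicInterval]) -> None:
        """Raise if any interval names an unknown chromosome or runs off it."""
        for iv in intervals:
            size = self[iv.chrom]
            if iv.end > size:
                raise ValueError(
                    f"interval {iv} exceeds chromosome length {size}"
                )


def _by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    for ivs in out.values():
        ivs.sort(key=lambda x: (x.start, x.end))
    return out


def intersect(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    min_overlap: int = 1,
    karyotype: Optional[Karyotype] = None,
) -> list[tuple[GenomicInterval, GenomicInterval, int]]:
    """All same-chromosome overlapping pairs with overlap >= ``min_overlap`` bp.

    Returns ``(a_interval, b_interval, overlap_length)`` triples sorted by the
    a-interval then the b-interval.  Half-open abutment is not an overlap.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if karyotype is not None:
        karyotype.validate(a)
        karyotype.validate(b)
    b_chrom = _by_chrom(b)
    b_starts = {
        chrom: np.fromiter((c.start for c in cands), dtype=np.int64, count=len(cands))
        for chrom, cands in b_chrom.items()
    }
    triples: list[tuple[GenomicInterval, GenomicInterval, int]] = []
    for iv in sorted(a, key=lambda x: (x.chrom, x.start, x.end)):
        cands = b_chrom.get(iv.chrom)
        if not cands:
            continue
        # candidates sorted by start: all with start < iv.end may overlap
        hi = int(np.searchsorted(b_starts[iv.chrom], iv.end, side="left"))
        for cand in cands[:hi]:
            ov = min(iv.end, cand.end) - max(iv.start, cand.start)
            if ov >= min_overlap:
                triples.append((iv, cand, ov))
    return triples


def closest(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    exclude_overlapping: bool = False,
    karyotype: Optional[Karyotype] = None,
) -> list[tuple[GenomicInterval, Optional[GenomicInterval], Optional[int]]]:
    """Nearest b-interval per a-interval with a signed reference distance.

    Distance is 0 iff the pair overlaps; negative when b lies upstream
    (lower coordinates) of a on the reference, positive downstream, measured
    edge-to-edge and ignoring strand.  With ``exclude_overlapping`` set,
    overlapping b-intervals are skipped.  Ties on ``|distance|`` break toward
    the smaller start coordinate.  Returns ``(a, b_or_None, distance_or_None)``
    in the order of the (sorted) a-intervals.
    """
    if karyotype is not None:
        karyotype.validate(a)
        karyotype.validate(b)
    b_chrom = _by_chrom(b)
    results = []
    for iv in sorted(a, key=lambda x: (x.chrom, x.start, x.end)):
        best: Optional[GenomicInterval] = None
        best_d: Optional[int] = None
        for cand in b_chrom.get(iv.chrom, ()):
            if cand.start < iv.end and iv.start < cand.end:
                if exclude_overlapping:
                    continue
                d = 0
            elif cand.end <= iv.start:
                d = cand.end - iv.start  # <= 0; abutment gives 0
            else:
                d = cand.start - iv.end
            if (
                best_d is None
                or abs(d) < abs(best_d)
                or (abs(d) == abs(best_d) and cand.start < best.start)
            ):
                best, best_d = cand, d
        results.append((iv, best, best_d))
    return results


def merge(
    a: Sequence[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Union of intervals, joining neighbours whose gap is <= ``max_gap`` bp.

    Abutting intervals join at ``max_gap=0``.  Idempotent; insensitive to
    input order.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    out: list[GenomicInterval] = []
    for chrom, ivs in sorted(_by_chrom(a).items()):
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_end <= max_gap:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


def shuffle(
    a: Sequence[GenomicInterval],
    karyotype: Karyotype,
    exclude: Sequence[GenomicInterval] = (),
    seed: int = 0,
    max_retries: int = 10_000,
) -> list[GenomicInterval]:
    """Randomly re-place each interval on its own chromosome, length preserved.

    Output intervals overlap neither ``exclude`` nor one another and are fully
    reproducible from ``seed``.  Raises :class:`ShufflePlacementError` naming
    the chromosome when placement fails within the retry budget.
    """
    karyotype.validate(a)
    rng = np.random.default_rng(seed)
    occupied = _by_chrom(exclude)
    placed: dict[str, list[tuple[int, int]]] = {
        chrom: [(iv.start, iv.end) for iv in ivs] for chrom, ivs in occupied.items()
    }
    out: list[GenomicInterval] = []
    for iv in a:
        chrom_len = karyotype[iv.chrom]
        span = chrom_len - iv.length
        if span < 0:
            raise ShufflePlacementError(
                f"interval longer than chromosome {iv.chrom}"
            )
        blocked = placed.setdefault(iv.chrom, [])
        for _ in range(max_retries):
            s = int(rng.integers(0, span + 1))
            e = s + iv.length
            if not any(s < be and bs < e for bs, be in blocked):
                blocked.append((s, e))
                out.append(iv.shifted(s))
                break
        else:
            raise ShufflePlacementError(
                f"could not place a {iv.length} bp interval on {iv.chrom} "
                f"after {max_retries} retries"
            )
    return out


# ---------------------------------------------------------------------------
# BED / chrom-sizes I/O (tab-separated, newline-terminated, no header)

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6; extra columns are ignored."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            strand = parts[5] if len(parts) > 5 else "."
            intervals.append(
                GenomicInterval(chrom, start, end, strand=strand, name=name, score=score)
            )
    return intervals


def write_bed(path: str | Path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n"
            )


def read_chrom_sizes(path: str | Path) -> Karyotype:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            sizes[parts[0]] = int(parts[1])
    return Karyotype(sizes)


def write_chrom_sizes(path: str | Path, karyotype: Karyotype) -> None:
    with open(path, "w") as fh:
        for chrom, size in karyotype.items():
            fh.write(f"{chrom}\t{size}\n")
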