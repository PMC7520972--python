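"""narrowPeak I/O, replicate-consensus filtering and signal-decile binning.

A :class:`Peak` wraps a :class:`~ctcfevo.intervals.GenomicInterval` with the
ENCODE narrowPeak attributes the downstream analyses use: the summit (absolute
bp), the read-pileup signal, and the -log10 p-value at the summit.  Consensus
filtering keeps peaks supported by at least ``min_support`` biological
replicates; the retained record carries the attributes of the replicate where
the signal was highest.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .intervals import GenomicInterval, merge

__all__ = [
    "Peak",
    "SignalBin",
    "read_narrowpeak",
    "write_narrowpeak",
    "consensus_peaks",
    "signal_deciles",
]


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    summit: int
    signal: float
    neglog10p: float
    neglog10q: float = -1.0
    replicate_support: int = 1

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside peak {self.interval}"
            )
        if self.signal < 0 or self.neglog10p < 0:
            raise ValueError("signal and -log10 p must be >= 0")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def name(self) -> str:
        return self.interval.name


@dataclass(frozen=True)
class SignalBin:
    """One of the equal-size bins of peaks ordered by descending signal."""

    bin_index: int  # 1 = strongest
    peaks: tuple[Peak, ...]


def read_narrowpeak(path: str | Path) -> list[Peak]:
    """Read an ENCODE narrowPeak (BED6+4) file.

    A summit offset of -1 is mapped to the interval midpoint.
    """
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise ValueError(
                    f"{path}:{lineno}: narrowPeak needs 10 columns, got {len(parts)}"
                )
            chrom = parts[0]
            start, end = int(parts[1]), int(parts[2])
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative start coordinate")
            name = parts[3]
            score = float(parts[4]) if parts[4] != "." else 0.0
            strand = parts[5]
            signal = float(parts[6])
            neglog10p = float(parts[7])
            neglog10q = float(parts[8])
            offset = int(parts[9])
            summit = start + offset if offset >= 0 else start + (end - start) // 2
            support = 1
            if "|support=" in name:
                support = int(name.rsplit("|support=", 1)[1])
            try:
                iv = GenomicInterval(chrom, start, end, strand=strand,
                                     name=name, score=score)
                peaks.append(Peak(iv, summit, signal, neglog10p, neglog10q,
                                  replicate_support=support))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_narrowpeak(path: str | Path, peaks: Iterable[Peak]) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                "\t".join(
                    (
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        iv.name,
                        f"{iv.score:g}",
                        iv.strand,
                        repr(p.signal),
                        repr(p.neglog10p),
                        repr(p.neglog10q),
                        str(p.summit - iv.start),
                    )
                )
                + "\n"
            )


def consensus_peaks(
    replicates: Sequence[Sequence[Peak]], min_support: int = 2
) -> list[Peak]:
    """Peaks reproducible in at least ``min_support`` biological replicates.

    Peaks from all replicates are clustered by single-linkage overlap (>= 1 bp);
    a cluster touching >= ``min_support`` distinct replicates yields one
    consensus record: the highest-signal member, annotated with the number of
    supporting replicates.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if min_support > len(replicates):
        raise ValueError(
            f"min_support={min_support} exceeds {len(replicates)} replicates"
        )
    tagged: list[tuple[int, Peak]] = [
        (rep_idx, p) for rep_idx, reps in enumerate(replicates) for p in reps
    ]
    if not tagged:
        return []
    # cluster by overlap: merged union regions define the clusters
    import bisect

    regions = merge([p.interval for _, p in tagged], max_gap=0)
    region_key = {(r.chrom, r.start): i for i, r in enumerate(regions)}
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    starts_by_chrom = {
        chrom: [r.start for r in rs] for chrom, rs in by_chrom.items()
    }
    clusters: dict[int, list[tuple[int, Peak]]] = {}
    for rep_idx, p in tagged:
        rs = by_chrom[p.chrom]
        j = bisect.bisect_right(starts_by_chrom[p.chrom], p.start) - 1
        r = rs[j]
        if r.start <= p.start and p.end <= r.end:
            clusters.setdefault(region_key[(r.chrom, r.start)], []).append(
                (rep_idx, p)
            )
    out = []
    for members in clusters.values():
        support = len({rep_idx for rep_idx, _ in members})
        if support < min_support:
            continue
        best = max(members, key=lambda m: (m[1].signal, -m[1].start))[1]
        name = best.name.split("|support=")[0]
        iv = replace(best.interval, name=f"{name}|support={support}")
        out.append(replace(best, interval=iv, replicate_support=support))
    out.sort(key=lambda p: (p.chrom, p.start, p.end))
    return out


def signal_deciles(peaks: Sequence[Peak], n_bins: int = 10) -> list[SignalBin]:
    """Split peaks into ``n_bins`` near-equal bins by descending signal.

    Bin 1 holds the strongest peaks; remainder elements go to the strongest
    bins first.  Ties in signal break by (chrom, start).
    """
    if len(peaks) < n_bins:
        raise ValueError(
            f"need >= {n_bins} peaks for {n_bins} bins, got {len(peaks)}; "
            "reduce the bin count in the configuration"
        )
    ranked = sorted(peaks, key=lambda p: (-p.signal, p.chrom, p.start))
    base, extra = divmod(len(ranked), n_bins)
    bins = []
    pos = 0
    for i in range(n_bins):
        size = base + (1 if i < extra else 0)
        bins.append(SignalBin(i + 1, tuple(ranked[pos : pos + size])))
        pos += size
    return bins
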