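"""Transposable-element content, age and enrichment of binding sites.

Repeat annotations arrive as a TSV distilled from a RepeatMasker-style
annotation: one row per repeat fragment with family, superfamily, percent
divergence from the family consensus (a proxy for insertion age: lower =
younger) and an element id grouping fragments of a single interrupted copy.

The per-peak profile reports the fraction of peak sequence masked by repeats
overall and per superfamily, the dominant family, and a length-weighted mean
divergence ("age") of the overlapping elements.  Cross-superfamily
overlapping annotations are resolved by assigning each base to the
lower-divergence (younger) element.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .intervals import GenomicInterval, Karyotype, merge
from .peaks import Peak, SignalBin
from .stats import TestResult, binom_test, bonferroni, chisq_gof

__all__ = [
    "RepeatElement",
    "RepeatProfile",
    "SUPERFAMILIES",
    "merge_fragments",
    "repeat_profile",
    "profile_peaks",
    "genome_background",
    "enrichment_tests",
    "repeat_by_signal_bin",
    "read_repeat_tsv",
    "write_repeat_tsv",
]

SUPERFAMILIES = ("SINE", "LINE", "LTR", "DNA", "Simple", "Other")

REPEAT_TSV_COLUMNS = (
    "chrom",
    "start",
    "end",
    "strand",
    "family",
    "superfamily",
    "pct_divergence",
    "element_id",
)


@dataclass(frozen=True)
class RepeatElement:
    interval: GenomicInterval
    family: str
    superfamily: str
    pct_divergence: float
    element_id: str

    def __post_init__(self):
        if not (0 <= self.pct_divergence <= 100):
            raise ValueError("pct_divergence must be in [0, 100]")
        if self.superfamily not in SUPERFAMILIES:
            raise ValueError(f"unknown superfamily {self.superfamily!r}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class RepeatProfile:
    peak_id: str
    masked_fraction: float
    superfamily_fractions: Mapping[str, float]
    dominant_family: Optional[str]
    age: Optional[float]  # length-weighted mean pct_divergence, None if unmasked


def merge_fragments(repeats: Iterable[RepeatElement]) -> list[RepeatElement]:
    """Join fragments sharing an element_id into one spanning element.

    The merged element spans the union of its fragments; its divergence is
    the length-weighted mean of fragment divergences.
    """
    groups: dict[str, list[RepeatElement]] = {}
    for r in repeats:
        groups.setdefault(r.element_id, []).append(r)
    out = []
    for eid, frags in groups.items():
        chroms = {f.chrom for f in frags}
        if len(chroms) > 1:
            raise ValueError(
                f"fragments of element {eid!r} span chromosomes {sorted(chroms)}"
            )
        if len(frags) == 1:
            out.append(frags[0])
            continue
        lengths = np.array([f.interval.length for f in frags], dtype=float)
        divs = np.array([f.pct_divergence for f in frags], dtype=float)
        span = GenomicInterval(
            frags[0].chrom,
            min(f.interval.start for f in frags),
            max(f.interval.end for f in frags),
            strand=frags[0].interval.strand,
            name=eid,
        )
        out.append(
            replace(
                frags[0],
                interval=span,
                pct_divergence=float(np.average(divs, weights=lengths)),
            )
        )
    out.sort(key=lambda r: (r.chrom, r.interval.start))
    return out


def _overlapping(
    peak_iv: GenomicInterval, index: Mapping[str, tuple]
) -> list[RepeatElement]:
    entry = index.get(peak_iv.chrom)
    if entry is None:
        return []
    elems, starts, ends = entry
    mask = (starts < peak_iv.end) & (ends > peak_iv.start)
    return [elems[i] for i in np.flatnonzero(mask)]


def _index(repeats: Sequence[RepeatElement]) -> dict[str, tuple]:
    """Per-chromosome (elements, starts, ends) arrays for fast overlap lookup."""
    by_chrom: dict[str, list[RepeatElement]] = {}
    for r in repeats:
        by_chrom.setdefault(r.chrom, []).append(r)
    index = {}
    for chrom, rs in by_chrom.items():
        rs.sort(key=lambda x: x.interval.start)
        index[chrom] = (
            rs,
            np.fromiter((r.interval.start for r in rs), dtype=np.int64, count=len(rs)),
            np.fromiter((r.interval.end for r in rs), dtype=np.int64, count=len(rs)),
        )
    return index


def repeat_profile(
    peak: Peak | GenomicInterval, repeats_by_chrom: Mapping[str, list[RepeatElement]]
) -> RepeatProfile:
    """Masked fractions, dominant family and age for one peak.

    masked_fraction = union of overlapping repeat bases / peak length.
    Per-superfamily fractions use a base-level assignment: a base covered by
    several superfamilies counts once, for the lowest-divergence element.
    """
    iv = peak.interval if isinstance(peak, Peak) else peak
    overl = _overlapping(iv, repeats_by_chrom)
    if not overl:
        return RepeatProfile(iv.name, 0.0, {sf: 0.0 for sf in SUPERFAMILIES}, None, None)
    length = iv.length
    # per-base winner-takes-all at the lowest divergence
    owner_div = np.full(length, np.inf)
    owner_idx = np.full(length, -1, dtype=int)
    for i, r in enumerate(overl):
        s = max(iv.start, r.interval.start) - iv.start
        e = min(iv.end, r.interval.end) - iv.start
        claim = r.pct_divergence < owner_div[s:e]
        owner_div[s:e][claim] = r.pct_divergence
        owner_idx[s:e][claim] = i
    masked = owner_idx >= 0
    masked_fraction = float(masked.mean())
    sf_fracs = {sf: 0.0 for sf in SUPERFAMILIES}
    fam_bases: dict[str, int] = {}
    weights: dict[int, int] = {}
    for i in np.unique(owner_idx[masked]):
        bases = int((owner_idx == i).sum())
        r = overl[i]
        sf_fracs[r.superfamily] += bases / length
        fam_bases[r.family] = fam_bases.get(r.family, 0) + bases
        weights[i] = bases
    dominant = max(fam_bases, key=lambda f: (fam_bases[f], f))
    age = float(
        np.average(
            [overl[i].pct_divergence for i in weights],
            weights=[weights[i] for i in weights],
        )
    )
    return RepeatProfile(iv.name, masked_fraction, sf_fracs, dominant, age)


def profile_peaks(
    peaks: Sequence[Peak], repeats: Sequence[RepeatElement]
) -> list[RepeatProfile]:
    """Repeat profile for every peak (repeats should be fragment-merged)."""
    by_chrom = _index(repeats)
    return [repeat_profile(p, by_chrom) for p in peaks]


def genome_background(
    repeats: Sequence[RepeatElement], karyotype: Karyotype
) -> dict[str, float]:
    """Per-superfamily fraction of the genome covered by repeats.

    The sum total of sequence occupied by each superfamily divided by total
    genome length; same-superfamily overlaps are union-counted.
    """
    genome_len = sum(size for _, size in karyotype.items())
    fracs = {}
    for sf in SUPERFAMILIES:
        ivs = [r.interval for r in repeats if r.superfamily == sf]
        covered = sum(m.length for m in merge(ivs)) if ivs else 0
        fracs[sf] = covered / genome_len
    return fracs


def enrichment_tests(
    class_overlap_counts: Mapping[str, tuple[int, int]],
    reference_proportion: float,
    superfamily_counts: Optional[Mapping[str, Sequence[float]]] = None,
    superfamily_expected: Optional[Sequence[float]] = None,
) -> dict[str, dict[str, TestResult]]:
    """Binomial enrichment vs a reference proportion, per class.

    ``class_overlap_counts`` maps class name -> (overlapping, total).  When
    per-superfamily observed counts and an expected composition are supplied,
    a chi-square goodness-of-fit per class is added.  P-values are
    Bonferroni-adjusted across classes within each test family.
    """
    if not (0 < reference_proportion < 1):
        raise ValueError("reference_proportion must be in (0, 1)")
    classes = list(class_overlap_counts)
    binom_results = []
    for cls in classes:
        k, n = class_overlap_counts[cls]
        if n <= 0:
            raise ValueError(f"class {cls!r} has zero total")
        binom_results.append(binom_test(k, n, reference_proportion))
    binom_results = bonferroni(binom_results)
    out: dict[str, dict[str, TestResult]] = {
        cls: {"binomial": res} for cls, res in zip(classes, binom_results)
    }
    if superfamily_counts is not None:
        if superfamily_expected is None:
            raise ValueError("superfamily_expected required with superfamily_counts")
        chi_results = [
            chisq_gof(superfamily_counts[cls], superfamily_expected)
            for cls in classes
            if cls in superfamily_counts
        ]
        chi_results = bonferroni(chi_results)
        for cls, res in zip(
            [c for c in classes if c in superfamily_counts], chi_results
        ):
            out[cls]["chisq"] = res
    return out


def repeat_by_signal_bin(
    bins: Sequence[SignalBin],
    repeats: Sequence[RepeatElement],
    families: Optional[Sequence[str]] = None,
    aggregate: str = "mean",
) -> list[Optional[float]]:
    """Per-signal-bin aggregate masked fraction (optionally family-restricted).

    ``families`` restricts masking to the named repeat families (e.g. B2/B4
    SINEs).  Empty bins report None, not 0.  ``aggregate`` is 'mean' or
    'median' of per-peak masked fractions.
    """
    if aggregate not in ("mean", "median"):
        raise ValueError("aggregate must be 'mean' or 'median'")
    if families is not None:
        repeats = [r for r in repeats if r.family in set(families)]
    by_chrom = _index(repeats)
    agg = np.mean if aggregate == "mean" else np.median
    out: list[Optional[float]] = []
    for b in bins:
        if not b.peaks:
            out.append(None)
            continue
        fracs = [repeat_profile(p, by_chrom).masked_fraction for p in b.peaks]
        out.append(float(agg(fracs)))
    return out


def read_repeat_tsv(path: str | Path) -> list[RepeatElement]:
    """Read the 8-column repeat annotation TSV (header required)."""
    out = []
    with open(path) as fh:
        header = tuple(fh.readline().rstrip("\n").split("\t"))
        if header != REPEAT_TSV_COLUMNS:
            raise ValueError(f"{path}: unexpected repeat header {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            chrom, start, end, strand, fam, sf, div, eid = line.split("\t")[:8]
            out.append(
                RepeatElement(
                    GenomicInterval(chrom, int(start), int(end), strand=strand, name=eid),
                    fam,
                    sf,
                    float(div),
                    eid,
                )
            )
    return out


def write_repeat_tsv(path: str | Path, repeats: Iterable[RepeatElement]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(REPEAT_TSV_COLUMNS) + "\n")
        for r in repeats:
            iv = r.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t{r.family}\t"
                f"{r.superfamily}\t{r.pct_divergence:g}\t{r.element_id}\n"
            )
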