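"""Motif orientation at TAD boundaries and cohesin colocalisation.

CTCF's canonical motif is directional; at TAD boundaries, loop-anchor CTCF
sites tend to point into the domain interior ("favourable" orientation,
consistent with convergent loop anchors).  This module scans peak sequences
with a position weight matrix (log2 odds against a background, both
strands), selects the summit-proximal hit per peak with an alternative-motif
fallback, relates peaks to TAD boundaries, and measures colocalisation of
CTCF with regions bound by at least two cohesin subunits (RAD21 plus STAG1
and/or STAG2).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .intervals import GenomicInterval
from .peaks import Peak, SignalBin
from .stats import TestResult, chisq_gof

__all__ = [
    "PWM",
    "MotifHit",
    "TADBoundary",
    "CohesinRegion",
    "read_meme_motifs",
    "scan_pwm",
    "select_motif",
    "tad_boundaries",
    "boundary_association",
    "orientation_call",
    "boundary_clusters",
    "cohesin_merge",
    "cohesin_colocalisation",
    "cooccupancy_by_signal",
]

BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")

FAVOURABLE = "favourable"
REVERSE = "reverse"
BOUNDARY_WINDOW = 50_000


@dataclass(frozen=True)
class PWM:
    """Per-position base probabilities with pseudocount normalisation."""

    motif_id: str
    matrix: np.ndarray  # shape (width, 4), columns ordered A, C, G, T
    pseudocount: float = 1e-3
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("matrix must have shape (width, 4)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        m = m + self.pseudocount
        m = m / m.sum(axis=1, keepdims=True)
        object.__setattr__(self, "matrix", m)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.matrix / np.asarray(self.background))

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def reverse_complement(self) -> "PWM":
        rc = self.matrix[::-1, ::-1]
        return PWM(self.motif_id, rc, 1e-12, self.background)


@dataclass(frozen=True)
class MotifHit:
    peak_id: str
    start: int  # absolute bp of the hit's leftmost base
    strand: str
    score: float  # log-odds bits
    dist_to_summit: int
    motif_id: str = ""
    canonical: bool = True


@dataclass(frozen=True)
class TADBoundary:
    position: int
    side: str  # 'start' or 'end'
    tad_id: str
    chrom: str


@dataclass(frozen=True)
class CohesinRegion:
    interval: GenomicInterval
    n_subunits: int
    subunits: frozenset[str]

    def __post_init__(self):
        if self.n_subunits < 2:
            raise ValueError("cohesin region requires >= 2 subunits")


def read_meme_motifs(path: str | Path) -> list[PWM]:
    """Read MEME minimal motif format (letter-probability matrices)."""
    motifs = []
    name = None
    rows: list[list[float]] = []
    in_matrix = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                if name is not None and rows:
                    motifs.append(PWM(name, np.array(rows)))
                name = line.split()[1]
                rows = []
                in_matrix = False
            elif line.startswith("letter-probability matrix"):
                in_matrix = True
            elif in_matrix:
                try:
                    vals = [float(x) for x in line.split()]
                except ValueError:
                    in_matrix = False
                    continue
                if len(vals) == 4:
                    rows.append(vals)
                else:
                    in_matrix = False
    if name is not None and rows:
        motifs.append(PWM(name, np.array(rows)))
    if not motifs:
        raise ValueError(f"{path}: no motifs found")
    return motifs


def _encode(sequence: str) -> np.ndarray:
    """A=0 C=1 G=2 T=3, anything else (incl. N) = -1."""
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut[np.frombuffer(sequence.encode(), dtype=np.uint8)]


def scan_pwm(
    sequence: str,
    pwm: PWM,
    threshold: Optional[float] = None,
    peak_id: str = "",
    offset: int = 0,
    summit: Optional[int] = None,
) -> list[MotifHit]:
    """Log-odds scan of both strands; hits with score >= threshold, by position.

    ``threshold`` defaults to 60% of the motif's maximum attainable log-odds
    score.  Windows containing non-ACGT characters are skipped.  ``offset``
    is the absolute coordinate of the sequence's first base; ``summit`` (if
    given, absolute) fills each hit's distance to the peak summit.
    """
    if threshold is None:
        threshold = 0.6 * pwm.max_score
    w = pwm.width
    enc = _encode(sequence)
    n = enc.size - w + 1
    if n <= 0:
        return []
    lo_fwd = pwm.log_odds
    # rc motif scored against the same background: exact strand symmetry
    lo_rev = np.log2(pwm.matrix[::-1, ::-1] / np.asarray(pwm.background))
    # window matrix of base indices
    idx = np.lib.stride_tricks.sliding_window_view(enc, w)
    valid = (idx >= 0).all(axis=1)
    hits = []
    pos_range = np.arange(n)
    for strand, lo in (("+", lo_fwd), ("-", lo_rev)):
        safe = np.where(idx < 0, 0, idx)
        scores = lo[np.arange(w)[None, :], safe].sum(axis=1)
        keep = valid & (scores >= threshold)
        for pos in pos_range[keep]:
            start = offset + int(pos)
            d = abs((start + w // 2) - summit) if summit is not None else 0
            hits.append(
                MotifHit(peak_id, start, strand, float(scores[pos]), d, pwm.motif_id)
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def select_motif(
    peak: Peak,
    hits: Sequence[MotifHit],
    sequence: str = "",
    alternative_pwms: Sequence[PWM] = (),
) -> Optional[MotifHit]:
    """Summit-proximal canonical hit, else best-scoring alternative hit.

    With >= 1 canonical hit the one nearest the consensus summit wins (ties:
    higher score, then leftmost).  With none, each alternative motif is
    scanned over ``sequence`` (assumed to start at the peak start) and the
    best-scoring hit overall is returned flagged non-canonical; None when
    nothing matches.
    """
    if hits:
        best = min(hits, key=lambda h: (h.dist_to_summit, -h.score, h.start))
        return best
    best_alt: Optional[MotifHit] = None
    for pwm in alternative_pwms:
        for h in scan_pwm(
            sequence, pwm, peak_id=peak.name, offset=peak.start, summit=peak.summit
        ):
            if best_alt is None or (h.score, -h.dist_to_summit) > (
                best_alt.score,
                -best_alt.dist_to_summit,
            ):
                best_alt = h
    if best_alt is not None:
        best_alt = MotifHit(
            best_alt.peak_id,
            best_alt.start,
            best_alt.strand,
            best_alt.score,
            best_alt.dist_to_summit,
            best_alt.motif_id,
            canonical=False,
        )
    return best_alt


def tad_boundaries(tads: Sequence[GenomicInterval]) -> list[TADBoundary]:
    """Start and end boundary per TAD; no deduplication across TADs."""
    out = []
    for i, t in enumerate(tads):
        tad_id = t.name if t.name != "." else f"tad{i}"
        out.append(TADBoundary(t.start, "start", tad_id, t.chrom))
        out.append(TADBoundary(t.end, "end", tad_id, t.chrom))
    return out


def boundary_association(
    peaks: Sequence[Peak],
    boundaries: Sequence[TADBoundary],
    window: int = BOUNDARY_WINDOW,
) -> dict[str, tuple[Optional[TADBoundary], Optional[int], bool]]:
    """Nearest boundary per peak by |summit - position|, association flag.

    Signed distance = summit - boundary position; associated iff |d| <=
    window.  Ties break toward the smaller boundary position.
    """
    by_chrom: dict[str, list[TADBoundary]] = {}
    for b in boundaries:
        by_chrom.setdefault(b.chrom, []).append(b)
    out = {}
    for p in peaks:
        cands = by_chrom.get(p.chrom)
        if not cands:
            out[p.name] = (None, None, False)
            continue
        best = min(cands, key=lambda b: (abs(p.summit - b.position), b.position))
        d = p.summit - best.position
        out[p.name] = (best, d, abs(d) <= window)
    return out


def orientation_call(motif: MotifHit, boundary: TADBoundary) -> str:
    """Favourable iff the motif points into the TAD interior."""
    if motif.strand not in ("+", "-"):
        raise ValueError("motif strand must be + or -")
    if boundary.side == "start":
        return FAVOURABLE if motif.strand == "+" else REVERSE
    return FAVOURABLE if motif.strand == "-" else REVERSE


def boundary_clusters(
    boundaries: Sequence[TADBoundary],
    favourable_peaks_with_class: Sequence[tuple[Peak, str]],
    window: int = BOUNDARY_WINDOW,
) -> dict[tuple[str, int, str], tuple[int, Optional[str]]]:
    """Per-boundary favourable-site count and evolutionary composition.

    Input peaks must already be restricted to favourable orientation.  Each
    peak counts toward every boundary within ``window`` of its summit.
    Composition is 'common_only', 'specific_only' or 'mixed' (None for
    boundaries with no sites).  Keys are (chrom, position, side).
    """
    out: dict[tuple[str, int, str], tuple[int, Optional[str]]] = {}
    by_chrom: dict[str, list[tuple[Peak, str]]] = {}
    for p, cls in favourable_peaks_with_class:
        by_chrom.setdefault(p.chrom, []).append((p, cls))
    for b in boundaries:
        classes = [
            cls
            for p, cls in by_chrom.get(b.chrom, ())
            if abs(p.summit - b.position) <= window
        ]
        if not classes:
            out[(b.chrom, b.position, b.side)] = (0, None)
            continue
        kinds = {"common" if c == "musculus_common" else "specific" for c in classes}
        comp = "mixed" if len(kinds) == 2 else f"{kinds.pop()}_only"
        out[(b.chrom, b.position, b.side)] = (len(classes), comp)
    return out


def cohesin_merge(
    subunit_peaks: Mapping[str, Sequence[Peak]]
) -> list[CohesinRegion]:
    """Maximal constant-count regions covered by >= 2 cohesin subunit sets.

    Coverage is counted per subunit (each subunit's peaks are union-collapsed
    first); output segments break wherever the set of covering subunits
    changes.
    """
    from .intervals import merge as _merge

    events: dict[str, list[tuple[int, int, str]]] = {}
    for name, peaks in subunit_peaks.items():
        for iv in _merge([p.interval for p in peaks]):
            events.setdefault(iv.chrom, []).append((iv.start, iv.end, name))
    out = []
    for chrom in sorted(events):
        points = sorted(
            {x for s, e, _ in events[chrom] for x in (s, e)}
        )
        for s, e in zip(points, points[1:]):
            covering = frozenset(
                name for bs, be, name in events[chrom] if bs <= s and e <= be
            )
            if len(covering) >= 2:
                out.append(
                    CohesinRegion(
                        GenomicInterval(chrom, s, e), len(covering), covering
                    )
                )
    # join adjacent segments with identical subunit sets
    joined: list[CohesinRegion] = []
    for reg in out:
        if (
            joined
            and joined[-1].interval.chrom == reg.interval.chrom
            and joined[-1].interval.end == reg.interval.start
            and joined[-1].subunits == reg.subunits
        ):
            prev = joined.pop()
            joined.append(
                CohesinRegion(
                    GenomicInterval(
                        reg.interval.chrom, prev.interval.start, reg.interval.end
                    ),
                    reg.n_subunits,
                    reg.subunits,
                )
            )
        else:
            joined.append(reg)
    return joined


def cohesin_colocalisation(
    peaks_with_class: Sequence[tuple[Peak, str]],
    cohesin_regions: Sequence[CohesinRegion],
) -> tuple[dict[str, float], dict[str, TestResult]]:
    """Per-class colocalised fraction and chi-square vs the pooled rate.

    A peak colocalises when it overlaps (>= 1 bp) any cohesin region.  Each
    class's colocalised/not counts are tested goodness-of-fit against the
    all-peaks proportion; degenerate pooled proportions (0 or 1) yield p = 1.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in cohesin_regions:
        by_chrom.setdefault(r.interval.chrom, []).append(r.interval)
    flags: list[tuple[str, bool]] = []
    for p, cls in peaks_with_class:
        hit = any(
            iv.start < p.end and p.start < iv.end
            for iv in by_chrom.get(p.chrom, ())
        )
        flags.append((cls, hit))
    total = len(flags)
    pooled = sum(h for _, h in flags) / total if total else 0.0
    fractions: dict[str, float] = {}
    tests: dict[str, TestResult] = {}
    for cls in dict.fromkeys(c for c, _ in flags):
        sub = [h for c, h in flags if c == cls]
        if not sub:
            continue
        frac = sum(sub) / len(sub)
        fractions[cls] = frac
        if 0 < pooled < 1:
            tests[cls] = chisq_gof(
                [sum(sub), len(sub) - sum(sub)],
                [pooled * len(sub), (1 - pooled) * len(sub)],
            )
        else:
            tests[cls] = TestResult("chisq_gof", 0.0, 1.0)
    return fractions, tests


def cooccupancy_by_signal(
    class_bins: Mapping[str, Sequence[SignalBin]],
    cohesin_regions: Sequence[CohesinRegion],
) -> dict[str, list[Optional[float]]]:
    """Per-signal-bin colocalised fraction for each class; None for empty bins."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in cohesin_regions:
        by_chrom.setdefault(r.interval.chrom, []).append(r.interval)

    def _frac(peaks: Sequence[Peak]) -> Optional[float]:
        if not peaks:
            return None
        n_hit = sum(
            any(
                iv.start < p.end and p.start < iv.end
                for iv in by_chrom.get(p.chrom, ())
            )
            for p in peaks
        )
        return n_hit / len(peaks)

    return {
        cls: [_frac(b.peaks) for b in bins] for cls, bins in class_bins.items()
    }
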