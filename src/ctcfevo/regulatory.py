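"""Regulatory-element definition, TSS proximity and DE-gene association.

Active regulatory elements are derived from histone-mark consensus peaks:
every H3K4me3 peak is a promoter (alone or with overlapping H3K27ac), and
every H3K27ac peak not overlapping any H3K4me3 peak is an enhancer.

Differentially expressed (DE) genes are associated with CTCF sites within a
+/- 50 kb window of the gene body, and the association's evolutionary class
is assigned by majority vote: the common class wins only when strictly more
common sites are present than EITHER subspecies-specific variety; otherwise
the gene is associated with a specific site, shared vs specific decided by
the more numerous variety (tie -> tissue_shared).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .intervals import GenomicInterval
from .peaks import Peak
from .tissues import TISSUE_SHARED, TISSUE_SPECIFIC

__all__ = [
    "RegulatoryElement",
    "DEGene",
    "GeneRegProfile",
    "define_regulatory",
    "distance_to_tss",
    "nearest_regulatory",
    "associate_de_genes",
    "profile_genes",
    "read_gene_tsv",
    "write_gene_tsv",
    "read_de_table",
    "write_de_table",
    "filter_de",
]

CLASS_COMMON = "musculus_common"
CLASS_SHARED = TISSUE_SHARED
CLASS_SPECIFIC = TISSUE_SPECIFIC
TSS_POOL_WINDOW = 100_000  # distances beyond +/- 100 kb are pooled
ASSOC_WINDOW = 50_000  # DE-gene association window around the gene body


@dataclass(frozen=True)
class RegulatoryElement:
    interval: GenomicInterval
    kind: str  # 'promoter' or 'enhancer'

    def __post_init__(self):
        if self.kind not in ("promoter", "enhancer"):
            raise ValueError(f"invalid kind {self.kind!r}")


@dataclass(frozen=True)
class DEGene:
    gene_id: str
    body: GenomicInterval
    tss: int
    strand: str
    log2fc: float  # positive = up in the focal subspecies
    fdr: float

    def __post_init__(self):
        if self.tss not in (self.body.start, self.body.end - 1, self.body.end):
            raise ValueError(
                f"TSS {self.tss} must sit at a gene-body edge of {self.body}"
            )
        if not (0 <= self.fdr <= 1):
            raise ValueError("fdr must be in [0, 1]")


@dataclass(frozen=True)
class GeneRegProfile:
    gene_id: str
    has_ctcf: bool
    has_promoter: bool
    n_enhancers_50kb: int
    ctcf_class: Optional[str]
    profile: Optional[str]  # one of the four CTCF-anchored profiles
    direction: Optional[str]  # 'up' or 'down'


def define_regulatory(
    h3k4me3_peaks: Sequence[Peak], h3k27ac_peaks: Sequence[Peak]
) -> list[RegulatoryElement]:
    """Promoters from H3K4me3, enhancers from H3K27ac-alone regions."""
    k4_by_chrom: dict[str, list[Peak]] = {}
    for p in h3k4me3_peaks:
        k4_by_chrom.setdefault(p.chrom, []).append(p)
    out = [RegulatoryElement(p.interval, "promoter") for p in h3k4me3_peaks]
    for p in h3k27ac_peaks:
        overlapped = any(
            q.start < p.end and p.start < q.end
            for q in k4_by_chrom.get(p.chrom, ())
        )
        if not overlapped:
            out.append(RegulatoryElement(p.interval, "enhancer"))
    out.sort(key=lambda e: (e.interval.chrom, e.interval.start))
    return out


def distance_to_tss(
    peaks: Sequence[Peak],
    genes: Sequence[DEGene],
    pool_window: int = TSS_POOL_WINDOW,
) -> dict[str, Optional[int]]:
    """Signed summit-to-nearest-TSS distance per peak (gene orientation).

    Negative = peak upstream of the gene; distances beyond ``pool_window``
    are clamped to +/- pool_window (the overflow pools).  Peaks on
    chromosomes without genes map to None.
    """
    by_chrom: dict[str, list[DEGene]] = {}
    for g in genes:
        by_chrom.setdefault(g.body.chrom, []).append(g)
    out: dict[str, Optional[int]] = {}
    for p in peaks:
        cands = by_chrom.get(p.chrom)
        if not cands:
            out[p.name] = None
            continue
        best_g = min(cands, key=lambda g: (abs(p.summit - g.tss), g.tss))
        d = p.summit - best_g.tss
        if best_g.strand == "-":
            d = -d
        out[p.name] = max(-pool_window, min(pool_window, d))
    return out


def nearest_regulatory(
    ctcf_peaks: Sequence[Peak], regels: Sequence[RegulatoryElement]
) -> dict[str, Optional[tuple[str, int]]]:
    """Nearest non-overlapping regulatory element per peak: (kind, distance).

    Elements overlapping the peak are excluded (those are colocalisations
    handled separately); ties on distance break toward the smaller start.
    Returns None for peaks with no non-overlapping element on their
    chromosome.
    """
    by_chrom: dict[str, list[RegulatoryElement]] = {}
    for e in regels:
        by_chrom.setdefault(e.interval.chrom, []).append(e)
    out: dict[str, Optional[tuple[str, int]]] = {}
    for p in ctcf_peaks:
        best: Optional[RegulatoryElement] = None
        best_d = None
        for e in by_chrom.get(p.chrom, ()):
            iv = e.interval
            if iv.start < p.end and p.start < iv.end:
                continue  # overlap -> excluded
            d = iv.start - p.end if iv.start >= p.end else p.start - iv.end
            if (
                best_d is None
                or d < best_d
                or (d == best_d and iv.start < best.interval.start)
            ):
                best, best_d = e, d
        out[p.name] = (best.kind, best_d) if best is not None else None
    return out


def _majority_class(n_common: int, n_shared: int, n_specific: int) -> str:
    """Majority vote over the class counts around one gene.

    Common wins only with strictly more common sites than either specific
    variety; otherwise the more numerous specific variety wins, ties going
    to tissue_shared.
    """
    if n_common > n_shared and n_common > n_specific:
        return CLASS_COMMON
    return CLASS_SHARED if n_shared >= n_specific else CLASS_SPECIFIC


def associate_de_genes(
    de_genes: Sequence[DEGene],
    peaks_with_class: Sequence[tuple[Peak, str]],
    window: int = ASSOC_WINDOW,
) -> dict[str, Optional[str]]:
    """Per-gene associated CTCF class, or None when no site is in the window.

    A gene is associated when >= 1 classified peak lies within ``window`` bp
    of the gene body (overlap = distance 0).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    by_chrom: dict[str, list[tuple[Peak, str]]] = {}
    for p, cls in peaks_with_class:
        by_chrom.setdefault(p.chrom, []).append((p, cls))
    out: dict[str, Optional[str]] = {}
    for g in de_genes:
        counts = {CLASS_COMMON: 0, CLASS_SHARED: 0, CLASS_SPECIFIC: 0}
        for p, cls in by_chrom.get(g.body.chrom, ()):
            gap = max(g.body.start - p.end, p.start - g.body.end, 0)
            if gap <= window:
                counts[cls] += 1
        if sum(counts.values()) == 0:
            out[g.gene_id] = None
        else:
            out[g.gene_id] = _majority_class(
                counts[CLASS_COMMON], counts[CLASS_SHARED], counts[CLASS_SPECIFIC]
            )
    return out


def profile_genes(
    de_genes: Sequence[DEGene],
    regels: Sequence[RegulatoryElement],
    ctcf_associations: Mapping[str, Optional[str]],
    window: int = ASSOC_WINDOW,
) -> list[GeneRegProfile]:
    """Regulatory-context profile for each DE gene.

    has_promoter iff a promoter overlaps the TSS (at most one is assigned,
    larger overlap then leftmost winning a tie); enhancers are counted
    without positional restraint within +/- window of the gene body.
    """
    proms = [e for e in regels if e.kind == "promoter"]
    enhs = [e for e in regels if e.kind == "enhancer"]
    proms_by_chrom: dict[str, list[RegulatoryElement]] = {}
    for e in proms:
        proms_by_chrom.setdefault(e.interval.chrom, []).append(e)
    enhs_by_chrom: dict[str, list[RegulatoryElement]] = {}
    for e in enhs:
        enhs_by_chrom.setdefault(e.interval.chrom, []).append(e)
    out = []
    for g in de_genes:
        assoc = ctcf_associations.get(g.gene_id)
        has_ctcf = assoc is not None
        # single promoter assigned at the TSS
        tss_candidates = [
            e
            for e in proms_by_chrom.get(g.body.chrom, ())
            if e.interval.start <= g.tss < e.interval.end
        ]
        has_promoter = bool(tss_candidates)
        n_enh = sum(
            1
            for e in enhs_by_chrom.get(g.body.chrom, ())
            if max(g.body.start - e.interval.end, e.interval.start - g.body.end, 0)
            <= window
        )
        profile = None
        if has_ctcf:
            if has_promoter and n_enh > 0:
                profile = "ctcf_promoter_enhancer"
            elif has_promoter:
                profile = "ctcf_promoter"
            elif n_enh > 0:
                profile = "ctcf_enhancer"
            else:
                profile = "ctcf_only"
        direction = None
        if g.log2fc != 0:
            direction = "up" if g.log2fc > 0 else "down"
        out.append(
            GeneRegProfile(
                g.gene_id, has_ctcf, has_promoter, n_enh, assoc, profile, direction
            )
        )
    return out


def filter_de(genes: Sequence[DEGene], fdr_threshold: float = 0.05) -> list[DEGene]:
    """Strict FDR filter for differential expression."""
    return [g for g in genes if g.fdr < fdr_threshold]


# ---------------------------------------------------------------------------
# I/O: gene models as 6-column TSV; DE table as 3-column TSV

def read_gene_tsv(path: str | Path, de_table: Optional[Mapping[str, tuple[float, float]]] = None) -> list[DEGene]:
    """Read gene models (id, chrom, start, end, strand, tss), header required.

    When a DE table mapping ``gene_id -> (log2fc, fdr)`` is given, those
    values are attached; genes absent from it get log2fc = 0, fdr = 1.
    """
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:6] != ["gene_id", "chrom", "start", "end", "strand", "tss"]:
            raise ValueError(f"{path}: unexpected gene header {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            gid, chrom, start, end, strand, tss = line.split("\t")[:6]
            lfc, fdr = (0.0, 1.0)
            if de_table is not None and gid in de_table:
                lfc, fdr = de_table[gid]
            out.append(
                DEGene(
                    gid,
                    GenomicInterval(chrom, int(start), int(end), strand=strand, name=gid),
                    int(tss),
                    strand,
                    lfc,
                    fdr,
                )
            )
    return out


def write_gene_tsv(path: str | Path, genes: Sequence[DEGene]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\ttss\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.body.chrom}\t{g.body.start}\t{g.body.end}\t"
                f"{g.strand}\t{g.tss}\n"
            )


def read_de_table(path: str | Path) -> dict[str, tuple[float, float]]:
    out = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["gene_id", "log2fc", "fdr"]:
            raise ValueError(f"{path}: unexpected DE header {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            gid, lfc, fdr = line.split("\t")[:3]
            out[gid] = (float(lfc), float(fdr))
    return out


def write_de_table(path: str | Path, table: Mapping[str, tuple[float, float]]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlog2fc\tfdr\n")
        for gid, (lfc, fdr) in table.items():
            fh.write(f"{gid}\t{lfc:g}\t{fdr:g}\n")
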