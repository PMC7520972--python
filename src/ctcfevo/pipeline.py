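"""Stage orchestration over a generated (or user-supplied) file bundle.

Each stage reads its inputs from the bundle directory, writes its outputs
into a run directory, and returns the key quantities as a plain dict (which
the CLI serialises into the run manifest).  Stages are individually
re-runnable; ``run_all`` executes them in dependency order.

Peak classes used by the class-stratified stages are the three the
cross-tissue analysis distinguishes: ``musculus_common``, and the
subspecies-specific sites split into ``tissue_shared`` and
``tissue_specific``.  Aligned-but-unbound sites are carried in the class
table but excluded from the three-class statistics.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from . import evo_class, regulatory, repeats, tad_cohesin, tissues
from .intervals import read_bed, read_chrom_sizes
from .peaks import Peak, consensus_peaks, read_narrowpeak, signal_deciles, write_narrowpeak
from .tissues import TISSUE_SHARED, TISSUE_SPECIFIC

__all__ = [
    "base_name",
    "run_consensus",
    "run_classify",
    "run_repeats",
    "run_tissues",
    "run_regulatory",
    "run_tad",
    "run_cohesin",
    "run_all",
]

CLASS_COMMON = "musculus_common"


def base_name(peak: Peak) -> str:
    """Peak name with any consensus support annotation stripped."""
    return peak.name.split("|support=")[0]


def _strip_support(peaks: Sequence[Peak]) -> list[Peak]:
    from dataclasses import replace

    out = []
    for p in peaks:
        if "|support=" in p.name:
            iv = replace(p.interval, name=base_name(p))
            out.append(replace(p, interval=iv))
        else:
            out.append(p)
    return out


def _write_tsv(path: Path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join("" if v is None else str(v) for v in row) + "\n")


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)


def run_consensus(bundle: Path, rundir: Path, min_support: int = 2) -> dict:
    """Replicate-consensus CTCF peaks for both subspecies."""
    out = {}
    for tag in ("A", "B"):
        reps = []
        r = 1
        while (bundle / f"ctcf{tag}_rep{r}.narrowPeak").exists():
            reps.append(read_narrowpeak(bundle / f"ctcf{tag}_rep{r}.narrowPeak"))
            r += 1
        if not reps:
            raise FileNotFoundError(f"no ctcf{tag}_rep*.narrowPeak in {bundle}")
        cons = consensus_peaks(reps, min_support=min_support)
        write_narrowpeak(rundir / f"consensus{tag}.narrowPeak", cons)
        out[f"n_consensus_{tag}"] = len(cons)
        out[f"n_replicates_{tag}"] = len(reps)
    return out


def _load_consensus(rundir: Path, tag: str) -> list[Peak]:
    return _strip_support(read_narrowpeak(rundir / f"consensus{tag}.narrowPeak"))


def run_classify(
    bundle: Path, rundir: Path, min_mapped_fraction: float = 0.5
) -> dict:
    """Evolutionary class per subspecies-A consensus peak."""
    peaks_a = _load_consensus(rundir, "A")
    peaks_b = _load_consensus(rundir, "B")
    omap = evo_class.read_orthology_tsv(bundle / "orthology.tsv")
    labels = evo_class.classify(peaks_a, peaks_b, omap, min_mapped_fraction)
    _write_tsv(
        rundir / "peak_classes.tsv",
        ("peak_id", "evo_class"),
        [(n, lab.value) for n, lab in labels.items()],
    )
    counts: dict[str, int] = {}
    for lab in labels.values():
        counts[lab.value] = counts.get(lab.value, 0) + 1
    return {"class_counts": counts, "n_peaks": len(labels)}


def _read_classes(rundir: Path) -> dict[str, str]:
    out = {}
    with open(rundir / "peak_classes.tsv") as fh:
        fh.readline()
        for line in fh:
            name, cls = line.rstrip("\n").split("\t")
            out[name] = cls
    return out


def run_repeats(bundle: Path, rundir: Path) -> dict:
    """TE content per evolutionary class, background and enrichment tests."""
    peaks_a = _load_consensus(rundir, "A")
    classes = _read_classes(rundir)
    kary = read_chrom_sizes(bundle / "genomeA.chrom.sizes")
    elements = repeats.merge_fragments(repeats.read_repeat_tsv(bundle / "repeats.tsv"))
    b2b4 = [r for r in elements if r.family in ("B2", "B4")]
    profiles = repeats.profile_peaks(peaks_a, elements)
    b2b4_profiles = repeats.profile_peaks(peaks_a, b2b4)
    background = repeats.genome_background(elements, kary)

    rows = []
    class_te_counts: dict[str, list[int]] = {}
    class_divs: dict[str, list[float]] = {}
    for p, prof, bprof in zip(peaks_a, profiles, b2b4_profiles):
        cls = classes[p.name]
        rows.append(
            (
                p.name,
                cls,
                f"{prof.masked_fraction:.4f}",
                f"{bprof.masked_fraction:.4f}",
                prof.dominant_family or "",
                "" if prof.age is None else f"{prof.age:.3f}",
            )
        )
        counts = class_te_counts.setdefault(cls, [0, 0])
        counts[0] += int(bprof.masked_fraction > 0)
        counts[1] += 1
        if bprof.age is not None:
            class_divs.setdefault(cls, []).append(bprof.age)
    _write_tsv(
        rundir / "repeat_profiles.tsv",
        ("peak_id", "evo_class", "masked_fraction", "b2b4_fraction",
         "dominant_family", "age"),
        rows,
    )
    b2b4_fraction = {
        cls: k / n for cls, (k, n) in class_te_counts.items() if n > 0
    }
    sine_background = background["SINE"]
    tests = repeats.enrichment_tests(
        {cls: (k, n) for cls, (k, n) in class_te_counts.items()},
        reference_proportion=max(min(sine_background, 0.99), 0.01),
    )
    report = {
        "b2b4_overlap_fraction": b2b4_fraction,
        "genome_background": background,
        "median_divergence": {
            cls: float(np.median(v)) for cls, v in class_divs.items() if v
        },
        "tests": {
            cls: {name: t.to_dict() for name, t in res.items()}
            for cls, res in tests.items()
        },
    }
    _write_json(rundir / "repeat_report.json", report)
    return report


def run_tissues(
    bundle: Path,
    rundir: Path,
    replicate_tissue: str = "liver_encode",
    top_k: int = 4,
    n_bins: int = 10,
) -> dict:
    """Occupancy matrix, diversity, conservation per bin, sharedness labels."""
    peaks_a = _load_consensus(rundir, "A")
    classes = _read_classes(rundir)
    tissue_sets = {}
    for f in sorted(bundle.glob("tissue_*.narrowPeak")):
        tissue_sets[f.stem.replace("tissue_", "")] = read_narrowpeak(f)
    matrix = tissues.build_occupancy(peaks_a, tissue_sets)
    matrix.to_csv(rundir / "occupancy.tsv", sep="\t")
    diversity = tissues.shannon_per_peak(matrix)
    diversity.to_csv(rundir / "diversity.tsv", sep="\t")
    labels = {
        n: evo_class.EvoClass(classes[n]) for n in diversity.index
    }
    cons_bins = tissues.conservation_per_bin(diversity, labels, n_bins=n_bins)
    combo = tissues.combination_counts(matrix)
    _write_json(
        rundir / "combination_counts.json",
        {"|".join(k) if k else "(none)": v for k, v in combo.items()},
    )
    focal = [
        n for n, c in classes.items()
        if c == evo_class.EvoClass.SPECIES_SPECIFIC_UNALIGNED.value
        and n in matrix.index
    ]
    sharedness = tissues.classify_sharedness(matrix, focal, replicate_tissue, top_k)
    _write_tsv(
        rundir / "sharedness.tsv",
        ("peak_id", "sharedness"),
        sorted(sharedness.items()),
    )
    n_shared = sum(1 for v in sharedness.values() if v == TISSUE_SHARED)
    report = {
        "n_tissues": len(tissue_sets),
        "conservation_per_bin": cons_bins,
        "shared_fraction_of_specific": n_shared / len(sharedness) if sharedness else None,
        "mean_shannon": float(diversity["shannon"].mean()),
    }
    _write_json(rundir / "tissue_report.json", report)
    return report


def _three_class(
    classes: Mapping[str, str], sharedness: Mapping[str, str]
) -> dict[str, str]:
    """Collapse evo class + sharedness into the three analysis classes."""
    out = {}
    for name, cls in classes.items():
        if cls == CLASS_COMMON:
            out[name] = CLASS_COMMON
        elif cls == evo_class.EvoClass.SPECIES_SPECIFIC_UNALIGNED.value:
            out[name] = sharedness.get(name, TISSUE_SPECIFIC)
    return out


def _read_sharedness(rundir: Path) -> dict[str, str]:
    out = {}
    with open(rundir / "sharedness.tsv") as fh:
        fh.readline()
        for line in fh:
            name, s = line.rstrip("\n").split("\t")
            out[name] = s
    return out


def run_regulatory(
    bundle: Path, rundir: Path, fdr_threshold: float = 0.05, window: int = 50_000
) -> dict:
    """Regulatory elements, DE-gene association and profile stratification."""
    peaks_a = _load_consensus(rundir, "A")
    classes = _read_classes(rundir)
    sharedness = _read_sharedness(rundir)
    three = _three_class(classes, sharedness)
    k4 = read_narrowpeak(bundle / "h3k4me3.narrowPeak")
    k27 = read_narrowpeak(bundle / "h3k27ac.narrowPeak")
    regels = regulatory.define_regulatory(k4, k27)
    de_table = regulatory.read_de_table(bundle / "de_table.tsv")
    genes = regulatory.read_gene_tsv(bundle / "genes.tsv", de_table)
    de_genes = regulatory.filter_de(genes, fdr_threshold)
    classified = [(p, three[p.name]) for p in peaks_a if p.name in three]
    assoc = regulatory.associate_de_genes(de_genes, classified, window=window)
    profiles = regulatory.profile_genes(de_genes, regels, assoc, window=window)
    _write_tsv(
        rundir / "gene_profiles.tsv",
        ("gene_id", "has_ctcf", "has_promoter", "n_enhancers_50kb",
         "ctcf_class", "profile", "direction"),
        [
            (g.gene_id, int(g.has_ctcf), int(g.has_promoter), g.n_enhancers_50kb,
             g.ctcf_class or "", g.profile or "", g.direction or "")
            for g in profiles
        ],
    )
    down_by_class: dict[str, list[int]] = {}
    for g in profiles:
        if g.ctcf_class and g.direction:
            down_by_class.setdefault(g.ctcf_class, []).append(
                1 if g.direction == "down" else 0
            )
    report = {
        "n_promoters": sum(1 for e in regels if e.kind == "promoter"),
        "n_enhancers": sum(1 for e in regels if e.kind == "enhancer"),
        "n_de_genes": len(de_genes),
        "n_associated": sum(1 for v in assoc.values() if v is not None),
        "down_fraction_by_class": {
            cls: sum(v) / len(v) for cls, v in down_by_class.items()
        },
        "n_genes_by_class": {cls: len(v) for cls, v in down_by_class.items()},
    }
    _write_json(rundir / "regulatory_report.json", report)
    return report


def run_tad(bundle: Path, rundir: Path, window: int = 50_000) -> dict:
    """Motif selection, boundary association and orientation per class."""
    from pyfaidx import Fasta

    peaks_a = _load_consensus(rundir, "A")
    classes = _read_classes(rundir)
    sharedness = _read_sharedness(rundir)
    three = _three_class(classes, sharedness)
    motifs = tad_cohesin.read_meme_motifs(bundle / "motifs.meme")
    canonical, alternatives = motifs[0], motifs[1:]
    tads = read_bed(bundle / "tads.bed")
    boundaries = tad_cohesin.tad_boundaries(tads)
    fasta = Fasta(str(bundle / "genomeA.fa"))
    assoc = tad_cohesin.boundary_association(peaks_a, boundaries, window=window)
    rows = []
    orient_by_class: dict[str, list[int]] = {}
    favourable_with_class = []
    for p in peaks_a:
        seq = str(fasta[p.chrom][p.start : p.end])
        hits = tad_cohesin.scan_pwm(
            seq, canonical, peak_id=p.name, offset=p.start, summit=p.summit
        )
        chosen = tad_cohesin.select_motif(p, hits, seq, alternatives)
        boundary, dist, associated = assoc[p.name]
        orientation = ""
        if chosen is not None and boundary is not None:
            orientation = tad_cohesin.orientation_call(chosen, boundary)
        rows.append(
            (
                p.name,
                three.get(p.name, classes[p.name]),
                "" if chosen is None else chosen.start,
                "" if chosen is None else chosen.strand,
                "" if chosen is None else f"{chosen.score:.3f}",
                "" if chosen is None else int(chosen.canonical),
                "" if dist is None else dist,
                int(associated),
                orientation,
            )
        )
        if chosen is not None and chosen.canonical and associated and p.name in three:
            cls = three[p.name]
            fav = orientation == tad_cohesin.FAVOURABLE
            orient_by_class.setdefault(cls, []).append(int(fav))
            if fav:
                favourable_with_class.append((p, cls))
    _write_tsv(
        rundir / "motif_boundary.tsv",
        ("peak_id", "class", "motif_start", "motif_strand", "motif_score",
         "canonical", "boundary_distance", "associated", "orientation"),
        rows,
    )
    clusters = tad_cohesin.boundary_clusters(
        boundaries, favourable_with_class, window=window
    )
    comp_counts: dict[str, int] = {}
    for n_sites, comp in clusters.values():
        if comp is not None:
            comp_counts[comp] = comp_counts.get(comp, 0) + 1
    report = {
        "favourable_fraction_by_class": {
            cls: sum(v) / len(v) for cls, v in orient_by_class.items() if v
        },
        "n_associated_with_motif": sum(
            len(v) for v in orient_by_class.values()
        ),
        "boundary_composition_counts": comp_counts,
    }
    _write_json(rundir / "tad_report.json", report)
    return report


def run_cohesin(bundle: Path, rundir: Path, n_bins: int = 10) -> dict:
    """Cohesin 2-of-3 merge, per-class colocalisation, signal co-occupancy."""
    peaks_a = _load_consensus(rundir, "A")
    classes = _read_classes(rundir)
    sharedness = _read_sharedness(rundir)
    three = _three_class(classes, sharedness)
    subunits = {
        name: read_narrowpeak(bundle / f"{name.lower()}.narrowPeak")
        for name in ("RAD21", "STAG1", "STAG2")
    }
    regions = tad_cohesin.cohesin_merge(subunits)
    with open(rundir / "cohesin_regions.bed", "w") as fh:
        for r in regions:
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                f"{','.join(sorted(r.subunits))}\t{r.n_subunits}\t.\n"
            )
    classified = [(p, three[p.name]) for p in peaks_a if p.name in three]
    fractions, tests = tad_cohesin.cohesin_colocalisation(classified, regions)
    class_bins = {}
    for cls in fractions:
        cls_peaks = [p for p, c in classified if c == cls]
        if len(cls_peaks) >= n_bins:
            class_bins[cls] = signal_deciles(cls_peaks, n_bins=n_bins)
    cooc = tad_cohesin.cooccupancy_by_signal(class_bins, regions)
    report = {
        "n_cohesin_regions": len(regions),
        "colocalised_fraction_by_class": fractions,
        "tests": {cls: t.to_dict() for cls, t in tests.items()},
        "cooccupancy_by_signal_bin": cooc,
    }
    _write_json(rundir / "cohesin_report.json", report)
    return report


STAGES = (
    ("consensus", run_consensus),
    ("classify", run_classify),
    ("repeats", run_repeats),
    ("tissues", run_tissues),
    ("regulatory", run_regulatory),
    ("tad", run_tad),
    ("cohesin", run_cohesin),
)


def run_all(bundle: Path, rundir: Path, skip_tad: bool = False) -> dict:
    """All stages in dependency order; returns the merged stage reports."""
    bundle, rundir = Path(bundle), Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    reports = {}
    if not (bundle / "genomeA.fa").exists():
        skip_tad = True  # no sequence, no motif scanning
    for name, fn in STAGES:
        if skip_tad and name == "tad":
            continue
        reports[name] = fn(bundle, rundir)
    manifest = {
        "stages": list(reports),
        "checksums": {
            f.name: hashlib.sha256(f.read_bytes()).hexdigest()
            for f in sorted(rundir.iterdir())
            if f.is_file() and f.name != "run_manifest.json"
        },
    }
    _write_json(rundir / "run_manifest.json", manifest)
    return reports
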