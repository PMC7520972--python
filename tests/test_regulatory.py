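"""Regulatory elements, TSS distances and DE-gene association rules."""

import itertools

import pytest

from ctcfevo.intervals import GenomicInterval
from ctcfevo.peaks import Peak
from ctcfevo.regulatory import (
    DEGene,
    associate_de_genes,
    define_regulatory,
    distance_to_tss,
    filter_de,
    nearest_regulatory,
    profile_genes,
    read_de_table,
    read_gene_tsv,
    write_de_table,
    write_gene_tsv,
    _majority_class,
)


def mk_peak(chrom, start, end, name="p", summit=None):
    return Peak(GenomicInterval(chrom, start, end, name=name),
                summit if summit is not None else (start + end) // 2, 1.0, 10.0)


def mk_gene(gid, chrom, start, end, strand="+", log2fc=1.0, fdr=0.01):
    tss = start if strand == "+" else end
    return DEGene(gid, GenomicInterval(chrom, start, end, strand=strand, name=gid),
                  tss, strand, log2fc, fdr)


# -------------------------------------------------------- regulatory element

def test_k4me3_with_overlapping_k27ac_is_promoter_only():
    k4 = [mk_peak("chr1", 100, 200)]
    k27 = [mk_peak("chr1", 150, 250)]
    regels = define_regulatory(k4, k27)
    assert [(e.kind, e.interval.start) for e in regels] == [("promoter", 100)]


def test_k27ac_alone_is_enhancer():
    regels = define_regulatory([], [mk_peak("chr1", 500, 600)])
    assert [(e.kind,) for e in regels] == [("enhancer",)]


def test_disjoint_sets_partition():
    k4 = [mk_peak("chr1", i * 10_000, i * 10_000 + 500) for i in range(5)]
    k27 = [mk_peak("chr1", 100_000 + i * 10_000, 100_000 + i * 10_000 + 500)
           for i in range(7)]
    regels = define_regulatory(k4, k27)
    kinds = [e.kind for e in regels]
    assert kinds.count("promoter") == 5 and kinds.count("enhancer") == 7


# ---------------------------------------------------------------- distances

def test_tss_distance_sign_convention():
    genes = [mk_gene("g", "chr1", 10_000, 20_000, "+")]
    up = [mk_peak("chr1", 8_800, 9_200, "up", summit=9_000)]
    assert distance_to_tss(up, genes)["up"] == -1000
    inside = [mk_peak("chr1", 14_800, 15_200, "in", summit=15_000)]
    assert distance_to_tss(inside, genes)["in"] == 5000
    # minus-strand gene: upstream is to the right
    genes_m = [mk_gene("g", "chr1", 10_000, 20_000, "-")]
    right = [mk_peak("chr1", 20_800, 21_200, "r", summit=21_000)]
    assert distance_to_tss(right, genes_m)["r"] == -1000


def test_tss_distance_pooled_beyond_window():
    genes = [mk_gene("g", "chr1", 500_000, 510_000, "+")]
    far = [mk_peak("chr1", 100, 500, "far", summit=300)]
    assert distance_to_tss(far, genes)["far"] == -100_000


def test_tss_distance_matches_brute_force(rng):
    genes = [mk_gene(f"g{i}", "chr1", int(s), int(s) + 5000,
                     "+" if rng.random() < 0.5 else "-")
             for i, s in enumerate(rng.integers(0, 900_000, size=100))]
    peaks = [mk_peak("chr1", int(s), int(s) + 200, f"p{i}")
             for i, s in enumerate(rng.integers(0, 900_000, size=200))]
    got = distance_to_tss(peaks, genes, pool_window=10**9)
    for p in peaks:
        best = min(genes, key=lambda g: (abs(p.summit - g.tss), g.tss))
        d = p.summit - best.tss
        if best.strand == "-":
            d = -d
        assert got[p.name] == d


def test_nearest_regulatory_excludes_overlap():
    peaks = [mk_peak("chr1", 10_000, 10_400, "a")]
    regels = define_regulatory(
        [mk_peak("chr1", 13_400, 13_800)],   # promoter at +3 kb
        [mk_peak("chr1", 18_400, 18_800)],   # enhancer at +8 kb
    )
    assert nearest_regulatory(peaks, regels)["a"] == ("promoter", 3000)
    only_overlap = define_regulatory([mk_peak("chr1", 10_100, 10_300)], [])
    assert nearest_regulatory(peaks, only_overlap)["a"] is None


def test_nearest_regulatory_matches_brute_force(rng):
    regels = define_regulatory(
        [mk_peak("chr1", int(s), int(s) + 300) for s in rng.integers(0, 900_000, 50)],
        [mk_peak("chr1", int(s), int(s) + 300) for s in rng.integers(0, 900_000, 50)],
    )
    peaks = [mk_peak("chr1", int(s), int(s) + 200, f"p{i}")
             for i, s in enumerate(rng.integers(0, 900_000, size=100))]
    got = nearest_regulatory(peaks, regels)
    for p in peaks:
        best, best_d = None, None
        for e in regels:
            iv = e.interval
            if iv.start < p.end and p.start < iv.end:
                continue
            d = iv.start - p.end if iv.start >= p.end else p.start - iv.end
            if best_d is None or d < best_d or (
                d == best_d and iv.start < best.interval.start
            ):
                best, best_d = e, d
        expected = None if best is None else (best.kind, best_d)
        assert got[p.name] == expected


# ------------------------------------------------------------- DE association

def majority_oracle(n_common, n_shared, n_specific):
    """Direct restatement of the voting rule, kept independent."""
    if n_common > n_shared and n_common > n_specific:
        return "musculus_common"
    if n_shared > n_specific:
        return "tissue_shared"
    if n_specific > n_shared:
        return "tissue_specific"
    return "tissue_shared"


def test_majority_vote_examples():
    assert _majority_class(2, 1, 1) == "musculus_common"
    # tie with a specific variety -> specific side wins
    assert _majority_class(1, 1, 0) == "tissue_shared"
    assert _majority_class(1, 0, 1) == "tissue_specific"


def test_majority_vote_exhaustive_up_to_three_per_class():
    for c, s, t in itertools.product(range(4), repeat=3):
        if c + s + t == 0:
            continue
        assert _majority_class(c, s, t) == majority_oracle(c, s, t), (c, s, t)


def test_association_window_and_majority():
    gene = mk_gene("g", "chr1", 100_000, 120_000)
    peaks = [
        (mk_peak("chr1", 60_000, 60_400, "c1"), "musculus_common"),
        (mk_peak("chr1", 130_000, 130_400, "c2"), "musculus_common"),
        (mk_peak("chr1", 95_000, 95_400, "s1"), "tissue_shared"),
        (mk_peak("chr1", 300_000, 300_400, "far"), "tissue_specific"),
    ]
    assert associate_de_genes([gene], peaks)["g"] == "musculus_common"


def test_association_none_when_no_peak_in_window():
    gene = mk_gene("g", "chr1", 100_000, 120_000)
    peaks = [(mk_peak("chr1", 300_000, 300_400), "musculus_common")]
    assert associate_de_genes([gene], peaks)["g"] is None


def test_association_window_monotonicity(rng):
    genes = [mk_gene(f"g{i}", "chr1", int(s), int(s) + 10_000)
             for i, s in enumerate(rng.integers(0, 900_000, size=50))]
    peaks = [(mk_peak("chr1", int(s), int(s) + 300), "musculus_common")
             for s in rng.integers(0, 900_000, size=100)]
    assoc_small = associate_de_genes(genes, peaks, window=10_000)
    assoc_large = associate_de_genes(genes, peaks, window=50_000)
    for gid in assoc_small:
        if assoc_small[gid] is not None:
            assert assoc_large[gid] is not None


# ------------------------------------------------------------------ profiles

def test_profile_classes():
    gene = mk_gene("g", "chr1", 100_000, 120_000)
    regels = define_regulatory(
        [mk_peak("chr1", 99_500, 100_500)],     # promoter over the TSS
        [mk_peak("chr1", 130_000, 130_800),     # enhancers in the window
         mk_peak("chr1", 60_000, 60_800)],
    )
    profiles = profile_genes([gene], regels, {"g": "musculus_common"})
    (prof,) = profiles
    assert prof.profile == "ctcf_promoter_enhancer"
    assert prof.has_promoter and prof.n_enhancers_50kb == 2
    assert prof.direction == "up"


def test_profile_ctcf_only():
    gene = mk_gene("g", "chr1", 100_000, 120_000, log2fc=-2.0)
    (prof,) = profile_genes([gene], [], {"g": "tissue_specific"})
    assert prof.profile == "ctcf_only" and prof.direction == "down"


def test_profile_unassociated_gene_has_no_profile():
    gene = mk_gene("g", "chr1", 100_000, 120_000)
    (prof,) = profile_genes([gene], [], {"g": None})
    assert prof.profile is None and not prof.has_ctcf


def test_de_filter_strict():
    genes = [mk_gene("a", "chr1", 0, 100, fdr=0.049),
             mk_gene("b", "chr1", 200, 300, fdr=0.05)]
    assert [g.gene_id for g in filter_de(genes)] == ["a"]


def test_gene_and_de_tsv_roundtrip(tmp_path):
    genes = [mk_gene("a", "chr1", 1000, 5000, "+", 1.5, 0.01),
             mk_gene("b", "chr2", 2000, 9000, "-", -0.7, 0.2)]
    write_gene_tsv(tmp_path / "g.tsv", genes)
    write_de_table(tmp_path / "de.tsv", {"a": (1.5, 0.01), "b": (-0.7, 0.2)})
    de = read_de_table(tmp_path / "de.tsv")
    back = read_gene_tsv(tmp_path / "g.tsv", de)
    assert [(g.gene_id, g.body.start, g.tss, g.log2fc, g.fdr) for g in back] == [
        (g.gene_id, g.body.start, g.tss, g.log2fc, g.fdr) for g in genes
    ]
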