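"""PWM scanning, boundary orientation and cohesin colocalisation."""

import math

import numpy as np
import pytest

from ctcfevo.intervals import GenomicInterval
from ctcfevo.peaks import Peak, SignalBin
from ctcfevo.tad_cohesin import (
    FAVOURABLE,
    REVERSE,
    CohesinRegion,
    MotifHit,
    PWM,
    TADBoundary,
    boundary_association,
    boundary_clusters,
    cohesin_colocalisation,
    cohesin_merge,
    cooccupancy_by_signal,
    orientation_call,
    read_meme_motifs,
    scan_pwm,
    select_motif,
    tad_boundaries,
)


def mk_peak(chrom, start, end, name="p", summit=None, signal=1.0):
    return Peak(GenomicInterval(chrom, start, end, name=name),
                summit if summit is not None else (start + end) // 2,
                signal, 10.0)


def consensus_pwm(consensus, p=0.97):
    idx = {b: i for i, b in enumerate("ACGT")}
    m = np.full((len(consensus), 4), (1 - p) / 3)
    for j, b in enumerate(consensus):
        m[j, idx[b]] = p
    return PWM("test", m, pseudocount=1e-9)


def revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


# ------------------------------------------------------------------ scanning

def test_planted_consensus_scores_closed_form():
    pwm = consensus_pwm("ACGT")
    seq = "TTTT" + "ACGT" + "TTTT"
    hits = scan_pwm(seq, pwm, threshold=5.0)
    expected = 4 * math.log2(0.97 / 0.25)
    fwd = [h for h in hits if h.strand == "+"]
    assert len(fwd) == 1
    assert fwd[0].start == 4
    assert fwd[0].score == pytest.approx(expected, abs=1e-6)


def test_uniform_pwm_scores_zero_everywhere():
    pwm = PWM("uniform", np.full((4, 4), 0.25), pseudocount=1e-9)
    hits = scan_pwm("ACGTACGT", pwm, threshold=-0.001)
    assert all(abs(h.score) < 1e-9 for h in hits)
    assert not scan_pwm("ACGTACGT", pwm, threshold=0.001)


def test_minus_strand_hit_same_score():
    pwm = consensus_pwm("ACCGGA")  # not reverse-complement palindromic
    planted = revcomp("ACCGGA")
    seq = "TTTTT" + planted + "TTTTT"
    hits = scan_pwm(seq, pwm, threshold=6 * math.log2(0.97 / 0.25) - 1e-6)
    assert len(hits) == 1
    assert hits[0].strand == "-"
    assert hits[0].start == 5
    assert hits[0].score == pytest.approx(6 * math.log2(0.97 / 0.25), abs=1e-6)


def test_strand_symmetry_random_sequences(rng):
    """score(seq, +) distribution equals score(revcomp(seq), -) exactly."""
    pwm = consensus_pwm("ACGTAC")
    bases = np.array(list("ACGT"))
    for _ in range(50):
        seq = "".join(bases[rng.integers(0, 4, 40)])
        fwd = scan_pwm(seq, pwm, threshold=-1e9)
        rev = scan_pwm(revcomp(seq), pwm, threshold=-1e9)
        fwd_plus = sorted(round(h.score, 9) for h in fwd if h.strand == "+")
        rev_minus = sorted(round(h.score, 9) for h in rev if h.strand == "-")
        assert fwd_plus == rev_minus


def test_windows_with_n_skipped():
    pwm = consensus_pwm("ACGT")
    hits = scan_pwm("ACNTACGT", pwm, threshold=-1e9)
    assert all(h.start >= 3 for h in hits)


def test_sequence_shorter_than_motif():
    assert scan_pwm("AC", consensus_pwm("ACGT")) == []


def test_meme_roundtrip(tmp_path):
    from ctcfevo.synthetic_data import CANONICAL_PWM, _write_meme

    _write_meme(tmp_path / "m.meme", [CANONICAL_PWM])
    (back,) = read_meme_motifs(tmp_path / "m.meme")
    assert back.motif_id == CANONICAL_PWM.motif_id
    assert back.width == CANONICAL_PWM.width
    assert np.allclose(back.matrix, CANONICAL_PWM.matrix, atol=1e-2)


# ------------------------------------------------------------- motif choice

def test_select_motif_summit_proximal():
    peak = mk_peak("chr1", 0, 200, summit=100)
    near = MotifHit("p", 108, "+", 5.0, 10)
    far = MotifHit("p", 58, "+", 9.0, 40)
    assert select_motif(peak, [near, far]) == near


def test_select_motif_alternative_fallback():
    peak = mk_peak("chr1", 0, 30, summit=15)
    alt = consensus_pwm("GGGCCC")
    seq = "A" * 12 + "GGGCCC" + "A" * 12
    chosen = select_motif(peak, [], sequence=seq, alternative_pwms=[alt])
    assert chosen is not None and not chosen.canonical
    assert chosen.start == 12


def test_select_motif_none_when_nothing_matches():
    peak = mk_peak("chr1", 0, 30, summit=15)
    alt = consensus_pwm("GGGCCC")
    assert select_motif(peak, [], sequence="A" * 30, alternative_pwms=[alt]) is None


# -------------------------------------------------------------- orientation

@pytest.mark.parametrize(
    "side,strand,expected",
    [
        ("start", "+", FAVOURABLE),
        ("start", "-", REVERSE),
        ("end", "-", FAVOURABLE),
        ("end", "+", REVERSE),
    ],
)
def test_orientation_rule(side, strand, expected):
    motif = MotifHit("p", 100, strand, 5.0, 0)
    boundary = TADBoundary(1000, side, "tad1", "chr1")
    assert orientation_call(motif, boundary) == expected


def test_orientation_translation_invariant():
    for shift in (0, 12_345):
        motif = MotifHit("p", 100 + shift, "+", 5.0, 0)
        b = TADBoundary(1000 + shift, "end", "t", "chr1")
        assert orientation_call(motif, b) == REVERSE


def test_boundary_association_window():
    tads = [GenomicInterval("chr1", 100_000, 1_100_000, name="t0")]
    boundaries = tad_boundaries(tads)
    assert len(boundaries) == 2
    near = mk_peak("chr1", 129_800, 130_200, "near", summit=130_000)
    far = mk_peak("chr1", 159_800, 160_200, "far", summit=160_000)
    assoc = boundary_association([near, far], boundaries, window=50_000)
    b, d, flag = assoc["near"]
    assert (b.position, d, flag) == (100_000, 30_000, True)
    assert assoc["far"][2] is False


def test_boundary_association_matches_exhaustive_scan(rng):
    tads = [GenomicInterval("chr1", int(s), int(s) + 100_000, name=f"t{i}")
            for i, s in enumerate(range(0, 900_000, 150_000))]
    boundaries = tad_boundaries(tads)
    peaks = [mk_peak("chr1", int(s), int(s) + 400, f"p{i}")
             for i, s in enumerate(rng.integers(0, 900_000, size=200))]
    assoc = boundary_association(peaks, boundaries)
    for p in peaks:
        best = min(boundaries, key=lambda b: (abs(p.summit - b.position), b.position))
        got_b, got_d, _ = assoc[p.name]
        assert (got_b.position, got_d) == (best.position, p.summit - best.position)


def test_boundary_clusters_composition():
    boundaries = [TADBoundary(100_000, "start", "t", "chr1")]
    peaks = [
        (mk_peak("chr1", 99_000, 99_400, "c"), "musculus_common"),
        (mk_peak("chr1", 101_000, 101_400, "s1"), "tissue_specific"),
        (mk_peak("chr1", 140_000, 140_400, "s2"), "tissue_shared"),
    ]
    clusters = boundary_clusters(boundaries, peaks)
    assert clusters[("chr1", 100_000, "start")] == (3, "mixed")
    only_common = boundary_clusters(boundaries, peaks[:1])
    assert only_common[("chr1", 100_000, "start")] == (1, "common_only")


# ------------------------------------------------------------------ cohesin

def test_cohesin_merge_pairwise():
    subunits = {
        "RAD21": [mk_peak("chr1", 100, 200)],
        "STAG1": [],
        "STAG2": [mk_peak("chr1", 150, 250)],
    }
    regions = cohesin_merge(subunits)
    assert len(regions) == 1
    r = regions[0]
    assert (r.interval.start, r.interval.end, r.n_subunits) == (150, 200, 2)
    assert r.subunits == frozenset({"RAD21", "STAG2"})


def test_cohesin_merge_three_way_subregion():
    subunits = {
        "RAD21": [mk_peak("chr1", 100, 200)],
        "STAG1": [mk_peak("chr1", 180, 300)],
        "STAG2": [mk_peak("chr1", 150, 250)],
    }
    regions = cohesin_merge(subunits)
    three = [r for r in regions if r.n_subunits == 3]
    assert [(r.interval.start, r.interval.end) for r in three] == [(180, 200)]


def test_cohesin_merge_matches_bitmap_oracle(rng):
    size = 50_000
    subunits = {}
    for name in ("RAD21", "STAG1", "STAG2"):
        peaks = []
        for i in range(60):
            s = int(rng.integers(0, size - 500))
            peaks.append(mk_peak("chr1", s, s + int(rng.integers(100, 500)),
                                 f"{name}{i}"))
        subunits[name] = peaks
    regions = cohesin_merge(subunits)
    cov = np.zeros(size, dtype=int)
    for peaks in subunits.values():
        sub = np.zeros(size, dtype=bool)
        for p in peaks:
            sub[p.start : p.end] = True
        cov += sub
    expected_bases = int((cov >= 2).sum())
    assert sum(r.interval.length for r in regions) == expected_bases
    for r in regions:
        assert (cov[r.interval.start : r.interval.end] >= 2).all()
        assert (cov[r.interval.start : r.interval.end] == r.n_subunits).all()


def test_colocalisation_fractions_and_null():
    regions = [CohesinRegion(GenomicInterval("chr1", 0, 10_000), 2,
                             frozenset({"RAD21", "STAG1"}))]
    peaks = [(mk_peak("chr1", i * 100, i * 100 + 50, f"p{i}"), "musculus_common")
             for i in range(20)]
    fracs, tests = cohesin_colocalisation(peaks, regions)
    assert fracs["musculus_common"] == 1.0
    assert tests["musculus_common"].p == pytest.approx(1.0)


def test_colocalisation_empty_region_set():
    peaks = [(mk_peak("chr1", 0, 100), "musculus_common")]
    fracs, _ = cohesin_colocalisation(peaks, [])
    assert fracs["musculus_common"] == 0.0


def test_cooccupancy_flat_when_independent(rng):
    peaks = []
    hit_regions = []
    for i in range(400):
        start = i * 1000
        p = mk_peak("chr1", start, start + 200, f"p{i}",
                    signal=float(rng.uniform(1, 100)))
        peaks.append(p)
        if rng.random() < 0.5:  # independent of signal
            hit_regions.append(CohesinRegion(
                GenomicInterval("chr1", start + 50, start + 150), 2,
                frozenset({"RAD21", "STAG2"})))
    from ctcfevo.peaks import signal_deciles

    bins = {"all": signal_deciles(peaks)}
    cooc = cooccupancy_by_signal(bins, hit_regions)["all"]
    assert len(cooc) == 10
    assert all(abs(f - 0.5) < 0.25 for f in cooc)  # no systematic trend
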