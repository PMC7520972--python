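"""Cross-tissue occupancy, Shannon diversity and sharedness classification."""

import math

import numpy as np
import pandas as pd
import pytest

from ctcfevo.evo_class import EvoClass
from ctcfevo.intervals import GenomicInterval
from ctcfevo.peaks import Peak
from ctcfevo.tissues import (
    TISSUE_SHARED,
    TISSUE_SPECIFIC,
    build_occupancy,
    bound_matrix,
    classify_sharedness,
    combination_counts,
    conservation_per_bin,
    conservation_trend_test,
    shannon_index,
    shannon_per_peak,
)


def mk_peak(chrom, start, end, name="p", neglog10p=10.0):
    return Peak(GenomicInterval(chrom, start, end, name=name),
                (start + end) // 2, 1.0, neglog10p)


def test_occupancy_counts_bound_tissues():
    liver = [mk_peak("chr1", 100, 200, "a"), mk_peak("chr1", 900, 1000, "b")]
    tissue_sets = {
        "t1": [mk_peak("chr1", 150, 250)],
        "t2": [mk_peak("chr1", 180, 300)],
        "t3": [mk_peak("chr1", 5000, 5100)],
    }
    m = build_occupancy(liver, tissue_sets)
    bm = bound_matrix(m)
    assert bm.loc["a"].sum() == 2
    assert bm.loc["b"].sum() == 0  # liver-only site


def test_occupancy_pvalue_from_largest_overlap():
    liver = [mk_peak("chr1", 100, 200, "a")]
    tissue_sets = {
        "t1": [mk_peak("chr1", 150, 250, neglog10p=4.0),   # 50 bp overlap
               mk_peak("chr1", 90, 190, neglog10p=7.0)],   # 90 bp overlap
    }
    m = build_occupancy(liver, tissue_sets)
    assert m.loc["a", "t1__neglog10p"] == 7.0


def test_occupancy_duplicate_tissue_rejected():
    liver = [mk_peak("chr1", 100, 200, "a")]
    with pytest.raises(ValueError, match="duplicate"):
        build_occupancy(liver * 2, {"t1": []})


def test_occupancy_binomial_recovery(rng):
    """Planted per-tissue binding probability 0.6 recovered in column means."""
    n = 2000
    liver = [mk_peak("chr1", i * 1000, i * 1000 + 200, f"p{i}") for i in range(n)]
    tissue_sets = {}
    for t in range(3):
        bound = rng.random(n) < 0.6
        tissue_sets[f"t{t}"] = [
            mk_peak("chr1", i * 1000 + 50, i * 1000 + 250)
            for i in range(n) if bound[i]
        ]
    m = build_occupancy(liver, tissue_sets)
    means = bound_matrix(m).mean(axis=0)
    assert np.allclose(means, 0.6, atol=0.03)


# ------------------------------------------------------- combination counts

def test_combination_counts_enumeration():
    liver = [mk_peak("chr1", i * 1000, i * 1000 + 100, f"p{i}") for i in range(4)]
    t1 = [mk_peak("chr1", 0, 100), mk_peak("chr1", 1000, 1100),
          mk_peak("chr1", 2000, 2100)]
    t2 = [mk_peak("chr1", 0, 100)]
    m = build_occupancy(liver, {"t1": t1, "t2": t2})
    counts = combination_counts(m)
    assert counts[("t1", "t2")] == 1
    assert counts[("t1",)] == 2
    assert counts[()] == 1
    assert sum(counts.values()) == 4


def test_combination_counts_matches_hash_tally(rng):
    n, n_tissues = 300, 12
    bound = rng.random((n, n_tissues)) < 0.3
    tissues = [f"t{j:02d}" for j in range(n_tissues)]
    data = {}
    for j, t in enumerate(tissues):
        data[f"{t}__bound"] = bound[:, j]
        data[f"{t}__neglog10p"] = np.where(bound[:, j], 5.0, np.nan)
    m = pd.DataFrame(data, index=[f"p{i}" for i in range(n)])
    counts = combination_counts(m)
    tally = {}
    for i in range(n):
        key = tuple(t for j, t in enumerate(tissues) if bound[i, j])
        tally[key] = tally.get(key, 0) + 1
    assert counts == tally
    # marginal per-tissue sums match column sums
    for j, t in enumerate(tissues):
        marginal = sum(v for k, v in counts.items() if t in k)
        assert marginal == int(bound[:, j].sum())


# ------------------------------------------------------------ Shannon index

def test_shannon_uniform_maximum():
    assert shannon_index([1.0] * 12) == pytest.approx(math.log(12))


def test_shannon_single_tissue_zero():
    assert shannon_index([3.7]) == 0.0
    assert shannon_index([]) == 0.0


def test_shannon_hand_computed_weights():
    h = shannon_index([1, 1, 2])
    expected = -(0.25 * math.log(0.25) * 2 + 0.5 * math.log(0.5))
    assert h == pytest.approx(expected)
    assert h == pytest.approx(1.0397, abs=1e-4)


def test_shannon_all_zero_weights_warns_uniform():
    with pytest.warns(UserWarning, match="uniform"):
        h = shannon_index([0.0, 0.0, 0.0])
    assert h == pytest.approx(math.log(3))


def test_shannon_bounds_random_rows(rng):
    for _ in range(200):
        k = int(rng.integers(0, 13))
        w = rng.uniform(0.1, 30, size=k)
        h = shannon_index(list(w))
        assert 0 <= h <= math.log(max(k, 1)) + 1e-12
        if k <= 1:
            assert h == 0.0


def test_shannon_per_peak_uses_bound_weights_only():
    liver = [mk_peak("chr1", 100, 200, "a")]
    m = build_occupancy(liver, {
        "t1": [mk_peak("chr1", 100, 200, neglog10p=5.0)],
        "t2": [mk_peak("chr1", 100, 200, neglog10p=5.0)],
        "t3": [],
    })
    div = shannon_per_peak(m)
    assert div.loc["a", "n_tissues_bound"] == 2
    assert div.loc["a", "shannon"] == pytest.approx(math.log(2))


# --------------------------------------------------- conservation per H bin

def test_conservation_all_common_bins_one(rng):
    div = pd.DataFrame(
        {"n_tissues_bound": 5, "shannon": rng.uniform(0, 2, 50)},
        index=[f"p{i}" for i in range(50)],
    )
    labels = {f"p{i}": EvoClass.MUSCULUS_COMMON for i in range(50)}
    fracs = conservation_per_bin(div, labels, n_bins=5)
    assert all(f == 1.0 for f in fracs if f is not None)


def test_conservation_empty_bin_is_missing():
    div = pd.DataFrame(
        {"n_tissues_bound": 2, "shannon": [0.0, 0.01, 2.0]},
        index=["a", "b", "c"],
    )
    labels = {k: EvoClass.MUSCULUS_COMMON for k in "abc"}
    fracs = conservation_per_bin(div, labels, n_bins=10)
    assert fracs[5] is None


def test_conservation_planted_monotone_association(rng):
    """Common peaks given systematically higher H: rising rank trend."""
    n = 600
    is_common = rng.random(n) < 0.5
    h = np.where(is_common, rng.uniform(1.0, 2.5, n), rng.uniform(0.0, 1.5, n))
    div = pd.DataFrame({"n_tissues_bound": 5, "shannon": h},
                       index=[f"p{i}" for i in range(n)])
    labels = {
        f"p{i}": (EvoClass.MUSCULUS_COMMON if is_common[i]
                  else EvoClass.SPECIES_SPECIFIC_UNALIGNED)
        for i in range(n)
    }
    fracs = conservation_per_bin(div, labels, n_bins=10)
    rho, p = conservation_trend_test(fracs)
    assert rho > 0 and p < 0.05


# -------------------------------------------------------------- sharedness

def _matrix_from_bool(bound, tissues):
    data = {}
    for j, t in enumerate(tissues):
        data[f"{t}__bound"] = bound[:, j]
        data[f"{t}__neglog10p"] = np.where(bound[:, j], 5.0, np.nan)
    return pd.DataFrame(data, index=[f"p{i}" for i in range(bound.shape[0])])


def test_sharedness_strict_intersection_rule():
    tissues = ["t1", "t2", "t3", "t4", "t5", "liver_encode"]
    bound = np.array([
        [1, 1, 1, 1, 0, 1],   # bound in top-4 + replicate -> shared
        [1, 1, 1, 0, 1, 1],   # misses one top tissue -> specific
        [1, 1, 1, 1, 1, 0],   # misses the replicate -> specific
    ], dtype=bool)
    m = _matrix_from_bool(bound, tissues)
    calls = classify_sharedness(m, list(m.index), "liver_encode", top_k=4)
    # ranking: t1-t3 shared by 3, t4 by 2, t5 by 1 -> top-4 = t1..t4
    assert calls["p0"] == TISSUE_SHARED
    assert calls["p1"] == TISSUE_SPECIFIC
    assert calls["p2"] == TISSUE_SPECIFIC


def test_sharedness_topk_monotonicity(rng):
    tissues = [f"t{j}" for j in range(8)] + ["liver_encode"]
    bound = rng.random((100, 9)) < 0.6
    m = _matrix_from_bool(bound, tissues)
    focal = list(m.index)
    shared_by_k = []
    for k in (2, 4, 6):
        calls = classify_sharedness(m, focal, "liver_encode", top_k=k)
        shared_by_k.append({n for n, v in calls.items() if v == TISSUE_SHARED})
    assert shared_by_k[2] <= shared_by_k[1] <= shared_by_k[0]


def test_sharedness_topk_too_large():
    tissues = ["t1", "t2", "liver_encode"]
    m = _matrix_from_bool(np.ones((5, 3), dtype=bool), tissues)
    with pytest.raises(ValueError):
        classify_sharedness(m, list(m.index), "liver_encode", top_k=3)


def test_sharedness_planted_fraction_recovery(rng):
    """10% of focal peaks planted bound in all designated tissues."""
    tissues = [f"t{j}" for j in range(12)] + ["liver_encode"]
    designated = ["t0", "t1", "t2", "t3", "liver_encode"]
    n = 2000
    shared = rng.random(n) < 0.10
    bound = rng.random((n, 13)) < 0.15
    for j, t in enumerate(tissues):
        if t in designated:
            bound[shared, j] = True
    m = _matrix_from_bool(bound, tissues)
    calls = classify_sharedness(m, list(m.index), "liver_encode", top_k=4)
    frac = sum(v == TISSUE_SHARED for v in calls.values()) / n
    assert frac == pytest.approx(0.10, abs=0.02)
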