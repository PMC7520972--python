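"""Cross-tissue occupancy, diversity and tissue-sharedness of binding sites.

An occupancy matrix records, for every liver consensus peak, whether it is
bound in each of a panel of tissues (>= 1 bp overlap with that tissue's
consensus peaks) and, when bound, the -log10 p of the overlapping tissue
peak.  The Shannon diversity index over the normalised per-tissue binding
weights summarises how broadly and evenly a site is bound; the conservation
fraction per diversity bin relates breadth of binding to evolutionary class.

A subspecies-specific site is *tissue-shared* when it is bound in ALL of the
top-k tissues (ranked by how many focal-class sites they share) AND in the
designated technical-replicate tissue; all other focal-class sites are
tissue-specific.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .evo_class import EvoClass
from .peaks import Peak

__all__ = [
    "build_occupancy",
    "combination_counts",
    "shannon_index",
    "shannon_per_peak",
    "conservation_per_bin",
    "classify_sharedness",
]

TISSUE_SHARED = "tissue_shared"
TISSUE_SPECIFIC = "tissue_specific"


def build_occupancy(
    liver_peaks: Sequence[Peak],
    tissue_peak_sets: Mapping[str, Sequence[Peak]],
) -> pd.DataFrame:
    """Peaks x tissues occupancy table.

    Returns a DataFrame indexed by peak name with, per tissue, a boolean
    ``<tissue>__bound`` column and a float ``<tissue>__neglog10p`` column
    (NaN when unbound).  The p-value is taken from the overlapping tissue
    peak with the largest overlap (ties -> higher -log10 p).
    """
    tissues = list(tissue_peak_sets)
    if len(set(tissues)) != len(tissues):
        raise ValueError("duplicate tissue names")
    names = [p.name for p in liver_peaks]
    if len(set(names)) != len(names):
        raise ValueError("duplicate liver peak names")
    data: dict[str, list] = {}
    for tissue, tpeaks in tissue_peak_sets.items():
        by_chrom: dict[str, list[Peak]] = {}
        for tp in tpeaks:
            by_chrom.setdefault(tp.chrom, []).append(tp)
        bound_col, p_col = [], []
        for lp in liver_peaks:
            best_ov, best_p = 0, float("nan")
            for tp in by_chrom.get(lp.chrom, ()):
                ov = min(lp.end, tp.end) - max(lp.start, tp.start)
                if ov >= 1 and (
                    ov > best_ov or (ov == best_ov and tp.neglog10p > best_p)
                ):
                    best_ov, best_p = ov, tp.neglog10p
            bound_col.append(best_ov >= 1)
            p_col.append(best_p if best_ov >= 1 else float("nan"))
        data[f"{tissue}__bound"] = bound_col
        data[f"{tissue}__neglog10p"] = p_col
    df = pd.DataFrame(data, index=pd.Index(names, name="peak"))
    df.attrs["tissues"] = tissues
    return df


def _tissue_names(matrix: pd.DataFrame) -> list[str]:
    return [c[: -len("__bound")] for c in matrix.columns if c.endswith("__bound")]


def bound_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Boolean peaks x tissues view of an occupancy table."""
    tissues = _tissue_names(matrix)
    out = matrix[[f"{t}__bound" for t in tissues]].copy()
    out.columns = tissues
    return out


def combination_counts(matrix: pd.DataFrame) -> dict[tuple[str, ...], int]:
    """Count peaks per exact tissue presence pattern (UpSet-style tally)."""
    bm = bound_matrix(matrix)
    tissues = list(bm.columns)
    counts: dict[tuple[str, ...], int] = {}
    for row in bm.itertuples(index=False):
        key = tuple(t for t, b in zip(tissues, row) if b)
        counts[key] = counts.get(key, 0) + 1
    return counts


def shannon_index(weights: Sequence[float]) -> float:
    """Shannon diversity H = -sum p_i ln p_i over normalised binding weights.

    ``weights`` are the -log10 p values of the bound tissues only.  H = 0 for
    zero or one bound tissues.  All-zero weights fall back to uniform
    proportions with a warning.
    """
    w = np.asarray([x for x in weights if not math.isnan(x)], dtype=float)
    if (w < 0).any():
        raise ValueError("binding weights must be >= 0")
    if w.size <= 1:
        return 0.0
    total = w.sum()
    if total == 0:
        warnings.warn(
            "all binding weights zero; Shannon index computed over uniform "
            "proportions",
            stacklevel=2,
        )
        p = np.full(w.size, 1.0 / w.size)
    else:
        p = w / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def shannon_per_peak(matrix: pd.DataFrame) -> pd.DataFrame:
    """DiversityRecord table: n_tissues_bound and Shannon H per peak."""
    tissues = _tissue_names(matrix)
    records = []
    for name, row in matrix.iterrows():
        weights = [
            row[f"{t}__neglog10p"] for t in tissues if row[f"{t}__bound"]
        ]
        records.append((name, len(weights), shannon_index(weights)))
    return pd.DataFrame(
        records, columns=["peak", "n_tissues_bound", "shannon"]
    ).set_index("peak")


def conservation_per_bin(
    diversity: pd.DataFrame,
    labels: Mapping[str, EvoClass],
    n_bins: int = 10,
) -> list[Optional[float]]:
    """Fraction of musculus-common peaks per equal-width Shannon bin.

    Bins span the observed H range; empty bins report None, not 0.
    """
    h = diversity["shannon"].to_numpy()
    common = np.array(
        [labels[name] == EvoClass.MUSCULUS_COMMON for name in diversity.index]
    )
    lo, hi = float(h.min()), float(h.max())
    if hi == lo:
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(h, edges[1:-1]), 0, n_bins - 1)
    out: list[Optional[float]] = []
    for b in range(n_bins):
        mask = idx == b
        out.append(float(common[mask].mean()) if mask.any() else None)
    return out


def conservation_trend_test(fractions: Sequence[Optional[float]]):
    """Spearman rank trend of conservation across diversity bins."""
    pts = [(i, f) for i, f in enumerate(fractions) if f is not None]
    xs, ys = zip(*pts)
    rho, p = _sps.spearmanr(xs, ys)
    return float(rho), float(p)


def classify_sharedness(
    matrix: pd.DataFrame,
    focal_peaks: Sequence[str],
    designated_replicate_tissue: str,
    top_k: int = 4,
) -> dict[str, str]:
    """Tissue-shared vs tissue-specific call for the focal-class peaks.

    Tissues (excluding the designated replicate) are ranked by the number of
    focal-class peaks they share; a focal peak is tissue_shared iff bound in
    all ``top_k`` top-ranked tissues AND in the designated replicate tissue.
    """
    bm = bound_matrix(matrix)
    tissues = list(bm.columns)
    if designated_replicate_tissue not in tissues:
        raise ValueError(
            f"designated tissue {designated_replicate_tissue!r} not in matrix"
        )
    rankable = [t for t in tissues if t != designated_replicate_tissue]
    if top_k >= len(tissues):
        raise ValueError(f"top_k={top_k} must be < number of tissues")
    focal = bm.loc[list(focal_peaks)]
    shared_counts = focal[rankable].sum(axis=0)
    # rank by count, name as deterministic tie-break
    ranked = sorted(rankable, key=lambda t: (-shared_counts[t], t))
    required = ranked[:top_k] + [designated_replicate_tissue]
    out = {}
    for name in focal_peaks:
        row = bm.loc[name]
        out[name] = (
            TISSUE_SHARED if all(row[t] for t in required) else TISSUE_SPECIFIC
        )
    return out
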