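"""Seeded generator for a miniature two-subspecies dataset with ground truth.

The generator emulates the study design end-to-end at desk scale: two
subspecies genomes with a controlled fraction of orthologous ("common")
binding sites, per-replicate ChIP-seq peak calls with dropout and boundary
jitter, SINE B2/B4 insertions under a controlled fraction of binding sites
with class-dependent divergence ages, cross-tissue occupancy with
class-dependent binding probabilities, TADs with boundary-proximal oriented
motifs planted in the genome sequence, cohesin subunit peaks with
class-dependent colocalisation, and a differential-expression table whose
direction is biased for genes associated with subspecies-specific sites.

Every planted parameter is recorded in the ground-truth tables so each
pipeline stage can be checked for parameter recovery.  Output is
byte-identical across runs with equal seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .evo_class import OrthologyBlock, OrthologyMap, write_orthology_tsv
from .intervals import GenomicInterval, Karyotype, write_bed, write_chrom_sizes
from .peaks import Peak, write_narrowpeak
from .repeats import RepeatElement, write_repeat_tsv
from .regulatory import write_de_table, write_gene_tsv, DEGene
from .tad_cohesin import PWM

__all__ = ["SimConfig", "GroundTruth", "generate", "make_replicates", "CANONICAL_PWM"]

CLASS_COMMON = "musculus_common"
CLASS_SPECIFIC = "species_specific_unaligned"
CLASS_ALIGNED_UNBOUND = "aligned_unbound"
SHARED = "tissue_shared"
SPECIFIC = "tissue_specific"

# CTCF-like 12-bp directional core: near-consensus probabilities so planted
# instances score close to the motif maximum.
_CANONICAL_CONSENSUS = "CCACCAGGTGGC"
_ALT_CONSENSUS = ("TGCAGTTCCG", "AGGTGGCGCT")


def _consensus_pwm(motif_id: str, consensus: str, p: float = 0.97) -> PWM:
    base_idx = {b: i for i, b in enumerate("ACGT")}
    m = np.full((len(consensus), 4), (1 - p) / 3)
    for j, b in enumerate(consensus):
        m[j, base_idx[b]] = p
    return PWM(motif_id, m, pseudocount=1e-9)


CANONICAL_PWM = _consensus_pwm("M1_canonical", _CANONICAL_CONSENSUS)
ALTERNATIVE_PWMS = tuple(
    _consensus_pwm(f"alt{i+1}", c) for i, c in enumerate(_ALT_CONSENSUS)
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic dataset.

    Class fractions, TE overlap rates, divergence ages, tissue-binding
    probabilities, orientation and cohesin rates default to the magnitudes
    the analyses are meant to recover.
    """

    seed: int = 0
    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000, "chr3": 10_000_000}
    )
    n_peaks: int = 2000
    peak_width: int = 400
    slot_bp: int = 5000  # minimum spacing between planted binding-site loci
    frac_common: float = 0.74
    frac_aligned_unbound: float = 0.06
    n_replicates: int = 3
    dropout_prob: float = 0.2
    jitter_sd: float = 5.0
    # transposable elements
    frac_specific_in_te: float = 0.34  # B2/B4 overlap of specific sites
    frac_common_in_te: float = 0.14
    te_div_young_mean: float = 17.0  # % divergence, specific-site TEs
    te_div_old_mean: float = 22.0  # common-site and background TEs
    te_div_sd: float = 3.0
    te_length: int = 200
    genome_sine_fraction: float = 0.20  # background SINE coverage target
    # cross-tissue occupancy
    n_tissues: int = 12
    replicate_tissue: str = "liver_encode"
    top_k: int = 4
    p_bind_common: float = 0.6
    p_bind_specific: float = 0.15
    frac_shared_of_specific: float = 0.10
    # TADs and motif orientation
    tad_size: int = 1_000_000
    tad_gap: int = 100_000
    frac_favourable: Mapping[str, float] = field(
        default_factory=lambda: {
            CLASS_COMMON: 0.70,
            SPECIFIC: 0.57,
            SHARED: 0.66,
            CLASS_ALIGNED_UNBOUND: 0.57,
        }
    )
    # cohesin
    cohesin_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            CLASS_COMMON: 0.80,
            SPECIFIC: 0.50,
            SHARED: 0.78,
            CLASS_ALIGNED_UNBOUND: 0.50,
        }
    )
    cohesin_width: int = 300
    p_three_subunits: float = 0.3
    # genes / differential expression
    n_genes: int = 1000
    gene_length_range: tuple[int, int] = (5_000, 30_000)
    frac_de: float = 0.35
    down_bias_specific: float = 0.65  # P(downregulated | specific-class assoc.)
    # histone marks
    p_promoter: float = 0.6
    p_promoter_k27ac: float = 0.5
    enhancers_per_gene: float = 1.0
    write_fasta: bool = True

    def validate(self) -> None:
        fracs = [
            self.frac_common,
            self.frac_aligned_unbound,
            self.frac_specific_in_te,
            self.frac_common_in_te,
            self.dropout_prob,
            self.p_bind_common,
            self.p_bind_specific,
            self.frac_shared_of_specific,
            self.frac_de,
            self.down_bias_specific,
            self.genome_sine_fraction,
            *self.frac_favourable.values(),
            *self.cohesin_rates.values(),
        ]
        if any(not (0 <= f <= 1) for f in fracs):
            raise ValueError("all fractions and probabilities must be in [0, 1]")
        if self.frac_common + self.frac_aligned_unbound > 1:
            raise ValueError("class fractions exceed 1")
        n_slots = sum(
            (size - 2 * self.slot_bp) // self.slot_bp for size in self.chrom_sizes.values()
        )
        if 2 * self.n_peaks > n_slots:
            raise ValueError(
                f"cannot pack {self.n_peaks} peak loci per subspecies into "
                f"{n_slots} available slots; enlarge the genome or slot_bp"
            )


@dataclass
class GroundTruth:
    """Planted per-peak and per-gene truth, consistent with the emitted files."""

    peaks: "list[dict]"
    genes: "list[dict]"
    config: SimConfig


def make_replicates(
    true_peaks: Sequence[Peak],
    n_reps: int,
    dropout_prob: float,
    jitter_sd: float,
    karyotype: Karyotype,
    rng: np.random.Generator,
) -> list[list[Peak]]:
    """Per-replicate peak sets with independent dropout and boundary jitter."""
    if dropout_prob >= 0.5:
        raise ValueError("dropout_prob must be < 0.5 for consensus recovery")
    reps: list[list[Peak]] = []
    for _ in range(n_reps):
        rep: list[Peak] = []
        for p in true_peaks:
            if rng.random() < dropout_prob:
                continue
            chrom_len = karyotype[p.chrom]
            if jitter_sd > 0:
                ds, de, dm = (int(round(x)) for x in rng.normal(0, jitter_sd, 3))
            else:
                ds = de = dm = 0
            start = max(0, p.start + ds)
            end = min(chrom_len, p.end + de)
            if end - start < 50:  # keep a sane minimum width under jitter
                start, end = p.start, p.end
            summit = min(max(p.summit + dm, start), end - 1)
            signal = p.signal * float(rng.lognormal(0, 0.15))
            neglog10p = max(0.0, p.neglog10p + float(rng.normal(0, 1)))
            iv = GenomicInterval(p.chrom, start, end, strand=".", name=p.name)
            rep.append(Peak(iv, summit, signal, neglog10p, p.neglog10q))
        reps.append(rep)
    return reps


def _assign_slots(
    cfg: SimConfig, rng: np.random.Generator, n_total: int
) -> list[tuple[str, int]]:
    """Non-adjacent slot centres (chrom, centre bp) for binding-site loci."""
    slots: list[tuple[str, int]] = []
    for chrom, size in cfg.chrom_sizes.items():
        n_chrom = (size - 2 * cfg.slot_bp) // cfg.slot_bp
        slots.extend(
            (chrom, cfg.slot_bp + i * cfg.slot_bp + cfg.slot_bp // 2)
            for i in range(n_chrom)
        )
    idx = rng.choice(len(slots), size=n_total, replace=False)
    return [slots[i] for i in sorted(idx)]


def _tads(cfg: SimConfig) -> list[GenomicInterval]:
    out = []
    i = 0
    for chrom, size in cfg.chrom_sizes.items():
        pos = cfg.tad_gap
        while pos + cfg.tad_size + cfg.tad_gap <= size:
            out.append(GenomicInterval(chrom, pos, pos + cfg.tad_size, name=f"tad{i}"))
            pos += cfg.tad_size + cfg.tad_gap
            i += 1
    return out


def _nearest_boundary(
    summit: int, chrom: str, boundaries: Mapping[str, list[tuple[int, str]]]
) -> tuple[int, str]:
    # independent inline arithmetic; ties toward the smaller position
    if not boundaries.get(chrom):
        return 0, "start"
    best = None
    for pos, side in boundaries[chrom]:
        key = (abs(summit - pos), pos)
        if best is None or key < best[0]:
            best = (key, pos, side)
    return best[1], best[2]


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def generate(config: SimConfig, outdir: str | Path) -> GroundTruth:
    """Emit the full file bundle into ``outdir`` and return the ground truth."""
    cfg = config
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    kary = Karyotype(cfg.chrom_sizes)
    kary_b = Karyotype({f"chrB{c[3:]}": s for c, s in cfg.chrom_sizes.items()})

    n_common = int(round(cfg.frac_common * cfg.n_peaks))
    n_unbound = int(round(cfg.frac_aligned_unbound * cfg.n_peaks))
    n_specific = cfg.n_peaks - n_common - n_unbound
    n_specific_b = n_specific  # subspecies B gets its own specific sites

    slot_list = _assign_slots(cfg, rng, cfg.n_peaks + n_specific_b)
    order = rng.permutation(cfg.n_peaks + n_specific_b)
    a_slots = [slot_list[i] for i in sorted(order[: cfg.n_peaks])]
    b_only_slots = [slot_list[i] for i in sorted(order[cfg.n_peaks :])]

    classes = np.array(
        [CLASS_COMMON] * n_common
        + [CLASS_ALIGNED_UNBOUND] * n_unbound
        + [CLASS_SPECIFIC] * n_specific
    )
    rng.shuffle(classes)

    # sharedness among specific sites
    spec_idx = np.flatnonzero(classes == CLASS_SPECIFIC)
    n_shared = int(round(cfg.frac_shared_of_specific * len(spec_idx)))
    shared_set = set(rng.choice(spec_idx, size=n_shared, replace=False).tolist())

    tads = _tads(cfg)
    boundaries: dict[str, list[tuple[int, str]]] = {c: [] for c in cfg.chrom_sizes}
    for t in tads:
        boundaries[t.chrom].append((t.start, "start"))
        boundaries[t.chrom].append((t.end, "end"))

    half = cfg.peak_width // 2
    motif_w = CANONICAL_PWM.width
    peaks_a: list[Peak] = []
    truth_rows: list[dict] = []
    te_rows: list[RepeatElement] = []
    blocks: list[OrthologyBlock] = []
    peaks_b_true: list[Peak] = []
    cohesin_events: dict[str, list[tuple[str, int, int]]] = {
        "RAD21": [], "STAG1": [], "STAG2": []
    }
    planted_motifs: dict[str, list[tuple[int, str]]] = {c: [] for c in cfg.chrom_sizes}

    b2b4_families = ("B2", "B4")
    eid_counter = 0
    for i, ((chrom, centre), cls) in enumerate(zip(a_slots, classes)):
        name = f"peakA{i:05d}"
        start, end = centre - half, centre + half
        summit = centre
        signal = float(rng.lognormal(2.5, 0.6))
        neglog10p = float(5 + rng.exponential(8))
        iv = GenomicInterval(chrom, start, end, name=name)
        peaks_a.append(Peak(iv, summit, signal, neglog10p, neglog10q=neglog10p / 2))

        # evolutionary structure: blocks under common and aligned-unbound loci
        if cls in (CLASS_COMMON, CLASS_ALIGNED_UNBOUND):
            bs, be = start - 500, end + 500
            chrom_b = f"chrB{chrom[3:]}"
            ori = "+" if rng.random() < 0.5 else "-"
            blocks.append(OrthologyBlock(chrom, bs, be, chrom_b, bs, be, ori))
            if cls == CLASS_COMMON:
                if ori == "+":
                    b_start, b_end = start, end
                    b_summit = summit
                else:
                    b_start = bs + (be - end)
                    b_end = bs + (be - start)
                    b_summit = bs + (be - 1 - summit)
                ivb = GenomicInterval(chrom_b, b_start, b_end, name=f"peakB{i:05d}")
                peaks_b_true.append(
                    Peak(ivb, b_summit, float(rng.lognormal(2.5, 0.6)),
                         float(5 + rng.exponential(8)))
                )

        # sharedness label
        if cls == CLASS_SPECIFIC:
            sharedness = SHARED if i in shared_set else SPECIFIC
        else:
            sharedness = ""

        # transposable element under the site
        te_rate = {
            CLASS_COMMON: cfg.frac_common_in_te,
            CLASS_ALIGNED_UNBOUND: cfg.frac_common_in_te,
            CLASS_SPECIFIC: cfg.frac_specific_in_te,
        }[cls]
        has_te = rng.random() < te_rate
        te_div = float("nan")
        if has_te:
            mean = (
                cfg.te_div_young_mean if cls == CLASS_SPECIFIC else cfg.te_div_old_mean
            )
            te_div = float(np.clip(rng.normal(mean, cfg.te_div_sd), 0.5, 60))
            fam = b2b4_families[int(rng.integers(2))]
            te_start = summit - cfg.te_length // 2
            te_rows.append(
                RepeatElement(
                    GenomicInterval(chrom, te_start, te_start + cfg.te_length,
                                    name=f"te{eid_counter}"),
                    fam,
                    "SINE",
                    te_div,
                    f"te{eid_counter}",
                )
            )
            eid_counter += 1

        # motif orientation vs the nearest TAD boundary
        b_pos, b_side = _nearest_boundary(summit, chrom, boundaries)
        fav_p = cfg.frac_favourable[sharedness or cls]
        favourable = rng.random() < fav_p
        if b_side == "start":
            strand = "+" if favourable else "-"
        else:
            strand = "-" if favourable else "+"
        motif_start = summit - motif_w // 2
        planted_motifs[chrom].append((motif_start, strand))

        # cohesin colocalisation
        rate = cfg.cohesin_rates[sharedness or cls]
        coloc = rng.random() < rate
        if coloc:
            cs = centre - cfg.cohesin_width // 2
            ce = cs + cfg.cohesin_width
            stag = "STAG1" if rng.random() < 0.5 else "STAG2"
            cohesin_events["RAD21"].append((chrom, cs, ce))
            cohesin_events[stag].append((chrom, cs + 10, ce + 10))
            if rng.random() < cfg.p_three_subunits:
                other = "STAG2" if stag == "STAG1" else "STAG1"
                cohesin_events[other].append((chrom, cs + 20, ce + 20))
        elif rng.random() < 0.3:
            # a lone subunit: present but never a >= 2-subunit region
            cs = centre - cfg.cohesin_width // 2
            cohesin_events["RAD21"].append((chrom, cs, cs + cfg.cohesin_width))

        truth_rows.append(
            {
                "peak_id": name,
                "chrom": chrom,
                "start": start,
                "end": end,
                "summit": summit,
                "evo_class": cls,
                "sharedness": sharedness,
                "te_b2b4": int(has_te),
                "te_divergence": te_div,
                "motif_start": motif_start,
                "motif_strand": strand,
                "boundary_pos": b_pos,
                "boundary_side": b_side,
                "orientation": "favourable" if favourable else "reverse",
                "cohesin": int(coloc),
            }
        )

    # subspecies-B-specific peaks at block-free loci
    for j, (chrom, centre) in enumerate(b_only_slots):
        chrom_b = f"chrB{chrom[3:]}"
        ivb = GenomicInterval(
            chrom_b, centre - half, centre + half, name=f"peakBspec{j:05d}"
        )
        peaks_b_true.append(
            Peak(ivb, centre, float(rng.lognormal(2.5, 0.6)),
                 float(5 + rng.exponential(8)))
        )

    # background repeats away from binding-site loci
    centres_by_chrom: dict[str, np.ndarray] = {}
    for chrom in cfg.chrom_sizes:
        cs = sorted(c for ch, c in slot_list if ch == chrom)
        centres_by_chrom[chrom] = np.asarray(cs, dtype=np.int64)
    genome_len = sum(cfg.chrom_sizes.values())
    target_sine = cfg.genome_sine_fraction * genome_len
    planted_sine = sum(
        r.interval.length for r in te_rows if r.superfamily == "SINE"
    )
    needed_union = max(0.0, target_sine - planted_sine)
    # uniform placements overlap; invert the Poisson coverage expectation
    # G(1 - exp(-nL/G)) = u  =>  n = -G ln(1 - u/G) / L
    n_bg = int(-genome_len * np.log1p(-needed_union / genome_len) / cfg.te_length)
    bg_families = ["Alu/B1", "B2", "B4", "B3"]
    chrom_names = list(cfg.chrom_sizes)
    chrom_probs = np.array([cfg.chrom_sizes[c] for c in chrom_names], dtype=float)
    chrom_probs /= chrom_probs.sum()
    for k in range(n_bg):
        chrom = chrom_names[int(rng.choice(len(chrom_names), p=chrom_probs))]
        size = cfg.chrom_sizes[chrom]
        centres = centres_by_chrom[chrom]
        for _ in range(50):
            s = int(rng.integers(0, size - cfg.te_length))
            # conflict iff any peak locus centre lies within `half` bp of
            # the element span
            lo = np.searchsorted(centres, s - half)
            hi = np.searchsorted(centres, s + cfg.te_length + half, side="right")
            if lo == hi:
                break
        else:
            continue
        div = float(np.clip(rng.normal(cfg.te_div_old_mean, cfg.te_div_sd), 0.5, 60))
        te_rows.append(
            RepeatElement(
                GenomicInterval(chrom, s, s + cfg.te_length, name=f"bg{k}"),
                bg_families[int(rng.integers(len(bg_families)))],
                "SINE",
                div,
                f"bg{k}",
            )
        )
    te_rows.sort(key=lambda r: (r.chrom, r.interval.start))

    # replicates for both subspecies
    reps_a = make_replicates(
        peaks_a, cfg.n_replicates, cfg.dropout_prob, cfg.jitter_sd, kary, rng
    )
    reps_b = make_replicates(
        peaks_b_true, cfg.n_replicates, cfg.dropout_prob, cfg.jitter_sd, kary_b, rng
    )

    # cross-tissue occupancy
    tissue_names = [f"tissue{t:02d}" for t in range(cfg.n_tissues)]
    designated = tissue_names[: cfg.top_k] + [cfg.replicate_tissue]
    all_tissues = tissue_names + [cfg.replicate_tissue]
    tissue_peaks: dict[str, list[Peak]] = {t: [] for t in all_tissues}
    for i, (p, cls) in enumerate(zip(peaks_a, classes)):
        shared = truth_rows[i]["sharedness"] == SHARED
        p_bind = cfg.p_bind_common if cls == CLASS_COMMON else cfg.p_bind_specific
        for t in all_tissues:
            bound = (shared and t in designated) or rng.random() < p_bind
            if bound:
                ivt = GenomicInterval(p.chrom, p.start, p.end, name=f"{t}_{p.name}")
                tissue_peaks[t].append(
                    Peak(ivt, p.summit, float(rng.lognormal(2.0, 0.5)),
                         float(3 + rng.exponential(10)))
                )

    # genes and differential expression
    genes: list[DEGene] = []
    gene_truth: list[dict] = []
    peaks_by_chrom: dict[str, list[int]] = {}
    for i, p in enumerate(peaks_a):
        peaks_by_chrom.setdefault(p.chrom, []).append(i)
    de_table: dict[str, tuple[float, float]] = {}
    for g in range(cfg.n_genes):
        chrom = chrom_names[int(rng.choice(len(chrom_names), p=chrom_probs))]
        size = cfg.chrom_sizes[chrom]
        glen = int(rng.integers(*cfg.gene_length_range))
        gstart = int(rng.integers(1000, size - glen - 1000))
        strand = "+" if rng.random() < 0.5 else "-"
        tss = gstart if strand == "+" else gstart + glen
        gid = f"gene{g:05d}"
        is_de = rng.random() < cfg.frac_de
        fdr = float(rng.uniform(0, 0.049)) if is_de else float(rng.uniform(0.05, 1))
        # true association class from the planted geometry
        counts = {CLASS_COMMON: 0, SHARED: 0, SPECIFIC: 0}
        for pi in peaks_by_chrom.get(chrom, ()):
            p = peaks_a[pi]
            gap = max(gstart - p.end, p.start - (gstart + glen), 0)
            if gap <= 50_000:
                cls = classes[pi]
                if cls == CLASS_COMMON:
                    counts[CLASS_COMMON] += 1
                elif cls == CLASS_SPECIFIC:
                    counts[truth_rows[pi]["sharedness"]] += 1
        if sum(counts.values()) == 0:
            assoc = ""
        elif counts[CLASS_COMMON] > counts[SHARED] and counts[CLASS_COMMON] > counts[SPECIFIC]:
            assoc = CLASS_COMMON
        elif counts[SHARED] >= counts[SPECIFIC]:
            assoc = SHARED
        else:
            assoc = SPECIFIC
        p_down = (
            cfg.down_bias_specific if assoc in (SHARED, SPECIFIC) else 0.5
        )
        magnitude = float(0.2 + abs(rng.normal(0, 1)))
        log2fc = -magnitude if rng.random() < p_down else magnitude
        genes.append(
            DEGene(gid, GenomicInterval(chrom, gstart, gstart + glen,
                                        strand=strand, name=gid),
                   tss, strand, log2fc, fdr)
        )
        de_table[gid] = (log2fc, fdr)
        gene_truth.append(
            {
                "gene_id": gid,
                "de": int(is_de),
                "assoc_class": assoc,
                "direction": "down" if log2fc < 0 else "up",
            }
        )

    # histone marks around gene TSSs plus distal enhancers
    k4me3: list[Peak] = []
    k27ac: list[Peak] = []
    for g_i, g in enumerate(genes):
        if rng.random() < cfg.p_promoter:
            s = max(0, g.tss - 500)
            iv = GenomicInterval(g.body.chrom, s, s + 1000, name=f"k4_{g.gene_id}")
            k4me3.append(Peak(iv, s + 500, float(rng.lognormal(2, 0.5)),
                              float(5 + rng.exponential(5))))
            if rng.random() < cfg.p_promoter_k27ac:
                iv2 = GenomicInterval(g.body.chrom, s + 200, s + 1200,
                                      name=f"k27p_{g.gene_id}")
                k27ac.append(Peak(iv2, s + 700, float(rng.lognormal(2, 0.5)),
                                  float(5 + rng.exponential(5))))
        n_enh = rng.poisson(cfg.enhancers_per_gene)
        for e in range(n_enh):
            off = int(rng.integers(2000, 50_000)) * (1 if rng.random() < 0.5 else -1)
            s = g.tss + off
            if s < 0 or s + 800 > cfg.chrom_sizes[g.body.chrom]:
                continue
            iv = GenomicInterval(g.body.chrom, s, s + 800,
                                 name=f"k27e_{g.gene_id}_{e}")
            k27ac.append(Peak(iv, s + 400, float(rng.lognormal(2, 0.5)),
                              float(5 + rng.exponential(5))))

    # ------------------------------------------------------------------ emit
    write_chrom_sizes(outdir / "genomeA.chrom.sizes", kary)
    write_chrom_sizes(outdir / "genomeB.chrom.sizes", kary_b)
    for r, rep in enumerate(reps_a, 1):
        write_narrowpeak(outdir / f"ctcfA_rep{r}.narrowPeak", rep)
    for r, rep in enumerate(reps_b, 1):
        write_narrowpeak(outdir / f"ctcfB_rep{r}.narrowPeak", rep)
    for t, tp in tissue_peaks.items():
        write_narrowpeak(outdir / f"tissue_{t}.narrowPeak", tp)
    write_narrowpeak(outdir / "h3k4me3.narrowPeak", k4me3)
    write_narrowpeak(outdir / "h3k27ac.narrowPeak", k27ac)
    for sub, evs in cohesin_events.items():
        subpeaks = [
            Peak(GenomicInterval(c, s, e, name=f"{sub.lower()}_{n}"),
                 (s + e) // 2, 1.0, 5.0)
            for n, (c, s, e) in enumerate(evs)
        ]
        subpeaks.sort(key=lambda p: (p.chrom, p.start))
        write_narrowpeak(outdir / f"{sub.lower()}.narrowPeak", subpeaks)
    write_repeat_tsv(outdir / "repeats.tsv", te_rows)
    write_orthology_tsv(outdir / "orthology.tsv", OrthologyMap(blocks))
    write_bed(outdir / "tads.bed", tads)
    write_gene_tsv(outdir / "genes.tsv", genes)
    write_de_table(outdir / "de_table.tsv", de_table)
    _write_meme(outdir / "motifs.meme", [CANONICAL_PWM, *ALTERNATIVE_PWMS])
    if cfg.write_fasta:
        _write_fasta(outdir / "genomeA.fa", cfg, rng, planted_motifs)

    truth = GroundTruth(truth_rows, gene_truth, cfg)
    _write_truth(outdir, truth)
    _write_manifest(outdir, cfg)
    return truth


def _write_meme(path: Path, pwms: Sequence[PWM]) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def _write_fasta(
    path: Path,
    cfg: SimConfig,
    rng: np.random.Generator,
    planted: Mapping[str, Sequence[tuple[int, str]]],
) -> None:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    with open(path, "w") as fh:
        for chrom, size in cfg.chrom_sizes.items():
            seq = bases[rng.integers(0, 4, size)]
            arr = bytearray(seq.tobytes())
            consensus = _CANONICAL_CONSENSUS
            for start, strand in planted[chrom]:
                s = consensus if strand == "+" else _revcomp(consensus)
                arr[start : start + len(s)] = s.encode()
            fh.write(f">{chrom}\n")
            text = bytes(arr)
            for off in range(0, size, 80):
                fh.write(text[off : off + 80].decode() + "\n")


def _write_truth(outdir: Path, truth: GroundTruth) -> None:
    pk = truth.peaks
    with open(outdir / "ground_truth_peaks.tsv", "w") as fh:
        cols = list(pk[0].keys())
        fh.write("\t".join(cols) + "\n")
        for row in pk:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
    with open(outdir / "ground_truth_genes.tsv", "w") as fh:
        cols = list(truth.genes[0].keys())
        fh.write("\t".join(cols) + "\n")
        for row in truth.genes:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")


def _config_dict(cfg: SimConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["chrom_sizes"] = dict(d["chrom_sizes"])
    d["frac_favourable"] = dict(d["frac_favourable"])
    d["cohesin_rates"] = dict(d["cohesin_rates"])
    d["gene_length_range"] = list(d["gene_length_range"])
    return d


def _write_manifest(outdir: Path, cfg: SimConfig) -> None:
    checksums = {}
    for f in sorted(outdir.iterdir()):
        if f.name == "manifest.json" or f.is_dir():
            continue
        checksums[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"config": _config_dict(cfg), "checksums": checksums}, fh, indent=1)


def read_ground_truth(outdir: str | Path) -> GroundTruth:
    """Reload the ground-truth tables written by :func:`generate`."""
    outdir = Path(outdir)

    def _read(path: Path) -> list[dict]:
        with open(path) as fh:
            cols = fh.readline().rstrip("\n").split("\t")
            rows = []
            for line in fh:
                vals = line.rstrip("\n").split("\t")
                row = dict(zip(cols, vals))
                for key in ("start", "end", "summit", "te_b2b4", "cohesin",
                            "motif_start", "boundary_pos", "de"):
                    if key in row:
                        row[key] = int(row[key])
                for key in ("te_divergence",):
                    if key in row:
                        row[key] = float(row[key])
                rows.append(row)
        return rows

    with open(outdir / "manifest.json") as fh:
        cfg_d = json.load(fh)["config"]
    cfg_d["gene_length_range"] = tuple(cfg_d["gene_length_range"])
    cfg = SimConfig(**cfg_d)
    return GroundTruth(
        _read(outdir / "ground_truth_peaks.tsv"),
        _read(outdir / "ground_truth_genes.tsv"),
        cfg,
    )
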