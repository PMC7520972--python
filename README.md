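# ctcfevo

Comparative analysis of CTCF binding-site evolution between two closely
related mouse subspecies (*Mus musculus domesticus*, BL6, and *M. m.
castaneus*, CAST), built as a tested, reusable pipeline over ChIP-seq peak
calls and genome annotations.

CTCF is an 11-zinc-finger DNA-binding protein that organises 3D genome
architecture: together with the cohesin complex (RAD21 plus STAG1 or STAG2)
it anchors chromatin loops, and its directional binding motif points inward
("convergently") at the boundaries of topologically associating domains
(TADs). In rodents, SINE B2/B4 transposable elements carry CTCF-motif-like
sequence and seed evolutionarily young binding sites. This package
implements the comparative analyses that characterise such young sites:

- **Interval engine** — exact BED-style `intersect`, `closest`, `merge` and
  matched random `shuffle` with oracle-verifiable semantics (0-based,
  half-open coordinates).
- **Replicate consensus** — narrowPeak I/O and the "present in ≥ 2
  biological replicates" filter, with attributes taken from the
  highest-signal replicate copy; signal-decile binning.
- **Evolutionary classification** — projection of peaks through a pairwise
  orthology block map; peaks bound at alignable orthologous locations in
  both subspecies are *musculus-common*, peaks whose sequence has no
  alignment in the other subspecies are *subspecies-specific* (aligned but
  unbound locations are kept as a third class).
- **Repeat analysis** — per-peak transposable-element masked fraction,
  length-weighted divergence age (% substitutions from the family
  consensus; lower = younger), genome background, binomial/chi-square
  enrichment.
- **Cross-tissue occupancy** — peaks × tissues occupancy matrix, UpSet-style
  combination counts, per-site Shannon diversity
  H = −Σ pᵢ ln pᵢ over normalised −log₁₀ p binding weights, conservation
  per diversity bin, and the strict tissue-shared rule (bound in all of the
  top-4 ranking tissues *and* the designated replicate tissue).
- **Regulatory association** — promoters (H3K4me3 ± H3K27ac) and enhancers
  (H3K27ac alone), nearest-TSS distances, ±50 kb DE-gene association with
  majority-vote class assignment, and regulatory-profile stratification.
- **TAD & cohesin** — PWM log-odds motif scanning on both strands,
  summit-proximal motif selection with alternative-motif fallback, boundary
  distance and favourable/reverse orientation calls, boundary cluster
  composition, 2-of-3 cohesin subunit merging and per-class colocalisation.
- **Synthetic data** — a seeded generator that emits the full input bundle
  (narrowPeak, repeat TSV, orthology TSV, TAD BED, gene/DE tables, MEME
  motifs, FASTA) with planted ground truth for every stage.

## Worked example

```sh
ctcfevo simulate --out bundle/ --seed 7 --n-peaks 1000
ctcfevo all --bundle bundle/ --rundir run/
```

The `all` command prints per-stage reports; on the bundle above it reports
(abridged):

```
"classify":   {"class_counts": {"musculus_common": 600,
                                "species_specific_unaligned": 174,
                                "aligned_unbound": 124}, "n_peaks": 898}
"repeats":    {"b2b4_overlap_fraction": {"musculus_common": 0.173,
                                         "species_specific_unaligned": 0.333, ...}}
"tissues":    {"shared_fraction_of_specific": 0.098, ...}
"cohesin":    {"colocalised_fraction_by_class": {"musculus_common": 0.785,
                                                 "tissue_specific": 0.535,
                                                 "tissue_shared": 0.647}}
```

Reading: of 898 consensus peaks, ~67 % classify as musculus-common (the
generator's default preset plants 74 %, and replicate dropout moves a share
of common peaks into the aligned-unbound class because their partner peak is
lost from the other subspecies' consensus). Subspecies-specific sites
overlap B2-B4 SINE elements about twice as often as common sites, ~10 % of
them are tissue-shared, and common sites colocalise with 2-subunit cohesin
regions markedly more often than tissue-specific ones — the planted
structure the pipeline is designed to recover.

Each stage can also be run individually (`consensus`, `classify`,
`repeats`, `tissues`, `regulatory`, `tad`, `cohesin`) against a persisted
run directory, and all numeric settings live in a flat `key = value` config
file (see `ctcfevo all --help`).

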