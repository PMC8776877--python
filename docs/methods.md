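# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the underlying experimental
procedure left the computational details open.

## Cross-resistance classification

A typing matrix holds one call per clone × panel phage in {S, R, NT}.
Classification is always relative to the strain's wild-type baseline:

- *acquired* resistances are phages typed R in the clone but S in the wild
  type; phages the wild type already resists are *not evaluable* and never
  enter any count; NT cells are excluded from all denominators.
- Receptor groups: every panel phage targets LPS, T4P or both. A clone's
  category is determined by the receptor groups of its acquired phages
  versus those of the applied phage(s): `none` (nothing acquired),
  `both_groups` (≥ 1 LPS-targeting and ≥ 1 T4P-targeting phage acquired),
  `same_receptor_only` (all acquired groups among the applied groups),
  `alternative_receptor_only` (otherwise). A dual-receptor phage (e.g.
  PA5oct, LPS + T4P) counts toward both groups, so acquiring it alone
  already yields `both_groups`; the source experiments did not specify how
  a dual-receptor phage contributes to group counts, and this is the
  package's convention.
- Self-resistance is assessed per applied phage, not per cocktail: a clone
  is "still sensitive" to an applied phage iff its call is S.
- Unique typing patterns group clones (per strain) by identical call
  vectors; the representative is the lexicographically smallest clone id —
  a deterministic stand-in for the original manual selection.
- Percentages are rounded to one decimal; an arm with no clones yields no
  row rather than a fabricated 0%.

## Variant pipeline

Variant calling itself is out of scope; calls are consumed from VCF v4.2
(effect class in the custom INFO key `EFF`, affected gene in `GENE`) or a
Snippy-style TSV. Conventions:

- Control filtering removes a variant iff an untreated-control variant
  matches it **exactly** on (chrom, pos, ref, alt). Position-only matching
  was considered and rejected: it would silently merge distinct alleles at
  mutational hotspots.
- The effect filter keeps missense, nonsense and frameshift. Intergenic
  variants can be rescued as promoter mutations when they lie within
  `promoter_window` (default 100 bp, strand-aware) upstream of a gene's
  transcription start; the window length is a package default — the
  original analysis marked promoter mutations without defining a window.
  Unknown effect strings map to `other` with a logged warning rather than
  failing the run.
- Six functional categories are fixed: LPS, EPS_mucoidity, T4P, flagella,
  global_regulatory, other. Five of these were enumerated explicitly by
  the source analysis, which nevertheless counted "six groups";
  flagella-related genes were discussed separately there and are taken as
  the sixth group. The gene → category map is total, defaulting to
  `other`.
- Tabulation reports, per clone, counts per category, the number of
  distinct genes and categories hit, and the two multi-hit flags (variants
  in 2–3 genes from different groups; ≥ 2 genes within one group).

## Deletion analysis

Coordinates are 0-based half-open internally; 1-based conventions appear
only at I/O boundaries (depth TSV, VCF). This keeps the interval algebra
free of off-by-one adjustments.

- `call_deletions` returns maximal runs of positions with depth ≤
  `depth_max` (default 0: strict absence of coverage) of length ≥
  `min_len` (default 10 kbp: below the smallest deletion of interest,
  above short mapping dropouts). An optional windowed mode tolerates
  sporadic stray reads by flagging positions whose centred windowed mean
  (default 500 bp) is ≤ 5% of the genome-wide median depth; smoothing can
  move called boundaries inward by up to half a window, which is why the
  strict mode is the default for exact-recovery work.
- A call whose majority (≥ 50% of its length) overlaps an annotated
  resident-prophage interval is labelled `prophage_induction` rather than
  `deletion`: a coverage hole at a prophage locus reflects phage induction,
  not chromosome loss, and such calls are excluded from cohort deletion
  statistics.
- Cohort statistics: each clone contributes the union of its own calls;
  the *core element* is the intersection of these per-clone regions over
  all deletion-bearing clones (possibly empty, possibly several
  intervals), and the *cumulated range* is the union length over all
  calls. Both are validated against per-base boolean-array computation in
  the test suite. Gene containment requires the full gene body inside the
  core. An empty cohort yields a defined empty summary, not an error.
- Flank extraction returns the `flank_len` bp on each side of an interval,
  clipped at genome edges with explicit clip flags (motif discovery itself
  is out of scope).

## Carrier state

"Full phage contig" is operationalised as canonical k-mer breadth: the
fraction of the phage genome's canonical k-mers (k = 21, lexicographic
min of k-mer and reverse complement, ambiguous bases skipped) present in a
single contig's k-mer set, maximised over the clone's contigs. The breadth
threshold is 0.95 on the best single contig; the original study gave no
numeric criterion, and 0.95 tolerates assembly edge effects while rejecting
genomes with ≥ ~5% missing sequence. Breadth is invariant to
reverse-complementing any contig. A clone is a carrier of a phage iff the
breadth criterion holds **and** the clone is typed resistant to that phage;
otherwise the blocking condition (`contig_absent` or
`phenotypically_sensitive`) is recorded. Carrier ⇒ resistant is asserted on
every output.

The summary counts carriers per strain × phage over explicitly assessed
clone sets (denominators legitimately differ per phage when treatment arms
differ), strain totals as **distinct** carrier clones, a jumbo-phage
subtotal (genome > 200 kbp) counted over carrier calls, and the wild-type
intact-prophage count as strain metadata.

## Fitness

Cumulative OD is the plain sum of OD600 readings over the uniform 20-min
grid — proportional to the trapezoidal area under the curve up to the
constant step factor, and exactly the summary the growth assay reported.
Flagging uses one-way ANOVA across {pooled controls, clone₁, …, cloneₘ}
followed by Tukey HSD; only the clone-vs-control contrasts decide the
flag (all-pairs p-values are available behind a flag), and a clone is
*significantly reduced* when its adjusted p < α (default 0.001) and its
mean lies below the control mean. The control group pools untreated
control clones and the wild type. Clones with fewer than two replicates
get an undefined flag with a recorded reason.

Associations between the binary reduced-growth flag and clone features use
two-sided Fisher exact tests on 2×2 tables per strain (deletion presence,
carrier state, polyvalent treatment); resistance breadth is ordinal and
tested with a linear-by-linear trend test. The original report named only
"correlation analysis"; Fisher-on-dichotomised-reduction was chosen as the
method matching the binary flag actually produced. Degenerate tables
(constant feature or constant flag) are reported with an NA p-value and a
note, never silently skipped.

## Synthetic-data generator

The generator emulates the selection experiment's design: treatments are
single phages and cocktails; 10 clones are picked per treatment arm plus
untreated controls and a wild type; growth is measured in triplicate over
18 h at 20-min intervals (the grid includes t = 0, hence 55 samples —
plate readers record an initial read); inoculum 1 × 10⁵ CFU/ml and phage
titer 1 × 10⁷ PFU/ml are carried as experiment metadata. Mechanisms per
treated clone:

- point mutations per functional category with probability
  `p_point_mutation` (default 0.3, matching the observed ~⅔ of clones with
  point mutations across several categories); receptor-category mutations
  break that receptor;
- one large deletion with probability `p_deletion` (default 0.23, the
  observed deletion fraction), always containing a fixed core interval
  that carries an LPS-synthesis gene (so deletion ⇒ LPS-phage resistance)
  plus a pigment-pathway gene, mirroring the genes the real core element
  carries;
- a clone resists a phage iff one of the phage's receptors is broken (a
  dual-receptor phage is therefore resisted when either receptor is lost);
- carried phage genomes (probability `p_carrier` per applied phage,
  default 0.3, within the observed 0–60% prevalence range) only for
  phages the clone resists, emitted as full-length extra contigs;
- with probability `p_no_mechanism` (default 0.15, matching the reported
  ~5–9/35 clones) a clone is resistant to its applied phages with no
  genomic cause, and is labelled as such in the truth.

Growth follows a logistic curve (initial OD 0.01, carrying capacity 1.2,
rate 0.012 min⁻¹ — saturating at ~10 h like a fast-growing wild type)
whose rate is scaled by the clone's growth factor: ×0.7 for deletion
clones and ×0.8 for carriers by default, multiplicative when combined.
Gaussian noise (sd 0.02 OD by default) is added and truncated at zero.

Genomic scales are reduced for tractability: the default chromosome is
200 kbp with 20–60 kbp deletions over a 6 kbp core (the real system has a
6.3 Mbp chromosome, 24–545 kbp deletions, 19 kbp core). The structure —
deletions sharing a core, genes inside/outside the deletion footprint —
is preserved; absolute printed sizes are not comparable to the real ones.
Gene placement is deterministic: the two core genes sit inside the
deletion core and all other genes outside the maximal deletion footprint,
so planted point mutations never fall in deleted regions and zero-noise
recovery is exact by construction.

What the generator does **not** emulate: read-level sequencing noise
(coverage is exact: `depth` outside deletions, 0 inside), assembly
fragmentation and errors (contigs are exact sequences), phage population
dynamics, biofilm spatial structure, and partial receptor loss. Passing
the end-to-end recovery tests therefore demonstrates the correctness of
the analysis logic under clean inputs, not robustness to real sequencing
artefacts — the windowed deletion mode and the 0.95 breadth threshold are
the knobs intended for noisy real data.

Determinism: one seeded generator drives clone sampling in fixed order;
growth noise and phage genome sequences use streams derived from the seed
with fixed offsets, so phage sequences do not change with cohort size.
Identical configs produce byte-identical datasets (checked by checksum in
the tests).

## Problem sizes used in the tests and the acceptance script

The suite and `scripts/acceptance.py` exercise the pipeline on reduced
instances chosen to keep the whole run in minutes on one CPU while leaving
every code path and invariant covered: a 60 kbp genome, a four-phage panel
(two LPS, one T4P, one dual-receptor) with 3–5 kbp genomes, 3–5 clones per
treatment arm, 200 random interval cohorts on a 10 kbp toy genome, 1,000
null cohorts for type-I-error calibration and 200 cohorts for power. The
calibration checks that the Tukey-based flag at α = 0.001 keeps its
empirical false-positive rate ≤ 0.005 and detects a 2-fold growth-rate
penalty (noise sd 0.02, 3 replicates) with power > 0.9.

## Known limitations

- The carrier criterion measures sequence containment; it cannot
  distinguish an extrachromosomal carrier genome from a chromosomally
  integrated one. Best-contig identity is reported so chromosome-embedded
  matches can be inspected, but intent is not decided by the package.
- The deletion caller is coverage-only; split-read/paired-end structural
  variant evidence is out of scope.
- Tukey HSD assumes equal group variances; with triplicate growth curves
  this is untestable per clone, and the Monte-Carlo calibration (which
  shows the procedure conservative at α = 0.001) is the practical
  justification.
- Fisher tests on dichotomised fitness discard effect-size information;
  the underlying cumulative-OD values are exported for any finer modelling.
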