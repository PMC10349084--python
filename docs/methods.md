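# Methods

This note documents the models and procedures implemented in `dlhscan`,
the defaults chosen where the underlying methodology is genuinely open,
and what the synthetic-data generators do and do not emulate.

## The classification rule

A candidate protein is called a putative DMSP-lyase homolog (DLH) when
three independent evidence classes agree:

* **Racemase-domain profile hit.** The Asp/Glu/Hydantoin racemase
  superfamily domain is detected with a position-specific scoring profile
  built from a seed alignment: columns with ≥50% residue occupancy become
  profile columns; per-column log-odds are `log2(freq / background)` with
  pseudocount 0.1 over a uniform background. Scanning is ungapped (a
  contiguous window of profile length at every start; queries shorter
  than the profile pay `gap_penalty` bits per uncovered column, default
  −2). Overlapping above-threshold windows are merged keeping the higher
  score. The threshold is the `(1 − fpr)` quantile (default `fpr = 0.01`)
  of best-hit scores over a decoy set, floored at 0 bits — a hit must at
  least beat the background model, because for a ~120-column profile the
  decoy quantile lies hundreds of bits below zero and admitting
  negative-log-odds windows produces spurious hits (and false domain
  "duplications") in unrelated sequence. Domain duplication is flagged
  when ≥2 non-overlapping hits remain after merging.
* **Canonical cysteine pair.** Every occurrence of `[D/N]CGF` (N-site)
  and `ECT[E/Q]` (C-site) is reported with the 1-based position of the
  cysteine (second residue of the window). The pair is accepted when some
  C-site lies strictly downstream of some N-site, mirroring the C108 <
  C265 arrangement of the reference enzyme; the order requirement is
  configurable off. `X` never matches a pattern. No spacing constraint is
  imposed — the reference arrangement is the only worked instance, and
  its spacing is not known to be conserved.
* **Motif evidence.** At least `min_motifs` (default 5) of the motif bank
  must match. The underlying surveys confirm "the unique motifs" without
  stating a count rule, so the majority default is exposed prominently
  rather than buried.

Evidence is retained in every `ClassificationResult` regardless of the
verdict, so near-misses can be audited.

## Discriminative motif discovery

The discovery algorithm is deterministic given a seed:

1. Positives and controls are split into train/hold-out halves by a
   seeded shuffle.
2. For each width w in [4, 15], every w-mer present in ≥20% of training
   positives is a candidate seed. Only **maximal** seeds are evaluated:
   a k-mer is dropped when a superstring seed occurs in ≥90% of the same
   sequences. A substring whose occurrences are (nearly) all explained by
   a longer seed carries no independent evidence, and evaluating it lets
   sampling noise promote truncated motifs over the full-width one; a
   substring with substantial independent occurrences (for example the
   shared core of two distinct motifs) survives the filter, and masking
   (step 6) re-exposes independent sub-motifs on later iterations in any
   case.
3. Each seed is refined into a PWM from its best match per training
   positive under a zero-or-one-occurrence (ZOOPS) model: a sequence
   contributes its best window only when that window scores at least half
   the seed's consensus score against the seed PWM, so motif-free
   sequences contribute nothing (including them memorizes their random
   windows and corrupts both the PWM and the threshold). Pseudocount 0.1
   per cell; the background is the pooled residue frequency of the
   controls — the family being discriminated against.
4. The match threshold maximizes training-set discrimination (TPR − FPR
   over per-sequence best scores). The largest threshold within one
   sequence's tolerance of the maximum is used: without the tolerance, a
   single noisy training sequence can drag the threshold deep into the
   background score range, which costs hold-out specificity.
5. Significance is a one-sided Fisher exact test on the hold-out halves
   (sequences with/without a match, positives vs. controls), multiplied
   by the number of seeds tested this iteration — a Bonferroni-style
   E-value. Ties are broken by more hold-out positives matched, then by
   greater width (a wider motif is more informative at equal evidence),
   then lexicographically.
6. The best motif is accepted if its E-value is below `alpha`
   (default 0.05), all its above-threshold occurrences in positives are
   masked with `X`, and the search repeats until `n_motifs` are found or
   nothing passes. Output is ordered by significance.

Scanning treats `X` as scoring 0 (the background log-odds). Logo export
uses per-column information content `IC = log2(20) − H` with no
small-sample correction; letter height is frequency × IC.

Published motif tables for this family exist only as figures, so the
shipped default bank is a synthetic stand-in
(`dlhscan.synthetic.DEFAULT_MOTIFS`) and any user-supplied bank in the
MEME-like text format can replace it.

## Phylogeny

Sequences are cut to the domain hit coordinates, aligned externally
(alignment construction is out of scope; aligned FASTA is consumed), and
columns with fewer than `min_occupancy = 10` non-gap residues are
removed — exactly the stated column rule; terminal-overhang heuristics
beyond it are not applied.

Distances use pairwise gap exclusion: `p` = mismatches / scored columns
over columns where both sequences have residues, with `X` matching
nothing. Models: `p_distance`, `poisson` (`d = −ln(1 − p)`) and the
default `kimura_protein` (`d = −ln(1 − p − 0.2 p²)`), the correction the
classic NJ tools apply for proteins. Saturated pairs are capped at a
configurable maximum (default 10 substitutions/site); a pair with zero
scored columns is an error naming the pair.

Neighbor-Joining is the canonical Saitou–Nei agglomeration on the Q
criterion with deterministic tie-breaking (smallest (i, j) in current
order). Negative branch lengths are clamped to zero with the deficit
transferred to the sister branch, preserving the joined distance.
Bootstrap resamples columns with replacement (seeded), rebuilds the tree
per replicate, and annotates each internal edge of the full-data tree
with the percentage of successful replicates containing the same
bipartition; degenerate replicates are skipped, logged and excluded from
the denominator. No consensus tree is built — support is mapped onto the
full-data topology, the common presentation for family trees. Trees are
scikit-bio `TreeNode` objects; Newick round trips preserve topology,
lengths and integer support labels.

## Ecology

* **Abundance** is percent of mapped reads: `100 × count /
  total_mapped` per cell; a zero-total sample becomes an NA column with a
  warning.
* **Environmental correlation** sums a taxon's gene abundances per
  sample, then computes Spearman rank correlation against each variable
  within each oceanic region, with pairwise deletion of missing values
  (correlation-by-available-data practice). Cells with <3 usable samples
  or constant vectors are NA. Benjamini–Hochberg correction runs across
  the emitted grid — the standard choice for grids of correlations.
  Correlation is per sample; depth-averaging per station before
  correlating is a deliberate non-default (sum per sample, correlate per
  sample) since pooling conventions vary between surveys.
* **Size factors** implement the median-of-ratios estimator directly:
  reference = per-gene geometric mean across samples (genes with any
  zero excluded); factor = median over genes of count/reference. Factors
  are defined up to a common scale: multiplying one sample's counts by k
  multiplies its factor *relative to any other sample* by exactly k (the
  absolute factor moves by k^(1−1/m) because the reference scales too).
* **Fold change** is the ratio of group means of normalized counts with
  pseudocount 0.5 on both means.
* **Depth-differential expression** splits samples at the euphotic
  boundary (200 m, configurable), computes per gene the difference of
  mean `log2(value + pseudocount)` between zones, and obtains two-sided
  p-values by seeded permutation of zone labels
  (`p = (1 + #{|t*| ≥ |t|}) / (1 + B)`), BH-corrected across genes. A
  gene is called enriched in its higher-mean zone when the adjusted p
  falls below `alpha`. A permutation test was chosen because the
  underlying surveys report "significantly expressed/upregulated" without
  naming a test; it is assumption-light and exactly reproducible given
  the seed. When the input is a raw count matrix, `normalize=True`
  applies the size factors first; percent-of-mapped-reads inputs are
  used as given.

## Synthetic data: what it emulates, and what it does not

The generators stand in for the external databases this kind of survey
mines (culture transcriptome collections, genome portals, ocean
metatranscriptome atlases). All outputs are pure functions of their
seeds, and each dataset ships with a truth manifest sufficient to score
recall and precision of every stage.

* **Protein sets.** Positives carry a noised copy (per-site substitution
  rate 0.05) of a fixed 120-residue domain consensus with both cysteine
  contexts planted inside it (spacing drawn from 60–100 residues,
  mirroring an active-site arrangement), plus each of ten motifs (widths
  4–15) with configurable penetrance, all at non-overlapping positions
  in background-composition flanks. 33% of positives receive a second,
  context-free domain copy — the family's reported duplication rate.
  Decoys carry the noised domain but are scrubbed of any canonical
  context, emulating bacterial racemases. The motif-discovery preset
  plants only the motif (no domain, no contexts): at full penetrance the
  4-residue cysteine contexts would otherwise dominate discovery and the
  planted-motif recovery measurement would measure the wrong signal.
* **Families.** Sequences evolve along a random binary tree by per-branch
  substitution (`P(sub) = 1 − e^{−b}` per site, uniform replacement), so
  the generating tree is the oracle for topology recovery; a two-clade
  design with a block of fixed differences provides the strong-signal
  bootstrap case.
* **Abundance/expression.** Station × depth samples carry environmental
  fields derived from latent standard normals. A taxon's per-sample
  total abundance is linked to a chosen variable through a Gaussian
  copula at a target Spearman ρ (using `r = 2 sin(πρ/6)` to convert the
  rank target to the latent Pearson correlation), then split across the
  taxon's genes by Dirichlet weights so the per-taxon sum — the quantity
  the correlation analysis uses — retains the target exactly up to
  sampling noise. Counts are negative-binomial (dispersion 1/10, a
  realistic overdispersion for expression data) around zone-specific
  means implementing the fold-change map; the planted depth contrast
  uses 8-fold, matching the magnitude of reported depth effects. The
  default depth-differential scenario uses 2 stations × 6 depths (6
  samples per zone) and 24 genes, the scale of a dinoflagellate DLH
  panel in a vertical-transect metatranscriptome.

Not emulated: real station layouts or nutrient climatologies, sequence
alignment artifacts (families are generated without indels), phylogenetic
autocorrelation between taxa, and compositional coupling between taxa in
the abundance table. Passing tests therefore demonstrate correctness of
the statistical machinery on data with known truth, not performance on
any particular ocean survey.

## Numerical and design choices

* Fisher exact p-values come from the hypergeometric distribution and are
  validated against exhaustive enumeration for all tables with group
  sizes ≤12; E-values are floored at the smallest positive float.
* Spearman uses average ranks for ties and the t approximation with n−2
  degrees of freedom, validated against the rank formula on all
  permutations up to n = 6.
* Identity calculations default to the pairwise-gap-excluded
  `aligned_columns` denominator, with `shorter_sequence` selectable —
  published identity figures for divergent pairs depend on this
  convention, so both are exposed.
* Seeds propagate through `numpy.random.default_rng`; every stochastic
  operation (train/hold-out split, bootstrap, permutation test,
  generators) takes an explicit seed and reproduces byte-identical
  output.
* Problem sizes in the validation suite (e.g. 200 additive trees, 20
  discovery runs, 10⁴ permutations) were chosen to give the binomial
  margins the assertions need while keeping a full run in tens of
  seconds.

## Known limitations

* The domain profile is an ungapped stand-in for a curated domain model:
  it ranks candidates well but does not produce alignment-quality hit
  boundaries (±2 residues in the validation), and it models no insert
  states.
* Motif discovery assumes ungapped motifs and one dominant occurrence
  per sequence; tandem motif repeats within one sequence are masked but
  not modeled.
* The bootstrap maps support onto the full-data topology only; there is
  no consensus-tree option.
* The depth-differential test treats samples as exchangeable under the
  null; station-level pseudo-replication is not modeled (a station term
  would require a mixed model, out of scope here).
* With small gene panels, median-of-ratios normalization absorbs part of
  a strong, one-sided depth effect into the size factors, biasing null
  genes slightly toward the opposite zone; the panel scale used here
  keeps the planted-gene calls exact, but panel-only normalization of
  heavily shifted matrices warrants caution in general.
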