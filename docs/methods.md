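# Methods

This note documents the models, estimators and numerical choices behind
tridram, and what the synthetic-data generator does and does not
emulate.

## Single-molecule co-accessibility model

Each proximity-ligated, bisulfite-converted molecule yields a read pair;
mate *i* carries GCH (GpC, accessibility) and HCG (CpG, endogenous
methylation) calls at the informative cytosines it covers. For a pair of
anchor feature sets A and B, the analysis path is:

1. **Anchoring.** For every call, the nearest filter-interval midpoint on
   its chromosome is found by binary search; ties between equidistant
   intervals go to the lower coordinate. Calls farther than *w*/2 from
   their nearest midpoint are discarded (default window *w* = 100 bp
   total, i.e. midpoint ± 50 bp). Reads with no retained call are
   dropped.
2. **Pairing.** Mates are summarized per read (call count, mean
   methylated fraction, anchor of the nearest retained call) and merged
   on read name so that only pairs with both mates anchored survive.
   Both mate-to-set assignments (mate 1→A with mate 2→B, and the
   reverse) are formed and pooled; a read qualifying in both directions
   is counted once. Separation is measured between anchor midpoints and
   restricted to a preset range (CTCF-style: ≥ 1 kb with a convergent
   + /− orientation rule; CRE–TSS: ≥ 5 kb; TF pairs: 50 bp window,
   separation 100–300 bp). Measuring separation between read positions
   instead is a one-line change (the observation table retains both).
3. **Clustering.** The (mean_A, mean_B) matrix is k-means clustered
   (k = 4 by default, 10 seeded restarts via scikit-learn); clusters are
   relabeled 1..k by descending grand mean so cluster 1 is always the
   jointly-open (or jointly-methylated) group. Clustering is display
   and summary only; the test below does not depend on it.
4. **Binarization.** A mate is called open iff its mean ≥ 0.5 (boundary
   counts as open) and it has ≥ 1 retained call; both thresholds are
   config keys. Because the published description does not fix this
   rule, the headline co-accessible fraction is reported twice: as
   100·n11/N from the thresholded table and as the relative size of the
   top k-means cluster.
5. **Dependence test.** Two-sided Fisher exact test (scipy) on the 2×2
   table of binary states. The reported odds ratio is the sample
   cross-product n11·n00/(n10·n01) — not the conditional-MLE estimate
   some packages return; with any zero cell, 0.5 is added to every cell
   (Haldane–Anscombe). A zero margin leaves the odds ratio undefined
   (reported as null) with p = 1.
6. **Randomized control.** Observations in which exactly one mate is
   anchored; the free mate's window is centered on the midpoint of its
   own call span, so it reports background accessibility at a
   comparable separation. The control is subsampled (seeded) to the
   size of the anchored set. The construction is this package's own —
   published descriptions do not fix distance matching or subsampling.

Co-methylation runs the identical machinery on HCG calls.

## Synthetic-data generator

The generator exists so that every stage has planted ground truth.

* **Genome**: uniform-random ACGT with GATC restriction sites every
  400 bp, GCH sites planted every 15 bp and HCG sites every 60 bp.
  Random background sequence contributes additional informative sites
  (a random base is GCH with probability ≈ 3/64), which is harmless
  because call simulation scans the realized sequence. Base composition
  is deliberately unrealistic; none of the statistics under test depend
  on it.
* **Contact pairs**: cis distances follow a truncated power law
  P(s) ∝ s^(−α) on [1 kb, L) by inverse-transform sampling; the left
  position is uniform on [0, L − s], so the distance law is exact and
  free of edge effects. Within-TAD and same-compartment pairs are
  up-weighted by rejection sampling (exact, since the proposal weight
  is bounded by the boost product).
* **Latent states**: each anchored read pair draws (open_1, open_2) from
  the 2×2 law with marginals (p1, p2) and odds ratio θ; p11 is the
  admissible root of the Plackett quadratic
  (θ−1)p11² − [1+(θ−1)(p1+p2)]p11 + θp1p2 = 0, verified in tests
  against a bisection oracle at 1e-10. Background mates draw
  independent Bernoulli(0.15) states. Latent states are per molecule,
  not per locus: the generator makes no claim about locus-level state
  persistence, footprint shape or TF residence time, so passing tests
  say nothing about those properties of real data.
* **Calls**: GCH calls are methylated with P(meth | open) = 0.8 and
  P(meth | closed) = 0.05 — chosen as a realistic enzyme-efficiency /
  protection contrast that leaves per-read binarization imperfect, so
  recovery tests exercise genuine noise. HCG calls are methylated at a
  0.75 baseline (a typical bulk mCpG level for pluripotent cells), and
  conversion failure flips unmethylated calls to methylated with
  ε = 0.01 by default (observed real-data failure rates are below 2%).
  Reads are 100 bp, matching common paired-end sequencing of such
  libraries; anchored mates are centered on their anchor ± 10 bp
  jitter.
* **Spike-ins**: unmethylated-template calls read methylated with
  probability ε (conversion failure); methylated-template calls read
  unmethylated with probability ε (detection failure).
* **Seeding**: one global seed; each stage draws from
  `default_rng([seed, stage_offset])`, so adding a stage never perturbs
  earlier draws and identical configs are byte-identical.

Not emulated: raw bisulfite FASTQ (only junction-bearing test reads are
emitted), sequencing error beyond ε, mapping artifacts, copy-number or
coverage biases, locus-persistent chromatin states, and trans contacts.

## Contact statistics

* **Expected model**: per-diagonal mean contact count, constrained to be
  non-increasing in distance by an isotonic fit weighted by diagonal
  length. This is the package's distance-stratified observed/expected
  normalization; it stands in where others use kNN-smoothed Hi-C
  scores. It is exact on distance-homogeneous matrices (so
  "uniform map → all statistics at their null value" holds to machine
  precision) and, being monotone, it cannot absorb alternating
  compartment structure.
* **Insulation**: for bin *i*, observed contacts in the
  upstream-flank × downstream-flank rectangle (flank 250 kb at 1 kb
  bins by default) are summed and divided by the expected-model sum
  over the same cells; the score is −log2(ratio) with pseudocount 1, so
  boundaries are local maxima. Bins within one flank of the chromosome
  edge are NaN. The exact rectangle statistic is this package's
  documented choice; published pipelines defer theirs to external
  references.
* **Boundaries**: bins strictly above the genome-wide 90% quantile that
  are ≥ every value within ± 2 kb; equal-valued plateau runs keep the
  lowest coordinate. On planted 5-block maps (interior boost 3) all
  four junctions are recovered within ±2 bins with ≤ 1 spurious call;
  note that the two bins flanking a junction carry identical rectangle
  statistics, so a one-bin offset against the nominal junction
  coordinate is expected.
* **Rescaled TAD pileup**: each TAD is extended by its own length on
  both sides, the 3L region mapped onto a 100×100 grid; per grid cell,
  obs and expected sums are accumulated and log2((obs+1)/(exp+1))
  averaged across TADs. Companion per-grid-bin means of any
  per-position track (methylation, accessibility) are supported.
* **Compartments**: leading eigenvector (numpy `eigh`) of the Pearson
  correlation matrix of the obs/exp map, zero-coverage bins masked. The
  sign is oriented by positive correlation with a user track
  (e.g. accessibility, A being the open compartment) or, absent one, by
  making the first non-zero entry positive. A map with no off-diagonal
  structure (constant obs/exp, or a single-sign eigenvector) is flagged
  unreliable.
* **Compartment strength**: mean obs/exp over same-label bin pairs
  divided by mean over cross-label pairs, restricted to intrachromosomal
  pairs ≥ 10 Mb apart. Count-normalized means (rather than raw sums)
  make the statistic exactly 1 on a structureless map and independent
  of the A/B label balance; this is the package's reading of the
  (AA+BB)/(AB+BA) ratio.
* **Aggregate pair enrichment**: per anchor pair, the
  log2((obs+ψ)/(exp+ψ)) submatrix in a window centred on the pair is
  stacked and averaged (ψ = 1 count throughout, a config key). The
  center/corner ratio compares the mean linear enrichment of the
  central nine bins with the mean over all four 3×3 corner blocks
  together; per-corner ratios are emitted for transparency. Pairs too
  close to the matrix edge are skipped and counted.
* **Per-pair score**: mean log2((obs+ψ)/(exp+ψ)) in a 10 kb window
  around each pair; groups are compared with the Wilcoxon rank-sum
  test. With ψ = 0 the score is exactly invariant to global matrix
  rescaling; with the default ψ = 1 the invariance is approximate at
  low counts.
* **Peak→gene association**: a feature within ±5 kb of any TSS goes to
  its nearest TSS; otherwise it goes to the same-TAD TSS with the
  highest contact score among candidates at 5 kb–2 Mb, score ties to
  the nearest candidate. Since the promoter window and the distance
  floor are both 5 kb, the floor only becomes active when the two
  parameters are configured apart; it is kept for exactly that reason.

## Read processing

* **Junction splitting** cuts at the midpoint of each 8-mer junction
  motif, so each product keeps one 4 bp half-site — the symmetric
  choice for a fill-in ligation junction; the split placement is this
  package's convention. Overlapping motif hits are all honored,
  left-to-right. Products under 20 bp (the usual trimming floor) are
  dropped. The motif list is configurable, e.g. to add the fully
  methylated GATCGATC junction or another enzyme's signatures.
* **Fends**: each restriction cut site carries two fragment-end ids
  (2i for its left side, 2i+1 for its right); + strand reads project to
  the nearest site at/downstream, − strand reads at/upstream; positions
  beyond the terminal sites get chromosome-terminal pseudo-fends.
  Deduplication keeps the first pair per unordered fend-pair key.
* **Contexts**: HCG = non-G, C, G (CpG channel); GCH = G, C, non-G
  (accessibility channel); GCG is ambiguous between the two enzymatic
  sources and excluded from both; − strand is classified on the
  reverse complement. Missing flanks at sequence edges count as non-G.

## Bulk tracks

Pileups keep positions with coverage ≥ 5 (per replicate) or ≥ 10
(merged); both floors are parameters. Conversion efficiency is the
unmethylated percentage of HCG calls on the unmethylated lambda
spike-in; the detection rate is the methylated percentage on methylated
controls (pUC19, plus GCH calls on GpC-methylated lambda).
Metaprofiles weight features equally (not by call count — the published
choice is unstated, equal weighting is this package's); empty bins are
NaN and excluded from means rather than zero-filled, because absence of
coverage is not evidence of absence of signal; − strand features are
column-reversed.

## Problem sizes and tolerances in the shipped checks

Odds-ratio recovery uses 20,000 anchored pairs at p1 = p2 = 0.3 (≈ 7
GCH calls per windowed mate), which bounds sampling error on the OR
near ±5% and leaves room for binarization attenuation inside the 15%
(θ ≤ 3) / 20% (θ = 10) bands. Type-I calibration uses 500 null
replicates of 2,000 pairs; the acceptance band [0.02, 0.08] reflects
both binomial noise and the conservatism of exact tests. Boundary
recovery uses a 500-bin Poisson map at depth 20; compartment recovery a
100-bin checkerboard at contrast 2, where the isotonic expected model
leaves the alternating signal intact and strength lands within 5% of
the constructed value 2.0. The decay-slope fit uses 50,000 pairs on a
10 Mb chromosome with log-spaced bins and a density (count/width)
regression in log–log space.

## Known limitations

* The expected model is per-chromosome and distance-only; no iterative
  (ICE-style) balancing is applied, so coverage biases in real data
  propagate into obs/exp statistics.
* `BinnedContactMatrix` is dense; practical up to a few thousand bins
  per chromosome, which covers 1 kb bins on the simulated genomes and
  250 kb bins genome-wide, but not 1 kb bins on full mammalian
  chromosomes.
* The randomized control and the binarization rule are documented
  stand-ins for under-specified published procedures; conclusions that
  depend sensitively on either should be checked against both reported
  headline fractions (threshold-based and cluster-based).
* Alignment, trimming, peak calling and differential testing are out of
  scope; the package consumes extractor-style call tables and `.pairs`
  text produced upstream.
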