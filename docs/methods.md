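# Methods

This note records the models behind each stage, the parameters that matter,
what the synthetic generators do and do not emulate, and the numerical
choices made where the design was genuinely open. It states no empirical
result that the test suite or the pipeline does not itself compute.

## Study design

The default design has four eggshell-colour groups — dark blue (DB), light
blue (LB), dark-brown/greenish (DP) and pink control (PK) — with 3, 3, 4
and 3 replicate shell-gland samples (13 total), and four default contrasts:
DB vs PK, LB vs PK, DP vs PK, DB vs DP. The source material is ambiguous
about the PK group size (the husbandry text implies four hens, the sample
table lists three); the sample table wins and the design is configurable.
A contrast "A_vs_B" reports log2FC = log2(mean_A / mean_B), so "up" always
means higher in the first-named group.

## Back-splice junction calling

Anchor length is fixed at 20 nt (configurable); a read must be at least
twice the anchor length. Anchor mapping is **exact** — a hash of every
genomic k-mer on both strands — rather than a mismatch-tolerant aligner:
alignment proper is a solved problem delegated to external mappers on real
data, and exact matching keeps the calling logic self-contained and fully
verifiable on toy genomes. Consequences: no tolerance for sequencing
errors, and repeats are handled by rejection (a read is used only when
exactly one breakpoint pair survives extension plus splice-site
validation; ambiguous reads are counted and discarded).

Coordinates are 0-based half-open internally and in BED output; GTF is
read/written 1-based inclusive. A candidate's span [start, end) always has
start < end in genome coordinates. For a '+' candidate start is the
acceptor and end the donor; splice validation requires `AG` immediately
before start and `GT` immediately after end. For a '−' candidate the
biological donor/acceptor roles attach to the opposite span ends and the
flank check becomes `AC` before start and `CT` after end (the reverse
complement of GT..AG read on the minus strand). Calling is invariant under
reverse-complementing the input read because both orientations are tried
and the flanks decide the strand; a span whose flanks match neither rule
is rejected.

"Unique" supporting reads are distinct (sequence, breakpoint) pairs after
exact-duplicate collapsing, tallied per sample; the support filter keeps a
candidate iff some single sample has ≥ 2 unique reads (the literal
"in at least one sample" reading — support is not pooled across samples).

Annotation classes partition candidates with this precedence within a
same-strand overlapping gene: wholly inside one exon → `one_exon`; both
breakpoints on exon boundaries spanning ≥ 2 exons → `annot_exons`; wholly
inside one intron → `intronic`; any other exon/intron mix → `exon_intron`.
Only opposite-strand overlap → `antisense`; no overlap → `intergenic`.

## Quantification

- miRNA "TPM" is counts-per-million **without a length term**: small-RNA
  tags are essentially length-homogeneous (~22 nt), so the per-kilobase
  factor cancels; this is stated prominently because the acronym usually
  implies length normalisation.
- FPKM = count × 10⁹ / (length × library size), with library size the
  column total of the analysed matrix — no external mapped-read figure.
- circRNA RPM = unique back-splice reads × 10⁶ / mapped reads per sample.
- 2^−ΔΔCt averages replicate Ct values per (gene, condition) before
  differencing. The reference gene is a parameter (GAPDH for mRNA, U6 for
  small RNAs by convention), never hard-coded. No amplification-efficiency
  correction is applied.

## Differential expression

The test is this package's own exact conditional negative-binomial test —
a documented stand-in for the dedicated DE packages used on real data,
sharing their model class (NB with variance μ + φμ²) and thresholds:

- **Normalisation**: median-of-ratios size factors (geometric-mean
  reference over features expressed in all samples), robust to a minority
  of strongly DE features; falls back to relative totals for degenerate
  matrices.
- **Dispersion**: per-feature method of moments, φ̂ = max(0, (s²−μ)/μ²) on
  normalised counts pooled across the two groups, then shrunk toward the
  10%-trimmed mean dispersion with weight 0.3 — a simple stabiliser for
  3–4 replicates that borrows strength across features.
- **Test**: groups' normalised pseudo-count totals S_A, S_B are compared
  conditionally on S_A + S_B under equal means; the sum of n iid NB(μ, φ)
  is NB with size n/φ, so P(S_B = x | s) ∝ f_B(x)·f_A(s−x). The two-sided
  p sums all outcome probabilities ≤ the observed one. At φ ≤ 1e−8 the
  conditional distribution is replaced by its exact Poisson limit, the
  binomial. All-zero features get p = 1.
- **Classification**: |log2FC| > 1 (the fold cutoff is read as an absolute
  value, since down-regulation is reported with negative log2FC) and
  either FDR < 0.05 (strict, mRNA/circRNA mode) or raw p ≤ 0.05
  (non-strict, miRNA mode). Both modes are exposed; neither is hard-coded.
  log2FC adds a pseudo-count of 1 to each normalised group mean so
  all-zero groups stay finite, and its sign always matches the sign of the
  mean difference.
- **BH adjustment** is implemented directly as the step-up definition
  (min over j ≥ i of p_(j)·m/j, clipped at 1) because the acceptance
  criterion requires exact equality with that definition; statsmodels is
  the independent cross-check in the unit suite.

## Target prediction

The internal predictor implements only the canonical seed grammar: target
sites matching the reverse complement of miRNA positions 2–7, graded 6mer
/ 7mer-A1 (+A opposite position 1) / 7mer-m8 (+pairing of position 8) /
8mer (both), strongest type per locus. No free-energy, conservation or
context scoring — production predictions from dedicated programs are
imported as TSV tables instead, and the two routes yield identical edge
records. U and T are equivalent on input. When two predictors are
imported, union or intersection of their (miRNA, target) pairs is a flag.

## ceRNA screens

Spearman is midrank-then-Pearson; constant vectors are defined as ρ = 0
(logged) rather than NaN so a flat feature can never pass a screen. The
inequality strictness follows the screen definitions exactly: ρ ≤ −0.5
non-strict, ρ > 0.5 strict, hypergeometric p < 0.05 strict.

The shared-miRNA test for a circRNA–mRNA pair is P(X ≥ m) with
X ~ Hypergeom(N, K, n): n = screened miRNAs regulating the circRNA, K =
screened miRNAs regulating the mRNA, m = their overlap. The universe N is
**not defined by the source method**; the default here is the number of
distinct miRNAs in the screened negative-pair set, configurable to all
expressed miRNAs. A consequence worth knowing: with n = K = m = 1 the
p-value is 1/N, so a meaningful screen needs a universe larger than 1/α —
tiny simulations will reject even perfect triples, which is correct
behaviour of the statistic, not a bug. No multiplicity correction is
applied to pair p-values by default (the screen is conventionally run on
raw p); BH is available behind a flag. Correlations use all samples of all
groups by default. The enrichment test shares the same hypergeometric
kernel, so one oracle suite covers both.

Connectivity is a node's count of distinct partners over the bipartite
circ–miRNA / miRNA–mRNA edges; rankings are per node type, descending
degree, ties broken lexicographically for determinism.

## Synthetic data: what it emulates, what it does not

The generators produce the *stated world* each recovery test assumes:

- **Counts**: NB(μ, φ) with variance μ + φμ², default baseline mean 100
  and dispersion 0.1 (typical of genuinely replicated bulk RNA-seq);
  planted features express their signed log2FC in the named group. The
  direction fixture plants the 24 printed fold-change rows (|log2FC| 3.28
  to 8.72) over ≥ 200 null features at baseline 1000 — a deep small-RNA
  library chosen a priori so the far side of the largest printed fold
  change (~1/420 of baseline) stays above the counting floor. Features
  printed in several contrasts get group means satisfying *all* their rows
  at once (offsets relative to the shared control compose).
- **ceRNA structure**: one latent N(0,1) per-sample signal per planted
  miRNA; counts are round(baseline·exp(±coupling·z + noise·ε)), positive
  for the miRNA, negative for its circRNA/mRNA partners, plus a
  within-feature rank tie-breaker so the planted correlations are exactly
  ±1 at zero noise (rounding would otherwise create ties at small counts).
  Defaults coupling 0.9, noise 0.2: planted |Spearman| ≈ 0.94 over 13
  samples, comfortably beyond the 0.5 cutoffs. Decoys are independent
  draws of the same spread, and decoy miRNAs are wired to decoy targets so
  the screens face a real null, not an empty one.
- **Genome/reads**: one chromosome (~60 kb at defaults) with 30 multi-exon
  genes on random strands; each planted circle spans whole exons of one
  gene, gets AG|...|GT flanks written into the genome (reverse-complemented
  on '−'), and contributes `junction_depth` reads crossing the back-splice
  at distinct offsets — so unique support is exact by construction.
  Background reads are collinear windows in random orientation. A separate
  class-covering fixture plants one circle per annotation class.

Not emulated: sequencing errors, quality-score realism, adapter content,
paired-end structure, rolling-circle multimers, hairpin structures for
novel-miRNA discovery, and group-level DE in the ceRNA matrices (the
correlation screens and the DE chain are validated on separate fixtures).
A green recovery test therefore establishes correctness of the algorithms
under clean data, not robustness to platform noise.

## Numerical choices

- All randomness flows from one master seed via numpy `SeedSequence`
  child seeds; fixed seed ⇒ byte-identical outputs.
- Exact-test tie handling: outcomes with probability ≤ p_obs·(1 + 1e−12)
  are summed, guarding against float jitter in "as extreme or more".
- Degenerate inputs: all-zero features p = 1; constant vectors ρ = 0;
  zero-support candidates RPM 0; empty networks rank to empty lists.
- The junction caller's per-read extension breaks out of the breakpoint
  scan at the first left-extension mismatch (longer splits cannot match).

## Known limitations

- Exact anchor matching cannot call junctions from reads with sequencing
  errors; on real data the anchor stage would be replaced by an aligner.
- The exact NB test conditions on rounded normalised totals; for very
  large totals the O(s) conditional sum dominates runtime.
- The DE stand-in matches the cited tools' model class and thresholds but
  not their shrinkage estimators; absolute p-values differ from DESeq2 or
  edgeR even on identical input.
- The hypergeometric universe choice materially changes pair p-values on
  small networks (see above); report N alongside any screened triple.
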