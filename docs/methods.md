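# Methods

This note documents the models and procedures implemented in `haloatlas`,
the parameters that matter, the numerical choices made where the
underlying procedure left them open, and what the synthetic-data tests do
and do not demonstrate about real data.

## Coordinate and format conventions

All genomic intervals are 0-based half-open internally. GFF3 (1-based
inclusive) and VCF (1-based) are converted at the I/O boundary and
converted back on write, so `read → write → read` round trips are exact.
Coverage is strand-aware: forward and reverse tracks are separate
`CoverageTrack` objects, matching stranded library preparations. bedGraph
values are parsed as floats; negative values and overlapping intervals are
rejected rather than silently merged. `SvRecord.pos` keeps the VCF's
1-based convention for traceability; mobilome clustering operates on
relative distances and is unaffected.

## RIP-Seq binding-region calling

The caller assumes per-nucleotide coverage of an immunoprecipitated (IP)
library and a tag-only control, and models enrichment as the
coordinate-wise log2 ratio

    LFC[i] = log2((s_ip·ip[i] + q) / (s_ctrl·ctrl[i] + q))

Two choices the bare ratio leaves open are explicit, exposed parameters:

- **Pseudocount** `q` (default 1.0), added to both numerator and
  denominator *after* scaling. It keeps the LFC finite where the control
  has zero coverage and shrinks ratios at low depth toward 0, which is the
  desired behavior for a depth-dependent signal.
- **Library scaling** (default `total-count`): each library is scaled to
  the mean total of the pair, `s_ip = T/(Σip)`, `s_ctrl = T/(Σctrl)` with
  `T = (Σip + Σctrl)/2`. Without it, a difference in sequencing depth
  shifts every position's LFC by a constant. `none` disables scaling for
  controlled experiments.

Binding regions are maximal runs of at least `min_run_length = 10`
consecutive positions with `LFC ≥ lfc_threshold = 1`. The threshold is
inclusive; two runs separated by even a single sub-threshold position are
never joined (no gap tolerance), since the run criterion is consecutive by
definition. Regions are reported maximal — not trimmed to a summit, not
extended. Consequences tested as properties: raising either threshold
never increases the number or total length of regions, and swapping IP and
control negates the track when scaling is off.

Replicate merging is interval union per (replicon, strand); overlapping or
book-ended regions coalesce and carry the union of replicate supports. The
operation is idempotent and commutative. Gene assignment flags a gene as
bound when ≥ 1 region overlaps it by ≥ `min_overlap = 1` nt on the same
strand; both knobs are exposed because gene-level binding calls are
sensitive to them and no single convention is canonical. Replicate
agreement is scored as observed intersection of bound-gene sets against
the independence expectation `|A|·|B|/N` with an upper-tail hypergeometric
p-value — the same arithmetic that yields a 3.8-fold enrichment for an
observed 157 against an expected 41.44.

## Nonredundant clustering

Sequences are clustered greedily, longest first (ties broken by lexical
id), each sequence joining the first cluster whose representative it
matches at or above the identity threshold — the documented CD-HIT
strategy, which makes the output deterministic and order-invariant.
Identity is computed from a Needleman–Wunsch global alignment (match +1,
mismatch 0, linear gap −1) as identical columns divided by alignment
length. The denominator is a genuine free choice (CD-HIT divides by the
shorter sequence length); both conventions are available via
`denominator={"alignment","shorter"}`, with `alignment` the default
because it penalizes length differences symmetrically. Thresholds are
inclusive: "at least 95%" admits exactly 0.95. No k-mer prefiltering is
implemented; the all-pairs cost is acceptable at the scale of one archaeal
genome's gene complement.

## Atlas assembly

Protein intensity, mRNA TPM and RPF TPM are incommensurate scales, so each
growth state's genes × layers matrix is quantile normalized: after
normalization every column holds the per-rank means of the column-sorted
input, ties receiving the mean of the reference values at their tied
ranks. Missing protein values (genes the proteomic assay never detected)
are excluded from rank computation and restored as missing — never
imputed into statistics. Columns containing missing values are mapped
through quantile interpolation against the common reference distribution
(the approach of limma's `normalizeQuantiles`); for complete columns this
reduces exactly to the sorted-row-means definition, which the tests assert
exactly.

Derived quantities: `TE = protein/(mRNA + 1)` and `RO = RPF/(mRNA + 1)`,
reported in log2 units in the atlas (the +1 pseudocount follows the
atlas's mRNA = TPM+1 convention and is configurable). Replicates are
averaged before normalization so one column per layer represents each
physiological state. Lagged mRNA–protein correlations are Pearson R on
log10(v+1)-transformed, pairwise-complete values; the transform is a flag
because correlations on raw intensities are dominated by the heavy right
tail. Cells with fewer than 3 complete pairs are reported missing.

CAI follows Sharp & Li: per synonymous family (bacterial/archaeal code,
table 11), `RSCU_c = count_c / mean(count)` and `w_c = RSCU_c / max RSCU`;
codons unobserved in the reference receive a count of 0.5 before RSCU;
single-codon families (Met, Trp) get w = 1; stop codons are excluded, and
a stop before the final codon is an error naming the sequence. A gene's
CAI is the geometric mean of w over its non-stop codons — order-invariant,
in (0, 1], and exactly 1 iff every codon is family-maximal. The reference
set is intended to be the most abundant ~5% of proteins by proteomic
intensity. Half-lives are collapsed to cluster representatives by the mean
over present members; absent members are ignored rather than dropping the
cluster.

## PTR inference

**Absolute (quintile) rule.** Per state, a gene is a candidate when its
mRNA is at or above the cohort's 80th percentile and its protein is at or
below the 20th percentile of *detected* proteins (`candidate_detected`)
or undetected (`candidate_undetected`). Percentiles use linear
interpolation; boundaries are inclusive. Both choices are conventions the
quintile language itself does not fix; they are documented here and
frozen in the tests.

**Undetected-protein filters.** Candidates whose protein was never
detected are excluded when the absence is plausibly technical:
transmembrane probability ≥ 0.9 (membrane proteins are systematically
under-detected), absence from the spectral assay library, or no tryptic
peptide of 7–30 residues under the standard trypsin rule (cleave after
K/R, not before P, zero missed cleavages). Manually curated exclusions
(annotation-version mismatches) enter as an explicit list, not a
computation. Every removed gene is logged once with all triggered
reasons, so the log partitions the removed set.

**Relative (transition) rule.** Per state transition, genes are classified
into the nine combinations of mRNA/protein DE status (up, down, not
significant) at |LFC| ≥ 1; time-course contrasts use adjusted p < 0.05
while array-based knockout contrasts use raw p < 0.05, selected by the
`p_kind` flag. The PTR-relevant class is mRNA up with protein down, both
significant. A built-in `naive_de` (Welch's t on log2 values with
Benjamini–Hochberg adjustment) lets synthetic pipelines run end to end; it
is a simple two-group test, not a replacement for count- or
intensity-aware DE models, whose output tables the module otherwise
consumes as input.

Candidates from both rules integrate by union with per-gene evidence tags
(`absolute_detected`, `absolute_undetected`, `relative`) plus the states
and transitions implicated.

## IS mobilization

SV allele sequences are matched to the IS catalog by local alignment
(BLASTN-like scoring: match +2, mismatch −3, gap open −5, extend −2).
A hit is accepted at ≥ 75% identity over the aligned columns and ≥ 80%
coverage of both the SV sequence and the IS element — the 80-80-80
homology rule with the identity leg relaxed for long-read error rates.
Ties break by higher identity, then lexical element id. Unassigned events
are dropped from clustering but retained in the event list.

"Starting within a 50-bp distance" is ambiguous between pairwise and
chained proximity; clustering is implemented as single-linkage chaining on
sorted starts (equivalently, transitive closure of the ≤ 50-bp adjacency),
which is order-independent and matches how neighboring-SV collapse is
normally done; the distance is configurable and a brute-force
transitive-closure oracle backs the tests. Events only cluster within the
same (library, replicon, class, element).

The support index divides a cluster's occurrence count `e` by the local
read coverage `c`, defined as the *mean* per-base depth over a 25-nt
bidirectional flank (51 positions, clipped at replicon edges); mean vs
median vs read count is a free choice and the statistic is exposed.
Class boundaries are inclusive on the left class: rare ≤ 0.1 <
common ≤ 0.5 < predominant. Per-library cluster counts are normalized *up*
to the most deeply sequenced library (factor `max_j reads_j / reads_i`),
so the reference library is unchanged. Strain means are compared with 68%
confidence intervals (mean ± one standard error): disjoint intervals →
"different", otherwise "not different", and fewer than two replicates per
strain yields "insufficient replicates" rather than a verdict.

## Enrichment statistics

The hypergeometric test reports the exact upper tail P(X ≥ k) for an
observed overlap k between a query set of size n and K feature-positive
genes in a universe of N (scipy's implementation, which evaluates the pmf
in log space). The multi-set intersection test reports
`expected = N·∏(|s_i|/N)` and fold = observed/expected; the p-value is
the exact hypergeometric for two sets and a seeded Monte-Carlo permutation
(uniform random subsets of the observed sizes, (hits+1)/(n_mc+1) estimator
so p is never exactly 0) beyond two. Mann–Whitney U uses complete
enumeration of group labelings for ≤ 8 observations per side — exact and
valid under ties — and the tie-corrected normal approximation above that;
two identical constant samples give p = 1 by convention. Feature
enrichment defaults to raw p against a 0.05 cutoff;
Benjamini–Hochberg adjustment is available but off by default. The
universe is always an explicit argument — coding-gene (2,579) versus
full-transcriptome (2,631) universes change every expectation, so no
default is safe.

## Synthetic data: what it emulates, and what it does not

- `gen_coverage_pair` plants non-overlapping enriched intervals
  (length 10–200 by default) on a uniform background with Poisson depth
  noise, separated by ≥ 20 nt so noise-free calls can be compared to the
  truth exactly. `seed` fixes placement and `noise_seed` the sampling
  noise, so biological replicates of one landscape are simulated by
  varying only `noise_seed`. Not emulated: mappability structure,
  transcript-abundance-coupled IP background, fragment-length
  autocorrelation. Passing plant-recover tests therefore demonstrates the
  caller's logic, not robustness to the correlated backgrounds of real
  RIP-Seq.
- `gen_abundance_tables` draws per-gene log10 mRNA from N(2, 0.5) with
  per-state biology N(0, 0.2), protein log-linear in mRNA (slope 1,
  scatter σ configurable), RPF tracking mRNA through a per-gene occupancy
  shift, and log-normal replicate noise. Planted PTR genes sit above every
  background mRNA and below every detected background protein (or are
  missing at all states), so at zero noise the quintile rule recovers them
  with recall = precision = 1 *by construction* — the test verifies the
  classifier, not the biological prevalence of discordance. Missingness in
  real proteomics is abundance-dependent; here it is planted.
- `gen_sv_calls` plants clusters with verbatim IS copies, member starts
  within the jitter window (≤ 50 bp, enforced), anchors 500 bp apart so
  same-element clusters never chain together, uniform depth, and decoys
  mutated to ~65% identity. Real nanopore SV calls have indel-rich
  sequences and coverage fluctuations; the 75/80/80 filter's behavior on
  borderline real alleles is not exercised.
- `gen_feature_flags` draws independent Bernoulli flags with an odds
  multiplier inside the planted set; real regulatory features co-occur.

## Problem sizes

Default test and reproduction scales — a 100-kb replicon with 50 planted
regions, 1,000 genes with 5% planted, 30 SV clusters with a 4-element
catalog — were chosen as the smallest sizes at which quintile structure,
all three e/c classes and run-length statistics are simultaneously
non-degenerate, and they keep the full suite fast enough to run on every
change.

## Known limitations

- The greedy clustering is O(n²) alignments; adequate for one genome,
  not for metagenomes.
- `naive_de` ignores mean–variance structure; use DESeq2/limma/proDA
  outputs as inputs for real contrasts.
- The Mann–Whitney exact branch enumerates C(n+m, n) labelings; it is
  capped at 8 per side by default.
- Gene assignment of binding regions uses a single overlap rule; real
  analyses may prefer fractional-overlap or UTR-aware rules.
- The mobilome module consumes SV calls; it does not re-align reads or
  deduplicate plasmid repeats — callers should align to a deduplicated
  reference upstream.
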