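# Methods

This note documents the models and procedures implemented in `ihat`, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmark does and does not show.

## Whole-gene profile construction

A query gene's model is built from the curated members of its COG in the
reference database:

- **Fusion rejection.** Proteins assigned to more than one COG are gene-
  fusion products (or similar) and are excluded from profile building.
  They remain reciprocal-search targets: the verification stage runs
  against the full database.
- **Multiple alignment.** Progressive alignment with a UPGMA guide tree
  over fractional shared 3-mer distances and profile–profile merges
  scored as the mean of pairwise substitution scores (BLOSUM62; gaps in
  existing columns contribute the extension penalty). All ties — guide
  tree, merge order, traceback — break lexicographically by sequence id,
  so the output is deterministic. There is no iterative refinement: a
  dedicated aligner would produce slightly better columns, but profile
  quality is tested functionally (does the pipeline find and verify its
  homologs), not by alignment benchmark.
- **Column model.** Henikoff position-based sequence weights (normalized
  to sum to the number of members) give effective counts `c_aj`;
  frequencies are pseudocount-blended with the background,
  `f_aj = (c_aj + beta*p_a) / (sum_a c_aj + beta)`, and scores are
  `s_aj = log2(f_aj/p_a)` bits. Background `p` is the Robinson–Robinson
  amino-acid frequency vector. `beta` defaults to 10 pseudocounts.
  At `beta = 0`, a residue absent from a column maps to a finite
  sentinel of -1000 bits (the minus-infinity case, kept finite so the
  DP stays well-defined). Columns with >= 50% gaps are not match
  columns and are dropped. The consensus is the per-column argmax of
  weighted counts, ties alphabetical.
- **Inclusion-threshold filter.** Each member is scored glocally (full
  profile, free sequence ends) against a provisional profile; members
  below `fraction x median member score` (default fraction 0.5, clamped
  at zero) are rejected and the profile is rebuilt once from the
  survivors. The threshold is this package's operationalization of a
  model-membership inclusion threshold; the original concept is internal
  to HMM toolchains and has no recoverable numeric value, so the rule is
  defined by a testable quantity and exposed in the API.

## Translated search and significance

Reads are translated in all six frames (bacterial code, table 11, by
default; stops rendered `*`). Each frame is scored against the profile
with a local affine-gap DP in bit units: gap open 7 bits, extend 1 bit
(a gap of length k costs `open + (k-1)*extend` throughout the package —
note this differs from BLAST's bookkeeping, where a length-k gap costs
`open + k*extend`; the convention is internal and consistent across all
stages). `*` scores -4 bits and `X` 0 bits at every column, so
alignments may cross stop codons and no ORF calling is required. One
hit is retained per fragment: the best score over frames, ties resolved
in frame order +1, +2, +3, -1, -2, -3 — multiple high-scoring segments
never inflate counts.

Because a gapped PSSM has no closed-form Karlin–Altschul parameters, the
score null is calibrated empirically per profile: 500 random peptides of
length 300 drawn from the background frequencies are scored with the
same DP, and a Gumbel is fitted by the method of moments
(`lambda = pi/(sigma*sqrt(6))`, `mu = mean - gamma/lambda`). Then
`E(S) = (L_eff/300) * exp(-lambda*(S - mu))` with the effective database
length `L_eff` fixed at 1e9 residues regardless of the actual database —
expectations are therefore comparable across databases of different
depth. The default reporting threshold is the permissive E <= 10;
significance never decides the final annotation (that is the reciprocal
check's job), and the cutoff can be disabled entirely.

An optional frameshift bridge (off by default) chains the two best
same-strand, different-frame segments with a fixed 10-bit penalty when
their profile and nucleotide spans are disjoint and collinear, for
reads carrying an indel sequencing error.

The search kernels are exact, vectorized DPs: each row is computed for a
whole batch of equal-length frames at once, with the insertion state
resolved by a running-maximum prefix scan (valid whenever
`open >= extend`, since closing and reopening a gap never pays). They
are verified against brute-force enumeration of all alignments on small
instances.

## Reciprocal best-hit verification

Each candidate's six-frame translations are locally aligned (BLOSUM62,
gap 11/1, score-only) against every protein in the full reference
database. The candidate is annotated as an isofunctional homolog only
when the query gene's COG is present in the COG set of **every**
top-scoring subject; the reported best hit is the tie-broken single
subject (bit score, then lexicographic id), and its species is recorded
for taxonomic summaries. Requiring unanimous support among exact-score
ties is deliberate: a read covering only a perfectly conserved shared
domain ties between paralogous families and carries no evidence for
either, and a reciprocal *best* hit, strictly read, requires a unique
best. A fused reference protein can still validate a candidate (its COG
set contains the query COG). Reciprocal E-values are reported with
fixed gapped-BLOSUM62 Gumbel constants (lambda 0.267 per raw unit,
K 0.041) against the database residue count, and no cutoff is applied —
the best positive-scoring hit decides, whatever its expectation.

## Evaluation apparatus

- **Exact sampler.** `ceil(coverage * L / length)` fragments, uniform
  start positions with replacement, uniform strand (minus-strand reads
  reverse-complemented), no error model — reads are literal genome
  substrings. The fixed count (rather than a Poisson-distributed one)
  makes dataset sizes reproducible and checkable. With the 1,456,888 bp
  reference-length fixture this yields exactly 29,138 reads at 1000 bp
  and 83,251 at 350 bp under 20x coverage.
- **Ground truth by containment.** A read counts as sampled from a gene
  only if it lies wholly between the gene's start and end loci
  (1-based, inclusive). This avoids bias from differential conservation
  at gene ends, and means a gene shorter than the read length has no
  truth reads at all. A consequence worth stating: a local search
  will legitimately annotate *boundary* reads that overhang a locus —
  their in-locus portion is a true homolog fragment — and those reads
  have no truth label. The benchmark therefore scores false positives
  as annotated reads from a *different* gene, a decoy locus, or pure
  intergenic sequence; same-gene boundary reads are tracked separately
  and are not errors a read-level classifier could avoid.
- **Toy world.** Families are concatenations of 4 domain blocks
  (45–70 residues) from a seeded library, diversified into 8 members at
  per-family substitution rates 0.03–0.30 (family 2 is the designated
  high-conservation family, family 3 the low-conservation one). With
  the decoy flag, families 0 and 1 share their first domain, mutated at
  only 2% in both — the ubiquitous-domain scenario; family 1 is present
  in the genome but absent from the query list. The last family is a
  listed query with no genome locus (the absent-gene scenario). One
  member per present family is reverse-translated with most-used codons
  (table 11) into a genome with 8 kb random intergenic spacers
  (~52 kb total), alternating strands. The benchmark samples 20x
  coverage at 350 bp — about 2,900 reads and 15–30 truth reads per
  gene — which keeps the full end-to-end run under two minutes on one
  CPU while leaving every per-gene count well above zero.
- **What the toy world does not emulate:** sequencing error (the exact
  model is deliberate), codon-usage variation and GC skew, paralog
  families inside one genome, incomplete reference databases, and
  realistic domain-architecture complexity. Passing the benchmark shows
  the pipeline's logic is sound under its stated assumptions, not that
  real-data sensitivity is 1.0.
- **Cutoff sweep.** The comparator is a plain six-frame local alignment
  against a single query protein with E-values from the fixed Gumbel
  constants, one hit per fragment, counted at cutoffs from 1e-5 down to
  1e-100. The low-conservation family's retention decays at far more
  permissive cutoffs than the high-conservation family's — the bias the
  cutoff-free design exists to remove.

## Abundance statistics

- **Resampling.** Databases are equalized by seeded uniform subsampling
  without replacement, preserving input order.
- **ESC normalization.** With marker density `m_i = marker_i/N_i` and
  `m_ref` the median density, `ESC_i = N_i * m_i / m_ref`. The defining
  (and exactly tested) property is that `marker_i / ESC_i` is constant
  across samples: one marker-gene's worth of sequence per genome
  sampled, which removes average-genome-size bias. The marker set is
  whatever the caller supplies; the synthetic fixtures use 5 planted
  single-copy families.
- **Quasipoisson GLM.** Counts with log link and `log(ESC)` offset,
  fitted by IRLS (convergence: relative deviance change < 1e-10, max
  100 iterations; coefficients identical to the Poisson fit).
  Dispersion `phi = sum((y-mu)^2/mu)/(n-p)` from Pearson residuals
  rescales inference only; standard errors are `phi`-scaled. Nested
  models are compared with `F = ((D0 - D)/dp)/phi` using the larger
  model's dispersion (standard quasi-likelihood practice) against
  `F(dp, n-p)`. Degrees of freedom are `(dp, n - p)`; with one
  covariate and n samples the residual df is `n - 2`.
- **Nutrient estimates.** Per site: values above the outlier limit
  (default 15,000 uM = 15 mM, for phosphate) are dropped; a site is
  accepted only with >= 3 surviving records; the summary is the median
  (the annual distributions are positively skewed).

## Numerical and reproducibility choices

- One base seed drives everything; each component salts its generator
  (`default_rng([seed, salt])`) so that streams are mutually
  independent — without salting, two components drawing from the same
  distribution replay each other's values, which in one observed case
  planted a family consensus among the calibration decoys.
- Results are independent of fragment processing order and worker
  scheduling; the thread pool in `annotate_all` is a throughput knob
  only.
- Degenerate inputs: empty fragment sets yield empty reports; an
  all-rejected member filter, a zero-variance calibration, an all-zero
  count response and non-nested model comparisons raise errors rather
  than guessing.

## Known limitations

- The aligner has no heuristic seeding; it is exact and O(mn), sized
  for curated families and simulated read sets, not for survey-scale
  databases.
- Species assignment inherits the reference database's coverage: the
  best reciprocal hit can only name species the database contains.
- The empirical Gumbel null assumes i.i.d. background composition;
  strongly biased read composition would shift E-values (the final
  verdict is cutoff-free, which limits the damage).
- `beta = 10` pseudocounts with very small families (2–3 members)
  flattens profiles noticeably; families that small are better served
  by a lower `beta` (exposed in the API).
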