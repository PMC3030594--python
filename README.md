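# ihat

Annotation of **isofunctional homologs** of multi-domain genes in
unassembled metagenomic reads — without expect-value-cutoff bias.

## The problem

Counting a gene's homologs across metagenomic samples is the first step
of almost any gene-centric ecology question (here, the polyphosphate
system: *ppk1*, *ppk2*, *ppx*, *pstS*, alkaline phosphatases). Two things
make it hard on unassembled reads:

1. **Expect-value cutoffs are biased.** Genes differ in conservation, so
   any fixed E-value cutoff keeps a different fraction of true reads for
   each gene: a cutoff stringent enough to clean up a conserved gene
   silently discards most reads of a poorly conserved one.
2. **Shared domains create heterofunctional false positives.** Multi-domain
   genes carry ubiquitous blocks (ATP-binding cassettes, sensor-kinase
   domains). A read covering only such a block matches the query family
   even though it comes from a different gene with a different function.

`ihat` addresses both with a three-stage pipeline:

1. **Query information.** For each query gene, curated members of its
   orthologous group (COG) are collected from a reference database
   (fusion products — proteins assigned to multiple COGs — are rejected,
   and members below an inclusion threshold are filtered out), aligned,
   and compiled into a **whole-gene position-specific score matrix**
   (PSSM): per-column log-odds `s_aj = log2(f_aj / p_a)` with Henikoff
   position-based sequence weights and background pseudocounts
   `f_aj = (c_aj + beta * p_a) / (sum_a c_aj + beta)`. A consensus
   sequence is emitted alongside. Modelling the full gene rather than
   single domains is the point: a read spanning a domain boundary is
   specific where a single-domain model is not.
2. **Translated search, no cutoff.** Reads are translated in all six
   frames and scored against the profile with a local affine-gap DP
   (stop codons score -4 bits, so no ORF calling is needed). E-values
   come from a per-profile empirical Gumbel null (random
   background-composition peptides) at a **fixed effective database
   length of 1e9 residues**, and candidates are kept at the permissive
   default E <= 10 — significance never decides the final call.
3. **Reciprocal best-hit verification.** Each candidate is aligned back
   against the **full** reference database. It is annotated as an
   isofunctional homolog only when every top-scoring reciprocal hit
   belongs to the query gene's COG; otherwise it is recorded as a failed
   (heterofunctional) homolog, with the best hit's species retained for
   taxonomic summaries.

The package also ships the evaluation apparatus (an exact-model read
sampler with locus ground truth and a synthetic "toy world" with planted
families, a shared-domain decoy paralog and an absent gene) and the
downstream statistics: effective-sequence-count (ESC) normalization,
which rescales sample sizes so single-copy marker-gene frequency is
constant across communities of different average genome size, and
quasipoisson regression (`counts ~ covariate`, log link, `log(ESC)`
offset, Pearson dispersion) with analysis-of-deviance F-tests.

## Worked example

Generate a synthetic world and annotate it:

```sh
$ ihat simulate --out demo --seed 5 --spacer-length 500 --coverage 8
toy world: genome 6453 bp, 148 fragments, 49 reference proteins, 5 query genes -> demo

$ ihat annotate --gene-list demo/genes.tsv --db-list demo/dblist.txt \
                --refdb demo/refdb --out demo/reports --seed 5
gene0 vs fragments: 31 candidates, 16 annotated, 15 failed -> demo/reports/gene0.fragments.report.txt
gene2 vs fragments: 20 candidates, 20 annotated, 0 failed -> demo/reports/gene2.fragments.report.txt
gene3 vs fragments: 27 candidates, 27 annotated, 0 failed -> demo/reports/gene3.fragments.report.txt
gene4 vs fragments: 25 candidates, 25 annotated, 0 failed -> demo/reports/gene4.fragments.report.txt
gene5 vs fragments: 0 candidates, 0 annotated, 0 failed -> demo/reports/gene5.fragments.report.txt
```

Reading the output: `gene0` is the target that shares a conserved domain
with a decoy paralog planted in the genome — its 15 failed calls are
reads that reached candidacy but lost the reciprocal COG check (mostly
decoy-gene reads: heterofunctional homologs correctly rejected). `gene5`
is in the query list but absent from the genome; zero calls is the
correct answer. Each report starts with a summary header followed by
one tab-separated line per call:

```
# gene: gene0
# database: fragments
# sequences_searched: 148
# candidates: 31
# annotated: 16
# failed: 15
[ANNOTATED]
frag000008	F0_M0	Species_0_0	COG0000	1.63e-27	119.1
...
```

Fit the abundance model for one gene against an environmental covariate
(counts with `log(ESC)` offset):

```sh
$ ihat stats --samples samples.tsv --gene ppk1 --covariate phosphate --out fit.json
ppk1 ~ phosphate: slope -1.2179, dispersion 1.32, F = 89.28, p = 2.76e-11
```

A negative slope means the gene's per-genome frequency falls as the
covariate rises; the p-value is from the deviance F-test against the
intercept-only model at the fitted dispersion.

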