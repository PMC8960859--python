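# Methods

This note documents the models and procedures `lanthnet` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the design choices made where the design was genuinely open.

## Mining

BGC-associated proteases are selected by case-insensitive substring match of
five keywords (*peptidase, proteinase, protease, hydrolase, beta-lactamase*)
against the product annotation only.  Annotation capitalization is wildly
inconsistent across public genomes, so case-insensitivity is the safe
default; matching is restricted to the product field because other qualifiers
are not reliably populated.  An empty keyword list is rejected rather than
silently selecting nothing.

The Pfam pool keeps an accession iff its hits with bit score strictly above 0
number at least 5 across all BGC proteases.  Manual curation of a domain pool
cannot be automated faithfully, so it is modelled as an optional allow/deny
accession list and no curation heuristic is invented.  Genome-wide harvest
then selects any protein with ≥ 1 pool-domain hit with score > 0, regardless
of BGC membership — this is what makes *hidden* (unclustered) proteases
visible to the downstream correlation.

The clustered-protease check scans the closed interval
`[anchor_start − w, anchor_end + w]` with `w = 10,000` nt around the
synthetase anchor gene, on the same contig; "up- and downstream" is read as
± w from the anchor gene's boundaries.  Closed-interval overlap keeps the
check symmetric and boundary-inclusive.

## Grouping

The clustering stand-in is deliberately simple and exact: an all-vs-all
pairwise-identity graph thresholded at the default cutoffs (0.45 proteases,
0.6 precursors), partitioned into connected components.  Connected-component
mode merges transitively — if A≈B and B≈C, then A, B, C group together even
when A and C are dissimilar — which is the behaviour that pulls remote
homologs into one group.

Identity is defined as identical positions of an optimal *global* alignment
divided by alignment columns, with match +1 / mismatch 0 / gap −1 (linear).
The dynamic program maximizes the triple (score, matches, −columns)
lexicographically, all three being additive along an alignment path, so
co-optimal tie-breaking cannot change the reported identity.  This is **not**
bit-compatible with production clusterers (local alignments, coverage rules,
prefilters); it preserves the algorithmic role with desk-scale determinism,
and results on real data would differ accordingly.  The O(n²) pair loop is
JIT-compiled with numba when available (pure-Python fallback otherwise) and
is comfortable up to a few thousand sequences.

Group labels `Pre_k` / `Prot_k` are assigned by descending member count with
ties broken by the lexicographically smallest member id — the labelling
scheme itself is arbitrary, so determinism and input-order invariance are the
only requirements.  Size filters default to 100 (proteases) and 10
(precursors); the 100-member cutoff presumes a corpus of >10⁵ genomes and is
lowered in desk-scale runs (the demo uses 10/10).

## Correlation network

For each genus, every precursor-group × protease-group pair with both groups
present in ≥ 1 genome of the genus is tested over the occurrence counts of
*all* n genomes of the genus.  Spearman's ρ is the Pearson correlation of
average ranks (ties get the mean rank of their block); the one-sided p-value
is the upper tail of Student's t with n−2 degrees of freedom at
t = ρ·√((n−2)/(1−ρ²)), clamped to p = 0 at ρ = 1 and p = 1 at ρ = −1.  The
upper tail is the right test because the workflow seeks positively
co-occurring partners; negative associations surface with p near 1 and are
not pursued.  An exact permutation p-value (all n! rank permutations) is
available behind a flag for n ≤ 10; note the t approximation is not exact at
the boundary — extreme reported values such as p ≈ 1e−78 at ρ = 1 cannot be
reproduced by a clamped t approximation and no attempt is made to.

Constant count vectors leave ρ undefined.  Such pairs are flagged and
excluded from the BH family entirely: assigning ρ = 0 would silently inflate
the number of tests and distort the adjustment.

Benjamini–Hochberg adjustment is applied **once across all genus-level tests
pooled** by default.  Per-genus families are available
(`bh_scope="per-genus"`); pooled is the conservative reading and matches
treating the whole screen as one experiment.  The prioritization filter is
ρ > 0.3 (strict), pAdj < 1e−5 (strict), I ≥ 10 (inclusive), with I the count
of genomes containing at least one member of both groups.

Networks are bipartite (precursor vs protease nodes); node attribute `size`
carries the genus-level member count and edge attribute `weight` carries ρ,
matching the usual node-size/edge-width styling.  The volcano table floors
pAdj at a configurable ε (default 1e−300) before taking −log10.

## Co-expression refinement

TPM for gene i: rateᵢ = countᵢ/lengthᵢ, TPMᵢ = 10⁶·rateᵢ/Σⱼrateⱼ; an
all-zero sample yields an all-zero row.  Upstream read processing (QC,
rRNA filtering, mapping, counting) is consumed as a finished count table and
not re-implemented.  Group-level TPM is the within-group sum; the matrix is
trimmed to the groups present in the genomic network (no overlap at all is an
error, since it signals mismatched inputs).  Pairwise Spearman tests run
across samples with the same one-sided p; BH is adjusted **within each
strain's family** before combination — each strain's matrix is a separate
experiment, so pooling across strains would mix families.  The strain
combination keeps pairs present in *all* strains by default (`"any"` gives
the union, provided because the requirement is a design choice).  Filters are
ρ > 0.4 and pAdj < 0.05, both strict.  The final candidates are the pairs in
the intersection of genomic and co-expression evidence, carrying both
evidence records.

## Synthetic data

The generator emulates the *statistical* structure the analysis relies on,
nothing more.

**Occurrence counts.**  Background groups are i.i.d. zero-inflated Poisson
(default rate 1.0, 30% structural zeros) across all genomes — sparse,
non-normal, heavily tied, which is exactly the regime where a rank statistic
is preferable.  A planted unit lives in one genus and consists of a precursor
group plus one or more protease partner groups; each partner's count vector
equals the precursor's in exactly `round(effect·n)` genomes of the genus and
is independent elsewhere.  This duplication construction gives population
Spearman ρ = 0 at effect 0, exactly 1 at effect 1, monotone in between, and
empirically ρ ≈ effect across the board.  Fixing the duplicated-genome
*count* (instead of a per-genome Bernoulli coin) removes the binomial
component of the sampling noise of the empirical ρ (sd 0.088 vs 0.108 at
n = 50, effect 0.7) — a variance-controlled design that makes recovery
experiments sharper without changing the population target.
`calibrate_effect` resolves the effect → ρ map empirically by bisection
rather than claiming a closed form.

**Sequences.**  One family per group: a random consensus over the 20 amino
acids, members point-mutated at rate 0.05 with at most 10% of positions
changed (enforced by redraw), so any two family members share ≥ 0.8 identity
by construction even in the gap-free alignment.  Consensi are redrawn until
all cross-family consensus identities are ≤ 0.3; cross-family member pairs
are verified post hoc when the set is small enough to afford the all-vs-all
check.  Default consensus lengths are 60 aa (proteases) and 30 aa
(precursors).

**Transcriptomes.**  Strains are genomes of the focal planted unit's genus
that contain both the precursor group and its co-expressed partners; genes
are the member proteins of that genome plus 200 "housekeeping" genes.  The
housekeeping background is essential: TPM is compositional, and without a
dominant independent library the focal unit's latent factor induces spurious
*negative* correlation between it and every other group.  Per sample, genes
of a co-expressed unit share a latent normal factor (weight 1.5) on the log
scale on top of per-gene baselines (ln-uniform 3.5–7), gene noise (sd 0.5),
and a per-sample depth factor (cancelled by TPM); counts are Poisson around
length-scaled expression with lengths uniform on 300–3000 nt.  Decoy
partners — genomically planted but co-expression off — get independent
expression.  Under the defaults, planted pairs show group-TPM Spearman ρ
well above 0.4 in every strain while decoys centre near 0.

**What passing tests do not show.**  The generator has no phylogenetic
signal beyond the genus block structure, no horizontal transfer, no
correlated backgrounds, no annotation errors, and identity families far
cleaner than real protein space; passing recovery tests demonstrates the
pipeline's statistical machinery, not performance on RefSeq-scale data.

## Experiment designs in the acceptance suite

Problem sizes were chosen to keep every check inside a few minutes on one
CPU while leaving the conclusions stable:

- *Type-I control*: 20 replicates of a null world (20 genera × 50 genomes,
  50 background groups per side, no planted pairs; ≈ 50,000 tests each) must
  yield zero filtered edges; raw-p calibration uses 10,000 null pairs in one
  genus.
- *Recovery*: effect calibrated to population ρ ≈ 0.7; one planted pair per
  genus, 20 genera × 50 genomes, no background groups, 20 seeds.  The
  experiment isolates the power of the screen at the default operating
  point: the false-positive burden of a dense null family is the type-I
  experiment's job, and a power analysis shows the one-sided Spearman test at
  ρ = 0.7, n = 50 has ≈ 0.9 power against p < 1e−5 *before* any multiplicity
  burden — so power and error control are necessarily asserted by separate
  experiments.  Precision and recall are means over seeds.
- *Refinement*: 5 genera × 50 genomes, one planted unit with one co-expressed
  partner and one decoy at effect 0.9, 3 strains × 20 samples, 20 seeds; the
  intersection must return exactly the co-expressed pair in ≥ 19/20.  A
  single larger run (34 genomic partners, 4 co-expressed) reproduces the
  many-to-few candidate reduction structurally.

## Known limitations

- The identity metric and the clustering are stand-ins; group boundaries on
  real data will differ from production clusterers.
- The t-approximate p-value is anti-conservative in the extreme tails at
  small n; the exact-permutation option is limited to n ≤ 10.
- Genus stratification only partially controls phylogenetic confounding;
  within-genus clonal structure can still inflate correlations.
- TPM compositionality couples groups through the library total; the
  refinement assumes member genes are a small fraction of the transcriptome.
- The pipeline consumes annotation, domain-hit, and count tables; it does not
  detect BGCs, run domain searches, or process reads.
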