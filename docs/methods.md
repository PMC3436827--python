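# Methods

This note documents the models and procedures the package implements,
the defaults it ships with, and the choices made where the design was
genuinely open.

## 1. UCNE detection (`grbcontext.scan`)

Ultraconserved non-coding elements (UCNEs) are called from pairwise
genome alignments with the reference genome fixed as the coordinate
system.  For each alignment block, a 61-column sliding window is
centred on every reference base; the percent identity of the window
(matching ACGT columns / 61) is assigned to the central base.  The
first and last full windows also supply values for the 30 reference
bases at each block end, and blocks shorter than one window take the
whole-block identity everywhere.  Gap columns and ambiguity codes count
as mismatches (conservative; identity means identical aligned bases).
Overlapping blocks contribute the per-base *maximum* identity
(best-alignment semantics, deterministic).

Maximal runs with identity ≥ 95% become candidate elements; bases
overlapping any CDS are subtracted (possibly splitting a run); fragments
shorter than 200 bp are dropped (strictly: 199 bp dies, 200 bp lives).
Survivors are classified positionally: UTR if they overlap any UTR base
(UTR beats intronic, a single base suffices — the annotation does not
rank them, so the more specific class wins), intronic if inside a gene
span, else intergenic with the two flanking genes recorded.

Blocks are scanned independently; runs are not merged across adjacent
blocks.  Consequence: boundary estimates smear by up to ±30 bp (the
window flank), so planted elements near the 200-bp threshold can be
eroded below it.  The recovery guarantee tested is therefore stated for
elements ≥ 260 bp.

## 2. Homology search (`grbcontext.homology`)

Candidate target segments (everything alignable to the query region
according to the pairwise alignments) are scored by Smith–Waterman
local alignment with affine gaps.  Defaults: match +5, mismatch −4, gap
of length L costs 12 + 4L — conventional DNA scoring for this kind of
search.  Bitscores are `(λ·raw − ln K)/ln 2` with λ solved from the
ungapped expected-score identity at uniform base composition
(λ ≈ 0.192 for +5/−4) and K = 0.1; both only fix a scale and all
comparisons happen within one scheme.

Significance is calibrated per pair: the subject is shuffled in
consecutive 20-bp windows (a shorter remainder window is permuted on
its own), preserving local base composition; a Gumbel distribution is
fitted by maximum likelihood to the shuffled score sample (default
500 shuffles) and `E = db_size × P(score ≥ observed)`.  The parametric
tail is the point: it resolves E-values far below 1/n_shuffles, which
an empirical rank cannot.  A degenerate sample (zero variance, e.g. a
mononucleotide subject) falls back to the empirical rank
`(r+1)/(n+1)`.  `db_size` defaults to the number of candidate regions
evaluated for that query — the effective search space of the decision
actually being made; an absolute convention would only rescale all
E-values jointly.  Hits at **E ≤ 1e-4** (inclusive) are accepted.

Paralog discrimination: reference-genome paralogs of each UCNE are
catalogued by aligning the UCNE to conserved reference segments outside
its own locus with the same machinery (paralogs need not themselves be
UCNEs).  A target-genome hit is flagged as a paralog if some catalogued
paralog aligns to the hit sequence with a *strictly lower* E-value than
the UCNE itself; exact ties keep ortholog status.  The target sequence
is the shuffled subject in both comparisons so the E-values are
commensurable.  Flagged hits are excluded from every retention tally.

Minus-strand candidates are reverse-complemented before alignment and
reported on the target forward strand.

## 3. Retention patterns and winner scores (`grbcontext.retention`)

For one reference gene and one duplicated genome, each intronic/UTR
UCNE is *present* in an ortholog copy if it has ≥ 1 accepted,
non-paralog hit within that copy's span.  The copy with the most
present UCNEs is the **major ortholog**; with a/b/c = UCNEs present
only in the major / in major and ≥ 1 minor / only in minors (all
minors pooled), a case is

- **winner-takes-all** if a/(a+b+c) > 0.8,
- **reciprocal** if c/(a+b+c) > 0.2,
- **concordant** otherwise.

Inequalities are strict (the two conditions are provably exclusive);
the boundary case a/n = 0.8 or c/n = 0.2 is concordant.  Major-count
ties break by larger bitscore column sum, then lexicographic id, and
are flagged.

The **winner score** weighs UCNEs by conservation: `c_ij` is the
bitscore of UCNE i in ortholog j (0 if not retained),
`C_total = Σ_ij c_ij`, `C_major` is the largest column sum, and
`W = 100·C_major/C_total`.  Summing `C_total` over *all* columns means
concordant retention depresses W below 100, making "one copy takes
100%" equivalent to "every minor column is zero".  Eligibility for the
winner-score analysis: ≥ 2 orthologs and ≥ 3 UCNEs retained in the
major copy; genes with no retained UCNE anywhere, or never more than
one ortholog, are dropped outright.

The **permutation null** models random retention: per shuffle, every
UCNE's row of scores is permuted independently across its gene's
ortholog columns, winner scores are recomputed with the major column
re-identified inside each replicate (freezing it would not be a random
retention model), and the histogram frequency vector is recorded; the
null is the per-bin mean ± sd over 500 shuffles.  Default bins are
width 5 from 50 to 100 (two orthologs imply W ≥ 50) and extend down to
0 when cases with more orthologs are present.  Binning is a convention;
it is configurable.

## 4. Clusters and subclusters (`grbcontext.clusters`)

A **cluster** is a maximal chain of UCNEs that stay on one chromosome
in *both* reference genomes with neighbours ≤ 0.5 Mb apart in both
(single-linkage along the reference order; elements without
second-genome coordinates are unlinkable singletons).  Reference-genome
gene association: hosts of intronic/UTR members plus flanks of
intergenic members, restricted to protein-coding, non-pseudogene models
with annotated CDS.

In a duplicated genome, the cluster's accepted non-paralog hits are
chained per chromosome/scaffold with the same 0.5 Mb rule into
**syntenic subclusters**; the one with the most distinct UCNEs is the
major subcluster.  Chaining happens first, assembly-aware merging
second.  A minor subcluster is merged into the major iff (it lies on an
unplaced scaffold OR is flanked by assembly gaps on both sides within
50 kb) AND its members occupy a reference-cluster index range disjoint
from the major's.  The published analysis performed this step by manual
inspection; automating it with an explicit audit report (every minor
considered, with the three condition outcomes) trades judgment for
reproducibility.  The 50-kb gap-flank distance is a generator-scale
convention with no analogue in the original manual step.

Duplicate-genome gene association uses a distance rule: a gene is
associated with a subcluster if it contains a member hit or lies within
0.1 Mb of the nearest one (interval gap distance, 0 when overlapping).
A gene is called a **target** if it is associated in *every* tested
genome, otherwise a **bystander**.  Cluster-level retention reuses the
gene-level (a, b, c) rule with presence meaning membership in the major
vs minor subclusters.

## 5. Evolutionary simulator (`grbcontext.sim`)

A cluster of N elements sits upstream of its target gene; a fraction q
of the N(N−1)/2 element pairs interact (pairs drawn uniformly without
replacement once per replicate; the count rounds half-up).  After
duplication, knockouts of single still-connected elements and synteny
breaks (which permanently disconnect everything distal to the break;
break sites are the gaps between consecutive connected elements, never
between the target gene and the proximal element) strike either copy.
An event is accepted iff afterwards every interacting pair has both
members connected to the target in at least one common copy.

The **stand-alone constraint** (each element must stay connected in
≥ 1 copy) is ON by default: without it, q = 0 erodes both copies to
nothing, which contradicts the stand-alone model's own prediction that
independent elements get *distributed* over the daughter genes rather
than lost.  Both modes are implemented; with the constraint off,
endpoints at low q can be empty and unlabelled.

Proposals are uniform over syntactic events (knockouts and breaks
weighted by `event_weights`, default 50/50 — the relative rates are not
identifiable from anything we reproduce, so they are exposed);
rejected proposals do not change state or advance the event counter,
so the chain is implemented equivalently (and exactly) by weighted
sampling over the enumerated acceptable-event set.  Fixation = that set
is empty; it is reached in ≤ 2N accepted events since each one strictly
reduces total connectivity.  Endpoints are tallied like empirical data:
a/b/c over the larger/smaller surviving copy (ties to copy 1, flagged)
and labelled with the same winner/concordant/reciprocal rule — the rule
choice for simulation endpoints is ours; an all-or-nothing criterion
would only raise the connectivity needed for a given winner fraction.

At q = 1 fixation is provably always winner-takes-all (two cliques can
cover the complete graph only if one copy retains every element); this
is verified by brute force at small N.  At q = 0.6, N = 20, the
winner fraction is ≈ 0.87 ± 0.01 — comfortably above the 75% level the
claim requires — and is N-independent within binomial error for
N ∈ {10, 20, 40}.

## 6. Synthetic data (`grbcontext.synth`)

The generator emulates the study's data regime end to end: a reference
chromosome of uniform-random sequence carrying genes with a fixed
5'UTR–CDS–3'UTR exon layout, one intron per intronic UCNE (UCNEs sit
150 bp from the flanking exons; intergenic UCNEs trail the gene at
300-bp spacing, so within-cluster gaps stay far below the 5-kb
`cluster_gap_bp` default); and a duplicated genome with `n_copies`
copies of every gene (copy k of all genes shares chromosome `chrDk+1`
by default; a scatter option puts each copy on its own scaffold to
exercise subcluster handling).

Retention scenarios: **winner** (survivors all in the per-gene
designated copy), **concordant** (survivors in all copies),
**reciprocal** (each survivor in one uniformly random copy), **random**
(independent Bernoulli per UCNE × copy).  Default survival probability
0.9, UCNE divergence 0.01 (keeps elements above the 95% identity
threshold), background divergence 0.30 (typical deep-vertebrate
neutral divergence scale), element lengths 200–600 bp.  A *lost* UCNE
is replaced by fresh random sequence — homology is destroyed while
coordinates stay alignable, so alignments remain gapless unless short
(1–5 bp) deletions are explicitly injected outside UCNEs.

What the generator does *not* emulate: repeat structure, rate
heterogeneity, selection, insertions, translocations, or assembly gaps
beyond the scatter option.  Passing tests therefore demonstrate
correctness of the *procedures* under the stated regime, not robustness
to every artefact of real genomes.

For retention and cluster analyses on synthetic data, hit tables can be
built directly from the duplicated-genome annotation (`hits_from_wgd`):
presence from the annotation, bitscores from an actual local alignment
of each element to its surviving copy.  This keeps large replicate
loops (e.g. 200-replicate recovery checks, 20-seed goodness-of-fit
loops) fast; the shuffle-E-value machinery is validated separately on
its own sensitivity/specificity suites.

## 7. Numerical and testing conventions

- All randomness flows from explicit seeds (`numpy.random.Generator`);
  identical configs give byte-identical outputs.
- Coordinates are 0-based half-open everywhere internally; GFF3
  converts at the boundary.
- Problem sizes in the test and acceptance suites: the q = 0.6
  simulation claim runs 2,000 replicates (binomial SE ≈ 0.008, which
  resolves the 0.75 bound at > 5 SE); N-independence uses 800
  replicates per N; the random-retention goodness-of-fit uses 20 seeds
  × 40 genes with a 200-shuffle null and adjacent-bin pooling to keep
  expected chi-square counts ≥ 2.  These sizes are the package's
  defaults for its own validation; the simulator's production default
  remains 10,000 replicates.
- Known limitations: conservation runs are not merged across alignment
  blocks; the E-value search-space convention is per-query; the
  assembly-gap flank distance is synthetic-scale; simulation endpoint
  labelling reuses the empirical rule.
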