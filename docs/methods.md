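# Methods

## Problem and model

`hogmapper` assigns protein sequences to gene families and subfamilies
organized as hierarchical orthologous groups (HOGs). A HOG is a set of
proteins descending from one speciation event; the top HOG of a family (the
*root-HOG*) is the family itself, and every duplication below it defines
nested sub-HOGs. Assignment by closest sequence (best local-alignment hit)
ignores this tree and systematically lands in over-specific subfamilies:
whenever a query diverged before a nested duplication, *all* of its closest
relatives belong to deeper sub-HOGs, so the best hit is too deep even under a
perfectly clock-like tree. Accelerated and asymmetric evolution after
duplication makes things worse.

The method counters this with *evolutionarily informed k-mers*. For every
k-mer and family, the reference is preprocessed into a single table entry
holding the k-mer's **ancestral HOG**: the last common ancestor (LCA) of the
most specific HOGs of all family members containing the k-mer. A k-mer shared
by two sibling sub-HOGs is credited to their parent; one private to a sub-HOG
stays there. The approximation errs on the general side when the same k-mer
arose twice independently (homoplasy), which is the conservative direction
for placement.

### Table construction

Sequences are concatenated with one sentinel per protein and a suffix array
is built over the concatenation (Manber–Myers prefix doubling on numpy
`lexsort`; the sentinel sorts before every residue, and k-mer windows never
cross one). All suffixes beginning with the same k-mer are adjacent in the
array, which yields the k-mer → protein groups in one pass and supports
binary-search membership queries. Per (k-mer, family) group the LCA of the
members' most specific HOGs is computed by iterated pairwise depth-table
walks (hierarchies are shallow; no heavy preprocessing is warranted). The
finished table is compressed sparse row: a dense offset index of length
`20**k + 1` over base-20 k-mer codes (alphabetically ordered canonical
alphabet, so `AA` → 0, `AC` → 1) plus a flat buffer of (family, ancestral
HOG) entries. The suffix array is an intermediate only and is not
serialized.

Non-canonical residues (X, B, Z, J, U, O, `*`, gaps) are retained in stored
sequences but every window touching one is skipped during indexing and
querying, so they never contribute counts in either direction.

### Scoring and assignment

A query is reduced to its set of `n` distinct canonical k-mers. For a HOG
with `x` hits out of `n` against a k-mer repertoire of `m` distinct k-mers,
the score is

    score = max(0, (x − E) / (n − E)),   E = n · p,   p = 1 − (1 − 20^(−k))^m

i.e. the observed hits in excess of the chance expectation `E`, rescaled so
that a full hit set scores 1. `p` is the chance that one query k-mer hits a
repertoire of `m` k-mers under a uniform background; `background="aa_freq"`
replaces `20^(−k)` with `(Σ_a f_a²)^k` estimated from reference residue
frequencies to absorb composition bias. The normalization therefore accounts
for query length (via `n`), repertoire size (via `m`), and optionally
composition.

Family level: scores are computed for the 100 candidates with the highest
raw hit counts (ties at the cutoff included), the best-scoring family wins,
and queries below `theta_family` (default 0.05) stay unassigned — that is
the knob that rejects non-homologous queries. Subfamily level: within the
winning family, `x` and `m` are restricted to table entries whose ancestral
HOG lies in the candidate's subtree, so each sub-HOG is scored on similarity
*in excess of its parent's*. The root-to-leaf path maximizing the sum of
these scores is selected (sum rather than max or deepest-accepted: it is
stable when several shallow nodes carry moderate evidence), then descent
proceeds from the root while each child's score passes `theta_sub` (default
0.1); the deepest accepted HOG is reported, the root-HOG itself if the first
child already fails. Two deliberate details:

- a child with zero attributed k-mers is never accepted, whatever the
  threshold — the chosen path is truncated at its last evidence-bearing
  node. Without this, a threshold of exactly 0 would descend to a leaf on no
  evidence;
- all ties (equal scores, equal path sums) break to the smallest identifier,
  making every benchmark deterministic.

Under the LCA rule, self-queries obey an exact path-safety theorem: every
k-mer of a reference protein maps, within its family, to its own HOG or an
ancestor of it, so sub-HOGs off the root→truth path collect zero hits and the
assignment can never be over-specific or wrong-path. The acceptance suite
asserts this with zero tolerated violations.

An *overlap score* — the fraction of query residues covered by windows of
family-matching k-mers that occur exactly once in the query — is reported to
flag partial (e.g. single-domain) matches; repeated query k-mers are ignored
because their placement is ambiguous.

## Benchmarking framework

The baseline is assignment by closest sequence under exact Smith-Waterman
(affine gaps; BLOSUM62, gap open 11, extend 1 by default — the field's
standard protein defaults; a gap of length L costs `open + L·extend`). The
engine is scikit-bio's `pair_align`; tests verify it against an independent
Gotoh dynamic-programming implementation. Ties on alignment score break to
the smallest protein id.

Each query's closest sequence falls in one of four configurations relative
to the query's true HOG: `true_subfamily` (same HOG), `over_specific` (truth
ancestral to the hit's HOG), `under_specific` (hit's HOG ancestral to
truth), `wrong_path` (different branches). These four are mutually exclusive
and exhaustive within a family; queries whose closest sequence is in a
different family are counted separately as family-level errors.

Validation computes precision/recall/F1 over score thresholds, the grid
being the sorted set of observed scores (no discretization artifacts in
F1_max). Family level: false positives are negatives assigned anywhere plus
positives assigned to a wrong family, at or above threshold; positives
assigned to their own family split into TP/FN by threshold; wrong-family and
unassigned positives count as FN (the treatment of unassigned positives at
high thresholds is a convention — they are missing from their family either
way). Negative sets are either random sequences (i.i.d. residues from
Swiss-Prot-like frequencies, lengths copied from the positives) or
contamination-style draws of one protein from each of n distinct
out-of-scope donor families.

Subfamily level, two counting schemes per query (restricted to family-level
true positives, and when two methods are compared, to their shared ones):
*implicit* — an assignment to a sub-HOG implies its parental sub-HOGs;
TP/FP/FN are the intersection/differences of the predicted and true
root-to-HOG paths with the root-HOG excluded (it carries no within-family
information); *stringent* — only an exact match earns a TP; a root-level
prediction with a true sub-HOG costs one FN and no FP.

## Synthetic data

The generator exists so the whole system is testable with known truth. One
ultrametric species tree of depth 1 (random topology, evenly spaced joins)
is shared by all families. Gene lineages duplicate along it as a Poisson
birth process (`duplication_rate` expected events per root-to-tip lineage);
each duplication spawns two sub-HOGs, nesting capped at `depth_max`. For the
uncapped process the expected duplication count has the closed form
`Σ_branches (e^(λ t1) − e^(λ t0))`, which the tests check at 3σ. Sequences
evolve by i.i.d. per-site replacement from a Swiss-Prot-like background
(substitution probability `1 − exp(−r·t)` per branch; replacement may be the
same residue, so the *visible* difference rate carries a `1 − Σ f²` factor);
there is no exchangeability matrix or site-rate heterogeneity — the package
tests placement logic, not phylogenetic realism. Post-duplication daughter
segments multiply the rate by `rate_boost`, one of the two (chosen at
random) additionally by `asymmetry`, until the next speciation or
duplication. Short indels occur at `indel_rate` per site per unit branch
length.

Defaults are the benchmark conditions: 50 families, 8 species, duplication
rate 1.2, `depth_max` 3, 150-residue roots, base rate 0.15, boost 4,
asymmetry 3, indels 0.01. The duplication rate was calibrated so that at
least ~20% of leave-one-out queries sit in the over-specific closest-sequence
configuration (pooled over seeds 1–5 the fraction is ≈0.23), the regime the
benchmark targets; the substitution rate was chosen so that 6-mer exact
matching retains sensitivity across the tree (divergence beyond ~40%
identity makes shared 6-mers vanishingly rare, mirroring the method's known
degradation on very distant references).

`make_fixture` designates species S1 as the query proteome and removes it
from the reference before table construction (leave-one-out). A query's true
HOG can then be absent from the reference (nobody else had members in its
subtree); benchmark truth uses its nearest surviving ancestor-or-self — the
most specific statement the reference can express. What passing these
benchmarks shows is that the placement machinery behaves as designed under
the generative model; it does not certify accuracy on real proteomes, whose
families are larger, older, unevenly sampled and not i.i.d. in composition.

## Problem sizes and numerics

The shipped benchmark uses 50 families × 8 species (~1000 reference
proteins, ~130 queries per seed, five seeds), k = 6. The dense CSR index at
k = 6 holds 64M+1 int64 offsets (~0.5 GB transient during construction);
k = 3 is used in the small oracle fixtures where brute-force enumeration is
the point. Scores are clamped to [0, 1]; `n = 0` profiles yield "no
assignment" rather than an error; `n ≤ E` yields score 0. Determinism: all
randomness flows from integer seeds through `numpy` generators; rebuilt
tables are byte-identical.

## Known limitations

- Exact k-mer matching loses sensitivity beyond ~600 MY-scale divergence;
  reduced alphabets or spaced seeds would be the natural extensions.
- The score's uniform-background chance model ignores k-mer autocorrelation
  within proteins; the `aa_freq` background corrects composition only to
  first order.
- The LCA attribution deliberately trades over-specific errors for
  under-specific ones; applications needing maximal depth should lower
  `theta_sub` and accept the precision cost.
- DIAMOND-style heuristic baselines are not reimplemented; external hit
  tables can be scored through the same validation code.
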