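# Methods

This note documents the models implemented in `redphylo`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Study design

The built-in taxon panel (`redphylo.datasets`) comprises 15 red algae —
five seaweeds (Bangiophyceae: *Porphyra*; Florideophyceae:
*Hildenbrandia*, *Palmaria*, *Calliarthron*, *Chondrus*), eight
non-seaweed mesophiles (Stylonematophyceae: *Rhodosorus*,
*Purpureofilum*; Compsopogonophyceae: *Compsopogon*, *Rhodochaete*;
Porphyridiophyceae: *Porphyridium*, *Erythrolobus*, *Timspurckia*;
Rhodellophyceae: *Rhodella*) and two extremophilic Cyanidiophytina
(*Galdieria*, *Cyanidioschyzon*) — plus three green algal outgroups.
Each taxon carries a data type (genome, partial genome, transcriptome)
that downstream presence calling uses.  The reference rooted topology
splits Cyanidiophytina from the mesophilic lineages, places the seaweeds
at the base of the mesophiles, Stylonematophyceae basal among the
remaining mesophiles, and Compsopogonophyceae sister to
Porphyridiophyceae + Rhodellophyceae.  The resolution *within*
Porphyridiophyceae is not constrained by any quantity computed here; we
use (*Porphyridium*, (*Erythrolobus*, *Timspurckia*)).

## Single-copy selection and supermatrix

A cluster passes single-copy selection iff (i) no taxon contributes two
or more members, (ii) at most 3 of the 15 red taxa are absent, (iii) at
most 1 of the 3 green taxa is absent.  Rejection reasons are evaluated in
a fixed order (multi-copy → red missingness → green missingness) so
reports are reproducible.  Alignments are retained when strictly longer
than 150 amino-acid columns with ≥ 15 rows; the two filters commute, and
the sequence-count threshold is applied *before* outgroup reduction (on
the full alignment).  "Missing" means zero members for a taxon; a
pre-filter dropping sequences shorter than 100 aa (off by default) is
assumed to have run upstream of clustering.  The provided gap-fraction
column trimmer (drop columns with > 50 % gaps) is plumbing only and is
not equivalent to conservation-score trimming.  Concatenation fills
missing taxa with `-` (the amino-acid FASTA convention rather than `?`)
and records 1-based inclusive partitions in gene-id order.

## Pseudo-likelihood species trees

For a rooted species triple {a,b,c} whose species-tree restriction has
cherry {a,b} and internal path length T (the sum of internal branch
lengths, in coalescent units, between the cherry's MRCA and the triple's
root node), the multispecies coalescent gives

    P(ab|c) = 1 − (2/3)e^{−T},   P(ac|b) = P(bc|a) = (1/3)e^{−T}.

The per-triple counts of the three rooted resolutions over the gene
trees are a sufficient statistic.  The objective is the sum over triples
of the multinomial log-likelihood (constant coefficients omitted;
triples with zero total count skipped); it is maximised over:

- **internal branch lengths** — bounded L-BFGS-B on [1e-8, 20]
  coalescent units with analytic gradients, objective tolerance 1e-6
  (the optimizer is run tighter, 1e-10, which costs little).  Terminal
  branch lengths are not estimable from triples and are reported absent.
- **rooted topologies** — hill climbing in the rooted-NNI
  neighbourhood (2 moves per internal non-root branch; moves on branches
  incident to the root re-position the root, so rootings are explored).
  A step accepts the best neighbour improving the optimised objective by
  more than 1e-8; equal scores break toward the lexicographically
  smallest canonical Newick, making the search deterministic.  Per-
  topology optima are cached by canonical form.

The default start tree is built by concordance-weighted agglomeration:
the pairwise weight w(x,y) is the fraction of counted triples containing
x and y in which {x,y} is the cherry, and clusters merge greedily by the
mean cross-pair weight (deterministic; ties broken lexicographically).
This replaces a literal "compatible-clade accretion" over majority
triples — the agglomeration is simpler, consistent under the coalescent
model, and only a starting point for the search.  Additional restarts
(default 10 on the CLI) perturb the start by 3 random NNI moves using
the run seed.

## Two-level bootstrap

Each replicate (i) samples genes with replacement, (ii) samples columns
with replacement within every sampled gene (jointly across rows, so
within-column linkage is preserved), (iii) reduces each pseudo-alignment
to its highest-priority green outgroup row, (iv) estimates a rooted gene
tree, and (v) reruns the species-tree search; replicates are summarised
by majority rule after pruning to the red taxa (the outgroup is kept
through the species-tree search and removed before consensus, so
supports are reported on the red-algal tree).  Random streams derive
from the master seed by replicate and gene indices, so each replicate is
independently reproducible.  A failed replicate is logged and skipped;
the run errors if more than 10 % fail.

The internal gene-tree estimator is neighbor joining (scikit-bio's
implementation) on Poisson-corrected distances d = −ln(1 − p), with p
the mismatch proportion over pairwise-complete (both rows non-gap)
columns; pairs with no shared columns or p ≥ 1 are capped at d = 10 with
a warning, and negative NJ branch lengths are clamped to zero (standard
practice; only the topology is consumed downstream).  This substitutes
for per-gene maximum likelihood; any external tool that writes Newick
can be plugged in via a command template.  Bootstrap-internal
species-tree searches default to 2 restarts: they start from the
consistent agglomeration tree, where extra restarts buy little.

Consensus follows the Phylip `consense` conventions: *strict* majority
rule keeps exactly the clades in > 50 % of the input trees (ties at
exactly 50 % excluded); the default *extended* mode greedily adds
compatible minority clades in descending frequency (50 % ties
eligible).  Supports are raw clade frequencies in percent.

## Pathway presence and Dollo losses

Candidates per query are the union of the 3 top-bit-score and 3
top-identity subjects (ties by subject id).  A candidate is validated as
an ortholog when it lies in the largest clade containing the reference
sequence whose leaves are all candidate-eligible (by default the
candidates themselves; optionally all red-algal labels, so non-candidate
red sequences do not break the clade).  Presence calling distinguishes
data types: a taxon with ≥ 1 validated ortholog is *present*; an
ortholog-less genome taxon is *absent*; an ortholog-less transcriptome
taxon is *ambiguous* by default, because transcriptome absence is weak
evidence, or *absent* under the strict policy used when losses are
independently supported.

Dollo parsimony allows one gain and unlimited losses.  The gain sits at
the MRCA of the present leaves (or at the root, for characters presumed
ancestral — planted-loss round-trip tests use this mode, since a planted
loss adjacent to the root would otherwise be absorbed into the gain
placement).  Losses are the maximal subtrees inside the gain clade with
no present leaf and at least one strictly absent leaf; ambiguous leaves
never force a loss but may be absorbed into one.  This construction is
provably minimal and is verified against exhaustive loss-subset search
on small trees.  A pathway-level call (present iff ≥ half of the
designated core enzymes are present; for the mevalonate pathway the core
is HMGR, MVK, PMK, MVD, the 3rd–6th enzymes) is our construction and is
configurable.

On the reference topology with the mevalonate pathway present only in
*Galdieria sulphuraria*, *Rhodosorus marinus* and *Purpureofilum
apyrenoidigerum*, the minimal reconstruction is three parallel losses:
the *Cyanidioschyzon* terminal branch, the seaweed ancestor, and the
ancestor of the non-Stylonematophyceae mesophiles.

## Synthetic data

The gene-tree generator runs the multispecies coalescent with one
lineage per species: within each species-tree branch of duration t
(coalescent units), k lineages coalesce at rate k(k−1)/2 with waiting
times truncated at t; survivors coalesce freely in the root population.
The species tree must be ultrametric so population start/end times are
well defined; the reference-tree builders set every internal branch to a
chosen length (default 1.0) and pad terminal branches accordingly.

Sequences evolve under an equal-exchangeability 20-state model: the root
sequence is uniform, and along a branch of b expected substitutions/site
each site changes with probability (19/20)(1 − e^{−(20/19)b}) to a
uniform different residue.  Gene-tree coalescent lengths are scaled by a
rate of 0.05 substitutions/site per coalescent unit by default — no
empirical calibration is implied; only relative divergence matters for
the tests.  Missingness is applied at the orthogroup level (whole taxa
dropped from genes), emulating transcriptome incompleteness.  The
generator does **not** emulate realistic exchangeabilities (LG/WAG),
among-site rate variation, indels, alignment error, or paralogy mistaken
for orthology — so passing tests demonstrate correctness of the
estimators under their own model assumptions, not robustness to these
real-data complications.

The orthogroup fixture plants one category per group (clean, multi-copy,
4-red-missing, 2-green-missing, 150-column, 14-row) with the verdict
known by construction; the first clean group sits exactly on the
151-column / 15-row retention boundary.

## Problem sizes and numerical notes

The test suite and the acceptance script run at the study's design sizes
where cheap (298 genes, 15+3 taxa, internal branches 1.0) and at reduced
scale where iteration dominates: bootstrap checks use 50 genes × 200
columns with 12–20 replicates, and recovery rates use 10–20 seeded
runs.  These sizes are the package's own choices for routine runs; all
scale linearly if increased.  Degenerate inputs are handled explicitly:
empty count tables score zero, zero-length branches give the star-triple
distribution (1/3, 1/3, 1/3), uniform triple counts drive branch lengths
to the lower bound, and identical sequences yield a deterministic
(arbitrary) NJ resolution.

## Known limitations

- Pseudo-likelihood treats triples as independent; supports and branch
  lengths inherit MP-EST's approximations.
- One sequence per species per gene; multi-allele extensions are out of
  scope.
- The NJ gene-tree substitute underperforms per-gene ML on saturated or
  short alignments; plug in an external ML tool for fidelity.
- Concatenation inference (e.g. Bayesian CAT-model analyses) is
  deliberately out of scope: the supermatrix is exported for external
  tools.
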