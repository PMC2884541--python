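# Methods

This note records the scientific and numerical choices behind `paleodup`:
what the screen assumes, where its definitions were genuinely open, and
what the bundled simulator does and does not emulate.

## The inference problem

Two eukaryotic supergroups anchor the screen: Archaeplastida (R) and
Opisthokonta (O).  Under the supergroup model of eukaryote phylogeny their
separation is among the earliest splits between extant eukaryotic lineages.
A gene-family tree therefore witnesses a *pre-split* ("early eukaryotic")
duplication whenever two paralogous clades each contain both R and O
members: both duplicates must already have existed in the common ancestor
of the two supergroups.  The method is purely topological — no molecular
clock, no dS saturation problems, no synteny requirement, which is what
makes it applicable at this age.

Because sequence-similarity clusters may mix paralogs that diverged before
the prokaryote/eukaryote split, duplications are not counted on raw trees
but inside **orthogroups**: eukaryote-only clades delimited by prokaryotic
outgroup context, each approximating the descendants of a single gene in
the first eukaryotic common ancestor.

## Definitions resolved by this implementation

Several operational details are not fixed by the verbal definitions; the
choices made here are:

* **Outgroup rooting score.**  Every edge of the unrooted tree is scored in
  both orientations: a candidate outgroup side that is prokaryote-pure
  scores its prokaryote count; a mixed side scores (prokaryotes −
  eukaryotes) minus a penalty large enough that any pure side wins.  Ties
  break on the lexicographically smallest sorted leaf-label set.  This
  makes rooting total (it also handles non-monophyletic prokaryotes) and
  deterministic.
* **Type II orthogroups.**  A maximal eukaryote-only clade whose sister is
  mixed is split *once* at its basal node when both children contain R and
  O members, giving two sister type II orthogroups; the consumed split is
  not itself a duplication call.  Splitting is deliberately not recursive:
  recursive splitting would dissolve every (RO)(RO) duplication into
  separate orthogroups and make the most frequent retention pattern
  unobservable.
* **Support gating.**  A duplication call at a node is gated on the
  *minimum* support over its non-leaf daughter clades — the daughters are
  the evidence that two R+O-competent clades exist, so the weakest daughter
  bounds the call.  A leaf daughter imposes no constraint; a node whose
  children are all leaves gates on its own support.  A missing support is
  "unknown", distinct from 0, and fails every threshold.  For the
  bipartition method the gate is the support of the edge itself.
* **Stringent criterion.**  On multifurcating nodes the shared-species
  requirement is evaluated on the best pair of daughter clades (preferring
  pairs with an R+O side, then maximal shared-species count), which makes
  the handling of unresolved nodes deterministic.
* **Retention patterns.**  Nested accepted calls are one duplication chain
  classified at the basal-most node; accepted calls in disjoint subtrees
  mean independent duplications and classify the orthogroup as `OTHER`.
  Summary tables count orthogroups, not events.
* **Percentages** use round-half-away-from-zero to one decimal; this
  reproduces every printed percentage of the reference screen's tables
  from its integer counts.
* **Filter order.**  Redundancy collapse (identity strictly > 80%, single
  linkage within species, representative = longest then smallest id) runs
  before domain filtering, then eligibility; each filter only removes
  members and is idempotent.
* **Protist placement.**  Paralog clades are re-identified in the
  protist-augmented tree as the smallest clades containing the original
  leaf sets.  Protist-inside-paralog and duplication-after-protist verdicts
  both require the defining clade's support to clear the threshold;
  anything else is "no resolution".

## The simulator

`simulate_family` evolves gene lineages along a fixed 14-species tree
(Ath, Ppa, Cre | Hsa, Tru, Spu | Sce, Spo | Eco, Rpr, Bsu | Mac, Sso, Pae).
One stem lineage enters the eukaryote root; with probability `p_early`
(default 0.3) it duplicates on the eukaryote stem — the signature the
screen is designed to detect.  Below the split, each lineage on each branch
receives Poisson(`dup_rate`) duplications and Poisson(`loss_rate`) losses
(defaults 0.05/branch, modest rates typical of conserved families; losses
are applied after duplications).  Prokaryotes contribute one basal gene
each.  Families that lose all eukaryotic genes are discarded and
resimulated, since empty families are unobservable in real cluster data.

Generation is two-phase: events are sampled into an explicit log, and the
tree is built by a deterministic replay of that log.  The test suite
re-implements the replay independently and checks tree-for-tree equality,
so the logged truth is guaranteed to describe the emitted tree.

**Supports** follow a two-tier model: clades whose species set matches a
species-tree clade draw `clamp(base_true − U(0, noise_width), 0, 100)`,
all others draw from `base_other` (defaults 95 / 55 / 25, chosen so that
concordant clades usually clear the 50–70 gates while discordant ones
often fail, as bootstrap values do in practice).  A consequence worth
knowing: a paralog clade altered by loss no longer matches any
species-tree species set and draws from the low tier, so noisy-support
recovery is deliberately conservative.

**Long-branch corruption** (`corrupt_with_lba`) detaches one gene of a
target species and re-attaches it as sister to the remaining eukaryotic
clade, reproducing the artifactual basal placement that a rapidly evolving
lineage suffers under long-branch attraction.  On duplication-free families
this creates relaxed calls (the remainder clade contains R and O) but never
stringent ones (no species can sit on both sides), which is the rationale
for the stringent criterion.

**Copy-number tables** come from a latent bivariate normal with Pearson
correlation `r = 2·sin(π·ρ/6)` — the inverse of the normal-score rank
correlation identity — mapped through a monotone exponential transform to
non-negative integers.  Realized Spearman correlation converges to the
target as n grows (within ±0.05 at n = 5000 in the tests); at ρ = 1 the
construction is comonotone and exact at any n.

What the simulator does **not** emulate: sequences and alignments (no
substitution model, no bootstrap resampling — supports are drawn, not
estimated), horizontal transfer, heterogeneous rates across families,
protist taxon sampling, and clustering noise (each family arrives as one
clean cluster).  Passing the simulation suite therefore validates the
screening logic, not the upstream tree-building steps, which remain the
user's responsibility.

## Statistics

* Spearman correlations use average ranks for ties (scipy).
* The correlation-difference permutation test reassigns group labels while
  preserving group sizes; the statistic is |ρ_A − ρ_B|.  Monte-Carlo p uses
  the add-one estimator (1 + hits)/(1 + n_perm), which cannot return 0; an
  exhaustive mode enumerates all assignments exactly and is used for small
  groups.  Degenerate permutations (constant vectors) count as non-hits.
* Term enrichment is the one-sided hypergeometric upper tail per term,
  Bonferroni-corrected over the terms with at least one study annotation.

## Problem sizes and numerical checks

The validation suite runs on deliberately small, fully enumerable
problems: all 11,463 unrooted binary topologies on 4–8 leaves for the
detector/oracle equivalence check, 500 simulated families for recovery
calibration (binomial 99% interval around `p_early`), 200 corrupted
families for the false-positive comparison, and exhaustive 3+3 label
enumeration for the permutation test.  These sizes give exact or
tightly-bounded expectations while keeping the whole suite fast.

## Known limitations

* The screen's sensitivity is bounded by the support gate; families whose
  duplication daughters are weakly supported are invisible at high
  thresholds (by design — the same trade-off applies to real bootstrap
  values).
* Orthogroup delineation trusts the outgroup rooting; a wrong root can
  convert a duplication into apparent lineage structure.  The bipartition
  method is root-free but requires ≥ 2 R and ≥ 2 O sequences.
* Losses are never inferred, only simulated; retention patterns describe
  presence/absence of R/O members in the daughters, not reconciled loss
  histories.
* The eligibility/cleaning filters assume precomputed identity and domain
  tables; the package does not run alignment, clustering or domain-scanning
  tools.
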