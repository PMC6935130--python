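# Methods

## Parsimony model

Characters are optimised independently on a fixed rooted cladogram.
Branch lengths are never used: the quantity minimised is the total step
cost of assigning one state to every node.  Two step structures are
built in, matching standard morphological practice: unordered (any change
costs 1) and ordered-linear (a morphocline; *i* → *j* costs |i − j|).
Both are symmetric with zero diagonal and satisfy the triangle
inequality, so character length is invariant to rerooting along any edge
and to the order of a node's children — properties the test suite asserts
on randomized instances.

The down-pass is the generalized Sankoff recurrence: for node *v* with
children *c₁..cₙ*,

    S_v(i) = Σ_j min_s [ S_{c_j}(s) + step(i, s) ],

summed over *all* children, i.e. polytomies are treated as hard.  The
rationale: consensus and bootstrap input trees legitimately contain
polytomies, and treating them as soft would require a tree-search step
that is outside this package's job (topologies are inputs here, never
searched for).  Tip rows are 0 for every attainable state and ∞
otherwise, with three special cases:

* **polymorphic cells** are uncertainty — zero cost for each listed
  state, i.e. the reconstruction pays the cheapest member, it is not
  forced to generate all of them.  This matches the default of the
  common parsimony programs.
* **missing cells** cost zero in every state.  Scoring them this way
  rather than pruning the taxon is length-equivalent (the test suite
  checks removability of all-missing taxa) and keeps reconstruction
  bookkeeping uniform.
* **inapplicable cells** (the NEXUS gap symbol) are treated exactly like
  missing for optimisation.  The distinction is preserved in the matrix
  container purely for file round-trip fidelity; no inapplicable-aware
  algorithm is attempted.

The up-pass computes, per node and state, the full-tree cost of the best
reconstruction placing the node in that state; states achieving the
global minimum form the node's MPR set.  Costs are exact integers
throughout — there is no floating point anywhere in length computation.

## ACCTRAN / DELTRAN

Resolutions are defined only on rooted trees (roots here come from
outgroup rooting, as is standard for cladistic matrices).  Assignment is
a preorder sweep: the root takes the lowest-coded state among those
achieving the minimum; every child then chooses among the states that
keep the tree at the global minimum given its parent's assigned state —
this candidate set is exactly `argmin_i [S_child(i) + step(parent, i)]`,
so any choice stays optimal and inside the child's MPR set.  ACCTRAN
picks the candidate *farthest* from the parent (maximal step cost),
forcing the change onto the current, rootward branch; DELTRAN picks the
*nearest*, deferring it.  Remaining ties break deterministically to the
lowest state code.  The suite verifies on randomized instances that both
modes always realise the Sankoff minimum and that every assigned state
lies in the node's MPR set.

Changes are read off branch by branch; an ordered multi-step transition
on one branch is reported as a single change (e.g. `0 --> 3`, 3 steps).
A change is flagged **ambiguous** unless the identical (branch, from,
to) triple appears in both resolutions.  **Unique and unreversed** is
primarily a per-character criterion — ci = 1.0 — combined with a
per-transition check (the derived state arises exactly once and no
change leaves it).  For multistate characters these two notions can
disagree; both are computed, and the flag requires both, so a ci = 1.0
character whose derived state is later left again is not marked.

## Fit indices

Per character, m (minimum steps on any tree) and g (maximum steps,
realised on the star tree over the tree's tips) bracket the observed
s.  m accounts for polymorphism by brute-force minimisation over the
listed states (exact hitting-set for unordered, range minimisation for
ordered); g minimises the star-tree sum over all possible centre states,
including unobserved intermediate states of ordered characters.
Ensemble CI/HI/RI are ratio-of-sums with character weights (default 1,
"equal weights"); they are kept as exact `Fraction`s and rounded to four
decimals only for display.  Undefined ratios (s = 0, or g = m) are
reported as such, never coerced to 0/0 surrogates.

**AC** is operationalised as the number of characters with ci = 1.0 whose
change (in the DELTRAN resolution, the presentation default) lies on an
internal branch, i.e. diagnoses a clade.  Because autapomorphies of
individual terminals are also of descriptive interest, a
`count_autapomorphies` flag widens the count to all ci = 1.0 characters
that change anywhere.

Parsimony-uninformative characters (m = g; their length is the same on
every tree) are *included* in the ensemble sums by default, with an
`exclude_uninformative` toggle.  Neither choice affects tree length; the
toggle exists because published CI values vary in this convention and a
reproduction attempt may need to flip it.  When several topologies are
compared with the toggle on, inclusion is intersected across topologies
so every report sums the same characters.

## Topology construction

Trees are dendropy objects under a thin wrapper.  Outgroup rooting
requires the outgroup to be a connected cluster of the unrooted tree and
is idempotent.  Grafting a taxon subdivides the stem branch above the
anchor (a tip, a clade, or the whole tree); `basal` mode on a
single-tip clade degenerates to `sister`.  Grafted edges get zero
lengths — parsimony never reads them.  Hypothesis rearrangement moves
named, currently-monophyletic clades to required sister/basal positions,
preserving within-clade structure and the tip set; contradictory
constraint pairs are reported by name rather than silently last-wins.

## Synthetic data generator

The generator emulates the structure of a compact morphological matrix:
default 27 taxa, 42 characters with 2–5 states, 18 ordered, 25% missing
cells, and optionally whole taxa scored for nothing (a fossil known from
elements that do not bear the characters).  Characters evolve by a
continuous-time Markov chain: equal-rates Mk for unordered characters;
for ordered characters a ±1 stepping chain (each permitted neighbour
move at rate `rate/2`), chosen because its admissible single events are
exactly the unit steps of the ordered cost structure, keeping simulation
and scoring consistent.  The root state is uniform (no stationary
weighting — irrelevant to parsimony behaviour, documented rather than
modelled).  The default rate of 0.05 changes per unit branch on
unit-length branches gives roughly 2–3 expected changes per character on
a 27-tip tree — enough homoplasy for the indices to be informative
without saturating.

Every realised event is recorded as (branch, from, to), so tests can
compare reconstructions against the true history: the event count upper-
bounds the parsimony length always, and in the low-rate regime
(expected 0.1 changes/character) the two coincide for ≥98% of characters
and the DELTRAN change lists match the true histories for ≥95% — both
asserted in the suite at 2,000 and 500 characters respectively.  One
integer seed drives tree shape, per-character histories and the missing
mask through independently spawned substreams.

What the generator does *not* emulate: rate heterogeneity across
lineages, correlated characters, ascertainment ("only variable characters
coded") bias, and non-random missingness beyond whole-taxon blanking.
Passing the synthetic tests therefore demonstrates algorithmic
correctness and statistical sanity of the pipeline, not robustness to
those real-data pathologies.

## File formats and numerics

NEXUS `DATA`/`CHARACTERS` blocks are parsed with typed, line-numbered
errors (malformed block, duplicate taxon, row length, undeclared symbol);
both `{..}` and `(..)` polymorphism delimiters are accepted; symbols
default to `0123456789`; interleaved matrices are read (each line must
begin with its taxon name) but written non-interleaved.  Ordering comes
from an `ASSUMPTIONS`/`TYPESET` block (`ord`/`unord` with 1-based ranges)
or a bare `ord: ...` fragment; naming a character both ways is an error,
unnamed characters default to unordered.  Character indices are 1-based
in every file and CLI flag, 0-based internally.  The parser is cross-
checked in the tests against dendropy's independent standard-data reader,
and write→parse round-trips are property-tested.

Problem sizes in the test suite (≤6 tips and ≤4 states for the 1,000
exhaustive-enumeration comparisons; 2,000/500 characters for the recovery
checks) were chosen so the brute-force oracles remain exact and the whole
suite stays fast while still covering polytomies, ordered characters,
polymorphism and missing data in every combination.

## Known limitations

* No inapplicable-state logic (gap ≡ missing for scoring).
* Only unordered and ordered-linear step matrices; no user-defined or
  asymmetric costs, and no likelihood/Bayesian ancestral states.
* Hard polytomies only; no polytomy penalty option, which is the first
  place to look if a reproduction of published PAUP* numbers computed on
  a consensus/bootstrap tree disagrees.
* ACCTRAN/DELTRAN use greedy preorder placement with documented
  tie-breaks; where several equally accelerated placements exist the
  choice is deterministic but software-specific, and such changes are
  flagged ambiguous anyway.
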