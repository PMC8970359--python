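# Methods

## Scope and model

`cdvkit` treats a protein as its domain architecture: an ordered list of
instances drawn from a closed eleven-type vocabulary (CdvA_alpha, CdvA_beta,
BWI, BWH, MIM1, MIM2, Snf7, Vps4_C, MIT, AAA_ATPase, ANCHR) with 1-based
inclusive coordinates and an evidence class (`db_scan` > `motif_regex` >
`ss_annotation` > `putative`). Everything downstream — interaction networks,
mechanism scenarios, ancestral reconstruction — consumes only architectures,
never raw homology. Homology search, multiple alignment, secondary-structure
prediction and Bayesian tree building are out of scope; their outputs enter
as FASTA, annotation TSV, H/E/C tracks and Newick files.

## Motif definitions

MIM2 variants are fixed templates over two residue classes, hydrophobic
φ = {A,I,L,M,F,V,P,G,W} and charged x = {R,K,D,E}, with literal prolines:

| pattern | template | length | guaranteed P |
|---|---|---|---|
| MIM2_Core | φPxφP | 5 | 2 |
| MIM2_total | φPxφP·xxPφP | 10 | 4 |
| MIM2_Sulf | xφxxφφPx·φPxφP | 13 | 3 |

The `·` is immediate concatenation — composite lengths then match the
aligned proline spacing of the motif alignments. φ deliberately includes P
and G, unusual for a hydrophobicity class but part of the printed
definition. The unknown residue X belongs to neither class and so never
satisfies a template position. All matches at all offsets are reported;
overlap resolution happens later, during architecture assembly (one MIM2
instance per protein, class precedence total > Sulf > Core > putative,
within a class the most proline-rich match).

Two softer calls carry package-chosen thresholds because no exact criterion
exists for them:

* **putative MIM2** — a window of `window = 15` residues lying in the
  C-terminal `cterm_fraction = 0.5` of the sequence with
  `min_prolines = 3` prolines; overlapping windows merge into maximal
  spans, and any full MIM2 match on the protein suppresses the call. The
  defaults are calibrated to flag the proline-rich CdvA tails of the two
  Thaumarchaeota that lack a clean motif, and are exposed as function
  parameters.
* **ANCHR** — within the first `nterm_len = 30` residues, the longest
  predicted helix run must reach `min_helix_run = 8` residues and contain
  no proline; a proline inside the run vetoes the call (helix-breaking).
  The thresholds reproduce the CdvBa1 (helix, no proline) vs CdvBa2
  (conserved proline) split on the packaged Asgard alignment fixture and
  are likewise parameters, not constants.

MIM1 has no published regular expression, so it is never called de novo;
it enters only through annotation input. This is a deliberate
anti-overreach choice.

## Architecture assembly and taxonomy

Overlapping same-type calls merge to their coordinate union (the minimal
reading of "summarise hits that represent the same domain"); merging is
idempotent and keeps the strongest evidence. CdvC candidates must carry
Vps4_C or MIT — the AAA+ ATPase region alone is too promiscuous — with an
explicit allowlist for the one euryarchaeal exception justified by
homology-search E-value. CdvB classes are defined set-theoretically:
CdvB = {Snf7, MIM2, BWH}; CdvB1/2 = {Snf7, MIM2} without BWH (and without
ANCHR, so the TACK and Asgard taxonomies cannot collide); CdvB3 = exactly
{Snf7}; Asgard homologs split into CdvBa1 (Snf7 + ANCHR) and CdvBa2
(Snf7 without ANCHR). Anything else is `unclassified`, never forced.
"Putative MIM2" instances count as MIM2 for classification and presence
matrices — the package's documented resolution of a genuinely open point.

Gene-neighborhood buckets use minimal pairwise gene-rank distance among Cdv
genes: ≤ 1 `direct`, ≤ 5 `close`, else `distant`; fewer than two Cdv genes
is `absent`. The two thresholds are package choices (no numeric criterion
is published).

## Interaction rules and mechanism engine

The default rule table: validated — MIM2–MIT binding, BWI–BWH binding,
Snf7–Snf7 polymerization, Vps4_C–Vps4_C polymerization; putative —
CdvA_beta self-polymerization (evidence in the literature is inconclusive)
and MIM1–MIT binding. Qualitative PPI networks collapse paralogs onto
family nodes (union of domains) and count validated edges once per
(family-pair, domain-pair); this is what makes the Thaumarchaeota and
Crenarchaeota ancestral networks both count four interactions while putative
edges are drawn but not counted.

Mechanism inference is a deterministic qualitative rewriting system, not a
kinetic model. State = which proteins are at the division site (as scaffold
or as bound enzyme), which domain instances are engaged, what has
polymerized, which candidate moves were forked away. Rules of play:

1. The start protein is the unique carrier of a membrane-binding domain
   (CdvA_alpha or ANCHR); ambiguity is an error unless a start is named.
2. Candidates are enabled rule applications touching at least one present
   protein. A candidate is *clean* when its rule is validated and both
   domain instances have free capacity; putative rules and re-use of an
   engaged domain make it *questionable*.
3. While clean candidates exist, the best by affinity rank fires
   (membrane binding > BWI–BWH > Snf7–Snf7 > MIM–MIT with descending MIM2
   proline count, MIM1 ranking as zero > Vps4_C–Vps4_C; lexicographic
   final tie-break). Questionable candidates stay dormant.
4. When only questionable candidates remain and no disassembly has
   happened, the scenario forks — one branch per candidate, capped by
   `max_branches = 8` — and each branch permanently disables its
   siblings' candidates. This is what splits the Thaumarchaeota run into
   the CdvA-ring scenario versus the CdvC-as-linker scenario, from rule
   metadata alone: at that state both remaining moves (putative CdvA_beta
   polymerization; re-using the disassembler's engaged MIT to recruit
   CdvB) are questionable. The Asgard MIM1/MIM2 routes never fork because
   a clean MIM2–MIT bind exists.
5. Polymerization applies to scaffold proteins only (a bound disassembler
   is an enzyme, not a ring component) and recruits every absent protein
   sharing the domain in one event.
6. A protein with MIT + AAA_ATPase is a disassembler. After it has bound a
   partner, all polymerized proteins of a bound family reachable through an
   enabled MIM–MIT rule are depolymerized in affinity order, and the
   scenario terminates (disassembly is the terminal phase). A disassembler
   whose MIT was re-used as a linker loses this capability — it cannot
   tether and depolymerize at once, which is exactly why the linker
   scenario ends unresolved. Proteins that polymerized but were never
   depolymerized are reported `unresolved` (CdvB3, having no MIM motif,
   is the canonical case).

Identical inputs always give the identical scenario list. Kinetics,
concentrations and membrane mechanics are explicitly not modelled; the
"CdvB before CdvB1/2" disassembly order is produced by the static
proline-count affinity rank alone.

## Ancestral reconstruction

Characters are binary domain presences, family-qualified (``CdvB:MIM2`` and
``CdvA:MIM2`` evolve independently). The bottom-up pass uses Hartigan's
generalization of Fitch's method: at each node keep the states attained by
the maximal number of children and add (children − maximum) to the score.
On binary nodes this is the classic intersection/union rule; on polytomies
it still returns the exact minimum number of changes, where the naive
"intersect if nonempty, else union" shortcut can overcount (five children
with sets {0},{0},{1},{1},{1} cost 2 changes, not 1). Exactness is enforced
in the tests by exhaustive enumeration over all internal labellings for
trees up to seven leaves.

Nodes whose most-parsimonious set contains both states are reported
`ambiguous`; no ACCTRAN/DELTRAN commitment is made by default. Two
resolution policies exist:

* `dollo_single_gain` — one gain at the most recent common ancestor of the
  presence leaves (counted as an origin event when that ancestor is the
  root), losses on the stems of absent subclades;
* `presence_bias` — ambiguous roots of *flagged* characters resolve to
  present, then one most-parsimonious labelling is propagated down (with
  binary states the root choice determines the rest). The flag list is
  meant for characters with auxiliary evidence, e.g. domains whose genes
  co-cluster across phyla; for the packaged four-taxon matrix the flags
  are `CdvB:Snf7`, `CdvB:MIM2` and the three CdvC characters. On that
  matrix the reconstruction is in fact already unambiguous — the root
  architecture CdvB {Snf7, MIM2} plus a complete CdvC falls straight out
  of parsimony — so the policy only matters for genuine one-vs-one ties,
  as in the simulation-based recovery test.

Branch lengths are ignored; likelihood methods are out of scope.

## Synthetic data

`generate_sequences` draws background residues i.i.d. uniformly from the 20
amino acids (optionally excluding proline) and plants motif instances by
sampling φ/x positions uniformly from their classes, recording every
planted span as ground truth. Uniform background is a deliberately simple
null: no archaeal composition bias, no indels, no phylogenetic correlation
between sequences. Consequently planted-motif recall is 1.0 by
construction, and precision is 1.0 exactly when the background excludes
proline (every template contains literal P). Passing these tests therefore
shows scanner correctness, not robustness to real archaeal proteome
composition. ANCHR planting writes a 12-residue helix run starting at
residue 3, proline-free or with one inserted mid-run proline.

`simulate_domain_evolution` evolves characters root→leaves with independent
per-branch gain/loss flips. Defaults (`gain_prob = 0`, `loss_prob = 0.1`)
mirror the loss-dominated regime of the reconstruction problem; 500
replicates on the packaged tree give a root-recovery rate comfortably above
the 0.9 property target at the default seed. Both generators are pure
functions of their seed.

Problem sizes used by the test suite and the reproduction script — 1,000
random sequences of length ≤ 200 for the scanner/oracle comparison, 200
random ≤ 7-leaf trees for the parsimony/brute-force comparison, 500
evolution replicates — are chosen so exhaustive oracles stay exact while
the whole suite runs in seconds.

## Fixtures and their limits

The packaged fixtures are figure-level transcriptions, marked as such in
their headers: the 51-organism architecture table reproduces the published
counts (37 organisms with at least one Cdv homolog, 14 without, eleven
domain types, the per-phylum architecture patterns, the euryarchaeal
allowlist case), but protein identifiers and domain coordinates are
plausible reconstructions, not supplementary-table values. The Asgard
alignment fixture preserves the helix/proline structure of the figure with
synthetic stand-in sequences. Conclusions that depend on exact coordinates
or on organisms outside the transcribed set are outside what these fixtures
can support.

## Known limitations

* No de-novo detection of Snf7, MIT, Vps4_C, AAA+ ATPase, BWI/BWH or MIM1 —
  these must come from annotation input.
* The mechanism engine is qualitative; it cannot order events that differ
  only kinetically, and its fork points are exactly the documented
  ambiguities of the rule set.
* Parsimony ignores branch lengths and rate heterogeneity; with
  loss-dominated evolution the presence-bias policy inflates root presence
  by design.
* The putative-MIM2 and gene-neighborhood thresholds are package defaults
  with no published counterpart; treat cross-study comparisons of those
  calls accordingly.
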