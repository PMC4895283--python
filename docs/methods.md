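# Methods

rriscan screens two sets of RNA sequences — queries (e.g. lncRNAs) against
targets (mRNAs and/or lncRNAs) — for local RNA–RNA interactions.  The
screen runs in five stages: (1) accessibility filtering, (2) tandem-repeat
soft-masking, (3) exact gapless reverse-complement seed search, (4)
accessibility-corrected minimum interaction energy on windows around each
seed, and (5) per-query target ranking by MinEnergy and SumEnergy.  This
note records the models, the parameter choices and their rationale, what
the synthetic benchmark does and does not emulate, and the numerical
decisions.

## Folding model and accessibility

The accessibility of a region r is the opening energy

    dE_acc(r) = -RT log P(r),   P(r) = Zc(r) / Z,

where Z is the partition function over nested (pseudoknot-free) secondary
structures and Zc(r) restricts the sum to structures in which every
position of r is unpaired.  R = 0.0019872 kcal/(mol K) and T = 310.15 K
(RT ≈ 0.616 kcal/mol); the temperature is a package default, physiological
and fixed.

Structures are scored by a deliberately small cooperative model rather than
the full nearest-neighbor ruleset, so that every dynamic program can be
verified against exhaustive structure enumeration:

* **per-pair energies** (kcal/mol): CG/GC 0.0, AU/UA +0.3, GU/UG +0.6;
* **stacking** for directly adjacent pairs (i, j), (i+1, j-1), from a
  Turner-style 6x6 table (the same table scores duplex stacking; it
  satisfies the strand-reversal identity exactly, which role-swap symmetry
  of interaction energies requires);
* **helix initiation** +4.0 kcal/mol charged once per helix, on its
  innermost pair;
* **steric constraints**: minimum hairpin loop of 3 unpaired residues, and
  a maximum pair span of 60 nt (folding is local, as in windowed
  accessibility tools; the span is configurable and `None` disables it).

The helix-initiation/stacking split is the load-bearing choice.  A purely
pair-additive model (no loop or initiation terms) over-pairs random RNA so
badly that every 12-mer costs 7–8 kcal/mol to open — accessibility then
cannot distinguish anything, because the cost is partner-choice entropy,
not structure.  With initiation charged once per helix, isolated chance
pairs are unstable while contiguous helices (e.g. a designed hairpin stem)
remain strongly folded.  Under the defaults, random 300-nt RNA at GC 0.5
has ~56% of positions unpaired in equilibrium, and ~85–90% of 8-nt windows
fall under the trained accessibility threshold t = 4.3 kcal/mol — the same
order as the retained-length fractions reported for real transcriptome
screens.  Setting `helix_init = 0` and an empty intramolecular stack table
recovers the pair-additive model, which the tests use for closed-form
checks.

Partition functions follow the unambiguous grammar

    Z[i,j)  = Z[i+1,j) + sum_k Zb(i,k) Z[k+1,j)
    Zb(i,k) = p(i,k) [ hw * Z[i+1,k) + (st(i,k) - hw) Zb(i+1,k-1) ]

with p, st, hw the Boltzmann factors of the pair, stack and helix-initiation
energies.  `partition_function` exposes the (optionally constrained) inside
DP directly.  For the pipeline, an outside pass yields the context weights
of every segment and of every pair, from which the constrained partition
function of *every* span [a, b) follows by the tightest-enclosing-pair
decomposition

    Zc(a,b) = Z[0,a) Z[b,n) + sum_{i<a<=b<=k} Ob(i,k) p(i,k) hw Z[i+1,a) Z[b,k)

in O(n^3) total per sequence (no stack correction can appear: a pair
directly inside a tightest enclosing pair would either enclose the window
itself or land inside it).  One pass therefore serves both the fixed-window
screening profile of Stage 1 and the arbitrary-span opening penalties of
Stage 4.

Numerics: all recursions run in linear space with per-nucleotide rescaling
(a ladder of rescaling factors is tried until the top value is in double
range); the rescaling cancels exactly in Zc/Z.  Opening energies are
clamped to be non-negative and monotone under span inclusion — both hold
exactly in real arithmetic — which also guarantees the validity of the
bounds used in Stage 4.  Spans whose scaled Zc underflows report +inf
(effectively inaccessible).  DP values agree with exhaustive enumeration to
1e-9 relative on short sequences.

## Accessible regions (Stage 1)

For window length `access_len` (default 8) the profile holds dE_acc of
every window; positions covered by any window with dE_acc strictly below t
(default 4.3 kcal/mol, the trained operating point; t = inf disables the
filter) are merged into maximal accessible regions, each at least
`access_len` long.  Ties at t are rejected (strict inequality).

## Tandem-repeat soft-masking (Stage 2)

A deterministic stand-in for probabilistic repeat maskers: for each period
p ≤ 50, maximal segments of the match indicator (residue i vs residue i-p)
with identity ≥ 0.9, total run length (template included) ≥ 20 and at
least two full copies of the unit (matched stretch ≥ p) are soft-masked.
Masked positions keep their coordinates; they are excluded from seed
matching only and may appear inside energy-evaluation windows.  Two
conditions protect the rule from degenerate behavior: the two-copies
requirement (without it a single chance match at a long period qualifies
and random sequence is masked wholesale), and an X-drop bound — a run is
severed where its score falls a fixed amount below its running peak, so two
long repeat tracts cannot bridge across a short non-repetitive insert by
letting their matches subsidize its mismatches.

## Seed search (Stage 3)

A seed aligns a query segment with the reverse complement of a target
segment, gaplessly: +1 per Watson-Crick column (A-U, C-G), -1 otherwise
(G-U wobble, mismatches, N, soft-masked positions).  Every antidiagonal of
the pairing matrix is scanned exactly — no spaced-seed heuristics — for
disjoint maximal scoring segments with score ≥ `seed_score` (default 8;
with ±1 scoring, score ≥ s implies length ≥ s).  "Maximal segments" means
recursive extraction of maximum-sum *trimmed* segments (every proper
prefix/suffix sum strictly positive; ties to smallest start, then end);
trimming makes the segment set invariant under strand-role exchange.  A
cumulative-sum bound skips antidiagonals that cannot reach the threshold.
Seeds are kept when their footprints intersect an accessible, unmasked
position on both molecules (intersection, not containment, so region
boundaries do not truncate alignments).

## Interaction energy (Stage 4)

Around each seed, windows of w nt (default 20) up- and downstream are cut
from both molecules and the minimum of

    E_int = E_hybrid + ED_query + ED_target

is computed exactly over all duplex structures in the windows: chains of
intermolecular pairs, query indices strictly increasing and target indices
strictly decreasing, with interior loops/bulges of total unpaired length
k ≤ 15 between consecutive pairs.  E_hybrid = duplex initiation (+4.1)
plus stacking for adjacent pairs plus loop penalties 4.0 + 0.5 k; the
opening constant is on the nearest-neighbor bulge scale, and without it
chains of short helices stitched through many cheap loops dominate every
window.  Intramolecular pairs inside the windows are excluded by
construction (accessibility and hybridization are separated).  Each ED term
is the opening energy of exactly the base-paired span, taken from the
full-length parent sequence — not the fixed-length screening window.

Because the ED terms couple both end pairs of the duplex, a single
right-anchored DP is only a heuristic.  Exactness is restored by
branch-and-bound over the duplex's first pair: for each start, reverse DPs
carrying the exact query-span (resp. target-span) opening energy plus a
single-position bound on the other molecule give a valid lower bound (ED is
monotone under span inclusion); starts are explored in bound order against
an incumbent from the heuristic and pruned when bounds cross.  The search
is verified equal to exhaustive duplex enumeration on small windows, and is
symmetric under exchanging query and target.

Interactions with optimal E_int ≥ 0 are discarded.  Within one (query,
target) pair, interactions whose query and target sites both overlap a
better interaction's sites are dropped (lowest E_int kept), so one physical
site found via several seeds is counted once.

## Ranking (Stage 5)

Per (query, target) pair with surviving interactions: MinEnergy = the
single most stable E_int; SumEnergy = sum of E_int strictly below the
cutoff x (default -16 kcal/mol), 0 if none qualify.  Targets of each query
are ranked ascending (more negative = rank 1), ties broken by target id;
pairs with SumEnergy 0 rank after all pairs with negative sums.  Both
rankings are total and deterministic.

## Evaluation harness

nTP-at-rank counts known targets within each query's top k, summed over
queries.  AUC-ROC is the Mann-Whitney probability that a random known
target has a more negative score than a random competitor, ties counting
1/2 (computed from averaged ranks).  `parameter_sweep` re-runs the full
pipeline per (t, s, w) grid point and tabulates candidate counts, nTP and
runtime, including the t = inf no-filter baseline.

## Synthetic benchmark

`generate_benchmark` emulates the situation the pipeline is built for: each
query has one true target carrying the exact reverse complement of a query
subsequence (site length 12 by default), embedded accessibly; decoys are
i.i.d. background (GC 0.5), and optionally a fraction of decoys carry the
*same* complement buried in a designed hairpin stem — present in sequence,
absent thermodynamically.  Defaults: 20 queries (200 nt) x 100 targets
(300 nt), seed 42.

Construction details that make the planted contrasts real under the
package's folding model: sites are chosen with C/G end residues and at
least background GC content (a controlled, composition-independent effect
size; and a complement planted next to poly-A must not extend the A-run,
or repeat masking erodes the seed); accessible plants sit in 60-nt poly-A
flanks (poly-A cannot pair with itself, and at the 60-nt pair span a fully
flanked site cannot reach anything else, so its opening cost is ~0-1.5
kcal/mol versus ~3 for background and >10 for stems); occluded plants are
buried inside a stem extended 6 bp beyond the plant on each side, so
surviving seeds cannot leak out of the inaccessible region by extending a
base or two into accessible sequence.

What passing tests show — and do not show.  The benchmark exercises every
stage end-to-end: under the default conditions the true target is ranked
first by MinEnergy for ≥ 90% of queries, and with the accessibility filter
at t = 4.3 the hairpin-occluded plants lose their seeds while accessible
plants keep them (the designed contrast behind the filter's benefit).  The
generator does not emulate real transcript length distributions,
composition biases, protein occupancy, or experimental noise; planted sites
are exact complements, whereas real interactions tolerate wobbles and
bulges.  Recovery rates on this benchmark therefore validate the
machinery, not transcriptome-scale accuracy.

## Problem sizes and determinism

Default benchmark runs (20 x 100 pairs, 34 knt of sequence) complete in a
few minutes on one CPU: accessibility is O(n^3) per sequence (~0.1 s at
300 nt), the seed scan is exact per antidiagonal with a vectorized bound,
and the Stage-4 search costs ~10-15 ms per window.  The pipeline proper
has no randomness: rankings, reports and logs are byte-identical across
runs; the only seed is the benchmark generator's.

## Known limitations

* The folding model is a coarse caricature of nearest-neighbor
  thermodynamics (no dangles, no loop-size-dependent hairpin terms, single
  affine duplex loop penalty); energies are comparable within this package,
  not with ViennaRNA/IntaRNA outputs.
* Sequences shorter than `access_len` produce no accessible windows and
  are effectively skipped.
* The maximum-pair-span default (60) is tuned to desk-scale transcripts;
  genuinely long-range intramolecular structure is invisible to it.
* Joint refolding of the two molecules around an interaction site is out
  of scope; reported structures are the intermolecular hybrids only.
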