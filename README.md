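# rriscan

Fast, accessibility-filtered screening of **local RNA–RNA interactions**
between a set of query RNAs (e.g. long non-coding RNAs) and a set of target
RNAs (mRNAs and/or lncRNAs).

Identifying which transcripts a regulatory RNA base-pairs with is a first
step toward its function, but joint secondary-structure prediction for two
RNAs costs O(L⁴)–O(L⁶) per pair and is hopeless across all pairs of a
transcriptome.  rriscan implements the practical alternative: decompose the
problem into cheap per-sequence screens followed by exact local energy
evaluation only where a sequence match exists.

## Pipeline

For queries Q and targets T, each candidate pair runs through five stages:

1. **Accessibility filter** — for every window of `access_len` nucleotides,
   the opening energy ΔE^acc = −RT·log(Zc/Z) is computed from the ratio of
   the window-constrained to the unconstrained partition function over
   nested secondary structures; positions in windows with ΔE^acc < t are
   *accessible* (a site that is to pair externally should not be paired
   internally).
2. **Tandem-repeat soft-masking** — repeats are excluded from seeding so
   they cannot explode the candidate count.
3. **Seed search** — all gapless reverse-complement matches between
   accessible, unmasked regions, scored +1 per Watson–Crick column and −1
   otherwise; disjoint maximal segments with score ≥ `seed_score` survive.
4. **Interaction energy** — on windows of ±`w` around each seed, the exact
   minimum of E_int = E_hybrid + ED_query + ED_target over all
   intermolecular duplex structures, where each ED term is the opening
   energy of exactly the base-paired span on that molecule.
5. **Ranking** — per (query, target) pair: **MinEnergy** (the single most
   stable local interaction; suited to short queries) and **SumEnergy**
   (the sum of local interaction energies below a cutoff x; suited to long
   RNAs with several sites).  Targets are ranked per query under each score.

Defaults are the trained operating point `t = 4.3 kcal/mol`,
`access_len = 8`, `seed_score = 8`, `w = 20`, `x = −16 kcal/mol`.
An evaluation harness (nTP-at-rank, Mann–Whitney AUC-ROC, (t, s, w)
parameter sweep) and a synthetic benchmark generator with planted —
optionally hairpin-occluded — interaction sites complete the package.
Model details and design rationale are in [docs/methods.md](docs/methods.md).

## Worked example

Generate a small synthetic benchmark (4 queries × 12 targets, one planted
true target per query) and screen it without the accessibility filter:

```bash
rriscan generate -o bench --n-queries 4 --n-targets 12 \
    --q-len 160 --t-len 220 --seed 11
rriscan run -q bench/queries.fasta -T bench/targets.fasta -o out --t inf
```

The log reports per-stage candidate counts:

```
rriscan INFO pipeline start: 4 queries x 12 targets
rriscan INFO step 2: masked 857/3280 positions
rriscan INFO step 1: accessible 3280/3280 positions (t=inf, access_len=8)
rriscan INFO step 3: 19 seeds (seed_score>=8)
rriscan INFO step 4: 19 windows -> 19 local interactions (w=20)
rriscan INFO step 5: 17 ranked (query, target) pairs (x=-16.0)
```

`out/rankings.tsv` holds both scores and both ranks per pair; for Q001 the
planted target T001 is recovered at rank 1 with a clear energy gap:

```
query_id  target_id  min_energy  sum_energy  n_interactions  rank_min  rank_sum
Q001      T001       -17.83      -17.83      1               1         1
Q001      T006        -9.30        0.0       1               2         4
Q001      T010        -8.54        0.0       1               3         7
```

MinEnergy −17.83 kcal/mol is the planted 12-bp duplex (hybridization
−18.7 plus opening penalties of 0.38 and 0.49 for the two sites, from
`out/interactions.tsv`); the best decoy is ~8.5 kcal/mol weaker.  Checking
the ranking against the generator's truth table:

```bash
rriscan evaluate --rankings out/rankings.tsv --truth bench/truth.tsv --ranks 1,2,5
 rank  ntp
    1    4
    2    4
    5    4
```

All four planted pairs rank first.  `rriscan sweep` runs the same loop
over a (t, s, w) grid, including the `t=inf` no-filter baseline.

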