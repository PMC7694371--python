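# Methods

## The integration statistic

Given paired log2 fold changes (LFC) for N genes measured at two omic
levels, each level is converted to ranks and the two ranks are averaged.
Concordance uses descending order at both levels (largest LFC → rank 1), so
`avg_rank_concordant = (rank_t_desc + rank_p_desc) / 2` runs from ~1
(concordantly up) to ~N (concordantly down). Discordance keeps the
descending transcript ranking but ranks protein LFCs ascending, so a high
`avg_rank_discordant` marks protein-up/transcript-down genes and a low value
the reverse. Because only ranks enter, the statistic is invariant under any
strictly increasing transform of either LFC column — the property that makes
it appropriate when the two platforms produce incomparable LFC scales.

Ties receive midranks (the mean of the positions they span). This keeps the
rank sum at N(N+1)/2, preserves the tie-free reflection identity
`rank_asc = N + 1 − rank_desc` in expectation, and is the standard choice
for rank statistics. In tie-free tables the two average ranks obey
`avg_concordant + avg_discordant = rank_t_desc + (N+1)/2`, which the test
suite uses as a structural check.

Top-k selection in each of the four directions breaks boundary ties by
gene_id lexicographically, making selections deterministic. For the
discordant directions a literal sign filter is applied by default (e.g.
protein-up selection requires `lfc_protein > 0` and `lfc_transcript < 0`)
before the top k are taken; whether such a filter should precede or follow
the rank cut is genuinely ambiguous, so the filter can be disabled
(`sign_filter=False`) to obtain pure rank selection.

The LFC correlation is the sample Pearson coefficient with the usual
two-sided t-approximation p-value on n − 2 degrees of freedom; no
permutation p is offered because the quantity is purely descriptive here.

## Identifier handling

LFC tables are read from TSV with configurable column names. Identifier
harmonisation is two-stage — a primary feature→gene mapping, then a fallback
mapping for the remainder (mirroring a direct-database-then-nomenclature-hop
conversion route); features unmapped after both stages are dropped and
counted, never silently. A feature mapping to k genes contributes k records.
Duplicate records per gene are then collapsed: the default `max_abs` rule
keeps the LFC of largest magnitude (ties → larger signed value), preserving
the extreme signal a rank statistic keys on; an arithmetic `mean` rule is
available by configuration. Only genes present at both levels after collapse
enter the integration; an empty intersection is a hard error.

When LFCs are computed from log2-scale expression matrices they are plain
group-mean differences with listwise deletion of genes that have any missing
value in either group. No normalisation or variance moderation is applied —
inputs are expected to be processed upstream.

## Pre-ranked gene-set enrichment

The enrichment score (ES) of a set with N_hit members in a ranking of N
genes is the signed maximal deviation of a running sum that increases by
`|score_i|^w / Σ_hits |score|^w` at each member and decreases by
`1/(N − N_hit)` at each non-member. `w = 1` is the default weighting;
`w = 0` reduces the ES to the classical two-sample Kolmogorov–Smirnov
statistic between hit and miss positions (verified against an independent
KS implementation in the tests). If every in-set score is zero at `w > 0`
the hit increments fall back to uniform `1/N_hit`. When the largest positive
and deepest negative excursions tie exactly in magnitude the positive one is
reported; such ties have measure zero for continuous scores.

Because the ranking is supplied externally, the only available null is
gene-set resampling: uniform random same-size subsets of the ranked
universe, 1000 permutations by default. Per set,
`NES = ES / mean(|same-sign null ES|)`; the permutation p-value uses the
add-one estimator `(1 + #{same-sign null with |ES| ≥ |ES_obs|}) /
(1 + #same-sign null)`, which cannot return 0 at finite permutation counts.
If no same-sign null values exist the NES is reported as NaN and p as
1/(0+1) = 1. FDR q pools the per-set-normalised null NES values and forms
the same-sign tail ratio (null tail fraction over observed tail fraction at
each NES), capped at 1, then monotonised by carrying a running maximum from
the most extreme |NES| outward — a conservative pass that can only raise q.

Sets with fewer than `min_size = 5` members in the universe are skipped and
logged; a name blocklist (e.g. for disease-specific pathways) can be
supplied. Enrichment runs independently on the transcript and the protein
ranking; the dual-level rule calls a set significant when q < 0.2 at both
levels with same-sign NES. Requiring two independent sub-threshold calls
multiplies the probabilities, an implied combined threshold of 0.2² = 0.04.

Numerically, the running sum is piecewise linear between hits, so its
extremes occur only at hit positions (maxima) or immediately before them
(minima). ES values are therefore computed from hit positions alone in
O(N_hit) per permutation, and one pool of full permutations per ranking
serves sets of every size (the first m entries of a uniform permutation are
a uniform size-m subset). This is exactly equivalent in distribution to
drawing fresh subsets per set — a test checks the two sampling routes agree
— and is what makes a 1000-permutation null over ~3,600 genes and dozens of
sets run in well under a second.

## Reference annotation

The plasma overlap intersects the top-100 discordant protein-up genes with a
plasma-proteome membership list and reports hits ordered by discordance
average rank (strongest first). The drug-target filter is two-stage: genes
with at least one approved-drug interaction, then the subset with a
concordant increase, operationalised as strictly positive LFC at both
levels. Both operations are pure set/join logic over the ranked table and
are checked against brute-force join oracles in the tests.

## The synthetic generator

Background LFC pairs are bivariate normal — the simplest model matching the
stated moments — with defaults emulating the target study conditions:
N = 3,598 shared genes, correlation ρ = 0.35, transcript margin
N(0.0, 0.5²), protein margin N(0.41, 1.2²) (protein spread deliberately
wider; the 0.5/1.2 scales are declared constants, as the emulated spreads
are known only qualitatively). Planted genes receive additive shifts of
3 × the level's scale (±1.5 transcript, ±3.6 protein): 30 concordant-up, 30
concordant-down, and 40 discordant (transcript down, protein up) genes by
default, of which 21 are flagged plasma-detectable. Gene sets are uniform
random draws (30 sets of 15–60 genes by default) plus one planted set equal
to the concordant-up genes; the drug table links half the concordant-up
genes plus 50 random background genes to fake approved drugs.

All generators are pure functions of (parameters, seed); a single seed fans
out to per-stage child seeds via `numpy.random.SeedSequence` (spawn order:
planted labels, LFC draw, expression matrices, gene sets, references), so
any stage can be regenerated in isolation. Expression matrices place group
means `baseline + lfc` vs. `baseline` with iid Gaussian noise, so the
group-mean-difference LFC recovers targets with standard error
`noise_sd·√(1/n_a + 1/n_b)`; default group sizes are 6 vs. 8, a realistic
small proteomic cohort.

What the generator does *not* emulate: probe-level microarray structure,
peptide-to-protein inference, missing-not-at-random proteomic dropout,
heavy-tailed or skewed LFC distributions, and correlated gene blocks.
Passing recovery tests therefore demonstrate the statistical machinery on
clean planted signal, not performance on real tumour data.

One calibration note: the planted shifts perturb the full-table sample
correlation away from the background ρ — the concordant and discordant
contributions partially cancel, leaving an expected full-table r ≈ 0.32
with a sampling sd of ~0.016 at N = 3,598, so single-study values typically
fall in 0.27–0.37 and the 20-replicate mean is stable near 0.32. ρ is kept
at the background value rather than re-tuned, since it parameterises the
background copula, not the planted tails.

## Problem sizes and determinism

Recovery properties are measured over 20 replicate studies at the full
default size (3,598 genes; 31 gene sets × 2 levels × 1000 permutations
each), which completes in seconds thanks to the sparse ES formulation.
Pipeline outputs are byte-stable: TSVs use fixed column orders and
6-significant-digit float formatting, manifests are sorted JSON, and all
randomness flows from the configured seed.

## Known limitations

- The dual-FDR combined threshold interprets the two levels' calls as
  independent; positively correlated datasets make the bound conservative
  in direction but not exact.
- Gene-set resampling nulls ignore inter-gene correlation, as does any
  pre-ranked enrichment scheme; q-values are therefore optimistic on data
  with strong co-expression blocks.
- The `max_abs` duplicate-collapse rule biases retained LFCs outward for
  genes with many features; use `mean` when duplicates are technical
  replicates rather than alternative probes.
- The plasma and drug references are membership lists only; no attempt is
  made to model detection probability or interaction strength.
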