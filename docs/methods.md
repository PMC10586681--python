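# Methods

This note documents the statistical model behind `coopnet`, the choices
made where the design was genuinely open, and what the synthetic-data
validation does and does not establish.

## Co-occurrence model

The sampling unit is the participant.  Each participant contributes a
*set* of canonical tokens: duplicates within one response are collapsed,
so a participant adds at most one count to any token frequency and at
most one to any pair's joint count.  For tokens *i*, *j* the 2×2 table
(n11, n10, n01, n00) counts participants mentioning both, one, or
neither, and the edge statistic is the log-likelihood ratio between the
saturated multinomial and the independence model,

    G = 2 Σ O ln(O/E),  E from the table margins,

with 0·ln 0 taken as 0.  G is the classic collocation G-statistic; it is
asymptotically χ²(1) under independence and, unlike Pearson's X², is
well behaved for the skewed tables that token data produce.  The edge
weight is +G when n11 exceeds its expectation (attractive pair), −G when
it falls short (repulsive), and the edge is omitted when the deviation
is exactly zero.  Pairs involving a token mentioned by every retained
participant have a zero margin; independence is untestable there and no
edge is drawn.

All token pairs are scored; no significance threshold prunes edges.  An
optional magnitude cutoff exists for display purposes only.

## Signed modularity

Printed formulas for signed modularity are notoriously loose about
pair-counting conventions, so the convention is fixed here explicitly:
v± is the total positive/negative edge weight with each undirected edge
counted **once**; node strengths s±_i sum incident weights; the
null-model expectation per ordered pair is e±_ij = s±_i s±_j / (2 v±)
(the sign-separated configuration model); and

    Q = 1 / (2 (v+ + v-)) · Σ_ordered pairs [(w+ - e+) - (w- - e-)] δ(M_i, M_j).

Consequences used as test anchors: on an all-positive graph Q equals
Newman–Girvan modularity exactly; the all-in-one partition scores 0; the
unit-weight triangle under singleton modules scores −1/3, and its
per-pair positive expectation is 2/3.  Within-module positive weight
above chance raises Q, within-module negative weight lowers it, which is
what makes repulsive edges informative for splitting.

## Optimizer

The Louvain heuristic is implemented directly on dense per-sign weight
matrices (the networks here have at most a few hundred nodes, so dense
linear algebra is both simplest and fastest).  Local moves use the
signed gain decomposition — positive-layer gain minus negative-layer
gain, each with its own null term; ties between candidate modules go to
the lowest module id, and a move must beat staying put by more than
1e-12 to be accepted, which makes every run terminate and makes the
reported modularity non-decreasing across phases.  Aggregation sums
weights into super-nodes per sign layer, accumulating ordered-pair
internal weight on the diagonal so strengths and totals are invariant
across levels.  The only stochastic ingredient is the node-visit order,
driven by a seeded generator, so a run is fully reproducible from its
seed.

## Consensus clustering

Louvain's restarts can disagree on weakly determined nodes.  Modules are
therefore fixed by consensus: `runs` restarts (default 100) with
distinct sub-seeds spawned from one master seed vote through the
co-classification matrix C, where C_ij is the fraction of runs placing i
and j together.  Entries below the threshold (default 0.40) are zeroed
and the remaining fractions form an all-positive graph that is
re-clustered the same way, iterating until every restart returns the
same partition (cap: 20 iterations; hitting the cap flags the result
rather than raising).  The stored matrix is always the first-round one,
computed on the original signed network — that is the matrix a network
figure should draw edges from.  The 0.40 threshold is used both inside
the consensus iteration and for such exports.

## Participant assignment and profiles

A participant belongs to the module containing the plurality of their
retained tokens.  Ties are broken toward the module whose member tokens
have the larger total corpus frequency — a module-level, data-driven
quantity — then toward the lower module id; both steps are deterministic.
Participants retaining no tokens stay unassigned and are excluded from
the contingency tables.

Emotion profiles count one unit per (participant, association mention,
retained label) triple and normalize within module to percentages.
Substance and behavior composition rows are normalized within substance
users and within behavior users respectively, so each row sums to 100
across modules.  Positive/negative affect shares aggregate the label
percentages through a configurable valence map (default: the standard
10/10 split of the 20-item schedule).

## Inference layer

* Module × misuse-type and module × intensity tables use Pearson's
  chi-square with no continuity correction; standardized residuals
  (O−E)/√E localize the deviations.  Intensity is dichotomized at the
  top response ("totally agree" = high; all else low).
* Per-label comparisons use tie-corrected Kruskal–Wallis H on
  per-participant label counts (the participant being the independent
  unit), with Dunn's pairwise z tests on pooled mid-ranks.  When every
  observation is identical the H statistic is undefined and the result
  is flagged rather than raised — this happens legitimately for rare
  labels.  Dunn p-values are unadjusted by default; Holm adjustment is
  available by flag.  The label comparison can be grouped either by
  module (df = k−1) or by misuse kind (df = 1); both groupings are
  exposed because either can be scientifically relevant.

## Synthetic generator

The generator emulates the survey's structure with planted truth:

* **Cohort**: default 546 participants over 4 latent modules with
  prevalence 0.35/0.21/0.29/0.15 and vocabularies of 26/19/17/15 tokens
  (77 total), keeping outputs dimensionally comparable to a realistic
  cohort of this design.
* **Tokens**: five distinct tokens per participant, drawn without
  replacement from a mixture putting weight `concentration` (default
  0.8) on the home module and the rest uniformly on the other modules;
  within-module popularity is Zipf with exponent 1, the canonical shape
  for word-frequency data.
* **Emotions**: two distinct labels per association from the
  distribution of the token's true module; 60% of each module's mass
  sits on six common labels with module-specific tilts, so exactly those
  six clear the 50% provision filter at realistic sizes.  Because the
  two labels are drawn without replacement, a label's expected share
  among recorded labels is its pair-inclusion probability halved, which
  slightly shrinks very concentrated labels relative to the per-draw
  distribution; tests compare against that closed form.
* **Category and intensity** follow the home module: the category base
  measure is a realistic substance/behavior mix, tilted per module by
  substance-odds factors 1.5/2.5/0.6/0.35 (extreme-module odds ratio
  ≈ 7), and the probability of a "totally agree" intensity response is
  0.66/0.74/0.60/0.60 by module.

What the generator does **not** emulate: real lexical surface forms and
synonym structure (tokens are synthetic identifiers; the merge map is
exercised with constructed cases), inter-individual vocabulary size
differences, and any coupling between emotion labels and the
*participant* beyond the token's module.  Passing recovery tests
therefore show the machinery is correct under the planted model, not
that real free associations satisfy that model.

### A calibration caveat

The survey design fixes exactly five distinct tokens per participant.
Even at the uniform-concentration baseline this induces a small negative
dependence between every token pair: with K = 5 draws from V tokens,
P(both) = (K/V)·((K−1)/(V−1)) < (K/V)², a joint-count deficit of about
1/K.  At n = 2000 participants and V = 77 this corresponds to a per-pair
noncentrality of roughly n/V² ≈ 0.34, which lifts the fraction of pairs
exceeding the χ²(1) 0.999 quantile from the nominal 0.001 to about
0.004–0.006.  This is a property of the design, not of the statistic:
on corpora with genuinely independent Bernoulli token inclusions the
G-statistic's exceedance rate sits at 0.001 (verified in the test
suite).  Analysts should expect the same mild baseline repulsion in real
fixed-quota association data.

## Problem sizes used in validation

The test suite validates the G-statistic exhaustively over all 2×2
tables with margins ≤ 20 against an explicit likelihood oracle (1e-9),
modularity over random ≤ 30-node graphs against a double-loop oracle
(1e-12), planted-partition recovery over 20 seeds at n = 600 with
4 × 20 tokens and concentration 0.9 (100 consensus runs, 40% threshold),
chi-square type-I error over 10,000 fixed-margin resamples, and
end-to-end power over 100 replicates at n = 500 under the default
module-category coupling (20 consensus runs per replicate, chosen so the
replicate loop stays light; recovery is already exact at that setting).
The acceptance script repeats the cohort-scale run and condensed
versions of these checks from a single command-line seed.

## Known limitations

* The Louvain optimizer is greedy; it carries no optimality guarantee,
  which is precisely why consensus clustering is the unit of inference.
* Dense matrices cap practical network size at a few thousand nodes —
  far above any free-association lexicon, but not suitable for generic
  large graphs.
* Merge maps are external input; the package deliberately performs no
  lemmatization, translation or synonym detection.
* Consensus may fail to converge on networks with genuinely ambiguous
  structure; the result is flagged (`converged=False`) and the modal
  partition of the final round is reported.
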