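# Methods

`specdelim` implements an integrative molecular species-delimitation
workflow of the kind used to dissect cryptic complexes of marine
invertebrates: specimens are sequenced for a mitochondrial barcode (COI)
and a nuclear marker (ITS2), candidate species are delimited
independently by statistical-parsimony networks, single-threshold GMYC
and posterior partition samples, and the candidates are reconciled by a
rule-based consensus into a final species hypothesis with explicit
uncertainty bounds.  This note records the models, the numerical choices,
and what the synthetic validation does and does not show.

## Registry accounting

The registry consumes one row per collecting site (region, coordinates,
depth range, sample size, clades sampled).  Species-level counting always
applies a *merge map* first — by default clades 20 and 28 count as the
single species "20/28", the final species concept for the packaged survey
— with clade-level counting available via `SpeciesMergeMap.identity()`.
Regions are read from an explicit column (they are oceanographic, not
geometric, divisions), depth ranges attach wholesale to every species at a
site (the source table's granularity), and dates stay text.  Species
rarefaction is analytic and exact for sampling without replacement:

    E[S_n] = sum_s ( 1 - C(N - N_s, n) / C(N, n) ),

computed with exact integer binomials, so the curve agrees with exhaustive
enumeration to floating-point round-off.

The packaged site table transcribes the published 133-site survey
(513 specimens, 8–4380 m).  Two statements in the survey's running text
disagree with its own table as printed (49 vs 46 multi-species sites;
"deeper than 200 m" vs one 190 m record for species 8); the package
follows the table and reports the table-derived values.  The packaged
specimen table is synthetic (no per-specimen list is published in
redistributable form): per-clade marker coverage was solved by integer
programming to match the printed coverage table column-for-column, and
specimens were assigned to sites by maximum flow against the site
capacities.  It supports the coverage-rule accounting (≥3 of 4 markers →
91 specimens) exactly; it does not carry real haplotypes.

## Haplotype workbench

Unique-haplotype collapsing uses exact symbol identity with gap and
missing characters treated as ordinary symbols (the behaviour of the
standard `uniqhaplo` script); a greedy wildcard mode exists but is off by
default because compatibility-based merging is order-dependent.  Flank
pruning trims leading and trailing columns containing `-`, `?` or `N` in
any retained row until both terminal columns are fully determinate —
interior columns (true indels) are never touched.  Ambiguity codes other
than `N` are kept: they are partially informative base calls.  A
`mode="auto"` policy replays the published alternative of dropping up to
*k* short sequences instead of pruning, keeping whichever choice retains
the most haplotypes (ties: fewer removals).  Coordinates are 0-based
half-open internally; reports print 1-based lengths.

## Distances

Uncorrected p-distances with pairwise deletion: the distance is the
fraction of differing sites among columns where **both** sequences carry a
determinate nucleotide (A/C/G/T); gaps, `?`, `N` and all IUPAC ambiguity
codes are uninformative.  A pair with no comparable columns is an error,
not zero.  Summaries report per-clade intraspecific ranges (NA for
singletons) and, per clade, the nearest neighbour (arg-min of the
between-clade minimum) with the (min, max) of the cross distances to that
neighbour — the "min–max (clade)" table convention.  Values are fractions
internally and percentages rounded to 0.1 in printed tables.

## Parsimony networks

Haplotypes are joined when their mutational step count (p-distance
numerator under the same pairwise-deletion rule, i.e. "gaps = missing")
does not exceed the connection limit; connected components are the
separate networks and hence the putative species.  Component membership is
decided entirely by the threshold graph; the per-component edge set is
then reduced to a minimum-spanning network in which *all* edges tied at
minimal weight are kept (network, not tree), and inferred intermediates
along multi-step edges are recorded for display only.

The connection limit is the largest step count j whose probability of
being fully parsimonious still reaches the configured confidence P
(default 0.95).  The original TCS program computes this probability from
its own implementation of the statistical-parsimony estimator; that
computation is not available as a published closed form, so this package
uses a calibrated per-step model: each additional step carries a
superimposition risk q = 5/(2m) for an m-column alignment, giving

    limit = max { j : (1 - q)^j >= P }.

The constant was calibrated against limits TCS prints for typical marker
lengths (13 steps at 658 columns, 9 at ~440) and the estimator is monotone
in m; for exact replay of a published limit, `fixed_limit` bypasses the
estimator entirely.  Published component counts should be reproduced with
`fixed_limit`, not the estimator, when the original alignment length is
uncertain.

## GMYC (single threshold)

An ultrametric gene tree is modelled as two branching regimes split at a
threshold time T.  During an inter-node interval with k species-level
lineages and n_j lineages inside putative species j, the total branching
rate is

    b = λ_y · k^{p_y} + λ_c · ( Σ_j n_j (n_j − 1) )^{p_c},

and the log-likelihood of the waiting times x_i between successive
branching events (conditioned on the root) is Σ ln b_i − Σ b_i x_i, with
the final interval contributing survival only.  The null model is the
single-regime case (one coalescent class spanning the tree).  T is
scanned exhaustively over the observed internal node heights plus the two
degenerate configurations (all-singleton and single-species); because the
single-species configuration is always a candidate, lnL_alt ≥ lnL_null by
construction.  Rates are optimized on (ln λ, p) with L-BFGS-B from three
deterministic multistarts, p bounded in [0.01, 3], moment-based initial
values, and entities are invariant to uniform branch-length rescaling.

The likelihood-ratio statistic 2(lnL_alt − lnL_null) is referred to a
χ² distribution; the degrees of freedom are not prescribed by the model
and default to 3 (extra rate, exponent, threshold), configurable.  On
single-species coalescent simulations the test is conservative (empirical
type-I error ≈ 0–4% at nominal 5%).

Node support averages over a four-member model-variant ensemble — both
exponents free, both fixed at 1, and the two mixed cases — weighted by
Akaike weights; a node's support is the weighted fraction of variants
whose ML threshold places a speciation event on it.  Entities re-form by
cutting only at nodes whose support reaches the cutoff (default 0.9), so
raising the cutoff can only merge entities.  Which variant set the
original analyses averaged over is not recoverable; the ensemble is
configurable.  GMYC is intended for unique-sequence trees: collapse
identical haplotypes before building the tree (the packaged pipeline does
so, using a UPGMA clock tree on p-distances when no externally built
ultrametric tree is supplied).

## Consensus

The mitochondrial network partition is the reference.  Conflicts raised by
the other partitions are adjudicated by ordered rules (defaults in
parentheses): R2 lumps a pair sharing a nuclear haplotype when both sides
are under-sampled (< 10 specimens) and their mitochondrial divergence is
within pooled intraspecific variation (< 4%); R3 rejects a split proposed
by a single method when its step distance is within the connection limit
and it lacks nuclear support; R4 keeps pairs separate on no-shared-nuclear
+ well-sampled grounds, on nuclear indel support, or on large
mitochondrial divergence (≥ 8%); R5 flags pairs whose smaller side has
fewer than 3 specimens as uncertain.  R5 is evaluated *before* the bare
distance clause of R4: a large distance resting on one or two specimens is
tentative, which is how sparse lineages are actually judged — without this
ordering the under-sampled clade triplet that generates the published
lower bound would be silently accepted.  The distance thresholds are
derived from the survey's printed extremes (max intra 3.4%, min inter
8.2%) and are configuration, not constants.

Every departure from the reference is logged with the rule and evidence;
replaying the log against the reference reconstructs the final partition
exactly.  Bounds: the lower bound applies all flagged lumps transitively;
the upper bound adds flagged (non-rejected) splits.  Posterior species
partitions (e.g. from a Bayesian multispecies-coalescent run) are consumed
only as partition samples and summarized as canonicalized relative
frequencies; the MCMC itself is out of scope.

## Synthetic data

The synthesizer emulates the survey's statistical structure: a Yule
species tree (default 0.3 speciations/lineage/My); multispecies Kingman
coalescent gene trees via msprime (haploid populations, mitochondrial
effective size ¼ of nuclear); strict-clock HKY sequences (κ = 4) at
0.011 substitutions/site/My per lineage — 2.2% pairwise divergence per
My, the standard invertebrate barcode calibration, whose log-normal prior
(log mean −4.466, log sd 0.075) spans 2.0–2.6%/My — for a 658-site
indel-free mitochondrial marker and a 360-site nuclear marker with a
branch-Poisson indel process (0.002 events/site/My, geometric lengths of
mean 3, insertions drawn i.i.d. and invariant afterwards); and specimen
metadata over ten named regions with overlapping species-specific
multinomial ranges and log-spaced overlapping depth bands, so sympatry
statistics are non-trivial.  θ is parameterized directly as the expected
within-species pairwise p-distance (default 0.008, matching the survey's
intraspecific ranges), giving haploid N = θ/(2·rate) in My units.

By default the species tree is rescaled, if necessary, so the shallowest
split is at least 1 My old (≈ 4.4% expected divergence).  This encodes the
study system's clear barcode gap (printed minimum interspecific distance
8.2% against maximum intraspecific 3.4%); it is the regime in which
threshold-based delimitation is expected to work, and recovery
experiments (TCS components = K; GMYC median |K̂ − K| ≤ 1 for K = 2..8)
are run under it.  What passing these tests shows is that the
implementation is correct under the model's own assumptions; it does not
show robustness to the things the generator omits — recombination,
selection, migration, alignment error, contamination, or rate variation
across lineages.

All randomness flows from one integer seed (numpy Generator; msprime and
dendropy seeds are derived integers below 2³¹), and identical seeds give
byte-identical output files.

## Problem sizes used in validation

The packaged validation runs at desk scale by design: five to eight
species with five or six specimens each for recovery experiments, 20
replicates per K for the recovery criterion, 50 single-species replicates
for the type-I error of the GMYC test, 100 random coalescent trees for
the likelihood-dominance property, and 200 haplotypes for the
network-component cross-check.  The survey-scale numbers (513 specimens,
28 clades) enter through the packaged printed tables rather than through
sequence downloads.

## Known limitations

- The connection-limit estimator is a calibrated surrogate for TCS's
  internal computation; exact reproduction of published limits requires
  `fixed_limit`.
- GMYC support ensembles are a design choice; absolute support values are
  comparable within this package, not across programs.
- The consensus rules reproduce published expert judgment on the packaged
  evidence; they are a codification, and new systems will likely need
  their thresholds revisited.
- Inserted nuclear-marker columns do not accumulate subsequent
  substitutions (a simplification of the indel process).
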