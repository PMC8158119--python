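# Methods

This note records the models, numerical conventions and design choices
behind `acunet`, and what its validation does and does not establish.

## The corpus and its fixture

The unit of data is a binary incidence matrix: rows are clinical studies
of acupuncture for poor ovarian response, columns are acupoints, a mark
means the study's prescription used the point.  The packaged corpus
(`acunet/data/table2.csv`) transcribes the published 13-study /
27-acupoint table cell by cell; it ships as a plain CSV asset rather than
code literals precisely so it can be audited against the printed source,
and a checksum test pins the transcription.  Study modality labels
(4 acupuncture, 5 electro-acupuncture, 4 transcutaneous electrical
acupoint stimulation) follow the table's column groups.  Column order is
the printed meridian row order — this matters (see tie-breaking below).

Screening arithmetic (`prisma_flow`) implements only the identity
`fulltext = identified − excluded_screening` and
`included = fulltext − excluded_fulltext` with non-negativity checks; the
literature search itself is out of scope.

## Co-occurrence proportions

The default edge weight is the *global* proportion p_ij = n_ij / N: the
fraction of all N studies using both points.  Two alternatives are kept as
modes because the literature is not always explicit about which
normalisation "proportion of co-occurrence" means: Jaccard
(n_ij over the union of the two study sets) and conditional-max
(n_ij over the rarer point's study count).  All modes satisfy
0 ≤ p ≤ 1 with p = 0 exactly when the points never co-occur; zero edges
are never materialized, isolated nodes are kept so downstream stages see
the full 27-point node set.

## Backbone extraction and tie-breaking

The backbone is the spanning forest minimising total dissimilarity
d = 1 − p, i.e. the maximum-weight spanning forest of p, via Kruskal's
algorithm with union-find.  A literal minimum-weight extraction
(`objective="min"`) exists for comparison but an association backbone
must keep the strongest co-occurrences.

Ties are ubiquitous here (every weight is a small multiple of 1/13), so
the tie rule decides the tree shape.  Edges of equal weight are taken in
the order of the graph's node list — for the packaged corpus, the printed
meridian row order (SP, CV, GV, ST, KI, LR, GB, BL, EX).  This is the
deterministic equivalent of what an input-order implementation does, and
it is the convention under which the corpus reproduces the published
three-community structure with hubs CV4, SP6 and SP10.  Under a
lexicographic-code tie rule the low-frequency points chain onto
alphabetically early codes (BL17, BL23) and the published hub structure
does not emerge; graphs whose node lists are constructed sorted get
lexicographic behaviour automatically.  A brute-force spanning-tree
enumeration oracle (≤ 8 nodes) resolves ties by the same rule and the
test suite checks exact edge-set agreement on random tied graphs.

## Communities, centralities, hubs

Modularity uses the standard Newman form with resolution γ (default 1)
and, on the backbone, edge weights — the backbone retains its surviving
proportions, so community structure should honour them.  Louvain is the
usual two-phase scheme (greedy local moves accepting the best positive
ΔQ, then aggregation, repeated to a fixed point).  The sweep order is the
node order by default, making the whole pipeline deterministic without a
seed; seeded-random order with restarts is available.  Against an
exhaustive maximum-modularity search (connected communities, ≤ 10 nodes)
Louvain lands within 0.05 of the optimum on ≥ 95% of random small graphs
and never exceeds it.

Betweenness is Brandes' accumulation; on the backbone it is computed
unweighted, which on a tree coincides with the weighted version (there is
exactly one path between any pair) — the equality is tested.  The
normalized value divides the raw pair count by (n−1)(n−2)/2.

Hub score = mean of min-max-normalized strength and normalized
betweenness, equal weights (no stated weighting exists; the combination
is configurable); a zero-range column contributes 0.5 to every node.
Default hub selection takes each community's best-scoring node, so the
hub count equals the community count; a global top-k mode exists.  The
five supplementary prescription points are expert-elicited input, shipped
as the `paper2021` configuration — expert elicitation has no computational
definition, so it is configuration, not computation.

### Sensitivity

The three-community / CV4-SP6-SP10 outcome holds at the shipped defaults
(global proportions, weighted Louvain at γ = 1, node-order ties).  It is
sensitive to the proportion mode (Jaccard fragments the network into five
communities), to the tie rule (above), and in principle to γ.  The test
suite regression-tests the default outcome so any configuration change
that breaks it is flagged.

## Trial statistics

*Exact Wilcoxon rank-sum.*  Mid-ranks for ties; the statistic is the
first sample's rank sum W.  The two-sided p sums the probabilities of all
C(n1+n2, n1) group assignments whose rank sum lies at least as far from
the null mean n1(N+1)/2 as observed — both tails by distance, not
doubling one tail, which stays well defined under asymmetric tied
distributions.  The distribution is computed by a subset-sum dynamic
program over doubled ranks (exact integer counts), memoized on the rank
multiset, and is verified against a full `itertools` enumeration oracle
for all pooled sizes ≤ 10.  Exact mode engages automatically up to pooled
size 20.  The normal approximation uses the tie-corrected variance and a
0.5 continuity correction (the convention of common commercial software;
both are switchable).

*Chi-square.*  Uncorrected Pearson statistic with 1 df; uncorrected is
the default because it reproduces the published fertilization-rate
p-values (0.8320, 0.4884, 0.6271) from the printed 2×2 counts to four
decimals, while the Yates correction would push these near-null tables to
p ≈ 1.  Margins must be positive.

*Regression.*  OLS via SVD least squares (`numpy.linalg.lstsq`), standard
errors from the unbiased residual variance, t-based p-values; rank
deficiency raises an error naming the collinear columns.  Cross-checked
against statsmodels and a derivative-free numeric minimiser; 95% CI
coverage is verified by simulation.

*Sample size.*  n = 2 (z_α/2 + z_β)² σ² / δ², ceiled, then inflated by
1/(1 − dropout) and ceiled again.  With the published inputs
(z = 1.96 / 0.8416, σ = 1.18, δ = 1.15) this gives 17 per group
unadjusted and 21-22 under conventional dropout inflations of 10-20%.
The source publication prints 23; no standard rounding path reaches that
figure from these inputs, so 17 is the package's reference value and the
discrepancy is simply noted.

## Synthetic trial generator

The generator emulates the *structure* of the published trial tables, not
any patient.  Defaults are the study's printed conditions: 10 vs 8
analyzed patients, per-arm age ~ N(40.0, 3.83²) / N(37.9, 3.87²), BMI and
infertility-duration distributions matched to printed means/SDs (gamma
for the right-skewed duration), prior COH cycles on 1..8 as a truncated
geometric with per-arm means near 3.9 / 3.4, AMH lognormal and AFC
rounded normal at printed levels.

Mature-oocyte counts are negative binomial (dispersion θ = 8 — printed
SDs ≈ means indicate only mild overdispersion once covariates vary) with
log mean

    η = β0 + β_arm·1[Ac+IVF] + β_cyc,IVF·cycles·1[IVF]
        + β_cyc,Ac·cycles·1[Ac+IVF] + β_age·(age − 40)

with β_cyc,IVF = −0.15, β_cyc,Ac = 0 (the published qualitative
contrast: the yield declines with repeated stimulation cycles only
without acupuncture) and β_age = −0.04.  β0 and β_arm are solved in
closed form (the lognormal moment of the age term and the exact sum over
the cycle pmf) so the expected arm means are exactly 1.30 and 2.75.
Fertilized counts are Binomial(mature, 0.9), matching printed
fertilization rates of ~87-92%.

Allocation uses permuted-block randomization (block 4) for the balanced
portion of the cohort; the excess of the larger arm is appended
afterwards, standing in for the differential post-randomization attrition
that produced the 10 vs 8 split (dropout itself is deliberately not
modeled).  A single seeded generator drives every draw, so identical
(config, seed) yields byte-identical CSV output.

Analysis intentionally runs OLS on the counts — as the original analysis
did — while generation is count-valued; the model mismatch is part of
what is being emulated.

**What passing tests show, and what they do not.**  The generator
reproduces printed margins and the arm-by-cycles interaction; it cannot
recover the unprinted joint distribution of age × cycles × outcome in the
real cohort, nor the actual per-patient values behind the published group
means, Wilcoxon p-values and regression lines.  Validation therefore
targets properties (oracle agreement, type-I error ≤ nominal,
slope-sign recovery at n = 500/arm) rather than those unpublishable
numbers.

## Problem sizes and numerical conventions

Stochastic validations use 10,000 null replicates for the exact-test
type-I error (n = 8 per arm), 100 random graphs apiece for the Kruskal,
betweenness and Louvain oracles (3-8 nodes, coarse weight grid so ties
occur), and 200 replicates at 500 patients/arm for slope-sign recovery —
sizes chosen so the whole suite completes in well under a minute while
the Monte-Carlo error of each rate stays below a percentage point or two.
Floating-point tie handling: the spanning-tree oracle quantizes total
weights to 9 decimals before comparing so summation order cannot flip a
tie; Dijkstra path counting treats lengths equal within 1e-15; Louvain
accepts moves only for gains above 1e-12.  Degenerate inputs (edgeless
graphs, empty samples, zero margins, zero-variance columns) raise typed
validation errors rather than returning NaN.

## Known limitations

- The corpus is small (13 studies) and the backbone is tie-dominated;
  conclusions about "the" network structure are conditional on the
  stated conventions, which is why they are explicit and tested.
- Exact rank-sum enumeration is exponential in spirit; the DP keeps it
  fast to pooled n ≈ 40, but the auto threshold stays at 20 to match
  common practice.
- The brute-force oracles refuse graphs beyond 8-10 nodes by design.
- No multiplicity adjustment is applied anywhere (none was applied in
  the emulated analysis); subgroup p-values are descriptive.
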