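# Methods

## The analysis pipeline

`amfdyn` analyzes sample-by-OTU read count tables from a paired
root/soil, multi-site, year-round sampling design. All statistics
operate on within-sample relative abundances (compositions); raw counts
are used only for detection (count > 0) and for alpha diversity.

**Rarity filter.** An OTU is discarded when its total read count over
all samples is below 10 *or* it is detected in fewer than 2 samples.
Both criteria are evaluated on the input table as one conjunction —
not sequentially — so the result is order-independent. Detection means
count > 0; no minimum-count detection floor is applied. If the filter
would empty a sample (possible only in degenerate tables), the pipeline
stops with an explicit error rather than silently dropping samples.

**Taxonomy rule.** For each OTU the best BLAST hit is the maximum by
(percent identity, query cover) with ties broken by subject identifier,
which makes the rule invariant to hit-row order. A taxon (the leading
token of the subject title, i.e. the genus) is assigned only when both
identity and cover are ≥ 95. The threshold is inclusive (≥, the
operational form used in practice even where prose says ">") and is a
parameter. OTUs whose qualifying hits are all titled "uncultured
Glomeromycotina" are labelled *uncultured*; OTUs with no qualifying hit
are *unclassified*. When an OTU has both uncultured and named
qualifying hits, the best *named* hit supplies the taxon.

**Group profiles and dominance.** Compositions are averaged, unweighted,
within each site × month × compartment group (12 groups for a six-month
site, 6 for a three-month site). An OTU's overall mean is the
unweighted mean over all group profiles and its site mean the mean over
that site's profiles; under a balanced design this equals the mean over
samples. OTUs are ranked by descending overall mean (ties broken by
OTU identifier). *Dominant* = site mean ≥ 1% at every site (the
threshold is a parameter; the rule is monotone in it). Per
site × compartment, an OTU is *persistent* when detected in every
sampled month, *seasonal* when detected in some but not all months,
*absent* otherwise; a `pooled` option merges detection across sites to
produce the single per-compartment label some summaries use.

**Co-dominance scan.** Given the ranked abundance vector x₁ ≥ x₂ ≥ …,
the deviation of candidate k is

    D(k) = Σ_{i≤k} (x_i − m_k)² + Σ_{i>k} x_i²

with the ideal share m_k = 1/k ("community" model: each co-dominant
holds an equal share of the whole community). The reported k minimizes
D, smallest k on ties; D(k) = 0 exactly when the community is k equal
shares summing to 1. Because the literature leaves the ideal profile
ambiguous, a second variant m_k = (Σ_{i≤k} x_i)/k ("topk": equal shares
of the top-k mass) is selectable by flag. On abundance structures like
the one simulated here the community model typically picks a k well
inside the dominant set; the scan reports the full curve so the choice
is inspectable.

**Univariate statistics.** Shannon diversity uses natural logarithms
(H′ = −Σ p ln p over nonzero proportions), the ecology default, so
H′ ≤ ln(richness). Normality (Shapiro–Wilk) and variance homogeneity
(Levene, mean-centered by default; median gives Brown–Forsythe) are
reported as prechecks next to each ANOVA rather than gating it — a
failed precheck flags the result but the parametric test still runs,
since the downstream decision belongs to the analyst. Tukey HSD
p-values come from the studentized range distribution; at k = 2 they
reduce exactly to the pooled-variance two-sample test (q = √2·|t|),
which the tests verify numerically. The compact letter display uses the
insert-and-absorb algorithm, letters ordered by descending group mean.
Diversity responses default to a two-way compartment × month model with
interaction; chemistry is compared one-way per site.

**PERMANOVA.** Distances are squared, Gower-centered, and partitioned
sequentially (Type-I) over the model terms, matching the adonis2
convention; pseudo-F per term uses the residual mean square of the full
model. p = (1 + #{F* ≥ F}) / (1 + n_perm) under whole-row label
permutation, with 999 permutations by default and an optional `strata`
column restricting permutation to blocks. On designs with n ≤ 9 an
exhaustive mode enumerates all n! arrangements and reports the exact
fraction (identity included). Permutation ties are compared with a
relative tolerance (10⁻⁹) so algebraically equal statistics count as
ties regardless of scale. Note that duplicating every sample leaves the
per-term R² invariant but rescales pseudo-F by the residual-df ratio —
R², not F, is the duplication-invariant quantity. Pairwise PERMANOVA
restricts the test to each level pair and adjusts p by Bonferroni
(default) or Benjamini–Hochberg.

**Mantel, RDA, NMDS.** The Mantel statistic is the Spearman correlation
of the two lower triangles, tested one-sided ("greater", the
conventional alternative for distance–distance association) by jointly
permuting one matrix's rows and columns; n = 5 admits exact enumeration
of all 120 permutations. RDA column-centers the composition matrix,
z-standardizes the environment matrix (with a condition-number guard
against collinearity), regresses Y on X and eigen-decomposes the fitted
values; axis shares are eigenvalues over total inertia (the vegan
convention — verified against vegan numerically), and constrained plus
unconstrained shares sum to 1. The overall model F is permutation
tested; a saturated (noiseless) fit is reported as F = ∞ with the
minimal attainable p. The per-OTU table gives the Spearman correlation
of each OTU with each environment variable with a permutation p (no
multiplicity adjustment unless requested, since how the original
analyses treated multiplicity is unknowable) and flags |r| ≥ 0.5.
NMDS minimizes Kruskal stress-1 by SMACOF majorization with isotonic
(monotone) regression, best of 20 seeded restarts by default; restarts
share one seeded stream, so more restarts can only improve the stress.

## The generator

The simulator draws a complete dataset — design grid, soil chemistry,
counts, taxonomy hits, truth labels — from a single seed, with one PRNG
sub-stream per sample (keyed by sample index) so partial regeneration
is reproducible.

*Design.* Two sites × 5 trees × 6 bimonthly months (May → March,
crossing the calendar-year boundary) × paired root+soil = 120 samples;
the `paper_design()` preset prunes site 2 to three months (May,
November, March), giving the 90-sample field layout.

*Soil chemistry.* pH, total C (%), total N (%) and total P (mg/kg) are
drawn per sample from positive-truncated normals around per-site ×
month means and SDs; the defaults are the published field measurements
of the two plantations the design mimics (e.g. site-1 May pH
4.74 ± 0.47). C/N is derived as TC/TN downstream. Months missing from
the published site-2 table fall back to the per-variable mean of its
measured months.

*Counts.* Each sample's expected composition starts from a fixed
baseline: 24 dominant OTUs with target proportions taken from the
published yearlong averages (0.184, 0.177, 0.046, …, summing to 0.840)
and a rare tail decaying as rank^−0.5 over the remaining mass, so the
largest tail OTU sits near 0.3% — clearly below the 1% dominance
threshold. On the log scale the baseline is perturbed by (i) a
compartment offset (±1.0 log-fold in root samples) for a designated
subset — mid-rank dominants in balanced +/− pairs plus rare-tail OTUs,
leaving the top-2 and the threshold-adjacent dominants neutral so the
designed means survive renormalization; the offset size was calibrated
so that the compartment term is detected essentially always at the
study's sample sizes, mirroring the sharp root/soil separation such
surveys report; and (ii) a pH response (slope ±1.0 per pH unit around
the site mean) for four designated OTUs, echoing the handful of
strongly pH-correlated taxa field data show. Seasonal OTUs (30 by
default, drawn from the top of the rare tail so they stay detectable)
are *structural* zeros: their proportion is forced to 0 in their
absence months and the vector renormalized. Counts are then
Dirichlet-multinomial: proportions × overdispersion θ (default 200, a
typical amplicon-scale concentration; θ = ∞ degrades to multinomial)
parameterize a Dirichlet draw, and the read depth is uniform on the
published per-sample range 3537–16435, since only the range is
reported. Row sums equal the drawn depths exactly.

*Truth labels.* Seasonality, pH response and compartment preference are
design facts and labelled directly. Dominance truth is computed from
the model's *exact* expected group compositions (evaluated at the
site × month mean pH): an OTU is truth-dominant when its minimum
expected site mean clears the threshold with margin (≥ 1.5×), truth
non-dominant when it falls clearly below (< 0.8×), and `None` inside
the band — at the study's sample sizes, an OTU sitting at the 1%
boundary has no unambiguous structural label, for the same reason
seasonality uses structural rather than sampling zeros. Recovery tests
therefore assert that every margin-clearing truth-dominant OTU is
flagged and every structural seasonal OTU classifies as seasonal;
behaviour exactly at the boundary is pinned by deterministic unit
tests instead.

*Taxonomy hits.* Each OTU receives a best hit that is below-threshold
(fraction ≈ 26/698), "uncultured Glomeromycotina" (≈ 75/698), or a
genus-labelled match drawn from a Glomus-dominated genus pool;
qualifying OTUs may get a weaker decoy hit so best-hit selection is
exercised.

## What the generator does and does not emulate

It reproduces the design's scale and balance, the published depth
range and chemistry distributions, a realistic rank-abundance shape
with designed dominance/seasonality/compartment/pH structure, and
enough Dirichlet overdispersion to make detection of rare OTUs
stochastic. It does **not** emulate tree-level random effects (samples
are independent given their design cell), spatial autocorrelation
within a site, phylogenetic signal among OTUs, chimeras or read-level
artefacts, or temporal autocorrelation beyond what the month-specific
chemistry means induce; the within-month between-tree variance is not
published, so θ is a free parameter rather than a calibrated one. The
designed pH coupling is deliberately strong so that recovery tests are
decisive; field Mantel correlations are typically far weaker. Passing
tests therefore demonstrate correctness of the *methods* under the
declared model, not effect sizes transferable to field data.

## Numerical choices and problem sizes

Permutation defaults: 999 permutations, observed arrangement included
in numerator and denominator, unrestricted row permutation (no strata)
unless requested. Ranking ties break by OTU identifier; best-hit ties
by subject identifier; co-dominance ties by smallest k — every
tie-break is deterministic. The dominance threshold (1%), taxonomy
threshold (95%), and correlation flag (0.5) are parameters with the
conventional defaults. Test-suite simulations use scaled problem
sizes — 200-OTU single-site datasets for the 100-replicate recovery
checks, 12-sample communities for the 500-replicate null calibrations,
the full 90-sample design for classifier-truth checks over five
seeds — chosen so the whole suite settles in about a minute while
leaving the statistical margins (≥ 90/100 detection, 3–7% type-I band)
comfortable. `scripts/acceptance.py` runs the full 90-sample design
with 499 permutations per test.

## Known limitations

Sequential (Type-I) PERMANOVA makes term order meaningful in unbalanced
designs; the acceptance script's term order (site, compartment, month)
mirrors the study's formula. The per-OTU environment correlations are
direct rank correlations — whether the original analyses used axis
scores or adjusted for multiplicity is not recoverable, so both are
options, not defaults. The NMDS stress surface is multimodal;
best-of-restarts with a seeded stream is reproducible but a different
restart budget can land elsewhere. RDA assumes linear responses on the
composition scale; no transformation (Hellinger etc.) is applied by
default.
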