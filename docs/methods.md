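# Methods

This note documents the models behind `subcellflow`, the defaults and why
they were chosen, what the simulator does and does not emulate, and the
numerical decisions that pin down exact behavior.

## Data model

A fractionation experiment is a feature × sample matrix of log2
intensities with missing values, where each sample is a (fraction,
condition, replicate) triple. The *experimental group* used for
filtering, missingness classification and testing is one
fraction × condition cell (its replicates); every preprocessing step
operates within one fraction at a time, because each fraction is an
independently acquired sub-experiment with its own bias structure.

Filtering retains a (feature, fraction) block when some condition group
in that fraction holds at least `min_valid = 3` observed values. Because
retention is per fraction, a protein can be quantifiable in FR1–2 and
absent from FR3–6; blocks that fail the filter stay missing and
contribute 0 to scaled profiles. After both imputation steps the matrix
is complete within retained blocks, and re-running imputation on a
complete table is the identity.

## Normalization

Cyclic loess against the row-mean reference: per fraction, each sample's
deviation from the per-feature mean over the fraction's samples is
smoothed against that mean with a lowess curve (span 0.7, fitted on
rows complete within the fraction) and subtracted; three iterations.
The span and iteration count are conventional values for
intensity-dependent bias removal and are config-exposed. Fractions with
fewer than 10 complete rows fall back to median centering with a
warning, since a trend cannot be estimated reliably there.
Normalization is applied jointly across conditions within a fraction
(config-switchable in spirit: run the function on condition subsets if
per-condition bias is suspected).

## Two-regime imputation

Missingness in DIA matrices has two natures, and each gets its own rule:

- **Partial (missing completely at random).** A cell missing while other
  replicates of its group are observed. Imputed, per fraction, as the
  plain average of the corresponding sample's values over the
  `k_neighbors = 10` nearest features under masked Euclidean distance on
  the fraction's columns (scikit-learn's KNNImputer). Euclidean distance
  on log2 rows matches features of similar abundance *and* shape, which
  is what makes plain neighbor averaging accurate (simulation tests hold
  the imputation RMSE under twice the measurement noise). With fewer
  complete neighbors than k, all available ones are used.
- **Absent (missing not at random).** A whole group missing — the
  protein was below detection in that compartment/condition. Every such
  cell in sample j is set to the `quantile = 0.025` quantile of sample
  j's observed values: a deterministic left-censored substitute. The
  quantile is computed by linear interpolation between order statistics
  (so observed values 1..100 impute 3.475), which is pinned to make the
  step bit-reproducible. Samples with fewer than 10 observed values
  cannot support a detection-limit estimate and raise.

Observed values are never altered by either step. The same
neighbor-average imputer is used for protein- and site-level matrices;
a regression-based variant for site-level data is a known alternative
and out of scope.

## Moderated testing

Two-group comparisons per fraction use empirical-Bayes variance
moderation. With per-feature residual variance s²_g on d_g df, the prior
(d₀, s₀²) is estimated by moment matching on log variances:
e_g = log s²_g − ψ(d_g/2) + log(d_g/2) has mean log s₀² + ψ(d₀/2) −
log(d₀/2) and excess variance ψ′(d₀/2); ψ′ is inverted by Newton
iteration. Then s²_post = (d₀s₀² + d_g s²_g)/(d₀+d_g), the moderated t
uses s_post, and the two-sided p comes from t with d₀+d_g df (capped at
the total df pooled across features). Non-positive excess variance means
no detectable heterogeneity and yields complete shrinkage (d₀ capped at
10⁶); degenerate inputs with fewer than two positive variances disable
moderation with a warning. A feature enters a contrast only when at
least one of the two groups originally held ≥ 3 observed values;
features with zero residual df in both groups are excluded and logged.
The implementation is checked against an independent reference
empirical-Bayes fit on a frozen 50-feature fixture to 1e-6 relative
error, and reduces exactly to the pooled two-sample t when d₀ = 0. No
intensity-dependent variance trend is modeled.

Benjamini-Hochberg correction is the standard step-up,
q_i = min_{j ≥ rank(i)} p_(j)·m/j capped at 1, applied across features
within each fraction (for differential tables) or within each time point
(for combined translocation p-values, matching one test family per
time-point-versus-control comparison).

## Movement score

Profiles are scaled per replicate (de-logged intensities divided by the
feature's total over fractions; missing fractions count 0) and averaged
over replicates per condition. Against the reference condition,
Δ_f = s_f(t) − s_f(ref); the acceptor is argmax Δ, the donor argmin Δ
(ties broken toward the lowest fraction index), and

    M = (Δ_acceptor + |Δ_donor|) / 2.

For a clean two-fraction move M equals the moved mass exactly; for
multi-fraction redistribution it is a lower bound, which keeps the score
conservative. An alternative M = Σ|Δ|/2 (total redistributed mass) is
available via `variant="total"`. M ∈ [0,1]; M = 1 only for a complete
one-hot-to-one-hot move; swapping the two profiles preserves M and swaps
donor with acceptor.

A genuine translocation must change abundance in *both* fractions, so
the per-fraction moderated-t p-values of donor and acceptor (computed on
normalized log2 intensities, not on scaled profiles) are combined with
Fisher's method, X² = −2(ln p_d + ln p_a) on 4 df, with p floored at
1e-300. Calls require M strictly above `score_min = 0.1` (10% of the
profile moved) and BH-corrected combined p below `fdr_max = 0.05`.
Features lacking a donor or acceptor p-value are excluded from calling,
never imputed. BH is applied after Fisher combination, per time point.
Moves are categorized by the neighborhood grouping cytosol (FR1–2),
membrane organelles (FR3–4), nuclear (FR5–6); the grouping is
configurable for other fraction counts.

## Compartment assignment

Profiles are max-normalized (each feature divided by its peak fraction),
clustered by Euclidean k-means (default k = 2 × number of compartments,
25 restarts, seeded — k is deliberately larger than the compartment
count so mixed-location groups can separate), and each cluster is
assigned to the location with the most markers in it. Ties and
marker-free clusters remain unassigned rather than guessed. Cluster
precision is the share of the cluster's markers belonging to the
assigned location. Per compartment, recall = markers of the location
assigned correctly / all its markers, precision = markers assigned
correctly / all markers assigned to the location, F = harmonic mean
(0 when P + R = 0). Marker bookkeeping pools markers across clusters
mapping to the same location. Report values are *truncated*, not
rounded, to two decimals (2/3 prints as 0.66), with full precision kept
alongside. Note the field's worked examples describe the
fraction-of-markers-correct statistic (recall under the confusion-matrix
convention) by the word "precision"; both columns are reported.
Marker-centroid correlation is the Pearson r of each marker's scaled
profile to its compartment centroid (mean profile over the compartment's
markers, self included); zero-variance profiles are flagged undefined.

## Group distributions

For a protein group, percentage_f = 100 × Σ_members intensity_f /
Σ_members Σ_f intensity_f per replicate × condition (rows sum to 100;
members missing in a fraction contribute 0 there). Shifts in one
fraction between conditions are tested with a two-sided paired t-test
across replicates (df = pairs − 1); zero-variance nonzero differences
are flagged rather than assigned a p-value.

## The simulator

`simulate` generates ground-truth datasets: each feature gets a
compartment template (default: six profiles with 85% of mass in one
fraction and 15% spilling into the adjacent one — single-niche-dominant
shapes that are realistic yet analytically tractable), a base abundance
drawn log-uniform over 20–30 log2 units (the dynamic range of deep MS
data without extreme tails), and Gaussian log2 noise (default sd 0.3).
A configurable proportion of features (default 5%) moves a uniform
delta ∈ [0.2, 0.4] of profile mass from its dominant fraction to a
random other fraction at and after an onset condition. True zero
proportions are emitted as missing, matching how search engines report
non-detection. Dropout is mcar + (1−mcar)·logistic(−slope·(x−midpoint)):
a 2% completely-at-random floor plus an intensity-dependent censoring
term (midpoint 18, slope 1 per log2 unit — cells near the bottom of the
simulated intensity range are preferentially lost). The per-cell dropout
regime is recorded for test assertions.

What the simulator does **not** emulate: batch/replicate effects beyond
i.i.d. noise, peptide-level rollup and site-localization uncertainty,
correlated noise between fractions, multi-compartment residency, and
the exact cross-fraction identification-overlap structure of real data
(spillover plus missingness only approximates it). Passing recovery
tests therefore demonstrate correctness of the statistical machinery
under the stated generative model, not performance guarantees on any
real dataset.

Recovery under the default conditions (1000 features, 6 fractions, 4
replicates, control + stimulated, 5% translocators, noise sd 0.3, both
dropout regimes) is part of the test suite: averaged over 10 seeds the
caller must recover ≥ 80% of injected translocators with empirical FDR
≤ 0.10, and null simulations must keep the type-I error at 0.05 ± 0.02.
The two-condition design is the minimal time course the caller needs;
longer courses reuse the identical machinery per time point. Problem
sizes in tests (a few hundred to a few thousand features, ≤ 20 null
replications) are chosen to exercise the asymptotics the estimators rely
on while keeping the suite quick to run.

## Numerical and design decisions

- Fraction indices are 1-based everywhere (FR1..FR6), matching how
  fractionation protocols label extracts.
- Missing values are empty TSV fields on write; "NA" also accepted on
  read. Floats are written as %.17g so round-trips are bit-exact.
- Donor/acceptor ties resolve to the lowest fraction index;
  marker-vote ties leave the cluster unassigned; contrasts are each
  time point versus the reference condition (not sequential).
- Seeds control the simulator, k-means restarts and nothing else; two
  runs with identical config and seed produce byte-identical outputs
  and manifests.
- Known limitations: no multi-compartment (mixed-profile) modeling, no
  batch correction, no variance-trend moderation, no site-to-protein
  aggregation. These are out of scope by design.
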