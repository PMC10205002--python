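# Methods

## The model

All statistics condition on a rooted phylogeny with branch lengths. Traits
are assumed to evolve by Brownian motion (BM): for any trait, the vector of
species values is multivariate normal with covariance proportional to
**C**, where **C**ᵢⱼ is the branch length shared by species *i* and *j* on
their paths from the root and **C**ᵢᵢ is the root-to-tip distance. The root
stem, when present in the Newick input, is excluded, so the clock starts at
the root split. Trees need not be ultrametric and are never rescaled.

Every estimator works in "whitened" space: data are centred at the
generalized-least-squares mean **a** = (1ᵀ**C**⁻¹1)⁻¹1ᵀ**C**⁻¹**Y** (the BM
estimate of the root state) and premultiplied by **E** = **C**^(−1/2),
computed as the symmetric inverse square root from the eigendecomposition.
The symmetric root (rather than a Cholesky factor) is the convention in the
geometric-morphometrics tooling this pipeline mirrors; it makes **E**
symmetric and basis-independent. Eigenvalues below 1e−12 of the largest are
treated as singular and raise an error rather than being regularized.

### Two-block PLS

Given blocks X₁ (n×p₁) and X₂ (n×p₂), the transformed blocks X̃ⱼ =
**E**(Xⱼ − 1**a**ⱼ) define the cross-covariance R₁₂ = X̃₁ᵀX̃₂/(n−1); the
first singular vectors u, v give scores s₁ = X̃₁u, s₂ = X̃₂v and the
statistic r_PLS = |cor(s₁, s₂)|. The (n−1) scaling cancels in r_PLS and is
fixed only so intermediates are reproducible. Only the first axis is
interpreted; v is sign-flipped so the score correlation is nonnegative.
Because only R₁₂ (p₁×p₂) is decomposed, p ≫ n blocks (300 profile bins vs
36 species) are handled without large intermediates.

Significance: the rows of X̃₂ are permuted (the whitener and phylogenetic
mean stay fixed — permutation breaks the trait association, not the
phylogenetic structure), r is recomputed for each of m permutations, and
p = (1 + #{r_perm ≥ r_obs})/(m + 1), ties counting as exceedances. The
alternative scheme (permuting raw rows and re-estimating the mean each
draw) is deliberately not used; the chosen scheme is the standard
residual-randomization style null for transformed data and is fixed so any
cross-software discrepancy can be localized. Rows of the centred block are
exchangeable only up to the one degree of freedom absorbed by the mean,
which makes the test very slightly conservative at small n; measured type-I
error at n = 36 sits at the lower edge of the nominal band.

### Phylogenetic regression with RRPP

The multivariate regression fits Ỹ = **E**Y on X̃ = **E**[1 | X] by
ordinary least squares in transformed space (equivalently GLS in species
space; the coefficients apply directly on the untransformed design scale).
Each predictor's marginal (type III) sum of squares is the RSS increase
when that column alone is dropped; pseudo-F = (SSₖ/dfₖ)/(RSS_full/df_res)
with df_res = n − k − 1. For a univariate response with **C** = **I** this
is exactly the classical partial F.

Significance by RRPP: for each term, the reduced (term-dropped) model's
residual rows are permuted and added back to its fitted values, the full
and reduced models are refit, and pseudo-F recomputed; p is the usual
(b+1)/(m+1). Reduced-model (not full-model) residuals are the standard
choice for marginal tests. One permutation-index stream per seed is shared
across terms so term p-values are comparable within a run. A perfect fit
(RSS ≈ 0 relative to the response scale) reports infinite pseudo-F and the
minimal attainable p rather than failing.

Reading the table: each term's `p_perm` is a single-test p-value, the way a
published ANOVA table is conventionally read (the default significance rule
in the pipeline, alpha = 0.05 raw). When the scientific claim is that *one
particular* predictor is the unique significant one among the eight
scanned, `AnovaTable.significant_terms(adjust="holm")` applies Holm
step-down familywise control; the known-truth recovery test uses that rule,
since with seven null predictors the raw rule alone flags a false positive
in roughly 1 − 0.95⁷ ≈ 30% of datasets no matter how well calibrated each
test is.

Predicted profiles along one compound's gradient hold every other
predictor at its GLS mean. Responsive regions are maximal runs of at least
`min_run` (default 2) consecutive bins whose predicted change Δ reaches
`frac_of_max` (default 0.5) of max Δ — an explicit formalization of what is
usually judged visually from predicted-profile overlays. kDa bounds come
from a user-supplied bin → kDa calibration; the built-in default is a
synthetic log-linear map from 260 to 3.5 kDa across the 300 bins (migration
distance is roughly linear in log molecular weight) and should be replaced
by a measured calibration whenever one exists.

### Profile complexity

Peak richness uses a strict sliding-window local-maximum rule (window 3,
truncated at the edges; the first and last bins are never peaks; plateaus
yield none) followed by the 10%-of-tallest-peak filter, where "tallest"
means the tallest *detected candidate*, which coincides with the tallest
bin whenever that bin is itself a peak. Entropy is −Σ pᵢ ln pᵢ in nats with
0·ln 0 = 0; the conventional minus sign is used so that entropy increases
with evenness and can serve as a complexity index (a signless Σ p ln p is
nonpositive and orders profiles backwards). Both the window width, the
height threshold and the number of bins (default 300) are configuration,
not constants.

### Compositional treatment

Profiles, the class table and the closed compound table are CLR-transformed
before any covariance/regression step; richness and entropy indices stay on
their original scale. The compound matrix is closed (normalized to sum to
one) before CLR when used as a PLS block, and used as absolute abundances
when it is the regression design — both framings are exposed
(`response_transform` / `predictor_transform` in `RunConfig`) because both
are defensible and the published description supports each in a different
stage. Zeros are replaced multiplicatively: zeros become δ and positive
parts are scaled by (1 − k·δ), preserving within-row ratios; δ defaults to
half the smallest positive entry of the matrix — deterministic and smaller
than anything observed. The choice is logged in the run manifest; natural
logarithms are used throughout.

## Synthetic data

`simulate_epg_dataset` emulates the study's shapes: a Yule (pure-birth)
tree with 36 tips (crown start, exponential waiting times, terminal edges
extended past the last split so no branch is zero); compound abundances as
exp of latent BM (positive, log-normal marginals, scale `compound_sd`
= 0.5); a latent CLR-scale profile as BM baseline (`profile_sd` = 0.5)
plus iid within-species noise (`noise_sd`, default 0.25); an optional
shared latent BM factor entering both blocks with weight `rho` (default
0.5); and a known effect, `beta` (default 2 CLR units per unit abundance)
times the abundance of compound 1, added to `effect_bins` (default 40–45)
before the latent profile is mapped to the simplex. The class table is a
neutral folded-normal closure. Lipid richness counts compounds above a
detection floor (`detection_limit` = 1, the median of the log-normal
marginals) because exponentiated BM is never exactly zero; entropy uses the
closed compound row. Every generator is a pure function of (config, seed);
stage seeds are spawned from the single dataset seed via
`numpy.random.SeedSequence`.

What the generator does *not* emulate: band-like spatial autocorrelation
along the profile (real electropherograms are smooth, so synthetic peak
richness is noise-driven and runs higher than real gels), realistic
chromatographic noise, measurement error on the tree, and non-BM
evolutionary modes. Passing tests therefore demonstrate correctness of the
estimators and calibration of the permutation procedures under the model's
own assumptions, not robustness to violations of them.

## Numerical choices

Designs are projected with thin-QR residual makers; permutations are
processed in batches of 256 with batched SVDs/matrix products to bound
memory; CLR inverse subtracts the row maximum before exponentiating so
extreme coordinates cannot overflow; rank deficiency, singular covariances,
species mismatches, negative compositions and all-zero rows are distinct
named errors, never silent fixes. Experiment sizes in the test suite (e.g.
200 replicate datasets at 499 permutations for calibration; 50 replicates
at 799 permutations for recovery) were chosen to keep Monte-Carlo error
comfortably below the widths of the assertion bands.

## Real-data benchmark layout

To run the published-table benchmark, place under `data/real/`: `tree.nwk`
(rooted Newick, branch lengths, tip labels matching the tables' species
column), `epg.csv` (species × 300 bins, rows summing to 1), `classes.csv`
(species × 11 class proportions), `compounds.csv` (species × 8 absolute
abundances; columns named `cholesterol`, `campesterol`, `stigmasterol`,
`ergosterol`, `linoleic_acid`, `vitamin_E`, `cholestanol`,
`provitamin_D3`), and `complexity.csv` (species × `R_P,H_P,R_L,H_L`). The
benchmark test then refits the multivariate regression (9999 permutations)
and compares the pseudo-F table and the two complexity regressions against
the published values.

## Known limitations

* BM is the only trait model (no Ornstein–Uhlenbeck, early-burst, or
  λ-rescaling); this matches the analysis being reproduced.
* Only the first PLS axis is tested; later axes are exposed unvalidated.
* The permutation schemes are fixed (documented above); other software may
  permute raw rows and differ slightly in p at small n.
* The unique-predictor recovery rate is bounded by the simulation itself:
  in a few percent of replicates the focal compound's exp(BM) abundance is
  nearly constant across species, and no method can detect an effect of a
  near-constant predictor.
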