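# Methods

This note documents the models, the defaults and why they were chosen, what
the synthetic trials do and do not emulate, and the numerical decisions inside
the estimators.

## Per-flight variance components

Each flight of each harvest cycle is analyzed with the genotype-random plot
model `y = 1μ + Xb + Zg + e` with replicate fixed (cell coding; the intercept
is absorbed into the replicate effects) and iid genetic and residual terms.
Heritability is reported as plot-level broad sense,
`H² = σ²_g/(σ²_g + σ²_e)`; no pedigree or marker information enters, so no
narrow-sense decomposition is attempted. `H²` is undefined (NaN, never a
silent zero) when the total variance is zero.

The bivariate model for the genetic correlation of an index with forage yield
stacks the two traits observed on the same plots, with an unstructured 2×2
genetic covariance `Σ ⊗ I` and an unstructured 2×2 residual covariance per
plot. Because the pairing is complete and both traits share the replicate
design, the marginal covariance is `Σ ⊗ ZZ' + R₀ ⊗ I`; on the eigenbasis of
`ZZ'` the restricted likelihood factors into 2×2 blocks and is maximized
directly over Cholesky-parameterized `Σ` and `R₀` (Nelder–Mead, two starts:
a moment start from genotype means/residuals and a neutral split). This
direct maximizer is deliberately a different algorithm from the EM/AI engine
used everywhere else, so the two REML paths cross-check each other in the
tests. The genetic correlation is undefined (NaN with an explanatory
property) when either genetic variance is at the zero boundary.

## The REML engine

The single-trait and random-regression models are fitted by one dense engine
on Henderson's mixed-model equations supporting any number of random terms,
each with `q` levels carrying `m` coefficients of shared unstructured
covariance `K` (`m = 1` recovers the scalar case), and a diagonal residual
(homogeneous or grouped by time point).

Each iteration computes the exact EM-REML update (monotone in the restricted
log-likelihood) and, after 3 warm-up EM steps, an average-information Newton
proposal with step-halving; the proposal with the higher restricted
log-likelihood is accepted, so the accepted path is never below the EM path —
monotonicity is preserved while convergence typically takes ~10 iterations
instead of hundreds. Convergence is declared at a relative log-likelihood
change below 1e-8 or a relative parameter change below 1e-6 (500 iterations
maximum); non-convergence is flagged on the result, never raised.

Covariance matrices are kept positive semidefinite by eigenvalue clipping
("bending") at a floor of 1e-8 after every update, with the number of clips
recorded in the fit. Residual variances are floored at 1e-12, which makes the
degenerate constant-response input return both components at the zero
boundary without failure. When the REML optimum lies on the PSD boundary
(singular `K`), any constrained iteration crawls along the boundary ridge and
the parameter-change criterion stops it there; the fitted covariance
functions are insensitive to the position along such ridges, but exact
parameter equivalence with other optimizers holds only at interior optima.

A rank-deficient fixed design raises immediately, naming the aliased columns
found by pivoted QR.

## Random regression

The growth model uses normalized (orthonormal) Legendre polynomials
`φ_k(t*) = sqrt((2k+1)/2) P_k(t*)` on `t* ∈ [−1, 1]`; "third order" means
polynomial degree 3, i.e. 4 coefficients. Orthonormality makes coefficient
covariances comparable across orders; plain `P_k` is available by
configuration. Time is cumulative growing degree days within the harvest
cycle, `max(0, (T_max + T_min)/2 − T_base)` per day with `T_base = 4` °C;
clamping negative increments at zero is the agronomic convention and is a
flag (default on). Standardization uses the min/max GDD of the observed
flights, extended to the harvest GDD when the terminal yield point is
appended.

Fixed effects are replicate × time-point cells (no smooth fixed time
trajectory): with many flights per cycle the cell means absorb any common
trend, and block effects have no trend of interest. Genetic and
permanent-environment terms use the same basis order by default
(independently configurable). The permanent-environment effect is drawn and
fitted per plot (genotype × replicate), the repeated unit across flights
within a cycle; a per-accession alternative would not be identifiable in a
single-trial fit alongside the genetic term. Each harvest cycle is fitted
separately; no cross-cutting covariance is modeled.

Terminal yield is appended as an extra time point at the harvest GDD after
multiplying by `sd(last-flight VI)/sd(yield)`, which matches its variance to
the adjacent index observation (rankings and correlations are unaffected by
the positive scaling). The yield rows form their own replicate × time cell
even when the harvest GDD coincides with the last flight.

The residual is homogeneous across time points by default (parsimony; a
heterogeneous structure is not identifiable enough to be a safe default —
per-time-point variances at the domain edges trade off against the plot-level
curves, and the edge groups can collapse toward zero). The per-time-point
option exists and warns when any time point has fewer than `2(order+1)`
records.

Derived quantities: covariance surfaces `φ(t)ᵀKφ(s)` (with an extrapolation
warning outside the standardized domain), genetic correlation curves
`r(t, T) = Cov(t, T)/sqrt(Var(t)Var(T))` (NaN where the genetic variance
vanishes, clipped to [−1, 1] only against roundoff), heritability
trajectories `H²(t) = V_g(t)/(V_g(t) + V_p(t) + σ²_e)`, and breeding-value
growth curves `φ(t)ᵀû_j` with top/bottom-decile flags from the terminal
breeding value.

## Stability

GGE: the genotype × environment mean-yield matrix is centered by environment
means and decomposed by SVD with genotype-focused scaling (the full singular
values go into the genotype scores; environments keep unit scale). Sign
conventions are fixed so results are deterministic: PC1 is oriented so the
mean environment score is positive (the average-environment axis points
toward higher mean yield), PC2 so the first genotype's score is
non-negative. Mean performance is the projection on the average-environment
axis; instability is the signed perpendicular projection. When the centered
matrix is rank 1 (purely additive data) there is no second dimension and the
stability projection is identically zero. Mean-vs-stability labels use median
splits by default, with thresholds configurable.

Growth-curve stability: genetic effects are evaluated at five evenly spaced
standardized time points (the default grid; configurable), z-scored across
cultivars within each cutting (unit variance, so the statistic is invariant
to affine rescaling of the raw index units), deviated from each cultivar's
own cross-cutting mean, and summarized as the SD across cuttings — per time
point and averaged. The same construction applies to per-cutting yield
BLUPs. Cultivars missing from any cutting are excluded and listed.

RSE is `sqrt(h²_VI/h²_FY)·r_g`, scale-invariant in the heritabilities, NaN
when the yield heritability is zero.

## Synthetic trials

The generator draws exactly the structure the estimators assume: an RCBD of
(by default) 36 cultivars × 5 replicates — the scale of a northeastern US
alfalfa cultivar trial — with 3 harvest cycles and 7 flights per cycle on a
GDD grid spanning roughly 80–560 °C·day per cycle (weekly flights over
temperate regrowth cycles). Default generating parameters:
`K_g = diag(1.0, 0.5, 0.2, 0.1)` (genetic signal concentrated in curve level
and slope), `K_p = 0.2 I₄`, `σ²_e = 0.5`, replicate-within-time effects with
SD 0.05 — together giving late-cycle plot heritability near 0.5, the moderate
regime such trials report. Values are in arbitrary index units; all
downstream statistics are scale-free or reported in the same units.

One master seed spawns independent named streams (genetic, instability,
permanent-environment, residual, fixed, yield), so zeroing one component does
not perturb the draws of the others, and identical seeds give byte-identical
tables.

Cross-cutting instability: cutting-specific genetic coefficients are
`u_jh = u_j + s_j η_jh` with `η` drawn from `K_g` and `s_j` a per-cultivar
instability SD (default 0). Terminal yield per plot and cutting is the plot's
curve value at the harvest GDD (genetic plus permanent-environment
contribution, for model consistency) plus fresh noise with SD `σ_e` by
default; the harvest GDD defaults to the last flight GDD (flights within
days of cutting, as late-season UAV campaigns are flown).

What the generator does not emulate: spatial field trend and neighbor
effects, radiometric/calibration error in the bands, missing flights or
unequal flight grids between replicates, augmented (unreplicated) designs,
and cross-cutting genetic covariance beyond the common-plus-deviation
structure. Passing recovery tests therefore demonstrates correctness of the
estimators under the stated model, not robustness to those field realities.

The Monte-Carlo problem sizes used by the statistical tests (200 seeds at
36 × 5 for the scalar models, 100 seeds at 36 × 5 × 8 flights for the random
regression, 100 seeds at 24 cultivars × 5 cuttings for the stability
correspondence) were chosen to keep the Monte-Carlo standard error of each
checked mean well below the tolerance it is checked against.

## Known limitations

- Boundary (singular-`K`) REML optima are reached only up to the bending
  floor; ridge positions may differ between optimizers (see above).
- The bivariate fitter requires complete trait pairs and drops incomplete
  plots.
- The growth-stability statistic inherits the noise of per-cutting BLUPs;
  with few replicates the SD of a perfectly stable cultivar is dominated by
  estimation noise, which attenuates rank correlations between growth- and
  yield-based instability.
- No spline bases, no multi-trait random regression across indices, no AMMI
  or which-won-where GGE views, no genomic relationship matrices, and no
  spatial correction.
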