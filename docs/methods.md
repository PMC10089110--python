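# Methods

This note documents the models behind `netcog`, the defaults and why they
were chosen, what the synthetic cohort does and does not emulate, and the
numerical decisions a user extending the package should know about.

## Latent network model

Each resting-state network with `n` subnetworks is modelled as a
multivariate Ornstein–Uhlenbeck (OU) process

    dx = A x dt + dW,    Cov(dW) = Q dt,

where `A` (Hz) is the effective-connectivity rate matrix: entry `A[t, s]`
is the influence of source `s` on target `t`. Self-connections are
parametrized in log-scaling space, `A_ii = −0.5·exp(a_ii)`, around an
inhibitory −0.5 Hz prior; this guarantees negative diagonals for any
finite `a_ii` and gives `a_ii` the interpretation of regional
excitability (more negative effective rate = more self-inhibited, less
excitable). Stability means every eigenvalue of `A` has negative real
part, and the stationary covariance solves `A Σ∞ + Σ∞ Aᵀ + Q = 0`.

Timeseries are sampled by **exact discretization**: `x_{k+1} = F x_k +
w_k` with `F = exp(A·dt)` and `Cov(w_k) = Σ∞ − F Σ∞ Fᵀ`, initial state
drawn from the stationary law. Exactness (rather than Euler stepping)
removes step-size bias, so the long-run sample covariance converges to
the Lyapunov solution in expectation at any `dt` — this is what makes the
covariance fidelity checks sharp.

The model is deliberately *neuronal-only*: there is no hemodynamic
convolution, scanner noise, or head motion. Spectral fits on synthetic
data therefore reach R² values that should not be compared to fits of
real BOLD cross-spectra.

## Cross-spectral modelling

The cross-spectral density of the stable network driven by stationary
noise with spectrum `G_v(ω) = α ω^(−β) I` is

    G(ω) = (iωI − A)⁻¹ G_v(ω) (iωI − A)⁻ᴴ,    ω = 2πf.

`β = 0` recovers white noise; `ω = 0` is excluded from every grid so
power-law spectra stay finite. The default analysis grid is 32
geometrically spaced frequencies from the fundamental `1/(N·dt)` to 80%
of Nyquist.

Empirical cross-spectra are estimated by OLS-fitted VAR(p) models
(default order 8, a common choice for spectral analyses of fMRI-like
series; configurable). The VAR spectrum `H(θ) Σ_res H(θ)ᴴ` is multiplied
by `dt` to convert the discrete-sample spectrum to the continuous-process
scale, so estimates are directly comparable with the forward model; the
scalar OU/AR(1) pair verifies this factor analytically. Aliasing of the
`1/ω²` tail beyond Nyquist is the dominant estimation bias at coarse
`dt`; the consistency tests therefore use `dt` small relative to the
network time constants.

The **inversion** is penalized least squares on the stacked real and
imaginary parts of all unique spectral entries:

    min_θ  Σ_ω ‖G_pred(ω; θ) − G_obs(ω)‖²_F + λ‖θ − θ_prior‖²,

over extrinsic rates (prior 0), diagonal log-scalings (prior 0, i.e.
−0.5 Hz), log-amplitude and exponent of the noise spectrum. Defaults:
λ = 0.1 (small relative to the data term's curvature, so the noiseless
round trip recovers parameters to well under 0.01 Hz), L-BFGS-B with 5
starts (the first at the prior, the rest randomized from a fixed seed),
and a post-hoc shrinkage of extrinsic entries in the rare case the
optimum is unstable. The inversion is a desk-scale tool (n ≤ 16): it has
no variational free energy, no model comparison, and no hemodynamic
parameters. Goodness of fit is `R² = 1 − SS_res/SS_tot` over all real and
imaginary components of the unique entries, with the grand component mean
as baseline — exactly 1 for a perfect fit, 0 for predicting the mean.

## Synthetic cohort

The generator's defaults mirror the two-group resting-state study design
the pipeline targets: 74 controls and 66 patients; 145 timepoints at
`dt = 2 s`; 7 networks of 4, 2, 8, 10, 14, 9 and 3 subnetworks (50
parcels, 470 directed EC parameters); age ~ N(37, 12²) truncated to
[18, 65]; gender proportions per group matching typical reported cohorts;
antipsychotic dose (chlorpromazine equivalents) lognormal for patients
(median ≈ 280 mg/day, consistent with reported 363 ± 305), zero for
controls.

Per network, group-mean extrinsic couplings are drawn with SD
`0.3/√n` Hz — the `1/√n` scaling keeps the coupling's spectral radius
below the −0.5 Hz self-inhibition for every network size, so stability
holds with high probability and the rejection/shrinkage safeguard is
rarely exercised. Between-subject variability is Gaussian with SD
0.05 Hz on extrinsic entries (0.05 in log-scaling units on diagonals).
No between-subject EC variance is reported for real cohorts; this value
was chosen once to give realistic single-connection z-scores at the
default sample sizes and is not tuned thereafter. Group differences of
`diff_effect = 0.2` Hz (SZ−HC) are planted on a seeded random 20% of
extrinsic connections per network, sign-balanced so alterations are
bidirectional ("aberrant, not merely reduced"). First-level estimation is
emulated by adding N(0, 0.01²) noise to the true EC and reporting that
variance as the posterior variance (floor 1e−8) — a stand-in for a full
generative-model inversion that preserves exactly the information the
group stage consumes: means and uncertainties.

Cognitive scores: seven domains plus a composite defined as the
cohort-standardized sum (a zero-variance sum standardizes to zeros).
Patients receive a −1 SD mean deficit in every domain, the canonical
magnitude for this population. An optional low-rank brain-behavior link
injects a latent variate `z` — the equal-weight (1/√k) combination of the
z-scored planted EC parameters — into each planted domain with loading
`c = ρ/√(k − (k−1)ρ²)`, which makes the *population* first canonical
correlation between the planted sets exactly `ρ`. Equal weights ensure
every planted parameter carries the same signal, so recovery statements
are statements about the pipeline rather than about a random weight draw.

Randomness: one global seed fans out to fixed substreams (cohort-level
draws, per-subject EC, per-subject estimation noise, per-score cognition),
so enlarging the cohort never reshuffles earlier subjects and serialized
cohorts are byte-identical across runs.

What the generator does **not** emulate: hemodynamics, measurement
artifacts, network identification (parcellation is taken as given),
non-Gaussian EC heterogeneity, and missing data. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative model, not robustness to real-data violations of it.

## Group-level inference

Per connection, subject posterior means are modelled as
`θ̂_i ~ N(x_iᵀθ², σ_i² + v)` with design (constant, diagnosis ±1,
centered age, gender 0/1, centered medication). The between-subject
variance `v ≥ 0` is estimated per connection by bounded scalar
maximization of the marginal likelihood (Brent search; a diagonal
random-effects covariance is a tractability choice). The group effects
carry a Gaussian prior: variance 1.0 on the constant column and 1/16 on
every effect column. The tight, zero-centered effect priors play the role
of "precise null" priors: they shrink weakly supported effects toward
zero and make the credible-interval criterion stringent under multiple
comparisons. The exact prior variances are declared assumptions (no
reference values exist); both are configurable.

A connection is flagged when the equal-tailed 95% credible interval of
its diagnosis coefficient excludes zero. Because diagnosis is coded ±1,
the SZ−HC difference is twice the coefficient; both are reported.
Exploratory model reduction and model averaging over reduced models are
intentionally not implemented; credible-interval exclusion is the single
significance criterion, recorded in output metadata.

Dysconnection summaries: per network, the binary matrix of flagged
connections yields nodal degrees (row sum + column sum, diagonal counted
once) normalized by the maximum degree `2n − 1` of an n-node directed
network. Counting the self-connection once is required for the maximum to
be attainable.

## Cognitive comparisons

Two-sample t tests per domain (Welch by default — variance pooling is an
explicit option since either convention is defensible) with family-wise
error control by the permutation distribution of the maximum |t| across
the 8 endpoints: `p_j = (1 + #{b: maxT_b ≥ |t_j|})/(B + 1)`, B = 10,000
by default, +1 smoothing so no p-value is zero. Raw per-score permutation
p-values use the same smoothing, so adjusted ≥ raw always.

## Brain-behavior CCA

Both variable sets are residualized on (intercept, age, gender,
medication) before any selection — the adjustment method is a declared
choice; residualization makes the outputs exactly orthogonal to the
covariates and is idempotent. All columns are z-scored inside the CCA;
correlations and weights come from the SVD of the whitened
cross-covariance `S_xx^{-1/2} S_xy S_yy^{-1/2}`, with a deterministic
sign convention (largest-|weight| x-entry positive) and an optional ridge
(default 0, auto-escalated to 1e−8 with a warning on numerically singular
within-set covariance).

Stepwise selection scores a candidate by **partial Λ**, the ratio of the
fuller to the reduced model's Wilks Λ. The implementation uses the
algebraically identical residualized form — partial Λ = 1 − R² of the
candidate residualized on the selected set against the other set
residualized the same way — which reduces each forward step over
hundreds of candidates to one QR decomposition and a matrix product; the
explicit ratio form is retained in the API and the two are tested for
agreement, as are greedy orderings against exhaustive nested-model
search. Partial F conversions: adding one x to m−1 selected, with p y's,
gives `F = ((1−Λ)/Λ)·((s−m−p)/p)` on (p, s−m−p) df; removing one y from
p, with q′ x's, gives `F = ((1−Λ)/Λ)·((s−p−q′)/q′)` on (q′, s−p−q′) df.
Ties break toward the lowest column index.

The **bagged ensemble** runs the stepwise pair on bootstrap resamples of
the subjects (default 200; resample seeds derived from the master seed by
counter; resamples with degenerate columns are skipped without changing
the frequency denominator). Two refinements keep the procedure calibrated
inside a resample:

- F statistics use the number of *unique* subjects in the resample as the
  effective sample size — duplicated rows carry no information, and
  without this correction the backward-elimination stopping rule fires
  immediately and retains every domain;
- the per-resample forward cap is
  `max(1, min(floor(0.05·q), floor(s_eff/9) − p))`: the 5%-of-variables
  rule, additionally bounded so that the selected x's plus the p candidate
  y's respect the sample-to-feature ratio of 9 that governs CCA stability.
  At small samples (s ≈ 58) this bound is the binding one and admits only
  one or two x's per resample, which is what produces informative,
  well-separated inclusion frequencies.

Inclusion frequency is the fraction of resamples selecting a feature.
Final top sets default to 3 x's and 3 y's (ranked by frequency, ties to
lower index), trimmed from the low-frequency end until the total obeys
`|x| + |y| ≤ floor(s/9)`.

Inference on the final model: Bartlett
`χ² = −(s − 1 − (q+p+1)/2)·ln Λ_k` with `(q−k+1)(p−k+1)` df, Rao's F, and
a permutation test (rows of Y permuted). Because the final model's
variables were chosen on the same data, its parametric p-value is
optimistic; the package reports it alongside the selection-aware check —
cross-validation with **in-fold re-selection** (a single-pass forward +
backward selector per training fold by default; the full ensemble can be
substituted at proportional cost). Reported are per-repeat fold means of
the out-of-sample first-variate correlation, their overall mean, and a
95% percentile interval across repeats (a standard interval; no
non-standard confidence levels are used). Out-of-sample correlations sit
below the in-sample estimate for genuine signal and are centered at zero
under the null.

## Functional connectivity

FC is the sample covariance (divisor n−1) of a subject's subnetwork
series, per the primary definition; correlation and an optional Fisher
transform are offered because display conventions for FC matrices vary.
Group differences: per unique edge, OLS of the FC entry on (intercept,
diagnosis ±1, covariates), two-sided t on the diagnosis coefficient,
Benjamini–Hochberg across all `n(n−1)/2` edges as one family
(within/between-network splits are summaries only), and the display
transform `−sign(t)·log10(q)` for `q < 0.05`, else 0. In small balanced
samples the medication covariate (zero for every control) is nearly
collinear with diagnosis and absorbs most of the group effect — a
faithful property of the design, worth remembering when choosing
covariates.

## Problem sizes in the shipped checks

The test suite exercises the pipeline at sizes chosen to make each
statistical statement sharp at desk scale: 50k-point series for
covariance/spectral fidelity, 100+100 subjects for group-GLM recovery,
200 patients and 200 bootstrap resamples for ensemble-CCA recovery
(10 seeded replicates), 150–1000 replicates for calibration of FDR,
family-wise error and the Bartlett test, and reduced repeat counts for
cross-validation. Seeds are fixed throughout, so every reported check is
deterministic.

## Known limitations

- The spectral inversion is least-squares, not a full Bayesian scheme: it
  reports no posterior over `A` and no model evidence.
- The random-effects variance is per-connection diagonal; correlated
  between-subject effects across connections are not modelled.
- The ensemble selector's frequency ranking is unstable when the true
  signal-to-sample ratio is poor (by design it then returns diffuse
  frequencies rather than a confident wrong answer).
- Permutation schemes assume exchangeability of subjects under the null;
  no nuisance-aware (e.g. Freedman–Lane) scheme is implemented.
- The cohort generator's planted link is linear and homoscedastic; CCA
  recovery results say nothing about nonlinear brain-behavior structure.
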