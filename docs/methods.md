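# Methods

## Scientific setting

In a near-threshold somatosensory detection task, electrical pulses at ten
individually calibrated intensity levels are delivered while a simultaneous
visual cue signals "stimulus present" or "stimulus absent"; the participant
reports whether the cue *matched* their percept.  Because the cue is
counterbalanced within each intensity level, the overt report (match vs
mismatch) is statistically independent of whether the target was detected —
the design property that lets brain responses to *detection* be dissociated
from responses to *reporting*.

Five trial-wise covariates summarise what a voxel could be encoding:

1. **intensity** — the linear stimulus level (1–10);
2. **detection** — the binary detected/missed outcome;
3. **p(detect)** — the detection probability implied by the participant's
   psychometric function at the presented intensity (a sigmoid in level);
4. **uncertainty** — the slope of the psychometric function at the presented
   intensity (an inverse-U in level, maximal at threshold);
5. **report** — the binary match/mismatch response (flat in level).

Each covariate defines one candidate GLM (a parametric modulation of a
common trial-onset regressor).  Voxel-wise Bayesian model selection over the
five candidates, across subjects, decides which covariate best explains each
voxel, and family-level inference protects the three mutually correlated
"+family" covariates (intensity, detection, p(detect)) from diluting one
another before they are compared within the winning regions.

## Psychometric model

Detection behaviour is modelled as a two-parameter logistic,

    p(x) = 1 / (1 + exp(-4 s (x - t50))),

with `t50` the 50% threshold (mA) and `s` the slope at threshold (1/mA); the
factor 4 makes `s` literally dp/dx at `t50`.  No lapse/guess asymptotes are
used: the experimental grid is constructed to span the full 0–100% dynamic
range.  Fitting is bounded maximum likelihood (L-BFGS-B from five starts;
`t50` confined to the tested intensity range, slope to (0, 50] /mA — the cap
guards against divergence on perfectly separated data; ties break to the
smaller slope).  The participant-level observer is the unweighted mean of
per-run fits (run trial counts are equal by design, so weighting is moot).

The experimental grid solves p(x) = .01 and .99 for T01 and T99, places them
at levels 2 and 9, and spaces ten levels equidistantly with step
(T99 − T01)/7.  A participant is excluded when the *run-averaged* observer,
evaluated against the grid fixed at calibration time, has p(level 1) > .10
or p(level 10) < .90 (strict inequalities) — the signature of threshold
drift after calibration.

## Synthetic cohorts

Raw data from such experiments cannot be redistributed, so the generator
reproduces the statistical structure the analysis assumes.  Defaults are the
study's design conditions:

| parameter | default | note |
|---|---|---|
| subjects | 12 | recovery-cohort size |
| runs × trials | 4 × 100 (+10 nulls) | per-level counts 16/27/40/53/64/64/53/40/27/16 |
| t50 population | 2.40 ± 0.69 mA | slope 2.05 ± 0.35 /mA, consistent with T01 = 1.84, T99 = 2.96 mA |
| ITI | uniform 2.5–7 s | jitter jointly rescaled to fit the run |
| TR / volumes | 2 s / 378 | run duration 12.6 min |
| RT | 364 ± 53 ms between subjects, 80 ms within; detected-trial shift −11.8 ± 14.8 ms across subjects | truncated to the 0.15–0.9 s response window |
| BOLD effect | 1% signal change per SD of modulator | plus 0.5% common onset response |
| noise | AR(1), ρ = 0.2, marginal SD 1% | plus cosine drift and motion-coupled nuisance |
| lattice | 20×20×20 voxels, 3 mm | six embedded 5×4×3 regions (five models + null) |

The per-level trial counts interpolate a normal density over levels whose
width is fixed by the stated extreme/threshold count ratio (16/64), with
largest-remainder rounding applied symmetrically — this reproduces every
stated count while keeping the normal weighting.  Cues are counterbalanced
within level (odd counts split randomly 9/8).  Reaction times are
truncated-Gaussian; detected trials are shifted faster by 11.77 ms.

Each of the five signal regions responds to trial onsets with the canonical
double-gamma HRF scaled by its generating covariate.  The HRF kernel is
normalised to unit peak so that amplitudes are percent signal change at the
single-event response peak.  The null region receives noise only; background
voxels additionally carry the drift and motion-coupled nuisance signal and
serve as the "tissue" compartment from which nuisance principal components
are computed (standing in for white-matter/CSF signals).  What the generator
does **not** emulate: physiological noise spectra, motion-induced spatial
displacement, susceptibility artefacts, spatial correlation of noise, and
between-region anatomical variability — passing tests therefore demonstrate
the *analysis logic* (model evidence discriminates the generating covariate;
family inference prevents dilution; SRPs reflect the generator), not
robustness to every property of acquired fMRI data.

## First-level Bayesian GLM

Each candidate design contains: the HRF-convolved onset regressor and its
temporal derivative, the parametric modulation by one z-scored covariate and
its derivative, a z-scored-RT modulation, six motion time courses, five
tissue principal components, two cosine drift terms, and a constant.
Z-scoring is per run; binary covariates are coded 0/1 before standardising
(equivalent to any two-point coding up to sign/scale); the intensity
covariate uses the level index (identical to mA after z-scoring because the
grid is equidistant).

Estimation is the conjugate normal–inverse-gamma model with a Zellner
g-prior: β | σ² ~ N(0, σ² g (X'X)⁻¹) with g equal to the number of scans
(unit information), σ² ~ InvGamma(0.1, 0.1).  The marginal likelihood (log
model evidence) is exact and closed-form — this replaces the spatially
regularised variational scheme sometimes used for this analysis; spatial
regularisation is instead realised by the analysis's own subsequent step of
smoothing the evidence maps (8 mm FWHM by default), which pools evidence
across neighbours before group inference.  The trade is exactness and
testability (the evidence is verified against numerical integration to
1e-3 nats) for the loss of adaptive, data-driven smoothness estimation.

Serial correlation is handled by exact AR(1) generalised least squares.  The
per-voxel AR coefficient is estimated once, from OLS residuals of a design
containing only the columns shared by all candidate models, and the same
whitening is applied to every candidate at that voxel: evidence differences
across models therefore never reflect differing noise models.  The whitened
cross-products are quadratic polynomials in ρ, so exact per-voxel GLS costs
no additional passes over the data.

## Random-effects model selection

Group inference treats each subject's generating model as a draw from a
population frequency vector r ~ Dirichlet(α₀), α₀ = 1 per model.  The
variational scheme alternates subject-assignment weights
u_nk ∝ exp(lnE_nk + ψ(α_k) − ψ(Σα)) with α = α₀ + Σ u_n until
max |Δα| < 1e-6.  It is validated against a Gibbs sampler over
(frequencies, assignments) — the exact posterior — to a frequency error
below 0.02.  Exceedance probabilities (the posterior probability that one
model's frequency tops all others) use 10⁶ Dirichlet samples for scalar
analyses, the exact regularised-incomplete-Beta formula for two models, and
2×10⁴ samples per voxel for maps (Monte-Carlo SE < 0.005); ties break by the
argmax convention so EPs sum to one exactly.

Family inference assigns each family a total prior mass of 1 split equally
among members (so the three-member +family uses α₀ = 1/3 per member), and
scores each family's *summed* frequency per Dirichlet sample.  Regions where
the +family exceeds EP ≥ .99 (clusters of k ≥ 50 voxels, 26-connectivity by
default — the connectivity is configurable since it is an analysis choice)
are then re-analysed comparing only the three members.  No explicit null
model is included: voxels explained by none of the covariates simply never
reach high EPs.

## Region statistics

Within each group ROI, each subject's probability peak (the voxel maximising
that model's share of summed evidence, exp(lnE_m − logsumexp lnE); ties to
the lowest linear index) provides the read-out point for the winning model's
modulator beta.  Group-level deviation of these betas from zero is tested
with the JZS (Cauchy-prior, r = 0.707) Bayes factor, computed by the
standard g-mixture integral and verified against direct double integration
of both marginal likelihoods and against an established implementation.
Behavioural detection×report independence uses a contingency-table Bayes
factor under the independent-multinomial sampling model with Dirichlet(1)
priors per row and the prior-margin adjustment under independence (which
keeps the test transpose-invariant); the joint-multinomial variant is
selectable.  Evidence bands: <3 negligible, 3–20 positive, 20–150 strong,
>150 very strong.

Stimulus-response profiles are the ten level-wise betas from a second GLM
with one onset regressor per intensity level (plus the RT and nuisance
columns), smoothed like the evidence maps and averaged over 4 mm-radius
spheres (centre-to-centre distance in mm; no grey-matter clipping) around
the subject peaks.  Group SRPs are classified as flat / linear / sigmoid /
inverse-U in two stages.  First a goodness-of-fit test against flatness:
the profile is labelled flat unless its SEM-standardised chi-square about
the weighted mean exceeds the 0.999 quantile of chi-square(9).  Only then
are the structured shapes fitted by bounded least squares and scored by
chi-square plus a conservative penalty of 9 per free parameter (the 0.997
quantile of a 1-df chi-square).  This design reflects two facts: the
4-parameter shapes can absorb roughly half of pure sampling noise on ten
points (so an unpenalised comparison overfits flat profiles), and a
level-independent response still shows irreducible per-level jitter because
each level's mean of the generating covariate is estimated from finitely
many trials — whereas genuine linear/sigmoid/inverse-U profiles exceed the
flatness threshold by orders of magnitude.  The inverse-U amplitude is
constrained positive with an interior peak so it cannot mimic a sigmoid's
rise.  In bootstrap stability analyses, replicate means are classified
against sqrt(2) times the full-cohort SEM, since a replicate mean carries
both the cohort mean's sampling error and the resampling error (each of
variance ~SEM^2), and an n-of-12 resampled SEM estimate is too noisy to
standardise against.

## Numerical choices and degenerate inputs

- All randomness flows through one seeded `numpy` generator per stage; any
  derived seeds come from the stage seed.
- Z-scoring a zero-variance covariate (e.g. every target detected) raises a
  degenerate-regressor error naming the covariate; rank-deficient designs
  raise an error naming the collinear columns.
- Perfectly separated psychometric data hit the slope cap rather than
  diverging; all-identical outcomes raise a non-identifiability error.
- Evidence-map smoothing below one voxel's width warns and proceeds; FWHM 0
  is the identity.
- The recovery experiment and its tests run at a desk scale chosen to keep a
  full end-to-end analysis in the order of minutes on one core: a 20³
  lattice with 60-voxel regions and 12 subjects.  These sizes are the
  package's default study conditions, not limits of the method; the lattice,
  region layout, cohort size and sample counts are all configurable.

## Known limitations

- The non-spatial conjugate GLM cannot adapt its effective smoothness per
  regressor the way a spatial variational prior can; evidence-map smoothing
  applies one isotropic kernel to all models.
- The VB approximation to the Dirichlet posterior adds assignment
  pseudo-counts even under completely uninformative evidence, so expected
  frequencies under flat evidence do not equal the prior mean (the exact
  posterior does); exceedance probabilities, which drive all decisions here,
  are far less affected and are oracle-checked.
- The synthetic noise model (white + AR(1) + drift + motion surrogates) is a
  stated assumption, not a measured reproduction of scanner noise.
- SRP shape classification is a descriptive label on ten points; profiles
  intermediate between shapes (e.g. a very shallow sigmoid) legitimately
  classify as their best simple description.
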