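# Methods

## Models

Log survival after a single acute dose d (Gy):

- LQ: ln S = −αd − βd², with α ≥ 0 (Gy⁻¹) and β > 0 (Gy⁻²).
- ELQ: ln S = −(α+γ)d + γ²/(2β)(1 − e^(−2βd/γ)), with γ > 0 (Gy⁻¹) or
  unbounded. Low-dose expansion −αd − βd² + (2β²/3γ)d³ + O(d⁴); high-dose
  asymptote −(α+γ)d + γ²/(2β). γ → ∞ is the LQ, represented exactly by the
  IEEE-infinity sentinel `GAMMA_UNBOUNDED` (every evaluation dispatches to
  the LQ branch, so the collapse is exact, not approximate).

The ELQ contains the constant-dose-rate protracted LQ: with repair rate λ
(h⁻¹), dose rate R (Gy/h) and a dose-rate-independent term δ (Gy⁻¹),
γ = 2β/(δ + λ/R); δ = 0 gives γ = 2βR/λ, and δ = 0 with R → ∞ gives the
unbounded (acute LQ) case. Dose is always Gy; λ and R must share the time
unit (documented contract, no conversion). The Lea–Catcheside factor
G(x) = (2/x²)(e^(−x) + x − 1), x = λT, is evaluated with `expm1` and switches
to a 4-term Taylor series below x = 10⁻⁴, so both branches are accurate to
~10⁻¹² near the switchover and G(0) = 1 exactly.

## Fitting

Weighted least squares with weights 1/sd_i². When no error bars are given,
sd_i = c·S_i (proportional-SD assumption); the proportionality constant c
only rescales the WSSR, so c = 1 by default and reported WSSR values are
comparable only within a fixed c. The default fit space is linear survival
(residuals (S_model − S_obs)/sd_i — relative least squares under the
proportional-SD assumption); log-survival space, where the same assumption
makes the residual SD constant, is an option. The two give estimates well
within one combined standard error of each other on the generator's data
(Monte-Carlo checked in the test suite).

LQ fits use a trust-region reflective solver with bounds α ≥ 0, β > 0,
started from the linearisation −ln S/d = α + βd. Convergence tolerances are
1e−10 on cost decrease and step (deterministic fits).

ELQ fits follow a two-stage rule:

1. Unconstrained α, multistarted from five deterministic points (including
   the LQ solution with γ = 10³, which makes the nested-model comparison
   meaningful); ties broken by lowest WSSR, then lowest γ.
2. If the best α is negative, refit with α fixed to exactly 0 and flag it.
   Fixed parameters carry no uncertainty entry.

The result is reported as the LQ limit (γ unbounded, LQ-fit parameters) when
either (a) γ exceeds a divergence ceiling of 10⁴ Gy⁻¹, or (b) the ELQ
objective fails to improve on the nested LQ fit by more than a 10⁻⁶ relative
margin — the cost surface is flat in γ on such data (noiseless LQ-generated
data being the extreme case) and γ is unidentified. Rule (b) also guarantees
the nesting property ELQ-WSSR ≤ LQ-WSSR.

Percentage uncertainties are 100·SE/estimate from the Gauss–Newton
covariance inv(JᵀJ) scaled by the reduced chi-square WSSR/(n−p); a noiseless
fit therefore reports ~0, and with scaling disabled the SEs track the
supplied error bars directly. Singular curvature yields infinite percentages,
not an exception. The α/β-ratio uncertainty uses first-order propagation; by
default cross-correlation is ignored (√(pct_α² + pct_β²) = 31.8% for the
published lung-line fit, versus the 30% quoted alongside it, which matches
α's uncertainty rounded), with the retained covariance available for the
correlated version.

## Isoeffects

Effect E = −ln(total survival) for n fractions totalling D, assuming complete
interfraction repair and no repopulation. LQ: E = αD + βD²/n, inverted via
the cancellation-free positive root D = 2E/(α + √(α² + 4βE/n)) (exact at
α = 0). ELQ: E(D) is strictly increasing, so the implicit equation is solved
by Brent's method on the analytic bracket [E/(α+γ), E/(α+γ) +
nγ²/(2β(α+γ))] — the lower end drops the repair term (overstating effect),
the upper end adds the asymptote offset — with geometric expansion as a
rounding guard; tolerance 10⁻¹² relative on D. Fraction numbers are treated
as integers in tables but the solver accepts real n. Reported doses are
rounded to 0.1 Gy at the presentation layer only.

Ratio-only LQ curves (clinical α/β shorthand) are anchored through the
reference schedule: D(1 + (D/n)/(α/β)) = D_ref(1 + d_ref/(α/β)), the
BED-style cancellation that removes the absolute α scale. The approximation
report scans candidate α/β values and returns the maximal contiguous
fraction-number interval with |D_LQ − D_ELQ| ≤ tolerance (default 1 Gy);
since every anchored curve passes through the reference point, the interval
is never empty when the reference n is in range.

Uncertainty bands perturb each free parameter by ±1 SE over all corners of
the hypercube (deterministic, preferred over sampling for reproducibility —
a convention, as no construction is prescribed for such bands), re-derive the
reference effect at each corner, and take the pointwise min/max together with
the nominal curve, so the band contains the nominal curve and every corner
curve still passes through the reference point. Perturbations that would
violate parameter bounds are clipped and flagged.

## Synthetic data

The four digitized cell-line datasets behind the published fits are not
available, so the generator emulates their structure: a ~12-point grid,
geometric-ish from 0.5 to 15 Gy (denser at low dose, as clonogenic assays
are designed), and multiplicative noise with SD proportional to the model
value — lognormal by default, parameterised to match the target mean and CV
exactly on positive support (a reflected normal is the alternative). Default
noise CV is 5%, a typical clonogenic-assay spread. Draws are clipped to
(0, 1]; clipping beyond 1% of draws raises a warning (it occurs routinely at
sub-Gy doses where S ≈ 1, biasing those points slightly low — a real feature
of bounded survival data). One master seed derives a substream per dose
*value*, so extending the grid never reshuffles existing draws. Fixture
configurations carry the published ELQ parameters as ground truth and the
published dose rates as metadata.

What passing tests show — and don't: the generator matches the fitting
procedure's noise assumption by construction, so parameter-recovery results
(median absolute relative error 1.5–4% per free parameter at CV 5%, 200
replicates per cell line) are a best case. Real clonogenic data have
Poisson plating statistics, inter-experiment batch effects, and unknown dose
grids; recovery there would be worse, and the published WSSR values are not
reproducible without the original datasets.

## Problem sizes

The stochastic recovery check uses 200 replicates per cell line at 12 doses
— enough for stable medians while keeping the whole suite under a minute of
fitting time. The isoeffect table checks cover all 81 printed dose cells and
the 9 survival/ratio cells; each is a closed-form evaluation or a single
root solve and runs in milliseconds.

## Known limitations

- Only the constant-dose-rate protraction factor is implemented; arbitrary
  dose-rate profiles R(t), split-dose/incomplete-repair corrections, and
  repopulation terms are out of scope.
- The fit-space convention of the original fitting procedure is not
  documented beyond the proportional-SD statement; linear-space weighting is
  this package's default and the log-space option quantifies the (small)
  difference.
- Isoeffect doses are tumour-cell-killing equivalences only; no normal-tissue
  complication modelling, and no overall-treatment-time factors.
- Joint high/low-dose-rate fitting (used elsewhere to argue for an LQ-type
  PC3 parameter set) is not implemented.
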