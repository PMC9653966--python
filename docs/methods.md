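# Methods

## The deconvolution model

The package treats each MRM product-ion channel as a mixture signal.
For a sample containing *n* isomers that share precursor and product
ions, the measured abundance ratio of product ion Pi to the reference
ion Ri obeys

    (Pi/Ri)_measured = Σ_x (Pi/Ri)_x · f_x ,

with `(Pi/Ri)_x` the characteristic formation yield of that fragment for
pure isomer *x* (measured once, from pure-compound injections at the top
calibration level) and `f_x` the isomer's fraction of the precursor-ion
signal. The model assumes:

- all isomers co-elute (shared retention window), so one integration
  window captures every component;
- ionization efficiency and fragmentation yields are concentration-
  independent over the working range, making the system linear;
- the Ri channel (precursor transition at low collision voltage) carries
  the summed precursor signal of all isomers and is itself free of
  fragmentation losses;
- no unmodeled co-eluting species shares both the precursor and the
  monitored products — violations surface as a deconvolution residual
  well above the noise, which is why the residual norm is always
  reported.

With *m* monitored transitions the coefficient matrix is *m*×*n*;
*m* = *n* gives an exact solve, *m* > *n* an overdetermined least-squares
solve whose redundancy guards against single-channel interference. Rank
deficiency (condition number above 1e8) is rejected with a message
naming the most nearly collinear isomer pair, since that is the
actionable diagnostic: those two isomers cannot be distinguished on the
chosen transitions.

### Solver choices

- **Non-negativity** (default on): solved with active-set NNLS.
  Negative abundances are unphysical; for interior solutions NNLS
  coincides with the unconstrained least-squares solution, so exactness
  on clean data is unaffected. The unconstrained solve remains available
  (`nonneg=False`) and is what the 2×2 analytic-inversion oracle tests
  exercise.
- **Closure** (rescaling fractions to sum to 1): off by default in
  peak-area mode — an unclosed solution plus the residual is more
  informative about unknown contributors — and on in scan-by-scan mode,
  where the per-isomer profiles are defined as a partition of the Ri
  signal.
- **Weighting**: the characteristic-ratio SDs are carried in the data
  model but the solve is unweighted. The replicate SDs of the shipped
  tables are nearly uniform across transitions, and an unweighted solve
  keeps the square and overdetermined variants directly comparable.

### Scan-by-scan mode

MRM channels are acquired interleaved (one dwell per transition per
cycle), so the Pi channels are linearly interpolated onto the Ri time
grid before the per-scan solve. Scans where Ri falls below 1% of its
in-window maximum are skipped and contribute zero to every profile: the
measured ratios are undefined near a zero denominator, and 1% of peak
height is low enough to retain >99.9% of a Gaussian peak's area. Linear
interpolation across the default 0.3-s stagger introduces relative
errors of order 1% at the 1% floor and <0.1% near the apex; tests that
check exact algebraic identities therefore use an aligned grid
(`dwell_offset=0`), while interleaved-grid tests use tolerances at the
interpolation level.

## Quantitation

Calibration regresses PAR (analyte/internal-standard peak-area ratio) on
nominal concentration, unweighted, all replicate points pooled (1/x
weighting is a config option; with the default five levels spanning
5–100 ng/mL and homoscedastic noise, unweighted OLS is appropriate).
LOD/LOQ use the standard-error-of-response and slope construction,
LOD = 3.3·Y-SE/|slope| and LOQ = 10·Y-SE/|slope|, with Y-SE the standard
error of the y-intercept; the ICH-style multipliers are defaults and can
be overridden. For isomer mixtures, each isomer's deconvolved fraction
of the Ri peak area is converted to a PAR and read off that isomer's
precursor-ion calibration curve — precursor-ion curves have nearly equal
slopes across an isomer pair, so both members are quantified with the
same sensitivity regardless of their differing fragment yields.

Matrix effect and recovery follow the three-set scheme:
ME% = 100·B/A (post-extraction spike vs neat solvent) and
RE% = 100·C/B (pre-extraction vs post-extraction spike).

## Validation plots

Accuracy and precision are summarized by regressing calculated on
expected fraction across the five-level standard-mixture ladder
(90/10, 75/25, 50/50, 25/75, 10/90), replicate injections entering as
individual points. Slope ≈ 1 is 100% accuracy; SE-Lin (residual standard
error, fraction scale) is the precision; |intercept| + 2·SE-Lin bounds
the smallest reliably recognizable relative abundance at ~95%
confidence. Fractions are kept in [0,1] internally and rendered as %
only in reports.

## Degradation kinetics

Below the Michaelis–Menten constant, plasma esterase hydrolysis is
pseudo-first-order, so ln(concentration) is fit against incubation time
by OLS with replicates pooled (pooling preserves the residual degrees of
freedom that the slope SE is computed from; fitting replicate means
would be a config-level change with negligible effect on the slope
itself). The half-life is t½ = ln 2/|k|. Because the incubation design
stops at 120 min, rates with |k| < 0.006 min⁻¹ cannot be distinguished
from measurement noise over the observed window; such fits are censored
and reported as "> 120 min" rather than as a numeric half-life. The
censoring threshold and the 120-min cap are module constants. Two fits
are compared by overlap of their k ± 2·SE intervals; a censored and an
uncensored fit are declared incomparable rather than silently ordered.

## Synthetic data

The generator emulates the study conditions the analysis assumes:

- **Peak shape**: Gaussian, retention time 1.8 min, width
  σ = t_R/√N with N = 5000 theoretical plates (σ ≈ 0.025 min ≈ 1.5 s) —
  the plate-count regime of a 20-mm column under a fast gradient. Run
  time 3.6 min, one scan per channel every 0.3 s, channels staggered by
  a 25-ms dwell.
- **Signal scale**: Ri area 1e6 counts·min at the 100 ng/mL top
  calibration level, scaling linearly with concentration; IS area 5e5
  counts·min.
- **Noise**: multiplicative log-normal on each channel's area
  (mean-unbiased), default CV 2%. This single noise knob reproduces the
  observed replicate scatter of characteristic-ratio measurements and
  lands the validation-plot SE-Lin in the experimentally reported
  0.01–0.03 band; it does not model scan-level shot noise, baseline
  drift, retention-time jitter, or matrix interferences, so passing
  tests demonstrate correctness of the deconvolution arithmetic under
  the stated error model, not robustness to every failure mode of real
  acquisitions.
- **Mixtures** co-elute exactly; every channel is the composition-
  weighted sum of the pure-isomer channels.
- **Degradation series**: per-isomer first-order decay from a
  mid-calibration total (default 55 ng/mL, matching plasma-spike
  levels), 3 replicates at 0/30/60/120 min; a direct concentration-
  readout variant (1 µM start) feeds the kinetics fit without the
  chromatographic layer.
- **ERMS sweeps**: precursor survival decays exponentially over the
  5–50 V range; fragment yields follow Gaussian-in-CV profiles with
  stated maxima, so the breakdown-curve builder must recover those
  maxima exactly.

All generators are seeded (`SynthConfig.seed`); identical configurations
produce byte-identical files.

## Problem sizes

The test suite and the acceptance script run on deliberately small
problems: 2-isomer systems with 2- or 6-transition matrices, 720-scan
chromatograms, 5-level × ≤6-replicate ladders, and 12-point kinetics
series. These match the experimental design the method targets; the
linear algebra is dimension-agnostic, and the random-matrix property
tests cover up to 8 equations.

## Known limitations

- Binary and small-*n* mixtures are the designed use case; automated
  transition selection for many-isomer panels is out of scope.
- The ratio-SD columns are not propagated into uncertainty estimates of
  the deconvolved fractions (validation-plot SE-Lin plays that role
  empirically).
- mzML support reads SRM chromatogram entries only (uncompressed or
  zlib, 32/64-bit float arrays); spectra and vendor raw formats are not
  parsed.
- Scan-by-scan profiles inherit linear-interpolation error across
  interleaved timestamps (~1% near the Ri floor).
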