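# Methods

## The classifier

A metric is an unordered wavenumber pair stored canonically (numerator index
< denominator index): a ratio and its reciprocal carry the same
discrimination information, so only the C(n, 2) canonical pairs are
enumerated. A ratio is *undefined* when the denominator magnitude is below
ε = 10⁻⁶ absorbance; undefined ratios are excluded from training, count as
misclassified during scoring, and abstain during voting, so degenerate
denominators can never inflate performance.

**Training.** For each metric the defined training ratios are split by
class. The rule is one-dimensional: polarity = the class with the higher
mean ratio; threshold = the midpoint between adjacent distinct sorted
ratios that maximises balanced accuracy under that polarity. Candidate cuts
are compared in exact integer arithmetic (balanced accuracy scaled by
2·n_T·n_NT) so ties are resolved deterministically — the lowest qualifying
threshold wins — without floating-point rounding noise. If no interior cut
reaches balanced accuracy 0.5 (degenerate distributions, e.g. all ratios
equal), the threshold is placed at the largest ratio so the rule degrades
to exactly 0.5; a metric with fewer than two defined ratios in either class
is marked untrainable and excluded downstream. The fitted rule therefore
never scores below 0.5 on its own training set.

**Scoring and selection.** Each trained rule is scored by balanced accuracy
on the test subset. Balanced accuracy is used because it is symmetric in
the two classes, matching the equal weight the application places on
sensitivity and specificity. The top-N selection (default N = 150) sorts by
score, breaking ties by the standardised class separation
|mean_T − mean_NT| / pooled sd and then by canonical pair order, making the
ranking a pure function of the data.

**Validation.** Selected metrics vote with weight equal to their test
score; the label is the class with the larger weighted sum, and an exact
tie goes to NT — a tie never asserts malignancy. A spectrum on which every
metric abstains is unclassifiable and counts as an error for its true
class.

**Splitting.** Spectra are divided 60/20/20 into train/test/validation,
with T and NT handled as separate strata and subset sizes fixed by
largest-remainder rounding. The protocol randomises at spectrum level by
default, which means spectra of one patient can appear on both sides of a
split; `group_by_patient=True` is available when patient-level independence
is wanted (see Limitations). The ten-repeat loop derives one child seed per
repeat from the master seed through a splitmix64 finaliser and re-randomises
all three subsets each time; the reported mean ± sd is therefore a pure
function of (dataset, configuration, master seed). Sample (ddof = 1)
standard deviation is reported.

## The synthetic generator

Each spectrum is built as

    scale × Σ_b (amplitude_b + Δ_b·1[T] + offset_pb) · exp(−(ν−c_b)²/2w_b²) + noise

per-spectrum `scale = exp(N(0, scale_sd))`, per-patient per-band
`offset ~ N(0, patient_sd)`, i.i.d. `N(0, noise_sd)` per grid point.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| grid | 1000–1800 cm⁻¹, 317 points | fingerprint region; 317 points give C(317,2) = 50 086 metrics, so the top 150 are ≈ 0.3 % of all metrics |
| patients | 10 T, 7 NT | the cohort sizes of the motivating study |
| spectra/patient | 50 | plausible pixel count per sample; not fixed by the study |
| planted bands | Δ = 0.15 on amplitude-1.0 bands at 1684, 1656, 1614, 1575, 1236 cm⁻¹ (σ = 6) | class signal at the key wavenumbers the analysis should recover; effect large enough to recover with margin, small enough to be non-trivial |
| neutral bands | 1545, 1450, 1400, 1080, 1020 cm⁻¹ (amplitudes 0.4–0.75) | stable ratio denominators; 1020 cm⁻¹ deliberately carries no class signal |
| noise_sd | 0.02 | ~2 % of the main band height, typical detector-level noise |
| scale_sd | 0.10 | ~10 % multiplicative sample-to-sample variation — the dominant systematic effect in tissue FTIR, and the one ratio metrics cancel by construction |
| patient_sd | 0.01 | small residual additive per-patient band variability; kept below the noise floor because multiplicative effects dominate inter-sample variation |

Band shape is Gaussian; Lorentzian/Voigt shapes, scattering artefacts,
baseline drift and spatial correlation between pixels are deliberately not
modelled — the generator exists to exercise the algorithmic contracts, not
to forge realistic biochemistry. Consequently, passing tests demonstrate
that the pipeline recovers planted multiplicative-noise-robust signal; they
do not certify performance on real tissue spectra.

Presets: `default` (planted signal as above), `null` (identical bands, all
Δ = 0), `strong-signal` (Δ = 0.5, low noise, no patient variation; cleanly
separable).

## Key-wavenumber reporting

Every selected metric increments the histogram count of both its
wavenumbers; repeats are pooled by default (single-run histograms are just
a one-element list). Annotation against a reference model is three-way:
wavenumbers inside an important interval expanded by ± one resolution
element (4 cm⁻¹) are *discriminating*, otherwise inside a neutral interval
*reference*, otherwise *unassigned*; important wins on overlap. Key
wavenumbers are count-weighted means of maximal runs of discriminating
wavenumbers no more than one resolution element (default gap = 4 cm⁻¹)
apart. Concordance between two key lists uses greedy globally-closest
matching under a tolerance — the lists are short (≤ 10 entries), so greedy
is deterministic and reproduces a one-to-one row layout; the default
tolerance is the 4 cm⁻¹ resolution, with 2× resolution exposed for the
narrative comparison in which four of the five key pairs agree.

## Numerical choices

- Wavenumber equality when matching columns or histogram bins: 10⁻⁶ cm⁻¹
  (float/text round-trip tolerance). Files are written with 17 significant
  digits so write∘read is the identity.
- Largest-remainder rounding hands leftover units to the largest fractional
  parts, ties broken in subset order (train, test, validation).
- Rendered percentages round half away from zero via decimal arithmetic;
  machine-readable outputs keep full precision.
- Child seeds are reduced mod 2³¹ for portability.

## Known limitations

- **Patient leakage under spectrum-level splitting.** With the default
  split, spectra from the same patient occur in training and validation, so
  per-patient idiosyncrasies act as usable signal. On null data this
  inflates apparent performance slightly above chance for unlucky
  patient-class alignments (ten-repeat mean rates typically land between
  0.45 and 0.65 rather than exactly 0.5). Patient-level grouping removes
  the leak at the cost of much coarser split granularity (17 assignable
  units).
- The per-metric threshold rule, scoring statistic and vote aggregation are
  principled stand-ins chosen for determinism and symmetry; other
  discriminant choices (e.g. distribution-overlap statistics) would slot
  into the same interfaces.
- Quality filtering (peak-absorbance bounds in the Amide I band) is a
  generic FTIR tissue QC and is off by default; no normalisation stage
  exists because ratio metrics are scale-invariant by construction, and the
  tests assert that classifications are unchanged under per-spectrum
  rescaling.
- Binary classes only; multiclass tissue discrimination is out of scope.
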