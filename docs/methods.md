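# Methods

## Duration estimation model

A bipolar electrogram is modeled as a transient burst of band-limited
activity in additive low-level noise. The detector makes no assumption about
morphology beyond that: activity is whatever raises the local standard
deviation of the filtered signal. The pipeline is

1. zero-phase bandpass 30–250 Hz (4th-order Butterworth, forward–backward),
2. zero-phase notch at the mains frequency (Q = 30 IIR, forward–backward),
3. sliding-window population SD with window length `w` ms,
4. thresholding at fraction `theta` of the SD-curve maximum: onset = first
   sample at/above threshold, offset = last such sample,
5. duration = offset − onset; `duration > c` ms flags abnormal prolongation.

Relative thresholding makes the estimate exactly invariant to amplitude
scaling, which is essential when the same rule must work in dense scar
(< 0.2 mV) and healthy tissue (> 1.0 mV). Taking the *first and last*
crossing over the whole trace (rather than the contiguous region around the
SD maximum) makes duration exactly non-increasing in `theta` (superlevel
sets are nested) and bridges separated deflections — split potentials are
deliberately merged into one interval; systematic double-potential analysis
is out of scope.

### Parameters

| parameter | meaning | default | tested range |
|---|---|---|---|
| `sd_window_ms` (w) | SD window length | 40 ms | 10–45 ms, step 5 |
| `sd_threshold_frac` (theta) | fraction of SD-curve max | 0.15 | 0.10–0.50, step 0.05 |
| `duration_cutoff_ms` (c) | abnormality cutoff (strict >) | 70 ms | 60–80 ms, step 5 |

Larger windows smear the envelope and lengthen estimates; larger thresholds
shorten them. The defaults are the operating point validated on clinical
maps by maximum diagnostic odds ratio against ablated segments.

### Numerical choices

- **Population SD** (divide by n): the window statistic is an energy-spread
  measure, not an inferential estimate.
- **Centred window, edge truncation**: the window at sample *i* covers
  `[i−(w−1)/2, i+w/2]` samples, truncated at the trace ends to a minimum of
  2 samples; output length equals input length. Centring avoids a
  systematic onset bias.
- **Window in samples** = `round_half_up(w · rate / 1000)`.
- **Implementation**: cumulative sums after per-row mean removal, with the
  accumulation in extended precision (`longdouble`) because the
  mean-of-squares identity cancels catastrophically on nearly-constant
  windows; agreement with a brute-force per-window evaluation is ~1e-11
  relative in the worst case.
- **Degenerate traces** (identically zero SD-curve) return duration 0 with a
  flag instead of raising, so that 10^5-point batches never abort; degenerate
  points are excluded from segment means.
- **Filter edges**: odd (point-symmetric) reflect padding, 300 samples for
  the bandpass and up to 2000 samples for the notch, whose Q = 30 resonance
  rings for ~200 ms. Traces must be at least 301 samples long to be filtered.
- **Ties in the grid-search argmax** resolve to the smallest window, then
  threshold, then cutoff; zero cells in the 2×2 table get the
  Haldane–Anscombe +0.5 correction (flagged in the output).

## 17-segment transform

The AHA model is realized as a deterministic geometric rule from three
landmarks (apex, base center, septal direction), replacing per-case manual
landmarking: the long-axis coordinate `t` (0 at base, 1 at apex) selects the
ring (basal < 1/3 ≤ mid < 2/3 ≤ apical < 0.85 ≤ apex cap), and the
circumferential angle from the septal direction (counterclockwise viewed
from the apex) selects the sector, with boundaries placed so sector centers
align with the anatomical labels (±30° around the septum for the six
60°-sectors, ±45° for the four apical sectors). All intervals are half-open,
so assignment is total and order-independent. Points beyond a 30 mm guard
past the axis extent raise a warning and clamp to the nearest ring.

Voltage classes follow the standard cutoffs — healthy > 1.0 mV, border zone
0.2–1.0 mV (boundaries inclusive), dense scar < 0.2 mV — applied to the
segment *mean* voltage. A segment is "ablated" when a lesion center falls in
it; an optional lesion radius extends lesions to spheres that mark any
segment containing a map point within the radius.

## Synthetic study conditions

The generator emulates a 16-patient high-density mapping cohort: 2000 points
per map (clinical maps average ~8000; 2000 keeps the full grid search fast
while leaving >100 points per segment), 400 ms single-beat traces at 1 kHz,
0.01 mV RMS noise floor (mini-electrode basket acquisition). Geometry is a
truncated ellipsoid (25 mm short-axis radius, 45 mm long semi-axis,
truncated at 80 %: apex-to-base ≈ 81 mm) sampled uniformly by triangle area.

One scar region per patient is drawn with location frequencies typical of
ischemic VT (inferior-basal predominant); its segments are dense scar, their
neighbors border zone ("halo"). EGMs are sums of Gabor wavelets (80–200 Hz
centers) time-rescaled so the support above 1 % of peak spans exactly the
requested ground-truth duration — a generator-side definition independent of
the detector under test. Sampled peak-to-peak amplitude equals the drawn
bipolar voltage exactly.

Three features are deliberately not a clean three-class toy, because the
validation statistics are only meaningful when ablation and duration
correlate imperfectly, as they do clinically:

- **Low-amplitude late components.** Border/dense EGMs have a dominant early
  deflection and geometrically decaying later components (late potentials
  are small). Consequently small SD windows *underestimate* duration — the
  sharp early peak sets a high relative threshold that the late components
  miss — while large windows overestimate, reproducing the qualitative
  window/threshold behavior the method is known for.
- **Per-segment duration random effects.** Points in one segment share a
  segment-level duration center (dense 90–175 ms, border 80–145 ms, healthy
  24–38 ms) with small per-point jitter; healthy-voltage segments *adjacent*
  to the scar/halo region draw from an elevated band (30–42 ms), mimicking
  the continuum of slowed conduction around scar.
- **Imperfect lesion placement.** 8 lesions per patient (≈ 7 ablated
  segments per patient, matching clinical counts): 70 % in scar/halo
  segments, 20 % spilling into the adjacent healthy segments, 10 % at remote
  bystander sites. This guarantees false negatives and false positives at
  every parameter triple, so the DOR surface has a genuine, data-driven
  interior maximum rather than a plateau of degenerate corrected values.

What the generator does **not** model: biophysical electrogram genesis,
wavefront-direction effects on bipolar amplitude, double potentials as a
separate category, catheter contact artifacts, respiration/beat-acceptance
gating, and continuous (sub-segment) scar geometry. Passing tests therefore
demonstrate correctness of the algorithmic chain and sane statistical
behavior under a plausible data model — not clinical performance.

At the defaults, dense-scar EGMs (amplitude down to 0.03 mV over a 0.01 mV
noise floor) saturate the detector — the SD-curve never falls below 15 % of
its maximum within the trace — which mirrors the low-voltage regime where
duration measurements are noise-limited; such segments are still correctly
abnormal.

## Statistics

Segment summaries pool across patients into one 2×2 table (abnormal ×
ablated); empty segments are excluded. DOR confidence intervals use the
log-normal approximation `exp(ln DOR ± z·sqrt(Σ 1/cell))`; the DOR p-value
is the two-sided z-test on ln DOR. The chi-square test is Pearson's without
continuity correction (1 df); binomial tests are exact, two-sided by the
minimum-likelihood method or one-sided on the lower tail. Coverage of the
95 % CI was checked by simulation from a fixed-odds model (90–99 % over 500
tables). The grid search evaluates the pooled DOR on the full lattice
(8 × 9 × 5 = 360 triples), computing durations once per (w, theta) and
reusing segment mean durations across cutoffs; a cohort with no ablated
segment anywhere is rejected as an error.

On the frozen study conditions (seed 7) the operating point yields DOR ≈ 16
(CI well above 1), sensitivity ≈ 0.71, specificity ≈ 0.87, and the grid
argmax lands at an interior cutoff (65 ms at that seed, best DOR ≈ 16.5);
the argmax is data-driven and moves by about one lattice step across seeds,
as expected for a 272-segment cohort.

## Design notes and limitations

- The EAMX interchange format (JSON header + CSV tables, or a single JSON
  container) is this package's own open schema; proprietary mapping-system
  exports are out of scope. Round-trips are bit-exact (17-significant-digit
  serialization, round-trip float parsing).
- Beat selection/windowing of the exported trace is an upstream
  (mapping-system) function; the detector analyzes the full exported trace.
- The 5 mm fill threshold used for 3-D coloring is display-only and never
  feeds statistics.
- Detection accuracy is quantified against generator truth: at the operating
  point, noiseless border-zone EGMs are recovered within ±w (duration) and
  ±w/2 (onset) in ≥ 95 % of traces; per-point prolongation agrees with the
  generating class for ≥ 90 % of points on full-scale maps.
- Sensitivity to the wavefront of activation, multi-beat stability and
  double-potential subclassification are known limitations of the
  single-beat, single-threshold design.
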