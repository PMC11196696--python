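# Methods

## Signal model and processing pipeline

A walk recorded by floor-mounted seismographs is modelled as a train of
impulsive footstep transients superimposed on a slowly varying baseline
(building sway, thermal drift, instrumental wander) and a broadband noise
floor. The pipeline estimates the baseline morphologically and removes it,
then reduces footstep detection to constrained peak picking.

**Per-sensor normalization.** Each trace is min-max scaled to [0, 1] and
its mean subtracted. The scaling makes the pipeline independent of sensor
gain (geophone amplitudes are treated as arbitrary units throughout — no
stage after normalization may consume absolute amplitude); the mean
subtraction removes the constant offset. Order matters only for numerical
convenience: the composition is invariant to any positive affine transform
of the input, which the test suite asserts.

**Alignment and aggregation.** Traces are linearly interpolated onto the
common grid at the nominal rate over the intersection of their time ranges.
Linear interpolation suffices because at 100 Hz a footstep transient spans
only a handful of samples and band-limited reconstruction has no headroom;
deviations are sub-sample. The aligned traces are combined with a rolling
maximum: pointwise max across sensors, then a rolling max of ±25 ms
(window 50 ms, half the peak refractory distance, so inter-sensor jitter is
absorbed without merging distinct steps). Taking the maximum lets whichever
sensor is nearest to a footfall dominate, which compensates
distance-dependent damping.

**Compound top-hat filter.** Grayscale opening (erosion then dilation)
removes positive spikes narrower than the structuring element; closing
(dilation then erosion) fills narrow dips. Their average follows the local
baseline while straddling the transients, so

    CTF(f) = f − (opening(f) + closing(f)) / 2

passes footstep transients and rejects low-frequency baseline structure.
The SE radius is 200 ms — the duration of a single footstep, so anything
wider than a footstep is treated as baseline. The boundary policy is a
shrinking window (min/max over the in-bounds SE support, no padding):
fabricated pad values would otherwise distort the first and last footfalls
of a pass, which carry the ambulation-time endpoints.

**SE shape and height.** The SE is "spherical": a semicircular height
profile h·sqrt(1 − (k/r)²), discretized to 2·round(radius·fs)+1 samples
(41 at 100 Hz). The vertical scale h is a genuinely open design choice; on
the normalized amplitude scale we default to h = 0.2. The choice matters:
the morphological "ball" must be shallow relative to the signal range so
that it rolls along the baseline rather than imprinting its own curvature.
Empirically, h near the full signal range produces CTF side lobes around
each footstep at roughly half the footstep-bump height, which survive the
later smoothing stages and create spurious peaks; at h = 0.2 the side-lobe
ratio drops below 0.1 and the detector output is clean. A flat SE (h = 0,
the classical rolling min/max) is exposed as an option and behaves almost
identically — detection uses only peak timestamps, never heights.

**Smoothing.** Two unit-DC-gain linear filters with 100 ms radius (21 taps)
follow: a Hamming window, which boosts peaks while suppressing residual
sample-scale jitter, and a rectangular moving average, which merges closely
adjoining double peaks (heel and toe strikes of the same footfall) into a
single maximum. Both use reflect padding so output length equals input
length and constants pass through unchanged.

**Peak detection.** The smoothed signal is re-min-max-normalized (the
height rule below is anchored to normalized amplitudes, and renormalization
makes it scale-free; it is idempotent when the signal is already in [0,1]).
Candidates are local maxima strictly greater than both neighbours, with
plateaus resolved to their midpoint sample. A candidate survives if its
height reaches the 95th percentile of the normalized amplitude distribution
over all samples; survivors are greedily pruned, highest first with the
earlier peak kept on ties, so that no two events are closer than 50 ms.

### Operating envelope of the percentile height rule

The 95th-percentile-of-samples rule has a structural consequence worth
stating plainly: by construction the threshold settles at the amplitude
level exceeded by exactly 5% of samples. After the two 100 ms filters each
footstep occupies an elevated bump of roughly 0.4 s, so the rule behaves
well only when the total bump area is somewhat above 5% of the analysed
window — then the threshold falls mid-bump, comfortably above the noise
ripple and below every bump top. If the walk occupies far less of the
window the threshold descends into the noise ripple (spurious peaks); if
it occupies much more, the threshold climbs into the bump tops (missed
steps). A walkway pass should therefore be analysed inside a recording
segment with quiet margins sized in proportion to the pass length — about
1.8 s of session per step on each side, i.e. a ~30 s segment for a typical
8-step pass. This matches how walkway-synchronised segments are cropped
from a continuous seismograph stream in practice, and the synthetic cohort
generator reproduces exactly this regime. The percentile, like every other
constant here, is configurable.

## Gait arithmetic

All six parameters are pure functions of the ordered event timestamps and
the walkway length; definitions are in the README. Two readings in the
definitions were fixed as follows. "Sum of step times" (ambulation time)
is the sum of successive inter-event intervals, identical to last-minus-
first event time. Cadence divides the raw count n of identified steps (not
n − 1 intervals) by the ambulation time — the literal ratio of steps to
walking duration. With n ≥ 3 events all six parameters are defined; with
exactly 2, cycle time and step length are reported as NaN. Step length
equals velocity · step time algebraically; both are "approximated"
parameters in the sense that they lean on the known walkway length, since
100 Hz sampling is too coarse for per-step localization from inter-sensor
arrival-time differences. TUG timing reuses the detector unchanged: the
first and last peaks of the session bound the test.

## Synthetic walks

Each footfall at time t_k and position x_k produces, at a sensor at
distance r, the causal ring

    A · exp(−(t − t_k − r/c)/τ) · sin(2πf(t − t_k − r/c)),  t ≥ t_k + r/c

with A = max(1 − α·r, 0.05) relative to unit source amplitude. Defaults and
their rationale:

| parameter | default | rationale |
|---|---|---|
| n_steps | 8 | a 4.88 m walkway pass at ~61 cm step length |
| step interval | 0.604 s mean | typical self-paced adult step time |
| interval SD | 0.015 s | ~2.5% CV, healthy steady-gait temporal variability |
| ring frequency f | 15 Hz | footstep energy band at 100 Hz sampling (Nyquist 50) |
| ring decay τ | 15 ms | sharp barefoot heel strike; visible transient ~60 ms |
| wave speed c | 300 m/s | effective surface-wave speed in a floor slab |
| attenuation α | 0.12 /m | mild damping over the ≤ 5 m sensor range |
| noise SD | 0.005 | quiet-room geophone floor, ~1% of nearest-sensor amplitude |
| drift | 0.02 @ 0.5 Hz + RW σ=0.0005 | sub-2 Hz wander; a 4.5 Hz-corner geophone strongly attenuates this band |
| session margins | 15 s (1.8 s/step in cohorts) | percentile-rule operating envelope above |

Sensors sit 1.5 m apart along the walkway, first and last on one side and
the middle sensor on the other. Inter-step intervals are truncated-normal
(±3 SD) so orderings stay physical; step positions advance uniformly along
the walkway. Everything is driven by one integer seed and is bit-reproducible.

What passing tests on these walks demonstrate: the pipeline's algebra,
its timing accuracy under noise, drift, attenuation and propagation delay,
its amplitude invariance, and its single-sensor redundancy. What they do
not demonstrate: performance under floor-slab dispersion and multipath,
footwear and surface variability, pathological gaits, or multiple
simultaneous walkers — none of which the generator models.

A systematic detail: the detected peak sits at the apex of the smoothed
transient, which for a causal ring lags the true impact onset by roughly
the ring rise time plus half its effective width (~17 ms at the defaults).
The lag is nearly constant across steps, so interval-based parameters
(step, cycle, ambulation time, cadence) are unaffected; only absolute
event times carry it.

## Agreement statistics

For each parameter across paired walks: paired two-sample t-test
(dof = n − 1, two-sided p, α = 0.05) with Cohen's d for paired data
defined as |mean(diff)| / sd(diff) (a pooled-SD variant is available);
ordinary least squares of one system on the other with
F = (n − 2)·R²/(1 − R²) as the model-necessity test; Pearson r with a
Fisher-z 95% CI (se_z = 1/√(n−3)) and SE(r) = √((1−r²)/(n−2)); and
Bland-Altman bias ± 1.96·sd of the paired differences as limits of
agreement. Degenerate inputs are handled explicitly: identical pairs give
t = 0, p = 1, d = 0; a constant non-zero difference has zero variance and
is flagged with an infinite t rather than an error; |r| = 1 collapses the
CI to a point. The t-test, regression and correlation delegate to scipy's
implementations; the Fisher CI is cross-checked against a seeded BCa
bootstrap in the test suite.

## Numerical and implementation choices

- Morphology is vectorized via sliding windows with ±∞ padding (never
  selected by min/max against finite values), which realises the shrinking-
  window boundary policy exactly; the test suite proves bit-equality with
  explicit min/max loops and cross-checks interior samples against
  scipy.ndimage grey morphology.
- Erosion/dilation on a constant shift it by exactly the SE peak height;
  opening/closing idempotence holds bit-exactly for flat SEs and to one ulp
  for non-flat SEs (height addition/subtraction rounds).
- The rolling maximum uses edge replication, which for a maximum equals the
  shrinking in-bounds window.
- Peak pruning is greedy highest-first with earlier-index tie-break — a
  deterministic total order, so outputs are reproducible byte-for-byte.
- Sampling rates are inferred from median timestamp spacing; a declared
  rate wins over the inferred one, and >1% spacing jitter triggers a
  warning. Times are recording-relative float seconds.
- CSV round-trips are bit-exact (`%.17g` on write, round-trip float parsing
  on read).

## Known limitations

- Spatial parameters (velocity, step length) require the walkway length;
  the package deliberately does not attempt arrival-time-difference
  localization of steps, which is unreliable at 100 Hz.
- The detector assumes one walker in a controlled environment; concurrent
  vibration sources will produce spurious events.
- Foot labels (left/right) are assigned from an externally observed first
  foot, never inferred from the signal.
- The percentile height rule requires the quiet-margin operating envelope
  described above; analysing a tightly cropped walk (no margins) degrades
  detection.
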