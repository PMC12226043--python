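# Methods

`vaguscap` re-implements, as a tested pipeline over simulated data, the
analysis used to characterize vagus-nerve activity in control and
long-sepsis mice: detection and sorting of compound action potentials
(CAPs) from cuff-electrode recordings, respiration-aware firing-rate
statistics, cytokine-response summaries, and per-mouse naive Bayes
decoding of immune state. The raw recordings of the original study are
not publicly deposited, so a synthetic-data generator stands in for them;
it is first-class, tested code, and its defaults encode the published
group-level statistics.

## The synthetic cohorts

A cohort is a set of mice, each carrying 2–4 CAP units. Each unit fires
as an inhomogeneous Poisson process with instantaneous rate

    lambda(t) = r_base * burst(t) * response(t) * jitter(t)

- `r_base` (CAPs/s) is the session-averaged baseline rate. Cohort rates
  are log-normal draws rescaled so the cohort mean matches the published
  group value exactly: mean 5.79 CAPs/s over 49 control (CON) units
  (15 mice), and 14.22 CAPs/s over 51 long-sepsis (LS) units (20 mice),
  with the LS right tail reaching the 20–70 CAPs/s range and no CON unit
  above ~18 CAPs/s. Per-mouse unit counts (3–4 for CON, 2–3 for LS)
  follow from the published per-mouse summed rates (18.84 and
  36.24 CAPs/s): units-per-mouse ≈ (per-mouse sum)/(per-unit mean).
- `burst(t)` implements respiratory modulation: bursts are a renewal
  process (duration ~ Normal(133.73, 10) ms for CON, (138.2, 10) for LS;
  onset-to-onset period ~ Normal(649.75, 60) / (694.87, 60) ms, floored
  at duration + 50 ms). Inside a burst the rate is multiplied by a gain
  g and outside by h = (1 − p·g)/(1 − p), where p is the expected burst
  time fraction, so the session average stays at `r_base`. The gain is
  calibrated so the CON within-burst rate equals the published
  13.09 CAPs/s (g = 13.09/5.79 ≈ 2.26).

  The published overall (5.79), within-burst (13.09) and inter-burst
  (0.88 CAPs/s) rates cannot all be realized by one stationary process,
  because they are linked by the partition identity
  `overall = p·burst + (1−p)·inter` and with p = 133.73/649.75 the
  published values give 3.39, not 5.79. The generator plants the overall
  rate, the burst timing and the within-burst rate; the inter-burst rate
  is then forced to ≈3.90 CAPs/s. This is a deliberate calibration
  priority, and it is why the pipeline recovers ~3.9 rather than 0.88
  CAPs/s between bursts.
- `response(t)` is 1 during baseline and steps to (1 + c1) / (1 + c2)
  after the first/second injection (20 and 40 min into the hour; an
  optional linear ramp is available via `response_ramp_min`). Responses
  are expressed relative to baseline, so a unit's category — increasing
  (+,+), decreasing (−,−), mixed (otherwise) — is exactly the sign
  pattern of (c1, c2). Planted category counts reproduce the published
  percentages: 33/13/3 (increasing/mixed/decreasing) of 49 CON units =
  67.35/26.53/6.12 %, and 14/22/15 of 51 LS units = 27.45/43.14/29.41 %.
  Magnitudes are uniform draws — CON 0.45–1.2 (increases) and 0.35–0.7
  (decreases), LS 0.15–0.3 — floored at ~4 standard errors of a
  last-10-min period-mean difference so that sign-based categorization
  recovers every planted category; the weak LS modulation relative to the
  high LS baselines is what degrades LS decodability, mirroring the
  published group contrast.
- `jitter(t)` is a mean-one Gamma multiplier (shape 4, SD 0.5) redrawn
  every second: physiological overdispersion beyond Poisson counting
  noise. Without it the decoder would saturate for both groups.

The continuous two-channel signal adds, at 32 kHz: Gaussian noise of
SD 2 µV, tripled inside respiratory bursts; biphasic
(negative-then-positive) 1.5-ms CAP templates at the planted spike times,
drawn from a 12-template bank (negative-lobe amplitudes 28/44/60 µV,
width scales 0.6/1.45, positive-lobe ratios 0.3/0.75) assigned so that no
two units of one mouse are separable only by amplitude or only by a
single shape factor; and a wide triphasic cardiac deflection at
10 beats/s (typical anesthetized mouse heart rate) that appears on both
channels within ±1 ms, with a large sharp R-like deflection plus noise
(SD 5 µV) — and no CAP templates — on the ECG channel. Template peaks sit
at ~12–30× the filtered noise SD, comfortably above the adaptive
threshold even inside bursts. All randomness derives from
`numpy.random.SeedSequence([seed, constant, mouse_index])`; identical
configurations are bit-reproducible.

What the generator does *not* emulate: waveform drift, electrode motion,
fiber-type conduction differences, respiratory waveform shape,
line noise, gradual (pharmacokinetic) cytokine responses by default, and
true overlapping-spike waveform superposition statistics beyond linear
addition. Tests passing on these fixtures therefore demonstrate that the
pipeline recovers the planted structure under calibrated, stationary
conditions — not that it would perform identically on real cuff data.

## Signal processing

- Band-pass: 4th-order Butterworth, 160–3000 Hz, applied
  forward-backward (zero phase). float32 recordings are filtered in
  float32 (relative error ~1e-4, half the memory traffic).
- Respiratory-burst detection uses a robust amplitude envelope: the
  sliding 20-ms *median* of |x|, evaluated on a 1-ms grid. A rank
  statistic is used instead of an RMS because individual CAP and cardiac
  transients occupy a small fraction of any window but dominate its
  power; at realistic event rates an RMS envelope is spike-dominated
  more than half the time and its median no longer tracks the noise
  floor. Bursts are runs where the envelope exceeds 2× its session
  median; gaps < 30 ms are merged, runs < 40 ms discarded.
- The adaptive threshold is 4.75× the robust noise SD (median(|x|)/0.6745
  over windows holding 1 s of in-regime samples, interpolated over time),
  estimated separately inside and outside bursts. Burst intervals are
  dilated by 12 ms when the in-burst threshold is *applied* (detected
  edges are only a few ms accurate; applying the low out-of-burst
  threshold to still-elevated edge samples sprays spurious events), but
  the noise of each regime is *estimated* from the undilated masks. The
  multiplier 4.75 (not 4) keeps the Gaussian false-crossing rate below
  ~2 events/min at a 2.8-kHz filtered bandwidth, including the
  tripled in-burst noise.
- Spike detection: supra-threshold local maxima of |x| (either polarity),
  greedily retained loudest-first with a 1-ms minimum separation, aligned
  at the extremum (ties: earliest sample), with 3-ms snippets. The two
  lobes of one biphasic waveform merge into one event; distinct events on
  the flank of a wider deflection stay separate. Events too close to the
  session edges for a full snippet are dropped. Overlapping CAPs closer
  than the refractory window are counted once — the dominant source of
  the few-percent undercount of high-rate units; overlap decomposition is
  out of scope.

## Spike sorting

Snippets are clustered via 2-D t-SNE (perplexity 30, clamped to (n−1)/3;
PCA initialization; fixed seed) followed by DBSCAN (eps 4.0, min_pts 10).
The embedding input is the mean-centered top-10 PCA of the *central 2 ms*
of each snippet: only ~20 samples carry template signal, so distances on
raw or per-sample-standardized full snippets are dominated by tail noise
and by the flanks of superimposed neighbouring events. For recordings
with more than 1500 events a subsample is embedded and every snippet is
assigned to the nearest cluster template; the subsample is drawn evenly
over amplitude ranks so that frequent event types (cardiac) cannot crowd
the embedding. Clusters whose mean waveforms are near-collinear
(cosine > 0.95) with near-equal amplitude (ratio < 1.3) are merged —
fragments of one unit; distinct units differ in shape or amplitude by
construction of any resolvable recording.

Cardiac handling replaces the original manual inspection with automated
rules: a cluster is cardiac if ≥ 80 % of its spikes fall within ±2 ms of
an ECG R-peak (R-peaks: |ECG| ≥ 5× robust SD, 50-ms refractory); it is an
artifact if ≥ 80 % of its spikes lie within ±4 ms of another cluster's
spikes (zero-phase filter-ringing echoes ride symmetrically around large
waveforms) or if it is R-peak-locked at the looser ±10 ms. Independent
Poisson units coincide with these at chance level (≲ 30 %), far below the
80 % threshold. Cardiac and artifact clusters are retained in outputs but
excluded from firing analysis — their events are duplicate detections of
deflections counted elsewhere.

A third category is treated differently: *unstable* clusters, whose
within-cluster waveform SD exceeds 0.115× their peak-to-peak amplitude
(clean units sit at noise/amplitude ≲ 0.1; measured fixture clusters
separate cleanly, ≤ 0.093 for units vs ≥ 0.137 for these). They arise
when the superposition of two overlapping CAPs flips the detection
extremum to a positive lobe, producing consistently mis-aligned snippets
of otherwise real spikes. Because each of their events is a unique spike
(not a duplicate), their events are folded into the nearest clean
cluster by template matching rather than discarded, preserving spike
counts.

Waveform metrics are computed on the mean waveform: peak-to-peak
amplitude (max − min) and half-height width (span where the dominant
phase exceeds half its peak, with linear interpolation at the
crossings).

## Firing analysis

Baseline statistics use the second 10 minutes of the 20-min baseline
([600, 1200) s); period summaries use the last 10 minutes of each 20-min
period. Per-mouse values sum the mouse's included, non-cardiac units.
The inclusion rule for response analysis excludes units whose baseline
rate is strictly higher than the population mean + 1 SD, or with more
than 5 consecutive zero one-minute bins after the first injection (≥ 6
bins, "more than" read strictly). The cytokine ratio is
(f_cyt − f_BL)/(f_cyt + f_BL), undefined (reported missing) only when
both are zero. Categorization compares last-10-min period means to the
baseline statistic; an exactly-zero delta (measure zero) is assigned to
"mixed" and logged. Heatmaps normalize each unit's 10-s-binned rates to
its own peak and order rows by peak time (ties by unit id; all-zero rows
last). Group comparisons gate on Shapiro-Wilk at alpha 0.05 (both
samples normal → two-tailed t-test, else Mann-Whitney U; KS on request).

## Decoding

Features are each unit's per-second rate convolved with a unit-sum
30-point Gaussian kernel (sigma = 5 points, so the support spans ±3
sigma; edges renormalized over the valid support). The session is split
50/50 stratified by class (BL / post-first / post-second injection),
reproducibly by seed. The Gaussian naive Bayes decoder is implemented
directly (per-class feature means and variances, variances floored at
1e−6 of the global feature variance; empirical priors; log-space
posteriors; argmax decoding with ties resolved toward the earlier class
in BL < C1 < C2); scikit-learn's `GaussianNB` serves as an independent
cross-check in the tests, never as the implementation. The primary
performance number is the per-class probability of correct assignment —
the mean posterior mass on the true class over that class's test
timepoints — with hard per-class accuracy reported alongside.

## Problem sizes and tolerances

The test suite runs spike-level recovery on the first five mice of each
fixture (the planted cohort calibration is asserted exactly on the full
fixtures), and `scripts/acceptance.py` repeats it over the complete
cohorts (15 + 20 mice, 20-min baseline segments at 32 kHz; 2-min
excerpts for burst timing; full-hour stage-level rate series for
categorization and decoding). Recovery of planted rates is expected
within ~10 % — the residual bias is the refractory-window undercount of
overlapping events (~4–9 %, largest for high-rate LS units). Numerical
tie-breaks are fixed throughout: earliest sample at equal magnitude,
earlier class at equal posterior, unit id at equal heatmap peak time.

## Known limitations

- Overlapping CAPs are counted once; rates of units above ~25 CAPs/s are
  biased low by up to ~10 % at LS-like event densities.
- The inter-burst rate target reflects the partition-identity conflict
  described above.
- t-SNE + DBSCAN sorting is tuned for the fixtures' template bank
  (separations ≥ ~4× the in-burst noise in PCA space); real recordings
  with drifting or near-identical waveforms would need the CLI-exposed
  eps/min_pts/perplexity knobs.
- The decoder treats timepoints independently; no temporal model.
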