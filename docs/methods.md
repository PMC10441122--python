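# Methods

This note documents the models, defaults and numerical choices behind
`mearf`, and what the synthetic-data tests do and do not establish about
real recordings.

## Protocol model

A recording is partitioned into contiguous half-open phases
`[start, end)`; the default is five 15-min phases S1, S2, E, P1, P2
(75 min total). The half-open convention makes spike and burst binning at
boundaries unambiguous: a boundary time belongs to the later phase. All
times are float seconds from recording start. Shortened protocols (any
labels/durations) are supported for desk-scale work; S1 — the first phase —
is always the normalization and activity-filter reference.

## Spike detection

The detector implements the peak-to-peak threshold contract: a candidate
trough (local minimum) is a spike when the signal maximum within ±1 ms
(half of the 2 ms window) exceeds it by more than `threshold_factor × SD`
(default 8×). Design choices:

* **Noise SD** is `1.4826 × MAD` over a reference window (by default the
  S1 phase). The MAD is used instead of the sample SD because the
  estimation window inevitably contains spikes; sparse 100 µV transients
  shift a MAD-based estimate of 5 µV noise by well under 0.3 µV.
* **Timestamping** is at the negative peak of the excursion, the most
  stable landmark of an extracellular spike.
* **Refractory merging** (default 1 ms) accepts candidate troughs
  deepest-first and drops candidates within the refractory span of an
  accepted spike. Depth-ordered greedy acceptance has a prefix property
  that time-ordered greedy lacks: removing the shallowest candidates
  (raising the threshold) cannot change decisions made for deeper ones, so
  the spike count is provably non-increasing in the threshold factor.
  Ties break toward the earlier sample.
* Channels whose noise SD is zero (dead or saturated) are flagged and
  skipped rather than given a degenerate threshold.

The detector is deterministic and scale-equivariant (rescaling signal and
noise SD together changes nothing).

## Burst detection (logISI)

Per electrode, the histogram of `log10(ISI in ms)` is built at 0.1-decade
bins, smoothed by a 3-bin moving average. The intra-burst peak is the
*largest* smoothed peak below 100 ms; the slow peak is the largest peak
after it; the threshold is the ISI at the leftmost minimum between them.
Taking the largest rather than the literal first local maximum matters in
practice: sparse histograms produce one-count bumps (e.g. at microsecond
intervals between near-simultaneous pooled onsets) that would otherwise be
mistaken for the fast peak. If no such pair of peaks exists the fallback
threshold is 100 ms (or the configured cutoff if smaller); trains with
fewer than 10 ISIs get no threshold and no bursts. Defaults (bin width,
smoothing, 100 ms cutoff, `min_spikes = 3`) are the canonical values of the
adaptive logISI family and are all exposed in configuration.

Bursts are maximal runs of ≥ `min_spikes` spikes with ISIs at or below the
threshold. The in/out-of-burst classification is per spike, so
`spikes-in-bursts + spikes-outside-bursts = total` holds identically — the
conservation property the metrics stage inherits.

**Network bursts** apply the same valley algorithm to the inter-onset
intervals of the pooled per-electrode burst onsets (onsets, not raw spikes,
per the inter-burst-interval formulation). Groups separated by gaps above
the threshold become candidate events; an event is reported when its
distinct electrodes reach 20 % of the bursting-active set (the same
S1-defined set the metrics use as denominator). Network-burst output is
reported for synchrony inspection but feeds no scalar metric — the four
metrics are per-electrode quantities.

## Metrics

Activity filters are computed once, in S1 (spiking-active: FR ≥ 0.1 Hz;
bursting-active: burst rate ≥ 0.04 Hz, i.e. 36 bursts per 900 s), and the
same sets are used as both the summation range and the denominator in every
phase. Freezing the sets at baseline keeps the S1 = 100 % normalization
meaningful: electrodes silenced by the exposure still count, which is
precisely how suppression becomes visible. Bursts belong to the phase
containing their start (no splitting; the mass of boundary-spanning bursts
is negligible at 15-min phases), while spikes are binned by their own
times, which keeps the conservation identity exact per phase.

MBD's denominator is ambiguous between the baseline bursting-active count
and the per-phase count of electrodes that actually burst; both are
implemented (`mbd_denominator="s1"` is the default, `"per_phase"` the
alternative). A phase with no bursts on the active set yields a missing
MBD, never 0 — a zero would fabricate a duration. A culture with an empty
baseline active set raises and is flagged, not silently zeroed.
Normalization divides by the culture's S1 value before multiplying by 100
so the baseline lands on exactly 100.0 in floating point; renormalizing a
normalized table is the identity.

The MBR time course counts bursts of the bursting-active set in 60 s bins,
scaled to bursts/min per electrode and normalized to the culture's S1 mean,
then aggregated as mean ± SEM across cultures.

## Phase statistics

Kruskal–Wallis (scipy, tie-corrected, chi-square reference with k−1 df) is
the omnibus; the all-pairs post-hoc is the Conover–Iman procedure computed
from the same pooled ranks, `t = (R̄_i − R̄_j) / sqrt(S² ((N−1−H)/(N−k))
(1/n_i + 1/n_j))` with N−k degrees of freedom, two-sided. Pairwise p-values
are Holm-adjusted over the 10 phase pairs; the adjustment is recorded in
the report and configurable. The four metrics are treated as separate
families (no correction across metrics), matching per-metric presentation.
Effect sizes are median percent changes on normalized values,
`100 (med_a − med_b)/med_b`, negative meaning a decrease in `a` relative to
the reference `b`.

At the study's sham sample size (19 cultures per phase group) the
simulated type-I error of the omnibus at α = 0.05 sits in the nominal band;
at much smaller group sizes the chi-square reference is conservative
(rejection rates slightly below 3 % for n = 10), which is the expected
small-sample behavior of the approximation, not an implementation artifact.

## Dosimetry

The sample is modeled as a single thermal compartment: under constant
absorbed power the temperature rise is `ΔT(t) = (SAR·τ/C)(1 − e^(−t/τ))`,
whose initial slope is exactly `SAR/C`, and the post-exposure tail decays
with the same τ. Heat loss appears only through the exponential
saturation — no extra parameters are introduced that a temperature probe
cannot constrain. SAR estimation fits this form by least squares over the
window from exposure onset to `t_on + min(5 min, exposure duration)`: long
enough to constrain τ, short enough to stay in the initial phase the slope
definition refers to. Initialization (`A = max ΔT`, `τ = span/3`) with
positivity bounds converges for every transient exercised; a
non-convergent fit or non-positive amplitude raises, with an optional
explicitly-flagged linear fit over the first 30 s as fallback. Reported
SAR is rounded to 3 significant figures; the raw value is kept.

With C = 4196.8 J/(kg K) (culture medium) and τ = 120 s — the time constant
consistent with a 0.80 °C steady-state rise at 28 W/kg — the model
reproduces the worked examples used in the acceptance checks. dBm
bookkeeping is exact arithmetic: `P = SAR_target / (SAR per watt)`,
reported to 0.1 dBm.

## Synthetic-data generator

The generator is a doubly stochastic network-burst model chosen to
reproduce the statistics the pipeline depends on — synchrony across
electrodes, bimodal ISI structure, a silent-electrode margin — rather than
any biophysics:

* **Network-burst events**: Poisson process at `network_burst_rate ×
  m(t)`, sampled exactly by thinning against the piecewise multiplier
  profile. Each event recruits each burst-capable electrode with
  `participation_prob`; a recruited electrode's burst has a
  negative-binomial spike count and jittered-normal intra-burst ISIs, with
  the burst onset jittered N(0, 10 ms) per electrode.
* **Tonic spikes**: independent Poisson per electrode, unaffected by
  burst-rate suppression.
* **Suppression modes**: per-phase multipliers on burst-initiation rate
  (exposure-like; leaves burst duration and tonic rate unchanged, so MBD
  and MOBFR stay flat while MBR/MFR drop), on tonic rate, or on per-spike
  retention (heat-like uniform thinning of all spikes). `persistent=True`
  extends E-phase multipliers through P1/P2 for the non-reversible
  scenario. Multipliers may relax exponentially at transitions
  (`onset_tau_s`, `recovery_tau_s`); the default is an instantaneous step,
  matching the recovery experiments, with the gradual mode exercised in
  the time-course tests.

Baseline defaults — 60 electrodes, 15 network bursts/min, participation
0.6, ~12 spikes/burst at ~8 ms ISI (≈ 90 ms bursts), tonic 0.5 Hz, 10 %
near-silent electrodes at 0.02 Hz — describe a mature (third-week)
dissociated cortical culture in the regime where activity is balanced
between random spikes and synchronized bursts. Absolute baseline rates are
not prescribed by the phenomena being modeled and are stated here as
config, not inferred claims; all are overridable. At these defaults a
culture carries ~540 k spikes over 75 min and analysis runs in well under a
second per culture, so the recovery experiments (13–16 cultures) are
desk-scale.

Waveform synthesis renders spike trains as biphasic ~1 ms templates
(negative lobe first, aligned at the negative peak) in white Gaussian
noise; only the peak-to-peak amplitude matters to the detector, so no
attempt is made at realistic spike shapes or correlated noise.

The generator reproduces: Poisson event statistics, binomial recruitment,
a bimodal ISI histogram, step or exponential suppression, first-order
heating with white measurement noise. It does **not** reproduce: burst
propagation structure, refractory interactions between events, rate drift
or culture aging within a session, electrode cross-talk, or non-white
noise. Passing recovery tests therefore establishes that the pipeline is
an unbiased estimator of suppression under the stated statistical
structure — not that detection is robust to every artifact of a real rig.

## Reproducibility

Every stochastic component takes a seed; one master seed expands to
per-culture seeds (kept below 2³¹) via numpy's `SeedSequence`, and
identical config + seed yields byte-identical outputs including persisted
CSVs. Orchestrated runs write every intermediate plus a manifest with all
parameters, seeds and the package version.

## Known limitations

* The peak-to-peak detector's sub-variant details (exact pairing of
  extrema within the window) follow the stated contract, not a specific
  legacy codebase; recordings at the margin of 8×SD may differ in single
  spikes from other implementations.
* The logISI valley is resolved at 0.1-decade resolution; thresholds are
  only meaningful to about one bin.
* The Conover post-hoc adjustment (Holm) is one defensible choice among
  several; the report records which was used.
* The thermal model is single-compartment; probe placement effects,
  convection and non-exponential early transients are out of scope.
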