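# Methods

This note documents the models, estimators and numerical choices behind
each analysis stage, what the synthetic generators do and do not emulate,
and the design decisions that were genuinely open.

## Time base and units

Time is in seconds, zero at epoch start; epochs are half-open
`[0, epoch_duration)`, so `mean_rate = n_spikes / epoch_duration` is
unambiguous. Spike waveform durations are in ms (onset to negative
peak), currents in pA (inward stored negative, amplitudes reported as
positive magnitudes with the direction recorded), potentials in mV,
charge in pA·ms. No unit inference is performed anywhere.

## Unit inclusion criteria

Putative dopaminergic units are admitted by waveform duration. In vivo,
a unit is kept only if its **median** per-spike duration is ≥ 1.1 ms —
the median summarizes the per-spike measurements into the per-unit
criterion, a choice that had to be made because only per-spike durations
exist in the data model; it is robust to a few mis-measured spikes. In
vitro, individual spikes shorter than 2 ms are dropped before any
statistic, and the pruned train is analyzed.

## Burst detection

The classic two-threshold rule for dopaminergic units: an ISI < 80 ms
between consecutive spikes opens a burst; subsequent ISIs ≤ 160 ms extend
it; the first ISI > 160 ms closes it. Three boundary conventions were
open and are fixed as follows:

* ISIs in [80, 160] ms extend an open burst but can never open one (the
  onset and termination conditions say nothing else about this band, and
  this is the standard reading);
* exactly 80 ms does not open, exactly 160 ms continues; comparisons use
  a 1e-6 ms tie tolerance so that float round-trips of boundary ISIs do
  not flip a decision;
* both spikes of the onset pair count as in-burst — otherwise SWB = 100 %
  would be unreachable.

Minimum burst size is 2; a train with fewer than 2 spikes yields an empty
burst set, not an error. Burst frequency is reported in Hz (bursts/s)
and burst duration in seconds; output columns carry the units in their
names since conventions differ between laboratories.

The detector is validated two independent ways: exhaustively against a
regex-based rule applier on all 4^7 ISI sequences over {40, 100, 120,
200} ms, and against generator packet labels on two-state synthetic
trains, where agreement is exact by the detectability constraints below.

## ISI coefficient of variation

CV (%) = 100 · σ/μ with σ from a least-squares Gaussian fit to the ISI
histogram (default bin width 10 ms, a compromise between resolution and
counting noise at a few hundred ISIs) and μ taken from the same fit.
The fit is initialized at the sample mean/sd with 1e-8 parameter
tolerance. Fallback to the sample sd/mean — flagged in the result — is
triggered by non-convergence, a non-physical μ ≤ 0, or fit R² < 0.8.
The R² guard matters: on a bimodal bursty ISI histogram a single
Gaussian latches onto one mode and reports a meaninglessly small σ while
"converging" happily; unimodal pacemaker histograms at the sample sizes
used here fit with R² > 0.93, so the 0.8 threshold separates the two
regimes cleanly. Fewer than 10 ISIs is an error (the histogram is not
fittable), and degenerate zero-variance trains return CV = 0 via the
fallback.

## Drug-response quantification

Rates are binned at 20 s on a grid anchored at the baseline-window start;
both windows must sit on the grid. Normalization sets the mean rate over
the 60 s immediately before application to 100 % — exactly, which the
tests assert — and the response is the mean normalized rate over the
bins strictly inside the application window, minus 100. Units with a
silent baseline are excluded (the ratio is undefined), never imputed.
All application-window bins are averaged, including onset/offset bins;
partial-suppression transients are part of the response by this
definition. Separate iontophoresis current doses are separate protocol
labels analyzed independently.

## mIPSC detection

The reference event-detection program is proprietary, so the scheme here
is built from its two documented facts — an 8 pA threshold and
baseline-to-peak amplitudes — plus choices of our own:

1. **Baseline**: trailing rolling median of the raw current over 500 ms.
   The window must be long relative to an event's footprint: with ~40 ms
   events at a few Hz the duty cycle is under 10 %, so a 500 ms median
   is unperturbed, while a 50 ms window is dragged down by the event
   itself and visibly squeezes the decay of the averaged waveform.
2. **Deflection**: d = baseline − current (positive inward), smoothed
   with a 1 ms boxcar for detection only.
3. **Candidates**: peaks of d above the threshold with *prominence* at
   least the threshold. The prominence requirement is what separates a
   genuine second event from noise wiggles as a decay tail hovers near
   the threshold — those re-cross the threshold but climb only a noise
   standard deviation above the intervening valley.
4. **Onset**: last sample before the peak where d is below 10 % of the
   event amplitude; **amplitude** is baseline-to-peak on smoothed d.
5. **Double peaks** (excluded from kinetics and per-cell statistics) are
   flagged by three complementary rules: a second candidate peak within
   the 5 ms inter-event refractory (unresolvable overlap); the next peak
   arriving before d decays to 50 % of the current event's amplitude;
   and two distinct rising phases within one event span — a
   Savitzky–Golay slope (≈1.1 ms window, quadratic) of the raw
   deflection that exceeds threshold/2 pA/ms, with hysteresis and a
   minimum per-phase gain of one threshold. The third rule is needed for
   pairs a few ms apart, which fuse into a single peak with a two-stage
   rise that no threshold-crossing count can see. Pairs closer than
   ~2 ms remain below the method's resolution.

Sampling below 2 kHz is rejected outright (rise times of ~1.5 ms are not
resolvable). On pure 2 pA noise the false-positive rate is < 0.05
events/s; on the standard regime (2 Hz, 30 ± 5 pA, τ 1.5/7 ms, 2 pA
noise) frequency, amplitude and decay are recovered within 10 % (median
over 100 seeds), with a known mild undercount (~5 %) from overlap
exclusion.

## mIPSC kinetics

Kinetics are measured on the *raw* baseline-subtracted deflection — the
detection smoothing would broaden a 1.6 ms rise by ~0.2 ms. Rise time is
t(90 %) − t(10 %) with linear interpolation between samples. The decay
constant is a free-amplitude single-exponential least-squares fit over
the **50 %-of-peak → 10 %-of-peak** span, initialized at half-decay-time
/ ln 2 with 1e-8 tolerances. The span choice is deliberate: a fit
anchored at the peak absorbs the not-yet-vanished rise component and
overestimates τ by ~16 % for τ_rise/τ_decay = 1.5/7 ms, whereas starting
at half-decay recovers τ to < 1 % on noiseless events (verified
analytically for both the 7 ms and 8.5 ms regimes).

Per-cell kinetics require more than 50 accepted events and default to an
onset-aligned **averaged waveform** (one fit on the mean), matching the
convention of averaging selected events; per-event fit averaging is
available as an option. Only *isolated* events — no neighbouring
detected event, accepted or not, within the 60 ms averaging window —
enter the average; a neighbour's tail otherwise inflates the fitted τ by
up to 15 %.

## Evoked and intrinsic currents

**GABA-evoked peak**: maximum baseline-subtracted inward deflection after
the puff-on mark, on a 1 ms boxcar-smoothed trace — the raw maximum of a
noisy plateau is an extreme order statistic and biases the peak (and any
blockade ratio computed from it) upward by several noise sd. Percent
blockade is 100 · blocked/control on these peaks.

**AHP tail**: peak (fast component) and trapezoidal charge transfer
(slow component) of the outward tail after the pulse-end mark,
integrated until the current first returns to baseline or the trace
ends. A tail whose smoothed maximum never exceeds baseline + 2 σ of the
pre-pulse noise is flagged as a zero response (again, the raw maximum
would never satisfy this on any noisy trace). Charge converges to the
analytic A·τ with sampling rate and is within 1 % at 5 kHz.

**I_h**: the sag develops with a ~100 ms time constant, so it is already
partly activated at any post-transient read-out point. The measurement
therefore fits a − b·exp(−t/τ) to the step current from 20 ms after
onset (past the capacitive transient) and reports |b|, the sag amplitude
extrapolated back to step onset; a steady-state-minus-instantaneous
subtraction at 20 ms would systematically undershoot by ~15 %.

**Passive properties**: the seal-test transient is fitted with a single
exponential whose extrapolated t = 0 amplitude gives I_peak (the first
recorded sample already lies ~Δt/τ down the transient); then
Rs = ΔV/I_peak, Rm = ΔV/I_ss − Rs, Cm = τ/(Rs‖Rm). On an ideal RC trace
all three are recovered to better than 2 %.

## Group statistics

Cells are the unit of analysis; animal counts are carried in summary
rows for transparency but not modelled (no hierarchical inference).
Mann–Whitney U is exact for combined n ≤ 20 without ties and otherwise
uses the tie-corrected normal approximation with continuity correction;
its type-I error at α = 0.05 is within [0.04, 0.06] in 10,000-rep null
simulations, as is one-way ANOVA's. Fully tied samples return p = 1
with a warning rather than an error. The post-hoc procedure after ANOVA
is Holm-adjusted pairwise Mann–Whitney — distribution-free and
consistent with the primary test — and is a configuration option, since
the choice is not dictated by anything in the analysis itself. The
two-sample KS test (asymptotic p) operates on pooled per-cell amplitude
subsamples: exactly 100 events per cell, seeded uniform subsampling,
cells with fewer accepted events excluded with a log entry, so that
heavy-event cells do not dominate the pooled distribution.

## Synthetic data: what it emulates, what it does not

**Spike trains.** Three ISI models: truncated-normal pacemaker ISIs
(absolute refractory floor 2 ms — the physiological floor, and the
truncation point), exponential ISIs with the same floor, and a
two-state model alternating burst packets with singleton spikes. In the
two-state model, packet-internal ISIs are truncated-normal strictly
below 80 ms and inter-event gaps strictly above 160 ms, so designed
packets are detectable *by construction* and detector-vs-label agreement
is exact — burst ground truth is defined by the generator's packets, not
by the detector, which keeps the validation non-circular. The packet
probability p solves p·E[size]/(p·E[size] + 1 − p) = f for the target
in-burst fraction f, and the gap mean is then solved so the overall mean
rate is hit; truncated-normal locations are calibrated (by root-finding
on the truncated mean) so truncation never shifts realized means.
Packets truncated by the epoch end to a single spike are relabeled
non-burst. An infeasible combination (gap mean forced ≤ 160 ms) raises
a config error rather than silently degrading. Optional between-unit
rate heterogeneity (`rate_sd`) draws each unit's mean rate from a
truncated normal; the cohort pipeline uses sds back-computed from the
reported group SEMs (≈1.2–1.5 Hz in vivo, 0.6 Hz in slices) because
cell-to-cell rate scatter in real cohorts far exceeds counting noise —
without it, a 0.3 Hz regime difference is spuriously "significant".

**Drug epochs** multiply the firing intensity by (1 + effect) inside the
window: thinning for suppression (each in-window spike kept with
probability 1 + effect), superposition of an independent Poisson train
for facilitation. Both preserve the ISI model outside the window.

**mIPSC traces** superpose difference-of-exponentials events — rise and
decay independently parameterized, peak-normalized so the drawn
amplitude is exact — at Poisson onset times on a flat baseline with
i.i.d. Gaussian noise. Not emulated: baseline drift, 50/60 Hz
interference, series-resistance filtering, amplitude–kinetics
correlations, or vesicular amplitude skew (amplitudes are truncated
normal). Passing tests therefore demonstrate correctness of the
estimators under stationary noise, not robustness to instrument
artifacts.

**Step protocols** are analytic (plateau with exponential edges, pure
exponential tail, instantaneous-plus-developing sag, ideal RC transient)
plus optional Gaussian noise, and return their analytic peak/integral
truth alongside.

All generators are deterministic given a single integer seed; per-unit
streams derive from (seed, unit index) so cohorts are reproducible under
any iteration order.

## The cohort pipeline

`run_pipeline` chains generation → QC → burst table → slice contrast →
muscimol response → mIPSC detection/kinetics/pooling → evoked and
intrinsic currents → report. Group regimes default to the study
conditions (rates 4.8/5.1 Hz with in-burst fractions 0.31/0.67, GABA
peaks 825/491 pA, AHP 662/727 pA with ~10.8k/9.0k pA·ms charge, I_h
425/437 pA, tabulated passive properties, measured mIPSC kinetics of
10–90 rise 1.4/1.9 ms and decay 6.9/8.5 ms — the generator's exponential
rise constants are backed out so the *measured* rise lands on those
values — muscimol −37.7 %/−15.0 %). Per-cell mIPSC rates and
amplitudes are not printed in the source material (only plotted), so
2.5 vs 1.6 Hz and 30 vs 22 pA with 80 s traces were fixed once — large
enough that every cell clears both the >50-event kinetics rule and the
100-event pooling rule, while preserving the reported effect direction.
Problem sizes (120 s epochs, 80 s patch traces at 5 kHz, the printed
cell counts) keep a full run around half a minute on one CPU. The
manifest records the config hash, package version and seed — and no
wall-clock data, so identical config + seed reproduce bit-identical
report directories.

## Known limitations

* Overlapping synaptic events closer than ~2 ms are unresolvable and
  events closer than ~60 ms are excluded from waveform averaging; at
  high event rates (≳5 Hz) the accepted-event frequency undercounts.
* The Gaussian-fit CV is only meaningful for unimodal ISI histograms;
  bursty trains deliberately fall back to the sample CV, which is then a
  mixture statistic.
* The burst criterion is a fixed-threshold rule; it does not adapt to a
  unit's own rate, and trains with mean ISIs near 80–160 ms sit on its
  sensitive boundary.
* No series-resistance compensation, liquid-junction correction, or
  vendor acquisition formats; inputs are plain CSV/JSON.
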