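"""Miniature synaptic-event detection, kinetics and evoked-current measures.

Detection scheme (thresholded baseline-subtracted deflection):

1. baseline = trailing rolling median of the raw current (500 ms window,
   long relative to the ~6 % duty cycle of events so the events themselves
   do not drag the baseline);
2. inward deflection d = baseline - current (positive for inward events),
   lightly smoothed with a ~1 ms boxcar to suppress single-sample noise
   excursions;
3. candidate events = peaks of the smoothed deflection exceeding the
   threshold (default 8 pA), separated by at least the inter-event
   refractory (5 ms);
4. onset = last sample before the peak where the deflection is below 10 %
   of the event amplitude; amplitude = baseline-to-peak deflection;
5. double peaks: if the next event's peak arrives before the deflection
   has decayed to 50 % of the current event's amplitude, both events are
   flagged and excluded from kinetics averaging.

Kinetics: 10-90 % rise time with linear interpolation between samples;
decay time constant from a free-amplitude single-exponential least-squares
fit over the 50 %-of-peak -> 10 %-of-peak span of the decay (starting the
fit at half-decay rather than at the peak keeps the fast rise component
from biasing the fitted constant), initialized at half-decay-time / ln 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, savgol_filter

from .datatypes import (
    CurrentTrace,
    EvokedResponse,
    MiniCellSummary,
    MiniEvent,
    PassiveProperties,
)
from .errors import ConfigError, ProtocolError, ResolutionError, ValidationError

MIN_SAMPLING_RATE = 2000.0


@dataclass
class DetectionConfig:
    """Mini-event detection parameters (times in ms, threshold in pA)."""

    threshold: float = 8.0
    baseline_window: float = 500.0
    min_interevent: float = 5.0
    peak_search_window: float = 10.0
    smooth: float = 1.0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ConfigError("threshold must be > 0")
        if min(self.baseline_window, self.min_interevent, self.peak_search_window) <= 0:
            raise ConfigError("detection windows must be > 0")


def _trailing_median(x: np.ndarray, window: int) -> np.ndarray:
    return (
        pd.Series(x).rolling(window, min_periods=1).median().to_numpy()
    )


def _boxcar(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def deflection(trace: CurrentTrace, cfg: DetectionConfig):
    """(smoothed inward deflection, raw deflection) in pA, baseline-subtracted."""
    win = max(int(cfg.baseline_window / 1e3 * trace.sampling_rate), 1)
    baseline = _trailing_median(trace.current, win)
    raw = baseline - trace.current  # positive = inward
    width = max(int(round(cfg.smooth / 1e3 * trace.sampling_rate)), 1)
    return _boxcar(raw, width), raw


def detect_minis(
    trace: CurrentTrace, cfg: DetectionConfig | None = None
) -> list[MiniEvent]:
    """Detect miniature inward synaptic events in an mIPSC trace.

    Raises
    ------
    ProtocolError
        Trace protocol is not ``mipsc``.
    ResolutionError
        Sampling rate below 2 kHz (rise times unresolvable).
    """
    cfg = cfg or DetectionConfig()
    if trace.protocol != "mipsc":
        raise ProtocolError(f"cell {trace.cell_id}: protocol {trace.protocol!r} != mipsc")
    if trace.sampling_rate < MIN_SAMPLING_RATE:
        raise ResolutionError(
            f"cell {trace.cell_id}: {trace.sampling_rate} Hz < 2 kHz minimum"
        )
    d, raw = deflection(trace, cfg)
    fs = trace.sampling_rate
    refractory = max(int(cfg.min_interevent / 1e3 * fs), 1)

    # candidate peaks must exceed the threshold AND rise by >= threshold
    # above the surrounding valleys (prominence): a noise wiggle on a decay
    # tail hovering near threshold re-crosses it but only climbs ~noise-sd
    # above the valley, so it is not a new event
    cand, _props = find_peaks(d, height=cfg.threshold, prominence=cfg.threshold)

    peaks: list[int] = []
    merged_double: set[int] = set()
    for p_abs in cand:
        p_abs = int(p_abs)
        if peaks and p_abs - peaks[-1] < refractory:
            # within the refractory of the previous peak: one event,
            # but an unresolvable overlap -> flag it
            if d[p_abs] > d[peaks[-1]]:
                peaks[-1] = p_abs
            merged_double.add(len(peaks) - 1)
        else:
            peaks.append(p_abs)

    events: list[MiniEvent] = []
    for k, p in enumerate(peaks):
        amp = float(d[p])
        back = d[:p][::-1]
        below = np.flatnonzero(back < 0.1 * amp)
        onset_idx = p - 1 - below[0] if below.size else 0
        events.append(
            MiniEvent(
                onset_time=onset_idx / fs,
                peak_time=p / fs,
                amplitude=amp,
                is_double_peak=k in merged_double,
            )
        )
    # overlap flagging: the next peak arrives before this event's deflection
    # has decayed to 50 % of its amplitude -> both events are contaminated
    for k in range(len(events) - 1):
        seg = d[peaks[k] : peaks[k + 1]]
        if not np.any(seg < 0.5 * events[k].amplitude):
            events[k].is_double_peak = True
            events[k + 1].is_double_peak = True
    # merged-complex flagging: two events closer than the rise time fuse
    # into a single peak with a two-stage rise; look for a second distinct
    # rising phase before the 50 %-decay point
    for k, ev in enumerate(events):
        if ev.is_double_peak:
            continue
        o = int(ev.onset_time * fs)
        p = peaks[k]
        below = np.flatnonzero(d[p:] < 0.5 * ev.amplitude)
        end = p + (int(below[0]) if below.size else 0)
        end = min(end, peaks[k + 1]) if k + 1 < len(peaks) else end
        if _n_rising_phases(raw[o:end], fs, cfg) >= 2:
            ev.is_double_peak = True
    return events


def _n_rising_phases(raw_seg: np.ndarray, fs: float, cfg: DetectionConfig) -> int:
    """Count distinct rising phases of an event segment.

    The local slope is a Savitzky-Golay first derivative (~1.1 ms window,
    quadratic) of the *raw* deflection — wide enough to suppress sample
    noise, narrow enough to preserve the brief slope dip left by a second
    event arriving only a few ms after the first. A phase starts when the
    slope exceeds threshold/2 per ms and only ends once it drops below
    half of that (hysteresis, so a momentary noise dip does not split one
    rise in two); a phase must gain at least the detection threshold in
    amplitude to count, so noise flutter near the peak never registers as
    a second phase.
    """
    wl = max(int(1.1e-3 * fs) // 2 * 2 + 1, 5)
    if raw_seg.size < wl + 2:
        return 1
    smooth = savgol_filter(raw_seg, wl, 2)
    slope = savgol_filter(raw_seg, wl, 2, deriv=1, delta=1e3 / fs)  # pA/ms
    hi = cfg.threshold / 2.0
    lo = hi / 2.0
    n = 0
    in_phase = False
    start = 0
    for i, s in enumerate(slope):
        if not in_phase and s > hi:
            in_phase = True
            start = i
        elif in_phase and s < lo:
            in_phase = False
            if smooth[i] - smooth[start] >= cfg.threshold:
                n += 1
    if in_phase and smooth[-1] - smooth[start] >= cfg.threshold:
        n += 1
    return n


def event_kinetics(
    events: list[MiniEvent], trace: CurrentTrace, cfg: DetectionConfig | None = None
) -> list[MiniEvent]:
    """Fill rise/decay kinetics of non-double-peak events in place.

    Events whose decay fit does not converge keep NaN kinetics. Returns
    the same list for chaining.
    """
    cfg = cfg or DetectionConfig()
    _, raw = deflection(trace, cfg)  # kinetics on the unsmoothed deflection
    fs = trace.sampling_rate
    onsets = [int(e.onset_time * fs) for e in events]
    for k, ev in enumerate(events):
        if ev.is_double_peak:
            continue
        p = int(round(ev.peak_time * fs))
        o = onsets[k]
        nxt = onsets[k + 1] if k + 1 < len(events) else raw.size
        rise = _rise_time_10_90(raw[o : p + 1], ev.amplitude, fs)
        tau = _fit_decay_tau(raw[p:nxt], ev.amplitude, fs)
        ev.rise_time_10_90 = rise
        ev.decay_tau = tau
    return events


def _rise_time_10_90(seg: np.ndarray, amp: float, fs: float) -> float:
    """10-90 % rise time in ms with linear interpolation between samples."""
    if seg.size < 2:
        return float("nan")
    t10 = _last_crossing(seg, 0.1 * amp)
    t90 = _last_crossing(seg, 0.9 * amp)
    if np.isnan(t10) or np.isnan(t90) or t90 <= t10:
        return float("nan")
    return (t90 - t10) / fs * 1e3


def _last_crossing(seg: np.ndarray, level: float) -> float:
    """Fractional index of the last upward crossing of ``level`` in ``seg``."""
    above = seg >= level
    idx = np.flatnonzero(~above[:-1] & above[1:])
    if idx.size == 0:
        return 0.0 if above[0] else float("nan")
    i = idx[-1]
    frac = (level - seg[i]) / (seg[i + 1] - seg[i])
    return i + frac


def _fit_decay_tau(seg: np.ndarray, amp: float, fs: float) -> float:
    """Single-exponential decay constant (ms) over the 50 % -> 10 % span."""
    below50 = np.flatnonzero(seg < 0.5 * amp)
    below10 = np.flatnonzero(seg < 0.1 * amp)
    if below50.size == 0:
        return float("nan")
    start = below50[0]
    end = below10[0] if below10.size else seg.size
    if end - start < 4:
        return float("nan")
    y = seg[start:end]
    t = np.arange(y.size) / fs * 1e3  # ms
    half_decay_ms = start / fs * 1e3
    tau0 = max(half_decay_ms / np.log(2.0), 1e-3)
    try:
        popt, _ = curve_fit(
            lambda x, a, tau: a * np.exp(-x / tau),
            t,
            y,
            p0=[y[0], tau0],
            xtol=1e-8,
            ftol=1e-8,
            maxfev=2000,
        )
    except RuntimeError:
        return float("nan")
    tau = float(popt[1])
    return tau if tau > 0 else float("nan")


MIN_EVENTS_FOR_KINETICS = 50  # averaged kinetics need more than this


def cell_summary(
    events: list[MiniEvent],
    trace: CurrentTrace,
    cfg: DetectionConfig | None = None,
    kinetics_mode: str = "averaged",
) -> MiniCellSummary:
    """Per-cell mIPSC summary.

    Amplitude and frequency are computed over accepted (non-double-peak)
    events. Averaged kinetics are computed only when more than 50 events
    were accepted: with ``kinetics_mode="averaged"`` (default) an
    onset-aligned mean waveform is built and fitted once; with
    ``"per_event"`` the per-event fits are averaged instead.
    """
    cfg = cfg or DetectionConfig()
    accepted = [e for e in events if not e.is_double_peak]
    n = len(accepted)
    freq = n / trace.duration
    mean_amp = float(np.mean([e.amplitude for e in accepted])) if n else float("nan")
    rise = tau = float("nan")
    if n > MIN_EVENTS_FOR_KINETICS:
        if kinetics_mode == "per_event":
            rises = [e.rise_time_10_90 for e in accepted if np.isfinite(e.rise_time_10_90)]
            taus = [e.decay_tau for e in accepted if np.isfinite(e.decay_tau)]
            rise = float(np.mean(rises)) if rises else float("nan")
            tau = float(np.mean(taus)) if taus else float("nan")
        elif kinetics_mode == "averaged":
            rise, tau = _averaged_waveform_kinetics(accepted, events, trace, cfg)
        else:
            raise ConfigError(f"unknown kinetics_mode {kinetics_mode!r}")
    return MiniCellSummary(
        cell_id=trace.cell_id,
        n_events=n,
        event_frequency=freq,
        mean_amplitude=mean_amp,
        averaged_rise=rise,
        averaged_decay_tau=tau,
        group=trace.group,
    )


def _averaged_waveform_kinetics(accepted, all_events, trace, cfg):
    """Kinetics of the onset-aligned mean waveform of *isolated* events.

    Isolation is judged against every detected event (accepted or not): a
    neighbouring event inside the averaging window — even one excluded as
    a double peak — would contaminate the mean and inflate the fitted
    decay.
    """
    _, d = deflection(trace, cfg)  # raw deflection; averaging suppresses noise
    fs = trace.sampling_rate
    pre = int(2e-3 * fs)
    post = int(60e-3 * fs)
    all_onsets = np.array(sorted(e.onset_time for e in all_events))
    segs = []
    for ev in accepted:
        o = int(ev.onset_time * fs)
        i = int(np.searchsorted(all_onsets, ev.onset_time))
        gap_prev = ev.onset_time - all_onsets[i - 1] if i > 0 else np.inf
        gap_next = all_onsets[i + 1] - ev.onset_time if i + 1 < all_onsets.size else np.inf
        isolated = gap_prev * fs > post and gap_next * fs > post
        if isolated and o - pre >= 0 and o + post < d.size:
            segs.append(d[o - pre : o + post])
    if not segs:
        return float("nan"), float("nan")
    mean_wave = np.mean(segs, axis=0)
    mean_wave = mean_wave - np.median(mean_wave[:pre])
    p = int(np.argmax(mean_wave))
    amp = float(mean_wave[p])
    rise = _rise_time_10_90(mean_wave[: p + 1], amp, fs)
    tau = _fit_decay_tau(mean_wave[p:], amp, fs)
    return rise, tau


def pool_for_cumulative(
    amplitudes_by_cell: dict[str, np.ndarray],
    events_per_cell: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, list[str]]:
    """Seeded subsample of exactly ``events_per_cell`` amplitudes per cell,
    concatenated; cells with fewer accepted events are excluded.

    Returns (pooled amplitudes, excluded cell ids).
    """
    rng = np.random.default_rng(seed)
    pooled = []
    excluded = []
    for cell_id in sorted(amplitudes_by_cell):
        amps = np.asarray(amplitudes_by_cell[cell_id], dtype=float)
        if amps.size < events_per_cell:
            excluded.append(cell_id)
            continue
        pooled.append(rng.choice(amps, size=events_per_cell, replace=False))
    return (
        np.concatenate(pooled) if pooled else np.empty(0),
        excluded,
    )


# ---------------------------------------------------------------------------
# evoked and intrinsic currents


def _mark_time(trace: CurrentTrace, *names: str) -> float:
    for t, desc in trace.stimulus_marks:
        if desc in names:
            return t
    raise ProtocolError(
        f"cell {trace.cell_id}: no stimulus mark {names} on this trace"
    )


def gaba_evoked_peak(trace: CurrentTrace) -> EvokedResponse:
    """Peak inward current evoked by GABA superfusion.

    Baseline is the median pre-stimulus current; the peak is the maximum
    baseline-subtracted inward deflection after the puff-on mark (lightly
    smoothed with a 1 ms boxcar so the reported peak of the slow evoked
    current is not the extreme order statistic of the sample noise),
    reported as a positive magnitude (inward convention recorded in
    ``direction``).
    """
    if trace.protocol != "gaba_puff":
        raise ProtocolError(f"cell {trace.cell_id}: protocol is not gaba_puff")
    t_on = _mark_time(trace, "puff_on")
    i_on = trace.index_at(t_on)
    if i_on >= trace.n_samples:
        raise ProtocolError(f"cell {trace.cell_id}: no post-stimulus samples")
    baseline = float(np.median(trace.current[:i_on])) if i_on else 0.0
    defl = baseline - trace.current[i_on:]  # inward positive
    defl = _boxcar(defl, max(int(1e-3 * trace.sampling_rate), 1))
    peak = float(np.max(defl))
    return EvokedResponse(
        cell_id=trace.cell_id,
        peak_amplitude=peak,
        charge_transfer=float("nan"),
        measurement_window=(t_on, trace.duration),
        direction="inward",
    )


def percent_blockade(control: EvokedResponse, blocked: EvokedResponse) -> float:
    """Percent of the control evoked peak remaining under blocker co-application."""
    if control.peak_amplitude <= 0:
        raise ValidationError("control peak must be > 0 for percent blockade")
    return 100.0 * blocked.peak_amplitude / control.peak_amplitude


def ahp_measures(trace: CurrentTrace, noise_sigma: float | None = None) -> EvokedResponse:
    """Peak amplitude and charge transfer of the outward AHP tail current.

    The outward tail after the pulse-end mark is baseline-subtracted
    (median pre-pulse current); charge transfer is the trapezoidal
    integral from pulse end until the current first returns to baseline
    (or the trace ends), in pA*ms. The fast AHP component is estimated by
    the peak, the slow component by the charge. Tails whose *smoothed*
    (1 ms boxcar) maximum never exceeds baseline + 2 sigma of the
    pre-pulse noise are flagged as zero responses — the raw maximum of a
    flat noisy tail is itself a several-sigma order statistic and would
    never flag.
    """
    if trace.protocol != "ahp":
        raise ProtocolError(f"cell {trace.cell_id}: protocol is not ahp")
    t_end = _mark_time(trace, "pulse_end")
    i_end = trace.index_at(t_end)
    pre = trace.current[:i_end]
    baseline = float(np.median(pre)) if pre.size else 0.0
    sigma = float(np.std(pre)) if noise_sigma is None else noise_sigma
    tail = trace.current[i_end:] - baseline  # outward positive
    peak = float(np.max(tail)) if tail.size else 0.0
    smooth_peak = (
        float(np.max(_boxcar(tail, max(int(1e-3 * trace.sampling_rate), 1))))
        if tail.size
        else 0.0
    )
    if smooth_peak <= 2.0 * sigma:
        return EvokedResponse(
            cell_id=trace.cell_id,
            peak_amplitude=0.0,
            charge_transfer=0.0,
            measurement_window=(t_end, trace.duration),
            direction="outward",
            zero_response=True,
        )
    below = np.flatnonzero(tail <= 0.0)
    stop = int(below[0]) if below.size else tail.size
    dt_ms = 1e3 / trace.sampling_rate
    charge = float(np.trapezoid(tail[:stop], dx=dt_ms))
    return EvokedResponse(
        cell_id=trace.cell_id,
        peak_amplitude=peak,
        charge_transfer=charge,
        measurement_window=(t_end, t_end + stop / trace.sampling_rate),
        direction="outward",
    )


INSTANTANEOUS_DELAY_S = 0.020  # read the "instantaneous" step current here
STEADY_STATE_SPAN_S = 0.050  # mean over the last 50 ms of the step


def ih_and_passive(trace: CurrentTrace, step_mv: float | None = None) -> PassiveProperties:
    """Hyperpolarization-activated current and/or passive membrane properties.

    For an ``ih`` trace: I_h = |steady-state - instantaneous| step current,
    with the instantaneous current read 20 ms after step onset (past the
    capacitive transient) and the steady state averaged over the last
    50 ms of the step.

    For a ``seal_test`` trace: the capacitive transient of a small voltage
    step is fitted with a single exponential; Rs = dV/I_peak (peak
    extrapolated back to step onset), Rm = dV/I_ss - Rs and
    Cm = tau / (Rs || Rm), the standard single-compartment estimates.

    ``step_mv`` overrides the step size when the trace metadata lacks it.
    """
    if trace.protocol not in ("ih", "seal_test"):
        raise ProtocolError(f"cell {trace.cell_id}: protocol is not ih/seal_test")
    t_on = _mark_time(trace, "step_on")
    t_off = _mark_time(trace, "step_off")
    i_on, i_off = trace.index_at(t_on), trace.index_at(t_off)
    pre = trace.current[:i_on]
    baseline = float(np.median(pre)) if pre.size else 0.0
    fs = trace.sampling_rate
    out = PassiveProperties(cell_id=trace.cell_id)

    if trace.protocol == "ih":
        # the sag develops with a ~100 ms time constant, so it is already
        # partly activated 20 ms into the step; fit the developing phase
        # and extrapolate its amplitude back to step onset
        k0 = i_on + int(INSTANTANEOUS_DELAY_S * fs)
        seg = trace.current[k0:i_off] - baseline
        t = (np.arange(seg.size) + (k0 - i_on)) / fs  # s from step onset
        ss0 = float(np.mean(seg[-max(int(STEADY_STATE_SPAN_S * fs), 1) :]))
        b0 = ss0 - float(seg[0])
        if abs(b0) < 1e-12:
            out.i_h = 0.0
            return out
        try:
            popt, _ = curve_fit(
                lambda x, a, b, tau: a - b * np.exp(-x / tau),
                t,
                seg,
                p0=[ss0, b0, 0.1],
                maxfev=5000,
            )
            out.i_h = abs(float(popt[1]))
        except RuntimeError:
            out.i_h = abs(ss0 - float(seg[0]))  # crude fallback
        return out

    if step_mv is None:
        raise ProtocolError(f"cell {trace.cell_id}: seal test needs step_mv")
    step = trace.current[i_on:i_off] - baseline
    i_ss = float(np.mean(step[-max(int(0.2 * step.size), 1) :]))
    t = np.arange(step.size) / fs * 1e3  # ms from step onset
    resid = step - i_ss
    # fit A*exp(-t/tau) to the transient; extrapolated peak = A + i_ss
    a0 = float(resid[0]) if resid[0] > 0 else float(np.max(resid))
    try:
        popt, _ = curve_fit(
            lambda x, a, tau: a * np.exp(-x / tau),
            t[: max(int(0.25 * step.size), 8)],
            resid[: max(int(0.25 * step.size), 8)],
            p0=[a0, 2.0],
            maxfev=5000,
        )
    except RuntimeError as exc:
        raise ValidationError(f"cell {trace.cell_id}: transient fit failed") from exc
    a, tau_ms = float(popt[0]), float(popt[1])
    i_peak = a + i_ss
    rs = 1e3 * step_mv / i_peak  # MOhm (mV/pA * 1e3)
    rm = 1e3 * step_mv / i_ss - rs
    r_par = rs * rm / (rs + rm)
    cm = 1e3 * tau_ms / r_par  # pF
    out.rs, out.rm, out.cm = rs, rm, cm
    return out
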