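"""Synthetic spike trains and voltage-clamp traces with known ground truth.

The generators emulate the statistical structure the downstream analyses
assume — pacemaker-like and bursty dopaminergic trains, Poisson-arriving
miniature synaptic currents with biexponential shape, and deterministic
evoked-current protocols — so that every analysis stage can be validated
against construction-time truth rather than against itself.

Burst ground truth is defined by generator "packets", not by the 80/160 ms
detector: a packet is a run of spikes whose internal ISIs are drawn below
80 ms, separated from everything else by gaps above 160 ms. Detector
agreement with packet labels is therefore a measured quantity, not an
identity baked into the generator.

All randomness flows from a single integer seed per config;
``numpy.random.default_rng`` streams derived per unit by fixed offsets keep
multi-unit cohorts reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .datatypes import IN_VIVO, CurrentTrace, SpikeTrain
from .errors import ConfigError, SizeError

REFRACTORY_MS = 2.0  # absolute refractory floor for all ISI models

PACEMAKER_GAUSSIAN = "pacemaker_gaussian"
POISSON_REFRACTORY = "poisson_refractory"
TWO_STATE_BURST = "two_state_burst"


@dataclass
class SpikeTrainSimConfig:
    """Configuration for spike-train simulation.

    ``intra_burst_isi`` and ``inter_event_isi`` are ``(mean_ms, sd_ms)``
    pairs. For the ``two_state_burst`` model the intra-burst mean must be
    < 80 ms and the inter-event mean > 160 ms so designed packets are
    detectable by construction; for ``pacemaker_gaussian`` the
    ``inter_event_isi`` pair *is* the pacemaker ISI distribution.

    ``burst_size`` is ``("fixed", k)`` or ``("poisson_shifted", mean)``
    (2 + Poisson(mean - 2)); sizes are always >= 2.

    ``rate_sd`` adds between-unit rate heterogeneity: each unit's own mean
    rate is drawn from N(mean_rate, rate_sd), truncated to stay positive
    and (for the burst model) within the feasible range of the 80/160 ms
    packet construction. Real cohorts show cell-to-cell rate scatter far
    above counting noise; 0 (the default) disables it.
    """

    mean_rate: float = 5.0
    rate_sd: float = 0.0
    in_burst_fraction_target: float = 0.0
    intra_burst_isi: tuple[float, float] = (40.0, 10.0)
    inter_event_isi: tuple[float, float] = (200.0, 10.0)
    burst_size: tuple[str, float] = ("poisson_shifted", 4.0)
    epoch_duration: float = 120.0
    n_units: int = 1
    seed: int = 0
    isi_model: str = PACEMAKER_GAUSSIAN
    group: str = ""
    condition: str = ""
    setting: str = IN_VIVO
    spike_duration_ms: tuple[float, float] = (1.5, 0.1)

    def __post_init__(self) -> None:
        if not (0.0 <= self.in_burst_fraction_target <= 1.0):
            raise ConfigError("in_burst_fraction_target must be in [0, 1]")
        if self.mean_rate <= 0 or self.epoch_duration <= 0 or self.n_units < 1:
            raise ConfigError("mean_rate, epoch_duration, n_units must be positive")
        if self.isi_model == TWO_STATE_BURST:
            if self.intra_burst_isi[0] >= 80.0:
                raise ConfigError("intra-burst ISI mean must be < 80 ms")
            if self.inter_event_isi[0] <= 160.0:
                raise ConfigError("inter-event ISI mean must be > 160 ms")
        if self.isi_model not in (PACEMAKER_GAUSSIAN, POISSON_REFRACTORY, TWO_STATE_BURST):
            raise ConfigError(f"unknown isi_model {self.isi_model!r}")


from functools import lru_cache


@lru_cache(maxsize=256)
def _truncnorm_loc(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Location of a normal(loc, sd) truncated to (lo, hi) whose truncated
    mean equals ``target_mean``. Keeps the realized ISI means on target
    despite truncation."""
    if sd == 0:
        return target_mean

    def err(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - target_mean

    lo_b = target_mean - 6 * sd
    hi_b = target_mean + 6 * sd
    try:
        return optimize.brentq(err, lo_b, hi_b, xtol=1e-9)
    except ValueError as exc:
        raise ConfigError(
            f"ISI distribution mean {target_mean} infeasible within ({lo}, {hi})"
        ) from exc


def _truncnorm_sample(rng, n, loc, sd, lo, hi):
    if sd == 0:
        return np.full(n, loc)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=n, random_state=rng)


def _burst_sizes(rng, n, burst_size):
    kind, p = burst_size
    if kind == "fixed":
        return np.full(n, int(p))
    if kind == "poisson_shifted":
        if p < 2:
            raise ConfigError("poisson_shifted burst size mean must be >= 2")
        return 2 + rng.poisson(p - 2.0, size=n)
    raise ConfigError(f"unknown burst size distribution {kind!r}")


def _expected_burst_size(burst_size) -> float:
    kind, p = burst_size
    return float(p)


def simulate_spike_train(cfg: SpikeTrainSimConfig):
    """Simulate spike trains with per-spike in-burst ground-truth labels.

    Returns
    -------
    (trains, labels) : (list of SpikeTrain, list of bool arrays)
        One train and one label array per unit. Labels mark generator
        packet membership (True = spike belongs to a designed burst).
        Packets truncated by the epoch end to fewer than 2 spikes are
        relabeled as non-burst (a single surviving spike is not a burst).
    """
    trains, labels = [], []
    for u in range(cfg.n_units):
        rng = np.random.default_rng((cfg.seed, u))
        unit_cfg = cfg
        if cfg.rate_sd > 0:
            lo = max(0.2, cfg.mean_rate - 3.0 * cfg.rate_sd)
            hi = cfg.mean_rate + 3.0 * cfg.rate_sd
            if cfg.isi_model == TWO_STATE_BURST:
                hi = min(hi, 0.95 * _max_feasible_rate(cfg))
            rate_u = float(np.clip(rng.normal(cfg.mean_rate, cfg.rate_sd), lo, hi))
            unit_cfg = replace(cfg, mean_rate=rate_u, rate_sd=0.0)
        times, lab = _simulate_unit(unit_cfg, rng)
        durations = np.maximum(
            rng.normal(cfg.spike_duration_ms[0], cfg.spike_duration_ms[1], times.size),
            0.1,
        )
        trains.append(
            SpikeTrain(
                unit_id=f"{cfg.group or 'unit'}_{u:03d}",
                spike_times=times,
                epoch_duration=cfg.epoch_duration,
                spike_durations=durations,
                group=cfg.group,
                condition=cfg.condition,
                setting=cfg.setting,
            )
        )
        labels.append(lab)
    return trains, labels


def _simulate_unit(cfg: SpikeTrainSimConfig, rng):
    if cfg.isi_model == PACEMAKER_GAUSSIAN:
        mean_ms = 1000.0 / cfg.mean_rate
        sd_ms = cfg.inter_event_isi[1]
        loc = _truncnorm_loc(mean_ms, sd_ms, REFRACTORY_MS, np.inf)
        n_max = int(cfg.epoch_duration * cfg.mean_rate * 1.5) + 50
        isis = _truncnorm_sample(rng, n_max, loc, sd_ms, REFRACTORY_MS, np.inf) / 1e3
        times = np.cumsum(isis)
        times = times[times < cfg.epoch_duration]
        return times, np.zeros(times.size, dtype=bool)

    if cfg.isi_model == POISSON_REFRACTORY:
        exp_mean = 1.0 / cfg.mean_rate - REFRACTORY_MS / 1e3
        if exp_mean <= 0:
            raise ConfigError("mean_rate too high for the 2 ms refractory floor")
        n_max = int(cfg.epoch_duration * cfg.mean_rate * 1.5) + 50
        isis = REFRACTORY_MS / 1e3 + rng.exponential(exp_mean, n_max)
        times = np.cumsum(isis)
        times = times[times < cfg.epoch_duration]
        return times, np.zeros(times.size, dtype=bool)

    return _simulate_two_state(cfg, rng)


def _max_feasible_rate(cfg: SpikeTrainSimConfig) -> float:
    """Highest mean rate at which the two-state construction can still keep
    inter-event gaps above 160 ms at this in-burst fraction."""
    f = cfg.in_burst_fraction_target
    es = _expected_burst_size(cfg.burst_size)
    p = 1.0 if f >= 1.0 else f / (f + es * (1.0 - f))
    spikes_per_event = p * es + (1.0 - p)
    time_in_packets = p * (es - 1.0) * cfg.intra_burst_isi[0] / 1e3
    return spikes_per_event / (0.160 + time_in_packets)


def _simulate_two_state(cfg: SpikeTrainSimConfig, rng):
    """Alternating packets and singletons.

    Each event is a packet with probability p, chosen so the expected
    fraction of spikes in packets equals the target f:
        p*E[size] / (p*E[size] + (1-p)) = f.
    The inter-event gap mean is then solved so the overall mean rate hits
    ``cfg.mean_rate`` given the time spent inside packets.
    """
    f = cfg.in_burst_fraction_target
    es = _expected_burst_size(cfg.burst_size)
    intra_mean, intra_sd = cfg.intra_burst_isi
    gap_sd = cfg.inter_event_isi[1]

    if f >= 1.0:
        p = 1.0
    else:
        p = f / (f + es * (1.0 - f))
    spikes_per_event = p * es + (1.0 - p)
    time_in_packets = p * (es - 1.0) * intra_mean / 1e3  # s per event
    gap_mean = spikes_per_event / cfg.mean_rate - time_in_packets
    if gap_mean * 1e3 <= 160.0 + 1e-9:
        raise ConfigError(
            "in_burst_fraction_target infeasible: required inter-event gap "
            f"({gap_mean * 1e3:.1f} ms) is not > 160 ms at this rate"
        )
    gap_loc = _truncnorm_loc(gap_mean * 1e3, gap_sd, 160.0 + 1e-6, np.inf)
    intra_loc = _truncnorm_loc(
        intra_mean, intra_sd, REFRACTORY_MS, 80.0 - 1e-6
    )

    # bulk pre-draw: enough events to cover the epoch with margin
    n_ev = int(cfg.epoch_duration / gap_mean * 1.5) + 20
    gaps = _truncnorm_sample(rng, n_ev, gap_loc, gap_sd, 160.0 + 1e-6, np.inf) / 1e3
    is_packet = rng.random(n_ev) < p
    sizes = _burst_sizes(rng, n_ev, cfg.burst_size)
    n_intra = int(np.sum(sizes[is_packet])) + 8
    intra_pool = (
        _truncnorm_sample(rng, n_intra, intra_loc, intra_sd, REFRACTORY_MS, 80.0 - 1e-6)
        / 1e3
    )

    times: list[float] = []
    labels: list[bool] = []
    t = 0.0
    pool_pos = 0
    for ev in range(n_ev):
        t += gaps[ev]
        if t >= cfg.epoch_duration:
            break
        if is_packet[ev]:
            size = int(sizes[ev])
            isis = intra_pool[pool_pos : pool_pos + size - 1]
            pool_pos += size - 1
            packet = t + np.concatenate([[0.0], np.cumsum(isis)])
            packet = packet[packet < cfg.epoch_duration]
            if packet.size >= 2:
                times.extend(packet)
                labels.extend([True] * packet.size)
            elif packet.size == 1:
                times.append(packet[0])
                labels.append(False)  # truncated packet: not a burst
            t = packet[-1] if packet.size else t
            if packet.size < size:
                break
        else:
            times.append(t)
            labels.append(False)
    return np.asarray(times), np.asarray(labels, dtype=bool)


def simulate_drug_epoch(
    train_cfg: SpikeTrainSimConfig, effect: float, drug_window: tuple[float, float]
):
    """Simulate trains whose firing intensity is scaled by (1+effect) inside
    ``drug_window``.

    Negative effects thin in-window spikes (each kept with probability
    1+effect); positive effects superpose an independent Poisson train at
    rate ``mean_rate * effect`` inside the window. ISI structure outside
    the window is untouched.

    Returns (trains, labels) like :func:`simulate_spike_train`; labels of
    superposed spikes are False.
    """
    if effect <= -1.0:
        raise ConfigError("effect must be > -1")
    lo, hi = drug_window
    if not (0.0 <= lo < hi <= train_cfg.epoch_duration):
        raise ConfigError("drug_window must lie within the epoch")
    base_trains, base_labels = simulate_spike_train(train_cfg)
    out_trains, out_labels = [], []
    for u, (tr, lab) in enumerate(zip(base_trains, base_labels)):
        rng = np.random.default_rng((train_cfg.seed, u, 7919))
        times, labels = tr.spike_times, lab
        in_win = (times >= lo) & (times < hi)
        if effect < 0:
            keep = ~in_win | (rng.random(times.size) < 1.0 + effect)
            times, labels = times[keep], labels[keep]
            durations = tr.spike_durations[keep]
        elif effect > 0:
            n_add = rng.poisson(train_cfg.mean_rate * effect * (hi - lo))
            add = np.sort(rng.uniform(lo, hi, n_add))
            order = np.argsort(np.concatenate([times, add]), kind="stable")
            merged_t = np.concatenate([times, add])[order]
            merged_l = np.concatenate([labels, np.zeros(n_add, bool)])[order]
            dur_add = np.maximum(
                rng.normal(*train_cfg.spike_duration_ms, n_add), 0.1
            )
            durations = np.concatenate([tr.spike_durations, dur_add])[order]
            # enforce strict monotonicity after superposition
            keep = np.concatenate([[True], np.diff(merged_t) > 0])
            times, labels, durations = merged_t[keep], merged_l[keep], durations[keep]
        else:
            durations = tr.spike_durations
        out_trains.append(
            SpikeTrain(
                unit_id=tr.unit_id,
                spike_times=times,
                epoch_duration=tr.epoch_duration,
                spike_durations=durations,
                group=tr.group,
                condition=tr.condition,
                setting=tr.setting,
            )
        )
        out_labels.append(labels)
    return out_trains, out_labels


# ---------------------------------------------------------------------------
# voltage-clamp traces


@dataclass
class TraceSimConfig:
    """Configuration for miniature-synaptic-current trace simulation.

    Events arrive as a Poisson process at ``event_rate``; each adds a
    difference-of-exponentials waveform
    ``A * (exp(-t/tau_decay) - exp(-t/tau_rise))`` normalized so its peak
    magnitude equals the drawn amplitude. Inward events are negative
    deflections at the -60 mV holding potential.
    """

    sampling_rate: float = 5000.0
    duration: float = 120.0
    event_rate: float = 2.0
    amplitude: tuple[float, float] = (30.0, 5.0)
    tau_rise: float = 1.5
    tau_decay: float = 7.0
    noise_sd: float = 2.0
    baseline_current: float = 0.0
    holding_potential: float = -60.0
    seed: int = 0
    cell_id: str = "sim"
    group: str = ""

    def __post_init__(self) -> None:
        if not (self.tau_decay > self.tau_rise > 0):
            raise ConfigError("need tau_decay > tau_rise > 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


def biexp_kernel(t_ms: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Unit-peak difference-of-exponentials waveform over times in ms."""
    t_peak = np.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)
    raw = np.exp(-t_ms / tau_decay) - np.exp(-t_ms / tau_rise)
    peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    out = np.where(t_ms >= 0, raw / peak, 0.0)
    return out


def simulate_mipsc_trace(cfg: TraceSimConfig):
    """Simulate a voltage-clamp trace of Poisson-arriving inward minis.

    Returns
    -------
    (trace, truth) : (CurrentTrace, dict)
        ``truth`` has ``onset_times`` (s, sorted) and ``amplitudes``
        (positive pA magnitudes) of every injected event.
    """
    expected = cfg.duration * cfg.event_rate
    if expected > 1e6:
        raise SizeError(f"{expected:.0f} expected events exceeds the 1e6 cap")
    rng = np.random.default_rng(cfg.seed)
    n_samples = int(round(cfg.duration * cfg.sampling_rate))
    n_events = rng.poisson(expected)
    onsets = np.sort(rng.uniform(0.0, cfg.duration, n_events))
    amps = np.maximum(rng.normal(*cfg.amplitude, n_events), 0.5)

    current = np.full(n_samples, cfg.baseline_current, dtype=float)
    span = int(10.0 * cfg.tau_decay / 1e3 * cfg.sampling_rate)
    k_t = np.arange(span) / cfg.sampling_rate * 1e3  # ms
    kernel = biexp_kernel(k_t, cfg.tau_rise, cfg.tau_decay)
    for onset, amp in zip(onsets, amps):
        i0 = int(np.ceil(onset * cfg.sampling_rate))
        if i0 >= n_samples:
            continue
        frac_ms = (i0 / cfg.sampling_rate - onset) * 1e3
        seg = amp * biexp_kernel(k_t + frac_ms, cfg.tau_rise, cfg.tau_decay)
        i1 = min(i0 + span, n_samples)
        current[i0:i1] -= seg[: i1 - i0]  # inward = negative
    if cfg.noise_sd > 0:
        current += rng.normal(0.0, cfg.noise_sd, n_samples)
    trace = CurrentTrace(
        cell_id=cfg.cell_id,
        sampling_rate=cfg.sampling_rate,
        current=current,
        holding_potential=cfg.holding_potential,
        group=cfg.group,
        protocol="mipsc",
    )
    return trace, {"onset_times": onsets, "amplitudes": amps}


def simulate_step_response(protocol: str, params: dict, seed: int | None = None):
    """Simulate a deterministic evoked/step protocol trace (+ optional noise).

    Protocols and their parameters (all times in s unless noted):

    * ``gaba_puff`` — ``amplitude_pa`` (positive magnitude of the inward
      plateau), ``t_on``, ``plateau_s``, ``tau_on_ms``, ``tau_off_ms``;
    * ``ahp`` — outward tail ``amplitude_pa``, ``tau_ms``, ``t_pulse_end``;
    * ``ih`` — hyperpolarizing step: ``step_mv``, ``instantaneous_pa``
      (magnitude of the immediate inward jump), ``sag_pa`` (slowly
      developing additional inward current = the measured I_h),
      ``tau_sag_ms``, ``t_on``, ``step_s`` (default 0.8);
    * ``seal_test`` — small step: ``step_mv``, ``rs_mohm``, ``rm_mohm``,
      ``cm_pf``, ``t_on``, ``step_s``.

    Common params: ``sampling_rate`` (default 10 kHz; 20 kHz for
    seal_test), ``duration``, ``baseline_pa``, ``noise_sd``,
    ``holding_mv``, ``cell_id``, ``group``.

    Returns (CurrentTrace, truth-dict with analytic peak/integral values).
    """
    p = dict(params)
    fs = p.pop("sampling_rate", 20000.0 if protocol == "seal_test" else 10000.0)
    duration = p.pop("duration", 2.0)
    baseline = p.pop("baseline_pa", 0.0)
    noise_sd = p.pop("noise_sd", 0.0)
    holding = p.pop("holding_mv", -55.0)
    cell_id = p.pop("cell_id", f"{protocol}_sim")
    group = p.pop("group", "")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    current = np.full(n, baseline, dtype=float)
    marks: list[tuple[float, str]] = []
    truth: dict = {}

    if protocol == "gaba_puff":
        amp = float(p["amplitude_pa"])
        t_on = p.get("t_on", 0.5)
        plateau = p.get("plateau_s", 0.5)
        tau_on = p.get("tau_on_ms", 50.0) / 1e3
        tau_off = p.get("tau_off_ms", 100.0) / 1e3
        rise = (t >= t_on) * (1.0 - np.exp(-np.maximum(t - t_on, 0) / tau_on))
        t_off = t_on + plateau
        decay = np.where(
            t < t_off, 1.0, np.exp(-np.maximum(t - t_off, 0) / tau_off)
        )
        env = np.minimum(rise, decay * (1.0 - np.exp(-plateau / tau_on)))
        current -= amp * env  # inward
        marks = [(t_on, "puff_on"), (t_off, "puff_off")]
        truth = {"peak_pa": amp * (1.0 - np.exp(-plateau / tau_on))}
        trace_protocol = "gaba_puff"
    elif protocol == "ahp":
        amp = float(p["amplitude_pa"])
        tau_ms = float(p["tau_ms"])
        t_end = p.get("t_pulse_end", 0.5)
        tail = (t >= t_end) * np.exp(-np.maximum(t - t_end, 0) / (tau_ms / 1e3))
        current += amp * tail  # outward
        marks = [(t_end, "pulse_end")]
        truth = {"peak_pa": amp, "charge_pa_ms": amp * tau_ms}
        trace_protocol = "ahp"
    elif protocol == "ih":
        step_mv = float(p.get("step_mv", 70.0))
        inst = float(p.get("instantaneous_pa", 200.0))
        sag = float(p["sag_pa"])
        tau_sag = p.get("tau_sag_ms", 120.0) / 1e3
        t_on = p.get("t_on", 0.5)
        step_s = p.get("step_s", 0.8)
        in_step = (t >= t_on) & (t < t_on + step_s)
        develop = 1.0 - np.exp(-np.maximum(t - t_on, 0) / tau_sag)
        current -= in_step * (inst + sag * develop)
        marks = [(t_on, "step_on"), (t_on + step_s, "step_off")]
        truth = {"i_h_pa": sag, "step_mv": step_mv}
        trace_protocol = "ih"
    elif protocol == "seal_test":
        step_mv = float(p.get("step_mv", 10.0))
        rs = float(p["rs_mohm"])
        rm = float(p["rm_mohm"])
        cm = float(p["cm_pf"])
        t_on = p.get("t_on", 0.2)
        step_s = p.get("step_s", 0.2)
        r_par = rs * rm / (rs + rm)  # MOhm
        tau_s = r_par * cm * 1e-6  # MOhm * pF = 1e-6 s
        i_peak = 1e3 * step_mv / rs  # pA
        i_ss = 1e3 * step_mv / (rs + rm)
        in_step = (t >= t_on) & (t < t_on + step_s)
        rel = np.maximum(t - t_on, 0.0)
        current += in_step * (i_ss + (i_peak - i_ss) * np.exp(-rel / tau_s))
        marks = [(t_on, "step_on"), (t_on + step_s, "step_off")]
        truth = {
            "rs_mohm": rs,
            "rm_mohm": rm,
            "cm_pf": cm,
            "tau_ms": tau_s * 1e3,
            "step_mv": step_mv,
        }
        trace_protocol = "seal_test"
    else:
        raise ConfigError(f"unknown step protocol {protocol!r}")

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        current = current + rng.normal(0.0, noise_sd, n)
    trace = CurrentTrace(
        cell_id=cell_id,
        sampling_rate=fs,
        current=current,
        holding_potential=holding,
        group=group,
        protocol=trace_protocol,
        stimulus_marks=marks,
    )
    return trace, truth
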