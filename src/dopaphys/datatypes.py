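"""Core data model for spike-train and voltage-clamp analyses.

Conventions fixed here and assumed everywhere else:

* time is in seconds, 0-based at epoch start; an epoch is half-open
  ``[0, epoch_duration)``;
* spike waveform durations are in milliseconds (onset to negative peak);
* currents are in pA, holding potentials in mV; inward currents are
  stored as negative samples, reported amplitudes are positive magnitudes;
* rates are in Hz, charge transfer in pA*ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

IN_VIVO = "in_vivo"
IN_VITRO = "in_vitro"

PROTOCOLS = ("mipsc", "gaba_puff", "ahp", "ih", "seal_test")


@dataclass
class SpikeTrain:
    """Spike times of one unit over a recording epoch.

    Parameters
    ----------
    unit_id : str
        Identifier of the unit/cell.
    spike_times : array of float
        Strictly increasing spike times in seconds from epoch start.
    epoch_duration : float
        Epoch length in seconds; all spikes lie in ``[0, epoch_duration)``.
    spike_durations : array of float, optional
        Per-spike waveform duration in ms (onset to negative peak); same
        length as ``spike_times``. Used by the QC inclusion criteria.
    group, condition : str
        Cohort label (e.g. ``"control"``/``"eNRG1"``) and pharmacological
        condition (e.g. ``"baseline"``/``"PTX"``).
    setting : str
        ``"in_vivo"`` or ``"in_vitro"``; selects the QC rule.
    """

    unit_id: str
    spike_times: np.ndarray
    epoch_duration: float
    spike_durations: np.ndarray | None = None
    group: str = ""
    condition: str = ""
    setting: str = IN_VIVO

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.ndim != 1:
            raise ValidationError(f"unit {self.unit_id}: spike_times must be 1-D")
        if self.spike_times.size and np.any(np.diff(self.spike_times) <= 0):
            raise ValidationError(
                f"unit {self.unit_id}: spike times not strictly increasing"
            )
        if self.epoch_duration <= 0:
            raise ValidationError(f"unit {self.unit_id}: epoch_duration must be > 0")
        if self.spike_times.size and (
            self.spike_times[0] < 0 or self.spike_times[-1] >= self.epoch_duration
        ):
            raise ValidationError(
                f"unit {self.unit_id}: spike times outside [0, epoch_duration)"
            )
        if self.spike_durations is not None:
            self.spike_durations = np.asarray(self.spike_durations, dtype=float)
            if self.spike_durations.shape != self.spike_times.shape:
                raise ValidationError(
                    f"unit {self.unit_id}: spike_durations length mismatch"
                )
            if self.spike_durations.size and np.any(self.spike_durations <= 0):
                raise ValidationError(
                    f"unit {self.unit_id}: spike_durations must be > 0"
                )
        if self.setting not in (IN_VIVO, IN_VITRO):
            raise ValidationError(f"unit {self.unit_id}: unknown setting {self.setting!r}")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def mean_rate(self) -> float:
        """Mean firing rate over the epoch, Hz."""
        return self.n_spikes / self.epoch_duration

    def isis(self) -> np.ndarray:
        """Interspike intervals in seconds."""
        return np.diff(self.spike_times)


@dataclass(frozen=True)
class Burst:
    """One detected burst, as inclusive indices into the parent spike train."""

    first_spike_index: int
    last_spike_index: int
    n_spikes: int
    duration: float

    def __post_init__(self) -> None:
        if self.last_spike_index < self.first_spike_index + 1:
            raise ValidationError("burst must contain at least 2 spikes")
        if self.n_spikes != self.last_spike_index - self.first_spike_index + 1:
            raise ValidationError("burst n_spikes inconsistent with indices")
        if self.duration < 0:
            raise ValidationError("burst duration must be >= 0")


@dataclass
class BurstSet:
    """Disjoint, ordered bursts detected in one spike train."""

    unit_id: str
    bursts: list[Burst] = field(default_factory=list)

    def __post_init__(self) -> None:
        last = -1
        for b in self.bursts:
            if b.first_spike_index <= last:
                raise ValidationError(
                    f"unit {self.unit_id}: bursts overlap or are unordered"
                )
            last = b.last_spike_index

    def __len__(self) -> int:
        return len(self.bursts)

    def __iter__(self):
        return iter(self.bursts)

    def in_burst_mask(self, n_spikes: int) -> np.ndarray:
        """Boolean mask over the train's spikes: True where the spike is in a burst."""
        mask = np.zeros(n_spikes, dtype=bool)
        for b in self.bursts:
            mask[b.first_spike_index : b.last_spike_index + 1] = True
        return mask


@dataclass
class BurstStats:
    """Per-unit firing-pattern statistics.

    ``swb`` is the percentage of all spikes falling inside bursts;
    ``cv_isi`` is the ISI coefficient of variation in percent (sd of a
    Gaussian fit to the ISI histogram divided by the mean ISI).
    ``mean_burst_duration`` is NaN when no bursts were detected.
    """

    unit_id: str
    mean_rate: float
    swb: float
    burst_frequency: float
    mean_burst_duration: float
    cv_isi: float
    n_spikes: int
    n_bursts: int
    group: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.swb <= 100.0 + 1e-9):
            raise ValidationError(f"unit {self.unit_id}: SWB outside [0, 100]")
        if self.n_bursts < 0:
            raise ValidationError(f"unit {self.unit_id}: negative burst count")


@dataclass
class CurrentTrace:
    """Uniformly sampled voltage-clamp current recording.

    ``stimulus_marks`` is a list of ``(time_s, description)`` pairs marking
    protocol events (puff onset, pulse end, step on/off).
    """

    cell_id: str
    sampling_rate: float
    current: np.ndarray
    holding_potential: float
    group: str = ""
    protocol: str = "mipsc"
    stimulus_marks: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.current = np.asarray(self.current, dtype=float)
        if self.sampling_rate <= 0:
            raise ValidationError(f"cell {self.cell_id}: sampling_rate must be > 0")
        if not np.all(np.isfinite(self.current)):
            raise ValidationError(f"cell {self.cell_id}: non-finite current samples")
        if self.protocol not in PROTOCOLS:
            raise ValidationError(f"cell {self.cell_id}: unknown protocol {self.protocol!r}")

    @property
    def n_samples(self) -> int:
        return int(self.current.size)

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def index_at(self, t: float) -> int:
        """Sample index of time ``t`` (floor)."""
        return int(t * self.sampling_rate)


@dataclass
class MiniEvent:
    """One detected miniature synaptic event.

    Amplitude is baseline-to-peak, reported as a positive magnitude in pA.
    ``rise_time_10_90`` and ``decay_tau`` are NaN until kinetics are fitted
    (and remain NaN for events excluded as double peaks).
    """

    onset_time: float
    peak_time: float
    amplitude: float
    rise_time_10_90: float = float("nan")
    decay_tau: float = float("nan")
    is_double_peak: bool = False

    def __post_init__(self) -> None:
        if self.peak_time < self.onset_time:
            raise ValidationError("mini event peak precedes onset")
        if self.amplitude < 0:
            raise ValidationError("mini amplitude must be a positive magnitude")


@dataclass
class MiniCellSummary:
    """Per-cell mIPSC summary.

    Averaged kinetics (``averaged_rise``, ``averaged_decay_tau``) are NaN
    unless more than 50 accepted (non-double-peak) events were available
    to build the averaged waveform.
    """

    cell_id: str
    n_events: int
    event_frequency: float
    mean_amplitude: float
    averaged_rise: float = float("nan")
    averaged_decay_tau: float = float("nan")
    group: str = ""


@dataclass
class RateTimeCourse:
    """Binned, baseline-normalized firing-rate series around a drug epoch.

    ``bin_edges`` are the left edges of the bins (seconds); bins tile the
    span from the start of the baseline window to the end of the epoch.
    Normalized rates are percent of the mean baseline-window rate, so the
    mean over baseline bins is 100 by construction.
    """

    unit_id: str
    bin_width: float
    bin_edges: np.ndarray
    bin_rates: np.ndarray
    baseline_window: tuple[float, float]
    drug_window: tuple[float, float]
    normalized_rates: np.ndarray

    def bins_in(self, window: tuple[float, float]) -> np.ndarray:
        """Indices of bins lying entirely inside ``window``."""
        lo, hi = window
        left = np.asarray(self.bin_edges)
        return np.flatnonzero((left >= lo - 1e-9) & (left + self.bin_width <= hi + 1e-9))


@dataclass
class EvokedResponse:
    """Peak amplitude and charge transfer of an evoked current.

    ``peak_amplitude`` is a positive magnitude in pA; the direction
    (inward/outward) is determined by the protocol and recorded in
    ``direction``. ``charge_transfer`` is in pA*ms (NaN when not measured).
    ``zero_response`` flags traces whose tail never cleared baseline noise.
    """

    cell_id: str
    peak_amplitude: float
    charge_transfer: float
    measurement_window: tuple[float, float]
    direction: str = "inward"
    zero_response: bool = False


@dataclass
class PassiveProperties:
    """Whole-cell passive parameters and hyperpolarization-activated current.

    ``i_h`` in pA, ``rs``/``rm`` in MOhm, ``cm`` in pF; fields that the
    recorded protocol cannot determine are NaN.
    """

    cell_id: str
    i_h: float = float("nan")
    rs: float = float("nan")
    rm: float = float("nan")
    cm: float = float("nan")


@dataclass
class GroupComparison:
    """Result of one group-level hypothesis test."""

    test_name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    measure: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError("p-value outside [0, 1]")
        if any(n < 1 for n in self.n_per_group):
            raise ValidationError("every group must have n >= 1")


@dataclass
class SummaryRow:
    """One mean +/- SEM row of a results table."""

    measure: str
    group: str
    n_cells: int
    mean: float
    sem: float
    n_animals: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValidationError("summary row needs n_cells >= 1")
        if np.isfinite(self.sem) and self.sem < 0:
            raise ValidationError("SEM must be >= 0")
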