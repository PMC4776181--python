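"""Firing-rate responses to drug application (iontophoresis, bath, superfusion).

Rates are binned (default 20 s bins), normalized so the mean rate over the
60 s immediately preceding drug application is 100 %, and summarized as a
signed percent change averaged over the bins inside the application
window. Units with a silent baseline are excluded (percent change is
undefined for them) rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import RateTimeCourse, SpikeTrain
from .errors import ConfigError, InsufficientDataError, NormalizationError
from .spikes import cv_of_isis


@dataclass
class DrugProtocol:
    """Timing of a drug-application experiment.

    ``baseline_window`` defaults to the 60 s immediately before the drug
    window; windows must not overlap, the baseline must precede the drug,
    and ``bin_width`` must divide both window lengths.
    """

    drug_window: tuple[float, float]
    baseline_window: tuple[float, float] | None = None
    label: str = ""
    bin_width: float = 20.0

    def __post_init__(self) -> None:
        if self.baseline_window is None:
            self.baseline_window = (self.drug_window[0] - 60.0, self.drug_window[0])
        b0, b1 = self.baseline_window
        d0, d1 = self.drug_window
        if not (b0 < b1 and d0 < d1):
            raise ConfigError("windows must have positive length")
        if b1 > d0:
            raise ConfigError("baseline window must precede the drug window")
        if self.bin_width <= 0:
            raise ConfigError("bin_width must be > 0")
        for name, length in (("baseline", b1 - b0), ("drug", d1 - d0)):
            if abs(length / self.bin_width - round(length / self.bin_width)) > 1e-9:
                raise ConfigError(f"bin_width must divide the {name} window length")
        if b0 < 0:
            raise ConfigError("baseline window starts before the epoch")


def bin_rates(train: SpikeTrain, protocol: DrugProtocol) -> RateTimeCourse:
    """Bin firing rates on a grid anchored at the baseline start and
    normalize to the mean baseline rate (= 100 %).

    Bins tile from the baseline start to the end of the epoch. Both
    windows must sit on this grid.

    Raises
    ------
    ConfigError
        Epoch does not cover both windows, or windows off the bin grid.
    NormalizationError
        Zero spikes in the baseline window.
    """
    b0 = protocol.baseline_window[0]
    if protocol.drug_window[1] > train.epoch_duration + 1e-9:
        raise ConfigError(
            f"unit {train.unit_id}: epoch does not cover the drug window"
        )
    for t in (*protocol.baseline_window, *protocol.drug_window):
        if abs((t - b0) / protocol.bin_width - round((t - b0) / protocol.bin_width)) > 1e-9:
            raise ConfigError("window boundaries must lie on the bin grid")
    n_bins = int(np.floor((train.epoch_duration - b0) / protocol.bin_width + 1e-9))
    edges = b0 + protocol.bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(train.spike_times, bins=edges)
    rates = counts / protocol.bin_width
    tc = RateTimeCourse(
        unit_id=train.unit_id,
        bin_width=protocol.bin_width,
        bin_edges=edges[:-1],
        bin_rates=rates,
        baseline_window=tuple(protocol.baseline_window),
        drug_window=tuple(protocol.drug_window),
        normalized_rates=np.full(n_bins, np.nan),
    )
    base_bins = tc.bins_in(protocol.baseline_window)
    base_rate = float(np.mean(rates[base_bins]))
    if base_rate == 0.0:
        raise NormalizationError(
            f"unit {train.unit_id}: zero baseline rate, percent change undefined"
        )
    tc.normalized_rates = 100.0 * rates / base_rate
    return tc


def percent_change(tc: RateTimeCourse) -> float:
    """Signed percent change: mean normalized rate over drug bins minus 100."""
    drug_bins = tc.bins_in(tc.drug_window)
    return float(np.mean(tc.normalized_rates[drug_bins])) - 100.0


def cohort_percent_change(
    trains: list[SpikeTrain], protocol: DrugProtocol
) -> pd.DataFrame:
    """Per-unit percent change table; silent-baseline units excluded with a
    logged reason column left in the table (``excluded``/``reason``)."""
    rows = []
    for tr in trains:
        try:
            change = percent_change(bin_rates(tr, protocol))
            rows.append(
                {"unit_id": tr.unit_id, "group": tr.group, "label": protocol.label,
                 "percent_change": change, "excluded": False, "reason": ""}
            )
        except NormalizationError as exc:
            rows.append(
                {"unit_id": tr.unit_id, "group": tr.group, "label": protocol.label,
                 "percent_change": np.nan, "excluded": True, "reason": str(exc)}
            )
    return pd.DataFrame(
        rows,
        columns=["unit_id", "group", "label", "percent_change", "excluded", "reason"],
    )


def condition_contrast(table: pd.DataFrame, value: str = "mean_rate_hz") -> pd.DataFrame:
    """Per-(group, condition) mean +/- SEM of a per-unit statistic.

    ``table`` is a cohort firing table with ``group`` and ``condition``
    columns (e.g. baseline vs PTX). Returns one row per cell of the
    group-by-condition design; SEM is NaN for n = 1. The cross-group,
    cross-condition hypothesis tests are run downstream on the raw
    per-unit values.
    """
    if "condition" not in table.columns or "group" not in table.columns:
        raise ConfigError("table must carry group and condition columns")
    rows = []
    for (grp, cond), sub in table.groupby(["group", "condition"], sort=True):
        x = sub[value].dropna().to_numpy()
        n = x.size
        rows.append(
            {
                "group": grp,
                "condition": cond,
                "n": n,
                "mean": float(np.mean(x)) if n else np.nan,
                "sem": float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["group", "condition", "n", "mean", "sem"])


def nmda_response(train: SpikeTrain, protocol: DrugProtocol):
    """Rate and ISI-CV inside the drug window, each normalized to its own
    baseline value x 100 (both 100 % = no effect).

    Raises
    ------
    InsufficientDataError
        Fewer than 10 ISIs in either window.
    """
    out = {}
    for name, (lo, hi) in (
        ("baseline", protocol.baseline_window),
        ("drug", protocol.drug_window),
    ):
        mask = (train.spike_times >= lo) & (train.spike_times < hi)
        times = train.spike_times[mask]
        if times.size < 11:
            raise InsufficientDataError(
                f"unit {train.unit_id}: <10 ISIs in the {name} window"
            )
        sub = SpikeTrain(
            unit_id=train.unit_id,
            spike_times=times - lo,
            epoch_duration=hi - lo,
            setting=train.setting,
        )
        cv, _ = cv_of_isis(sub)
        out[name] = (sub.mean_rate, cv)
    base_rate, base_cv = out["baseline"]
    drug_rate, drug_cv = out["drug"]
    if base_cv == 0.0:
        raise InsufficientDataError(
            f"unit {train.unit_id}: zero baseline CV, normalization undefined"
        )
    return 100.0 * drug_rate / base_rate, 100.0 * drug_cv / base_cv
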