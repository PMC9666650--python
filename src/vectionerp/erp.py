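"""Condition ERP averages, difference waves and window mean amplitudes.

ERPs are epoch averages time-locked to motion onset, computed separately per
condition (CW/CCW collapsed).  The analysis quantities downstream are the
per-electrode mean amplitudes in the early (160-220 ms) and late (260-300 ms)
windows, with inclusive bounds (61 and 41 samples at 1000 Hz).  Grand
averages weight subjects equally (mean of subject ERPs, not pooled epochs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import Condition, ValidationError
from .preprocessing import EpochSet

__all__ = [
    "EARLY_WINDOW",
    "LATE_WINDOW",
    "ErpWaveform",
    "WindowAmplitudes",
    "average_condition",
    "difference_wave",
    "window_mean_amplitude",
    "grand_average",
]

EARLY_WINDOW = (160.0, 220.0)
LATE_WINDOW = (260.0, 300.0)


@dataclass
class ErpWaveform:
    """Channels x time average waveform (uV) with its provenance label."""

    data: np.ndarray
    times: np.ndarray
    channel_labels: list[str]
    n_epochs: int
    label: dict

    def __post_init__(self) -> None:
        if self.data.shape != (len(self.channel_labels), len(self.times)):
            raise ValidationError("ERP shape does not match channels x times")


@dataclass
class WindowAmplitudes:
    """Per-electrode mean amplitude (uV) over one analysis window."""

    window: tuple[float, float]
    values: np.ndarray
    channel_labels: list[str]
    label: dict


def average_condition(epochs: EpochSet, condition: Condition | str) -> ErpWaveform:
    """Pointwise mean across all epochs of one condition (directions collapsed)."""
    sel = epochs.select_condition(condition)
    if sel.n_epochs == 0:
        raise ValidationError(f"no epochs for condition {condition!r}")
    subject = sel.labels["subject"].iloc[0] if len(sel.labels) else ""
    group = sel.labels["group"].iloc[0] if len(sel.labels) else ""
    return ErpWaveform(
        data=sel.data.mean(axis=0),
        times=epochs.times,
        channel_labels=list(epochs.channel_labels),
        n_epochs=sel.n_epochs,
        label={"subject": subject, "condition": Condition(condition).value, "group": group},
    )


def difference_wave(coh: ErpWaveform, inc: ErpWaveform) -> ErpWaveform:
    """Coherent minus incoherent, pointwise."""
    if coh.channel_labels != inc.channel_labels or not np.array_equal(coh.times, inc.times):
        raise ValidationError("difference wave requires matching channels and times")
    return ErpWaveform(
        data=coh.data - inc.data,
        times=coh.times,
        channel_labels=list(coh.channel_labels),
        n_epochs=min(coh.n_epochs, inc.n_epochs),
        label={
            "subject": coh.label.get("subject", ""),
            "condition": "difference",
            "group": coh.label.get("group", ""),
            "parents": (coh.n_epochs, inc.n_epochs),
        },
    )


def window_mean_amplitude(
    wave: ErpWaveform, window: tuple[float, float]
) -> WindowAmplitudes:
    """Per-electrode mean over samples with start <= t <= end (inclusive)."""
    start, end = window
    if start < wave.times[0] or end > wave.times[-1]:
        raise ValidationError(f"window {window} outside epoch times")
    mask = (wave.times >= start) & (wave.times <= end)
    return WindowAmplitudes(
        window=(float(start), float(end)),
        values=wave.data[:, mask].mean(axis=1),
        channel_labels=list(wave.channel_labels),
        label=dict(wave.label),
    )


def grand_average(waves: list[ErpWaveform]) -> ErpWaveform:
    """Mean of subject ERPs, each subject weighted equally."""
    if not waves:
        raise ValidationError("no waveforms to average")
    first = waves[0]
    for w in waves[1:]:
        if w.channel_labels != first.channel_labels or not np.array_equal(w.times, first.times):
            raise ValidationError("grand average requires matching channels and times")
    return ErpWaveform(
        data=np.mean([w.data for w in waves], axis=0),
        times=first.times,
        channel_labels=list(first.channel_labels),
        n_epochs=sum(w.n_epochs for w in waves),
        label={"subject": "grand", "condition": first.label.get("condition", ""), "group": ""},
    )
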