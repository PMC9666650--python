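"""Preprocessing chain: filtering, re-referencing, epoching, baseline, rejection.

The chain mirrors standard ERP practice for this experiment: 50/100 Hz FIR
notch filters, a 0.1-30 Hz zero-phase FIR band-pass, common-average
re-referencing over the EEG channels (EOG excluded), segmentation into 600 ms
epochs from -200 to +400 ms around motion onset, baseline correction over the
200 ms pre-stimulus interval, sliding-window artifact rejection (200 ms
windows stepping by 50 ms; an epoch is dropped when any window shows a
standard deviation above 35 uV in the EOG/Fp1/Fp2/Fz channels or a signal
range above 100 uV), and participant exclusion below 30 artifact-free epochs
per condition.

All filters are linear-phase FIR kernels applied in a single symmetric pass
(odd symmetric kernel => exactly zero phase), with reflection padding at the
edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .cluster import EOG_CHANNELS
from .io_formats import Condition, Direction, Event, EventKind, Recording, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "EpochSet",
    "FilterSpec",
    "RejectionCriteria",
    "apply_filters",
    "rereference_common_average",
    "epoch_recording",
    "baseline_correct",
    "reject_artifacts",
    "check_participant_inclusion",
]


@dataclass
class EpochSet:
    """Epochs x channels x time tensor (uV) with per-epoch labels.

    ``times`` are ms relative to motion onset (default -200..+399 inclusive,
    600 samples at 1000 Hz); ``labels`` is a DataFrame with one row per epoch
    (columns: condition, direction, subject, group).
    """

    data: np.ndarray
    times: np.ndarray
    channel_labels: list[str]
    labels: pd.DataFrame
    srate: float = 1000.0
    baseline_corrected: bool = False
    rejection_applied: bool = False
    rejection_log: pd.DataFrame | None = None
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValidationError("epoch data must be epochs x channels x time")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValidationError("channel label count mismatch")
        if self.data.shape[2] != len(self.times):
            raise ValidationError("time axis length mismatch")
        if len(self.labels) != self.data.shape[0]:
            raise ValidationError("label rows must match epoch count")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def eeg_channel_indices(self) -> np.ndarray:
        return np.array(
            [i for i, c in enumerate(self.channel_labels) if c not in EOG_CHANNELS]
        )

    def select_condition(self, condition: Condition | str) -> "EpochSet":
        cond = Condition(condition).value
        mask = (self.labels["condition"] == cond).to_numpy()
        return replace(
            self,
            data=self.data[mask],
            labels=self.labels.loc[mask].reset_index(drop=True),
        )

    def log_stage(self, stage: str, **params) -> None:
        self.provenance.append({"stage": stage, **params})


# ---------------------------------------------------------------------------
# Filtering


@dataclass(frozen=True)
class FilterSpec:
    """FIR filter parameters (all frequencies in Hz).

    Transition widths control kernel length (~3.3 / width * srate taps with a
    Hamming window); the high-pass transition dominates and its default of
    0.1 Hz yields a ~33 s kernel at 1000 Hz, appropriate for continuous
    recordings.  Tests on short fixtures may widen it.
    """

    notch: tuple[float, ...] = (50.0, 100.0)
    notch_width: float = 2.0  # half-width of each stop band
    highpass: float = 0.1
    lowpass: float = 30.0
    hp_transition: float = 0.1
    lp_transition: float = 7.5


def _odd(n: int) -> int:
    return n + 1 if n % 2 == 0 else n


def _kernel_length(transition: float, srate: float) -> int:
    return _odd(max(int(np.ceil(3.3 / transition * srate)), 3))


def design_bandpass(spec: FilterSpec, srate: float) -> np.ndarray:
    numtaps = _kernel_length(min(spec.hp_transition, spec.lp_transition), srate)
    return signal.firwin(
        numtaps, [spec.highpass, spec.lowpass], pass_zero=False, fs=srate, window="hamming"
    )


def design_notch(freq: float, spec: FilterSpec, srate: float) -> np.ndarray:
    numtaps = _kernel_length(spec.notch_width, srate)
    return signal.firwin(
        numtaps,
        [freq - spec.notch_width, freq + spec.notch_width],
        pass_zero=True,
        fs=srate,
        window="hamming",
    )


def zero_phase_filter(data: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Apply an odd-length symmetric FIR kernel with exactly zero phase.

    Reflection padding of half the kernel length on each side, 'valid'
    convolution, so the output length equals the input length and there is no
    group delay.
    """
    half = len(kernel) // 2
    if data.shape[-1] <= half:
        raise ValidationError(
            f"signal too short ({data.shape[-1]} samples) for kernel of {len(kernel)} taps"
        )
    padded = np.pad(data, [(0, 0)] * (data.ndim - 1) + [(half, half)], mode="reflect")
    return signal.fftconvolve(padded, kernel[(None,) * (data.ndim - 1)], mode="valid", axes=-1)


def apply_filters(rec: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Notch (50/100 Hz) then band-pass (0.1-30 Hz) zero-phase FIR filtering.

    Filtering precedes re-referencing in the standard chain; both notch and
    band-pass frequencies must lie below Nyquist.
    """
    nyq = rec.srate / 2
    top = max([spec.lowpass + spec.lp_transition, *[f + spec.notch_width for f in spec.notch]])
    if top >= nyq:
        raise ValidationError(f"filter edge {top} Hz at or above Nyquist {nyq} Hz")
    data = rec.data
    for f in spec.notch:
        data = zero_phase_filter(data, design_notch(f, spec, rec.srate))
    data = zero_phase_filter(data, design_bandpass(spec, rec.srate))
    out = Recording(
        data=data,
        srate=rec.srate,
        channel_labels=list(rec.channel_labels),
        reference=rec.reference,
        events=list(rec.events),
        log=rec.log + [{"stage": "apply_filters", "spec": spec}],
    )
    return out


# ---------------------------------------------------------------------------
# Re-referencing


def rereference_common_average(rec: Recording) -> Recording:
    """Re-reference EEG channels to their common average; EOG left untouched.

    Idempotent: applying twice subtracts an (already zero) mean again and is
    logged rather than raised.
    """
    eeg_idx = [i for i, c in enumerate(rec.channel_labels) if c not in EOG_CHANNELS]
    if len(eeg_idx) < 2:
        raise ValidationError("common average needs >= 2 EEG channels")
    if rec.reference == "common_average":
        logger.info("recording already common-average referenced; applying again is a no-op")
    data = rec.data.copy()
    avg = data[eeg_idx].mean(axis=0)
    data[eeg_idx] -= avg
    return Recording(
        data=data,
        srate=rec.srate,
        channel_labels=list(rec.channel_labels),
        reference="common_average",
        events=list(rec.events),
        log=rec.log + [{"stage": "rereference_common_average", "n_eeg": len(eeg_idx)}],
    )


# ---------------------------------------------------------------------------
# Epoching and baseline


def epoch_recording(
    rec: Recording,
    event_kind: EventKind = EventKind.MOTION_ONSET,
    tmin_ms: float = -200.0,
    tmax_ms: float = 400.0,
    subject: str = "",
    group: str = "",
) -> EpochSet:
    """Extract one epoch per ``event_kind`` event, [tmin, tmax) around it.

    The epoch spans ``tmin_ms`` inclusive to ``tmax_ms`` exclusive (600
    samples for -200..+400 ms at 1000 Hz).  Events whose window exceeds the
    recording bounds are dropped with a logged warning.
    """
    i0 = int(round(tmin_ms / 1000 * rec.srate))
    i1 = int(round(tmax_ms / 1000 * rec.srate))
    times = np.arange(i0, i1) / rec.srate * 1000.0
    epochs, rows, dropped = [], [], 0
    for ev in rec.events:
        if ev.kind != event_kind:
            continue
        a, b = ev.sample_index + i0, ev.sample_index + i1
        if a < 0 or b > rec.n_samples:
            dropped += 1
            continue
        epochs.append(rec.data[:, a:b])
        rows.append(
            {
                "condition": ev.condition.value,
                "direction": ev.direction.value,
                "subject": subject,
                "group": group,
            }
        )
    if dropped:
        logger.warning("dropped %d epochs whose window exceeded recording bounds", dropped)
    if not epochs:
        raise ValidationError("no usable motion-onset events to epoch")
    es = EpochSet(
        data=np.stack(epochs),
        times=times,
        channel_labels=list(rec.channel_labels),
        labels=pd.DataFrame(rows),
        srate=rec.srate,
    )
    es.log_stage("epoch_recording", n_epochs=len(epochs), n_dropped=dropped)
    return es


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract each epoch's per-channel mean over the [-200, 0) ms baseline."""
    if epochs.baseline_corrected:
        raise ValidationError("baseline correction already applied")
    mask = (epochs.times >= -200.0) & (epochs.times < 0.0)
    if not mask.any():
        raise ValidationError("no samples in the baseline interval")
    out = replace(
        epochs,
        data=epochs.data - epochs.data[:, :, mask].mean(axis=2, keepdims=True),
        baseline_corrected=True,
    )
    out.log_stage("baseline_correct", n_baseline_samples=int(mask.sum()))
    return out


# ---------------------------------------------------------------------------
# Artifact rejection


@dataclass(frozen=True)
class RejectionCriteria:
    """Sliding-window artifact rejection thresholds.

    (a) windowed standard deviation above ``sd_threshold`` in any of
    ``sd_channels`` (ocular channels and frontal electrodes), or (b) windowed
    signal range above ``range_threshold`` in any EEG channel.  Both use
    strict inequality; the windowed SD uses the unbiased (n-1) denominator.
    """

    window_len_ms: float = 200.0
    window_step_ms: float = 50.0
    sd_threshold: float = 35.0
    sd_channels: tuple[str, ...] = ("hEOG", "vEOG", "Fp1", "Fp2", "Fz")
    range_threshold: float = 100.0
    range_channels: tuple[str, ...] | None = None  # None = all EEG channels


def _window_starts(n_samples: int, win: int, step: int) -> np.ndarray:
    # only full windows are evaluated
    return np.arange(0, n_samples - win + 1, step)


def reject_artifacts(
    epochs: EpochSet, criteria: RejectionCriteria = RejectionCriteria()
) -> tuple[EpochSet, pd.DataFrame]:
    """Drop epochs that trigger any sliding-window criterion.

    Returns the kept epochs and a log with one row per input epoch
    (kept/rejected, and for rejected epochs the first triggering window,
    channel and rule).
    """
    win = int(round(criteria.window_len_ms / 1000 * epochs.srate))
    step = int(round(criteria.window_step_ms / 1000 * epochs.srate))
    n_t = epochs.data.shape[2]
    if win > n_t:
        raise ValidationError("rejection window longer than the epoch")
    name_to_idx = {c: i for i, c in enumerate(epochs.channel_labels)}
    missing = [c for c in criteria.sd_channels if c not in name_to_idx]
    if missing:
        raise ValidationError(f"sd_channels absent from data: {missing}")
    sd_idx = np.array([name_to_idx[c] for c in criteria.sd_channels])
    if criteria.range_channels is None:
        rng_idx = epochs.eeg_channel_indices()
    else:
        missing = [c for c in criteria.range_channels if c not in name_to_idx]
        if missing:
            raise ValidationError(f"range_channels absent from data: {missing}")
        rng_idx = np.array([name_to_idx[c] for c in criteria.range_channels])

    starts = _window_starts(n_t, win, step)
    # (epochs, channels, windows, win_samples) view via stride tricks
    windows = np.lib.stride_tricks.sliding_window_view(epochs.data, win, axis=2)[:, :, starts]
    sd = windows[:, sd_idx].std(axis=-1, ddof=1)  # (n_ep, n_sd_ch, n_win)
    rng = windows[:, rng_idx].max(axis=-1) - windows[:, rng_idx].min(axis=-1)
    hit_sd = sd > criteria.sd_threshold
    hit_rng = rng > criteria.range_threshold

    rows = []
    keep = np.ones(epochs.n_epochs, dtype=bool)
    for e in range(epochs.n_epochs):
        rule = window = channel = None
        # first triggering (window, channel, rule) in window-major order
        for w_i, start in enumerate(starts):
            sd_ch = np.flatnonzero(hit_sd[e, :, w_i])
            rng_ch = np.flatnonzero(hit_rng[e, :, w_i])
            if sd_ch.size:
                rule, window = "sd", start
                channel = epochs.channel_labels[sd_idx[sd_ch[0]]]
                break
            if rng_ch.size:
                rule, window = "range", start
                channel = epochs.channel_labels[rng_idx[rng_ch[0]]]
                break
        rejected = rule is not None
        keep[e] = not rejected
        rows.append(
            {
                "epoch": e,
                "kept": not rejected,
                "rule": rule,
                "window_start_sample": window,
                "channel": channel,
            }
        )
    log = pd.DataFrame(rows)
    kept = replace(
        epochs,
        data=epochs.data[keep],
        labels=epochs.labels.loc[keep].reset_index(drop=True),
        rejection_applied=True,
        rejection_log=log,
    )
    kept.log_stage(
        "reject_artifacts",
        n_in=epochs.n_epochs,
        n_rejected=int((~keep).sum()),
        criteria=criteria,
    )
    return kept, log


def check_participant_inclusion(
    kept: EpochSet, min_trials: int = 30
) -> tuple[bool, dict[str, int]]:
    """Include a participant only with >= ``min_trials`` artifact-free epochs
    in *both* conditions (a count of exactly 30 is included: the rule is
    "fewer than 30")."""
    if not kept.rejection_applied:
        raise ValidationError("inclusion check requires rejection to have been applied")
    counts = {
        cond.value: int((kept.labels["condition"] == cond.value).sum())
        for cond in (Condition.COHERENT, Condition.INCOHERENT)
    }
    included = all(c >= min_trials for c in counts.values())
    logger.info("participant inclusion: counts=%s included=%s", counts, included)
    return included, counts


def collapse_directions(epochs: EpochSet) -> EpochSet:
    """Collapse CW and CCW trials within condition (labels only; data kept)."""
    labels = epochs.labels.copy()
    labels["direction"] = Direction.NONE.value
    out = replace(epochs, labels=labels)
    out.log_stage("collapse_directions")
    return out
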