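"""Synthetic multi-subject EEG epochs and vection behavior.

No public recording of this experiment exists, so every downstream stage is
exercised on synthetic cohorts whose statistical structure matches what the
analysis assumes:

* two ERP components time-locked to motion onset — an early peak inside
  160-220 ms and a later, polarity-reversed peak inside 260-300 ms — with a
  compact central scalp topography;
* multiplicative attenuation of both components in the coherent condition
  (the vection-consistent stimulus evokes *smaller* central amplitudes than
  the incoherent control), with a larger condition difference for
  left-handers in the early component only;
* 1/f (pink) channel noise with a shared spatially-correlated component plus
  white sensor noise;
* blink and signal-range artifacts with ground-truth labels, for oracle
  testing of the rejection rules;
* per-trial vection reports (presence, onset latency, duration, 0-10
  strength) whose subject-level strength is rank-coupled to the subject's
  expected coherent-condition central amplitude.

Everything is deterministic given the seeds in the specs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cluster import CHANNELS_64, EOG_CHANNELS, SensorLayout, standard_layout
from .io_formats import Condition, Direction, TrialBehavior, ValidationError
from .preprocessing import EpochSet

logger = logging.getLogger(__name__)

__all__ = [
    "ErpComponent",
    "ErpTemplateSpec",
    "CohortSpec",
    "BehaviorSpec",
    "SyntheticCohort",
    "simulate_subject_epochs",
    "simulate_cohort",
    "inject_artifacts",
    "simulate_behavior",
    "planted_electrodes",
]


@dataclass(frozen=True)
class ErpComponent:
    """One spatiotemporal ERP component.

    Temporal profile: Gaussian pulse ``amplitude * exp(-(t-latency)^2/(2*width^2))``.
    Spatial profile: generalized Gaussian ``exp(-(d/spread)^order)`` over the
    2D-projected montage distance ``d`` from ``center`` (order 4 by default: a
    compact plateau with sharp falloff, which makes the planted electrode set
    well defined for recovery tests).
    """

    peak_latency_ms: float
    width_ms: float
    amplitude_uv: float
    center: str = "Cz"
    spread: float = 0.5  # radians in the azimuthal projection
    order: float = 4.0
    group_effect: bool = False  # condition attenuation differs by handedness


@dataclass(frozen=True)
class ErpTemplateSpec:
    """Two-component template: early central negativity, reversed late peak."""

    components: tuple[ErpComponent, ...] = (
        ErpComponent(190.0, 20.0, -8.0, "Cz", 0.93, group_effect=True),
        ErpComponent(280.0, 15.0, 6.0, "Cz", 0.80, group_effect=False),
    )

    def validate(self, tmin_ms: float, tmax_ms: float) -> None:
        for c in self.components:
            if not (tmin_ms <= c.peak_latency_ms <= tmax_ms):
                raise ValidationError("component latency outside the epoch window")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort structure and noise model.

    ``condition_attenuation`` scales the coherent-condition component
    amplitude (< 1: coherent responses are attenuated).  For components
    marked ``group_effect``, left-handers' condition difference
    (1 - attenuation) is ``group_effect_ratio`` times the right-handers'.
    Noise: pink (1/f power) noise of ``pink_rms_uv`` total RMS per channel, a
    fraction ``shared_noise_mix`` of which is a single spatially-shared
    process, plus white noise of ``white_sd_uv``.
    """

    n_left: int = 28
    n_right: int = 29
    trials_per_condition: int = 50
    condition_attenuation: float = 0.7
    group_effect_ratio: float = 2.0
    pink_rms_uv: float = 8.0
    white_sd_uv: float = 3.0
    shared_noise_mix: float = 0.5
    subject_scale_sigma: float = 0.2  # log-normal sigma of per-subject gain
    attenuation_jitter_sd: float = 0.08
    artifact_rates: dict = field(default_factory=lambda: {"blink": 0.05, "range": 0.03})
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.condition_attenuation < 1):
            raise ValidationError("condition_attenuation must be in (0, 1)")
        if self.group_effect_ratio <= 0:
            raise ValidationError("group_effect_ratio must be positive")
        for k, v in self.artifact_rates.items():
            if not (0 <= v <= 1):
                raise ValidationError(f"artifact rate {k}={v} outside [0, 1]")

    def group_attenuation(self, group: str, component: ErpComponent) -> float:
        """Mean attenuation factor for a group on one component."""
        base = self.condition_attenuation
        if component.group_effect and group == "left":
            return 1.0 - self.group_effect_ratio * (1.0 - base)
        return base


# ---------------------------------------------------------------------------
# Template projection


def _spatial_weights(layout: SensorLayout, comp: ErpComponent) -> np.ndarray:
    d = np.linalg.norm(layout.pos2d - layout.pos2d[layout.index(comp.center)], axis=1)
    return np.exp(-((d / comp.spread) ** comp.order))


def _temporal_profile(times_ms: np.ndarray, comp: ErpComponent) -> np.ndarray:
    return np.exp(-((times_ms - comp.peak_latency_ms) ** 2) / (2 * comp.width_ms**2))


def template_projection(
    template: ErpTemplateSpec,
    layout: SensorLayout,
    times_ms: np.ndarray,
    component_scales: np.ndarray | None = None,
) -> np.ndarray:
    """Channels x time template signal; ``component_scales`` multiplies each
    component's amplitude (condition/group/subject scaling)."""
    scales = (
        np.ones(len(template.components)) if component_scales is None else component_scales
    )
    out = np.zeros((layout.n, len(times_ms)))
    for comp, s in zip(template.components, scales):
        w = _spatial_weights(layout, comp)
        out += s * comp.amplitude_uv * np.outer(w, _temporal_profile(times_ms, comp))
    return out


def planted_electrodes(
    template: ErpTemplateSpec, layout: SensorLayout, component: int
) -> list[int]:
    """Ground-truth effect electrodes: spatial weight >= half maximum."""
    w = _spatial_weights(layout, template.components[component])
    return sorted(np.flatnonzero(w >= 0.5 * w.max()).tolist())


# ---------------------------------------------------------------------------
# Noise


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], n_t: int) -> np.ndarray:
    """Unit-RMS pink noise (power ~ 1/f) along the last axis."""
    white = rng.standard_normal(shape + (n_t,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_t)
    gain = np.zeros_like(freqs)
    gain[1:] = 1.0 / np.sqrt(freqs[1:])
    shaped = np.fft.irfft(spec * gain, n=n_t, axis=-1)
    rms = shaped.std(axis=-1, keepdims=True)
    rms[rms == 0] = 1.0
    return shaped / rms


def _noise_block(
    rng: np.random.Generator, cohort: CohortSpec, n_epochs: int, n_ch: int, n_t: int
) -> np.ndarray:
    if cohort.pink_rms_uv == 0 and cohort.white_sd_uv == 0:
        return np.zeros((n_epochs, n_ch, n_t))
    out = np.zeros((n_epochs, n_ch, n_t))
    if cohort.pink_rms_uv > 0:
        mix = cohort.shared_noise_mix
        own = _pink_noise(rng, (n_epochs, n_ch), n_t)
        shared = _pink_noise(rng, (n_epochs,), n_t)[:, None, :]
        out += cohort.pink_rms_uv * (np.sqrt(1 - mix**2) * own + mix * shared)
    if cohort.white_sd_uv > 0:
        out += cohort.white_sd_uv * rng.standard_normal((n_epochs, n_ch, n_t))
    return out


# ---------------------------------------------------------------------------
# Subject and cohort simulation

_TMIN, _TMAX, _SRATE = -200.0, 400.0, 1000.0


def _epoch_times() -> np.ndarray:
    return np.arange(_TMIN, _TMAX)


@dataclass
class SubjectParams:
    subject: str
    group: str
    gain: float  # log-normal per-subject amplitude scale
    attenuations: np.ndarray  # per-component coherent attenuation factor


def _draw_subject_params(
    template: ErpTemplateSpec,
    cohort: CohortSpec,
    subject: str,
    group: str,
    rng: np.random.Generator,
) -> SubjectParams:
    gain = float(np.exp(rng.normal(0.0, cohort.subject_scale_sigma)))
    jitter = float(rng.normal(0.0, cohort.attenuation_jitter_sd))
    atts = np.array(
        [
            np.clip(cohort.group_attenuation(group, c) + jitter, 0.02, 0.98)
            for c in template.components
        ]
    )
    return SubjectParams(subject=subject, group=group, gain=gain, attenuations=atts)


def simulate_subject_epochs(
    template: ErpTemplateSpec,
    cohort: CohortSpec,
    subject_id: str,
    group: str,
    seed: int | np.random.SeedSequence,
    params: SubjectParams | None = None,
    layout: SensorLayout | None = None,
) -> tuple[EpochSet, SubjectParams]:
    """Both conditions' epochs for one subject (-200..+400 ms at 1000 Hz).

    Each epoch is the condition- and subject-scaled template plus pink and
    white noise.  Directions alternate so each condition splits evenly
    between CW and CCW.
    """
    cohort.validate()
    template.validate(_TMIN, _TMAX)
    layout = layout if layout is not None else standard_layout()
    rng = np.random.default_rng(seed)
    if params is None:
        params = _draw_subject_params(template, cohort, subject_id, group, rng)
    times = _epoch_times()
    n_t = times.size
    n_eeg = layout.n
    channels = list(layout.names) + EOG_CHANNELS
    n_ch = len(channels)
    n_per = cohort.trials_per_condition

    coh_scales = params.gain * params.attenuations
    inc_scales = params.gain * np.ones_like(params.attenuations)
    sig = {
        Condition.COHERENT: template_projection(template, layout, times, coh_scales),
        Condition.INCOHERENT: template_projection(template, layout, times, inc_scales),
    }

    data = np.empty((2 * n_per, n_ch, n_t))
    rows = []
    for ci, cond in enumerate((Condition.COHERENT, Condition.INCOHERENT)):
        block = _noise_block(rng, cohort, n_per, n_ch, n_t)
        block[:, :n_eeg, :] += sig[cond][None]
        data[ci * n_per : (ci + 1) * n_per] = block
        for k in range(n_per):
            rows.append(
                {
                    "condition": cond.value,
                    "direction": (Direction.CW if k % 2 == 0 else Direction.CCW).value,
                    "subject": subject_id,
                    "group": group,
                }
            )
    epochs = EpochSet(
        data=data,
        times=times,
        channel_labels=channels,
        labels=pd.DataFrame(rows),
        srate=_SRATE,
    )
    epochs.log_stage("simulate_subject_epochs", subject=subject_id, group=group)
    return epochs, params


@dataclass
class SyntheticCohort:
    subjects: list[str]
    groups: dict[str, str]
    epoch_sets: dict[str, EpochSet]
    params: dict[str, SubjectParams]
    layout: SensorLayout
    template: ErpTemplateSpec
    cohort_spec: CohortSpec

    def subject_score(self, subject: str) -> float:
        """Signed expected coherent central amplitude of the early component.

        This is the subject-level quantity the brain-behavior coupling acts
        on: gain x coherent attenuation x signed component amplitude.
        """
        comp = self.template.components[0]
        p = self.params[subject]
        return float(comp.amplitude_uv * p.gain * p.attenuations[0])

    def standardized_scores(self) -> dict[str, float]:
        vals = np.array([self.subject_score(s) for s in self.subjects])
        sd = vals.std()
        if sd == 0:
            return {s: 0.0 for s in self.subjects}
        z = (vals - vals.mean()) / sd
        return dict(zip(self.subjects, z))

    def ground_truth(self) -> dict:
        return {
            "planted_electrodes_early": planted_electrodes(self.template, self.layout, 0),
            "planted_electrodes_late": planted_electrodes(self.template, self.layout, 1),
            "group_effect_components": [
                i for i, c in enumerate(self.template.components) if c.group_effect
            ],
            "subject_params": {
                s: {
                    "group": p.group,
                    "gain": p.gain,
                    "attenuations": p.attenuations.tolist(),
                }
                for s, p in self.params.items()
            },
        }


def simulate_cohort(
    template: ErpTemplateSpec = ErpTemplateSpec(),
    cohort: CohortSpec = CohortSpec(),
    layout: SensorLayout | None = None,
) -> SyntheticCohort:
    """Simulate all subjects of both handedness groups (deterministic per seed)."""
    cohort.validate()
    layout = layout if layout is not None else standard_layout()
    root = np.random.SeedSequence(cohort.seed)
    n_total = cohort.n_left + cohort.n_right
    seeds = root.spawn(n_total)
    subjects, groups, epoch_sets, params = [], {}, {}, {}
    specs = [("left", i) for i in range(cohort.n_left)] + [
        ("right", i) for i in range(cohort.n_right)
    ]
    for (group, i), seq in zip(specs, seeds):
        sid = f"{group[0]}{i + 1:02d}"
        es, p = simulate_subject_epochs(template, cohort, sid, group, seq, layout=layout)
        subjects.append(sid)
        groups[sid] = group
        epoch_sets[sid] = es
        params[sid] = p
    return SyntheticCohort(
        subjects=subjects,
        groups=groups,
        epoch_sets=epoch_sets,
        params=params,
        layout=layout,
        template=template,
        cohort_spec=cohort,
    )


# ---------------------------------------------------------------------------
# Artifact injection


def inject_artifacts(
    epochs: EpochSet,
    artifact_rates: dict | None = None,
    seed: int | np.random.SeedSequence = 0,
    blink_amp_uv: float = 150.0,
    blink_sigma_ms: float = 35.0,
    range_amp_uv: float = 75.0,
) -> tuple[EpochSet, pd.DataFrame]:
    """Insert labeled blink and range artifacts into randomly chosen epochs.

    Blinks: a Gaussian deflection (sigma 35 ms, default peak 150 uV) on the
    vertical EOG with 80% projection to Fp1/Fp2 — large enough that the
    best-aligned 200 ms rejection window shows an SD well above 35 uV.
    Range artifacts: one full cycle of a +-75 uV sine (150 uV peak-to-peak)
    over 100 ms in one random EEG channel.  Returns the modified epochs and a
    ground-truth label table (epoch, artifact type).
    """
    rates = artifact_rates or {"blink": 0.0, "range": 0.0}
    for k, v in rates.items():
        if not (0 <= v <= 1):
            raise ValidationError(f"artifact rate {k}={v} outside [0, 1]")
    rng = np.random.default_rng(seed)
    data = epochs.data.copy()
    n_ep, _, n_t = data.shape
    t = np.arange(n_t)
    name_to_idx = {c: i for i, c in enumerate(epochs.channel_labels)}
    labels = []

    blink_targets = [(name_to_idx[c], g) for c, g in
                     (("vEOG", 1.0), ("Fp1", 0.8), ("Fp2", 0.8)) if c in name_to_idx]
    eeg_idx = epochs.eeg_channel_indices()
    srate_ms = epochs.srate / 1000.0

    for e in range(n_ep):
        has_blink = rng.random() < rates.get("blink", 0.0)
        has_range = rng.random() < rates.get("range", 0.0)
        if has_blink:
            center = rng.uniform(0.2 * n_t, 0.8 * n_t)
            pulse = blink_amp_uv * np.exp(
                -((t - center) ** 2) / (2 * (blink_sigma_ms * srate_ms) ** 2)
            )
            for ch, gain in blink_targets:
                data[e, ch] += gain * pulse
            labels.append({"epoch": e, "type": "blink"})
        if has_range:
            ch = int(rng.choice(eeg_idx))
            start = int(rng.uniform(0.1 * n_t, 0.7 * n_t))
            width = int(100 * srate_ms)
            seg = np.arange(width)
            data[e, ch, start : start + width] += range_amp_uv * np.sin(
                2 * np.pi * seg / width
            )
            labels.append({"epoch": e, "type": "range"})

    out = replace(epochs, data=data)
    out.log_stage("inject_artifacts", rates=rates, n_labeled=len(labels))
    return out, pd.DataFrame(labels, columns=["epoch", "type"])


# ---------------------------------------------------------------------------
# Behavior simulation


@dataclass(frozen=True)
class ConditionBehavior:
    """Per-condition behavioral distributions (times in s, strength 0-10)."""

    presence_prob: float
    latency_median_s: float
    latency_sigma: float
    duration_median_s: float
    duration_sigma: float
    strength_center: float
    strength_sd: float


@dataclass(frozen=True)
class BehaviorSpec:
    """Vection report generator.

    Defaults echo the study's summary table: vection on nearly every coherent
    trial (median 47-48 of 50) with ~6 s onset latency, ~13 s total duration
    and median strength 5; vection on very few incoherent trials (median
    4-4.5 of 50) with longer latency, shorter duration, strength 0 overall.
    ``strength_brain_coupling`` is the target rank correlation between the
    subject's expected signed coherent central amplitude and their strength
    reports (negative: stronger vection with lower central amplitude, the
    direction reported for the real cohort).
    """

    coherent: ConditionBehavior = ConditionBehavior(0.95, 6.0, 0.5, 13.0, 0.4, 5.0, 2.0)
    incoherent: ConditionBehavior = ConditionBehavior(0.08, 12.0, 0.4, 4.0, 0.5, 2.0, 1.0)
    strength_trial_sd: float = 1.0
    strength_brain_coupling: float = -0.4
    motion_duration_s: float = 20.0
    post_motion_s: float = 10.0

    def for_condition(self, condition: Condition) -> ConditionBehavior:
        return self.coherent if Condition(condition) == Condition.COHERENT else self.incoherent


def simulate_behavior(
    spec: BehaviorSpec,
    n_trials: int,
    condition: Condition | str,
    subject_score: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
    motion_onset_s: float = 4.0,
) -> list[TrialBehavior]:
    """Simulate one subject's trial reports for one condition.

    ``subject_score`` is the standardized signed coherent central amplitude
    from the EEG simulation; the subject's strength level is coupled to it
    through a Gaussian copula with correlation ``strength_brain_coupling``
    before discretization to the 0-10 scale.  Per trial: presence is
    Bernoulli; present trials get a log-normal onset latency (truncated below
    the 20 s motion duration) and a log-normal total duration truncated so
    vection ends by trial end (motion + 10 s); absent trials get strength 0.
    """
    cond = Condition(condition)
    cb = spec.for_condition(cond)
    rng = np.random.default_rng(seed)
    rho = spec.strength_brain_coupling
    if not (-1 <= rho <= 1):
        raise ValidationError("strength_brain_coupling must be in [-1, 1]")
    z = rho * subject_score + np.sqrt(1 - rho**2) * rng.standard_normal()
    subject_strength = cb.strength_center + cb.strength_sd * z

    trial_end = motion_onset_s + spec.motion_duration_s + spec.post_motion_s
    motion_offset = motion_onset_s + spec.motion_duration_s
    out: list[TrialBehavior] = []
    for trial in range(1, n_trials + 1):
        direction = Direction.CW if trial % 2 else Direction.CCW
        present = rng.random() < cb.presence_prob
        intervals: list[tuple[float, float]] = []
        strength = 0
        if present:
            latency = float(
                np.exp(rng.normal(np.log(cb.latency_median_s), cb.latency_sigma))
            )
            latency = min(latency, spec.motion_duration_s - 0.5)
            duration = float(
                np.exp(rng.normal(np.log(cb.duration_median_s), cb.duration_sigma))
            )
            onset = motion_onset_s + latency
            offset = min(onset + duration, trial_end)
            intervals = [(onset, offset)]
            strength = int(np.clip(round(subject_strength + spec.strength_trial_sd * rng.standard_normal()), 0, 10))
        out.append(
            TrialBehavior(
                trial=trial,
                condition=cond,
                direction=direction,
                motion_onset_time=motion_onset_s,
                motion_offset_time=motion_offset,
                vection_intervals=intervals,
                strength=strength,
            )
        )
    return out
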