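"""End-to-end analysis driver.

``run_all`` executes synthesize (or ingest) -> preprocess -> ERP window
amplitudes -> cluster permutation tests (condition contrast per handedness
group, handedness contrast on condition differences; early and late windows)
-> behavioral group comparisons -> brain-behavior correlations, and writes
delimited-text/JSON results plus a reproducibility manifest.  Every
stochastic stage draws its seed from the single master seed, so a run is
fully determined by its config.

Subjects are simulated and preprocessed one at a time; only per-subject
window amplitudes and behavioral summaries are retained, which keeps memory
flat in cohort size.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import behavior_comparison_table, summarize_participant
from .cluster import (
    ClusterTestResult,
    jaccard,
    permutation_test,
    standard_layout,
)
from .correlation import correlation_table, extract_cluster_amplitude
from .erp import EARLY_WINDOW, LATE_WINDOW, average_condition, window_mean_amplitude
from .io_formats import Condition, ValidationError, write_results_table
from .preprocessing import (
    RejectionCriteria,
    baseline_correct,
    check_participant_inclusion,
    collapse_directions,
    reject_artifacts,
)
from .synthetic import (
    BehaviorSpec,
    CohortSpec,
    ErpTemplateSpec,
    SubjectParams,
    simulate_behavior,
    simulate_subject_epochs,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_all"]

WINDOWS = {"early": EARLY_WINDOW, "late": LATE_WINDOW}


@dataclass(frozen=True)
class PipelineConfig:
    """Single configuration object for a full run."""

    mode: str = "synthetic"
    template: ErpTemplateSpec = field(default_factory=ErpTemplateSpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    behavior: BehaviorSpec = field(default_factory=BehaviorSpec)
    rejection: RejectionCriteria = field(default_factory=RejectionCriteria)
    n_perm: int = 1000
    cluster_alpha: float = 0.01
    null_percentile: float = 99.0
    bonferroni_behavior: int = 8
    bonferroni_correlation: int = 4
    min_trials: int = 30
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("synthetic",):
            raise ValidationError(f"unsupported pipeline mode {self.mode!r}")
        if self.n_perm < 100:
            raise ValidationError(f"n_perm={self.n_perm} below the minimum of 100")
        if not (0 < self.cluster_alpha < 1):
            raise ValidationError("cluster_alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        simple = {f.name for f in dataclasses.fields(cls)} - {
            "template", "cohort", "behavior", "rejection"
        }
        for key, val in raw.items():
            if key in simple:
                kwargs[key] = val
            elif key == "cohort":
                kwargs["cohort"] = CohortSpec(**val)
            elif key == "rejection":
                kwargs["rejection"] = RejectionCriteria(**val)
            else:
                raise ValidationError(f"unknown config key {key!r}")
        return cls(**kwargs)

    def content_hash(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    out_dir: Path
    window_amplitudes: dict  # (window, condition) -> DataFrame subjects x electrodes
    cluster_results: dict  # (contrast, window[, group]) -> ClusterTestResult
    behavior_table: pd.DataFrame
    correlation_tables: dict
    inclusion: pd.DataFrame
    manifest: dict


def _cluster_record(res: ClusterTestResult, names: list[str]) -> dict:
    return {
        "design": res.design,
        "n_permutations": res.n_permutations,
        "exact": res.exact,
        "seed": res.seed,
        "critical_value": res.critical_value,
        "p_value": res.p_value,
        "significant": res.significant,
        "largest_cluster": None
        if res.largest_cluster is None
        else {
            "electrodes": [names[i] for i in res.largest_cluster.members],
            "member_indices": list(res.largest_cluster.members),
            "sign": res.largest_cluster.sign,
            "mass": res.largest_cluster.mass,
        },
        "clusters": [
            {"electrodes": [names[i] for i in c.members], "sign": c.sign, "mass": c.mass}
            for c in res.clusters
        ],
    }


def run_all(config: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    """Run the full analysis; outputs are byte-identical across repeat runs."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    layout = standard_layout()
    names = layout.names
    n_elec = layout.n

    root = np.random.SeedSequence(config.seed)
    cohort = replace(config.cohort, seed=config.seed)
    n_total = cohort.n_left + cohort.n_right
    subject_seeds = np.random.SeedSequence(cohort.seed).spawn(n_total)
    aux = root.spawn(3)
    artifact_rng = np.random.default_rng(aux[0])
    behavior_root = aux[1]
    perm_rng = np.random.default_rng(aux[2])

    specs = [("left", i) for i in range(cohort.n_left)] + [
        ("right", i) for i in range(cohort.n_right)
    ]

    # ---- per-subject EEG: simulate, inject artifacts, preprocess, window means
    amp: dict[tuple[str, str], dict[str, np.ndarray]] = {
        (w, c.value): {} for w in WINDOWS for c in (Condition.COHERENT, Condition.INCOHERENT)
    }
    params: dict[str, SubjectParams] = {}
    groups: dict[str, str] = {}
    subjects: list[str] = []
    inclusion_rows, rejection_frames = [], []

    from .synthetic import inject_artifacts

    for (group, i), seq in zip(specs, subject_seeds):
        sid = f"{group[0]}{i + 1:02d}"
        subjects.append(sid)
        groups[sid] = group
        epochs, p = simulate_subject_epochs(
            config.template, cohort, sid, group, seq, layout=layout
        )
        params[sid] = p
        epochs, truth = inject_artifacts(
            epochs, cohort.artifact_rates,
            seed=int(artifact_rng.integers(2**31)),
        )
        epochs = baseline_correct(epochs)
        kept, rej_log = reject_artifacts(epochs, config.rejection)
        rej_log = rej_log.assign(subject=sid)
        rejection_frames.append(rej_log)
        included, counts = check_participant_inclusion(kept, config.min_trials)
        inclusion_rows.append({"subject": sid, "group": group, "included": included, **counts})
        if not included:
            continue
        kept = collapse_directions(kept)
        for cond in (Condition.COHERENT, Condition.INCOHERENT):
            wave = average_condition(kept, cond)
            for wname, window in WINDOWS.items():
                # EEG channels only (layout order); EOG is artifact-detection plumbing
                amp[(wname, cond.value)][sid] = window_mean_amplitude(wave, window).values[:n_elec]

    inclusion = pd.DataFrame(inclusion_rows)
    included_subjects = [s for s in subjects if inclusion.set_index("subject").loc[s, "included"]]
    if len(included_subjects) < 4:
        raise ValidationError("too few included participants for group statistics")

    window_amplitudes = {
        key: pd.DataFrame(
            np.vstack([v[s] for s in included_subjects if s in v]),
            index=[s for s in included_subjects if s in v],
            columns=names,
        )
        for key, v in amp.items()
    }

    # ---- cluster permutation tests
    cluster_results: dict[tuple, ClusterTestResult] = {}
    for wname in WINDOWS:
        coh = window_amplitudes[(wname, "coherent")]
        inc = window_amplitudes[(wname, "incoherent")]
        diffs = coh - inc
        by_group = {
            g: diffs.loc[[s for s in diffs.index if groups[s] == g]] for g in ("left", "right")
        }
        for g in ("left", "right"):
            cluster_results[("condition", wname, g)] = permutation_test(
                by_group[g].to_numpy(), None, "paired", layout.adjacency,
                n_perm=config.n_perm, alpha_cluster=config.cluster_alpha,
                seed=int(perm_rng.integers(2**31)), percentile=config.null_percentile,
            )
        cluster_results[("handedness", wname)] = permutation_test(
            by_group["left"].to_numpy(), by_group["right"].to_numpy(), "independent",
            layout.adjacency, n_perm=config.n_perm, alpha_cluster=config.cluster_alpha,
            seed=int(perm_rng.integers(2**31)), percentile=config.null_percentile,
        )

    # ---- behavior (no participant exclusion; all simulated subjects)
    scores = _standardized_scores(params, config.template, subjects)
    behavior_seeds = behavior_root.spawn(n_total)
    summaries = []
    by_subject_cond: dict[tuple[str, str], dict] = {}
    for sid, seq in zip(subjects, behavior_seeds):
        sub_seeds = seq.spawn(2)
        for cond, s in zip((Condition.COHERENT, Condition.INCOHERENT), sub_seeds):
            trials = simulate_behavior(
                config.behavior, cohort.trials_per_condition, cond,
                subject_score=scores[sid], seed=s,
            )
            summ = summarize_participant(trials, cond, subject=sid)
            summaries.append(summ)
            by_subject_cond[(sid, cond.value)] = summ.as_dict()
    behavior_table = behavior_comparison_table(
        summaries, groups, bonferroni_m=config.bonferroni_behavior
    )

    # ---- brain-behavior correlations (coherent condition, pooled groups)
    correlation_tables: dict[str, pd.DataFrame] = {}
    for wname in WINDOWS:
        candidates = [
            cluster_results[("condition", wname, g)] for g in ("left", "right")
        ]
        sig = [r for r in candidates if r.significant and r.largest_cluster is not None]
        if not sig:
            logger.info("no significant condition cluster in %s window; no correlations", wname)
            continue
        best = max(sig, key=lambda r: abs(r.largest_cluster.mass))
        coh = window_amplitudes[(wname, "coherent")]
        cluster_amp = extract_cluster_amplitude(
            coh.to_numpy(), best.largest_cluster.members
        )
        beh = pd.DataFrame(
            [by_subject_cond[(s, "coherent")] for s in coh.index]
        )
        correlation_tables[wname] = correlation_table(
            cluster_amp, beh, wname, bonferroni_m=config.bonferroni_correlation
        )

    # ---- write outputs
    write_results_table(pd.concat(rejection_frames, ignore_index=True), out_dir / "rejection_log.csv")
    write_results_table(inclusion, out_dir / "inclusion.csv")
    for (wname, cond), df in window_amplitudes.items():
        df.round(10).to_csv(out_dir / f"window_amplitudes_{wname}_{cond}.csv")
    write_results_table(behavior_table.round(10), out_dir / "behavior_comparisons.csv")
    for wname, df in correlation_tables.items():
        write_results_table(df.round(10), out_dir / f"correlations_{wname}.csv")
    cluster_json = {
        "_".join(k): _cluster_record(r, names) for k, r in cluster_results.items()
    }
    (out_dir / "cluster_results.json").write_text(
        json.dumps(cluster_json, indent=2, sort_keys=True)
    )
    manifest = {
        "package_version": __version__,
        "config_hash": config.content_hash(),
        "master_seed": config.seed,
        "mode": config.mode,
        "n_subjects": n_total,
        "n_included": len(included_subjects),
        "n_permutations": config.n_perm,
        "windows": {k: list(v) for k, v in WINDOWS.items()},
        "montage_hash": hashlib.sha256(layout.pos3d.tobytes()).hexdigest()[:16],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return PipelineResult(
        out_dir=out_dir,
        window_amplitudes=window_amplitudes,
        cluster_results=cluster_results,
        behavior_table=behavior_table,
        correlation_tables=correlation_tables,
        inclusion=inclusion,
        manifest=manifest,
    )


def _standardized_scores(
    params: dict[str, SubjectParams], template: ErpTemplateSpec, subjects: list[str]
) -> dict[str, float]:
    comp = template.components[0]
    vals = np.array(
        [comp.amplitude_uv * params[s].gain * params[s].attenuations[0] for s in subjects]
    )
    sd = vals.std()
    if sd == 0:
        return {s: 0.0 for s in subjects}
    z = (vals - vals.mean()) / sd
    return dict(zip(subjects, z))


def recovery_metrics(result: PipelineResult, truth: dict) -> dict:
    """Jaccard overlap of recovered largest clusters with planted electrode sets."""
    out = {}
    for wname, key in (("early", "planted_electrodes_early"), ("late", "planted_electrodes_late")):
        planted = set(truth[key])
        for g in ("left", "right"):
            res = result.cluster_results[("condition", wname, g)]
            members = set(res.largest_cluster.members) if res.largest_cluster else set()
            out[f"jaccard_{wname}_{g}"] = jaccard(members, planted)
    return out
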