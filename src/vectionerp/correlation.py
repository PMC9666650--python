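"""Brain-behavior correlations: cluster mean amplitude vs. vection measures.

After the condition contrast identifies the largest significant electrode
cluster in a window, each subject's coherent-condition window amplitudes are
averaged over the cluster electrodes; left- and right-handers are pooled and
the cluster mean amplitude is correlated with each behavioral measure using
Spearman's rho (t-approximation p at the cohort's n), Bonferroni-corrected
over the 4 measures per window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ValidationError

__all__ = [
    "CorrelationResult",
    "extract_cluster_amplitude",
    "spearman_correlation",
    "spearman_exact_p",
    "bonferroni_adjust",
    "correlation_table",
]


@dataclass
class CorrelationResult:
    measure: str
    window: str
    rho: float
    p: float
    p_adjusted: float
    n: int

    def as_dict(self) -> dict:
        return {
            "measure": self.measure,
            "window": self.window,
            "rho": self.rho,
            "p": self.p,
            "p_adjusted": self.p_adjusted,
            "n": self.n,
        }


def extract_cluster_amplitude(
    subject_amplitudes: np.ndarray, cluster_electrodes
) -> np.ndarray:
    """Per-subject unweighted mean amplitude over the cluster electrodes.

    ``subject_amplitudes`` is subjects x electrodes (coherent-condition window
    means, groups pooled).
    """
    members = np.asarray(list(cluster_electrodes), dtype=int)
    if members.size == 0:
        raise ValidationError(
            "empty cluster: no significant condition cluster, correlation undefined"
        )
    amps = np.asarray(subject_amplitudes, dtype=float)
    if members.max() >= amps.shape[1]:
        raise ValidationError("cluster electrode index outside the amplitude matrix")
    return amps[:, members].mean(axis=1)


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman's rho (average ranks for ties) with two-sided t-approximation p.

    Returns (nan, nan) with a raised error if either variable has zero rank
    variance (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D and equally long")
    n = len(x)
    if n < 4:
        raise ValidationError("Spearman correlation needs n >= 4")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        raise ValidationError("zero rank variance: rho undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) > 1.0 - 1e-12:
        rho = math.copysign(1.0, rho)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho**2))
    p = float(2 * stats.t.sf(abs(t), n - 2))
    return rho, p


def spearman_exact_p(x, y) -> tuple[float, float]:
    """Exact permutation p for Spearman's rho (test oracle; n <= 10)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n > 10:
        raise ValidationError("exact Spearman enumeration limited to n <= 10")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = total = 0
    for perm in permutations(ry):
        r = abs(np.corrcoef(rx, np.asarray(perm))[0, 1])
        count += r >= obs - 1e-12
        total += 1
    return float(np.corrcoef(rx, ry)[0, 1]), count / total


def bonferroni_adjust(p: float, m: int) -> float:
    """min(1, m * p)."""
    if m < 1:
        raise ValidationError("Bonferroni family size must be >= 1")
    return min(1.0, m * p)


def correlation_table(
    cluster_amplitude: np.ndarray,
    behavior: pd.DataFrame,
    window: str,
    measures=("presence_count", "onset_latency_s", "duration_s", "strength"),
    bonferroni_m: int = 4,
) -> pd.DataFrame:
    """Correlate cluster mean amplitude with each behavioral measure.

    ``behavior`` has one row per pooled subject, aligned with
    ``cluster_amplitude``; rows with a missing measure (e.g. latency for a
    subject with no vection-present trials) are dropped pairwise.
    """
    rows = []
    for measure in measures:
        y = behavior[measure].to_numpy(dtype=float)
        ok = ~np.isnan(y) & ~np.isnan(cluster_amplitude)
        rho, p = spearman_correlation(cluster_amplitude[ok], y[ok])
        rows.append(
            CorrelationResult(
                measure=measure,
                window=window,
                rho=rho,
                p=p,
                p_adjusted=bonferroni_adjust(p, bonferroni_m),
                n=int(ok.sum()),
            ).as_dict()
        )
    return pd.DataFrame(rows)
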