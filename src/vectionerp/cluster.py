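"""Spatial cluster-based permutation tests on per-electrode window amplitudes.

The multiple-comparison problem across 64 electrodes is handled with the
max-statistic cluster permutation approach: electrode-level t-tests are
thresholded at p < 0.01 (two-sided), suprathreshold electrodes are grouped
into spatially adjacent, same-sign clusters, each cluster's *mass* is the sum
of its member t values, and the observed largest |mass| is compared against
the 99th percentile of the permutation null distribution of the maximum
cluster mass (1000 permutations by default).

Two designs are supported:

* ``paired`` — within-group condition contrast on per-subject condition
  differences; the null permutes by random per-subject sign flips.
* ``independent`` — handedness contrast on per-subject condition differences;
  the null permutes group labels.

Clustering is spatial only: the tested quantity is already a scalar per
electrode (the window mean amplitude), so there is no temporal dimension.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
from scipy import spatial, stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io_formats import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SensorLayout",
    "ElectrodeStats",
    "Cluster",
    "ClusterTestResult",
    "standard_layout",
    "build_adjacency",
    "electrode_level_test",
    "form_clusters",
    "permutation_test",
]

#: 64-channel 10-10 montage recorded against FCz (BrainProducts-style cap).
CHANNELS_64 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10",
    "AF7", "AF3", "AF4", "AF8", "F5", "F1", "F2", "F6",
    "FT9", "FT7", "FC3", "FC4", "FT8", "FT10",
    "C5", "C1", "C2", "C6", "TP7", "CP3", "CPz", "CP4", "TP8",
    "P5", "P1", "P2", "P6", "PO7", "PO3", "POz", "PO4", "PO8",
]

EOG_CHANNELS = ["hEOG", "vEOG"]


@dataclass
class SensorLayout:
    """Channel names with scalp coordinates and a spatial adjacency graph."""

    names: list[str]
    pos3d: np.ndarray  # (n, 3) metres, head frame
    pos2d: np.ndarray  # (n, 2) azimuthal-equidistant projection
    adjacency: np.ndarray | None = None  # (n, n) bool, symmetric, irreflexive
    method: str = ""
    params: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def neighbor_counts(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def is_connected(self) -> bool:
        n_comp, _ = connected_components(csr_matrix(self.adjacency), directed=False)
        return n_comp == 1


def _azimuthal_projection(pos3d: np.ndarray) -> np.ndarray:
    """Project head-frame 3D positions to the plane (angle-preserving from Cz)."""
    p = pos3d - pos3d.mean(axis=0) * 0  # positions are already head-centred
    r = np.linalg.norm(p, axis=1)
    polar = np.arccos(np.clip(p[:, 2] / r, -1, 1))
    az = np.arctan2(p[:, 1], p[:, 0])
    return np.stack([polar * np.cos(az), polar * np.sin(az)], axis=1)


def standard_layout(names: list[str] | None = None) -> SensorLayout:
    """10-10 sensor layout from the standard template montage, with adjacency."""
    import mne

    names = list(names) if names is not None else list(CHANNELS_64)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("standard_1005")
    ch_pos = montage.get_positions()["ch_pos"]
    missing = [n for n in names if n not in ch_pos]
    if missing:
        raise ValidationError(f"channels missing from template montage: {missing}")
    pos3d = np.array([ch_pos[n] for n in names])
    layout = SensorLayout(names=names, pos3d=pos3d, pos2d=_azimuthal_projection(pos3d))
    return build_adjacency(layout)


def build_adjacency(
    layout: SensorLayout,
    method: str = "delaunay",
    prune_factor: float = 1.5,
    radius: float | None = None,
) -> SensorLayout:
    """Attach a spatial adjacency graph to ``layout``.

    Default: Delaunay triangulation of the 2D projection with edges longer
    than ``prune_factor`` x the median edge length removed.  Degenerate
    layouts (fewer than 3 points, or collinear points) fall back to the
    fixed-radius method with a warning.
    """
    n = layout.n
    pos = layout.pos2d
    adj = np.zeros((n, n), dtype=bool)

    def _radius_method(r: float | None) -> None:
        d = spatial.distance.squareform(spatial.distance.pdist(pos))
        if r is None:
            nn = np.partition(d + np.where(np.eye(n, dtype=bool), np.inf, 0.0), 0, axis=1)[:, 0]
            r = prune_factor * float(np.median(nn))
        mask = (d <= r) & ~np.eye(n, dtype=bool)
        adj[:] = mask
        layout.method = "radius"
        layout.params = {"radius": r}

    if method == "radius" or n < 3:
        _radius_method(radius)
    else:
        try:
            tri = spatial.Delaunay(pos)
            edges = set()
            for simplex in tri.simplices:
                for i, j in combinations(simplex, 2):
                    edges.add((min(i, j), max(i, j)))
            lengths = {e: np.linalg.norm(pos[e[0]] - pos[e[1]]) for e in edges}
            cutoff = prune_factor * float(np.median(list(lengths.values())))
            for (i, j), length in lengths.items():
                if length <= cutoff:
                    adj[i, j] = adj[j, i] = True
            layout.method = "delaunay"
            layout.params = {"prune_factor": prune_factor, "edge_cutoff": cutoff}
        except spatial.QhullError:
            logger.warning("degenerate layout; falling back to radius adjacency")
            _radius_method(radius)

    layout.adjacency = adj
    logger.info(
        "adjacency (%s): %d channels, median neighbor count %.1f",
        layout.method, n, float(np.median(adj.sum(axis=1))),
    )
    return layout


# ---------------------------------------------------------------------------
# Electrode-level statistics


@dataclass
class ElectrodeStats:
    """Per-electrode t statistics and two-sided p values."""

    t: np.ndarray
    p: np.ndarray
    design: str  # "paired" | "independent"
    n: tuple[int, ...]
    df: int


def _paired_t(diff: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """One-sample t on per-subject differences; zero variance -> t=0, p=1."""
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    df = n - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero = sd == 0
    t = np.where(zero, 0.0, t)
    p = 2 * stats.t.sf(np.abs(t), df)
    p = np.where(zero, 1.0, p)
    if np.any(zero):
        logger.warning("zero-variance electrodes in paired test: %d", int(zero.sum()))
    return t, p, df


def _independent_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Two-sample pooled-variance t; zero pooled variance -> t=0, p=1."""
    na, nb = a.shape[0], b.shape[0]
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / df
    se = np.sqrt(sp2 * (1 / na + 1 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / se
    zero = se == 0
    t = np.where(zero, 0.0, t)
    p = 2 * stats.t.sf(np.abs(t), df)
    p = np.where(zero, 1.0, p)
    return t, p, df


def electrode_level_test(
    values_a: np.ndarray,
    values_b: np.ndarray | None,
    design: str,
) -> ElectrodeStats:
    """Per-electrode t-test.

    paired: ``values_a`` are per-subject differences (subjects x electrodes);
    ``values_b`` may be the second condition (then differences are formed
    internally as a - b).  independent: ``values_a``/``values_b`` are the two
    groups' per-subject condition differences.
    """
    a = np.asarray(values_a, dtype=float)
    if design == "paired":
        diff = a if values_b is None else a - np.asarray(values_b, dtype=float)
        if diff.shape[0] < 2:
            raise ValidationError("paired design needs >= 2 subjects")
        t, p, df = _paired_t(diff)
        return ElectrodeStats(t=t, p=p, design="paired", n=(diff.shape[0],), df=df)
    if design == "independent":
        b = np.asarray(values_b, dtype=float)
        if a.shape[0] < 2 or b.shape[0] < 2:
            raise ValidationError("independent design needs >= 2 subjects per group")
        t, p, df = _independent_t(a, b)
        return ElectrodeStats(t=t, p=p, design="independent", n=(a.shape[0], b.shape[0]), df=df)
    raise ValidationError(f"unknown design {design!r}")


# ---------------------------------------------------------------------------
# Cluster formation


@dataclass(frozen=True)
class Cluster:
    members: tuple[int, ...]  # electrode indices, sorted
    sign: int
    mass: float  # sum of member t values


def _clusters_from_t(
    t: np.ndarray, supra: np.ndarray, adjacency: np.ndarray
) -> list[Cluster]:
    """Connected same-sign components of the suprathreshold electrode set."""
    idx = np.flatnonzero(supra)
    if idx.size == 0:
        return []
    sign = np.sign(t)
    clusters: list[Cluster] = []
    unvisited = set(idx.tolist())
    while unvisited:
        start = min(unvisited)
        s = sign[start]
        comp = [start]
        unvisited.discard(start)
        frontier = [start]
        while frontier:
            cur = frontier.pop()
            for nb in np.flatnonzero(adjacency[cur]):
                if nb in unvisited and sign[nb] == s:
                    unvisited.discard(int(nb))
                    comp.append(int(nb))
                    frontier.append(int(nb))
        comp.sort()
        clusters.append(Cluster(members=tuple(comp), sign=int(s), mass=float(t[comp].sum())))
    return clusters


def form_clusters(
    stats_: ElectrodeStats, adjacency: np.ndarray, alpha: float = 0.01
) -> list[Cluster]:
    """Partition electrodes with p < alpha into adjacent same-sign clusters."""
    if stats_.t.shape[0] != adjacency.shape[0]:
        raise ValidationError("stats and adjacency cover different electrode sets")
    supra = stats_.p < alpha
    return _clusters_from_t(stats_.t, supra, adjacency)


def _largest(clusters: list[Cluster]) -> Cluster | None:
    """Largest-|mass| cluster; ties broken by size then lexicographic members."""
    if not clusters:
        return None
    return max(clusters, key=lambda c: (abs(c.mass), len(c.members), tuple(-m for m in c.members)))


# ---------------------------------------------------------------------------
# Permutation test


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    largest_cluster: Cluster | None
    null_max_mass: np.ndarray
    critical_value: float
    p_value: float
    significant: bool
    n_permutations: int
    seed: int | None
    design: str
    electrode_stats: ElectrodeStats
    exact: bool = False


def _tcrit(alpha: float, df: int) -> float:
    return float(stats.t.isf(alpha / 2, df))


def _max_masses_from_t(
    t_mat: np.ndarray, tcrit: float, adjacency: np.ndarray
) -> np.ndarray:
    """Max |cluster mass| per row of a (n_perm, n_elec) t matrix (0 if none)."""
    out = np.zeros(t_mat.shape[0])
    supra_mat = np.abs(t_mat) > tcrit
    for i in np.flatnonzero(supra_mat.any(axis=1)):
        clusters = _clusters_from_t(t_mat[i], supra_mat[i], adjacency)
        if clusters:
            out[i] = max(abs(c.mass) for c in clusters)
    return out


def _paired_null(
    diff: np.ndarray, signs: np.ndarray, tcrit: float, adjacency: np.ndarray
) -> np.ndarray:
    """Null max masses for sign-flip permutations (signs: n_perm x n_subj of +-1).

    Sign flips leave per-subject squared values unchanged, so only the mean
    varies across permutations; the t statistic for every permutation comes
    from one matrix product.
    """
    n = diff.shape[0]
    ss = (diff**2).sum(axis=0)  # constant across sign flips
    mean = signs @ diff / n  # (n_perm, n_elec)
    var = (ss[None, :] - n * mean**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mat = mean / np.sqrt(var / n)
    t_mat = np.nan_to_num(t_mat, nan=0.0, posinf=0.0, neginf=0.0)
    return _max_masses_from_t(t_mat, tcrit, adjacency)


def _independent_null(
    x: np.ndarray, na: int, sel: np.ndarray, tcrit: float, adjacency: np.ndarray
) -> np.ndarray:
    """Null max masses for label permutations.

    ``x`` stacks both groups (n x n_elec); ``sel`` is n_perm x n binary with
    exactly ``na`` ones per row selecting the relabelled first group.  Total
    and total-of-squares are label-invariant, so group means and the pooled
    variance for every permutation reduce to matrix products.
    """
    n = x.shape[0]
    nb = n - na
    tot = x.sum(axis=0)
    tot2 = (x**2).sum(axis=0)
    sum_a = sel @ x  # (n_perm, n_elec)
    sum2_a = sel @ (x**2)
    mean_a = sum_a / na
    mean_b = (tot[None, :] - sum_a) / nb
    sswithin = tot2[None, :] - na * mean_a**2 - nb * mean_b**2
    df = n - 2
    sp2 = np.maximum(sswithin, 0.0) / df
    se = np.sqrt(sp2 * (1 / na + 1 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mat = (mean_a - mean_b) / se
    t_mat = np.nan_to_num(t_mat, nan=0.0, posinf=0.0, neginf=0.0)
    return _max_masses_from_t(t_mat, tcrit, adjacency)


def permutation_test(
    values_a: np.ndarray,
    values_b: np.ndarray | None,
    design: str,
    adjacency: np.ndarray,
    n_perm: int = 1000,
    alpha_cluster: float = 0.01,
    seed: int | None = None,
    percentile: float = 99.0,
    method: str = "auto",
) -> ClusterTestResult:
    """Max-mass spatial cluster permutation test.

    The observed largest cluster's |mass| is compared against the
    ``percentile`` (default 99th) percentile of the null distribution of the
    per-permutation maximum |mass|; the permutation p value uses the +1/+1
    correction and does not count the observed data as a permutation.  When
    the permutation space holds fewer than 100 distinct relabellings, the
    full space is enumerated instead (with a warning) and the p value is the
    exact proportion of the space reaching the observed mass; ``method`` can
    force either route ("exact" is limited to small designs).
    """
    if method not in ("auto", "exact", "montecarlo"):
        raise ValidationError(f"unknown permutation method {method!r}")
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    observed = electrode_level_test(values_a, values_b, design)
    clusters = form_clusters(observed, adjacency, alpha_cluster)
    largest = _largest(clusters)
    obs_mass = abs(largest.mass) if largest is not None else 0.0
    tcrit = _tcrit(alpha_cluster, observed.df)
    rng = np.random.default_rng(seed)
    exact = False

    if design == "paired":
        a = np.asarray(values_a, dtype=float)
        diff = a if values_b is None else a - np.asarray(values_b, dtype=float)
        n = diff.shape[0]
        if method == "exact" or (method == "auto" and 2**n < 100):
            if method == "auto":
                logger.warning(
                    "only %d distinct sign-flip patterns (< 100); using exact enumeration",
                    2**n,
                )
            if n > 20:
                raise ValidationError("exact sign-flip enumeration limited to <= 20 subjects")
            signs = np.array(list(product((1.0, -1.0), repeat=n)))
            exact = True
        else:
            signs = rng.choice((1.0, -1.0), size=(n_perm, n))
        null = _paired_null(diff, signs, tcrit, adjacency)
    elif design == "independent":
        a = np.asarray(values_a, dtype=float)
        b = np.asarray(values_b, dtype=float)
        x = np.vstack([a, b])
        n, na = x.shape[0], a.shape[0]
        from math import comb

        if method == "exact" or (method == "auto" and comb(n, na) < 100):
            if method == "auto":
                logger.warning(
                    "only %d distinct group relabellings (< 100); using exact enumeration",
                    comb(n, na),
                )
            if comb(n, na) > 200_000:
                raise ValidationError("exact relabelling enumeration too large")
            sel = np.zeros((comb(n, na), n))
            for i, c in enumerate(combinations(range(n), na)):
                sel[i, list(c)] = 1.0
            exact = True
        else:
            sel = np.zeros((n_perm, n))
            for i in range(n_perm):
                sel[i, rng.choice(n, size=na, replace=False)] = 1.0
        null = _independent_null(x, na, sel, tcrit, adjacency)
    else:
        raise ValidationError(f"unknown design {design!r}")

    critical = float(np.percentile(null, percentile))
    if exact:
        p_value = float(np.mean(null >= obs_mass))
    else:
        p_value = float((1 + np.sum(null >= obs_mass)) / (len(null) + 1))
    significant = largest is not None and obs_mass > critical
    return ClusterTestResult(
        clusters=clusters,
        largest_cluster=largest,
        null_max_mass=null,
        critical_value=critical,
        p_value=p_value,
        significant=bool(significant),
        n_permutations=len(null),
        seed=seed,
        design=design,
        electrode_stats=observed,
        exact=exact,
    )


def jaccard(a: set[int] | tuple, b: set[int] | tuple) -> float:
    """Jaccard overlap between two electrode index sets."""
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)
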