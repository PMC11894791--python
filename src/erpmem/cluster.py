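"""Two-step spatiotemporal cluster-mass permutation testing for ERPs.

Step 1 (sensor-level forming criterion): a pointwise F statistic of the
condition effect is computed for every sensor and sample.  Per sensor,
only supra-threshold stretches lasting at least ``min_run`` consecutive
samples (5 samples = 20 ms at 250 Hz) survive.  Surviving sensor-time
points are then linked spatiotemporally — same sensor and adjacent
samples, or neighboring sensors and the same sample — and every connected
component becomes a cluster whose *mass* is the sum of its F values.

Step 2 (cluster-level criterion): the same pipeline is run on permuted
data — per-subject random sign flips of the effect contrast for
within-subject effects, random group-label reassignment for
between-subject factors — recording the MAXIMUM cluster mass of each
permutation (0 when nothing survives).  The *critical cluster mass* is the
95th percentile of that null sample; empirical clusters heavier than it
are significant, and each gets the Monte-Carlo p-value
``(1 + #{null >= mass}) / (1 + n_perm)``.

Taking the per-permutation maximum (rather than pooling all permuted
clusters) is what gives family-wise error control: the probability that
any null cluster beats the 95th percentile of the max-mass distribution
is at most about 5%.

All effects reduce to a single per-subject contrast, so F carries one
numerator degree of freedom and equals a squared t:

* ``paired`` — condition difference, one-sample t, df (1, n-1);
* ``interaction_within`` — difference of differences, df (1, n-1);
* ``interaction_mixed`` — within-subject difference compared across two
  groups with a pooled-variance two-sample t, df (1, n1+n2-2);
* ``three_way_mixed`` — within-subject double difference compared across
  groups, df (1, n1+n2-2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import f as f_dist

from ._rng import component_rng
from .epochs import EpochSet
from .layout import SensorLayout

__all__ = [
    "EffectSpec",
    "FMap",
    "Cluster",
    "PermNull",
    "PermTestResult",
    "pointwise_f",
    "form_clusters",
    "perm_null",
    "cluster_test",
    "cluster_mean_amplitude",
    "spatiotemporal_adjacency",
]

#: sentinel replacing an infinite F (zero contrast variance, nonzero mean)
F_SENTINEL = 1e12

_WITHIN_DESIGNS = ("paired", "interaction_within")
_MIXED_DESIGNS = ("interaction_mixed", "three_way_mixed")


@dataclass
class EffectSpec:
    """Maps a named effect onto the condition labels of an EpochSet.

    ``cells`` is ``(a, b)`` for the 2-level designs (contrast ``a - b``)
    or ``((a1, a2), (b1, b2))`` for the 2x2 contrasts
    (``(a1 - a2) - (b1 - b2)``).  For mixed designs ``groups`` maps each
    subject to one of exactly two group labels.
    """

    name: str
    design: str
    cells: tuple
    groups: dict | None = None

    def __post_init__(self) -> None:
        if self.design not in _WITHIN_DESIGNS + _MIXED_DESIGNS:
            raise ValueError(f"unknown design type {self.design!r}")
        if self.design in _MIXED_DESIGNS and not self.groups:
            raise ValueError(f"{self.design} requires a subject -> group mapping")

    def _cell_labels(self) -> list[str]:
        if self.design in ("paired", "interaction_mixed"):
            a, b = self.cells
            return [a, b]
        (a1, a2), (b1, b2) = self.cells
        return [a1, a2, b1, b2]


def subject_contrasts(
    epochs: EpochSet, effect: EffectSpec
) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-subject effect contrast, (n_subjects, n_sensors, n_times).

    For mixed designs also returns a 0/1 group indicator aligned with the
    subject axis (1 = lexicographically larger group label).
    """
    labels = effect._cell_labels()
    missing = [c for c in labels if c not in epochs.conditions]
    if missing:
        raise ValueError(f"conditions not in epochs: {missing}")
    idx = [epochs.condition_index(c) for c in labels]
    v = epochs.values
    if effect.design in ("paired", "interaction_mixed"):
        contrast = v[:, idx[0]] - v[:, idx[1]]
    else:
        contrast = (v[:, idx[0]] - v[:, idx[1]]) - (v[:, idx[2]] - v[:, idx[3]])

    if effect.design in _WITHIN_DESIGNS:
        return contrast, None
    groups = effect.groups
    missing_subj = [s for s in epochs.subjects if s not in groups]
    if missing_subj:
        raise ValueError(f"subjects without group labels: {missing_subj}")
    levels = sorted({groups[s] for s in epochs.subjects})
    if len(levels) != 2:
        raise ValueError(f"between-subject factor needs 2 groups, got {levels}")
    z = np.array([groups[s] == levels[1] for s in epochs.subjects], dtype=float)
    if z.sum() < 2 or (1 - z).sum() < 2:
        raise ValueError("each group needs at least 2 subjects")
    return contrast, z


def _one_sample_f(signs: np.ndarray, c_flat: np.ndarray) -> np.ndarray:
    """F = t^2 of sign-flipped one-sample tests, batched over sign rows.

    ``signs``: (n_batch, n_subj) of +/-1; ``c_flat``: (n_subj, P).
    """
    n = c_flat.shape[0]
    ssq = np.einsum("sp,sp->p", c_flat, c_flat)  # invariant to sign flips
    m = signs @ c_flat / n
    var = (ssq[None, :] - n * m**2) / (n - 1)
    num = n * m**2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = num / var
    f = np.where(var > 0, f, np.where(num > 0, F_SENTINEL, 0.0))
    return f


def _pooled_f(z_rows: np.ndarray, c_flat: np.ndarray) -> np.ndarray:
    """F = t^2 of pooled-variance two-sample tests across group labelings.

    ``z_rows``: (n_batch, n_subj) of 0/1 indicators (group sizes fixed).
    """
    n = c_flat.shape[0]
    n1 = z_rows[0].sum()
    n0 = n - n1
    ssq = np.einsum("sp,sp->p", c_flat, c_flat)
    s1 = z_rows @ c_flat
    s0 = c_flat.sum(axis=0)[None, :] - s1
    m1, m0 = s1 / n1, s0 / n0
    ss_within = ssq[None, :] - n1 * m1**2 - n0 * m0**2
    var = ss_within / (n - 2)
    num = (m1 - m0) ** 2 / (1.0 / n1 + 1.0 / n0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = num / var
    f = np.where(var > 0, f, np.where(num > 0, F_SENTINEL, 0.0))
    return f


@dataclass
class FMap:
    """Pointwise F statistics over the sensor x time grid."""

    f: np.ndarray  # (n_sensors, n_times)
    df: tuple[int, int]
    p: np.ndarray
    sensor_ids: list[int]
    time_ms: np.ndarray
    sample_rate: float
    degenerate: np.ndarray | None = None  # points where F was capped


def pointwise_f(epochs: EpochSet, effect: EffectSpec) -> FMap:
    """Mass-univariate F-test of an effect at every sensor and sample."""
    contrast, z = subject_contrasts(epochs, effect)
    n = contrast.shape[0]
    shape = contrast.shape[1:]
    c_flat = contrast.reshape(n, -1)
    if z is None:
        if n < 2:
            raise ValueError("need at least 2 subjects")
        f = _one_sample_f(np.ones((1, n)), c_flat)[0]
        df = (1, n - 1)
    else:
        f = _pooled_f(z[None, :], c_flat)[0]
        df = (1, n - 2)
    f = f.reshape(shape)
    p = f_dist.sf(np.minimum(f, F_SENTINEL / 2), *df)
    return FMap(
        f=f,
        df=df,
        p=p,
        sensor_ids=list(epochs.sensor_ids),
        time_ms=epochs.time_ms,
        sample_rate=epochs.sample_rate,
        degenerate=(f >= F_SENTINEL),
    )


# -- cluster formation ---------------------------------------------------


def _prune_short_runs(mask: np.ndarray, min_run: int) -> np.ndarray:
    """Zero out per-sensor supra-threshold runs shorter than ``min_run``."""
    if min_run <= 1:
        return mask
    ns, nt = mask.shape
    padded = np.zeros((ns, nt + 2), dtype=np.int8)
    padded[:, 1:-1] = mask
    d = np.diff(padded, axis=1)
    rs, cs = np.nonzero(d == 1)
    _, ce = np.nonzero(d == -1)
    keep = (ce - cs) >= min_run
    out = np.zeros_like(mask)
    for r, c0, c1 in zip(rs[keep], cs[keep], ce[keep]):
        out[r, c0:c1] = True
    return out


def spatiotemporal_adjacency(sensor_adj: sparse.csr_matrix, n_t: int) -> sparse.csr_matrix:
    """Adjacency over the flattened (sensor, time) grid, node index
    ``sensor * n_t + t``: same sensor & adjacent samples, or neighboring
    sensors & same sample."""
    ns = sensor_adj.shape[0]
    T = sparse.diags([np.ones(n_t - 1)], [1], shape=(n_t, n_t), format="csr")
    T = (T + T.T).astype(bool)
    grid = sparse.kron(sensor_adj.astype(bool), sparse.eye(n_t, dtype=bool), format="csr")
    grid = grid + sparse.kron(sparse.eye(ns, dtype=bool), T, format="csr")
    return grid.tocsr()


@dataclass
class Cluster:
    """A connected supra-threshold sensor-time region."""

    sensor_ids: list[int]
    window_ms: tuple[float, float]  # half-open [onset, offset)
    sample_span: tuple[int, int]  # half-open sample indices
    mass: float
    n_points: int
    p: float | None = None
    significant: bool | None = None
    mask: np.ndarray | None = None  # (n_sensors, n_times) boolean footprint


def _clusters_from_mask(
    f: np.ndarray, mask: np.ndarray, grid_adj: sparse.csr_matrix
) -> tuple[np.ndarray, np.ndarray, int]:
    """Connected-component labels of the surviving points.

    Returns (flat indices, labels, n_components)."""
    idx = np.flatnonzero(mask.ravel())
    if idx.size == 0:
        return idx, np.empty(0, dtype=int), 0
    sub = grid_adj[idx][:, idx]
    n_comp, labels = connected_components(sub, directed=False)
    return idx, labels, n_comp


def form_clusters(
    fmap: FMap,
    adjacency: sparse.spmatrix | SensorLayout,
    forming_alpha: float = 0.05,
    min_run: int = 5,
    grid_adj: sparse.csr_matrix | None = None,
) -> list[Cluster]:
    """Form spatiotemporal clusters from an F map.

    Points with pointwise ``p < forming_alpha`` that persist for at least
    ``min_run`` consecutive samples on their sensor are clustered through
    the spatiotemporal adjacency.  Clusters are sorted by descending mass,
    ties broken by earliest onset then lowest sensor ID.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    if not (0.0 < forming_alpha < 1.0):
        raise ValueError("forming_alpha must be in (0, 1)")
    sensor_adj = (
        adjacency.adjacency_matrix() if isinstance(adjacency, SensorLayout) else adjacency
    )
    ns, nt = fmap.f.shape
    if sensor_adj.shape[0] != ns:
        raise ValueError("adjacency does not cover the FMap sensors")
    if grid_adj is None:
        grid_adj = spatiotemporal_adjacency(sensor_adj, nt)
    f_crit = f_dist.isf(forming_alpha, *fmap.df)
    mask = _prune_short_runs(fmap.f > f_crit, min_run)
    idx, labels, n_comp = _clusters_from_mask(fmap.f, mask, grid_adj)
    dt = 1000.0 / fmap.sample_rate
    clusters: list[Cluster] = []
    for k in range(n_comp):
        nodes = idx[labels == k]
        sens = np.unique(nodes // nt)
        times = nodes % nt
        t0, t1 = int(times.min()), int(times.max()) + 1
        cmask = np.zeros((ns, nt), dtype=bool)
        cmask.ravel()[nodes] = True
        clusters.append(
            Cluster(
                sensor_ids=[fmap.sensor_ids[s] for s in sens],
                window_ms=(float(fmap.time_ms[t0]), float(fmap.time_ms[t1 - 1] + dt)),
                sample_span=(t0, t1),
                mass=float(fmap.f.ravel()[nodes].sum()),
                n_points=int(nodes.size),
                mask=cmask,
            )
        )
    clusters.sort(key=lambda c: (-c.mass, c.sample_span[0], min(c.sensor_ids)))
    return clusters


# -- permutation null ----------------------------------------------------


@dataclass
class PermNull:
    """Max-cluster-mass permutation null sample."""

    max_mass: np.ndarray
    critical_mass: float
    n_perm: int
    seed: int | None
    scheme: str


def _max_masses(
    f_all: np.ndarray,
    ns: int,
    nt: int,
    f_crit: float,
    min_run: int,
    grid_adj: sparse.csr_matrix,
) -> np.ndarray:
    out = np.zeros(f_all.shape[0])
    for k in range(f_all.shape[0]):
        fk = f_all[k].reshape(ns, nt)
        mask = _prune_short_runs(fk > f_crit, min_run)
        if not mask.any():
            continue
        idx, labels, n_comp = _clusters_from_mask(fk, mask, grid_adj)
        masses = np.bincount(labels, weights=fk.ravel()[idx], minlength=n_comp)
        out[k] = masses.max()
    return out


def _all_sign_patterns(n: int) -> np.ndarray:
    bits = np.arange(2**n)[:, None] >> np.arange(n)[None, :]
    return np.where(bits & 1, 1.0, -1.0)


def perm_null(
    epochs: EpochSet,
    effect: EffectSpec,
    adjacency: sparse.spmatrix | SensorLayout,
    n_perm: int = 1000,
    seed: int = 0,
    forming_alpha: float = 0.05,
    min_run: int = 5,
    exhaustive: bool = False,
    _batch: int = 256,
) -> PermNull:
    """Monte-Carlo max-cluster-mass null distribution.

    Within-subject effects are permuted by independent per-subject sign
    flips of the effect contrast (exact exchangeability for 2-level
    factors); between-subject factors by random group-label reassignment
    preserving group sizes.  ``exhaustive=True`` enumerates all ``2^n``
    sign patterns instead (within designs only).
    """
    if not exhaustive and n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    contrast, z = subject_contrasts(epochs, effect)
    n = contrast.shape[0]
    ns, nt = contrast.shape[1:]
    c_flat = contrast.reshape(n, -1)
    sensor_adj = (
        adjacency.adjacency_matrix() if isinstance(adjacency, SensorLayout) else adjacency
    )
    grid_adj = spatiotemporal_adjacency(sensor_adj, nt)
    rng = component_rng(seed, "permutation")

    if z is None:
        df = (1, n - 1)
        scheme = "per-subject sign flips of the within-subject effect contrast"
        if exhaustive:
            patterns = _all_sign_patterns(n)
        else:
            patterns = rng.choice([-1.0, 1.0], size=(n_perm, n))
        stat = _one_sample_f
    else:
        if exhaustive:
            raise NotImplementedError("exhaustive enumeration is for within designs")
        df = (1, n - 2)
        scheme = "group-label reassignment preserving group sizes"
        patterns = np.stack([rng.permutation(z) for _ in range(n_perm)])
        stat = _pooled_f

    f_crit = f_dist.isf(forming_alpha, *df)
    n_total = patterns.shape[0]
    null = np.empty(n_total)
    for start in range(0, n_total, _batch):
        chunk = patterns[start : start + _batch]
        f_all = stat(chunk, c_flat)
        null[start : start + _batch] = _max_masses(
            f_all, ns, nt, f_crit, min_run, grid_adj
        )
    return PermNull(
        max_mass=null,
        critical_mass=float(np.percentile(null, 95)),
        n_perm=n_total,
        seed=seed,
        scheme=scheme,
    )


@dataclass
class PermTestResult:
    """Empirical clusters plus their Monte-Carlo reference distribution."""

    effect: str
    clusters: list[Cluster]
    critical_mass: float
    null_max_mass: np.ndarray
    n_perm: int
    seed: int
    forming_alpha: float
    min_run: int
    scheme: str

    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.significant]

    def to_dict(self) -> dict:
        return {
            "effect": self.effect,
            "critical_mass": self.critical_mass,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "forming_alpha": self.forming_alpha,
            "min_run_samples": self.min_run,
            "permutation_scheme": self.scheme,
            "clusters": [
                {
                    "sensors": [int(s) for s in c.sensor_ids],
                    "window_ms": list(c.window_ms),
                    "mass": c.mass,
                    "n_points": c.n_points,
                    "p": c.p,
                    "significant": bool(c.significant),
                }
                for c in self.clusters
            ],
        }


def cluster_test(
    epochs: EpochSet,
    effect: EffectSpec,
    adjacency: sparse.spmatrix | SensorLayout,
    n_perm: int = 1000,
    seed: int = 0,
    forming_alpha: float = 0.05,
    min_run: int = 5,
) -> PermTestResult:
    """Full two-step cluster-based permutation test of an effect.

    Deterministic given (data, seed).  Cluster p-values use the +1
    correction, so the smallest attainable p is ``1 / (1 + n_perm)``.
    """
    fmap = pointwise_f(epochs, effect)
    clusters = form_clusters(fmap, adjacency, forming_alpha, min_run)
    null = perm_null(
        epochs, effect, adjacency, n_perm=n_perm, seed=seed,
        forming_alpha=forming_alpha, min_run=min_run,
    )
    for c in clusters:
        c.p = float((1 + np.sum(null.max_mass >= c.mass)) / (1 + null.n_perm))
        c.significant = bool(c.mass > null.critical_mass)
    return PermTestResult(
        effect=effect.name,
        clusters=clusters,
        critical_mass=null.critical_mass,
        null_max_mass=null.max_mass,
        n_perm=null.n_perm,
        seed=seed,
        forming_alpha=forming_alpha,
        min_run=min_run,
        scheme=null.scheme,
    )


def cluster_mean_amplitude(epochs: EpochSet, cluster: Cluster):
    """Per-subject, per-condition mean amplitude over a cluster's sensor
    set and time window (the rectangular region used for follow-up
    ANOVAs and t-tests)."""
    import pandas as pd

    known = set(epochs.sensor_ids)
    sens = [s for s in cluster.sensor_ids if s in known]
    if not sens:
        raise ValueError("cluster sensors do not intersect the epochs")
    pos = {s: k for k, s in enumerate(epochs.sensor_ids)}
    sidx = [pos[s] for s in sens]
    tmask = epochs.time_mask(cluster.window_ms)
    if not tmask.any():
        raise ValueError("cluster window does not intersect the epoch window")
    means = epochs.values[:, :, sidx][..., tmask].mean(axis=(2, 3))
    records = []
    for i, subj in enumerate(epochs.subjects):
        for j, cond in enumerate(epochs.conditions):
            records.append(
                {"subject": subj, "condition": cond, "mean_uv": float(means[i, j])}
            )
    return pd.DataFrame(records)
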