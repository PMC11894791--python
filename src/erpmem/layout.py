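"""Sensor layouts: positions on the scalp, neighbor graphs, ROI masks.

High-density EEG analyses need to know which sensors are spatial neighbors
(for cluster formation) and which belong to broad regions of interest such
as *posterior* or *anterior* sites.  A :class:`SensorLayout` bundles sensor
IDs, unit-sphere 3D positions, an explicit symmetric adjacency edge set,
and named ROI masks, and round-trips through a small JSON format so that a
real montage can be substituted for the packaged synthetic one.

The packaged default is a 129-sensor quasi-uniform arrangement on the upper
hemisphere (a Fibonacci spiral), a stand-in geometry with the same sensor
count and neighbor density as common high-density nets.  It is synthetic:
it does not reproduce any manufacturer's montage.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SensorLayout",
    "neighbors_from_distance",
    "hemisphere_layout",
    "DisconnectedGraphWarning",
]


class DisconnectedGraphWarning(UserWarning):
    """Raised (as a warning) when a neighbor threshold leaves the sensor
    graph disconnected."""


@dataclass
class SensorLayout:
    """Sensor IDs, positions, adjacency and ROI masks.

    Parameters
    ----------
    ids
        Sensor identifiers (integers, as printed in cluster reports).
    positions
        ``(n, 3)`` unit-norm 3D coordinates. Convention: +y is anterior
        (toward the nose), -y posterior, +z superior.
    edges
        Set of ``(i, j)`` **index** pairs with ``i < j``; symmetric and
        irreflexive by construction.
    rois
        Mapping from ROI name to a list of sensor IDs.
    """

    ids: list[int]
    positions: np.ndarray
    edges: set[tuple[int, int]]
    rois: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.ids), 3):
            raise ValueError("positions must be (n_sensors, 3)")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sensor ids must be unique")
        n = len(self.ids)
        for i, j in self.edges:
            if i == j:
                raise ValueError("adjacency must be irreflexive")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError("edge index out of range")
        self.edges = {(min(i, j), max(i, j)) for i, j in self.edges}
        id_set = set(self.ids)
        for name, members in self.rois.items():
            if not set(members) <= id_set:
                raise ValueError(f"ROI {name!r} contains unknown sensor ids")

    # -- basic accessors -------------------------------------------------

    @property
    def n_sensors(self) -> int:
        return len(self.ids)

    def index(self, sensor_id: int) -> int:
        return self.ids.index(sensor_id)

    def indices(self, sensor_ids) -> np.ndarray:
        pos = {s: k for k, s in enumerate(self.ids)}
        return np.asarray([pos[s] for s in sensor_ids], dtype=int)

    def adjacency_matrix(self) -> csr_matrix:
        """Boolean symmetric sparse adjacency in sensor-index order."""
        n = self.n_sensors
        if self.edges:
            rows, cols = zip(*self.edges)
            rows, cols = np.asarray(rows), np.asarray(cols)
            r = np.concatenate([rows, cols])
            c = np.concatenate([cols, rows])
        else:
            r = c = np.empty(0, dtype=int)
        data = np.ones(len(r), dtype=bool)
        return csr_matrix((data, (r, c)), shape=(n, n))

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_sensors, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def is_connected(self) -> bool:
        if self.n_sensors == 1:
            return True
        n_comp, _ = connected_components(self.adjacency_matrix(), directed=False)
        return n_comp == 1

    def roi_indices(self, roi) -> np.ndarray:
        """Indices for an ROI name, a list of names (union), or an explicit
        id list.  Selection never touches data values, only the index set."""
        if isinstance(roi, str):
            members = self.rois[roi]
        elif roi and all(isinstance(r, str) for r in roi):
            seen: list[int] = []
            for name in roi:
                for s in self.rois[name]:
                    if s not in seen:
                        seen.append(s)
            members = seen
        else:
            members = list(roi)
        return self.indices(members)

    def subset(self, sensor_ids) -> "SensorLayout":
        """Restrict the layout to a subset of sensors (ROI masking)."""
        idx = self.indices(sensor_ids)
        keep = {int(i) for i in idx}
        remap = {old: new for new, old in enumerate(idx)}
        edges = {
            (min(remap[i], remap[j]), max(remap[i], remap[j]))
            for i, j in self.edges
            if i in keep and j in keep
        }
        ids = [self.ids[i] for i in idx]
        rois = {
            name: [s for s in members if s in set(ids)]
            for name, members in self.rois.items()
        }
        rois = {name: members for name, members in rois.items() if members}
        return SensorLayout(ids=ids, positions=self.positions[idx], edges=edges, rois=rois)

    def neighbors_of(self, sensor_id: int, radius: int = 1) -> list[int]:
        """Sensor IDs within ``radius`` graph hops of ``sensor_id``
        (including itself)."""
        start = self.index(sensor_id)
        frontier = {start}
        seen = {start}
        for _ in range(radius):
            nxt = set()
            for i, j in self.edges:
                if i in frontier:
                    nxt.add(j)
                if j in frontier:
                    nxt.add(i)
            frontier = nxt - seen
            seen |= nxt
        return [self.ids[k] for k in sorted(seen)]

    # -- JSON I/O --------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "ids": [int(s) for s in self.ids],
            "positions": self.positions.tolist(),
            "edges": sorted([int(i), int(j)] for i, j in self.edges),
            "rois": {k: [int(s) for s in v] for k, v in self.rois.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SensorLayout":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            ids=[int(s) for s in payload["ids"]],
            positions=np.asarray(payload["positions"], dtype=float),
            edges={(int(i), int(j)) for i, j in payload["edges"]},
            rois={k: [int(s) for s in v] for k, v in payload.get("rois", {}).items()},
        )


def neighbors_from_distance(
    positions: np.ndarray, threshold: float
) -> set[tuple[int, int]]:
    """Edge set ``{(i, j): dist(i, j) <= threshold, i < j}`` from Euclidean
    inter-sensor distance.

    Emits a :class:`DisconnectedGraphWarning` if the resulting graph does
    not connect all sensors.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    dist = squareform(pdist(positions))
    ii, jj = np.where(np.triu(dist <= threshold, k=1))
    edges = {(int(i), int(j)) for i, j in zip(ii, jj)}
    if n > 1:
        probe = SensorLayout(ids=list(range(n)), positions=positions, edges=set(edges))
        if not probe.is_connected():
            warnings.warn(
                f"threshold {threshold} leaves the sensor graph disconnected",
                DisconnectedGraphWarning,
                stacklevel=2,
            )
    return edges


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Quasi-uniform points on the upper unit hemisphere."""
    k = np.arange(n)
    # z from just above the equator rim to near the pole
    z = (k + 0.5) / n
    r = np.sqrt(1.0 - z**2)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * k
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _auto_threshold(positions: np.ndarray, target_median_degree: int = 6) -> float:
    """Smallest pairwise-distance quantile whose graph has median degree at
    least the target and is connected."""
    dist = squareform(pdist(positions))
    cand = np.unique(dist[np.triu_indices_from(dist, k=1)])
    n = positions.shape[0]
    # binary search over sorted candidate distances
    lo, hi = 0, len(cand) - 1
    best = cand[-1]
    while lo <= hi:
        mid = (lo + hi) // 2
        thr = cand[mid]
        adj = dist <= thr
        np.fill_diagonal(adj, False)
        deg = adj.sum(axis=1)
        n_comp, _ = connected_components(csr_matrix(adj), directed=False)
        if np.median(deg) >= target_median_degree and n_comp == 1:
            best = thr
            hi = mid - 1
        else:
            lo = mid + 1
    return float(best)


def hemisphere_layout(
    n_sensors: int = 129,
    target_median_degree: int = 6,
    roi_fraction: float = 0.35,
) -> SensorLayout:
    """Packaged synthetic layout: ``n_sensors`` quasi-uniform points on the
    upper hemisphere with distance-threshold adjacency tuned so the median
    neighbor count is about ``target_median_degree``.

    ROI masks: ``posterior`` (most negative y, i.e. back of the head) and
    ``anterior`` (most positive y), each holding ``roi_fraction`` of the
    sensors.  Sensor IDs run 1..n.
    """
    positions = _fibonacci_hemisphere(n_sensors)
    thr = _auto_threshold(positions, target_median_degree)
    edges = neighbors_from_distance(positions, thr)
    ids = list(range(1, n_sensors + 1))
    n_roi = max(1, int(round(roi_fraction * n_sensors)))
    order = np.argsort(positions[:, 1])  # ascending y: back ... front
    posterior = sorted(int(ids[i]) for i in order[:n_roi])
    anterior = sorted(int(ids[i]) for i in order[-n_roi:])
    return SensorLayout(
        ids=ids,
        positions=positions,
        edges=edges,
        rois={"posterior": posterior, "anterior": anterior},
    )
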