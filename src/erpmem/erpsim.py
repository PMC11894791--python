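"""Synthetic ERP condition averages with known ground-truth effects.

The simulator works at the level of per-subject, per-condition average
ERPs (the quantities the cluster statistics consume): each average is the
sum of

* injected :class:`EffectPatch` amplitudes — rectangular sensor x time
  regions carrying a per-condition mean amplitude plus a subject-level
  amplitude deviation shared across conditions (so condition contrasts
  remain exactly the configured differences),
* a per-subject constant offset (subject random effect), and
* structured noise: Gaussian innovations given AR(1) temporal correlation
  and then mixed across sensors by a normalized graph-diffusion operator,
  so nearby sensors are correlated and spatial clustering is non-trivial.

Both the AR filter and the diffusion operator are variance-normalized, so
the marginal per-sample noise SD equals the configured ``noise_sd``
exactly, whatever the smoothing length or autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from ._rng import component_rng
from .epochs import EpochSet
from .layout import SensorLayout

__all__ = ["EffectPatch", "ErpGenConfig", "gen_epochs", "gen_condition_averages"]


@dataclass
class EffectPatch:
    """A rectangular sensor x time ground-truth effect.

    The spatial extent is either an explicit sensor-ID list or a graph
    ball (``center`` + ``radius`` hops on the layout adjacency).
    ``amplitudes`` maps condition label -> mean amplitude in microvolts;
    unlisted conditions get 0.  For between-subject designs a key may be
    prefixed ``"group@condition"``, which overrides the plain condition
    key for subjects of that group.  ``subject_sd`` is the SD of a
    subject-level amplitude deviation added identically to every
    condition.
    """

    window_ms: tuple[float, float]
    amplitudes: dict[str, float]
    sensors: list[int] | None = None
    center: int | None = None
    radius: int = 1
    subject_sd: float = 0.0

    def resolve_sensors(self, layout: SensorLayout) -> list[int]:
        if self.sensors is not None:
            ids = list(self.sensors)
        elif self.center is not None:
            ids = layout.neighbors_of(self.center, radius=self.radius)
        else:
            raise ValueError("patch needs either explicit sensors or a center")
        if not ids:
            raise ValueError("patch sensor set is empty")
        unknown = set(ids) - set(layout.ids)
        if unknown:
            raise ValueError(f"patch sensors not in layout: {sorted(unknown)}")
        return ids


@dataclass
class ErpGenConfig:
    """Noise and effect structure of the simulated epochs."""

    n_sensors: int = 129
    sample_rate: float = 250.0
    window_ms: tuple[float, float] = (-200.0, 1200.0)
    baseline_ms: tuple[float, float] = (-200.0, 0.0)
    noise_sd: float = 1.0  # microvolts, per sample, at the average level
    smoothing_steps: int = 2  # graph-diffusion passes
    ar_coef: float = 0.5  # temporal AR(1) coefficient
    subject_sd: float = 0.0  # constant per-subject offset SD
    effects: list[EffectPatch] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.subject_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if not (0.0 <= self.ar_coef < 1.0):
            raise ValueError("AR coefficient must be in [0, 1)")
        if self.smoothing_steps < 0:
            raise ValueError("smoothing steps must be non-negative")
        w0, w1 = self.window_ms
        b0, b1 = self.baseline_ms
        if not (w0 <= b0 < b1 <= w1):
            raise ValueError("epoch window must contain the baseline window")

    def time_axis(self) -> np.ndarray:
        dt = 1000.0 / self.sample_rate
        n = int(round((self.window_ms[1] - self.window_ms[0]) / dt))
        return self.window_ms[0] + dt * np.arange(n)


def _diffusion_operator(layout: SensorLayout, steps: int) -> np.ndarray:
    """Row-normalized k-step lazy diffusion on the sensor graph.

    Rows are rescaled to unit L2 norm so iid unit-variance input keeps
    unit marginal variance per sensor after mixing.
    """
    n = layout.n_sensors
    if steps == 0:
        return np.eye(n)
    A = layout.adjacency_matrix().toarray().astype(float)
    deg = A.sum(axis=1)
    deg[deg == 0] = 1.0
    W = 0.5 * (np.eye(n) + A / deg[:, None])  # lazy random-walk step
    S = np.linalg.matrix_power(W, steps)
    norms = np.sqrt((S**2).sum(axis=1))
    return S / norms[:, None]


def _ar1_noise(rng, shape, rho: float) -> np.ndarray:
    """Stationary unit-variance AR(1) noise along the last axis."""
    w = rng.standard_normal(shape)
    if rho == 0.0:
        return w
    e = w * np.sqrt(1.0 - rho**2)
    e[..., 0] = w[..., 0]  # x_0 drawn from the stationary distribution
    return lfilter([1.0], [1.0, -rho], e, axis=-1)


def gen_condition_averages(
    cfg: ErpGenConfig,
    subjects: list,
    conditions: list[str],
    layout: SensorLayout,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    subject_groups: dict | None = None,
) -> tuple[EpochSet, list[dict]]:
    """Simulate per-subject condition-average epochs.

    Returns the :class:`EpochSet` and the resolved ground truth: one dict
    per patch with the sensor-ID list, time window and per-condition
    amplitudes actually injected.
    """
    if layout.n_sensors != cfg.n_sensors:
        raise ValueError(
            f"layout has {layout.n_sensors} sensors, config expects {cfg.n_sensors}"
        )
    if rng is None:
        rng = component_rng(seed, "epochs_encoding")
    time_ms = cfg.time_axis()
    n_s, n_c = len(subjects), len(conditions)
    n_sen, n_t = layout.n_sensors, len(time_ms)

    S = _diffusion_operator(layout, cfg.smoothing_steps)
    values = np.zeros((n_s, n_c, n_sen, n_t))
    if cfg.noise_sd > 0:
        noise = _ar1_noise(rng, (n_s, n_c, n_sen, n_t), cfg.ar_coef)
        values += cfg.noise_sd * np.einsum("ij,scjt->scit", S, noise)
    if cfg.subject_sd > 0:
        values += rng.normal(0.0, cfg.subject_sd, size=n_s)[:, None, None, None]

    truth: list[dict] = []
    for patch in cfg.effects:
        ids = patch.resolve_sensors(layout)
        idx = layout.indices(ids)
        w0, w1 = patch.window_ms
        e0, e1 = time_ms[0], time_ms[-1] + 1000.0 / cfg.sample_rate
        if not (e0 <= w0 < w1 <= e1):
            raise ValueError(f"patch window {patch.window_ms} outside epoch {(e0, e1)}")
        tmask = (time_ms >= w0) & (time_ms < w1)
        base_amp = np.array([patch.amplitudes.get(c, 0.0) for c in conditions])
        amp = np.tile(base_amp, (n_s, 1))  # (subject, condition)
        if subject_groups is not None:
            for si, subj in enumerate(subjects):
                grp = subject_groups.get(subj)
                if grp is None:
                    continue
                for ci, c in enumerate(conditions):
                    key = f"{grp}@{c}"
                    if key in patch.amplitudes:
                        amp[si, ci] = patch.amplitudes[key]
        b = (
            rng.normal(0.0, patch.subject_sd, size=n_s)
            if patch.subject_sd > 0
            else np.zeros(n_s)
        )
        bump = amp + b[:, None]  # (subject, condition)
        region = np.ix_(range(n_s), range(n_c), idx, np.where(tmask)[0])
        values[region] += bump[:, :, None, None]
        truth.append(
            {
                "sensors": ids,
                "window_ms": (float(w0), float(w1)),
                "amplitudes": {c: float(a) for c, a in patch.amplitudes.items()},
                "subject_sd": float(patch.subject_sd),
            }
        )

    epochs = EpochSet(
        values=values,
        time_ms=time_ms,
        sensor_ids=list(layout.ids),
        conditions=list(conditions),
        subjects=list(subjects),
        sample_rate=cfg.sample_rate,
        baseline_ms=cfg.baseline_ms,
    )
    return epochs, truth


def _within_varying(sub: pd.DataFrame, candidates: list[str]) -> list[str]:
    """Columns that vary within at least one subject (true within-subject
    factors).  A between-subject factor (constant per subject, e.g. the
    stimulation group) does not define a condition label — it lives in the
    design's group column instead."""
    cols = []
    for col in candidates:
        if sub[col].isna().all():
            continue
        per_subject = sub.groupby("subject")[col].nunique(dropna=True)
        if (per_subject > 1).any():
            cols.append(col)
    return cols


def _condition_labels(design: pd.DataFrame, task: str) -> list[str]:
    """Within-subject condition labels implied by a design table.

    Encoding: the within-varying cells among category / stimulation /
    phase joined with ``/`` (study 1: ``category/stimulation``; study 2:
    ``category/phase``).  Retrieval: ``old:`` cells over category (and
    stimulation where within-subject; the on/off phase is collapsed at
    retrieval) plus ``new:category`` baselines.
    """
    sub = design.loc[design["task"] == task]
    labels: list[str] = []
    if task == "encoding":
        cols = _within_varying(sub, ["category", "stimulation", "phase"])
        for key, _ in sub.groupby(cols, dropna=False):
            key = key if isinstance(key, tuple) else (key,)
            labels.append("/".join(str(k) for k in key))
    else:
        old = sub.loc[sub["role"] == "old"]
        cols = _within_varying(old, ["category", "stimulation"])
        for key, _ in old.groupby(cols, dropna=False):
            key = key if isinstance(key, tuple) else (key,)
            labels.append("old:" + "/".join(str(k) for k in key))
        for cat in sorted(sub.loc[sub["role"] == "new", "category"].unique()):
            labels.append(f"new:{cat}")
    return sorted(labels)


def gen_epochs(
    cfg: ErpGenConfig,
    design: pd.DataFrame,
    layout: SensorLayout,
    seed: int = 0,
    task: str = "encoding",
) -> tuple[EpochSet, list[dict]]:
    """Simulate condition-average epochs for a design table's task phase.

    Conditions are derived from the design's cells; subjects from its
    subject column.  See :func:`gen_condition_averages` for the model.
    """
    if task not in ("encoding", "retrieval"):
        raise ValueError(f"unknown task {task!r}")
    subjects = sorted(design["subject"].unique())
    conditions = _condition_labels(design, task)
    groups = (
        design.drop_duplicates("subject").set_index("subject")["group"].to_dict()
    )
    component = "epochs_encoding" if task == "encoding" else "epochs_retrieval"
    rng = component_rng(seed, component)
    return gen_condition_averages(
        cfg, subjects, conditions, layout, rng=rng, subject_groups=groups
    )
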