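"""ERP epoch containers, baseline correction and condition averaging.

An :class:`EpochSet` holds per-subject, per-condition averaged ERPs as a
``(subject, condition, sensor, time)`` array in microvolts, with an
explicit uniform time axis in milliseconds relative to stimulus onset.

Time intervals are half-open ``[start, end)`` throughout: at 250 Hz sample
``i`` covers ``[t_i, t_i + 4 ms)``, which makes cluster-duration arithmetic
(e.g. "5 samples = 20 ms") unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "EpochSet",
    "baseline_correct",
    "average_by_condition",
    "save_epochs",
    "load_epochs",
]


@dataclass
class EpochSet:
    """Per-subject, per-condition sensor x time ERP averages (microvolts)."""

    values: np.ndarray  # (n_subjects, n_conditions, n_sensors, n_times)
    time_ms: np.ndarray
    sensor_ids: list[int]
    conditions: list[str]
    subjects: list
    sample_rate: float
    baseline_ms: tuple[float, float] = (-200.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        expected = (
            len(self.subjects),
            len(self.conditions),
            len(self.sensor_ids),
            len(self.time_ms),
        )
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} does not match labels {expected}"
            )
        if len(self.time_ms) >= 2:
            steps = np.diff(self.time_ms)
            if np.any(steps <= 0):
                raise ValueError("time axis must be strictly increasing")
            if not np.allclose(steps, steps[0]):
                raise ValueError("time axis must be uniform")
            if not np.isclose(steps[0], 1000.0 / self.sample_rate):
                raise ValueError("time step inconsistent with sample_rate")
        b0, b1 = self.baseline_ms
        if not (self.epoch_window_ms[0] <= b0 < b1 <= self.epoch_window_ms[1]):
            raise ValueError("baseline window must lie inside the epoch window")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sample_rate

    @property
    def epoch_window_ms(self) -> tuple[float, float]:
        # half-open: the last sample covers [t_last, t_last + dt)
        return (float(self.time_ms[0]), float(self.time_ms[-1]) + self.dt_ms)

    def time_mask(self, window_ms: tuple[float, float]) -> np.ndarray:
        """Boolean mask of samples whose [t, t+dt) bin starts in
        the half-open ``[start, end)`` window."""
        start, end = window_ms
        return (self.time_ms >= start) & (self.time_ms < end)

    def condition_index(self, condition: str) -> int:
        return self.conditions.index(condition)

    def select_conditions(self, conditions: list[str]) -> "EpochSet":
        idx = [self.condition_index(c) for c in conditions]
        return replace(self, values=self.values[:, idx], conditions=list(conditions))

    def select_sensors(self, sensor_ids) -> "EpochSet":
        pos = {s: k for k, s in enumerate(self.sensor_ids)}
        idx = [pos[s] for s in sensor_ids]
        return replace(
            self, values=self.values[:, :, idx], sensor_ids=list(sensor_ids)
        )

    def select_time(self, window_ms: tuple[float, float]) -> "EpochSet":
        mask = self.time_mask(window_ms)
        if not mask.any():
            raise ValueError(f"window {window_ms} contains no samples")
        new_time = self.time_ms[mask]
        # keep the baseline attribute valid even when it is cropped away
        t0, t1 = float(new_time[0]), float(new_time[-1]) + self.dt_ms
        b0 = min(max(self.baseline_ms[0], t0), t1 - self.dt_ms)
        b1 = min(max(self.baseline_ms[1], b0 + self.dt_ms), t1)
        return replace(
            self,
            values=self.values[..., mask],
            time_ms=new_time,
            baseline_ms=(float(b0), float(b1)),
        )


def collapse_conditions(epochs: EpochSet, mapping: dict[str, list[str]]) -> EpochSet:
    """Average groups of conditions into new labels (equal weights).

    Used e.g. to collapse the on/off stimulation phase out of a design
    before testing effects that do not involve it.
    """
    labels = sorted(mapping)
    parts = []
    for label in labels:
        idx = [epochs.condition_index(c) for c in mapping[label]]
        parts.append(epochs.values[:, idx].mean(axis=1))
    return replace(
        epochs, values=np.stack(parts, axis=1), conditions=labels
    )


def baseline_correct(epochs: EpochSet, window_ms: tuple[float, float] | None = None) -> EpochSet:
    """Subtract each trace's mean over the baseline window.

    Idempotent: correcting twice equals correcting once.
    """
    window_ms = tuple(window_ms) if window_ms is not None else epochs.baseline_ms
    w0, w1 = window_ms
    e0, e1 = epochs.epoch_window_ms
    if not (e0 <= w0 < w1 <= e1):
        raise ValueError(f"baseline window {window_ms} outside epoch window {(e0, e1)}")
    mask = epochs.time_mask(window_ms)
    if not mask.any():
        raise ValueError(f"baseline window {window_ms} contains no samples")
    mean = epochs.values[..., mask].mean(axis=-1, keepdims=True)
    return replace(epochs, values=epochs.values - mean, baseline_ms=(float(w0), float(w1)))


def average_by_condition(
    trial_values: np.ndarray,
    trial_subjects,
    trial_conditions,
    time_ms: np.ndarray,
    sensor_ids,
    sample_rate: float,
    baseline_ms: tuple[float, float] = (-200.0, 0.0),
) -> tuple[EpochSet, pd.DataFrame]:
    """Average trial-level epochs into per-subject condition means.

    Parameters
    ----------
    trial_values
        ``(n_trials, n_sensors, n_times)`` trial epochs.
    trial_subjects, trial_conditions
        Per-trial subject and condition labels.

    Returns
    -------
    (EpochSet, counts)
        Condition averages plus a tidy table of trial counts per
        subject x condition cell.

    Raises
    ------
    ValueError
        If any subject x condition cell is empty (the error names the
        subject and the cell).
    """
    trial_values = np.asarray(trial_values, dtype=float)
    trial_subjects = list(trial_subjects)
    trial_conditions = list(trial_conditions)
    if not (len(trial_subjects) == len(trial_conditions) == trial_values.shape[0]):
        raise ValueError("trial labels must match the number of trials")

    subjects = sorted(set(trial_subjects), key=str)
    conditions = sorted(set(trial_conditions))
    sub_pos = {s: i for i, s in enumerate(subjects)}
    cond_pos = {c: i for i, c in enumerate(conditions)}

    shape = (len(subjects), len(conditions)) + trial_values.shape[1:]
    sums = np.zeros(shape)
    counts = np.zeros((len(subjects), len(conditions)), dtype=int)
    for row, (s, c) in enumerate(zip(trial_subjects, trial_conditions)):
        sums[sub_pos[s], cond_pos[c]] += trial_values[row]
        counts[sub_pos[s], cond_pos[c]] += 1
    empty = np.argwhere(counts == 0)
    if empty.size:
        i, j = empty[0]
        raise ValueError(
            f"no trials for subject {subjects[i]!r} in condition {conditions[j]!r}"
        )
    means = sums / counts[:, :, None, None]
    epochs = EpochSet(
        values=means,
        time_ms=time_ms,
        sensor_ids=list(sensor_ids),
        conditions=conditions,
        subjects=subjects,
        sample_rate=sample_rate,
        baseline_ms=baseline_ms,
    )
    count_table = pd.DataFrame(
        [
            {"subject": s, "condition": c, "n_trials": int(counts[sub_pos[s], cond_pos[c]])}
            for s in subjects
            for c in conditions
        ]
    )
    return epochs, count_table


# -- HDF5 container ------------------------------------------------------
#
# Layout: /erp (subject x condition x sensor x time, float64, microvolts),
# /time_ms, /sensors, /conditions, /subjects; attributes sample_rate_hz,
# baseline_ms; optional ground truth under /truth/... (free-form datasets
# and attributes written by the simulator).


def save_epochs(path, epochs: EpochSet, truth: dict | None = None) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("erp", data=epochs.values)
        fh.create_dataset("time_ms", data=epochs.time_ms)
        fh.create_dataset("sensors", data=np.asarray(epochs.sensor_ids, dtype=int))
        str_dt = h5py.string_dtype("utf-8")
        fh.create_dataset(
            "conditions", data=np.asarray(epochs.conditions, dtype=object), dtype=str_dt
        )
        fh.create_dataset(
            "subjects",
            data=np.asarray([str(s) for s in epochs.subjects], dtype=object),
            dtype=str_dt,
        )
        fh.attrs["sample_rate_hz"] = float(epochs.sample_rate)
        fh.attrs["baseline_ms"] = np.asarray(epochs.baseline_ms, dtype=float)
        if truth:
            grp = fh.create_group("truth")
            for key, val in truth.items():
                if isinstance(val, str):
                    grp.attrs[key] = val
                else:
                    grp.create_dataset(key, data=np.asarray(val))


def load_epochs(path) -> tuple[EpochSet, dict]:
    with h5py.File(path, "r") as fh:
        epochs = EpochSet(
            values=fh["erp"][()],
            time_ms=fh["time_ms"][()],
            sensor_ids=[int(s) for s in fh["sensors"][()]],
            conditions=[c.decode() if isinstance(c, bytes) else str(c) for c in fh["conditions"][()]],
            subjects=[s.decode() if isinstance(s, bytes) else str(s) for s in fh["subjects"][()]],
            sample_rate=float(fh.attrs["sample_rate_hz"]),
            baseline_ms=tuple(float(b) for b in fh.attrs["baseline_ms"]),
        )
        truth: dict = {}
        if "truth" in fh:
            grp = fh["truth"]
            truth.update({k: grp.attrs[k] for k in grp.attrs})
            truth.update({k: grp[k][()] for k in grp})
    return epochs, truth
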