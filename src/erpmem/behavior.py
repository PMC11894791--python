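"""Trial-level recognition behavior from a dual-process generative model.

Recognition of a studied ("old") item is modeled as a mixture of two
processes: with probability ``R`` the item is *recollected* and answered
"old" at the top confidence anchor; otherwise a *familiarity* strength is
drawn from a unit-variance Gaussian centered at ``d_fam`` (standard-normal
units; new items are centered at 0) and binned through a set of strictly
increasing response criteria into a (response, confidence) pair.  This is
the classic dual-process account in which familiarity supports graded
confidence while recollection loads on the highest anchor.

Two response dialects are supported:

``eleven_point``
    Two-question format: an old/new judgment followed by a 0-10 confidence
    rating (the 0-100 scale collapsed to integer anchors).  The strength
    axis is cut by 21 criteria into 22 bins; the lower 11 map to response
    "new" with confidence 10..0 and the upper 11 to response "old" with
    confidence 0..10, so the old/new boundary is the middle criterion
    (index 10).

``six_point``
    Single 6-point scale: anchors 1-3 mean "new", 4-6 mean "old"
    (5 criteria; the old/new boundary is criterion index 2).

Closed forms used by tests: with recollection probability R, familiarity
mean d and old/new boundary criterion c,

    hit rate = R + (1 - R) * (1 - Phi(c - d)),   false-alarm rate = 1 - Phi(c)

(plus any configured false-recollection mass for new items).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._rng import component_rng

__all__ = [
    "BehaviorGenConfig",
    "gen_recognition",
    "default_criteria",
    "expected_rates",
    "TOP_ANCHOR",
]

#: top confidence anchor per dialect (the recollection anchor)
TOP_ANCHOR = {"eleven_point": 10, "six_point": 6}

#: number of criteria each dialect requires
N_CRITERIA = {"eleven_point": 21, "six_point": 5}

#: index of the criterion acting as the old/new decision boundary
BOUNDARY_INDEX = {"eleven_point": 10, "six_point": 2}


def default_criteria(dialect: str) -> np.ndarray:
    """Evenly spread criteria with the old/new boundary at +0.25.

    A slightly conservative boundary (above 0) reproduces the usual
    finding that false-alarm rates sit below 50%.
    """
    k = N_CRITERIA[dialect]
    b = BOUNDARY_INDEX[dialect]
    lo = np.linspace(-2.5, 0.25, b + 1)  # criteria 0..b
    hi = np.linspace(0.25, 3.0, k - b)[1:]  # criteria b+1..k-1
    return np.concatenate([lo, hi])


@dataclass
class BehaviorGenConfig:
    """Generative parameters for the recognition task.

    ``recollection`` and ``familiarity`` map cell keys to per-cell R and
    d_fam.  Cell keys are ``"category|stimulation|phase"`` strings where
    any component may be ``"*"``; the most specific matching key wins.

    ``subject_sd_dfam`` and ``subject_sd_logit_r`` add subject-level
    random shifts (shared across cells) to d_fam and to logit(R), giving
    the between-subject spread that a random-intercept model absorbs.
    """

    dialect: str = "eleven_point"
    recollection: dict = field(default_factory=lambda: {"*|*|*": 0.3})
    familiarity: dict = field(default_factory=lambda: {"*|*|*": 1.0})
    criteria: np.ndarray | None = None
    false_recollection: float = 0.0
    subject_sd_dfam: float = 0.0
    subject_sd_logit_r: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dialect not in TOP_ANCHOR:
            raise ValueError(f"unknown dialect {self.dialect!r}")
        if self.criteria is None:
            self.criteria = default_criteria(self.dialect)
        self.criteria = np.asarray(self.criteria, dtype=float)
        if len(self.criteria) != N_CRITERIA[self.dialect]:
            raise ValueError(
                f"{self.dialect} requires {N_CRITERIA[self.dialect]} criteria, "
                f"got {len(self.criteria)}"
            )
        if np.any(np.diff(self.criteria) <= 0):
            raise ValueError("criteria must be strictly increasing")
        for table in (self.recollection, self.familiarity):
            for v in table.values():
                if table is self.recollection and not (0.0 <= v <= 1.0):
                    raise ValueError("recollection probabilities must be in [0, 1]")
        if not (0.0 <= self.false_recollection <= 1.0):
            raise ValueError("false-recollection probability must be in [0, 1]")

    @property
    def boundary(self) -> float:
        return float(self.criteria[BOUNDARY_INDEX[self.dialect]])

    def lookup(self, table: dict, category, stimulation, phase) -> float:
        """Most-specific wildcard lookup of a per-cell parameter."""
        cat = "*" if pd.isna(category) else str(category)
        stim = "*" if pd.isna(stimulation) else str(stimulation)
        ph = "*" if pd.isna(phase) else str(phase)
        candidates = []
        for key, value in table.items():
            kc, ks, kp = key.split("|")
            if kc in (cat, "*") and ks in (stim, "*") and kp in (ph, "*"):
                specificity = (kc != "*") + (ks != "*") + (kp != "*")
                candidates.append((specificity, key, value))
        if not candidates:
            raise KeyError(
                f"no parameter for cell ({cat}, {stim}, {ph}) in {sorted(table)}"
            )
        candidates.sort(key=lambda t: (t[0], t[1]))
        return float(candidates[-1][2])


def _bin_strengths(cfg: BehaviorGenConfig, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map familiarity strengths to (response, confidence) arrays."""
    bins = np.searchsorted(cfg.criteria, x, side="right")
    b = BOUNDARY_INDEX[cfg.dialect]
    if cfg.dialect == "six_point":
        confidence = bins + 1  # anchors 1..6
        response = np.where(confidence >= 4, "old", "new")
    else:
        response = np.where(bins > b, "old", "new")
        confidence = np.where(bins > b, bins - (b + 1), b - bins)
    return response.astype(object), confidence.astype(int)


def gen_recognition(
    cfg: BehaviorGenConfig, design: pd.DataFrame, seed: int | None = None
) -> pd.DataFrame:
    """Simulate the recognition task over a design table.

    Only retrieval rows of the design are used.  Returns a table with
    columns (subject, group, session, trial, category, stimulation, phase,
    truth, response, confidence), one row per retrieval trial.
    """
    rng = component_rng(cfg.seed if seed is None else seed, "behavior")
    ret = design.loc[design["task"] == "retrieval"].reset_index(drop=True)
    if ret.empty:
        raise ValueError("design has no retrieval trials")

    subjects = sorted(ret["subject"].unique())
    d_shift = {
        s: rng.normal(0.0, cfg.subject_sd_dfam) if cfg.subject_sd_dfam > 0 else 0.0
        for s in subjects
    }
    r_shift = {
        s: rng.normal(0.0, cfg.subject_sd_logit_r) if cfg.subject_sd_logit_r > 0 else 0.0
        for s in subjects
    }

    n = len(ret)
    response = np.empty(n, dtype=object)
    confidence = np.empty(n, dtype=int)
    top = TOP_ANCHOR[cfg.dialect]

    is_old = (ret["role"] == "old").to_numpy()
    u_rec = rng.uniform(size=n)
    x = rng.standard_normal(n)

    for i in range(n):
        row = ret.iloc[i]
        if is_old[i]:
            r = cfg.lookup(cfg.recollection, row["category"], row["stimulation"], row["phase"])
            if 0.0 < r < 1.0 and r_shift[row["subject"]] != 0.0:
                logit = np.log(r / (1.0 - r)) + r_shift[row["subject"]]
                r = 1.0 / (1.0 + np.exp(-logit))
            d = cfg.lookup(cfg.familiarity, row["category"], row["stimulation"], row["phase"])
            d = d + d_shift[row["subject"]]
        else:
            r = cfg.false_recollection
            d = 0.0
        if u_rec[i] < r:
            response[i] = "old"
            confidence[i] = top
        else:
            resp, conf = _bin_strengths(cfg, np.array([x[i] + d]))
            response[i] = resp[0]
            confidence[i] = int(conf[0])

    out = ret[
        ["subject", "group", "session", "trial", "category", "stimulation", "phase"]
    ].copy()
    out["truth"] = np.where(is_old, "old", "new")
    out["response"] = response
    out["confidence"] = confidence
    return out


def expected_rates(
    cfg: BehaviorGenConfig, r: float, d_fam: float
) -> tuple[float, float]:
    """Model-implied (hit, false-alarm) rates for a cell with recollection
    probability ``r`` and familiarity mean ``d_fam``."""
    c = cfg.boundary
    hit = r + (1.0 - r) * norm.sf(c - d_fam)
    fa = cfg.false_recollection + (1.0 - cfg.false_recollection) * norm.sf(c)
    return float(hit), float(fa)
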