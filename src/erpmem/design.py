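"""Study designs: balanced trial tables for the two emulated experiments.

Study 1 is a within-subject crossover: each subject encodes 60 scenes
(30 unpleasant, 30 neutral) on each of two consecutive days, once under
active auricular stimulation (taVNS) and once under sham, and returns a
week later for a recognition test in which the 120 encoded images are
intermixed with 120 new ones.  The image pool holds 240 unique images in
four counterbalanced sets of 60.

Study 2 is a mixed design: stimulation (taVNS vs sham) is between
subjects, and during the single 120-trial encoding session the images are
presented in alternating blocks of exactly four per stimulation half-cycle
(on / off).  Retrieval again shows 120 old + 120 new images on a 6-point
old/new-confidence scale.

Encoding orders are pseudorandom with no more than two scenes of the same
affective category in a row, enforced by constrained sequential sampling
with restart on dead ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import component_rng

__all__ = ["DesignSpec", "build_design", "max_category_run"]

CATEGORIES = ("unpleasant", "neutral")
STIMULATIONS = ("taVNS", "sham")
PHASES = ("on", "off")


@dataclass
class DesignSpec:
    """Structural parameters of a study design."""

    study: int
    n_subjects: int
    n_old_per_cell: int  # old trials per within-cell at retrieval
    n_new: int
    cells: list[tuple] = field(default_factory=list)
    confidence_dialect: str = "eleven_point"  # anchors 0-10 vs 1-6
    image_duration_ms: int = 3000
    iti_range_ms: tuple[int, int] = (4000, 5000)
    block_size: int | None = None  # study 2: images per on/off half-cycle

    def __post_init__(self) -> None:
        if self.study not in (1, 2):
            raise ValueError(f"unknown study code {self.study!r}")
        if self.n_subjects < 1 or self.n_old_per_cell < 1 or self.n_new < 1:
            raise ValueError("counts must be positive")
        if self.confidence_dialect not in ("eleven_point", "six_point"):
            raise ValueError(f"unknown dialect {self.confidence_dialect!r}")

    @property
    def n_old(self) -> int:
        return self.n_old_per_cell * len(self.cells)

    @property
    def pool_size(self) -> int:
        return self.n_old + self.n_new


def _default_spec(study: int, n_subjects: int | None) -> DesignSpec:
    if study == 1:
        return DesignSpec(
            study=1,
            n_subjects=30 if n_subjects is None else n_subjects,
            n_old_per_cell=30,
            n_new=120,
            cells=[(c, s) for c in CATEGORIES for s in STIMULATIONS],
            confidence_dialect="eleven_point",
            iti_range_ms=(4000, 5000),
        )
    return DesignSpec(
        study=2,
        n_subjects=65 if n_subjects is None else n_subjects,
        n_old_per_cell=30,
        n_new=120,
        cells=[(c, p) for c in CATEGORIES for p in PHASES],
        confidence_dialect="six_point",
        iti_range_ms=(2500, 5000),
        block_size=4,
    )


def max_category_run(categories) -> int:
    """Longest run of identical consecutive labels."""
    longest = run = 0
    prev = object()
    for c in categories:
        run = run + 1 if c == prev else 1
        longest = max(longest, run)
        prev = c
    return longest


def _constrained_category_sequence(
    rng: np.random.Generator,
    position_groups: list,
    quotas: dict,
    max_run: int = 2,
    max_restarts: int = 10_000,
) -> list[str]:
    """Category sequence with per-group quotas and no run longer than
    ``max_run``, by weighted sequential sampling with restarts."""
    n = len(position_groups)
    for _ in range(max_restarts):
        remaining = {g: dict(q) for g, q in quotas.items()}
        seq: list[str] = []
        ok = True
        for pos in range(n):
            group = position_groups[pos]
            banned = None
            if len(seq) >= max_run and all(c == seq[-1] for c in seq[-max_run:]):
                banned = seq[-1]
            cats = [
                c
                for c, k in remaining[group].items()
                if k > 0 and c != banned
            ]
            if not cats:
                ok = False
                break
            weights = np.array([remaining[group][c] for c in cats], dtype=float)
            choice = rng.choice(len(cats), p=weights / weights.sum())
            cat = cats[choice]
            remaining[group][cat] -= 1
            seq.append(cat)
        if ok:
            return seq
    raise RuntimeError("could not satisfy category-order constraint")


def _image_pool(spec: DesignSpec) -> pd.DataFrame:
    """Image pool split into four sets of n/4 images, each half unpleasant
    and half neutral.  Image ids run 1..pool_size."""
    per_set = spec.pool_size // 4
    half = per_set // 2
    rows = []
    img = 1
    for s in range(4):
        for cat in CATEGORIES:
            for _ in range(half):
                rows.append({"image": img, "set": s, "category": cat})
                img += 1
    return pd.DataFrame(rows)


def _deal(rng, pool: pd.DataFrame, set_id: int, category: str) -> list[int]:
    imgs = pool.loc[(pool["set"] == set_id) & (pool["category"] == category), "image"]
    return list(rng.permutation(imgs.to_numpy()))


def _study1_subject(rng, spec: DesignSpec, subject: int, pool: pd.DataFrame) -> list[dict]:
    rows: list[dict] = []
    # counterbalancing: rotate set roles and stimulation order across subjects
    role_rotation = subject % 4
    sets = [(s + role_rotation) % 4 for s in range(4)]
    stim_order = (
        ("taVNS", "sham") if subject % 2 == 0 else ("sham", "taVNS")
    )
    set_for_stim = {stim_order[0]: sets[0], stim_order[1]: sets[1]}
    new_sets = sets[2:]

    per_session = 2 * spec.n_old_per_cell
    half = spec.n_old_per_cell
    for session, stim in enumerate(stim_order, start=1):
        cats = _constrained_category_sequence(
            rng,
            position_groups=["s"] * per_session,
            quotas={"s": {c: half for c in CATEGORIES}},
        )
        stacks = {c: _deal(rng, pool, set_for_stim[stim], c) for c in CATEGORIES}
        for trial, cat in enumerate(cats, start=1):
            rows.append(
                {
                    "subject": subject,
                    "group": "within",
                    "session": session,
                    "task": "encoding",
                    "trial": trial,
                    "image": stacks[cat].pop(),
                    "category": cat,
                    "stimulation": stim,
                    "phase": pd.NA,
                    "role": "old",
                }
            )

    # retrieval: 120 old (with their encoding stimulation) + 120 new, shuffled
    ret: list[dict] = []
    for row in rows[:]:
        ret.append(
            {
                "subject": subject,
                "group": "within",
                "session": 3,
                "task": "retrieval",
                "image": row["image"],
                "category": row["category"],
                "stimulation": row["stimulation"],
                "phase": pd.NA,
                "role": "old",
            }
        )
    for set_id in new_sets:
        for cat in CATEGORIES:
            for img in _deal(rng, pool, set_id, cat):
                ret.append(
                    {
                        "subject": subject,
                        "group": "within",
                        "session": 3,
                        "task": "retrieval",
                        "image": img,
                        "category": cat,
                        "stimulation": pd.NA,
                        "phase": pd.NA,
                        "role": "new",
                    }
                )
    order = rng.permutation(len(ret))
    for trial, k in enumerate(order, start=1):
        ret[k]["trial"] = trial
    ret.sort(key=lambda r: r["trial"])
    return rows + ret


def _study2_subject(rng, spec: DesignSpec, subject: int, pool: pd.DataFrame) -> list[dict]:
    rows: list[dict] = []
    stim = STIMULATIONS[subject % 2]
    role_rotation = subject % 4
    sets = [(s + role_rotation) % 4 for s in range(4)]
    set_for_phase = {"on": sets[0], "off": sets[1]}
    new_sets = sets[2:]

    n_enc = 2 * 2 * spec.n_old_per_cell  # categories x phases x per-cell count
    block = spec.block_size or 4
    if n_enc % (2 * block) != 0:
        raise ValueError("on/off blocks must tile the encoding sequence exactly")
    phases = []
    for b in range(n_enc // block):
        phases.extend([PHASES[b % 2]] * block)

    cats = _constrained_category_sequence(
        rng,
        position_groups=phases,
        quotas={p: {c: spec.n_old_per_cell for c in CATEGORIES} for p in PHASES},
    )
    stacks = {
        (p, c): _deal(rng, pool, set_for_phase[p], c)
        for p in PHASES
        for c in CATEGORIES
    }
    for trial, (phase, cat) in enumerate(zip(phases, cats), start=1):
        rows.append(
            {
                "subject": subject,
                "group": stim,
                "session": 1,
                "task": "encoding",
                "trial": trial,
                "image": stacks[(phase, cat)].pop(),
                "category": cat,
                "stimulation": stim,
                "phase": phase,
                "role": "old",
            }
        )

    ret: list[dict] = []
    for row in rows[:]:
        ret.append(
            {
                "subject": subject,
                "group": stim,
                "session": 2,
                "task": "retrieval",
                "image": row["image"],
                "category": row["category"],
                "stimulation": stim,
                "phase": row["phase"],
                "role": "old",
            }
        )
    for set_id in new_sets:
        for cat in CATEGORIES:
            for img in _deal(rng, pool, set_id, cat):
                ret.append(
                    {
                        "subject": subject,
                        "group": stim,
                        "session": 2,
                        "task": "retrieval",
                        "image": img,
                        "category": cat,
                        "stimulation": pd.NA,
                        "phase": pd.NA,
                        "role": "new",
                    }
                )
    order = rng.permutation(len(ret))
    for trial, k in enumerate(order, start=1):
        ret[k]["trial"] = trial
    ret.sort(key=lambda r: r["trial"])
    return rows + ret


def build_design(
    study: int, seed: int = 0, n_subjects: int | None = None
) -> tuple[DesignSpec, pd.DataFrame]:
    """Build the complete balanced trial-level design table for a study.

    Returns the :class:`DesignSpec` and a table with one row per trial
    (encoding and retrieval) per subject.  Deterministic given ``seed``.
    """
    if study not in (1, 2):
        raise ValueError(f"unknown study code {study!r}")
    spec = _default_spec(study, n_subjects)
    rng = component_rng(seed, "design")
    pool = _image_pool(spec)
    rows: list[dict] = []
    make = _study1_subject if study == 1 else _study2_subject
    for subject in range(1, spec.n_subjects + 1):
        rows.extend(make(rng, spec, subject, pool))
    table = pd.DataFrame(rows)
    col_order = [
        "subject",
        "group",
        "session",
        "task",
        "trial",
        "image",
        "category",
        "stimulation",
        "phase",
        "role",
    ]
    return spec, table[col_order].reset_index(drop=True)
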