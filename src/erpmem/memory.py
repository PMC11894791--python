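"""Signal-detection recognition-memory indices.

Discrimination is summarized per stratum (e.g. affective category x
stimulation) by the Pr index, ``p(hit) - p(false alarm)``, and by d-prime,
``z(p[hit]) - z(p[false alarm])`` with the standard-normal quantile
function.  Confidence splits the "old" responses into *recollection*
(top-anchor responses: rating 10 on the 0-10 dialect, anchor 6 on the
6-point dialect) and *familiarity* (sub-top "old" responses).  Split
numerators are restricted to the relevant confidence band while the
denominators stay the full old/new trial counts, which makes the split
exactly additive: recollection Pr + familiarity Pr = overall Pr.

Extreme rates (0 or 1) are replaced by ``1/(2N)`` and ``1 - 1/(2N)``
before the quantile transform so d-prime stays finite; the correction is
recorded in output metadata.

Subjects who cannot discriminate old from new items (overall Pr <= 0) are
excluded before inferential analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "old_response_mask",
    "rates",
    "pr_index",
    "d_prime",
    "memory_indices",
    "exclude_poor_performers",
    "TOP_ANCHOR",
]

from .behavior import TOP_ANCHOR

MEMORY_CLASSES = ("overall", "recollection", "familiarity")

#: numerator classes with fewer trials than this are flagged unstable
MIN_STABLE_TRIALS = 5


def old_response_mask(table: pd.DataFrame, dialect: str) -> pd.Series:
    """Boolean mask of trials answered "old".

    The eleven-point dialect carries an explicit response column (the
    two-question format); the six-point dialect derives it from the
    anchors (4-6 = old)."""
    if dialect == "six_point":
        return table["confidence"] >= 4
    return table["response"] == "old"


def _class_mask(table: pd.DataFrame, memory_class: str, dialect: str,
                rec_anchors=None) -> pd.Series:
    """Mask restricting "old"-response numerators to a memory class."""
    old_resp = old_response_mask(table, dialect)
    if rec_anchors is None:
        rec_anchors = {TOP_ANCHOR[dialect]}
    rec = table["confidence"].isin(set(rec_anchors))
    if memory_class == "overall":
        return old_resp
    if memory_class == "recollection":
        return old_resp & rec
    if memory_class == "familiarity":
        return old_resp & ~rec
    raise ValueError(f"unknown memory class {memory_class!r}")


def _match_new_trials(new: pd.DataFrame, strata: list[str], key: tuple) -> pd.DataFrame:
    """New trials matching a stratum on the columns where new trials carry
    labels (new items share a pool across e.g. stimulation levels, so FA
    rates are matched only on the columns defined for them)."""
    sel = new
    for col, val in zip(strata, key):
        if sel[col].notna().any():
            sel = sel.loc[sel[col] == val]
    return sel


def rates(
    table: pd.DataFrame,
    strata: list[str],
    memory_class: str = "overall",
    dialect: str = "eleven_point",
    rec_anchors=None,
) -> pd.DataFrame:
    """Hit and false-alarm rates (and counts) per stratum.

    Hit = #(old trials answered "old" in the class) / #(old trials in the
    stratum); FA likewise over new trials.  Denominators are all old/new
    trials regardless of memory class (the additive convention).
    """
    missing = [c for c in strata if c not in table.columns]
    if missing:
        raise ValueError(f"stratum columns not in table: {missing}")
    if dialect not in TOP_ANCHOR:
        raise ValueError(f"unknown dialect {dialect!r}")
    if rec_anchors is not None:
        top = TOP_ANCHOR[dialect]
        if not set(rec_anchors) <= set(range(top + 1)):
            raise ValueError("rec_anchors outside the dialect's range")

    old = table.loc[table["truth"] == "old"]
    new = table.loc[table["truth"] == "new"]
    hit_mask = _class_mask(old, memory_class, dialect, rec_anchors)
    fa_mask = _class_mask(new, memory_class, dialect, rec_anchors)

    records = []
    groups = old.groupby(strata, dropna=False, sort=True, observed=True)
    for key, grp in groups:
        key = key if isinstance(key, tuple) else (key,)
        new_grp = _match_new_trials(new, strata, key)
        n_old, n_new = len(grp), len(new_grp)
        if n_old == 0 or n_new == 0:
            raise ValueError(f"stratum {dict(zip(strata, key))} has an empty denominator")
        hits = int(hit_mask.loc[grp.index].sum())
        fas = int(fa_mask.loc[new_grp.index].sum())
        rec = dict(zip(strata, key))
        rec.update(
            memory_class=memory_class,
            n_old=n_old,
            n_new=n_new,
            n_hits=hits,
            n_fas=fas,
            hit_rate=hits / n_old,
            fa_rate=fas / n_new,
            unstable=(memory_class != "overall" and hits < MIN_STABLE_TRIALS),
        )
        records.append(rec)
    return pd.DataFrame(records)


def pr_index(hit: float, fa: float) -> float:
    """Discrimination index Pr = p(hit) - p(false alarm)."""
    if not (0.0 <= hit <= 1.0 and 0.0 <= fa <= 1.0):
        raise ValueError("rates must be in [0, 1]")
    return hit - fa


def _corrected(rate: float, n: int) -> float:
    if n <= 0:
        raise ValueError("trial counts must be positive")
    if rate <= 0.0:
        return 1.0 / (2 * n)
    if rate >= 1.0:
        return 1.0 - 1.0 / (2 * n)
    return rate


def d_prime(hit: float, fa: float, n_old: int, n_new: int) -> float:
    """d' = z(hit) - z(fa) with the 1/(2N) extreme-rate correction.

    Antisymmetric (d'(h, f) = -d'(f, h) when n_old == n_new), increasing
    in the hit rate and decreasing in the false-alarm rate.
    """
    h = _corrected(hit, n_old)
    f = _corrected(fa, n_new)
    return float(norm.ppf(h) - norm.ppf(f))


def memory_indices(
    table: pd.DataFrame,
    strata: list[str],
    dialect: str = "eleven_point",
    rec_anchors=None,
) -> pd.DataFrame:
    """Tidy table of memory indices: one row per stratum x memory class,
    with hit/FA rates, Pr, d' and trial counts."""
    frames = []
    for mc in MEMORY_CLASSES:
        r = rates(table, strata, mc, dialect, rec_anchors)
        r["pr"] = r["hit_rate"] - r["fa_rate"]
        r["d_prime"] = [
            d_prime(row.hit_rate, row.fa_rate, row.n_old, row.n_new)
            for row in r.itertuples()
        ]
        frames.append(r)
    out = pd.concat(frames, ignore_index=True)
    out.attrs["extreme_rate_correction"] = "1/(2N)"
    out.attrs["dialect"] = dialect
    return out


def exclude_poor_performers(
    table: pd.DataFrame, dialect: str = "eleven_point"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop subjects whose overall Pr (all trials pooled) is <= 0.

    Returns the filtered table and an exclusion report (one row per
    subject with their overall Pr and whether they were removed).

    Raises if every subject would be excluded.
    """
    per_subject = rates(table, ["subject"], "overall", dialect)
    per_subject["pr"] = per_subject["hit_rate"] - per_subject["fa_rate"]
    per_subject["excluded"] = per_subject["pr"] <= 0.0
    excluded = set(per_subject.loc[per_subject["excluded"], "subject"])
    if len(excluded) == len(per_subject):
        raise ValueError("all subjects have Pr <= 0; nothing left to analyze")
    report = per_subject[["subject", "n_old", "n_new", "hit_rate", "fa_rate", "pr", "excluded"]]
    filtered = table.loc[~table["subject"].isin(excluded)].reset_index(drop=True)
    return filtered, report
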