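"""Study-shaped runs: simulate -> analyze -> report.

A :class:`RunConfig` describes one synthetic study run: which design to
emulate, the root seed, generator noise/effect settings, and the analysis
parameters (forming alpha, duration rule, permutation count, analysis
windows and ROIs).  ``simulate`` writes the design/behavior tables and
epoch files; ``analyze`` runs the cluster permutation tests with their
follow-ups plus the behavioral chain (exclusion -> memory indices ->
mixed models -> Bayes factors); ``run_study`` does both in memory.

Analysis windows (encoding early 200-600 ms, encoding late 600-1200 ms,
retrieval 400-1000 ms) are tested independently with no cross-window
correction, and the retrieval analysis follows the two-stage logic of the
emulated designs: first test the affective-category x stimulation
interaction among old-item ERPs, then compare significant clusters'
amplitudes against the correctly-identified-new baselines to check that
they reflect old/new memory effects.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .anova import paired_t, pooled_t, rm_anova_2x2, welch_t
from .behavior import BehaviorGenConfig, gen_recognition
from .cluster import EffectSpec, cluster_mean_amplitude, cluster_test
from .design import build_design
from .epochs import EpochSet, baseline_correct, collapse_conditions, load_epochs, save_epochs
from .erpsim import EffectPatch, ErpGenConfig, gen_epochs
from .layout import SensorLayout, hemisphere_layout
from .lmm import LmmSpec, bf10_bic, fit_random_intercept_lmm
from .memory import exclude_poor_performers, memory_indices

__all__ = [
    "ConfigError",
    "DataError",
    "RunConfig",
    "SimulatedStudy",
    "simulate_study",
    "analyze_study",
    "run_study",
    "simulate",
    "analyze",
    "report_text",
]


class ConfigError(Exception):
    """Invalid run configuration (CLI exit code 2)."""


class DataError(Exception):
    """Missing or inconsistent input data (CLI exit code 3)."""


DEFAULT_WINDOWS = {
    "encoding_early": (200.0, 600.0),
    "encoding_late": (600.0, 1200.0),
    "retrieval": (400.0, 1000.0),
}
DEFAULT_ROIS = {"encoding": ["posterior"], "retrieval": ["anterior", "posterior"]}


@dataclass
class RunConfig:
    """Everything needed to reproduce one synthetic study run."""

    study: int = 1
    seed: int = 0
    n_subjects: int | None = None
    n_sensors: int = 129
    n_perm: int = 1000
    forming_alpha: float = 0.05
    min_run: int = 5
    windows: dict = field(default_factory=lambda: dict(DEFAULT_WINDOWS))
    rois: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_ROIS.items()})
    noise_sd: float = 1.0
    smoothing_steps: int = 2
    ar_coef: float = 0.5
    erp_subject_sd: float = 0.25
    effect_scale: float = 1.0  # 0 turns the run into a pure-noise null study

    def __post_init__(self) -> None:
        if self.study not in (1, 2):
            raise ConfigError(f"unknown study code {self.study!r}")
        if self.n_perm < 100:
            raise ConfigError("n_perm must be >= 100")
        if not (0.0 < self.forming_alpha < 1.0):
            raise ConfigError("forming_alpha must be in (0, 1)")
        if self.min_run < 1:
            raise ConfigError("min_run must be >= 1")
        epoch = (-200.0, 1200.0)
        for name, (w0, w1) in self.windows.items():
            if not (epoch[0] <= w0 < w1 <= epoch[1]):
                raise ConfigError(f"window {name} = {(w0, w1)} outside epoch {epoch}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise ConfigError(f"cannot read config: {exc}") from exc
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "windows" in raw:
            raw["windows"] = {k: tuple(v) for k, v in raw["windows"].items()}
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["windows"] = {k: list(v) for k, v in self.windows.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


# -- generator defaults: the emulated study conditions -------------------


def roi_center_sensor(layout: SensorLayout, roi: str) -> int:
    """Sensor closest to an ROI's centroid, used to anchor effect patches."""
    idx = layout.roi_indices(roi)
    pos = layout.positions[idx]
    d = ((pos - pos.mean(axis=0)) ** 2).sum(axis=1)
    return int(layout.ids[int(idx[int(np.argmin(d))])])


def default_behavior_config(study: int, seed: int = 0) -> BehaviorGenConfig:
    """Dual-process parameters producing recognition performance of the
    magnitude the emulated designs report (overall Pr around 0.5,
    recollection-dominated, a small emotional memory advantage and a
    slight recollection boost under active stimulation)."""
    if study == 1:
        return BehaviorGenConfig(
            dialect="eleven_point",
            recollection={
                "unpleasant|taVNS|*": 0.40,
                "unpleasant|sham|*": 0.38,
                "neutral|taVNS|*": 0.27,
                "neutral|sham|*": 0.30,
            },
            familiarity={"unpleasant|*|*": 1.0, "neutral|*|*": 0.9},
            subject_sd_dfam=0.35,
            subject_sd_logit_r=0.5,
            seed=seed,
        )
    return BehaviorGenConfig(
        dialect="six_point",
        recollection={
            "unpleasant|taVNS|*": 0.49,
            "unpleasant|sham|*": 0.42,
            "neutral|taVNS|*": 0.32,
            "neutral|sham|*": 0.26,
        },
        familiarity={"unpleasant|*|*": 0.9, "neutral|*|*": 0.8},
        subject_sd_dfam=0.35,
        subject_sd_logit_r=0.5,
        seed=seed,
    )


def default_erp_effects(
    study: int, task: str, layout: SensorLayout, scale: float = 1.0
) -> list[EffectPatch]:
    """Ground-truth patches emulating the studies' reported effects: a
    posterior emotion (LPP) main effect at encoding, an early-window
    emotion x stimulation interaction, and late old/new (+ interaction)
    effects at retrieval."""
    post = roi_center_sensor(layout, "posterior")
    ant = roi_center_sensor(layout, "anterior")
    s = scale
    if task == "encoding":
        if study == 1:
            return [
                EffectPatch(  # emotion main effect (LPP)
                    window_ms=(300.0, 1000.0), center=post, radius=3,
                    amplitudes={"unpleasant/taVNS": 1.2 * s, "unpleasant/sham": 1.2 * s},
                    subject_sd=0.3,
                ),
                EffectPatch(  # early-window interaction
                    window_ms=(416.0, 548.0), center=post, radius=2,
                    amplitudes={"unpleasant/taVNS": 1.5 * s}, subject_sd=0.3,
                ),
                EffectPatch(  # late-window interaction
                    window_ms=(672.0, 724.0), center=post, radius=2,
                    amplitudes={"unpleasant/taVNS": 1.2 * s}, subject_sd=0.3,
                ),
            ]
        return [
            EffectPatch(
                window_ms=(300.0, 1000.0), center=post, radius=3,
                amplitudes={"unpleasant/on": 1.2 * s, "unpleasant/off": 1.2 * s},
                subject_sd=0.3,
            ),
            EffectPatch(  # emotion effect enhanced in the active group
                window_ms=(476.0, 600.0), center=post, radius=2,
                amplitudes={
                    "taVNS@unpleasant/on": 1.5 * s,
                    "taVNS@unpleasant/off": 1.5 * s,
                },
                subject_sd=0.3,
            ),
        ]
    if study == 1:
        old_conditions = [
            "old:unpleasant/taVNS", "old:unpleasant/sham",
            "old:neutral/taVNS", "old:neutral/sham",
        ]
        return [
            EffectPatch(  # late old/new effect
                window_ms=(400.0, 800.0), center=ant, radius=3,
                amplitudes={c: 1.0 * s for c in old_conditions}, subject_sd=0.3,
            ),
            EffectPatch(  # old/new increase for unpleasant-under-taVNS
                window_ms=(672.0, 776.0), center=ant, radius=2,
                amplitudes={"old:unpleasant/taVNS": 1.5 * s}, subject_sd=0.3,
            ),
        ]
    return [
        EffectPatch(
            window_ms=(400.0, 800.0), center=ant, radius=3,
            amplitudes={"old:unpleasant": 1.0 * s, "old:neutral": 1.0 * s},
            subject_sd=0.3,
        ),
        EffectPatch(
            window_ms=(500.0, 636.0), center=ant, radius=2,
            amplitudes={"taVNS@old:unpleasant": 1.5 * s}, subject_sd=0.3,
        ),
    ]


def default_erp_config(config: RunConfig, task: str, layout: SensorLayout) -> ErpGenConfig:
    return ErpGenConfig(
        n_sensors=config.n_sensors,
        noise_sd=config.noise_sd,
        smoothing_steps=config.smoothing_steps,
        ar_coef=config.ar_coef,
        subject_sd=config.erp_subject_sd,
        effects=default_erp_effects(config.study, task, layout, config.effect_scale),
    )


# -- simulation ----------------------------------------------------------


@dataclass
class SimulatedStudy:
    config: RunConfig
    layout: SensorLayout
    design: pd.DataFrame
    behavior: pd.DataFrame
    epochs_encoding: EpochSet
    truth_encoding: list[dict]
    epochs_retrieval: EpochSet
    truth_retrieval: list[dict]

    @property
    def dialect(self) -> str:
        return "eleven_point" if self.config.study == 1 else "six_point"

    def groups(self) -> dict:
        return (
            self.design.drop_duplicates("subject")
            .set_index("subject")["group"]
            .to_dict()
        )


def simulate_study(config: RunConfig) -> SimulatedStudy:
    """Generate design, behavior and epochs for a run configuration."""
    layout = hemisphere_layout(config.n_sensors)
    _, design = build_design(config.study, seed=config.seed, n_subjects=config.n_subjects)
    behavior = gen_recognition(
        default_behavior_config(config.study, seed=config.seed), design
    )
    enc_cfg = default_erp_config(config, "encoding", layout)
    ret_cfg = default_erp_config(config, "retrieval", layout)
    epochs_enc, truth_enc = gen_epochs(enc_cfg, design, layout, seed=config.seed, task="encoding")
    epochs_ret, truth_ret = gen_epochs(ret_cfg, design, layout, seed=config.seed, task="retrieval")
    return SimulatedStudy(
        config=config,
        layout=layout,
        design=design,
        behavior=behavior,
        epochs_encoding=epochs_enc,
        truth_encoding=truth_enc,
        epochs_retrieval=epochs_ret,
        truth_retrieval=truth_ret,
    )


# -- ERP analysis --------------------------------------------------------


def _erp_effects_for(config: RunConfig, task: str, groups: dict) -> list[tuple[str, EffectSpec, dict | None]]:
    """(label, effect spec, collapse-mapping) triples tested per task."""
    if config.study == 1:
        if task == "encoding":
            return [(
                "category_x_stimulation",
                EffectSpec(
                    name="category_x_stimulation",
                    design="interaction_within",
                    cells=(
                        ("unpleasant/taVNS", "neutral/taVNS"),
                        ("unpleasant/sham", "neutral/sham"),
                    ),
                ),
                None,
            )]
        return [(
            "category_x_stimulation_old",
            EffectSpec(
                name="category_x_stimulation_old",
                design="interaction_within",
                cells=(
                    ("old:unpleasant/taVNS", "old:neutral/taVNS"),
                    ("old:unpleasant/sham", "old:neutral/sham"),
                ),
            ),
            None,
        )]
    if task == "encoding":
        collapse = {
            "unpleasant": ["unpleasant/on", "unpleasant/off"],
            "neutral": ["neutral/on", "neutral/off"],
        }
        return [
            (
                "category_x_stimulation",
                EffectSpec(
                    name="category_x_stimulation",
                    design="interaction_mixed",
                    cells=("unpleasant", "neutral"),
                    groups=groups,
                ),
                collapse,
            ),
            (
                "category_x_stimulation_x_phase",
                EffectSpec(
                    name="category_x_stimulation_x_phase",
                    design="three_way_mixed",
                    cells=(
                        ("unpleasant/on", "unpleasant/off"),
                        ("neutral/on", "neutral/off"),
                    ),
                    groups=groups,
                ),
                None,
            ),
        ]
    return [(
        "category_x_memory_x_stimulation",
        EffectSpec(
            name="category_x_memory_x_stimulation",
            design="three_way_mixed",
            cells=(
                ("old:unpleasant", "new:unpleasant"),
                ("old:neutral", "new:neutral"),
            ),
            groups=groups,
        ),
        None,
    )]


def _ttest_dict(res) -> dict:
    return {"t": res.t, "df": res.df, "p": res.p, "infinite": res.infinite}


def _followups_study1(sim: SimulatedStudy, task: str, means: pd.DataFrame) -> dict:
    wide = means.pivot(index="subject", columns="condition", values="mean_uv")
    out: dict = {}
    if task == "encoding":
        cells = [["unpleasant/taVNS", "unpleasant/sham"], ["neutral/taVNS", "neutral/sham"]]
        values = np.stack(
            [np.stack([wide[c].to_numpy() for c in row], axis=1) for row in cells],
            axis=1,
        )
        anova = rm_anova_2x2(values)
        out["anova"] = {
            k: {"F": e.F, "df": list(e.df), "p": e.p, "eta_p2": e.eta_p2}
            for k, e in anova.items()
        }
        out["t_tests"] = {
            "unpleasant_vs_neutral_taVNS": _ttest_dict(
                paired_t(wide["unpleasant/taVNS"], wide["neutral/taVNS"])
            ),
            "unpleasant_vs_neutral_sham": _ttest_dict(
                paired_t(wide["unpleasant/sham"], wide["neutral/sham"])
            ),
            "taVNS_vs_sham_unpleasant": _ttest_dict(
                paired_t(wide["unpleasant/taVNS"], wide["unpleasant/sham"])
            ),
            "taVNS_vs_sham_neutral": _ttest_dict(
                paired_t(wide["neutral/taVNS"], wide["neutral/sham"])
            ),
        }
        return out
    cells = [
        ["old:unpleasant/taVNS", "old:unpleasant/sham"],
        ["old:neutral/taVNS", "old:neutral/sham"],
    ]
    values = np.stack(
        [np.stack([wide[c].to_numpy() for c in row], axis=1) for row in cells],
        axis=1,
    )
    anova = rm_anova_2x2(values)
    out["anova"] = {
        k: {"F": e.F, "df": list(e.df), "p": e.p, "eta_p2": e.eta_p2}
        for k, e in anova.items()
    }
    # stage 2: do the interaction clusters reflect old/new differences?
    out["old_new_t_tests"] = {
        "new_unpleasant_vs_old_unpleasant_taVNS": _ttest_dict(
            paired_t(wide["old:unpleasant/taVNS"], wide["new:unpleasant"])
        ),
        "new_unpleasant_vs_old_unpleasant_sham": _ttest_dict(
            paired_t(wide["old:unpleasant/sham"], wide["new:unpleasant"])
        ),
        "old_unpleasant_taVNS_vs_sham": _ttest_dict(
            paired_t(wide["old:unpleasant/taVNS"], wide["old:unpleasant/sham"])
        ),
        "new_neutral_vs_old_neutral_taVNS": _ttest_dict(
            paired_t(wide["old:neutral/taVNS"], wide["new:neutral"])
        ),
        "new_neutral_vs_old_neutral_sham": _ttest_dict(
            paired_t(wide["old:neutral/sham"], wide["new:neutral"])
        ),
        "old_neutral_taVNS_vs_sham": _ttest_dict(
            paired_t(wide["old:neutral/taVNS"], wide["old:neutral/sham"])
        ),
    }
    return out


def _followups_study2(sim: SimulatedStudy, task: str, means: pd.DataFrame) -> dict:
    wide = means.pivot(index="subject", columns="condition", values="mean_uv")
    groups = sim.groups()
    glab = np.array([groups[s] for s in wide.index])
    out: dict = {"t_tests": {}}

    def per_group(cond_a, cond_b, label):
        for g in ("taVNS", "sham"):
            sel = glab == g
            out["t_tests"][f"{label}_{g}"] = _ttest_dict(
                paired_t(wide.loc[sel, cond_a], wide.loc[sel, cond_b])
            )

    def between(cond, label):
        a = wide.loc[glab == "taVNS", cond]
        b = wide.loc[glab == "sham", cond]
        out["t_tests"][f"{label}_taVNS_vs_sham"] = _ttest_dict(welch_t(a, b))

    if task == "encoding":
        cols = ["unpleasant/on", "unpleasant/off", "neutral/on", "neutral/off"]
        unp = wide[["unpleasant/on", "unpleasant/off"]].mean(axis=1)
        neu = wide[["neutral/on", "neutral/off"]].mean(axis=1)
        for g in ("taVNS", "sham"):
            sel = glab == g
            out["t_tests"][f"unpleasant_vs_neutral_{g}"] = _ttest_dict(
                paired_t(unp[sel], neu[sel])
            )
        out["t_tests"]["unpleasant_taVNS_vs_sham"] = _ttest_dict(
            welch_t(unp[glab == "taVNS"], unp[glab == "sham"])
        )
        out["t_tests"]["neutral_taVNS_vs_sham"] = _ttest_dict(
            welch_t(neu[glab == "taVNS"], neu[glab == "sham"])
        )
        return out
    per_group("old:unpleasant", "new:unpleasant", "old_vs_new_unpleasant")
    per_group("old:neutral", "new:neutral", "old_vs_new_neutral")
    between("old:unpleasant", "old_unpleasant")
    between("old:neutral", "old_neutral")
    return out


def _analyze_erp(sim: SimulatedStudy) -> tuple[dict, dict[str, pd.DataFrame]]:
    config = sim.config
    groups = sim.groups()
    results: dict = {}
    mean_tables: dict[str, pd.DataFrame] = {}
    for window_name, window in config.windows.items():
        task = "encoding" if window_name.startswith("encoding") else "retrieval"
        epochs = sim.epochs_encoding if task == "encoding" else sim.epochs_retrieval
        epochs = baseline_correct(epochs)
        roi = config.rois.get(task, ["posterior"])
        roi_ids = [int(sim.layout.ids[i]) for i in sim.layout.roi_indices(roi)]
        sub_layout = sim.layout.subset(roi_ids)
        sub = epochs.select_sensors(roi_ids).select_time(tuple(window))
        results[window_name] = {}
        for label, effect, collapse in _erp_effects_for(config, task, groups):
            data = collapse_conditions(sub, collapse) if collapse else sub
            res = cluster_test(
                data,
                effect,
                sub_layout,
                n_perm=config.n_perm,
                seed=config.seed,
                forming_alpha=config.forming_alpha,
                min_run=config.min_run,
            )
            entry = res.to_dict()
            entry["follow_up"] = []
            for ci, cl in enumerate(res.significant_clusters()):
                means = cluster_mean_amplitude(epochs.select_sensors(roi_ids), cl)
                mean_tables[f"{window_name}.{label}.cluster{ci + 1}"] = means
                follow = (
                    _followups_study1(sim, task, means)
                    if config.study == 1
                    else _followups_study2(sim, task, means)
                )
                follow["cluster_index"] = ci + 1
                entry["follow_up"].append(follow)
            results[window_name][label] = entry
    return results, mean_tables


# -- behavioral analysis -------------------------------------------------


def _lmm_table(fit) -> list[dict]:
    return [
        {
            "term": r.term,
            "estimate": r.estimate,
            "se": r.se,
            "t": r.t,
            "df": r.df,
            "p": r.p,
        }
        for r in fit.coef.itertuples()
    ]


def _bf_per_term(data: pd.DataFrame, spec: LmmSpec) -> dict:
    """BIC Bayes factor for each term: full ML fit vs the fit without it."""
    full_terms = spec.resolved_terms()
    fit_full = fit_random_intercept_lmm(data, LmmSpec(
        spec.response, spec.factors, terms=full_terms, group=spec.group), reml=False)
    out = {}
    for term in full_terms:
        reduced = [t for t in full_terms if t != term]
        fit_red = fit_random_intercept_lmm(data, LmmSpec(
            spec.response, spec.factors, terms=reduced, group=spec.group), reml=False)
        cmp_ = bf10_bic(fit_full, fit_red)
        out[term] = {"bf10": cmp_.bf10, "label": cmp_.label, "method": cmp_.method}
    return out


def _analyze_behavior(sim: SimulatedStudy) -> tuple[dict, dict[str, pd.DataFrame]]:
    dialect = sim.dialect
    try:
        filtered, report = exclude_poor_performers(sim.behavior, dialect)
    except ValueError as exc:
        raise DataError(str(exc)) from exc
    strata = ["subject", "category", "stimulation"]
    indices = memory_indices(filtered, strata, dialect)

    overall = indices.loc[indices["memory_class"] == "overall"].copy()
    split = indices.loc[indices["memory_class"] != "overall"].copy()
    split = split.rename(columns={"memory_class": "memory"})

    results: dict = {
        "dialect": dialect,
        "extreme_rate_correction": "1/(2N)",
        "n_subjects_analyzed": int(filtered["subject"].nunique()),
        "n_subjects_excluded": int(report["excluded"].sum()),
        "models": {},
    }
    factors = ["category", "stimulation"]
    for response in ("pr", "d_prime"):
        spec = LmmSpec(response, factors)
        fit = fit_random_intercept_lmm(overall, spec)
        results["models"][f"item_recognition_{response}"] = {
            "coef": _lmm_table(fit),
            "sigma2_subject": fit.sigma2_subject,
            "sigma2_resid": fit.sigma2_resid,
            "bic": fit.bic,
            "bf10": _bf_per_term(overall, spec),
        }
    for response in ("pr", "d_prime"):
        spec = LmmSpec(response, factors + ["memory"])
        fit = fit_random_intercept_lmm(split, spec)
        results["models"][f"confidence_split_{response}"] = {
            "coef": _lmm_table(fit),
            "sigma2_subject": fit.sigma2_subject,
            "sigma2_resid": fit.sigma2_resid,
            "bic": fit.bic,
            "bf10": _bf_per_term(split, spec),
        }
    tables = {"memory_indices": indices, "exclusions": report}
    return results, tables


# -- top-level runs ------------------------------------------------------


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (bool, int, float, str)) or obj is None:
        return obj
    return str(obj)


def analyze_study(sim: SimulatedStudy) -> tuple[dict, dict[str, pd.DataFrame]]:
    """Run the full analysis chain on a simulated study."""
    erp, mean_tables = _analyze_erp(sim)
    behavior, behavior_tables = _analyze_behavior(sim)
    report = {
        "study": sim.config.study,
        "seed": sim.config.seed,
        "config": _json_safe(asdict(sim.config)),
        "erp": erp,
        "behavior": behavior,
    }
    tables = {**behavior_tables, **mean_tables}
    return _json_safe(report), tables


def run_study(config: RunConfig) -> tuple[dict, dict[str, pd.DataFrame]]:
    """simulate -> analyze in memory; deterministic given the config."""
    sim = simulate_study(config)
    return analyze_study(sim)


# -- disk-based stages (the CLI surface) ---------------------------------


def simulate(config: RunConfig, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate_study(config)
    sim.design.to_csv(out / "design.tsv", sep="\t", index=False)
    sim.behavior.to_csv(out / "behavior.tsv", sep="\t", index=False)
    sim.layout.to_json(out / "layout.json")
    truth_enc = {"patches": json.dumps(_json_safe(sim.truth_encoding))}
    truth_ret = {"patches": json.dumps(_json_safe(sim.truth_retrieval))}
    save_epochs(out / "epochs_encoding.h5", sim.epochs_encoding, truth=truth_enc)
    save_epochs(out / "epochs_retrieval.h5", sim.epochs_retrieval, truth=truth_ret)
    config.to_yaml(out / "config.yaml")


def _load_simulated(config: RunConfig, in_dir) -> SimulatedStudy:
    ind = Path(in_dir)
    for name in ("design.tsv", "behavior.tsv", "layout.json",
                 "epochs_encoding.h5", "epochs_retrieval.h5"):
        if not (ind / name).exists():
            raise DataError(f"missing input file: {ind / name}")
    design = pd.read_csv(ind / "design.tsv", sep="\t")
    behavior = pd.read_csv(ind / "behavior.tsv", sep="\t")
    layout = SensorLayout.from_json(ind / "layout.json")
    epochs_enc, t_enc = load_epochs(ind / "epochs_encoding.h5")
    epochs_ret, t_ret = load_epochs(ind / "epochs_retrieval.h5")
    # subject labels in HDF5 are strings; align the tables to them
    if all(str(s).isdigit() for s in epochs_enc.subjects):
        epochs_enc.subjects = [int(s) for s in epochs_enc.subjects]
        epochs_ret.subjects = [int(s) for s in epochs_ret.subjects]
    return SimulatedStudy(
        config=config,
        layout=layout,
        design=design,
        behavior=behavior,
        epochs_encoding=epochs_enc,
        truth_encoding=json.loads(t_enc.get("patches", "[]")),
        epochs_retrieval=epochs_ret,
        truth_retrieval=json.loads(t_ret.get("patches", "[]")),
    )


def analyze(config: RunConfig, in_dir, out_dir) -> dict:
    """Re-run the analysis from saved intermediates (no re-simulation)."""
    sim = _load_simulated(config, in_dir)
    report, tables = analyze_study(sim)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "results.json", "w") as fh:
        json.dump(report, fh, indent=1)
    for name, table in tables.items():
        table.to_csv(out / f"{name.replace('.', '_')}.tsv", sep="\t", index=False)
    return report


def report_text(in_dir) -> str:
    """Human-readable summary of a results.json."""
    path = Path(in_dir) / "results.json"
    if not path.exists():
        raise DataError(f"missing results file: {path}")
    with open(path) as fh:
        res = json.load(fh)
    lines = [f"Study {res['study']} run (seed {res['seed']})", ""]
    for window, effects in res["erp"].items():
        for label, entry in effects.items():
            sig = [c for c in entry["clusters"] if c["significant"]]
            lines.append(
                f"[{window}] {label}: {len(entry['clusters'])} cluster(s), "
                f"{len(sig)} significant (critical mass "
                f"{entry['critical_mass']:.1f}, {entry['n_perm']} permutations)"
            )
            for c in sig:
                lines.append(
                    f"    mass={c['mass']:.1f}  window={c['window_ms'][0]:.0f}-"
                    f"{c['window_ms'][1]:.0f} ms  sensors={len(c['sensors'])}  "
                    f"p={c['p']:.4f}"
                )
    beh = res["behavior"]
    lines.append("")
    lines.append(
        f"Behavior: {beh['n_subjects_analyzed']} subjects analyzed, "
        f"{beh['n_subjects_excluded']} excluded (Pr <= 0)"
    )
    for model, entry in beh["models"].items():
        sig_terms = [
            f"{c['term']} (t({c['df']:.1f})={c['t']:.2f}, p={c['p']:.3g})"
            for c in entry["coef"]
            if c["term"] != "(Intercept)" and c["p"] < 0.05
        ]
        lines.append(f"  {model}: " + (", ".join(sig_terms) if sig_terms else "no significant terms"))
    return "\n".join(lines)
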