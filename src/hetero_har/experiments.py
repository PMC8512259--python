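"""The four heterogeneity experiments and the k-sensitivity analysis.

Every experiment runs a paired design: the adaptation arm (GFK + SVM) and
the benchmark arm (plain linear SVM) consume identical windows and splits.

* cross-sensor: per subject, Sensor 1 windows are the labelled source and
  Sensor 2 windows of the *same* session are the unlabelled target.
* cross-subject: per target subject (Sensor 1 only), the k candidate
  subjects with the lowest rank-of-domain (ROD) scores are pooled into the
  source; the benchmark pools k uniformly-random candidates.
* joint: like cross-subject but the target is the subject's Sensor 2 data
  while candidates contribute Sensor 1 data (both heterogeneities at once).
* cross-scenario: one pooled source group performing contiguous task blocks
  ("separate") against a pooled target group performing interleaved short
  bouts ("mixed", typing excluded), both with 4-s windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import EvaluationReport, evaluate, fit_predict_baseline, fit_predict_da
from .exceptions import ConfigError, DataError
from .features import DomainDataset, standardize, windows_to_dataset
from .gfk import rod, select_dimension
from .preprocess import convert_units, regularize_sampling, segment
from .synth import (
    TASKS,
    AnnotationTrack,
    Dropout,
    ScenarioSpec,
    SensorModel,
    SensorRecording,
    SubjectProfile,
    apply_sensor_model,
    make_cohort,
    simulate_ideal_session,
    _child_seeds,
)

MIXED_TASKS = tuple(t for t in TASKS if t != "Tp")


def default_sensor1() -> SensorModel:
    """Reference wristband: uniform 32 Hz, g/64 unit, narrow +/-2 g range."""
    return SensorModel(
        sensor_id="S1",
        unit="g64",
        rate_hz=32.0,
        jitter=0.0,
        bias=(0.3, -0.2, 0.25),  # g/64 units, ~0.004 g
        scale_error=(1.0, 1.0, 1.0),
        range_g=2.0,
        noise_sd=0.4,
    )


def default_sensor2() -> SensorModel:
    """Heterogeneous wristband: uneven ~26 Hz sampling in g units, per-axis
    bias and scale error, a mounting-orientation offset, a wide +/-8 g
    range, a higher noise floor and sporadic dropouts."""
    return SensorModel(
        sensor_id="S2",
        unit="g",
        rate_hz=26.0,
        jitter=0.25,
        bias=(0.03, -0.02, 0.025),
        scale_error=(1.08, 0.94, 1.05),
        mounting_deg=(12.0, -8.0, 15.0),
        range_g=8.0,
        noise_sd=0.02,
        dropout=Dropout(rate_per_min=0.3, dur_mean_s=1.5, dur_sd_s=1.0),
    )


def identity_sensor(sensor_id: str = "ID") -> SensorModel:
    """Sensor model that reproduces the ideal series samplewise."""
    return SensorModel(sensor_id=sensor_id, unit="m_s2", rate_hz=32.0)


@dataclass
class ExperimentConfig:
    """Cohort, sensor, scenario and analysis settings of one experiment."""

    n_subjects: int = 10
    heterogeneity: float = 1.0
    k: int = 5
    random_draws: int = 1
    svm_C: float = 1.0
    d_max: Optional[int] = 10
    window_s: float = 10.0
    separate_bout_s: float = 60.0
    mixed_bout_s: float = 10.0
    circuits: int = 7
    mixed_total_s: Optional[float] = None
    rod_d: int = 5
    same_cohort_groups: bool = False
    outlier_subject: Optional[int] = None
    outlier_factor: float = 3.0
    sensor1: SensorModel = field(default_factory=default_sensor1)
    sensor2: SensorModel = field(default_factory=default_sensor2)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError("need at least 2 subjects")
        if not 1 <= self.k <= self.n_subjects - 1:
            raise ConfigError("k must satisfy 1 <= k <= n_subjects - 1")
        if self.random_draws < 1:
            raise ConfigError("random_draws must be >= 1")

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        raw = dict(raw)
        for key in ("sensor1", "sensor2"):
            if key in raw and isinstance(raw[key], dict):
                spec = dict(raw[key])
                if "dropout" in spec and isinstance(spec["dropout"], dict):
                    spec["dropout"] = Dropout(**spec["dropout"])
                for tup in ("bias", "scale_error"):
                    if tup in spec:
                        spec[tup] = tuple(spec[tup])
                raw[key] = SensorModel(**spec)
        return cls(**raw)


def separate_scenario(cfg: ExperimentConfig) -> ScenarioSpec:
    return ScenarioSpec("separate", TASKS, bout_s=cfg.separate_bout_s)


def mixed_scenario(cfg: ExperimentConfig) -> ScenarioSpec:
    return ScenarioSpec(
        "mixed",
        MIXED_TASKS,
        bout_s=cfg.mixed_bout_s,
        circuits=cfg.circuits,
        total_s=cfg.mixed_total_s,
    )


def build_cohort(cfg: ExperimentConfig, seed: int) -> list[SubjectProfile]:
    cohort = make_cohort(cfg.n_subjects, cfg.heterogeneity, seed)
    if cfg.outlier_subject is not None:
        boosted = make_cohort(
            cfg.n_subjects, cfg.heterogeneity * cfg.outlier_factor, seed
        )
        cohort[cfg.outlier_subject] = boosted[cfg.outlier_subject]
    return cohort


def session_dataset(
    recording: SensorRecording,
    track: AnnotationTrack,
    window_s: float,
    subject: str,
    scenario: str,
) -> DomainDataset:
    """Raw recording -> m/s^2 -> uniform 32 Hz -> windows -> features."""
    rec = regularize_sampling(convert_units(recording))
    windows = segment(rec, track, window_s, subject=subject, scenario=scenario)
    return windows_to_dataset(windows)


def cohort_datasets(
    cohort: Sequence[SubjectProfile],
    scenario: ScenarioSpec,
    sensors: Sequence[SensorModel],
    window_s: float,
    seed: int,
) -> list[dict[str, DomainDataset]]:
    """Per-subject datasets, one per sensor, all sensors sharing the ideal
    motion of the session (worn simultaneously)."""
    out = []
    subject_seeds = _child_seeds(seed, max(len(cohort), 1))
    for subject, sseed in zip(cohort, subject_seeds):
        ideal_seed, *sensor_seeds = _child_seeds(sseed, 1 + len(sensors))
        ideal, track = simulate_ideal_session(subject, scenario, ideal_seed)
        per_sensor = {}
        for sensor, snseed in zip(sensors, sensor_seeds):
            rec = apply_sensor_model(ideal, sensor, snseed)
            per_sensor[sensor.sensor_id] = session_dataset(
                rec, track, window_s, subject.subject_id, scenario.kind
            )
        out.append(per_sensor)
    return out


def pairwise_rod(
    target: DomainDataset, candidate: DomainDataset, cfg: ExperimentConfig
) -> float:
    """ROD between two domains on their z-scored features.

    Computed at the small fixed dimension ``cfg.rod_d`` (capped by the
    structural limit): with only tens of windows per domain, the deep PCA
    directions are sampling noise and saturate the principal angles for
    every pair alike, so ranking candidates needs the stable leading
    directions only.
    """
    Xt = standardize(target).X
    Xc = standardize(candidate).X
    cap = min(Xc.shape[1], Xc.shape[0] - 1, Xt.shape[0] - 1) // 2
    return rod(Xc, Xt, min(cfg.rod_d, cap)).value


def _pool(datasets: Sequence[DomainDataset]) -> DomainDataset:
    return DomainDataset(
        X=np.vstack([d.X for d in datasets]),
        y=np.concatenate([d.y for d in datasets]),
        subject="+".join(d.subject for d in datasets),
        sensor=datasets[0].sensor,
        scenario=datasets[0].scenario,
    )


def run_cross_sensor(cfg: ExperimentConfig, seed: int) -> list[dict]:
    """Within-subject Sensor 1 -> Sensor 2 transfer, one report pair each."""
    cohort_seed, session_seed = _child_seeds(seed, 2)
    cohort = build_cohort(cfg, cohort_seed)
    datasets = cohort_datasets(
        cohort,
        separate_scenario(cfg),
        [cfg.sensor1, cfg.sensor2],
        cfg.window_s,
        session_seed,
    )
    results = []
    for subject, per_sensor in zip(cohort, datasets):
        source = per_sensor[cfg.sensor1.sensor_id]
        target = per_sensor[cfg.sensor2.sensor_id]
        da = evaluate(target.y, fit_predict_da(source, target, cfg.svm_C, cfg.d_max))
        base = evaluate(target.y, fit_predict_baseline(source, target, cfg.svm_C))
        results.append({"subject": subject.subject_id, "da": da, "baseline": base})
    return results


def _source_selection_run(
    cfg: ExperimentConfig,
    targets: Sequence[DomainDataset],
    candidates_per_target: Sequence[Sequence[DomainDataset]],
    seed: int,
) -> list[dict]:
    """Shared ROD-selection machinery for cross-subject and joint runs."""
    draw_seeds = _child_seeds(seed, max(len(targets), 1))
    results = []
    for target, candidates, dseed in zip(targets, candidates_per_target, draw_seeds):
        rods = np.array([pairwise_rod(target, c, cfg) for c in candidates])
        order = np.argsort(rods, kind="stable")
        selected = order[: cfg.k]
        source = _pool([candidates[i] for i in selected])
        da = evaluate(target.y, fit_predict_da(source, target, cfg.svm_C, cfg.d_max))
        da.rod_mean = float(rods.mean())
        da.rod_selected_mean = float(rods[selected].mean())
        rng = np.random.default_rng(dseed)
        baselines = []
        for _ in range(cfg.random_draws):
            drawn = rng.choice(len(candidates), size=cfg.k, replace=False)
            pool = _pool([candidates[i] for i in drawn])
            baselines.append(
                evaluate(target.y, fit_predict_baseline(pool, target, cfg.svm_C))
            )
        results.append(
            {
                "subject": target.subject,
                "da": da,
                "baseline": baselines,
                "rod_all": rods,
                "rod_all_mean": float(rods.mean()),
                "rod_selected_mean": float(rods[selected].mean()),
                "selected": [candidates[i].subject for i in selected],
            }
        )
    return results


def run_cross_subject(cfg: ExperimentConfig, seed: int) -> list[dict]:
    """Leave-one-subject-out transfer on Sensor 1, ROD-selected sources."""
    cohort_seed, session_seed, select_seed = _child_seeds(seed, 3)
    cohort = build_cohort(cfg, cohort_seed)
    datasets = cohort_datasets(
        cohort, separate_scenario(cfg), [cfg.sensor1], cfg.window_s, session_seed
    )
    flat = [per[cfg.sensor1.sensor_id] for per in datasets]
    targets = flat
    candidates = [[d for j, d in enumerate(flat) if j != i] for i in range(len(flat))]
    return _source_selection_run(cfg, targets, candidates, select_seed)


def run_joint(cfg: ExperimentConfig, seed: int) -> list[dict]:
    """Joint cross-sensor + cross-subject transfer (Sensor 1 -> Sensor 2)."""
    cohort_seed, session_seed, select_seed = _child_seeds(seed, 3)
    cohort = build_cohort(cfg, cohort_seed)
    datasets = cohort_datasets(
        cohort,
        separate_scenario(cfg),
        [cfg.sensor1, cfg.sensor2],
        cfg.window_s,
        session_seed,
    )
    targets = [per[cfg.sensor2.sensor_id] for per in datasets]
    flat1 = [per[cfg.sensor1.sensor_id] for per in datasets]
    candidates = [
        [d for j, d in enumerate(flat1) if j != i] for i in range(len(flat1))
    ]
    return _source_selection_run(cfg, targets, candidates, select_seed)


def run_cross_scenario(cfg: ExperimentConfig, seed: int) -> dict:
    """Pooled separate-scenario source group vs pooled mixed-scenario target
    group, 4-s windows, typing excluded."""
    s1, s2, s3, s4 = _child_seeds(seed, 4)
    group1 = build_cohort(cfg, s1)
    if cfg.same_cohort_groups:
        # Dispersion-only shift: the same subjects perform both scenarios,
        # so the two domains differ only in the task-timeline layout.
        group2 = group1
    else:
        group2 = make_cohort(cfg.n_subjects, cfg.heterogeneity, s2)
    window_s = 4.0
    src_sets = cohort_datasets(
        group1, separate_scenario(cfg), [cfg.sensor1], window_s, s3
    )
    tgt_scenario = mixed_scenario(cfg)
    tgt_sets = []
    subject_seeds = _child_seeds(s4, len(group2))
    for subject, sseed in zip(group2, subject_seeds):
        ideal_seed, sensor_seed = _child_seeds(sseed, 2)
        ideal, track = simulate_ideal_session(subject, tgt_scenario, ideal_seed)
        if "Tp" in track.labels:
            raise DataError("typing present in mixed-scenario annotations")
        rec = apply_sensor_model(ideal, cfg.sensor1, sensor_seed)
        tgt_sets.append(
            session_dataset(rec, track, window_s, subject.subject_id, "mixed")
        )
    source_all = _pool([per[cfg.sensor1.sensor_id] for per in src_sets])
    keep = source_all.y != "Tp"
    source = DomainDataset(
        X=source_all.X[keep], y=source_all.y[keep],
        subject=source_all.subject, sensor=source_all.sensor, scenario="separate",
    )
    target = _pool(tgt_sets)
    vocab = MIXED_TASKS
    da = evaluate(
        target.y, fit_predict_da(source, target, cfg.svm_C, cfg.d_max), vocab
    )
    base = evaluate(target.y, fit_predict_baseline(source, target, cfg.svm_C), vocab)
    return {"da": da, "baseline": base, "task_vocabulary": vocab}


def sensitivity_k(
    cfg: ExperimentConfig, k_range: Sequence[int], seed: int
) -> pd.DataFrame:
    """Mean accuracy and mean defined per-task F1 vs k for both arms.

    The mean F1 averages per-(subject, task) F1 values, skipping undefined
    entries; the skipped count is reported per (k, arm) as
    ``excluded_cases``.
    """
    k_range = list(k_range)
    if not k_range:
        raise ConfigError("k_range must be nonempty")
    if any(not 1 <= k <= cfg.n_subjects - 1 for k in k_range):
        raise ConfigError("k_range must lie within [1, n_subjects - 1]")
    rows = []
    for k in k_range:
        cfg_k = replace(cfg, k=k)
        results = run_cross_subject(cfg_k, seed)
        for arm in ("da", "baseline"):
            f1s: list[float] = []
            excluded = 0
            accs = []
            for res in results:
                reports = [res["da"]] if arm == "da" else res["baseline"]
                for rep in reports:
                    accs.append(rep.accuracy)
                    for f1 in rep.task_f1.values():
                        if f1 is None:
                            excluded += 1
                        else:
                            f1s.append(f1)
            rows.append(
                {
                    "k": k,
                    "arm": arm,
                    "mean_accuracy": float(np.mean(accs)),
                    "mean_task_f1": float(np.mean(f1s)) if f1s else np.nan,
                    "excluded_cases": excluded,
                }
            )
    return pd.DataFrame(rows)
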