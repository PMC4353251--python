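"""End-to-end dual-session workload experiment on synthetic subjects.

For each synthetic subject: generate two recording sessions (the "replaced"
group draws a fresh electrode perturbation for session 2, the "remained"
group re-uses session 1's), extract the 37-feature stream, run the k-fold
session-transfer protocol for every requested classifier kind, direction and
feature subset, with matched empirical nulls, and aggregate per-subject
medians. Everything is reproducible from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import synthgen
from .features import (
    EEG_FEATURES,
    FEATURE_NAMES,
    PERIPHERAL_FEATURES,
    FeatureConfig,
    FeatureFrame,
    assemble_features,
)
from .evaluation import empirical_null, run_kfold
from .learning import (
    KINDS,
    ClassifierConfig,
    FoldSpec,
    make_folds,
    train_classifier,
    zscore_apply,
    zscore_fit,
)
from .saliency import SaliencyReport, aggregate_saliency, ruck_saliency

SUBSETS = ("all", "EEG-only", "peripheral-only")
GROUPS = ("remained", "replaced")


@dataclass
class ExperimentConfig:
    """Shape and seeds of the simulated study.

    The defaults reproduce the study shape: 20 subjects split 10/10 between
    the remained and replaced groups, two sessions of two 900 s trials, k=10
    folds, all four classifier kinds.
    """

    n_subjects: int = 20
    n_replaced: int = 10
    replacement_severity: float = 0.5
    trial_duration_s: float = 900.0
    k: int = 10
    approaches: tuple[str, ...] = KINDS
    feature_subsets: tuple[str, ...] = ("all",)
    directions: tuple[str, ...] = ("S1->S2",)
    master_seed: int = 0
    effect_scale: float = 1.0
    event_mode: str = "jittered"
    with_nulls: bool = True
    collect_saliency: bool = False
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or not 0 <= self.n_replaced <= self.n_subjects:
            raise ValueError("need n_subjects >= 1 and 0 <= n_replaced <= n_subjects")
        if not 0.0 <= self.replacement_severity <= 1.0:
            raise ValueError("replacement_severity must lie in [0, 1]")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        unknown = set(self.approaches) - set(KINDS)
        if unknown:
            raise ValueError(f"unknown approaches: {sorted(unknown)}")
        unknown = set(self.feature_subsets) - set(SUBSETS)
        if unknown:
            raise ValueError(f"unknown feature subsets: {sorted(unknown)}")
        for d in self.directions:
            if d not in ("S1->S2", "S2->S1"):
                raise ValueError(f"unknown direction: {d!r}")


def subset_columns(subset: str, names: tuple[str, ...] = FEATURE_NAMES) -> np.ndarray:
    """Column indices of a named feature subset within the canonical order."""
    if subset == "all":
        keep = names
    elif subset == "EEG-only":
        keep = EEG_FEATURES
    elif subset == "peripheral-only":
        keep = PERIPHERAL_FEATURES
    else:
        raise ValueError(f"unknown feature subset: {subset!r}")
    return np.asarray([names.index(n) for n in keep])


def feature_subset(frame: FeatureFrame, subset: str) -> FeatureFrame:
    """Reduce a FeatureFrame to one of the named subsets."""
    cols = subset_columns(subset, frame.names)
    return FeatureFrame(
        timestamps=frame.timestamps,
        values=frame.values[:, cols],
        names=tuple(frame.names[i] for i in cols),
    )


def session_matrix(
    recording: synthgen.Recording, config: FeatureConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Stacked (X, y) for one session: one row per second, y in {0 low, 1 high}."""
    frames = assemble_features(recording, config)
    xs, ys = [], []
    for frame, workload, _session in frames:
        xs.append(frame.values)
        ys.append(np.full(len(frame.values), 1 if workload == "high" else 0))
    return np.vstack(xs), np.concatenate(ys)


@dataclass
class SubjectData:
    subject: int
    group: str
    x: dict[str, np.ndarray]  # session label -> feature matrix
    y: dict[str, np.ndarray]


def simulate_subject(config: ExperimentConfig, subject: int) -> SubjectData:
    """Generate both sessions for one subject and extract feature matrices."""
    group = "replaced" if subject < config.n_replaced else "remained"
    ss = np.random.SeedSequence([config.master_seed, subject])
    seeds = [int(s % 2**31) for s in ss.generate_state(5)]
    rng = np.random.default_rng(seeds[0])
    low, high = synthgen.default_workload_profiles(config.effect_scale)

    pert_s1 = synthgen.replacement_perturbation(config.replacement_severity, seeds[1])
    if group == "replaced":
        pert_s2 = synthgen.replacement_perturbation(config.replacement_severity, seeds[2])
    else:
        pert_s2 = pert_s1

    x, y = {}, {}
    for label, pert, seed in (("S1", pert_s1, seeds[3]), ("S2", pert_s2, seeds[4])):
        order = ("low", "high") if rng.random() < 0.5 else ("high", "low")
        rec = synthgen.generate_session(
            low,
            high,
            order,
            config.trial_duration_s,
            seed,
            pert,
            session_label=label,
            event_mode=config.event_mode,
        )
        x[label], y[label] = session_matrix(rec, config.features)
    return SubjectData(subject=subject, group=group, x=x, y=y)


def run_subject(
    data: SubjectData, config: ExperimentConfig
) -> tuple[list[dict], list[np.ndarray]]:
    """All fold-level records for one subject, plus per-fold ANN saliencies."""
    rows: list[dict] = []
    saliencies: list[np.ndarray] = []
    ss = np.random.SeedSequence([config.master_seed, data.subject, 1])
    base_seeds = iter(int(s % 2**31) for s in ss.generate_state(512))
    for direction in config.directions:
        learn_label, test_label = direction.split("->")
        y_learn = data.y[learn_label]
        fold_spec = FoldSpec(k=config.k, seed=next(base_seeds))
        folds = make_folds(y_learn, fold_spec)
        for subset in config.feature_subsets:
            cols = subset_columns(subset)
            x_learn = data.x[learn_label][:, cols]
            x_test = data.x[test_label][:, cols]
            y_test = data.y[test_label]
            for kind in config.approaches:
                seed = next(base_seeds)
                records = run_kfold(
                    x_learn,
                    y_learn,
                    x_test,
                    y_test,
                    fold_spec,
                    kind,
                    seed,
                    config.classifier,
                    folds=folds,
                    direction=direction,
                    feature_subset=subset,
                )
                if config.with_nulls:
                    records += empirical_null(
                        x_learn,
                        y_learn,
                        x_test,
                        y_test,
                        fold_spec,
                        kind,
                        next(base_seeds),
                        config.classifier,
                        folds=folds,
                        direction=direction,
                        feature_subset=subset,
                    )
                for rec in records:
                    rows.append(
                        {
                            "subject": data.subject,
                            "group": data.group,
                            "direction": rec.direction,
                            "subset": rec.feature_subset,
                            "kind": rec.kind,
                            "fold": rec.fold,
                            "accuracy": rec.accuracy,
                            "d_prime": rec.d_prime,
                            "nested_accuracy": rec.nested_accuracy,
                            "nested_d_prime": rec.nested_d_prime,
                            "null_flag": rec.null_flag,
                        }
                    )
                if (
                    config.collect_saliency
                    and kind == "ANN"
                    and subset == "all"
                    and direction == config.directions[0]
                ):
                    for learn, _ in folds:
                        norm = zscore_fit(x_learn[learn], fitted_on=learn_label)
                        xn = zscore_apply(norm, x_learn[learn])
                        clf = train_classifier(
                            "ANN", xn, y_learn[learn], config.classifier,
                            next(base_seeds), norm,
                        )
                        saliencies.append(ruck_saliency(clf, xn))
    return rows, saliencies


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full experiment; returns tidy fold-level results, per-subject
    medians, and (optionally) the omnibus saliency report."""
    all_rows: list[dict] = []
    all_sal: list[np.ndarray] = []
    for subject in range(config.n_subjects):
        data = simulate_subject(config, subject)
        rows, sal = run_subject(data, config)
        all_rows.extend(rows)
        all_sal.extend(sal)
    results = pd.DataFrame(all_rows)
    medians = (
        results.groupby(["subject", "group", "direction", "subset", "kind", "null_flag"])[
            ["accuracy", "d_prime"]
        ]
        .median()
        .reset_index()
        .rename(columns={"accuracy": "median_accuracy", "d_prime": "median_d_prime"})
    )
    out: dict = {"results": results, "medians": medians}
    if all_sal:
        out["saliency"] = aggregate_saliency(all_sal, FEATURE_NAMES)
    return out
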