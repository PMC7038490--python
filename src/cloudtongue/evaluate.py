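"""End-to-end fuzzy evaluation: classify a sample's flavor, drop five
cloud droplets from that flavor's descriptor, locate each in the flavor's
word regions, and compose the evaluation sentence."""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .classify import GASVMClassifier
from .cloud import CloudDescriptor2D, DropletCloud, backward_cloud_2d, forward_cloud_2d
from .errors import InvalidConfigError, InvalidValueError, RegistryError
from .preprocessing import TastePCA
from .regions import OUTSIDE, RegionSet, WordFrequencyTable, build_region_set, locate
from .synthetic import (
    PanelConfig,
    SyntheticConfig,
    default_config,
    default_panel_configs,
    generate_panel_votes,
    generate_taste_dataset,
)

__all__ = [
    "FlavorModel",
    "FlavorModelRegistry",
    "FittedPipeline",
    "Evaluation",
    "compose_sentence",
    "evaluate_sample",
    "fit_flavor_models",
    "PipelineConfig",
    "run_pipeline",
    "write_report",
]

N_DROPLETS = 5


@dataclass(frozen=True)
class FlavorModel:
    descriptor: CloudDescriptor2D
    regions: RegionSet


class FlavorModelRegistry(dict):
    """Mapping flavor -> :class:`FlavorModel` with a helpful KeyError."""

    def __missing__(self, key):
        raise RegistryError(f"no flavor model registered for label {key!r}")


@dataclass
class Evaluation:
    """One sample's fuzzy evaluation."""

    sample_id: str
    predicted_flavor: str
    droplets: DropletCloud
    region_indices: list[int]
    words: list[str]
    sentence: str

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "predicted_flavor": self.predicted_flavor,
            "droplets": [
                {"x1": d.x1, "x2": d.x2, "mu": d.mu} for d in self.droplets
            ],
            "region_indices": list(self.region_indices),
            "words": list(self.words),
            "sentence": self.sentence,
        }


def compose_sentence(words: Sequence[str]) -> str:
    """Join the selected words into the fixed evaluation sentence form."""
    if not words:
        raise InvalidValueError("cannot compose a sentence from zero words")
    return "This liquor is " + ", ".join(str(w).lower() for w in words)


def evaluate_sample(
    features,
    classifier,
    registry: Mapping[str, FlavorModel],
    seed: int | np.random.Generator | None = None,
    sample_id: str = "",
    outside: str = "outermost",
) -> Evaluation:
    """Fuzzy-evaluate one 10-channel feature vector.

    The classifier picks the flavor; five droplets are generated from
    that flavor's cloud descriptor (not from the sample's own
    coordinates) and located in the flavor's word regions.  Unique words
    are reported centre -> periphery.  Droplets beyond the outer cap are
    assigned the outermost word (``outside="outermost"``, default) or
    redrawn until inside (``outside="resample"``).
    """
    if outside not in ("outermost", "resample"):
        raise InvalidValueError(f"unknown outside policy {outside!r}")
    x = np.asarray(features, dtype=float).reshape(1, -1)
    flavor = str(classifier.predict(x)[0])
    try:
        model = registry[flavor]
    except KeyError:
        raise RegistryError(f"no flavor model registered for label {flavor!r}")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    droplets = forward_cloud_2d(model.descriptor, N_DROPLETS, rng)
    if outside == "resample":
        for _ in range(1000):
            idx = np.array(
                [locate(model.regions, (x1, x2)) for x1, x2 in droplets.points]
            )
            out = idx == OUTSIDE
            if not out.any():
                break
            redraw = forward_cloud_2d(model.descriptor, int(out.sum()), rng)
            droplets.x1[out] = redraw.x1
            droplets.x2[out] = redraw.x2
            droplets.mu[out] = redraw.mu

    n_regions = len(model.regions.multipliers)
    indices = []
    for x1, x2 in droplets.points:
        i = locate(model.regions, (x1, x2))
        indices.append(n_regions if i == OUTSIDE else i)
    words = []
    for i in sorted(set(indices)):  # centre -> periphery, de-duplicated
        word = model.regions.words[i - 1]
        if word not in words:
            words.append(word)
    return Evaluation(
        sample_id=sample_id,
        predicted_flavor=flavor,
        droplets=droplets,
        region_indices=indices,
        words=words,
        sentence=compose_sentence(words),
    )


@dataclass
class PipelineConfig:
    """Configuration of the full train-and-evaluate pipeline.

    ``data`` may be a path to a CSV with columns
    ``sample_id,flavor,ch01..ch10`` or ``None`` to simulate with
    ``synthetic_config``.  ``train_fraction`` 0.7 reproduces the 14/6
    per-flavor split.
    """

    data: str | None = None
    synthetic_config: SyntheticConfig | None = None
    panel_configs: Mapping[str, PanelConfig] | None = None
    train_fraction: float = 0.7
    n_evaluated_per_flavor: int = 2
    cap: float = 3.0
    ga_pop_size: int = 20
    ga_max_generations: int = 20
    ga_cv_folds: int = 5
    outside: str = "outermost"

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise InvalidConfigError("train_fraction must be in (0, 1)")


def _load_table(config: PipelineConfig, seed: int) -> pd.DataFrame:
    if config.data is not None:
        table = pd.read_csv(config.data)
        missing = {"sample_id", "flavor"} - set(table.columns)
        if missing:
            raise InvalidConfigError(f"data table missing columns: {sorted(missing)}")
        return table
    synth = config.synthetic_config or default_config()
    return generate_taste_dataset(synth, seed)


@dataclass
class FittedPipeline:
    """Trained classifier + PCA + per-flavor cloud models."""

    classifier: GASVMClassifier
    pca: TastePCA
    registry: FlavorModelRegistry
    vote_tables: dict[str, WordFrequencyTable]


def fit_flavor_models(
    X_train,
    y_train,
    *,
    panel_configs: Mapping[str, PanelConfig] | None = None,
    cap: float = 3.0,
    ga_pop_size: int = 20,
    ga_max_generations: int = 20,
    ga_cv_folds: int = 5,
    seed: int = 0,
) -> FittedPipeline:
    """Fit everything the evaluator needs on a training table.

    GA-SVM on the 10-channel features; PCA (2 components) on the same
    training rows; per-flavor backward cloud on the training projections;
    word regions from a seeded panel vote draw per flavor.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    flavors = sorted(set(y_train))
    if len(flavors) < 2:
        raise InvalidConfigError(
            f"classification needs >= 2 flavor classes; got {flavors}"
        )
    ss = np.random.SeedSequence(seed)
    s_ga, s_panel = (int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(2))
    clf = GASVMClassifier(
        pop_size=ga_pop_size,
        max_generations=ga_max_generations,
        cv_folds=ga_cv_folds,
        random_state=s_ga,
    ).fit(X_train, y_train)
    pca = TastePCA(n_components=2).fit(X_train)
    scores_train = pca.transform(X_train)

    panel_configs = panel_configs or default_panel_configs()
    registry = FlavorModelRegistry()
    vote_tables: dict[str, WordFrequencyTable] = {}
    for flavor, child in zip(flavors, np.random.SeedSequence(s_panel).spawn(len(flavors))):
        mask = y_train == flavor
        desc = backward_cloud_2d(scores_train[mask])
        if flavor not in panel_configs:
            raise InvalidConfigError(f"no panel config for flavor {flavor!r}")
        votes = generate_panel_votes(
            panel_configs[flavor], int(child.generate_state(1)[0] % (2**31 - 1))
        )
        vote_tables[flavor] = votes
        registry[flavor] = FlavorModel(desc, build_region_set(desc, votes, cap))
    return FittedPipeline(clf, pca, registry, vote_tables)


def run_pipeline(config: PipelineConfig, seed: int) -> dict:
    """Train the classifier, build flavor cloud models, evaluate held-out
    samples, and return a JSON-serialisable report.

    Steps: stratified train/test split of the feature table; GA-SVM fit on
    the 10-channel training features; PCA fit on the training split only;
    backward cloud on the training projections per flavor; region sets
    from the panel vote tables; fuzzy evaluation of held-out samples.
    """
    ss = np.random.SeedSequence(seed)
    s_data, s_split, s_fit, s_eval = (
        int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(4)
    )
    table = _load_table(config, s_data)
    feature_cols = [c for c in table.columns if c.startswith("ch")]
    X = table[feature_cols].to_numpy(dtype=float)
    y = table["flavor"].to_numpy()
    flavors = sorted(set(y))
    if len(flavors) < 2:
        raise InvalidConfigError(
            f"classification needs >= 2 flavor classes; got {flavors}"
        )

    idx_train, idx_test = train_test_split(
        np.arange(len(y)),
        train_size=config.train_fraction,
        stratify=y,
        random_state=s_split,
    )
    fitted = fit_flavor_models(
        X[idx_train],
        y[idx_train],
        panel_configs=config.panel_configs,
        cap=config.cap,
        ga_pop_size=config.ga_pop_size,
        ga_max_generations=config.ga_max_generations,
        ga_cv_folds=config.ga_cv_folds,
        seed=s_fit,
    )
    clf, pca, registry = fitted.classifier, fitted.pca, fitted.registry
    vote_tables = fitted.vote_tables
    descriptors = {f: registry[f].descriptor for f in flavors}
    test_pred = clf.predict(X[idx_test])
    accuracy = 100.0 * float(np.mean(test_pred == y[idx_test]))

    # pick n held-out samples per flavor for the worked evaluation table
    eval_rng = np.random.default_rng(s_eval)
    chosen: list[int] = []
    for flavor in flavors:
        pool = idx_test[y[idx_test] == flavor]
        take = min(config.n_evaluated_per_flavor, pool.size)
        chosen.extend(eval_rng.choice(pool, size=take, replace=False))
    evaluations = []
    for j, i in enumerate(chosen):
        ev = evaluate_sample(
            X[i],
            clf,
            registry,
            seed=np.random.default_rng([s_eval, j]),
            sample_id=str(table["sample_id"].iloc[i]),
            outside=config.outside,
        )
        d = ev.to_dict()
        d["actual_flavor"] = str(y[i])
        evaluations.append(d)

    return {
        "seed": seed,
        "n_train": int(idx_train.size),
        "n_test": int(idx_test.size),
        "test_accuracy_percent": accuracy,
        "best_params": {"c": clf.best_params_.c, "g": clf.best_params_.g},
        "best_cv_fitness_percent": clf.best_fitness_,
        "contribution_rates": pca.contribution_rates_.tolist(),
        "descriptors": {f: d.to_dict() for f, d in descriptors.items()},
        "vote_counts": {
            f: {w: c for w, c in t.entries} for f, t in vote_tables.items()
        },
        "regions": {f: registry[f].regions.to_dict() for f in flavors},
        "evaluations": evaluations,
    }


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
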