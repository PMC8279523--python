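"""The deep methylation clock: architecture spec, saliency-based feature
selection, grid search and fivefold cross-validated training.

The protocol is two-stage.  Stage 1 trains a wide network on the full
probe panel and scores every probe by the 95th percentile (linear
interpolation) of its absolute output gradients across samples; the top-k
probes are fixed.  Stage 2 grid-searches architecture/regularization on
the reduced panel by k-fold cross-validated MAE, then trains the final
model on all samples with the winning configuration.  The winning
configuration of the reference run — four hidden layers of 512 ELU units,
Adam at 1e-4, 30% dropout, L2 1e-3, MAE loss, five folds — is the default
``NetworkSpec``.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ..errors import ConfigurationError, HarmonizationError, ValidationError
from ..meth_io import BetaMatrix
from .nn import MLP, train_mlp

__all__ = [
    "NetworkSpec",
    "saliency_importance",
    "DeepClockModel",
    "build_network",
    "train",
    "gradient_importance",
    "select_top_features",
    "grid_search",
    "stratified_age_folds",
    "fit_deep_clock",
    "predict_deep",
    "save_model_bundle",
    "load_model_bundle",
]

DEFAULT_GRID = {
    "n_hidden_layers": [2, 3, 4, 5],
    "neurons_per_layer": [128, 256, 512, 1024],
    "activation": ["elu", "relu", "selu"],
    "optimizer": ["adam", "amsgrad", "nadam"],
    "learning_rate": [1e-3, 1e-4],
    "dropout_rate": [0.15, 0.3, 0.5],
    "l2_coefficient": [1e-6, 1e-4, 1e-3, 1e-2, 1e-1],
}


@dataclass(frozen=True)
class NetworkSpec:
    """Hyperparameters of one feed-forward age regressor.

    Ranges mirror the grid the clock was tuned over; the loss is fixed to
    MAE.  ``epochs``/``batch_size`` bound the training run; early stopping
    (10% seeded holdout, patience 20, restore best) usually ends sooner.
    """

    n_hidden_layers: int = 4
    neurons_per_layer: int = 512
    activation: str = "elu"
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    dropout_rate: float = 0.30
    l2_coefficient: float = 1e-3
    loss: str = "mae"
    epochs: int = 300
    batch_size: int = 64
    seed: int = 0
    #: dropout applied to the input layer during training; used in the
    #: saliency stage to spread usage across redundant correlated probes
    input_dropout: float = 0.0

    def __post_init__(self) -> None:
        checks = [
            ("n_hidden_layers", 2 <= self.n_hidden_layers <= 5, "must be in [2, 5]"),
            ("neurons_per_layer", 128 <= self.neurons_per_layer <= 1024, "must be in [128, 1024]"),
            ("activation", self.activation in {"elu", "relu", "selu"}, "must be elu|relu|selu"),
            ("optimizer", self.optimizer in {"adam", "amsgrad", "nadam"}, "must be adam|amsgrad|nadam"),
            ("learning_rate", self.learning_rate > 0, "must be positive"),
            ("dropout_rate", 0.15 <= self.dropout_rate <= 0.5, "must be in [0.15, 0.5]"),
            ("input_dropout", 0.0 <= self.input_dropout < 0.9, "must be in [0, 0.9)"),
            ("l2_coefficient", 1e-6 <= self.l2_coefficient <= 0.1, "must be in [1e-6, 0.1]"),
            ("loss", self.loss == "mae", "is fixed to 'mae'"),
            ("epochs", self.epochs >= 0, "must be >= 0"),
            ("batch_size", self.batch_size >= 1, "must be >= 1"),
        ]
        for name, ok, msg in checks:
            if not ok:
                raise ConfigurationError(f"NetworkSpec.{name} {msg} (got {getattr(self, name)!r})")


@dataclass
class DeepClockModel:
    """A trained deep clock: selected probes + network + training record."""

    spec: NetworkSpec
    selected_probes: list[str]
    network: MLP
    training_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.selected_probes)) != len(self.selected_probes):
            raise ValidationError("selected_probes must be unique")
        if self.network.input_width != len(self.selected_probes):
            raise ValidationError("network input width != number of selected probes")


def build_network(spec: NetworkSpec, input_width: int) -> MLP:
    """Instantiate the untrained network for a spec (seeded init)."""
    if input_width < 1:
        raise ConfigurationError("input_width must be >= 1")
    sizes = [input_width] + [spec.neurons_per_layer] * spec.n_hidden_layers + [1]
    return MLP(
        sizes,
        activation=spec.activation,
        dropout=spec.dropout_rate,
        l2=spec.l2_coefficient,
        seed=spec.seed,
        input_dropout=spec.input_dropout,
    )


def train(model: MLP, matrix: BetaMatrix, ages, spec: NetworkSpec, val_fraction=0.1):
    """Train a network on a beta matrix against ages (years); returns the
    per-epoch MAE loss trace."""
    X = matrix.to_feature_array()
    return train_mlp(
        model,
        X,
        np.asarray(ages, dtype=float),
        epochs=spec.epochs,
        batch_size=spec.batch_size,
        optimizer=spec.optimizer,
        learning_rate=spec.learning_rate,
        seed=spec.seed,
        val_fraction=val_fraction,
    )


def gradient_importance(model: MLP, matrix: BetaMatrix) -> pd.Series:
    """Score each probe by the 95th percentile of its absolute output
    gradients across samples (dropout disabled).

    The per-sample gradient d(age)/d(beta_probe) is exact backprop, not a
    finite-difference estimate; the percentile uses linear interpolation
    between order statistics.
    """
    if model.input_width != matrix.shape[0]:
        raise ValidationError(
            f"matrix has {matrix.shape[0]} probes but network expects {model.input_width}"
        )
    grads = model.input_gradients(matrix.to_feature_array())
    scores = np.percentile(np.abs(grads), 95.0, axis=0)
    return pd.Series(scores, index=matrix.probe_ids, name="importance")


def select_top_features(table: pd.Series, k: int) -> list[str]:
    """The k most important probes, descending score, ties by ascending ID."""
    if k > len(table):
        raise ValidationError(f"k={k} exceeds table size {len(table)}")
    order = sorted(table.items(), key=lambda kv: (-kv[1], kv[0]))
    return [pid for pid, _ in order[:k]]


def stratified_age_folds(ages, n_folds: int, seed: int) -> np.ndarray:
    """Seeded age-decile-stratified fold assignment (one fold id per sample)."""
    ages = np.asarray(ages, dtype=float)
    n = len(ages)
    if n < n_folds:
        raise ValidationError("fewer samples than folds")
    rng = np.random.default_rng(seed)
    deciles = pd.qcut(ages, q=min(10, max(1, n // n_folds)), labels=False, duplicates="drop")
    folds = np.empty(n, dtype=int)
    offset = 0
    for d in np.unique(deciles):
        idx = np.flatnonzero(deciles == d)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[i] = (j + offset) % n_folds
        offset += len(idx)  # rotate so small strata do not pile into fold 0
    return folds


def grid_search(
    matrix: BetaMatrix,
    ages,
    grid: dict | None = None,
    budget: int | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    base_spec: NetworkSpec = NetworkSpec(),
    search_epochs: int | None = None,
):
    """Pick the spec minimizing cv_folds-fold CV mean MAE.

    ``grid`` maps NetworkSpec field names to candidate values; ``budget``
    evaluates a seeded uniform subsample of the full cartesian product
    (pass None for the full grid).  ``search_epochs`` caps the epoch
    budget during screening (the winner is retrained at full budget by
    the caller); None screens at each spec's own epoch count.  Returns
    ``(best_spec, score_table)`` with one row per evaluated configuration.
    """
    grid = dict(grid) if grid else dict(DEFAULT_GRID)
    if any(len(v) == 0 for v in grid.values()) or not grid:
        raise ConfigurationError("grid must be non-empty")
    keys = sorted(grid)
    combos = list(itertools.product(*(grid[k] for k in keys)))
    rng = np.random.default_rng(seed)
    if budget is not None:
        if budget < 1:
            raise ConfigurationError("budget must be >= 1")
        if budget < len(combos):
            pick = rng.choice(len(combos), size=budget, replace=False)
            combos = [combos[i] for i in sorted(pick)]
    ages = np.asarray(ages, dtype=float)
    folds = stratified_age_folds(ages, cv_folds, seed)
    X = matrix.to_feature_array()

    rows = []
    best_spec, best_mae = None, np.inf
    for combo in combos:
        spec = replace(base_spec, **dict(zip(keys, combo)), seed=seed)
        n_epochs = spec.epochs if search_epochs is None else min(spec.epochs, search_epochs)
        abs_err = np.empty(len(ages))
        for f in range(cv_folds):
            tr, va = folds != f, folds == f
            net = build_network(replace(spec, seed=seed + f), X.shape[1])
            train_mlp(
                net, X[tr], ages[tr],
                epochs=n_epochs, batch_size=spec.batch_size,
                optimizer=spec.optimizer, learning_rate=spec.learning_rate,
                seed=spec.seed + f,
            )
            abs_err[va] = np.abs(net.predict(X[va]) - ages[va])
        mae = float(abs_err.mean())
        rows.append({**dict(zip(keys, combo)), "cv_mae": mae})
        if mae < best_mae:
            best_mae, best_spec = mae, spec
    return best_spec, pd.DataFrame(rows)


def saliency_importance(
    matrix: BetaMatrix,
    ages,
    spec: NetworkSpec | None = None,
    ensemble: int = 3,
    seed: int = 0,
) -> pd.Series:
    """Ensemble-averaged gradient-modulus importance over the full panel.

    Trains ``ensemble`` independently seeded networks and averages their
    per-probe importance scores.  The default spec adds input dropout
    (0.5) and stronger L2 (1e-2) on top of the reference architecture:
    input dropout forces each net to spread usage across redundant
    correlated CpGs instead of memorizing a sparse subset, and averaging
    across seeds cancels the saliency that noise probes pick up from any
    single fit — both are needed for a stable ranking.
    """
    if ensemble < 1:
        raise ConfigurationError("ensemble must be >= 1")
    if spec is None:
        spec = NetworkSpec(seed=seed, epochs=150, input_dropout=0.5, l2_coefficient=1e-2)
    ages = np.asarray(ages, dtype=float)
    total: pd.Series | None = None
    for i in range(ensemble):
        s = replace(spec, seed=spec.seed + i)
        net = build_network(s, matrix.shape[0])
        train(net, matrix, ages, s)
        imp = gradient_importance(net, matrix)
        total = imp if total is None else total + imp
    return total / ensemble


def deep_cv_predictions(
    matrix: BetaMatrix,
    ages,
    spec: NetworkSpec,
    cv_folds: int = 5,
    seed: int = 0,
) -> pd.Series:
    """Out-of-fold predictions for one spec under seeded stratified CV.

    Useful for head-to-head accuracy comparisons against other clock
    families on identical fold assignments (pair with
    ``stratified_age_folds(ages, cv_folds, seed)``).
    """
    ages = np.asarray(ages, dtype=float)
    folds = stratified_age_folds(ages, cv_folds, seed)
    X = matrix.to_feature_array()
    oof = np.empty(len(ages))
    for f in range(cv_folds):
        tr, va = folds != f, folds == f
        net = build_network(replace(spec, seed=seed + f), X.shape[1])
        train_mlp(
            net, X[tr], ages[tr],
            epochs=spec.epochs, batch_size=spec.batch_size,
            optimizer=spec.optimizer, learning_rate=spec.learning_rate,
            seed=seed + f,
        )
        oof[va] = net.predict(X[va])
    return pd.Series(oof, index=matrix.sample_ids, name="predicted_age")


def fit_deep_clock(
    matrix: BetaMatrix,
    meta: pd.DataFrame,
    k: int = 1000,
    grid: dict | None = None,
    budget: int | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    stage1_spec: NetworkSpec | None = None,
    stage1_ensemble: int = 3,
    grid_search_epochs: int | None = 60,
):
    """Run the full two-stage protocol; returns (DeepClockModel, oof_preds).

    Stage 1 scores every probe by ensemble-averaged gradient-modulus
    importance (:func:`saliency_importance`) and fixes the top ``k``.
    Stage 2 grid-searches on the
    reduced panel (screening each candidate at ``grid_search_epochs``
    epochs), trains the final model on all samples with the winning spec
    at the full epoch budget, and reports out-of-fold predictions (every
    sample predicted exactly once by a model that never saw it).
    """
    if k > matrix.shape[0]:
        raise ValidationError(f"k={k} exceeds probe count {matrix.shape[0]}")
    ages = meta.set_index("sample_id").loc[matrix.sample_ids, "age"].to_numpy(float)
    if len(ages) < 2 * cv_folds:
        raise ValidationError(f"need >= {2 * cv_folds} samples")

    importance = saliency_importance(
        matrix, ages, spec=stage1_spec, ensemble=stage1_ensemble, seed=seed
    )
    selected = select_top_features(importance, k)
    reduced = BetaMatrix(matrix.values.loc[selected])

    # grid candidates are final-model fits: saliency-stage input dropout off
    base = stage1_spec if stage1_spec is not None else NetworkSpec(seed=seed, epochs=150)
    best_spec, score_table = grid_search(
        reduced, ages, grid=grid, budget=budget, cv_folds=cv_folds, seed=seed,
        base_spec=replace(base, seed=seed, input_dropout=0.0),
        search_epochs=grid_search_epochs,
    )

    folds = stratified_age_folds(ages, cv_folds, seed)
    X = reduced.to_feature_array()
    oof = np.empty(len(ages))
    fold_metrics = []
    for f in range(cv_folds):
        tr, va = folds != f, folds == f
        net = build_network(replace(best_spec, seed=seed + 100 + f), X.shape[1])
        train_mlp(
            net, X[tr], ages[tr],
            epochs=best_spec.epochs, batch_size=best_spec.batch_size,
            optimizer=best_spec.optimizer, learning_rate=best_spec.learning_rate,
            seed=seed + 100 + f,
        )
        oof[va] = net.predict(X[va])
        err = np.abs(oof[va] - ages[va])
        fold_metrics.append({"fold": f, "n_val": int(va.sum()),
                             "mae": float(err.mean()), "medae": float(np.median(err))})

    final_net = build_network(replace(best_spec, seed=seed + 999), X.shape[1])
    final_trace = train_mlp(
        final_net, X, ages,
        epochs=best_spec.epochs, batch_size=best_spec.batch_size,
        optimizer=best_spec.optimizer, learning_rate=best_spec.learning_rate,
        seed=seed + 999,
    )
    model = DeepClockModel(
        spec=best_spec,
        selected_probes=selected,
        network=final_net,
        training_metadata={
            "fold_assignment": {s: int(f) for s, f in zip(matrix.sample_ids, folds)},
            "fold_metrics": fold_metrics,
            "grid_scores": score_table.to_dict(orient="records"),
            "final_epochs_run": len(final_trace),
            "seed": seed,
            "stage1_ensemble": stage1_ensemble,
            "importance_top": {p: float(importance[p]) for p in selected[:50]},
        },
    )
    oof_preds = pd.Series(oof, index=matrix.sample_ids, name="predicted_age")
    return model, oof_preds


def predict_deep(model: DeepClockModel, matrix: BetaMatrix) -> pd.Series:
    """Predict ages; the matrix must carry exactly the model's probe panel."""
    if matrix.probe_ids != model.selected_probes:
        raise HarmonizationError(
            "matrix probes do not match the model panel; run "
            "harmonize_to_panel(matrix, model.selected_probes) first"
        )
    preds = model.network.predict(matrix.to_feature_array())
    return pd.Series(preds, index=matrix.sample_ids, name="predicted_age")


# -- model bundle IO --------------------------------------------------------

def save_model_bundle(model: DeepClockModel, out_dir) -> None:
    """Write spec.yaml, selected_probes.txt, weights.npz, metadata.json."""
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "spec.yaml", "w") as fh:
        yaml.safe_dump(asdict(model.spec), fh)
    (out / "selected_probes.txt").write_text("\n".join(model.selected_probes) + "\n")
    arrays = {f"W{i}": w for i, w in enumerate(model.network.W)}
    arrays.update({f"b{i}": b for i, b in enumerate(model.network.b)})
    arrays["input_center"] = model.network.input_center
    np.savez(out / "weights.npz", **arrays)
    with open(out / "metadata.json", "w") as fh:
        json.dump(model.training_metadata, fh, indent=1)


def load_model_bundle(in_dir) -> DeepClockModel:
    import yaml

    src = Path(in_dir)
    with open(src / "spec.yaml") as fh:
        spec = NetworkSpec(**yaml.safe_load(fh))
    probes = (src / "selected_probes.txt").read_text().split()
    net = build_network(spec, len(probes))
    with np.load(src / "weights.npz") as data:
        net.W = [data[f"W{i}"] for i in range(len(net.W))]
        net.b = [data[f"b{i}"] for i in range(len(net.b))]
        if "input_center" in data:
            net.input_center = data["input_center"]
    meta = json.loads((src / "metadata.json").read_text()) if (src / "metadata.json").exists() else {}
    return DeepClockModel(spec=spec, selected_probes=probes, network=net, training_metadata=meta)
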