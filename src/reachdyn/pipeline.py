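"""End-to-end orchestration: corpus generation, training, evaluation.

A single global seed fans out to per-stage seeds through a documented
derivation (CRC-32 of the stage name XOR'd with the seed, reduced mod 2^31),
so every stage is individually reproducible.
"""

from __future__ import annotations

import itertools
import warnings
import zlib

import numpy as np

from .arm_model import ArmModel, build_default_arm_model
from .dataset import (
    MovementDataset,
    NormalizationStats,
    add_peak_to_peak_noise,
    apply_zscore,
    assemble_dataset,
    channel_ranges,
    fit_zscore,
    invert_zscore,
    make_sequence_windows,
    split_dataset,
)
from .dynamics import compute_trajectory_torques
from .networks import (
    SurrogateSpec,
    build_surrogate,
    predict_windows,
    train_surrogate,
)
from .trajectory import (
    DEFAULT_DT,
    DEFAULT_DURATIONS,
    build_workspace_grid,
    enumerate_movements,
    synthesize_movement,
)

__all__ = [
    "derive_seed",
    "generate_corpus",
    "prepare_split_arrays",
    "evaluate_rmse_windows",
    "reduced_gru_experiment",
]


def derive_seed(seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed and the stage name."""
    return (zlib.crc32(stage.encode()) ^ (seed * 2654435761)) % (2**31)


def _parse_grid_shape(shape) -> tuple[int, int, int]:
    if isinstance(shape, str):
        parts = tuple(int(p) for p in shape.lower().split("x"))
    else:
        parts = tuple(int(p) for p in shape)
    if len(parts) != 3 or any(p not in (1, 2, 3) for p in parts):
        raise ValueError("grid shape must be three factors from {1,2,3}, e.g. '3x3x3'")
    return parts


_SUBGRID_LEVELS = {1: (1,), 2: (0, 2), 3: (0, 1, 2)}


def generate_corpus(
    model: ArmModel | None = None,
    grid_shape="3x3x3",
    durations=DEFAULT_DURATIONS,
    dt: float = DEFAULT_DT,
    manifest_extra: dict | None = None,
) -> MovementDataset:
    """Build the workspace grid, synthesize every movement, compute torques.

    ``grid_shape`` selects a subgrid of the 3x3x3 vertex grid per axis
    (``"2x2x2"`` keeps the corner vertices). The corpus is deterministic:
    grid construction, IK and inverse dynamics involve no randomness.
    """
    if model is None:
        model = build_default_arm_model()
    grid = build_workspace_grid(model)
    shape = _parse_grid_shape(grid_shape)
    keep = set(itertools.product(*(_SUBGRID_LEVELS[s] for s in shape)))
    grid = [v for v in grid if v.index in keep]
    specs = enumerate_movements(grid, durations=durations, dt=dt)
    trajectories, torques, ids, durs = [], [], [], []
    for spec in specs:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # benign range-of-motion excursions
            jt = synthesize_movement(model, spec)
        trajectories.append(jt)
        torques.append(compute_trajectory_torques(model, jt))
        a, b = spec.start.index, spec.end.index
        ids.append(f"v{a[0]}{a[1]}{a[2]}-v{b[0]}{b[1]}{b[2]}-T{spec.duration:g}")
        durs.append(spec.duration)
    return assemble_dataset(
        trajectories,
        torques,
        dynamic_dofs=model.dynamic_dofs,
        traj_ids=ids,
        durations=durs,
        manifest_extra={
            "grid_shape": "x".join(map(str, shape)),
            "n_vertices": len(grid),
            "dt": dt,
            "model_hash": model.hash(),
            **(manifest_extra or {}),
        },
    )


def prepare_split_arrays(
    dataset: MovementDataset,
    feature_stats: NormalizationStats,
    target_stats: NormalizationStats,
    split: str,
    features_by_traj: dict | None = None,
):
    """Per-trajectory (X, Y) float32 pairs with normalized features/targets."""
    pairs = []
    for rec in dataset.records(split):
        feats = (
            features_by_traj[rec.traj_id]
            if features_by_traj is not None
            else dataset.reduced_features(rec)
        )
        X = apply_zscore(feats, feature_stats).astype(np.float32)
        Y = apply_zscore(rec.tau, target_stats).astype(np.float32)
        pairs.append((X, Y))
    return pairs


def evaluate_rmse_windows(
    net,
    dataset: MovementDataset,
    feature_stats: NormalizationStats,
    target_stats: NormalizationStats,
    split: str = "test",
    L: int = 100,
    stride: int = 1,
    features_by_traj: dict | None = None,
) -> tuple[float, int]:
    """De-normalized pooled torque RMSE with L-sample input windows.

    Returns (rmse_nm, n_windows).
    """
    X, Y, _ = make_sequence_windows(
        dataset, L, stride=stride, split=split,
        feature_stats=feature_stats, features_by_traj=features_by_traj,
    )
    pred = invert_zscore(predict_windows(net, X), target_stats)
    rmse = float(np.sqrt(np.mean((pred - Y) ** 2)))
    return rmse, X.shape[0]


def noisy_test_features(
    dataset: MovementDataset, fraction: float, seed: int
) -> dict[str, np.ndarray]:
    """Raw reduced features of the test split, perturbed channel-wise with
    Gaussian noise of sd = fraction x (channel peak-to-peak range over the
    test split). Targets are untouched."""
    ranges = channel_ranges(dataset, split="test")
    out = {}
    for k, rec in enumerate(dataset.records("test")):
        feats = dataset.reduced_features(rec)
        out[rec.traj_id] = add_peak_to_peak_noise(
            feats, fraction, ranges, seed=derive_seed(seed, f"noise/{rec.traj_id}")
        )
    return out


def reduced_gru_experiment(
    seed: int = 1,
    grid_shape="2x2x2",
    durations=(0.5, 1.0),
    epochs: int = 100,
    patience: int = 25,
    noise_fractions=(0.01, 0.05),
    verbose: bool = False,
) -> dict:
    """The reduced-scale surrogate study: train GRU-1-115 and evaluate.

    Generates the corner-vertex corpus at 0.5/1.0 s, splits 71/15/14 by
    trajectory (stratified by duration), trains a one-layer 115-unit GRU at
    learning rate 5e-4 (Adam, early stopping) in stateful per-step mode, and
    reports de-normalized pooled test RMSE with 100-sample windows, clean
    and under peak-to-peak input noise.
    """
    dataset = generate_corpus(grid_shape=grid_shape, durations=durations)
    dataset = split_dataset(dataset, seed=derive_seed(seed, "split"))
    feature_stats = fit_zscore(dataset, "features")
    target_stats = fit_zscore(dataset, "tau")
    train_pairs = prepare_split_arrays(dataset, feature_stats, target_stats, "train")
    val_pairs = prepare_split_arrays(dataset, feature_stats, target_stats, "val")
    spec = SurrogateSpec(
        arch="gru", layers=1, hidden_size=115, learning_rate=5e-4,
        seed=derive_seed(seed, "init"), input_dim=dataset.n_features,
    )
    net = build_surrogate(spec)
    net, hist = train_surrogate(
        net, train_pairs, val_pairs, epochs=epochs, patience=patience,
        seed=derive_seed(seed, "shuffle"), mode="stateful", verbose=verbose,
    )
    rmse_clean, n_windows = evaluate_rmse_windows(
        net, dataset, feature_stats, target_stats
    )
    result = {
        "dataset": dataset,
        "net": net,
        "history": hist,
        "feature_stats": feature_stats,
        "target_stats": target_stats,
        "rmse_clean": rmse_clean,
        "n_test_windows": n_windows,
        "rmse_noisy": {},
    }
    for frac in noise_fractions:
        feats = noisy_test_features(dataset, frac, seed)
        rmse, _ = evaluate_rmse_windows(
            net, dataset, feature_stats, target_stats, features_by_traj=feats
        )
        result["rmse_noisy"][frac] = rmse
    return result
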