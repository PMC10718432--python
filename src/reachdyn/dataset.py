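"""Dataset assembly: feature reduction, splits, normalization, windowing, noise.

A movement corpus is a list of trajectories, each carrying the full state
series [q, q', q'', tau] at 1 ms. For network training the 69 kinematic
values per sample are reduced by dropping the identically-zero velocity and
acceleration channels of the static DOFs, leaving 29 features by default
(23 q + 3 dynamic q' + 3 dynamic q''). Splits are assigned per whole
trajectory (never per sample, to avoid temporal leakage), stratified by
movement duration. Torque targets are z-scored with statistics fitted on the
training split only, and predictions are de-normalized before any error is
reported in N m.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrajectoryRecord",
    "MovementDataset",
    "NormalizationStats",
    "assemble_dataset",
    "split_dataset",
    "fit_zscore",
    "apply_zscore",
    "invert_zscore",
    "make_sequence_windows",
    "add_peak_to_peak_noise",
    "channel_ranges",
]

SPLIT_NAMES = ("train", "val", "test")


@dataclass
class TrajectoryRecord:
    """One movement's aligned kinematics and kinetics."""

    traj_id: str
    duration: float
    dt: float
    times: np.ndarray
    q: np.ndarray  # (T, n)
    qd: np.ndarray
    qdd: np.ndarray
    tau: np.ndarray  # (T, n)
    split: str | None = None

    @property
    def n_samples(self) -> int:
        return self.q.shape[0]


@dataclass
class MovementDataset:
    """Corpus of trajectories + feature-reduction config + manifest."""

    trajectories: list[TrajectoryRecord]
    dynamic_dofs: np.ndarray  # indices of dynamic DOFs in the q layout
    manifest: dict = field(default_factory=dict)

    @property
    def n_dofs(self) -> int:
        return self.trajectories[0].q.shape[1]

    @property
    def n_features(self) -> int:
        return self.n_dofs + 2 * len(self.dynamic_dofs)

    def reduced_features(self, rec: TrajectoryRecord) -> np.ndarray:
        """Per-sample reduced kinematic vector: [q (all), q' and q'' of the
        dynamic DOFs only]. With every DOF dynamic this is the full 3n."""
        dyn = self.dynamic_dofs
        return np.concatenate([rec.q, rec.qd[:, dyn], rec.qdd[:, dyn]], axis=1)

    def feature_layout(self) -> list[str]:
        dyn = list(map(int, self.dynamic_dofs))
        n = self.n_dofs
        return (
            [f"q[{i}]" for i in range(n)]
            + [f"qd[{i}]" for i in dyn]
            + [f"qdd[{i}]" for i in dyn]
        )

    def records(self, split: str | None = None) -> list[TrajectoryRecord]:
        if split is None:
            return list(self.trajectories)
        return [t for t in self.trajectories if t.split == split]

    @property
    def n_samples(self) -> int:
        return sum(t.n_samples for t in self.trajectories)

    # -- persistence ------------------------------------------------------
    def save(self, h5_path, manifest_path=None) -> None:
        import h5py

        with h5py.File(h5_path, "w") as fh:
            fh.attrs["dynamic_dofs"] = self.dynamic_dofs
            for k, rec in enumerate(self.trajectories):
                g = fh.create_group(f"traj/{k:05d}")
                g.attrs["traj_id"] = rec.traj_id
                g.attrs["duration"] = rec.duration
                g.attrs["dt"] = rec.dt
                g.attrs["split"] = rec.split or ""
                for name in ("times", "q", "qd", "qdd", "tau"):
                    g.create_dataset(name, data=getattr(rec, name))
        if manifest_path is not None:
            with open(manifest_path, "w") as fh:
                json.dump(self.manifest, fh, indent=1)

    @classmethod
    def load(cls, h5_path, manifest_path=None) -> "MovementDataset":
        import h5py

        trajectories = []
        with h5py.File(h5_path, "r") as fh:
            dyn = np.asarray(fh.attrs["dynamic_dofs"])
            for key in sorted(fh["traj"]):
                g = fh[f"traj/{key}"]
                trajectories.append(
                    TrajectoryRecord(
                        traj_id=g.attrs["traj_id"],
                        duration=float(g.attrs["duration"]),
                        dt=float(g.attrs["dt"]),
                        times=g["times"][:],
                        q=g["q"][:],
                        qd=g["qd"][:],
                        qdd=g["qdd"][:],
                        tau=g["tau"][:],
                        split=g.attrs["split"] or None,
                    )
                )
        manifest = {}
        if manifest_path is not None:
            with open(manifest_path) as fh:
                manifest = json.load(fh)
        return cls(trajectories=trajectories, dynamic_dofs=dyn, manifest=manifest)


def assemble_dataset(
    trajectories,
    torque_series,
    dynamic_dofs,
    traj_ids=None,
    durations=None,
    manifest_extra: dict | None = None,
) -> MovementDataset:
    """Zip joint trajectories with their torque series into a corpus.

    ``trajectories`` are JointTrajectory-like objects with times/q/qd/qdd;
    ``torque_series`` the aligned (T, n) torque arrays.
    """
    if len(trajectories) != len(torque_series):
        raise ValueError("trajectories and torque series differ in count")
    records = []
    for k, (jt, tau) in enumerate(zip(trajectories, torque_series)):
        tid = traj_ids[k] if traj_ids is not None else f"traj{k:05d}"
        if jt.q.shape[0] != tau.shape[0]:
            raise ValueError(f"misaligned kinematics/torques for trajectory {tid}")
        dt = float(jt.times[1] - jt.times[0])
        dur = durations[k] if durations is not None else float(jt.times[-1])
        records.append(
            TrajectoryRecord(
                traj_id=tid,
                duration=dur,
                dt=dt,
                times=jt.times,
                q=jt.q,
                qd=jt.qd,
                qdd=jt.qdd,
                tau=tau,
            )
        )
    ds = MovementDataset(trajectories=records, dynamic_dofs=np.asarray(dynamic_dofs, dtype=int))
    ds.manifest = {
        "n_trajectories": len(records),
        "n_state_vectors": int(ds.n_samples),
        "durations": sorted({r.duration for r in records}),
        "n_features": ds.n_features,
        "feature_layout": ds.feature_layout(),
        **(manifest_extra or {}),
    }
    return ds


def split_dataset(
    dataset: MovementDataset,
    fractions=(0.71, 0.15, 0.14),
    seed: int = 0,
) -> MovementDataset:
    """Assign whole trajectories to train/val/test, stratified by duration.

    Within each duration stratum trajectories are shuffled (seeded) and
    allocated by largest-remainder counting, so per-duration trajectory
    counts across splits differ by at most one from the ideal quota.
    """
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions < 0) or abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    by_duration: dict[float, list[TrajectoryRecord]] = {}
    for rec in dataset.trajectories:
        by_duration.setdefault(rec.duration, []).append(rec)
    for dur, recs in sorted(by_duration.items()):
        if len(recs) < np.count_nonzero(fractions):
            raise ValueError(
                f"duration stratum {dur}: fewer trajectories ({len(recs)}) than splits"
            )
        order = rng.permutation(len(recs))
        quotas = fractions * len(recs)
        counts = np.floor(quotas).astype(int)
        remainder = len(recs) - counts.sum()
        # largest fractional remainders get the leftover trajectories
        for i in np.argsort(-(quotas - counts))[:remainder]:
            counts[i] += 1
        bounds = np.concatenate([[0], np.cumsum(counts)])
        for s, name in enumerate(SPLIT_NAMES):
            for idx in order[bounds[s] : bounds[s + 1]]:
                recs[idx].split = name
    dataset.manifest["splits"] = {
        name: {
            "n_trajectories": len(dataset.records(name)),
            "n_samples": int(sum(r.n_samples for r in dataset.records(name))),
        }
        for name in SPLIT_NAMES
    }
    dataset.manifest["split_seed"] = seed
    return dataset


# ---------------------------------------------------------------------------
# z-score normalization

@dataclass
class NormalizationStats:
    mean: np.ndarray
    std: np.ndarray
    constant: np.ndarray  # bool mask of zero-variance channels

    @classmethod
    def fit(cls, values: np.ndarray, eps: float = 1e-12) -> "NormalizationStats":
        mean = values.mean(axis=0)
        std = values.std(axis=0)
        constant = std <= eps
        if np.any(constant):
            warnings.warn(
                f"{int(constant.sum())} constant channel(s) flagged; passed through unchanged"
            )
        return cls(mean=mean, std=std, constant=constant)


def fit_zscore(dataset: MovementDataset, what: str = "tau") -> NormalizationStats:
    """Fit per-channel z-score statistics on the training split only."""
    recs = dataset.records("train")
    if not recs:
        raise ValueError("no training split assigned; call split_dataset first")
    if what == "tau":
        values = np.concatenate([r.tau for r in recs], axis=0)
    elif what == "features":
        values = np.concatenate([dataset.reduced_features(r) for r in recs], axis=0)
    else:
        raise ValueError(f"unknown quantity {what!r}")
    return NormalizationStats.fit(values)


def apply_zscore(values: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    std = np.where(stats.constant, 1.0, stats.std)
    mean = np.where(stats.constant, 0.0, stats.mean)
    return (values - mean) / std


def invert_zscore(values: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    std = np.where(stats.constant, 1.0, stats.std)
    mean = np.where(stats.constant, 0.0, stats.mean)
    return values * std + mean


# ---------------------------------------------------------------------------
# sequence windows

def make_sequence_windows(
    dataset: MovementDataset,
    L: int,
    stride: int = 1,
    split: str | None = None,
    feature_stats: NormalizationStats | None = None,
    target_stats: NormalizationStats | None = None,
    features_by_traj: dict | None = None,
    dtype=np.float32,
):
    """Sliding windows of L consecutive reduced-kinematics vectors.

    The target of each window is the torque at its final sample
    (many-to-one). Windows never cross a trajectory boundary; a trajectory
    shorter than L contributes none (with a warning). Returns
    (X (N, L, F), Y (N, n_dofs), meta list of (traj_id, end_index)).
    ``features_by_traj`` optionally overrides the input series per trajectory
    id (e.g. noise-perturbed kinematics).
    """
    if L < 1:
        raise ValueError("window length must be >= 1")
    Xs, Ys, meta = [], [], []
    for rec in dataset.records(split):
        feats = (
            features_by_traj[rec.traj_id]
            if features_by_traj is not None
            else dataset.reduced_features(rec)
        )
        if feature_stats is not None:
            feats = apply_zscore(feats, feature_stats)
        targets = rec.tau
        if target_stats is not None:
            targets = apply_zscore(targets, target_stats)
        T = feats.shape[0]
        if T < L:
            warnings.warn(f"trajectory {rec.traj_id} shorter than window ({T} < {L})")
            continue
        ends = np.arange(L - 1, T, stride)
        starts = ends - L + 1
        idx = starts[:, None] + np.arange(L)[None, :]
        Xs.append(feats[idx].astype(dtype))
        Ys.append(targets[ends].astype(dtype))
        meta.extend((rec.traj_id, int(e)) for e in ends)
    if not Xs:
        return (
            np.empty((0, L, dataset.n_features), dtype=dtype),
            np.empty((0, dataset.n_dofs), dtype=dtype),
            [],
        )
    return np.concatenate(Xs), np.concatenate(Ys), meta


# ---------------------------------------------------------------------------
# noise injection

def channel_ranges(dataset: MovementDataset, split: str = "test") -> np.ndarray:
    """Peak-to-peak range (max - min) of each reduced kinematic channel over
    the given split."""
    feats = np.concatenate(
        [dataset.reduced_features(r) for r in dataset.records(split)], axis=0
    )
    return np.ptp(feats, axis=0)


def add_peak_to_peak_noise(
    series: np.ndarray, fraction: float, ranges: np.ndarray, seed: int
) -> np.ndarray:
    """Additive Gaussian noise, per-channel sd = fraction x channel range.

    Applied to kinematic inputs only (targets are never perturbed); a zero
    fraction returns the input bit-identically.
    """
    if fraction < 0:
        raise ValueError("noise fraction must be >= 0")
    if fraction == 0:
        return series
    rng = np.random.default_rng(seed)
    return series + rng.normal(0.0, fraction * ranges, size=series.shape)
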