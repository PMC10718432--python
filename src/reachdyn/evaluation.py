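"""Surrogate evaluation: RMSE tables, noise robustness, model comparison.

Errors are always reported in N m after de-normalization. The
sequence-length sweep evaluates a 100-sample-trained network with shorter
inputs by truncating each window to its last L samples (the recurrence just
runs fewer steps). Noise robustness perturbs the *inputs only* with
peak-to-peak-scaled Gaussian noise and reports degradation ratios
RMSE_noisy / RMSE_clean, quoted to two decimals. Architecture comparison
follows the rank-based recipe: per-movement RMSE distributions, a
Kolmogorov-Smirnov normality screen, a Kruskal-Wallis omnibus test and
pairwise Mann-Whitney tests (Holm-adjusted by default; raw p-values
available for parity with studies that report them unadjusted).
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import MovementDataset, NormalizationStats, invert_zscore, make_sequence_windows
from .networks import SurrogateNetwork, predict_windows

__all__ = [
    "EvaluationReport",
    "compute_rmse",
    "sequence_length_sweep",
    "noise_robustness",
    "degradation_ratio",
    "compare_architectures",
    "latency_benchmark",
]

SEQUENCE_LENGTHS = (10, 20, 50, 100)
NOISE_FRACTIONS = (0.01, 0.05)


def compute_rmse(predicted: np.ndarray, target: np.ndarray, scope: str = "pooled"):
    """Root-mean-square torque error, pooled or per DOF (N m)."""
    predicted = np.asarray(predicted, dtype=float)
    target = np.asarray(target, dtype=float)
    if predicted.shape != target.shape:
        raise ValueError(f"shape mismatch {predicted.shape} vs {target.shape}")
    se = (predicted - target) ** 2
    if scope == "pooled":
        return float(np.sqrt(se.mean()))
    if scope == "per_dof":
        return np.sqrt(se.reshape(-1, se.shape[-1]).mean(axis=0))
    raise ValueError("scope must be 'pooled' or 'per_dof'")


def sequence_length_sweep(
    net: SurrogateNetwork,
    windows: np.ndarray,
    targets: np.ndarray,
    target_stats: NormalizationStats,
    lengths=SEQUENCE_LENGTHS,
) -> pd.DataFrame:
    """Pooled RMSE vs input sequence length for a 100-sample-trained net.

    ``windows`` are normalized input windows (N, L_max, F); ``targets`` the
    raw (de-normalized) torques at each window's final sample.
    """
    L_max = windows.shape[1]
    rows = []
    for L in lengths:
        if L > L_max:
            raise ValueError(f"length {L} exceeds trained window length {L_max}")
        pred = invert_zscore(predict_windows(net, windows[:, L_max - L :]), target_stats)
        rows.append({"length": L, "rmse_nm": compute_rmse(pred, targets)})
    return pd.DataFrame(rows)


def degradation_ratio(rmse_noisy: float, rmse_clean: float) -> float:
    """Noise degradation multiplier; 1.0 at zero noise by construction."""
    if rmse_clean < 0 or rmse_noisy < 0:
        raise ValueError("RMSE values must be non-negative")
    return rmse_noisy / rmse_clean


def noise_robustness(
    net: SurrogateNetwork,
    dataset: MovementDataset,
    feature_stats: NormalizationStats,
    target_stats: NormalizationStats,
    fractions=NOISE_FRACTIONS,
    seed: int = 0,
    L: int = 100,
) -> pd.DataFrame:
    """RMSE and degradation ratios under peak-to-peak input noise.

    The clean baseline uses the identical windows without noise; noise is
    regenerated from ``seed`` so the table is reproducible.
    """
    from .pipeline import evaluate_rmse_windows, noisy_test_features

    clean, _ = evaluate_rmse_windows(net, dataset, feature_stats, target_stats, L=L)
    rows = [{"noise_fraction": 0.0, "rmse_nm": clean, "ratio": 1.0}]
    for frac in fractions:
        feats = noisy_test_features(dataset, frac, seed)
        rmse, _ = evaluate_rmse_windows(
            net, dataset, feature_stats, target_stats, L=L, features_by_traj=feats
        )
        rows.append(
            {"noise_fraction": frac, "rmse_nm": rmse, "ratio": degradation_ratio(rmse, clean)}
        )
    return pd.DataFrame(rows)


def compare_architectures(
    groups: dict[str, np.ndarray],
    alpha: float = 0.05,
    adjust: str | None = "holm",
) -> dict:
    """Rank-based comparison of per-movement RMSE distributions.

    Returns a dict with a per-group normality screen (one-sample KS against
    a fitted normal), the Kruskal-Wallis omnibus test, and pairwise
    Mann-Whitney tests with significance flags at ``alpha``. ``adjust`` is
    ``"holm"`` (default) or ``None`` for raw p-values.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    for name, vals in groups.items():
        if len(vals) < 5:
            raise ValueError(f"group {name!r} has fewer than 5 trials")
    normality = {}
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        sd = vals.std(ddof=1)
        if sd == 0:
            normality[name] = {"statistic": np.nan, "p": np.nan, "normal": False}
            continue
        stat, p = stats.kstest(vals, "norm", args=(vals.mean(), sd))
        normality[name] = {"statistic": float(stat), "p": float(p), "normal": p > alpha}
    pooled = np.concatenate([np.asarray(v, dtype=float) for v in groups.values()])
    if np.ptp(pooled) == 0:
        warnings.warn("all groups identical and constant; reporting non-significance")
        omnibus = {"statistic": np.nan, "p": 1.0, "significant": False}
        pairwise = []
        names = sorted(groups)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                pairwise.append(
                    {"a": a, "b": b, "statistic": np.nan, "p": 1.0,
                     "p_adjusted": 1.0, "significant": False}
                )
        return {"normality": normality, "omnibus": omnibus,
                "pairwise": pd.DataFrame(pairwise), "alpha": alpha}
    kw_stat, kw_p = stats.kruskal(*groups.values())
    omnibus = {"statistic": float(kw_stat), "p": float(kw_p), "significant": kw_p < alpha}
    names = sorted(groups)
    pairs, pvals, ustats = [], [], []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            va, vb = np.asarray(groups[a]), np.asarray(groups[b])
            if np.ptp(np.concatenate([va, vb])) == 0:
                u, p = np.nan, 1.0
            else:
                u, p = stats.mannwhitneyu(va, vb, alternative="two-sided")
            pairs.append((a, b))
            pvals.append(float(p))
            ustats.append(float(u) if np.isfinite(u) else np.nan)
    if adjust == "holm":
        from statsmodels.stats.multitest import multipletests

        _, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    elif adjust is None:
        p_adj = np.asarray(pvals)
    else:
        raise ValueError("adjust must be 'holm' or None")
    pairwise = pd.DataFrame(
        {
            "a": [p[0] for p in pairs],
            "b": [p[1] for p in pairs],
            "statistic": ustats,
            "p": pvals,
            "p_adjusted": p_adj,
            "significant": p_adj < alpha,
        }
    )
    return {"normality": normality, "omnibus": omnibus, "pairwise": pairwise, "alpha": alpha}


def latency_benchmark(
    net: SurrogateNetwork,
    lengths=SEQUENCE_LENGTHS,
    input_dim: int | None = None,
    repetitions: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Median forward-pass latency per output sample (informational only).

    Wall-clock numbers are hardware-dependent and are never used in
    correctness checks; the table records the median, the coefficient of
    variation across repetitions, and the device ("cpu" for this numpy
    implementation).
    """
    d = input_dim or net.spec.input_dim
    rng = np.random.default_rng(seed)
    rows = []
    for L in lengths:
        x = rng.normal(size=(L, 1, d)).astype(np.float32)
        net.forward(x)  # warm-up
        times = np.empty(repetitions)
        for i in range(repetitions):
            t0 = time.perf_counter()
            net.forward(x)
            times[i] = time.perf_counter() - t0
        med = float(np.median(times))
        rows.append(
            {
                "network": net.name,
                "length": L,
                "latency_per_sample_ms": med * 1e3,
                "cv": float(times.std() / times.mean()),
                "device": "cpu",
                "repetitions": repetitions,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    """Container for the evaluation artefacts of one or more networks."""

    length_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    noise_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    comparison: dict | None = None
    latency: pd.DataFrame | None = None

    def save(self, out_dir) -> None:
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.length_tables.items():
            df.to_csv(out / f"length_sweep_{name}.csv", index=False)
        for name, df in self.noise_tables.items():
            df.to_csv(out / f"noise_{name}.csv", index=False)
        if self.latency is not None:
            self.latency.to_csv(out / "latency.csv", index=False)
        if self.comparison is not None:
            payload = {
                "normality": self.comparison["normality"],
                "omnibus": self.comparison["omnibus"],
                "alpha": self.comparison["alpha"],
                "pairwise": self.comparison["pairwise"].to_dict(orient="records"),
            }
            with open(out / "comparison.json", "w") as fh:
                json.dump(payload, fh, indent=1)
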