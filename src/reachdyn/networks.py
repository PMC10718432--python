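"""Recurrent surrogate networks mapping kinematic sequences to joint torques.

Three architectures of increasing gating complexity -- Elman RNN, GRU and
LSTM -- share a common structure: ``layers`` recurrent hidden layers of
``hidden_size`` units whose state recirculates across timesteps, followed by
a linear readout to the 23 joint torques. Networks are trained by
backpropagation through time with Adam on z-scored torque targets, either

* ``stateful`` mode: per-step loss over whole trajectories with truncated
  backpropagation (default chunk 100 samples), the hidden state carried
  across chunks -- cheap, since every sample is a training target; or
* ``window`` mode: shuffled mini-batches of fixed-length windows with the
  loss on the final step only (the evaluation-time protocol).

Everything is plain numpy (float32) and deterministic given a seed and a
fixed thread count. The naming convention is XXX-Y-ZZZ: architecture,
number of hidden layers, nodes per layer (the Elman network is named "RNN").
"""

from __future__ import annotations

import copy
import json
import time
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "SurrogateSpec",
    "SurrogateNetwork",
    "TrainingHistory",
    "build_surrogate",
    "train_surrogate",
    "hyperparameter_grid_search",
    "predict_stateful",
    "predict_windows",
    "parameter_count",
    "save_checkpoint",
    "load_checkpoint",
]

ARCHITECTURES = ("elman", "gru", "lstm")
_GATES = {"elman": 1, "gru": 3, "lstm": 4}
_DISPLAY = {"elman": "RNN", "gru": "GRU", "lstm": "LSTM"}

HIDDEN_SIZES = (23, 69, 115)
LEARNING_RATES = (1e-4, 5e-4, 1e-3)
LAYER_COUNTS = (1, 3, 5)


@dataclass(frozen=True)
class SurrogateSpec:
    arch: str
    layers: int = 1
    hidden_size: int = 115
    learning_rate: float = 5e-4
    seed: int = 0
    input_dim: int = 29
    output_dim: int = 23

    def __post_init__(self):
        if self.arch not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.arch!r}; choose from {ARCHITECTURES}")

    @property
    def name(self) -> str:
        return f"{_DISPLAY[self.arch]}-{self.layers}-{self.hidden_size}"


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class SurrogateNetwork:
    """Parameter container + forward/backward passes for one spec.

    Parameters per layer l: input weights ``Wx{l}`` (D_l, G*H), recurrent
    weights ``Wh{l}`` (H, G*H) and biases ``bx{l}``/``bh{l}``; readout
    ``Wo``/``bo``. G is the per-architecture gate count (1/3/4).
    """

    def __init__(self, spec: SurrogateSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        G = _GATES[spec.arch]
        H = spec.hidden_size
        k = 1.0 / np.sqrt(H)
        self.params: dict[str, np.ndarray] = {}
        d_in = spec.input_dim
        for l in range(spec.layers):
            self.params[f"Wx{l}"] = rng.uniform(-k, k, (d_in, G * H)).astype(np.float32)
            # orthogonal recurrent blocks (one per gate): standard for gated
            # recurrent nets, keeps the state spectrum well-conditioned
            blocks = []
            for _ in range(G):
                a = rng.normal(size=(H, H))
                qm, rm = np.linalg.qr(a)
                blocks.append(qm * np.sign(np.diag(rm)))
            self.params[f"Wh{l}"] = np.concatenate(blocks, axis=1).astype(np.float32)
            self.params[f"bx{l}"] = rng.uniform(-k, k, G * H).astype(np.float32)
            self.params[f"bh{l}"] = rng.uniform(-k, k, G * H).astype(np.float32)
            d_in = H
        self.params["Wo"] = rng.uniform(-k, k, (H, spec.output_dim)).astype(np.float32)
        self.params["bo"] = rng.uniform(-k, k, spec.output_dim).astype(np.float32)

    @property
    def name(self) -> str:
        return self.spec.name

    @property
    def dtype(self):
        return self.params["Wo"].dtype

    def zero_state(self, batch: int):
        H = self.spec.hidden_size
        h = [np.zeros((batch, H), dtype=self.dtype) for _ in range(self.spec.layers)]
        if self.spec.arch == "lstm":
            c = [np.zeros((batch, H), dtype=self.dtype) for _ in range(self.spec.layers)]
            return h, c
        return h, None

    def copy(self) -> "SurrogateNetwork":
        dup = SurrogateNetwork.__new__(SurrogateNetwork)
        dup.spec = self.spec
        dup.params = {k: v.copy() for k, v in self.params.items()}
        return dup

    # -- forward ----------------------------------------------------------
    def forward(self, X: np.ndarray, state=None, want_cache: bool = False):
        """Run a chunk X (T, B, D). Returns (Y (T, B, O), state, cache)."""
        spec = self.spec
        T, B, _ = X.shape
        h, c = state if state is not None else self.zero_state(B)
        h, c = list(h), (list(c) if c is not None else None)
        caches = []
        inp = X
        for l in range(spec.layers):
            if spec.arch == "elman":
                inp, h[l], cache = self._fwd_elman(inp, h[l], l, want_cache)
            elif spec.arch == "gru":
                inp, h[l], cache = self._fwd_gru(inp, h[l], l, want_cache)
            else:
                inp, h[l], c[l], cache = self._fwd_lstm(inp, h[l], c[l], l, want_cache)
            caches.append(cache)
        Y = inp @ self.params["Wo"] + self.params["bo"]
        full_cache = {"caches": caches, "X": X, "top": inp} if want_cache else None
        return Y, (h, c), full_cache

    def _fwd_elman(self, X, h, l, want_cache):
        p = self.params
        T, B, _ = X.shape
        gx = X @ p[f"Wx{l}"] + p[f"bx{l}"] + p[f"bh{l}"]
        Wh = p[f"Wh{l}"]
        H_seq = np.empty((T, B, self.spec.hidden_size), dtype=self.dtype)
        Hprev = np.empty_like(H_seq) if want_cache else None
        for t in range(T):
            if want_cache:
                Hprev[t] = h
            h = np.tanh(gx[t] + h @ Wh)
            H_seq[t] = h
        cache = {"H": H_seq, "Hprev": Hprev, "X": X, "l": l} if want_cache else None
        return H_seq, h, cache

    def _fwd_gru(self, X, h, l, want_cache):
        p = self.params
        T, B, _ = X.shape
        H = self.spec.hidden_size
        gx = X @ p[f"Wx{l}"] + p[f"bx{l}"]
        Wh, bh = p[f"Wh{l}"], p[f"bh{l}"]
        Wh_rz, Wh_n = Wh[:, : 2 * H], Wh[:, 2 * H :]
        bh_rz, bh_n = bh[: 2 * H], bh[2 * H :]
        H_seq = np.empty((T, B, H), dtype=self.dtype)
        if want_cache:
            cache = {
                "R": np.empty((T, B, H), self.dtype),
                "Z": np.empty((T, B, H), self.dtype),
                "N": np.empty((T, B, H), self.dtype),
                "GHN": np.empty((T, B, H), self.dtype),
                "Hprev": np.empty((T, B, H), self.dtype),
                "X": X,
                "l": l,
            }
        for t in range(T):
            rz = _sigmoid(gx[t, :, : 2 * H] + h @ Wh_rz + bh_rz)
            r, z = rz[:, :H], rz[:, H:]
            ghn = h @ Wh_n + bh_n
            n = np.tanh(gx[t, :, 2 * H :] + r * ghn)
            if want_cache:
                cache["R"][t], cache["Z"][t], cache["N"][t] = r, z, n
                cache["GHN"][t], cache["Hprev"][t] = ghn, h
            h = (1.0 - z) * n + z * h
            H_seq[t] = h
        return H_seq, h, cache if want_cache else None

    def _fwd_lstm(self, X, h, c, l, want_cache):
        p = self.params
        T, B, _ = X.shape
        H = self.spec.hidden_size
        gx = X @ p[f"Wx{l}"] + p[f"bx{l}"] + p[f"bh{l}"]
        Wh = p[f"Wh{l}"]
        H_seq = np.empty((T, B, H), dtype=self.dtype)
        if want_cache:
            cache = {
                "I": np.empty((T, B, H), self.dtype),
                "F": np.empty((T, B, H), self.dtype),
                "G": np.empty((T, B, H), self.dtype),
                "O": np.empty((T, B, H), self.dtype),
                "C": np.empty((T, B, H), self.dtype),
                "Cprev": np.empty((T, B, H), self.dtype),
                "Hprev": np.empty((T, B, H), self.dtype),
                "X": X,
                "l": l,
            }
        for t in range(T):
            a = gx[t] + h @ Wh
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            if want_cache:
                cache["Cprev"][t], cache["Hprev"][t] = c, h
            c = f * c + i * g
            h = o * np.tanh(c)
            if want_cache:
                cache["I"][t], cache["F"][t], cache["G"][t] = i, f, g
                cache["O"][t], cache["C"][t] = o, c
            H_seq[t] = h
        return H_seq, h, c, cache if want_cache else None

    # -- backward ---------------------------------------------------------
    def backward(self, full_cache, dY: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss with upstream dL/dY (T, B, O)."""
        p = self.params
        grads = {}
        top = full_cache["top"]
        grads["Wo"] = np.tensordot(top, dY, axes=([0, 1], [0, 1]))
        grads["bo"] = dY.sum(axis=(0, 1))
        dH_seq = dY @ p["Wo"].T
        for l in range(self.spec.layers - 1, -1, -1):
            cache = full_cache["caches"][l]
            if self.spec.arch == "elman":
                dH_seq = self._bwd_elman(cache, dH_seq, grads)
            elif self.spec.arch == "gru":
                dH_seq = self._bwd_gru(cache, dH_seq, grads)
            else:
                dH_seq = self._bwd_lstm(cache, dH_seq, grads)
        return grads

    def _bwd_elman(self, cache, dH_seq, grads):
        l = cache["l"]
        Wh = self.params[f"Wh{l}"]
        H_seq, Hprev, X = cache["H"], cache["Hprev"], cache["X"]
        T = H_seq.shape[0]
        dA = np.empty_like(H_seq)
        dh = np.zeros_like(H_seq[0])
        for t in range(T - 1, -1, -1):
            da = (dH_seq[t] + dh) * (1.0 - H_seq[t] ** 2)
            dA[t] = da
            dh = da @ Wh.T
        grads[f"Wx{l}"] = np.tensordot(X, dA, axes=([0, 1], [0, 1]))
        grads[f"Wh{l}"] = np.tensordot(Hprev, dA, axes=([0, 1], [0, 1]))
        b = dA.sum(axis=(0, 1))
        grads[f"bx{l}"] = b
        grads[f"bh{l}"] = b.copy()
        return dA @ self.params[f"Wx{l}"].T

    def _bwd_gru(self, cache, dH_seq, grads):
        l = cache["l"]
        H = self.spec.hidden_size
        Wh = self.params[f"Wh{l}"]
        Wh_rz, Wh_n = Wh[:, : 2 * H], Wh[:, 2 * H :]
        R, Z, N, GHN, Hprev, X = (
            cache["R"], cache["Z"], cache["N"], cache["GHN"], cache["Hprev"], cache["X"],
        )
        T, B, _ = R.shape
        dAx = np.empty((T, B, 3 * H), self.dtype)  # grads wrt gx slots (r,z,n)
        dGh = np.empty((T, B, 3 * H), self.dtype)  # grads wrt (a_r, a_z, ghn)
        dh = np.zeros((B, H), self.dtype)
        for t in range(T - 1, -1, -1):
            dht = dH_seq[t] + dh
            r, z, n, ghn, hp = R[t], Z[t], N[t], GHN[t], Hprev[t]
            dn = dht * (1.0 - z)
            da_n = dn * (1.0 - n * n)
            dz = dht * (hp - n)
            da_z = dz * z * (1.0 - z)
            dghn = da_n * r
            dr = da_n * ghn
            da_r = dr * r * (1.0 - r)
            dAx[t, :, :H], dAx[t, :, H : 2 * H], dAx[t, :, 2 * H :] = da_r, da_z, da_n
            dGh[t, :, :H], dGh[t, :, H : 2 * H], dGh[t, :, 2 * H :] = da_r, da_z, dghn
            dh = dht * z + np.concatenate([da_r, da_z], axis=1) @ Wh_rz.T + dghn @ Wh_n.T
        grads[f"Wx{l}"] = np.tensordot(X, dAx, axes=([0, 1], [0, 1]))
        grads[f"Wh{l}"] = np.tensordot(Hprev, dGh, axes=([0, 1], [0, 1]))
        grads[f"bx{l}"] = dAx.sum(axis=(0, 1))
        grads[f"bh{l}"] = dGh.sum(axis=(0, 1))
        return dAx @ self.params[f"Wx{l}"].T

    def _bwd_lstm(self, cache, dH_seq, grads):
        l = cache["l"]
        H = self.spec.hidden_size
        Wh = self.params[f"Wh{l}"]
        I, F, G, O, C, Cprev, Hprev, X = (
            cache["I"], cache["F"], cache["G"], cache["O"],
            cache["C"], cache["Cprev"], cache["Hprev"], cache["X"],
        )
        T, B, _ = I.shape
        dA = np.empty((T, B, 4 * H), self.dtype)
        dh = np.zeros((B, H), self.dtype)
        dc = np.zeros((B, H), self.dtype)
        for t in range(T - 1, -1, -1):
            dht = dH_seq[t] + dh
            i, f, g, o, c, cp = I[t], F[t], G[t], O[t], C[t], Cprev[t]
            tc = np.tanh(c)
            do = dht * tc
            dct = dht * o * (1.0 - tc * tc) + dc
            di = dct * g
            df = dct * cp
            dg = dct * i
            dc = dct * f
            da = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            dA[t] = da
            dh = da @ Wh.T
        grads[f"Wx{l}"] = np.tensordot(X, dA, axes=([0, 1], [0, 1]))
        grads[f"Wh{l}"] = np.tensordot(Hprev, dA, axes=([0, 1], [0, 1]))
        b = dA.sum(axis=(0, 1))
        grads[f"bx{l}"] = b
        grads[f"bh{l}"] = b.copy()
        return dA @ self.params[f"Wx{l}"].T


def build_surrogate(spec: SurrogateSpec) -> SurrogateNetwork:
    """Construct a seeded network from its spec."""
    return SurrogateNetwork(spec)


def parameter_count(net: SurrogateNetwork) -> int:
    return int(sum(v.size for v in net.params.values()))


# ---------------------------------------------------------------------------
# optimisation

class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            m = self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            v = self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


@dataclass
class TrainingHistory:
    train_mse: list = field(default_factory=list)
    val_mse: list = field(default_factory=list)
    wall_time: float = 0.0
    final_epoch: int = 0
    best_epoch: int = 0


def _group_by_length(pairs):
    groups: dict[int, list] = {}
    for X, Y in pairs:
        groups.setdefault(X.shape[0], []).append((X, Y))
    return groups


def _stateful_mse(net: SurrogateNetwork, pairs) -> float:
    """Per-step MSE over whole trajectories (hidden state from zero)."""
    se, n = 0.0, 0
    for T, group in sorted(_group_by_length(pairs).items()):
        X = np.stack([g[0] for g in group], axis=1)  # (T, B, F)
        Y = np.stack([g[1] for g in group], axis=1)
        pred, _, _ = net.forward(X)
        se += float(((pred - Y) ** 2).sum())
        n += Y.size
    return se / max(n, 1)


def train_surrogate(
    net: SurrogateNetwork,
    train_data,
    val_data,
    epochs: int = 100,
    seed: int = 0,
    mode: str = "stateful",
    tbptt: int = 100,
    batch_trajectories: int = 4,
    batch_windows: int = 256,
    patience: int = 10,
    state_reset_prob: float = 0.25,
    verbose: bool = False,
):
    """Train by BPTT with Adam; returns (best network, TrainingHistory).

    ``train_data``/``val_data`` are lists of per-trajectory (X, Y) arrays in
    stateful mode (X (T, F), Y (T, O), already normalized, float32), or
    window tensors (X (N, L, F), Y (N, O)) in window mode. The network held
    at the best validation epoch is returned; training stops early when
    validation MSE has not improved for ``patience`` epochs.
    """
    if mode not in ("stateful", "window"):
        raise ValueError("mode must be 'stateful' or 'window'")
    if (mode == "stateful" and not train_data) or (
        mode == "window" and len(train_data[0]) == 0
    ):
        raise ValueError("empty training data")
    t0 = time.perf_counter()
    rng = np.random.default_rng(seed)
    opt = _Adam(net.params, net.spec.learning_rate)
    hist = TrainingHistory()
    best = net.copy()
    best_val = np.inf
    since_best = 0
    for epoch in range(epochs):
        if mode == "stateful":
            train_mse = _epoch_stateful(
                net, opt, train_data, rng, tbptt, batch_trajectories, state_reset_prob
            )
        else:
            train_mse = _epoch_window(net, opt, train_data, rng, batch_windows)
        if not np.isfinite(train_mse):
            raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
        if mode == "stateful":
            val_mse = _stateful_mse(net, val_data)
        else:
            Xv, Yv = val_data
            val_mse = float(np.mean((predict_windows(net, Xv) - Yv) ** 2))
        hist.train_mse.append(train_mse)
        hist.val_mse.append(val_mse)
        hist.final_epoch = epoch + 1
        if verbose:
            print(f"epoch {epoch + 1:3d}  train {train_mse:.5f}  val {val_mse:.5f}")
        if val_mse < best_val:
            best_val = val_mse
            best = net.copy()
            hist.best_epoch = epoch + 1
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    hist.wall_time = time.perf_counter() - t0
    return best, hist


def _epoch_stateful(net, opt, pairs, rng, tbptt, batch_trajectories, state_reset_prob=0.0):
    groups = _group_by_length(pairs)
    order = []
    for T in sorted(groups):
        idx = rng.permutation(len(groups[T]))
        for s in range(0, len(idx), batch_trajectories):
            order.append((T, idx[s : s + batch_trajectories]))
    order = [order[i] for i in rng.permutation(len(order))]
    se, n = 0.0, 0
    for T, idx in order:
        group = groups[T]
        X = np.stack([group[i][0] for i in idx], axis=1)
        Y = np.stack([group[i][1] for i in idx], axis=1)
        state = None
        for s in range(0, T, tbptt):
            # occasional hidden-state resets expose the net to the zero
            # initial state it will see at evaluation time on short windows
            if state is not None and state_reset_prob > 0 and rng.random() < state_reset_prob:
                state = None
            xc, yc = X[s : s + tbptt], Y[s : s + tbptt]
            pred, state, cache = net.forward(xc, state, want_cache=True)
            err = pred - yc
            se += float((err**2).sum())
            n += yc.size
            grads = net.backward(cache, (2.0 / yc.size) * err)
            opt.step(net.params, grads)
    return se / max(n, 1)


def _epoch_window(net, opt, data, rng, batch_windows):
    X, Y = data
    N = X.shape[0]
    order = rng.permutation(N)
    se, n = 0.0, 0
    for s in range(0, N, batch_windows):
        idx = order[s : s + batch_windows]
        xb = np.swapaxes(X[idx], 0, 1)  # (L, B, F)
        yb = Y[idx]
        pred, _, cache = net.forward(xb, want_cache=True)
        err = pred[-1] - yb
        se += float((err**2).sum())
        n += yb.size
        dY = np.zeros_like(pred)
        dY[-1] = (2.0 / yb.size) * err
        grads = net.backward(cache, dY)
        opt.step(net.params, grads)
    return se / max(n, 1)


# ---------------------------------------------------------------------------
# inference

def predict_stateful(net: SurrogateNetwork, X: np.ndarray) -> np.ndarray:
    """Per-step predictions over one full trajectory X (T, F)."""
    Y, _, _ = net.forward(X[:, None, :].astype(np.float32))
    return Y[:, 0, :]


def predict_windows(net: SurrogateNetwork, X: np.ndarray, batch: int = 512) -> np.ndarray:
    """Final-step predictions for windows X (N, L, F); recurrence starts
    from the zero state for each window."""
    outs = []
    for s in range(0, X.shape[0], batch):
        xb = np.swapaxes(X[s : s + batch].astype(np.float32), 0, 1)
        Y, _, _ = net.forward(xb)
        outs.append(Y[-1])
    return np.concatenate(outs) if outs else np.empty((0, net.spec.output_dim))


# ---------------------------------------------------------------------------
# grid search

def hyperparameter_grid_search(
    train_data,
    val_data,
    archs=ARCHITECTURES,
    layer_counts=(1,),
    hidden_sizes=HIDDEN_SIZES,
    learning_rates=LEARNING_RATES,
    budget_epochs: int = 15,
    mode: str = "stateful",
    input_dim: int = 29,
    output_dim: int = 23,
    seed: int = 0,
    **train_kw,
):
    """Train every hyperparameter combination for a short epoch budget.

    Returns a pandas DataFrame with one row per configuration (validation
    RMSE on normalized torques), sorted best-first. Individual failures are
    recorded in the table rather than raised.
    """
    import pandas as pd

    rows = []
    for arch in archs:
        for layers in layer_counts:
            for hidden in hidden_sizes:
                for lr in learning_rates:
                    spec = SurrogateSpec(
                        arch=arch, layers=layers, hidden_size=hidden,
                        learning_rate=lr, seed=seed,
                        input_dim=input_dim, output_dim=output_dim,
                    )
                    row = {
                        "name": spec.name, "arch": arch, "layers": layers,
                        "hidden_size": hidden, "learning_rate": lr,
                    }
                    try:
                        net = build_surrogate(spec)
                        net, hist = train_surrogate(
                            net, train_data, val_data, epochs=budget_epochs,
                            seed=seed, mode=mode, patience=budget_epochs, **train_kw,
                        )
                        row["val_rmse"] = float(np.sqrt(min(hist.val_mse)))
                        row["epochs"] = hist.final_epoch
                    except Exception as err:  # recorded, not fatal
                        row["val_rmse"] = np.nan
                        row["error"] = str(err)
                    rows.append(row)
    return pd.DataFrame(rows).sort_values("val_rmse").reset_index(drop=True)


# ---------------------------------------------------------------------------
# serialization

def save_checkpoint(net: SurrogateNetwork, path, aux: dict | None = None) -> None:
    """Weights + spec (+ optional auxiliary arrays, e.g. z-score stats)."""
    payload = {f"param/{k}": v for k, v in net.params.items()}
    if aux:
        payload.update({f"aux/{k}": np.asarray(v) for k, v in aux.items()})
    payload["spec_json"] = np.frombuffer(
        json.dumps(asdict(net.spec)).encode(), dtype=np.uint8
    )
    np.savez(path, **payload)


def load_checkpoint(path) -> tuple[SurrogateNetwork, dict]:
    with np.load(path) as data:
        spec = SurrogateSpec(**json.loads(bytes(data["spec_json"].tobytes()).decode()))
        net = SurrogateNetwork.__new__(SurrogateNetwork)
        net.spec = spec
        net.params = {
            k.split("/", 1)[1]: data[k] for k in data.files if k.startswith("param/")
        }
        aux = {k.split("/", 1)[1]: data[k] for k in data.files if k.startswith("aux/")}
    return net, aux
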