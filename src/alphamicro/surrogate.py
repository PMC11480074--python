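"""Multilayer-perceptron surrogate trained with Levenberg-Marquardt.

The production network maps the 4 design inputs (source-region code,
alpha energy, nucleus radius, cell radius) to the 21 transformed targets
(z_max plus 20 spectral densities) through two tanh hidden layers of 10
and 26 nodes and a linear output layer.  Inputs are min-max normalised to
[-1, 1] with bounds taken from the training partition and stored with the
model; targets stay in the ln(1+x) transform space, which is the space the
mean-squared-error loss and all reported RMSE values live in.

Training is damped Gauss-Newton (Levenberg-Marquardt): with residual
Jacobian J and residuals r, each step solves ``(J^T J + lambda I) delta =
-J^T r``; a step is accepted only if the training MSE decreases, whereupon
``lambda`` shrinks by 10, otherwise ``lambda`` grows by 10 and the solve is
retried.  Validation-based early stopping keeps the best-validation
snapshot and halts after a budget of consecutive epochs without
improvement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg as sla

from alphamicro.dataset import (
    DesignPoint,
    input_columns,
    inverse_transform_targets,
    target_columns,
)
from alphamicro.spectra import N_BINS, SingleEventSpectrum

__all__ = [
    "MLPParams",
    "TrainConfig",
    "LMState",
    "init_params",
    "forward",
    "jacobian",
    "lm_step",
    "train",
    "fit_surrogate",
    "grid_search",
    "predict_spectrum",
    "save_model",
    "load_model",
]


@dataclass
class MLPParams:
    """Weights/biases of a feed-forward net with tanh hidden layers.

    ``sizes`` is (n_in, *hidden, n_out); ``weights[l]`` has shape
    (sizes[l], sizes[l+1]).  ``input_lo``/``input_hi`` are the min-max
    normalisation bounds mapping each input onto [-1, 1].
    """

    sizes: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    input_lo: np.ndarray
    input_hi: np.ndarray

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    @property
    def n_params(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def to_vector(self) -> np.ndarray:
        parts = []
        for w, b in zip(self.weights, self.biases):
            parts += [w.ravel(), b.ravel()]
        return np.concatenate(parts)

    def with_vector(self, vec: np.ndarray) -> "MLPParams":
        ws, bs, off = [], [], 0
        for w, b in zip(self.weights, self.biases):
            ws.append(vec[off:off + w.size].reshape(w.shape).copy())
            off += w.size
            bs.append(vec[off:off + b.size].copy())
            off += b.size
        return replace(self, weights=ws, biases=bs)

    def copy(self) -> "MLPParams":
        return replace(self, weights=[w.copy() for w in self.weights],
                       biases=[b.copy() for b in self.biases])

    def normalize(self, x: np.ndarray) -> np.ndarray:
        span = np.where(self.input_hi > self.input_lo,
                        self.input_hi - self.input_lo, 1.0)
        return 2.0 * (x - self.input_lo) / span - 1.0


def init_params(sizes, input_lo, input_hi, rng: np.random.Generator,
                mode: str = "uniform") -> MLPParams:
    """Seeded weight initialisation.

    ``mode="uniform"`` (default): layer-wise uniform draws scaled by
    fan-in, U(-sqrt(3/n_in), +sqrt(3/n_in)).  ``mode="nguyen_widrow"``:
    each tanh unit's weight vector rescaled to magnitude
    ``0.7 * H**(1/n_in)`` with biases tiling the active range, so the
    sigmoids partition the [-1, 1] input region.
    """
    sizes = tuple(int(s) for s in sizes)
    ws, bs = [], []
    n_layers = len(sizes) - 1
    for l, (n_in, n_out) in enumerate(zip(sizes[:-1], sizes[1:])):
        if mode == "uniform" or l == n_layers - 1:
            s = np.sqrt(3.0 / n_in)
            ws.append(rng.uniform(-s, s, size=(n_in, n_out)))
            bs.append(rng.uniform(-s, s, size=n_out))
        elif mode == "nguyen_widrow":
            beta = 0.7 * n_out ** (1.0 / n_in)
            w = rng.uniform(-1.0, 1.0, size=(n_in, n_out))
            norms = np.linalg.norm(w, axis=0, keepdims=True)
            norms[norms == 0] = 1.0
            w = beta * w / norms
            b = beta * np.linspace(-1.0, 1.0, n_out) * np.sign(w[0])
            ws.append(w)
            bs.append(b)
        else:
            raise ValueError(f"unknown init mode {mode!r}")
    return MLPParams(sizes=sizes, weights=ws, biases=bs,
                     input_lo=np.asarray(input_lo, dtype=float),
                     input_hi=np.asarray(input_hi, dtype=float))


def _forward_full(params: MLPParams, x: np.ndarray) -> list[np.ndarray]:
    """Activations per layer (a0 = normalised input ... aL = output)."""
    a = [params.normalize(np.atleast_2d(np.asarray(x, dtype=float)))]
    last = params.n_layers - 1
    for l, (w, b) in enumerate(zip(params.weights, params.biases)):
        z = a[-1] @ w + b
        a.append(z if l == last else np.tanh(z))
    return a


def forward(params: MLPParams, x) -> np.ndarray:
    """Network output(s) in transformed target space; batch or single."""
    x_arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x_arr)):
        raise ValueError("non-finite network input")
    out = _forward_full(params, x_arr)[-1]
    return out[0] if x_arr.ndim == 1 else out


def jacobian(params: MLPParams, x) -> np.ndarray:
    """Analytic residual Jacobian, shape (n_samples * n_out, n_params).

    Row (n, o) holds the derivative of output o of sample n with respect
    to every weight and bias, in parameter-vector order.
    """
    acts = _forward_full(params, x)
    n = acts[0].shape[0]
    n_out = params.sizes[-1]
    jac = np.zeros((n, n_out, params.n_params))

    # D[l][n,o,j] = d y_o / d z_l[j]; output layer is the identity.
    offsets = []
    off = 0
    for w, b in zip(params.weights, params.biases):
        offsets.append(off)
        off += w.size + b.size

    last = params.n_layers - 1
    # Output layer: dy_o/dW[k,o'] = a_{L-1}[k] delta_{oo'}; bias: delta.
    w_out = params.weights[last]
    blk = jac[:, :, offsets[last]:offsets[last] + w_out.size]
    blk4 = blk.reshape(n, n_out, w_out.shape[0], n_out)
    for o in range(n_out):
        blk4[:, o, :, o] = acts[last]
    bias_blk = jac[:, :, offsets[last] + w_out.size:offsets[last] + w_out.size + n_out]
    bias_blk[:, np.arange(n_out), np.arange(n_out)] = 1.0

    d = None  # (n, n_out, width of layer l)
    for l in range(last - 1, -1, -1):
        w_next = params.weights[l + 1]
        if d is None:
            d = w_next.T[None, :, :] * (1.0 - acts[l + 1][:, None, :] ** 2)
        else:
            d = np.einsum("noi,ji->noj", d, w_next, optimize=True)
            d *= (1.0 - acts[l + 1][:, None, :] ** 2)
        w = params.weights[l]
        blk = jac[:, :, offsets[l]:offsets[l] + w.size]
        blk4 = blk.reshape(n, n_out, w.shape[0], w.shape[1])
        np.einsum("noj,nk->nokj", d, acts[l], out=blk4, optimize=True)
        jac[:, :, offsets[l] + w.size:offsets[l] + w.size + w.shape[1]] = d
    return jac.reshape(n * n_out, params.n_params)


@dataclass
class TrainConfig:
    hidden: tuple[int, ...] = (10, 26)
    lam0: float = 1e-3
    lam_factor: float = 10.0
    lam_max: float = 1e10
    max_epochs: int = 1000
    patience: int = 20  # consecutive epochs without validation improvement
    max_retries: int = 12  # lambda increases within one epoch
    mse_goal: float = 0.0
    n_restarts: int = 1  # optional independent inits; best validation wins
    init: str = "uniform"  # or "nguyen_widrow"


@dataclass
class LMState:
    lam: float
    epoch: int = 0
    best_params: MLPParams | None = None
    best_val_mse: float = np.inf
    val_fail_count: int = 0
    train_history: list = field(default_factory=list)
    val_history: list = field(default_factory=list)
    stalled: bool = False


def _mse(params: MLPParams, x: np.ndarray, y: np.ndarray) -> float:
    r = forward(params, x) - y
    return float(np.mean(r * r))


def _normal_matrices(params: MLPParams, x: np.ndarray, y: np.ndarray):
    jac = jacobian(params, x)
    r = (forward(params, x) - y).ravel()
    # J^T J via a rank-k update on the (fortran-contiguous) transpose.
    jt = jac.T
    try:
        jtj = sla.blas.dsyrk(1.0, jt)
        jtj = jtj + np.triu(jtj, 1).T
    except Exception:  # pragma: no cover - BLAS fallback
        jtj = jt @ jac
    jtr = jt @ r
    return jtj, jtr, r


def lm_step(state: LMState, params: MLPParams, x: np.ndarray, y: np.ndarray,
            config: TrainConfig) -> tuple[MLPParams, LMState, bool]:
    """One Levenberg-Marquardt epoch on the training batch.

    Returns (params, state, accepted).  The training MSE after an accepted
    step is strictly lower than before; a rejected epoch leaves the
    parameters unchanged and flags the state as stalled once ``lam``
    exceeds ``lam_max``.
    """
    jtj, jtr, r = _normal_matrices(params, x, y)
    mse0 = float(np.mean(r * r))
    n_res = r.size
    vec = params.to_vector()
    eye = np.eye(vec.size)
    for _ in range(config.max_retries):
        try:
            cf = sla.cho_factor(jtj + state.lam * eye, check_finite=False)
            delta = sla.cho_solve(cf, -jtr, check_finite=False)
        except np.linalg.LinAlgError:
            state.lam *= config.lam_factor
            continue
        cand = params.with_vector(vec + delta)
        rc = (forward(cand, x) - y).ravel()
        mse1 = float(rc @ rc) / n_res
        if np.isfinite(mse1) and mse1 < mse0:
            state.lam = max(state.lam / config.lam_factor, 1e-12)
            return cand, state, True
        state.lam *= config.lam_factor
        if state.lam > config.lam_max:
            break
    if state.lam > config.lam_max:
        state.stalled = True
    return params, state, False


def train(x_train: np.ndarray, y_train: np.ndarray,
          x_val: np.ndarray, y_val: np.ndarray,
          config: TrainConfig, rng: np.random.Generator,
          params: MLPParams | None = None,
          input_bounds: tuple[np.ndarray, np.ndarray] | None = None,
          ) -> tuple[MLPParams, LMState]:
    """Train an MLP with LM + validation early stopping; deterministic.

    Runs ``config.n_restarts`` independent initialisations (child RNG
    streams) and returns the snapshot with the lowest validation MSE,
    along with that run's optimiser state and loss histories.  Restart
    selection uses validation data only.
    """
    if params is None and config.n_restarts > 1:
        best: tuple[MLPParams, LMState] | None = None
        for stream in rng.spawn(config.n_restarts):
            cand = train(x_train, y_train, x_val, y_val,
                         replace(config, n_restarts=1), stream,
                         input_bounds=input_bounds)
            if best is None or cand[1].best_val_mse < best[1].best_val_mse:
                best = cand
        return best
    x_train = np.asarray(x_train, dtype=float)
    y_train = np.atleast_2d(np.asarray(y_train, dtype=float))
    x_val = np.asarray(x_val, dtype=float)
    y_val = np.atleast_2d(np.asarray(y_val, dtype=float))
    if params is None:
        if input_bounds is None:
            lo, hi = x_train.min(axis=0), x_train.max(axis=0)
        else:
            lo, hi = input_bounds
        sizes = (x_train.shape[1], *config.hidden, y_train.shape[1])
        params = init_params(sizes, lo, hi, rng, mode=config.init)
    state = LMState(lam=config.lam0)
    state.best_params = params.copy()
    state.best_val_mse = _mse(params, x_val, y_val)
    while state.epoch < config.max_epochs:
        params, state, accepted = lm_step(state, params, x_train, y_train, config)
        state.epoch += 1
        train_mse = _mse(params, x_train, y_train)
        val_mse = _mse(params, x_val, y_val)
        if not np.isfinite(train_mse):
            raise RuntimeError("training diverged: non-finite loss")
        state.train_history.append(train_mse)
        state.val_history.append(val_mse)
        if val_mse < state.best_val_mse:
            state.best_val_mse = val_mse
            state.best_params = params.copy()
            state.val_fail_count = 0
        else:
            state.val_fail_count += 1
        if state.val_fail_count >= config.patience:
            break
        if state.stalled or train_mse <= config.mse_goal:
            break
    return state.best_params, state


def _partition_matrices(df: pd.DataFrame):
    xcols, tcols = input_columns(), target_columns()
    out = {}
    for part in ("train", "val", "test"):
        sub = df[df["partition"] == part]
        out[part] = (sub[xcols].to_numpy(float), sub[tcols].to_numpy(float))
    return out

def fit_surrogate(df: pd.DataFrame, config: TrainConfig,
                  rng: np.random.Generator) -> tuple[MLPParams, LMState]:
    """Train on a partitioned dataset table (transformed-target columns)."""
    parts = _partition_matrices(df)
    return train(*parts["train"], *parts["val"], config, rng)


def grid_search(df: pd.DataFrame, rng: np.random.Generator,
                h1_range=range(10, 21), h2_range=range(10, 41),
                config: TrainConfig | None = None,
                ) -> tuple[pd.DataFrame, tuple[int, int]]:
    """Validation-RMSE table over hidden-layer sizes; returns the argmin.

    One network is trained per (h1, h2) with a child RNG stream, and the
    validation RMSE (transformed space, all outputs pooled) is recorded.
    """
    if config is None:
        config = TrainConfig()
    parts = _partition_matrices(df)
    table = pd.DataFrame(index=list(h1_range), columns=list(h2_range), dtype=float)
    streams = rng.spawn(len(table.index) * len(table.columns))
    k = 0
    for h1 in table.index:
        for h2 in table.columns:
            cfg = replace(config, hidden=(int(h1), int(h2)))
            params, state = train(*parts["train"], *parts["val"], cfg, streams[k])
            k += 1
            table.loc[h1, h2] = np.sqrt(_mse(params, *parts["val"]))
    best_flat = np.unravel_index(np.nanargmin(table.to_numpy()), table.shape)
    best = (int(table.index[best_flat[0]]), int(table.columns[best_flat[1]]))
    return table, best


def predict_spectrum(params: MLPParams, design: DesignPoint,
                     renormalize: bool = True) -> SingleEventSpectrum:
    """Surrogate prediction as a spectrum object.

    The forward pass is inverse-transformed (undo the +1/ln and the x4
    z_max scale), negative densities are clipped to zero and, by default,
    the density is renormalised to unit area (recorded via ``n_events=0``
    metadata convention: predicted spectra carry no event count).
    """
    t = forward(params, design.as_inputs())
    z_max, f = inverse_transform_targets(t)
    if z_max <= 0:
        raise ValueError(f"non-positive predicted z_max ({z_max:.4g} Gy)")
    f = np.maximum(f, 0.0)
    if renormalize:
        area = float(np.sum(f)) * z_max / N_BINS
        if area <= 0:
            raise ValueError("predicted spectrum has zero area")
        f = f / area
    return SingleEventSpectrum(z_max=float(z_max), f=f, n_events=0)


def save_model(params: MLPParams, path) -> None:
    """Persist as a plain structured text (JSON) file."""
    doc = {
        "sizes": list(params.sizes),
        "input_lo": params.input_lo.tolist(),
        "input_hi": params.input_hi.tolist(),
        "weights": [w.tolist() for w in params.weights],
        "biases": [b.tolist() for b in params.biases],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> MLPParams:
    with open(path) as fh:
        doc = json.load(fh)
    return MLPParams(
        sizes=tuple(doc["sizes"]),
        weights=[np.asarray(w, dtype=float) for w in doc["weights"]],
        biases=[np.asarray(b, dtype=float) for b in doc["biases"]],
        input_lo=np.asarray(doc["input_lo"], dtype=float),
        input_hi=np.asarray(doc["input_hi"], dtype=float),
    )
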