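"""A permutation-invariant set regressor (DeepSets) in plain NumPy.

The architecture is the standard sum-decomposition for set functions:
``f(S) = rho(mean_{x in S} phi(x))`` with a shared per-element MLP ``phi``,
mean pooling, and a post-pooling MLP ``rho``.  Mean pooling makes the output
exactly invariant to element order (up to floating-point accumulation) and
insensitive to set cardinality, which suits pixel sets of varying size.

The implementation is deliberately compact: dense layers with ReLU, squared
error loss, Adam updates, manual backpropagation.  Inputs are YCbCr triplets
mapped to [-1, 1]; targets are standardized during training and restored on
prediction.  All randomness (initialisation, batch order, per-set
subsampling) flows from a single seed, so training is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError


@dataclass
class DeepSetsConfig:
    phi_widths: tuple[int, ...] = (64, 64)  # per-element MLP, input width 3
    rho_widths: tuple[int, ...] = (32,)  # post-pool MLP, output width 1
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 16
    max_set_size: int = 256  # training-time subsample cap per set
    seed: int = 0

    def validate(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.max_set_size < 1:
            raise ConfigurationError("epochs, batch size and set cap must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning rate must be > 0")


def _init_mlp(widths: list[int], rng: np.random.Generator) -> list[dict]:
    layers = []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
        layers.append({"w": w, "b": np.zeros(fan_out)})
    return layers


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / (1 - self.beta1**self.t)
            vhat = self.v[i] / (1 - self.beta2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class DeepSetsRegressor:
    """phi -> mean pool -> rho regression over YCbCr pixel sets."""

    def __init__(self, config: DeepSetsConfig | None = None):
        self.config = config or DeepSetsConfig()
        self.config.validate()
        self._phi: list[dict] | None = None
        self._rho: list[dict] | None = None
        self._y_mean = 0.0
        self._y_sd = 1.0
        self._constant: float | None = None

    # --- helpers -----------------------------------------------------------

    @staticmethod
    def _encode(x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=np.float64) - 128.0) / 128.0

    def _params(self) -> list[np.ndarray]:
        out = []
        for layer in (self._phi or []) + (self._rho or []):
            out += [layer["w"], layer["b"]]
        return out

    @staticmethod
    def _mlp_forward(layers: list[dict], x: np.ndarray, final_linear: bool) -> list[np.ndarray]:
        acts = [x]
        for i, layer in enumerate(layers):
            z = acts[-1] @ layer["w"] + layer["b"]
            last = i == len(layers) - 1
            acts.append(z if (final_linear and last) else np.maximum(z, 0.0))
        return acts

    # --- training ----------------------------------------------------------

    def fit(self, sets: list[np.ndarray], targets: np.ndarray) -> "DeepSetsRegressor":
        cfg = self.config
        y = np.asarray(targets, dtype=np.float64)
        if len(sets) != y.shape[0] or len(sets) < 2:
            raise ConfigurationError("need >= 2 sets with one target each")
        rng = np.random.default_rng(cfg.seed)

        self._y_mean = float(y.mean())
        self._y_sd = float(y.std())
        if self._y_sd == 0.0:
            # degenerate target: the optimum is the constant itself
            self._constant = self._y_mean
            return self
        yn = (y - self._y_mean) / self._y_sd

        # seeded per-set subsample to bound the per-step cost
        train_sets = []
        for s in sets:
            s = self._encode(s)
            if s.shape[0] > cfg.max_set_size:
                idx = rng.choice(s.shape[0], cfg.max_set_size, replace=False)
                s = s[idx]
            train_sets.append(s)

        phi_dims = [3, *cfg.phi_widths]
        rho_dims = [cfg.phi_widths[-1], *cfg.rho_widths, 1]
        self._phi = _init_mlp(phi_dims, rng)
        self._rho = _init_mlp(rho_dims, rng)
        opt = _Adam(self._params(), cfg.learning_rate)

        n = len(train_sets)
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                self._train_step(
                    [train_sets[i] for i in batch], yn[batch], opt
                )
        return self

    def _train_step(self, sets: list[np.ndarray], yn: np.ndarray, opt: _Adam) -> None:
        counts = np.array([s.shape[0] for s in sets])
        stacked = np.concatenate(sets, axis=0)
        seg = np.repeat(np.arange(len(sets)), counts)

        phi_acts = self._mlp_forward(self._phi, stacked, final_linear=False)
        pooled = np.zeros((len(sets), phi_acts[-1].shape[1]))
        np.add.at(pooled, seg, phi_acts[-1])
        pooled /= counts[:, None]
        rho_acts = self._mlp_forward(self._rho, pooled, final_linear=True)
        pred = rho_acts[-1][:, 0]

        m = len(sets)
        d_out = (2.0 / m) * (pred - yn)  # d(MSE)/d(pred)

        grads: list[np.ndarray] = []
        # backward through rho
        delta = d_out[:, None]
        rho_grads = []
        for i in range(len(self._rho) - 1, -1, -1):
            a_in = rho_acts[i]
            if i != len(self._rho) - 1:
                delta = delta * (rho_acts[i + 1] > 0)
            rho_grads.append((a_in.T @ delta, delta.sum(axis=0)))
            delta = delta @ self._rho[i]["w"].T
        rho_grads.reverse()

        # broadcast pooled gradient back to elements
        delta_el = delta[seg] / counts[seg][:, None]
        phi_grads = []
        for i in range(len(self._phi) - 1, -1, -1):
            a_in = phi_acts[i]
            delta_el = delta_el * (phi_acts[i + 1] > 0)
            phi_grads.append((a_in.T @ delta_el, delta_el.sum(axis=0)))
            if i > 0:
                delta_el = delta_el @ self._phi[i]["w"].T
        phi_grads.reverse()

        for gw, gb in phi_grads + rho_grads:
            grads += [gw, gb]
        opt.step(self._params(), grads)

    # --- inference ---------------------------------------------------------

    def predict_set(self, triplets: np.ndarray) -> float:
        """Predict from the *full* pixel set; exactly permutation invariant."""
        if self._constant is not None:
            return self._constant
        if self._phi is None:
            raise ConfigurationError("model is not fitted")
        x = self._encode(triplets)
        phi_out = self._mlp_forward(self._phi, x, final_linear=False)[-1]
        pooled = phi_out.mean(axis=0, keepdims=True)
        out = self._mlp_forward(self._rho, pooled, final_linear=True)[-1][0, 0]
        return float(out * self._y_sd + self._y_mean)

    # --- (de)serialization -------------------------------------------------

    def state_dict(self) -> dict:
        return {
            "config": self.config.__dict__.copy(),
            "y_mean": self._y_mean,
            "y_sd": self._y_sd,
            "constant": self._constant,
            "phi": [{"w": l["w"].copy(), "b": l["b"].copy()} for l in self._phi or []],
            "rho": [{"w": l["w"].copy(), "b": l["b"].copy()} for l in self._rho or []],
        }

    @classmethod
    def from_state_dict(cls, state: dict) -> "DeepSetsRegressor":
        cfg = DeepSetsConfig(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in state["config"].items()
        })
        model = cls(cfg)
        model._y_mean = state["y_mean"]
        model._y_sd = state["y_sd"]
        model._constant = state["constant"]
        model._phi = [{"w": np.asarray(l["w"]), "b": np.asarray(l["b"])} for l in state["phi"]] or None
        model._rho = [{"w": np.asarray(l["w"]), "b": np.asarray(l["b"])} for l in state["rho"]] or None
        return model
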