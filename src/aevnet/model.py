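"""Per-element atomic networks whose outputs sum to a pK prediction.

One feed-forward network per chemical species; every atom's AEV row is
propagated through the network of its species and the scalar outputs are
summed to give the predicted affinity (pK units). The decomposition into
per-atom contributions is exact by construction.

Implemented directly on NumPy (no deep-learning framework): forward,
backward, dropout, and the Adam optimizer are all explicit, which keeps
training bit-reproducible from a single integer seed.
"""

from __future__ import annotations

import copy
import csv
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .aev import AEVParams, AEVMatrix, aev_length

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "Prediction",
    "AffinityModel",
    "EnsembleModel",
    "train",
    "consensus_predict",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of each atomic network (output width 1 is implicit)."""

    hidden_sizes: tuple[int, ...] = (256, 128, 64)
    activation: str = "relu"
    dropout_p: float = 0.25
    n_species: int = 10

    def __post_init__(self) -> None:
        object.__setattr__(self, "hidden_sizes", tuple(self.hidden_sizes))
        if not self.hidden_sizes or any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden_sizes must be positive")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.activation != "relu":
            raise ValueError("only 'relu' activation is supported")
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 64
    max_epochs: int = 250
    loss: str = "mse"
    seed: int = 0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    standardize_features: bool = False
    weight_decay: float = 0.0  # decoupled (AdamW-style), weights only
    input_noise: float = 0.0  # train-time Gaussian jitter, units of feature std

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("learning_rate, batch_size, max_epochs must be positive")
        if self.loss != "mse":
            raise ValueError("only 'mse' loss is supported")
        for b in (self.adam_beta1, self.adam_beta2):
            if not 0 < b < 1:
                raise ValueError("adam betas must be in (0, 1)")


@dataclass
class Prediction:
    pk: float
    atomic_contributions: np.ndarray
    std: Optional[float] = None


def _init_layers(sizes: Sequence[int], rng: np.random.Generator):
    """Uniform fan-in (Kaiming-style bound 1/sqrt(fan_in)) initialisation."""
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        bound = 1.0 / math.sqrt(fan_in)
        weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
        biases.append(rng.uniform(-bound, bound, size=fan_out))
    return weights, biases


class AffinityModel:
    """Stack of per-species feed-forward networks with sum pooling.

    Parameters are plain float64 arrays: ``weights[s][l]`` / ``biases[s][l]``
    for species ``s``, layer ``l``. The species order is frozen in
    ``aev_params.species`` and stored with every checkpoint.
    """

    def __init__(self, spec: NetworkSpec, aev_params: AEVParams,
                 seed: int = 0) -> None:
        if spec.n_species != aev_params.n_species:
            raise ValueError("spec.n_species must match aev_params.species")
        self.spec = spec
        self.aev_params = aev_params
        self.input_width = aev_length(aev_params)
        sizes = [self.input_width, *spec.hidden_sizes, 1]
        rng = np.random.default_rng(seed)
        self.weights: list[list[np.ndarray]] = []
        self.biases: list[list[np.ndarray]] = []
        for _ in range(spec.n_species):
            w, b = _init_layers(sizes, rng)
            self.weights.append(w)
            self.biases.append(b)
        # optional per-feature affine input scaling (off unless fitted)
        self.feature_mean: Optional[np.ndarray] = None
        self.feature_scale: Optional[np.ndarray] = None
        self.feature_clip: Optional[float] = None

    def set_feature_scaler(self, mean: np.ndarray, scale: np.ndarray,
                           clip: Optional[float] = 10.0) -> None:
        """Per-feature affine input scaling with optional winsorizing.

        ``clip`` bounds standardized inputs: features that were almost
        inactive in training can otherwise blow up on a new system and
        dominate the prediction.
        """
        mean = np.asarray(mean, float)
        scale = np.asarray(scale, float)
        if mean.shape != (self.input_width,) or scale.shape != (self.input_width,):
            raise ValueError("scaler shape mismatch")
        if np.any(scale <= 0):
            raise ValueError("scale entries must be positive")
        self.feature_mean, self.feature_scale = mean, scale
        self.feature_clip = clip

    # -- forward / backward --------------------------------------------

    @property
    def n_layers(self) -> int:
        return len(self.spec.hidden_sizes) + 1

    def species_indices(self, elements: Sequence[str]) -> np.ndarray:
        return np.array(
            [self.aev_params.species_index(e) for e in elements], dtype=np.intp
        )

    def _forward_species(self, s: int, x: np.ndarray, *, train_rng=None,
                         cache: Optional[list] = None) -> np.ndarray:
        """Forward rows ``x`` through network ``s``; dropout only if train_rng."""
        p = self.spec.dropout_p
        h = x
        if self.feature_mean is not None:
            h = (h - self.feature_mean) / self.feature_scale
            if self.feature_clip is not None:
                h = np.clip(h, -self.feature_clip, self.feature_clip)
        for l in range(self.n_layers):
            z = h @ self.weights[s][l] + self.biases[s][l]
            last = l == self.n_layers - 1
            if not last:
                a = np.maximum(z, 0.0)
                if train_rng is not None and p > 0.0:
                    mask = (train_rng.random(a.shape) >= p) / (1.0 - p)
                    a = a * mask
                else:
                    mask = None
                if cache is not None:
                    cache.append((h, z, mask))
                h = a
            else:
                if cache is not None:
                    cache.append((h, z, None))
                h = z
        return h[:, 0]

    def predict(self, aevs: AEVMatrix | np.ndarray,
                species: Sequence[str] | np.ndarray) -> Prediction:
        """Sum of per-atom network outputs; dropout inactive."""
        x = aevs.values if isinstance(aevs, AEVMatrix) else np.asarray(aevs, float)
        if x.ndim != 2 or x.shape[1] != self.input_width:
            raise ValueError(
                f"AEV width {x.shape[1] if x.ndim == 2 else '?'} does not match "
                f"model input width {self.input_width}"
            )
        sp = (np.asarray(species, dtype=np.intp) if not isinstance(species[0], str)
              else self.species_indices(species)) if len(species) else np.empty(0, np.intp)
        if len(sp) != x.shape[0]:
            raise ValueError("species/AEV length mismatch")
        contrib = np.zeros(x.shape[0])
        for s in np.unique(sp):
            rows = np.nonzero(sp == s)[0]
            contrib[rows] = self._forward_species(int(s), x[rows])
        return Prediction(pk=float(contrib.sum()), atomic_contributions=contrib)

    def input_gradients(self, aevs: AEVMatrix | np.ndarray,
                        species: Sequence[str] | np.ndarray) -> np.ndarray:
        """d(total pK)/d(AEV row) for every atom, at inference (no dropout)."""
        x = aevs.values if isinstance(aevs, AEVMatrix) else np.asarray(aevs, float)
        sp = (self.species_indices(species) if len(species) and isinstance(species[0], str)
              else np.asarray(species, dtype=np.intp))
        grads = np.zeros_like(x)
        for s in np.unique(sp):
            rows = np.nonzero(sp == s)[0]
            cache: list = []
            self._forward_species(int(s), x[rows], cache=cache)
            # d out / d out = 1 for each row independently
            delta = np.ones((rows.size, 1))
            for l in range(self.n_layers - 1, -1, -1):
                h, z, _ = cache[l]
                dx = delta @ self.weights[int(s)][l].T
                if l > 0:
                    _, z_prev, mask_prev = cache[l - 1]
                    dx = dx * (z_prev > 0)
                delta = dx
            grads[rows] = delta
        if self.feature_mean is not None:
            grads = grads / self.feature_scale
            if self.feature_clip is not None:
                z = (x - self.feature_mean) / self.feature_scale
                grads = grads * (np.abs(z) <= self.feature_clip)
        return grads

    # -- parameter utilities -------------------------------------------

    def parameters(self):
        for s in range(self.spec.n_species):
            for l in range(self.n_layers):
                yield self.weights[s][l]
                yield self.biases[s][l]

    def copy_parameters(self):
        return copy.deepcopy((self.weights, self.biases))

    def set_parameters(self, params) -> None:
        self.weights, self.biases = copy.deepcopy(params)

    def zero_like_parameters(self):
        return [
            [np.zeros_like(self.weights[s][l]) for l in range(self.n_layers)]
            for s in range(self.spec.n_species)
        ], [
            [np.zeros_like(self.biases[s][l]) for l in range(self.n_layers)]
            for s in range(self.spec.n_species)
        ]


class _Adam:
    def __init__(self, model: AffinityModel, cfg: TrainConfig) -> None:
        self.cfg = cfg
        self.m = model.zero_like_parameters()
        self.v = model.zero_like_parameters()
        self.t = 0

    def step(self, model: AffinityModel, grads_w, grads_b) -> None:
        c = self.cfg
        self.t += 1
        bc1 = 1.0 - c.adam_beta1**self.t
        bc2 = 1.0 - c.adam_beta2**self.t
        for s in range(model.spec.n_species):
            for l in range(model.n_layers):
                if c.weight_decay > 0.0:
                    model.weights[s][l] *= 1.0 - c.learning_rate * c.weight_decay
                for param, grad, m, v in (
                    (model.weights[s][l], grads_w[s][l], self.m[0][s][l], self.v[0][s][l]),
                    (model.biases[s][l], grads_b[s][l], self.m[1][s][l], self.v[1][s][l]),
                ):
                    m *= c.adam_beta1
                    m += (1 - c.adam_beta1) * grad
                    v *= c.adam_beta2
                    v += (1 - c.adam_beta2) * grad**2
                    param -= c.learning_rate * (m / bc1) / (np.sqrt(v / bc2) + c.adam_eps)


def _batch_loss_and_grads(model: AffinityModel, X: np.ndarray, sp: np.ndarray,
                          sys_idx: np.ndarray, y: np.ndarray,
                          rng: Optional[np.random.Generator]):
    """MSE over systems in a batch; returns loss and parameter gradients."""
    n_sys = y.size
    contrib = np.zeros(X.shape[0])
    caches: dict[int, tuple[np.ndarray, list]] = {}
    for s in np.unique(sp):
        rows = np.nonzero(sp == s)[0]
        cache: list = []
        contrib[rows] = model._forward_species(int(s), X[rows], train_rng=rng,
                                               cache=cache)
        caches[int(s)] = (rows, cache)
    pk = np.bincount(sys_idx, weights=contrib, minlength=n_sys)
    resid = pk - y
    loss = float(np.mean(resid**2))
    if not np.isfinite(loss):
        raise FloatingPointError(f"non-finite training loss ({loss})")

    datom = (2.0 / n_sys) * resid[sys_idx]  # d loss / d per-atom output
    gw, gb = model.zero_like_parameters()
    for s, (rows, cache) in caches.items():
        delta = datom[rows][:, None]
        for l in range(model.n_layers - 1, -1, -1):
            h, z, _ = cache[l]
            gw[s][l] += h.T @ delta
            gb[s][l] += delta.sum(axis=0)
            if l > 0:
                dx = delta @ model.weights[s][l].T
                _, z_prev, mask_prev = cache[l - 1]
                dx = dx * (z_prev > 0)
                if mask_prev is not None:
                    dx = dx * mask_prev
                delta = dx
    return loss, gw, gb


def _stack(dataset):
    """Concatenate a list of (AEVMatrix|array, species indices, pk) records."""
    X, sp, sys_idx, y = [], [], [], []
    for b, (aevs, species, pk) in enumerate(dataset):
        x = aevs.values if isinstance(aevs, AEVMatrix) else np.asarray(aevs, float)
        X.append(x)
        sp.append(np.asarray(species, dtype=np.intp))
        sys_idx.append(np.full(x.shape[0], b, dtype=np.intp))
        y.append(pk)
    return (np.concatenate(X), np.concatenate(sp), np.concatenate(sys_idx),
            np.asarray(y, dtype=np.float64))


def _eval_loss(model: AffinityModel, dataset) -> float:
    X, sp, sys_idx, y = _stack(dataset)
    contrib = np.zeros(X.shape[0])
    for s in np.unique(sp):
        rows = np.nonzero(sp == s)[0]
        contrib[rows] = model._forward_species(int(s), X[rows])
    pk = np.bincount(sys_idx, weights=contrib, minlength=y.size)
    return float(np.mean((pk - y) ** 2))


def train(dataset, spec: NetworkSpec, cfg: TrainConfig, val,
          aev_params: AEVParams, *, verbose: bool = False):
    """Minibatch Adam training with best-validation-loss checkpointing.

    ``dataset`` / ``val``: sequences of ``(aev_rows, species_indices, pk)``.
    Returns ``(model, history)`` where history rows are
    ``(epoch, train_loss, val_loss)``. Fully reproducible given cfg.seed.
    """
    if not len(dataset) or not len(val):
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    model = AffinityModel(spec, aev_params, seed=cfg.seed)
    noise_scale = None
    if cfg.standardize_features or cfg.input_noise > 0.0:
        X_all = np.concatenate([
            r[0].values if isinstance(r[0], AEVMatrix) else np.asarray(r[0], float)
            for r in dataset
        ])
        scale = X_all.std(axis=0)
        scale = np.where(scale > 1e-12, scale, 1.0)
        # floor: near-inactive features must not be amplified to spikes
        scale = np.maximum(scale, 0.02 * scale.max())
        if cfg.standardize_features:
            model.set_feature_scaler(X_all.mean(axis=0), scale)
        noise_scale = cfg.input_noise * scale
    opt = _Adam(model, cfg)
    best = (math.inf, model.copy_parameters())
    history: list[tuple[int, float, float]] = []
    n = len(dataset)
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        ep_loss, n_batches = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            batch = [dataset[k] for k in order[start : start + cfg.batch_size]]
            X, sp, sys_idx, y = _stack(batch)
            if cfg.input_noise > 0.0:
                X = X + rng.normal(size=X.shape) * noise_scale
            loss, gw, gb = _batch_loss_and_grads(model, X, sp, sys_idx, y, rng)
            opt.step(model, gw, gb)
            ep_loss += loss
            n_batches += 1
        train_loss = ep_loss / n_batches
        val_loss = _eval_loss(model, val)
        history.append((epoch, train_loss, val_loss))
        if val_loss < best[0]:
            best = (val_loss, model.copy_parameters())
        if verbose and (epoch % 10 == 0 or epoch == 1):
            print(f"epoch {epoch:4d}  train {train_loss:.5f}  val {val_loss:.5f}")
    model.set_parameters(best[1])
    return model, history


def write_history_csv(history, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch", "train_loss", "val_loss"])
        w.writerows(history)


# ---------------------------------------------------------------------------
# Ensembles


class EnsembleModel:
    """k independently initialised/trained models; consensus mean and spread."""

    def __init__(self, members: Sequence[AffinityModel]) -> None:
        if not members:
            raise ValueError("empty ensemble")
        self.members = list(members)

    def predict(self, aevs, species) -> Prediction:
        return consensus_predict(self.members, aevs, species)


def consensus_predict(members: Sequence[AffinityModel], aevs, species) -> Prediction:
    """Mean pK over members; std is the population standard deviation."""
    if not members:
        raise ValueError("empty ensemble")
    preds = [m.predict(aevs, species) for m in members]
    pks = np.array([p.pk for p in preds])
    contrib = np.mean([p.atomic_contributions for p in preds], axis=0)
    return Prediction(pk=float(pks.mean()),
                      atomic_contributions=contrib,
                      std=float(pks.std()))


# ---------------------------------------------------------------------------
# Checkpoints (self-describing: spec + AEV params + species order + weights)


def save_checkpoint(model: AffinityModel, path) -> None:
    meta = {
        "format": "aevnet-checkpoint-1",
        "network_spec": {
            "hidden_sizes": list(model.spec.hidden_sizes),
            "activation": model.spec.activation,
            "dropout_p": model.spec.dropout_p,
            "n_species": model.spec.n_species,
        },
        "aev_params": model.aev_params.to_dict(),
        "species_order": list(model.aev_params.species),
    }
    if model.feature_mean is not None and model.feature_clip is not None:
        meta["feature_clip"] = model.feature_clip
    arrays = {"__meta__": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    if model.feature_mean is not None:
        arrays["feature_mean"] = model.feature_mean
        arrays["feature_scale"] = model.feature_scale
    for s in range(model.spec.n_species):
        for l in range(model.n_layers):
            arrays[f"w_{s}_{l}"] = model.weights[s][l]
            arrays[f"b_{s}_{l}"] = model.biases[s][l]
    np.savez(path, **arrays)


def load_checkpoint(path) -> AffinityModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("format") != "aevnet-checkpoint-1":
            raise ValueError(f"{path}: not an aevnet checkpoint")
        spec = NetworkSpec(**meta["network_spec"])
        aev_params = AEVParams.from_dict(meta["aev_params"])
        model = AffinityModel(spec, aev_params, seed=0)
        if "feature_mean" in data:
            model.set_feature_scaler(data["feature_mean"], data["feature_scale"],
                                     clip=meta.get("feature_clip"))
        for s in range(spec.n_species):
            for l in range(model.n_layers):
                model.weights[s][l] = data[f"w_{s}_{l}"].copy()
                model.biases[s][l] = data[f"b_{s}_{l}"].copy()
    return model
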