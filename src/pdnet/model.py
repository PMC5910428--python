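"""Residue-type probability network with shared per-neighbor subnetworks.

Architecture.  Each of the N target–neighbor feature rows of a cluster is fed
to two subnetworks that *share parameters across neighbor slots*:

* the **residue-probability subnetwork** maps a 31-feature row to 20 softmax
  probabilities;
* the **weight subnetwork** maps the same row to a single scalar weight
  (softplus by default, so the weight is a nonnegative relevance measure).

Each neighbor's probability vector is multiplied by its weight, the N scaled
vectors are concatenated in ascending-neighbor-distance order (20·N values)
and passed through a fully connected head ending in a 20-way softmax: the
predicted probabilities of the 20 amino acids for the central residue.

Training minimizes class-weighted categorical cross-entropy (sample weight
W_i = N_max/N_i for native class i) by mini-batch stochastic gradient descent
with Nesterov momentum.  Everything — forward pass, backpropagation through
the weighted concatenation and the shared subnets, and the optimizer — is
implemented in NumPy; gradients for the shared subnets accumulate over all
neighbor slots because the slots literally reuse the same arrays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .dataset import Dataset, class_weights
from .geometry_features import FEATURE_VERSION, PAIR_FEATURE_SIZE, ChainContext
from .structure_io import ResidueRecord

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "ModelParams",
    "PredictionProfile",
    "TrainingError",
    "forward_prob_subnet",
    "forward_weight_subnet",
    "forward_full",
    "categorical_cross_entropy",
    "train",
    "predict_profile",
    "save_model",
    "load_model",
]

MODEL_FILE_VERSION = 1


class TrainingError(RuntimeError):
    """Training aborted (empty fold, NaN loss, shape mismatch)."""


@dataclass
class ModelConfig:
    """Layer sizes and architectural switches.

    Hidden widths are tunable configuration, not part of the method: the
    defaults are a compromise between capacity and desk-scale speed.
    ``weight_activation`` is ``softplus`` (nonnegative, interpretable
    weights) or ``linear``.
    """

    n_neighbors: int = 15
    prob_hidden: tuple[int, ...] = (64, 64)
    weight_hidden: tuple[int, ...] = (32, 32)
    head_hidden: tuple[int, ...] = (256, 256)
    weight_activation: str = "softplus"
    standardize: bool = True
    feature_version: str = FEATURE_VERSION

    def __post_init__(self) -> None:
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if self.weight_activation not in ("softplus", "linear"):
            raise ValueError("weight_activation must be 'softplus' or 'linear'")


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    Defaults are the full-scale settings (learning rate 0.01, Nesterov
    momentum 0.9, batch 40 000, 1000 epochs); desk-scale runs pass smaller
    ``batch_size`` / ``epochs``.
    """

    learning_rate: float = 0.01
    nesterov_momentum: float = 0.9
    batch_size: int = 40000
    epochs: int = 1000
    seed: int = 0
    class_weighting: bool = True

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.epochs) <= 0:
            raise ValueError("learning_rate, batch_size and epochs must be positive")
        if not 0 <= self.nesterov_momentum < 1:
            raise ValueError("nesterov_momentum must lie in [0, 1)")


def _he_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _init_stack(rng: np.random.Generator, sizes: list[int]) -> list[list[np.ndarray]]:
    return [[_he_uniform(rng, a, b), np.zeros(b)] for a, b in zip(sizes[:-1], sizes[1:])]


@dataclass
class ModelParams:
    """All trainable arrays plus the configuration they were built for."""

    config: ModelConfig
    prob_subnet: list  # [[W, b], ...] — hidden ReLU layers then 20-logit layer
    weight_subnet: list  # hidden ReLU layers then 1-logit layer
    head: list  # hidden ReLU layers then 20-logit layer
    feature_mean: np.ndarray = field(default_factory=lambda: np.zeros(PAIR_FEATURE_SIZE))
    feature_scale: np.ndarray = field(default_factory=lambda: np.ones(PAIR_FEATURE_SIZE))

    @classmethod
    def initialize(cls, config: ModelConfig, seed: int = 0) -> "ModelParams":
        rng = np.random.default_rng(seed)
        return cls(
            config=config,
            prob_subnet=_init_stack(rng, [PAIR_FEATURE_SIZE, *config.prob_hidden, 20]),
            weight_subnet=_init_stack(rng, [PAIR_FEATURE_SIZE, *config.weight_hidden, 1]),
            head=_init_stack(rng, [20 * config.n_neighbors, *config.head_hidden, 20]),
        )

    def all_layers(self) -> list:
        return [*self.prob_subnet, *self.weight_subnet, *self.head]


# ---------------------------------------------------------------------------
# Forward passes


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def _mlp_forward(x: np.ndarray, layers: list) -> tuple[np.ndarray, list[np.ndarray]]:
    """ReLU MLP up to the final linear layer; returns logits and activations."""
    acts = [x]
    h = x
    for w, b in layers[:-1]:
        h = np.maximum(h @ w + b, 0.0)
        acts.append(h)
    w, b = layers[-1]
    return h @ w + b, acts


def _check_pairs(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != PAIR_FEATURE_SIZE:
        raise ValueError(f"pair features must have {PAIR_FEATURE_SIZE} values, "
                         f"got {x.shape[-1]}")
    return x


def _standardized(x: np.ndarray, params: ModelParams) -> np.ndarray:
    if not params.config.standardize:
        return x
    return (x - params.feature_mean) / params.feature_scale


def forward_prob_subnet(pairs: np.ndarray, params: ModelParams) -> np.ndarray:
    """20 residue-type probabilities for each pair-feature row (sum to 1)."""
    x = _standardized(_check_pairs(pairs), params)
    logits, _ = _mlp_forward(x, params.prob_subnet)
    return _softmax(logits)


def forward_weight_subnet(pairs: np.ndarray, params: ModelParams) -> np.ndarray:
    """Scalar relevance weight for each pair-feature row."""
    x = _standardized(_check_pairs(pairs), params)
    logits, _ = _mlp_forward(x, params.weight_subnet)
    w = _softplus(logits) if params.config.weight_activation == "softplus" else logits
    return w[..., 0]


def forward_full(clusters: np.ndarray, params: ModelParams) -> np.ndarray:
    """Predicted 20-way probability for each cluster.

    ``clusters`` has shape (N, 31) or (batch, N, 31), rows in ascending
    neighbor distance; the concatenation order is significant.
    """
    x = _check_pairs(np.asarray(clusters, dtype=float))
    single = x.ndim == 2
    if single:
        x = x[None]
    n = params.config.n_neighbors
    if x.shape[1] != n:
        raise ValueError(f"cluster has {x.shape[1]} neighbor rows, model expects {n}")
    b = x.shape[0]
    flat = x.reshape(b * n, PAIR_FEATURE_SIZE)
    p = forward_prob_subnet(flat, params).reshape(b, n, 20)
    w = forward_weight_subnet(flat, params).reshape(b, n, 1)
    concat = (w * p).reshape(b, n * 20)
    logits, _ = _mlp_forward(concat, params.head)
    out = _softmax(logits)
    return out[0] if single else out


def categorical_cross_entropy(probs: np.ndarray, labels: np.ndarray,
                              sample_weights: np.ndarray | None = None,
                              eps: float = 1e-12) -> float:
    """(Weighted) mean negative log-probability of the true class."""
    probs = np.atleast_2d(probs)
    labels = np.atleast_1d(labels)
    nll = -np.log(probs[np.arange(len(labels)), labels] + eps)
    if sample_weights is None:
        return float(nll.mean())
    sw = np.asarray(sample_weights, dtype=float)
    return float((sw * nll).sum() / sw.sum())


# ---------------------------------------------------------------------------
# Training (manual backprop + SGD with Nesterov momentum)


def _mlp_backward(dlogits: np.ndarray, acts: list[np.ndarray], layers: list,
                  grads: list) -> np.ndarray:
    """Backprop through `_mlp_forward`; accumulates into `grads`, returns dx."""
    delta = dlogits
    for li in range(len(layers) - 1, -1, -1):
        w, _ = layers[li]
        a = acts[li]
        grads[li][0] += a.T @ delta
        grads[li][1] += delta.sum(axis=0)
        delta = delta @ w.T
        if li > 0:
            delta = delta * (a > 0)
    return delta


def _full_forward_backward(params: ModelParams, x: np.ndarray, y: np.ndarray,
                           sw: np.ndarray) -> tuple[float, list]:
    """Loss and gradients for one batch; x is (b, N, 31) standardized."""
    cfg = params.config
    b, n = x.shape[0], cfg.n_neighbors
    flat = x.reshape(b * n, PAIR_FEATURE_SIZE)

    p_logits, p_acts = _mlp_forward(flat, params.prob_subnet)
    p = _softmax(p_logits)
    w_logits, w_acts = _mlp_forward(flat, params.weight_subnet)
    if cfg.weight_activation == "softplus":
        wgt = _softplus(w_logits)
    else:
        wgt = w_logits
    p3 = p.reshape(b, n, 20)
    w3 = wgt.reshape(b, n, 1)
    concat = (w3 * p3).reshape(b, n * 20)
    logits, h_acts = _mlp_forward(concat, params.head)
    out = _softmax(logits)

    sw_sum = sw.sum()
    nll = -np.log(out[np.arange(b), y] + 1e-12)
    loss = float((sw * nll).sum() / sw_sum)
    if not np.isfinite(loss):
        raise TrainingError("NaN/inf loss encountered")

    # d loss / d logits of the head softmax + cross entropy.
    dlogits = out.copy()
    dlogits[np.arange(b), y] -= 1.0
    dlogits *= (sw / sw_sum)[:, None]

    grads = [[np.zeros_like(w), np.zeros_like(bb)] for w, bb in params.all_layers()]
    n_prob, n_wsub = len(params.prob_subnet), len(params.weight_subnet)
    g_prob, g_wsub, g_head = (grads[:n_prob], grads[n_prob:n_prob + n_wsub],
                              grads[n_prob + n_wsub:])

    dconcat = _mlp_backward(dlogits, h_acts, params.head, g_head)
    dv = dconcat.reshape(b, n, 20)
    dw3 = (dv * p3).sum(axis=2, keepdims=True)
    dp3 = dv * w3

    # Weight subnet: softplus' = sigmoid.
    dw_logits = dw3.reshape(b * n, 1)
    if cfg.weight_activation == "softplus":
        dw_logits = dw_logits / (1.0 + np.exp(-w_logits))
    _mlp_backward(dw_logits, w_acts, params.weight_subnet, g_wsub)

    # Probability subnet: softmax Jacobian.
    dp = dp3.reshape(b * n, 20)
    dp_logits = p * (dp - (dp * p).sum(axis=1, keepdims=True))
    _mlp_backward(dp_logits, p_acts, params.prob_subnet, g_prob)
    return loss, grads


def train(dataset: Dataset, config: TrainConfig | None = None,
          model_config: ModelConfig | None = None,
          val_fold: int | None = None) -> tuple[ModelParams, list[float]]:
    """Fit the network on a dataset; returns parameters and per-epoch loss.

    ``val_fold`` designates one cross-validation fold as held-out (excluded
    from training); pass ``None`` to train on everything.  Deterministic for
    a given ``config.seed`` up to floating-point reduction order.
    """
    cfg = config or TrainConfig()
    mask = np.ones(len(dataset.labels), dtype=bool) if val_fold is None \
        else dataset.folds != val_fold
    x = np.asarray(dataset.features[mask], dtype=float)
    y = np.asarray(dataset.labels[mask], dtype=int)
    if len(y) == 0:
        raise TrainingError("training fold is empty")

    mcfg = model_config or ModelConfig(n_neighbors=dataset.manifest.n_neighbors)
    if mcfg.n_neighbors != dataset.manifest.n_neighbors:
        raise TrainingError(
            f"model n_neighbors={mcfg.n_neighbors} but dataset has "
            f"N={dataset.manifest.n_neighbors}")
    params = ModelParams.initialize(mcfg, seed=cfg.seed)
    if mcfg.standardize:
        flat = x.reshape(-1, PAIR_FEATURE_SIZE)
        params.feature_mean = flat.mean(axis=0)
        params.feature_scale = np.maximum(flat.std(axis=0), 1e-6)
        x = (x - params.feature_mean) / params.feature_scale
        # _full_forward_backward receives pre-standardized batches.

    if cfg.class_weighting:
        counts = np.bincount(y, minlength=20)
        cw = class_weights(counts)
        sample_w = cw[y]
    else:
        sample_w = np.ones(len(y))

    layers = params.all_layers()
    velocity = [[np.zeros_like(w), np.zeros_like(b)] for w, b in layers]
    rng = np.random.default_rng(cfg.seed)
    mom, lr = cfg.nesterov_momentum, cfg.learning_rate
    trace: list[float] = []
    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(y))
        losses, weights = [], []
        for start in range(0, len(y), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss, grads = _full_forward_backward(params, x[idx], y[idx], sample_w[idx])
            losses.append(loss)
            weights.append(sample_w[idx].sum())
            for (w, b), (vw, vb), (gw, gb) in zip(layers, velocity, grads):
                vw *= mom
                vw -= lr * gw
                vb *= mom
                vb -= lr * gb
                # Nesterov look-ahead update.
                w += mom * vw - lr * gw
                b += mom * vb - lr * gb
        trace.append(float(np.average(losses, weights=weights)))
    return params, trace


# ---------------------------------------------------------------------------
# Inference on structures


@dataclass
class PredictionProfile:
    """Per-position 20-way probabilities (alphabetical amino-acid order)."""

    position_ids: list[str]
    probabilities: np.ndarray  # (L, 20), rows sum to 1
    native: list[str] | None = None  # one-letter codes when known
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (position, reason)

    def __len__(self) -> int:
        return len(self.position_ids)


def predict_profile(residues: list[ResidueRecord], params: ModelParams,
                    n_neighbors: int | None = None) -> PredictionProfile:
    """Predict the amino-acid probability profile of a backbone.

    One profile row per residue for which a cluster can be formed; residues
    that cannot be featurized (missing backbone atoms, too few neighbors)
    are listed in ``skipped`` with a reason rather than silently dropped.
    Occupancy is not screened at prediction time — the structure is taken
    as given.
    """
    from .dataset import extract_clusters

    n = n_neighbors if n_neighbors is not None else params.config.n_neighbors
    if n != params.config.n_neighbors:
        raise ValueError(f"model was trained for N={params.config.n_neighbors}, "
                         f"requested N={n}")
    ctx = ChainContext(residues, skip_incomplete=True)
    result = extract_clusters(residues, n, require_full_occupancy=False,
                              require_standard_target=False, context=ctx)
    if not result.clusters:
        raise ValueError("no residue could be featurized for prediction")
    feats = np.stack([c.features for c in result.clusters])
    probs = forward_full(feats, params)
    return PredictionProfile(
        position_ids=[c.position_id for c in result.clusters],
        probabilities=np.atleast_2d(probs),
        native=[residues[c.target_index].aa_type for c in result.clusters],
        skipped=result.dropped,
    )


# ---------------------------------------------------------------------------
# Parameter persistence


def save_model(params: ModelParams, path) -> None:
    """Write a versioned .npz parameter archive."""
    arrays: dict[str, np.ndarray] = {
        "feature_mean": params.feature_mean,
        "feature_scale": params.feature_scale,
    }
    for group, layers in (("prob", params.prob_subnet),
                          ("wsub", params.weight_subnet),
                          ("head", params.head)):
        for i, (w, b) in enumerate(layers):
            arrays[f"{group}_{i}_w"] = w
            arrays[f"{group}_{i}_b"] = b
    meta = {"file_version": MODEL_FILE_VERSION, "config": asdict(params.config)}
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path) -> ModelParams:
    """Read a parameter archive; validates the feature-order version."""
    with np.load(path) as f:
        meta = json.loads(bytes(f["meta_json"]).decode())
        if meta["file_version"] != MODEL_FILE_VERSION:
            raise ValueError(f"model file version {meta['file_version']} unsupported")
        cfg_dict = meta["config"]
        for key in ("prob_hidden", "weight_hidden", "head_hidden"):
            cfg_dict[key] = tuple(cfg_dict[key])
        config = ModelConfig(**cfg_dict)
        if config.feature_version != FEATURE_VERSION:
            raise ValueError(f"model feature order {config.feature_version!r} "
                             f"!= current {FEATURE_VERSION!r}")

        def stack(group: str, n_layers: int) -> list:
            return [[f[f"{group}_{i}_w"], f[f"{group}_{i}_b"]] for i in range(n_layers)]

        return ModelParams(
            config=config,
            prob_subnet=stack("prob", len(config.prob_hidden) + 1),
            weight_subnet=stack("wsub", len(config.weight_hidden) + 1),
            head=stack("head", len(config.head_hidden) + 1),
            feature_mean=f["feature_mean"],
            feature_scale=f["feature_scale"],
        )
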