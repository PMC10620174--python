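"""Dual adversarial deconfounding autoencoder (Dual AD-AE).

A fully-connected autoencoder (d -> 32 -> 16 -> 32 -> d, rectifier hidden
units, linear outputs) compresses each lesion's radiomic vector into a
16-dimensional embedding. Two adversarial classification heads (16 -> 50 ->
50 -> n_classes) branch from the embedding and try to predict the center and
the scanner. Training alternates two steps per mini-batch:

* adversary step — update only the heads (nu1, nu2), minimizing the
  categorical cross-entropy of their center/scanner predictions;
* autoencoder step — update only encoder/decoder (phi, psi), minimizing

      MSE(x, g_psi(f_phi(x)))  -  lambda1 * L(h_nu1(f_phi(x)), c)
                               -  lambda2 * L(h_nu2(f_phi(x)), s)

  i.e. reconstruction minus the lambda-weighted adversary losses, so the
  encoder learns embeddings from which the confounders cannot be predicted.
  The reconstruction term is the squared error averaged over samples *and*
  features (the convention of the deconfounding-autoencoder lineage); with
  per-sample summed squared norms instead, lambda = 1 would leave the
  cross-entropy terms numerically irrelevant and no deconfusion pressure.

The networks are small enough that plain numpy with hand-written
backpropagation and Adam is fast; gradients are norm-clipped because the
maximized adversary term is unbounded. Early stopping monitors the same
objective on a held-out lesion-level validation split and the best-validation
snapshot is returned.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .core_data import LesionTable

GRAD_CLIP_NORM = 5.0


class SpecError(ValueError):
    """Invalid architecture specification."""


class TrainingError(RuntimeError):
    """Training preconditions violated (e.g. label missing from the train split)."""


class DivergenceError(RuntimeError):
    """Loss became non-finite during training."""


# ---------------------------------------------------------------------------
# Specs and configs
# ---------------------------------------------------------------------------

@dataclass
class ArchitectureSpec:
    """Layer widths; defaults are the published architecture for d = 45
    features, 2 centers and 5 scanners."""

    input_dim: int = 45
    encoder_widths: tuple[int, ...] = (45, 32, 16)
    decoder_widths: tuple[int, ...] = (16, 32, 45)
    adversary_hidden: tuple[int, ...] = (50, 50)
    n_centers: int = 2
    n_scanners: int = 5

    def __post_init__(self) -> None:
        if self.encoder_widths[0] != self.input_dim or self.decoder_widths[-1] != self.input_dim:
            raise SpecError("encoder input and decoder output must equal input_dim")
        emb = self.encoder_widths[-1]
        if self.decoder_widths[0] != emb:
            raise SpecError(
                f"embedding width {emb} != decoder input width {self.decoder_widths[0]}"
            )
        if min(self.n_centers, self.n_scanners) < 2:
            raise SpecError("each confounder needs >= 2 classes")

    @property
    def embedding_dim(self) -> int:
        return self.encoder_widths[-1]

    def head_widths(self, n_classes: int) -> tuple[int, ...]:
        return (self.embedding_dim, *self.adversary_hidden, n_classes)

    @classmethod
    def for_data(cls, d: int, n_centers: int, n_scanners: int) -> "ArchitectureSpec":
        return cls(
            input_dim=d,
            encoder_widths=(d, 32, 16),
            decoder_widths=(16, 32, d),
            n_centers=n_centers,
            n_scanners=n_scanners,
        )


@dataclass
class TrainingConfig:
    """Published training settings: batch 128, lambda1 = lambda2 = 1; the
    optimizer, patience and validation split are package choices."""

    lambda1: float = 1.0
    lambda2: float = 1.0
    batch_size: int = 128
    adversary_steps_per_ae_step: int = 5
    lr_ae: float = 1e-3
    lr_adversary: float = 3e-3
    max_epochs: int = 2000
    patience: int = 40
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda weights must be >= 0")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")


# ---------------------------------------------------------------------------
# Dense stacks: forward / backward
# ---------------------------------------------------------------------------

def _init_stack(prefix: str, widths: tuple[int, ...], rng: np.random.Generator, params: dict) -> None:
    # He-normal initialization, matched to the rectifier hidden units
    for i in range(len(widths) - 1):
        fan_in = widths[i]
        params[f"{prefix}.W{i}"] = rng.standard_normal((widths[i], widths[i + 1])) * np.sqrt(
            2.0 / fan_in
        )
        params[f"{prefix}.b{i}"] = np.zeros(widths[i + 1])


def _forward(params: dict, prefix: str, n_layers: int, x: np.ndarray) -> list[np.ndarray]:
    """ReLU hidden layers, linear last layer. Returns all activations,
    caches[0] = input, caches[-1] = output."""
    caches = [x]
    for i in range(n_layers):
        z = caches[-1] @ params[f"{prefix}.W{i}"] + params[f"{prefix}.b{i}"]
        caches.append(np.maximum(z, 0.0) if i < n_layers - 1 else z)
    return caches


def _backward(
    params: dict, prefix: str, n_layers: int, caches: list[np.ndarray], grad_out: np.ndarray
) -> tuple[dict, np.ndarray]:
    """Backprop through the stack; returns (param grads, grad wrt input)."""
    grads = {}
    g = grad_out
    for i in reversed(range(n_layers)):
        if i < n_layers - 1:  # derivative of the rectifier
            g = g * (caches[i + 1] > 0)
        grads[f"{prefix}.W{i}"] = caches[i].T @ g
        grads[f"{prefix}.b{i}"] = g.sum(axis=0)
        g = g @ params[f"{prefix}.W{i}"].T
    return grads, g


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient wrt the logits."""
    n = logits.shape[0]
    p = _softmax(logits)
    loss = float(-np.mean(np.log(np.maximum(p[np.arange(n), labels], 1e-300))))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class _Adam:
    """Standard Adam over a named-parameter subset."""

    def __init__(self, names: list[str], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.names, self.lr, self.b1, self.b2, self.eps = list(names), lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for name in self.names:
            g = grads.get(name)
            if g is None:
                continue
            m = self.m.setdefault(name, np.zeros_like(g))
            v = self.v.setdefault(name, np.zeros_like(g))
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _clip_grads(grads: dict, max_norm: float = GRAD_CLIP_NORM) -> dict:
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        grads = {k: g * scale for k, g in grads.items()}
    return grads


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

_STACKS = ("encoder", "decoder", "head_center", "head_scanner")


@dataclass
class TrainedDualADAE:
    """Parameters of encoder (phi), decoder (psi) and the two adversary heads
    (nu1: center, nu2: scanner), plus the training history."""

    spec: ArchitectureSpec
    params: dict[str, np.ndarray]
    history: dict[str, list] = field(default_factory=dict)
    classes: dict[str, list[str]] = field(default_factory=dict)
    best_epoch: int | None = None

    def _stack_widths(self, stack: str) -> tuple[int, ...]:
        return {
            "encoder": self.spec.encoder_widths,
            "decoder": self.spec.decoder_widths,
            "head_center": self.spec.head_widths(self.spec.n_centers),
            "head_scanner": self.spec.head_widths(self.spec.n_scanners),
        }[stack]

    def _n_layers(self, stack: str) -> int:
        return len(self._stack_widths(stack)) - 1

    def stack_param_names(self, stack: str) -> list[str]:
        return [
            f"{stack}.{kind}{i}" for i in range(self._n_layers(stack)) for kind in ("W", "b")
        ]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # -- persistence: one portable .npz with a JSON metadata entry ----------

    def save(self, path) -> None:
        meta = {
            "spec": asdict(self.spec),
            "history": self.history,
            "classes": self.classes,
            "best_epoch": self.best_epoch,
        }
        np.savez(
            path,
            __meta__=np.frombuffer(json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8),
            **self.params,
        )

    @classmethod
    def load(cls, path) -> "TrainedDualADAE":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            params = {k: data[k].copy() for k in data.files if k != "__meta__"}
        spec_dict = meta["spec"]
        for key in ("encoder_widths", "decoder_widths", "adversary_hidden"):
            spec_dict[key] = tuple(spec_dict[key])
        return cls(
            spec=ArchitectureSpec(**spec_dict),
            params=params,
            history=meta["history"],
            classes=meta["classes"],
            best_epoch=meta["best_epoch"],
        )


def init_model(spec: ArchitectureSpec, seed: int) -> TrainedDualADAE:
    """Reproducibly initialize all four stacks (same seed -> identical params)."""
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}
    _init_stack("encoder", spec.encoder_widths, rng, params)
    _init_stack("decoder", spec.decoder_widths, rng, params)
    _init_stack("head_center", spec.head_widths(spec.n_centers), rng, params)
    _init_stack("head_scanner", spec.head_widths(spec.n_scanners), rng, params)
    return TrainedDualADAE(spec=spec, params=params)


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def _as_matrix(model: TrainedDualADAE, data) -> np.ndarray:
    x = data.features if isinstance(data, LesionTable) else np.asarray(data, float)
    if x.ndim != 2 or x.shape[1] != model.spec.input_dim:
        raise ValueError(
            f"expected (n, {model.spec.input_dim}) features, got {x.shape}"
        )
    return x


def encode(model: TrainedDualADAE, data) -> np.ndarray:
    """Embed lesions: rows of the (n, 16) output align with the input rows."""
    x = _as_matrix(model, data)
    return _forward(model.params, "encoder", model._n_layers("encoder"), x)[-1]


def reconstruct(model: TrainedDualADAE, data) -> tuple[np.ndarray, float]:
    """Decode the embedding back to feature space; returns (x_hat, MSE) with
    MSE the mean squared residual over rows and features."""
    x = _as_matrix(model, data)
    emb = encode(model, x)
    xhat = _forward(model.params, "decoder", model._n_layers("decoder"), emb)[-1]
    return xhat, float(np.mean((x - xhat) ** 2))


def head_logits(model: TrainedDualADAE, data, head: str) -> np.ndarray:
    stack = {"center": "head_center", "scanner": "head_scanner"}[head]
    emb = encode(model, data)
    return _forward(model.params, stack, model._n_layers(stack), emb)[-1]


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _objective(
    model: TrainedDualADAE, x: np.ndarray, c: np.ndarray, s: np.ndarray, cfg: TrainingConfig
) -> tuple[float, float, float, float]:
    """(objective, recon, ce_center, ce_scanner) on a data split; recon is the
    squared error averaged over samples and features."""
    p, m = model.params, model
    emb = _forward(p, "encoder", m._n_layers("encoder"), x)[-1]
    xhat = _forward(p, "decoder", m._n_layers("decoder"), emb)[-1]
    recon = float(np.mean((x - xhat) ** 2))
    ce1, _ = _cross_entropy(_forward(p, "head_center", m._n_layers("head_center"), emb)[-1], c)
    ce2, _ = _cross_entropy(_forward(p, "head_scanner", m._n_layers("head_scanner"), emb)[-1], s)
    return recon - cfg.lambda1 * ce1 - cfg.lambda2 * ce2, recon, ce1, ce2


def adversary_step(
    model: TrainedDualADAE,
    x: np.ndarray,
    c: np.ndarray,
    s: np.ndarray,
    opt: _Adam,
) -> tuple[float, float]:
    """Update only the two heads, minimizing their cross-entropies; phi/psi
    are left untouched."""
    p, m = model.params, model
    emb = _forward(p, "encoder", m._n_layers("encoder"), x)[-1]
    grads: dict[str, np.ndarray] = {}
    losses = []
    for stack, labels in (("head_center", c), ("head_scanner", s)):
        caches = _forward(p, stack, m._n_layers(stack), emb)
        loss, gout = _cross_entropy(caches[-1], labels)
        g, _ = _backward(p, stack, m._n_layers(stack), caches, gout)
        grads.update(g)
        losses.append(loss)
    opt.step(p, _clip_grads(grads))
    return losses[0], losses[1]


def ae_step(
    model: TrainedDualADAE,
    x: np.ndarray,
    c: np.ndarray,
    s: np.ndarray,
    cfg: TrainingConfig,
    opt: _Adam,
) -> float:
    """Update only encoder/decoder, minimizing reconstruction minus the
    lambda-weighted adversary losses (heads frozen)."""
    p, m = model.params, model
    enc_caches = _forward(p, "encoder", m._n_layers("encoder"), x)
    emb = enc_caches[-1]
    dec_caches = _forward(p, "decoder", m._n_layers("decoder"), emb)
    xhat = dec_caches[-1]
    recon = float(np.mean((x - xhat) ** 2))

    grad_xhat = 2.0 * (xhat - x) / x.size
    dec_grads, g_emb = _backward(p, "decoder", m._n_layers("decoder"), dec_caches, grad_xhat)

    for stack, labels, lam in (
        ("head_center", c, cfg.lambda1),
        ("head_scanner", s, cfg.lambda2),
    ):
        if lam == 0:
            continue
        caches = _forward(p, stack, m._n_layers(stack), emb)
        _, gout = _cross_entropy(caches[-1], labels)
        _, g_in = _backward(p, stack, m._n_layers(stack), caches, gout)
        g_emb = g_emb - lam * g_in  # encoder *maximizes* the adversary loss

    enc_grads, _ = _backward(p, "encoder", m._n_layers("encoder"), enc_caches, g_emb)
    grads = {**dec_grads, **enc_grads}
    opt.step(p, _clip_grads(grads))
    return recon


def train(
    model: TrainedDualADAE, table: LesionTable, config: TrainingConfig
) -> TrainedDualADAE:
    """Alternating minimax training on a (standardized) lesion table.

    Returns the best-validation snapshot; ``model`` itself is not mutated.
    The per-epoch history records the training reconstruction loss, head
    cross-entropies, and the validation objective.
    """
    model = copy.deepcopy(model)
    cfg = config
    x = _as_matrix(model, table)
    centers = sorted(set(table.df["center"]))
    scanners = sorted(set(table.df["scanner"]))
    if len(centers) != model.spec.n_centers or len(scanners) != model.spec.n_scanners:
        raise TrainingError(
            f"table has {len(centers)} centers / {len(scanners)} scanners; "
            f"spec expects {model.spec.n_centers} / {model.spec.n_scanners}"
        )
    model.classes = {"center": centers, "scanner": scanners}
    c = np.searchsorted(centers, table.df["center"].to_numpy())
    s = np.searchsorted(scanners, table.df["scanner"].to_numpy())

    rng = np.random.default_rng(cfg.seed)
    n = x.shape[0]
    perm = rng.permutation(n)
    n_val = max(int(round(cfg.validation_fraction * n)), 1)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) < cfg.batch_size // 4:
        raise TrainingError("too few training rows after the validation split")
    for name, labels in (("center", c), ("scanner", s)):
        missing = set(labels[val_idx]) - set(labels[tr_idx])
        if missing:
            raise TrainingError(
                f"{name} class(es) {sorted(missing)} present in validation but absent "
                "from training"
            )

    ae_params = model.stack_param_names("encoder") + model.stack_param_names("decoder")
    adv_params = model.stack_param_names("head_center") + model.stack_param_names("head_scanner")
    opt_ae = _Adam(ae_params, cfg.lr_ae)
    opt_adv = _Adam(adv_params, cfg.lr_adversary)
    train_adversaries = cfg.lambda1 > 0 or cfg.lambda2 > 0

    history = {"recon": [], "ce_center": [], "ce_scanner": [], "val_objective": []}
    best_obj, best_params, best_epoch = np.inf, None, None
    stale = 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(tr_idx))
        ep_recon, ep_ce1, ep_ce2, n_batches = 0.0, 0.0, 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            batch = tr_idx[order[start : start + cfg.batch_size]]
            xb, cb, sb = x[batch], c[batch], s[batch]
            if train_adversaries:
                for _ in range(cfg.adversary_steps_per_ae_step):
                    ce1, ce2 = adversary_step(model, xb, cb, sb, opt_adv)
            else:
                ce1 = ce2 = 0.0
            recon = ae_step(model, xb, cb, sb, cfg, opt_ae)
            ep_recon += recon
            ep_ce1 += ce1
            ep_ce2 += ce2
            n_batches += 1
        ep_recon /= n_batches
        if not np.isfinite(ep_recon):
            raise DivergenceError(f"non-finite training loss at epoch {epoch}")

        val_obj, *_ = _objective(model, x[val_idx], c[val_idx], s[val_idx], cfg)
        if not np.isfinite(val_obj):
            raise DivergenceError(f"non-finite validation objective at epoch {epoch}")
        history["recon"].append(ep_recon)
        history["ce_center"].append(ep_ce1 / n_batches)
        history["ce_scanner"].append(ep_ce2 / n_batches)
        history["val_objective"].append(val_obj)

        if val_obj < best_obj:
            best_obj, best_epoch, stale = val_obj, epoch, 0
            best_params = {k: v.copy() for k, v in model.params.items()}
        else:
            stale += 1
            if stale >= cfg.patience:
                break

    model.params = best_params if best_params is not None else model.params
    model.history = history
    model.best_epoch = best_epoch
    return model
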