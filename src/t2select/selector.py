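"""Attention-based feature selector for clinical tabular data.

Each feature is mapped to a learned d-dimensional token (numeric feature j
with value x becomes ``x * w_j + b_j``; a categorical feature looks up a
per-category embedding row), a shared learned CLS token is prepended, and
the sequence passes through pre-norm multi-head self-attention block(s)
with no positional encodings — features are nominal, so tokens carry their
identity through their own parameters, which makes the encoder exactly
equivariant to feature permutations.

Training jointly optimizes

    L_total = L_cls + lambda1 * L_stat + lambda2 * R

where ``L_cls`` is binary cross-entropy of a linear head on the encoded CLS
token, ``L_stat`` is the negative mean per-feature ridge-regularized
Hotelling T² between outcome groups on the encoded feature tokens
(maximizing group separability), and ``R`` is a mean squared-norm penalty
on the encoded tokens that stops the optimizer from inflating the
ridge-regularized T² by simply blowing up the representation scale.
Optimization is full-batch Adam for a fixed number of epochs; everything is
deterministic given the seed.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import _autodiff as ad
from ._autodiff import Tensor
from .cohort import CohortTable, PreprocessorState, apply_preprocessor, fit_preprocessor
from .schema import FeatureSchema


@dataclass(frozen=True)
class SelectorHyperparams:
    """Training hyperparameters.

    Defaults follow the reference configuration: a single transformer layer
    with 8 heads, 32-dimensional tokens, both loss coefficients 1e-5, Adam
    at learning rate 1e-4 and 3500 full-batch epochs.
    """

    d_token: int = 32
    n_layers: int = 1
    n_heads: int = 8
    lr: float = 1e-4
    epochs: int = 3500
    lambda1: float = 1e-5  # weight of the statistical (separability) loss
    lambda2: float = 1e-5  # weight of the embedding-norm regularizer
    ridge: float = 1e-3  # covariance ridge inside the differentiable T²
    posthoc_ridge: float = 0.0  # ridge for the post-training significance test
    ffn_factor: int = 4
    init_scale: float = 0.02
    dtype: str = "float32"  # float64 available for gradient checking
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_token % self.n_heads:
            raise ValueError("d_token must be divisible by n_heads")
        if self.lr <= 0 or self.epochs < 1:
            raise ValueError("lr must be positive and epochs >= 1")
        if min(self.lambda1, self.lambda2, self.ridge, self.posthoc_ridge) < 0:
            raise ValueError("lambda1, lambda2 and ridge must be non-negative")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be float32 or float64")


class TrainingDiverged(RuntimeError):
    pass


_ALLOCATOR_TUNED = False


def _tune_allocator() -> None:
    """Raise glibc's mmap threshold so the large attention buffers are
    recycled from the heap instead of being mapped and faulted afresh every
    epoch.  No-op off glibc; safe to call repeatedly."""
    global _ALLOCATOR_TUNED
    if _ALLOCATOR_TUNED:
        return
    _ALLOCATOR_TUNED = True
    try:
        import ctypes

        libc = ctypes.CDLL("libc.so.6")
        m_mmap_threshold = -3
        libc.mallopt(m_mmap_threshold, 256 * 1024 * 1024)
    except Exception:
        pass


def _init_params(
    schema: FeatureSchema, hp: SelectorHyperparams, rng: np.random.Generator
) -> dict[str, Tensor]:
    d = hp.d_token
    s = hp.init_scale
    dt = np.dtype(hp.dtype)
    params: dict[str, Tensor] = {}
    p = schema.n_features
    params["tok_w"] = ad.parameter(rng.normal(0, s, (p, d)).astype(dt))
    params["tok_b"] = ad.parameter(rng.normal(0, s, (p, d)).astype(dt))
    for spec in schema.specs:
        if spec.kind == "categorical":
            params[f"emb_{spec.name}"] = ad.parameter(
                rng.normal(0, s, (len(spec.categories), d)).astype(dt)
            )
    params["cls"] = ad.parameter(rng.normal(0, s, (d,)).astype(dt))
    for layer in range(hp.n_layers):
        pre = f"l{layer}_"
        params[pre + "ln1_g"] = ad.parameter(np.ones(d, dtype=dt))
        params[pre + "ln1_b"] = ad.parameter(np.zeros(d, dtype=dt))
        for name in ("wq", "wk", "wv", "wo"):
            params[pre + name] = ad.parameter(rng.normal(0, s, (d, d)).astype(dt))
            params[pre + name + "_b"] = ad.parameter(np.zeros(d, dtype=dt))
        params[pre + "ln2_g"] = ad.parameter(np.ones(d, dtype=dt))
        params[pre + "ln2_b"] = ad.parameter(np.zeros(d, dtype=dt))
        h = d * hp.ffn_factor
        params[pre + "ffn1"] = ad.parameter(rng.normal(0, s, (d, h)).astype(dt))
        params[pre + "ffn1_b"] = ad.parameter(np.zeros(h, dtype=dt))
        params[pre + "ffn2"] = ad.parameter(rng.normal(0, s, (h, d)).astype(dt))
        params[pre + "ffn2_b"] = ad.parameter(np.zeros(d, dtype=dt))
    params["head_w"] = ad.parameter(rng.normal(0, s, (d,)).astype(dt))
    params["head_b"] = ad.parameter(np.zeros((), dtype=dt))
    return params


@dataclass
class TrainedSelector:
    """Learned tokenizer/encoder/head parameters plus preprocessing state
    and the full per-epoch training log."""

    schema: FeatureSchema
    hp: SelectorHyperparams
    params: dict[str, Tensor]
    preprocessor: PreprocessorState | None = None
    training_log: pd.DataFrame | None = None

    # -- numpy-facing forward passes -----------------------------------
    def tokenize_cohort(self, table: CohortTable) -> np.ndarray:
        return tokenize(table, self).data

    def encode_cohort(self, table: CohortTable) -> np.ndarray:
        return encode(tokenize(table, self), self).data

    def predict_logits(self, table: CohortTable) -> np.ndarray:
        return classification_logit(encode(tokenize(table, self), self), self).data

    def predict_proba(self, table: CohortTable) -> np.ndarray:
        from scipy.special import expit

        return expit(self.predict_logits(table))

    # -- serialization ---------------------------------------------------
    def save(self, path) -> None:
        arrays = {k: v.data for k, v in self.params.items()}
        meta = {
            "hp": asdict(self.hp),
            "schema": self.schema.to_dict(),
            "preprocessor": None
            if self.preprocessor is None
            else {
                "means": self.preprocessor.means,
                "sds": self.preprocessor.sds,
                "label_maps": self.preprocessor.label_maps,
            },
        }
        arrays["_meta"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        )
        if self.training_log is not None:
            buf = io.StringIO()
            self.training_log.to_csv(buf, index=False)
            arrays["_log"] = np.frombuffer(buf.getvalue().encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "TrainedSelector":
        with np.load(path) as data:
            meta = json.loads(bytes(data["_meta"]).decode())
            schema = FeatureSchema.from_dict(meta["schema"])
            hp = SelectorHyperparams(**meta["hp"])
            params = {
                k: ad.parameter(data[k])
                for k in data.files
                if not k.startswith("_")
            }
            pre = None
            if meta["preprocessor"] is not None:
                pre = PreprocessorState(
                    means=meta["preprocessor"]["means"],
                    sds=meta["preprocessor"]["sds"],
                    label_maps=meta["preprocessor"]["label_maps"],
                    schema=schema,
                )
            log = None
            if "_log" in data.files:
                log = pd.read_csv(io.StringIO(bytes(data["_log"]).decode()))
        return cls(schema=schema, hp=hp, params=params, preprocessor=pre,
                   training_log=log)


# ---------------------------------------------------------------------------
# forward-pass operations


def tokenize(table: CohortTable, selector: TrainedSelector) -> Tensor:
    """Map an encoded cohort to an (n, p+1, d) token array, CLS first."""
    schema = selector.schema
    if table.schema.names != schema.names:
        raise ValueError("cohort schema does not match the selector's schema")
    params = selector.params
    n, p = table.n, table.p
    d = selector.hp.d_token

    dt = selector.params["tok_w"].data.dtype
    x = Tensor(table.values[:, :, None].astype(dt))  # (n, p, 1), constant
    tokens = x * params["tok_w"].reshape(1, p, d) + params["tok_b"].reshape(1, p, d)
    cat_idx = [j for j, s in enumerate(schema.specs) if s.kind == "categorical"]
    if cat_idx:
        # replace the affine tokens of categorical features by embedding rows
        keep = np.array([j for j in range(p) if j not in set(cat_idx)], dtype=int)
        parts = [tokens.transpose(1, 0, 2)[keep]]  # (m, n, d)
        order = list(keep)
        for j in cat_idx:
            spec = schema.specs[j]
            codes = table.values[:, j].astype(int)
            if (codes < 0).any() or (codes >= len(spec.categories)).any():
                raise ValueError(f"column {spec.name!r} holds unencoded categories")
            emb = ad.embedding_lookup(params[f"emb_{spec.name}"], codes)  # (n, d)
            parts.append(emb.reshape(1, n, d))
            order.append(j)
        stacked = ad.concat(parts, axis=0)  # (p, n, d) in permuted order
        inv = np.argsort(np.array(order))
        tokens = stacked[inv].transpose(1, 0, 2)
    cls_tok = params["cls"].reshape(1, 1, d) + Tensor(np.zeros((n, 1, d), dtype=dt))
    return ad.concat([cls_tok, tokens], axis=1)  # (n, p+1, d)


def encode(tokens: Tensor, selector: TrainedSelector) -> Tensor:
    """Pre-norm multi-head self-attention block(s) with feed-forward
    sublayers and residual connections; shape-preserving."""
    hp = selector.hp
    params = selector.params
    n, t, d = tokens.shape
    heads, dh = hp.n_heads, d // hp.n_heads
    h = tokens
    for layer in range(hp.n_layers):
        pre = f"l{layer}_"
        a = ad.layer_norm(h, params[pre + "ln1_g"], params[pre + "ln1_b"])

        def split_heads(z: Tensor) -> Tensor:
            return z.reshape(n, t, heads, dh).transpose(0, 2, 1, 3)

        # scale folded into q (cheaper than scaling the t x t score matrix)
        q = split_heads(a @ params[pre + "wq"] + params[pre + "wq_b"]) * (
            1.0 / float(np.sqrt(dh))
        )
        k = split_heads(a @ params[pre + "wk"] + params[pre + "wk_b"])
        v = split_heads(a @ params[pre + "wv"] + params[pre + "wv_b"])
        scores = q @ k.transpose(0, 1, 3, 2)
        attn = ad.softmax(scores, axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(n, t, d)
        h = h + (ctx @ params[pre + "wo"] + params[pre + "wo_b"])
        a2 = ad.layer_norm(h, params[pre + "ln2_g"], params[pre + "ln2_b"])
        ff = ad.gelu(a2 @ params[pre + "ffn1"] + params[pre + "ffn1_b"])
        h = h + (ff @ params[pre + "ffn2"] + params[pre + "ffn2_b"])
    return h


def classification_logit(encoded: Tensor, selector: TrainedSelector) -> Tensor:
    """Affine map of the encoded CLS token to one logit per sample."""
    d = selector.hp.d_token
    cls_out = encoded[:, 0, :]  # (n, d)
    return (cls_out * selector.params["head_w"].reshape(1, d)).sum(axis=1) + \
        selector.params["head_b"]


def statistical_loss(encoded: Tensor, outcome: np.ndarray, ridge: float) -> Tensor:
    """Negative mean per-feature ridge-regularized Hotelling T² between
    outcome groups, computed on the encoded feature tokens (CLS excluded).

    For feature j with class token matrices X0 (n0 x d) and X1 (n1 x d):
    T²_j = (n0 n1/(n0+n1)) δ_jᵀ (S_j + ridge I)⁻¹ δ_j with S_j the pooled
    covariance (denominator n0+n1−2).  The loss is −mean_j T²_j, so gradient
    descent *increases* separability.
    """
    y = np.asarray(outcome).astype(int)
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    n0, n1 = len(idx0), len(idx1)
    if min(n0, n1) < 2:
        raise ValueError("each outcome class needs at least 2 samples")
    feats = encoded[:, 1:, :]  # (n, p, d)
    x0 = feats[idx0].transpose(1, 0, 2)  # (p, n0, d)
    x1 = feats[idx1].transpose(1, 0, 2)
    m0 = x0.mean(axis=1, keepdims=True)  # (p, 1, d)
    m1 = x1.mean(axis=1, keepdims=True)
    c0 = x0 - m0
    c1 = x1 - m1
    s_pooled = (c0.transpose(0, 2, 1) @ c0 + c1.transpose(0, 2, 1) @ c1) * (
        1.0 / (n0 + n1 - 2)
    )  # (p, d, d)
    delta = (m1 - m0).reshape(m0.shape[0], m0.shape[2])  # (p, d)
    t2 = ad.batched_inv_quad(delta, s_pooled, ridge) * (n0 * n1 / (n0 + n1))
    return -t2.mean()


def embedding_norm_penalty(encoded: Tensor) -> Tensor:
    """Mean squared L2 norm of the encoded tokens (all positions)."""
    return (encoded * encoded).sum(axis=-1).mean()


def total_loss(
    logits: Tensor,
    outcome: np.ndarray,
    encoded: Tensor,
    hp: SelectorHyperparams,
) -> tuple[Tensor, float, float]:
    """Joint objective; returns (total, L_cls value, L_stat value)."""
    l_cls = ad.bce_with_logits(logits, outcome)
    if hp.lambda1 > 0:
        l_stat = statistical_loss(encoded, outcome, hp.ridge)
    else:
        l_stat = Tensor(0.0)
    if hp.lambda2 > 0:
        reg = embedding_norm_penalty(encoded)
    else:
        reg = Tensor(0.0)
    total = l_cls + hp.lambda1 * l_stat + hp.lambda2 * reg
    return total, float(l_cls.data), float(l_stat.data)


def train(
    cohort: CohortTable,
    hp: SelectorHyperparams,
    preprocess: bool = True,
) -> TrainedSelector:
    """Full-batch Adam training of the joint objective.

    When ``preprocess`` is true the preprocessor is fitted on the supplied
    cohort (the selector's single full-cohort fit has no held-out split) and
    attached to the returned selector.
    """
    _tune_allocator()
    cohort.require_both_classes()
    pre_state = None
    if preprocess:
        pre_state = fit_preprocessor(cohort)
        cohort = apply_preprocessor(pre_state, cohort)

    rng = np.random.default_rng(hp.seed)
    params = _init_params(cohort.schema, hp, rng)
    selector = TrainedSelector(
        schema=cohort.schema, hp=hp, params=params, preprocessor=pre_state
    )

    # Adam state (library defaults: beta1=0.9, beta2=0.999, eps=1e-8)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    m = {k: np.zeros_like(v.data) for k, v in params.items()}
    v = {k: np.zeros_like(t.data) for k, t in params.items()}

    log_rows = []
    y = cohort.outcome
    for epoch in range(1, hp.epochs + 1):
        for t in params.values():
            t.grad = None
        tokens = tokenize(cohort, selector)
        encoded = encode(tokens, selector)
        logits = classification_logit(encoded, selector)
        loss, l_cls, l_stat = total_loss(logits, y, encoded, hp)
        if not np.isfinite(loss.data):
            raise TrainingDiverged(f"non-finite loss at epoch {epoch}")
        loss.backward()
        bc1 = 1.0 - beta1**epoch
        bc2 = 1.0 - beta2**epoch
        for k, t in params.items():
            g = t.grad if t.grad is not None else np.zeros_like(t.data)
            m[k] = beta1 * m[k] + (1 - beta1) * g
            v[k] = beta2 * v[k] + (1 - beta2) * g**2
            t.data = t.data - hp.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + eps)
        log_rows.append(
            {"epoch": epoch, "l_cls": l_cls, "l_stat": l_stat,
             "total": float(loss.data)}
        )
    selector.training_log = pd.DataFrame(log_rows)
    return selector


def random_selector(
    schema: FeatureSchema, hp: SelectorHyperparams
) -> TrainedSelector:
    """An untrained selector with seeded random initialization — the null
    reference for calibration studies of the post-hoc significance test."""
    rng = np.random.default_rng(hp.seed)
    return TrainedSelector(
        schema=schema, hp=hp, params=_init_params(schema, hp, rng)
    )
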