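"""Character-level causal sequence model with a training loop.

The classifier at the heart of this package is a small decoder-only
transformer trained with the plain next-token objective

    p(x_t | x_<t; theta) = softmax(W h_t + b),
    L(theta) = - mean over non-pad tokens of log p(x_t | x_<t; theta),

where ``h_t`` is the final hidden state at position ``t``.  Class
membership is read out generatively: a class-tag token is appended to
every training string, and at inference the next-token distribution at
the end of the prompt is restricted to the tag tokens.

The model is implemented directly in NumPy with a hand-written backward
pass.  This keeps the full computation graph — token embeddings,
per-layer hidden states, attention weights, and gradients with respect
to the input embeddings — available to the interpretability modules
(gradient x embedding attribution, integrated gradients, windowed
reference-based attribution, layer-wise SVD projection) without any
framework dependency.  Gradient correctness is pinned by
finite-difference tests.

Architecture: learned token + positional embeddings, pre-norm
transformer blocks (causal multi-head self-attention and a GELU MLP,
both with residual connections), a final layer norm, and an untied
output projection.  Defaults are desk-scale (2 layers, d_model 64,
4 heads, context 128) and trainable in minutes on one CPU; all sizes
are configurable upward.

Optimization follows the standard recipe for this model family: AdamW
(weight decay 0.01, applied to weight matrices only), initial learning
rate 1e-4, cosine decay with linear warmup.  Checkpoints are evaluated
periodically and the exported model is the checkpoint with the best
evaluation macro-F1 (ties broken toward the earlier step).
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping, Sequence

import numpy as np
from scipy.special import erf

from .dataprep import LabeledDataset

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
PAD_TOKEN = "<pad>"
DELIMITER = "<"
_NEG_INF = -1e9
_LN_EPS = 1e-5
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


class EncodingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Vocabulary
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Vocabulary:
    """Pure character-level vocabulary with reserved pad and tag tokens."""

    tokens: tuple[str, ...]
    tag_tokens: tuple[str, ...]

    @property
    def token_to_id(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.tokens)}

    @property
    def pad_id(self) -> int:
        return 0

    @property
    def x_id(self) -> int:
        return self.token_to_id["X"]

    @property
    def tag_ids(self) -> dict[str, int]:
        return {t: self.token_to_id[t] for t in self.tag_tokens}

    def __len__(self) -> int:
        return len(self.tokens)

    def encode(self, text: str, pad_to: int | None = None) -> np.ndarray:
        """Map characters to ids; non-canonical residues become 'X'.

        With ``pad_to`` the result is right-padded with the pad token;
        longer inputs are a validation error.
        """
        t2i = self.token_to_id
        x_id = self.x_id
        ids = [t2i.get(ch, x_id) for ch in text]
        if pad_to is not None:
            if len(ids) > pad_to:
                raise EncodingError(
                    f"text of length {len(ids)} exceeds pad_to={pad_to}"
                )
            ids = ids + [self.pad_id] * (pad_to - len(ids))
        return np.asarray(ids, dtype=np.int64)

    def decode(self, ids: Sequence[int]) -> str:
        """Inverse of :meth:`encode` after pad stripping."""
        return "".join(self.tokens[i] for i in ids if i != self.pad_id)

    def to_json(self) -> str:
        return json.dumps({"tokens": list(self.tokens),
                           "tag_tokens": list(self.tag_tokens)})

    @classmethod
    def from_json(cls, payload: str) -> "Vocabulary":
        d = json.loads(payload)
        return cls(tuple(d["tokens"]), tuple(d["tag_tokens"]))


def make_vocab(tags: Sequence[str]) -> Vocabulary:
    """Vocabulary over the 20 canonical amino acids, 'X', '<' and tags.

    Tag tokens must be single characters outside the residue alphabet
    (so character-level encoding stays unambiguous).
    """
    base = [PAD_TOKEN] + list(CANONICAL_AA) + ["X", DELIMITER]
    for t in tags:
        if len(t) != 1 or t in base:
            raise ValueError(f"tag token {t!r} must be a single novel character")
    return Vocabulary(tokens=tuple(base + list(tags)), tag_tokens=tuple(tags))


def default_tag_map(class_labels: Sequence[str]) -> dict[str, str]:
    """One digit tag per class, in the given class order."""
    if len(class_labels) > 10:
        raise ValueError("at most 10 classes supported by digit tags")
    return {label: str(i) for i, label in enumerate(class_labels)}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ModelConfig:
    n_layers: int = 2
    d_model: int = 64
    n_heads: int = 4
    context_length: int = 128
    d_ff: int | None = None  # defaults to 4 * d_model
    init_std: float = 0.02
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")

    @property
    def ff_dim(self) -> int:
        return self.d_ff if self.d_ff is not None else 4 * self.d_model


@dataclasses.dataclass(frozen=True)
class TrainingConfig:
    batch_size: int = 64
    learning_rate: float = 1e-4
    weight_decay: float = 0.01
    warmup_steps: int = 100
    max_steps: int = 600
    seed: int = 0
    pad_to: int = 100
    eval_interval: int = 100
    eval_subset: int = 500
    loss_on: str = "all"  # "all" or "tag" (tag-only ablation)

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclasses.dataclass(frozen=True)
class LossReport:
    step: int
    train_loss: float
    eval_loss: float | None
    eval_macro_f1: float | None = None


@dataclasses.dataclass
class ForwardStates:
    """Full forward trace for the interpretability modules.

    ``hidden[0]`` is the embedding layer after positional mixing;
    ``hidden[l]`` is the residual stream after block ``l``, giving
    ``n_layers + 1`` matrices of shape (positions, d_model).
    ``attentions[l]`` has shape (n_heads, positions, positions).
    """

    logits: np.ndarray
    embeddings: np.ndarray
    hidden: list[np.ndarray]
    attentions: list[np.ndarray]


# ---------------------------------------------------------------------------
# Numerics
# ---------------------------------------------------------------------------

def _gelu(x: np.ndarray):
    """Exact GELU; returns the activation and the CDF term for backward."""
    phi = 0.5 * (1.0 + erf(x * np.sqrt(0.5)))
    return x * phi, phi


def _gelu_grad(x: np.ndarray, phi: np.ndarray) -> np.ndarray:
    return phi + x * np.exp(-0.5 * x * x) * _INV_SQRT_2PI


def _mm_acc(a3: np.ndarray, b3: np.ndarray) -> np.ndarray:
    """sum_{b,t} a[b,t,:] outer b[b,t,:]  ==  a2^T @ b2 via BLAS."""
    return a3.reshape(-1, a3.shape[-1]).T @ b3.reshape(-1, b3.shape[-1])


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def _ln_forward(x, g, b):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return xhat * g + b, (xhat, inv)


def _ln_backward(dy, cache, g):
    xhat, inv = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv * (
        dxhat
        - dxhat.mean(-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(-1, keepdims=True)
    )
    return dx, dg, db


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class CausalTransformer:
    """Decoder-only transformer exposing logits, embeddings, states, grads."""

    def __init__(self, config: ModelConfig, vocab: Vocabulary, seed: int = 0):
        self.config = config
        self.vocab = vocab
        self.dtype = np.dtype(config.dtype)
        rng = np.random.default_rng(seed)
        d, dff, V, T = (config.d_model, config.ff_dim, len(vocab),
                        config.context_length)
        std = config.init_std

        def w(*shape):
            return (rng.normal(0.0, std, size=shape)).astype(self.dtype)

        p: dict[str, np.ndarray] = {
            "wte": w(V, d),
            "wpe": w(T, d),
            "lnf_g": np.ones(d, self.dtype),
            "lnf_b": np.zeros(d, self.dtype),
            "w_out": w(d, V),
            "b_out": np.zeros(V, self.dtype),
        }
        for l in range(config.n_layers):
            p[f"l{l}_ln1_g"] = np.ones(d, self.dtype)
            p[f"l{l}_ln1_b"] = np.zeros(d, self.dtype)
            for name in ("q", "k", "v", "o"):
                p[f"l{l}_w{name}"] = w(d, d)
                p[f"l{l}_b{name}"] = np.zeros(d, self.dtype)
            p[f"l{l}_ln2_g"] = np.ones(d, self.dtype)
            p[f"l{l}_ln2_b"] = np.zeros(d, self.dtype)
            p[f"l{l}_w1"] = w(d, dff)
            p[f"l{l}_b1"] = np.zeros(dff, self.dtype)
            p[f"l{l}_w2"] = w(dff, d)
            p[f"l{l}_b2"] = np.zeros(d, self.dtype)
        self.params = p

    # -- helpers -----------------------------------------------------------

    @property
    def n_layers(self) -> int:
        return self.config.n_layers

    def _check_ids(self, ids: np.ndarray) -> np.ndarray:
        ids = np.atleast_2d(np.asarray(ids, dtype=np.int64))
        if ids.size and (ids.min() < 0 or ids.max() >= len(self.vocab)):
            raise ValueError("token id out of vocabulary range")
        if ids.shape[1] > self.config.context_length:
            raise ValueError(
                f"sequence length {ids.shape[1]} exceeds context "
                f"{self.config.context_length}"
            )
        return ids

    def token_embeddings(self, ids: np.ndarray) -> np.ndarray:
        """Token-embedding rows E(x) (no positional term), (B, T, d)."""
        return self.params["wte"][self._check_ids(ids)]

    # -- forward -----------------------------------------------------------

    def _forward(self, x_tok: np.ndarray, cache: bool):
        """Forward from token embeddings (B, T, d); adds positions inside."""
        p = self.params
        cfg = self.config
        B, T, d = x_tok.shape
        if T > cfg.context_length:
            raise ValueError("sequence exceeds context length")
        h = cfg.n_heads
        dh = d // h
        scale = 1.0 / np.sqrt(dh)
        mask = np.triu(np.full((T, T), _NEG_INF, dtype=x_tok.dtype), k=1)

        x = x_tok + p["wpe"][:T]
        hidden = [x]
        attns = []
        caches = []
        for l in range(cfg.n_layers):
            a, ln1c = _ln_forward(x, p[f"l{l}_ln1_g"], p[f"l{l}_ln1_b"])
            q = a @ p[f"l{l}_wq"] + p[f"l{l}_bq"]
            k = a @ p[f"l{l}_wk"] + p[f"l{l}_bk"]
            v = a @ p[f"l{l}_wv"] + p[f"l{l}_bv"]
            qh = q.reshape(B, T, h, dh).transpose(0, 2, 1, 3)
            kh = k.reshape(B, T, h, dh).transpose(0, 2, 1, 3)
            vh = v.reshape(B, T, h, dh).transpose(0, 2, 1, 3)
            scores = qh @ kh.transpose(0, 1, 3, 2) * scale + mask
            att = softmax(scores, axis=-1)
            ov = att @ vh
            o = ov.transpose(0, 2, 1, 3).reshape(B, T, d)
            attn_out = o @ p[f"l{l}_wo"] + p[f"l{l}_bo"]
            x2 = x + attn_out
            m, ln2c = _ln_forward(x2, p[f"l{l}_ln2_g"], p[f"l{l}_ln2_b"])
            f1 = m @ p[f"l{l}_w1"] + p[f"l{l}_b1"]
            gact, gphi = _gelu(f1)
            x3 = x2 + gact @ p[f"l{l}_w2"] + p[f"l{l}_b2"]
            hidden.append(x3)
            attns.append(att)
            if cache:
                caches.append(
                    dict(x=x, a=a, ln1c=ln1c, qh=qh, kh=kh, vh=vh, att=att,
                         o=o, x2=x2, m=m, ln2c=ln2c, f1=f1, gact=gact,
                         gphi=gphi)
                )
            x = x3
        hf, lnfc = _ln_forward(x, p["lnf_g"], p["lnf_b"])
        logits = hf @ p["w_out"] + p["b_out"]
        trace = dict(hidden=hidden, attns=attns, caches=caches,
                     hf=hf, lnfc=lnfc, x_last=x)
        return logits, trace

    def forward(self, ids: np.ndarray) -> np.ndarray:
        """Logits (B, T, V) — or (T, V) for a 1-D input."""
        ids_arr = self._check_ids(ids)
        logits, _ = self._forward(self.token_embeddings(ids_arr), cache=False)
        return logits[0] if np.asarray(ids).ndim == 1 else logits

    def forward_from_embeddings(self, x_tok: np.ndarray) -> np.ndarray:
        """Logits from explicit token embeddings (used by attribution)."""
        single = x_tok.ndim == 2
        if single:
            x_tok = x_tok[None]
        logits, _ = self._forward(x_tok.astype(self.dtype), cache=False)
        return logits[0] if single else logits

    def forward_states(self, ids: np.ndarray) -> ForwardStates:
        """Logits, token embeddings, per-layer hidden states, attentions."""
        ids_arr = self._check_ids(ids)
        emb = self.token_embeddings(ids_arr)
        logits, trace = self._forward(emb, cache=True)
        return ForwardStates(
            logits=logits[0],
            embeddings=emb[0],
            hidden=[h[0] for h in trace["hidden"]],
            attentions=[a[0] for a in trace["attns"]],
        )

    # -- backward ----------------------------------------------------------

    def _backward(self, trace, dlogits, want_params: bool):
        """Backprop to the token embeddings and (optionally) parameters."""
        p = self.params
        cfg = self.config
        B, T, V = dlogits.shape
        d = cfg.d_model
        h = cfg.n_heads
        dh = d // h
        scale = 1.0 / np.sqrt(dh)
        grads: dict[str, np.ndarray] = {}

        def acc(name, val):
            if want_params:
                grads[name] = grads.get(name, 0) + val

        hf = trace["hf"]
        acc("w_out", _mm_acc(hf, dlogits))
        acc("b_out", dlogits.sum((0, 1)))
        dhf = dlogits @ p["w_out"].T
        dx, dg, db = _ln_backward(dhf, trace["lnfc"], p["lnf_g"])
        acc("lnf_g", dg)
        acc("lnf_b", db)

        for l in reversed(range(cfg.n_layers)):
            c = trace["caches"][l]
            # MLP branch
            dmlp = dx
            acc(f"l{l}_w2", _mm_acc(c["gact"], dmlp))
            acc(f"l{l}_b2", dmlp.sum((0, 1)))
            dgact = dmlp @ p[f"l{l}_w2"].T
            df1 = dgact * _gelu_grad(c["f1"], c["gphi"])
            acc(f"l{l}_w1", _mm_acc(c["m"], df1))
            acc(f"l{l}_b1", df1.sum((0, 1)))
            dm = df1 @ p[f"l{l}_w1"].T
            dx2_ln, dg, db = _ln_backward(dm, c["ln2c"], p[f"l{l}_ln2_g"])
            acc(f"l{l}_ln2_g", dg)
            acc(f"l{l}_ln2_b", db)
            dx2 = dx + dx2_ln
            # Attention branch
            dattn_out = dx2
            acc(f"l{l}_wo", _mm_acc(c["o"], dattn_out))
            acc(f"l{l}_bo", dattn_out.sum((0, 1)))
            do = dattn_out @ p[f"l{l}_wo"].T
            dov = do.reshape(B, T, h, dh).transpose(0, 2, 1, 3)
            att, vh, qh, kh = c["att"], c["vh"], c["qh"], c["kh"]
            datt = dov @ vh.transpose(0, 1, 3, 2)
            dvh = att.transpose(0, 1, 3, 2) @ dov
            dscores = att * (datt - (datt * att).sum(-1, keepdims=True))
            dqh = dscores @ kh * scale
            dkh = dscores.transpose(0, 1, 3, 2) @ qh * scale
            dq = dqh.transpose(0, 2, 1, 3).reshape(B, T, d)
            dk = dkh.transpose(0, 2, 1, 3).reshape(B, T, d)
            dv = dvh.transpose(0, 2, 1, 3).reshape(B, T, d)
            a = c["a"]
            for name, dval in (("q", dq), ("k", dk), ("v", dv)):
                acc(f"l{l}_w{name}", _mm_acc(a, dval))
                acc(f"l{l}_b{name}", dval.sum((0, 1)))
            da = dq @ p[f"l{l}_wq"].T + dk @ p[f"l{l}_wk"].T + dv @ p[f"l{l}_wv"].T
            dx_ln, dg, db = _ln_backward(da, c["ln1c"], p[f"l{l}_ln1_g"])
            acc(f"l{l}_ln1_g", dg)
            acc(f"l{l}_ln1_b", db)
            dx = dx2 + dx_ln

        if want_params:
            grads["wpe"] = np.zeros_like(p["wpe"])
            grads["wpe"][:T] = dx.sum(0)
        return dx, grads

    def grad_wrt_embeddings(self, x_tok: np.ndarray, dlogits: np.ndarray) -> np.ndarray:
        """d(scalar)/d(token embeddings) given d(scalar)/d(logits)."""
        single = x_tok.ndim == 2
        if single:
            x_tok, dlogits = x_tok[None], dlogits[None]
        _, trace = self._forward(x_tok.astype(self.dtype), cache=True)
        dx, _ = self._backward(trace, dlogits.astype(self.dtype), want_params=False)
        return dx[0] if single else dx

    def loss_and_grads(self, ids: np.ndarray, loss_mask: np.ndarray):
        """Mean next-token NLL (nats/token over masked targets) + grads."""
        ids = self._check_ids(ids)
        x_tok = self.token_embeddings(ids)
        logits, trace = self._forward(x_tok, cache=True)
        B, T, V = logits.shape
        probs = softmax(logits[:, :-1], axis=-1)
        targets = ids[:, 1:]
        mask = loss_mask[:, 1:].astype(self.dtype)
        n_tok = mask.sum()
        if n_tok == 0:
            raise ValueError("loss mask selects no target tokens")
        picked = np.take_along_axis(probs, targets[..., None], axis=-1)[..., 0]
        loss = float(-(np.log(np.maximum(picked, 1e-12)) * mask).sum() / n_tok)

        dlogits = np.zeros_like(logits)
        dsl = probs.copy()
        np.put_along_axis(
            dsl, targets[..., None],
            np.take_along_axis(dsl, targets[..., None], axis=-1) - 1.0, axis=-1,
        )
        dlogits[:, :-1] = dsl * (mask / n_tok)[..., None]
        dx, grads = self._backward(trace, dlogits, want_params=True)
        grads["wte"] = np.zeros_like(self.params["wte"])
        np.add.at(grads["wte"], ids.ravel(), dx.reshape(-1, dx.shape[-1]))
        return loss, grads

    # -- generation --------------------------------------------------------

    def generate_greedy(self, ids: np.ndarray, k: int) -> list[int]:
        """Greedily extend a prompt by ``k`` tokens; pad is never emitted."""
        out: list[int] = []
        cur = list(np.atleast_1d(np.asarray(ids, dtype=np.int64)))
        for _ in range(k):
            logits = self.forward(np.asarray(cur))
            row = logits[-1].copy()
            row[self.vocab.pad_id] = -np.inf
            nxt = int(np.argmax(row))
            out.append(nxt)
            cur.append(nxt)
            if len(cur) >= self.config.context_length:
                break
        return out

    # -- persistence -------------------------------------------------------

    def save(self, path: str) -> None:
        meta = json.dumps(
            {"config": dataclasses.asdict(self.config),
             "vocab": json.loads(self.vocab.to_json()),
             "tag_map": getattr(self, "tag_map", None)}
        )
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path: str) -> "CausalTransformer":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            vocab = Vocabulary(tuple(meta["vocab"]["tokens"]),
                               tuple(meta["vocab"]["tag_tokens"]))
            model = cls(ModelConfig(**meta["config"]), vocab)
            if meta.get("tag_map"):
                model.tag_map = dict(meta["tag_map"])
            for k in model.params:
                model.params[k] = data[k]
        return model


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _encode_dataset(
    ds: LabeledDataset, vocab: Vocabulary, tag_map: Mapping[str, str],
    mode: str, pad_to: int,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Encode (text, label) items into padded id rows plus loss masks."""
    rows, labels = [], []
    for text, label in ds.items:
        if mode == "tifree":
            s = text + tag_map[label]
        elif mode == "tiinc":
            s = text + DELIMITER + tag_map[label]
        else:
            raise ValueError(f"unknown mode {mode!r}")
        rows.append(s)
        labels.append(label)
    width = max(len(s) for s in rows)
    if pad_to is not None:
        width = max(width, pad_to + (1 if mode == "tifree" else 2))
    ids = np.stack([vocab.encode(s, pad_to=width) for s in rows])
    mask = ids != vocab.pad_id
    return ids, mask, labels


def _cosine_lr(step: int, cfg: TrainingConfig) -> float:
    if step < cfg.warmup_steps:
        return cfg.learning_rate * (step + 1) / max(1, cfg.warmup_steps)
    span = max(1, cfg.max_steps - cfg.warmup_steps)
    frac = (step - cfg.warmup_steps) / span
    return cfg.learning_rate * 0.5 * (1.0 + np.cos(np.pi * min(frac, 1.0)))


def _tag_argmax(model: CausalTransformer, ids: np.ndarray,
                prompt_lens: np.ndarray) -> list[int]:
    """Predicted tag id for each row, batched over rows of equal width."""
    tag_id_list = list(model.vocab.tag_ids.values())
    preds = []
    for start in range(0, len(ids), 256):
        chunk = ids[start : start + 256]
        logits, _ = model._forward(model.token_embeddings(chunk), cache=False)
        for row_logits, plen in zip(logits, prompt_lens[start : start + 256]):
            tag_logits = row_logits[plen - 1][tag_id_list]
            preds.append(tag_id_list[int(np.argmax(tag_logits))])
    return preds


def _eval_model(model, ids, mask, labels, tag_map, mode, subset, rng):
    """Eval loss (nats/token) and tag macro-F1 on a seeded subset."""
    from sklearn.metrics import f1_score

    if subset and len(ids) > subset:
        pick = rng.choice(len(ids), size=subset, replace=False)
        ids, mask = ids[pick], mask[pick]
        labels = [labels[i] for i in pick]
    losses = []
    for start in range(0, len(ids), 256):
        logits, _ = model._forward(
            model.token_embeddings(ids[start : start + 256]), cache=False)
        probs = softmax(logits[:, :-1], axis=-1)
        targets = ids[start : start + 256, 1:]
        m = mask[start : start + 256, 1:]
        picked = np.take_along_axis(probs, targets[..., None], axis=-1)[..., 0]
        losses.append(-(np.log(np.maximum(picked, 1e-12)) * m).sum())
        losses.append(m.sum())
    eval_loss = float(sum(losses[::2]) / max(sum(losses[1::2]), 1))

    # Index of the tag token per row; logits just before it predict it.
    tag_pos = mask.sum(1) - 1
    preds = _tag_argmax(model, ids, tag_pos)
    id_to_label = {model.vocab.tag_ids[tag_map[lbl]]: lbl for lbl in tag_map}
    pred_labels = [id_to_label[p] for p in preds]
    macro = float(f1_score(labels, pred_labels, average="macro",
                           labels=sorted(tag_map), zero_division=0))
    return eval_loss, macro


def train_model(
    train: LabeledDataset,
    eval: LabeledDataset | None,
    tag_map: Mapping[str, str],
    arch: ModelConfig = ModelConfig(),
    cfg: TrainingConfig = TrainingConfig(),
    mode: str = "tifree",
) -> tuple[CausalTransformer, list[LossReport]]:
    """Train on tagged next-token prediction; return the best checkpoint.

    TI-free items are 100-residue fragments with the tag appended
    directly; TI-inclusive items get ``"<" + tag``.  Loss covers all
    non-pad tokens by default (``cfg.loss_on="tag"`` restricts it to
    the tag position).  The returned model is the periodic checkpoint
    with the highest eval macro-F1, ties broken toward the earlier
    step; with no eval set, the final model is returned.
    """
    if not train.items:
        raise ValueError("empty training dataset")
    vocab = make_vocab([tag_map[lbl] for lbl in tag_map])
    model = CausalTransformer(arch, vocab, seed=cfg.seed)
    model.tag_map = dict(tag_map)  # class label -> tag token, for export
    ids, mask, _ = _encode_dataset(train, vocab, tag_map, mode, cfg.pad_to)
    if cfg.loss_on == "tag":
        # Only the final non-pad token (the tag) contributes to the loss.
        tag_pos = mask.sum(1) - 1
        mask = np.zeros_like(mask)
        mask[np.arange(len(mask)), tag_pos] = True
    eval_data = None
    if eval is not None and eval.items:
        eval_data = _encode_dataset(eval, vocab, tag_map, mode, cfg.pad_to)

    rng = np.random.default_rng(cfg.seed + 1)
    opt_m = {k: np.zeros_like(v) for k, v in model.params.items()}
    opt_v = {k: np.zeros_like(v) for k, v in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    reports: list[LossReport] = []
    best = (-1.0, 0, None)  # (macro_f1, step, params snapshot)
    order = rng.permutation(len(ids))
    cursor = 0

    for step in range(cfg.max_steps):
        if cursor + cfg.batch_size > len(order):
            order = rng.permutation(len(ids))
            cursor = 0
        batch = order[cursor : cursor + cfg.batch_size]
        cursor += cfg.batch_size
        loss, grads = model.loss_and_grads(ids[batch], mask[batch])
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite training loss at step {step}: {loss}")
        lr = _cosine_lr(step, cfg)
        t = step + 1
        for k, g in grads.items():
            opt_m[k] = beta1 * opt_m[k] + (1 - beta1) * g
            opt_v[k] = beta2 * opt_v[k] + (1 - beta2) * g * g
            mhat = opt_m[k] / (1 - beta1**t)
            vhat = opt_v[k] / (1 - beta2**t)
            pk = model.params[k]
            if cfg.weight_decay and pk.ndim == 2:
                pk -= lr * cfg.weight_decay * pk
            pk -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(pk.dtype)

        last = step == cfg.max_steps - 1
        if (step + 1) % cfg.eval_interval == 0 or last:
            if eval_data is not None:
                e_ids, e_mask, e_labels = eval_data
                eval_loss, macro = _eval_model(
                    model, e_ids, e_mask, e_labels, tag_map, mode,
                    cfg.eval_subset, np.random.default_rng(cfg.seed + 2))
                if macro > best[0]:
                    best = (macro, step,
                            {k: v.copy() for k, v in model.params.items()})
                reports.append(LossReport(step + 1, loss, eval_loss, macro))
            else:
                reports.append(LossReport(step + 1, loss, None, None))

    if best[2] is not None:
        model.params = best[2]
    return model, reports
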