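"""A compact bidirectional masked-item transformer for next-item prediction.

The model follows the BERT4Rec recipe: item + position embeddings feed a
stack of bidirectional transformer-encoder blocks; training masks a
random subset of positions (cloze task) plus, per sequence, one instance
that masks only the final position (the next-item pretext); prediction
appends a MASK token after the observed context and reads the item
distribution at that position.

The implementation is pure numpy (forward, manual backpropagation, Adam)
so it runs anywhere; it is sized for CPU-scale experiments, not for
production-scale training. Gradients are verified against finite
differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np

from ._util import id_key

__all__ = ["TransformerConfig", "MaskedSeqModel", "make_training_instances",
           "fit_masked_model", "predict_next"]

PAD = 0
_NEG = -1e9  # additive attention bias on padded keys


@dataclass
class TransformerConfig:
    """Architecture and training hyperparameters.

    Defaults are a CPU-scale reduction of the usual BERT4Rec settings:
    2 layers, 2 heads, 64-dim hidden; cloze masking probability 0.2; the
    window ``max_seq`` should be base_max × (n+1) when training on
    sequences enriched with n items per anchor.
    """

    n_layers: int = 2
    n_heads: int = 2
    d_model: int = 64
    d_ff: int = 128
    max_seq: int = 50
    mask_prob: float = 0.2
    steps: int = 400
    batch_size: int = 32
    lr: float = 1e-3
    seed: int = 0
    init_scale: float = 0.02
    final_instance_frac: float = 0.5  # share of batch devoted to last-position instances
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.max_seq < 1:
            raise ValueError("max_seq must be >= 1")
        if not (0.0 < self.mask_prob <= 1.0):
            raise ValueError("mask_prob must be in (0, 1]")
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")


def _gelu(x: np.ndarray) -> np.ndarray:
    c, a = 0.7978845608028654, 0.044715
    return 0.5 * x * (1.0 + np.tanh(c * (x + a * x**3)))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    c, a = 0.7978845608028654, 0.044715
    t = np.tanh(c * (x + a * x**3))
    return 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * c * (1.0 + 3.0 * a * x**2)


def _layernorm(x, g, b, eps=1e-6):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv, g)


def _layernorm_grad(dy, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv * (dxhat - dxhat.mean(-1, keepdims=True)
                - xhat * (dxhat * xhat).mean(-1, keepdims=True))
    return dx, dg, db


def _softmax(x: np.ndarray) -> np.ndarray:
    m = x.max(-1, keepdims=True)
    e = np.exp(x - m)
    return e / e.sum(-1, keepdims=True)


class MaskedSeqModel:
    """Bidirectional masked-item model over a fixed item vocabulary.

    Token ids: 0 = PAD, 1..V = items (in deterministic id order),
    V+1 = MASK. The output projection ties the item embedding matrix.
    """

    def __init__(self, items: Sequence[str], config: TransformerConfig):
        self.items = sorted(set(map(str, items)), key=id_key)
        if len(self.items) < 2:
            raise ValueError("vocabulary needs at least 2 items")
        self.config = config
        self.item_to_token = {it: i + 1 for i, it in enumerate(self.items)}
        self.mask_id = len(self.items) + 1
        self.vocab_size = len(self.items) + 2
        self.loss_trace: list[float] = []
        self._dtype = np.dtype(config.dtype)
        self._init_params(np.random.default_rng(config.seed))
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # ---------------------------------------------------------------- setup
    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        D, F, T, V = cfg.d_model, cfg.d_ff, cfg.max_seq, self.vocab_size
        s = cfg.init_scale

        def w(*shape):
            return (rng.normal(scale=s, size=shape)).astype(self._dtype)

        p: dict[str, np.ndarray] = {"E": w(V, D), "P": w(T, D),
                                    "ln_e_g": np.ones(D, self._dtype),
                                    "ln_e_b": np.zeros(D, self._dtype),
                                    "b_out": np.zeros(V, self._dtype)}
        for l in range(cfg.n_layers):
            for name in ("Wq", "Wk", "Wv", "Wo"):
                p[f"{name}{l}"] = w(D, D)
            for name in ("bq", "bk", "bv", "bo"):
                p[f"{name}{l}"] = np.zeros(D, self._dtype)
            p[f"W1_{l}"] = w(D, F)
            p[f"b1_{l}"] = np.zeros(F, self._dtype)
            p[f"W2_{l}"] = w(F, D)
            p[f"b2_{l}"] = np.zeros(D, self._dtype)
            for ln in ("ln1", "ln2"):
                p[f"{ln}_g{l}"] = np.ones(D, self._dtype)
                p[f"{ln}_b{l}"] = np.zeros(D, self._dtype)
        self.params = p
        # embedding row 0 is PAD; keep it at zero
        self.params["E"][PAD] = 0.0

    # -------------------------------------------------------------- forward
    def _forward_hidden(self, tokens: np.ndarray):
        cfg = self.config
        p = self.params
        B, T = tokens.shape
        H, D = cfg.n_heads, cfg.d_model
        K = D // H
        scale = 1.0 / np.sqrt(K)
        bias = np.where(tokens == PAD, _NEG, 0.0).astype(self._dtype)[:, None, None, :]

        x0 = p["E"][tokens] + p["P"][None, :T, :]
        x, ln_e_cache = _layernorm(x0, p["ln_e_g"], p["ln_e_b"])
        caches = {"tokens": tokens, "ln_e": ln_e_cache, "layers": []}

        def split(m):  # (B,T,D) -> (B,H,T,K)
            return m.reshape(B, T, H, K).transpose(0, 2, 1, 3)

        for l in range(cfg.n_layers):
            x_in = x
            q = split(x @ p[f"Wq{l}"] + p[f"bq{l}"])
            k = split(x @ p[f"Wk{l}"] + p[f"bk{l}"])
            v = split(x @ p[f"Wv{l}"] + p[f"bv{l}"])
            scores = q @ k.transpose(0, 1, 3, 2) * scale + bias
            A = _softmax(scores)
            ctx = (A @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
            attn_out = ctx @ p[f"Wo{l}"] + p[f"bo{l}"]
            x1, ln1_cache = _layernorm(x_in + attn_out, p[f"ln1_g{l}"], p[f"ln1_b{l}"])
            h_pre = x1 @ p[f"W1_{l}"] + p[f"b1_{l}"]
            h = _gelu(h_pre)
            ffn_out = h @ p[f"W2_{l}"] + p[f"b2_{l}"]
            x, ln2_cache = _layernorm(x1 + ffn_out, p[f"ln2_g{l}"], p[f"ln2_b{l}"])
            caches["layers"].append(
                dict(x_in=x_in, q=q, k=k, v=v, A=A, ctx=ctx, ln1=ln1_cache,
                     x1=x1, h_pre=h_pre, h=h, ln2=ln2_cache))
        return x, caches

    def logits_at(self, tokens: np.ndarray, positions: tuple[np.ndarray, np.ndarray]
                  ) -> np.ndarray:
        """Vocabulary logits at the given (batch, position) indices."""
        hidden, _ = self._forward_hidden(tokens)
        g = hidden[positions]
        return g @ self.params["E"].T + self.params["b_out"]

    # ------------------------------------------------------------- backward
    def loss_and_grads(self, tokens: np.ndarray, labels: np.ndarray,
                       want_grads: bool = True):
        """Masked cross-entropy and (optionally) parameter gradients.

        ``labels`` holds the original token id at masked positions and -1
        elsewhere; only masked positions contribute to the loss.
        """
        cfg = self.config
        p = self.params
        B, T = tokens.shape
        H, D = cfg.n_heads, cfg.d_model
        K = D // H
        scale = 1.0 / np.sqrt(K)

        hidden, caches = self._forward_hidden(tokens)
        bidx, tidx = np.nonzero(labels >= 0)
        if len(bidx) == 0:
            raise ValueError("no masked positions in batch")
        G = hidden[bidx, tidx]
        logits = G @ p["E"].T + p["b_out"]
        probs = _softmax(logits.astype(np.float64))
        y = labels[bidx, tidx]
        M = len(y)
        loss = float(-np.mean(np.log(probs[np.arange(M), y] + 1e-12)))
        if not want_grads:
            return loss, None

        dlogits = probs.copy()
        dlogits[np.arange(M), y] -= 1.0
        dlogits = (dlogits / M).astype(self._dtype)

        grads = {k: np.zeros_like(v) for k, v in p.items()}
        grads["b_out"] = dlogits.sum(0)
        grads["E"] += dlogits.T @ G
        dG = dlogits @ p["E"]
        dx = np.zeros_like(hidden)
        dx[bidx, tidx] = dG

        def merge(m):  # (B,H,T,K) -> (B,T,D)
            return m.transpose(0, 2, 1, 3).reshape(B, T, D)

        for l in reversed(range(cfg.n_layers)):
            c = caches["layers"][l]
            dres2, dg2, db2 = _layernorm_grad(dx, c["ln2"])
            grads[f"ln2_g{l}"] += dg2
            grads[f"ln2_b{l}"] += db2
            # FFN branch
            dffn = dres2
            grads[f"W2_{l}"] += c["h"].reshape(-1, cfg.d_ff).T @ dffn.reshape(-1, D)
            grads[f"b2_{l}"] += dffn.sum((0, 1))
            dh = dffn @ p[f"W2_{l}"].T
            dh_pre = dh * _gelu_grad(c["h_pre"])
            grads[f"W1_{l}"] += c["x1"].reshape(-1, D).T @ dh_pre.reshape(-1, cfg.d_ff)
            grads[f"b1_{l}"] += dh_pre.sum((0, 1))
            dx1 = dres2 + dh_pre @ p[f"W1_{l}"].T
            dres1, dg1, db1 = _layernorm_grad(dx1, c["ln1"])
            grads[f"ln1_g{l}"] += dg1
            grads[f"ln1_b{l}"] += db1
            # attention branch
            dattn = dres1
            grads[f"Wo{l}"] += c["ctx"].reshape(-1, D).T @ dattn.reshape(-1, D)
            grads[f"bo{l}"] += dattn.sum((0, 1))
            dctx = (dattn @ p[f"Wo{l}"].T).reshape(B, T, H, K).transpose(0, 2, 1, 3)
            dA = dctx @ c["v"].transpose(0, 1, 3, 2)
            dv = c["A"].transpose(0, 1, 3, 2) @ dctx
            dS = c["A"] * (dA - (dA * c["A"]).sum(-1, keepdims=True))
            dq = dS @ c["k"] * scale
            dk = dS.transpose(0, 1, 3, 2) @ c["q"] * scale
            x_in_flat = c["x_in"].reshape(-1, D)
            for name, dmat in (("Wq", dq), ("Wk", dk), ("Wv", dv)):
                dm = merge(dmat)
                grads[f"{name}{l}"] += x_in_flat.T @ dm.reshape(-1, D)
                grads[f"b{name[1]}{l}"] += dm.sum((0, 1))
            dx_in = (merge(dq) @ p[f"Wq{l}"].T + merge(dk) @ p[f"Wk{l}"].T
                     + merge(dv) @ p[f"Wv{l}"].T)
            dx = dres1 + dx_in

        dx0, dg_e, db_e = _layernorm_grad(dx, caches["ln_e"])
        grads["ln_e_g"] += dg_e
        grads["ln_e_b"] += db_e
        np.add.at(grads["E"], tokens, dx0)
        grads["P"][:T] += dx0.sum(0)
        grads["E"][PAD] = 0.0  # PAD embedding stays frozen
        return loss, grads

    def adam_step(self, grads: Mapping[str, np.ndarray]) -> None:
        cfg = self.config
        self._adam_t += 1
        t = self._adam_t
        b1, b2, eps = cfg.adam_beta1, cfg.adam_beta2, cfg.adam_eps
        corr = np.sqrt(1.0 - b2**t) / (1.0 - b1**t)
        for k, g in grads.items():
            m = self._adam_m[k]
            v = self._adam_v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            self.params[k] -= (cfg.lr * corr * m / (np.sqrt(v) + eps)).astype(self._dtype)
        self.params["E"][PAD] = 0.0

    # ------------------------------------------------------------ inference
    def encode(self, seq: Sequence[str]) -> list[int]:
        """Map item ids to token ids, dropping items outside the vocabulary."""
        return [self.item_to_token[i] for i in map(str, seq) if i in self.item_to_token]

    def predict_next(self, seq: Sequence[str]) -> dict[str, float]:
        """Score every catalogue item as the next item after ``seq``.

        Appends MASK after the (clipped) context and returns the softmax
        scores at that position, excluding PAD and MASK.
        """
        ids = self.encode(seq)
        if not ids:
            raise ValueError("no in-vocabulary items in the input sequence")
        T = self.config.max_seq
        window = ids[-(T - 1):] + [self.mask_id]
        tokens = np.zeros((1, T), dtype=np.int64)
        tokens[0, T - len(window):] = window
        logits = self.logits_at(tokens, (np.array([0]), np.array([T - 1])))[0]
        probs = _softmax(logits.astype(np.float64))
        return {item: float(probs[tok]) for item, tok in self.item_to_token.items()}

    def scores(self, user: str, context: Sequence[str]) -> dict[str, float]:
        """Evaluation adapter: ignore the user id, score from the context."""
        return self.predict_next(context)

    # ---------------------------------------------------------- persistence
    def save(self, path: str) -> None:
        meta = {"items": self.items, "config": asdict(self.config)}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path: str) -> "MaskedSeqModel":
        data = np.load(path if str(path).endswith(".npz") else str(path) + ".npz")
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = cls(meta["items"], TransformerConfig(**meta["config"]))
        for k in model.params:
            model.params[k] = data[k]
        return model


def make_training_instances(token_ids: Sequence[int], mask_prob: float, max_seq: int,
                            rng: np.random.Generator, mask_id: int
                            ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Build the two training instances for one sequence.

    Returns ``(tokens, labels)`` pairs, left-padded to ``max_seq`` with the
    suffix kept: one cloze instance (each position masked independently
    with ``mask_prob``, at least one) and one next-item instance masking
    only the final position. Labels are the original ids at masked
    positions and -1 elsewhere.
    """
    if not (0.0 < mask_prob <= 1.0):
        raise ValueError("mask_prob must be in (0, 1]")
    ids = list(token_ids)[-max_seq:]
    n = len(ids)
    base = np.zeros(max_seq, dtype=np.int64)
    base[max_seq - n:] = ids
    live = np.zeros(max_seq, dtype=bool)
    live[max_seq - n:] = True

    out = []
    # cloze instance
    pick = (rng.random(max_seq) < mask_prob) & live
    if not pick.any():
        pick[rng.choice(np.flatnonzero(live))] = True
    tokens = base.copy()
    labels = np.full(max_seq, -1, dtype=np.int64)
    labels[pick] = base[pick]
    tokens[pick] = mask_id
    out.append((tokens, labels))
    # final-position (next-item pretext) instance
    tokens = base.copy()
    labels = np.full(max_seq, -1, dtype=np.int64)
    tokens[-1] = mask_id
    labels[-1] = base[-1]
    out.append((tokens, labels))
    return out


def fit_masked_model(train: Mapping[str, Sequence] | Sequence[Sequence[str]],
                     config: TransformerConfig,
                     items: Sequence[str] | None = None) -> MaskedSeqModel:
    """Train a masked-item model on per-user sequences.

    ``train`` maps user → sequence (of item ids or (item, year) pairs) or
    is a bare list of sequences. Each step samples sequences, generates a
    mix of cloze and final-position instances, and takes one Adam step on
    the masked cross-entropy. The per-step loss is recorded on
    ``model.loss_trace``.
    """
    if isinstance(train, Mapping):
        seqs = [train[u] for u in sorted(train, key=id_key)]
    else:
        seqs = list(train)
    seqs = [[e[0] if isinstance(e, tuple) else str(e) for e in s] for s in seqs]
    seqs = [s for s in seqs if s]
    if not seqs:
        raise ValueError("no non-empty training sequences")
    if items is None:
        items = sorted({i for s in seqs for i in s}, key=id_key)
    model = MaskedSeqModel(items, config)
    encoded = [model.encode(s) for s in seqs]
    encoded = [s for s in encoded if s]

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EE2]))
    n_cloze = max(1, int(round(config.batch_size * (1.0 - config.final_instance_frac))))
    for _ in range(config.steps):
        idx = rng.integers(len(encoded), size=config.batch_size)
        batch_tokens, batch_labels = [], []
        for j, si in enumerate(idx):
            cloze, final = make_training_instances(
                encoded[si], config.mask_prob, config.max_seq, rng, model.mask_id)
            tokens, labels = cloze if j < n_cloze else final
            batch_tokens.append(tokens)
            batch_labels.append(labels)
        loss, grads = model.loss_and_grads(np.stack(batch_tokens), np.stack(batch_labels))
        model.adam_step(grads)
        model.loss_trace.append(loss)
    return model


def predict_next(model: MaskedSeqModel, seq: Sequence[str]) -> dict[str, float]:
    """Module-level alias of :meth:`MaskedSeqModel.predict_next`."""
    return model.predict_next(seq)
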