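"""A small encoder-decoder Transformer in pure numpy.

Implements the standard architecture — token embeddings with sinusoidal
positions, pre-norm residual blocks of multi-head scaled dot-product
attention and position-wise feed-forward layers, causal masking in the
decoder, cross-attention to the encoder memory — with hand-written
backpropagation and an Adam optimizer. Sized for short clinical
phrases (tens of tokens, vocabularies of a few hundred to a few
thousand types), where a desk-scale CPU model is sufficient; the
two-step coding method does not depend on model scale.

All randomness flows through a single numpy Generator, so training and
decoding are bit-reproducible for a given seed in a fixed BLAS
configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["TransformerParams", "Seq2SeqTransformer", "Adam"]

NEG_INF = -1e9


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    x = x - x.max(axis=axis, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=axis, keepdims=True)


def _softmax_backward(dy: np.ndarray, y: np.ndarray) -> np.ndarray:
    return (dy - (dy * y).sum(axis=-1, keepdims=True)) * y


def sinusoidal_positions(max_len: int, d_model: int, dtype=np.float64) -> np.ndarray:
    """Fixed sinusoidal position encodings, shape (max_len, d_model)."""
    pos = np.arange(max_len)[:, None].astype(dtype)
    i = np.arange(d_model)[None, :].astype(dtype)
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    enc = np.zeros((max_len, d_model), dtype=dtype)
    enc[:, 0::2] = np.sin(angle[:, 0::2])
    enc[:, 1::2] = np.cos(angle[:, 1::2])
    return enc


@dataclass
class TransformerParams:
    """Flat parameter store with matching gradient buffers."""

    values: dict[str, np.ndarray] = field(default_factory=dict)
    grads: dict[str, np.ndarray] = field(default_factory=dict)

    def add(self, name: str, array: np.ndarray) -> None:
        self.values[name] = array
        self.grads[name] = np.zeros_like(array)

    def zero_grad(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0

    def accumulate(self, name: str, grad: np.ndarray) -> None:
        self.grads[name] += grad


class Adam:
    """Adam with bias correction; deterministic given update order."""

    def __init__(self, params: TransformerParams, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.values.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.values.items()}

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for k in sorted(self.params.values):
            g = self.params.grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            self.params.values[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Seq2SeqTransformer:
    """Encoder-decoder Transformer with manual backprop.

    Token id 0 is reserved for padding on both sides. The forward pass
    keeps per-layer caches so :meth:`backward` can be called once per
    forward; gradients accumulate into the parameter store.
    """

    def __init__(
        self,
        src_vocab_size: int,
        tgt_vocab_size: int,
        d_model: int = 64,
        n_heads: int = 4,
        n_enc_layers: int = 2,
        n_dec_layers: int = 2,
        ffn_dim: int = 128,
        max_len: int = 64,
        seed: int = 0,
        dtype=np.float32,
    ):
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        self.src_vocab_size = src_vocab_size
        self.tgt_vocab_size = tgt_vocab_size
        self.d_model = d_model
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.n_enc_layers = n_enc_layers
        self.n_dec_layers = n_dec_layers
        self.ffn_dim = ffn_dim
        self.max_len = max_len
        self.dtype = dtype
        self.pos = sinusoidal_positions(max_len, d_model, dtype)
        self.params = TransformerParams()
        self._init_params(np.random.default_rng(seed))
        self._cache: dict = {}

    # ---------------------------------------------------------- init

    def _glorot(self, rng, fan_in: int, fan_out: int) -> np.ndarray:
        scale = math.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-scale, scale, size=(fan_in, fan_out)).astype(self.dtype)

    def _init_params(self, rng) -> None:
        p = self.params
        d, f = self.d_model, self.ffn_dim
        p.add("src_emb", (rng.normal(0, 1.0 / math.sqrt(d),
              size=(self.src_vocab_size, d))).astype(self.dtype))
        p.add("tgt_emb", (rng.normal(0, 1.0 / math.sqrt(d),
              size=(self.tgt_vocab_size, d))).astype(self.dtype))
        for side, n_layers in (("enc", self.n_enc_layers), ("dec", self.n_dec_layers)):
            for l in range(n_layers):
                pre = f"{side}{l}"
                attns = ["self"] if side == "enc" else ["self", "cross"]
                for a in attns:
                    for m in ("q", "k", "v", "o"):
                        p.add(f"{pre}.{a}.W{m}", self._glorot(rng, d, d))
                        p.add(f"{pre}.{a}.b{m}", np.zeros(d, dtype=self.dtype))
                p.add(f"{pre}.ffn.W1", self._glorot(rng, d, f))
                p.add(f"{pre}.ffn.b1", np.zeros(f, dtype=self.dtype))
                p.add(f"{pre}.ffn.W2", self._glorot(rng, f, d))
                p.add(f"{pre}.ffn.b2", np.zeros(d, dtype=self.dtype))
                n_ln = 2 if side == "enc" else 3
                for i in range(1, n_ln + 1):
                    p.add(f"{pre}.ln{i}.g", np.ones(d, dtype=self.dtype))
                    p.add(f"{pre}.ln{i}.b", np.zeros(d, dtype=self.dtype))
        for side in ("enc", "dec"):
            p.add(f"{side}_ln.g", np.ones(d, dtype=self.dtype))
            p.add(f"{side}_ln.b", np.zeros(d, dtype=self.dtype))
        p.add("out.W", self._glorot(rng, d, self.tgt_vocab_size))
        p.add("out.b", np.zeros(self.tgt_vocab_size, dtype=self.dtype))

    # ------------------------------------------------- primitive layers

    _LN_EPS = 1e-5

    def _layer_norm(self, x, name, cache):
        g = self.params.values[f"{name}.g"]
        b = self.params.values[f"{name}.b"]
        mu = x.mean(-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self._LN_EPS)
        xhat = xc * inv
        cache[name] = (xhat, inv)
        return xhat * g + b

    def _layer_norm_backward(self, dy, name, cache):
        xhat, inv = cache[name]
        g = self.params.values[f"{name}.g"]
        self.params.accumulate(f"{name}.g",
                               (dy * xhat).reshape(-1, xhat.shape[-1]).sum(0))
        self.params.accumulate(f"{name}.b", dy.reshape(-1, dy.shape[-1]).sum(0))
        dxhat = dy * g
        d = xhat.shape[-1]
        return (dxhat - dxhat.mean(-1, keepdims=True)
                - xhat * (dxhat * xhat).mean(-1, keepdims=True)) * inv

    def _split_heads(self, x):
        B, T, _ = x.shape
        return x.reshape(B, T, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def _merge_heads(self, x):
        B, h, T, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, T, h * dh)

    def _mha(self, x_q, x_kv, name, mask, cache):
        """Multi-head attention. ``mask`` is additive, broadcastable to
        (B, heads, Tq, Tk); disallowed positions hold NEG_INF."""
        c: dict = {}
        q = self._split_heads(self._linear_qkv(x_q, name, "q", c))
        k = self._split_heads(self._linear_qkv(x_kv, name, "k", c))
        v = self._split_heads(self._linear_qkv(x_kv, name, "v", c))
        scores = q @ k.transpose(0, 1, 3, 2) / math.sqrt(self.d_head)
        if mask is not None:
            scores = scores + mask
        a = _softmax(scores, axis=-1)
        heads = a @ v
        merged = self._merge_heads(heads)
        out = self._linear_qkv(merged, name, "o", c)
        c["attn"] = (q, k, v, a)
        cache[name] = c
        return out

    def _linear_qkv(self, x, name, which, cache):
        W = self.params.values[f"{name}.W{which}"]
        b = self.params.values[f"{name}.b{which}"]
        cache[f"x{which}"] = x
        return x @ W + b

    def _linear_qkv_backward(self, dy, name, which, cache):
        x = cache[f"x{which}"]
        W = self.params.values[f"{name}.W{which}"]
        self.params.accumulate(f"{name}.W{which}",
                               x.reshape(-1, x.shape[-1]).T @ dy.reshape(-1, dy.shape[-1]))
        self.params.accumulate(f"{name}.b{which}", dy.reshape(-1, dy.shape[-1]).sum(0))
        return dy @ W.T

    def _mha_backward(self, dout, name, cache):
        c = cache[name]
        q, k, v, a = c["attn"]
        dmerged = self._linear_qkv_backward(dout, name, "o", c)
        dheads = self._split_heads(dmerged)
        da = dheads @ v.transpose(0, 1, 3, 2)
        dv = a.transpose(0, 1, 3, 2) @ dheads
        dscores = _softmax_backward(da, a) / math.sqrt(self.d_head)
        dq = dscores @ k
        dk = dscores.transpose(0, 1, 3, 2) @ q
        dx_q = self._linear_qkv_backward(self._merge_heads(dq), name, "q", c)
        dx_kv = self._linear_qkv_backward(self._merge_heads(dk), name, "k", c)
        dx_kv += self._linear_qkv_backward(self._merge_heads(dv), name, "v", c)
        return dx_q, dx_kv

    def _ffn(self, x, name, cache):
        c: dict = {}
        h = self._ffn_linear(x, name, 1, c)
        r = np.maximum(h, 0.0)
        c["relu_in"] = h
        out = self._ffn_linear(r, name, 2, c)
        cache[name] = c
        return out

    def _ffn_linear(self, x, name, i, cache):
        W = self.params.values[f"{name}.W{i}"]
        b = self.params.values[f"{name}.b{i}"]
        cache[f"x{i}"] = x
        return x @ W + b

    def _ffn_linear_backward(self, dy, name, i, cache):
        x = cache[f"x{i}"]
        W = self.params.values[f"{name}.W{i}"]
        self.params.accumulate(f"{name}.W{i}",
                               x.reshape(-1, x.shape[-1]).T @ dy.reshape(-1, dy.shape[-1]))
        self.params.accumulate(f"{name}.b{i}", dy.reshape(-1, dy.shape[-1]).sum(0))
        return dy @ W.T

    def _ffn_backward(self, dout, name, cache):
        c = cache[name]
        dr = self._ffn_linear_backward(dout, name, 2, c)
        dh = dr * (c["relu_in"] > 0)
        return self._ffn_linear_backward(dh, name, 1, c)

    # ------------------------------------------------------- masks

    @staticmethod
    def pad_mask(ids: np.ndarray) -> np.ndarray:
        """Additive key-padding mask of shape (B, 1, 1, T)."""
        return np.where(ids == 0, NEG_INF, 0.0)[:, None, None, :]

    @staticmethod
    def causal_mask(T: int) -> np.ndarray:
        """Additive lower-triangular mask of shape (1, 1, T, T)."""
        m = np.triu(np.full((T, T), NEG_INF), k=1)
        return m[None, None, :, :]

    # ------------------------------------------------------- encoder

    def encode(self, src_ids: np.ndarray, cache: dict | None = None) -> np.ndarray:
        """Run the encoder; src_ids shape (B, T_src), 0 = pad."""
        c = cache if cache is not None else {}
        B, T = src_ids.shape
        emb = self.params.values["src_emb"][src_ids] * math.sqrt(self.d_model)
        x = (emb + self.pos[:T]).astype(self.dtype)
        c["src_ids"] = src_ids
        mask = self.pad_mask(src_ids)
        for l in range(self.n_enc_layers):
            pre = f"enc{l}"
            ln1 = self._layer_norm(x, f"{pre}.ln1", c)
            x = x + self._mha(ln1, ln1, f"{pre}.self", mask, c)
            ln2 = self._layer_norm(x, f"{pre}.ln2", c)
            x = x + self._ffn(ln2, f"{pre}.ffn", c)
        memory = self._layer_norm(x, "enc_ln", c)
        c["src_mask"] = mask
        return memory

    def _encode_backward(self, dmemory, c):
        dx = self._layer_norm_backward(dmemory, "enc_ln", c)
        for l in reversed(range(self.n_enc_layers)):
            pre = f"enc{l}"
            dln2 = self._ffn_backward(dx, f"{pre}.ffn", c)
            dx = dx + self._layer_norm_backward(dln2, f"{pre}.ln2", c)
            dq, dkv = self._mha_backward(dx, f"{pre}.self", c)
            dln1 = dq + dkv
            dx = dx + self._layer_norm_backward(dln1, f"{pre}.ln1", c)
        src_ids = c["src_ids"]
        demb = dx * math.sqrt(self.d_model)
        np.add.at(self.params.grads["src_emb"], src_ids.ravel(),
                  demb.reshape(-1, self.d_model))

    # ------------------------------------------------------- decoder

    def decode(self, tgt_in_ids: np.ndarray, memory: np.ndarray,
               src_mask: np.ndarray, cache: dict | None = None) -> np.ndarray:
        """Run the decoder; returns logits (B, T_tgt, tgt_vocab)."""
        c = cache if cache is not None else {}
        B, T = tgt_in_ids.shape
        emb = self.params.values["tgt_emb"][tgt_in_ids] * math.sqrt(self.d_model)
        x = (emb + self.pos[:T]).astype(self.dtype)
        c["tgt_ids"] = tgt_in_ids
        self_mask = self.causal_mask(T) + self.pad_mask(tgt_in_ids)
        for l in range(self.n_dec_layers):
            pre = f"dec{l}"
            ln1 = self._layer_norm(x, f"{pre}.ln1", c)
            x = x + self._mha(ln1, ln1, f"{pre}.self", self_mask, c)
            ln2 = self._layer_norm(x, f"{pre}.ln2", c)
            x = x + self._mha(ln2, memory, f"{pre}.cross", src_mask, c)
            ln3 = self._layer_norm(x, f"{pre}.ln3", c)
            x = x + self._ffn(ln3, f"{pre}.ffn", c)
        h = self._layer_norm(x, "dec_ln", c)
        c["out_h"] = h
        return h @ self.params.values["out.W"] + self.params.values["out.b"]

    def _decode_backward(self, dlogits, c):
        h = c["out_h"]
        W = self.params.values["out.W"]
        self.params.accumulate("out.W", h.reshape(-1, self.d_model).T
                               @ dlogits.reshape(-1, self.tgt_vocab_size))
        self.params.accumulate("out.b",
                               dlogits.reshape(-1, self.tgt_vocab_size).sum(0))
        dx = self._layer_norm_backward(dlogits @ W.T, "dec_ln", c)
        dmemory = np.zeros_like(c["memory"])
        for l in reversed(range(self.n_dec_layers)):
            pre = f"dec{l}"
            dln3 = self._ffn_backward(dx, f"{pre}.ffn", c)
            dx = dx + self._layer_norm_backward(dln3, f"{pre}.ln3", c)
            dq, dkv = self._mha_backward(dx, f"{pre}.cross", c)
            dmemory += dkv
            dx = dx + self._layer_norm_backward(dq, f"{pre}.ln2", c)
            dq, dkv = self._mha_backward(dx, f"{pre}.self", c)
            dx = dx + self._layer_norm_backward(dq + dkv, f"{pre}.ln1", c)
        tgt_ids = c["tgt_ids"]
        demb = dx * math.sqrt(self.d_model)
        np.add.at(self.params.grads["tgt_emb"], tgt_ids.ravel(),
                  demb.reshape(-1, self.d_model))
        return dmemory

    # ------------------------------------------------------- training

    def loss_and_grad(self, src_ids: np.ndarray, tgt_in_ids: np.ndarray,
                      labels: np.ndarray) -> float:
        """Teacher-forced cross-entropy; accumulates parameter grads.

        ``labels`` holds the shifted target ids with 0 marking padding
        positions excluded from the loss.
        """
        c: dict = {}
        memory = self.encode(src_ids, c)
        c["memory"] = memory
        logits = self.decode(tgt_in_ids, memory, c["src_mask"], c)
        B, T, V = logits.shape
        probs = _softmax(logits.astype(np.float64), axis=-1)
        mask = labels != 0
        n_tok = int(mask.sum())
        if n_tok == 0:
            raise ValueError("batch contains no unpadded target tokens")
        idx = np.nonzero(mask)
        loss = -float(np.log(probs[idx[0], idx[1], labels[mask]] + 1e-12).sum()) / n_tok
        dlogits = probs
        dlogits[idx[0], idx[1], labels[mask]] -= 1.0
        dlogits *= mask[:, :, None] / n_tok
        dmemory = self._decode_backward(dlogits.astype(self.dtype), c)
        self._encode_backward(dmemory, c)
        return loss

    # ------------------------------------------------------- decoding

    def beam_search(self, src_ids: Sequence[int], beam_size: int,
                    max_len: int | None = None, bos: int = 1, eos: int = 2
                    ) -> list[tuple[list[int], float]]:
        """Beam-search decode one source; returns hypotheses sorted by
        length-normalized log-probability, best first.

        Each hypothesis is the token-id list between BOS and EOS
        (exclusive) with its mean per-token log-probability.
        """
        max_len = min(max_len or self.max_len, self.max_len)
        src = np.asarray(src_ids, dtype=np.int64)[None, :]
        memory = self.encode(src)
        src_mask = self.pad_mask(src)
        beams: list[tuple[list[int], float]] = [([bos], 0.0)]
        finished: list[tuple[list[int], float]] = []
        for _ in range(max_len - 1):
            if not beams:
                break
            T = max(len(b[0]) for b in beams)
            tgt = np.zeros((len(beams), T), dtype=np.int64)
            for i, (toks, _) in enumerate(beams):
                tgt[i, : len(toks)] = toks
            mem = np.repeat(memory, len(beams), axis=0)
            msk = np.repeat(src_mask, len(beams), axis=0)
            logits = self.decode(tgt, mem, msk)
            candidates: list[tuple[list[int], float]] = []
            for i, (toks, score) in enumerate(beams):
                logp = np.log(_softmax(logits[i, len(toks) - 1].astype(np.float64)))
                top = np.argsort(-logp)[: beam_size]
                for t in top:
                    candidates.append((toks + [int(t)], score + float(logp[t])))
            candidates.sort(key=lambda c: -c[1] / (len(c[0]) - 1))
            beams = []
            for toks, score in candidates:
                if toks[-1] == eos:
                    finished.append((toks[1:-1], score / max(len(toks) - 1, 1)))
                else:
                    beams.append((toks, score))
                if len(beams) >= beam_size:
                    break
            if len(finished) >= beam_size:
                break
        for toks, score in beams:  # unfinished hypotheses at max_len
            finished.append((toks[1:], score / max(len(toks) - 1, 1)))
        finished.sort(key=lambda c: -c[1])
        return finished[:beam_size]
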