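"""Neural translation of noisy procedure text into canonical descriptions.

Step 1 of the two-step coding system: an encoder-decoder Transformer is
trained on the parallel corpus (noisy source phrase -> canonical code
description) and, at inference, beam search yields the top-k candidate
descriptions per source with their scores. The downstream matching step
consumes these candidates; retaining the top three supports top-3
accuracy evaluation.

Word-level vocabularies are built from the training pairs; source
tokens unseen in training map to a single UNK symbol. The default
configuration is desk-scale (2+2 layers, 64-dim embeddings) — the
method does not depend on model size, and a GPU-scale configuration is
a matter of these same knobs.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import ParallelPair
from .transformer import Seq2SeqTransformer, Adam

__all__ = ["Vocab", "NmtConfig", "TranslationCandidates", "Translator", "train"]

PAD, BOS, EOS, UNK = 0, 1, 2, 3
_SPECIALS = ("<pad>", "<bos>", "<eos>", "<unk>")


class Vocab:
    """Word-level token inventory with reserved special symbols."""

    def __init__(self, tokens: Sequence[str]):
        self.id_to_token: list[str] = list(_SPECIALS) + list(tokens)
        self.token_to_id = {t: i for i, t in enumerate(self.id_to_token)}
        if len(self.token_to_id) != len(self.id_to_token):
            raise ValueError("duplicate tokens in vocabulary")

    @classmethod
    def build(cls, sentences: Sequence[str], min_freq: int = 1) -> "Vocab":
        counts = Counter(tok for s in sentences for tok in s.split())
        kept = sorted(t for t, c in counts.items() if c >= min_freq)
        return cls(kept)

    def __len__(self) -> int:
        return len(self.id_to_token)

    def encode(self, sentence: str) -> list[int]:
        return [self.token_to_id.get(t, UNK) for t in sentence.split()]

    def decode(self, ids: Sequence[int]) -> str:
        return " ".join(
            self.id_to_token[i] for i in ids if i not in (PAD, BOS, EOS)
        )


@dataclass(frozen=True)
class NmtConfig:
    """Hyperparameters of the translation model.

    ``beam_size`` bounds the candidate count k requested at decode
    time. ``vocab_min_freq`` folds rare (often misspelled) source
    tokens into UNK.
    """

    embed_dim: int = 64
    layers: int = 2
    heads: int = 4
    ffn_dim: int = 128
    max_len: int = 48
    beam_size: int = 5
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-3
    vocab_min_freq: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beam_size < 3:
            raise ValueError("beam_size must be at least 3 (top-3 retention)")
        for name in ("embed_dim", "layers", "heads", "ffn_dim", "max_len", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class TranslationCandidates:
    """Ordered top-k decoded sentences with scores for one source."""

    source: str
    candidates: tuple[tuple[str, float], ...]
    k: int

    def __post_init__(self) -> None:
        scores = [s for _, s in self.candidates]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("candidate scores must be non-increasing")
        if len(self.candidates) > self.k:
            raise ValueError("more candidates than k")

    @property
    def sentences(self) -> list[str]:
        return [s for s, _ in self.candidates]

    @property
    def best(self) -> str:
        return self.candidates[0][0]


class Translator:
    """A trained translation model plus its vocabularies."""

    def __init__(self, model: Seq2SeqTransformer, src_vocab: Vocab,
                 tgt_vocab: Vocab, config: NmtConfig,
                 loss_history: list[float] | None = None):
        self.model = model
        self.src_vocab = src_vocab
        self.tgt_vocab = tgt_vocab
        self.config = config
        self.loss_history = loss_history or []

    # -------------------------------------------------------- decoding

    def translate(self, source: str, k: int = 3) -> TranslationCandidates:
        """Beam-search decode the k best distinct candidate sentences.

        Distinctness is judged after detokenization (different beam
        paths can stringify identically). Scores are mean per-token
        log-probabilities, non-increasing in rank.
        """
        if k < 1:
            raise ValueError("k must be at least 1")
        if k > self.config.beam_size:
            raise ValueError(
                f"k={k} exceeds beam_size={self.config.beam_size}")
        if not source or not source.split():
            raise ValueError("empty source")
        src_ids = self.src_vocab.encode(source)[: self.config.max_len]
        hyps = self.model.beam_search(src_ids, self.config.beam_size)
        seen: set[str] = set()
        out: list[tuple[str, float]] = []
        for ids, score in hyps:
            sent = self.tgt_vocab.decode(ids)
            if sent and sent not in seen:
                seen.add(sent)
                out.append((sent, score))
            if len(out) == k:
                break
        if not out:  # degenerate decode (all-empty hypotheses)
            out = [("<empty>", float("-inf"))]
        return TranslationCandidates(source=source, candidates=tuple(out), k=k)

    def translate_many(self, sources: Sequence[str], k: int = 3
                       ) -> list[TranslationCandidates]:
        return [self.translate(s, k) for s in sources]

    # ------------------------------------------------------ persistence

    def save(self, directory: str | Path) -> None:
        """Write a checkpoint directory: config JSON, vocab files,
        weights blob."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "config.json").write_text(json.dumps(asdict(self.config), indent=1))
        (d / "src_vocab.txt").write_text(
            "\n".join(self.src_vocab.id_to_token[len(_SPECIALS):]))
        (d / "tgt_vocab.txt").write_text(
            "\n".join(self.tgt_vocab.id_to_token[len(_SPECIALS):]))
        np.savez(d / "weights.npz", **self.model.params.values)

    @classmethod
    def load(cls, directory: str | Path) -> "Translator":
        d = Path(directory)
        config = NmtConfig(**json.loads((d / "config.json").read_text()))
        src_vocab = Vocab((d / "src_vocab.txt").read_text().splitlines())
        tgt_vocab = Vocab((d / "tgt_vocab.txt").read_text().splitlines())
        model = _build_model(len(src_vocab), len(tgt_vocab), config)
        with np.load(d / "weights.npz") as blob:
            for k in model.params.values:
                model.params.values[k][...] = blob[k]
        return cls(model, src_vocab, tgt_vocab, config)


def _build_model(n_src: int, n_tgt: int, config: NmtConfig) -> Seq2SeqTransformer:
    return Seq2SeqTransformer(
        src_vocab_size=n_src,
        tgt_vocab_size=n_tgt,
        d_model=config.embed_dim,
        n_heads=config.heads,
        n_enc_layers=config.layers,
        n_dec_layers=config.layers,
        ffn_dim=config.ffn_dim,
        max_len=config.max_len,
        seed=config.seed,
    )


def _pad_batch(seqs: list[list[int]], width: int) -> np.ndarray:
    out = np.zeros((len(seqs), width), dtype=np.int64)
    for i, s in enumerate(seqs):
        out[i, : len(s)] = s
    return out


def train(pairs: Sequence[ParallelPair], config: NmtConfig = NmtConfig(),
          verbose: bool = False) -> Translator:
    """Train a translation model on a parallel corpus.

    Teacher-forced cross-entropy with Adam; batches reshuffled each
    epoch from the seeded generator, so training is deterministic for
    a given corpus, configuration, and seed. Raises on an empty corpus
    or on any target longer than ``max_len`` (named by case_id).
    """
    if not pairs:
        raise ValueError("cannot train on an empty corpus")
    for p in pairs:
        if len(p.target.split()) + 2 > config.max_len:  # room for BOS/EOS
            raise ValueError(
                f"target of pair {p.case_id!r} exceeds max_len={config.max_len}")
    src_vocab = Vocab.build([p.source for p in pairs], config.vocab_min_freq)
    tgt_vocab = Vocab.build([p.target for p in pairs], min_freq=1)
    model = _build_model(len(src_vocab), len(tgt_vocab), config)
    opt = Adam(model.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)

    src_ids = [src_vocab.encode(p.source)[: config.max_len] or [UNK] for p in pairs]
    tgt_ids = [tgt_vocab.encode(p.target) for p in pairs]
    n = len(pairs)
    history: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        total, seen = 0.0, 0
        for start in range(0, n, config.batch_size):
            batch = order[start: start + config.batch_size]
            bs = [src_ids[i] for i in batch]
            bt = [tgt_ids[i] for i in batch]
            s_w = max(len(x) for x in bs)
            t_w = max(len(x) for x in bt) + 1
            src = _pad_batch(bs, s_w)
            tgt_in = _pad_batch([[BOS] + t for t in bt], t_w)
            labels = _pad_batch([t + [EOS] for t in bt], t_w)
            model.params.zero_grad()
            loss = model.loss_and_grad(src, tgt_in, labels)
            opt.step()
            total += loss * len(batch)
            seen += len(batch)
        history.append(total / seen)
        if verbose:
            print(f"epoch {epoch + 1}/{config.epochs}: loss {history[-1]:.4f}")
    return Translator(model, src_vocab, tgt_vocab, config, history)
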