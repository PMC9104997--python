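"""Substructure embeddings: a trainable fixture model and molecule pooling.

Substructure "sentences" (sequences of integer Morgan-environment
identifiers) are treated as text and embedded with a skip-gram model with
negative sampling.  The package ships a small NumPy trainer so the whole
pipeline runs self-contained; an externally trained identifier->vector
table in the same text format can be loaded instead when available.

A molecule's 300-dimensional embedding is the sum of the vectors of all
identifiers in its sentence; identifiers absent from the vocabulary
contribute the reserved UNK vector.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = ["EmbeddingModel", "train_fixture_embedding"]

UNK_TOKEN = "UNK"


@dataclass
class EmbeddingModel:
    """Identifier -> vector table with a reserved UNK fallback row."""

    dim: int
    vocabulary: dict[int, np.ndarray]
    unk_vector: np.ndarray

    def __post_init__(self):
        if self.unk_vector.shape != (self.dim,):
            raise ValueError("unk_vector has wrong dimension")
        for key, vec in self.vocabulary.items():
            if vec.shape != (self.dim,):
                raise ValueError(f"vector for identifier {key} has wrong dimension")

    def vector(self, identifier: int) -> np.ndarray:
        return self.vocabulary.get(identifier, self.unk_vector)

    def embed_sentence(self, sentence: Sequence[int]) -> np.ndarray:
        """Sum-pool identifier vectors; an empty sentence gives zeros."""
        out = np.zeros(self.dim)
        for ident in sentence:
            out += self.vector(ident)
        return out

    @classmethod
    def zeros(cls, dim: int = 300) -> "EmbeddingModel":
        """All-zero model; useful for isolating the descriptor block."""
        return cls(dim=dim, vocabulary={}, unk_vector=np.zeros(dim))

    def save(self, path: str | Path) -> None:
        """Write a two-column text table: token, then `dim` reals.

        The UNK row is stored under the reserved token ``UNK``; all other
        tokens are integer identifiers.
        """
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# iltox embedding, dim={self.dim}\n")
            fh.write(UNK_TOKEN + " " + " ".join(f"{v:.8g}" for v in self.unk_vector) + "\n")
            for key in sorted(self.vocabulary):
                vec = self.vocabulary[key]
                fh.write(f"{key} " + " ".join(f"{v:.8g}" for v in vec) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingModel":
        vocab: dict[int, np.ndarray] = {}
        unk = None
        dim = None
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                token, *vals = line.split()
                vec = np.array([float(v) for v in vals])
                if dim is None:
                    dim = vec.size
                elif vec.size != dim:
                    raise ValueError(
                        f"row for {token!r} has {vec.size} values, expected {dim}")
                if token == UNK_TOKEN:
                    unk = vec
                else:
                    vocab[int(token)] = vec
        if dim is None or unk is None:
            raise ValueError(f"{path}: no UNK row found; not a valid embedding table")
        return cls(dim=dim, vocabulary=vocab, unk_vector=unk)


def train_fixture_embedding(corpus: Iterable[Sequence[int]],
                            dim: int = 300,
                            min_count: int = 1,
                            seed: int = 0,
                            window: int = 5,
                            epochs: int = 3,
                            n_negative: int = 5,
                            learning_rate: float = 0.025) -> EmbeddingModel:
    """Train a skip-gram embedding over substructure-identifier sentences.

    A NumPy implementation of skip-gram with negative sampling (unigram^0.75
    noise distribution, linearly decaying learning rate).  Identifiers seen
    fewer than `min_count` times are dropped from the vocabulary and resolve
    to the UNK vector at lookup time.  Fully deterministic for a fixed seed.

    Parameters
    ----------
    corpus : iterable of sentences (sequences of int identifiers)
    dim : embedding dimension (300 matches the feature-vector layout)
    min_count : minimum corpus frequency for a vocabulary entry
    seed : RNG seed; the same corpus and seed reproduce the model bit-exactly
    window : maximum symmetric context window
    epochs : passes over the corpus
    n_negative : negative samples per (center, context) pair
    """
    sentences = [list(s) for s in corpus]
    if not sentences or all(len(s) == 0 for s in sentences):
        raise ValueError("cannot train an embedding on an empty corpus")
    if dim < 1:
        raise ValueError("dim must be >= 1")

    counts = Counter(tok for s in sentences for tok in s)
    vocab_tokens = sorted(tok for tok, c in counts.items() if c >= min_count)
    rng = np.random.default_rng(seed)
    if not vocab_tokens:
        # Degenerate corpus: everything is rare; only the UNK row exists.
        unk = (rng.random(dim) - 0.5) / dim
        return EmbeddingModel(dim=dim, vocabulary={}, unk_vector=unk)

    index = {tok: i for i, tok in enumerate(vocab_tokens)}
    v = len(vocab_tokens)

    # Input (center) and output (context) matrices, word2vec-style init.
    w_in = (rng.random((v, dim)) - 0.5) / dim
    w_out = np.zeros((v, dim))

    freqs = np.array([counts[t] for t in vocab_tokens], dtype=float)
    noise = freqs ** 0.75
    noise /= noise.sum()

    # Pre-extract (center, context) index pairs; out-of-vocabulary tokens
    # are skipped as training positions but still break up the window the
    # way a dropped word would not (standard subsampling is not applied).
    pairs = []
    for s in sentences:
        ids = [index.get(tok, -1) for tok in s]
        for pos, ci in enumerate(ids):
            if ci < 0:
                continue
            lo = max(0, pos - window)
            hi = min(len(ids), pos + window + 1)
            for q in range(lo, hi):
                if q != pos and ids[q] >= 0:
                    pairs.append((ci, ids[q]))
    if not pairs:
        unk = (rng.random(dim) - 0.5) / dim
        return EmbeddingModel(dim=dim, vocabulary={}, unk_vector=unk)
    pairs = np.array(pairs, dtype=np.int64)

    n_pairs = pairs.shape[0]
    batch = 512
    total_steps = epochs * ((n_pairs + batch - 1) // batch)
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch):
            sel = pairs[order[start:start + batch]]
            centers, contexts = sel[:, 0], sel[:, 1]
            negs = rng.choice(v, size=(sel.shape[0], n_negative), p=noise)
            lr = learning_rate * max(1.0 - step / total_steps, 1e-4)
            step += 1

            h = w_in[centers]                                   # (b, dim)
            targets = np.concatenate([contexts[:, None], negs], axis=1)
            tvecs = w_out[targets]                              # (b, 1+k, dim)
            logits = np.einsum("bd,bkd->bk", h, tvecs)
            sig = 1.0 / (1.0 + np.exp(-np.clip(logits, -30, 30)))
            label = np.zeros_like(sig)
            label[:, 0] = 1.0
            err = sig - label                                   # (b, 1+k)

            grad_h = np.einsum("bk,bkd->bd", err, tvecs)
            grad_t = err[:, :, None] * h[:, None, :]
            # Average per-row within the batch: a token repeated many times
            # in one batch otherwise takes a multiplied step and diverges.
            g_in = np.zeros_like(w_in)
            np.add.at(g_in, centers, grad_h)
            c_in = np.bincount(centers, minlength=v)[:, None]
            w_in -= lr * g_in / np.maximum(c_in, 1)
            g_out = np.zeros_like(w_out)
            flat_t = targets.ravel()
            np.add.at(g_out, flat_t, grad_t.reshape(-1, dim))
            c_out = np.bincount(flat_t, minlength=v)[:, None]
            w_out -= lr * g_out / np.maximum(c_out, 1)

    unk = w_in.mean(axis=0)
    vocabulary = {tok: w_in[i].copy() for tok, i in index.items()}
    return EmbeddingModel(dim=dim, vocabulary=vocabulary, unk_vector=unk)
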