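"""Lightweight text encoders producing fixed-width content vectors.

The desk-scale configuration uses a hashed embedding-bag: every token maps
deterministically (stable CRC hash, not Python's salted ``hash``) to a row of a
seeded Gaussian embedding table, and a text is encoded as the mean of its token
vectors. Random-projection bags of words preserve lexical separability well
enough for the sequence classifier to learn on top of, run in microseconds on
one CPU, and keep the whole pipeline deterministic per seed. The embedding
width H is configurable; contextual encoders with H = 768 slot in behind the
same ``encode`` interface.
"""

from __future__ import annotations

import re
import warnings
import zlib

import numpy as np

__all__ = ["tokenize_for_encoding", "EmbeddingBagEncoder"]

_TOKEN_RE = re.compile(r"\[[A-Za-z_]+\]|[\w']+")


def tokenize_for_encoding(text: str) -> list[str]:
    """Lowercased tokens; bracketed mask tokens ([DRUG_*], [URL], ...) stay whole."""
    return [t.lower() for t in _TOKEN_RE.findall(text)]


class EmbeddingBagEncoder:
    """Frozen hashed embedding-bag content encoder.

    Parameters
    ----------
    dim : embedding width H (default 32).
    vocab_size : number of hash buckets; collisions are rare below ~1e4 tokens.
    seed : seeds the Gaussian embedding table, making encoding fully
        deterministic across processes and platforms.
    """

    def __init__(self, dim: int = 32, vocab_size: int = 4096, seed: int = 0):
        self.dim = int(dim)
        self.vocab_size = int(vocab_size)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        self._table = rng.standard_normal((self.vocab_size, self.dim)) / np.sqrt(
            self.dim
        )

    def _bucket(self, token: str) -> int:
        return zlib.crc32(token.encode("utf-8")) % self.vocab_size

    def token_vector(self, token: str) -> np.ndarray:
        return self._table[self._bucket(token.lower())]

    def encode(self, text: str) -> np.ndarray:
        """Mean of the token vectors; the zero vector (with a warning) if no tokens."""
        tokens = tokenize_for_encoding(text)
        if not tokens:
            warnings.warn("encoding empty token sequence; returning zero vector",
                          stacklevel=2)
            return np.zeros(self.dim)
        idx = np.fromiter((self._bucket(t) for t in tokens), dtype=np.intp)
        return self._table[idx].mean(axis=0)

    def encode_batch(self, texts) -> np.ndarray:
        return np.stack([self.encode(t) for t in texts]) if len(texts) else np.zeros(
            (0, self.dim)
        )
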