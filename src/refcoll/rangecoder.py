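"""Byte-oriented range coder with adaptive contextual frequency models.

The coder is a 32-bit carry-less range coder (Schindler/Subbotin style):
instead of propagating carries it sacrifices a sliver of the coding range
whenever the top bytes of ``low`` and ``low + range`` disagree while the
range has shrunk below the renormalization threshold.  Frequencies are
adaptive with add-1 initialization, increment 32 and halving when the
total reaches 2^16 — the total therefore always fits under the coder's
bottom threshold, so ``range // total`` never collapses to zero.

Encoder and decoder must drive *identical* model state; every model
exposes a digest so tests can assert bit-identical trajectories.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["RangeEncoder", "RangeDecoder", "AdaptiveModel", "ContextModel"]

_TOP = 1 << 24
_BOT = 1 << 16
_MASK = 0xFFFFFFFF


class RangeEncoder:
    def __init__(self) -> None:
        self.low = 0
        self.range = _MASK
        self.out = bytearray()

    def encode(self, cum: int, freq: int, total: int) -> None:
        """Encode a symbol occupying [cum, cum+freq) of [0, total)."""
        r = self.range // total
        self.low = (self.low + r * cum) & _MASK
        self.range = r * freq
        while True:
            if (self.low ^ (self.low + self.range)) & _MASK < _TOP:
                pass
            elif self.range < _BOT:
                self.range = (-self.low) & (_BOT - 1)
            else:
                break
            self.out.append((self.low >> 24) & 0xFF)
            self.low = (self.low << 8) & _MASK
            self.range = (self.range << 8) & _MASK

    def finish(self) -> bytes:
        for _ in range(4):
            self.out.append((self.low >> 24) & 0xFF)
            self.low = (self.low << 8) & _MASK
        return bytes(self.out)


class RangeDecoder:
    def __init__(self, data: bytes, offset: int = 0) -> None:
        self.data = data
        self.pos = offset
        self.low = 0
        self.range = _MASK
        self.code = 0
        for _ in range(4):
            self.code = ((self.code << 8) | self._next_byte()) & _MASK

    def _next_byte(self) -> int:
        if self.pos < len(self.data):
            b = self.data[self.pos]
            self.pos += 1
            return b
        return 0  # zero-padding past the flushed tail

    def decode_target(self, total: int) -> int:
        """Cumulative-frequency target of the next symbol."""
        self._r = self.range // total
        t = ((self.code - self.low) & _MASK) // self._r
        return total - 1 if t >= total else t

    def decode_update(self, cum: int, freq: int, total: int) -> None:
        r = self._r
        self.low = (self.low + r * cum) & _MASK
        self.range = r * freq
        while True:
            if (self.low ^ (self.low + self.range)) & _MASK < _TOP:
                pass
            elif self.range < _BOT:
                self.range = (-self.low) & (_BOT - 1)
            else:
                break
            self.code = ((self.code << 8) | self._next_byte()) & _MASK
            self.low = (self.low << 8) & _MASK
            self.range = (self.range << 8) & _MASK


class AdaptiveModel:
    """Adaptive frequency table over ``n`` symbols (add-1 initialized)."""

    INCREMENT = 32
    RESCALE_LIMIT = 1 << 16

    __slots__ = ("freq", "total")

    def __init__(self, n: int) -> None:
        self.freq = np.ones(n, dtype=np.int64)
        self.total = n

    def _update(self, symbol: int) -> None:
        self.freq[symbol] += self.INCREMENT
        self.total += self.INCREMENT
        if self.total >= self.RESCALE_LIMIT:
            self.freq = (self.freq + 1) >> 1
            self.total = int(self.freq.sum())

    def encode(self, enc: RangeEncoder, symbol: int) -> None:
        cum = int(self.freq[:symbol].sum())
        enc.encode(cum, int(self.freq[symbol]), self.total)
        self._update(symbol)

    def decode(self, dec: RangeDecoder) -> int:
        target = dec.decode_target(self.total)
        cumsum = np.cumsum(self.freq)
        symbol = int(np.searchsorted(cumsum, target, side="right"))
        cum = int(cumsum[symbol - 1]) if symbol else 0
        dec.decode_update(cum, int(self.freq[symbol]), self.total)
        self._update(symbol)
        return symbol

    def digest_update(self, h) -> None:
        h.update(self.freq.tobytes())


class ContextModel:
    """Family of adaptive models selected by a context key."""

    def __init__(self, n_symbols: int) -> None:
        self.n_symbols = n_symbols
        self.contexts: dict = {}

    def _model(self, ctx) -> AdaptiveModel:
        m = self.contexts.get(ctx)
        if m is None:
            m = AdaptiveModel(self.n_symbols)
            self.contexts[ctx] = m
        return m

    def encode(self, enc: RangeEncoder, ctx, symbol: int) -> None:
        self._model(ctx).encode(enc, symbol)

    def decode(self, dec: RangeDecoder, ctx) -> int:
        return self._model(ctx).decode(dec)

    def digest_update(self, h) -> None:
        for ctx in sorted(self.contexts, key=repr):
            h.update(repr(ctx).encode())
            self.contexts[ctx].digest_update(h)


def models_digest(models: dict[str, ContextModel]) -> str:
    """Hex digest of the full adaptive state of a model family."""
    h = hashlib.sha256()
    for name in sorted(models):
        h.update(name.encode())
        models[name].digest_update(h)
    return h.hexdigest()
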