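"""Shared helpers: error types, named RNG substreams, small validators."""

from __future__ import annotations

import zlib

import numpy as np


class ConfigError(ValueError):
    """A configuration field is missing or out of range."""


class FormatError(ValueError):
    """An input file violates its declared format."""


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a generator for a named substream of a global seed.

    Each stage draws from its own stream keyed by ``name``, so adding a new
    stage never perturbs the draws of existing ones.
    """
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


def check_fraction(value: float, name: str, *, lo: float = 0.0, hi: float = 1.0,
                   lo_open: bool = False, hi_open: bool = False) -> None:
    ok = (value > lo if lo_open else value >= lo) and (value < hi if hi_open else value <= hi)
    if not ok:
        raise ConfigError(f"{name} must be in {'(' if lo_open else '['}{lo}, {hi}"
                          f"{')' if hi_open else ']'}; got {value}")


def check_count(value: int, name: str, minimum: int = 1) -> None:
    if not isinstance(value, (int, np.integer)) or value < minimum:
        raise ConfigError(f"{name} must be an integer >= {minimum}; got {value!r}")
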