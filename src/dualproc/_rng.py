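"""Seed-substream helpers.

A single integer seed drives every stochastic stage (cohort generation, fit
restarts, imputation, permutation).  Named substreams are derived from the
root seed so that regenerating one stage never perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def _name_key(name: str) -> int:
    # crc32 is stable across platforms/sessions, unlike hash()
    return zlib.crc32(name.encode("utf-8"))


def substream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``."""
    ss = np.random.SeedSequence([int(seed), _name_key(name), int(index)])
    return np.random.default_rng(ss)


def child_seed(seed: int, name: str, index: int = 0) -> int:
    """A derived integer seed (< 2**31) for APIs that take plain seeds."""
    ss = np.random.SeedSequence([int(seed), _name_key(name), int(index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
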