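"""Deterministic random-stream derivation.

Every stochastic operation takes an integer ``seed`` and derives its own
independent stream with :func:`child_rng`. A child stream is identified by a
path of small non-negative integers (e.g. ``(arm, replicate)``), mapped onto
``numpy.random.SeedSequence(seed, spawn_key=path)``. The derivation is a pure
function of ``(seed, path)``: it does not depend on call order, so serial and
parallel execution of independent cells produce identical draws.
"""

from __future__ import annotations

import numpy as np

__all__ = ["child_rng", "child_seed"]


def child_rng(seed: int, *path: int) -> np.random.Generator:
    """Return the generator for stream ``path`` under root ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=tuple(int(p) for p in path)))


def child_seed(seed: int, *path: int) -> int:
    """A 31-bit integer seed derived from ``(seed, path)``.

    Used where a third-party API wants a plain ``random_state`` integer.
    """
    state = np.random.SeedSequence(int(seed), spawn_key=tuple(int(p) for p in path)).generate_state(1)[0]
    return int(state) % (2**31)
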