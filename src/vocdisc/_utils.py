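"""Shared helpers: seed derivation and small numeric utilities."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "rng_for"]


def derive_seed(master_seed: int, stage: str) -> int:
    """Derive a stable per-stage seed below 2**31 from a master seed.

    Uses CRC32 of the stage name mixed into a SeedSequence so that every
    stochastic stage of a run is replayable in isolation.
    """
    tag = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, tag])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def rng_for(master_seed: int, stage: str) -> np.random.Generator:
    """Generator seeded with :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(master_seed, stage))
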