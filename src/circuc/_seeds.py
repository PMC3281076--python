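"""Stage-keyed derivation of random streams from a single master seed.

Every randomized stage draws its generator through :func:`stage_rng` so that
one master seed reproduces a full pipeline run, while stages remain
statistically independent of each other and of the number of times other
stages consume randomness.
"""

from __future__ import annotations

import zlib

import numpy as np


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31)."""
    key = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence([int(master_seed), key])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Generator for a named stage, derived from the master seed."""
    return np.random.default_rng(stage_seed(master_seed, stage))
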