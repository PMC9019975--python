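"""Deterministic seed derivation.

Every source of randomness in the pipeline draws from a generator derived
from the single master seed plus a structured key (phase, pile id, ...).
Because the derivation ignores execution order, per-pile computations can run
in any order (or concurrently) and still reproduce the serial result.
"""

from __future__ import annotations

import numpy as np

# Phase codes used in spawn keys; distinct per independent random consumer.
PHASE_SYNTH = 0
PHASE_RARE = 1
PHASE_PRELIMINARY = 2
PHASE_METAGROUP = 3
PHASE_FINAL = 4
PHASE_OUTLIER = 5
PHASE_SINGLE = 6
PHASE_QC = 7


def derive_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Generator for the random consumer identified by ``key`` under ``master_seed``."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)


def derive_seed(master_seed: int, *key: int) -> int:
    """A plain integer sub-seed (below 2**31) for the given key."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
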