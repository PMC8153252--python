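"""Named random substreams derived from one master seed.

Every stochastic stage of the pipeline draws from its own named stream so
that changing one stage (e.g. the behavioral trace) never perturbs another
(e.g. input spike sampling) under the same master seed.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream `name` of master `seed`.

    The stream key is a CRC32 hash of the name, so streams are stable across
    sessions and independent of the order in which they are created.
    """
    if seed is None:
        raise ValueError("seed must be an integer, not None")
    key = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))
    return np.random.default_rng(ss)
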