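"""Named random substreams derived from a single root seed.

Every stochastic stage of the pipeline (genotypes, dropout, herbivory, ...)
draws from its own named substream so that stages are independently
reproducible and adding draws to one stage does not perturb another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream `name` of root `seed`.

    The substream key is a CRC32 of the name, so the mapping is stable
    across sessions and platforms.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))
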