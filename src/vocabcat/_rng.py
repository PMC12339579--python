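"""Named substreams derived from one root seed.

All randomness in the package flows from a root integer seed; independent
components draw from child seeds derived via a hash of a name tuple, so
stochastic tests are isolated from one another.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_seed(seed: int, *names: str | int) -> int:
    """A reproducible child seed (< 2^31) for the named substream."""
    tag = zlib.crc32(repr(names).encode("utf-8"))
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def substream(seed: int, *names: str | int) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, *names))
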