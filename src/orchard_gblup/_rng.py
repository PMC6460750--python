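"""Named random substreams derived from a single master seed.

Every stochastic draw in the package flows through :func:`substream`, keyed by
a stable name, so adding a new feature (a new stream) never perturbs draws in
existing streams.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def _name_entropy(name: str) -> list[int]:
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    # four 32-bit words are plenty of entropy for stream separation
    return [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``master_seed``."""
    seq = np.random.SeedSequence([int(master_seed) & 0xFFFFFFFF, *_name_entropy(name)])
    return np.random.default_rng(seq)


def substream_seed(master_seed: int, name: str) -> int:
    """A positive 31-bit integer seed for external tools (e.g. msprime)."""
    rng = substream(master_seed, name)
    return int(rng.integers(1, 2**31 - 1))
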