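"""Named, reproducible random substreams.

Every stochastic stage of the pipeline draws from a substream derived from a
single master seed plus a path of string labels, so that (a) a session is
byte-reproducible from its master seed and (b) changing the number of draws
in one stage does not perturb any other stage.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "randbelow"]


def _label_key(label: str | int) -> int:
    if isinstance(label, int):
        return label & 0xFFFFFFFF
    return zlib.crc32(label.encode("utf-8"))


def substream(master_seed: int, *path: str | int) -> np.random.Generator:
    """Return a Generator for the substream identified by ``path``.

    The same (seed, path) pair always yields an identical stream; distinct
    paths yield statistically independent streams (SeedSequence spawn keys).
    """
    key = tuple(_label_key(p) for p in path)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(master_seed), spawn_key=key))


def randbelow(n: int, rng: np.random.Generator) -> int:
    """Uniform integer in [0, n) for arbitrary-precision ``n``.

    Rejection sampling on raw bits so the draw is exactly uniform even when
    ``n`` exceeds 64 bits (needed for exact composition counts).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    k = n.bit_length()
    nbytes = (k + 7) // 8
    shift = nbytes * 8 - k
    while True:
        u = int.from_bytes(rng.bytes(nbytes), "big") >> shift
        if u < n:
            return u
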