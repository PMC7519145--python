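"""Seed-stream management.

A single master seed fans out into named child streams (weather, genotypes,
effects, folds, chain, ...) so that each component of a run is independently
reproducible: changing the number of SNPs does not perturb the weather draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream", "child_seed"]


def _label_key(label: str) -> int:
    # stable across processes/platforms (hash() is salted, so not usable)
    return zlib.crc32(label.encode("utf-8"))


def stream(seed: int, label: str = "") -> np.random.Generator:
    """Return a Generator for the named child stream of ``seed``."""
    if label:
        ss = np.random.SeedSequence([int(seed), _label_key(label)])
    else:
        ss = np.random.SeedSequence(int(seed))
    return np.random.default_rng(ss)


def child_seed(seed: int, label: str) -> int:
    """A derived integer seed (< 2**31) for APIs that want a plain int."""
    return int(np.random.SeedSequence([int(seed), _label_key(label)]).generate_state(1)[0] % (2**31))
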