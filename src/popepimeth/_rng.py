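"""Seed bookkeeping: one root seed, independent per-stage streams.

Each stage derives its generator from ``(root_seed, crc32(label))`` so that a
stage can be re-run in isolation and still produce the bytes it produced inside
a full pipeline run.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng", "stage_seed"]


def stage_seed(root_seed: int, label: str) -> int:
    """A reproducible 31-bit integer seed for the given stage label."""
    h = zlib.crc32(label.encode("utf-8")) & 0x7FFFFFFF
    ss = np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF, h])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def stage_rng(root_seed: int, label: str) -> np.random.Generator:
    """Generator for one named stage, independent of all other labels."""
    h = zlib.crc32(label.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF, h]))
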