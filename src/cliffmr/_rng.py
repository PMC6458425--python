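"""Deterministic random-number substreams.

One master seed drives a whole study; independent stages (exposure GWAS
noise, outcome GWAS noise, cohort genotypes, bootstraps ...) each get their
own generator derived by stable hashing of ``(seed, stage_name)``.  The
hash is zlib.crc32, which is stable across platforms and Python versions,
so identical seeds give byte-identical output everywhere.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, stage: str) -> np.random.Generator:
    """Return a Generator for a named stage of a seeded computation.

    Distinct stage names yield statistically independent streams; the
    exposure and outcome samples of a two-sample design, in particular,
    never share noise.
    """
    tag = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))
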