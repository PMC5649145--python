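"""Deterministic seed derivation.

One master seed drives the whole pipeline; every stage (fold splitting,
resampling, subsampling, model fitting) receives an independent child seed so
that changing the number of repetitions of one stage does not perturb the
random streams of another.
"""

from __future__ import annotations

import numpy as np

_MOD = 2**31  # keep derived seeds valid for every scikit-learn random_state


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent integer seeds from ``seed``."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % _MOD) for c in ss.spawn(n)]
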