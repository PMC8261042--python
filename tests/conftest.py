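"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest


def random_pedigree(n: int, rng, n_founders: int | None = None):
    """Random topologically ordered pedigree (sire_idx, dam_idx)."""
    nf = n_founders if n_founders is not None else max(2, n // 4)
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    for i in range(nf, n):
        s = rng.integers(0, i)
        d = rng.integers(0, i)
        while d == s:
            d = rng.integers(0, i)
        # some unknown parents sprinkled in
        sire[i] = s if rng.random() > 0.1 else -1
        dam[i] = d if rng.random() > 0.1 else -1
    return sire, dam


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def trio():
    """Sire, dam (both founders) and one offspring."""
    return np.array([-1, -1, 0]), np.array([-1, -1, 1])
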