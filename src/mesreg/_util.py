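"""Shared numerical helpers."""

from __future__ import annotations

import numpy as np


def sample_index_sets(rng: np.random.Generator, n: int, k: int, b: int) -> np.ndarray:
    """Draw ``b`` uniform random size-``k`` subsets of range(n), as a (b, k)
    integer array (order within a row unspecified).

    For small k/n, iid draws are rejected until each row is duplicate-free
    (conditioning on distinctness yields exactly the uniform subset law and
    is far cheaper than permuting n elements per row); for dense sets the
    argpartition route is used instead. Deterministic given the generator
    state.
    """
    if not 0 < k <= n:
        raise ValueError(f"need 0 < k <= n, got k={k}, n={n}")
    if k > n // 8:
        u = rng.random((b, n))
        return np.argpartition(u, k - 1, axis=1)[:, :k]
    out = rng.integers(0, n, size=(b, k))
    for _ in range(1000):
        s = np.sort(out, axis=1)
        bad = (np.diff(s, axis=1) == 0).any(axis=1)
        if not bad.any():
            return out
        out[bad] = rng.integers(0, n, size=(int(bad.sum()), k))
    raise RuntimeError("subset rejection sampling failed to converge")
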