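"""Small shared helpers: seeding, progressive p-value correction, output headers."""

from __future__ import annotations

import hashlib
from typing import Iterable

import numpy as np

__version__ = "0.1.0"


def spawn_rngs(seed: int | None, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent generators from one master seed.

    Child streams are order-stable: the k-th stream is the same no matter
    how many siblings are spawned after it.
    """
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def rng_from(seed: int | None) -> np.random.Generator:
    return np.random.default_rng(seed)


def holm_progressive(pvals: Iterable[float]) -> np.ndarray:
    """Progressive Holm correction for correlogram classes.

    Class k (1-based) is corrected considering only classes 1..k: the
    Holm-adjusted value for the k-th entry of the first k raw p-values.
    NaN entries propagate as NaN and are skipped in the correction.
    """
    p = np.asarray(list(pvals), dtype=float)
    out = np.full_like(p, np.nan)
    for k in range(len(p)):
        if np.isnan(p[k]):
            continue
        window = p[: k + 1]
        sub = window[~np.isnan(window)]
        m = len(sub)
        order = np.argsort(sub, kind="stable")
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * sub[idx])
            adj[idx] = min(1.0, running)
        # entry k is the last valid entry inside the window
        out[k] = adj[m - 1]
    return out


def config_hash(params: dict) -> str:
    payload = repr(sorted(params.items())).encode()
    return hashlib.sha1(payload).hexdigest()[:12]


def output_header(seed, params: dict | None = None) -> str:
    params = params or {}
    items = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
    return f"# assemblage v{__version__} | seed={seed} | {items} | config={config_hash(params)}"
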