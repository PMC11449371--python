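"""Small numerical helpers shared across the pipeline."""

from __future__ import annotations

import numpy as np


def child_seed(*parts: int) -> int:
    """Derive a deterministic 31-bit seed from a tuple of integers.

    Every stage of the pipeline derives its RNG seed from the global seed
    plus its own coordinates (checkpoint index, sample index, retry counter,
    ...) so that reruns are bitwise reproducible and stages are independent.
    """
    ss = np.random.SeedSequence([int(p) & 0x7FFFFFFF for p in parts])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Plain Pearson correlation between two 1-d vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("Pearson correlation undefined: zero variance input")
    return float((xc @ yc) / denom)


def pearson_rows(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of every row of ``X`` against the vector ``y``.

    Rows with zero variance get correlation 0 (they can never be selected
    as nearest fakes, which is the behaviour we want downstream).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    ynorm = np.sqrt(yc @ yc)
    if ynorm == 0:
        raise ValueError("Pearson correlation undefined: target has zero variance")
    xnorm = np.sqrt(np.einsum("ij,ij->i", Xc, Xc))
    out = np.zeros(X.shape[0])
    ok = xnorm > 0
    out[ok] = (Xc[ok] @ yc) / (xnorm[ok] * ynorm)
    return out


def corr_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation via the exact t transform.

    t = r * sqrt(n - 2) / sqrt(1 - r^2) with n - 2 degrees of freedom.
    """
    from scipy import stats

    if n < 4:
        raise ValueError(f"need at least 4 observations for a correlation test, got {n}")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))
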