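"""Independent brute-force oracles used to validate the implementation.

Everything here is written from first principles — nested loops and
direct definitions — and deliberately shares no code with the package.
"""

from __future__ import annotations

import numpy as np


def count_strikes(pixels: np.ndarray) -> int:
    """Brute-force strike counter for synthetic clips.

    A strike is a rising edge of limb presence in the wheel-surface band
    (the rows at and below the surface line at 88% of frame height).
    Presence is judged against the per-pixel temporal minimum, so static
    scenery cancels.  The mirrored top band is also checked, making the
    count invariant to vertical flips; horizontal flips do not move the
    band at all.
    """
    t, h, w = pixels.shape
    s = int(round(0.88 * h))
    best = 0
    for band in (pixels[:, s:, :], pixels[:, : h - s, :]):
        delta = band - band.min(axis=0)
        presence = delta.reshape(t, -1).max(axis=1) > 0.3
        onsets = int(presence[0]) + int(np.sum(presence[1:] & ~presence[:-1]))
        best = max(best, onsets)
    return best


def naive_conv2d_same(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Direct quadruple-loop 2-D convolution, same padding, stride 1.

    ``x``: (H, W, Cin); ``w``: (kh, kw, Cin, Cout); returns (H, W, Cout).
    """
    h, wd, cin = x.shape
    kh, kw, _, cout = w.shape
    ph0 = (kh - 1) // 2
    pw0 = (kw - 1) // 2
    out = np.zeros((h, wd, cout), dtype=np.float64)
    for y in range(h):
        for xx in range(wd):
            for i in range(kh):
                for j in range(kw):
                    yy, xj = y + i - ph0, xx + j - pw0
                    if 0 <= yy < h and 0 <= xj < wd:
                        for o in range(cout):
                            out[y, xx, o] += float(x[yy, xj] @ w[i, j, :, o])
    return out + b


def naive_maxpool2(x: np.ndarray) -> np.ndarray:
    """2x2/stride-2 max pool of an (H, W, C) map, ceil-mode."""
    h, w, c = x.shape
    oh, ow = (h + 1) // 2, (w + 1) // 2
    out = np.full((oh, ow, c), -np.inf)
    for y in range(h):
        for xx in range(w):
            out[y // 2, xx // 2] = np.maximum(out[y // 2, xx // 2], x[y, xx])
    return out


def naive_softmax(logits: np.ndarray) -> np.ndarray:
    e = np.exp(np.asarray(logits, dtype=np.float64))
    return e / e.sum(axis=-1, keepdims=True)


def naive_cross_entropy(logits: np.ndarray, labels) -> float:
    probs = naive_softmax(logits)
    return float(np.mean([-np.log(probs[i, y]) for i, y in enumerate(labels)]))


def block_output_shape(h: int, w: int, n_blocks: int = 3) -> tuple[int, int]:
    """Spatial size after repeated same-conv + ceil-mode 2x2 pooling."""
    for _ in range(n_blocks):
        h = (h + 1) // 2
        w = (w + 1) // 2
    return h, w


def least_squares_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Closed-form simple OLS: slope, intercept, r^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    slope = float(((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum())
    intercept = float(ym - slope * xm)
    resid = y - (slope * x + intercept)
    r2 = float(1.0 - (resid**2).sum() / ((y - ym) ** 2).sum())
    return slope, intercept, r2


def chi2_2xk(counts_a, counts_b) -> tuple[float, int]:
    """Textbook Pearson chi-squared for a 2 x K table: statistic and df."""
    table = np.asarray([counts_a, counts_b], dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    stat = float(((table - expected) ** 2 / expected).sum())
    return stat, table.shape[1] - 1
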