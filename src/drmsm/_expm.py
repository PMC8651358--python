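"""Vectorized matrix exponential for stacks of small intensity matrices.

The panel likelihood needs ``expm(Q_i * dt_i)`` for thousands of 5x5
generators per evaluation.  Looping scipy.linalg.expm over the stack
dominates the fit time, so this module implements the classic
scaling-and-squaring Pade(13) approximant with all matrix products
batched over the leading axis.  A single scaling power is chosen from
the largest infinity norm in the stack; generators built from yearly
visit intervals have norms well below the Pade-13 threshold, so the
squaring phase is almost always empty.
"""

from __future__ import annotations

import numpy as np

# Pade(13) numerator coefficients b_0..b_13 (Higham 2005).
_B = (
    64764752532480000.0,
    32382376266240000.0,
    7771770303897600.0,
    1187353796428800.0,
    129060195264000.0,
    10559470521600.0,
    670442572800.0,
    33522128640.0,
    1323241920.0,
    40840800.0,
    960960.0,
    16380.0,
    182.0,
    1.0,
)

# ||A|| threshold below which Pade(13) is accurate to unit roundoff.
_THETA_13 = 5.371920351148152


def expm_batch(a: np.ndarray) -> np.ndarray:
    """Matrix exponential of a stack of square matrices.

    Parameters
    ----------
    a : ndarray, shape (..., n, n)
        Real matrices; any number of leading batch dimensions.

    Returns
    -------
    ndarray of the same shape with ``expm`` applied to each matrix.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim < 2 or a.shape[-1] != a.shape[-2]:
        raise ValueError(f"expected stacked square matrices, got shape {a.shape}")
    n = a.shape[-1]
    if a.size == 0:
        return a.copy()

    norm = np.abs(a).sum(axis=-1).max()
    if not np.isfinite(norm):
        raise ValueError("non-finite entries in matrix stack")
    s = 0 if norm <= _THETA_13 else int(np.ceil(np.log2(norm / _THETA_13)))
    x = a / (2.0**s) if s else a

    ident = np.broadcast_to(np.eye(n), x.shape)
    x2 = x @ x
    x4 = x2 @ x2
    x6 = x4 @ x2
    b = _B
    u = x @ (
        x6 @ (b[13] * x6 + b[11] * x4 + b[9] * x2)
        + b[7] * x6
        + b[5] * x4
        + b[3] * x2
        + b[1] * ident
    )
    v = (
        x6 @ (b[12] * x6 + b[10] * x4 + b[8] * x2)
        + b[6] * x6
        + b[4] * x4
        + b[2] * x2
        + b[0] * ident
    )
    p = np.linalg.solve(v - u, v + u)
    for _ in range(s):
        p = p @ p
    return p
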