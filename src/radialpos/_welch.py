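"""Welch's unequal-variance two-tailed t-test, shared across modules.

Thin wrapper around scipy that (a) also returns the Welch–Satterthwaite
degrees of freedom (unrounded), and (b) defines the degenerate
zero-variance cases explicitly: two groups with identical means and no
variance compare as t = 0, p = 1; distinct means with no variance give
p = 0.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .errors import SampleSizeError


def welch_ttest(a, b) -> tuple[float, float, float]:
    """Return ``(t, df, p)`` for Welch's two-tailed t-test of a vs b.

    Raises :class:`SampleSizeError` if either group has fewer than two
    observations.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise SampleSizeError(f"each group needs n >= 2, got {na} and {nb}")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    sa2, sb2 = va / na, vb / nb
    se2 = sa2 + sb2
    if se2 == 0.0:
        # both groups constant
        if a.mean() == b.mean():
            return 0.0, float(na + nb - 2), 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), float(na + nb - 2), 0.0
    df = se2**2 / (sa2**2 / (na - 1) + sb2**2 / (nb - 1))
    t = float((a.mean() - b.mean()) / math.sqrt(se2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, float(df), p
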