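"""Upper-tail hypergeometric kernel shared by the ceRNA caller and ORA.

P[X >= k] for X ~ Hypergeometric(N, K, n): the chance of drawing at least k
marked items in n draws without replacement from a universe of N containing
K marked items. The tail is inclusive, so k = 0 gives exactly 1.
"""

from __future__ import annotations

from scipy.stats import hypergeom as _hypergeom

from .models import ValidationError


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n), clipped to [0, 1]."""
    if N <= 0:
        raise ValidationError("universe size N must be positive")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"K={K} and n={n} must lie in [0, N={N}]")
    if k < 0:
        raise ValidationError("k must be >= 0")
    if k == 0:
        return 1.0
    if k > min(K, n):
        return 0.0
    p = float(_hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)
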