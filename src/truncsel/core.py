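"""Standard-normal machinery for truncation selection.

Truncation selection retains every candidate whose selection criterion (SC)
exceeds a threshold ``t``.  For an SC distributed N(mu, sigma^2) this selects
the upper tail with proportion

    alpha = 1 - Phi((t - mu) / sigma),

and the expected standardized superiority of the selected candidates is the
selection intensity

    i(alpha) = phi(Phi^-1(1 - alpha)) / alpha,

the mean of the upper-``alpha`` tail of N(0, 1).  These three functions —
tail proportion, quantile threshold, and intensity — are the primitives the
breeder's equation DG = b * sigma * i(alpha) is built from.

All tail probabilities are computed through survival functions (``norm.sf`` /
``norm.isf``), never ``1 - cdf``, to preserve precision in the far tail.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from .errors import InvalidInputError

__all__ = [
    "upper_tail_proportion",
    "threshold_for_proportion",
    "selection_intensity",
]

# Beyond this standardized threshold phi(x) underflows to a subnormal double
# and the ratio phi(x)/alpha loses accuracy; switch to the Mills-ratio
# asymptotic E[X | X > x] ~ x + 1/x.  alpha there is < 3e-316, far below any
# meaningful selected proportion.
_MILLS_CUTOVER = 38.0


def _validate_open_unit(alpha, name: str = "alpha") -> np.ndarray:
    a = np.asarray(alpha, dtype=float)
    if not np.all(np.isfinite(a)) or np.any(a <= 0.0) or np.any(a >= 1.0):
        raise InvalidInputError(
            f"{name} must lie strictly inside (0, 1); got {alpha!r}"
        )
    return a


def upper_tail_proportion(x):
    """Proportion alpha(x) of a N(0,1) population above threshold ``x``.

    Parameters
    ----------
    x : float or array_like
        Threshold in standard-deviation units.  Must be finite.

    Returns
    -------
    float or ndarray
        ``1 - Phi(x)``, strictly decreasing in ``x``.  Complements the lower
        tail exactly: ``upper_tail_proportion(x) + upper_tail_proportion(-x)``
        is 1 to machine precision.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"threshold must be finite; got {x!r}")
    out = norm.sf(arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def threshold_for_proportion(alpha, mu: float = 0.0, sigma: float = 1.0):
    """Threshold selecting the upper proportion ``alpha`` from N(mu, sigma^2).

    Returns ``mu + sigma * Phi^-1(1 - alpha)``, computed via the inverse
    survival function.  Round-trips with :func:`upper_tail_proportion`:
    ``upper_tail_proportion((t - mu)/sigma)`` recovers ``alpha``.

    Raises
    ------
    InvalidInputError
        If ``alpha`` is not strictly inside (0, 1) or ``sigma <= 0``.
    """
    a = _validate_open_unit(alpha)
    if not np.isfinite(sigma) or sigma <= 0.0:
        raise InvalidInputError(f"sigma must be positive; got {sigma!r}")
    if not np.isfinite(mu):
        raise InvalidInputError(f"mu must be finite; got {mu!r}")
    out = mu + sigma * norm.isf(a)
    return float(out) if np.isscalar(alpha) or a.ndim == 0 else out


def selection_intensity(alpha):
    """Selection intensity i(alpha): mean of the upper-``alpha`` tail of N(0,1).

        i(alpha) = phi(Phi^-1(1 - alpha)) / alpha

    Strictly decreasing in ``alpha``; tends to 0 as ``alpha -> 1`` (no
    selection) and grows like ``x + 1/x`` with ``x = Phi^-1(1 - alpha)`` under
    vanishing ``alpha``.  Satisfies ``i(alpha) * alpha = phi(Phi^-1(1-alpha))``
    exactly by construction.

    The direct ratio is numerically exact over the entire representable range
    of ``alpha`` because ``alpha`` is an input, not a computed tail mass; only
    where phi underflows (``alpha`` below ~3e-316) is the Mills-ratio
    asymptotic substituted.
    """
    a = _validate_open_unit(alpha)
    x = norm.isf(a)
    with np.errstate(over="ignore"):
        direct = norm.pdf(x) / a
    mills = x + 1.0 / np.where(x != 0.0, x, 1.0)
    out = np.where(x > _MILLS_CUTOVER, mills, direct)
    return float(out) if np.isscalar(alpha) or a.ndim == 0 else out
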