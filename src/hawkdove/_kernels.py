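"""Optional numba-compiled hot loops.

Everything here has a pure-NumPy twin in :mod:`hawkdove.engine`; the
kernels only trade interpreter overhead for speed. The engine falls
back to the NumPy path when numba is unavailable, and the test-suite
cross-checks the two paths against each other.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dep in practice
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


# runtime switch: tests flip this to exercise the NumPy reference path
ENABLED = HAVE_NUMBA


@njit(cache=True)
def pair_and_pay(
    sorted_idx: np.ndarray,
    sorted_gid: np.ndarray,
    strategy: np.ndarray,
    resources: np.ndarray,
    benefit: float,
    cost: float,
) -> None:
    """Sequentially pair agents within each group block and accrue
    both payoffs.

    ``sorted_idx`` lists agent rows grouped by ``sorted_gid`` (same
    order), already randomly permuted within each group; the odd agent
    out of an odd-sized block sits out. Mutates ``resources`` in
    place.
    """
    n = sorted_idx.size
    hh = 0.5 * (benefit - cost)
    dd = 0.5 * benefit
    i = 0
    while i < n:
        g = sorted_gid[i]
        j = i + 1
        while j < n and sorted_gid[j] == g:
            j += 1
        m = i + ((j - i) & ~1)  # last pairable position in this block
        for k in range(i, m, 2):
            a = sorted_idx[k]
            b = sorted_idx[k + 1]
            sa = strategy[a]
            sb = strategy[b]
            if sa == 1:
                if sb == 1:
                    resources[a] += hh
                    resources[b] += hh
                else:
                    resources[a] += benefit
            else:
                if sb == 1:
                    resources[b] += benefit
                else:
                    resources[a] += dd
                    resources[b] += dd
        i = j
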