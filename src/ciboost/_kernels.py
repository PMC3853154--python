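"""Hot numeric kernels for the line search.

The stage-weight search evaluates the smoothed concordance index on a grid
of candidate weights; each evaluation is a stable sigmoid mean over every
comparable pair, so the scan is the innermost cost of training.  When numba
is importable the scan is JIT-compiled; otherwise a chunked numpy
broadcast computes the same values.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False


def _grid_scan_numpy(d, e, grid):
    vals = np.empty(grid.shape[0])
    chunk = max(1, int(4e6) // max(1, d.shape[0]))
    for lo in range(0, grid.shape[0], chunk):
        g = grid[lo : lo + chunk]
        vals[lo : lo + chunk] = expit(d[:, None] + e[:, None] * g[None, :]).mean(axis=0)
    return vals


def _sci_at_numpy(d, e, rho):
    return float(np.mean(expit(d + rho * e)))


if _HAVE_NUMBA:

    @njit(cache=True, fastmath=True)
    def _grid_scan_nb(d, e, grid):  # pragma: no cover - exercised via wrapper
        npairs = d.shape[0]
        vals = np.empty(grid.shape[0])
        for k in range(grid.shape[0]):
            rho = grid[k]
            acc = 0.0
            for q in range(npairs):
                z = d[q] + rho * e[q]
                if z >= 0.0:
                    acc += 1.0 / (1.0 + np.exp(-z))
                else:
                    ez = np.exp(z)
                    acc += ez / (1.0 + ez)
            vals[k] = acc / npairs
        return vals

    def grid_scan(d, e, grid):
        return _grid_scan_nb(
            np.ascontiguousarray(d), np.ascontiguousarray(e), np.ascontiguousarray(grid)
        )

    def sci_at(d, e, rho):
        return float(grid_scan(d, e, np.array([rho]))[0])

else:
    grid_scan = _grid_scan_numpy
    sci_at = _sci_at_numpy
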