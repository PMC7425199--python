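"""Optional numba acceleration for the scalar hot-path functions.

If numba is unavailable the decorators are no-ops and the same Python
code runs unchanged.
"""

import math

# On-disk caching is deliberately off: numba does not invalidate a
# caller's cache when an inlined jitted callee changes.
try:  # pragma: no cover - acceleration only
    from numba import njit as _njit

    def jit(f):
        return _njit(cache=False)(f)
except Exception:  # pragma: no cover
    def jit(f):
        return f


@jit
def sexp(x):
    """exp with clipping; rate arguments can overflow transiently."""
    if x > 300.0:
        x = 300.0
    elif x < -300.0:
        x = -300.0
    return math.exp(x)
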