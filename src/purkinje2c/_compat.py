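"""Numba shim.

The simulation kernel is compiled with numba when available (it always is in a
standard install); setting PURKINJE2C_NO_JIT=1 falls back to plain Python, which
is orders of magnitude slower but useful when debugging the kernel line by line.
"""

import os

__all__ = ["njit", "HAVE_NUMBA"]

if os.environ.get("PURKINJE2C_NO_JIT", "0") == "1":
    HAVE_NUMBA = False
else:
    try:
        import numba  # noqa: F401

        HAVE_NUMBA = True
    except ImportError:  # pragma: no cover
        HAVE_NUMBA = False

if HAVE_NUMBA:
    from numba import njit as _numba_njit

    def njit(*args, **kwargs):
        kwargs.setdefault("cache", True)
        kwargs.setdefault("fastmath", False)
        return _numba_njit(*args, **kwargs)

else:  # pragma: no cover - exercised only with PURKINJE2C_NO_JIT=1

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]) and not kwargs:
            return args[0]

        def wrap(func):
            return func

        return wrap
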