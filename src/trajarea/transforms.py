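"""Outcome transforms applied before regression."""

from __future__ import annotations

import numpy as np

VALID_TRANSFORMS = ("identity", "log1p")


class TransformDomainError(ValueError):
    """Raised when values fall outside a transform's domain."""


def apply_transform(values, transform: str) -> np.ndarray:
    """Apply a named transform elementwise, propagating missing values.

    Parameters
    ----------
    values : array-like
        Numeric values; NaN marks missing and maps to NaN.
    transform : {"identity", "log1p"}
        ``log1p`` computes log(1 + x) and requires nonnegative input.

    Returns
    -------
    numpy.ndarray of float64.
    """
    arr = np.asarray(values, dtype=float)
    if transform == "identity":
        return arr.copy()
    if transform == "log1p":
        with np.errstate(invalid="ignore"):
            bad = arr < 0
        if bad.any():
            rows = np.nonzero(bad)[0].tolist()
            raise TransformDomainError(
                f"log1p requires nonnegative input; negative values at rows {rows}"
            )
        return np.log1p(arr)
    raise ValueError(f"unknown transform {transform!r}; expected one of {VALID_TRANSFORMS}")
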