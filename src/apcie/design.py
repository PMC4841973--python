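"""Effect-coded APC design matrix and its null space.

Because cohort = period - age on a Lexis grid, the three categorical
blocks of an age-period-cohort regression are linearly dependent and the
design matrix has rank one less than its column count.  Its kernel is
one-dimensional; the unit-norm kernel vector ``B0`` depends only on the
numbers of age and period categories.  The intrinsic estimator restricts
estimation to the orthogonal complement of ``B0``.

Conventions (fixed for bit-exact reproducibility):

* rows ordered age-major: cell (i, j) at row ``(i-1)*p + (j-1)``;
* columns ordered intercept, age, period, cohort;
* effect (deviation / sum-to-zero) coding with the LAST category of each
  block dropped: the dropped category's implied coefficient is the
  negative sum of the block's coefficients;
* ``B0`` has unit norm and its first component exceeding 1e-8 in
  magnitude is made positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space

__all__ = ["DesignSpec", "build_design", "null_vector", "project_identifiable"]


@dataclass(frozen=True)
class DesignSpec:
    """An APC design matrix with its offset convention and kernel vector.

    ``X`` is ``(a*p) x m`` with ``m = 2*(a+p) - 3`` columns; ``column_map``
    gives ``(block, category_label)`` per column; ``B0`` spans ``ker(X)``.
    The offset enters the Poisson linear predictor as ``log(exposure)``
    with fixed coefficient one (it is not a column of ``X``).
    """

    a: int
    p: int
    X: np.ndarray
    column_map: list[tuple[str, str]]
    B0: np.ndarray

    @property
    def m(self) -> int:
        return self.X.shape[1]

    def block_slice(self, block: str) -> slice:
        """Column slice of one coefficient block in the stacked vector."""
        a, p = self.a, self.p
        if block == "intercept":
            return slice(0, 1)
        if block == "age":
            return slice(1, a)
        if block == "period":
            return slice(a, a + p - 1)
        if block == "cohort":
            return slice(a + p - 1, self.m)
        raise ValueError(f"unknown block {block!r}")

    def block_size(self, block: str) -> int:
        """Number of categories in a block (including the dropped one)."""
        return {"intercept": 1, "age": self.a, "period": self.p,
                "cohort": self.a + self.p - 1}[block]


def _effect_code(categories: np.ndarray, n: int) -> np.ndarray:
    """Sum-to-zero coding: n-1 columns, last category coded all -1."""
    Z = np.zeros((categories.size, n - 1))
    for row, c in enumerate(categories):
        if c == n - 1:
            Z[row, :] = -1.0
        else:
            Z[row, c] = 1.0
    return Z


def build_design(a: int, p: int) -> DesignSpec:
    """Build the effect-coded APC design for an ``a x p`` grid.

    Raises ``ValueError`` unless ``a >= 2`` and ``p >= 2``.
    """
    if a < 2 or p < 2:
        raise ValueError(f"need at least 2 age and 2 period categories, got a={a}, p={p}")
    n_coh = a + p - 1
    i = np.repeat(np.arange(a), p)          # 0-based age row per grid row
    j = np.tile(np.arange(p), a)            # 0-based period column
    k = (a - 1) - i + j                     # 0-based cohort index

    X = np.hstack([
        np.ones((a * p, 1)),
        _effect_code(i, a),
        _effect_code(j, p),
        _effect_code(k, n_coh),
    ])
    column_map = [("intercept", "mu")]
    column_map += [("age", str(c + 1)) for c in range(a - 1)]
    column_map += [("period", str(c + 1)) for c in range(p - 1)]
    column_map += [("cohort", str(c + 1)) for c in range(n_coh - 1)]

    spec = DesignSpec(a=a, p=p, X=X, column_map=column_map, B0=np.empty(0))
    object.__setattr__(spec, "B0", null_vector(spec))
    return spec


def null_vector(design: DesignSpec) -> np.ndarray:
    """Unit-norm basis of ``ker(X)`` with a deterministic sign.

    The kernel must be exactly one-dimensional; anything else signals a
    coding bug or a degenerate grid.  The intercept is estimable, so the
    first component of ``B0`` is numerically zero, and within each block
    the components are linear in the category index.
    """
    ns = null_space(design.X)
    if ns.shape[1] != 1:
        raise np.linalg.LinAlgError(
            f"kernel dimension {ns.shape[1]} != 1 for a={design.a}, p={design.p}"
        )
    b0 = ns[:, 0]
    lead = np.flatnonzero(np.abs(b0) > 1e-8)
    if lead.size and b0[lead[0]] < 0:
        b0 = -b0
    return b0


def project_identifiable(theta: np.ndarray, design: DesignSpec) -> np.ndarray:
    """Project a stacked coefficient vector onto the identifiable subspace.

    Returns ``theta - (theta . B0) B0``, the component orthogonal to the
    kernel.  Moving along ``B0`` changes no fitted cell count, so only
    this projection is determined by the data.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (design.m,):
        raise ValueError(f"theta has length {theta.size}, expected {design.m}")
    b0 = design.B0
    return theta - (theta @ b0) * b0
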