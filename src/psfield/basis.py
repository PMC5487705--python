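"""B-spline bases, difference penalties, and the PS-ANOVA spatial design.

The spatial surface over a field grid is represented as a tensor-product
P-spline reparameterized into an ANOVA-type sum: three fixed linear columns
(row, column, row*column) plus five penalized random blocks -- two main
smooth trends, two linear-by-smooth interactions, and one smooth-by-smooth
interaction.  Each random block carries a diagonal precision obtained from
the eigendecomposition of the univariate difference penalties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "BSplineBasis",
    "DifferencePenalty",
    "PSANOVADesign",
    "bspline_basis",
    "difference_penalty",
    "mixed_model_transform",
    "build_psanova",
]

#: eigenvalues below EIG_RTOL * max(eigenvalue) count as the penalty null space
EIG_RTOL = 1e-10


@dataclass(frozen=True)
class BSplineBasis:
    """Univariate B-spline basis on equally spaced knots.

    ``n_knots`` counts the equally spaced knots spanning ``[domain_lo,
    domain_hi]`` with both endpoints included, giving ``n_knots - 1``
    segments and ``n_knots - 1 + degree`` basis functions.  The knot vector
    is extended equidistantly by ``degree`` knots on each side.
    """

    domain_lo: float
    domain_hi: float
    n_knots: int
    degree: int = 3

    def __post_init__(self) -> None:
        if self.n_knots < 2:
            raise ValueError(f"n_knots must be >= 2, got {self.n_knots}")
        if self.degree < 1:
            raise ValueError(f"degree must be >= 1, got {self.degree}")
        if not self.domain_hi > self.domain_lo:
            raise ValueError("domain_hi must exceed domain_lo")

    @property
    def n_basis(self) -> int:
        return self.n_knots - 1 + self.degree

    @property
    def knots(self) -> np.ndarray:
        """Full extended knot vector (inner knots plus boundary extension)."""
        inner = np.linspace(self.domain_lo, self.domain_hi, self.n_knots)
        h = (self.domain_hi - self.domain_lo) / (self.n_knots - 1)
        left = self.domain_lo - h * np.arange(self.degree, 0, -1)
        right = self.domain_hi + h * np.arange(1, self.degree + 1)
        return np.concatenate([left, inner, right])

    def design_matrix(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the basis at ``x`` (dense ``len(x) x n_basis`` matrix)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if x.ndim != 1:
            raise ValueError("x must be one-dimensional")
        if x.size and (x.min() < self.domain_lo or x.max() > self.domain_hi):
            raise ValueError(
                f"covariate values outside basis domain "
                f"[{self.domain_lo}, {self.domain_hi}]: "
                f"range seen [{x.min()}, {x.max()}]"
            )
        # range-checked above; extrapolate=True only guards the right endpoint
        return BSpline.design_matrix(x, self.knots, self.degree, extrapolate=True).toarray()


def bspline_basis(x: np.ndarray, n_knots: int, degree: int = 3) -> np.ndarray:
    """Basis matrix for ``x`` on ``n_knots`` equally spaced knots over its range."""
    x = np.asarray(x, dtype=float)
    return BSplineBasis(float(x.min()), float(x.max()), n_knots, degree).design_matrix(x)


@dataclass(frozen=True)
class DifferencePenalty:
    """Difference penalty ``D'D`` with its eigendecomposition.

    ``eigenvalues`` are sorted ascending; for order 2 the null space has
    dimension exactly 2 (constant and linear sequences).
    """

    n_basis: int
    order: int
    matrix: np.ndarray = field(repr=False)
    eigenvalues: np.ndarray = field(repr=False)
    eigenvectors: np.ndarray = field(repr=False)

    @property
    def null_dim(self) -> int:
        cutoff = EIG_RTOL * self.eigenvalues.max()
        return int(np.sum(self.eigenvalues < cutoff))

    def positive(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvectors and eigenvalues of the penalized (non-null) subspace."""
        nd = self.null_dim
        return self.eigenvectors[:, nd:], self.eigenvalues[nd:]

    def null(self) -> np.ndarray:
        return self.eigenvectors[:, : self.null_dim]


def difference_penalty(n_basis: int, order: int = 2) -> DifferencePenalty:
    """Order-``order`` difference penalty on ``n_basis`` coefficients."""
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    if n_basis <= order:
        raise ValueError(f"n_basis ({n_basis}) must exceed order ({order})")
    D = np.diff(np.eye(n_basis), n=order, axis=0)
    P = D.T @ D
    w, V = np.linalg.eigh(P)
    w = np.clip(w, 0.0, None)  # eigh can return tiny negatives
    return DifferencePenalty(n_basis, order, P, w, V)


def mixed_model_transform(
    basis: BSplineBasis, penalty: DifferencePenalty, x: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reparameterize a penalized B-spline as fixed + diagonal-precision random part.

    Returns ``(X_fix, Z, lam)`` where ``Z = B @ U_+`` spans the penalized
    subspace with implied diagonal penalty ``lam`` and ``X_fix`` holds the
    unpenalized polynomial columns beyond the intercept (for order 2, the
    single column ``x``).
    """
    if penalty.n_basis != basis.n_basis:
        raise ValueError(
            f"penalty built for {penalty.n_basis} coefficients, "
            f"basis has {basis.n_basis}"
        )
    x = np.asarray(x, dtype=float)
    B = basis.design_matrix(x)
    U_pos, lam = penalty.positive()
    Z = B @ U_pos
    if penalty.order == 2:
        X_fix = x[:, None].copy()
    else:
        X_fix = B @ penalty.null()[:, 1:]  # drop the constant direction
    return X_fix, Z, lam


#: names of the five random spatial blocks, in canonical order
SPATIAL_BLOCKS = ("f1", "f2", "h3", "h4", "f5")


@dataclass(frozen=True)
class PSANOVADesign:
    """PS-ANOVA spatial design evaluated at the plot coordinates.

    ``X_s`` holds centered/scaled linear columns ``[r, c, r*c]`` (the
    intercept lives in the general fixed part).  ``Z`` maps each of the five
    block names to its design matrix and ``precision`` to the strictly
    positive diagonal of its penalty.  The surface is invariant to the
    affine centering/scaling, which only stabilizes the normal equations.
    """

    row_basis: BSplineBasis
    col_basis: BSplineBasis
    order: int
    row_center: float
    row_scale: float
    col_center: float
    col_scale: float
    U_r: np.ndarray = field(repr=False)
    lam_r: np.ndarray = field(repr=False)
    U_c: np.ndarray = field(repr=False)
    lam_c: np.ndarray = field(repr=False)
    X_s: np.ndarray = field(repr=False)
    Z: dict = field(repr=False)
    precision: dict = field(repr=False)

    @property
    def block_dims(self) -> dict:
        return {k: self.Z[k].shape[1] for k in SPATIAL_BLOCKS}

    @property
    def n_random(self) -> int:
        """Total number of random spatial coefficients across the five blocks."""
        return sum(self.block_dims.values())

    def _scaled(self, r: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return (r - self.row_center) / self.row_scale, (c - self.col_center) / self.col_scale

    def spatial_matrices(self, r: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, dict]:
        """Evaluate ``X_s`` and the five ``Z`` blocks at arbitrary in-range coordinates."""
        r = np.asarray(r, dtype=float)
        c = np.asarray(c, dtype=float)
        Br = self.row_basis.design_matrix(r)
        Bc = self.col_basis.design_matrix(c)
        Zr = Br @ self.U_r
        Zc = Bc @ self.U_c
        rt, ct = self._scaled(r, c)
        X_s = np.column_stack([rt, ct, rt * ct])
        Z = {
            "f1": Zr,
            "f2": Zc,
            "h3": Zr * ct[:, None],
            "h4": Zc * rt[:, None],
            "f5": (Zr[:, :, None] * Zc[:, None, :]).reshape(len(r), -1),
        }
        return X_s, Z


def build_psanova(
    rows: np.ndarray,
    cols: np.ndarray,
    n_knots_r: int,
    n_knots_c: int,
    degree: int = 3,
    order: int = 2,
    row_range: tuple[float, float] | None = None,
    col_range: tuple[float, float] | None = None,
) -> PSANOVADesign:
    """Assemble the PS-ANOVA design at the observed plot coordinates.

    ``row_range``/``col_range`` give the grid bounds; coordinates outside
    them are rejected.  Non-rectangular coordinate sets (missing plots) are
    allowed as long as they lie within the bounds.
    """
    rows = np.asarray(rows, dtype=float)
    cols = np.asarray(cols, dtype=float)
    if rows.shape != cols.shape or rows.ndim != 1:
        raise ValueError("rows and cols must be equal-length vectors")
    if row_range is None:
        row_range = (float(rows.min()), float(rows.max()))
    if col_range is None:
        col_range = (float(cols.min()), float(cols.max()))
    for name, x, (lo, hi) in (("row", rows, row_range), ("column", cols, col_range)):
        if x.min() < lo or x.max() > hi:
            raise ValueError(f"{name} coordinates outside the grid bounds [{lo}, {hi}]")

    row_basis = BSplineBasis(row_range[0], row_range[1], n_knots_r, degree)
    col_basis = BSplineBasis(col_range[0], col_range[1], n_knots_c, degree)
    pen_r = difference_penalty(row_basis.n_basis, order)
    pen_c = difference_penalty(col_basis.n_basis, order)
    U_r, lam_r = pen_r.positive()
    U_c, lam_c = pen_c.positive()

    row_center = 0.5 * (row_range[0] + row_range[1])
    col_center = 0.5 * (col_range[0] + col_range[1])
    row_scale = 0.5 * (row_range[1] - row_range[0]) or 1.0
    col_scale = 0.5 * (col_range[1] - col_range[0]) or 1.0

    qr_, qc_ = lam_r.size, lam_c.size
    # Kronecker-sum precision for the smooth-by-smooth interaction, column
    # index ordering (j over rows, k over cols) matching the face-splitting
    # product used in spatial_matrices.
    precision = {
        "f1": lam_r.copy(),
        "f2": lam_c.copy(),
        "h3": lam_r.copy(),
        "h4": lam_c.copy(),
        "f5": np.add.outer(lam_r, lam_c).ravel(),
    }
    design = PSANOVADesign(
        row_basis=row_basis,
        col_basis=col_basis,
        order=order,
        row_center=row_center,
        row_scale=row_scale,
        col_center=col_center,
        col_scale=col_scale,
        U_r=U_r,
        lam_r=lam_r,
        U_c=U_c,
        lam_c=lam_c,
        X_s=np.empty((0, 3)),
        Z={},
        precision=precision,
    )
    X_s, Z = design.spatial_matrices(rows, cols)
    design = PSANOVADesign(
        row_basis=row_basis,
        col_basis=col_basis,
        order=order,
        row_center=row_center,
        row_scale=row_scale,
        col_center=col_center,
        col_scale=col_scale,
        U_r=U_r,
        lam_r=lam_r,
        U_c=U_c,
        lam_c=lam_c,
        X_s=X_s,
        Z=Z,
        precision=precision,
    )
    assert design.block_dims["f5"] == qr_ * qc_
    return design
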