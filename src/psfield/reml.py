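"""REML fitting of the spatial mixed model via effective-dimension updates.

The model is ``y = X b + sum_k Z_k u_k + e`` with ``u_k ~ N(0, s2_k P_k^-1)``
for diagonal precision structures ``P_k`` and ``e ~ N(0, s2_e I)``.  Variance
components are estimated by the fixed point

    s2_k <- u_k' P_k u_k / ED_k,    s2_e <- e'e / (n - ED_b - sum_k ED_k),

with the mixed-model equations re-solved each iteration; the stationary
point satisfies the REML estimating equations.  Effective dimensions are

    ED_k = q_k - lam_k * trace(P_k C^kk),   lam_k = s2_e / s2_k,

with ``C^kk`` the k-th diagonal block of the inverse coefficient matrix.
Because every ``P_k`` is diagonal only the diagonal of the inverse is ever
needed; a large identity-precision block with disjoint column supports
(genotypes) is absorbed through its Schur complement, which keeps single
fits on full trial grids in the seconds range.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

logger = logging.getLogger(__name__)

__all__ = [
    "RandomBlock",
    "MixedModelSpec",
    "VarianceComponents",
    "FitResult",
    "HeritabilityResult",
    "fit_reml",
    "effective_dimensions",
    "heritability",
    "predict_surface",
    "nugget_variogram",
    "reml_deviance",
]

#: relative eigenvalue cutoff shared with the basis module
EIG_RTOL = 1e-10


@dataclass
class RandomBlock:
    """One independent random-effect block with diagonal precision."""

    name: str
    Z: np.ndarray
    prec: np.ndarray  # strictly positive diagonal of the precision structure
    labels: list | None = None

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        self.prec = np.asarray(self.prec, dtype=float)
        if self.Z.shape[1] != self.prec.size:
            raise ValueError(f"block {self.name}: Z has {self.Z.shape[1]} columns "
                             f"but precision has {self.prec.size} entries")
        if np.any(self.prec <= 0):
            raise ValueError(f"block {self.name}: precision entries must be > 0")

    @property
    def q(self) -> int:
        return self.Z.shape[1]


@dataclass
class MixedModelSpec:
    """Design matrices and metadata for one trial-level mixed model."""

    y: np.ndarray
    X: np.ndarray
    x_names: list
    blocks: dict
    rows: np.ndarray | None = None
    cols: np.ndarray | None = None
    psanova: object | None = None
    xs_index: list | None = None  # columns of X holding the linear spatial part
    n_rows: int | None = None
    n_cols: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        n = self.y.size
        if self.X.shape[0] != n:
            raise ValueError("X row count does not match y")
        for b in self.blocks.values():
            if b.Z.shape[0] != n:
                raise ValueError(f"block {b.name} row count does not match y")
        if np.any(~np.isfinite(self.y)):
            raise ValueError("y must not contain missing values; drop them upstream")

    @property
    def n(self) -> int:
        return self.y.size


@dataclass
class VarianceComponents:
    """REML variance components; smoothing ratios are always recomputed."""

    components: dict
    sigma2_e: float
    floored: set = field(default_factory=set)

    @property
    def lambdas(self) -> dict:
        """``s2_e / s2_k`` for every non-floored block."""
        return {
            k: self.sigma2_e / v
            for k, v in self.components.items()
            if k not in self.floored and v > 0
        }

    def as_dict(self) -> dict:
        d = {k: float(v) for k, v in self.components.items()}
        d["sigma2_e"] = float(self.sigma2_e)
        return d


@dataclass
class FitResult:
    spec: MixedModelSpec
    variance: VarianceComponents
    beta: np.ndarray
    beta_names: list
    blups: dict
    effective_dims: dict
    ed_beta: float
    residuals: np.ndarray
    fitted: np.ndarray
    pev_geno: np.ndarray | None
    deviance: float
    n_iter: int
    converged: bool
    aliased: list
    diag_cinv: dict = field(repr=False, default_factory=dict)
    trace: list = field(repr=False, default_factory=list)

    @property
    def ed_residual(self) -> float:
        return self.spec.n - self.ed_beta - sum(self.effective_dims.values())

    @property
    def ed_spatial(self) -> float:
        from .basis import SPATIAL_BLOCKS

        return sum(self.effective_dims.get(k, 0.0) for k in SPATIAL_BLOCKS)

    def spatial_component(self) -> np.ndarray:
        """Fitted spatial trend (linear + smooth) at the observed plots."""
        from .basis import SPATIAL_BLOCKS

        if self.spec.xs_index is None:
            raise ValueError("fit has no spatial component")
        out = self.spec.X[:, self.spec.xs_index] @ self.beta[self.spec.xs_index]
        for k in SPATIAL_BLOCKS:
            if k in self.blups:
                out = out + self.spec.blocks[k].Z @ self.blups[k]
        return out


@dataclass
class HeritabilityResult:
    h2_ed: float
    h2_pev: float
    n_g: int
    ed_g: float
    l_zero: int | None = None
    h2_ed_l: float | None = None  # ED form using the computed l


# ---------------------------------------------------------------------------
# aliasing


def _drop_aliased(X: np.ndarray, names: list) -> tuple[np.ndarray, list, list]:
    """Remove linearly dependent columns (QR with pivoting)."""
    if X.shape[1] == 0:
        return X, list(names), []
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    keep = np.sort(piv[:rank])
    dropped = [names[i] for i in sorted(piv[rank:])]
    return X[:, keep], [names[i] for i in keep], dropped


# ---------------------------------------------------------------------------
# one solve of the mixed-model equations


class _MMESystem:
    """Precomputed cross-products; per-iteration solves at given lambdas."""

    def __init__(self, spec: MixedModelSpec, absorb: str = "auto"):
        X, x_names, dropped = _drop_aliased(spec.X, spec.x_names)
        if dropped:
            logger.info("aliased fixed-effect columns dropped: %s", dropped)
        self.X = X
        self.x_names = x_names
        self.dropped = dropped
        self.p = X.shape[1]
        self.block_names = list(spec.blocks)
        self.blocks = spec.blocks
        self.y = spec.y
        self.n = spec.n

        # decide which block (if any) to absorb via Schur complement
        self.absorb_name = None
        if absorb == "auto":
            for name in self.block_names:
                b = spec.blocks[name]
                if b.q >= 200 and _has_disjoint_columns(b.Z):
                    self.absorb_name = name
                    break
        elif absorb:
            self.absorb_name = absorb if absorb in self.block_names else None

        ordered = [n_ for n_ in self.block_names if n_ != self.absorb_name]
        if self.absorb_name:
            ordered.append(self.absorb_name)
        self.order = ordered
        mats = [X] + [spec.blocks[n_].Z for n_ in ordered]
        self.offsets = np.cumsum([0] + [m.shape[1] for m in mats])
        self.W = np.concatenate(mats, axis=1)
        self.m = self.W.shape[1]
        self.C0 = self.W.T @ self.W
        self.r0 = self.W.T @ self.y
        self.yty = float(self.y @ self.y)

        # orthonormalization constant making the REML deviance invariant to
        # affine reparameterizations of the fixed part
        if self.p:
            Rx = np.linalg.qr(X, mode="r")
            self.logdet_xr = float(np.sum(np.log(np.abs(np.diag(Rx)))))
        else:
            self.logdet_xr = 0.0

        if self.absorb_name:
            qg = spec.blocks[self.absorb_name].q
            self.core = slice(0, self.m - qg)
            self.gslc = slice(self.m - qg, self.m)
            self.A0 = self.C0[self.core, self.core].copy()
            self.Bg = np.ascontiguousarray(self.C0[self.core, self.gslc])
            self.dg0 = np.diag(self.C0)[self.gslc].copy()

    def block_slice(self, name: str) -> slice:
        i = self.order.index(name) + 1
        return slice(self.offsets[i], self.offsets[i + 1])

    def penalty_vector(self, lambdas: dict) -> np.ndarray:
        pen = np.zeros(self.m)
        for name in self.order:
            pen[self.block_slice(name)] = lambdas[name] * self.blocks[name].prec
        return pen

    def solve(self, lambdas: dict) -> dict:
        """Solve the MME at the given smoothing ratios.

        Returns theta, the diagonal of the inverse coefficient matrix, the
        log-determinant of the coefficient matrix, and the residual SSE.
        """
        pen = self.penalty_vector(lambdas)
        if self.absorb_name:
            D = self.dg0 + pen[self.gslc]
            A = self.A0 + np.diag(pen[self.core])
            Bd = self.Bg / D[None, :]
            S = A - Bd @ self.Bg.T
            cF, low = linalg.cho_factor(S, lower=True, check_finite=False)
            rhs = self.r0[self.core] - Bd @ self.r0[self.gslc]
            th_core = linalg.cho_solve((cF, low), rhs, check_finite=False)
            u_g = (self.r0[self.gslc] - self.Bg.T @ th_core) / D
            Sinv = linalg.cho_solve((cF, low), np.eye(S.shape[0]), check_finite=False)
            V = Sinv @ Bd
            diag = np.concatenate([
                np.diag(Sinv),
                1.0 / D + np.einsum("ij,ij->j", Bd, V),
            ])
            theta = np.concatenate([th_core, u_g])
            logdet = 2.0 * float(np.sum(np.log(np.diag(cF)))) + float(np.sum(np.log(D)))
        else:
            C = self.C0 + np.diag(pen)
            cF, low = linalg.cho_factor(C, lower=True, check_finite=False)
            theta = linalg.cho_solve((cF, low), self.r0, check_finite=False)
            Cinv = linalg.cho_solve((cF, low), np.eye(self.m), check_finite=False)
            diag = np.diag(Cinv).copy()
            logdet = 2.0 * float(np.sum(np.log(np.diag(cF))))
        resid = self.y - self.W @ theta
        return {
            "theta": theta,
            "diag_cinv": diag,
            "logdet_c": logdet,
            "resid": resid,
            "sse": float(resid @ resid),
            "ypwy": self.yty - float(theta @ self.r0),
        }

    def effective_dims(self, sol: dict, lambdas: dict) -> dict:
        eds = {}
        for name in self.order:
            b = self.blocks[name]
            d = sol["diag_cinv"][self.block_slice(name)]
            eds[name] = float(b.q - lambdas[name] * (b.prec @ d))
        return eds

    def deviance(self, sol: dict, sigma2: dict, sigma2_e: float) -> float:
        """-2 x restricted log-likelihood at the given variance components."""
        q_tot = self.m - self.p
        dev = self.n * math.log(sigma2_e)
        for name in self.order:
            b = self.blocks[name]
            dev += b.q * math.log(sigma2[name]) - float(np.sum(np.log(b.prec)))
        dev += sol["logdet_c"] - (self.p + q_tot) * math.log(sigma2_e)
        dev += sol["ypwy"] / sigma2_e
        dev += (self.n - self.p) * math.log(2.0 * math.pi)
        dev -= 2.0 * self.logdet_xr
        return float(dev)


def _has_disjoint_columns(Z: np.ndarray) -> bool:
    """True when each row of Z touches at most one column (Z'Z diagonal)."""
    return bool(np.all(np.count_nonzero(Z, axis=1) <= 1))


# ---------------------------------------------------------------------------
# fitting


def fit_reml(
    spec: MixedModelSpec,
    tol: float = 1e-8,
    max_iter: int = 200,
    absorb: str = "auto",
    init: dict | None = None,
) -> FitResult:
    """Fit the mixed model by the ED-based REML fixed point.

    Non-convergence within ``max_iter`` returns a flagged result rather than
    raising.  Components are floored at ``1e-10 * var(y)``; a floored
    component is reported with ED 0 and excluded from the lambda ratios.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    sys_ = _MMESystem(spec, absorb=absorb)
    n, p = sys_.n, sys_.p
    if n <= p:
        raise ValueError(f"need n > rank(X): n={n}, rank={p}")
    names = sys_.order
    vary = float(np.var(spec.y)) if n > 1 else 1.0
    floor = 1e-10 * max(vary, np.finfo(float).tiny)
    start = vary / (len(names) + 1) if vary > 0 else 1.0
    sigma2 = {k: max(start, floor) for k in names}
    sigma2_e = max(start, floor)
    if init:
        sigma2.update({k: max(v, floor) for k, v in init.items() if k in sigma2})
        if "sigma2_e" in init:
            sigma2_e = max(init["sigma2_e"], floor)

    eds_old: dict | None = None
    dev_old = np.inf
    converged = False
    trace = []
    sol = None
    eds: dict = {}
    dev = np.nan
    log_hist: dict = {k: [] for k in names}
    for it in range(1, max_iter + 1):
        lambdas = {k: sigma2_e / sigma2[k] for k in names}
        sol = sys_.solve(lambdas)
        eds = sys_.effective_dims(sol, lambdas)
        dev = sys_.deviance(sol, sigma2, sigma2_e)
        trace.append({"iter": it, "deviance": dev, **eds})

        # fixed-point update
        new_sigma2 = {}
        for name in names:
            u = sol["theta"][sys_.block_slice(name)]
            num = float((u * sys_.blocks[name].prec) @ u)
            ed = eds[name]
            new_sigma2[name] = num / ed if (ed > 1e-10 and num > 0) else floor
            new_sigma2[name] = max(new_sigma2[name], floor)
            # a component that uses < 1e-3 effective parameters and is still
            # shrinking is dead; snap it to the floor instead of letting the
            # fixed point crawl towards zero geometrically
            if ed < 1e-3 and new_sigma2[name] < sigma2[name]:
                new_sigma2[name] = floor
        df_resid = n - p - sum(eds.values())
        new_sigma2_e = max(sol["sse"] / df_resid, floor) if df_resid > 0 else floor

        if eds_old is not None:
            ed_change = max(
                abs(eds[k] - eds_old[k]) / (1.0 + abs(eds[k])) for k in names
            )
            dev_change = abs(dev - dev_old) / (1.0 + abs(dev))
            if ed_change < tol and dev_change < tol:
                # keep the components used in the final solve so that the
                # reported EDs/BLUPs/deviance are mutually consistent
                converged = True
                break
        eds_old, dev_old = eds, dev
        sigma2, sigma2_e = new_sigma2, new_sigma2_e

        # Aitken extrapolation: components decaying (or growing) at a stable
        # geometric rate are jumped to their fixed point, which rescues the
        # otherwise linearly slow collapse of null variance components
        for k in names:
            log_hist[k].append(math.log(sigma2[k]))
        if it >= 6 and it % 3 == 0:
            for k in names:
                h = log_hist[k]
                d1, d2 = h[-2] - h[-3], h[-1] - h[-2]
                if abs(d1) > 1e-14 and abs(d2) > 1e-14 and d1 * d2 > 0:
                    rho = d2 / d1
                    if 0.2 < rho < 0.9995:
                        jump = np.clip(d2 * rho / (1.0 - rho), -40.0, 40.0)
                        sigma2[k] = max(math.exp(h[-1] + jump), floor)
                        log_hist[k][-1] = math.log(sigma2[k])

    if not converged:
        logger.warning("REML fixed point not converged after %d iterations", max_iter)

    floored = {k for k, v in sigma2.items() if v <= floor * (1 + 1e-9)}
    vc = VarianceComponents(components=sigma2, sigma2_e=sigma2_e, floored=floored)
    theta = sol["theta"]
    blups = {k: theta[sys_.block_slice(k)].copy() for k in names}
    eds_out = {k: (0.0 if k in floored else max(eds[k], 0.0)) for k in names}
    diag_cinv = {k: sol["diag_cinv"][sys_.block_slice(k)].copy() for k in names}
    diag_cinv["__fixed__"] = sol["diag_cinv"][: p].copy()
    pev = None
    if "geno" in names:
        pev = sigma2_e * diag_cinv["geno"]
    fitted = spec.y - sol["resid"]
    return FitResult(
        spec=spec,
        variance=vc,
        beta=theta[:p].copy(),
        beta_names=sys_.x_names,
        blups=blups,
        effective_dims=eds_out,
        ed_beta=float(p),
        residuals=sol["resid"],
        fitted=fitted,
        pev_geno=pev,
        deviance=dev,
        n_iter=it,
        converged=converged,
        aliased=sys_.dropped,
        diag_cinv=diag_cinv,
        trace=trace,
    )


def effective_dimensions(fit: FitResult) -> dict:
    """Named effective dimensions, including the fixed part and the residual."""
    out = {"fixed": fit.ed_beta}
    out.update(fit.effective_dims)
    out["residual"] = fit.ed_residual
    return out


def evaluate_at(spec: MixedModelSpec, components: dict, sigma2_e: float,
                absorb: str = "auto") -> dict:
    """Solve the MME once at fixed variance components (no iteration).

    Returns effective dimensions, BLUPs, residuals and the REML deviance;
    used by oracle tests and by :func:`reml_deviance`.
    """
    sys_ = _MMESystem(spec, absorb=absorb)
    lambdas = {k: sigma2_e / components[k] for k in sys_.order}
    sol = sys_.solve(lambdas)
    eds = sys_.effective_dims(sol, lambdas)
    dev = sys_.deviance(sol, components, sigma2_e)
    blups = {k: sol["theta"][sys_.block_slice(k)] for k in sys_.order}
    return {
        "eds": eds,
        "beta": sol["theta"][: sys_.p],
        "blups": blups,
        "resid": sol["resid"],
        "deviance": dev,
        "diag_cinv": {k: sol["diag_cinv"][sys_.block_slice(k)] for k in sys_.order},
    }


def reml_deviance(
    spec: MixedModelSpec,
    components: dict,
    sigma2_e: float,
    method: str = "mme",
) -> float:
    """-2 x restricted log-likelihood at the supplied variance components.

    ``method='mme'`` uses the coefficient-matrix determinant identity used
    in production; ``method='dense'`` forms the marginal covariance V
    explicitly (textbook formula, small instances only).  Both agree.
    """
    if sigma2_e <= 0 or any(components[k] <= 0 for k in spec.blocks):
        raise ValueError("variance components must be > 0")
    if method == "mme":
        return evaluate_at(spec, components, sigma2_e)["deviance"]
    if method != "dense":
        raise ValueError(f"unknown method {method!r}")
    X, _, _ = _drop_aliased(spec.X, spec.x_names)
    n, p = spec.n, X.shape[1]
    V = sigma2_e * np.eye(n)
    for name, b in spec.blocks.items():
        V += components[name] * (b.Z / b.prec[None, :]) @ b.Z.T
    sign, logdetV = np.linalg.slogdet(V)
    if sign <= 0:
        raise ValueError("marginal covariance not positive definite")
    Vinv = np.linalg.inv(V)
    XtViX = X.T @ Vinv @ X
    sign2, logdetX = np.linalg.slogdet(XtViX)
    if sign2 <= 0:
        raise ValueError("X'V^-1X not positive definite")
    P = Vinv - Vinv @ X @ np.linalg.solve(XtViX, X.T @ Vinv)
    y = spec.y
    dev = logdetV + logdetX + float(y @ P @ y) + (n - p) * math.log(2.0 * math.pi)
    Rx = np.linalg.qr(X, mode="r")
    dev -= 2.0 * float(np.sum(np.log(np.abs(np.diag(Rx)))))
    return float(dev)


# ---------------------------------------------------------------------------
# heritability


def heritability(fit: FitResult, compute_l: bool = False) -> HeritabilityResult:
    """ED-based and PEV-based generalized heritability of the genotype block.

    The headline ED form uses ``l = 0`` zero eigenvalues of the genotype hat
    matrix; with ``compute_l=True`` the eigen-count and the corresponding
    corrected value are also reported (dense eigendecomposition -- intended
    for small instances).
    """
    if "geno" not in fit.spec.blocks:
        raise ValueError("fit has no genotype block")
    geno = fit.spec.blocks["geno"]
    n_g = geno.q
    sigma2_g = fit.variance.components["geno"]
    if "geno" in fit.variance.floored or sigma2_g <= 0:
        warnings.warn("genotypic variance at floor; heritability set to 0")
        return HeritabilityResult(0.0, 0.0, n_g, 0.0)
    ed_g = fit.effective_dims["geno"]
    h2_ed = ed_g / n_g
    h2_pev = 1.0 - float(np.mean(fit.pev_geno)) / sigma2_g
    l_zero = None
    h2_ed_l = None
    if compute_l:
        l_zero = _count_zero_hat_eigenvalues(fit)
        if n_g - l_zero > 0:
            h2_ed_l = ed_g / (n_g - l_zero)
    return HeritabilityResult(
        h2_ed=float(np.clip(h2_ed, 0.0, 1.0)),
        h2_pev=float(np.clip(h2_pev, 0.0, 1.0)),
        n_g=n_g,
        ed_g=float(ed_g),
        l_zero=l_zero,
        h2_ed_l=h2_ed_l,
    )


def _count_zero_hat_eigenvalues(fit: FitResult) -> int:
    """Zero eigenvalues of the genotype hat matrix H_g (dense, small n only)."""
    sys_ = _MMESystem(fit.spec, absorb=None)
    lambdas = {}
    for k in sys_.order:
        s2 = fit.variance.components[k]
        lambdas[k] = fit.variance.sigma2_e / max(s2, 1e-300)
    pen = sys_.penalty_vector(lambdas)
    C = sys_.C0 + np.diag(pen)
    Cinv = np.linalg.inv(C)
    g = sys_.block_slice("geno")
    # nonzero eigenvalues of H_g = Z_g E_g C^-1 W' equal those of C^-1_g W'Z_g
    M = Cinv[g, :] @ sys_.C0[:, g]
    ev = np.linalg.eigvals(M)
    mags = np.abs(ev)
    cutoff = EIG_RTOL * max(mags.max(), 1.0)
    return int(np.sum(mags < cutoff))


# ---------------------------------------------------------------------------
# surface prediction and residual diagnostics


def predict_surface(
    fit: FitResult,
    row_step: float | None = None,
    col_step: float | None = None,
    density: int = 4,
) -> pd.DataFrame:
    """Evaluate the fitted spatial trend on a fine grid within the plot range.

    Defaults to ``density`` points per plot unit in each direction.  Rows
    outside the observed coordinate range are a range error.
    """
    spec = fit.spec
    if spec.psanova is None or spec.rows is None:
        raise ValueError("fit has no spatial component")
    des = spec.psanova
    lo_r, hi_r = des.row_basis.domain_lo, des.row_basis.domain_hi
    lo_c, hi_c = des.col_basis.domain_lo, des.col_basis.domain_hi
    if row_step is None:
        row_step = 1.0 / density
    if col_step is None:
        col_step = 1.0 / density
    r_grid = np.arange(lo_r, hi_r + 1e-9, row_step)
    c_grid = np.arange(lo_c, hi_c + 1e-9, col_step)
    rr, cc = np.meshgrid(r_grid, c_grid, indexing="ij")
    vals = surface_at(fit, rr.ravel(), cc.ravel())
    return pd.DataFrame({"row": rr.ravel(), "col": cc.ravel(), "trend": vals})


def surface_at(fit: FitResult, r: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Fitted spatial trend at arbitrary in-range coordinates."""
    from .basis import SPATIAL_BLOCKS

    spec = fit.spec
    des = spec.psanova
    if des is None:
        raise ValueError("fit has no spatial component")
    X_s, Z = des.spatial_matrices(np.asarray(r, float), np.asarray(c, float))
    beta_s = np.zeros(3)
    for j, nm in enumerate(("xs_r", "xs_c", "xs_rc")):
        if nm in fit.beta_names:
            beta_s[j] = fit.beta[fit.beta_names.index(nm)]
    out = X_s @ beta_s
    for k in SPATIAL_BLOCKS:
        if k in fit.blups:
            out = out + Z[k] @ fit.blups[k]
    return out


def nugget_variogram(fit: FitResult) -> pd.DataFrame:
    """Semivariogram of the independent (nugget) residuals.

    For each absolute displacement ``(|dr|, |dc|) != (0, 0)`` returns the
    mean of ``0.5 (e_i - e_j)^2`` over all plot pairs at that displacement.
    """
    spec = fit.spec
    if spec.rows is None or spec.cols is None:
        raise ValueError("plot coordinates unavailable")
    if spec.n < 2:
        raise ValueError("need at least 2 observed plots")
    r = np.asarray(spec.rows, float)
    c = np.asarray(spec.cols, float)
    e = fit.residuals
    iu, ju = np.triu_indices(spec.n, k=1)
    dr = np.abs(r[iu] - r[ju])
    dc = np.abs(c[iu] - c[ju])
    gamma = 0.5 * (e[iu] - e[ju]) ** 2
    df = pd.DataFrame({"dr": dr, "dc": dc, "gamma": gamma})
    out = (
        df.groupby(["dr", "dc"], as_index=False)
        .agg(semivariance=("gamma", "mean"), n_pairs=("gamma", "size"))
        .sort_values(["dr", "dc"], ignore_index=True)
    )
    return out
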