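"""Simulation of partially replicated (p-rep) field trials with known truth.

Layouts put a fraction ``p_rep`` of the test genotypes twice -- once in each
of two contiguous block halves -- with the remaining genotypes unreplicated
and check varieties filling the leftover plots.  Phenotypes add, on top of
the genotype effects, a choice of field trend (none / plane / smooth bumps /
separable AR1xAR1 Gaussian field), random row and column effects, a block
shift, and independent nugget noise.  A truth record accompanies every
simulated trial so parameter-recovery tests are self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, toeplitz

from .models import TrialData

__all__ = [
    "SurfaceSpec",
    "SimulationParams",
    "generate_prep_layout",
    "simulate_phenotypes",
    "simulate_trial",
    "smooth_surface",
    "ar1_field",
]


@dataclass(frozen=True)
class SurfaceSpec:
    """Field-trend generator settings.

    ``kind`` is one of ``none``, ``plane``, ``smooth``, ``ar1field``:
    plane uses ``slope_r``/``slope_c`` per plot unit; smooth rescales a
    seeded bump surface to range ``amplitude``; ar1field draws a zero-mean
    Gaussian field with separable AR1 correlations ``rho_r``/``rho_c`` and
    marginal variance ``sigma2_xi``.
    """

    kind: str = "none"
    slope_r: float = 0.0
    slope_c: float = 0.0
    amplitude: float = 0.0
    shape_seed: int = 0
    sigma2_xi: float = 0.0
    rho_r: float = 0.0
    rho_c: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "plane", "smooth", "ar1field"):
            raise ValueError(f"unknown surface kind {self.kind!r}")
        if self.amplitude < 0 or self.sigma2_xi < 0:
            raise ValueError("amplitude and sigma2_xi must be >= 0")
        if not (-1 < self.rho_r < 1 and -1 < self.rho_c < 1):
            raise ValueError("autocorrelations must lie in (-1, 1)")


@dataclass(frozen=True)
class SimulationParams:
    n_rows: int
    n_cols: int
    n_geno: int
    p_rep: float = 0.30
    n_checks: int = 0
    mu: float = 10.0
    block_shift: float = 0.0
    sigma2_g: float = 1.0
    sigma2_r: float = 0.0
    sigma2_c: float = 0.0
    sigma2_e: float = 1.0
    surface: SurfaceSpec = field(default_factory=SurfaceSpec)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_rows, self.n_cols, self.n_geno) < 1:
            raise ValueError("grid dimensions and n_geno must be >= 1")
        if not 0 <= self.p_rep <= 1:
            raise ValueError("p_rep must lie in [0, 1]")
        if not 0 <= self.missing_rate <= 0.29:
            raise ValueError("missing_rate must lie in [0, 0.29]")
        for nm in ("sigma2_g", "sigma2_r", "sigma2_c", "sigma2_e"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")

    @property
    def n_plots(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_duplicated(self) -> int:
        return int(round(self.p_rep * self.n_geno))

    @property
    def n_check_plots(self) -> int:
        return self.n_plots - self.n_geno - self.n_duplicated


def generate_prep_layout(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> TrialData:
    """Randomized p-rep layout (phenotype left missing).

    The grid is split row-major into two contiguous halves (the resolvable
    blocks); each duplicated genotype appears exactly once per block, and
    unreplicated genotypes and check plots are randomized within blocks.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n_plots = params.n_plots
    n_dup = params.n_duplicated
    needed = params.n_geno + n_dup
    if needed > n_plots:
        raise ValueError(
            f"infeasible layout: {needed} genotype plots required "
            f"but only {n_plots} available"
        )
    n_check_plots = params.n_check_plots
    if n_check_plots > 0 and params.n_checks == 0:
        raise ValueError(
            f"{n_check_plots} leftover plots but n_checks = 0; "
            "add check entries or enlarge n_geno"
        )

    genos = [f"G{i + 1:04d}" for i in range(params.n_geno)]
    dup = list(rng.choice(params.n_geno, size=n_dup, replace=False))
    dup_set = set(dup)
    unrep = [i for i in range(params.n_geno) if i not in dup_set]

    s1 = (n_plots + 1) // 2  # block 1 plots (row-major first half)
    s2 = n_plots - s1
    if n_dup > min(s1, s2):
        raise ValueError("infeasible layout: more duplicated entries than block plots")
    # split checks roughly proportionally; unreplicated entries fill the rest,
    # clamped so both blocks can be completed
    free1 = s1 - n_dup
    lo = max(0, free1 - len(unrep))
    hi = min(n_check_plots, free1)
    if lo > hi:
        raise ValueError("infeasible layout: cannot balance the two blocks")
    c1 = int(np.clip(round(n_check_plots * s1 / n_plots), lo, hi))
    u1 = free1 - c1
    if not (0 <= u1 <= len(unrep) and 0 <= c1 <= n_check_plots):
        raise ValueError("infeasible layout: cannot balance the two blocks")

    perm = rng.permutation(len(unrep))
    unrep1 = [unrep[i] for i in perm[:u1]]
    unrep2 = [unrep[i] for i in perm[u1:]]

    checks = [f"CHK{i + 1}" for i in range(params.n_checks)]
    check_plots = [checks[i % len(checks)] for i in range(n_check_plots)] if checks else []
    chk1, chk2 = check_plots[:c1], check_plots[c1:]

    entries1 = [genos[i] for i in dup] + [genos[i] for i in unrep1] + chk1
    entries2 = [genos[i] for i in dup] + [genos[i] for i in unrep2] + chk2
    assert len(entries1) == s1 and len(entries2) == s2
    entries1 = [entries1[i] for i in rng.permutation(s1)]
    entries2 = [entries2[i] for i in rng.permutation(s2)]

    rows = np.repeat(np.arange(1, params.n_rows + 1), params.n_cols)
    cols = np.tile(np.arange(1, params.n_cols + 1), params.n_rows)
    entries = entries1 + entries2
    blocks = ["B1"] * s1 + ["B2"] * s2
    df = pd.DataFrame(
        {
            "row": rows,
            "col": cols,
            "genotype": entries,
            "check": [g.startswith("CHK") for g in entries],
            "block": blocks,
            "y": np.nan,
        }
    )
    return TrialData(df, params.n_rows, params.n_cols)


def smooth_surface(
    shape_seed: int,
    amplitude: float,
    n_rows: int,
    n_cols: int,
    r: np.ndarray | None = None,
    c: np.ndarray | None = None,
) -> np.ndarray:
    """Reproducible smooth trend: tilted plane plus 2-4 Gaussian bumps.

    Bump centers/widths derive deterministically from ``shape_seed``; the
    surface is rescaled so its range over the full grid equals ``amplitude``
    and centered to grid mean zero.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if r is None or c is None:
        rr, cc = np.meshgrid(
            np.arange(1, n_rows + 1), np.arange(1, n_cols + 1), indexing="ij"
        )
        r, c = rr.ravel().astype(float), cc.ravel().astype(float)
    r = np.asarray(r, float)
    c = np.asarray(c, float)
    if amplitude == 0:
        return np.zeros_like(r)
    srng = np.random.default_rng(shape_seed)
    n_bumps = int(srng.integers(2, 5))
    tilt_r, tilt_c = srng.uniform(-1, 1, size=2)
    centers_r = srng.uniform(1, n_rows, size=n_bumps)
    centers_c = srng.uniform(1, n_cols, size=n_bumps)
    widths_r = srng.uniform(0.15, 0.45, size=n_bumps) * n_rows
    widths_c = srng.uniform(0.15, 0.45, size=n_bumps) * n_cols
    heights = srng.uniform(-1, 1, size=n_bumps)

    def raw(rv, cv):
        f = tilt_r * rv / n_rows + tilt_c * cv / n_cols
        for j in range(n_bumps):
            f = f + heights[j] * np.exp(
                -0.5 * ((rv - centers_r[j]) / widths_r[j]) ** 2
                - 0.5 * ((cv - centers_c[j]) / widths_c[j]) ** 2
            )
        return f

    rr, cc = np.meshgrid(
        np.arange(1, n_rows + 1, dtype=float),
        np.arange(1, n_cols + 1, dtype=float),
        indexing="ij",
    )
    grid_vals = raw(rr.ravel(), cc.ravel())
    span = grid_vals.max() - grid_vals.min()
    if span == 0:
        return np.zeros_like(r)
    scale = amplitude / span
    offset = grid_vals.mean()
    return (raw(r, c) - offset) * scale


def ar1_field(
    rng: np.random.Generator,
    n_rows: int,
    n_cols: int,
    sigma2_xi: float,
    rho_r: float,
    rho_c: float,
) -> np.ndarray:
    """Zero-mean Gaussian field with separable AR1xAR1 correlation (grid array)."""
    Lr = cholesky(toeplitz(rho_r ** np.arange(n_rows)), lower=True)
    Lc = cholesky(toeplitz(rho_c ** np.arange(n_cols)), lower=True)
    Z = rng.standard_normal((n_rows, n_cols))
    return np.sqrt(sigma2_xi) * (Lr @ Z @ Lc.T)


def _surface_values(
    params: SimulationParams, r: np.ndarray, c: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    s = params.surface
    if s.kind == "none":
        return np.zeros_like(r, dtype=float)
    if s.kind == "plane":
        return s.slope_r * (r - r.mean()) + s.slope_c * (c - c.mean())
    if s.kind == "smooth":
        return smooth_surface(
            s.shape_seed, s.amplitude, params.n_rows, params.n_cols, r, c
        )
    field_ = ar1_field(rng, params.n_rows, params.n_cols, s.sigma2_xi, s.rho_r, s.rho_c)
    return field_[r.astype(int) - 1, c.astype(int) - 1]


def simulate_phenotypes(
    layout: TrialData,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> tuple[TrialData, dict]:
    """Attach phenotypes to a layout; returns the trial and a truth record."""
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    df = layout.plots.copy()
    r = df["row"].to_numpy(float)
    c = df["col"].to_numpy(float)

    tests = sorted(df.loc[~df["check"], "genotype"].unique())
    g_eff = dict(zip(tests, rng.normal(0.0, np.sqrt(params.sigma2_g), len(tests))))
    checks = sorted(df.loc[df["check"], "genotype"].unique())
    sd_g = float(np.sqrt(params.sigma2_g))
    if checks:
        offsets = (
            np.linspace(-1.0, 1.0, len(checks)) * sd_g
            if len(checks) > 1
            else np.array([0.0])
        )
        g_eff.update(dict(zip(checks, offsets)))
    geno_vals = df["genotype"].map(g_eff).to_numpy(float)

    row_eff = rng.normal(0.0, np.sqrt(params.sigma2_r), layout.n_rows)
    col_eff = rng.normal(0.0, np.sqrt(params.sigma2_c), layout.n_cols)
    trend = _surface_values(params, r, c, rng)
    nugget = rng.normal(0.0, np.sqrt(params.sigma2_e), len(df))
    block_vals = np.where(df["block"] == "B2", params.block_shift, 0.0)

    y = (
        params.mu
        + block_vals
        + geno_vals
        + trend
        + row_eff[df["row"] - 1]
        + col_eff[df["col"] - 1]
        + nugget
    )
    df["y"] = y
    if params.missing_rate > 0:
        mask = rng.random(len(df)) < params.missing_rate
        df.loc[mask, "y"] = np.nan

    truth = {
        "params": {
            **{k: v for k, v in asdict(params).items() if k != "surface"},
            "surface": asdict(params.surface),
        },
        "genotype_effects": {g: float(v) for g, v in g_eff.items()},
        "trend": trend.tolist(),
        "row_effects": row_eff.tolist(),
        "col_effects": col_eff.tolist(),
        "realized": {
            "var_g": float(np.var([g_eff[t] for t in tests], ddof=1)) if len(tests) > 1 else 0.0,
            "var_nugget": float(np.var(nugget, ddof=1)) if len(df) > 1 else 0.0,
            "trend_range": float(trend.max() - trend.min()) if len(df) else 0.0,
        },
    }
    return TrialData(df, layout.n_rows, layout.n_cols, layout.trait, layout.units), truth


def simulate_trial(params: SimulationParams) -> tuple[TrialData, dict]:
    """Layout plus phenotypes from a single seed (fully reproducible)."""
    rng = np.random.default_rng(params.seed)
    layout = generate_prep_layout(params, rng)
    return simulate_phenotypes(layout, params, rng)
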