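"""Trial tables, model assembly, and model-comparison metrics.

Builds the spatial mixed model (fixed: intercept, check varieties, resolvable
block, linear spatial columns; random: five spatial smooth blocks, row,
column, test genotypes) and the non-spatial baseline (fixed: intercept,
checks, block; random: genotypes) from a plot table, and provides the
comparison metrics used to contrast the two fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .basis import SPATIAL_BLOCKS, build_psanova
from .reml import FitResult, MixedModelSpec, RandomBlock

__all__ = [
    "TrialData",
    "default_knots",
    "build_spats_model",
    "build_nonspatial_model",
    "pearson_between_environments",
    "spearman_between_models",
    "genotypic_cv",
    "residual_reduction",
    "ed_percentages",
]

REQUIRED_COLUMNS = ["row", "col", "genotype", "check", "block", "y"]


@dataclass
class TrialData:
    """Plot-level records of one field trial on a rectangular grid."""

    plots: pd.DataFrame
    n_rows: int
    n_cols: int
    trait: str = "y"
    units: str = ""

    def __post_init__(self) -> None:
        df = self.plots
        missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValueError(f"trial table missing columns: {missing_cols}")
        df = df.copy()
        df["row"] = df["row"].astype(int)
        df["col"] = df["col"].astype(int)
        df["check"] = df["check"].astype(bool)
        df["y"] = pd.to_numeric(df["y"])
        if df.duplicated(["row", "col"]).any():
            dup = df[df.duplicated(["row", "col"], keep=False)].iloc[0]
            raise ValueError(f"duplicate plot coordinates ({dup.row}, {dup.col})")
        if df["row"].min() < 1 or df["row"].max() > self.n_rows:
            raise ValueError("row index outside [1, n_rows]")
        if df["col"].min() < 1 or df["col"].max() > self.n_cols:
            raise ValueError("col index outside [1, n_cols]")
        obs = df[df["y"].notna()]
        if obs["genotype"].isna().any() or (obs["genotype"].astype(str) == "").any():
            raise ValueError("non-missing plots must carry a genotype label")
        if obs["block"].isna().any():
            raise ValueError("non-missing plots must carry a block label")
        self.plots = df.reset_index(drop=True)

    @property
    def observed(self) -> pd.DataFrame:
        return self.plots[self.plots["y"].notna()]

    @property
    def n_blocks(self) -> int:
        return self.observed["block"].nunique()

    def test_genotypes(self) -> list:
        obs = self.observed
        return sorted(obs.loc[~obs["check"], "genotype"].unique())


def default_knots(n: int) -> int:
    """Default knot count: about one knot per two plot positions.

    ``n // 2 + 1`` equally spaced knots (endpoints included), capped at the
    number of positions.
    """
    return min(n, n // 2 + 1)


def _indicator(values: pd.Series, levels: list) -> np.ndarray:
    idx = {v: j for j, v in enumerate(levels)}
    Z = np.zeros((len(values), len(levels)))
    for i, v in enumerate(values):
        j = idx.get(v)
        if j is not None:
            Z[i, j] = 1.0
    return Z


def _fixed_part(trial: TrialData, obs: pd.DataFrame) -> tuple[list, list]:
    """Intercept, check-variety, and block columns with names."""
    cols = [np.ones(len(obs))]
    names = ["intercept"]
    checks = sorted(obs.loc[obs["check"], "genotype"].unique())
    for ck in checks:
        cols.append((obs["genotype"] == ck).to_numpy(float))
        names.append(f"check[{ck}]")
    blocks = sorted(obs["block"].unique())
    if len(blocks) < 2:
        warnings.warn("only one resolvable block observed; block effect dropped")
    else:
        for b in blocks[1:]:
            cols.append((obs["block"] == b).to_numpy(float))
            names.append(f"block[{b}]")
    return cols, names


def _geno_block(trial: TrialData, obs: pd.DataFrame) -> RandomBlock:
    tests = trial.test_genotypes()
    if not tests:
        raise ValueError("no test genotypes: all entries are flagged as checks")
    Z = _indicator(obs["genotype"], tests)
    return RandomBlock("geno", Z, np.ones(len(tests)), labels=tests)


def build_spats_model(
    trial: TrialData,
    n_knots_r: int | None = None,
    n_knots_c: int | None = None,
    degree: int = 3,
) -> MixedModelSpec:
    """Assemble the spatial mixed model for one trial.

    Knot counts default to :func:`default_knots` of the grid dimensions.
    """
    if n_knots_r is None:
        n_knots_r = default_knots(trial.n_rows)
    if n_knots_c is None:
        n_knots_c = default_knots(trial.n_cols)
    obs = trial.observed
    rows = obs["row"].to_numpy(float)
    cols_ = obs["col"].to_numpy(float)
    design = build_psanova(
        rows,
        cols_,
        n_knots_r,
        n_knots_c,
        degree=degree,
        row_range=(1.0, float(trial.n_rows)),
        col_range=(1.0, float(trial.n_cols)),
    )

    xcols, xnames = _fixed_part(trial, obs)
    xs_start = len(xcols)
    for j, nm in enumerate(("xs_r", "xs_c", "xs_rc")):
        xcols.append(design.X_s[:, j])
        xnames.append(nm)
    X = np.column_stack(xcols)

    blocks: dict = {}
    for k in SPATIAL_BLOCKS:
        blocks[k] = RandomBlock(k, design.Z[k], design.precision[k])
    row_levels = sorted(obs["row"].unique())
    col_levels = sorted(obs["col"].unique())
    blocks["row"] = RandomBlock(
        "row", _indicator(obs["row"], row_levels), np.ones(len(row_levels)),
        labels=row_levels,
    )
    blocks["col"] = RandomBlock(
        "col", _indicator(obs["col"], col_levels), np.ones(len(col_levels)),
        labels=col_levels,
    )
    blocks["geno"] = _geno_block(trial, obs)

    return MixedModelSpec(
        y=obs["y"].to_numpy(float),
        X=X,
        x_names=xnames,
        blocks=blocks,
        rows=rows,
        cols=cols_,
        psanova=design,
        xs_index=list(range(xs_start, xs_start + 3)),
        n_rows=trial.n_rows,
        n_cols=trial.n_cols,
        meta={"model": "spats", "trait": trial.trait,
              "n_knots_r": n_knots_r, "n_knots_c": n_knots_c},
    )


def build_nonspatial_model(trial: TrialData) -> MixedModelSpec:
    """Baseline model: intercept, checks, block fixed; genotypes random."""
    obs = trial.observed
    xcols, xnames = _fixed_part(trial, obs)
    X = np.column_stack(xcols)
    blocks = {"geno": _geno_block(trial, obs)}
    return MixedModelSpec(
        y=obs["y"].to_numpy(float),
        X=X,
        x_names=xnames,
        blocks=blocks,
        rows=obs["row"].to_numpy(float),
        cols=obs["col"].to_numpy(float),
        psanova=None,
        xs_index=None,
        n_rows=trial.n_rows,
        n_cols=trial.n_cols,
        meta={"model": "nonspatial", "trait": trial.trait},
    )


# ---------------------------------------------------------------------------
# comparison metrics


def genotype_blups(fit: FitResult) -> pd.Series:
    """Test-genotype BLUPs as a labelled series."""
    geno = fit.spec.blocks["geno"]
    return pd.Series(fit.blups["geno"], index=geno.labels, name="blup")


def pearson_between_environments(
    blups_by_env: dict, min_common: int = 30
) -> pd.DataFrame:
    """Pairwise Pearson correlations of genotype values between environments.

    Environment pairs sharing fewer than ``min_common`` genotypes are
    flagged as excluded (correlation reported as NaN).
    """
    envs = list(blups_by_env)
    if len(envs) < 2:
        raise ValueError("need at least 2 environments")
    rows = []
    for i, a in enumerate(envs):
        for b in envs[i + 1:]:
            sa, sb = pd.Series(blups_by_env[a]), pd.Series(blups_by_env[b])
            common = sa.index.intersection(sb.index)
            n = len(common)
            if n >= min_common:
                r = float(stats.pearsonr(sa[common], sb[common])[0])
                included = True
            else:
                r, included = float("nan"), False
            rows.append({"env_a": a, "env_b": b, "n_common": n,
                         "pearson_r": r, "included": included})
    return pd.DataFrame(rows)


def spearman_between_models(blups_a, blups_b) -> float:
    """Spearman rank correlation over the shared genotype set (ties averaged)."""
    sa, sb = pd.Series(blups_a), pd.Series(blups_b)
    common = sa.index.intersection(sb.index)
    if len(common) < 3:
        raise ValueError(f"need >= 3 shared genotypes, got {len(common)}")
    return float(stats.spearmanr(sa[common], sb[common]).statistic)


def genotypic_cv(fit: FitResult, trial_mean: float) -> float:
    """Genotypic coefficient of variation: ``100 * sd_g / mean`` (percent)."""
    if trial_mean <= 0:
        raise ValueError(f"trial mean must be > 0, got {trial_mean}")
    s2g = fit.variance.components.get("geno", 0.0)
    if "geno" in fit.variance.floored:
        s2g = 0.0
    return 100.0 * float(np.sqrt(s2g)) / trial_mean


def residual_reduction(fit_spatial: FitResult, fit_nonspatial: FitResult) -> float:
    """Spatial-model residual variance as a percentage of the non-spatial one."""
    a, b = fit_spatial.spec, fit_nonspatial.spec
    if a.n != b.n or not (
        np.array_equal(a.rows, b.rows) and np.array_equal(a.cols, b.cols)
    ):
        raise ValueError("fits were not computed on identical observation sets")
    return 100.0 * fit_spatial.variance.sigma2_e / fit_nonspatial.variance.sigma2_e


def ed_percentages(eds: dict, ndigits: int | None = 0) -> dict:
    """Share (%) of each spatial component in the total spatial ED."""
    total = sum(eds.values())
    if total <= 0:
        return {k: 0.0 for k in eds}
    out = {k: 100.0 * v / total for k, v in eds.items()}
    if ndigits is not None:
        out = {k: round(v, ndigits) if ndigits else round(v) for k, v in out.items()}
    return out
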