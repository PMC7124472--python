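"""Normalization, per-peptide linear models, empirical-Bayes moderated t
statistics and FDR adjustment for the kinase-inhibition contrasts.

The workflow mirrors the standard single-channel microarray treatment of a
complete log2 intensity matrix:

1. quantile normalization equalizes the per-run intensity distributions;
2. one global linear model per peptide with an indicator per
   (strain, treatment) group and a blocking factor for batch (replicate by
   default) removes batch shifts and yields group means;
3. residual variances are shrunk toward a prior (d0, s0^2) estimated by
   moment matching on log s^2 (digamma/trigamma inversion), giving the
   moderated t statistic

       t = logFC / (sd_unscaled * s_post),
       s_post^2 = (d0 s0^2 + d s^2) / (d0 + d),

   referred to a t distribution with d0 + d degrees of freedom;
4. per strain, the treated-vs-mock contrast p values are Benjamini-Hochberg
   adjusted over the family of all retained peptides.

The contrast is drug minus mock in log2, so hypo-phosphorylation upon kinase
inhibition gives logFC < 0 and fold change FC = 2^logFC < 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import ConfigError, ContractError


# ---------------------------------------------------------------------------
# quantile normalization


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every column to the same distribution (per-rank column means).

    Ties within a column receive the mean of the target values spanned by
    their rank range.  Requires a complete matrix.
    """
    if values.isna().any().any():
        raise ContractError("quantile normalization requires a complete matrix")
    arr = values.to_numpy(dtype=float)
    n, m = arr.shape
    target = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(m):
        order = np.argsort(arr[:, j], kind="mergesort")
        col = np.empty(n)
        col[order] = target
        uniq, inv = np.unique(arr[:, j], return_inverse=True)
        sums = np.bincount(inv, weights=col)
        cnts = np.bincount(inv)
        out[:, j] = (sums / cnts)[inv]
    return pd.DataFrame(out, index=values.index, columns=values.columns)


# ---------------------------------------------------------------------------
# linear model


def build_design_matrix(
    design: pd.DataFrame, batch_column: str = "batch"
) -> pd.DataFrame:
    """Group-means parameterization: one indicator per (strain, treatment)
    group, plus batch factor levels (reference level dropped)."""
    groups = []
    for row in design.itertuples(index=False):
        groups.append(f"g_{row.strain}_{row.treatment}")
    group_levels = list(dict.fromkeys(groups))
    batches = list(design[batch_column])
    batch_levels = sorted(set(batches))
    cols: dict[str, np.ndarray] = {}
    for g in group_levels:
        cols[g] = np.array([1.0 if x == g else 0.0 for x in groups])
    for b in batch_levels[1:]:
        cols[f"batch_{b}"] = np.array(
            [1.0 if x == b else 0.0 for x in batches]
        )
    X = pd.DataFrame(cols, index=design["run_id"])
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        aliased = _aliased_columns(X.to_numpy(), list(X.columns))
        raise ConfigError(f"design matrix is rank deficient; aliased: {aliased}")
    return X


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    keep: list[int] = []
    aliased = []
    for j in range(X.shape[1]):
        cand = keep + [j]
        if np.linalg.matrix_rank(X[:, cand]) == len(cand):
            keep.append(j)
        else:
            aliased.append(names[j])
    return aliased


@dataclass
class LinearFit:
    """Per-peptide OLS fit against a shared design matrix."""

    coef: pd.DataFrame  # peptides x coefficients
    s2: pd.Series  # residual variance per peptide
    df_resid: int
    cov_unscaled: np.ndarray  # (X'X)^-1 over coefficient order


def fit_linear_model(values: pd.DataFrame, X: pd.DataFrame) -> LinearFit:
    """Ordinary least squares per peptide (rows) against the runs design."""
    if list(values.columns) != list(X.index):
        raise ConfigError("matrix columns do not match design matrix rows")
    Xm = X.to_numpy(dtype=float)
    Y = values.to_numpy(dtype=float)
    n, p = Xm.shape
    rank = np.linalg.matrix_rank(Xm)
    if rank < p:
        raise ConfigError(
            f"design matrix rank {rank} < {p} columns; aliased: "
            f"{_aliased_columns(Xm, list(X.columns))}"
        )
    pinv = np.linalg.pinv(Xm)
    B = Y @ pinv.T
    resid = Y - B @ Xm.T
    df = n - rank
    if df <= 0:
        raise ConfigError("no residual degrees of freedom")
    s2 = (resid**2).sum(axis=1) / df
    cov = np.linalg.inv(Xm.T @ Xm)
    return LinearFit(
        coef=pd.DataFrame(B, index=values.index, columns=X.columns),
        s2=pd.Series(s2, index=values.index, name="s2"),
        df_resid=df,
        cov_unscaled=cov,
    )


# ---------------------------------------------------------------------------
# empirical-Bayes prior


@dataclass
class EBayesPrior:
    d0: float  # prior degrees of freedom (may be inf)
    s0_sq: float  # prior variance


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return float("inf")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> EBayesPrior:
    """Moment-match a scaled inverse chi-square prior to the observed
    residual variances (the classical moderated-t hyperparameter fit).

    Works on log s^2: the excess dispersion of log s^2 beyond what a
    chi-square with ``df`` degrees of freedom explains determines d0 through
    a trigamma inversion; no positive excess means d0 = inf (complete
    shrinkage to a single variance).
    """
    s2 = np.asarray(s2, dtype=float)
    if len(s2) < 2:
        raise ConfigError("need at least two residual variances")
    if np.ptp(s2) == 0.0:
        return EBayesPrior(d0=float("inf"), s0_sq=float(s2[0]))
    pos = s2[s2 > 0]  # zero variances carry no log-scale information
    z = np.log(pos)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        # no excess dispersion beyond chi-square sampling noise: shrink
        # completely, to the pooled mean variance
        return EBayesPrior(d0=float("inf"), s0_sq=float(s2.mean()))
    d0 = 2.0 * trigamma_inverse(evar)
    s0_sq = float(
        np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    )
    return EBayesPrior(d0=d0, s0_sq=s0_sq)


# ---------------------------------------------------------------------------
# moderated t and contrasts


def contrast_vector(
    X_columns: Sequence[str], strain: str
) -> pd.Series:
    """Treated-minus-mock contrast for one strain over the fit coefficients."""
    c = pd.Series(0.0, index=list(X_columns))
    drug, mock = f"g_{strain}_drug", f"g_{strain}_mock"
    for name in (drug, mock):
        if name not in c.index:
            raise ConfigError(f"contrast coefficient {name!r} not in design")
    c[drug] = 1.0
    c[mock] = -1.0
    return c


def moderated_t(
    fit: LinearFit,
    prior: EBayesPrior,
    contrast: pd.Series,
    strain: str | None = None,
) -> pd.DataFrame:
    """Moderated t test of one contrast for every peptide.

    With d0 = 0 this reduces to the classical t statistic on the contrast;
    with d0 = inf the variance is fully shrunk to s0^2 and the reference
    distribution becomes normal.
    """
    missing = [c for c in contrast.index if c not in fit.coef.columns]
    if missing:
        raise ConfigError(f"contrast names unknown coefficients: {missing}")
    c = contrast.reindex(fit.coef.columns, fill_value=0.0).to_numpy()
    logfc = fit.coef.to_numpy() @ c
    var_unscaled = float(c @ fit.cov_unscaled @ c)
    d = fit.df_resid
    s2 = fit.s2.to_numpy()
    if np.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = float("inf")
    else:
        s2_post = (prior.d0 * prior.s0_sq + d * s2) / (prior.d0 + d)
        df_total = prior.d0 + d
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / np.sqrt(var_unscaled * s2_post)
    t = np.where((logfc == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    out = pd.DataFrame(
        {
            "peptide_id": fit.coef.index,
            "logFC": logfc,
            "FC": np.exp2(logfc),
            "t_mod": t,
            "df_total": df_total,
            "p": p,
        }
    )
    if strain is not None:
        out.insert(1, "strain", strain)
    return out


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def run_contrasts(
    fit: LinearFit,
    prior: EBayesPrior,
    strains: Sequence[str],
) -> pd.DataFrame:
    """Per-strain treated-vs-mock moderated tests with per-strain BH families."""
    frames = []
    for strain in strains:
        c = contrast_vector(fit.coef.columns, strain)
        res = moderated_t(fit, prior, c, strain=strain)
        res["p_adj"] = bh_adjust(res["p"].to_numpy())
        frames.append(res)
    return pd.concat(frames, ignore_index=True)
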