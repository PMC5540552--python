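"""Metabolite handling rules and covariate residualization.

Metabolite measures arrive as non-negative concentrations where a zero
means "below detection" (replaced by the per-measure minimum positive
value), quality-rejected entries and undefined derived ratios are
missing, and all present values are then log2 transformed. Missing
values are carried as NaN and handled complete-case per measure
downstream; they are never silently zero.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger("immunomap.preprocess")


def replace_zeros(values: pd.DataFrame) -> pd.DataFrame:
    """Replace zeros by the per-measure minimum positive value.

    Columns with no positive value are dropped with a warning. Idempotent:
    the output contains no zeros among present values.
    """
    out = values.copy()
    dropped = []
    for col in out.columns:
        x = out[col]
        pos = x[x > 0]
        if pos.empty:
            dropped.append(col)
            continue
        out.loc[x == 0, col] = pos.min()
    if dropped:
        msg = f"dropping {len(dropped)} measure(s) with no positive values: {dropped}"
        logger.warning(msg)
        warnings.warn(msg)
        out = out.drop(columns=dropped)
    return out


def clean_metabolites(raw: pd.DataFrame,
                      rejected: pd.DataFrame | None = None,
                      log2: bool = True) -> pd.DataFrame:
    """Apply the metabolite cleaning rules: zero -> per-measure minimum
    positive value, rejected -> missing, then log2 of present values.

    Parameters
    ----------
    raw : samples x measures, non-negative where present (NaN = missing).
    rejected : optional boolean mask (same shape) of quality-rejected
        entries, set to missing before the zero rule.
    log2 : apply the final log2 transform (skip to inspect the
        concentration-scale intermediate).
    """
    vals = raw.copy().astype(float)
    present = vals.notna()
    if (vals[present] < 0).any().any():
        raise ValueError("metabolite concentrations must be non-negative")
    if rejected is not None:
        rej = rejected.reindex_like(vals).fillna(False).astype(bool)
        vals = vals.mask(rej)
    vals = replace_zeros(vals)
    if log2:
        vals = np.log2(vals)
    return vals


def residualize(matrix: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Replace each column of ``matrix`` (samples x variables) by its
    least-squares residuals on an intercept plus ``covariates``.

    Residuals are orthogonal to the covariates to numerical precision.
    Missing values in a variable are preserved: the fit for that variable
    uses its complete cases only.
    """
    cov = covariates.loc[matrix.index]
    if cov.isna().any().any():
        raise ValueError("covariates must be complete for all samples")
    X = np.column_stack([np.ones(len(cov))] + [cov[c].to_numpy(float) for c in cov.columns])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = []
        kept = [0]
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, kept + [j]]) == len(kept):
                bad.append(cov.columns[j - 1])
            else:
                kept.append(j)
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")

    Y = matrix.to_numpy(float)
    out = np.full_like(Y, np.nan)
    complete = ~np.isnan(Y)
    all_complete = complete.all(axis=0)
    if all_complete.any():
        beta, *_ = np.linalg.lstsq(X, Y[:, all_complete], rcond=None)
        out[:, all_complete] = Y[:, all_complete] - X @ beta
    for j in np.where(~all_complete)[0]:
        m = complete[:, j]
        if m.sum() <= X.shape[1]:
            continue  # too few cases; stays NaN
        beta, *_ = np.linalg.lstsq(X[m], Y[m, j], rcond=None)
        out[m, j] = Y[m, j] - X[m] @ beta
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def exclusion_filter(samples, flags: pd.DataFrame) -> pd.Index:
    """Return the samples with neither exclusion flag set.

    ``flags`` carries boolean columns ``lipid_med`` (on cholesterol-lowering
    medication) and ``pregnant``; counts removed per reason are logged.
    """
    samples = pd.Index(samples)
    unknown = flags.index.difference(samples)
    if len(unknown):
        raise ValueError(f"unknown sample IDs in flags: {list(unknown)}")
    fl = flags.reindex(samples).fillna(False).astype(bool)
    for col in ("lipid_med", "pregnant"):
        if col not in fl.columns:
            fl[col] = False
    n_med = int(fl["lipid_med"].sum())
    n_preg = int((fl["pregnant"] & ~fl["lipid_med"]).sum())
    keep = samples[~(fl["lipid_med"] | fl["pregnant"])]
    logger.info("exclusion_filter: removed %d on lipid medication, %d pregnant; %d retained",
                n_med, n_preg, len(keep))
    if len(keep) == 0:
        warnings.warn("all samples excluded")
    return keep


def scale_to_sd(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each column to standard-deviation units (mean 0, SD 1),
    complete-case per column; applied per dataset after exclusions."""
    out = matrix.astype(float).copy()
    for col in out.columns:
        x = out[col]
        sd = x.std(skipna=True)
        if sd == 0 or np.isnan(sd):
            raise ValueError(f"cannot SD-scale constant column {col!r}")
        out[col] = (x - x.mean(skipna=True)) / sd
    return out
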