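"""Module eigengene-metabolite association with cross-cohort meta-analysis.

Per cohort, each module eigengene is regressed on each metabolite
measure (both scaled to SD units) adjusting for age, sex and, when
available, oral-contraceptive use; per-(module, measure) estimates are
combined across cohorts by fixed-effects inverse-variance meta-analysis,
the meta p-values are BH-FDR corrected within each module, and
associations are flagged at a Bonferroni-tightened threshold
(0.05 / number of modules = 6.25e-3 for 8 modules). Missing metabolite
values are excluded complete-case per measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("immunomap.associations")

DEFAULT_THRESHOLD = 6.25e-3


def _ols_single(y: np.ndarray, x: np.ndarray, covars: np.ndarray
                ) -> tuple[float, float, float, int]:
    """OLS of y on [1, x, covars]; returns (beta_x, SE, two-sided t p, n)."""
    n = len(y)
    X = np.column_stack([np.ones(n), x] + ([covars] if covars.size else []))
    k = X.shape[1]
    df = n - k
    if df < 1:
        raise ValueError("not enough complete cases for the model")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = resid @ resid / df
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = float(np.sqrt(sigma2 * XtX_inv[1, 1]))
    b = float(beta[1])
    if se == 0:
        return b, se, 0.0 if b != 0 else 1.0, n
    t = b / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return b, se, float(p), n


def fit_association(eigengene: pd.Series, measure: pd.Series,
                    covariates: pd.DataFrame | None = None
                    ) -> tuple[float, float, float, int]:
    """Regress the SD-scaled eigengene on the SD-scaled measure plus covariates.

    Complete cases only (pairwise missing removal); returns the measure's
    coefficient, its standard error, the two-sided t p-value (residual
    degrees of freedom), and the n used.
    """
    df = pd.DataFrame({"y": eigengene, "x": measure})
    cov_cols = []
    if covariates is not None and covariates.shape[1] > 0:
        for c in covariates.columns:
            df[c] = covariates[c]
            cov_cols.append(c)
    df = df.dropna()
    n = len(df)
    n_params = 2 + len(cov_cols)
    if n < max(10, n_params + 2):
        raise ValueError(f"only {n} complete cases for {n_params} parameters")
    y = df["y"].to_numpy(float)
    x = df["x"].to_numpy(float)
    y = (y - y.mean()) / y.std(ddof=1)
    x = (x - x.mean()) / x.std(ddof=1)
    covars = df[cov_cols].to_numpy(float) if cov_cols else np.empty((n, 0))
    return _ols_single(y, x, covars)


def inverse_variance_meta(estimates) -> tuple[float, float, float, float]:
    """Fixed-effects inverse-variance combination of (beta, SE) pairs.

    Returns (beta_meta, SE_meta, z, two-sided normal p).
    """
    estimates = list(estimates)
    if len(estimates) < 1:
        raise ValueError("at least one study is required")
    betas = np.array([e[0] for e in estimates], float)
    ses = np.array([e[1] for e in estimates], float)
    if (ses <= 0).any():
        raise ValueError("all standard errors must be positive")
    w = 1.0 / ses ** 2
    beta_meta = float((w * betas).sum() / w.sum())
    se_meta = float(1.0 / np.sqrt(w.sum()))
    z = beta_meta / se_meta
    p = 2.0 * stats.norm.sf(abs(z))
    return beta_meta, se_meta, float(z), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * m / (rank + 1))
        adjusted[i] = running
    return adjusted


def module_metabolite_scan(cohorts: list[dict], threshold: float = DEFAULT_THRESHOLD
                           ) -> pd.DataFrame:
    """Meta-analytic module-metabolite scan over >= 1 cohorts.

    Each cohort is a dict with keys ``eigengenes`` (samples x modules),
    ``metabolites`` (samples x measures) and optional ``covariates``
    (samples x columns; columns entirely absent in a cohort are simply
    not used there). All cohorts must share the same module/measure grid.

    Returns one row per (module, measure) with per-cohort beta/SE/p/n,
    meta beta/SE/z/p, the within-module BH-adjusted meta p and the
    significance flag at ``threshold``.
    """
    if not cohorts:
        raise ValueError("at least one cohort is required")
    modules = list(cohorts[0]["eigengenes"].columns)
    measures = list(cohorts[0]["metabolites"].columns)
    for i, c in enumerate(cohorts[1:], start=2):
        miss_mod = set(modules) ^ set(c["eigengenes"].columns)
        miss_meas = set(measures) ^ set(c["metabolites"].columns)
        if miss_mod or miss_meas:
            raise ValueError(f"cohort {i} grid mismatch; differing cells: "
                             f"modules {sorted(miss_mod)}, measures {sorted(miss_meas)}")
    cov_cols = [set(c["covariates"].columns) if c.get("covariates") is not None else set()
                for c in cohorts]
    union = set().union(*cov_cols)
    for i, cols in enumerate(cov_cols, start=1):
        if cols != union:
            logger.info("cohort %d lacks covariate(s) %s; dropped for that cohort",
                        i, sorted(union - cols))
    rows = []
    for module in modules:
        for measure in measures:
            per = []
            for c in cohorts:
                cov = c.get("covariates")
                b, se, p, n = fit_association(c["eigengenes"][module],
                                              c["metabolites"][measure], cov)
                per.append((b, se, p, n))
            bm, sem, z, pm = inverse_variance_meta([(b, se) for b, se, _, _ in per])
            row = {"module": module, "measure": measure,
                   "meta_beta": bm, "meta_se": sem, "meta_z": z, "meta_p": pm}
            for i, (b, se, p, n) in enumerate(per, start=1):
                row.update({f"beta_{i}": b, f"se_{i}": se, f"p_{i}": p, f"n_{i}": n})
            rows.append(row)
    result = pd.DataFrame(rows)
    result["meta_p_adj"] = np.nan
    for module in modules:
        mask = result["module"] == module
        result.loc[mask, "meta_p_adj"] = bh_fdr(result.loc[mask, "meta_p"].to_numpy())
    result["significant"] = result["meta_p_adj"] < threshold
    n_sig = int(result["significant"].sum())
    logger.info("module_metabolite_scan: %d/%d significant at %g", n_sig, len(result),
                threshold)
    return result


def sensitivity_adjust(cohorts: list[dict], extra_covariates: dict[int, pd.DataFrame],
                       threshold: float = DEFAULT_THRESHOLD,
                       baseline: pd.DataFrame | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-run the scan with extra covariates in selected cohorts and compare.

    ``extra_covariates`` maps a cohort index (0-based) to a samples x
    columns frame appended to that cohort's covariates (e.g. leukocyte or
    platelet counts, or a single gene's expression). Returns the adjusted
    scan and a comparison table with per-(module, measure) status in
    {maintained, lost, gained, absent}.
    """
    if baseline is None:
        baseline = module_metabolite_scan(cohorts, threshold=threshold)
    if not extra_covariates:
        comparison = baseline[["module", "measure", "significant"]].copy()
        comparison["status"] = np.where(baseline["significant"], "maintained", "absent")
        return baseline, comparison
    adjusted_cohorts = []
    for i, c in enumerate(cohorts):
        c2 = dict(c)
        if i in extra_covariates:
            extra = extra_covariates[i]
            missing = extra.index.symmetric_difference(c["eigengenes"].index)
            if len(missing):
                raise ValueError(f"extra covariate samples mismatch in cohort {i}")
            base_cov = c.get("covariates")
            c2["covariates"] = extra if base_cov is None else base_cov.join(extra)
        adjusted_cohorts.append(c2)
    adjusted = module_metabolite_scan(adjusted_cohorts, threshold=threshold)
    merged = baseline.merge(adjusted, on=["module", "measure"],
                            suffixes=("_before", "_after"))
    status = np.select(
        [merged["significant_before"] & merged["significant_after"],
         merged["significant_before"] & ~merged["significant_after"],
         ~merged["significant_before"] & merged["significant_after"]],
        ["maintained", "lost", "gained"], default="absent")
    comparison = merged[["module", "measure"]].copy()
    comparison["status"] = status
    for s in ("maintained", "lost", "gained"):
        logger.info("sensitivity_adjust: %s = %d", s, int((status == s).sum()))
    return adjusted, comparison


def longitudinal_stability(scan_t1: pd.DataFrame, scan_t2: pd.DataFrame,
                           threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Associations significant at both time points.

    Both scans must cover the same (module, measure) grid; returns the
    grid with per-time significance and the stable flag, with per-module
    stable counts logged.
    """
    g1 = set(zip(scan_t1["module"], scan_t1["measure"]))
    g2 = set(zip(scan_t2["module"], scan_t2["measure"]))
    if g1 != g2:
        raise ValueError(f"grid mismatch; cells not shared: {sorted(g1 ^ g2)[:10]}")
    s1 = scan_t1.set_index(["module", "measure"])["meta_p_adj"] < threshold
    s2 = scan_t2.set_index(["module", "measure"])["meta_p_adj"] < threshold
    out = pd.DataFrame({"significant_t1": s1, "significant_t2": s2.reindex(s1.index)})
    out["stable"] = out["significant_t1"] & out["significant_t2"]
    for module, grp in out.groupby(level="module"):
        logger.info("longitudinal_stability %s: %d stable", module, int(grp["stable"].sum()))
    return out.reset_index()
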