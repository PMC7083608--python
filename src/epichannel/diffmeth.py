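"""Per-CpG differential methylation testing between two groups.

Each CpG site is tested with a binomial logistic regression on the
(methylated, coverage) counts of the samples,

    logit(pi_j) = b0 + b1 * group_j (+ family indicators),

fit by iteratively reweighted least squares.  Significance comes from the
likelihood-ratio (deviance) chi-square with one degree of freedom between
the full model and the null model without the group term — for two groups
and no covariate this is exactly the pooled 2x2 G-test.  The family
covariate absorbs clutch effects in the split-clutch experimental design
and is attached automatically whenever both groups are experimental.

P-values are adjusted with Benjamini–Hochberg by default; the adjuster is
pluggable so alternative q-value methods can be used behind the same
interface.  A site is a DMS when q < ``alpha_q`` (strict) and the absolute
weighted mean methylation difference is >= ``min_diff_pct`` percentage
points, where the weighted group level is the coverage-weighted pooled
proportion ``100 * sum(methylated) / sum(coverage)``.
"""

from __future__ import annotations

import logging
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AnalysisConfig, EXPERIMENTAL, MethylationMatrix, SampleSheet

logger = logging.getLogger(__name__)

__all__ = [
    "group_levels",
    "site_lrt",
    "adjust_pvalues",
    "call_dms",
    "compare_groups",
]

_ETA_CAP = 30.0
_MAX_ITER = 100
_DEV_TOL = 1e-8


def group_levels(
    m: MethylationMatrix,
    sheet: SampleSheet,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Coverage-weighted group methylation levels (%) and their difference.

    ``meth_diff`` is ``level_b - level_a`` in percentage points; rows where
    a group has no present sample get NaN levels.
    """
    ia = m.sample_index([s for s in sheet.samples_in_group(group_a) if s in m.samples])
    ib = m.sample_index([s for s in sheet.samples_in_group(group_b) if s in m.samples])

    def level(idx: np.ndarray) -> np.ndarray:
        cov = m.coverage[:, idx].sum(axis=1).astype(float)
        meth = m.methylated[:, idx].sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov > 0, 100.0 * meth / np.maximum(cov, 1), np.nan)

    la, lb = level(ia), level(ib)
    return pd.DataFrame({
        "chrom": m.chrom,
        "pos": m.pos,
        "level_a": la,
        "level_b": lb,
        "meth_diff": lb - la,
    })


def _binomial_deviance(y: np.ndarray, n: np.ndarray, mu: np.ndarray) -> float:
    """2 * sum[y ln(y/mu) + (n-y) ln((n-y)/(n-mu))] with 0 ln 0 = 0."""
    with np.errstate(invalid="ignore", divide="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = np.where(n - y > 0, (n - y) * np.log((n - y) / (n - mu)), 0.0)
    return float(2.0 * (t1 + t2).sum())


def _fit_binomial_glm(
    X: np.ndarray, y: np.ndarray, n: np.ndarray
) -> tuple[float, bool, bool]:
    """IRLS fit of a binomial logistic GLM.

    Returns (deviance, converged, separation_capped).  The linear
    predictor is capped at +/-30 so complete separation yields a finite,
    numerically saturated fit instead of divergence.
    """
    frac = np.clip((y + 0.5) / (n + 1.0), 1e-6, 1 - 1e-6)
    eta = np.log(frac / (1 - frac))
    dev_prev = np.inf
    capped = False
    converged = False
    for _ in range(_MAX_ITER):
        eta = np.clip(eta, -_ETA_CAP, _ETA_CAP)
        capped = capped or bool((np.abs(eta) >= _ETA_CAP).any())
        p = 1.0 / (1.0 + np.exp(-eta))
        mu = n * p
        w = n * p * (1 - p)
        w = np.maximum(w, 1e-12)
        z = eta + (y - mu) / w
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        eta = X @ beta
        dev = _binomial_deviance(y, n, n * (1.0 / (1.0 + np.exp(-np.clip(eta, -_ETA_CAP, _ETA_CAP)))))
        if abs(dev_prev - dev) < _DEV_TOL:
            converged = True
            dev_prev = dev
            break
        dev_prev = dev
    return dev_prev, converged, capped


def site_lrt(
    methylated: np.ndarray,
    coverage: np.ndarray,
    group: np.ndarray,
    families: Sequence[str] | None = None,
) -> tuple[float, int, float, str]:
    """Likelihood-ratio test of the group effect at one CpG site.

    Parameters
    ----------
    methylated, coverage
        Per-sample counts; only present samples should be passed.
    group
        0/1 indicator per sample.
    families
        Optional family labels; encoded as drop-first dummy columns in
        both the full and null design.

    Returns
    -------
    (lrt_stat, df, p, flag) where flag is '' or one of 'separation',
    'nonconvergence', 'confounded'.  p is NaN for the latter two flags.
    """
    y = np.asarray(methylated, dtype=float)
    n = np.asarray(coverage, dtype=float)
    g = np.asarray(group, dtype=float)
    if len(np.unique(g)) < 2:
        raise ValueError("both groups must be represented")
    if min((g == 0).sum(), (g == 1).sum()) < 2:
        raise ValueError("need >= 2 samples per group")
    cols_null: list[np.ndarray] = [np.ones_like(g)]
    if families is not None:
        fam = pd.Categorical(list(families))
        for level in fam.categories[1:]:
            cols_null.append((np.asarray(fam) == level).astype(float))
    X_null = np.column_stack(cols_null)
    X_full = np.column_stack(cols_null + [g])
    if families is not None:
        if np.linalg.matrix_rank(X_full) <= np.linalg.matrix_rank(X_null):
            return np.nan, 1, np.nan, "confounded"
    dev_full, conv_full, cap_full = _fit_binomial_glm(X_full, y, n)
    dev_null, conv_null, _ = _fit_binomial_glm(X_null, y, n)
    if not (conv_full and conv_null):
        return np.nan, 1, np.nan, "nonconvergence"
    stat = max(dev_null - dev_full, 0.0)
    p = float(stats.chi2.sf(stat, df=1))
    return stat, 1, p, ("separation" if cap_full else "")


def adjust_pvalues(
    p_list: Sequence[float],
    method: str | Callable[[np.ndarray], np.ndarray] = "bh",
) -> np.ndarray:
    """Multiple-testing adjustment; Benjamini–Hochberg step-up by default.

    NaN entries propagate as NaN and are excluded from the adjustment.
    ``method`` may be a callable mapping a p array to a q array, so other
    q-value estimators plug in behind the same interface.
    """
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        return p.copy()
    if callable(method):
        return np.asarray(method(p), dtype=float)
    if method.lower() not in {"bh", "fdr_bh"}:
        raise ValueError(f"unknown adjustment method {method!r}")
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        from statsmodels.stats.multitest import multipletests

        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def call_dms(results: pd.DataFrame, alpha_q: float, min_diff_pct: float) -> np.ndarray:
    """DMS mask: q strictly below alpha AND |weighted diff| >= threshold."""
    q = results["q"].to_numpy(dtype=float)
    diff = results["meth_diff"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        return (q < alpha_q) & (np.abs(diff) >= min_diff_pct)


def compare_groups(
    m: MethylationMatrix,
    sheet: SampleSheet,
    group_a: str,
    group_b: str,
    config: AnalysisConfig,
    adjust: str | Callable[[np.ndarray], np.ndarray] = "bh",
) -> pd.DataFrame:
    """Full two-group comparison over all sites of a filtered matrix.

    Orchestrates weighted levels -> per-site LRT (family covariate iff both
    groups are experimental) -> BH adjustment -> DMS call.  The sign
    convention is ``meth_diff = group_b - group_a`` (reference, target);
    the group names are recorded in ``DataFrame.attrs``.
    """
    sa = [s for s in sheet.samples_in_group(group_a) if s in m.samples]
    sb = [s for s in sheet.samples_in_group(group_b) if s in m.samples]
    use_family = (
        sheet.cohort_of_group(group_a) == EXPERIMENTAL
        and sheet.cohort_of_group(group_b) == EXPERIMENTAL
    )
    ia = m.sample_index(sa)
    ib = m.sample_index(sb)
    idx = np.concatenate([ia, ib])
    group = np.concatenate([np.zeros(len(ia)), np.ones(len(ib))])
    fams = (
        [sheet.family_of(s) for s in sa] + [sheet.family_of(s) for s in sb]
        if use_family else None
    )

    levels = group_levels(m, sheet, group_a, group_b)
    cov = m.coverage[:, idx]
    meth = m.methylated[:, idx]
    present = cov > 0

    n_sites = m.n_sites
    stat = np.full(n_sites, np.nan)
    pval = np.full(n_sites, np.nan)
    flags = np.full(n_sites, "", dtype=object)
    ga_mask = group == 0
    for i in range(n_sites):
        pres = present[i]
        if pres[ga_mask].sum() < 2 or pres[~ga_mask].sum() < 2:
            flags[i] = "insufficient"
            continue
        fam_i = [f for f, keep in zip(fams, pres) if keep] if fams else None
        s, _, p, fl = site_lrt(meth[i, pres], cov[i, pres], group[pres], fam_i)
        stat[i], pval[i], flags[i] = s, p, fl

    out = levels.copy()
    out["lrt_stat"] = stat
    out["df"] = 1
    out["p"] = pval
    out["q"] = adjust_pvalues(pval, adjust)
    out["flag"] = flags
    out["is_dms"] = call_dms(out, config.alpha_q, config.min_diff_pct)
    out.attrs["group_a"] = group_a
    out.attrs["group_b"] = group_b
    out.attrs["family_covariate"] = use_family
    n_flag = int((flags != "").sum())
    if n_flag:
        logger.info(
            "compare_groups %s vs %s: %d flagged site(s): %s",
            group_a, group_b, n_flag,
            dict(pd.Series(flags[flags != ""]).value_counts()),
        )
    return out
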