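"""Two-population Weir–Cockerham FST, windowed means, and the
delta.mean.FST randomization test.

Per-SNP differentiation uses the Weir & Cockerham (1984) theta estimator
``a / (a + b + c)`` built from the among-population (a), among-individual
(b) and within-individual (c) variance components, computed from sample
sizes, alt-allele frequencies and observed heterozygosities of the two
populations.  Negative estimates are retained (not floored at zero), the
convention of vcftools' per-site output; a site monomorphic overall has an
undefined denominator and yields NaN.

The windowed statistic is the arithmetic mean of per-SNP estimates within
+/- ``halfwin_bp`` of a focal CpG, after setting genotypes with depth
below ``min_dp`` missing and discarding SNPs whose joint missing fraction
exceeds ``max_missing``.  The ratio-of-sums estimator
``sum(a) / sum(a+b+c)`` is also available but the arithmetic mean is
primary.

delta.mean.FST = mean over expected-direction sites minus mean over
opposite-direction sites, with a one-tailed randomization p (H1: opposite
sites are more differentiated, i.e. the delta is negative): the pooled
values are randomly reassigned to the two group sizes and
``p = #(delta* < delta_obs) / n_boot``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import VariantTable

logger = logging.getLogger(__name__)

__all__ = [
    "wc_fst_components",
    "wc_fst_site",
    "per_snp_fst",
    "mean_fst_window",
    "FstWindowResult",
    "delta_mean_fst_test",
]


def wc_fst_components(gt1: np.ndarray, gt2: np.ndarray) -> tuple[float, float, float]:
    """Weir–Cockerham variance components (a, b, c) for one biallelic site.

    ``gt1``/``gt2`` are alt-allele dosages (0/1/2) of the *genotyped*
    diploid individuals of each population.
    """
    gt1 = np.asarray(gt1, dtype=float)
    gt2 = np.asarray(gt2, dtype=float)
    if len(gt1) == 0 or len(gt2) == 0:
        raise ValueError("each population needs >= 1 genotyped individual")
    r = 2.0
    n_i = np.array([len(gt1), len(gt2)], dtype=float)
    p_i = np.array([gt1.mean() / 2.0, gt2.mean() / 2.0])
    h_i = np.array([(gt1 == 1).mean(), (gt2 == 1).mean()])
    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1.0)
    pbar = (n_i * p_i).sum() / (r * nbar)
    s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1.0) * nbar)
    hbar = (n_i * h_i).sum() / (r * nbar)
    if nbar <= 1 or nc <= 0:
        return np.nan, np.nan, np.nan
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
    )
    c = hbar / 2.0
    return float(a), float(b), float(c)


def wc_fst_site(gt1: np.ndarray, gt2: np.ndarray) -> float:
    """Per-site theta-hat = a / (a + b + c); NaN when the site is monomorphic."""
    a, b, c = wc_fst_components(gt1, gt2)
    denom = a + b + c
    if not np.isfinite(denom) or denom == 0:
        return np.nan
    return a / denom


def per_snp_fst(
    v: VariantTable,
    pop1: Sequence[str],
    pop2: Sequence[str],
    min_dp: int = 0,
    max_missing: float = 1.0,
) -> np.ndarray:
    """Per-SNP theta-hat with depth masking and a joint missingness filter.

    Genotypes with DP < ``min_dp`` (when DP is recorded) are set missing;
    SNPs whose missing fraction across both populations exceeds
    ``max_missing`` or with a fully missing population give NaN.
    """
    i1 = v.sample_index(pop1)
    i2 = v.sample_index(pop2)
    out = np.full(v.n_variants, np.nan)
    for k in range(v.n_variants):
        g1 = v.gt[k, i1].astype(float)
        g2 = v.gt[k, i2].astype(float)
        if min_dp > 0:
            d1 = v.dp[k, i1]
            d2 = v.dp[k, i2]
            g1 = np.where((d1 >= 0) & (d1 < min_dp), -1, g1)
            g2 = np.where((d2 >= 0) & (d2 < min_dp), -1, g2)
        miss = float((g1 < 0).sum() + (g2 < 0).sum()) / (len(g1) + len(g2))
        if miss > max_missing:
            continue
        g1 = g1[g1 >= 0]
        g2 = g2[g2 >= 0]
        if len(g1) == 0 or len(g2) == 0:
            continue
        out[k] = wc_fst_site(g1, g2)
    return out


@dataclass
class FstWindowResult:
    """Mean per-SNP FST in a window around one focal CpG site."""

    chrom: str
    pos: int
    mean_fst: float
    weighted_fst: float
    n_snps: int


def mean_fst_window(
    chrom: str,
    pos: int,
    v: VariantTable,
    pop1: Sequence[str],
    pop2: Sequence[str],
    halfwin_bp: int,
    max_missing: float,
    min_dp: int,
) -> FstWindowResult:
    """Arithmetic mean of retained per-SNP estimates in ``pos +/- halfwin``.

    Negative estimates are retained.  With no retained SNP the means are
    NaN and ``n_snps`` is 0.  ``weighted_fst`` is the secondary
    ratio-of-sums estimator over the same SNPs.
    """
    in_win = (v.chrom == chrom) & (v.pos >= pos - halfwin_bp) & (v.pos <= pos + halfwin_bp)
    sub = v.subset(in_win)
    theta = per_snp_fst(sub, pop1, pop2, min_dp=min_dp, max_missing=max_missing)
    ok = ~np.isnan(theta)
    if not ok.any():
        return FstWindowResult(chrom, pos, np.nan, np.nan, 0)
    # ratio-of-sums needs the components; recompute for retained SNPs
    i1 = sub.sample_index(pop1)
    i2 = sub.sample_index(pop2)
    num = den = 0.0
    for k in np.flatnonzero(ok):
        g1 = sub.gt[k, i1].astype(float)
        g2 = sub.gt[k, i2].astype(float)
        if min_dp > 0:
            g1 = np.where((sub.dp[k, i1] >= 0) & (sub.dp[k, i1] < min_dp), -1, g1)
            g2 = np.where((sub.dp[k, i2] >= 0) & (sub.dp[k, i2] < min_dp), -1, g2)
        a, b, c = wc_fst_components(g1[g1 >= 0], g2[g2 >= 0])
        if np.isfinite(a):
            num += a
            den += a + b + c
    weighted = num / den if den != 0 else np.nan
    return FstWindowResult(
        chrom, pos, float(np.mean(theta[ok])), float(weighted), int(ok.sum())
    )


@dataclass
class DeltaFstResult:
    delta: float
    p: float
    n_expected: int
    n_opposite: int
    n_boot: int


def delta_mean_fst_test(
    expected_values: Sequence[float],
    opposite_values: Sequence[float],
    n_boot: int,
    seed: int | np.random.Generator,
    mode: str = "permutation",
    plus_one_correction: bool = False,
) -> DeltaFstResult:
    """One-tailed randomization test of expected minus opposite mean FST.

    The null distribution reassigns the pooled window means at random to
    the two group sizes (``mode='permutation'``, without replacement, the
    default) or resamples with replacement (``mode='bootstrap'``).
    ``p = #(delta* < delta_obs) / n_boot`` exactly, which can be 0; the
    (count+1)/(n_boot+1) correction is available via
    ``plus_one_correction``.
    """
    exp = np.asarray(expected_values, dtype=float)
    opp = np.asarray(opposite_values, dtype=float)
    exp = exp[~np.isnan(exp)]
    opp = opp[~np.isnan(opp)]
    if len(exp) == 0 or len(opp) == 0:
        raise ValueError("both groups must be nonempty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    delta_obs = float(exp.mean() - opp.mean())
    pooled = np.concatenate([exp, opp])
    n_e = len(exp)
    count = 0
    for _ in range(n_boot):
        if mode == "permutation":
            perm = rng.permutation(pooled)
        elif mode == "bootstrap":
            perm = rng.choice(pooled, size=len(pooled), replace=True)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        d = perm[:n_e].mean() - perm[n_e:].mean()
        if d < delta_obs:
            count += 1
    p = (count + 1) / (n_boot + 1) if plus_one_correction else count / n_boot
    return DeltaFstResult(delta_obs, float(p), len(exp), len(opp), n_boot)


def fst_window_table(
    sites: pd.DataFrame,
    v: VariantTable,
    pop1: Sequence[str],
    pop2: Sequence[str],
    halfwin_bp: int,
    max_missing: float,
    min_dp: int,
) -> pd.DataFrame:
    """Window means for every row of a (chrom, pos[, direction]) table."""
    rows = []
    for _, r in sites.iterrows():
        res = mean_fst_window(
            str(r["chrom"]), int(r["pos"]), v, pop1, pop2,
            halfwin_bp, max_missing, min_dp,
        )
        row = {
            "chrom": res.chrom, "pos": res.pos,
            "mean_fst": res.mean_fst, "weighted_fst": res.weighted_fst,
            "n_snps": res.n_snps,
        }
        if "direction" in sites.columns:
            row["direction"] = r["direction"]
        rows.append(row)
    return pd.DataFrame(rows)
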