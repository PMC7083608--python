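"""Genomic-feature annotation of CpG sites and per-gene response tests.

Each site is assigned one of four features with the precedence
promoter > exon > intron > intergenic across all overlapping genes.  The
promoter is ``promoter_up`` bp upstream to ``promoter_down`` bp downstream
of the TSS (strand-aware, 1-based inclusive).  The nearest TSS is found by
absolute distance (ties broken toward the lexicographically smallest gene
id); a site is associated with a gene when it lies inside the gene span or
within ``tss_assoc_bp`` of the TSS.  Signed TSS distances are negative
upstream of the TSS in the gene's reading direction.

Two tests accompany the annotation:

* a chi-square goodness-of-fit of the DMS feature counts against the
  feature proportions of all tested CpG sites, and
* a per-gene Fisher exact test of whether the pop-DMS associated with one
  gene are nonrandomly distributed over the categories inducible / stable
  / inconclusive relative to the remaining pop-DMS, by exhaustive
  enumeration of 2x3 tables with fixed margins (Monte-Carlo fallback for
  astronomically large margins).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .io_formats import GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureCall",
    "annotate_feature",
    "annotate_sites",
    "associate_gene",
    "feature_distribution_test",
    "fisher_exact_2xk",
    "gene_response_table",
]

PROMOTER = "promoter"
EXON = "exon"
INTRON = "intron"
INTERGENIC = "intergenic"
FEATURES = (PROMOTER, EXON, INTRON, INTERGENIC)
_PRECEDENCE = {PROMOTER: 0, EXON: 1, INTRON: 2, INTERGENIC: 3}


@dataclass(frozen=True)
class FeatureCall:
    """Feature assignment of one CpG site."""

    chrom: str
    pos: int
    feature: str
    gene_id: str | None
    tss_distance: float  # signed, negative = upstream; NaN if no gene on chrom


def _promoter_window(g: GeneModel, up: int, down: int) -> tuple[int, int]:
    if g.strand == "+":
        return g.tss - up, g.tss + down
    return g.tss - down, g.tss + up


def _signed_tss_distance(g: GeneModel, pos: int) -> int:
    """Distance from TSS in reading direction; negative = upstream."""
    return pos - g.tss if g.strand == "+" else g.tss - pos


def annotate_feature(
    chrom: str,
    pos: int,
    genes: Sequence[GeneModel],
    promoter_up: int,
    promoter_down: int,
    tss_assoc_bp: int = 10000,
) -> FeatureCall:
    """Classify one site by the promoter > exon > intron > intergenic rule.

    The result is independent of the input order of ``genes``: the feature
    is the highest-precedence one over all overlapping genes, and the
    associated gene is chosen deterministically (in-gene or nearest-TSS
    within ``tss_assoc_bp``, ties toward the smaller gene id).
    """
    same_chrom = [g for g in genes if g.chrom == chrom]
    best_feature = INTERGENIC
    feature_genes: dict[str, list[GeneModel]] = {PROMOTER: [], EXON: [], INTRON: []}
    for g in same_chrom:
        ps, pe = _promoter_window(g, promoter_up, promoter_down)
        if ps <= pos <= pe:
            feature_genes[PROMOTER].append(g)
        if g.start <= pos <= g.end:
            if any(s <= pos <= e for s, e in g.exons):
                feature_genes[EXON].append(g)
            else:
                feature_genes[INTRON].append(g)
    for f in (PROMOTER, EXON, INTRON):
        if feature_genes[f]:
            best_feature = f
            break

    nearest: GeneModel | None = None
    nearest_dist = np.inf
    for g in sorted(same_chrom, key=lambda x: x.gene_id):
        d = abs(_signed_tss_distance(g, pos))
        if d < nearest_dist:
            nearest, nearest_dist = g, d

    in_gene_genes = feature_genes[EXON] + feature_genes[INTRON]
    if in_gene_genes:
        host = min(
            in_gene_genes,
            key=lambda g: (abs(_signed_tss_distance(g, pos)), g.gene_id),
        )
        return FeatureCall(
            chrom, pos, best_feature, host.gene_id,
            float(_signed_tss_distance(host, pos)),
        )
    if nearest is None:
        return FeatureCall(chrom, pos, INTERGENIC, None, np.nan)
    dist = float(_signed_tss_distance(nearest, pos))
    gene_id = nearest.gene_id if nearest_dist <= tss_assoc_bp else None
    return FeatureCall(chrom, pos, best_feature, gene_id, dist)


def associate_gene(call: FeatureCall, tss_assoc_bp: int) -> str | None:
    """Gene id iff the site is in-gene or within ``tss_assoc_bp`` of the TSS."""
    if call.gene_id is None:
        return None
    if call.feature in (EXON, INTRON):
        return call.gene_id
    if np.isnan(call.tss_distance) or abs(call.tss_distance) > tss_assoc_bp:
        return None
    return call.gene_id


def annotate_sites(
    sites: pd.DataFrame,
    genes: Sequence[GeneModel],
    promoter_up: int,
    promoter_down: int,
    tss_assoc_bp: int,
    exclude_chrom_prefixes: tuple[str, ...] = ("chrUn",),
) -> pd.DataFrame:
    """Feature calls for every (chrom, pos) row of a table.

    Sites on unplaced scaffolds (chromosome names starting with one of
    ``exclude_chrom_prefixes``) keep their feature but are never
    associated with a gene.
    """
    rows = []
    for _, r in sites.iterrows():
        chrom, pos = str(r["chrom"]), int(r["pos"])
        call = annotate_feature(chrom, pos, genes, promoter_up, promoter_down, tss_assoc_bp)
        gene = associate_gene(call, tss_assoc_bp)
        if any(chrom.startswith(p) for p in exclude_chrom_prefixes):
            gene = None
        rows.append({
            "chrom": chrom, "pos": pos, "feature": call.feature,
            "gene_id": gene if gene is not None else "",
            "tss_distance": call.tss_distance,
        })
    return pd.DataFrame(rows, columns=["chrom", "pos", "feature", "gene_id", "tss_distance"])


def feature_distribution_test(
    dms_counts: dict[str, int],
    background_counts: dict[str, int],
) -> tuple[float, int, float]:
    """Chi-square goodness-of-fit of DMS features against background.

    Expected counts are the DMS total spread over the background feature
    proportions.  Features with a zero background count are merged into
    the remaining categories' complement (dropped with df reduced).
    """
    feats = [f for f in FEATURES if background_counts.get(f, 0) > 0]
    dropped = [f for f in FEATURES if background_counts.get(f, 0) == 0]
    if dropped:
        logger.info("feature_distribution_test: dropping empty background %s", dropped)
    obs = np.array([dms_counts.get(f, 0) for f in feats], dtype=float)
    bg = np.array([background_counts[f] for f in feats], dtype=float)
    expected = obs.sum() * bg / bg.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = len(feats) - 1
    return chi2, df, float(stats.chi2.sf(chi2, df=df))


def _log_table_prob(row1: np.ndarray, cols: np.ndarray, r1: int, n: int) -> float:
    """log multivariate-hypergeometric probability of one 2xk table."""
    return float(
        (gammaln(cols + 1) - gammaln(row1 + 1) - gammaln(cols - row1 + 1)).sum()
        + gammaln(r1 + 1) + gammaln(n - r1 + 1) - gammaln(n + 1)
    )


def fisher_exact_2xk(
    row1: Sequence[int],
    row2: Sequence[int],
    max_tables: int = 10_000_000,
    mc_reps: int = 200_000,
    seed: int = 0,
    tol: float = 1e-12,
) -> float:
    """Two-sided Fisher exact p for a 2xk contingency table.

    Enumerates all tables with the observed margins and sums the
    probabilities of tables no more probable than the observed one
    (ties included within ``tol``).  Columns with a zero total are
    dropped.  If the margin space exceeds ``max_tables`` the p-value is
    estimated by Monte-Carlo sampling from the null (flagged in the log).
    """
    row1 = np.asarray(row1, dtype=np.int64)
    row2 = np.asarray(row2, dtype=np.int64)
    if row1.shape != row2.shape:
        raise ValueError("rows must have equal length")
    keep = (row1 + row2) > 0
    row1, row2 = row1[keep], row2[keep]
    k = len(row1)
    if k <= 1:
        return 1.0
    cols = row1 + row2
    r1 = int(row1.sum())
    n = int(cols.sum())
    log_p_obs = _log_table_prob(row1, cols, r1, n)

    bound = 1
    for c in cols:
        bound *= min(int(c), r1) + 1
        if bound > max_tables:
            break
    if bound > max_tables:
        logger.warning("fisher_exact_2xk: margins too large; Monte-Carlo p (seed=%d)", seed)
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_hypergeometric(cols, r1, size=mc_reps)
        logs = np.array([_log_table_prob(d, cols, r1, n) for d in draws])
        return float((logs <= log_p_obs + tol).mean())

    total = 0.0
    p_obs = np.exp(log_p_obs)

    def recurse(j: int, remaining: int, partial: list[int]) -> None:
        nonlocal total
        if j == k - 1:
            if remaining <= cols[j]:
                tab = np.array(partial + [remaining], dtype=np.int64)
                pr = np.exp(_log_table_prob(tab, cols, r1, n))
                if pr <= p_obs * (1 + tol) + tol:
                    total += pr
            return
        lo = max(0, remaining - int(cols[j + 1:].sum()))
        hi = min(int(cols[j]), remaining)
        for x in range(lo, hi + 1):
            recurse(j + 1, remaining - x, partial + [x])

    recurse(0, r1, [])
    return float(min(total, 1.0))


def gene_response_table(
    channel_table: pd.DataFrame,
    features: pd.DataFrame,
    min_sites: int = 2,
) -> pd.DataFrame:
    """Per-gene summary of pop-DMS categories with a Fisher exact p.

    For each gene with >= ``min_sites`` associated pop-DMS, the 2x3 table
    (gene's inducible/stable/inconclusive counts versus those of all
    remaining pop-DMS of the contrast) is tested for a correlated
    response.
    """
    from .channel_classify import CATEGORIES, EXPECTED, OPPOSITE

    merged = channel_table.merge(features[["chrom", "pos", "gene_id"]], on=["chrom", "pos"], how="left")
    merged["gene_id"] = merged["gene_id"].fillna("")
    total = {c: int((merged["category"] == c).sum()) for c in CATEGORIES}
    rows = []
    for gene, sub in merged[merged["gene_id"] != ""].groupby("gene_id"):
        if len(sub) < min_sites:
            continue
        gene_counts = [int((sub["category"] == c).sum()) for c in CATEGORIES]
        rest = [total[c] - gc for c, gc in zip(CATEGORIES, gene_counts)]
        p = fisher_exact_2xk(gene_counts, rest)
        ind = sub[sub["category"] == "inducible"]
        rows.append({
            "gene_id": gene,
            "n_wild": len(sub),
            "inducible": gene_counts[0],
            "expected_inducible": int((ind["direction"] == EXPECTED).sum()),
            "opposite_inducible": int((ind["direction"] == OPPOSITE).sum()),
            "stable": gene_counts[1],
            "inconclusive": gene_counts[2],
            "fisher_p": p,
        })
    out = pd.DataFrame(rows, columns=[
        "gene_id", "n_wild", "inducible", "expected_inducible",
        "opposite_inducible", "stable", "inconclusive", "fisher_p",
    ])
    return out.sort_values(["n_wild", "gene_id"], ascending=[False, True]).reset_index(drop=True)
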