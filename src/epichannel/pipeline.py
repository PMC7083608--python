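"""End-to-end orchestration: filter -> DMS -> classify -> FST -> annotate.

The library-level entry point is :func:`run_contrast`, which executes one
salinity contrast (reference wild population versus a target wild
population, with the matching experimental acclimation groups) on
in-memory inputs and returns every intermediate table plus a summary
dictionary shaped like the study's headline results: pop-DMS counts,
stable/inducible/inconclusive split, expected/opposite direction split,
enrichment chi-square, delta.mean.FST with its randomization p, ANOVA of
delta.meth.diff, and the per-gene response table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import channel_classify as cc
from . import diffmeth, gene_annotation, popgen_fst, qc_filtering
from .io_formats import (
    AnalysisConfig,
    GeneModel,
    MethylationMatrix,
    SampleSheet,
    VariantTable,
)

logger = logging.getLogger(__name__)

__all__ = ["ContrastResult", "run_contrast", "classify_all_sites"]

# contrast -> (wild target group, within group, trans group)
CONTRASTS = {
    "decrease": ("NYN6", "within6", "trans6"),
    "increase": ("SYL33", "within33", "trans33"),
}
REFERENCE_WILD = "KIE20"
CONTROL_GROUP = "ctrl20"


@dataclass
class ContrastResult:
    """All artifacts of one salinity contrast."""

    contrast: str
    filtered: MethylationMatrix
    filter_report: pd.DataFrame
    wild_table: pd.DataFrame
    blacklist: pd.DataFrame
    pop_dms: pd.DataFrame
    within_table: pd.DataFrame
    trans_table: pd.DataFrame
    channel_table: pd.DataFrame
    enrichment: cc.EnrichmentResult | None
    fst_windows: pd.DataFrame
    delta_fst: popgen_fst.DeltaFstResult | None
    features: pd.DataFrame
    gene_table: pd.DataFrame
    summary: dict = field(default_factory=dict)


def classify_all_sites(
    within_table: pd.DataFrame,
    trans_table: pd.DataFrame,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Channel category for every tested CpG (not only pop-DMS).

    Used by the enrichment randomization, which asks how a random CpG set
    of the same size would split over the categories.
    """
    key = ["chrom", "pos"]
    w = within_table.set_index(key)[["q", "meth_diff"]].rename(
        columns={"q": "q_w", "meth_diff": "d_w"}
    )
    t = trans_table.set_index(key)[["q", "meth_diff"]].rename(
        columns={"q": "q_t", "meth_diff": "d_t"}
    )
    j = w.join(t, how="inner").reset_index()
    cats = [
        cc.classify_channel(
            r.q_w, r.d_w, r.q_t, r.d_t, config.alpha_q, config.min_diff_pct
        )[0]
        for r in j.itertuples()
    ]
    j["category"] = cats
    return j[["chrom", "pos", "category"]]


def run_contrast(
    matrix: MethylationMatrix,
    sheet: SampleSheet,
    variants: VariantTable | None,
    genes: Sequence[GeneModel],
    config: AnalysisConfig,
    contrast: str = "decrease",
    filtered: MethylationMatrix | None = None,
    filter_report: pd.DataFrame | None = None,
    run_enrichment: bool = True,
    run_fst: bool = True,
) -> ContrastResult:
    """Execute one full contrast on in-memory inputs.

    ``filtered`` short-circuits the filter chain when the caller has
    already run it (the chain is contrast-independent).  FST needs
    ``variants``; passing None skips the SNP-correction filter and the
    FST stage.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"contrast must be one of {sorted(CONTRASTS)}")
    target_wild, within_group, trans_group = CONTRASTS[contrast]
    rng = np.random.default_rng(config.seed)

    wild_samples = [s for s in sheet.samples if sheet.df.loc[s, "cohort"] == "wild"]
    if filtered is None:
        filtered, filter_report = qc_filtering.run_filter_chain(
            matrix, sheet, variants, config,
            snp_samples=[s for s in wild_samples if variants is None or s in variants.samples],
        )
    assert filter_report is not None

    # wild comparison (reference vs target) and lab-artifact blacklist
    wild_table = diffmeth.compare_groups(filtered, sheet, REFERENCE_WILD, target_wild, config)
    blacklist_table = diffmeth.compare_groups(filtered, sheet, REFERENCE_WILD, CONTROL_GROUP, config)
    blacklist = blacklist_table[blacklist_table["is_dms"]][["chrom", "pos"]]
    wild_dms = wild_table[wild_table["is_dms"]].reset_index(drop=True)
    pop_dms = qc_filtering.drop_blacklist(wild_dms, blacklist)

    # experimental comparisons: control vs acclimation groups (family covariate)
    within_table = diffmeth.compare_groups(filtered, sheet, CONTROL_GROUP, within_group, config)
    trans_table = diffmeth.compare_groups(filtered, sheet, CONTROL_GROUP, trans_group, config)

    channel_table = cc.build_channel_table(
        pop_dms[["chrom", "pos", "meth_diff"]], within_table, trans_table,
        config.alpha_q, config.min_diff_pct,
    )

    enrichment = None
    if run_enrichment and len(channel_table):
        all_cats = classify_all_sites(within_table, trans_table, config)
        observed = {
            c: int((channel_table["category"] == c).sum()) for c in cc.CATEGORIES
        }
        enrichment = cc.enrichment_randomization(
            all_cats["category"].to_numpy(), observed, len(channel_table),
            config.n_enrich_reps, rng,
        )

    # windowed FST at inducible sites, split by direction
    fst_windows = pd.DataFrame()
    delta_fst = None
    if run_fst and variants is not None and len(channel_table):
        inducible = channel_table[
            (channel_table["category"] == cc.INDUCIBLE)
            & channel_table["direction"].isin([cc.EXPECTED, cc.OPPOSITE])
        ]
        if len(inducible):
            pop1 = [s for s in variants.samples if s.startswith(REFERENCE_WILD)]
            pop2 = [s for s in variants.samples if s.startswith(target_wild)]
            fst_windows = popgen_fst.fst_window_table(
                inducible[["chrom", "pos", "direction"]], variants, pop1, pop2,
                config.fst_halfwin_bp, config.fst_max_missing, config.fst_min_dp,
            )
            exp_vals = fst_windows.loc[
                fst_windows["direction"] == cc.EXPECTED, "mean_fst"
            ].dropna()
            opp_vals = fst_windows.loc[
                fst_windows["direction"] == cc.OPPOSITE, "mean_fst"
            ].dropna()
            if len(exp_vals) and len(opp_vals):
                delta_fst = popgen_fst.delta_mean_fst_test(
                    exp_vals, opp_vals, config.n_fst_boot, rng,
                    mode=config.fst_boot_mode,
                    plus_one_correction=config.fst_p_correction,
                )

    # gene annotation of pop-DMS, feature randomness, per-gene response
    features = gene_annotation.annotate_sites(
        channel_table[["chrom", "pos"]], genes,
        config.promoter_up, config.promoter_down, config.tss_assoc_bp,
    )
    background = gene_annotation.annotate_sites(
        filtered.site_frame(), genes,
        config.promoter_up, config.promoter_down, config.tss_assoc_bp,
    )
    feat_test = (np.nan, 0, np.nan)
    if len(features):
        feat_test = gene_annotation.feature_distribution_test(
            features["feature"].value_counts().to_dict(),
            background["feature"].value_counts().to_dict(),
        )
    gene_table = gene_annotation.gene_response_table(channel_table, features)

    n_pop = len(channel_table)
    counts = {c: int((channel_table["category"] == c).sum()) for c in cc.CATEGORIES}
    ind = channel_table[channel_table["category"] == cc.INDUCIBLE]
    n_exp_dir = int((ind["direction"] == cc.EXPECTED).sum())
    n_opp_dir = int((ind["direction"] == cc.OPPOSITE).sum())
    summary = {
        "contrast": contrast,
        "n_sites_tested": int(filtered.n_sites),
        "n_pop_dms": n_pop,
        "n_blacklisted": int(len(wild_dms) - n_pop),
        "category_counts": counts,
        "category_pct": {
            c: (100.0 * v / n_pop if n_pop else np.nan) for c, v in counts.items()
        },
        "n_expected_direction": n_exp_dir,
        "n_opposite_direction": n_opp_dir,
        "pct_expected_direction": (
            100.0 * n_exp_dir / (n_exp_dir + n_opp_dir)
            if (n_exp_dir + n_opp_dir) else np.nan
        ),
        "enrichment_chi2": enrichment.chi2 if enrichment else np.nan,
        "enrichment_p": enrichment.p if enrichment else np.nan,
        "delta_mean_fst": delta_fst.delta if delta_fst else np.nan,
        "delta_mean_fst_p": delta_fst.p if delta_fst else np.nan,
        "feature_chi2": feat_test[0],
        "feature_df": feat_test[1],
        "feature_p": feat_test[2],
    }
    return ContrastResult(
        contrast=contrast,
        filtered=filtered,
        filter_report=filter_report,
        wild_table=wild_table,
        blacklist=blacklist,
        pop_dms=pop_dms,
        within_table=within_table,
        trans_table=trans_table,
        channel_table=channel_table,
        enrichment=enrichment,
        fst_windows=fst_windows,
        delta_fst=delta_fst,
        features=features,
        gene_table=gene_table,
        summary=summary,
    )
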