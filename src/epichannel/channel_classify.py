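"""Classification of population DMS into epigenetic information channels.

A pop-DMS (a CpG differentially methylated between two wild populations)
is confronted with a two-generation acclimation experiment in which the
reference population was shifted to the target salinity, within one
("within") or across two ("trans") generations:

* **stable** — neither acclimation group differs from the control
  (q >= alpha in both comparisons): a candidate selection-based mark.
* **inducible** — at least one acclimation group is differentially
  methylated versus the control (q < alpha AND |diff| >= threshold): a
  candidate detection-based (plastic) mark.
* **inconclusive** — a significant q in some comparison but no comparison
  reaches the effect-size threshold.

Precedence is inducible > inconclusive > stable when the two comparisons
disagree, matching the "at least one acclimation group" definition.

For inducible sites the induced direction is matched against the wild
difference: **expected** when the experimental change has the same sign
as the wild population difference, **opposite** otherwise.  Similarity is
quantified by

    delta.meth.diff = 100 - (meth.diff.wild - meth.diff.exp)

after orienting each site so the wild difference is non-negative (both
signs flipped when it is negative, orientation recorded); 100 means the
induced change exactly reproduces the wild difference.  A two-way ANOVA
(delta.meth.diff ~ methylation direction x acclimation) compares within-
versus transgenerational acclimation, and a randomization test checks
whether pop-DMS are enriched for inducible sites relative to random CpG
sets of the same size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "STABLE",
    "INDUCIBLE",
    "INCONCLUSIVE",
    "classify_channel",
    "classify_direction",
    "delta_meth_diff",
    "build_channel_table",
    "acclimation_anova",
    "enrichment_randomization",
    "hepatosomatic_index",
]

STABLE = "stable"
INDUCIBLE = "inducible"
INCONCLUSIVE = "inconclusive"
CATEGORIES = (INDUCIBLE, STABLE, INCONCLUSIVE)

EXPECTED = "expected"
OPPOSITE = "opposite"
NOT_APPLICABLE = "not-applicable"


def classify_channel(
    q_within: float,
    diff_within: float,
    q_trans: float,
    diff_trans: float,
    alpha_q: float,
    min_diff_pct: float,
) -> tuple[str, frozenset[str]]:
    """Category of one pop-DMS from its two control comparisons.

    Returns (category, induced_by) where induced_by lists which
    acclimation comparisons ('within', 'trans') reached full differential
    methylation.  NaN q-values count as non-significant.
    """
    sig_w = (not np.isnan(q_within)) and q_within < alpha_q
    sig_t = (not np.isnan(q_trans)) and q_trans < alpha_q
    full_w = sig_w and abs(diff_within) >= min_diff_pct
    full_t = sig_t and abs(diff_trans) >= min_diff_pct
    induced = frozenset(
        name for name, full in (("within", full_w), ("trans", full_t)) if full
    )
    if induced:
        return INDUCIBLE, induced
    if sig_w or sig_t:
        return INCONCLUSIVE, frozenset()
    return STABLE, frozenset()


def classify_direction(
    wild_diff: float,
    diff_within: float,
    diff_trans: float,
    induced_by: frozenset[str],
) -> tuple[str, bool]:
    """Match the induced change's sign against the wild difference.

    For each inducing comparison the label is 'expected' if the signs
    agree.  When both comparisons induce and conflict, the
    transgenerational comparison decides and the conflict is flagged.
    A wild difference of exactly zero cannot be matched.
    """
    if not induced_by:
        return NOT_APPLICABLE, False
    if wild_diff == 0 or np.isnan(wild_diff):
        return NOT_APPLICABLE, True
    labels = {}
    if "within" in induced_by:
        labels["within"] = EXPECTED if np.sign(diff_within) == np.sign(wild_diff) else OPPOSITE
    if "trans" in induced_by:
        labels["trans"] = EXPECTED if np.sign(diff_trans) == np.sign(wild_diff) else OPPOSITE
    if len(labels) == 2 and labels["within"] != labels["trans"]:
        return labels["trans"], True
    return next(iter(labels.values())), False


def delta_meth_diff(wild_diff, exp_diff):
    """Similarity of an induced change to the wild difference.

    ``100 - (meth.diff.wild - meth.diff.exp)`` after flipping both signs
    where the wild difference is negative, so the statistic always rewards
    movement toward the wild state.  100 = exact match; overshoot gives
    values above 100.  Accepts scalars or arrays.
    """
    wild = np.asarray(wild_diff, dtype=float)
    exp = np.asarray(exp_diff, dtype=float)
    sign = np.where(wild < 0, -1.0, 1.0)
    out = 100.0 - (sign * wild - sign * exp)
    if out.ndim == 0:
        return float(out)
    return out


def build_channel_table(
    pop_dms: pd.DataFrame,
    res_within: pd.DataFrame,
    res_trans: pd.DataFrame,
    alpha_q: float,
    min_diff_pct: float,
) -> pd.DataFrame:
    """Classify every pop-DMS against the two experimental comparisons.

    ``pop_dms`` needs chrom/pos/meth_diff (the wild difference, target
    minus reference); ``res_within``/``res_trans`` are the control-versus-
    acclimation DiffMeth tables (diff = acclimated minus control).  Sites
    missing from either comparison are dropped with a logged count.
    """
    key = ["chrom", "pos"]
    w = res_within.set_index(key)[["meth_diff", "q"]].rename(
        columns={"meth_diff": "exp_diff_within", "q": "q_within"}
    )
    t = res_trans.set_index(key)[["meth_diff", "q"]].rename(
        columns={"meth_diff": "exp_diff_trans", "q": "q_trans"}
    )
    df = pop_dms.rename(columns={"meth_diff": "wild_diff"}).set_index(key)
    joined = df.join(w, how="left").join(t, how="left")
    missing = joined["q_within"].isna() & joined["exp_diff_within"].isna() | (
        joined["q_trans"].isna() & joined["exp_diff_trans"].isna()
    )
    n_missing = int(
        (joined["exp_diff_within"].isna() | joined["exp_diff_trans"].isna()).sum()
    )
    if n_missing:
        logger.info(
            "build_channel_table: %d pop-DMS missing from an experimental "
            "comparison; dropped", n_missing,
        )
    joined = joined[~(joined["exp_diff_within"].isna() | joined["exp_diff_trans"].isna())]

    rows = []
    for (chrom, pos), r in joined.iterrows():
        category, induced_by = classify_channel(
            r["q_within"], r["exp_diff_within"], r["q_trans"], r["exp_diff_trans"],
            alpha_q, min_diff_pct,
        )
        direction, conflict = classify_direction(
            r["wild_diff"], r["exp_diff_within"], r["exp_diff_trans"], induced_by
        )
        flipped = r["wild_diff"] < 0
        d_within = delta_meth_diff(r["wild_diff"], r["exp_diff_within"])
        d_trans = delta_meth_diff(r["wild_diff"], r["exp_diff_trans"])
        sign = -1.0 if flipped else 1.0
        if category == INDUCIBLE:
            ref_diff = r["exp_diff_trans"] if "trans" in induced_by else r["exp_diff_within"]
            meth_dir = "hypo" if sign * ref_diff < 0 else "hyper"
        else:
            meth_dir = ""
        rows.append({
            "chrom": chrom, "pos": pos,
            "category": category,
            "induced_by": "+".join(sorted(induced_by)),
            "direction": direction,
            "meth_direction": meth_dir,
            "wild_diff": r["wild_diff"],
            "exp_diff_within": r["exp_diff_within"],
            "exp_diff_trans": r["exp_diff_trans"],
            "delta_meth_diff_within": d_within,
            "delta_meth_diff_trans": d_trans,
            "orientation_flipped": bool(flipped),
            "direction_conflict": bool(conflict),
        })
    out = pd.DataFrame(rows, columns=[
        "chrom", "pos", "category", "induced_by", "direction", "meth_direction",
        "wild_diff", "exp_diff_within", "exp_diff_trans",
        "delta_meth_diff_within", "delta_meth_diff_trans",
        "orientation_flipped", "direction_conflict",
    ])
    return out


@dataclass
class AnovaResult:
    """Type-II two-way ANOVA summary for delta.meth.diff."""

    f_acclimation: float
    p_acclimation: float
    f_interaction: float
    p_interaction: float
    df_resid: int
    interaction_estimable: bool = True


def acclimation_anova(
    values: np.ndarray,
    meth_direction: np.ndarray,
    acclimation: np.ndarray,
) -> AnovaResult:
    """delta.meth.diff ~ methylation direction x acclimation.

    Fixed-effects least squares on the 2x2 design with Type-II sums of
    squares (robust to unbalanced cells).  Requires >= 2 observations per
    occupied cell; an empty cell makes the interaction inestimable.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "direction": np.asarray(meth_direction, dtype=object),
        "acclimation": np.asarray(acclimation, dtype=object),
    })
    cells = df.groupby(["direction", "acclimation"], observed=True).size()
    n_dir = df["direction"].nunique()
    n_acc = df["acclimation"].nunique()
    if len(cells) < n_dir * n_acc:
        logger.warning("acclimation_anova: empty cell; interaction not estimable")
        model = smf.ols("value ~ C(direction) + C(acclimation)", data=df).fit()
        tab = sm.stats.anova_lm(model, typ=2)
        return AnovaResult(
            float(tab.loc["C(acclimation)", "F"]),
            float(tab.loc["C(acclimation)", "PR(>F)"]),
            np.nan, np.nan, int(model.df_resid), interaction_estimable=False,
        )
    if (cells < 2).any():
        raise ValueError("need >= 2 observations per design cell")
    model = smf.ols("value ~ C(direction) * C(acclimation)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    inter = "C(direction):C(acclimation)"
    return AnovaResult(
        float(tab.loc["C(acclimation)", "F"]),
        float(tab.loc["C(acclimation)", "PR(>F)"]),
        float(tab.loc[inter, "F"]),
        float(tab.loc[inter, "PR(>F)"]),
        int(model.df_resid),
    )


@dataclass
class EnrichmentResult:
    observed: dict[str, int]
    expected: dict[str, float]
    chi2: float
    df: int
    p: float
    n_reps: int


def enrichment_randomization(
    all_categories: np.ndarray,
    observed_counts: dict[str, int],
    n_popdms: int,
    reps: int,
    seed: int | np.random.Generator,
) -> EnrichmentResult:
    """Are pop-DMS enriched for inducible sites relative to random CpGs?

    ``all_categories`` holds the channel category of every tested CpG site
    (classified with the same rules as the pop-DMS).  ``reps`` random
    subsets of size ``n_popdms`` are drawn without replacement; the three
    category counts averaged over replicates are the expected values of a
    chi-square test (df = 2) against the observed pop-DMS counts.
    """
    cats = np.asarray(all_categories, dtype=object)
    n_total = len(cats)
    if n_popdms > n_total:
        raise ValueError(f"n_popdms {n_popdms} exceeds {n_total} classified sites")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    code_of = {c: i for i, c in enumerate(CATEGORIES)}
    codes = np.array([code_of[c] for c in cats], dtype=np.int64)
    totals = np.zeros(len(CATEGORIES), dtype=np.int64)
    for _ in range(reps):
        pick = rng.choice(n_total, size=n_popdms, replace=False)
        totals += np.bincount(codes[pick], minlength=len(CATEGORIES))
    expected = totals / reps
    obs = np.array([observed_counts.get(c, 0) for c in CATEGORIES], dtype=float)
    if (expected == 0).any():
        # guard: merge nothing, but avoid division by zero for empty categories
        nonzero = expected > 0
        chi2 = float(((obs[nonzero] - expected[nonzero]) ** 2 / expected[nonzero]).sum())
        dof = int(nonzero.sum()) - 1
    else:
        chi2 = float(((obs - expected) ** 2 / expected).sum())
        dof = len(CATEGORIES) - 1
    p = float(stats.chi2.sf(chi2, df=dof))
    return EnrichmentResult(
        observed={c: int(o) for c, o in zip(CATEGORIES, obs)},
        expected={c: float(e) for c, e in zip(CATEGORIES, expected)},
        chi2=chi2, df=dof, p=p, n_reps=reps,
    )


def hepatosomatic_index(liver_weight: float, total_weight: float) -> float:
    """HSI = liver weight / total weight * 100 (same units, both > 0)."""
    if liver_weight <= 0 or total_weight <= 0:
        raise ValueError("weights must be strictly positive")
    return 100.0 * liver_weight / total_weight
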