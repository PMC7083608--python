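"""Site and sample filtering chain for RRBS count matrices.

The chain turns raw per-sample CpG count matrices into the analysis-ready
set, applied in this order:

1. minimum coverage (entries below ``min_cov`` reads become absent),
2. per-sample high-coverage percentile cap (PCR-bias guard),
3. removal of CpG sites confounded by C>T / G>A SNPs,
4. between-sample coverage normalisation (median scaling),
5. presence filter (site observed in >= ``min_per_group`` samples of every
   group),
6. sex-chromosome removal.

Each step is idempotent and only ever removes or rescales data.  The
per-step attrition is collected in a report table, mirroring how RRBS
studies report site counts after each filter.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import AnalysisConfig, MethylationMatrix, SampleSheet, VariantTable

logger = logging.getLogger(__name__)

__all__ = [
    "filter_min_coverage",
    "filter_high_coverage",
    "correct_snp_overlap",
    "normalize_coverage",
    "filter_presence",
    "drop_chromosome",
    "drop_blacklist",
    "run_filter_chain",
]


def _drop_empty_sites(cov: np.ndarray, meth: np.ndarray, m: MethylationMatrix) -> MethylationMatrix:
    keep = (cov > 0).any(axis=1)
    return MethylationMatrix(m.chrom[keep], m.pos[keep], m.samples, cov[keep], meth[keep])


def filter_min_coverage(m: MethylationMatrix, min_cov: int) -> MethylationMatrix:
    """Mark entries with coverage below ``min_cov`` absent; drop empty sites."""
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    low = (m.coverage > 0) & (m.coverage < min_cov)
    cov = np.where(low, 0, m.coverage)
    meth = np.where(low, 0, m.methylated)
    out = _drop_empty_sites(cov, meth, m)
    logger.info(
        "filter_min_coverage: %d entr(ies) below %d reads removed; %d -> %d sites",
        int(low.sum()), min_cov, m.n_sites, out.n_sites,
    )
    return out


def filter_high_coverage(m: MethylationMatrix, percentile: float) -> MethylationMatrix:
    """Remove entries above each sample's empirical coverage percentile.

    The threshold is the linear-interpolation percentile of that sample's
    present coverages; entries strictly above it become absent.  Samples
    with fewer than 10 present sites are left uncapped with a warning.
    """
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    cov = m.coverage.copy()
    meth = m.methylated.copy()
    n_removed = 0
    for j in range(m.n_samples):
        vals = m.coverage[:, j][m.coverage[:, j] > 0]
        if len(vals) < 10:
            logger.warning(
                "filter_high_coverage: sample %s has %d present sites; cap skipped",
                m.samples[j], len(vals),
            )
            continue
        thr = np.percentile(vals, percentile, method="linear")
        over = cov[:, j] > thr
        n_removed += int(over.sum())
        cov[over, j] = 0
        meth[over, j] = 0
    out = _drop_empty_sites(cov, meth, m)
    logger.info(
        "filter_high_coverage: %d entr(ies) above the %.4g%% cap removed; %d -> %d sites",
        n_removed, percentile, m.n_sites, out.n_sites,
    )
    return out


def snp_excluded_positions(
    v: VariantTable,
    min_gq: float,
    min_maf: float,
    samples: Sequence[str] | None = None,
) -> set[tuple[str, int]]:
    """CpG C positions confounded by C>T (at pos) or G>A (at pos+1) SNPs.

    A variant qualifies when its mean genotype quality across genotyped
    samples is >= ``min_gq`` and its sample minor-allele frequency is
    >= ``min_maf``.  Frequencies are computed from the genotypes of the
    reference cohort given by ``samples`` (all VCF samples by default).
    """
    if samples is not None:
        idx = v.sample_index(samples)
        gt = v.gt[:, idx]
        gq = v.gq[:, idx]
    else:
        gt = v.gt
        gq = v.gq
    genotyped = gt >= 0
    n_gt = genotyped.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(n_gt > 0, np.where(genotyped, gt, 0).sum(axis=1) / (2 * np.maximum(n_gt, 1)), np.nan)
        maf = np.minimum(af, 1 - af)
        has_gq = (gq >= 0) & genotyped
        mean_gq = np.where(
            has_gq.any(axis=1),
            np.where(has_gq, gq, 0).sum(axis=1) / np.maximum(has_gq.sum(axis=1), 1),
            np.nan,
        )
    ok = (n_gt > 0) & (maf >= min_maf) & (mean_gq >= min_gq)
    excluded: set[tuple[str, int]] = set()
    for i in np.flatnonzero(ok):
        if v.ref[i] == "C" and v.alt[i] == "T":
            excluded.add((str(v.chrom[i]), int(v.pos[i])))
        elif v.ref[i] == "G" and v.alt[i] == "A":
            excluded.add((str(v.chrom[i]), int(v.pos[i]) - 1))
    return excluded


def correct_snp_overlap(
    m: MethylationMatrix,
    v: VariantTable,
    min_gq: float,
    min_maf: float,
    samples: Sequence[str] | None = None,
) -> MethylationMatrix:
    """Remove CpG sites whose methylation call a C>T or G>A SNP could fake.

    Bisulfite conversion reads an unmethylated C as T, so a genuine C>T
    SNP at the C (or G>A at the paired G, pos+1) is indistinguishable from
    unmethylation and the site is dropped outright.
    """
    excluded = snp_excluded_positions(v, min_gq, min_maf, samples)
    if not excluded:
        return m.copy()
    hit = np.array(
        [(str(c), int(p)) in excluded for c, p in zip(m.chrom, m.pos)], dtype=bool
    )
    logger.info("correct_snp_overlap: removed %d SNP-confounded site(s)", int(hit.sum()))
    return m.subset_sites(~hit)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Deterministic half-away-from-zero rounding (x >= 0 here)."""
    return np.floor(x + 0.5)


def normalize_coverage(m: MethylationMatrix, target: str = "median") -> MethylationMatrix:
    """Scale each sample's coverages to a common median.

    With per-sample median coverage ``m_j``, the scale factor is
    ``t / m_j`` where ``t`` is the median (or max) of the ``m_j``.
    Counts are rescaled with half-away-from-zero rounding, methylated
    counts preserve the methylation fraction to rounding, and present
    entries keep coverage >= 1.
    """
    medians = np.empty(m.n_samples)
    for j in range(m.n_samples):
        vals = m.coverage[:, j][m.coverage[:, j] > 0]
        if len(vals) == 0:
            raise ValueError(f"sample {m.samples[j]} has no present sites")
        medians[j] = np.median(vals)
    t = np.median(medians) if target == "median" else np.max(medians)
    factors = t / medians
    present = m.coverage > 0
    cov = np.where(present, np.maximum(_round_half_away(m.coverage * factors), 1), 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(present, m.methylated / np.maximum(m.coverage, 1), 0.0)
    meth = np.where(present, np.minimum(_round_half_away(cov * frac), cov), 0)
    logger.info(
        "normalize_coverage: target median %.3g, factors %.3g..%.3g",
        t, factors.min(), factors.max(),
    )
    return MethylationMatrix(
        m.chrom, m.pos, m.samples, cov.astype(np.int64), meth.astype(np.int64)
    )


def filter_presence(
    m: MethylationMatrix,
    sheet: SampleSheet,
    groups: Sequence[str],
    min_per_group: int,
) -> MethylationMatrix:
    """Keep sites present in >= ``min_per_group`` samples of EVERY group."""
    if not groups:
        raise ValueError("groups must be nonempty")
    keep = np.ones(m.n_sites, dtype=bool)
    for g in groups:
        members = [s for s in sheet.samples_in_group(g) if s in m.samples]
        if len(members) < min_per_group:
            raise ValueError(
                f"group {g!r} has {len(members)} samples in the matrix; "
                f"presence >= {min_per_group} is unsatisfiable"
            )
        idx = m.sample_index(members)
        keep &= (m.coverage[:, idx] > 0).sum(axis=1) >= min_per_group
    logger.info("filter_presence: %d -> %d sites", m.n_sites, int(keep.sum()))
    return m.subset_sites(keep)


def drop_chromosome(m: MethylationMatrix, chrom_label: str) -> MethylationMatrix:
    """Remove all sites on one chromosome (e.g. the sex chromosome)."""
    hit = m.chrom == chrom_label
    if not hit.any():
        logger.warning("drop_chromosome: label %r not present; no-op", chrom_label)
        return m.copy()
    logger.info("drop_chromosome: removed %d site(s) on %s", int(hit.sum()), chrom_label)
    return m.subset_sites(~hit)


def drop_blacklist(dms: pd.DataFrame, blacklist: pd.DataFrame) -> pd.DataFrame:
    """Set-difference of DMS tables keyed by (chrom, pos).

    ``blacklist`` is itself the DMS table of a wild-reference versus
    experimental-control comparison, flagging laboratory artifacts.
    """
    if blacklist.empty or dms.empty:
        return dms.copy()
    black = set(zip(blacklist["chrom"].astype(str), blacklist["pos"].astype(int)))
    keep = [
        (str(c), int(p)) not in black
        for c, p in zip(dms["chrom"], dms["pos"])
    ]
    out = dms[np.asarray(keep, dtype=bool)].reset_index(drop=True)
    logger.info("drop_blacklist: %d -> %d DMS", len(dms), len(out))
    return out


def run_filter_chain(
    m: MethylationMatrix,
    sheet: SampleSheet,
    variants: VariantTable | None,
    config: AnalysisConfig,
    groups: Sequence[str] | None = None,
    snp_samples: Sequence[str] | None = None,
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Apply the full filter chain in the published order; report attrition."""
    groups = list(groups) if groups is not None else sheet.groups
    steps: list[tuple[str, int]] = [("input", m.n_sites)]
    m = filter_min_coverage(m, config.min_cov)
    steps.append(("min_coverage", m.n_sites))
    m = filter_high_coverage(m, config.high_cov_percentile)
    steps.append(("high_coverage_cap", m.n_sites))
    if variants is not None:
        m = correct_snp_overlap(
            m, variants, config.snp_min_gq, config.snp_min_maf, snp_samples
        )
    steps.append(("snp_correction", m.n_sites))
    m = normalize_coverage(m, config.normalize_target)
    steps.append(("coverage_normalization", m.n_sites))
    m = filter_presence(m, sheet, groups, config.min_per_group)
    steps.append(("presence", m.n_sites))
    m = drop_chromosome(m, config.sex_chrom)
    steps.append(("drop_sex_chromosome", m.n_sites))
    report = pd.DataFrame(steps, columns=["step", "n_sites"])
    return m, report
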