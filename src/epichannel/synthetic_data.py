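"""Synthetic RRBS + genotype data with planted ground truth.

The generator emulates the statistical structure the pipeline assumes so
every stage is testable without any sequencing download:

* three wild populations along a salinity cline (reference KIE20 plus the
  low- and high-salinity targets NYN6 and SYL33, n = 15–16) and five
  experimental groups bred from the reference population (control,
  within- and transgenerational acclimation to each foreign salinity,
  n = 12, split-clutch families shared across groups);
* bimodal per-CpG baseline methylation (a 50:50 mixture of Beta(0.5, 8)
  and Beta(8, 0.5), the classic low/high methylation modes of vertebrate
  CpGs);
* planted site classes: population effects of >= 15 percentage points, a
  subset of which are experimentally inducible in the expected or the
  opposite direction, with the transgenerational induced effect closer to
  the wild difference than the within-generation effect (accentuation
  across generations);
* family random effects on the logit scale, negative-binomially
  overdispersed coverage, beta-binomial methylated counts (so the data
  are *harsher* than the binomial test assumes);
* Balding–Nichols population genotypes with class-specific target F:
  SNPs near inducible-opposite sites are more differentiated than those
  near inducible-expected sites, mirroring the hypothesis that opposite
  responses sit in diverged genomic backgrounds.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    EXPERIMENTAL,
    WILD,
    GeneModel,
    MethylationMatrix,
    SampleSheet,
    VariantTable,
    write_coverage_file,
    write_gff,
    write_sample_sheet,
    write_vcf,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeLayout",
    "SimulationParams",
    "TruthTable",
    "Scenario",
    "generate_layout",
    "simulate_methylation",
    "simulate_genotypes",
    "inject_cpg_snps",
    "simulate_scenario",
    "write_scenario",
    "null_params",
]

# planted class labels
NULL = "null"
POP_EFFECT = "pop-effect"          # stable-only: wild effect, no induction
IND_EXPECTED = "inducible-expected"
IND_OPPOSITE = "inducible-opposite"
INCONCLUSIVE_EFFECT = "inconclusive-effect"

WILD_GROUPS = ("NYN6", "KIE20", "SYL33")
EXP_GROUPS = ("ctrl20", "within6", "within33", "trans6", "trans33")
REFERENCE_GROUP = "KIE20"
TARGET_GROUP = "NYN6"


@dataclass
class GenomeLayout:
    """Chromosome sizes, CpG positions, gene models and the sex chromosome."""

    chroms: dict[str, int]
    cpg: pd.DataFrame  # columns chrom, pos
    genes: list[GeneModel]
    sex_chrom: str


@dataclass
class TruthTable:
    """Planted ground truth for methylation sites and SNPs.

    ``sites``: chrom, pos, pi0, planted_class, delta_wild, delta_within,
    delta_trans (percentage points), clipped flag.
    ``snps``: chrom, pos, snp_class, target_f, ancestral_f and the three
    per-population alt frequencies.
    """

    sites: pd.DataFrame
    snps: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class SimulationParams:
    """Study conditions of the default synthetic scenario.

    Group sizes, effect sizes and thresholds mirror the field study the
    pipeline targets: three wild populations of 15–16 fish, five
    experimental split-clutch groups of 12, planted wild differences of
    25–35 percentage points (comfortably above the 15-point call
    threshold), induced effects that approach the wild difference across
    two generations (trans = 0.9 x wild, within = 0.6 x trans), mean
    coverage 30 with negative-binomial dispersion 5, beta-binomial
    intra-sample correlation 0.01 and logit-scale family effects of
    s.d. 0.3.
    """

    n_chroms: int = 3
    chrom_len: int = 1_000_000
    n_cpg: int = 5000
    n_genes: int = 60
    n_wild: tuple[int, int, int] = (15, 16, 15)   # NYN6, KIE20, SYL33
    n_exp: int = 12
    n_families: int = 6
    # baseline methylation: w*Beta(0.5,8) + (1-w)*Beta(8,0.5)
    bimodal_weight: float = 0.5
    pi0_mode: str = "bimodal"       # or "uniform" (calibration scenarios)
    pi0_uniform_range: tuple[float, float] = (0.2, 0.8)
    # planted classes
    n_ind_expected: int = 40
    n_ind_opposite: int = 20
    n_inconclusive: int = 20
    n_stable_only: int = 20
    delta_wild_range: tuple[float, float] = (25.0, 35.0)
    delta_wild_fixed: float | None = None   # overrides range when set
    trans_fraction: float = 0.9     # delta_trans = trans_fraction * delta_wild
    within_fraction: float = 0.6    # delta_within = within_fraction * delta_trans
    # half the 15-pp call threshold: a clearly sub-threshold induced effect,
    # ~2 standard errors below the threshold at n=12, coverage 30
    delta_inconclusive: float = 7.5
    eligible_pi0: tuple[float, float] = (0.15, 0.85)
    # noise
    sigma_family: float = 0.3
    rho: float = 0.01               # beta-binomial intra-sample correlation
    mean_coverage: float = 30.0
    coverage_dispersion: float = 5.0
    # genotypes
    n_snps: int = 2000
    n_per_pop_geno: tuple[int, int, int] = (15, 16, 15)
    f_background: float = 0.02
    f_expected: float = 0.005
    f_opposite: float = 0.15
    snps_per_inducible_window: int = 10
    geno_halfwin_bp: int = 5000
    mean_dp: float = 20.0
    # injected CpG-confounding SNPs
    inject_fraction: float = 0.01
    inject_maf_range: tuple[float, float] = (0.1, 0.5)


def null_params(**overrides) -> SimulationParams:
    """A no-effect scenario for calibration of the site test.

    No planted effects, no family effects, binomial counts (rho = 0) and
    uniform mid-range baseline methylation, i.e. exactly the regime in
    which the chi-square reference distribution of the likelihood-ratio
    test is exercisable at every site.
    """
    base = SimulationParams(
        n_ind_expected=0, n_ind_opposite=0, n_inconclusive=0, n_stable_only=0,
        sigma_family=0.0, rho=0.0, pi0_mode="uniform",
    )
    return replace(base, **overrides)


def generate_layout(
    n_chroms: int = 3,
    chrom_len: int = 1_000_000,
    n_cpg: int = 5000,
    n_genes: int = 60,
    seed: int | np.random.Generator = 0,
) -> GenomeLayout:
    """Random genome layout: CpG positions, non-overlapping genes, sex chrom.

    The last chromosome is labelled ``chr19`` (the sex chromosome of the
    target organism) so sex-chromosome removal is exercisable; the others
    are ``chr1``, ``chr2``, ...  CpG positions are uniform without
    collision, kept >= 2 bp apart so forward C and paired G positions
    never collide between sites.
    """
    if min(n_chroms, chrom_len, n_cpg) < 1 or n_genes < 0:
        raise ValueError("layout parameters must be positive")
    if n_cpg * 4 > n_chroms * chrom_len:
        raise ValueError("CpG density infeasible for the requested genome size")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = [f"chr{i + 1}" for i in range(n_chroms - 1)] + ["chr19"]
    chroms = {name: chrom_len for name in names}

    per = np.full(n_chroms, n_cpg // n_chroms)
    per[: n_cpg % n_chroms] += 1
    cpg_rows = []
    for name, k in zip(names, per):
        # sample on a half grid then double: guarantees >= 2 bp spacing
        grid = rng.choice(chrom_len // 2 - 2, size=k, replace=False)
        pos = np.sort(grid) * 2 + 2
        cpg_rows.append(pd.DataFrame({"chrom": name, "pos": pos}))
    cpg = pd.concat(cpg_rows, ignore_index=True)

    genes: list[GeneModel] = []
    if n_genes:
        per_g = np.full(n_chroms, n_genes // n_chroms)
        per_g[: n_genes % n_chroms] += 1
        gid = 0
        for name, k in zip(names, per_g):
            if k == 0:
                continue
            slot = chrom_len // k
            for j in range(k):
                gid += 1
                lo = j * slot + 1
                span = int(rng.integers(2000, min(20000, slot - 1000)))
                start = int(rng.integers(lo, lo + slot - span - 500))
                end = start + span
                strand = "+" if rng.random() < 0.5 else "-"
                n_ex = int(rng.integers(2, 9))
                cuts = np.sort(rng.choice(span - 1, size=2 * n_ex, replace=False)) + start
                exons = tuple(
                    (int(cuts[2 * i]), int(cuts[2 * i + 1])) for i in range(n_ex)
                )
                genes.append(GeneModel(f"G{gid:04d}", name, strand, start, end, exons))
    return GenomeLayout(chroms=chroms, cpg=cpg, genes=genes, sex_chrom="chr19")


def _draw_pi0(params: SimulationParams, n: int, rng: np.random.Generator) -> np.ndarray:
    if params.pi0_mode == "uniform":
        lo, hi = params.pi0_uniform_range
        return rng.uniform(lo, hi, size=n)
    low = rng.beta(0.5, 8.0, size=n)
    high = rng.beta(8.0, 0.5, size=n)
    pick = rng.random(n) < params.bimodal_weight
    return np.where(pick, low, high)


def _design_sheet(params: SimulationParams) -> SampleSheet:
    rows = []
    for g, n in zip(WILD_GROUPS, params.n_wild):
        for i in range(n):
            rows.append({
                "sample": f"{g}_{i + 1:02d}", "cohort": WILD, "group": g,
                "family": "", "sex": "F" if i % 2 == 0 else "M",
            })
    for g in EXP_GROUPS:
        for i in range(params.n_exp):
            fam = f"F{i % params.n_families + 1}"  # split-clutch: families span groups
            rows.append({
                "sample": f"{g}_{i + 1:02d}", "cohort": EXPERIMENTAL, "group": g,
                "family": fam, "sex": "F" if i % 2 == 0 else "M",
            })
    df = pd.DataFrame(rows).set_index("sample")
    return SampleSheet(df)


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_methylation(
    layout: GenomeLayout,
    params: SimulationParams,
    seed: int | np.random.Generator = 0,
) -> tuple[MethylationMatrix, SampleSheet, TruthTable]:
    """Simulate the full count matrix, sample sheet and site ground truth.

    Planted sites are drawn from autosomal CpGs whose baseline methylation
    leaves headroom for the full effect (``eligible_pi0``); the effect
    sign points away from the nearer probability boundary so a planted
    30-point difference is realised as ~30 points.  Group means outside
    [0.01, 0.99] after adding effects are clipped with a logged count.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sheet = _design_sheet(params)
    n_sites = len(layout.cpg)
    chrom = layout.cpg["chrom"].to_numpy(dtype=object)
    pos = layout.cpg["pos"].to_numpy(dtype=np.int64)

    pi0 = _draw_pi0(params, n_sites, rng)
    planted_class = np.full(n_sites, NULL, dtype=object)
    delta_wild = np.zeros(n_sites)
    delta_within = np.zeros(n_sites)
    delta_trans = np.zeros(n_sites)

    n_planted = (
        params.n_ind_expected + params.n_ind_opposite
        + params.n_inconclusive + params.n_stable_only
    )
    if n_planted:
        lo, hi = params.eligible_pi0
        eligible = np.flatnonzero(
            (pi0 >= lo) & (pi0 <= hi) & (chrom != layout.sex_chrom)
        )
        if len(eligible) < n_planted:
            raise ValueError(
                f"only {len(eligible)} eligible sites for {n_planted} planted effects"
            )
        chosen = rng.choice(eligible, size=n_planted, replace=False)
        labels = (
            [IND_EXPECTED] * params.n_ind_expected
            + [IND_OPPOSITE] * params.n_ind_opposite
            + [INCONCLUSIVE_EFFECT] * params.n_inconclusive
            + [POP_EFFECT] * params.n_stable_only
        )
        for idx, label in zip(chosen, labels):
            sign = 1.0 if pi0[idx] <= 0.5 else -1.0
            if params.delta_wild_fixed is not None:
                mag = params.delta_wild_fixed
            else:
                mag = rng.uniform(*params.delta_wild_range)
            dw = sign * mag
            planted_class[idx] = label
            delta_wild[idx] = dw
            if label == IND_EXPECTED:
                delta_trans[idx] = params.trans_fraction * dw
                delta_within[idx] = params.within_fraction * delta_trans[idx]
            elif label == IND_OPPOSITE:
                delta_trans[idx] = -params.trans_fraction * dw
                delta_within[idx] = params.within_fraction * delta_trans[idx]
            elif label == INCONCLUSIVE_EFFECT:
                delta_within[idx] = sign * params.delta_inconclusive
                delta_trans[idx] = sign * params.delta_inconclusive

    # per-group mean methylation per site
    group_mean: dict[str, np.ndarray] = {}
    for g in WILD_GROUPS + EXP_GROUPS:
        if g == TARGET_GROUP:
            mean = pi0 + delta_wild / 100.0
        elif g == "within6":
            mean = pi0 + delta_within / 100.0
        elif g == "trans6":
            mean = pi0 + delta_trans / 100.0
        else:  # KIE20, SYL33, ctrl20, within33, trans33 stay at baseline
            mean = pi0.copy()
        group_mean[g] = mean
    n_clipped = int(sum(
        ((m < 0.01) | (m > 0.99)).sum() for m in group_mean.values()
    ))
    clipped_sites = np.zeros(n_sites, dtype=bool)
    for g in group_mean:
        clipped_sites |= (group_mean[g] < 0.01) | (group_mean[g] > 0.99)
        group_mean[g] = np.clip(group_mean[g], 0.01, 0.99)
    if n_clipped:
        logger.info("simulate_methylation: clipped %d group-mean value(s)", n_clipped)

    samples = sheet.samples
    n_samp = len(samples)
    coverage = np.zeros((n_sites, n_samp), dtype=np.int64)
    methylated = np.zeros((n_sites, n_samp), dtype=np.int64)

    k = params.coverage_dispersion
    p_nb = k / (k + params.mean_coverage)
    families = sorted({sheet.family_of(s) for s in samples if sheet.family_of(s)})
    fam_effect = {
        f: rng.normal(0.0, params.sigma_family, size=n_sites) if params.sigma_family > 0
        else np.zeros(n_sites)
        for f in families
    }
    for j, s in enumerate(samples):
        g = sheet.df.loc[s, "group"]
        mean = group_mean[g]
        fam = sheet.family_of(s)
        if fam:
            mean = _expit(_logit(mean) + fam_effect[fam])
        cov = rng.negative_binomial(k, p_nb, size=n_sites)
        cov = np.maximum(cov, 1)  # truncate at >= 1 read
        if params.rho > 0:
            s_ab = (1.0 - params.rho) / params.rho
            p_cell = rng.beta(mean * s_ab, (1.0 - mean) * s_ab)
        else:
            p_cell = mean
        meth = rng.binomial(cov, p_cell)
        coverage[:, j] = cov
        methylated[:, j] = meth

    matrix = MethylationMatrix(chrom, pos, samples, coverage, methylated)
    truth_sites = pd.DataFrame({
        "chrom": chrom, "pos": pos, "pi0": pi0,
        "planted_class": planted_class,
        "delta_wild": delta_wild,
        "delta_within": delta_within,
        "delta_trans": delta_trans,
        "clipped": clipped_sites,
    })
    return matrix, sheet, TruthTable(sites=truth_sites)


def simulate_genotypes(
    layout: GenomeLayout,
    truth: TruthTable,
    params: SimulationParams,
    seed: int | np.random.Generator = 0,
    wild_samples: list[str] | None = None,
) -> tuple[VariantTable, pd.DataFrame]:
    """Balding–Nichols genotypes for the three wild populations.

    SNP positions are uniform over the autosomes, plus a guaranteed
    ``snps_per_inducible_window`` SNPs within +/- ``geno_halfwin_bp`` of
    every planted inducible site.  Each SNP's three population frequencies
    are drawn from Beta(p(1-F)/F, (1-p)(1-F)/F) around an ancestral
    frequency p ~ U(0.05, 0.95), with class-specific target F; genotypes
    are Hardy–Weinberg draws, depth is Poisson(``mean_dp``), GQ fixed 60.

    Returns the variant table and a SNP truth frame.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if wild_samples is None:
        wild_samples = [
            f"{g}_{i + 1:02d}"
            for g, n in zip(WILD_GROUPS, params.n_per_pop_geno)
            for i in range(n)
        ]
    pop_of = np.array([s.split("_")[0] for s in wild_samples], dtype=object)

    cpg_taken = set(zip(layout.cpg["chrom"], layout.cpg["pos"]))
    cpg_taken |= {(c, p + 1) for c, p in zip(layout.cpg["chrom"], layout.cpg["pos"])}
    autosomes = [c for c in layout.chroms if c != layout.sex_chrom]

    positions: list[tuple[str, int]] = []
    classes: list[str] = []
    taken = set(cpg_taken)

    def place(chrom_name: str, lo: int, hi: int, snp_class: str, count: int) -> None:
        placed = 0
        attempts = 0
        while placed < count and attempts < count * 50:
            attempts += 1
            p = int(rng.integers(max(1, lo), hi + 1))
            if (chrom_name, p) in taken:
                continue
            taken.add((chrom_name, p))
            positions.append((chrom_name, p))
            classes.append(snp_class)
            placed += 1

    inducible = truth.sites[
        truth.sites["planted_class"].isin([IND_EXPECTED, IND_OPPOSITE])
    ]
    for _, r in inducible.iterrows():
        snp_class = "expected" if r["planted_class"] == IND_EXPECTED else "opposite"
        place(
            str(r["chrom"]),
            int(r["pos"]) - params.geno_halfwin_bp,
            min(int(r["pos"]) + params.geno_halfwin_bp, layout.chroms[str(r["chrom"])]),
            snp_class,
            params.snps_per_inducible_window,
        )
    n_uniform = max(params.n_snps - len(positions), 0)
    for _ in range(n_uniform):
        chrom_name = autosomes[int(rng.integers(len(autosomes)))]
        place(chrom_name, 1, layout.chroms[chrom_name], "background", 1)

    f_of = {
        "background": params.f_background,
        "expected": params.f_expected,
        "opposite": params.f_opposite,
    }
    n_var = len(positions)
    chrom = np.array([c for c, _ in positions], dtype=object)
    pos = np.array([p for _, p in positions], dtype=np.int64)
    anc = rng.uniform(0.05, 0.95, size=n_var)
    pop_freq = np.zeros((n_var, len(WILD_GROUPS)))
    for i in range(n_var):
        F = f_of[classes[i]]
        a = anc[i] * (1 - F) / F
        b = (1 - anc[i]) * (1 - F) / F
        pop_freq[i] = rng.beta(a, b, size=len(WILD_GROUPS))

    gt = np.zeros((n_var, len(wild_samples)), dtype=np.int8)
    for gi, g in enumerate(WILD_GROUPS):
        cols = np.flatnonzero(pop_of == g)
        freq = pop_freq[:, gi][:, None]
        gt[:, cols] = rng.binomial(2, np.broadcast_to(freq, (n_var, len(cols))))
    dp = rng.poisson(params.mean_dp, size=(n_var, len(wild_samples))).astype(np.int32)
    dp = np.maximum(dp, 1)
    gq = np.full((n_var, len(wild_samples)), 60, dtype=np.int32)

    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=n_var)]
    alt = np.empty(n_var, dtype=object)
    for i in range(n_var):
        choices = [b for b in "ACGT" if b != ref[i]]
        alt[i] = choices[int(rng.integers(3))]

    v = VariantTable(chrom, pos, ref.astype(object), alt, list(wild_samples), gt, dp, gq)
    snp_truth = pd.DataFrame({
        "chrom": chrom, "pos": pos, "snp_class": classes,
        "target_f": [f_of[c] for c in classes], "ancestral_f": anc,
        "freq_NYN6": pop_freq[:, 0], "freq_KIE20": pop_freq[:, 1],
        "freq_SYL33": pop_freq[:, 2],
    })
    order = np.lexsort((snp_truth["pos"], snp_truth["chrom"]))
    return v, snp_truth.iloc[order].reset_index(drop=True)


def inject_cpg_snps(
    v: VariantTable,
    layout: GenomeLayout,
    fraction: float,
    seed: int | np.random.Generator = 0,
    maf_range: tuple[float, float] = (0.1, 0.5),
    exclude: set[tuple[str, int]] | None = None,
) -> tuple[VariantTable, pd.DataFrame]:
    """Add C>T / G>A SNPs at a fraction of CpG sites (confound injection).

    Half the injected variants are C>T at the forward C position, half
    G>A at the paired G (pos + 1); allele frequencies are uniform in
    ``maf_range`` across all samples so they pass the MAF gate.  Sites in
    ``exclude`` (e.g. planted-effect sites) are never injected.  Returns
    the augmented table and the injected-site truth frame.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0,1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cpg = layout.cpg
    candidates = [
        (str(c), int(p)) for c, p in zip(cpg["chrom"], cpg["pos"])
        if exclude is None or (str(c), int(p)) not in exclude
    ]
    n_inject = int(round(fraction * len(cpg)))
    if n_inject == 0:
        return v, pd.DataFrame(columns=["chrom", "pos", "kind"])
    pick = rng.choice(len(candidates), size=min(n_inject, len(candidates)), replace=False)
    rows = []
    chrom, pos, ref, alt, gts = [], [], [], [], []
    for idx_n, idx in enumerate(pick):
        c, p = candidates[idx]
        if idx_n % 2 == 0:
            snp_pos, snp_ref, snp_alt, kind = p, "C", "T", "C>T"
        else:
            snp_pos, snp_ref, snp_alt, kind = p + 1, "G", "A", "G>A"
        af = rng.uniform(*maf_range)
        gts.append(rng.binomial(2, af, size=len(v.samples)).astype(np.int8))
        chrom.append(c)
        pos.append(snp_pos)
        ref.append(snp_ref)
        alt.append(snp_alt)
        rows.append({"chrom": c, "pos": p, "kind": kind})
    n = len(chrom)
    dp = np.maximum(rng.poisson(20.0, size=(n, len(v.samples))), 1).astype(np.int32)
    gq = np.full((n, len(v.samples)), 60, dtype=np.int32)
    injected = VariantTable(
        np.array(chrom, dtype=object), np.array(pos, dtype=np.int64),
        np.array(ref, dtype=object), np.array(alt, dtype=object),
        list(v.samples), np.vstack(gts), dp, gq,
    )
    merged = VariantTable.concat([v, injected])
    truth = pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
    return merged, truth


@dataclass
class Scenario:
    """An in-memory synthetic study: counts, metadata, genotypes, truth."""

    matrix: MethylationMatrix
    sheet: SampleSheet
    variants: VariantTable
    layout: GenomeLayout
    truth: TruthTable
    injected_cpg_snps: pd.DataFrame
    params: SimulationParams


def simulate_scenario(
    params: SimulationParams | None = None,
    seed: int = 0,
) -> Scenario:
    """One-call scenario generator; deterministic in (params, seed)."""
    params = params or SimulationParams()
    rng = np.random.default_rng(seed)
    layout = generate_layout(
        params.n_chroms, params.chrom_len, params.n_cpg, params.n_genes, rng
    )
    matrix, sheet, truth = simulate_methylation(layout, params, rng)
    variants, snp_truth = simulate_genotypes(layout, truth, params, rng)
    planted = truth.sites[truth.sites["planted_class"] != NULL]
    exclude = set(zip(planted["chrom"].astype(str), planted["pos"].astype(int)))
    variants, injected = inject_cpg_snps(
        variants, layout, params.inject_fraction, rng,
        maf_range=params.inject_maf_range, exclude=exclude,
    )
    truth.snps = snp_truth
    return Scenario(matrix, sheet, variants, layout, truth, injected, params)


def write_scenario(scenario: Scenario, outdir: str | Path) -> None:
    """Write a scenario to disk in the pipeline's input formats.

    One Bismark-style coverage file per sample, a TSV sample sheet, an
    uncompressed VCF, a GFF3 gene file and the truth tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    covdir = outdir / "coverage"
    covdir.mkdir(exist_ok=True)
    for s in scenario.matrix.samples:
        write_coverage_file(scenario.matrix, s, covdir / f"{s}.cov")
    write_sample_sheet(scenario.sheet, outdir / "sample_sheet.tsv")
    write_vcf(scenario.variants, outdir / "variants.vcf", scenario.layout.chroms)
    write_gff(scenario.layout.genes, outdir / "genes.gff3")
    scenario.truth.sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    scenario.truth.snps.to_csv(outdir / "truth_snps.tsv", sep="\t", index=False)
    scenario.injected_cpg_snps.to_csv(
        outdir / "truth_injected_cpg_snps.tsv", sep="\t", index=False
    )
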