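"""Readers, writers and validated in-memory types for all on-disk formats.

Every downstream module consumes the containers defined here:

* :class:`MethylationMatrix` — per-CpG, per-sample (coverage, methylated)
  integer read-count pairs from Bismark-style coverage files.
* :class:`SampleSheet` — sample metadata (cohort, group, family, sex).
* :class:`VariantTable` — biallelic SNP genotypes with depth and quality.
* :class:`GeneModel` — gene span, strand, TSS and exon structure.
* :class:`AnalysisConfig` — every numeric threshold of the analysis,
  mirrored field-for-field by the YAML config file.

Coordinates are 1-based inclusive everywhere, the convention shared by
Bismark coverage files, VCF and GFF3.  BED-style half-open inputs are not
accepted, which avoids mixed conventions in a single pipeline.

A CpG site is keyed by the forward-strand C position.  Reverse-strand
calls at ``pos + 1`` can be folded into the forward site at read time
(counts summed) when the set of forward-strand positions is known;
methylation at a CpG is then a single destranded locus.

Missing data at a (site, sample) cell is explicit: internally a cell with
``coverage == 0`` means *absent* (no observation), never an observed
coverage of zero.  Rows with zero total counts in input files are
normalised to absent with a logged count.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "CpGSite",
    "MethylationMatrix",
    "SampleSheet",
    "VariantTable",
    "GeneModel",
    "AnalysisConfig",
    "read_coverage_file",
    "read_sample_sheet",
    "read_vcf_minimal",
    "read_gff_genes",
    "write_results_table",
    "read_results_table",
    "write_matrix",
    "read_matrix",
]

WILD = "wild"
EXPERIMENTAL = "experimental"


@dataclass(frozen=True, order=True)
class CpGSite:
    """A CpG locus keyed by the 1-based forward-strand cytosine position."""

    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")


def _site_order(chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Total order by (chrom string, pos int) used throughout the package."""
    return np.lexsort((pos, chrom))


class MethylationMatrix:
    """Per-site, per-sample methylation read counts.

    Parameters
    ----------
    chrom, pos
        Site coordinates, 1-based forward-strand C positions.
    samples
        Ordered sample identifiers.
    coverage, methylated
        Integer arrays of shape ``(n_sites, n_samples)``.  A cell with
        coverage 0 is *absent* (no observation for that sample at that
        site); present cells satisfy ``0 <= methylated <= coverage``.
    """

    def __init__(
        self,
        chrom: Sequence[str],
        pos: Sequence[int],
        samples: Sequence[str],
        coverage: np.ndarray,
        methylated: np.ndarray,
    ) -> None:
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.samples = list(samples)
        self.coverage = np.asarray(coverage, dtype=np.int64)
        self.methylated = np.asarray(methylated, dtype=np.int64)
        self._validate()
        self._sort()

    def _validate(self) -> None:
        n, s = self.coverage.shape
        if self.methylated.shape != (n, s):
            raise ValueError("coverage and methylated shapes differ")
        if len(self.chrom) != n or len(self.pos) != n:
            raise ValueError("site annotation length mismatch")
        if len(self.samples) != s:
            raise ValueError("sample list length mismatch")
        if len(set(self.samples)) != s:
            raise ValueError("duplicate sample ids")
        if (self.pos < 1).any():
            raise ValueError("positions must be >= 1")
        if (self.methylated < 0).any() or (self.coverage < 0).any():
            raise ValueError("negative counts")
        if (self.methylated > self.coverage).any():
            raise ValueError("methylated exceeds coverage")
        keys = list(zip(self.chrom, self.pos))
        if len(set(keys)) != n:
            raise ValueError("duplicate (chrom, pos) sites")

    def _sort(self) -> None:
        order = _site_order(self.chrom, self.pos)
        self.chrom = self.chrom[order]
        self.pos = self.pos[order]
        self.coverage = self.coverage[order]
        self.methylated = self.methylated[order]

    # -- basic interface -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def present(self) -> np.ndarray:
        """Boolean (n_sites, n_samples) mask of observed cells."""
        return self.coverage > 0

    def sites(self) -> list[CpGSite]:
        return [CpGSite(c, int(p)) for c, p in zip(self.chrom, self.pos)]

    def site_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "pos": self.pos})

    def sample_index(self, sample_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return np.array([lookup[s] for s in sample_ids], dtype=np.intp)

    def subset_sites(self, mask: np.ndarray) -> "MethylationMatrix":
        mask = np.asarray(mask, dtype=bool)
        return MethylationMatrix(
            self.chrom[mask], self.pos[mask], self.samples,
            self.coverage[mask], self.methylated[mask],
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "MethylationMatrix":
        idx = self.sample_index(sample_ids)
        return MethylationMatrix(
            self.chrom, self.pos, [self.samples[i] for i in idx],
            self.coverage[:, idx], self.methylated[:, idx],
        )

    def copy(self) -> "MethylationMatrix":
        return MethylationMatrix(
            self.chrom.copy(), self.pos.copy(), list(self.samples),
            self.coverage.copy(), self.methylated.copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MethylationMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.coverage, other.coverage)
            and np.array_equal(self.methylated, other.methylated)
        )

    @staticmethod
    def merge(matrices: Sequence["MethylationMatrix"]) -> "MethylationMatrix":
        """Union of sites across single/multi-sample matrices.

        A sample missing at a site is absent there (coverage 0 cell).
        """
        if not matrices:
            raise ValueError("nothing to merge")
        frames = []
        for k, m in enumerate(matrices):
            df = pd.DataFrame(
                np.concatenate([m.coverage, m.methylated], axis=1),
                index=pd.MultiIndex.from_arrays([m.chrom, m.pos]),
                columns=[f"c{k}_{s}" for s in m.samples]
                + [f"m{k}_{s}" for s in m.samples],
            )
            frames.append(df)
        merged = pd.concat(frames, axis=1).fillna(0).astype(np.int64)
        samples: list[str] = []
        cov_cols: list[str] = []
        meth_cols: list[str] = []
        for k, m in enumerate(matrices):
            for s in m.samples:
                if s in samples:
                    raise ValueError(f"duplicate sample id across matrices: {s}")
                samples.append(s)
                cov_cols.append(f"c{k}_{s}")
                meth_cols.append(f"m{k}_{s}")
        chrom = merged.index.get_level_values(0).to_numpy(dtype=object)
        pos = merged.index.get_level_values(1).to_numpy(dtype=np.int64)
        return MethylationMatrix(
            chrom, pos, samples,
            merged[cov_cols].to_numpy(), merged[meth_cols].to_numpy(),
        )


@dataclass
class SampleSheet:
    """Sample metadata table.

    ``df`` is indexed by sample id with columns ``cohort`` (wild or
    experimental), ``group``, ``family`` (empty string when absent; required
    for experimental samples) and ``sex`` (F, M or unknown).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"cohort", "group", "family", "sex"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"sample sheet missing columns {required - set(self.df.columns)}")
        if self.df.index.duplicated().any():
            dup = self.df.index[self.df.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample id(s): {dup}")
        bad = set(self.df["cohort"]) - {WILD, EXPERIMENTAL}
        if bad:
            raise ValueError(f"unknown cohort label(s): {bad}")
        exp = self.df[self.df["cohort"] == EXPERIMENTAL]
        no_family = exp[exp["family"].astype(str).isin(["", "nan"])]
        if len(no_family):
            raise ValueError(
                f"experimental samples without family id: {no_family.index.tolist()}"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.df.index)

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.df["group"]))

    def samples_in_group(self, group: str) -> list[str]:
        sel = self.df[self.df["group"] == group]
        if sel.empty:
            raise KeyError(f"no samples in group {group!r}")
        return list(sel.index)

    def cohort_of_group(self, group: str) -> str:
        cohorts = set(self.df.loc[self.df["group"] == group, "cohort"])
        if len(cohorts) != 1:
            raise ValueError(f"group {group!r} spans cohorts {cohorts}")
        return cohorts.pop()

    def family_of(self, sample: str) -> str:
        return str(self.df.loc[sample, "family"])


# genotype codes: number of alt alleles, -1 for missing
GT_MISSING = -1


@dataclass
class VariantTable:
    """Biallelic SNP records with per-sample genotype, depth and quality.

    ``gt`` holds alt-allele dosage (0, 1, 2) with -1 for missing; ``dp``
    and ``gq`` hold per-genotype depth and quality with -1 for missing.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    samples: list[str]
    gt: np.ndarray
    dp: np.ndarray
    gq: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.gt = np.asarray(self.gt, dtype=np.int8)
        self.dp = np.asarray(self.dp, dtype=np.int32)
        self.gq = np.asarray(self.gq, dtype=np.int32)
        n = len(self.pos)
        s = len(self.samples)
        for arr, name in ((self.gt, "gt"), (self.dp, "dp"), (self.gq, "gq")):
            if arr.shape != (n, s):
                raise ValueError(f"{name} shape {arr.shape} != ({n}, {s})")
        if (self.pos < 1).any():
            raise ValueError("positions must be >= 1")
        order = _site_order(self.chrom, self.pos)
        for name in ("chrom", "pos", "ref", "alt", "gt", "dp", "gq"):
            setattr(self, name, getattr(self, name)[order])

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    def sample_index(self, sample_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise KeyError(f"samples not in variant table: {missing}")
        return np.array([lookup[s] for s in sample_ids], dtype=np.intp)

    def subset(self, mask: np.ndarray) -> "VariantTable":
        mask = np.asarray(mask, dtype=bool)
        return VariantTable(
            self.chrom[mask], self.pos[mask], self.ref[mask], self.alt[mask],
            list(self.samples), self.gt[mask], self.dp[mask], self.gq[mask],
        )

    @staticmethod
    def concat(tables: Sequence["VariantTable"]) -> "VariantTable":
        if not tables:
            raise ValueError("nothing to concatenate")
        samples = tables[0].samples
        for t in tables[1:]:
            if t.samples != samples:
                raise ValueError("sample lists differ between variant tables")
        return VariantTable(
            np.concatenate([t.chrom for t in tables]),
            np.concatenate([t.pos for t in tables]),
            np.concatenate([t.ref for t in tables]),
            np.concatenate([t.alt for t in tables]),
            list(samples),
            np.concatenate([t.gt for t in tables]),
            np.concatenate([t.dp for t in tables]),
            np.concatenate([t.gq for t in tables]),
        )


@dataclass(frozen=True)
class GeneModel:
    """Gene span with strand, TSS and exons, 1-based inclusive."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError("invalid gene span")
        for s, e in self.exons:
            if s < self.start or e > self.end or s > e:
                raise ValueError(
                    f"exon ({s},{e}) outside gene span ({self.start},{self.end})"
                )

    @property
    def tss(self) -> int:
        """Transcription start: gene start on +, gene end on -."""
        return self.start if self.strand == "+" else self.end


@dataclass
class AnalysisConfig:
    """All numeric thresholds of the analysis, YAML-mirrorable.

    Defaults reproduce the published filtering and calling chain: minimum
    coverage 10, per-sample 99.9th-percentile coverage cap, SNP exclusion
    at GQ >= 20 and MAF >= 0.005, presence in >= 9 individuals per group,
    sex-chromosome removal, q < 0.0125 (Bonferroni 0.05/4 over the four
    pairwise designs) with >= 15 percentage-point weighted difference,
    promoter = TSS -1500/+500 bp, 10-kb TSS gene association, +/-5-kb FST
    windows (<= 60% missing genotypes, depth >= 5), 1000 enrichment
    replicates and 10,000 FST randomizations.
    """

    alpha_q: float = 0.0125
    min_diff_pct: float = 15.0
    min_cov: int = 10
    high_cov_percentile: float = 99.9
    min_per_group: int = 9
    sex_chrom: str = "chr19"
    snp_min_gq: float = 20.0
    snp_min_maf: float = 0.005
    promoter_up: int = 1500
    promoter_down: int = 500
    tss_assoc_bp: int = 10000
    fst_halfwin_bp: int = 5000
    fst_max_missing: float = 0.6
    fst_min_dp: int = 5
    n_enrich_reps: int = 1000
    n_fst_boot: int = 10000
    seed: int = 0
    # non-printed switches
    normalize_target: str = "median"  # or "max"
    fst_p_correction: bool = False    # (count+1)/(n+1) instead of count/n
    fst_boot_mode: str = "permutation"  # or "bootstrap"

    def __post_init__(self) -> None:
        if not 0 < self.alpha_q < 1:
            raise ValueError("alpha_q must be in (0,1)")
        if not 0 <= self.fst_max_missing <= 1:
            raise ValueError("fst_max_missing must be in [0,1]")
        for name in (
            "min_diff_pct", "min_cov", "high_cov_percentile", "min_per_group",
            "snp_min_gq", "snp_min_maf", "promoter_up", "promoter_down",
            "tss_assoc_bp", "fst_halfwin_bp", "fst_min_dp",
            "n_enrich_reps", "n_fst_boot",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.normalize_target not in {"median", "max"}:
            raise ValueError("normalize_target must be 'median' or 'max'")
        if self.fst_boot_mode not in {"permutation", "bootstrap"}:
            raise ValueError("fst_boot_mode must be 'permutation' or 'bootstrap'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_COV_COLS = ["chrom", "start", "end", "pct_meth", "count_meth", "count_unmeth"]


def read_coverage_file(
    path: str | Path,
    sample_id: str,
    destrand_positions: set[tuple[str, int]] | None = None,
) -> MethylationMatrix:
    """Read one Bismark-style coverage file into a single-sample matrix.

    The dialect is six tab-separated columns: chrom, start, end (equal to
    start for a single cytosine), percent methylation, methylated count,
    unmethylated count.  Coverage is the sum of the two counts; the percent
    column is redundant and only cross-checked (counts win on conflict).

    When ``destrand_positions`` (the known forward-strand C positions) is
    given, a row at ``pos`` whose site is not in the set but whose ``pos-1``
    is, is treated as the reverse-strand call of the CpG at ``pos-1`` and
    its counts are summed into that site.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", names=_COV_COLS, header=None, comment="#",
            dtype={"chrom": str},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"{path}: malformed coverage file: {exc}") from exc
    for col in ("start", "end", "count_meth", "count_unmeth"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ValueError(f"{path}: malformed row at line {line}: non-numeric {col}")
        df[col] = df[col].astype(np.int64)
    mism = df["start"] != df["end"]
    if mism.any():
        line = int(mism.idxmax()) + 1
        raise ValueError(f"{path}: line {line}: start != end (expected single cytosine)")
    cov = df["count_meth"] + df["count_unmeth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        implied = np.where(cov > 0, 100.0 * df["count_meth"] / cov.replace(0, 1), 0.0)
    off = np.abs(implied - df["pct_meth"].astype(float)) > 0.5
    if off.any():
        logger.warning(
            "%s: %d row(s) with %%meth inconsistent with counts by >0.5; counts win",
            path, int(off.sum()),
        )
    zero = cov == 0
    if zero.any():
        logger.info("%s: %d zero-coverage row(s) treated as absent", path, int(zero.sum()))
    df = df[~zero]
    cov = cov[~zero]

    keys = pd.DataFrame({
        "chrom": df["chrom"].to_numpy(),
        "pos": df["start"].to_numpy(),
        "cov": cov.to_numpy(),
        "meth": df["count_meth"].to_numpy(),
    })
    if destrand_positions is not None:
        fold = [
            (c, p) not in destrand_positions and (c, p - 1) in destrand_positions
            for c, p in zip(keys["chrom"], keys["pos"])
        ]
        fold = np.asarray(fold)
        if fold.any():
            keys.loc[fold, "pos"] -= 1
            logger.info("%s: folded %d reverse-strand row(s)", path, int(fold.sum()))
    agg = keys.groupby(["chrom", "pos"], as_index=False, sort=False).sum()
    return MethylationMatrix(
        agg["chrom"].to_numpy(dtype=object),
        agg["pos"].to_numpy(),
        [sample_id],
        agg["cov"].to_numpy().reshape(-1, 1),
        agg["meth"].to_numpy().reshape(-1, 1),
    )


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a TSV/CSV sample sheet with columns sample, cohort, group, family, sex."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    required = {"sample", "cohort", "group", "family", "sex"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample sheet missing columns {required - set(df.columns)}")
    df = df.set_index("sample")
    return SampleSheet(df[["cohort", "group", "family", "sex"]])


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    out = sheet.df.reset_index()
    out = out.rename(columns={out.columns[0]: "sample"})
    out.to_csv(path, sep="\t", index=False)


def read_vcf_minimal(path: str | Path, samples: Sequence[str]) -> VariantTable:
    """Read biallelic SNPs (GT, optional DP/GQ) for the requested samples.

    Multiallelic records are skipped with a logged count.  Records where
    REF or ALT is not a single base are skipped likewise (indels).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    overlap = [s for s in samples if s in vcf.samples]
    if not overlap:
        raise ValueError("no overlap between VCF samples and requested samples")
    vcf.close()
    vcf = VCF(str(path), samples=overlap)
    got = list(vcf.samples)

    chrom, pos, ref, alt, gts, dps, gqs = [], [], [], [], [], [], []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
        g = np.asarray(rec.genotypes, dtype=object)
        row = np.full(len(got), GT_MISSING, dtype=np.int8)
        for j, call in enumerate(g):
            a, b = call[0], call[1]
            if a >= 0 and b >= 0:
                row[j] = a + b
        gts.append(row)
        try:
            dp = rec.format("DP")
        except KeyError:  # FORMAT field absent from the header
            dp = None
        dps.append(
            np.full(len(got), -1, dtype=np.int32) if dp is None
            else np.where(dp[:, 0] < 0, -1, dp[:, 0]).astype(np.int32)
        )
        try:
            gq = rec.format("GQ")
        except KeyError:
            gq = None
        gqs.append(
            np.full(len(got), -1, dtype=np.int32) if gq is None
            else np.where(np.isnan(gq[:, 0].astype(float)), -1, gq[:, 0]).astype(np.int32)
        )
    vcf.close()
    if n_skipped:
        logger.info("%s: skipped %d multiallelic/non-SNP record(s)", path, n_skipped)
    if not pos:
        empty = np.zeros((0, len(got)), dtype=np.int32)
        return VariantTable(
            np.array([], dtype=object), np.array([], dtype=np.int64),
            np.array([], dtype=object), np.array([], dtype=object),
            got, empty.astype(np.int8), empty, empty,
        )
    return VariantTable(
        np.array(chrom, dtype=object), np.array(pos, dtype=np.int64),
        np.array(ref, dtype=object), np.array(alt, dtype=object),
        got, np.vstack(gts), np.vstack(dps), np.vstack(gqs),
    )


def read_gff_genes(path: str | Path) -> list[GeneModel]:
    """Read gene and exon features from a GFF3 file into GeneModels.

    Exons are attached to genes via Parent attributes.  A gene without
    exon children receives a single implicit exon spanning the gene.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    gene_ids = set()
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        gene_ids.add(g.id)
        exons = sorted(
            (e.start, e.end) for e in db.children(g, featuretype="exon")
        )
        if not exons:
            exons = [(g.start, g.end)]
        genes.append(
            GeneModel(
                gene_id=g.id, chrom=g.seqid, strand=g.strand,
                start=g.start, end=g.end, exons=tuple(exons),
            )
        )
    for e in db.features_of_type("exon"):
        parents = list(db.parents(e, featuretype="gene"))
        if not parents:
            raise ValueError(f"exon {e.id or e.start} has no parent gene")
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


# ---------------------------------------------------------------------------
# writers / round-trip tables
# ---------------------------------------------------------------------------

def write_results_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write any result table as TSV with header, deterministic column order."""
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"chrom": str})


def write_matrix(m: MethylationMatrix, path: str | Path) -> None:
    """Write a MethylationMatrix as wide TSV (cov_/meth_ column pairs).

    Absent cells are written as 0/0 and read back as absent — lossless
    because present cells always have coverage >= 1.
    """
    cols: dict[str, np.ndarray] = {"chrom": m.chrom, "pos": m.pos}
    for j, s in enumerate(m.samples):
        cols[f"cov_{s}"] = m.coverage[:, j]
        cols[f"meth_{s}"] = m.methylated[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path) -> MethylationMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    samples = [c[4:] for c in df.columns if c.startswith("cov_")]
    cov = df[[f"cov_{s}" for s in samples]].to_numpy(dtype=np.int64)
    meth = df[[f"meth_{s}" for s in samples]].to_numpy(dtype=np.int64)
    return MethylationMatrix(
        df["chrom"].to_numpy(dtype=object), df["pos"].to_numpy(dtype=np.int64),
        samples, cov, meth,
    )


def write_coverage_file(m: MethylationMatrix, sample: str, path: str | Path) -> None:
    """Write one sample of a matrix as a Bismark-style coverage file."""
    j = m.sample_index([sample])[0]
    present = m.coverage[:, j] > 0
    cov = m.coverage[present, j]
    meth = m.methylated[present, j]
    pct = 100.0 * meth / cov
    out = pd.DataFrame({
        "chrom": m.chrom[present],
        "start": m.pos[present],
        "end": m.pos[present],
        "pct": np.round(pct, 6),
        "meth": meth,
        "unmeth": cov - meth,
    })
    out.to_csv(path, sep="\t", index=False, header=False)


def write_vcf(v: VariantTable, path: str | Path, contigs: dict[str, int] | None = None) -> None:
    """Write a VariantTable as uncompressed VCF 4.2 with GT:DP:GQ."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(v.samples) + "\n"
        )
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", GT_MISSING: "./."}
        for i in range(v.n_variants):
            fields = [
                str(v.chrom[i]), str(v.pos[i]), ".", str(v.ref[i]), str(v.alt[i]),
                ".", "PASS", ".", "GT:DP:GQ",
            ]
            for j in range(len(v.samples)):
                dp = "." if v.dp[i, j] < 0 else str(v.dp[i, j])
                gq = "." if v.gq[i, j] < 0 else str(v.gq[i, j])
                fields.append(f"{gt_str[int(v.gt[i, j])]}:{dp}:{gq}")
            fh.write("\t".join(fields) + "\n")


def write_gff(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write GeneModels as a minimal GFF3 (gene + exon features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda x: (x.chrom, x.start, x.gene_id)):
            fh.write(
                f"{g.chrom}\tepichannel\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for k, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tepichannel\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{k};Parent={g.gene_id}\n"
                )
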