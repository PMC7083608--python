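"""Filter-chain behavior: boundaries, idempotence, SNP-overlap rules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epichannel.io_formats import MethylationMatrix, SampleSheet, VariantTable
from epichannel.qc_filtering import (
    correct_snp_overlap,
    drop_blacklist,
    drop_chromosome,
    filter_high_coverage,
    filter_min_coverage,
    filter_presence,
    normalize_coverage,
)


def mk_matrix(cov, meth, chroms=None):
    cov = np.atleast_2d(np.asarray(cov))
    meth = np.atleast_2d(np.asarray(meth))
    n = cov.shape[0]
    chroms = chroms or ["chr1"] * n
    return MethylationMatrix(
        chroms, np.arange(1, n + 1) * 10,
        [f"s{j}" for j in range(cov.shape[1])], cov, meth,
    )


def mk_variants(records, samples=("s0", "s1")):
    """records: list of (chrom, pos, ref, alt, gts)"""
    n = len(records)
    gt = np.array([r[4] for r in records], dtype=np.int8).reshape(n, len(samples))
    dp = np.full((n, len(samples)), 20, dtype=np.int32)
    gq = np.full((n, len(samples)), 60, dtype=np.int32)
    return VariantTable(
        [r[0] for r in records], [r[1] for r in records],
        [r[2] for r in records], [r[3] for r in records],
        list(samples), gt, dp, gq,
    )


class TestMinCoverage:
    def test_boundary(self):
        m = mk_matrix([[9], [10]], [[4], [5]])
        out = filter_min_coverage(m, 10)
        assert out.n_sites == 1 and out.coverage[0, 0] == 10

    def test_all_absent_site_removed(self):
        m = mk_matrix([[9, 8], [12, 15]], [[1, 1], [2, 2]])
        out = filter_min_coverage(m, 10)
        assert out.n_sites == 1 and list(out.pos) == [20]

    def test_idempotent(self):
        m = mk_matrix([[9, 30], [12, 15], [40, 3]], [[1, 10], [2, 2], [30, 1]])
        once = filter_min_coverage(m, 10)
        assert filter_min_coverage(once, 10) == once


class TestHighCoverage:
    def test_percentile_oracle_1_to_1000(self):
        cov = np.arange(1, 1001).reshape(-1, 1)
        m = mk_matrix(cov, np.zeros_like(cov))
        out = filter_high_coverage(m, 99.9)
        # threshold = linear-interp 99.9th percentile of 1..1000 = 999.001
        thr = np.percentile(np.arange(1, 1001), 99.9)
        assert thr == pytest.approx(999.001)
        assert out.n_sites == 999 and out.coverage.max() == 999

    def test_uniform_coverage_untouched(self):
        cov = np.full((50, 2), 10)
        m = mk_matrix(cov, np.zeros_like(cov))
        assert filter_high_coverage(m, 99.9) == m

    def test_percentile_100_degenerate(self):
        cov = np.arange(1, 101).reshape(-1, 1)
        m = mk_matrix(cov, np.zeros_like(cov))
        assert filter_high_coverage(m, 100) == m

    def test_small_sample_skipped_with_warning(self, caplog):
        cov = np.array([[5], [9000]])
        m = mk_matrix(cov, np.zeros_like(cov))
        with caplog.at_level("WARNING"):
            out = filter_high_coverage(m, 99.9)
        assert out == m and "cap skipped" in caplog.text


class TestSnpOverlap:
    def test_c_to_t_at_c_position_removes_site(self):
        m = mk_matrix([[20, 20]], [[5, 5]])
        v = mk_variants([("chr1", 10, "C", "T", [0, 1])])
        assert correct_snp_overlap(m, v, 20, 0.005).n_sites == 0

    def test_g_to_a_at_paired_g_removes_site(self):
        m = mk_matrix([[20, 20]], [[5, 5]])
        v = mk_variants([("chr1", 11, "G", "A", [1, 0])])
        assert correct_snp_overlap(m, v, 20, 0.005).n_sites == 0

    def test_non_matching_substitution_kept(self):
        m = mk_matrix([[20, 20]], [[5, 5]])
        v = mk_variants([("chr1", 10, "A", "G", [1, 1])])
        assert correct_snp_overlap(m, v, 20, 0.005).n_sites == 1

    def test_maf_and_gq_gates(self):
        m = mk_matrix([[20, 20]], [[5, 5]])
        low_maf = mk_variants([("chr1", 10, "C", "T", [0, 0])])  # MAF 0
        assert correct_snp_overlap(m, low_maf, 20, 0.005).n_sites == 1
        low_gq = mk_variants([("chr1", 10, "C", "T", [0, 1])])
        low_gq.gq[:] = 10
        assert correct_snp_overlap(m, low_gq, 20, 0.005).n_sites == 1


class TestNormalize:
    def test_scaling_to_median_of_medians(self):
        # medians 10 and 20 -> target 15, factors 1.5 and 0.75
        cov = np.column_stack([np.full(11, 10), np.full(11, 20)])
        meth = (cov * 0.5).astype(int)
        out = normalize_coverage(mk_matrix(cov, meth))
        assert out.coverage[:, 0].max() == 15 and out.coverage[:, 1].max() == 15

    def test_entry_rescaling_preserves_fraction(self):
        # (cov 10, meth 5), factor 1.5 -> (15, 8): 0.5*15 = 7.5 rounds to 8
        cov = np.column_stack([np.full(3, 10), np.full(3, 20)])
        meth = np.column_stack([np.full(3, 5), np.full(3, 10)])
        out = normalize_coverage(mk_matrix(cov, meth))
        assert out.coverage[0, 0] == 15 and out.methylated[0, 0] == 8

    def test_equal_medians_identity(self):
        cov = np.full((9, 3), 12)
        m = mk_matrix(cov, (cov * 0.25).astype(int))
        assert normalize_coverage(m) == m

    def test_fraction_preserved_within_one_read(self):
        rng = np.random.default_rng(0)
        cov = rng.integers(10, 60, size=(60, 4))
        meth = rng.binomial(cov, 0.3)
        m = mk_matrix(cov, meth)
        out = normalize_coverage(m)
        f0 = m.methylated / m.coverage
        f1 = out.methylated / out.coverage
        assert (np.abs(f1 - f0) <= 1.0 / out.coverage + 1e-12).all()
        assert (out.coverage >= 1).all()

    def test_idempotent_after_equalization(self):
        cov = np.column_stack([np.full(11, 10), np.full(11, 20)])
        m = mk_matrix(cov, (cov * 0.5).astype(int))
        once = normalize_coverage(m)
        assert normalize_coverage(once) == once


class TestPresence:
    @staticmethod
    def _sheet(n_per_group):
        rows = []
        for g, n in n_per_group.items():
            for i in range(n):
                rows.append({"sample": f"{g}_{i}", "cohort": "wild", "group": g,
                             "family": "", "sex": "F"})
        return SampleSheet(pd.DataFrame(rows).set_index("sample"))

    def test_boundary_and_drop(self):
        sheet = self._sheet({"A": 10, "B": 10})
        cov = np.zeros((2, 20), dtype=int)
        cov[0, :9] = 10   # 9 of A present
        cov[0, 10:19] = 10  # 9 of B present
        cov[1, :8] = 10   # 8 of A present
        cov[1, 10:] = 10
        m = MethylationMatrix(
            ["chr1", "chr1"], [10, 20],
            [f"{g}_{i}" for g in ("A", "B") for i in range(10)],
            cov, np.zeros_like(cov),
        )
        out = filter_presence(m, sheet, ["A", "B"], 9)
        assert list(out.pos) == [10]

    def test_unsatisfiable_group_errors(self):
        sheet = self._sheet({"A": 5})
        cov = np.full((1, 5), 10)
        m = MethylationMatrix(["chr1"], [10], [f"A_{i}" for i in range(5)],
                              cov, np.zeros_like(cov))
        with pytest.raises(ValueError, match="unsatisfiable"):
            filter_presence(m, sheet, ["A"], 9)

    def test_min_zero_keeps_all(self):
        sheet = self._sheet({"A": 3})
        cov = np.array([[10, 0, 0]])
        m = MethylationMatrix(["chr1"], [10], ["A_0", "A_1", "A_2"],
                              cov, np.zeros_like(cov))
        out = filter_presence(m, sheet, ["A"], 0)
        assert out.n_sites == 1


class TestDropChromosome:
    def test_removes_labelled_sites(self):
        m = mk_matrix([[10], [10], [10]], [[1], [1], [1]],
                      chroms=["chr1", "chr19", "chr19"])
        out = drop_chromosome(m, "chr19")
        assert out.n_sites == 1 and out.chrom[0] == "chr1"

    def test_absent_label_noop_warns(self, caplog):
        m = mk_matrix([[10]], [[1]])
        with caplog.at_level("WARNING"):
            out = drop_chromosome(m, "chrZZ")
        assert out == m and "no-op" in caplog.text

    def test_commutes_with_presence(self):
        rows = [{"sample": f"s{j}", "cohort": "wild", "group": "A",
                 "family": "", "sex": "F"} for j in range(3)]
        sheet = SampleSheet(pd.DataFrame(rows).set_index("sample"))
        rng = np.random.default_rng(1)
        cov = rng.integers(0, 3, size=(30, 3)) * 10
        m = MethylationMatrix(
            ["chr19" if i % 3 == 0 else "chr1" for i in range(30)],
            np.arange(1, 31) * 7, ["s0", "s1", "s2"], cov, np.zeros_like(cov),
        )
        a = drop_chromosome(filter_presence(m, sheet, ["A"], 2), "chr19")
        b = filter_presence(drop_chromosome(m, "chr19"), sheet, ["A"], 2)
        assert a == b


class TestBlacklist:
    def test_set_difference(self):
        dms = pd.DataFrame({"chrom": ["chr1"] * 4, "pos": [1, 2, 3, 4]})
        black = pd.DataFrame({"chrom": ["chr1"], "pos": [3]})
        out = drop_blacklist(dms, black)
        assert list(out["pos"]) == [1, 2, 4]

    def test_empty_blacklist_identity(self):
        dms = pd.DataFrame({"chrom": ["chr1"], "pos": [1]})
        out = drop_blacklist(dms, pd.DataFrame(columns=["chrom", "pos"]))
        pd.testing.assert_frame_equal(out, dms)

    def test_superset_blacklist_empties(self):
        dms = pd.DataFrame({"chrom": ["chr1"], "pos": [1]})
        black = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [1, 2]})
        assert len(drop_blacklist(dms, black)) == 0


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_filters_idempotent_on_random_matrices(seed):
    """Applying each filter twice equals applying it once."""
    rng = np.random.default_rng(seed)
    n, s = rng.integers(5, 40), rng.integers(2, 5)
    cov = rng.integers(0, 60, size=(n, s))
    meth = rng.binomial(cov, 0.4)
    keep = cov.any(axis=1)
    if not keep.any():
        return
    m = MethylationMatrix(
        ["chr1"] * int(keep.sum()), np.flatnonzero(keep) + 1,
        [f"s{j}" for j in range(s)], cov[keep], meth[keep],
    )
    f1 = filter_min_coverage(m, 10)
    assert filter_min_coverage(f1, 10) == f1
    if f1.n_sites:
        # the percentile cap is one-shot (threshold recomputed on censored
        # data can nibble further); it must only ever remove entries
        f2 = filter_high_coverage(f1, 99.0)
        assert f2.n_sites <= f1.n_sites
        assert (f2.coverage > 0).sum() <= (f1.coverage > 0).sum()
        assert drop_chromosome(f2, "chrZZ") == f2
        # normalization is idempotent up to integer rounding: re-running
        # changes no methylation fraction by more than one read
        f3 = normalize_coverage(f2)
        f4 = normalize_coverage(f3)
        pres = f3.coverage > 0
        d = np.abs(
            f4.methylated[pres] / f4.coverage[pres]
            - f3.methylated[pres] / f3.coverage[pres]
        )
        assert (d <= 1.0 / f4.coverage[pres] + 1e-12).all()
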