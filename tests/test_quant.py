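"""iBAQ quantification, matrix filters, imputation and normalization."""

import re

import numpy as np
import pandas as pd
import pytest

from tiffms.quant import (QuantMatrix, build_quant_matrix,
                          count_theoretical_peptides, ibaq, impute_missing,
                          missingness_filter, protein_rollup,
                          quantifiable_filter, read_matrix,
                          reproducibility_stats, width_normalize, write_matrix)


def brute_force_tryptic_count(seq, min_len=7, max_len=30):
    """Independent enumeration of fully tryptic cleavage products."""
    sites = [0] + [i + 1 for i in range(len(seq) - 1)
                   if seq[i] in "KR" and seq[i + 1] != "P"] + [len(seq)]
    peptides = {seq[a:b] for a, b in zip(sites, sites[1:])}
    return sum(1 for p in peptides if min_len <= len(p) <= max_len)


class TestDigestion:
    def test_single_product(self):
        assert count_theoretical_peptides("AAAAAAAK") == 1

    def test_short_products_filtered(self):
        assert count_theoretical_peptides("AAAKAAAR") == 0

    def test_no_cleavage_before_proline(self):
        # KP junction is not cleaved: one product of length 9
        assert count_theoretical_peptides("AAAKPAAAR") == 1

    def test_empty_sequence(self):
        assert count_theoretical_peptides("") == 0

    def test_brute_force_oracle(self, rng):
        residues = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(100):
            n = rng.integers(10, 120)
            seq = "".join(rng.choice(residues, size=n))
            assert count_theoretical_peptides(seq) == brute_force_tryptic_count(seq)


class TestIbaq:
    def test_toy_example(self):
        assert ibaq(3e6, 3) == pytest.approx(1e6)

    def test_linearity(self):
        assert ibaq(5e6 * 3.0, 4) == pytest.approx(3.0 * ibaq(5e6, 4))

    def test_zero_theoretical_unquantifiable(self):
        assert ibaq(1e6, 0) is None

    def test_molar_proportionality(self):
        """Equal molar amounts, 3 vs 12 peptides: iBAQ ratio near 1 when
        per-peptide intensities are proportional to copy number."""
        rng = np.random.default_rng(21)
        abundance = 1e6
        for sigma, tol in ((0.0, 1e-9), (0.3, 0.8)):
            eff_a = 10.0 ** rng.normal(0, sigma, 3)
            eff_b = 10.0 ** rng.normal(0, sigma, 12)
            ibaq_a = ibaq(float(np.sum(abundance * eff_a)), 3)
            ibaq_b = ibaq(float(np.sum(abundance * eff_b)), 12)
            assert np.log10(ibaq_a / ibaq_b) == pytest.approx(0.0, abs=max(tol, 1e-9))


def matrix_from(values, groups=None, is_log2=True):
    frame = pd.DataFrame(values).astype(float)
    frame.columns = [str(c) for c in frame.columns]
    return QuantMatrix(frame, groups or {}, is_log2=is_log2)


class TestFilters:
    def test_missingness_boundary_closed(self):
        m = matrix_from({"a1": [1.0], "a2": [np.nan], "a3": [1.0], "a4": [np.nan]},
                        groups={c: "A" for c in ("a1", "a2", "a3", "a4")})
        assert len(missingness_filter(m, 0.5).values) == 1     # 50% kept
        m2 = matrix_from({"a1": [np.nan], "a2": [np.nan], "a3": [1.0],
                          "a4": [np.nan]},
                         groups={c: "A" for c in ("a1", "a2", "a3", "a4")})
        assert len(missingness_filter(m2, 0.5).values) == 0    # 75% dropped

    def test_any_condition_suffices(self):
        groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        m = matrix_from({"a1": [1.0], "a2": [1.0], "b1": [np.nan], "b2": [np.nan]},
                        groups=groups)
        assert len(missingness_filter(m, 0.5).values) == 1

    def test_all_observed_unchanged(self):
        m = matrix_from({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        out = missingness_filter(m, 0.5)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_quantifiable_two_valid_in_one_group(self):
        groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        m = matrix_from({"a1": [1.0], "a2": [1.0], "b1": [np.nan], "b2": [np.nan]},
                        groups=groups)
        assert len(quantifiable_filter(m, 2).values) == 1

    def test_quantifiable_one_everywhere_dropped(self):
        groups = {"a1": "A", "b1": "B"}
        m = matrix_from({"a1": [1.0], "b1": [1.0]}, groups=groups)
        assert len(quantifiable_filter(m, 2).values) == 0

    def test_empty_matrix(self):
        m = QuantMatrix(pd.DataFrame(columns=["a"], dtype=float), {}, is_log2=True)
        assert len(quantifiable_filter(m, 2).values) == 0

    def test_filters_monotone_in_threshold(self, rng):
        vals = rng.normal(20, 2, size=(60, 6))
        vals[rng.random(vals.shape) < 0.45] = np.nan
        groups = {str(i): ("A" if i < 3 else "B") for i in range(6)}
        m = matrix_from(pd.DataFrame(vals, columns=[str(i) for i in range(6)]),
                        groups=groups)
        kept_strict = set(missingness_filter(m, 0.3).values.index)
        kept_loose = set(missingness_filter(m, 0.6).values.index)
        assert kept_strict <= kept_loose
        q_strict = set(quantifiable_filter(m, 3).values.index)
        q_loose = set(quantifiable_filter(m, 2).values.index)
        assert q_strict <= q_loose


class TestImputation:
    def test_zero_sd_column_imputes_the_mean(self):
        m = matrix_from({"a": [20.0, 20.0, 20.0, np.nan]})
        out = impute_missing(m, seed=1)
        assert out.values["a"].iloc[3] == pytest.approx(20.0)

    def test_observed_cells_untouched_and_deterministic(self, rng):
        vals = rng.normal(20, 2, size=(50, 4))
        vals[rng.random(vals.shape) < 0.3] = np.nan
        m = matrix_from(pd.DataFrame(vals, columns=list("abcd")))
        out1 = impute_missing(m, seed=5)
        out2 = impute_missing(m, seed=5)
        pd.testing.assert_frame_equal(out1.values, out2.values)
        obs = ~m.values.isna()
        pd.testing.assert_frame_equal(out1.values.where(obs), m.values.where(obs))
        assert not out1.values.isna().any().any()

    def test_imputed_distribution_matches_parameters(self):
        """10^4 imputed cells: mean/sd within 1% of (m - 1.8 s, 0.3 s)."""
        observed = np.asarray([14.0, 16.0, 18.0, 20.0, 22.0, 24.0, 26.0])
        col = np.concatenate([observed, np.full(10_000, np.nan)])
        m = matrix_from(pd.DataFrame({"a": col}))
        out = impute_missing(m, width=0.3, downshift=1.8, seed=9)
        drawn = out.values["a"].to_numpy()[len(observed):]
        mean_obs, sd_obs = observed.mean(), observed.std(ddof=1)
        target_mean = mean_obs - 1.8 * sd_obs
        target_sd = 0.3 * sd_obs
        assert abs(drawn.mean() - target_mean) <= 0.01 * abs(target_mean)
        assert abs(drawn.std(ddof=1) - target_sd) <= 0.01 * target_sd

    def test_sparse_column_falls_back_to_global(self, caplog):
        m = matrix_from({"a": [20.0, 21.0, 19.0], "b": [np.nan, np.nan, 20.0]})
        out = impute_missing(m, seed=2)
        assert not out.values.isna().any().any()

    def test_linear_scale_rejected(self):
        m = matrix_from({"a": [1.0]}, is_log2=False)
        with pytest.raises(ValueError, match="log2"):
            impute_missing(m)


class TestWidthNormalize:
    def test_three_point_example(self):
        m = matrix_from({"a": [1.0, 2.0, 3.0]})
        out = width_normalize(m)
        assert out.values["a"].tolist() == [-1.0, 0.0, 1.0]

    def test_postcondition_median0_iqr1(self, rng):
        vals = rng.normal(20, 3, size=(200, 5))
        vals[rng.random(vals.shape) < 0.2] = np.nan
        m = matrix_from(pd.DataFrame(vals, columns=list("abcde")))
        out = width_normalize(m)
        for col in out.values:
            obs = out.values[col].dropna().to_numpy()
            assert np.median(obs) == pytest.approx(0.0, abs=1e-9)
            q1, q3 = np.percentile(obs, [25, 75])
            assert q3 - q1 == pytest.approx(1.0, abs=1e-9)

    def test_idempotence(self, rng):
        vals = rng.normal(0, 1, size=(100, 3))
        m = matrix_from(pd.DataFrame(vals, columns=list("abc")))
        once = width_normalize(m)
        twice = width_normalize(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_zero_iqr_median_centered_only(self):
        m = matrix_from({"a": [5.0, 5.0, 5.0, 5.0]})
        out = width_normalize(m)
        assert (out.values["a"] == 0.0).all()


class TestReproducibility:
    def test_cv_percent_example(self):
        m = matrix_from({"r1": [100.0], "r2": [110.0], "r3": [90.0]},
                        groups={"r1": "A", "r2": "A", "r3": "A"}, is_log2=False)
        stats = reproducibility_stats(m)
        assert stats["cv_percent"].loc[0, "A"] == pytest.approx(10.0)
        assert stats["cv_percent_median"]["A"] == pytest.approx(10.0)

    def test_duplicate_columns_correlate_perfectly(self, rng):
        col = rng.normal(20, 2, 50)
        m = matrix_from(pd.DataFrame({"r1": col, "r2": col}))
        stats = reproducibility_stats(m)
        assert stats["run_correlations"].loc["r1", "r2"] == pytest.approx(1.0)

    def test_single_observation_cv_undefined(self):
        m = matrix_from({"r1": [100.0, 50.0], "r2": [110.0, np.nan],
                         "r3": [90.0, np.nan]},
                        groups={"r1": "A", "r2": "A", "r3": "A"}, is_log2=False)
        stats = reproducibility_stats(m)
        assert np.isnan(stats["cv_percent"].loc[1, "A"])
        assert stats["cv_percent_median"]["A"] == pytest.approx(10.0)


class TestRollupAndIo:
    def test_rollup_razor_assignment(self, small_library, small_run):
        from tiffms.matcher import MatchParams, transfer_ids
        from tiffms.rt_alignment import AlignmentModel
        from tests.conftest import align_with_truth

        lib, truth = small_library
        features = align_with_truth(small_run[0], truth)
        results = transfer_ids(features, lib, AlignmentModel.identity(),
                               MatchParams())
        totals = protein_rollup(results, features, lib)
        assert totals and all(v > 0 for v in totals.values())
        assert all(re.match(r"[TE]P\d+", p) for p in totals)

    def test_matrix_roundtrip(self, tmp_path):
        frame = pd.DataFrame({"r1": [1.0, np.nan], "r2": [2.0, 3.0]},
                             index=["P1", "P2"])
        m = QuantMatrix(frame, {"r1": "A", "r2": "B"}, is_log2=False)
        write_matrix(m, tmp_path / "m.tsv", tmp_path / "meta.tsv")
        back = read_matrix(tmp_path / "m.tsv", tmp_path / "meta.tsv")
        pd.testing.assert_frame_equal(back.values, m.values, check_names=False)
        assert back.group_of == {"r1": "A", "r2": "B"}

    def test_build_matrix_flags_unquantifiable(self):
        totals = {"r1": {"P1": 3e6, "P2": 1e6}, "r2": {"P1": 6e6}}
        matrix = build_quant_matrix(totals, {"P1": 3}, {"r1": "A", "r2": "A"})
        assert matrix.values.loc["P1", "r1"] == pytest.approx(1e6)
        assert matrix.values.loc["P1", "r2"] == pytest.approx(2e6)
        assert np.isnan(matrix.values.loc["P2", "r1"])
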