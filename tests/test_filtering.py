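"""Adduct/mode deduplication, RSD filtering and the data dictionary."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidqc import (
    apply_rsd_filter,
    build_data_dictionary,
    collapse_lipids,
    filter_features,
    qc_rsd_per_ion,
    rsd,
)
from lipidqc.filtering import select_adduct_within_mode


class TestRsd:
    def test_hand_computed_value(self):
        assert rsd([1.0, 2.0, 3.0]) == pytest.approx(50.0)  # sd 1, mean 2

    def test_constant_vector_is_zero(self):
        assert rsd([5.0, 5.0, 5.0]) == 0.0

    def test_single_value_raises(self):
        with pytest.raises(ValueError):
            rsd([1.0])

    def test_zero_mean_is_flagged_nan(self):
        assert math.isnan(rsd([-1.0, 1.0]))

    def test_scale_invariance(self):
        v = [3.0, 4.0, 7.0, 5.5]
        assert rsd(v) == pytest.approx(rsd([x * 1e4 for x in v]))


class TestAdductSelection:
    def _ions_frame(self, ion_ids):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            {
                "mode": rng.choice(["positive", "negative"], len(ion_ids)),
                "adduct": rng.choice(["[M+H]+", "[M+Na]+", "[M-H]-"], len(ion_ids)),
            },
            index=ion_ids,
        )

    def test_lowest_rsd_wins(self):
        ions = self._ions_frame(["x", "y"])
        qc_rsd = pd.Series({"x": 8.0, "y": 12.0})
        assert select_adduct_within_mode(["x", "y"], qc_rsd, ions) == "x"

    def test_undefined_rsd_loses_to_any_defined(self):
        ions = self._ions_frame(["x", "y"])
        qc_rsd = pd.Series({"x": math.nan, "y": 40.0})
        assert select_adduct_within_mode(["x", "y"], qc_rsd, ions) == "y"
        assert select_adduct_within_mode(["x"], pd.Series({"x": math.nan}), ions) is None

    def test_exact_tie_is_deterministic(self):
        ions = pd.DataFrame(
            {"mode": ["positive", "positive"], "adduct": ["[M+Na]+", "[M+H]+"]},
            index=["x", "y"],
        )
        qc_rsd = pd.Series({"x": 10.0, "y": 10.0})
        picks = {select_adduct_within_mode(["x", "y"], qc_rsd, ions) for _ in range(5)}
        assert picks == {"y"}  # adduct label breaks the tie lexicographically

    def test_matches_brute_force_argmin_on_random_groups(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(2, 6))
            ids = [f"i{j}" for j in range(n)]
            ions = pd.DataFrame(
                {"mode": ["positive"] * n, "adduct": [f"[A{j}]+" for j in range(n)]},
                index=ids,
            )
            values = rng.uniform(1.0, 40.0, n)
            qc_rsd = pd.Series(values, index=ids)
            expected = ids[int(np.argmin(values))]
            assert select_adduct_within_mode(ids, qc_rsd, ions) == expected


class TestCrossModeDedup:
    def test_collapse_on_pipeline_output(self, default_matrices, default_run):
        db = default_run[0]
        _, normalized, _, _ = default_matrices
        selection, groups = collapse_lipids(normalized)
        qc_rsd = qc_rsd_per_ion(normalized)
        for g in groups:
            if g.final_ion is None:
                continue
            # winner optimality: no member beats the selected ion
            final_rsd = qc_rsd[g.final_ion]
            defined = [r for r in g.member_rsd.values() if not math.isnan(r)]
            assert all(final_rsd <= r + 1e-12 for r in defined)
            # single-mode lipids carry no correlation
            if len(g.members) == 1:
                assert g.spearman_rho is None

    def test_correlated_dual_mode_pair_flagged_concordant(
        self, default_matrices, default_run
    ):
        """Dual-polarity ions of one lipid share its true concentration, so
        with mild noise their cross-mode rank correlation clears 0.80."""
        _, normalized, _, _ = default_matrices
        _, groups = collapse_lipids(normalized)
        dual = [g for g in groups if g.spearman_rho is not None]
        assert dual, "the default database must contain dual-mode lipids"
        assert np.mean([g.concordant for g in dual]) >= 0.8

    def test_rho_matches_rank_then_correlate_oracle(self, default_matrices):
        _, normalized, _, _ = default_matrices
        _, groups = collapse_lipids(normalized)
        nonblank = normalized.nonblank_values()
        checked = 0
        for g in groups:
            if g.spearman_rho is None:
                continue
            a, b = (g.selected_per_mode["positive"], g.selected_per_mode["negative"])
            ra = stats.rankdata(nonblank[a])
            rb = stats.rankdata(nonblank[b])
            oracle = np.corrcoef(ra, rb)[0, 1]
            assert g.spearman_rho == pytest.approx(oracle, abs=1e-12)
            checked += 1
        assert checked >= 3


class TestRsdFilter:
    def _toy_matrix(self, rsd_values):
        from lipidqc import FeatureMatrix

        ions = list(rsd_values)
        rng = np.random.default_rng(1)
        qc_rows = {}
        for ion, target in rsd_values.items():
            base = 1000.0
            # five QC values with the requested RSD (scaled two-point spread)
            spread = base * target / 100.0
            qc_rows[ion] = base + spread * np.array([-1, -1, 0, 1, 1]) * np.sqrt(5 / 4) / np.sqrt(8 / 5)
        values = pd.DataFrame(qc_rows, index=[f"QC{i}" for i in range(5)])
        samples = pd.DataFrame(
            {
                "sample_type": ["qc"] * 5,
                "batch": [1] * 5,
                "injection_order": range(1, 6),
                "duplicate_of": [""] * 5,
            },
            index=values.index,
        )
        ann = pd.DataFrame(
            {
                "ion_id": ions,
                "lipid_id": ions,
                "name": ions,
                "mode": ["positive"] * len(ions),
                "adduct": ["[M+H]+"] * len(ions),
                "mz": [500.0] * len(ions),
                "expected_rt": [5.0] * len(ions),
                "inchikey": [""] * len(ions),
                "is_internal_standard": [ion.startswith("IS") for ion in ions],
                "is_known": [True] * len(ions),
            },
            index=ions,
        )
        return FeatureMatrix(values=values, samples=samples, ions=ann)

    def test_boundary_semantics_and_standard_removal(self):
        fm = self._toy_matrix({"keep": 10.0, "edge": 25.0, "drop": 30.0, "IS1": 5.0})
        qc_rsd = pd.Series({"keep": 10.0, "edge": 25.0, "drop": 25.01, "IS1": 5.0})
        filtered, log = apply_rsd_filter(fm, qc_rsd)
        assert list(filtered.ion_ids) == ["keep", "edge"]
        reasons = dict(zip(log["ion_id"], log["reason"]))
        assert reasons["drop"] == "qc_rsd_above_threshold"
        assert reasons["IS1"] == "internal_standard"

    def test_filter_is_idempotent(self):
        fm = self._toy_matrix({"a": 10.0, "b": 40.0, "IS1": 5.0})
        once, log1 = apply_rsd_filter(fm)
        twice, log2 = apply_rsd_filter(once)
        assert list(once.ion_ids) == list(twice.ion_ids)
        assert len(log2) == 0

    def test_survivor_count_matches_recount(self, default_matrices):
        _, normalized, _, _ = default_matrices
        qc_rsd = qc_rsd_per_ion(normalized)
        filtered, log = apply_rsd_filter(normalized, qc_rsd)
        expected = sum(
            1
            for ion in normalized.ion_ids
            if not bool(normalized.ions.loc[ion, "is_internal_standard"])
            and not (not math.isnan(qc_rsd[ion]) and qc_rsd[ion] > 25.0)
        )
        assert len(filtered.ion_ids) == expected
        assert len(filtered.ion_ids) + len(log) == len(normalized.ion_ids)


class TestFinalProduct:
    def test_each_lipid_appears_once_and_no_standards(
        self, default_matrices, default_run
    ):
        db = default_run[0]
        _, normalized, _, _ = default_matrices
        result = filter_features(normalized, db)
        lipids = list(result.matrix.values.columns)
        assert len(lipids) == len(set(lipids))
        standards = {ion.lipid_id for ion in db if ion.is_internal_standard}
        assert not standards & set(lipids)

    def test_dictionary_bijection_and_flags(self, default_matrices, default_run):
        db = default_run[0]
        _, normalized, _, _ = default_matrices
        result = filter_features(normalized, db)
        assert len(result.dictionary) == result.matrix.values.shape[1]
        assert set(result.dictionary["lipid_id"]) == set(result.matrix.values.columns)
        for _, row in result.dictionary.iterrows():
            ion = db.get(row["ion_id"])
            assert row["is_known"] == ion.is_known
            assert row["mz"] == ion.mz

    def test_dictionary_round_trips(self, tmp_path, default_matrices, default_run):
        db = default_run[0]
        _, normalized, _, _ = default_matrices
        result = filter_features(normalized, db)
        path = tmp_path / "dict.csv"
        result.dictionary.to_csv(path, index=False)
        back = pd.read_csv(path, keep_default_na=False,
                           float_precision="round_trip")
        pd.testing.assert_frame_equal(back, result.dictionary)

    def test_orphan_ion_raises(self, default_matrices, default_run):
        db = default_run[0]
        _, normalized, _, _ = default_matrices
        trimmed = normalized.copy_with(values=normalized.values.copy())
        trimmed.ions.loc["ghost"] = trimmed.ions.iloc[0]
        trimmed.values["ghost"] = 1.0
        with pytest.raises(ValueError, match="ghost"):
            build_data_dictionary(trimmed, db)
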