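import numpy as np
import pandas as pd
import pytest

from synmtl.featurization import (
    CellLineRecord, FeaturizationError, build_cell_features,
    build_drug_features, compute_descriptors, compute_fingerprint,
    featurize_drugs, filter_descriptors, impute_missing_genes)

# On-bit positions for ethanol under the shipped featurizer version
# (radius 3, 1024 bits), computed once and frozen.
ETHANOL_BITS = {33, 80, 222, 294, 386, 807}


class TestFingerprint:
    def test_frozen_ethanol_bits(self):
        fp = compute_fingerprint("CCO")
        assert fp.shape == (1024,)
        assert set(np.flatnonzero(fp)) == ETHANOL_BITS

    def test_binary_and_deterministic(self):
        fp1 = compute_fingerprint("CC(=O)Oc1ccccc1C(=O)O")  # aspirin
        fp2 = compute_fingerprint("CC(=O)Oc1ccccc1C(=O)O")
        assert set(np.unique(fp1)) <= {0, 1}
        assert np.array_equal(fp1, fp2)

    def test_spelling_invariance(self):
        assert np.array_equal(compute_fingerprint("CCO"),
                              compute_fingerprint("OCC"))

    def test_configurable_width(self):
        assert compute_fingerprint("CCO", n_bits=512).shape == (512,)

    def test_unparseable_smiles_names_drug(self):
        with pytest.raises(FeaturizationError, match="drug42"):
            compute_fingerprint("not_a_molecule", drug_id="drug42")


class TestDescriptors:
    def test_ethanol_molecular_weight(self):
        # C2H6O from standard atomic masses: 2*12.011 + 6*1.008 + 15.999
        desc = compute_descriptors("CCO")
        assert desc["MolWt"] == pytest.approx(46.069, abs=0.01)

    def test_methane_all_finite(self):
        desc = compute_descriptors("C")
        assert np.isfinite(desc.to_numpy()).all()

    def test_parse_failure(self):
        with pytest.raises(FeaturizationError):
            compute_descriptors("][")


class TestFilterDescriptors:
    def test_definition_applied(self):
        panel = pd.DataFrame({"A": [1, 1, 1], "B": [1, 2, 3],
                              "C": [1, np.nan, 2]})
        assert filter_descriptors(panel) == ["B"]

    def test_clean_panel_keeps_all_in_native_order(self):
        panel = pd.DataFrame({"Z": [1, 2], "A": [3, 5]})
        assert filter_descriptors(panel) == ["Z", "A"]

    def test_matches_brute_force_scan(self, rng):
        panel = pd.DataFrame(rng.normal(size=(10, 15)),
                             columns=[f"d{i}" for i in range(15)])
        panel.iloc[3, 2] = np.nan
        panel["d7"] = 4.2  # constant
        panel.iloc[0, 11] = np.nan
        kept = filter_descriptors(panel)
        expected = [c for c in panel.columns
                    if not panel[c].isna().any()
                    and panel[c].nunique() > 1]
        assert kept == expected

    def test_degenerate_set_errors(self):
        panel = pd.DataFrame({"A": [1.0, 1.0], "B": [np.nan, 2.0]})
        with pytest.raises(ValueError):
            filter_descriptors(panel)

    def test_needs_two_drugs(self):
        with pytest.raises(ValueError):
            filter_descriptors(pd.DataFrame({"A": [1.0]}))


@pytest.fixture(scope="module")
def feature_set():
    table = pd.DataFrame({
        "drug_id": ["d1", "d2", "d3", "d4", "d5"],
        "smiles": ["CCO", "CC(=O)O", "c1ccccc1", "CCN", "CCCC"],
    })
    return build_drug_features(featurize_drugs(table))


class TestBuildDrugFeatures:
    def test_row_width_is_bits_plus_kept(self, feature_set):
        d = 1024 + len(feature_set.kept_descriptor_names)
        assert feature_set.feature_matrix.shape == (5, d)

    def test_zscore_columns(self, feature_set):
        m = feature_set.feature_matrix
        assert np.abs(m.mean(axis=0)).max() < 1e-6
        stds = m.std(axis=0)
        nonconst = stds > 1e-12
        assert np.abs(stds[nonconst] - 1.0).max() < 1e-6

    def test_stored_stats_reproduce_sample_moments(self, feature_set):
        fs = feature_set
        raw = fs.feature_matrix * fs.zscore_stds + fs.zscore_means
        assert np.allclose(raw.mean(axis=0), fs.zscore_means)
        nonconst = raw.std(axis=0) > 1e-12
        assert np.allclose(raw.std(axis=0)[nonconst], fs.zscore_stds[nonconst])

    def test_transform_roundtrip_is_exact(self, feature_set):
        fs = feature_set
        raw = fs.feature_matrix * fs.zscore_stds + fs.zscore_means
        assert np.allclose(fs.transform(raw), fs.feature_matrix)

    def test_no_zero_variance_descriptor_kept(self, feature_set):
        fs = feature_set
        desc_block = fs.feature_matrix[:, 1024:]
        raw = desc_block * fs.zscore_stds[1024:] + fs.zscore_means[1024:]
        assert (raw.std(axis=0) > 0).all()


class TestImputeMissingGenes:
    def test_mean_of_two(self):
        ref = pd.DataFrame({"c1": [2.0], "c2": [4.0]}, index=["g"])
        target = CellLineRecord("x", "lung", pd.Series(dtype=float, index=[]))
        with pytest.raises(ValueError):
            impute_missing_genes(ref, target)
        target = CellLineRecord("x", "lung", pd.Series({"h": 1.0}))
        with pytest.raises(ValueError):
            impute_missing_genes(ref, target)

    def test_fills_with_reference_mean(self):
        ref = pd.DataFrame({"c1": [2.0, 1.0], "c2": [4.0, 3.0]},
                           index=["g1", "g2"])
        target = CellLineRecord("x", "lung", pd.Series({"g1": 9.0}))
        out = impute_missing_genes(ref, target)
        assert out.expression["g2"] == pytest.approx(2.0)  # mean of [1, 3]
        assert out.expression["g1"] == pytest.approx(9.0)

    def test_identity_when_complete(self):
        ref = pd.DataFrame({"c1": [2.0], "c2": [4.0]}, index=["g"])
        target = CellLineRecord("x", "lung", pd.Series({"g": 7.0}))
        assert impute_missing_genes(ref, target) is target

    def test_matches_brute_force_means(self, rng):
        genes = [f"g{i}" for i in range(20)]
        ref = pd.DataFrame(rng.normal(size=(20, 4)), index=genes,
                           columns=list("abcd"))
        present = genes[:8]
        target = CellLineRecord("x", "lung",
                                pd.Series(rng.normal(size=8), index=present))
        out = impute_missing_genes(ref, target)
        for g in genes[8:]:
            assert out.expression[g] == pytest.approx(ref.loc[g].mean())


class TestBuildCellFeatures:
    def _records(self, matrix: pd.DataFrame):
        return [CellLineRecord(c, "t", matrix[c]) for c in matrix.columns]

    def test_topk_matches_brute_force(self, rng):
        genes = [f"g{i:02d}" for i in range(10)]
        m = pd.DataFrame(rng.normal(size=(10, 4)), index=genes,
                         columns=list("abcd"))
        fs = build_cell_features(self._records(m), k=3)
        variances = m.var(axis=1)
        expected = list(variances.sort_values(ascending=False,
                                              kind="stable").index[:3])
        assert fs.selected_genes == expected
        assert fs.feature_matrix.shape == (4, 3)

    def test_variance_ties_break_by_gene_id(self):
        m = pd.DataFrame({"a": [0.0, 0.0, 0.0], "b": [2.0, 2.0, 4.0]},
                         index=["gB", "gA", "gC"])  # gA and gB identical variance
        fs = build_cell_features(self._records(m), k=2)
        assert fs.selected_genes == ["gC", "gA"]

    def test_k_equals_gene_count_keeps_all(self, rng):
        m = pd.DataFrame(rng.normal(size=(5, 3)), index=[f"g{i}" for i in range(5)],
                         columns=list("abc"))
        fs = build_cell_features(self._records(m), k=5)
        assert len(fs.selected_genes) == 5

    def test_too_few_genes_errors(self, rng):
        m = pd.DataFrame(rng.normal(size=(4, 3)), index=[f"g{i}" for i in range(4)],
                         columns=list("abc"))
        with pytest.raises(ValueError):
            build_cell_features(self._records(m), k=5)

    def test_zscore_invariant(self, rng):
        m = pd.DataFrame(rng.normal(size=(30, 6)),
                         index=[f"g{i}" for i in range(30)],
                         columns=list("abcdef"))
        fs = build_cell_features(self._records(m), k=20)
        assert np.abs(fs.feature_matrix.mean(axis=0)).max() < 1e-6
        assert np.abs(fs.feature_matrix.std(axis=0) - 1.0).max() < 1e-6
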