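"""Data model, I/O, preprocessing chain, PCA and map agreement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from subcellmap import (
    ProfileDataset,
    MarkerAnnotation,
    agreement_matrix,
    aggregate_protein_groups,
    concatenate_replicates,
    drop_channels,
    filter_complete_profiles,
    merge_marker_classes,
    pca_project,
    read_profile_table,
    remove_contaminants,
    sum_normalize_rows,
)
from conftest import make_dataset


class TestReadProfileTable:
    def test_roundtrip(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(
            "accession\tc1\tc2\tc3\tc4\tc5\tc6\tc7\tc8\tc9\tc10\n"
            + "\n".join(f"P{i}\t" + "\t".join("1" for _ in range(10)) for i in range(3))
        )
        ds = read_profile_table(p)
        assert ds.matrix.shape == (3, 10)
        assert list(ds.accessions) == ["P0", "P1", "P2"]

    def test_duplicate_accession_raises(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("accession\tc1\nP1\t1\nP1\t2\n")
        with pytest.raises(ValueError, match="P1"):
            read_profile_table(p)

    def test_na_preserved_as_missing(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("accession\tc1\tc2\nP1\tNA\t2\nP2\t1\t2\n")
        ds = read_profile_table(p)
        assert ds.matrix.isna().sum().sum() == 1
        assert np.isnan(ds.matrix.loc["P1", "c1"])

    def test_non_numeric_cell_names_location(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("accession\tc1\nP1\tbogus\n")
        with pytest.raises(ValueError, match="bogus"):
            read_profile_table(p)


class TestSumNormalize:
    def test_simple_ratios(self):
        out = sum_normalize_rows(np.array([[1.0, 3.0]]))
        assert np.allclose(out, [[0.25, 0.75]])

    def test_equal_row_and_zeros_kept(self):
        out = sum_normalize_rows(np.array([[1.0] * 10, [0.0, 1.0, 1.0] + [0.0] * 7]))
        assert np.allclose(out[0], 0.1)
        assert out[1, 0] == 0.0 and np.isclose(out[1, 1], 0.5)

    def test_zero_row_raises_with_name(self):
        df = pd.DataFrame([[1.0, 1.0], [0.0, 0.0]], index=["ok", "bad"])
        with pytest.raises(ValueError, match="bad"):
            sum_normalize_rows(df)

    @given(
        arrays(
            float,
            (4, 6),
            elements=st.floats(min_value=0.01, max_value=1e6, allow_nan=False),
        )
    )
    def test_idempotent_and_rows_sum_to_one(self, mat):
        once = sum_normalize_rows(mat)
        assert np.allclose(once.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(sum_normalize_rows(once), once, atol=1e-12)


class TestAggregate:
    def test_median_of_psms(self):
        psm = pd.DataFrame([[0.2, 0.8], [0.4, 0.6], [1.0, 0.0]], index=["a", "b", "c"])
        agg = aggregate_protein_groups(psm, ["G1", "G1", "G2"])
        assert np.allclose(agg.loc["G1"], [0.3, 0.7])
        assert np.allclose(agg.loc["G2"], [1.0, 0.0])

    def test_odd_count_middle_value(self):
        psm = pd.DataFrame([[0.1], [0.5], [0.9]], index=list("abc"))
        agg = aggregate_protein_groups(psm, ["G"] * 3)
        assert agg.loc["G", 0] == 0.5

    def test_no_renormalisation_after_median(self):
        # medians of simplex rows need not sum to 1; they must be left alone
        psm = pd.DataFrame([[0.2, 0.8], [0.8, 0.2]], index=["a", "b"])
        agg = aggregate_protein_groups(psm, ["G", "G"])
        assert np.allclose(agg.loc["G"], [0.5, 0.5])


class TestFilterComplete:
    def test_removes_rows_with_any_missing(self):
        m = np.ones((5, 3))
        ds = make_dataset(m)
        ds.matrix.iloc[1, 0] = np.nan
        ds.matrix.iloc[3, 2] = np.nan
        out = filter_complete_profiles(ds)
        assert out.n_proteins == 3
        assert list(out.accessions) == ["P0", "P2", "P4"]

    def test_identity_when_complete(self, small_data):
        ds, _ = small_data
        out = filter_complete_profiles(ds)
        assert out.matrix.equals(ds.matrix)

    def test_all_missing_warns_and_empties(self):
        ds = make_dataset(np.ones((2, 2)))
        ds.matrix.iloc[:, 0] = np.nan
        with pytest.warns(UserWarning):
            out = filter_complete_profiles(ds)
        assert out.n_proteins == 0

    @given(
        arrays(
            float,
            (8, 4),
            elements=st.one_of(st.just(np.nan), st.floats(0, 10, allow_nan=False)),
        )
    )
    def test_count_matches_bruteforce_scan(self, mat):
        ds = make_dataset(np.abs(mat))
        expected = sum(0 if np.isnan(row).any() else 1 for row in ds.matrix.to_numpy())
        assert filter_complete_profiles(ds).n_proteins == expected


class TestChannelsAndContaminants:
    def test_drop_channels(self):
        ds = make_dataset(np.random.default_rng(0).random((4, 60)))
        out = drop_channels(ds, ["ch0", "ch7", "ch59"])
        assert out.n_channels == 57
        assert len(out.channel_meta) == 57

    def test_drop_unknown_channel_raises(self):
        ds = make_dataset(np.ones((2, 3)))
        with pytest.raises(ValueError, match="nope"):
            drop_channels(ds, ["nope"])

    def test_drop_all_raises(self):
        ds = make_dataset(np.ones((2, 2)))
        with pytest.raises(ValueError):
            drop_channels(ds, ["ch0", "ch1"])

    def test_remove_contaminants(self):
        ds = make_dataset(np.ones((4, 2)), accs=["A", "B", "C", "D"])
        out = remove_contaminants(ds, ["B", "D", "NOT_PRESENT"])
        assert list(out.accessions) == ["A", "C"]

    def test_remove_contaminants_empty_list_identity(self):
        ds = make_dataset(np.ones((3, 2)))
        assert remove_contaminants(ds, []).n_proteins == 3


class TestConcatenateReplicates:
    def _reps(self, n=3, shared=5):
        rng = np.random.default_rng(1)
        out = []
        for i in range(n):
            accs = [f"S{j}" for j in range(shared)] + [f"only{i}"]
            out.append(make_dataset(rng.random((shared + 1, 4)), accs=accs))
        return out

    def test_intersection_and_channel_stack(self):
        reps = self._reps()
        out = concatenate_replicates(reps)
        assert out.n_proteins == 5
        assert out.n_channels == 12
        assert sorted(out.channel_meta["replicate"].unique()) == [1, 2, 3]

    def test_single_dataset_identity(self):
        (ds,) = self._reps(n=1)
        out = concatenate_replicates([ds])
        assert out.matrix.equals(ds.matrix)

    def test_disjoint_accessions_raise(self):
        a = make_dataset(np.ones((2, 2)), accs=["A", "B"])
        b = make_dataset(np.ones((2, 2)), accs=["C", "D"])
        with pytest.raises(ValueError, match="shared"):
            concatenate_replicates([a, b])

    def test_conflicting_marker_labels_raise(self):
        a = make_dataset(np.ones((2, 2)), accs=["A", "B"], marker_class=["ER", "unknown"])
        b = make_dataset(np.ones((2, 2)), accs=["A", "B"], marker_class=["Golgi", "unknown"])
        with pytest.raises(ValueError, match="conflicting"):
            concatenate_replicates([a, b])

    def test_order_insensitive_up_to_channel_metadata(self):
        reps = self._reps()
        fwd = concatenate_replicates(reps)
        rev = concatenate_replicates(reps[::-1])
        assert set(fwd.accessions) == set(rev.accessions)
        # same profile content, channels permuted
        assert np.allclose(
            np.sort(fwd.matrix.to_numpy(), axis=1), np.sort(rev.matrix.to_numpy(), axis=1)
        )


class TestMergeMarkerClasses:
    MERGES = {
        "nucleus": "nucleus/chromatin",
        "chromatin": "nucleus/chromatin",
        "ribosome 40S": "ribosome",
        "ribosome 60S": "ribosome",
    }

    def test_twelve_to_ten(self):
        classes = [
            "cytosol", "proteasome", "nucleus", "chromatin", "ribosome 40S",
            "ribosome 60S", "peroxisome", "mitochondrion", "lysosome", "Golgi",
            "PM", "ER",
        ]
        labels = {f"P{i}": c for i, c in enumerate(classes)}
        merged = merge_marker_classes(MarkerAnnotation(labels, classes), self.MERGES)
        assert len(merged.classes) == 10
        assert merged.labels["P2"] == "nucleus/chromatin"
        assert merged.labels["P5"] == "ribosome"

    def test_empty_map_identity(self):
        mk = MarkerAnnotation({"P1": "ER"}, ["ER", "Golgi"])
        out = merge_marker_classes(mk, {})
        assert out.classes == mk.classes and out.labels == mk.labels

    def test_merge_all_into_one(self):
        mk = MarkerAnnotation({"P1": "A", "P2": "B"}, ["A", "B"])
        out = merge_marker_classes(mk, {"A": "all", "B": "all"})
        assert out.classes == ["all"]

    def test_unknown_class_raises(self):
        mk = MarkerAnnotation({"P1": "ER"}, ["ER"])
        with pytest.raises(ValueError, match="ghost"):
            merge_marker_classes(mk, {"ghost": "ER"})


class TestPca:
    def test_collinear_points_single_component(self):
        pts = np.outer(np.arange(5, dtype=float), [3.0, 4.0])
        res = pca_project(make_dataset(pts), 2)
        assert np.isclose(res.variance_fraction[0], 1.0)

    def test_variance_fractions_sum_to_one_full_rank(self):
        X = np.abs(np.random.default_rng(2).random((20, 5)))
        res = pca_project(make_dataset(X))
        assert np.isclose(res.variance_fraction.sum(), 1.0)
        assert np.all(np.diff(res.variance_fraction) <= 1e-12)

    def test_reconstruction_from_all_components(self):
        X = np.abs(np.random.default_rng(3).random((10, 4)))
        res = pca_project(make_dataset(X))
        recon = res.scores.to_numpy() @ res.loadings.to_numpy()
        assert np.allclose(recon, X - X.mean(0), atol=1e-10)

    def test_scores_orthogonal_and_total_variance_preserved(self):
        X = np.abs(np.random.default_rng(4).random((30, 6)))
        res = pca_project(make_dataset(X))
        S = res.scores.to_numpy()
        off = S.T @ S - np.diag(np.diag(S.T @ S))
        assert np.allclose(off, 0, atol=1e-8)
        assert np.isclose(S.var(axis=0, ddof=0).sum(), (X - X.mean(0)).var(axis=0, ddof=0).sum())

    def test_sign_convention_deterministic(self):
        X = np.abs(np.random.default_rng(5).random((12, 4)))
        a = pca_project(make_dataset(X))
        b = pca_project(make_dataset(X))
        assert a.scores.equals(b.scores)
        for j in range(a.loadings.shape[0]):
            row = a.loadings.to_numpy()[j]
            assert row[np.argmax(np.abs(row))] > 0

    def test_bad_component_count(self):
        ds = make_dataset(np.ones((3, 3)))
        with pytest.raises(ValueError):
            pca_project(ds, 0)

    def test_scores_tsv_roundtrip_with_variance_header(self, tmp_path):
        from subcellmap import write_pca_scores

        X = np.abs(np.random.default_rng(6).random((8, 3)))
        res = pca_project(make_dataset(X), 2)
        path = tmp_path / "pca.tsv"
        write_pca_scores(res, path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("# variance_fraction")
        back = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        assert np.allclose(back.to_numpy(), res.scores.to_numpy(), atol=1e-6)


class TestAgreement:
    def test_identical_assignments_full_agreement(self):
        a = pd.Series({"P1": "ER", "P2": "Golgi", "P3": "ER"})
        table, pct, n = agreement_matrix(a, a.copy())
        assert pct == 100.0 and n == 3
        assert table.loc["ER", "ER"] == 2

    def test_fully_discordant(self):
        a = pd.Series({"P1": "ER", "P2": "Golgi"})
        b = pd.Series({"P1": "Golgi", "P2": "ER"})
        _, pct, _ = agreement_matrix(a, b)
        assert pct == 0.0

    def test_one_discordant_in_ten(self):
        a = pd.Series({f"P{i}": "ER" for i in range(10)})
        b = a.copy()
        b["P9"] = "Golgi"
        _, pct, n = agreement_matrix(a, b)
        assert n == 10 and np.isclose(pct, 90.0)

    def test_class_map_translates_vocabulary(self):
        a = pd.Series({"P1": "nucleus/chromatin"})
        b = pd.Series({"P1": "chromatin"})
        _, pct, _ = agreement_matrix(a, b, {"chromatin": "nucleus/chromatin"})
        assert pct == 100.0

    def test_unknowns_excluded_and_empty_raises(self):
        a = pd.Series({"P1": "unknown"})
        b = pd.Series({"P1": "ER"})
        with pytest.raises(ValueError):
            agreement_matrix(a, b)
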