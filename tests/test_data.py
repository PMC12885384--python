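"""Dataset I/O, curation filters, and split construction."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest

import sccvae
from sccvae.data import (
    CONTROL_TOKEN,
    PERTURBATION_KEY,
    dense_X,
    filter_distinguishable,
    filter_min_cells,
    make_split,
    perturbation_counts,
    read_dataset,
)


def _toy_adata(counts: dict, m=10, seed=0):
    """Populations with given cell counts, genes named g0..g{m-1}."""
    rng = np.random.default_rng(seed)
    names, X = [], []
    for p, k in counts.items():
        names += [p] * k
        X.append(rng.normal(size=(k, m)))
    obs = pd.DataFrame({PERTURBATION_KEY: names}, index=[f"c{i}" for i in range(len(names))])
    return ad.AnnData(X=np.vstack(X), obs=obs, var=pd.DataFrame(index=[f"g{i}" for i in range(m)]))


class TestReadDataset:
    def test_tsv_round_trip(self, tmp_path):
        frame = pd.DataFrame(
            {
                PERTURBATION_KEY: [CONTROL_TOKEN, "g1", "g2"],
                "g0": [0.1, 0.2, 0.3],
                "g1": [1.0, 2.0, 3.0],
                "g2": [0.0, 0.5, 1.0],
            },
            index=pd.Index(["cellA", "cellB", "cellC"], name="cell_id"),
        )
        frame.to_csv(tmp_path / "toy.tsv", sep="\t")
        adata = read_dataset(tmp_path / "toy.tsv", format="tsv")
        assert adata.shape == (3, 3)
        assert len(perturbation_counts(adata)) == 2

    def test_h5ad_round_trip(self, tmp_path, small_adata):
        small_adata.write_h5ad(tmp_path / "d.h5ad")
        back = read_dataset(tmp_path / "d.h5ad")
        assert np.allclose(dense_X(back), dense_X(small_adata))
        assert (back.obs[PERTURBATION_KEY].astype(str) == small_adata.obs[PERTURBATION_KEY].astype(str)).all()

    def test_mtx_dir_round_trip(self, tmp_path, small_adata):
        import scipy.io
        import scipy.sparse

        d = tmp_path / "mtx"
        d.mkdir()
        scipy.io.mmwrite(d / "matrix.mtx", scipy.sparse.csr_matrix(dense_X(small_adata)))
        pd.Series(small_adata.obs_names).to_csv(d / "barcodes.tsv", sep="\t", index=False, header=False)
        pd.Series(small_adata.var_names).to_csv(d / "features.tsv", sep="\t", index=False, header=False)
        small_adata.obs[[PERTURBATION_KEY]].rename_axis("cell_id").to_csv(d / "annotation.tsv", sep="\t")
        back = read_dataset(d, format="mtx_dir")
        assert np.allclose(dense_X(back), dense_X(small_adata), atol=1e-6)

    def test_missing_annotation_column(self, tmp_path):
        pd.DataFrame({"g0": [1.0]}, index=["c0"]).to_csv(tmp_path / "bad.tsv", sep="\t")
        with pytest.raises(KeyError):
            read_dataset(tmp_path / "bad.tsv", format="tsv")

    def test_unmeasured_targets_dropped_with_warning(self, tmp_path):
        adata = _toy_adata({CONTROL_TOKEN: 3, "g1": 2, "NOT_A_GENE": 2})
        adata.write_h5ad(tmp_path / "d.h5ad")
        with pytest.warns(UserWarning, match="NOT_A_GENE"):
            back = read_dataset(tmp_path / "d.h5ad")
        assert back.n_obs == 5

    def test_no_controls_rejected(self, tmp_path):
        adata = _toy_adata({"g1": 3})
        adata.write_h5ad(tmp_path / "d.h5ad")
        with pytest.raises(ValueError, match="control"):
            read_dataset(tmp_path / "d.h5ad")


class TestFilterMinCells:
    def test_strict_threshold_semantics(self):
        adata = _toy_adata({CONTROL_TOKEN: 10, "g1": 199, "g2": 200, "g3": 300}, m=5)
        out = filter_min_cells(adata, 200)
        kept = set(perturbation_counts(out).index)
        assert kept == {"g2", "g3"}  # 199 < 200 removed, exactly 200 retained
        assert (out.obs[PERTURBATION_KEY] == CONTROL_TOKEN).sum() == 10

    def test_min_cells_one_is_identity(self):
        adata = _toy_adata({CONTROL_TOKEN: 5, "g1": 1, "g2": 7}, m=4)
        assert filter_min_cells(adata, 1).n_obs == adata.n_obs


class TestFilterDistinguishable:
    def test_null_perturbation_scores_near_half_and_is_removed(self):
        """Perturbed cells drawn from the control distribution give CV
        accuracy ~ 0.5, below the 0.6 gate, across seeded repeats."""
        rng = np.random.default_rng(0)
        scores = []
        for rep in range(10):
            adata = _toy_adata({CONTROL_TOKEN: 120, "g1": 80}, m=20, seed=rep)
            out, s = filter_distinguishable(adata, score_threshold=0.6, seed=rep)
            scores.append(s["g1"])
            assert "g1" not in set(perturbation_counts(out).index)
        assert abs(np.mean(scores) - 0.5) < 0.08

    def test_shifted_perturbation_retained(self):
        adata = _toy_adata({CONTROL_TOKEN: 120, "g1": 80}, m=60)
        X = dense_X(adata)
        X[adata.obs[PERTURBATION_KEY] == "g1", :50] += 2.0  # large shift on 50 genes
        adata.X = X
        out, s = filter_distinguishable(adata, score_threshold=0.6, seed=0)
        assert s["g1"] > 0.9
        assert "g1" in set(perturbation_counts(out).index)

    def test_zero_threshold_is_identity(self, small_adata):
        out, _ = filter_distinguishable(small_adata, score_threshold=0.0, seed=0)
        assert set(perturbation_counts(out).index) == set(perturbation_counts(small_adata).index)

    def test_tiny_class_skipped(self):
        adata = _toy_adata({CONTROL_TOKEN: 50, "g1": 3}, m=5)
        out, s = filter_distinguishable(adata, seed=0)
        assert np.isnan(s["g1"])
        assert "g1" not in set(perturbation_counts(out).index)


class TestMakeSplit:
    def test_in_distribution_fractions(self):
        adata = _toy_adata({CONTROL_TOKEN: 20, "g1": 10}, m=4)
        split = make_split(adata, "in_distribution", seed=0)
        pert = adata.obs[PERTURBATION_KEY]
        roles = split.roles[pert == "g1"]
        assert (roles == "train").sum() == 7 and (roles == "val").sum() == 1 and (roles == "test").sum() == 2

    def test_roles_partition_all_cells(self, small_adata):
        split = make_split(small_adata, "in_distribution", seed=1)
        assert set(split.roles.index) == set(small_adata.obs_names)
        assert split.roles.isin(["train", "val", "test"]).all()

    def test_ood_rotation_covers_each_perturbation_once(self, small_adata):
        held = [
            make_split(small_adata, "out_of_distribution", split_index=i, seed=3).held_out_perturbations
            for i in range(5)
        ]
        all_perts = set(perturbation_counts(small_adata).index)
        assert set().union(*held) == all_perts
        assert sum(len(h) for h in held) == len(all_perts)  # disjoint

    def test_ood_no_leakage_and_controls_never_held_out(self, small_adata):
        split = make_split(small_adata, "out_of_distribution", split_index=0, seed=3)
        pert = small_adata.obs[PERTURBATION_KEY].astype(str)
        for q in split.held_out_perturbations:
            assert (split.roles[(pert == q).to_numpy()] == "test").all()
        ctrl_roles = split.roles[(pert == CONTROL_TOKEN).to_numpy()]
        assert set(ctrl_roles) <= {"train", "val"}

    def test_deterministic(self, small_adata):
        a = make_split(small_adata, "out_of_distribution", 2, seed=9)
        b = make_split(small_adata, "out_of_distribution", 2, seed=9)
        assert (a.roles == b.roles).all()

    def test_too_few_perturbations_for_ood(self):
        adata = _toy_adata({CONTROL_TOKEN: 10, "g1": 5}, m=4)
        with pytest.raises(ValueError):
            make_split(adata, "out_of_distribution", 0, seed=0)

    def test_split_tsv_export(self, tmp_path, small_adata):
        split = make_split(small_adata, "in_distribution", seed=0)
        split.save_tsv(tmp_path / "split.tsv")
        back = pd.read_csv(tmp_path / "split.tsv", sep="\t", index_col="cell_id")["role"]
        assert (back == split.roles).all()
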