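"""Per-gene PCA models: fitting, application, persistence, export."""

import numpy as np
import pandas as pd
import pytest

import ddpheno as dp
from conftest import random_log2_coverage


def binned(values, gene="G", stage="log2"):
    values = np.asarray(values, float)
    return dp.BinnedCoverage(
        gene,
        [f"{gene}:{j}" for j in range(values.shape[1])],
        [f"s{i}" for i in range(values.shape[0])],
        values,
        stage,
    )


class TestFilterGenes:
    def raw(self, totals, gene="G"):
        vals = np.array(totals, float)[:, None]
        return dp.BinnedCoverage(gene, [f"{gene}:0"],
                                 [f"s{i}" for i in range(len(totals))],
                                 vals, "raw_mean")

    def test_all_zero_gene_dropped(self):
        assert dp.filter_genes({"G": self.raw([0, 0, 0, 0])}) == set()

    def test_exactly_half_nonzero_kept(self):
        # 5 of 10 nonzero: the >=50% boundary is inclusive
        raw = self.raw([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        assert dp.filter_genes({"G": raw}) == {"G"}

    @pytest.mark.parametrize("frac", [0.30, 0.40, 0.49, 0.50, 0.60, 0.70])
    def test_threshold_sweep_matches_oracle(self, frac):
        n = 100
        k = round(frac * n)
        raw = self.raw([1] * k + [0] * (n - k))
        expected = {"G"} if k / n >= 0.5 else set()
        assert dp.filter_genes({"G": raw}) == expected


class TestFitGeneModel:
    def test_rank_one_data_single_component(self, rng):
        pattern = rng.normal(size=12)
        weights = rng.normal(size=50)
        X = binned(np.outer(weights, pattern) + 3.0)
        model = dp.fit_gene_model(X)
        assert model.n_components == 1
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_isotropic_noise_hits_component_cap(self, rng):
        # 40 bins of iid noise: EVR ~ 1/40 each, so 80% needs ~32 > 16
        X = random_log2_coverage("G", 500, 40, rng)
        model = dp.fit_gene_model(X)
        assert model.n_components == 16

    def test_matches_eigendecomposition_oracle(self, rng):
        X = binned(rng.normal(size=(60, 8)) @ rng.normal(size=(8, 8)))
        model = dp.fit_gene_model(X, variance_target=0.999, max_components=8)
        Z = model.standardize(X.values)
        cov = Z.T @ Z / (Z.shape[0] - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        evr = evals / evals.sum()
        k = model.n_components
        np.testing.assert_allclose(model.explained_variance_ratio, evr[:k],
                                   atol=1e-8)
        for i in range(k):
            v = evecs[:, i]
            j = int(np.argmax(np.abs(v)))
            if v[j] < 0:
                v = -v
            np.testing.assert_allclose(model.loadings[i], v, atol=1e-8)

    def test_zero_variance_bins_contribute_nothing(self, rng):
        vals = rng.normal(size=(30, 5))
        vals[:, 2] = 7.0  # constant bin
        model = dp.fit_gene_model(binned(vals), variance_target=0.999)
        assert model.train_sd[2] == 1.0
        Z = model.standardize(vals)
        assert np.all(Z[:, 2] == 0)

    def test_loadings_orthonormal(self, rng):
        model = dp.fit_gene_model(binned(rng.normal(size=(40, 10))))
        gram = model.loadings @ model.loadings.T
        np.testing.assert_allclose(gram, np.eye(model.n_components), atol=1e-8)

    def test_evr_non_increasing(self, rng):
        model = dp.fit_gene_model(binned(rng.normal(size=(50, 12))))
        assert np.all(np.diff(model.explained_variance_ratio) <= 1e-12)

    def test_rank_bound_uses_samples_minus_one(self, rng):
        X = binned(rng.normal(size=(5, 30)))  # 5 samples, 30 bins
        model = dp.fit_gene_model(X, variance_target=1.0, max_components=16)
        assert model.n_components <= 4

    def test_sign_convention_deterministic(self, rng):
        vals = rng.normal(size=(40, 6))
        m1 = dp.fit_gene_model(binned(vals))
        m2 = dp.fit_gene_model(binned(vals.copy()))
        np.testing.assert_array_equal(m1.loadings, m2.loadings)
        for row in m1.loadings:
            assert row[int(np.argmax(np.abs(row)))] > 0

    def test_constant_input_yields_empty_model(self):
        model = dp.fit_gene_model(binned(np.full((10, 4), 3.0)))
        assert model.n_components == 0


class TestApplyGeneModel:
    def test_training_projection_idempotent(self, rng):
        X = binned(rng.normal(size=(30, 6)))
        model = dp.fit_gene_model(X)
        p1 = dp.apply_gene_model(model, X)
        p2 = dp.apply_gene_model(model, X)
        Z = model.standardize(X.values)
        np.testing.assert_allclose(p1.to_numpy(), (Z @ model.loadings.T).T,
                                   atol=1e-8)
        pd.testing.assert_frame_equal(p1, p2)

    def test_train_mean_row_projects_to_zero(self, rng):
        X = binned(rng.normal(size=(30, 6)))
        model = dp.fit_gene_model(X)
        X_new = binned(np.tile(model.train_mean, (3, 1)))
        proj = dp.apply_gene_model(model, X_new)
        np.testing.assert_allclose(proj.to_numpy(), 0.0, atol=1e-12)

    def test_hand_built_projection(self):
        """2 bins, 3 samples: projections verified by manual arithmetic."""
        vals = np.array([[0.0, 0.0], [1.0, 2.0], [2.0, 4.0]])
        X = binned(vals)
        model = dp.fit_gene_model(X)
        # mean (1,2), sd (sqrt(2/3), sqrt(8/3)); standardized columns are
        # identical -> PC1 loading (1/sqrt2, 1/sqrt2)
        np.testing.assert_allclose(model.train_mean, [1.0, 2.0])
        np.testing.assert_allclose(model.loadings[0],
                                   [1 / np.sqrt(2), 1 / np.sqrt(2)], atol=1e-12)
        proj = dp.apply_gene_model(model, X).to_numpy()[0]
        z = (vals - [1.0, 2.0]) / np.sqrt([2 / 3, 8 / 3])
        np.testing.assert_allclose(proj, z @ model.loadings[0], atol=1e-12)

    def test_bin_mismatch_demands_rebinning(self, rng):
        X = binned(rng.normal(size=(30, 6)))
        model = dp.fit_gene_model(X)
        other = dp.BinnedCoverage("G", [f"G:{j + 1}" for j in range(6)],
                                  X.sample_ids, X.values, "log2")
        with pytest.raises(ValueError, match="re-bin"):
            dp.apply_gene_model(model, other)


class TestTrainingSetProperties:
    def test_ddp_orthogonality(self, fitted_small):
        """Distinct phenotypes of one gene are uncorrelated on training data."""
        table = fitted_small["table"]
        for gene in fitted_small["store"].models:
            rows = table.values.loc[[i for i in table.values.index
                                     if i.startswith(gene + ":")]]
            if len(rows) < 2:
                continue
            corr = np.corrcoef(rows.to_numpy())
            off = corr[~np.eye(len(corr), dtype=bool)]
            assert np.abs(off).max() < 1e-6

    def test_variance_ordering_matches_rank(self, fitted_small):
        table = fitted_small["table"]
        for gene, model in fitted_small["store"].models.items():
            variances = [
                table.values.loc[f"{gene}:PC{r}"].var()
                for r in range(1, model.n_components + 1)
            ]
            assert all(a >= b - 1e-10 for a, b in zip(variances, variances[1:]))

    def test_caps_respected(self, fitted_small):
        for model in fitted_small["store"].models.values():
            assert model.n_components <= 16
            if model.n_components < 16:
                assert model.explained_variance_ratio.sum() >= 0.80 - 1e-12


class TestModelStore:
    def test_empty_store_roundtrip(self, tmp_path):
        store = dp.ModelStore({}, {}, {"note": "empty"})
        dp.save_models(store, tmp_path / "m.zip")
        back = dp.load_models(tmp_path / "m.zip")
        assert back.models == {} and back.config == {"note": "empty"}

    def test_projections_identical_after_roundtrip(self, tmp_path, rng):
        models, schemes, probes = {}, {}, {}
        for i in range(50):
            gene = f"G{i}"
            X = random_log2_coverage(gene, 25, int(rng.integers(3, 12)), rng)
            models[gene] = dp.fit_gene_model(X)
            schemes[gene] = dp.BinScheme(gene, "chr1", "+", 0, len(X.bin_ids),
                                         [(j, j + 1) for j in range(len(X.bin_ids))])
            probes[gene] = X
        store = dp.ModelStore(models, schemes)
        dp.save_models(store, tmp_path / "m.zip")
        back = dp.load_models(tmp_path / "m.zip")
        assert set(back.models) == set(models)
        for gene, X in probes.items():
            a = dp.apply_gene_model(models[gene], X)
            b = dp.apply_gene_model(back.models[gene], X)
            np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())
        assert back.schemes["G3"] == schemes["G3"]

    def test_version_mismatch_reported(self, tmp_path):
        store = dp.ModelStore({}, {}, version="ddpheno-store-0")
        dp.save_models(store, tmp_path / "m.zip")
        with pytest.raises(ValueError, match="ddpheno-store-0"):
            dp.load_models(tmp_path / "m.zip")


class TestExportBed:
    def region(self, gene, chrom="chr1", start=100, end=200, strand="+"):
        return dp.GeneRegion(gene, chrom, strand, start, end, start, end,
                             "protein_coding")

    def table(self, data):
        return dp.PhenotypeTable(pd.DataFrame(
            data, columns=["s1", "s2", "s3"]
        ))

    def test_two_components_two_rows(self, tmp_path):
        table = dp.PhenotypeTable(pd.DataFrame(
            [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]],
            index=["G:PC1", "G:PC2"], columns=["s1", "s2", "s3"],
        ))
        bed = dp.export_bed(table, {"G": self.region("G")},
                            tmp_path / "p.bed", tmp_path / "p.groups")
        assert len(bed) == 2
        groups = pd.read_csv(tmp_path / "p.groups", sep="\t", header=None)
        assert groups[1].tolist() == ["G", "G"]
        assert (bed["start"] == 100).all() and (bed["end"] == 101).all()

    def test_negative_strand_tss(self, tmp_path):
        table = dp.PhenotypeTable(pd.DataFrame(
            [[1.0]], index=["G:PC1"], columns=["s1"],
        ))
        bed = dp.export_bed(table, {"G": self.region("G", strand="-")},
                            tmp_path / "p.bed")
        assert bed["start"].iloc[0] == 199  # gene_end - 1

    def test_rows_sorted_by_position(self, tmp_path):
        table = dp.PhenotypeTable(pd.DataFrame(
            [[1.0], [2.0], [3.0]],
            index=["B:PC1", "A:PC1", "C:PC1"], columns=["s1"],
        ))
        regions = {
            "A": self.region("A", start=500, end=600),
            "B": self.region("B", start=100, end=200),
            "C": self.region("C", chrom="chr2", start=10, end=20),
        }
        bed = dp.export_bed(table, regions, tmp_path / "p.bed")
        assert bed["phenotype_id"].tolist() == ["B:PC1", "A:PC1", "C:PC1"]

    def test_empty_table_headers_only(self, tmp_path):
        bed = dp.export_bed(dp.PhenotypeTable(pd.DataFrame()), {},
                            tmp_path / "p.bed")
        assert len(bed) == 0
        header = (tmp_path / "p.bed").read_text().splitlines()[0]
        assert header.startswith("#chr\tstart\tend\tphenotype_id")

    def test_missing_region_metadata_raises(self, tmp_path):
        table = dp.PhenotypeTable(pd.DataFrame(
            [[1.0]], index=["G:PC1"], columns=["s1"],
        ))
        with pytest.raises(ValueError, match="metadata"):
            dp.export_bed(table, {}, tmp_path / "p.bed")


def test_phenotype_ids_parse_and_ranks_contiguous():
    with pytest.raises(ValueError, match="contiguous"):
        dp.PhenotypeTable(pd.DataFrame(
            [[1.0], [2.0]], index=["G:PC1", "G:PC3"], columns=["s"],
        ))
    with pytest.raises(ValueError, match="invalid"):
        dp.PhenotypeTable(pd.DataFrame([[1.0]], index=["G-PC1"], columns=["s"]))
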