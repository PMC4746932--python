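import numpy as np
import pandas as pd
import pytest

import gdttc
from gdttc.containers import ValidationError
from gdttc.decorrelate import decorrelation_diagnostics
from gdttc.network import significant_pairs


def _expr_from(Y, tissue, donors):
    genes = [f"G{i:03d}" for i in range(Y.shape[0])]
    return gdttc.ExpressionMatrix(pd.DataFrame(Y, index=genes, columns=donors),
                                  tissue=tissue)


class TestBuildTransform:
    def test_h_zero_symmetric_is_identity(self, family_kinship):
        T = gdttc.build_transform(0.0, family_kinship)
        assert np.abs(T.matrix - np.eye(family_kinship.n_donors)).max() < 1e-10

    def test_h_zero_rotation_is_orthonormal_eigenbasis(self, family_kinship):
        T = gdttc.build_transform(0.0, family_kinship, form="rotation")
        assert np.allclose(T.matrix, family_kinship.eigenvectors.T)
        assert np.abs(T.matrix @ T.matrix.T - np.eye(family_kinship.n_donors)).max() < 1e-10

    @pytest.mark.parametrize("h", [0.1, 0.5, 0.9])
    @pytest.mark.parametrize("form", ["symmetric_sqrt", "rotation"])
    def test_whitening_contract(self, family_kinship, h, form):
        T = gdttc.build_transform(h, family_kinship, form=form)
        assert T.whitening_deviation(family_kinship) < 1e-8

    def test_h_one_rejected(self, family_kinship):
        with pytest.raises(ValidationError):
            gdttc.build_transform(1.0, family_kinship)


class TestApplyTransform:
    def test_all_h_zero_is_identity(self, family_kinship, rng):
        donors = family_kinship.donors
        expr = _expr_from(rng.standard_normal((5, len(donors))), "T1", donors)
        out = gdttc.apply_transform(expr, {g: 0.0 for g in expr.genes}, family_kinship)
        assert out.decorrelated
        assert np.abs(out.values - expr.values).max() < 1e-10

    def test_missing_estimate_listed(self, family_kinship, rng):
        donors = family_kinship.donors
        expr = _expr_from(rng.standard_normal((3, len(donors))), "T1", donors)
        with pytest.raises(ValidationError, match="G002"):
            gdttc.apply_transform(expr, {"G000": 0.1, "G001": 0.2}, family_kinship)

    def test_linearity_per_gene(self, family_kinship, rng):
        donors = family_kinship.donors
        n = len(donors)
        y1, y2 = rng.standard_normal(n), rng.standard_normal(n)
        a, b = 1.7, -0.4
        h = 0.6
        combo = _expr_from(np.vstack([y1, y2, a * y1 + b * y2]), "T1", donors)
        out = gdttc.apply_transform(combo, {g: h for g in combo.genes}, family_kinship)
        lhs = out.values[2]
        rhs = a * out.values[0] + b * out.values[1]
        assert np.abs(lhs - rhs).max() < 1e-10

    def test_monte_carlo_whitening(self, family_kinship):
        """Empirical covariance of 2000 transformed draws is close to I."""
        K = family_kinship
        n = K.n_donors
        h = 0.8
        sigma = h * K.values + (1 - h) * np.eye(n)
        L = np.linalg.cholesky(sigma + 1e-12 * np.eye(n))
        rng = np.random.default_rng(5)
        draws = L @ rng.standard_normal((n, 2000))
        D = gdttc.build_transform(h, K).matrix
        Z = D @ draws
        cov = Z @ Z.T / 2000
        assert np.abs(cov - np.eye(n)).max() < 0.1

    def test_forms_agree_on_uncentered_correlation_magnitude(self, family_kinship, rng):
        """Symmetric and rotation forms differ by the orthonormal factor U,
        so inner products and norms (hence cosine correlations) coincide;
        rank-based correlations do not, which is why the form is a fixed
        per-run configuration choice."""
        donors = family_kinship.donors
        n = len(donors)
        expr = _expr_from(rng.standard_normal((4, n)), "T1", donors)
        h = {g: 0.5 for g in expr.genes}
        sym = gdttc.apply_transform(expr, h, family_kinship, form="symmetric_sqrt")
        rot = gdttc.apply_transform(expr, h, family_kinship, form="rotation")

        def cosine(a, b):
            return a @ b / np.sqrt((a @ a) * (b @ b))

        for i in range(3):
            r_sym = cosine(sym.values[i], sym.values[i + 1])
            r_rot = cosine(rot.values[i], rot.values[i + 1])
            assert abs(abs(r_sym) - abs(r_rot)) < 1e-10


class TestDiagnostics:
    @staticmethod
    def _shared_genetic_cohort(seed=13):
        """Moderate shared genetic (cis-like) signal for every gene plus one
        planted non-genetic module; the transform should strip the former
        and keep the latter."""
        cfg = gdttc.SimulationConfig(
            n_donors=120, n_snps=300, genes_per_tissue=60,
            heritability_range=(0.3, 0.3), n_planted_modules=1, module_size=15,
            signal_strength=0.6, donor_overlap_fraction=1.0, seed=seed,
            n_families=6, share_genetic_across_tissues=True,
        )
        return gdttc.simulate_cohort(cfg)

    def test_cis_fraction_drops_when_correlation_is_genetic(self):
        coh = self._shared_genetic_cohort()
        K = gdttc.compute_kinship(coh.genotypes)
        e1, e2 = coh.expression["T1"], coh.expression["T2"]
        d1 = gdttc.apply_transform(e1, gdttc.estimate_heritability_matrix(e1, K), K)
        d2 = gdttc.apply_transform(e2, gdttc.estimate_heritability_matrix(e2, K), K)
        before = significant_pairs(e1, e2, 1e-3)
        after = significant_pairs(d1, d2, 1e-3)
        report = decorrelation_diagnostics(before, after, coh.truth.drivers)
        assert report.n_significant_after < report.n_significant_before
        assert report.cis_fraction_after < report.cis_fraction_before
        assert report.mean_shared_drivers_after < report.mean_shared_drivers_before

    def test_empty_edge_sets_report_zeros(self):
        empty1 = gdttc.EdgeSet("T1", "T2", [], genes_a=("G1",), genes_b=("G1",))
        empty2 = gdttc.EdgeSet("T1", "T2", [], genes_a=("G1",), genes_b=("G1",))
        report = decorrelation_diagnostics(empty1, empty2, {})
        assert report.n_significant_before == 0
        assert report.cis_fraction_after == 0.0

    def test_disjoint_gene_universes_rejected(self):
        a = gdttc.EdgeSet("T1", "T2", [], genes_a=("G1",), genes_b=("G2",))
        b = gdttc.EdgeSet("T1", "T2", [], genes_a=("X1",), genes_b=("X2",))
        with pytest.raises(ValidationError, match="disjoint"):
            decorrelation_diagnostics(a, b, {})
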