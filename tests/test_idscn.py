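"""IDSCN: partial correlations, leave-one-in Z-scores, edge summarization."""

import numpy as np
import pandas as pd
import pytest

from pgsubtype.cohort import CohortSpec, generate_cohort, plant_edge_perturbations
from pgsubtype.idscn import (EdgeSummary, ReferenceNetwork, build_reference,
                             compute_idscns, edge_significance,
                             idscn_based_clustering, idscn_for_subject,
                             partial_correlation_matrix, top_altered_edges)


def first_order_partial_oracle(x, y, z):
    """r_xy.z = (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2))."""
    r = lambda a, b: np.corrcoef(a, b)[0, 1]
    return (r(x, y) - r(x, z) * r(y, z)) / np.sqrt(
        (1 - r(x, z) ** 2) * (1 - r(y, z) ** 2))


class TestPartialCorrelation:
    def test_no_covariates_equals_plain_correlation(self, rng):
        x = rng.standard_normal((25, 6))
        assert np.allclose(partial_correlation_matrix(x), np.corrcoef(x.T), atol=1e-12)

    def test_first_order_closed_form(self, rng):
        z = rng.standard_normal(50)
        x = 0.6 * z + rng.standard_normal(50)
        y = -0.4 * z + rng.standard_normal(50)
        pcc = partial_correlation_matrix(np.column_stack([x, y]), z[:, None])
        assert pcc[0, 1] == pytest.approx(first_order_partial_oracle(x, y, z),
                                          abs=1e-10)

    def test_symmetric_unit_diagonal(self, rng):
        x = rng.standard_normal((30, 8))
        c = rng.standard_normal((30, 2))
        pcc = partial_correlation_matrix(x, c)
        assert np.allclose(pcc, pcc.T, atol=1e-12)
        assert np.allclose(np.diag(pcc), 1.0)
        assert np.all(np.abs(pcc) <= 1.0)

    def test_rank_deficient_covariates_rejected(self, rng):
        x = rng.standard_normal((20, 4))
        c = np.ones((20, 2))  # collinear with intercept
        with pytest.raises(ValueError, match="rank"):
            partial_correlation_matrix(x, c)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match="subjects"):
            partial_correlation_matrix(rng.standard_normal((4, 3)),
                                       rng.standard_normal((4, 2)))


class TestBuildReference:
    def test_reference_matrix_matches_roi_count(self):
        cohort = generate_cohort(CohortSpec(seed=0))
        ref = build_reference(cohort.subset("HC"))
        assert ref.pcc.shape == (166, 166)
        assert ref.n_hc == 57
        assert ref.covariates == ("age", "sex", "tiv")

    def test_block_structure_visible_in_reference(self):
        spec = CohortSpec(n_id=10, n_hc=50, n_roi=20, n_skeleton=20, seed=8,
                          tiv_scale_sd=0.0, age_slope=0.0,
                          noise_structure={"kind": "block", "n_blocks": 4,
                                           "block_size": 5, "rho": 0.6})
        cohort = generate_cohort(spec)
        ref = build_reference(cohort.subset("HC"))
        blocks = np.zeros((20, 20), dtype=bool)
        for k in range(4):
            blocks[k * 5:(k + 1) * 5, k * 5:(k + 1) * 5] = True
        np.fill_diagonal(blocks, False)
        off = ~blocks & ~np.eye(20, dtype=bool)
        assert ref.pcc[blocks].mean() > 0.3
        assert abs(ref.pcc[off].mean()) < 0.15

    def test_duplicated_controls_leave_reference_unchanged(self):
        cohort = generate_cohort(CohortSpec(n_id=5, n_hc=20, n_roi=8,
                                            n_skeleton=8, seed=2))
        hc = cohort.subset("HC")
        ref = build_reference(hc)
        import pandas as pd
        doubled = type(hc)(
            features=pd.concat([hc.features, hc.features.set_axis(
                [f"{s}b" for s in hc.features.index])]),
            pheno=pd.concat([hc.pheno, hc.pheno.set_axis(
                [f"{s}b" for s in hc.pheno.index])]),
        )
        ref2 = build_reference(doubled)
        assert np.allclose(ref.pcc, ref2.pcc, atol=1e-10)

    def test_non_hc_rows_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="HC"):
            build_reference(small_cohort)


def idscn_direct_oracle(ref_pcc, n_hc, hc_x, hc_c, sub_x, sub_c):
    """Rebuild the perturbed network pair-by-pair with statsmodels OLS
    residuals, then apply the printed Z formula."""
    import statsmodels.api as sm

    x_aug = np.vstack([hc_x, sub_x])
    c_aug = np.vstack([hc_c, sub_c])
    design = sm.add_constant(c_aug)
    r = x_aug.shape[1]
    resid = np.column_stack([sm.OLS(x_aug[:, k], design).fit().resid
                             for k in range(r)])
    pcc_aug = np.corrcoef(resid.T)
    delta = pcc_aug - ref_pcc
    with np.errstate(divide="ignore", invalid="ignore"):  # unit diagonal
        z = delta / ((1 - ref_pcc**2) / (n_hc - 1))
    return delta, z


class TestIdscnForSubject:
    @pytest.fixture()
    def toy(self, rng):
        n_hc, r = 20, 10
        hc_x = rng.standard_normal((n_hc, r))
        hc_c = rng.standard_normal((n_hc, 2))
        ref = ReferenceNetwork(pcc=partial_correlation_matrix(hc_x, hc_c),
                               n_hc=n_hc, covariates=("a", "b"))
        sub_x = rng.standard_normal(r)
        sub_c = rng.standard_normal(2)
        return ref, hc_x, hc_c, sub_x, sub_c

    def test_matches_direct_recomputation_oracle(self, toy):
        ref, hc_x, hc_c, sub_x, sub_c = toy
        net = idscn_for_subject(ref, sub_x, hc_x, hc_c, sub_c)
        delta_o, z_o = idscn_direct_oracle(ref.pcc, ref.n_hc, hc_x, hc_c,
                                           sub_x, sub_c)
        iu = np.triu_indices(10, 1)
        assert np.allclose(net.delta_pcc[iu], delta_o[iu], atol=1e-10)
        assert np.allclose(net.z[iu], z_o[iu], atol=1e-10)

    def test_sign_of_z_matches_sign_of_delta(self, toy):
        ref, hc_x, hc_c, sub_x, sub_c = toy
        net = idscn_for_subject(ref, sub_x, hc_x, hc_c, sub_c)
        iu = np.triu_indices(10, 1)
        assert np.all(np.sign(net.z[iu]) == np.sign(net.delta_pcc[iu]))

    def test_p_is_two_sided_normal_tail_of_z(self, toy):
        ref, hc_x, hc_c, sub_x, sub_c = toy
        net = idscn_for_subject(ref, sub_x, hc_x, hc_c, sub_c)
        from scipy import stats
        iu = np.triu_indices(10, 1)
        assert np.allclose(net.p[iu], 2 * stats.norm.sf(np.abs(net.z[iu])),
                           atol=1e-15)
        # hence an unperturbed edge (delta = 0, z = 0) has p exactly 1
        assert 2 * stats.norm.sf(0.0) == 1.0

    def test_null_z_calibrated(self, rng):
        n_hc, r = 57, 10
        hc_x = rng.standard_normal((n_hc, r))
        ref = ReferenceNetwork(pcc=partial_correlation_matrix(hc_x),
                               n_hc=n_hc, covariates=())
        iu = np.triu_indices(r, 1)
        means, rates = [], []
        for _ in range(200):
            sub = rng.standard_normal(r)
            net = idscn_for_subject(ref, sub, hc_x, np.empty((n_hc, 0)),
                                    np.empty(0))
            sig = edge_significance(net, method="bonferroni")
            means.append(np.nanmean(net.z[iu]))
            rates.append(sig[iu].mean())
        assert -0.1 < np.mean(means) < 0.1
        assert np.mean(rates) <= 0.05

    def test_decoupled_pair_produces_largest_z_on_that_edge(self, rng):
        """Injecting a subject that breaks one correlated region pair should
        put its most extreme |z| on exactly that edge (>= 90% of injections)."""
        n_hc, r = 50, 10
        shared = rng.standard_normal((n_hc, 1))
        hc_x = rng.standard_normal((n_hc, r)) * 0.4
        hc_x[:, 0] += shared[:, 0]
        hc_x[:, 1] += shared[:, 0]
        ref = ReferenceNetwork(pcc=partial_correlation_matrix(hc_x),
                               n_hc=n_hc, covariates=())
        hits = 0
        for _ in range(50):
            sub = rng.standard_normal(r) * 0.4
            s = rng.standard_normal()
            sub[0] += 2.5 * np.sign(s)
            sub[1] -= 2.5 * np.sign(s)
            net = idscn_for_subject(ref, sub, hc_x, np.empty((n_hc, 0)),
                                    np.empty(0))
            iu = np.triu_indices(r, 1)
            k = np.nanargmax(np.abs(net.z[iu]))
            hits += (iu[0][k], iu[1][k]) == (0, 1)
        assert hits >= 45


class TestEdgeSignificance:
    def test_no_significance_without_signal(self, rng):
        net = idscn_for_subject(
            ReferenceNetwork(pcc=np.eye(4), n_hc=30, covariates=()),
            np.zeros(4), rng.standard_normal((30, 4)),
            np.empty((30, 0)), np.empty(0))
        net.z[:] = 0.0
        net.p[:] = 1.0
        sig = edge_significance(net)
        assert not sig.any()

    def test_bonferroni_threshold_matches_oracle(self):
        r = 5  # m = 10 upper-triangle tests
        p = np.ones((r, r))
        iu = np.triu_indices(r, 1)
        vals = np.array([0.001, 0.004, 0.006, 0.02, 0.2, 0.3, 0.5, 0.7, 0.9, 0.99])
        p[iu] = vals
        p = np.minimum(p, p.T)
        from pgsubtype.idscn import SubjectIdscn
        net = SubjectIdscn(subject_id="t", delta_pcc=np.zeros((r, r)),
                           z=np.zeros((r, r)), p=p)
        sig = edge_significance(net, alpha=0.05, method="bonferroni")
        expected = vals < 0.05 / 10
        assert np.array_equal(sig[iu], expected)

    def test_unknown_method_rejected(self, rng):
        from pgsubtype.idscn import SubjectIdscn
        net = SubjectIdscn("t", np.zeros((3, 3)), np.zeros((3, 3)), np.ones((3, 3)))
        with pytest.raises(ValueError):
            edge_significance(net, method="holm")


@pytest.fixture(scope="module")
def perturbed_cohort():
    pairs = [(2 * k, 2 * k + 1) for k in range(8)]
    spec = CohortSpec(n_id=50, n_hc=40, n_roi=24, n_skeleton=24, seed=21,
                      noise_structure={"kind": "pairs", "pairs": pairs, "rho": 0.8})
    cohort = generate_cohort(spec)
    return plant_edge_perturbations(cohort, pairs, magnitude=3.0, seed=22), pairs


class TestTopAlteredEdges:
    def test_counts_match_loop_oracle(self, perturbed_cohort):
        cohort, _ = perturbed_cohort
        nets = compute_idscns(cohort)
        iu = np.triu_indices(24, 1)
        oracle = np.zeros(iu[0].size, dtype=int)
        for net in nets:
            for k in range(iu[0].size):
                if net.significant[iu[0][k], iu[1][k]]:
                    oracle[k] += 1
        summary = top_altered_edges(nets, min_subjects=1, top_k=10**9)
        got = {e: c for e, c in zip(summary.edges, summary.counts)}
        for k in range(iu[0].size):
            e = (int(iu[0][k]), int(iu[1][k]))
            assert got.get(e, 0) == oracle[k]

    def test_cap_applies_when_many_edges_qualify(self, perturbed_cohort):
        cohort, _ = perturbed_cohort
        nets = compute_idscns(cohort)
        summary = top_altered_edges(nets, min_subjects=25, top_k=5)
        assert len(summary.edges) == 5

    def test_no_edge_meets_criterion_gives_empty_list(self, perturbed_cohort):
        cohort, _ = perturbed_cohort
        nets = compute_idscns(cohort)
        summary = top_altered_edges(nets, min_subjects=10**6, top_k=20)
        assert summary.edges == []

    def test_planted_pairs_rank_first(self, perturbed_cohort):
        cohort, pairs = perturbed_cohort
        nets = compute_idscns(cohort)
        summary = top_altered_edges(nets, min_subjects=25, top_k=8)
        assert set(summary.edges) == set(pairs)


class TestIdscnClustering:
    def test_identical_structure_recovers_reference_labels(self, rng):
        z = np.vstack([rng.normal(5, 0.3, (20, 4)), rng.normal(-5, 0.3, (25, 4))])
        ids = [f"S{i}" for i in range(45)]
        summary = EdgeSummary(edges=[(0, 1)] * 4, counts=np.ones(4),
                              mean_abs_z=np.ones(4),
                              z_table=pd.DataFrame(z, index=ids),
                              min_subjects=1, top_k=4)
        ref = np.array([1] * 20 + [2] * 25)
        labels, crosstab, ari = idscn_based_clustering(summary, c=2, seed=0,
                                                       reference_labels=ref)
        assert ari == 1.0
        assert crosstab.to_numpy().max(axis=1).sum() == 45

    def test_empty_edges_rejected(self):
        summary = EdgeSummary(edges=[], counts=np.array([]), mean_abs_z=np.array([]),
                              z_table=pd.DataFrame(), min_subjects=1, top_k=0)
        with pytest.raises(ValueError):
            idscn_based_clustering(summary)
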