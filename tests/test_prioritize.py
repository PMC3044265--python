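import numpy as np
import pytest

from netprior.bayes import ConjugatePrior
from netprior.kernel import diffusion_kernel
from netprior.network import PPINetwork
from netprior.prioritize import (
    BatchScorer,
    build_design_matrix,
    cipher_proximity,
    cipher_score,
    ols_r2_score,
    rank_candidates,
    score_candidate_bf,
)
from netprior.profiles import AssociationSet, PhenotypeProfile


@pytest.fixture
def toy():
    """Path network, five diseases, a few associations."""
    net = PPINetwork.from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])
    kern = diffusion_kernel(net, 0.2)
    rng = np.random.default_rng(0)
    m = 9
    S = np.clip(rng.uniform(0.05, 0.5, (m, m)), 0, 1)
    S = (S + S.T) / 2
    np.fill_diagonal(S, 1.0)
    profile = PhenotypeProfile(tuple(f"d{i}" for i in range(m)), S)
    assoc = AssociationSet.from_pairs(
        [("d0", "a"), ("d1", "b"), ("d2", "c"), ("d3", "e"), ("d0", "d"), ("d5", "b")]
    )
    return net, kern, profile, assoc


class TestDesignMatrix:
    def test_scheme1_single_kernel_has_two_columns(self, toy):
        _, kern, profile, assoc = toy
        y, X = build_design_matrix("d1", ("c",), [kern], profile, assoc)
        assert X.shape == (profile.m - 1, 2)  # self row excluded by default
        y2, X2 = build_design_matrix("d1", ("c",), [kern], profile, assoc, exclude_self=False)
        assert X2.shape == (profile.m, 2)
        assert np.all(X2[:, 0] == 1.0)

    def test_pq_plus_one_columns(self, toy):
        net, kern, profile, assoc = toy
        kern2 = diffusion_kernel(net, 0.3)
        y, X = build_design_matrix("d0", ("a", "b", "c"), [kern, kern2], profile, assoc)
        assert X.shape[1] == 3 * 2 + 1  # p=3 model genes, q=2 kernels

    def test_override_enters_all_columns(self, toy):
        _, kern, profile, assoc = toy
        _, X = build_design_matrix("d2", ("a",), [kern], profile, assoc, exclude_self=False)
        d2 = profile.position("d2")
        assert X[d2, 1] == kern.proximity("a", "a")


class TestBayesFactorScoring:
    def test_absent_candidate_scores_log_bf_zero(self, toy):
        _, kern, profile, assoc = toy
        assert score_candidate_bf("d1", "not_a_gene", [kern], profile, assoc) == 0.0

    def test_scheme2_includes_known_genes(self, toy):
        _, kern, profile, assoc = toy
        s1 = score_candidate_bf("d0", "c", [kern], profile, assoc, scheme=1)
        s2 = score_candidate_bf("d0", "c", [kern], profile, assoc, scheme=2)
        assert s1 != s2  # d0 has two known genes that enter the scheme-2 design

    def test_inert_extra_network(self, toy):
        """A network sharing no genes adds all-zero columns and no evidence."""
        _, kern, profile, assoc = toy
        other = diffusion_kernel(PPINetwork.from_edges([("x1", "x2")]), 0.2)
        for cand in ("a", "c", "e"):
            solo = score_candidate_bf("d1", cand, [kern], profile, assoc)
            both = score_candidate_bf("d1", cand, [kern, other], profile, assoc)
            assert both == pytest.approx(solo, abs=1e-10)

    def test_batch_scorer_matches_reference(self, toy):
        net, kern, profile, assoc = toy
        kern2 = diffusion_kernel(net, 0.35)
        prior = ConjugatePrior(0.7)
        for excl in (True, False):
            batch = BatchScorer([kern, kern2], profile, assoc, method="bf",
                                prior=prior, exclude_self=excl)
            for d in profile.disease_index:
                got = batch(d, ["a", "c", "e", "nope"])
                want = [score_candidate_bf(d, c, [kern, kern2], profile, assoc,
                                           prior=prior, exclude_self=excl)
                        for c in ["a", "c", "e", "nope"]]
                assert np.allclose(got, want, atol=1e-10)


class TestRanking:
    def test_simple_order(self):
        ranked = rank_candidates("d", ["g1", "g2", "g3"], lambda d, c: [3.0, 2.0, 1.0])
        assert [e.gene for e in ranked.entries] == ["g1", "g2", "g3"]
        assert [e.rank for e in ranked.entries] == [1.0, 2.0, 3.0]
        assert [e.rank_ratio for e in ranked.entries] == pytest.approx([1 / 3, 2 / 3, 1.0])

    def test_average_rank_for_ties(self):
        ranked = rank_candidates("d", list("abcd"), lambda d, c: [1.0] * 4)
        assert all(e.rank == 2.5 for e in ranked.entries)
        assert all(e.rank_ratio == 2.5 / 4 for e in ranked.entries)
        # display order deterministic by identifier
        assert [e.gene for e in ranked.entries] == ["a", "b", "c", "d"]

    def test_top_of_hundred(self):
        genes = [f"g{i:03d}" for i in range(100)]
        scores = {g: 0.0 for g in genes}
        scores["g042"] = 5.0
        ranked = rank_candidates("d", genes, lambda d, c: [scores[g] for g in c])
        assert ranked.rank_ratio("g042") == pytest.approx(0.01)

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            rank_candidates("d", ["g1", "g1"], lambda d, c: [1, 2])

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            rank_candidates("d", [], lambda d, c: [])


class TestCipher:
    def test_affine_proximity_scores_one(self, toy):
        """x_g affine in y_d with positive slope gives correlation exactly 1."""
        from netprior.kernel import GeneProximity

        _, _, profile, _ = toy
        d = "d1"
        y = profile.row(d)
        # one helper gene per disease; the candidate's proximity to helper k
        # is an affine map of y_k, so x = 2 y + 0.05 entrywise
        helpers = [f"h{i}" for i in range(profile.m)]
        genes = tuple(sorted(["cand", *helpers]))
        Z = np.zeros((len(genes), len(genes)))
        prox = GeneProximity(gene_index=genes, Z=Z)
        ci = prox.position("cand")
        for k, h in enumerate(helpers):
            Z[ci, prox.position(h)] = 2.0 * y[k] + 0.05
        Z[ci, ci] = 2.0 * 1.0 + 0.05  # override entry for the query disease
        assoc = AssociationSet.from_pairs(
            [(f"d{k}", helpers[k]) for k in range(profile.m)]
        )
        r = cipher_score(d, "cand", prox, profile, assoc, exclude_self=False)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_vector_scores_zero_with_warning(self, toy):
        _, kern, profile, assoc = toy
        with pytest.warns(UserWarning, match="zero-variance"):
            assert cipher_score("d1", "ghost", kern, profile, assoc) == 0.0

    def test_hand_computed_pearson(self, toy):
        net, _, profile, assoc = toy
        prox = cipher_proximity(net)
        from netprior.profiles import gene_proximity_vector

        x = gene_proximity_vector(prox, "b", profile, assoc, override={"d2": ("b",)})
        y = profile.row("d2")
        keep = np.arange(profile.m) != profile.position("d2")
        xc, yc = x[keep] - x[keep].mean(), y[keep] - y[keep].mean()
        expect = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
        assert cipher_score("d2", "b", net, profile, assoc) == pytest.approx(expect, abs=1e-12)

    def test_shortest_path_kernel_values(self, toy):
        net, _, _, _ = toy
        prox = cipher_proximity(net)
        i, j = prox.position("a"), prox.position("b")
        assert prox.Z[i, i] == 1.0
        assert prox.Z[i, j] == pytest.approx(np.exp(-1.0))
        k = prox.position("c")
        assert prox.Z[i, k] == pytest.approx(np.exp(-4.0))

    def test_disconnected_pairs_zero(self):
        net = PPINetwork.from_edges([("a", "b"), ("c", "d")])
        prox = cipher_proximity(net)
        assert prox.proximity("a", "c") == 0.0

    def test_diffusion_kernel_variant(self, toy):
        net, kern, profile, assoc = toy
        r_sp = cipher_score("d1", "b", net, profile, assoc, sp_kernel=True)
        r_dk = cipher_score("d1", "b", net, profile, assoc, sp_kernel=False)
        assert r_sp != r_dk  # different proximity matrices, both finite
        assert np.isfinite(r_sp) and np.isfinite(r_dk)


class TestOlsR2:
    def test_exact_linear_fit_scores_one(self, toy):
        """y exactly affine in the candidate's proximity column gives R^2 = 1."""
        from netprior.kernel import GeneProximity

        _, _, profile, _ = toy
        d = "d1"
        y = profile.row(d)
        helpers = [f"h{i}" for i in range(profile.m)]
        genes = tuple(sorted(["cand", *helpers]))
        Z = np.zeros((len(genes), len(genes)))
        prox = GeneProximity(gene_index=genes, Z=Z)
        ci = prox.position("cand")
        for k, h in enumerate(helpers):
            Z[ci, prox.position(h)] = 3.0 * y[k] + 0.2
        Z[ci, ci] = 3.0 * 1.0 + 0.2
        assoc = AssociationSet.from_pairs(
            [(f"d{k}", helpers[k]) for k in range(profile.m)]
        )
        assert ols_r2_score(d, "cand", [prox], profile, assoc) == pytest.approx(1.0, abs=1e-12)

    def test_zero_column_scores_zero(self, toy):
        _, kern, profile, assoc = toy
        assert ols_r2_score("d1", "ghost", [kern], profile, assoc) == 0.0

    def test_matches_normal_equations_oracle(self, toy):
        net, kern, profile, assoc = toy
        kern2 = diffusion_kernel(net, 0.3)
        for cand in ("a", "c", "e"):
            got = ols_r2_score("d1", cand, [kern, kern2], profile, assoc)
            y, X = build_design_matrix("d1", (cand,), [kern, kern2], profile, assoc)
            yc = y - y.mean()
            Xc = X[:, 1:] - X[:, 1:].mean(axis=0)
            beta = np.linalg.pinv(Xc.T @ Xc) @ Xc.T @ yc
            r2 = 1 - ((yc - Xc @ beta) @ (yc - Xc @ beta)) / (yc @ yc)
            assert got == pytest.approx(r2, abs=1e-10)

    def test_batch_ols_and_cipher_match_reference(self, toy):
        net, kern, profile, assoc = toy
        batch = BatchScorer([kern], profile, assoc, method="ols")
        for d in profile.disease_index:
            got = batch(d, ["a", "c", "ghost"])
            want = [ols_r2_score(d, c, [kern], profile, assoc) for c in ["a", "c", "ghost"]]
            assert np.allclose(got, want, atol=1e-10)
        prox = cipher_proximity(net)
        batch_c = BatchScorer([prox], profile, assoc, method="cipher")
        for d in profile.disease_index:
            got = batch_c(d, ["a", "c"])
            want = [cipher_score(d, c, prox, profile, assoc) for c in ["a", "c"]]
            assert np.allclose(got, want, atol=1e-10)


def test_single_kernel_integration_reduces_to_single_network(toy):
    _, kern, profile, assoc = toy
    solo = BatchScorer([kern], profile, assoc, method="bf")
    for d in profile.disease_index:
        got = solo(d, ["a", "b", "c"])
        want = [score_candidate_bf(d, c, [kern], profile, assoc) for c in ["a", "b", "c"]]
        assert np.allclose(got, want, atol=1e-12)
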