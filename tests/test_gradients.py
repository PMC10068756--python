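"""Gradient estimation: affinity, diffusion embedding, alignment, contrast."""

import warnings

import numpy as np
import pytest
from scipy import linalg as sla

from psyfusion.containers import FCMatrix, GradientSet, NetworkPartition
from psyfusion.gradients import (
    AffinityMatrix,
    GradientConfig,
    build_affinity,
    diffusion_embedding,
    gradient_contrast,
    gradients_from_fc,
    group_template,
    procrustes_align,
)


def labels(n):
    return [f"U{i}" for i in range(n)]


def dense_embedding_oracle(W, alpha=0.5, n_components=5):
    """Brute-force reference: explicit Markov operator, nonsymmetric eig."""
    d = W.sum(axis=1)
    Wa = W / np.outer(d**alpha, d**alpha)
    P = Wa / Wa.sum(axis=1, keepdims=True)
    evals, evecs = np.linalg.eig(P)
    order = np.argsort(evals.real)[::-1]
    evals = evals.real[order]
    evecs = evecs.real[:, order]
    lam = evals[1 : n_components + 1]
    psi = evecs / evecs[:, [0]]
    return psi[:, 1 : n_components + 1] * (lam / (1 - lam)), lam


class TestAffinity:
    def test_identical_rows_have_unit_similarity(self):
        # units 0 and 1 have literally identical connectivity profiles
        z = np.array([[0.0, 0.0, 0.8, 0.6],
                      [0.0, 0.0, 0.8, 0.6],
                      [0.8, 0.8, 0.0, 0.7],
                      [0.6, 0.6, 0.7, 0.0]])
        aff = build_affinity(FCMatrix(z, labels(4)), GradientConfig(sparsity=0.0))
        assert aff.values[0, 1] == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(aff.values, aff.values.T)

    def test_orthogonal_rows_have_zero_similarity(self):
        z = np.zeros((4, 4))
        z[0, 1] = z[1, 0] = 1.0
        z[2, 3] = z[3, 2] = 1.0
        aff = build_affinity(FCMatrix(z, labels(4)), GradientConfig(sparsity=0.0))
        assert aff.values[0, 2] == 0.0

    def test_hand_computed_worked_fixture(self):
        # 4x4 matrix, sparsity 0.5 keeps the top 2 entries per row
        z = np.array([[0.0, 0.8, 0.6, 0.2],
                      [0.8, 0.0, 0.5, 0.1],
                      [0.6, 0.5, 0.0, 0.4],
                      [0.2, 0.1, 0.4, 0.0]])
        cfg = GradientConfig(sparsity=0.5)
        aff = build_affinity(FCMatrix(z, labels(4)), cfg)
        # thresholded rows: r0=(0,.8,.6,0) r1=(.8,0,.5,0) r2=(.6,.5,0,0)
        # r3=(.2,0,.4,0); cos(r0,r1) = .6*.5 / (1*0.943398)
        r0 = np.array([0.0, 0.8, 0.6, 0.0])
        r1 = np.array([0.8, 0.0, 0.5, 0.0])
        r3 = np.array([0.2, 0.0, 0.4, 0.0])
        expected01 = (r0 @ r1) / (np.linalg.norm(r0) * np.linalg.norm(r1))
        expected03 = (r0 @ r3) / (np.linalg.norm(r0) * np.linalg.norm(r3))
        assert aff.values[0, 1] == pytest.approx(expected01, abs=1e-10)
        assert aff.values[0, 3] == pytest.approx(expected03, abs=1e-10)

    def test_negative_similarities_clipped(self):
        z = np.array([[0.0, 1.0, -1.0],
                      [1.0, 0.0, -0.5],
                      [-1.0, -0.5, 0.0]])
        aff = build_affinity(FCMatrix(z, labels(3)), GradientConfig(sparsity=0.0))
        assert aff.values.min() >= 0.0

    def test_all_zero_row_rejected(self):
        z = np.zeros((3, 3))
        with pytest.raises(ValueError):
            build_affinity(FCMatrix(z, labels(3)), GradientConfig(sparsity=0.0))


def two_block_affinity(rng, n=20, bridge=0.05, within=1.0):
    W = bridge * rng.random((n, n)) * 0.1
    half = n // 2
    W[:half, :half] += within * (0.8 + 0.2 * rng.random((half, half)))
    W[half:, half:] += within * (0.8 + 0.2 * rng.random((half, half)))
    W[0, half] = W[half, 0] = bridge
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0.0)
    return W


class TestDiffusionEmbedding:
    def test_agrees_with_dense_oracle(self, rng):
        for n in (20, 50):
            W = rng.random((n, n))
            W = (W + W.T) / 2
            np.fill_diagonal(W, 0)
            g = diffusion_embedding(AffinityMatrix(W, labels(n), 0.0),
                                    GradientConfig(n_components=5))
            oracle, lam = dense_embedding_oracle(W)
            for k in range(5):
                c = np.corrcoef(g.scores[:, k], oracle[:, k])[0, 1]
                assert abs(c) > 0.999
            np.testing.assert_allclose(g.eigenvalues, lam, atol=1e-8)

    def test_principal_gradient_separates_weakly_bridged_cliques(self, rng):
        W = two_block_affinity(rng, n=10)
        g = diffusion_embedding(AffinityMatrix(W, labels(10), 0.0))
        pg = g.principal
        assert np.ptp(np.sign(pg[:5])) == 0 and np.ptp(np.sign(pg[5:])) == 0
        assert np.sign(pg[0]) != np.sign(pg[5])

    def test_permutation_equivariance(self, rng):
        W = two_block_affinity(rng, n=12)
        perm = rng.permutation(12)
        g1 = diffusion_embedding(AffinityMatrix(W, labels(12), 0.0))
        g2 = diffusion_embedding(
            AffinityMatrix(W[np.ix_(perm, perm)], [labels(12)[i] for i in perm], 0.0))
        for k in range(min(3, g1.n_components)):
            c = np.corrcoef(g1.scores[perm, k], g2.scores[:, k])[0, 1]
            assert abs(c) > 0.999

    def test_uniform_affinity_flags_degenerate_spectrum(self):
        W = np.ones((8, 8)) - np.eye(8)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            diffusion_embedding(AffinityMatrix(W, labels(8), 0.0))

    def test_disconnected_graph_warns_and_restricts(self, rng):
        W = np.zeros((8, 8))
        W[:5, :5] = 0.5
        W[5:, 5:] = 0.5
        np.fill_diagonal(W, 0.0)
        with pytest.warns(RuntimeWarning, match="components"):
            g = diffusion_embedding(AffinityMatrix(W, labels(8), 0.0))
        assert np.all(g.scores[5:] == 0)


class TestProcrustes:
    def make_set(self, rng, n=20, k=4):
        scores = rng.normal(size=(n, k))
        return GradientSet(scores, np.linspace(0.9, 0.5, k), labels(n))

    def test_self_alignment_is_identity(self, rng):
        g = self.make_set(rng)
        aligned = procrustes_align(g, g)
        np.testing.assert_allclose(aligned.scores, g.scores, atol=1e-10)

    def test_sign_flip_recovered(self, rng):
        g = self.make_set(rng)
        flipped = GradientSet(g.scores * np.array([-1, 1, -1, 1]),
                              g.eigenvalues, g.unit_labels)
        aligned = procrustes_align(flipped, g)
        np.testing.assert_allclose(aligned.scores, g.scores, atol=1e-10)

    def test_random_rotation_recovered(self, rng):
        g = self.make_set(rng)
        Q = sla.qr(rng.normal(size=(4, 4)))[0]
        rotated = GradientSet(g.scores @ Q, g.eigenvalues, g.unit_labels)
        aligned = procrustes_align(rotated, g)
        np.testing.assert_allclose(aligned.scores, g.scores, atol=1e-8)

    def test_dimension_mismatch_rejected(self, rng):
        g = self.make_set(rng)
        small = GradientSet(g.scores[:, :2], g.eigenvalues[:2], g.unit_labels)
        with pytest.raises(ValueError):
            procrustes_align(small, g)


class TestGradientContrast:
    def part(self, n):
        return NetworkPartition(labels(n), ["VIS" if i < n // 2 else "DMN"
                                            for i in range(n)])

    def aligned(self, scores):
        return GradientSet(scores, np.ones(scores.shape[1]), labels(scores.shape[0]),
                           aligned_to="template")

    def test_identical_conditions_give_zero_differences(self, rng):
        sets = [self.aligned(rng.normal(size=(10, 2))) for _ in range(4)]
        out = gradient_contrast(sets, sets, self.part(10))
        np.testing.assert_allclose(out.unit_stats["mean_diff"], 0.0)

    def test_shrinking_scores_halves_compression_metrics(self, rng):
        base = [self.aligned(rng.normal(size=(10, 2))) for _ in range(4)]
        shrunk = [self.aligned(g.scores * 0.5) for g in base]
        out = gradient_contrast(shrunk, base, self.part(10))
        comp = out.compression
        for s in range(4):
            drug = comp.query("condition=='drug' and subject==@s")
            plac = comp.query("condition=='placebo' and subject==@s")
            assert drug["sd"].item() == pytest.approx(0.5 * plac["sd"].item())
            assert drug["range"].item() == pytest.approx(0.5 * plac["range"].item())

    def test_unaligned_inputs_rejected(self, rng):
        g = GradientSet(rng.normal(size=(10, 2)), np.ones(2), labels(10))
        with pytest.raises(ValueError):
            gradient_contrast([g], [g], self.part(10))


def test_group_template_and_full_chain_runs(rng):
    from psyfusion.fc_static import pairwise_fc, post_injection_window
    from psyfusion.synthetic import SimConfig, simulate_parcel_bold

    cfg = SimConfig(n_volumes=300, injection_index=100, seed=3)
    fcs = []
    for s in ("sub-01", "sub-02"):
        ts = simulate_parcel_bold(cfg, s, "placebo")
        fcs.append(pairwise_fc(ts, post_injection_window(ts)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        template = group_template(fcs)
        aligned = [procrustes_align(gradients_from_fc(fc), template) for fc in fcs]
    assert all(a.aligned_to == "template" for a in aligned)
    assert all(np.isfinite(a.scores).all() for a in aligned)
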