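import numpy as np
import pandas as pd
import pytest

from conftest import make_linear_generator, make_random_generator
from ganwgcna import trajectory
from ganwgcna.data_io import ExpressionMatrix
from ganwgcna.trajectory import (
    ResembledFakeError,
    SimulationConfig,
    average_profile,
    interpolate_pair,
    resembled_fake,
)


class TestInterpolatePair:
    def test_zero_delta_gives_identical_rows(self):
        gen = make_random_generator(seed=3)
        z = np.ones(3)
        traj = interpolate_pair(gen, z, z, steps=9)
        assert traj.shape == (11, 12)
        assert np.allclose(traj, traj[0])

    def test_linear_generator_matches_feature_space_interpolation(self):
        gen = make_linear_generator(n_genes=8, latent_dim=2, seed=0)
        rng = np.random.default_rng(1)
        z0, z1 = rng.normal(size=2), rng.normal(size=2)
        traj = interpolate_pair(gen, z0, z1, steps=99, dtype=np.float64)
        f = np.arange(101)[:, None] / 100.0
        expected = (1 - f) * gen.generate(z0[None], dtype=np.float64) + f * gen.generate(
            z1[None], dtype=np.float64
        )
        assert np.allclose(traj, expected, atol=1e-9)

    def test_midpoint_latent_is_the_mean(self):
        gen = make_linear_generator()
        z0 = np.array([1.0, 0.0])
        z1 = np.array([0.0, 2.0])
        traj = interpolate_pair(gen, z0, z1, steps=99, dtype=np.float64)
        mid = gen.generate(((z0 + z1) / 2)[None], dtype=np.float64)[0]
        assert np.allclose(traj[50], mid, atol=1e-12)

    def test_endpoints_reproduce_generator_outputs(self):
        gen = make_random_generator(seed=9)
        rng = np.random.default_rng(2)
        z0, z1 = rng.normal(size=3), rng.normal(size=3)
        # single-precision decoding is batch-blocked, so a lone decode can
        # differ from the batched one in the last float32 bits only
        traj = interpolate_pair(gen, z0, z1)
        assert np.allclose(traj[0], gen.generate(z0[None])[0], atol=1e-6)
        assert np.allclose(traj[-1], gen.generate(z1[None])[0], atol=1e-6)
        # in double precision the endpoints match the lone decode to rounding
        traj64 = interpolate_pair(gen, z0, z1, dtype=np.float64)
        assert np.allclose(traj64[0], gen.generate(z0[None], dtype=np.float64)[0], atol=1e-12)
        assert np.allclose(traj64[-1], gen.generate(z1[None], dtype=np.float64)[0], atol=1e-12)

    def test_length_mismatch_rejected(self):
        gen = make_random_generator()
        with pytest.raises(ValueError, match="mismatch"):
            interpolate_pair(gen, np.zeros(3), np.zeros(4))


class TestResembledFake:
    def test_recovers_target_on_linear_manifold(self):
        # orthonormal linear generator: the best candidates cluster around the
        # true latent and the achieved correlation approaches 1
        gen = make_linear_generator(n_genes=8, latent_dim=2, seed=0, orthonormal=True)
        z_star = np.array([0.8, -0.4])
        x_target = gen.generate(z_star[None], dtype=np.float64)[0]
        rf = resembled_fake(gen, x_target, "s", n_candidates=20000, k=10,
                            threshold=0.95, seed=1)
        assert rf.achieved_r >= 0.99
        assert (rf.contributing_r >= 0.95).all()

    def test_degenerate_parameters_reduce_to_best_candidate(self):
        gen = make_random_generator(seed=2)
        rng = np.random.default_rng(0)
        x_target = gen.generate(rng.normal(size=(1, 3)))[0]
        rf = resembled_fake(gen, x_target, "s", n_candidates=500, k=1,
                            threshold=0.0, seed=3)
        assert rf.achieved_r == pytest.approx(float(rf.contributing_r[0]), abs=1e-6)

    def test_same_seed_identical_result(self):
        gen = make_random_generator(seed=2)
        x_target = gen.generate(np.ones((1, 3)))[0]
        a = resembled_fake(gen, x_target, "s", n_candidates=500, k=3, threshold=0.0, seed=5)
        b = resembled_fake(gen, x_target, "s", n_candidates=500, k=3, threshold=0.0, seed=5)
        assert np.array_equal(a.z_bar, b.z_bar)
        assert a.achieved_r == b.achieved_r

    def test_failure_names_sample_and_best_r(self):
        gen = make_linear_generator(n_genes=8, latent_dim=2, seed=0, orthonormal=True)
        # a target orthogonal to the generator's column space is unreachable
        rng = np.random.default_rng(4)
        x = rng.normal(size=8)
        q = gen.net.W[0]
        x -= q @ (q.T @ x)  # project out the reachable subspace
        with pytest.raises(ResembledFakeError, match="sampleX") as err:
            resembled_fake(gen, x, "sampleX", n_candidates=200, k=5,
                           threshold=0.99, max_retries=2, seed=0)
        assert err.value.best_r < 0.99

    def test_k_larger_than_pool_rejected(self):
        gen = make_random_generator()
        with pytest.raises(ValueError, match="n_candidates"):
            resembled_fake(gen, np.zeros(12), "s", n_candidates=5, k=10)


def _two_group_matrix(gen, n_sn=2, n_cn=3, seed=0):
    rng = np.random.default_rng(seed)
    zs = rng.normal(size=(n_sn + n_cn, gen.latent_dim))
    vals = gen.generate(zs, dtype=np.float64).T
    ids = [f"SN{i}" for i in range(n_sn)] + [f"CN{i}" for i in range(n_cn)]
    return ExpressionMatrix(
        values=pd.DataFrame(vals, index=gen.gene_ids, columns=ids),
        sample_group=pd.Series(["SN"] * n_sn + ["CN"] * n_cn, index=ids),
    )


class TestAverageProfile:
    CFG = SimulationConfig(n_candidates=4000, k=5, threshold=0.9, max_retries=3, seed=0)

    def test_single_pair_equals_interpolate_pair(self):
        gen = make_linear_generator(n_genes=8, latent_dim=2, seed=0, orthonormal=True)
        X = _two_group_matrix(gen, n_sn=1, n_cn=1)
        stack = average_profile([gen], X, self.CFG)
        assert stack.values.shape == (1, 101, 8)
        fakes = {r.sample_id: r for r in _refakes(gen, X, self.CFG)}
        expected = interpolate_pair(gen, fakes["SN0"].z_bar, fakes["CN0"].z_bar)
        assert np.allclose(stack.values[0], expected, atol=1e-6)

    def test_pair_combinatorics_and_log(self):
        gen = make_linear_generator(n_genes=8, latent_dim=2, seed=0, orthonormal=True)
        X = _two_group_matrix(gen, n_sn=2, n_cn=3)
        stack = average_profile([gen, gen], X, self.CFG)
        assert stack.n_repeats == 2
        assert stack.n_timesteps == 101
        # one fake per sample per checkpoint
        assert len(stack.fake_log) == 2 * 5
        assert (stack.fake_log.n_candidates == self.CFG.n_candidates).all()
        assert (stack.fake_log.k == self.CFG.k).all()

    def test_endpoints_equal_group_means_of_fakes(self):
        # the pair mean at t=0 is the mean over SN fakes (exact by linearity
        # of the mean over pairs; the generator itself need not be linear)
        gen = make_random_generator(n_genes=12, latent_dim=3, seed=7)
        X = _two_group_matrix(gen, n_sn=2, n_cn=2, seed=1)
        cfg = SimulationConfig(n_candidates=4000, k=5, threshold=0.5, max_retries=3, seed=0)
        stack = average_profile([gen], X, cfg)
        fakes = _refakes(gen, X, cfg)
        sn_mean = np.mean(
            [gen.generate(f.z_bar[None])[0] for f in fakes if f.sample_id.startswith("SN")],
            axis=0,
        )
        assert np.allclose(stack.values[0, 0], sn_mean, atol=1e-5)

    def test_failure_aborts_with_sample_names(self):
        gen = make_linear_generator(n_genes=8, latent_dim=2, seed=0, orthonormal=True)
        X = _two_group_matrix(gen, n_sn=1, n_cn=1)
        strict = SimulationConfig(n_candidates=50, k=10, threshold=0.999999,
                                  max_retries=1, seed=0)
        with pytest.raises(ResembledFakeError):
            average_profile([gen], X, strict)

    def test_nonlinear_generator_departs_from_feature_space_interpolation(self):
        # the method's point: decoding a latent segment through a nonlinear
        # generator is not a straight line in expression space
        gen = make_random_generator(n_genes=12, latent_dim=3, hidden=(16, 16), seed=11)
        rng = np.random.default_rng(0)
        z0, z1 = rng.normal(size=3), rng.normal(size=3)
        traj = interpolate_pair(gen, z0, z1)
        f = np.arange(101)[:, None] / 100.0
        linear = (1 - f) * traj[0] + f * traj[-1]
        assert not np.allclose(traj, linear, atol=1e-3)


def _refakes(gen, X, cfg):
    from ganwgcna._utils import child_seed

    out = []
    samples = X.samples_in("SN") + X.samples_in("CN")
    for si, s in enumerate(samples):
        out.append(
            resembled_fake(
                gen, X.values[s].to_numpy(), s,
                n_candidates=cfg.n_candidates, k=cfg.k, threshold=cfg.threshold,
                max_retries=cfg.max_retries, seed=child_seed(cfg.seed, 0, si),
            )
        )
    return out
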