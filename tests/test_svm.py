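"""Quasi-Gaussian SVM: kernel bounds, oracle agreement, DPU equivalence."""

import numpy as np
import pytest

from epihybrid import (
    Decision,
    DomainError,
    SVMModel,
    decision_function,
    dpu_dataflow_eval,
    kernel_eval,
)
from epihybrid.svm import SupportVectorROM, load_svm_bundle, save_svm_bundle


def make_model(rng, L=50, gamma=0.5, b=0.1, log_transform=False, positive=False):
    loc = 2.0 if positive else 0.0
    sv = (loc + rng.normal(0, 1, (L, 31))).astype(np.float32)
    if positive:
        sv = np.abs(sv) + np.float32(0.05)
    alphas = rng.normal(0, 1, L).astype(np.float32)
    return SVMModel(
        support_vectors=sv,
        alphas=alphas,
        b=b,
        sigma=1.0 / gamma,
        s_max=float(sv.max()),
        s_min=float(sv.min()),
        f_max=float(sv.max()) + 1.0,
        f_min=float(sv.min()) - 1.0,
        gamma_eff=gamma,
        log_transform=log_transform,
    )


def oracle_score(x, model):
    """Double-precision direct evaluation of the decision function."""
    u = np.asarray(x, dtype=np.float64)
    sv = model.support_vectors.astype(np.float64)
    if model.log_transform:
        u, sv = np.log(u), np.log(sv)
    d2 = np.sum((u[None, :] - sv) ** 2, axis=1)
    k = np.exp(-float(model.gamma_eff) * d2)
    return float(model.alphas.astype(np.float64) @ k - float(model.b))


class TestKernel:
    def test_identical_vectors_give_unit_kernel(self, rng):
        model = make_model(rng, L=3)
        x = model.support_vectors[0]
        k = kernel_eval(x, x, model)
        assert abs(float(k) - 1.0) <= 1e-4

    def test_kernel_within_unit_interval(self, rng):
        model = make_model(rng, L=10, gamma=0.05)
        for _ in range(50):
            x = rng.normal(0, 1, 31).astype(np.float32)
            k = float(kernel_eval(x, model.support_vectors[0], model))
            assert 0.0 < k <= 1.0

    def test_kernel_vanishes_at_large_gamma(self, rng):
        model = make_model(rng, L=1, gamma=1e6)
        x = (model.support_vectors[0] + 1.0).astype(np.float32)
        assert float(kernel_eval(x, model.support_vectors[0], model)) <= 1e-30

    def test_matches_direct_formula(self, rng):
        model = make_model(rng, L=1, gamma=0.5)
        for _ in range(100):
            x = rng.normal(0, 1, 31).astype(np.float32)
            got = float(kernel_eval(x, model.support_vectors[0], model))
            d2 = np.sum((x.astype(np.float64) - model.support_vectors[0].astype(np.float64)) ** 2)
            ref = np.exp(-0.5 * d2)
            if ref > 1e-20:
                assert abs(got - ref) / ref <= 5e-4


class TestDecisionFunction:
    def test_single_sv_at_x(self, rng):
        model = make_model(rng, L=1, b=0.0)
        object.__setattr__(model, "alphas", np.array([1.0], dtype=np.float32))
        d = decision_function(model.support_vectors[0], model)
        assert abs(d.score - 1.0) <= 1e-4
        assert d.label == 1

    def test_large_offset_forces_interictal(self, rng):
        model = make_model(rng, L=5, gamma=0.2)
        big_b = float(np.sum(np.abs(model.alphas))) + 1.0
        m2 = SVMModel(
            support_vectors=model.support_vectors,
            alphas=model.alphas,
            b=big_b,
            sigma=model.sigma,
            s_max=model.s_max,
            s_min=model.s_min,
            f_max=model.f_max,
            f_min=model.f_min,
            gamma_eff=float(model.gamma_eff),
        )
        for _ in range(20):
            x = rng.normal(0, 3, 31).astype(np.float32)
            assert decision_function(x, m2).label == 0

    def test_agrees_with_double_oracle(self, rng):
        """Labels match the double-precision oracle whenever the score is
        clearly away from the boundary; scores agree to 1e-3."""
        model = make_model(rng, L=50, gamma=0.05)
        n_checked = 0
        for _ in range(300):
            x = rng.normal(0, 1, 31).astype(np.float32)
            d = decision_function(x, model)
            ref = oracle_score(x, model)
            assert abs(d.score - ref) <= 1e-3
            if abs(ref) > 1e-3:
                n_checked += 1
                assert d.label == (1 if ref >= 0 else 0)
        assert n_checked > 200

    def test_permutation_invariance_of_label(self, rng):
        model = make_model(rng, L=20, gamma=0.1)
        perm = rng.permutation(20)
        permuted = SVMModel(
            support_vectors=model.support_vectors[perm],
            alphas=model.alphas[perm],
            b=float(model.b),
            sigma=model.sigma,
            s_max=model.s_max,
            s_min=model.s_min,
            f_max=model.f_max,
            f_min=model.f_min,
            gamma_eff=float(model.gamma_eff),
        )
        for _ in range(20):
            x = rng.normal(0, 1, 31).astype(np.float32)
            d1, d2 = decision_function(x, model), decision_function(x, permuted)
            assert abs(d1.score - d2.score) <= 1e-5 * max(1.0, abs(d1.score))
            if abs(d1.score) > 1e-4:
                assert d1.label == d2.label


class TestDPUDataflow:
    def test_bit_identical_scores(self, rng):
        for trial in range(50):
            model = make_model(rng, L=int(rng.integers(1, 30)), gamma=0.1)
            x = rng.normal(0, 1, 31).astype(np.float32)
            d1 = decision_function(x, model)
            d2 = dpu_dataflow_eval(x, model)
            assert d1.score == d2.score
            assert d1.label == d2.label

    def test_single_sv_score_is_alpha_minus_b(self, rng):
        model = make_model(rng, L=1, b=0.25)
        x = model.support_vectors[0]
        d = dpu_dataflow_eval(x, model)
        expected = float(model.alphas[0]) * 1.0 - 0.25
        assert abs(d.score - expected) <= 1e-4 * max(1.0, abs(expected))

    def test_log_transform_paths_agree(self, rng):
        model = make_model(rng, L=10, gamma=0.3, log_transform=True, positive=True)
        for _ in range(10):
            x = (np.abs(rng.normal(2, 1, 31)) + 0.05).astype(np.float32)
            d1 = decision_function(x, model)
            d2 = dpu_dataflow_eval(x, model)
            assert d1.score == d2.score

    def test_rom_is_read_sequentially_once(self, rng):
        model = make_model(rng, L=7)
        rom = SupportVectorROM(model)
        rows = [np.array(r) for r, _ in rom]
        assert rom.reads == 7
        assert all(np.array_equal(rows[i], model.support_vectors[i]) for i in range(7))


class TestLogTransform:
    def test_nonpositive_feature_raises_with_hint(self, rng):
        model = make_model(rng, L=2, log_transform=True, positive=True)
        x = np.zeros(31, dtype=np.float32)
        with pytest.raises(DomainError, match="epsilon_floor"):
            decision_function(x, model)

    def test_epsilon_floor_admits_zeros(self, rng):
        base = make_model(rng, L=2, log_transform=True, positive=True)
        model = SVMModel(
            support_vectors=base.support_vectors,
            alphas=base.alphas,
            b=float(base.b),
            sigma=base.sigma,
            s_max=base.s_max,
            s_min=base.s_min,
            f_max=base.f_max,
            f_min=base.f_min,
            gamma_eff=float(base.gamma_eff),
            log_transform=True,
            epsilon_floor=1e-7,
        )
        d = decision_function(np.zeros(31, dtype=np.float32), model)
        assert np.isfinite(d.score)


class TestDecisionAndBundle:
    def test_decision_sign_convention(self):
        assert Decision.from_score(0.0).label == 1
        assert Decision.from_score(-1e-8).label == 0

    def test_bundle_roundtrip(self, tmp_path, rng):
        model = make_model(rng, L=5)
        path = tmp_path / "svm.json"
        save_svm_bundle(model, path)
        back = load_svm_bundle(path)
        assert np.array_equal(back.support_vectors, model.support_vectors)
        assert np.array_equal(back.alphas, model.alphas)
        assert back.b == model.b
        assert float(back.gamma_eff) == float(model.gamma_eff)
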