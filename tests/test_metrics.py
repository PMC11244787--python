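import numpy as np
import pytest

import oracles
from ssefuse import GrayImage, ValidationError, metric_report
from ssefuse.metrics import (
    ag,
    api,
    correlation_coefficient,
    edge_field,
    entropy,
    fusion_symmetry,
    gradient_preservation,
    information_loss_restricted,
    mi_total,
    mutual_information,
    sd,
    spatial_frequency,
)


def raw8(px):
    return GrayImage(np.asarray(px, float), "raw8")


def random_raw8(rng, shape=(16, 16)):
    return raw8(rng.integers(0, 256, size=shape))


class TestIntensityStats:
    def test_constant(self):
        img = raw8(np.full((5, 5), 37.0))
        assert api(img) == 37.0
        assert sd(img) == 0.0

    def test_two_level(self):
        px = np.zeros((4, 4))
        px[:2] = 255.0
        img = raw8(px)
        assert api(img) == pytest.approx(127.5)
        assert sd(img) == pytest.approx(127.5)

    def test_sd_matches_oracle(self, rng):
        img = random_raw8(rng)
        assert sd(img) == pytest.approx(oracles.sd(img.pixels), abs=1e-10)


class TestAverageGradient:
    def test_constant_zero(self):
        assert ag(raw8(np.full((6, 6), 9.0))) == 0.0

    def test_horizontal_ramp(self):
        px = np.tile(np.arange(8.0), (8, 1))
        assert ag(raw8(px)) == pytest.approx(1.0)

    def test_matches_oracle(self, rng):
        img = random_raw8(rng)
        assert ag(img) == pytest.approx(oracles.ag(img.pixels), abs=1e-10)


class TestEntropy:
    def test_constant_zero(self):
        assert entropy(raw8(np.full((4, 4), 12.0))) == 0.0

    def test_two_equal_levels(self):
        px = np.zeros((4, 4))
        px[:, 2:] = 200.0
        assert entropy(raw8(px)) == pytest.approx(1.0)

    def test_uniform_256_levels(self):
        px = np.arange(256.0).reshape(16, 16)
        assert entropy(raw8(px)) == pytest.approx(8.0)

    def test_bounds(self, rng):
        h = entropy(random_raw8(rng, (32, 32)))
        assert 0.0 <= h <= 8.0

    def test_matches_oracle(self, rng):
        img = random_raw8(rng)
        assert entropy(img) == pytest.approx(oracles.entropy(img.pixels), abs=1e-10)


class TestMutualInformation:
    def test_self_equals_entropy(self, rng):
        img = random_raw8(rng, (32, 32))
        assert mutual_information(img, img) == pytest.approx(entropy(img), abs=1e-10)

    def test_symmetry(self, rng):
        x, y = random_raw8(rng), random_raw8(rng)
        assert mutual_information(x, y) == pytest.approx(
            mutual_information(y, x), abs=1e-12
        )

    def test_independent_uniform_near_zero(self):
        # with 8 distinct levels at 128x128 the finite-sample bias is
        # about (64 - 15) / (2 N ln 2) ~ 0.002 bits; a full 256-level
        # histogram would carry ~2 bits of bias at this sample size
        rng = np.random.default_rng(7)
        x = raw8(rng.integers(0, 8, (128, 128)) * 36.0)
        y = raw8(rng.integers(0, 8, (128, 128)) * 36.0)
        assert mutual_information(x, y) < 0.05

    def test_matches_oracle(self, rng):
        x, y = random_raw8(rng), random_raw8(rng)
        assert mutual_information(x, y) == pytest.approx(
            oracles.mutual_information(x.pixels, y.pixels), abs=1e-10
        )

    def test_nonnegative(self, rng):
        x, y = random_raw8(rng, (24, 24)), random_raw8(rng, (24, 24))
        assert mutual_information(x, y) >= 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            mutual_information(raw8(np.zeros((4, 4))), raw8(np.zeros((4, 5))))


class TestSpatialFrequency:
    def test_constant_zero(self):
        assert spatial_frequency(raw8(np.full((5, 5), 80.0))) == 0.0

    def test_checkerboard_matches_oracle(self):
        px = 255.0 * (np.indices((8, 8)).sum(axis=0) % 2)
        assert spatial_frequency(raw8(px)) == pytest.approx(
            oracles.spatial_frequency(px), abs=1e-10
        )

    def test_random_matches_oracle(self, rng):
        img = random_raw8(rng)
        assert spatial_frequency(img) == pytest.approx(
            oracles.spatial_frequency(img.pixels), abs=1e-10
        )


class TestCorrelationCoefficient:
    def test_perfect(self, rng):
        a = random_raw8(rng)
        assert correlation_coefficient(a, a, a) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self, rng):
        a = random_raw8(rng)
        f = raw8(255.0 - a.pixels)
        assert correlation_coefficient(a, a, f) == pytest.approx(-1.0)

    def test_matches_pearson_oracle(self, rng):
        a, b, f = (random_raw8(rng) for _ in range(3))
        expect = (
            oracles.pearson(a.pixels, f.pixels) + oracles.pearson(b.pixels, f.pixels)
        ) / 2.0
        assert correlation_coefficient(a, b, f) == pytest.approx(expect, abs=1e-12)

    def test_in_unit_interval(self, rng):
        a, b, f = (random_raw8(rng, (24, 24)) for _ in range(3))
        assert -1.0 <= correlation_coefficient(a, b, f) <= 1.0

    def test_zero_variance_rejected(self, rng):
        a = random_raw8(rng)
        const = raw8(np.full((16, 16), 10.0))
        with pytest.raises(ValidationError, match="B"):
            correlation_coefficient(a, const, a)


class TestFusionSymmetry:
    def test_symmetric_sources(self, rng):
        a = random_raw8(rng)
        assert fusion_symmetry(a, a, a) == pytest.approx(2.0)

    def test_one_sided_endpoint(self):
        # MI(B, F) is exactly zero when B is constant, so F = A puts all
        # the mutual information on one side
        rng = np.random.default_rng(11)
        a = random_raw8(rng, (64, 64))
        b = raw8(np.full((64, 64), 7.0))
        assert fusion_symmetry(a, b, a) == pytest.approx(1.5)

    def test_bounds(self, rng):
        a, b, f = (random_raw8(rng, (24, 24)) for _ in range(3))
        assert 1.5 <= fusion_symmetry(a, b, f) <= 2.0

    def test_zero_mi_rejected(self):
        const = raw8(np.full((8, 8), 3.0))
        with pytest.raises(ValidationError):
            fusion_symmetry(const, const, const)


class TestEdgeField:
    def test_constant(self):
        ef = edge_field(raw8(np.full((5, 5), 50.0)))
        np.testing.assert_array_equal(ef.g, 0.0)
        np.testing.assert_array_equal(ef.alpha, 0.0)

    def test_vertical_step_orientation(self):
        px = np.zeros((5, 5))
        px[:, 3:] = 200.0
        ef = edge_field(raw8(px))
        assert ef.g[2, 2] > 0
        assert ef.alpha[2, 2] == pytest.approx(0.0)  # purely horizontal change

    def test_offset_invariance(self, rng):
        px = rng.integers(0, 200, (8, 8)).astype(float)
        ef1 = edge_field(raw8(px))
        ef2 = edge_field(raw8(px + 50.0))
        np.testing.assert_allclose(ef1.g, ef2.g, atol=1e-9)

    def test_matches_oracle(self, rng):
        px = rng.integers(0, 256, (8, 8)).astype(float)
        ef = edge_field(raw8(px))
        g, alpha = oracles._sobel_fields(px)
        np.testing.assert_allclose(ef.g, g, atol=1e-9)
        np.testing.assert_allclose(ef.alpha, alpha, atol=1e-9)


class TestGradientPreservation:
    def test_complementarity_identity(self, rng):
        a, b = random_raw8(rng, (32, 32)), random_raw8(rng, (32, 32))
        f = raw8(np.floor((a.pixels + b.pixels) / 2.0))
        q, loss, n, nm = gradient_preservation(a, b, f)
        assert q + loss + nm == pytest.approx(1.0, abs=1e-6)
        # and the independently computed restricted loss agrees
        assert information_loss_restricted(a, b, f) == pytest.approx(loss, abs=1e-10)

    def test_no_artifacts_when_fused_gradient_dominated(self, rng):
        a = random_raw8(rng, (16, 16))
        b = raw8(a.pixels.copy())
        q, loss, n, nm = gradient_preservation(a, b, raw8(a.pixels.copy()))
        assert n == 0.0 and nm == 0.0  # g_F == g_A == g_B, never strictly above

    def test_nm_matches_bruteforce(self, rng):
        a, b, f = (random_raw8(rng, (32, 32)) for _ in range(3))
        q, loss, n, nm = gradient_preservation(a, b, f)
        oq, ol, on, onm = oracles.gradient_family(a.pixels, b.pixels, f.pixels)
        assert nm == pytest.approx(onm, abs=1e-10)
        assert q == pytest.approx(oq, abs=1e-10)
        assert n == pytest.approx(on, abs=1e-10)
        assert loss == pytest.approx(ol, abs=1e-10)

    def test_identity_fusion_beats_noise(self, rng):
        a = random_raw8(rng, (32, 32))
        b = random_raw8(rng, (32, 32))
        f_good = raw8(a.pixels.copy())
        f_noise = random_raw8(rng, (32, 32))
        q_good, *_ = gradient_preservation(a, b, f_good)
        q_noise, *_ = gradient_preservation(a, b, f_noise)
        assert q_good >= q_noise

    def test_all_flat_vacuous(self):
        const = raw8(np.full((8, 8), 5.0))
        q, loss, n, nm = gradient_preservation(const, const, const)
        assert (q, loss, n, nm) == (1.0, 0.0, 0.0, 0.0)


class TestMetricReport:
    def test_fields_match_individual_ops(self, rng):
        a, b = random_raw8(rng, (24, 24)), random_raw8(rng, (24, 24))
        f = raw8(np.floor((a.pixels + b.pixels) / 2.0))
        rep = metric_report(a, b, f)
        assert rep.API == api(f)
        assert rep.SD == sd(f)
        assert rep.AG == ag(f)
        assert rep.H == entropy(f)
        assert rep.MI == mi_total(a, b, f)
        assert rep.SF == spatial_frequency(f)
        assert rep.CC == correlation_coefficient(a, b, f)
        assert rep.FS == fusion_symmetry(a, b, f)

    def test_constant_triple_raises_on_cc(self):
        const = raw8(np.full((8, 8), 42.0))
        with pytest.raises(ValidationError):
            metric_report(const, const, const)

    def test_report_serializable(self, rng):
        import json

        a, b, f = (random_raw8(rng, (16, 16)) for _ in range(3))
        text = json.dumps(metric_report(a, b, f).to_dict())
        assert "Q_abf" in text
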