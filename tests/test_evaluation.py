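"""PSNR, greedy matching, rank AUC and the attribute-leakage probe."""

import numpy as np
import pytest

from fedleak import evaluation as ev
from fedleak import synthetic_data as sd


class TestPSNR:
    def test_identical_images_are_infinite(self, rng):
        img = rng.random((8, 8))
        assert ev.psnr(img, img) == float("inf")

    @pytest.mark.parametrize("offset,expected", [
        (0.5, 20 * np.log10(2.0)),      # MSE 0.25 -> about 6.021 dB
        (0.1, 20.0),                    # MSE 0.01 -> exactly 20 dB
    ])
    def test_constant_offset_closed_form(self, offset, expected):
        a = np.full((16, 16), 0.2)
        assert ev.psnr(a, a + offset) == pytest.approx(expected)

    def test_symmetry(self, rng):
        a, b = rng.random((8, 8)), rng.random((8, 8))
        assert ev.psnr(a, b) == pytest.approx(ev.psnr(b, a))

    def test_strictly_decreases_with_noise_amplitude(self):
        rng = np.random.default_rng(0)
        base = rng.random((16, 16))
        noise = rng.normal(size=(16, 16))
        vals = [ev.psnr(base, np.clip(base + amp * noise, 0, 1))
                for amp in (0.05, 0.1, 0.2, 0.4)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ev.psnr(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_report_caps_infinite_values(self, rng):
        img = rng.random((8, 8))
        report = ev.psnr_report([img], [img.copy()])
        assert report.mean == float("inf")
        assert report.to_dict()["mean"] == ev.PSNR_CAP_DB


def _greedy_oracle(matrix):
    """Step-by-step simulation of the matching rule: repeatedly take the
    largest PSNR among unassigned originals and reconstructions."""
    n = matrix.shape[0]
    free_r, free_c = set(range(n)), set(range(n))
    pairs = []
    while free_r:
        best, best_val = None, -np.inf
        for i in sorted(free_r):
            for j in sorted(free_c):
                if matrix[i, j] > best_val:
                    best, best_val = (i, j), matrix[i, j]
        pairs.append(best)
        free_r.discard(best[0])
        free_c.discard(best[1])
    return pairs


class TestGreedyMatch:
    def test_single_pair(self, rng):
        a = [rng.random((4, 4))]
        b = [rng.random((4, 4))]
        pairs, _ = ev.greedy_match(a, b)
        assert [(i, j) for i, j, _ in pairs] == [(0, 0)]

    def test_dominant_diagonal_is_identity(self, rng):
        originals = [rng.random((6, 6)) for _ in range(3)]
        recons = [np.clip(o + rng.normal(0, 0.01, o.shape), 0, 1)
                  for o in originals]
        pairs, _ = ev.greedy_match(originals, recons)
        assert sorted((i, j) for i, j, _ in pairs) == [(0, 0), (1, 1),
                                                       (2, 2)]

    def test_matches_brute_force_simulation_on_random_matrices(self):
        """100 random 4x4 PSNR matrices, greedy rule vs direct oracle."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            originals = [rng.random((5, 5)) for _ in range(4)]
            recons = [rng.random((5, 5)) for _ in range(4)]
            pairs, matrix = ev.greedy_match(originals, recons)
            assert [(i, j) for i, j, _ in pairs] == _greedy_oracle(matrix)

    def test_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            ev.greedy_match([rng.random((4, 4))],
                            [rng.random((4, 4))] * 2)

    def test_assignment_is_a_bijection_and_mean_consistent(self, rng):
        originals = [rng.random((4, 4)) for _ in range(5)]
        recons = [rng.random((4, 4)) for _ in range(5)]
        report = ev.psnr_report(originals, recons)
        rows = [i for i, _, _ in report.pairs]
        cols = [j for _, j, _ in report.pairs]
        assert sorted(rows) == list(range(5)) and sorted(cols) == \
            list(range(5))
        assert report.mean == pytest.approx(
            np.mean([v for _, _, v in report.pairs]))


class TestAUC:
    def test_perfect_separation(self):
        assert ev.auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_full_inversion(self):
        assert ev.auc([0.4, 0.6], [1, 0]) == 0.0

    def test_worked_example(self):
        assert ev.auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_matches_exhaustive_pair_counting(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(4, 11))
            scores = np.round(rng.random(n), 2)   # ties likely
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert ev.auc(scores, labels) == pytest.approx(
                wins / (len(pos) * len(neg)))

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        assert ev.auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ev.auc([0.1, 0.9], [1, 1])


def _attribute_set(n, seed, pop=sd.ADULT):
    images, ages, sexes = [], [], []
    rng_master = np.random.SeedSequence(seed)
    for i, s in enumerate(rng_master.spawn(n)):
        rng = np.random.default_rng(s)
        age = int(rng.integers(18, 91))
        sex = i % 2
        images.append(sd.make_image(pop, int(rng.random() < 0.5), age, sex,
                                    32, rng).pixels)
        ages.append(age)
        sexes.append(sex)
    return images, np.array(ages), np.array(sexes)


class TestLeakageProbe:
    def test_clean_originals_recover_attributes(self):
        train = _attribute_set(20, 100)
        images, ages, sexes = _attribute_set(30, 200)
        sex_auc, age_mae = ev.leakage_probe((train[0], train[1]), images,
                                            ages, sexes)
        assert sex_auc >= 0.9
        assert age_mae <= 15.0

    def test_pure_noise_reconstructions_sit_in_chance_band(self):
        train = _attribute_set(20, 300)
        rng = np.random.default_rng(4)
        noise = [rng.random((32, 32)) for _ in range(35)]
        ages = rng.integers(18, 91, 35)
        sexes = np.array([i % 2 for i in range(35)])
        probe = ev.AttributeProbe().fit(train[0], train[1])
        sex_auc, _ = ev.leakage_probe(None, noise, ages, sexes, probe=probe)
        scores = probe.predict(noise)[1]
        lo, hi = ev.permutation_band(scores, sexes, n_permutations=500,
                                     rng=np.random.default_rng(0))
        assert lo <= sex_auc <= hi

    def test_identical_inputs_give_identical_metrics(self):
        train = _attribute_set(10, 400)
        images, ages, sexes = _attribute_set(12, 500)
        a = ev.leakage_probe((train[0], train[1]), images, ages, sexes)
        b = ev.leakage_probe((train[0], train[1]), images, ages, sexes)
        assert a == b

    def test_mismatched_attribute_columns_rejected(self):
        train = _attribute_set(4, 600)
        with pytest.raises(ValueError):
            ev.leakage_probe((train[0], train[1]), train[0][:3],
                             [1, 2], [0, 1])


def test_rescale_unit_handles_constant_images():
    assert np.all(ev.rescale_unit(np.full((4, 4), 3.0)) == 0.5)
    img = np.array([[0.0, 2.0], [4.0, 1.0]])
    out = ev.rescale_unit(img)
    assert out.min() == 0.0 and out.max() == 1.0


def test_montage_written(tmp_path, rng):
    imgs = [rng.random((8, 8)) for _ in range(2)]
    ev.save_montage(imgs, imgs, tmp_path / "m.png")
    from PIL import Image

    assert Image.open(tmp_path / "m.png").size == (16, 16)


from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp


@given(hnp.arrays(np.float64, (6, 6), elements=st.floats(0, 1)),
       hnp.arrays(np.float64, (6, 6), elements=st.floats(0, 1)))
@settings(deadline=None, derandomize=True, max_examples=50)
def test_psnr_is_symmetric_and_nonnegative_on_unit_images(a, b):
    if np.array_equal(a, b):
        assert ev.psnr(a, b) == float("inf")
    else:
        assert ev.psnr(a, b) == pytest.approx(ev.psnr(b, a))
        assert ev.psnr(a, b) >= 0.0
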