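"""Utility and attack-success metrics.

Classifier utility is the rank-based AUC (probability that a random
positive outranks a random negative, ties counted half).  Attack success
is the peak signal-to-noise ratio PSNR = 20 log10(MAX_I / sqrt(MSE)) in
decibels, with MAX_I the width of the possible pixel range (1.0 for [0,1]
images).  Because batch reconstructions come back in arbitrary order,
original-reconstruction pairs are assigned greedily: repeatedly take the
largest PSNR among the still-unassigned rows and columns.  (This is the
reported matching procedure; it is *not* guaranteed to be the PSNR-optimal
bijection, e.g. a Hungarian assignment, and is not claimed to be.)

Demographic leakage is quantified by an attribute probe fitted on clean
held-out synthetic images: sex AUC from the laterality contrast of the
side marker, age MAE in years from the matched-filter disc decoder with a
linear calibration.  A permutation band gives the chance region for the
sex AUC at the evaluated sample size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from . import synthetic_data as sd

__all__ = [
    "psnr", "rescale_unit", "greedy_match", "PSNRReport", "psnr_report",
    "auc", "AttributeProbe", "leakage_probe", "permutation_band",
    "save_montage", "PSNR_CAP_DB",
]

PSNR_CAP_DB = 99.0  # serialized stand-in for infinite PSNR


def psnr(original: np.ndarray, reconstruction: np.ndarray,
         max_intensity: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    a, b = np.asarray(original, float), np.asarray(reconstruction, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if max_intensity <= 0:
        raise ValueError("max_intensity must be positive")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(20.0 * np.log10(max_intensity / np.sqrt(mse)))


def rescale_unit(image: np.ndarray) -> np.ndarray:
    """Affine min-max rescale to [0, 1] (constant images map to 0.5)."""
    img = np.asarray(image, float)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.full_like(img, 0.5)
    return (img - lo) / (hi - lo)


def greedy_match(originals, reconstructions,
                 max_intensity: float = 1.0):
    """Greedy original-reconstruction assignment by descending PSNR.

    Repeatedly selects the globally largest PSNR cell among unassigned
    originals (rows) and reconstructions (columns); ties break on (row,
    column) order for determinism.  Returns ``(pairs, matrix)`` where
    ``pairs`` is a list of (row, column, psnr) in assignment order.
    """
    if len(originals) != len(reconstructions):
        raise ValueError("need equally many originals and reconstructions")
    n = len(originals)
    matrix = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            matrix[i, j] = psnr(originals[i], reconstructions[j],
                                max_intensity)
    free_r, free_c = list(range(n)), list(range(n))
    pairs = []
    while free_r:
        best = None
        for i in free_r:
            for j in free_c:
                if best is None or matrix[i, j] > matrix[best[0], best[1]]:
                    best = (i, j)
        pairs.append((best[0], best[1], float(matrix[best])))
        free_r.remove(best[0])
        free_c.remove(best[1])
    return pairs, matrix


@dataclass
class PSNRReport:
    pairs: list                 # (original idx, reconstruction idx, psnr)
    matrix: np.ndarray
    mean: float
    std: float                  # sample standard deviation (ddof=1)

    def to_dict(self) -> dict:
        cap = lambda v: min(v, PSNR_CAP_DB)
        return {"pairs": [(int(i), int(j), cap(v)) for i, j, v in self.pairs],
                "mean": cap(self.mean),
                "std": self.std if np.isfinite(self.std) else 0.0}


def psnr_report(originals, reconstructions,
                max_intensity: float = 1.0) -> PSNRReport:
    pairs, matrix = greedy_match(originals, reconstructions, max_intensity)
    vals = np.array([v for _, _, v in pairs])
    std = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return PSNRReport(pairs=pairs, matrix=matrix, mean=float(vals.mean()),
                      std=std)


def auc(scores, labels) -> float:
    """Rank-based AUC; requires both classes present."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC is undefined with a single class")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# demographic attribute probe


class AttributeProbe:
    """Predicts sex (continuous laterality score) and age (calibrated years).

    Fitting uses clean generated images that must be disjoint from the
    attacked clients' data; the age channel fits a linear map from the
    decoder's raw age estimate to the true age.
    """

    def __init__(self):
        self._age_coef = (1.0, 0.0)

    def fit(self, images, ages) -> "AttributeProbe":
        raw = np.array([sd.decode_attributes(img)[0] for img in images])
        ages = np.asarray(ages, float)
        if len(images) >= 2 and np.ptp(raw) > 0:
            slope, intercept = np.polyfit(raw, ages, 1)
            self._age_coef = (float(slope), float(intercept))
        return self

    def sex_score(self, image: np.ndarray) -> float:
        """Right-minus-left marker contrast; positive favours sex 1."""
        img = np.asarray(image, float)
        left, right = sd._sex_boxes(img.shape[0])
        return float(img[right].mean() - img[left].mean())

    def predict(self, images):
        sex_scores = np.array([self.sex_score(img) for img in images])
        raw_age = np.array([sd.decode_attributes(img)[0] for img in images])
        a, b = self._age_coef
        return a * raw_age + b, sex_scores


def leakage_probe(probe_train: tuple, eval_images, true_ages, true_sexes,
                  probe: AttributeProbe | None = None,
                  ) -> tuple[float, float]:
    """(sex AUC, age MAE in years) of the attribute probe on ``eval_images``.

    ``probe_train`` is ``(images, ages)`` of clean synthetic images used to
    fit the probe; pass ``probe`` to reuse an already-fitted one.
    """
    true_ages = np.asarray(true_ages, float)
    true_sexes = np.asarray(true_sexes).astype(int)
    if len(eval_images) != len(true_ages) or len(eval_images) != len(true_sexes):
        raise ValueError("attribute columns must match the evaluated images")
    if probe is None:
        probe = AttributeProbe().fit(*probe_train)
    age_pred, sex_scores = probe.predict(eval_images)
    return (auc(sex_scores, true_sexes),
            float(np.mean(np.abs(age_pred - true_ages))))


def permutation_band(scores, labels, n_permutations: int = 2000,
                     coverage: float = 0.95,
                     rng: np.random.Generator | None = None,
                     ) -> tuple[float, float]:
    """Central chance interval for the AUC under label permutation."""
    rng = np.random.default_rng(0) if rng is None else rng
    labels = np.asarray(labels).astype(int)
    sims = np.empty(n_permutations)
    for i in range(n_permutations):
        sims[i] = auc(scores, rng.permutation(labels))
    lo = (1.0 - coverage) / 2.0
    return (float(np.quantile(sims, lo)),
            float(np.quantile(sims, 1.0 - lo)))


def save_montage(originals, reconstructions, path) -> None:
    """Side-by-side PNG: originals on the top row, reconstructions below."""
    from PIL import Image

    def to8(img):
        return np.round(rescale_unit(img) * 255).astype(np.uint8)

    rows = [np.concatenate([to8(i) for i in originals], axis=1),
            np.concatenate([to8(i) for i in reconstructions], axis=1)]
    Image.fromarray(np.concatenate(rows, axis=0), mode="L").save(path)
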