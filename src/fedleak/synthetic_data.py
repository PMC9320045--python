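"""Synthetic two-population chest-image federation.

Stands in for the real adult (CheXpert-like) and pediatric (Mendeley-like)
X-ray collections so the full pipeline — federated training, gradient
inversion, demographic-leakage probes, differential privacy — runs without
any downloads.  Each grayscale image is a smooth population-dependent
background plus three deterministic content features:

* a soft disc whose radius grows monotonically with patient **age**
  (an "ossification marker"), placed at a fixed upper-central position;
* a bright corner square whose **laterality** (left vs right) encodes sex,
  mimicking a radiographic side marker;
* a Gaussian "lesion" blob in the lower image half when the binary finding
  **label** is 1.

Age and sex are therefore recoverable from pixels by this module's own
decoder, which makes attribute leakage from reconstructed images measurable.

The default federation is a 36-client partition: 5 large adult clients plus
31 small clients (14 pediatric with sizes 2x{500,200,100,30,10,2,1}, and 17
adult with sizes 2x30, 5x10, 5x2, 5x1), each split into train/validation/test
by a size-dependent rule cascade (70/15/15 for n >= 50, equal thirds with the
remainder to train for 10 <= n < 50, train-only below 10).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "LabeledImage", "ClientSpec", "FederationLayout",
    "split_client_dataset", "build_default_layout", "generate_images",
    "make_image", "decode_attributes", "save_dataset", "save_layout",
    "load_layout",
]

ADULT = "adult"
PEDIATRIC = "pediatric"

# sizes of the 31 small clients (the reconstruction-attack targets)
_PEDIATRIC_SIZES = (500, 500, 200, 200, 100, 100, 30, 30, 10, 10, 2, 2, 1, 1)
_ADULT_SMALL_SIZES = (30, 30, 10, 10, 10, 10, 10, 2, 2, 2, 2, 2, 1, 1, 1, 1, 1)

DEFAULT_LARGE_CLIENT_SIZE = 200  # each of the 5 large adult clients
MIN_RESOLUTION = 8

_AGE_MAX = 100.0

# intensity layout: background texture spans [_BG_LO, _BG_HI]; the encoded
# content features sit strictly above it
_BG_LO, _BG_HI = 0.05, 0.78
_DISC_LEVEL, _LESION_LEVEL, _MARKER_LEVEL = 0.88, 0.95, 0.98
_DISC_CENTER = lambda res: (0.40 * res, 0.50 * res)


@dataclass
class LabeledImage:
    """One grayscale image with its label and demographic ground truth."""

    pixels: np.ndarray          # (res, res) float in [0, 1]
    label: int                  # 1 = finding present
    patient_id: str
    age: int                    # years
    sex: int                    # binary category, 0 or 1
    population: str             # "adult" | "pediatric"

    def __post_init__(self):
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("pixel values must lie in [0, 1]")
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("pixels must be a square H=W array")
        if self.age < 0:
            raise ValueError("age must be a nonnegative integer")


@dataclass
class ClientSpec:
    client_id: str
    population: str
    n_total: int
    n_train: int
    n_val: int
    n_test: int

    def __post_init__(self):
        if self.n_train + self.n_val + self.n_test != self.n_total:
            raise ValueError("split sizes must sum to n_total")
        if self.n_total < 10 and (self.n_val or self.n_test):
            raise ValueError("clients below 10 images are train-only")
        if min(self.n_train, self.n_val, self.n_test) < 0:
            raise ValueError("split sizes must be nonnegative")


@dataclass
class FederationLayout:
    clients: list = field(default_factory=list)
    seed: int = 0

    def client(self, client_id: str) -> ClientSpec:
        for c in self.clients:
            if c.client_id == client_id:
                return c
        raise KeyError(client_id)


def split_client_dataset(n_total: int) -> tuple[int, int, int]:
    """Train/val/test sizes for one client under the size-dependent cascade.

    n < 10       -> everything to train (no local validation or testing)
    10 <= n < 50 -> equal thirds, remainder assigned to the training split
    n >= 50      -> floor(0.7 n) / floor(0.15 n) / remainder
    """
    if not isinstance(n_total, (int, np.integer)) or n_total < 1:
        raise ValueError(f"n_total must be a positive integer, got {n_total!r}")
    n = int(n_total)
    if n < 10:
        return n, 0, 0
    if n < 50:
        third = n // 3
        return n - 2 * third, third, third
    n_train = int(np.floor(0.7 * n))
    n_val = int(np.floor(0.15 * n))
    return n_train, n_val, n - n_train - n_val


def build_default_layout(seed: int = 0, scale: float = 1.0,
                         large_client_size: int = DEFAULT_LARGE_CLIENT_SIZE,
                         ) -> FederationLayout:
    """The 36-client federation: 5 large adult + 14 pediatric + 17 small adult.

    ``scale`` < 1 shrinks every client (floor); a client shrunk to zero images
    is rejected rather than silently dropped, because the imbalance pattern is
    part of the study design.
    """
    sizes = ([("large", ADULT, large_client_size)] * 5
             + [("small", PEDIATRIC, n) for n in _PEDIATRIC_SIZES]
             + [("small", ADULT, n) for n in _ADULT_SMALL_SIZES])
    clients = []
    for i, (kind, pop, n) in enumerate(sizes):
        n_scaled = int(np.floor(n * scale))
        if n_scaled < 1:
            raise ValueError(
                f"scale {scale} shrinks client {i} ({pop}, n={n}) to zero images")
        tr, va, te = split_client_dataset(n_scaled)
        clients.append(ClientSpec(
            client_id=f"c{i:02d}_{pop}_{kind}", population=pop,
            n_total=n_scaled, n_train=tr, n_val=va, n_test=te))
    return FederationLayout(clients=clients, seed=int(seed))


# ---------------------------------------------------------------------------
# image synthesis


def _disc_mask(shape, center: tuple[float, float], radius: float,
               softness: float = 0.7) -> np.ndarray:
    if isinstance(shape, (int, np.integer)):
        shape = (int(shape), int(shape))
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    d = np.hypot(yy - center[0], xx - center[1])
    return np.clip((radius - d) / softness + 0.5, 0.0, 1.0)


def _age_radius(age: float, res: int) -> float:
    return res * (0.06 + 0.18 * min(float(age), _AGE_MAX) / _AGE_MAX)


def _sex_boxes(res: int):
    s = max(2, res // 8)
    r0 = res // 16
    return (slice(r0, r0 + s), slice(r0, r0 + s)), \
           (slice(r0, r0 + s), slice(res - r0 - s, res - r0))


def make_image(population: str, label: int, age: int, sex: int,
               resolution: int, rng: np.random.Generator,
               patient_id: str = "p0") -> LabeledImage:
    """Render one synthetic image with the deterministic content features."""
    if resolution < MIN_RESOLUTION:
        raise ValueError(
            f"resolution must be >= {MIN_RESOLUTION}, got {resolution}")
    res = resolution
    yy, xx = np.mgrid[0:res, 0:res] / res

    if population == ADULT:
        fy, fx = rng.uniform(0.6, 1.4, size=2)
        p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
        img = np.sin(2 * np.pi * fy * yy + p1) \
            + np.cos(2 * np.pi * fx * xx + p2) + 0.6 * yy
    elif population == PEDIATRIC:
        f = rng.uniform(1.6, 2.4)
        p = rng.uniform(0, 2 * np.pi)
        r = np.hypot(yy - 0.5, xx - 0.5)
        img = np.cos(2 * np.pi * f * r + p) - 1.2 * r
    else:
        raise ValueError(f"unknown population {population!r}")
    # full-contrast background kept strictly darker than the content
    # features so they remain decodable over any texture
    img = _BG_LO + (_BG_HI - _BG_LO) * (img - img.min()) \
        / max(img.max() - img.min(), 1e-9)

    # content features are alpha-blended toward fixed bright levels (all
    # above _BG_HI) so they stay visible over any background texture
    # age: soft disc at a fixed upper-central position, radius monotone in age
    disc = _disc_mask(res, _DISC_CENTER(res), _age_radius(age, res))
    img = img * (1.0 - disc) + _DISC_LEVEL * disc
    # sex: laterality of a bright corner square ("side marker")
    left, right = _sex_boxes(res)
    img[left if sex == 0 else right] = _MARKER_LEVEL
    # label: lesion blob in the lower half
    if label:
        cy = rng.uniform(0.68, 0.85) * res
        cx = rng.uniform(0.25, 0.75) * res
        d2 = (np.mgrid[0:res, 0:res][0] - cy) ** 2 \
            + (np.mgrid[0:res, 0:res][1] - cx) ** 2
        blob = np.exp(-d2 / (2 * (0.10 * res) ** 2))
        img = img * (1.0 - blob) + _LESION_LEVEL * blob

    img = img + rng.normal(0.0, 0.02, size=(res, res))
    return LabeledImage(pixels=np.clip(img, 0.0, 1.0), label=int(label),
                        patient_id=patient_id, age=int(age), sex=int(sex),
                        population=population)


def generate_images(layout: FederationLayout, resolution: int = 32,
                    seed: int | None = None, prevalence: float = 0.5,
                    ) -> dict:
    """Render every client's images, keyed ``client_id -> split -> [images]``.

    Labels are drawn independently per image with the configured prevalence
    (no per-client label distribution is enforced).  Reproducible: the pixel
    stream of each image is derived from (seed, client index, image index),
    so equal arguments give byte-identical output.
    """
    if resolution < MIN_RESOLUTION:
        raise ValueError(
            f"resolution must be >= {MIN_RESOLUTION}, got {resolution}")
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    seed = layout.seed if seed is None else int(seed)
    data = {}
    for ci, spec in enumerate(layout.clients):
        splits = {"train": [], "val": [], "test": []}
        counts = (("train", spec.n_train), ("val", spec.n_val),
                  ("test", spec.n_test))
        img_index = 0
        for split, n in counts:
            for _ in range(n):
                rng = np.random.default_rng(
                    np.random.SeedSequence((seed, ci, img_index)))
                label = int(rng.random() < prevalence)
                if spec.population == ADULT:
                    age = int(rng.integers(18, 91))
                else:
                    age = int(rng.integers(0, 18))
                sex = int(rng.integers(0, 2))
                pid = f"{spec.client_id}:p{img_index:04d}"
                splits[split].append(make_image(
                    spec.population, label, age, sex, resolution, rng, pid))
                img_index += 1
        data[spec.client_id] = splits
    return data


# ---------------------------------------------------------------------------
# attribute decoding (ground-truth oracle for the leakage probes)


def decode_attributes(pixels: np.ndarray) -> tuple[float, int]:
    """Best-effort (age estimate, sex estimate) from an image's pixels.

    Sex is read from the laterality of the corner marker (left brighter ->
    0, right brighter -> 1; exact on clean generated images).  Age is read
    from the area of the above-background disc at its fixed position:
    radius = sqrt(area / pi), inverted through the radius-age map, which
    resolves ages to a few years at 32x32.  On arbitrary images the
    decoder still returns a defined answer (constant images decode as sex
    0 and the youngest age).
    """
    img = np.asarray(pixels, dtype=float)
    res = img.shape[0]
    left, right = _sex_boxes(res)
    sex = int(img[right].mean() > img[left].mean())

    cy, cx = _DISC_CENTER(res)
    rmax = _age_radius(_AGE_MAX, res)
    yy, xx = np.mgrid[0:res, 0:res].astype(float)
    dist = np.hypot(yy - cy, xx - cx)
    thresh = 0.5 * (_BG_HI + _DISC_LEVEL)
    coverage = (img >= thresh).astype(float)
    # walk annuli outward from the disc centre; the first ring that is
    # mostly below the disc level marks the (subpixel) edge.  Stopping at
    # the edge keeps distant bright structures from inflating the estimate.
    radius = 0.0
    for r in range(1, int(np.ceil(rmax)) + 2):
        ring = coverage[(dist > r - 1) & (dist <= r)]
        frac = float(ring.mean()) if ring.size else 0.0
        if frac < 0.5:
            radius = (r - 1) + frac
            break
        radius = float(r)
    age = (radius / res - 0.06) / 0.18 * _AGE_MAX
    return float(np.clip(age, 0.0, _AGE_MAX)), sex


# ---------------------------------------------------------------------------
# serialization


def save_layout(layout: FederationLayout, path) -> None:
    payload = {"seed": layout.seed,
               "clients": [asdict(c) for c in layout.clients]}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_layout(path) -> FederationLayout:
    payload = json.loads(Path(path).read_text())
    return FederationLayout(
        clients=[ClientSpec(**c) for c in payload["clients"]],
        seed=payload["seed"])


def save_dataset(data: dict, outdir, layout: FederationLayout | None = None,
                 ) -> None:
    """Write 8-bit grayscale PNGs plus a sidecar metadata CSV."""
    from PIL import Image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = ["client_id,split,patient_id,label,age,sex,filename"]
    for client_id, splits in data.items():
        for split, images in splits.items():
            for img in images:
                fname = f"{client_id}_{split}_{img.patient_id.split(':')[-1]}.png"
                arr = np.round(img.pixels * 255).astype(np.uint8)
                Image.fromarray(arr, mode="L").save(outdir / fname)
                rows.append(f"{client_id},{split},{img.patient_id},"
                            f"{img.label},{img.age},{img.sex},{fname}")
    (outdir / "metadata.csv").write_text("\n".join(rows) + "\n")
    if layout is not None:
        save_layout(layout, outdir / "layout.json")
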