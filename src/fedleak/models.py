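"""Classifier architectures and parameter-set plumbing.

Three architectures are available behind one interface:

* ``toy_cnn`` — a small convolutional network (3 conv blocks with batch
  normalization, single-logit sigmoid head over the flattened feature map)
  that runs on the package's numpy autodiff engine.  It trains and is
  attacked in seconds on one CPU and is the workhorse of every experiment.
* ``densenet121`` and ``resnet50`` — exact architectural enumerations of the
  standard networks (layer names, array shapes, batch-norm bookkeeping),
  used for parameter counting, freezing-mode analysis and the one-channel
  input adaptation.  They do not provide a forward pass.

All architectures take one-channel grayscale input and end in a single
logit (binary "finding present" task).  Layer freezing modes: ``none``
(everything trainable, batch-norm running statistics keep updating),
``batch_norm`` (batch-norm affine parameters untrainable and running
statistics locked), ``all_but_last`` (only the final linear layer trains).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import autodiff as ad

__all__ = [
    "ModelConfig", "LayerParam", "ParameterSet", "ToyCNN", "build_model",
    "adapt_first_layer", "grayscale_normalization_constants",
    "apply_freezing", "count_parameters", "FREEZING_MODES",
]

FREEZING_MODES = ("none", "batch_norm", "all_but_last")
ARCHITECTURES = ("toy_cnn", "densenet121", "resnet50")

# kinds: convolution / linear weights, bn affine params, bn running buffers
_BN_AFFINE = ("bn_weight", "bn_bias")
_BUFFERS = ("bn_mean", "bn_var")


@dataclass
class ModelConfig:
    architecture: str = "toy_cnn"
    input_channels: int = 1
    n_outputs: int = 1
    freezing: str = "none"
    resolution: int = 32

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.freezing not in FREEZING_MODES:
            raise ValueError(f"unknown freezing mode {self.freezing!r}")


@dataclass
class LayerParam:
    name: str
    array: np.ndarray
    trainable: bool
    kind: str            # conv | linear_weight | linear_bias | bn_* | bn_mean/var
    is_final: bool = False


class ParameterSet:
    """Ordered named collection of parameter arrays with trainability flags."""

    def __init__(self, entries: list[LayerParam]):
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")
        for e in entries:
            if not np.all(np.isfinite(e.array)):
                raise ValueError(f"non-finite values in {e.name}")
        self._entries = {e.name: e for e in entries}
        self.bn_locked = False   # set by apply_freezing(batch_norm)

    def __iter__(self):
        return iter(self._entries.values())

    def __getitem__(self, name: str) -> LayerParam:
        return self._entries[name]

    def __contains__(self, name):
        return name in self._entries

    @property
    def names(self):
        return list(self._entries)

    def trainable_names(self):
        return [e.name for e in self if e.trainable]

    def copy(self) -> "ParameterSet":
        ps = ParameterSet([replace(e, array=e.array.copy()) for e in self])
        ps.bn_locked = self.bn_locked
        return ps

    def arrays(self, trainable_only: bool = False) -> dict:
        return {e.name: e.array for e in self
                if e.trainable or not trainable_only}

    def save(self, path) -> None:
        np.savez(path, **{e.name: e.array for e in self})

    def load_arrays(self, path) -> "ParameterSet":
        archive = np.load(path)
        out = self.copy()
        for e in out:
            e.array = archive[e.name].astype(float)
        return out


def count_parameters(pset: ParameterSet, trainable_only: bool = False) -> int:
    """Number of parameters, excluding batch-norm running buffers."""
    return sum(e.array.size for e in pset
               if e.kind not in _BUFFERS and (e.trainable or not trainable_only))


# ---------------------------------------------------------------------------
# toy CNN (the only architecture with a forward pass)

_TOY_CHANNELS = (8, 16, 16)
_BN_EPS = 1e-5
# grayscale normalization constants (channel means of the usual RGB values)
GRAY_MEAN, GRAY_STD = 0.449, 0.226


class ToyCNN:
    """Three conv/BN/relu blocks and a single-logit linear head over the
    flattened final feature map.

    The spatial head (rather than global pooling) keeps the location of a
    lesion visible to the classifier, which makes the synthetic task
    learnable from scratch in a handful of rounds, and gives the network
    several times more trainable parameters than the image has pixels —
    which is what makes the attack's gradient-matching problem well
    determined.  Sized so a full 20k-iteration inversion attack on one
    32x32 image finishes in minutes on a single CPU.
    """

    def __init__(self, config: ModelConfig):
        self.config = config

    def _feature_dim(self) -> int:
        side = self.config.resolution // 4   # two stride-2 blocks
        return _TOY_CHANNELS[-1] * side * side

    def init_params(self, seed: int = 0) -> ParameterSet:
        rng = np.random.default_rng(seed)
        entries = []
        c_in = self.config.input_channels
        for i, c_out in enumerate(_TOY_CHANNELS, start=1):
            fan_in = c_in * 9
            entries.append(LayerParam(
                f"conv{i}.weight",
                rng.normal(0, np.sqrt(2.0 / fan_in), (c_out, c_in, 3, 3)),
                True, "conv"))
            entries.append(LayerParam(f"conv{i}.bias", np.zeros(c_out),
                                      True, "conv"))
            entries.append(LayerParam(f"bn{i}.weight", np.ones(c_out),
                                      True, "bn_weight"))
            entries.append(LayerParam(f"bn{i}.bias", np.zeros(c_out),
                                      True, "bn_bias"))
            entries.append(LayerParam(f"bn{i}.running_mean", np.zeros(c_out),
                                      False, "bn_mean"))
            entries.append(LayerParam(f"bn{i}.running_var", np.ones(c_out),
                                      False, "bn_var"))
            c_in = c_out
        fdim = self._feature_dim()
        entries.append(LayerParam(
            "fc.weight",
            rng.normal(0, 1.0 / np.sqrt(fdim), (fdim, self.config.n_outputs)),
            True, "linear_weight", is_final=True))
        entries.append(LayerParam("fc.bias", np.zeros(self.config.n_outputs),
                                  True, "linear_bias", is_final=True))
        pset = ParameterSet(entries)
        return apply_freezing(pset, self.config.freezing)

    # -- forward --
    def forward(self, tensors: dict, x: ad.Tensor, pset: ParameterSet,
                train_mode: bool = False,
                update_stats: bool | None = None) -> ad.Tensor:
        """Logits for a batch.  ``tensors`` maps parameter names to graph
        tensors (leaves during training / attack, constants otherwise).

        In train mode with unlocked batch norm, normalization uses batch
        statistics and (unless ``update_stats`` is False, e.g. when an
        attacker replays the client's forward pass) the running buffers in
        ``pset`` are updated in place; otherwise the stored running
        statistics are used as constants.
        """
        if update_stats is None:
            update_stats = train_mode
        # grayscale standardization, same constants as the full-size models
        h = ad.mul_const(ad.add_const(x, -GRAY_MEAN), 1.0 / GRAY_STD)
        strides = (1, 2, 2)
        for i in range(1, len(_TOY_CHANNELS) + 1):
            h = ad.conv2d(h, tensors[f"conv{i}.weight"],
                          tensors[f"conv{i}.bias"], stride=strides[i - 1],
                          pad=1)
            h = self._batch_norm(h, i, tensors, pset, train_mode,
                                 update_stats)
            h = ad.relu(h)
        h = ad.reshape(h, (x.shape[0], -1))                # flatten spatial map
        z = ad.add(ad.matmul(h, tensors["fc.weight"]),
                   ad.reshape(tensors["fc.bias"], (1, -1)))
        return ad.reshape(z, (x.shape[0],))

    def _batch_norm(self, h, i, tensors, pset, train_mode, update_stats):
        use_batch_stats = train_mode and not pset.bn_locked
        if use_batch_stats:
            m = ad.mean_(h, axis=(0, 2, 3), keepdims=True)
            centred = ad.sub(h, m)
            v = ad.mean_(ad.mul(centred, centred), axis=(0, 2, 3),
                         keepdims=True)
            if update_stats:
                mom = 0.1
                rm = pset[f"bn{i}.running_mean"]
                rv = pset[f"bn{i}.running_var"]
                rm.array = (1 - mom) * rm.array + mom * m.data.reshape(-1)
                rv.array = (1 - mom) * rv.array + mom * v.data.reshape(-1)
            norm = ad.mul(centred,
                          ad.pow_const(ad.add_const(v, _BN_EPS), -0.5))
        else:
            rm = pset[f"bn{i}.running_mean"].array.reshape(1, -1, 1, 1)
            rv = pset[f"bn{i}.running_var"].array.reshape(1, -1, 1, 1)
            norm = ad.mul(ad.sub(h, ad.constant(rm)),
                          ad.constant((rv + _BN_EPS) ** -0.5))
        gamma = ad.reshape(tensors[f"bn{i}.weight"], (1, -1, 1, 1))
        beta = ad.reshape(tensors[f"bn{i}.bias"], (1, -1, 1, 1))
        return ad.add(ad.mul(norm, gamma), beta)

    def predict_proba(self, pset: ParameterSet, images: np.ndarray) -> np.ndarray:
        """Evaluation-mode probabilities for an (N, H, W) image stack."""
        from scipy.special import expit

        x = ad.constant(images[:, None, :, :])
        tensors = {e.name: ad.constant(e.array) for e in pset}
        z = self.forward(tensors, x, pset, train_mode=False)
        return expit(z.data)


# ---------------------------------------------------------------------------
# reference architectures (parameter enumeration only)


class ArchitectureTable:
    """Shape-level model: supports counting/freezing/adaptation, no forward."""

    def __init__(self, config: ModelConfig, entries_fn):
        self.config = config
        self._entries_fn = entries_fn

    def init_params(self, seed: int = 0) -> ParameterSet:
        rng = np.random.default_rng(seed)
        pset = ParameterSet(self._entries_fn(self.config, rng))
        return apply_freezing(pset, self.config.freezing)

    def forward(self, *a, **k):
        raise NotImplementedError(
            f"{self.config.architecture} is enumerated for parameter "
            "analysis only; use toy_cnn for training and attacks")


def _conv_entry(name, rng, out_c, in_c, k):
    fan_in = in_c * k * k
    return LayerParam(name, rng.normal(0, np.sqrt(2.0 / fan_in),
                                       (out_c, in_c, k, k)), True, "conv")


def _bn_entries(prefix, rng, c):
    return [LayerParam(f"{prefix}.weight", np.ones(c), True, "bn_weight"),
            LayerParam(f"{prefix}.bias", np.zeros(c), True, "bn_bias"),
            LayerParam(f"{prefix}.running_mean", np.zeros(c), False, "bn_mean"),
            LayerParam(f"{prefix}.running_var", np.ones(c), False, "bn_var")]


def _densenet121_entries(config: ModelConfig, rng) -> list[LayerParam]:
    growth, bn_size, blocks = 32, 4, (6, 12, 24, 16)
    e = [_conv_entry("features.conv0.weight", rng, 64,
                     config.input_channels, 7)]
    e += _bn_entries("features.norm0", rng, 64)
    f = 64
    for bi, n_layers in enumerate(blocks, start=1):
        for li in range(1, n_layers + 1):
            p = f"features.denseblock{bi}.denselayer{li}"
            e += _bn_entries(f"{p}.norm1", rng, f)
            e.append(_conv_entry(f"{p}.conv1.weight", rng,
                                 bn_size * growth, f, 1))
            e += _bn_entries(f"{p}.norm2", rng, bn_size * growth)
            e.append(_conv_entry(f"{p}.conv2.weight", rng, growth,
                                 bn_size * growth, 3))
            f += growth
        if bi < len(blocks):
            p = f"features.transition{bi}"
            e += _bn_entries(f"{p}.norm", rng, f)
            e.append(_conv_entry(f"{p}.conv.weight", rng, f // 2, f, 1))
            f //= 2
    e += _bn_entries("features.norm5", rng, f)
    e.append(LayerParam("classifier.weight",
                        rng.normal(0, 0.01, (config.n_outputs, f)),
                        True, "linear_weight", is_final=True))
    e.append(LayerParam("classifier.bias", np.zeros(config.n_outputs),
                        True, "linear_bias", is_final=True))
    return e


def _resnet50_entries(config: ModelConfig, rng) -> list[LayerParam]:
    blocks, expansion = (3, 4, 6, 3), 4
    e = [_conv_entry("conv1.weight", rng, 64, config.input_channels, 7)]
    e += _bn_entries("bn1", rng, 64)
    f = 64
    for li, (n_blocks, planes) in enumerate(zip(blocks, (64, 128, 256, 512)),
                                            start=1):
        for b in range(n_blocks):
            p = f"layer{li}.{b}"
            e.append(_conv_entry(f"{p}.conv1.weight", rng, planes, f, 1))
            e += _bn_entries(f"{p}.bn1", rng, planes)
            e.append(_conv_entry(f"{p}.conv2.weight", rng, planes, planes, 3))
            e += _bn_entries(f"{p}.bn2", rng, planes)
            e.append(_conv_entry(f"{p}.conv3.weight", rng,
                                 planes * expansion, planes, 1))
            e += _bn_entries(f"{p}.bn3", rng, planes * expansion)
            if b == 0:
                e.append(_conv_entry(f"{p}.downsample.0.weight", rng,
                                     planes * expansion, f, 1))
                e += _bn_entries(f"{p}.downsample.1", rng, planes * expansion)
            f = planes * expansion
    e.append(LayerParam("fc.weight", rng.normal(0, 0.01, (config.n_outputs, f)),
                        True, "linear_weight", is_final=True))
    e.append(LayerParam("fc.bias", np.zeros(config.n_outputs),
                        True, "linear_bias", is_final=True))
    return e


# ---------------------------------------------------------------------------
# operations


def build_model(config: ModelConfig, init_seed: int = 0):
    """Instantiate an architecture and its initial ParameterSet."""
    if config.architecture == "toy_cnn":
        model = ToyCNN(config)
    elif config.architecture == "densenet121":
        model = ArchitectureTable(config, _densenet121_entries)
    elif config.architecture == "resnet50":
        model = ArchitectureTable(config, _resnet50_entries)
    else:  # pragma: no cover - caught by ModelConfig
        raise ValueError(f"unknown architecture {config.architecture!r}")
    return model, model.init_params(init_seed)


def adapt_first_layer(three_channel_kernel: np.ndarray) -> np.ndarray:
    """Collapse an RGB first-layer kernel to one input channel by summing.

    The three per-channel kernels are summed elementwise over the input-
    channel axis; for an input that is constant across channels this leaves
    the layer's response unchanged (linearity), which is what makes reusing
    pretrained RGB weights on grayscale input sound.  No rescaling is
    applied — the sum is used verbatim.
    """
    k = np.asarray(three_channel_kernel)
    if k.ndim != 4 or k.shape[1] != 3:
        raise ValueError(
            f"expected kernel of shape (out, 3, kh, kw), got {k.shape}")
    return k.sum(axis=1, keepdims=True)


def grayscale_normalization_constants(rgb_means, rgb_stds):
    """Grayscale (mu, sigma) as channel means of RGB constants, 3 decimals."""
    mus, sds = np.asarray(rgb_means, float), np.asarray(rgb_stds, float)
    if mus.shape != (3,) or sds.shape != (3,):
        raise ValueError("expected three per-channel means and stds")
    return round(float(mus.mean()), 3), round(float(sds.mean()), 3)


def apply_freezing(pset: ParameterSet, mode: str) -> ParameterSet:
    """Return a copy of ``pset`` with trainability flags set by ``mode``."""
    if mode not in FREEZING_MODES:
        raise ValueError(f"unknown freezing mode {mode!r}")
    out = pset.copy()
    for e in out:
        if e.kind in _BUFFERS:
            e.trainable = False
        elif mode == "none":
            e.trainable = True
        elif mode == "batch_norm":
            e.trainable = e.kind not in _BN_AFFINE
        else:  # all_but_last
            e.trainable = e.is_final
    out.bn_locked = mode != "none"
    return out
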