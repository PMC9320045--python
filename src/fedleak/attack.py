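"""Gradient-inversion (DLG-style) reconstruction attack on parameter deltas.

Threat model: an honest-but-curious server that follows the protocol but
inspects the parameter updates it receives.  Clients share parameters, not
gradients, so the attack first forms a gradient proxy as the signed
difference ``before - after`` of the trainable entries; for one plain SGD
step this equals lr times the true gradient, and the matching objective
below is scale-invariant, so the unknown learning-rate factor is
irrelevant.

The attack then optimizes a randomly initialized dummy image batch so that
the autodiff gradient of the classification loss at the dummy batch matches
the proxy.  The default objective is one minus the cosine similarity
between the two gradients (concatenated over all trainable entries) plus a
small anisotropic total-variation prior on the dummy pixels; minimization
uses Adam applied to the *sign* of the loss gradient, with the step size
cut by 10x after 3/8, 5/8 and 7/8 of the iteration budget.  True labels
are supplied to the attack (label recovery is assumed to be solved
analytically elsewhere) as an unordered multiset; the ordering ambiguity
of batch reconstructions is resolved downstream by greedy PSNR matching.

The attack function receives only the model definition, parameter sets,
deltas and labels — never client images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .federated_core import bce_loss
from .models import ParameterSet

__all__ = [
    "AttackConfig", "AttackResult", "infer_gradient", "total_variation",
    "matching_loss", "run_attack",
]

LOSS_MODES = ("cosine", "printed_denominator", "l2")
ZERO_GRADIENT_SENTINEL = 1.0  # cosine term returned for a zero-norm target


@dataclass
class AttackConfig:
    max_iterations: int = 5000       # 20000 reproduces the full-scale setting
    initial_step: float = 0.1
    decay_factor: float = 0.1
    decay_fractions: tuple = (3 / 8, 5 / 8, 7 / 8)
    tv_weight: float = 0.01
    trials: int = 3
    loss_mode: str = "cosine"

    def __post_init__(self):
        if min(self.initial_step, self.decay_factor, self.trials) <= 0 \
                or self.max_iterations < 0 or self.tv_weight < 0:
            raise ValueError("attack configuration values must be positive")
        if list(self.decay_fractions) != sorted(self.decay_fractions):
            raise ValueError("decay fractions must be sorted ascending")
        if self.loss_mode not in LOSS_MODES:
            raise ValueError(f"unknown loss mode {self.loss_mode!r}")


@dataclass
class AttackResult:
    reconstructions: np.ndarray      # best trial's dummy batch (B, H, W)
    trial_finals: list               # final matching loss per trial
    best_trial: int
    all_reconstructions: list        # every trial's final dummy batch
    loss_trace: list                 # best trial's iteration losses


def infer_gradient(params_before: ParameterSet,
                   params_after: ParameterSet) -> dict:
    """Gradient proxy: signed difference before - after over trainables.

    The shared updates are parameter states, and the server recovers the
    SGD direction by differencing consecutive states.  The difference is
    kept signed — an elementwise absolute value would destroy the gradient
    direction that the matching loss depends on.
    """
    if params_before.names != params_after.names:
        raise ValueError("parameter sets are not congruent")
    out = {}
    for name in params_before.trainable_names():
        a, b = params_before[name].array, params_after[name].array
        if a.shape != b.shape:
            raise ValueError(f"shape mismatch in {name}")
        out[name] = a - b
    return out


def total_variation(x: ad.Tensor) -> ad.Tensor:
    """Anisotropic TV of an image batch (N, C, H, W): mean absolute
    vertical plus mean absolute horizontal neighbour difference.

    Averaging (rather than summing) keeps the prior's scale independent of
    the image size, so the default weight balances against the unit-scale
    cosine matching term.
    """
    n, c, h, w = x.shape
    flat = np.arange(n * c * h * w).reshape(n, c, h, w)
    dv = ad.sub(ad.take_flat(x, flat[:, :, 1:, :]),
                ad.take_flat(x, flat[:, :, :-1, :]))
    dh = ad.sub(ad.take_flat(x, flat[:, :, :, 1:]),
                ad.take_flat(x, flat[:, :, :, :-1]))
    return ad.add(ad.mean_(ad.abs_(dv)), ad.mean_(ad.abs_(dh)))


def matching_loss(dummy_grads: dict, target_grads: dict,
                  dummy_images: ad.Tensor, tv_weight: float,
                  mode: str = "cosine") -> ad.Tensor:
    """Distance between dummy and target gradients plus the TV prior.

    ``cosine``: 1 - <g', g> / (||g'|| ||g||), computed over the
    concatenation of all trainable entries.  ``printed_denominator`` uses
    ||g' - g|| as the normalizer instead (kept for comparison; the cosine
    normalizer is the default reading).  ``l2``: plain squared Euclidean
    distance (the original DLG objective).
    """
    if set(dummy_grads) != set(target_grads):
        raise ValueError("gradient entries are not congruent")
    names = sorted(dummy_grads)
    tv = ad.mul_const(total_variation(dummy_images), tv_weight)

    if mode == "l2":
        sq = None
        for name in names:
            d = ad.sub(dummy_grads[name], ad.constant(target_grads[name]))
            term = ad.sum_(ad.mul(d, d))
            sq = term if sq is None else ad.add(sq, term)
        return ad.add(sq, tv)

    target_sq = float(sum((g ** 2).sum() for g in target_grads.values()))
    if target_sq == 0.0:
        import warnings

        warnings.warn("zero-norm target gradient; matching term replaced "
                      "by a sentinel constant")
        return ad.add(ad.constant(np.array(ZERO_GRADIENT_SENTINEL)), tv)

    dot = None
    dummy_sq = None
    diff_sq = None
    for name in names:
        g = dummy_grads[name]
        t = ad.constant(target_grads[name])
        d_term = ad.sum_(ad.mul(g, t))
        s_term = ad.sum_(ad.mul(g, g))
        dot = d_term if dot is None else ad.add(dot, d_term)
        dummy_sq = s_term if dummy_sq is None else ad.add(dummy_sq, s_term)
        if mode == "printed_denominator":
            df = ad.sub(g, t)
            f_term = ad.sum_(ad.mul(df, df))
            diff_sq = f_term if diff_sq is None else ad.add(diff_sq, f_term)

    if mode == "cosine":
        denom = ad.mul(ad.pow_const(ad.add_const(dummy_sq, 1e-24), 0.5),
                       ad.constant(np.sqrt(target_sq)))
    else:
        denom = ad.pow_const(ad.add_const(diff_sq, 1e-24), 0.5)
    return ad.add(ad.sub(ad.constant(np.array(1.0)), ad.div(dot, denom)),
                  tv)


def _dummy_gradients(model, params_before: ParameterSet, x: ad.Tensor,
                     labels: np.ndarray) -> dict:
    """Autodiff gradient of the classification loss at the dummy batch,
    differentiable w.r.t. the dummy pixels (double backprop)."""
    leaves = {}
    tensors = {}
    for e in params_before:
        t = ad.leaf(e.array)
        tensors[e.name] = t
        if e.trainable:
            leaves[e.name] = t
    logits = model.forward(tensors, x, params_before, train_mode=True,
                           update_stats=False)
    loss = bce_loss(logits, labels)
    grads = ad.grad(loss, list(leaves.values()))
    return dict(zip(leaves, grads))


def run_attack(model, params_before: ParameterSet, target_delta: dict,
               labels: np.ndarray, config: AttackConfig,
               rng: np.random.Generator, resolution: int | None = None,
               ) -> AttackResult:
    """Reconstruct the client's training batch from its parameter delta.

    For each trial a dummy batch is drawn from a standard normal
    distribution and optimized; trials are ranked by final matching loss
    (never by PSNR, which needs ground truth and is evaluation-only).
    Dummy pixels are unconstrained during optimization; rescale for
    display or PSNR afterwards.
    """
    labels = np.asarray(labels, dtype=float)
    batch = len(labels)
    res = resolution if resolution is not None else model.config.resolution
    target = {k: v for k, v in target_delta.items()}

    trial_finals, finals_x, traces = [], [], []
    for _ in range(config.trials):
        x_data = rng.standard_normal((batch, 1, res, res))
        m = np.zeros_like(x_data)
        v = np.zeros_like(x_data)
        step = config.initial_step
        boundaries = {int(f * config.max_iterations)
                      for f in config.decay_fractions}
        trace = []
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        for it in range(config.max_iterations):
            if it in boundaries:
                step *= config.decay_factor
            x = ad.leaf(x_data)
            dummy = _dummy_gradients(model, params_before, x, labels)
            loss = matching_loss(dummy, target, x, config.tv_weight,
                                 config.loss_mode)
            gx, = ad.grad(loss, [x])
            g = np.sign(gx.data)
            m = beta1 * m + (1 - beta1) * g
            v = beta2 * v + (1 - beta2) * g * g
            t = it + 1
            m_hat = m / (1 - beta1 ** t)
            v_hat = v / (1 - beta2 ** t)
            x_data = x_data - step * m_hat / (np.sqrt(v_hat) + eps)
            trace.append(float(loss.data))
        trial_finals.append(trace[-1] if trace else float("inf"))
        finals_x.append(x_data[:, 0])
        traces.append(trace)

    best = int(np.argmin(trial_finals))
    return AttackResult(reconstructions=finals_x[best],
                        trial_finals=trial_finals, best_trial=best,
                        all_reconstructions=finals_x,
                        loss_trace=traces[best])
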