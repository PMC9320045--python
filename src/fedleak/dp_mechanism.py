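"""Differentially private local training (DP-SGD) with Rényi accounting.

Each local SGD step on a client becomes: clip every per-sample gradient to
an l2 bound C (globally across layers, or layer-wise), average, and add
Gaussian noise with standard deviation sigma*C.  Privacy is tracked as
Rényi differential privacy (RDP) of the subsampled Gaussian mechanism at a
fixed grid of orders alpha — 1.1..10.9 in steps of 0.1 and 12..63 in steps
of 1 — accumulated additively over steps and converted to an (epsilon,
delta) guarantee by minimising RDP(alpha) + log(1/delta)/(alpha - 1) over
the grid.

The subsampling analysis assumes Poisson sampling with rate q = batch/n,
the standard regime for the sampled-Gaussian RDP bound; plain shuffled
minibatching (what local training actually does) is treated as an
approximation of that regime.  Per-client delta follows
delta = min(0.9/n_train, 1e-2), deliberately capped at 1e-2 even for
one-image clients.  The noise multiplier is calibrated per client by binary
search so that the budget planned for all scheduled steps meets the target
epsilon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "default_alpha_grid", "PrivacySpec", "AccountantState",
    "clip_per_sample", "noisy_aggregate", "delta_for_client", "rdp_step",
    "convert_to_eps", "calibrate_noise", "calibrate_clipping",
    "make_dp_hook",
]

DELTA_CAP = 1e-2
DEFAULT_EPSILONS = (1.0, 3.0, 6.0, 10.0)


def default_alpha_grid() -> np.ndarray:
    """Rényi orders tracked by the accountant: [1.1, 10.9] step 0.1 and
    [12, 63] step 1."""
    fine = np.round(np.arange(11, 110) / 10.0, 1)
    coarse = np.arange(12, 64, dtype=float)
    return np.concatenate([fine, coarse])


@dataclass
class PrivacySpec:
    """Per-client privacy parameters for DP-SGD."""

    target_epsilon: float
    delta: float
    clip_bound: float | np.ndarray      # scalar (global) or per-layer vector
    noise_multiplier: float
    sampling_rate: float                # q = batch size / dataset size
    planned_steps: int
    clipping_mode: str = "global"       # "global" | "per_layer"

    def __post_init__(self):
        if self.target_epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not 0.0 < self.delta < 1.0:
            raise ValueError("delta must lie in (0, 1)")
        bounds = (list(self.clip_bound.values())
                  if isinstance(self.clip_bound, dict) else self.clip_bound)
        if np.any(np.asarray(bounds) <= 0):
            raise ValueError("clipping bound must be positive")
        if self.noise_multiplier <= 0:
            raise ValueError("noise multiplier must be positive")
        if not 0.0 < self.sampling_rate <= 1.0:
            raise ValueError("sampling rate must lie in (0, 1]")
        if self.clipping_mode not in ("global", "per_layer"):
            raise ValueError(f"unknown clipping mode {self.clipping_mode!r}")


@dataclass
class AccountantState:
    """Cumulative RDP per order alpha."""

    alphas: np.ndarray = field(default_factory=default_alpha_grid)
    rdp: np.ndarray = None
    steps: int = 0

    def __post_init__(self):
        self.alphas = np.asarray(self.alphas, dtype=float)
        if np.any(self.alphas <= 1.0):
            raise ValueError("Rényi orders must exceed 1")
        if self.rdp is None:
            self.rdp = np.zeros_like(self.alphas)

    def step(self, q: float, sigma: float) -> None:
        self.rdp = self.rdp + rdp_step(q, sigma, self.alphas)
        self.steps += 1


# ---------------------------------------------------------------------------
# per-sample clipping and noising


def _flat_norms(grads: dict) -> np.ndarray:
    """Per-sample l2 norms over the concatenation of all entries."""
    sq = None
    for g in grads.values():
        s = (g.reshape(g.shape[0], -1) ** 2).sum(axis=1)
        sq = s if sq is None else sq + s
    return np.sqrt(sq)


def clip_per_sample(grads: dict, C, mode: str = "global") -> dict:
    """Scale each sample's gradient to l2 norm at most C, preserving direction.

    ``grads`` maps entry name -> array with a leading batch axis.  In
    ``global`` mode the bound applies to the norm over all entries jointly;
    in ``per_layer`` mode each entry is clipped to its own bound (C may be a
    scalar, reused for every layer, or a mapping name -> bound).
    """
    if mode == "global":
        if not np.isscalar(C) or C <= 0:
            raise ValueError("global clipping requires a positive scalar C")
        norms = _flat_norms(grads)
        scale = np.minimum(1.0, C / np.maximum(norms, 1e-12))
        return {k: g * scale.reshape((-1,) + (1,) * (g.ndim - 1))
                for k, g in grads.items()}
    if mode == "per_layer":
        out = {}
        for k, g in grads.items():
            c_k = float(C[k]) if isinstance(C, dict) else float(C)
            if c_k <= 0:
                raise ValueError(f"nonpositive clipping bound for {k}")
            n = np.sqrt((g.reshape(g.shape[0], -1) ** 2).sum(axis=1))
            s = np.minimum(1.0, c_k / np.maximum(n, 1e-12))
            out[k] = g * s.reshape((-1,) + (1,) * (g.ndim - 1))
        return out
    raise ValueError(f"unknown clipping mode {mode!r}")


def noisy_aggregate(clipped: dict, C, sigma: float,
                    rng: np.random.Generator, mode: str = "global") -> dict:
    """(sum of clipped per-sample gradients + N(0, sigma^2 C^2 I)) / batch."""
    out = {}
    for k, g in clipped.items():
        b = g.shape[0]
        c_k = float(C[k]) if (mode == "per_layer" and isinstance(C, dict)) \
            else float(np.asarray(C).reshape(-1)[0]) if not np.isscalar(C) \
            else float(C)
        noise = rng.normal(0.0, sigma * c_k, size=g.shape[1:]) \
            if sigma > 0 else 0.0
        out[k] = (g.sum(axis=0) + noise) / b
    return out


def delta_for_client(n_train: int) -> float:
    """delta = min(0.9 / n_train, 1e-2): below the inverse dataset size,
    with a fixed cap for very small clients."""
    if n_train < 1:
        raise ValueError("n_train must be positive")
    return min(0.9 / float(n_train), DELTA_CAP)


# ---------------------------------------------------------------------------
# RDP of the (sub)sampled Gaussian mechanism
#
# For q = 1 this is the analytic Gaussian-mechanism value alpha/(2 sigma^2).
# For q < 1 we evaluate log A_alpha = log E_{z~N(0,s^2)} [((1-q) + q
# e^{(2z-1)/(2s^2)})^alpha] with the stable series of the standard sampled-
# Gaussian analysis: a binomial expansion for integer alpha, and the
# two-sided erfc-weighted expansion around the crossover point z0 for
# fractional alpha.


def _log_add(a: float, b: float) -> float:
    return np.logaddexp(a, b)


def _log_sub(a: float, b: float) -> float:
    if b >= a:
        raise ValueError("log_sub requires a > b")
    if b == -np.inf:
        return a
    return a + math.log1p(-math.exp(b - a))


def _log_erfc(x: float) -> float:
    # log(erfc(x)) = log(2) + log Phi(-x sqrt(2)), stable for large x
    return math.log(2.0) + special.log_ndtr(-x * math.sqrt(2.0))


def _log_a_int(q: float, sigma: float, alpha: int) -> float:
    log_a = -np.inf
    for i in range(alpha + 1):
        log_coef = (special.gammaln(alpha + 1) - special.gammaln(i + 1)
                    - special.gammaln(alpha - i + 1)
                    + i * math.log(q) + (alpha - i) * math.log1p(-q))
        log_a = _log_add(log_a, log_coef + (i * i - i) / (2.0 * sigma ** 2))
    return log_a


def _log_a_frac(q: float, sigma: float, alpha: float) -> float:
    log_a0, log_a1 = -np.inf, -np.inf
    z0 = sigma ** 2 * math.log(1.0 / q - 1.0) + 0.5
    i = 0
    while True:
        coef = special.binom(alpha, i)
        log_coef = math.log(abs(coef)) if coef != 0 else -np.inf
        j = alpha - i
        log_t0 = log_coef + i * math.log(q) + j * math.log1p(-q)
        log_t1 = log_coef + j * math.log(q) + i * math.log1p(-q)
        log_e0 = math.log(0.5) + _log_erfc((i - z0) / (math.sqrt(2) * sigma))
        log_e1 = math.log(0.5) + _log_erfc((z0 - j) / (math.sqrt(2) * sigma))
        log_s0 = log_t0 + (i * i - i) / (2.0 * sigma ** 2) + log_e0
        log_s1 = log_t1 + (j * j - j) / (2.0 * sigma ** 2) + log_e1
        if coef > 0:
            log_a0 = _log_add(log_a0, log_s0)
            log_a1 = _log_add(log_a1, log_s1)
        else:
            log_a0 = _log_sub(log_a0, log_s0)
            log_a1 = _log_sub(log_a1, log_s1)
        i += 1
        if max(log_s0, log_s1) < -30 and i > alpha:
            break
    return _log_add(log_a0, log_a1)


def rdp_step(q: float, sigma: float, alphas) -> np.ndarray:
    """Per-order RDP increment of one subsampled-Gaussian step."""
    if not 0.0 <= q <= 1.0:
        raise ValueError("sampling rate must lie in [0, 1]")
    if sigma <= 0:
        raise ValueError("noise multiplier must be positive")
    alphas = np.asarray(alphas, dtype=float)
    if np.any(alphas <= 1.0):
        raise ValueError("Rényi orders must exceed 1")
    if q == 0.0:
        return np.zeros_like(alphas)
    if q == 1.0:
        return alphas / (2.0 * sigma ** 2)
    out = np.empty_like(alphas)
    for k, a in enumerate(alphas):
        if float(a).is_integer():
            log_a = _log_a_int(q, sigma, int(a))
        else:
            log_a = _log_a_frac(q, sigma, float(a))
        out[k] = log_a / (a - 1.0)
    return out


def convert_to_eps(state: AccountantState, delta: float) -> tuple[float, float]:
    """Optimal (epsilon, alpha): epsilon = min_alpha RDP(alpha) +
    log(1/delta)/(alpha - 1)."""
    if not 0.0 < delta < 1.0:
        raise ValueError("delta must lie in (0, 1)")
    if state.alphas.size == 0:
        raise ValueError("empty accountant state")
    eps = state.rdp + math.log(1.0 / delta) / (state.alphas - 1.0)
    k = int(np.argmin(eps))
    return float(eps[k]), float(state.alphas[k])


def calibrate_noise(target_epsilon: float, delta: float, q: float,
                    planned_steps: int, alphas=None,
                    sigma_range: tuple[float, float] = (0.2, 200.0),
                    tol: float = 1e-3) -> float:
    """Smallest noise multiplier meeting the target budget after all steps."""
    if target_epsilon <= 0 or planned_steps < 1:
        raise ValueError("need positive target epsilon and at least one step")
    alphas = default_alpha_grid() if alphas is None else np.asarray(alphas)

    def spent(sigma: float) -> float:
        st = AccountantState(alphas=alphas,
                             rdp=planned_steps * rdp_step(q, sigma, alphas),
                             steps=planned_steps)
        return convert_to_eps(st, delta)[0]

    lo, hi = sigma_range
    if spent(hi) > target_epsilon:
        raise ValueError(
            f"budget epsilon={target_epsilon} infeasible within sigma <= {hi}")
    if spent(lo) <= target_epsilon:
        return lo
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if spent(mid) <= target_epsilon:
            hi = mid
        else:
            lo = mid
    return hi


# ---------------------------------------------------------------------------
# clipping-bound calibration from an auxiliary (non-client) dataset


def calibrate_clipping(model, pset, aux_images: np.ndarray,
                       aux_labels: np.ndarray, epochs: int = 3,
                       batch_size: int = 10, lr: float = 0.01,
                       seed: int = 0, mode: str = "global"):
    """Median unclipped per-sample gradient l2 norm under non-private training.

    Runs ``epochs`` of plain SGD on the auxiliary dataset (which must be
    disjoint from every client's data) with the federated training
    hyperparameters, recording each sample's full-gradient l2 norm at every
    step.  Returns the median norm (``global`` mode) or a name -> median
    mapping of per-layer norms (``per_layer``).
    """
    from .federated_core import local_train, TrainConfig, per_sample_gradients

    if len(aux_images) == 0:
        raise ValueError("auxiliary dataset is empty")
    rng = np.random.default_rng(seed)
    params = pset.copy()
    cfg = TrainConfig(batch_size=batch_size, initial_lr=lr)
    global_norms: list[float] = []
    layer_norms: dict[str, list] = {}

    def recorder(grads: dict) -> dict:
        for v in _flat_norms(grads):
            global_norms.append(float(v))
        for k, g in grads.items():
            n = np.sqrt((g.reshape(g.shape[0], -1) ** 2).sum(axis=1))
            layer_norms.setdefault(k, []).extend(n.tolist())
        return {k: g.mean(axis=0) for k, g in grads.items()}

    for _ in range(epochs):
        params, _ = local_train(model, params, aux_images, aux_labels, cfg,
                                lr=lr, rng=rng, dp_hook=recorder)

    if mode == "global":
        c = float(np.median(global_norms))
        if c <= 0:
            raise ValueError(
                "median gradient norm is zero (degenerate model/data); "
                "choose the clipping bound manually")
        return c
    return {k: float(np.median(v)) for k, v in layer_norms.items()}


# ---------------------------------------------------------------------------
# wiring into federated training


def make_dp_hook(spec: PrivacySpec, accountant: AccountantState,
                 rng: np.random.Generator):
    """Gradient-step hook: clip per-sample gradients, noise, account."""

    def hook(per_sample_grads: dict) -> dict:
        clipped = clip_per_sample(per_sample_grads, spec.clip_bound,
                                  spec.clipping_mode)
        noisy = noisy_aggregate(clipped, spec.clip_bound,
                                spec.noise_multiplier, rng,
                                spec.clipping_mode)
        accountant.step(spec.sampling_rate, spec.noise_multiplier)
        return noisy

    return hook
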