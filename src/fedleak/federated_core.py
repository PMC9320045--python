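"""Federated averaging simulation with capture of the attack surface.

One communication round: the server sends the global parameters to the
selected clients; each client runs one local epoch of minibatch SGD on the
binary cross-entropy loss (optionally through a differential-privacy hook
that replaces plain mean gradients with clipped-and-noised ones); the
server aggregates the updated parameters by dataset-size-weighted
averaging.  What the server observes from client k — and what the
reconstruction attack consumes — is the signed parameter difference
``before - after`` over the trainable entries, recorded per round in a
:class:`RoundRecord`.

Scheduling mirrors a conservative hospital-federation protocol: learning
rate 0.01 reduced by 10x when the global model's mean validation AUC has
not improved for three consecutive rounds, early stopping after five
flat rounds, at most 20 rounds, batch size 10 (shrunk to the dataset size
for smaller clients), and the best-by-mean-AUC global model returned.
Optional client subsampling draws round(fraction * n_clients) clients per
round, each client limited to a maximum number of selections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .evaluation import auc
from .models import ParameterSet

__all__ = [
    "TrainConfig", "RoundRecord", "FederationResult", "bce_loss",
    "local_train", "per_sample_gradients", "federated_average",
    "select_clients", "run_federation",
]


@dataclass
class TrainConfig:
    max_rounds: int = 20
    local_epochs: int = 1
    batch_size: int = 10
    initial_lr: float = 0.01
    plateau_factor: float = 0.1
    plateau_patience: int = 3
    early_stop_patience: int = 5
    client_fraction: float = 1.0
    max_selections: int | None = None    # per-client participation quota

    def __post_init__(self):
        for name in ("max_rounds", "local_epochs", "batch_size",
                     "initial_lr", "plateau_factor", "plateau_patience",
                     "early_stop_patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.client_fraction <= 1.0:
            raise ValueError("client_fraction must lie in (0, 1]")


@dataclass
class RoundRecord:
    round_index: int
    deltas: dict                 # client_id -> {name: before - after}
    buffers: dict                # client_id -> {name: post-training buffer}
    train_sizes: dict            # client_id -> n_train
    client_aucs: dict            # client_id -> AUC of the new global model
    mean_auc: float
    lr: float
    selected: list


@dataclass
class FederationResult:
    best_params: ParameterSet
    best_round: int
    best_mean_auc: float
    history: list
    final_params: ParameterSet
    global_snapshots: list = field(default_factory=list)


def bce_loss(logits: ad.Tensor, labels: np.ndarray) -> ad.Tensor:
    """Mean binary cross-entropy from logits, numerically stable."""
    y = ad.constant(np.asarray(labels, dtype=float))
    softplus = ad.add(ad.relu(logits),
                      ad.log(ad.add_const(ad.exp(ad.neg(ad.abs_(logits))),
                                          1.0)))
    return ad.mean_(ad.sub(softplus, ad.mul(y, logits)))


def _forward_loss(model, pset: ParameterSet, images: np.ndarray,
                  labels: np.ndarray, train_mode: bool):
    """Build the loss graph; returns (loss, leaf tensors of trainables)."""
    leaves = {}
    tensors = {}
    for e in pset:
        t = ad.leaf(e.array)
        tensors[e.name] = t
        if e.trainable:
            leaves[e.name] = t
    x = ad.constant(images[:, None, :, :])
    logits = model.forward(tensors, x, pset, train_mode=train_mode)
    return bce_loss(logits, labels), leaves


def per_sample_gradients(model, pset: ParameterSet, images: np.ndarray,
                         labels: np.ndarray) -> dict:
    """Per-sample gradients of the (unaveraged) loss w.r.t. trainables.

    Requires locked batch-norm statistics: with batch statistics active the
    per-sample loss is not a sum over samples and per-sample gradients are
    not well defined (which is exactly why private training freezes batch
    normalization).
    """
    if not pset.bn_locked:
        raise ValueError("per-sample gradients require frozen batch-norm "
                         "statistics (freezing mode 'batch_norm' or "
                         "'all_but_last')")
    out: dict[str, list] = {}
    for i in range(len(images)):
        loss, leaves = _forward_loss(model, pset, images[i:i + 1],
                                     labels[i:i + 1], train_mode=True)
        grads = ad.grad(loss, list(leaves.values()))
        for name, g in zip(leaves, grads):
            out.setdefault(name, []).append(g.data)
    return {k: np.stack(v) for k, v in out.items()}


def local_train(model, pset: ParameterSet, images: np.ndarray,
                labels: np.ndarray, config: TrainConfig, lr: float,
                rng: np.random.Generator, dp_hook=None,
                ) -> tuple[ParameterSet, dict]:
    """One client's local update; returns (new params, before-minus-after).

    Runs ``config.local_epochs`` epochs of minibatch SGD with batch size
    min(config.batch_size, n).  With ``dp_hook`` supplied, every step feeds
    per-sample gradients through the hook (clip + noise + accounting)
    instead of using the plain minibatch mean.
    """
    n = len(images)
    if n == 0:
        raise ValueError("empty client training set")
    if dp_hook is not None and not pset.bn_locked:
        raise ValueError("private training requires frozen batch-norm "
                         "statistics")
    before = {name: pset[name].array.copy()
              for name in pset.trainable_names()}
    params = pset.copy()
    batch = min(config.batch_size, n)
    for _ in range(config.local_epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            xb, yb = images[idx], labels[idx]
            if dp_hook is None:
                loss, leaves = _forward_loss(model, params, xb, yb,
                                             train_mode=True)
                grads = ad.grad(loss, list(leaves.values()))
                mean_grads = {name: g.data
                              for name, g in zip(leaves, grads)}
            else:
                psg = per_sample_gradients(model, params, xb, yb)
                mean_grads = dp_hook(psg)
            for name, g in mean_grads.items():
                params[name].array = params[name].array - lr * g
    delta = {name: before[name] - params[name].array for name in before}
    return params, delta


def federated_average(updates: list) -> ParameterSet:
    """Dataset-size-weighted mean of client parameter sets.

    ``updates`` is a list of ``(ParameterSet, n_train)``; every array —
    including batch-norm running buffers — is averaged with weights
    proportional to the clients' training-set sizes.
    """
    if not updates:
        raise ValueError("nothing to aggregate")
    first = updates[0][0]
    names = first.names
    total = float(sum(n for _, n in updates))
    if total <= 0:
        raise ValueError("total weight must be positive")
    out = first.copy()
    for name in names:
        ref_shape = first[name].array.shape
        acc = np.zeros(ref_shape)
        for ps, n in updates:
            if ps.names != names or ps[name].array.shape != ref_shape:
                raise ValueError("incongruent parameter sets")
            acc = acc + (n / total) * ps[name].array
        out[name].array = acc
    return out


def select_clients(n_clients: int, fraction: float, quota: list,
                   rng: np.random.Generator) -> list:
    """Uniform subsample of round(fraction * n) clients with remaining quota.

    Rounding is half-up (fraction 0.3 of 36 clients selects 11).  ``quota``
    is a mutable per-client remaining-selections list, decremented in place;
    None entries mean unlimited.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    eligible = [i for i in range(n_clients)
                if quota[i] is None or quota[i] > 0]
    if not eligible:
        raise ValueError("no clients with remaining selection quota")
    k = int(np.floor(fraction * n_clients + 0.5))
    k = max(1, min(k, len(eligible)))
    chosen = sorted(rng.choice(eligible, size=k, replace=False).tolist())
    for i in chosen:
        if quota[i] is not None:
            quota[i] -= 1
    return chosen


def _evaluate_global(model, pset: ParameterSet, layout, data) -> dict:
    """AUC of the global model on every client's validation set.

    Clients without validation data, or whose (tiny) validation split holds
    a single class, are excluded — they contribute to training and
    aggregation but not to the model-selection criterion.
    """
    out = {}
    for spec in layout.clients:
        val = data[spec.client_id]["val"]
        if not val:
            continue
        labels = np.array([im.label for im in val])
        if labels.min() == labels.max():
            continue
        images = np.stack([im.pixels for im in val])
        scores = model.predict_proba(pset, images)
        out[spec.client_id] = auc(scores, labels)
    return out


def run_federation(layout, data, model, init_params: ParameterSet,
                   config: TrainConfig, seed: int = 0,
                   dp_hook_factory=None,
                   record_globals: bool = False) -> FederationResult:
    """Orchestrate federated training; returns the best global model and the
    full round history (every per-client delta — the attack surface).

    ``dp_hook_factory(client_id, n_train, rng)`` may return a DP step hook
    per client (or None for non-private training).  The next global model is
    reconstructed from the recorded deltas (global minus weighted deltas,
    with buffers averaged separately), so the history replays exactly.
    """
    ss = np.random.SeedSequence(seed)
    rng_select, rng_order = [np.random.default_rng(s) for s in ss.spawn(2)]
    client_rngs = {spec.client_id: np.random.default_rng(s)
                   for spec, s in zip(layout.clients,
                                      ss.spawn(len(layout.clients)))}
    dp_hooks = {}
    if dp_hook_factory is not None:
        for spec in layout.clients:
            dp_hooks[spec.client_id] = dp_hook_factory(
                spec.client_id, spec.n_train,
                client_rngs[spec.client_id])

    global_params = init_params.copy()
    quota = [config.max_selections for _ in layout.clients]
    lr = config.initial_lr
    history: list[RoundRecord] = []
    snapshots: list[ParameterSet] = []
    best_params, best_round, best_auc = global_params.copy(), -1, -np.inf
    bad_rounds = 0

    for rnd in range(config.max_rounds):
        selected_idx = select_clients(len(layout.clients),
                                      config.client_fraction, quota,
                                      rng_select)
        selected = [layout.clients[i] for i in selected_idx]
        deltas, buffers, sizes = {}, {}, {}
        for spec in selected:
            train = data[spec.client_id]["train"]
            images = np.stack([im.pixels for im in train])
            labels = np.array([im.label for im in train], dtype=float)
            updated, delta = local_train(
                model, global_params, images, labels, config, lr,
                client_rngs[spec.client_id],
                dp_hook=dp_hooks.get(spec.client_id))
            deltas[spec.client_id] = delta
            buffers[spec.client_id] = {
                e.name: updated[e.name].array.copy()
                for e in updated if e.kind in ("bn_mean", "bn_var")}
            sizes[spec.client_id] = spec.n_train

        global_params = _aggregate_round(global_params, deltas, buffers,
                                         sizes)
        if record_globals:
            snapshots.append(global_params.copy())
        client_aucs = _evaluate_global(model, global_params, layout, data)
        mean_auc = float(np.mean(list(client_aucs.values()))) \
            if client_aucs else float("nan")
        history.append(RoundRecord(
            round_index=rnd, deltas=deltas, buffers=buffers,
            train_sizes=sizes, client_aucs=client_aucs, mean_auc=mean_auc,
            lr=lr, selected=[s.client_id for s in selected]))

        if client_aucs and mean_auc > best_auc:
            best_auc, best_round = mean_auc, rnd
            best_params = global_params.copy()
            bad_rounds = 0
        else:
            bad_rounds += 1
            if bad_rounds == config.plateau_patience:
                lr *= config.plateau_factor
            if bad_rounds >= config.early_stop_patience:
                break

    return FederationResult(best_params=best_params, best_round=best_round,
                            best_mean_auc=best_auc, history=history,
                            final_params=global_params,
                            global_snapshots=snapshots)


def _aggregate_round(global_params: ParameterSet, deltas: dict,
                     buffers: dict, sizes: dict) -> ParameterSet:
    """Weighted aggregation expressed through the recorded deltas/buffers.

    Builds each client's post-training parameter set as (global - delta)
    for trainable entries plus its recorded buffers, then applies
    :func:`federated_average` — so replaying a :class:`RoundRecord` through
    ``federated_average`` reproduces the stored global model bit for bit.
    """
    reconstructed = []
    for cid, delta in deltas.items():
        ps = global_params.copy()
        for name, d in delta.items():
            ps[name].array = ps[name].array - d
        for name, b in buffers[cid].items():
            ps[name].array = b.copy()
        reconstructed.append((ps, sizes[cid]))
    return federated_average(reconstructed)
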