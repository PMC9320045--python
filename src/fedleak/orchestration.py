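"""Named experiment scenarios and the ``fedleak`` command-line interface.

Each scenario reproduces one arm of the study design end to end on
synthetic data and writes its artifacts (round history, parameter
archives, privacy reports, reconstructions, summary tables) under an
output directory.  Summaries are deterministic for a fixed configuration:
every number in a summary table is re-derivable from the serialized
per-module artifacts.

Scenarios
---------
``baseline_fl``         federated training per layer-freezing mode (AUC table)
``freezing_sweep``      early-round inversion attack per freezing mode (PSNR)
``attack_stage``        attack during round 1 vs after several rounds
``attack_batch_sweep``  attack batches of 1 / 2 / 4 / 10 images
``dp_sweep``            private training at epsilon in {1, 3, 6, 10} (AUC)
``dp_attack``           attack on non-private vs epsilon=10 private updates
``subsampling``         private training with client fraction 0.3, quota 5
``layerwise_clipping``  private training with per-layer clipping bounds

Presets: ``desk`` runs every scenario in minutes on one CPU (reduced large
clients, 32x32 images, shortened attacks); ``tiny`` is a seconds-scale
smoke preset; ``full`` uses the complete study sizes and the 20k-iteration
attack budget.
"""

from __future__ import annotations

import argparse
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import dp_mechanism as dp
from . import evaluation as ev
from . import synthetic_data as sd
from .attack import AttackConfig, infer_gradient, run_attack
from .federated_core import TrainConfig, local_train, run_federation
from .models import ModelConfig, build_model

__all__ = ["ScenarioConfig", "run_scenario", "SCENARIOS", "main"]

log = logging.getLogger("fedleak")

SCENARIOS = ("baseline_fl", "freezing_sweep", "attack_stage",
             "attack_batch_sweep", "dp_sweep", "dp_attack", "subsampling",
             "layerwise_clipping")
PRESETS = {
    # roster: "study" = the full 36-client layout, "reduced" = a 9-client
    # miniature with the same size classes (for smoke runs)
    "tiny": dict(roster="reduced", large=20, rounds=3, dp_rounds=2,
                 iters=300, trials=2),
    "desk": dict(roster="study", large=40, rounds=10, dp_rounds=5,
                 iters=2000, trials=3),
    "full": dict(roster="study", large=200, rounds=20, dp_rounds=10,
                 iters=20000, trials=3),
}
RESOLUTION = 32


@dataclass
class ScenarioConfig:
    scenario: str
    seed: int = 0
    out_dir: str | Path = "fedleak_out"
    preset: str = "desk"

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; "
                             f"choose from {SCENARIOS}")
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")


# ---------------------------------------------------------------------------
# shared pieces


def _federation(seed: int, preset: dict):
    if preset["roster"] == "study":
        layout = sd.build_default_layout(seed,
                                         large_client_size=preset["large"])
    else:
        sizes = ([(sd.ADULT, preset["large"])] * 2
                 + [(sd.PEDIATRIC, n) for n in (30, 10, 2, 1)]
                 + [(sd.ADULT, n) for n in (10, 2, 1)])
        layout = sd.FederationLayout(clients=[
            sd.ClientSpec(f"c{i:02d}_{pop}", pop, n,
                          *sd.split_client_dataset(n))
            for i, (pop, n) in enumerate(sizes)], seed=seed)
    data = sd.generate_images(layout, RESOLUTION, seed=seed)
    return layout, data


def _auxiliary_clip_bound(seed: int, mode: str = "global"):
    """Clipping bound(s): median unclipped per-sample gradient norms from a
    short non-private run on auxiliary data disjoint from every client."""
    aux_rng = np.random.SeedSequence((seed, 0xA0))
    aux = [sd.make_image(sd.PEDIATRIC, i % 2, int(5 + 2 * (i % 7)), i % 2,
                         RESOLUTION, np.random.default_rng(s), f"aux:p{i}")
           for i, s in enumerate(aux_rng.spawn(30))]
    model, params = build_model(
        ModelConfig(architecture="toy_cnn", freezing="batch_norm",
                    resolution=RESOLUTION), init_seed=seed)
    return dp.calibrate_clipping(
        model, params, np.stack([im.pixels for im in aux]),
        np.array([im.label for im in aux], float), epochs=3, seed=seed,
        mode=mode)


def _train(layout, data, freezing: str, seed: int, rounds: int,
           dp_factory=None, **cfg_kw):
    model, params = build_model(
        ModelConfig(architecture="toy_cnn", freezing=freezing,
                    resolution=RESOLUTION), init_seed=seed)
    cfg = TrainConfig(max_rounds=rounds, **cfg_kw)
    result = run_federation(layout, data, model, params, cfg, seed=seed,
                            dp_hook_factory=dp_factory)
    return model, params, result


def _dp_factory(epsilon: float, rounds: int, clip, batch_size: int = 10,
                mode: str = "global", reports=None):
    """Per-client DP hooks with individually calibrated noise multipliers."""

    def factory(client_id, n_train, rng):
        q = min(1.0, batch_size / n_train)
        steps = rounds * int(np.ceil(n_train / min(batch_size, n_train)))
        delta = dp.delta_for_client(n_train)
        sigma = dp.calibrate_noise(epsilon, delta, q, steps)
        spec = dp.PrivacySpec(epsilon, delta, clip, sigma, q, steps,
                              clipping_mode=mode)
        acct = dp.AccountantState()
        if reports is not None:
            reports[client_id] = (spec, acct)
        log.info("scenario=dp client=%s event=calibrated sigma=%.4f "
                 "delta=%.2e steps=%d", client_id, sigma, delta, steps)
        return dp.make_dp_hook(spec, acct, rng)

    return factory


def _privacy_report(reports: dict) -> dict:
    out = {}
    for cid, (spec, acct) in sorted(reports.items()):
        eps, alpha = dp.convert_to_eps(acct, spec.delta) if acct.steps \
            else (0.0, float(acct.alphas[-1]))
        out[cid] = {
            "target_epsilon": spec.target_epsilon, "delta": spec.delta,
            "clip_bound": spec.clip_bound
            if np.isscalar(spec.clip_bound) else "per_layer",
            "noise_multiplier": spec.noise_multiplier,
            "steps": acct.steps, "spent_epsilon": round(eps, 4),
            "best_alpha": alpha}
    return out


def _single_image_client(layout):
    """A pediatric client holding exactly one training image."""
    for spec in layout.clients:
        if spec.population == sd.PEDIATRIC and spec.n_train == 1:
            return spec
    raise RuntimeError("layout has no one-image pediatric client")


def _client_batch(data, client_id):
    train = data[client_id]["train"]
    return (np.stack([im.pixels for im in train]),
            np.array([im.label for im in train], dtype=float), train)


def _attack_client(model, global_params, data, spec, atk_cfg, rng,
                   lr=0.01):
    """One local update followed by the inversion attack on its delta."""
    images, labels, train = _client_batch(data, spec.client_id)
    updated, delta = local_train(model, global_params, images, labels,
                                 TrainConfig(), lr=lr, rng=rng)
    result = run_attack(model, global_params, delta, labels, atk_cfg, rng)
    recon = np.stack([ev.rescale_unit(r) for r in result.reconstructions])
    report = ev.psnr_report([im.pixels for im in train], list(recon))
    return result, recon, report


# ---------------------------------------------------------------------------
# scenarios


def _scenario_baseline_fl(cfg, preset, out):
    rows = {}
    for freezing in ("none", "batch_norm", "all_but_last"):
        layout, data = _federation(cfg.seed, preset)
        _, _, result = _train(layout, data, freezing, cfg.seed,
                              preset["rounds"])
        rows[freezing] = {"mean_auc": round(result.best_mean_auc, 4),
                          "best_round": result.best_round,
                          "rounds_run": len(result.history)}
        _dump_history(result, out / f"history_{freezing}.jsonl")
        log.info("scenario=baseline_fl freezing=%s event=done auc=%.3f",
                 freezing, result.best_mean_auc)
    return {"auc_by_freezing": rows}


def _scenario_freezing_sweep(cfg, preset, out):
    rows = {}
    layout, data = _federation(cfg.seed, preset)
    target = _single_image_client(layout)
    atk_cfg = AttackConfig(max_iterations=preset["iters"],
                           trials=preset["trials"])
    for mode_idx, freezing in enumerate(("none", "batch_norm",
                                         "all_but_last")):
        model, params, _ = _train(layout, data, freezing, cfg.seed, 1)
        rng = np.random.default_rng(np.random.SeedSequence(
            (cfg.seed, mode_idx)))
        _, recon, report = _attack_client(model, params, data, target,
                                          atk_cfg, rng)
        np.save(out / f"recon_{freezing}.npy", recon)
        rows[freezing] = {"mean_psnr": round(report.mean, 3),
                          "std_psnr": round(report.std, 3)}
    return {"attacked_client": target.client_id, "psnr_by_freezing": rows}


def _scenario_attack_stage(cfg, preset, out):
    layout, data = _federation(cfg.seed, preset)
    target = _single_image_client(layout)
    model, params, result = _train(layout, data, "batch_norm", cfg.seed,
                                   max(preset["rounds"], 5))
    atk_cfg = AttackConfig(max_iterations=preset["iters"],
                           trials=preset["trials"])
    rows = {}
    # early: global model at initialization; late: after several rounds
    stages = {"early": params, "late": result.final_params}
    for stage, start_params in stages.items():
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed,
                                                            stage == "late")))
        _, recon, report = _attack_client(model, start_params, data, target,
                                          atk_cfg, rng)
        np.save(out / f"recon_{stage}.npy", recon)
        rows[stage] = {"mean_psnr": round(report.mean, 3),
                       "std_psnr": round(report.std, 3)}
    return {"attacked_client": target.client_id, "psnr_by_stage": rows}


def _scenario_attack_batch_sweep(cfg, preset, out):
    layout, data = _federation(cfg.seed, preset)
    model, params, result = _train(layout, data, "batch_norm", cfg.seed,
                                   min(4, preset["rounds"]))
    start = result.final_params
    atk_cfg = AttackConfig(max_iterations=preset["iters"],
                           trials=preset["trials"])
    rows = {}
    for batch in (1, 2, 4, 10):
        spec = next(s for s in layout.clients
                    if s.population == sd.PEDIATRIC and s.n_train == batch)
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, batch)))
        _, recon, report = _attack_client(model, start, data, spec, atk_cfg,
                                          rng)
        np.save(out / f"recon_batch{batch}.npy", recon)
        rows[str(batch)] = {"client": spec.client_id,
                            "mean_psnr": round(report.mean, 3),
                            "std_psnr": round(report.std, 3)}
    return {"psnr_by_batch_size": rows}


def _scenario_dp_sweep(cfg, preset, out):
    rows, all_reports = {}, {}
    clip = _auxiliary_clip_bound(cfg.seed)
    for eps in dp.DEFAULT_EPSILONS:
        layout, data = _federation(cfg.seed, preset)
        reports = {}
        _, _, result = _train(
            layout, data, "batch_norm", cfg.seed, preset["dp_rounds"],
            dp_factory=_dp_factory(eps, preset["dp_rounds"], clip,
                                   reports=reports))
        rows[str(eps)] = {"mean_auc": round(result.best_mean_auc, 4),
                          "rounds_run": len(result.history)}
        all_reports[str(eps)] = _privacy_report(reports)
        log.info("scenario=dp_sweep eps=%s event=done auc=%.3f", eps,
                 result.best_mean_auc)
    (out / "privacy_reports.json").write_text(
        json.dumps(all_reports, indent=1, sort_keys=True))
    return {"auc_by_epsilon": rows}


def _scenario_dp_attack(cfg, preset, out):
    layout, data = _federation(cfg.seed, preset)
    target = _single_image_client(layout)
    model, params, _ = _train(layout, data, "batch_norm", cfg.seed, 1)
    atk_cfg = AttackConfig(max_iterations=preset["iters"],
                           trials=preset["trials"])
    images, labels, train = _client_batch(data, target.client_id)
    rows = {}
    for arm, eps in (("non_private", None), ("epsilon_10", 10.0)):
        rng = np.random.default_rng(np.random.SeedSequence(
            (cfg.seed, arm == "non_private")))
        hook = None
        if eps is not None:
            q = 1.0
            steps = preset["dp_rounds"]
            delta_k = dp.delta_for_client(target.n_train)
            sigma = dp.calibrate_noise(eps, delta_k, q, steps)
            spec = dp.PrivacySpec(eps, delta_k,
                                  _auxiliary_clip_bound(cfg.seed), sigma,
                                  q, steps)
            hook = dp.make_dp_hook(spec, dp.AccountantState(), rng)
        _, delta = local_train(model, params, images, labels, TrainConfig(),
                               lr=0.01, rng=rng, dp_hook=hook)
        result = run_attack(model, params, delta, labels, atk_cfg, rng)
        recon = np.stack([ev.rescale_unit(r) for r in result.reconstructions])
        report = ev.psnr_report([im.pixels for im in train], list(recon))
        np.save(out / f"recon_{arm}.npy", recon)
        ev.save_montage([im.pixels for im in train], list(recon),
                        out / f"montage_{arm}.png")
        rows[arm] = {"mean_psnr": round(report.mean, 3),
                     "std_psnr": round(report.std, 3),
                     "best_trial_loss": round(
                         result.trial_finals[result.best_trial], 6)}
    return {"attacked_client": target.client_id, "psnr_by_privacy": rows}


def _scenario_subsampling(cfg, preset, out):
    layout, data = _federation(cfg.seed, preset)
    reports = {}
    rounds = preset["dp_rounds"]
    _, _, result = _train(
        layout, data, "batch_norm", cfg.seed, rounds,
        dp_factory=_dp_factory(10.0, rounds, _auxiliary_clip_bound(cfg.seed),
                               reports=reports),
        client_fraction=0.3, max_selections=5)
    n_sel = len(result.history[0].selected)
    (out / "privacy_reports.json").write_text(
        json.dumps(_privacy_report(reports), indent=1, sort_keys=True))
    return {"clients_per_round": n_sel,
            "mean_auc": round(result.best_mean_auc, 4),
            "rounds_run": len(result.history)}


def _scenario_layerwise_clipping(cfg, preset, out):
    layout, data = _federation(cfg.seed, preset)
    bounds = _auxiliary_clip_bound(cfg.seed, mode="per_layer")
    reports = {}
    rounds = preset["dp_rounds"]
    _, _, result = _train(
        layout, data, "batch_norm", cfg.seed, rounds,
        dp_factory=_dp_factory(10.0, rounds, bounds, mode="per_layer",
                               reports=reports))
    (out / "clipping_bounds.json").write_text(
        json.dumps({k: round(v, 6) for k, v in sorted(bounds.items())},
                   indent=1))
    return {"mean_auc": round(result.best_mean_auc, 4),
            "n_layer_bounds": len(bounds),
            "rounds_run": len(result.history)}


_RUNNERS = {
    "baseline_fl": _scenario_baseline_fl,
    "freezing_sweep": _scenario_freezing_sweep,
    "attack_stage": _scenario_attack_stage,
    "attack_batch_sweep": _scenario_attack_batch_sweep,
    "dp_sweep": _scenario_dp_sweep,
    "dp_attack": _scenario_dp_attack,
    "subsampling": _scenario_subsampling,
    "layerwise_clipping": _scenario_layerwise_clipping,
}


def _dump_history(result, path: Path) -> None:
    with open(path, "w") as fh:
        for rec in result.history:
            fh.write(json.dumps({
                "round": rec.round_index, "mean_auc": rec.mean_auc,
                "lr": rec.lr, "selected": rec.selected,
                "client_aucs": {k: round(v, 6)
                                for k, v in sorted(rec.client_aucs.items())},
            }, sort_keys=True) + "\n")


def run_scenario(cfg: ScenarioConfig) -> dict:
    """Execute one named scenario; returns and serializes its summary."""
    preset = PRESETS[cfg.preset]
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("scenario=%s preset=%s seed=%d event=start", cfg.scenario,
             cfg.preset, cfg.seed)
    try:
        summary = _RUNNERS[cfg.scenario](cfg, preset, out)
    except Exception as exc:
        raise RuntimeError(
            f"scenario {cfg.scenario!r} (preset {cfg.preset}, seed "
            f"{cfg.seed}) failed: {exc}") from exc
    summary = {"scenario": cfg.scenario, "preset": cfg.preset,
               "seed": cfg.seed, **summary}
    (out / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n")
    _summary_csv(summary, out / "summary.csv")
    log.info("scenario=%s event=done", cfg.scenario)
    return summary


def _summary_csv(summary: dict, path: Path) -> None:
    """Flatten the summary into a two-column CSV table."""
    import pandas as pd

    rows = []

    def walk(prefix, obj):
        if isinstance(obj, dict):
            for k in sorted(obj):
                walk(f"{prefix}.{k}" if prefix else str(k), obj[k])
        else:
            rows.append((prefix, obj))

    walk("", summary)
    pd.DataFrame(rows, columns=["key", "value"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# train / attack commands: parameter archives for offline attack replay


def train_command(out_dir, architecture="toy_cnn", freezing="batch_norm",
                  rounds=10, fraction=1.0, seed=0, preset="desk",
                  epsilon=None) -> dict:
    """Train a federation and archive every round's attack surface.

    Writes ``layout.json``, ``history.jsonl``, and per round r a directory
    ``round_XX/`` with the round-start global parameters (``global.npz``),
    each client's delta (``<client>.delta.npz``) and the clients' label
    multisets (``labels.json``) — everything ``attack_command`` needs.
    """
    preset_d = PRESETS[preset]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout, data = _federation(seed, preset_d)
    sd.save_layout(layout, out / "layout.json")
    model, params = build_model(
        ModelConfig(architecture=architecture, freezing=freezing,
                    resolution=RESOLUTION), init_seed=seed)
    dp_factory = None
    if epsilon is not None:
        dp_factory = _dp_factory(float(epsilon), preset_d["dp_rounds"],
                                 _auxiliary_clip_bound(seed))
    rounds = preset_d["dp_rounds"] if epsilon is not None else rounds
    from .federated_core import run_federation as _run

    result = _run(layout, data, model, params,
                  TrainConfig(max_rounds=rounds, client_fraction=fraction),
                  seed=seed, dp_hook_factory=dp_factory,
                  record_globals=True)
    _dump_history(result, out / "history.jsonl")
    start = params
    for rec, snap in zip(result.history, result.global_snapshots):
        rdir = out / f"round_{rec.round_index:02d}"
        rdir.mkdir(exist_ok=True)
        start.save(rdir / "global.npz")
        labels = {}
        for cid, delta in rec.deltas.items():
            np.savez(rdir / f"{cid}.delta.npz", **delta)
            labels[cid] = [im.label for im in data[cid]["train"]]
        (rdir / "labels.json").write_text(json.dumps(labels, indent=1,
                                                     sort_keys=True))
        start = snap
    result.best_params.save(out / "best_global.npz")
    log.info("event=train_done rounds=%d best_auc=%.3f",
             len(result.history), result.best_mean_auc)
    return {"rounds_run": len(result.history),
            "best_mean_auc": round(result.best_mean_auc, 4),
            "best_round": result.best_round}


def attack_command(archive_dir, round_index, client_id, out_dir,
                   trials=3, iters=2000, seed=0, architecture="toy_cnn",
                   freezing="batch_norm") -> dict:
    """Replay the inversion attack against an archived parameter delta."""
    arch_dir = Path(archive_dir) / f"round_{int(round_index):02d}"
    model, params = build_model(
        ModelConfig(architecture=architecture, freezing=freezing,
                    resolution=RESOLUTION), init_seed=seed)
    params = params.load_arrays(arch_dir / "global.npz")
    delta_archive = np.load(arch_dir / f"{client_id}.delta.npz")
    delta = {k: delta_archive[k] for k in delta_archive.files}
    labels = np.array(json.loads(
        (arch_dir / "labels.json").read_text())[client_id], dtype=float)
    cfg = AttackConfig(max_iterations=int(iters), trials=int(trials))
    result = run_attack(model, params, delta, labels, cfg,
                        np.random.default_rng(seed))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    recon = np.stack([ev.rescale_unit(r) for r in result.reconstructions])
    np.save(out / "reconstruction.npy", recon)
    from PIL import Image

    for i, r in enumerate(recon):
        Image.fromarray(np.round(r * 255).astype(np.uint8),
                        mode="L").save(out / f"reconstruction_{i:02d}.png")
    summary = {"client": client_id, "round": int(round_index),
               "trial_losses": [round(v, 6) for v in result.trial_finals],
               "best_trial": result.best_trial}
    (out / "attack.json").write_text(json.dumps(summary, indent=1,
                                                sort_keys=True) + "\n")
    return summary


# ---------------------------------------------------------------------------
# flat YAML-style experiment configs

_CONFIG_KEYS = {"scenario", "seed", "out", "preset"}


def load_config(path) -> ScenarioConfig:
    import yaml

    payload = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(payload) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return ScenarioConfig(scenario=payload.get("scenario", "baseline_fl"),
                          seed=int(payload.get("seed", 0)),
                          out_dir=payload.get("out", "fedleak_out"),
                          preset=payload.get("preset", "desk"))


# ---------------------------------------------------------------------------
# CLI


def main(argv=None) -> int:
    parser = argparse.ArgumentParser(
        prog="fedleak",
        description="Federated X-ray-style training, gradient-inversion "
                    "attacks and differentially private defenses on "
                    "synthetic data.")
    parser.add_argument("-v", "--verbose", action="store_true")
    sub = parser.add_subparsers(dest="command", required=True)

    p_run = sub.add_parser("run", help="run a named scenario")
    p_run.add_argument("--scenario", required=False)
    p_run.add_argument("--config", help="flat YAML config file")
    p_run.add_argument("--preset", default="desk", choices=sorted(PRESETS))
    p_run.add_argument("--seed", type=int, default=0)
    p_run.add_argument("--out", default="fedleak_out")

    p_rep = sub.add_parser("report", help="regenerate summary tables")
    p_rep.add_argument("dir")

    p_tr = sub.add_parser("train", help="train a federation and archive "
                                        "per-round parameter deltas")
    p_tr.add_argument("--architecture", default="toy_cnn")
    p_tr.add_argument("--freezing", default="batch_norm")
    p_tr.add_argument("--rounds", type=int, default=10)
    p_tr.add_argument("--fraction", type=float, default=1.0)
    p_tr.add_argument("--preset", default="desk", choices=sorted(PRESETS))
    p_tr.add_argument("--seed", type=int, default=0)
    p_tr.add_argument("--dp", action="store_true")
    p_tr.add_argument("--epsilon", type=float, default=10.0)
    p_tr.add_argument("--out", required=True)

    p_at = sub.add_parser("attack", help="invert an archived client delta")
    p_at.add_argument("--archive", required=True)
    p_at.add_argument("--round", type=int, required=True)
    p_at.add_argument("--client", required=True)
    p_at.add_argument("--trials", type=int, default=3)
    p_at.add_argument("--iters", type=int, default=2000)
    p_at.add_argument("--seed", type=int, default=0)
    p_at.add_argument("--freezing", default="batch_norm")
    p_at.add_argument("--out", required=True)

    args = parser.parse_args(argv)
    logging.basicConfig(
        level=logging.INFO if args.verbose else logging.WARNING,
        format="%(levelname)s %(message)s")

    if args.command == "run":
        if args.config:
            cfg = load_config(args.config)
        elif args.scenario:
            cfg = ScenarioConfig(scenario=args.scenario, seed=args.seed,
                                 out_dir=args.out, preset=args.preset)
        else:
            parser.error("run requires --scenario or --config")
        summary = run_scenario(cfg)
        print(json.dumps(summary, indent=1, sort_keys=True))
        return 0

    if args.command == "report":
        summary = json.loads((Path(args.dir) / "summary.json").read_text())
        _summary_csv(summary, Path(args.dir) / "summary.csv")
        print(json.dumps(summary, indent=1, sort_keys=True))
        return 0

    if args.command == "train":
        summary = train_command(
            args.out, architecture=args.architecture,
            freezing=args.freezing, rounds=args.rounds,
            fraction=args.fraction, seed=args.seed, preset=args.preset,
            epsilon=args.epsilon if args.dp else None)
        print(json.dumps(summary, indent=1, sort_keys=True))
        return 0

    if args.command == "attack":
        summary = attack_command(args.archive, args.round, args.client,
                                 args.out, trials=args.trials,
                                 iters=args.iters, seed=args.seed,
                                 freezing=args.freezing)
        print(json.dumps(summary, indent=1, sort_keys=True))
        return 0

    return 1


if __name__ == "__main__":  # pragma: no cover
    raise SystemExit(main())
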