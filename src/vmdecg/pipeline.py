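"""End-to-end orchestration: simulate -> tune -> decompose -> train -> report.

Also houses the ablation harness comparing decomposition front-ends
(raw signal, fixed-parameter decomposition, optimizer-tuned decomposition)
at a matched training budget over repeated seeds, with paired t-tests
between arms.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .datasets import SignalDataset, make_dataset, save_dataset
from .nn import AttentionClassifier, EncoderConfig, EvalReport, TrainHyperparams, paired_ttest
from .tpe import default_hyperparam_space, history_to_json, tpe_optimize
from .tuning import TuningSpace, tune_vmd
from .vmd import VMDConfig, vmd

__all__ = [
    "PipelineConfig",
    "AblationResult",
    "decompose_dataset",
    "run_pipeline",
    "run_ablation",
]


@dataclass
class PipelineConfig:
    """All stage parameters; every section validates on construction."""

    seed: int = 0
    outdir: str = "pipeline_out"
    # simulation
    n_points: int = 200
    n_replicates: int = 5
    noise_sigma: float = 5.0
    record_length: int = 512
    fs: float = 300.0
    # decomposition
    tuning_enabled: bool = True
    tuning_N: int = 40
    tuning_T: int = 60
    K_range: tuple = (3, 8)
    alpha_range: tuple = (500.0, 5000.0)
    fixed_K: int = 6
    fixed_alpha: float = 2500.0
    vmd_tau: float = 0.0
    vmd_max_iter: int = 200
    # encoder / training
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    training: TrainHyperparams = field(default_factory=lambda: TrainHyperparams(epochs=10))
    # hyperparameter search
    hyperopt_enabled: bool = False
    hyperopt_trials: int = 12
    hyperopt_epoch_cap: int = 5

    def validate(self) -> None:
        # constructing the per-stage configs raises on invalid values
        VMDConfig(K=self.fixed_K, alpha=self.fixed_alpha, tau=self.vmd_tau,
                  max_iter=self.vmd_max_iter)
        TuningSpace(K_range=tuple(self.K_range), alpha_range=tuple(self.alpha_range))
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        enc = EncoderConfig(**raw.pop("encoder", {}))
        hp = TrainHyperparams(**raw.pop("training", {}))
        cfg = cls(encoder=enc, training=hp, **raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)


def decompose_dataset(ds: SignalDataset, cfg: VMDConfig) -> np.ndarray:
    """VMD of every record; returns (n_records, K, N) mode array."""
    return np.stack([vmd(s.samples, cfg).modes for s in ds.signals])


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig):
    """Execute all stages, persisting every intermediate under ``outdir``.

    Returns ``(EvalReport, manifest)``; the manifest maps artifact names to
    content hashes so identical config+seed runs are verifiable as
    bit-identical.
    """
    config.validate()
    log = logging.getLogger(__name__)
    out = config.outdir
    os.makedirs(out, exist_ok=True)
    manifest = {"seed": config.seed, "artifacts": {}}

    def _register(name, path):
        manifest["artifacts"][name] = _sha256(path)

    t_stage = time.time()

    def _tick(done_stage):
        nonlocal t_stage
        log.info("stage %s finished in %.1fs", done_stage, time.time() - t_stage)
        t_stage = time.time()

    stage = "simulate"
    try:
        ds = make_dataset(
            n_points=config.n_points,
            n_replicates=config.n_replicates,
            noise_sigma=config.noise_sigma,
            record_length=config.record_length,
            fs=config.fs,
            seed=config.seed,
        )
        save_dataset(ds, os.path.join(out, "dataset"))
        _register("dataset.csv", os.path.join(out, "dataset.csv"))
        _register("dataset.npz", os.path.join(out, "dataset.npz"))
        _tick(stage)

        stage = "tune-vmd"
        if config.tuning_enabled:
            ref_idx = int(np.flatnonzero([s.label == "model0" for s in ds.signals])[0])
            front, (K_star, alpha_star), obj = tune_vmd(
                ds.signals[ref_idx].samples,
                TuningSpace(K_range=tuple(config.K_range), alpha_range=tuple(config.alpha_range)),
                N=config.tuning_N,
                T=config.tuning_T,
                seed=config.seed,
                fs=config.fs,
                vmd_defaults=VMDConfig(tau=config.vmd_tau, max_iter=config.vmd_max_iter),
            )
            front_df = pd.DataFrame(
                {
                    "K": np.round(front.positions()[:, 0]).astype(int),
                    "alpha": front.positions()[:, 1],
                    "sk": front.fitnesses()[:, 0],
                    "dkl": front.fitnesses()[:, 1],
                    "rank": [m.rank for m in front.members],
                    "scd": [m.scd for m in front.members],
                }
            )
            front_df.to_csv(os.path.join(out, "pareto_front.csv"), index=False)
            _register("pareto_front.csv", os.path.join(out, "pareto_front.csv"))
            sel = {"K": K_star, "alpha": alpha_star, "sk": obj.sk, "dkl": obj.dkl}
            with open(os.path.join(out, "vmd_selection.json"), "w") as fh:
                json.dump(sel, fh, indent=2)
            _register("vmd_selection.json", os.path.join(out, "vmd_selection.json"))
        else:
            K_star, alpha_star = config.fixed_K, config.fixed_alpha
        _tick(stage)

        stage = "decompose"
        vcfg = VMDConfig(K=K_star, alpha=alpha_star, tau=config.vmd_tau,
                         max_iter=config.vmd_max_iter)
        modes = decompose_dataset(ds, vcfg)
        np.savez(os.path.join(out, "modes.npz"), modes=modes.astype(np.float32),
                 K=K_star, alpha=alpha_star)
        _register("modes.npz", os.path.join(out, "modes.npz"))
        _tick(stage)

        stage = "tune-hyper"
        hp = config.training
        if config.hyperopt_enabled:
            model = AttentionClassifier(modes, ds.y, config.encoder)
            space = default_hyperparam_space()

            def _objective(conf):
                trial_hp = TrainHyperparams(
                    batch_size=int(conf["batch_size"]),
                    learning_rate=float(conf["learning_rate"]),
                    epochs=min(int(conf["epochs"]), config.hyperopt_epoch_cap),
                    momentum=float(conf["momentum"]),
                    seed=config.seed,
                )
                res = model.fit(ds.train_idx, ds.test_idx, trial_hp)
                return 1.0 - res.report.accuracy / 100.0

            best, history = tpe_optimize(
                _objective, space, n_trials=config.hyperopt_trials,
                n_startup=min(5, config.hyperopt_trials - 1), seed=config.seed,
            )
            with open(os.path.join(out, "hyperopt_history.json"), "w") as fh:
                fh.write(history_to_json(history))
            _register("hyperopt_history.json", os.path.join(out, "hyperopt_history.json"))
            hp = TrainHyperparams(
                batch_size=int(best.config["batch_size"]),
                learning_rate=float(best.config["learning_rate"]),
                epochs=min(int(best.config["epochs"]), config.hyperopt_epoch_cap),
                momentum=float(best.config["momentum"]),
                seed=config.seed,
            )

        _tick("tune-hyper")
        stage = "train"
        model = AttentionClassifier(modes, ds.y, config.encoder)
        res = model.fit(ds.train_idx, ds.test_idx, hp)
        report = res.report
        with open(os.path.join(out, "report.json"), "w") as fh:
            json.dump(
                {
                    "accuracy": report.accuracy,
                    "per_class_accuracy": report.per_class_accuracy.tolist(),
                    "loss_curve": report.loss_curve.tolist(),
                    "K": int(K_star),
                    "alpha": float(alpha_star),
                },
                fh,
                indent=2,
            )
        _register("report.json", os.path.join(out, "report.json"))
        pd.DataFrame(report.confusion).to_csv(os.path.join(out, "confusion.csv"), index=False)
        _register("confusion.csv", os.path.join(out, "confusion.csv"))
        _tick(stage)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return report, manifest


@dataclass
class AblationResult:
    arms: list                      # arm names
    accuracies: dict                # arm -> list of n_repeats accuracies
    best: dict                      # arm -> best accuracy
    mean: dict                      # arm -> mean accuracy
    p_values: np.ndarray            # pairwise paired-t matrix

    def to_frame(self, reference: str | None = None) -> pd.DataFrame:
        reference = reference or self.arms[-1]
        j = self.arms.index(reference)
        rows = []
        for i, arm in enumerate(self.arms):
            rows.append(
                {
                    "arm": arm,
                    "decomposition": arm,
                    "classifier": "attention",
                    "best_accuracy": self.best[arm],
                    "mean_accuracy": self.mean[arm],
                    "p_value": self.p_values[i, j],
                }
            )
        return pd.DataFrame(rows)


def run_ablation(config: PipelineConfig, arms=("none", "fixed", "mocoa"),
                 n_repeats: int = 10, precomputed=None):
    """Train each decomposition arm ``n_repeats`` times at a matched budget.

    Arms: ``none`` (raw signal as a single channel), ``fixed``
    (decomposition at the fixed K/alpha comparator) and ``mocoa``
    (optimizer-tuned decomposition).  ``precomputed`` may carry
    ``{"dataset": ..., "modes": {arm: array}}`` to reuse artifacts.
    Returns an :class:`AblationResult`.
    """
    arms = list(arms)
    if len(arms) < 2:
        raise ValueError("ablation needs at least 2 arms")
    config.validate()

    pre = precomputed or {}
    ds = pre.get("dataset")
    if ds is None:
        ds = make_dataset(
            n_points=config.n_points,
            n_replicates=config.n_replicates,
            noise_sigma=config.noise_sigma,
            record_length=config.record_length,
            fs=config.fs,
            seed=config.seed,
        )
    modes_by_arm = dict(pre.get("modes", {}))
    for arm in arms:
        if arm in modes_by_arm:
            continue
        if arm == "none":
            modes_by_arm[arm] = ds.X[:, None, :]
        elif arm == "fixed":
            modes_by_arm[arm] = decompose_dataset(
                ds, VMDConfig(K=config.fixed_K, alpha=config.fixed_alpha,
                              tau=config.vmd_tau, max_iter=config.vmd_max_iter)
            )
        elif arm == "mocoa":
            ref_idx = int(np.flatnonzero([s.label == "model0" for s in ds.signals])[0])
            _, (K_star, alpha_star), _ = tune_vmd(
                ds.signals[ref_idx].samples,
                TuningSpace(K_range=tuple(config.K_range), alpha_range=tuple(config.alpha_range)),
                N=config.tuning_N, T=config.tuning_T, seed=config.seed, fs=config.fs,
                vmd_defaults=VMDConfig(tau=config.vmd_tau, max_iter=config.vmd_max_iter),
            )
            modes_by_arm[arm] = decompose_dataset(
                ds, VMDConfig(K=K_star, alpha=alpha_star, tau=config.vmd_tau,
                              max_iter=config.vmd_max_iter)
            )
        else:
            raise ValueError(f"unknown ablation arm {arm!r}")

    accs = {}
    for arm in arms:
        model = AttentionClassifier(modes_by_arm[arm], ds.y, config.encoder)
        arm_accs = []
        for r in range(n_repeats):
            hp = dataclasses.replace(config.training, seed=config.seed + r)
            res = model.fit(ds.train_idx, ds.test_idx, hp)
            arm_accs.append(res.report.accuracy)
        accs[arm] = arm_accs

    n = len(arms)
    P = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, p = paired_ttest(accs[arms[i]], accs[arms[j]])
            P[i, j] = P[j, i] = p
    return AblationResult(
        arms=arms,
        accuracies=accs,
        best={a: float(max(v)) for a, v in accs.items()},
        mean={a: float(np.mean(v)) for a, v in accs.items()},
        p_values=P,
    )
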