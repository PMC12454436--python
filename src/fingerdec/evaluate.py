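"""Metrics, behavioral tests, control sweeps and pipeline orchestration.

Accuracy is the fraction of correctly classified held-out trials; chance
is 1/n_classes (50% for two classes, 25% for four).  The four-class
confusion matrix is displayed in the fixed order RM, RI, LM, LI, with
across-subject aggregation reported as mean (SD) of row percentages.
Behavioral learning is assessed by paired t-tests on per-subject block
mean reaction times: block 1 against each later block, and block 12
against each earlier block; raw two-sided p-values are reported with
flags at 0.05 and 0.01 (no multiplicity correction, matching the
presentation convention of SRTT block plots).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion

from . import decoder as dec
from . import interpret as interp
from . import phase as ph
from . import preprocess as pre
from . import simulate as sim
from .data import EpochSet, save_epochs_h5, save_trials_csv

logger = logging.getLogger("fingerdec")

#: display order of the four-class confusion matrix
CONFUSION_ORDER = ("RM", "RI", "LM", "LI")


def accuracy(pred, truth) -> float:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.size == 0 or pred.size != truth.size:
        raise ValueError("predictions and truth must be equal-length and non-empty")
    return float((pred == truth).mean())


def chance_level(n_classes: int) -> float:
    if n_classes < 2:
        raise ValueError("chance level requires n_classes >= 2")
    return 1.0 / n_classes


@dataclass
class ConfusionMatrix:
    counts: np.ndarray            # (c, c) rows = actual, cols = predicted
    class_order: tuple[str, ...]
    percent_mean: np.ndarray | None = None   # across-subject mean of row %
    percent_sd: np.ndarray | None = None

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    def row_percent(self) -> np.ndarray:
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        sums[sums == 0] = 1.0
        return 100.0 * self.counts / sums

    def formatted(self) -> pd.DataFrame:
        """Mean (SD) row-percentage table, e.g. '83 (7)'."""
        mean = self.percent_mean if self.percent_mean is not None else self.row_percent()
        sd = self.percent_sd if self.percent_sd is not None else np.zeros_like(mean)
        cells = [
            [f"{mean[i, j]:.0f} ({sd[i, j]:.0f})" for j in range(len(self.class_order))]
            for i in range(len(self.class_order))
        ]
        return pd.DataFrame(
            cells,
            index=[f"Actual {c}" for c in self.class_order],
            columns=[f"Predicted {c}" for c in self.class_order],
        )


def confusion(pred, truth, class_order=CONFUSION_ORDER) -> ConfusionMatrix:
    """Confusion counts with a fixed class display order."""
    pred = np.asarray(pred, dtype=str)
    truth = np.asarray(truth, dtype=str)
    unknown = set(pred) | set(truth)
    unknown -= set(class_order)
    if unknown:
        raise ValueError(f"labels {sorted(unknown)} not in class order {class_order}")
    counts = _sk_confusion(truth, pred, labels=list(class_order))
    return ConfusionMatrix(counts=counts, class_order=tuple(class_order))


def aggregate_confusions(mats: list[ConfusionMatrix]) -> ConfusionMatrix:
    """Across-subject aggregation: summed counts plus mean (SD) row percent."""
    order = mats[0].class_order
    pct = np.stack([m.row_percent() for m in mats])
    return ConfusionMatrix(
        counts=np.sum([m.counts for m in mats], axis=0),
        class_order=order,
        percent_mean=pct.mean(axis=0),
        percent_sd=pct.std(axis=0, ddof=1) if len(mats) > 1 else np.zeros_like(pct[0]),
    )


def rt_block_tests(tables: list[pd.DataFrame], n_blocks: int = 12,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Paired t-tests on per-subject block-mean RTs (correct trials only).

    Compares block 1 vs blocks 2..n and block n vs blocks 1..n-1.
    Zero-variance comparisons are reported non-significant with p = 1.
    """
    if len(tables) < 2:
        raise ValueError("paired block tests require at least 2 subjects")
    means = []
    for tab in tables:
        ok = tab[tab["correct"].astype(bool)]
        bm = ok.groupby("block")["rt"].mean()
        missing = set(range(1, n_blocks + 1)) - set(bm.index)
        if missing:
            raise ValueError(f"subject missing block(s) {sorted(missing)}")
        means.append(bm.reindex(range(1, n_blocks + 1)).to_numpy())
    means = np.stack(means)        # (subjects, blocks)

    def paired(ref: int, other: int):
        a, b = means[:, ref - 1], means[:, other - 1]
        if np.allclose(a, b):
            return 0.0, 1.0
        t, p = stats.ttest_rel(a, b)
        return float(t), float(p)

    rows = []
    for other in range(2, n_blocks + 1):
        t, p = paired(1, other)
        rows.append({"comparison": f"block1_vs_block{other}", "t": t, "p": p})
    for other in range(1, n_blocks):
        t, p = paired(n_blocks, other)
        rows.append({"comparison": f"block{n_blocks}_vs_block{other}", "t": t, "p": p})
    out = pd.DataFrame(rows)
    out["sig_05"] = out["p"] < alpha
    out["sig_01"] = out["p"] < 0.01
    return out


def temporal_sensitivity(
    x: EpochSet,
    windows: list[tuple[float, float]],
    task: str = "four",
    hp: dec.LFCNNHyperparams | None = None,
    seed: int = 0,
    n_outer: int = 6,
    n_inner: int = 5,
) -> pd.DataFrame:
    """Decoding accuracy per (center_s, width_s) crop window.

    All windows are validated against the epoch extent before any
    training starts.  Returns mean and SD of outer-fold accuracies.
    """
    for center, width in windows:          # validate everything up front
        pre.crop_window(x.select(np.arange(min(1, x.n_trials))), center, width)
    rows = []
    for center, width in windows:
        xc = pre.crop_window(x, center, width)
        res = dec.train(xc, task=task, hp=hp, seed=seed, n_outer=n_outer,
                        n_inner=n_inner)
        rows.append({
            "center_s": center, "width_s": width,
            "accuracy_mean": res.mean_accuracy,
            "accuracy_sd": float(res.fold_accuracy.std(ddof=1)),
        })
        logger.info("window (%.3f, %.3f): accuracy %.3f", center, width,
                    res.mean_accuracy)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# configuration & pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Schema-validated pipeline configuration; unknown keys are rejected."""

    n_subjects: int = 2
    seed: int = 0
    out_dir: str = "fingerdec_out"
    # simulator
    cycles_per_block: int = 10
    n_blocks: int = 12
    n_channels: int = 204
    noise_sd: float = 0.1
    amplitude: float = 1.0
    phase_shift: bool = False
    # preprocessing
    highpass_hz: float | None = None
    resample_hz: float | None = None
    window: tuple[float, float] = (-0.5, 0.5)
    lock: str = "response"
    zscore_mode: str = "pooled"
    # model
    k: int = 32
    p: int = 7
    pool_factor: int = 10
    max_epochs: int = 1000
    patience: int = 3
    batch_size: int = 100
    learn_rate: float = 3e-3
    l2_weight: float = 3e-2
    n_outer: int = 6
    n_inner: int = 5
    tasks: tuple[str, ...] = ("LR", "withinL", "withinR", "four")
    # stats
    run_phase_analysis: bool = False
    n_permutations: int = 1000
    alpha: float = 0.05
    # orchestration: last stage to execute (simulate < behavior < decode
    # < interpret < phase < report)
    stop_after: str = "report"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise sim.ConfigurationError(
                f"unknown config key(s): {sorted(unknown)}"
            )
        cfg = cls(**{k: (tuple(v) if isinstance(v, list) else v)
                     for k, v in raw.items()})
        for t in cfg.tasks:
            if t not in dec.TASKS:
                raise sim.ConfigurationError(f"unknown task {t!r}")
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _prepare_subject(cfg: RunConfig, subject: int) -> tuple[pd.DataFrame, EpochSet]:
    seed = cfg.seed + 100 * subject
    fm = sim.build_forward_model(
        n_channels=cfg.n_channels, seed=seed + 1, noise_sd=cfg.noise_sd,
        phase_shift=sim.PhaseShift() if cfg.phase_shift else None,
    ).scaled(cfg.amplitude)
    srtt = sim.SRTTConfig(cycles_per_block=cfg.cycles_per_block,
                          n_blocks=cfg.n_blocks)
    table, epochs, _ = sim.simulate_subject(
        seed, cfg=srtt, fm=fm, window=cfg.window,
        subject_id=f"sub-{subject:02d}",
    )
    if cfg.highpass_hz:
        epochs = pre.highpass(epochs, cfg.highpass_hz)
    if cfg.resample_hz:
        epochs = pre.downsample(epochs, cfg.resample_hz)
    epochs = pre.select_correct(epochs, table)
    epochs = pre.zscore_epochs(epochs, per_channel=cfg.zscore_mode == "per_channel")
    return table, epochs


def run_pipeline(cfg: RunConfig) -> dict:
    """Simulate -> preprocess -> decode (4 tasks) -> interpret -> phase
    analysis -> report.  Writes metrics CSV/JSON plus logs into
    ``cfg.out_dir`` and returns the report dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
                    "subjects": {}, "tasks": {}}
    order = ["simulate", "behavior", "decode", "interpret", "phase", "report"]
    if cfg.stop_after not in order:
        raise sim.ConfigurationError(f"unknown stage {cfg.stop_after!r}")
    last = order.index(cfg.stop_after)

    def done(stage_name: str) -> bool:
        return order.index(stage_name) >= last

    stage = "simulate"
    try:
        subjects = []
        for s in range(cfg.n_subjects):
            table, epochs = _prepare_subject(cfg, s)
            subjects.append((table, epochs))
            save_trials_csv(out / f"sub-{s:02d}_trials.csv", table)
            save_epochs_h5(out / f"sub-{s:02d}_epochs.h5", epochs)
        if done("simulate"):
            (out / "report.json").write_text(json.dumps(report, indent=2))
            return report

        stage = "behavior"
        if cfg.n_subjects >= 2:
            rt_tests = rt_block_tests([t for t, _ in subjects],
                                      n_blocks=cfg.n_blocks)
            rt_tests.to_csv(out / "rt_block_tests.csv", index=False)
            report["rt_tests"] = {
                "n_significant_05": int(rt_tests["sig_05"].sum()),
                "block12_vs_block1_p": float(
                    rt_tests.set_index("comparison")
                    .loc[f"block{cfg.n_blocks}_vs_block1", "p"]
                ),
            }
        if done("behavior"):
            (out / "report.json").write_text(json.dumps(report, indent=2))
            return report

        stage = "decode"
        hp = dec.LFCNNHyperparams(
            k=cfg.k, p=cfg.p, pool_factor=cfg.pool_factor,
            max_epochs=cfg.max_epochs, patience=cfg.patience,
            batch_size=cfg.batch_size, learn_rate=cfg.learn_rate,
            l2_weight=cfg.l2_weight,
        )
        results: dict[str, list[dec.TrainResult]] = {t: [] for t in cfg.tasks}
        for s, (table, epochs) in enumerate(subjects):
            for task in cfg.tasks:
                res = dec.train(epochs, task=task, hp=hp,
                                seed=cfg.seed + 100 * s,
                                n_outer=cfg.n_outer, n_inner=cfg.n_inner)
                results[task].append(res)
                res.predictions.to_csv(
                    out / f"sub-{s:02d}_{task}_predictions.csv", index=False
                )
        for task in cfg.tasks:
            accs = np.array([r.mean_accuracy for r in results[task]])
            pooled = np.array([r.pooled_accuracy for r in results[task]])
            report["tasks"][task] = {
                "chance": chance_level(len(dec.TASK_CLASS_NAMES[task])),
                "accuracy_mean": float(accs.mean()),
                "accuracy_sd": float(accs.std(ddof=1)) if accs.size > 1 else 0.0,
                "pooled_accuracy_mean": float(pooled.mean()),
            }
        if "four" in cfg.tasks:
            mats = []
            names = dec.TASK_CLASS_NAMES["four"]
            for r in results["four"]:
                mats.append(confusion(
                    [names[i] for i in r.predictions["y_pred"]],
                    [names[i] for i in r.predictions["y_true"]],
                ))
            agg = aggregate_confusions(mats)
            agg.formatted().to_csv(out / "confusion_four.csv")
            report["tasks"]["four"]["confusion_diag_mean"] = [
                float(v) for v in np.diag(agg.percent_mean)
            ]
        if done("decode"):
            (out / "report.json").write_text(json.dumps(report, indent=2))
            return report

        stage = "interpret"
        first_four = results.get("four", results[cfg.tasks[0]])[0]
        pats = [interp.activation_patterns(
            m, subjects[0][1].data[first_four.trial_mask][
                first_four.folds.inner_index[f + 1]],
            data_scope=f"outer_fold_{f + 1}_train")
            for f, m in enumerate(first_four.models)]
        A_avg = interp.average_patterns(pats)
        np.savetxt(out / "patterns_avg.csv", A_avg, delimiter=",")
        interp.save_patterns_h5(out / "patterns_fold1.h5", pats[0])
        layout = sim.sensor_layout(cfg.n_channels)
        interp.plot_topography(A_avg[:, 0], layout,
                               path=out / "pattern_component0.png")
        report["interpretation"] = {"pattern_shape": list(A_avg.shape)}
        if done("interpret"):
            (out / "report.json").write_text(json.dumps(report, indent=2))
            return report

        stage = "phase"
        if cfg.run_phase_analysis:
            tabs = []
            for s, (table, epochs) in enumerate(subjects):
                tabs.append(ph.cross_phase_decoding(
                    epochs, task="four", hp=hp, seed=cfg.seed + 100 * s,
                    n_outer=cfg.n_outer, n_inner=cfg.n_inner))
            tests = ph.phase_transfer_tests(tabs, alpha=cfg.alpha)
            tests.to_csv(out / "phase_transfer_tests.csv", index=False)
            report["phase"] = tests.to_dict(orient="records")

        stage = "report"
        (out / "report.json").write_text(json.dumps(report, indent=2))
        logger.info("pipeline complete; report at %s", out / "report.json")
        return report
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
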