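"""Experiment orchestration: patient-level cross-validation, training,
evaluation and approach comparison.

Folds are built at patient level (all series of a patient travel together);
outlier-flagged series are kept in training sets but never appear in test
lists.  Training follows the clinical protocol: Adam with learning rate
0.001, batch size 1, a fixed epoch budget, optional warm start from a
pre-trained checkpoint with the output head reinitialised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .losses import bbox_loss_t, dice_loss_t, get_loss
from .metrics import MetricReport, dsc, hausdorff, mean_surface_distance, paired_wilcoxon
from .networks import NetworkSpec, SegmentationNetwork, build_network, transfer_weights
from .nn import Adam
from .preprocessing import class_vector_to_volume, keep_largest_component, normalize_intensity
from .volumes import CaseRecord, argmax_labels, PredictionVolume

__all__ = [
    "TrainConfig",
    "FoldPlan",
    "make_folds",
    "train_fold",
    "evaluate_fold",
    "compare_approaches",
    "run_experiment",
    "TrainResult",
]

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    loss: str = "pdl"
    network: str = "dmnet"
    base_filters: int = 8
    epochs: int = 10
    learning_rate: float = 0.001
    batch_size: int = 1
    exclude_background: bool = True
    postprocess: bool = True
    seed: int = 0
    pretrain: SegmentationNetwork | None = None
    convs_per_level: int = 2
    levels: int = 4

    def __post_init__(self):
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("learning_rate > 0, epochs >= 1, batch_size >= 1 required")


@dataclass
class FoldPlan:
    folds: list[dict]  # each: {"test_patients", "train_patients", "test_series"}
    excluded_series: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.folds)


def make_folds(cases: list[CaseRecord], k: int = 5, seed: int = 0) -> FoldPlan:
    """Shuffle patients by seed and deal them round-robin into ``k`` folds.

    Fold sizes differ by at most one patient; outlier series are excluded
    from every test list (they remain available for training)."""
    patients = sorted({c.patient_id for c in cases})
    if len(patients) < k:
        raise ValueError(f"need at least {k} patients, have {len(patients)}")
    rng = np.random.default_rng(seed)
    order = [patients[i] for i in rng.permutation(len(patients))]
    assignment = {p: i % k for i, p in enumerate(order)}
    excluded = [c.series_id for c in cases if c.is_outlier]
    folds = []
    for f in range(k):
        test_p = sorted(p for p, i in assignment.items() if i == f)
        train_p = sorted(p for p in patients if p not in test_p)
        test_series = [
            c.series_id for c in cases
            if c.patient_id in test_p and not c.is_outlier
        ]
        folds.append({"test_patients": test_p, "train_patients": train_p,
                      "test_series": test_series})
    return FoldPlan(folds=folds, excluded_series=excluded)


def _prepare_inputs(case: CaseRecord, masked: bool):
    img = normalize_intensity(case.image).data[..., None].astype(np.float32)
    cv = None
    if masked:
        vec = case.class_vector
        if vec is None:
            raise ValueError(f"case {case.series_id} lacks a class vector")
        cv = class_vector_to_volume(vec, case.image.shape)
    return img, cv


@dataclass
class TrainResult:
    network: SegmentationNetwork
    epoch_losses: list[float]
    log_rows: pd.DataFrame


def _make_spec(cfg: TrainConfig, shape, n_classes: int) -> NetworkSpec:
    return NetworkSpec(
        name=cfg.network,
        input_shape=tuple(shape) + (1,),
        n_classes=n_classes,
        base_filters=cfg.base_filters,
        levels=cfg.levels,
        convs_per_level=cfg.convs_per_level,
        seed=cfg.seed,
    )


def train_fold(fold: dict, cfg: TrainConfig, cases: list[CaseRecord]) -> TrainResult:
    """Train the configured network/loss on one fold's training patients."""
    train_cases = [c for c in cases if c.patient_id in set(fold["train_patients"])]
    if not train_cases:
        raise ValueError("fold has no training cases")
    shape = train_cases[0].image.shape
    n_classes = train_cases[0].labels.n_channels
    spec = _make_spec(cfg, shape, n_classes)
    if cfg.pretrain is not None:
        net, manifest = transfer_weights(cfg.pretrain, spec)
        log.info("warm start: %d copied, %d reinitialized",
                 len(manifest["copied"]), len(manifest["reinitialized"]))
    else:
        net = build_network(spec)
    loss_fn = get_loss(cfg.loss)
    opt = Adam(net.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1000)
    masked = cfg.network in ("mnet", "dmnet")
    epoch_losses: list[float] = []
    rows = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_cases))
        losses = []
        for i in order:
            case = train_cases[i]
            img, cv = _prepare_inputs(case, masked)
            p = case.labels.data.astype(np.float32)
            opt.zero_grad()
            q = net.forward(img, class_volume=cv, training=True)
            loss = loss_fn(p, q, cfg.exclude_background)
            val = float(loss.data)
            if not np.isfinite(val):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, series {case.series_id}"
                )
            loss.backward()
            opt.step()
            losses.append(val)
            row = dict(epoch=epoch, series_id=case.series_id, loss=val)
            if cfg.loss == "pdl":  # per-step component breakdown for the log
                row["dice"] = float(dice_loss_t(p, q.data, cfg.exclude_background).data)
                row["bbox"] = float(bbox_loss_t(p, q.data).data)
            rows.append(row)
        epoch_losses.append(float(np.mean(losses)))
        log.info("epoch %d mean %s loss %.4f", epoch, cfg.loss, epoch_losses[-1])
    return TrainResult(network=net, epoch_losses=epoch_losses,
                       log_rows=pd.DataFrame(rows))


def predict_case(net: SegmentationNetwork, case: CaseRecord,
                 postprocess: bool = True):
    """Forward pass -> probability volume -> hardened (optionally cleaned) labels."""
    masked = net.spec.name in ("mnet", "dmnet")
    img, cv = _prepare_inputs(case, masked)
    q = net.forward(img, class_volume=cv, training=False)
    prob = np.clip(q.data.astype(float), 0.0, 1.0)
    prob /= prob.sum(axis=-1, keepdims=True)
    pred = PredictionVolume(prob, channel_names=case.labels.channel_names,
                            spacing=case.labels.spacing)
    hard = argmax_labels(pred)
    if postprocess:
        hard = keep_largest_component(hard)
    return pred, hard


def evaluate_fold(net: SegmentationNetwork, fold: dict, cases: list[CaseRecord],
                  postprocess: bool = True) -> pd.DataFrame:
    """Per non-excluded test series and per structure: DSC, HD (mm), MSD (mm).

    Empty predicted structures keep their DSC row; HD/MSD are flagged missing
    (NaN)."""
    by_series = {c.series_id: c for c in cases}
    rows = []
    for sid in fold["test_series"]:
        case = by_series[sid]
        _, hard = predict_case(net, case, postprocess=postprocess)
        for c, structure in enumerate(case.labels.channel_names):
            if c == 0:
                continue
            gt = case.labels.data[..., c].astype(bool)
            pr = hard.data[..., c].astype(bool)
            row = dict(series_id=sid, structure=structure, dsc=dsc(gt, pr))
            if gt.any() and pr.any():
                row["hd"] = hausdorff(gt, pr, case.labels.spacing)
                row["msd"] = mean_surface_distance(gt, pr, case.labels.spacing)
            else:
                row["hd"] = np.nan
                row["msd"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def compare_approaches(reports: dict[str, pd.DataFrame],
                       alpha: float = 0.05) -> pd.DataFrame:
    """Aggregate several approaches' per-case rows and test every approach
    pair per structure/metric with the two-sided paired Wilcoxon signed-rank
    test.  Identical samples (all-zero differences) are reported as
    non-significant with a NaN p-value, by convention."""
    names = list(reports)
    base_series = None
    for name, rows in reports.items():
        series = set(rows["series_id"])
        if base_series is None:
            base_series = series
        elif series != base_series:
            raise ValueError(
                f"approach {name!r} covers a different series set; difference: "
                f"{sorted(series ^ base_series)}"
            )
    records = []
    metrics = [m for m in ("dsc", "hd", "msd") if m in next(iter(reports.values())).columns]
    structures = sorted(next(iter(reports.values()))["structure"].unique())
    for structure in structures:
        for metric in metrics:
            for i, a in enumerate(names):
                for b in names[i + 1:]:
                    ra = reports[a].query("structure == @structure").set_index("series_id")[metric]
                    rb = reports[b].query("structure == @structure").set_index("series_id")[metric]
                    joined = pd.concat([ra, rb], axis=1, keys=["a", "b"]).dropna()
                    try:
                        p = paired_wilcoxon(joined["a"].to_numpy(), joined["b"].to_numpy())
                    except ValueError:
                        p = np.nan
                    records.append(dict(
                        approach_a=a, approach_b=b, structure=structure,
                        metric=metric, p_value=p,
                        significant=bool(p < alpha) if np.isfinite(p) else False,
                    ))
    return pd.DataFrame.from_records(records)


def run_experiment(cases: list[CaseRecord], cfg: TrainConfig, k: int = 2,
                   seed: int = 0) -> dict:
    """Full cross-validated experiment: returns per-case metric rows pooled
    over folds, the fold plan and per-fold training curves."""
    plan = make_folds(cases, k=k, seed=seed)
    all_rows = []
    curves = []
    for f, fold in enumerate(plan.folds):
        fold_cfg = TrainConfig(**{**vars(cfg), "seed": cfg.seed + f})
        result = train_fold(fold, fold_cfg, cases)
        rows = evaluate_fold(result.network, fold, cases, postprocess=cfg.postprocess)
        rows["fold"] = f
        all_rows.append(rows)
        curves.append(result.epoch_losses)
    rows = pd.concat(all_rows, ignore_index=True)
    return {"rows": rows, "plan": plan, "curves": curves,
            "report": MetricReport(rows.drop(columns=["fold"]))}
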