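"""Training loop, augmentation, dataset splitting, and evaluation metrics.

Optimization follows the protocol the architecture was designed around:
AdamW (lr 1e-3, weight decay 1e-4), batch size 16, cosine-annealed learning
rate lr_e = lr * (1 + cos(pi * e / E)) / 2 with no restarts, and smoothed
cross-entropy with alpha = 0.1.  Every epoch re-draws the RIPCS point set of
each sample (randomized selection is the principal augmentation), then
applies, each with probability 0.5: a random rotation about z, clipped
Gaussian coordinate jitter, and Gaussian RI noise.  Evaluation always uses
the deterministic RIPCS variant and eval-mode (running-statistics, no
dropout) forward passes.

Metrics (accuracy, macro recall/precision/F1, one-vs-rest AUC, confusion
matrix) are computed with scikit-learn.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
)

from .errors import InvalidConfigError, InvalidDatasetError
from .phantom import PhantomSpec, generate_dataset
from .ripcs import PROV_RIIES, RIPCSConfig, TrainingPointSet, ripcs_select
from .rpnet import RPNet, RPNetConfig
from .nn import AdamW
from .voxelcloud import (
    RIPointCloud,
    SamplerConfig,
    normalize_unit_sphere,
    random_sample,
    segmented_equilibrium_sample,
    voxel_to_points,
)

__all__ = [
    "TrainConfig",
    "MetricsReport",
    "stratified_split",
    "smoothed_cross_entropy",
    "augment",
    "cosine_lr",
    "train",
    "evaluate",
    "compute_metrics",
    "metrics_from_predictions",
    "ABLATION_ARMS",
    "ArmSpec",
    "ripcs_config_for_strategy",
    "build_phantom_clouds",
    "run_ablation",
]

N_CLASSES = 3


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    weight_decay: float = 1e-4
    #: Adam moment decays; beta2=0.99 adapts the second moment fast enough
    #: for the short schedules used on desk-scale data
    betas: tuple[float, float] = (0.9, 0.99)
    epochs: int = 200
    batch_size: int = 16
    label_smoothing: float = 0.1
    augment_prob: float = 0.5
    jitter_sigma: float = 0.01
    jitter_clip: float = 0.05
    ri_noise_sigma: float = 0.002
    seed: int = 0
    kfold: int = 5

    def validate(self) -> None:
        if not 0 <= self.label_smoothing < 1:
            raise InvalidConfigError("label_smoothing must be in [0, 1)")
        if self.batch_size < 1 or self.epochs < 1:
            raise InvalidConfigError("batch_size and epochs must be >= 1")


@dataclass
class MetricsReport:
    accuracy: float
    recall_macro: float
    precision_macro: float
    f1_macro: float
    auc_per_class: list[float | None]
    auc_mean: float
    confusion: np.ndarray  # (3, 3), rows = truth

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "recall_macro": self.recall_macro,
            "precision_macro": self.precision_macro,
            "f1_macro": self.f1_macro,
            "auc_per_class": self.auc_per_class,
            "auc_mean": self.auc_mean,
            "confusion": np.asarray(self.confusion).tolist(),
        }


def stratified_split(
    labels: np.ndarray, ratio: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Per class, floor(ratio * n_c) samples go to train, the rest to test.
    Disjoint, exhaustive, deterministic given the seed."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise InvalidDatasetError("no labelled samples to split")
    if not 0 < ratio < 1:
        raise InvalidConfigError(f"ratio must be in (0, 1), got {ratio}")
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        if members.size == 0:
            raise InvalidDatasetError(f"class {c} has no samples")
        perm = rng.permutation(members)
        k = int(math.floor(ratio * members.size))
        train_idx.append(perm[:k])
        test_idx.append(perm[k:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def smoothed_cross_entropy(
    logprobs: np.ndarray, labels: np.ndarray | int, alpha: float = 0.1
) -> float:
    """Mean of -sum_c q_c log p_c with q = (1-alpha) onehot + alpha / C."""
    logprobs = np.atleast_2d(np.asarray(logprobs, dtype=np.float64))
    labels = np.atleast_1d(np.asarray(labels, dtype=np.int64))
    n, C = logprobs.shape
    q = np.full((n, C), alpha / C)
    q[np.arange(n), labels] += 1.0 - alpha
    return float(-(q * logprobs).sum(axis=1).mean())


def _smoothed_targets(labels: np.ndarray, C: int, alpha: float) -> np.ndarray:
    q = np.full((len(labels), C), alpha / C)
    q[np.arange(len(labels)), labels] += 1.0 - alpha
    return q


def augment(
    ts: TrainingPointSet, config: TrainConfig, seed: int
) -> TrainingPointSet:
    """Stochastic training augmentation; deterministic given the seed.

    Independently with probability ``augment_prob`` each: rotate coordinates
    by a uniform angle about z; jitter coordinates with clipped Gaussian
    noise; add Gaussian noise to the RI channel.  Geometric transforms never
    touch RI and vice versa.
    """
    rng = np.random.default_rng(seed)
    xyz = ts.xyz.copy()
    ri = ts.ri.copy()
    p = config.augment_prob
    if rng.random() < p:
        a = rng.uniform(0.0, 2.0 * np.pi)
        c, s = np.cos(a), np.sin(a)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        xyz = xyz @ rot.T
    if rng.random() < p and config.jitter_sigma > 0:
        jit = rng.normal(0.0, config.jitter_sigma, xyz.shape)
        xyz = xyz + np.clip(jit, -config.jitter_clip, config.jitter_clip)
    if rng.random() < p and config.ri_noise_sigma > 0:
        ri = ri + rng.normal(0.0, config.ri_noise_sigma, ri.shape)
    return TrainingPointSet(xyz, ri, ts.provenance.copy(), ts.label)


def cosine_lr(lr: float, epoch: int, total_epochs: int) -> float:
    """Cosine annealing to zero, no restarts."""
    return lr * (1.0 + math.cos(math.pi * epoch / total_epochs)) / 2.0


def _derived_seed(ss: np.random.SeedSequence, *key: int) -> int:
    return int(np.random.SeedSequence(list(ss.entropy if isinstance(ss.entropy, tuple)
                                           else [ss.entropy]) + list(key)).generate_state(1)[0] % (2**31))


def train(
    clouds: list[RIPointCloud],
    labels: np.ndarray,
    model_config: RPNetConfig,
    config: TrainConfig,
    ripcs_config: RIPCSConfig,
) -> tuple[RPNet, list[dict]]:
    """Run the full optimization loop on normalized clouds.

    Every epoch draws a fresh randomized RIPCS point set per sample, applies
    the stochastic augmentations, and steps AdamW under the cosine schedule.
    Returns the fitted model and a per-epoch history of learning rate and
    mean training loss.  Fully reproducible given the seeds in the configs.
    """
    config.validate()
    labels = np.asarray(labels, dtype=np.int64)
    if len(clouds) != len(labels):
        raise InvalidDatasetError("clouds and labels length mismatch")
    if np.unique(labels).size < 2:
        raise InvalidDatasetError("need at least 2 classes in the training set")

    root = np.random.SeedSequence(config.seed)
    init_seed, shuffle_seed, drop_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(3)
    )
    model = RPNet(model_config, seed=init_seed)
    opt = AdamW(
        model.parameters(),
        lr=config.lr,
        weight_decay=config.weight_decay,
        betas=config.betas,
    )
    order_rng = np.random.default_rng(shuffle_seed)
    drop_rng = np.random.default_rng(drop_seed)

    history: list[dict] = []
    n = len(clouds)
    for epoch in range(config.epochs):
        lr_e = cosine_lr(config.lr, epoch, config.epochs)
        order = order_rng.permutation(n)
        losses: list[float] = []
        for lo in range(0, n, config.batch_size):
            batch = order[lo : lo + config.batch_size]
            sets = []
            for i in batch:
                sel_seed = _derived_seed(root, 1, epoch, int(i))
                sel = ripcs_select(clouds[i], replace(ripcs_config, seed=sel_seed))
                sets.append(augment(sel, config, _derived_seed(root, 2, epoch, int(i))))
            logp = model.forward_sets(sets, train=True, dropout_rng=drop_rng)
            y = labels[batch]
            q = _smoothed_targets(y, model_config.n_classes, config.label_smoothing)
            losses.append(float(-(q * logp).sum(axis=1).mean()))
            model.backward((np.exp(logp) - q) / len(batch))
            opt.step(lr_e)
            opt.zero_grad()
        history.append(
            {"epoch": epoch, "lr": lr_e, "loss": float(np.mean(losses))}
        )
    return model, history


def predict(
    model: RPNet, clouds: list[RIPointCloud], ripcs_config: RIPCSConfig, eval_seed: int = 0
) -> np.ndarray:
    """Eval-mode class probability scores (n, C) under deterministic RIPCS."""
    scores = []
    for i in range(0, len(clouds), 64):
        sets = [
            ripcs_select(
                c,
                replace(
                    ripcs_config,
                    seed=_derived_seed(np.random.SeedSequence(eval_seed), 3, j),
                    fps_start="deterministic",
                ),
            )
            for j, c in enumerate(clouds[i : i + 64], start=i)
        ]
        scores.append(np.exp(model.forward_sets(sets, train=False)))
    return np.concatenate(scores)


def metrics_from_predictions(
    y_true: np.ndarray, scores: np.ndarray
) -> MetricsReport:
    """Metrics from true labels and (n, C) probability scores."""
    y_true = np.asarray(y_true, dtype=np.int64)
    scores = np.asarray(scores, dtype=np.float64)
    y_pred = scores.argmax(axis=1)
    C = scores.shape[1]
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=list(range(C)), average="macro", zero_division=0
    )
    aucs: list[float | None] = []
    for c in range(C):
        pos = (y_true == c).astype(int)
        if pos.min() == pos.max():  # class absent (or only class) in test set
            warnings.warn(f"class {c} absent from the test set; AUC undefined")
            aucs.append(None)
        else:
            aucs.append(float(roc_auc_score(pos, scores[:, c])))
    defined = [a for a in aucs if a is not None]
    return MetricsReport(
        accuracy=float(accuracy_score(y_true, y_pred)),
        recall_macro=float(rec),
        precision_macro=float(prec),
        f1_macro=float(f1),
        auc_per_class=aucs,
        auc_mean=float(np.mean(defined)) if defined else float("nan"),
        confusion=confusion_matrix(y_true, y_pred, labels=list(range(C))),
    )


compute_metrics = metrics_from_predictions  # convenience alias


def evaluate(
    model: RPNet,
    clouds: list[RIPointCloud],
    labels: np.ndarray,
    ripcs_config: RIPCSConfig,
    eval_seed: int = 0,
) -> MetricsReport:
    if len(clouds) == 0:
        raise InvalidDatasetError("empty test set")
    scores = predict(model, clouds, ripcs_config, eval_seed)
    return metrics_from_predictions(np.asarray(labels), scores)


# ---------------------------------------------------------------------------
# ablation experiment matrix


@dataclass(frozen=True)
class ArmSpec:
    """One experiment arm: input channels, voxel-to-cloud sampling mode, and
    RIPCS strategy."""

    channels: int
    vox_sampling: str  # "random" | "segmented"
    strategy: str  # "fps" | "riies" | "hybrid"


ABLATION_ARMS: dict[str, ArmSpec] = {
    "3D-R-FPS": ArmSpec(3, "random", "fps"),
    "3D-S-FPS": ArmSpec(3, "segmented", "fps"),
    "4D-R-FPS": ArmSpec(4, "random", "fps"),
    "4D-S-FPS": ArmSpec(4, "segmented", "fps"),
    "4D-R-RIIES": ArmSpec(4, "random", "riies"),
    "4D-S-RIIES": ArmSpec(4, "segmented", "riies"),
    "4D-R-Hybrid": ArmSpec(4, "random", "hybrid"),
    "4D-S-Hybrid": ArmSpec(4, "segmented", "hybrid"),
}

def hybrid_riies_count(K: int) -> int:
    """RIIES share of the hybrid selector.

    The band sample count is treated as the protocol constant it is at full
    scale (224 of 1024): the precision of the band statistics scales as
    1/sqrt(n_riies), so when K shrinks the FPS subset absorbs the reduction
    and the band draw stays at 224 — capped so FPS keeps at least K/8.
    At K=1024 this is exactly 800 + 224; at the desk scale K=256 it is
    32 + 224.
    """
    return min(224, round(K * 7 / 8))


def ripcs_config_for_strategy(
    strategy: str,
    K: int,
    ri_interval: tuple[float, float] = (1.345, 1.355),
    n_riies: int | None = None,
) -> RIPCSConfig:
    if strategy == "fps":
        n_r = 0
    elif strategy == "riies":
        n_r = K
    elif strategy == "hybrid":
        n_r = hybrid_riies_count(K) if n_riies is None else n_riies
    else:
        raise InvalidConfigError(f"unknown RIPCS strategy {strategy!r}")
    return RIPCSConfig(K=K, n_fps=K - n_r, n_riies=n_r, ri_interval=ri_interval)


def build_phantom_clouds(
    spec: PhantomSpec,
    n_per_class: tuple[int, int, int],
    sampler: SamplerConfig,
    seed: int = 0,
) -> tuple[list[RIPointCloud], np.ndarray]:
    """Phantoms -> foreground clouds -> M-point sampled, unit-normalized
    clouds with labels.  The shared front end of every experiment arm."""
    volumes = generate_dataset(spec, n_per_class, seed=seed)
    clouds: list[RIPointCloud] = []
    labels = np.empty(len(volumes), dtype=np.int64)
    for i, lv in enumerate(volumes):
        full = voxel_to_points(lv.volume, lv.mask)
        cfg = replace(sampler, seed=_derived_seed(np.random.SeedSequence(seed), 4, i))
        if cfg.mode == "segmented":
            sampled = segmented_equilibrium_sample(full, cfg)
        else:
            sampled = random_sample(full, cfg.M, cfg.seed)
        cloud = normalize_unit_sphere(sampled)
        cloud.label = lv.label
        clouds.append(cloud)
        labels[i] = lv.label
    return clouds, labels


def run_ablation(
    arms: list[str],
    n_per_class: tuple[int, int, int] = (60, 60, 60),
    spec: PhantomSpec | None = None,
    M: int = 2048,
    L: int = 6,
    K: int = 256,
    epochs: int = 50,
    seeds: tuple[int, ...] = (0,),
    data_seed: int = 0,
    split_seed: int = 0,
    model_profile: str = "tiny",
) -> dict[str, list[float]]:
    """Run named experiment arms on a shared synthetic dataset and return the
    held-out accuracy per training seed for each arm.

    The phantom volumes and the 8:2 stratified split are shared across arms;
    arms differing only in voxel-to-cloud sampling reuse the same volumes.
    """
    spec = spec or PhantomSpec(grid_shape=(96, 96, 63), voxel_spacing=1.0 / 3.0)
    cloud_cache: dict[str, tuple[list[RIPointCloud], np.ndarray]] = {}
    results: dict[str, list[float]] = {}
    for name in arms:
        arm = ABLATION_ARMS[name]
        if arm.vox_sampling not in cloud_cache:
            cloud_cache[arm.vox_sampling] = build_phantom_clouds(
                spec,
                n_per_class,
                SamplerConfig(M=M, L=L, mode=arm.vox_sampling),
                seed=data_seed,
            )
        clouds, labels = cloud_cache[arm.vox_sampling]
        tr, te = stratified_split(labels, 0.8, seed=split_seed)
        ripcs_cfg = ripcs_config_for_strategy(arm.strategy, K)
        if model_profile == "tiny":
            mcfg = RPNetConfig.tiny(arm.channels)
        else:
            mcfg = RPNetConfig.default(arm.channels)
        accs: list[float] = []
        for s in seeds:
            tcfg = TrainConfig(epochs=epochs, seed=int(s))
            model, _ = train(
                [clouds[i] for i in tr], labels[tr], mcfg, tcfg, ripcs_cfg
            )
            rep = evaluate(model, [clouds[i] for i in te], labels[te], ripcs_cfg)
            accs.append(rep.accuracy)
        results[name] = accs
    return results


def ripcs_robustness(
    model: RPNet,
    clouds: list[RIPointCloud],
    labels: np.ndarray,
    ripcs_config: RIPCSConfig,
    n_runs: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean and std of accuracy over repeated *randomized* RIPCS draws,
    quantifying sensitivity to point-selection stochasticity."""
    accs = []
    for r in range(n_runs):
        scores = []
        for j, c in enumerate(clouds):
            sel = ripcs_select(
                c, replace(ripcs_config, seed=_derived_seed(np.random.SeedSequence(seed), 5, r, j),
                           fps_start="random")
            )
            scores.append(np.exp(model.forward_sets([sel], train=False))[0])
        accs.append(float(accuracy_score(labels, np.argmax(scores, axis=1))))
    return float(np.mean(accs)), float(np.std(accs))
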