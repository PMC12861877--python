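"""Declarative configuration and end-to-end orchestration.

``run_pipeline`` executes simulate -> features -> threshold search ->
train -> evaluate -> report, writing every intermediate artifact (dataset
manifests, feature tables, search logs, training logs, metric tables) and
a final JSON report.  The whole run is a pure function of
``(config, config.seed)``; every stage derives its own sub-seed.
"""

from __future__ import annotations

import csv
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.linear_model import LogisticRegression

from twincross import learning, metrics, synthetic, thresholds
from twincross.features import FEATURE_NAMES
from twincross.seeding import subseed

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class ChannelConfig:
    name: str = "GU"
    n_benign: int = 100
    n_malignant: int = 100
    image_size: int = 96
    contrast_amplitude: float = 60.0
    label_noise_rate: float = 0.0


@dataclass(frozen=True)
class SearchConfig:
    rounds: int = 8
    init_low: float = 0.5
    init_high: float = 0.8
    fine_step: float = 0.001
    fine_window: float = 0.05

    def __post_init__(self) -> None:
        if not self.init_low < self.init_high:
            raise ConfigError(
                f"init threshold pair must satisfy t_low < t_high, got "
                f"({self.init_low}, {self.init_high})"
            )
        if self.rounds < 1:
            raise ConfigError("rounds must be >= 1")


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 20
    alpha: float = 100.0
    ratio: int = 10
    eta0: float = 1e-3
    backbone: str = "mlp"
    policy_enabled: bool = True
    policy_lr: float = 5.0


@dataclass(frozen=True)
class RunConfig:
    channels: tuple[ChannelConfig, ...] = (ChannelConfig(),)
    patch_size: int = 16
    glcm_levels: int = 32
    search: SearchConfig = field(default_factory=SearchConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    seed: int = 0
    out_dir: str = "runs/out"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        channels = tuple(
            ChannelConfig(**c) for c in d.pop("channels", [{}])
        )
        search = SearchConfig(**d.pop("search", {}))
        training = TrainingConfig(**d.pop("training", {}))
        return cls(channels=channels, search=search, training=training, **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _channel_spec(cfg: ChannelConfig, patch_size: int) -> synthetic.ChannelSpec:
    return synthetic.ChannelSpec(
        name=cfg.name,
        n_benign=cfg.n_benign,
        n_malignant=cfg.n_malignant,
        image_size=cfg.image_size,
        patch_size=patch_size,
        lesion_geometry=synthetic.LesionGeometry(
            n_lesions=(1, 3),
            semi_axis=(0.2 * cfg.image_size, 0.45 * cfg.image_size),
        ),
        lesion_texture=synthetic.TextureParams(
            contrast_amplitude=cfg.contrast_amplitude
        ),
        label_noise_rate=cfg.label_noise_rate,
    )


def prepare_channel(
    cfg: ChannelConfig,
    patch_size: int,
    search_cfg: SearchConfig,
    seed: int,
    out_dir: Path | None = None,
    glcm_levels: int = 32,
) -> tuple[learning.ChannelInputs, thresholds.SearchTrace, synthetic.LabeledPatchDataset]:
    """simulate + features + threshold search for one channel."""
    spec = _channel_spec(cfg, patch_size)
    ds = synthetic.build_channel_dataset(spec, subseed(seed, "simulate", cfg.name))
    feats = learning.TwinFeatures.from_patches(ds.patches, levels=glcm_levels)

    train_ids = np.flatnonzero(ds.split == "train")
    val_ids = np.flatnonzero(ds.split == "val")
    test_ids = np.flatnonzero(ds.split == "test")
    y_train_noisy = ds.noisy_labels[train_ids]
    y_val_noisy = ds.noisy_labels[val_ids]

    scorer = LogisticRegression(max_iter=500, random_state=0)
    scorer.fit(feats.X_plus[train_ids], y_train_noisy)
    scores = thresholds.score_patches(scorer, feats.X_plus[train_ids])

    pool = thresholds.ScoredPool(
        X=feats.X_plus[train_ids],
        scores=scores,
        X_val=feats.X_plus[val_ids],
        y_val=y_val_noisy,
    )
    pair, trace = thresholds.search_thresholds(
        pool,
        learning.binary_logistic_factory(),
        rounds=search_cfg.rounds,
        init=(search_cfg.init_low, search_cfg.init_high),
        fine_step=search_cfg.fine_step,
        fine_window=search_cfg.fine_window,
        seed=subseed(seed, "search", cfg.name),
    )
    part = thresholds.partition_by_thresholds(scores, pair)

    inputs = learning.ChannelInputs(
        name=cfg.name,
        feats=feats,
        rp=train_ids[part.rp],
        ns=train_ids[part.ns],
        val_pos=val_ids[y_val_noisy == 1],
        val_neg=val_ids[y_val_noisy == 0],
        test_ids=test_ids,
        test_labels=ds.labels[test_ids],
    )
    if out_dir is not None:
        _write_manifest(ds, out_dir / f"manifest_{cfg.name}.csv")
        _write_features(feats, ds, out_dir / f"features_{cfg.name}.csv")
        trace.write_csv(out_dir / f"search_{cfg.name}.csv")
    return inputs, trace, ds


def _write_manifest(ds: synthetic.LabeledPatchDataset, path: Path) -> None:
    pd.DataFrame(
        {
            "patch_id": np.arange(len(ds)),
            "channel": ds.channel,
            "split": ds.split,
            "label": ds.labels,
            "noisy_label": ds.noisy_labels,
            "source_image": ds.source_image,
            "row": ds.grid_row,
            "col": ds.grid_col,
        }
    ).to_csv(path, index=False)


def _write_features(
    feats: learning.TwinFeatures, ds: synthetic.LabeledPatchDataset, path: Path
) -> None:
    df = pd.DataFrame(feats.X_plus, columns=list(FEATURE_NAMES))
    df.insert(0, "patch_id", np.arange(len(ds)))
    df.to_csv(path, index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the final run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    report: dict = {"seed": config.seed, "channels": {}}
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    stage = "prepare"
    try:
        prepared = []
        for cfg in config.channels:
            inputs, trace, _ = prepare_channel(
                cfg, config.patch_size, config.search, config.seed,
                out_dir=out, glcm_levels=config.glcm_levels,
            )
            prepared.append(inputs)
            report["channels"][cfg.name] = {
                "thresholds": {
                    "t_low": trace.incumbent.t_low,
                    "t_high": trace.incumbent.t_high,
                },
                "n_rp": int(len(inputs.rp)),
                "n_ns": int(len(inputs.ns)),
            }
        timings[stage] = time.perf_counter() - t0

        stage = "train"
        t0 = time.perf_counter()
        tr = config.training
        results = learning.run_cross_learning(
            prepared,
            epochs=tr.epochs,
            alpha=tr.alpha,
            ratio=tr.ratio,
            eta0=tr.eta0,
            policy_enabled=tr.policy_enabled,
            policy_lr=tr.policy_lr,
            backbone=tr.backbone,
            seed=subseed(config.seed, "train"),
        )
        timings[stage] = time.perf_counter() - t0

        stage = "report"
        bundles = {}
        for name, res in results.items():
            bundles[name] = res.metrics
            report["channels"][name]["metrics"] = res.metrics.as_dict()
            report["channels"][name]["learning_rate"] = res.learning_rate
            for branch_res in (res.pl, res.nl):
                log_path = out / f"training_{name}_{branch_res.branch}.csv"
                with open(log_path, "w", newline="") as fh:
                    writer = csv.DictWriter(
                        fh,
                        fieldnames=[
                            "epoch", "f1", "f1_trailing_mean", "reward", "n_psi"
                        ],
                    )
                    writer.writeheader()
                    writer.writerows(branch_res.log_rows)
        metrics.write_metrics_report(bundles, out / "metrics.json")
        report["macro"] = json.loads((out / "metrics.json").read_text())["macro"]
    except Exception as exc:  # noqa: BLE001 - re-raise with stage label
        raise PipelineStageError(stage, exc) from exc

    report["timings_info"] = {k: round(v, 3) for k, v in timings.items()}
    payload = {k: v for k, v in report.items() if k != "timings_info"}
    (out / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    return report
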