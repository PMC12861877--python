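"""Reusable synthetic benchmark constructions.

These are the controlled experiments the test-suite and the acceptance
report both run: a Beta-mixture score pool with a known optimal threshold
region, and a noisy positive-only training-set construction for measuring
noise-filter efficacy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from twincross import learning, synthetic, thresholds
from twincross.seeding import rng_for, subseed


def beta_mixture_pool(
    n_per_class: int = 1000, n_val: int = 500, seed: int = 0
) -> thresholds.ScoredPool:
    """Scores from Beta(2,8) negatives / Beta(8,2) positives.

    The optimal double-threshold pair lies near the density crossing at
    0.5; features are the scores themselves, so a linear backbone can
    realize the Bayes rule.
    """
    rng = rng_for(seed, "beta-mixture")
    neg = rng.beta(2, 8, n_per_class)
    pos = rng.beta(8, 2, n_per_class)
    scores = np.r_[neg, pos]
    neg_v = rng.beta(2, 8, n_val)
    pos_v = rng.beta(8, 2, n_val)
    return thresholds.ScoredPool(
        X=scores.reshape(-1, 1),
        scores=scores,
        X_val=np.r_[neg_v, pos_v].reshape(-1, 1),
        y_val=np.r_[np.zeros(n_val), np.ones(n_val)].astype(int),
    )


def separable_channel(
    n_benign: int,
    n_malignant: int,
    seed: int,
    contrast_amplitude: float = 60.0,
    label_noise_rate: float = 0.0,
    image_size: int = 96,
    patch_size: int = 16,
    name: str = "GU",
) -> synthetic.LabeledPatchDataset:
    """A high-contrast (linearly separable) synthetic channel."""
    spec = synthetic.ChannelSpec(
        name=name,
        n_benign=n_benign,
        n_malignant=n_malignant,
        image_size=image_size,
        patch_size=patch_size,
        lesion_geometry=synthetic.LesionGeometry(
            n_lesions=(1, 3),
            semi_axis=(0.2 * image_size, 0.45 * image_size),
        ),
        lesion_texture=synthetic.TextureParams(
            contrast_amplitude=contrast_amplitude
        ),
        label_noise_rate=label_noise_rate,
    )
    return synthetic.build_channel_dataset(spec, seed)


@dataclass(frozen=True)
class NoisyPLExperiment:
    """A PL branch construction with known injected-noise ids."""

    feats: learning.TwinFeatures
    sets: learning.TrainingSets
    noise_ids: frozenset[int]  # truly-negative ids planted in p_t_ori
    labels: np.ndarray  # clean labels for every featurized patch


def make_noisy_pl_experiment(
    seed: int,
    n_core: int = 40,
    noise_rate: float = 0.2,
    ratio: int = 10,
    n_val_pos: int = 30,
    n_val_neg: int = 60,
) -> NoisyPLExperiment:
    """Positive core with ``noise_rate`` planted negatives, 1:ratio opposite.

    The dataset is high-contrast (separable).  ``p_t_ori`` holds
    ``n_core`` ids of which ``round(noise_rate * n_core)`` are truly
    negative (the injected noise the filter should remove); ``n_t_ori``
    holds ``ratio * n_core`` true negatives; validation sets are clean.
    """
    n_noise = int(np.floor(noise_rate * n_core + 0.5))
    n_true_pos = n_core - n_noise
    need_pos = n_true_pos + n_val_pos
    need_neg = n_noise + ratio * n_core + n_val_neg
    ds = separable_channel(need_neg, need_pos, seed)
    feats = learning.TwinFeatures.from_patches(ds.patches)

    rng = rng_for(seed, "noisy-pl")
    pos_ids = rng.permutation(np.flatnonzero(ds.labels == 1))
    neg_ids = rng.permutation(np.flatnonzero(ds.labels == 0))

    true_pos = pos_ids[:n_true_pos]
    noise = neg_ids[:n_noise]
    opposite = neg_ids[n_noise : n_noise + ratio * n_core]
    val_pos = pos_ids[n_true_pos : n_true_pos + n_val_pos]
    val_neg = neg_ids[n_noise + ratio * n_core :][:n_val_neg]

    sets = learning.TrainingSets(
        branch="PL",
        p_t_ori=np.sort(np.r_[true_pos, noise]),
        p_v_ori=np.sort(val_pos),
        n_t_ori=np.sort(opposite),
        n_v_ori=np.sort(val_neg),
        ratio=ratio,
    )
    return NoisyPLExperiment(
        feats=feats,
        sets=sets,
        noise_ids=frozenset(int(i) for i in noise),
        labels=ds.labels,
    )


def noise_filter_run(
    seed: int,
    epochs: int = 40,
    policy_enabled: bool = True,
    policy_lr: float = 5.0,
    alpha: float = 100.0,
    **experiment_kwargs,
) -> tuple[learning.BranchResult, NoisyPLExperiment]:
    """One noisy-PL run with the policy on or off; logistic backbone."""
    exp = make_noisy_pl_experiment(seed, **experiment_kwargs)
    result = learning.run_branch_loop(
        exp.feats,
        exp.sets,
        learning.logistic_backbone_factory(),
        epochs=epochs,
        alpha=alpha,
        policy_lr=policy_lr,
        policy_enabled=policy_enabled,
        seed=subseed(seed, "noise-filter-run"),
    )
    return result, exp


def removal_precision(
    result: learning.BranchResult, exp: NoisyPLExperiment, last_k: int = 5
) -> float:
    """Fraction of late-epoch removals that are injected-noise ids."""
    removed = np.concatenate(result.psi_history[-last_k:])
    if len(removed) == 0:
        return 0.0
    hits = sum(1 for i in removed if int(i) in exp.noise_ids)
    return hits / len(removed)
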