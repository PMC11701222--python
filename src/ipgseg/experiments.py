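"""Reproducible study-condition experiments over the full pipeline.

Each function here sets up a synthetic study from scratch — scene,
oracle corruption, seed labels — runs the relevant pipeline stages, and
measures an outcome.  The test suite asserts properties of these outcomes
and the acceptance script reports them, so the experiment definitions live
in one place.

Study conditions: the default desk-scale scene (64x64, 24 bands so 22
three-band groups, 4 classes), five seed labels per category, 50 loop
iterations with one admitted pseudo label per category per iteration, and
the standard gate thresholds.  "Moderate" oracle corruption is the
calibrated level at which a single band group misassigns roughly 10-20% of
pixels (see :mod:`ipgseg.synthetic`).
"""

from __future__ import annotations

import numpy as np

from .classifier import (
    TrainConfig,
    build_training_set,
    extract_patches,
    predict_map,
    train_classifier,
)
from .loop import IPGConfig, initialize, run
from .metrics import MetricReport, confusion, overall_accuracy
from .scene_io import decompose_bands, normalize_group, sample_seed_labels
from .segmenter import OracleSegmenter
from .synthetic import (
    MODERATE_BOUNDARY_BAND,
    MODERATE_FEATURE_NOISE_SD,
    MODERATE_FLIP_RHO,
    SceneSpec,
    export_oracle,
    generate_scene,
)
from .voting import MaskStack, assign, tally

SEEDS_PER_CLASS = 5


def _default_spec(seed: int, noise_sd: float = 0.05) -> SceneSpec:
    return SceneSpec(seed=seed, noise_sd=noise_sd)


def _few_label_spec(seed: int) -> SceneSpec:
    """The hard few-label regime for the classifier benefit experiment.

    Eight fragmented, irregular class regions with spectrally similar
    signatures (minimum pairwise angle 15 degrees) and strong per-band
    noise: five labels per class leave a patch classifier clearly below
    ceiling, so augmenting the training set has measurable room to help —
    the regime the framework is designed for.
    """
    return SceneSpec(seed=seed, classes=8, region_model="grown-blobs",
                     theta_min_deg=15.0, noise_sd=0.5, min_region_pixels=64)


def zero_noise_recovery(seed: int, iterations: int = 50) -> dict:
    """Run the loop on a zero-noise scene with a clean oracle.

    Returns pseudo-label precision against ground truth, agreement of the
    voted map with ground truth on assigned pixels, and the sizes involved.
    """
    scene = generate_scene(_default_spec(seed, noise_sd=0.0))
    backend = OracleSegmenter(export_oracle(scene))
    seeds = sample_seed_labels(scene.truth, SEEDS_PER_CLASS, seed + 1)
    pseudo, voted, _ = run(scene.cube, seeds, backend,
                           IPGConfig(iterations=iterations, seed=seed))
    truth = scene.truth.labels
    hits = sum(truth[e.row, e.col] == e.category for e in pseudo.entries)
    assigned = voted.labels.labels > 0
    agree = (voted.labels.labels[assigned] == truth[assigned]).mean()
    return {
        "precision": hits / len(pseudo.entries),
        "voted_agreement": float(agree),
        "n_pseudo": len(pseudo.entries),
        "n_assigned": int(assigned.sum()),
        "n_pixels": truth.size,
    }


def _mask_stack(scene, backend, seeds) -> MaskStack:
    state = initialize(seeds, scene.spec.classes)
    groups = [normalize_group(g) for g in decompose_bands(scene.cube).groups]
    h, w = scene.truth.shape
    decisions = np.zeros((len(groups), scene.spec.classes, h, w), dtype=bool)
    for cat in range(1, scene.spec.classes + 1):
        prompts = state.prompts.for_category(cat)
        for j, img in enumerate(groups):
            decisions[j, cat - 1] = backend.segment(img, prompts).mask
    return MaskStack(decisions)


def voting_concentration(seed: int, n_scenes: int = 10,
                         flip_rho: float = 0.2) -> dict:
    """Compare fused-map error against mean single-group error.

    Each scene's band groups are corrupted independently at ``flip_rho``;
    the fused assignment should err far less often than an average single
    group does.
    """
    voted_errs, single_errs, wins = [], [], 0
    for i in range(n_scenes):
        scene = generate_scene(_default_spec(seed + i))
        backend = OracleSegmenter(export_oracle(
            scene, flip_rho=flip_rho, boundary_band=MODERATE_BOUNDARY_BAND))
        seeds = sample_seed_labels(scene.truth, SEEDS_PER_CLASS, seed + i)
        stack = _mask_stack(scene, backend, seeds)
        truth = scene.truth.labels
        single = np.mean([
            (assign(tally(MaskStack(stack.decisions[j:j + 1])))
             .labels.labels != truth).mean()
            for j in range(stack.n_groups)
        ])
        voted = (assign(tally(stack)).labels.labels != truth).mean()
        voted_errs.append(float(voted))
        single_errs.append(float(single))
        if voted < single:
            wins += 1
    return {
        "voted_error": float(np.mean(voted_errs)),
        "single_group_error": float(np.mean(single_errs)),
        "wins": wins,
        "n_scenes": n_scenes,
        "n_groups": stack.n_groups,
        "n_pixels": truth.size,
    }


def pseudo_label_benefit(seed: int, n_pairs: int = 10,
                         iterations: int = 50,
                         train_epochs: int = 100) -> dict:
    """Paired comparison of classifier accuracy with and without pseudo
    labels under moderate oracle corruption.

    For each generator seed, one loop run produces the pseudo labels; two
    classifiers are then trained from the same initialization — seeds only
    versus seeds plus pseudo labels — and scored on the identical held-out
    pixel set (ground-truth pixels that entered neither training set).
    """
    oa_with, oa_without, precisions = [], [], []
    aa_with, kappa_with = [], []
    wins = 0
    for i in range(n_pairs):
        scene = generate_scene(_few_label_spec(seed + i))
        backend = OracleSegmenter(export_oracle(
            scene,
            flip_rho=MODERATE_FLIP_RHO,
            boundary_band=MODERATE_BOUNDARY_BAND,
            feature_noise_sd=MODERATE_FEATURE_NOISE_SD,
        ))
        seeds = sample_seed_labels(scene.truth, SEEDS_PER_CLASS, seed + i)
        pseudo, _, _ = run(scene.cube, seeds, backend,
                           IPGConfig(iterations=iterations, seed=seed + i))
        truth = scene.truth.labels
        if pseudo.entries:
            hits = sum(truth[e.row, e.col] == e.category for e in pseudo.entries)
            precisions.append(hits / len(pseudo.entries))

        eval_mask = truth > 0
        for r, c in seeds.pixels() | {(e.row, e.col) for e in pseudo.entries}:
            eval_mask[r, c] = False

        cfg = TrainConfig(epochs=train_epochs, seed=seed + i)
        pair = {}
        for tag, pseudo_labels in (("with", pseudo.as_pixel_labels()),
                                   ("without", [])):
            training = build_training_set(seeds, pseudo_labels, truth.shape,
                                          scene.spec.classes)
            dataset = extract_patches(scene.cube, training)
            clf = train_classifier(dataset, cfg)
            pred = predict_map(clf, scene.cube)
            cm = confusion(scene.truth, pred.labels.labels, eval_mask)
            pair[tag] = overall_accuracy(cm)
            if tag == "with":
                report = MetricReport.from_confusion(cm)
                aa_with.append(report.aa)
                kappa_with.append(report.kappa)
        oa_with.append(pair["with"])
        oa_without.append(pair["without"])
        if pair["with"] >= pair["without"]:
            wins += 1
    return {
        "oa_with_pseudo": float(np.mean(oa_with)),
        "oa_seeds_only": float(np.mean(oa_without)),
        "aa_with_pseudo": float(np.mean(aa_with)),
        "kappa_with_pseudo": float(np.mean(kappa_with)),
        "oa_with_per_seed": oa_with,
        "oa_without_per_seed": oa_without,
        "pseudo_precision": float(np.mean(precisions)) if precisions else float("nan"),
        "wins": wins,
        "n_pairs": n_pairs,
        "n_eval_pixels": int(eval_mask.sum()),
    }
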