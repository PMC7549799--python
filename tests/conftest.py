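"""Shared fixtures: small rasters and one session-scoped end-to-end study.

The end-to-end study (the expensive part) is computed once: a 6-class
synthetic fin dataset, 20 training and 20 test images per class at noise
sigma 0.02, descriptors extracted under both the default magnitude pruning
and the unpruned stack (re-using each image's Gaussian stack), centroid
models trained, and one-vs-rest reports produced for both modes.
"""

from __future__ import annotations

import numpy as np
import pytest

from finid import (
    DEFAULT_CONFIG,
    TrainingSet,
    evaluate_classifier,
    generate_dataset,
    stratified_split,
    train_median_classifier,
)
from finid.features import (
    assign_orientations,
    compute_descriptor,
    detect_extrema,
    gradient_field,
    localize_keypoint,
)
from finid.scale_space import (
    build_scale_stack,
    dog_differences,
    dog_threshold,
    reduce_scales,
)

E2E_SEED = 0
N_PER_CLASS = 20
NOISE_SIGMA = 0.02


def extract_with_modes(image, config=DEFAULT_CONFIG, modes=("abs_le", "none")):
    """Per-mode (candidate count, descriptors) sharing one Gaussian stack."""
    ss, fc = config.scale_space, config.features
    stack = build_scale_stack(image, ss.sigma0, ss.k, ss.n_levels)
    dog = dog_differences(stack)
    thr = dog_threshold(dog, pooling=ss.pooling)
    fields = {}

    def field_for(level):
        if level not in fields:
            fields[level] = gradient_field(stack.levels[level])
        return fields[level]

    out = {}
    for mode in modes:
        reduced = reduce_scales(dog, thr, mode=mode)
        candidates = detect_extrema(reduced, edge_exclusion=fc.edge_exclusion)
        descriptors = []
        for cand in candidates:
            kp = localize_keypoint(
                dog, cand, fc.contrast_threshold, fc.max_iter,
                fc.edge_response_threshold,
            )
            if kp is None:
                continue
            lvl = int(np.clip(
                round(np.log(kp.sigma / ss.sigma0) / np.log(ss.k)),
                0, ss.n_levels - 1,
            ))
            fld = field_for(lvl)
            for okp in assign_orientations(
                kp, fld, fc.n_bins, fc.window_sigma_factor, fc.peak_mode
            ):
                desc = compute_descriptor(okp, fld, fc.sigma_g_mode)
                if desc is not None:
                    descriptors.append(desc)
        out[mode] = (len(candidates), descriptors)
    return out


@pytest.fixture(scope="session")
def e2e_study():
    """Dataset, per-mode extractions, models and reports for the fixed seed."""
    dataset = generate_dataset(
        n_per_class=2 * N_PER_CLASS, base_seed=E2E_SEED, noise_sigma=NOISE_SIGMA
    )
    train, test = stratified_split(dataset, train_frac=0.5, seed=E2E_SEED)
    study = {"train": train, "test": test}
    for split_name, split in (("train", train), ("test", test)):
        rows = []
        for sample in split:
            per_mode = extract_with_modes(sample.image)
            rows.append((sample.label, per_mode))
        study[f"{split_name}_extracted"] = rows
    for mode in ("abs_le", "none"):
        ts = TrainingSet()
        for label, per_mode in study["train_extracted"]:
            _, descs = per_mode[mode]
            if descs:
                ts.add_image(label, descs)
        model = train_median_classifier(ts, aggregator="mean")
        keep = [
            (label, per_mode[mode][1])
            for label, per_mode in study["test_extracted"]
            if per_mode[mode][1]
        ]
        report = evaluate_classifier(
            model, [d for _, d in keep], [l for l, _ in keep]
        )
        n_candidates = sum(
            per_mode[mode][0]
            for _, per_mode in study["train_extracted"] + study["test_extracted"]
        )
        study[mode] = {
            "training_set": ts,
            "model": model,
            "report": report,
            "n_candidates": n_candidates,
        }
    return study


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
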