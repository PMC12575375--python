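"""Self-contained synthetic benchmark of the pixel-classification pipeline.

Emulates a hand-annotated train/validate/test design on phantom fields:
several training fields, one validation field for threshold calibration and
one held-out test field, all rendered from one master seed. The annotated
slice of each field is its focal slice, where every pixel carries a ground
-truth class. Reported numbers are one-vs-rest AUROCs per class on the
pooled test pixels, plus the calibrated pore threshold and its F1.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import classify
from .features import FeatureConfig, compute_features
from .phantom import PhantomOutput, PhantomSpec, generate_phantom
from .stack_io import GroundTruthMask


@dataclasses.dataclass
class BenchmarkResult:
    model: classify.PixelClassifier
    report: classify.EvalReport
    pore_threshold: float
    n_structures: dict[str, int]  # annotated circular structures per split
    fields: dict[str, list[PhantomOutput]]

    @property
    def auroc_pore(self) -> float:
        return self.report.auroc[1]

    @property
    def auroc_nucleus(self) -> float:
        return self.report.auroc[2]

    @property
    def auroc_nucleolus(self) -> float:
        return self.report.auroc[3]


def field_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-field seeds derived from one master seed."""
    rng = np.random.default_rng(master_seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def generate_fields(
    master_seed: int = 42,
    n_train: int = 8,
    n_val: int = 1,
    n_test: int = 1,
    base_spec: PhantomSpec = PhantomSpec(),
) -> dict[str, list[PhantomOutput]]:
    """Render the train/validate/test phantom fields for the benchmark."""
    seeds = field_seeds(master_seed, n_train + n_val + n_test)
    outs = [
        generate_phantom(dataclasses.replace(base_spec, seed=s)) for s in seeds
    ]
    return {
        "train": outs[:n_train],
        "validate": outs[n_train : n_train + n_val],
        "test": outs[n_train + n_val :],
    }


def annotated_set(
    fields: list[PhantomOutput],
    role: str,
    feature_config: FeatureConfig = FeatureConfig(),
) -> classify.TrainingSet:
    """Build a TrainingSet from the focal slice of each phantom field."""
    items = []
    for out in fields:
        z = out.spec_echo.focal_slice
        fs = compute_features(out.stack.voxels[z], feature_config)
        mask = GroundTruthMask(labels=out.truth[z].labels, slice_index=z)
        items.append((fs, mask))
    return classify.TrainingSet(items=items, role=role)


def run_benchmark(
    master_seed: int = 42,
    n_train: int = 8,
    n_val: int = 1,
    n_test: int = 1,
    base_spec: PhantomSpec = PhantomSpec(),
    n_estimators: int = 200,
    feature_config: FeatureConfig = FeatureConfig(),
) -> BenchmarkResult:
    """Train, calibrate and evaluate the classifier on phantom fields."""
    fields = generate_fields(master_seed, n_train, n_val, n_test, base_spec)
    train_set = annotated_set(fields["train"], "train", feature_config)
    val_set = annotated_set(fields["validate"], "validate", feature_config)
    test_set = annotated_set(fields["test"], "test", feature_config)
    model = classify.train(
        train_set, n_estimators=n_estimators, seed=master_seed,
        feature_config=feature_config,
    )
    threshold = classify.calibrate_threshold(model, val_set)
    report = classify.evaluate(model, test_set)
    return BenchmarkResult(
        model=model,
        report=report,
        pore_threshold=threshold,
        n_structures={
            "train": train_set.n_structures,
            "validate": val_set.n_structures,
            "test": test_set.n_structures,
        },
        fields=fields,
    )
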