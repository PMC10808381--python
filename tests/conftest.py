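"""Shared fixtures: synthetic study datasets and record builders.

The expensive end-to-end artifacts (plates generated at the study's
default conditions, segmented and featurized) are session-scoped so the
ensemble, evaluation and acceptance tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from seedsalt import extract_plate_table, generate_dataset, preset
from seedsalt.features import (COLOR_COLUMNS, ColorFeatures, MORPHO_COLUMNS,
                               MorphoFeatures, SeedRecord)
from seedsalt.synthetic import default_spec

INT_FEATURES = {"area", "hisgreypeak", "hue16max", "hue32max", "hue64max"}


def make_record(plate: str, label: int, condition=None, rng=None, **overrides) -> SeedRecord:
    """A SeedRecord with plausible random features, overridable per column."""
    rng = rng or np.random.default_rng(0)
    vals = {}
    for col in MORPHO_COLUMNS + COLOR_COLUMNS:
        v = float(rng.normal(50.0, 10.0))
        vals[col] = v
    vals.update(overrides)
    for col in INT_FEATURES:
        vals[col] = int(round(abs(vals[col])))
    morpho = MorphoFeatures(**{c: vals[c] for c in MORPHO_COLUMNS})
    color = ColorFeatures(**{c: vals[c] for c in COLOR_COLUMNS})
    return SeedRecord(plate=plate, label=label, morpho=morpho, color=color,
                      condition=condition)


def make_class_records(n_per_class: int, shift: float, seed: int = 0,
                       columns: tuple[str, ...] = ("q1r", "q2r", "q3r"),
                       plate_size: int = 10) -> list[SeedRecord]:
    """Two-class record set where the salt class's ``columns`` (by default
    the red quartiles, which shift together under the salt effect) are each
    offset by ``shift`` feature standard deviations (sd = 10)."""
    rng = np.random.default_rng(seed)
    records = []
    for cls, offset in (("non-salt", 0.0), ("salt", shift * 10.0)):
        for i in range(n_per_class):
            plate = f"{cls}_{i // plate_size}"
            rec = make_record(plate, i, condition=cls, rng=rng)
            for column in columns:
                target = rec.color if column in COLOR_COLUMNS else rec.morpho
                setattr(target, column, getattr(target, column) + offset)
            records.append(rec)
    return records


def extract_labeled(plates, config):
    records = []
    for plate in plates:
        records.extend(extract_plate_table(plate.image, config,
                                           condition=plate.condition))
    return records


@pytest.fixture(scope="session")
def fluo_config():
    return preset("FLUO")


@pytest.fixture(scope="session")
def small_plate():
    """One 512x512 FLUO plate with 50 seeds, shared by fast tests."""
    spec = default_spec("FLUO", "non-salt", seed=42, height=512, width=512,
                        dish_center=(256.0, 256.0), dish_radius=200.0, n_seeds=50)
    from seedsalt import generate_plate

    return generate_plate(spec)


@pytest.fixture(scope="session")
def endtoend_run(fluo_config):
    """Default salt effect, 1 training plate per class, 20 test plates per
    class: returns (predictions, truth dict)."""
    from seedsalt import classify_plates, train_ensemble

    salt = default_spec("FLUO", "salt")
    non = default_spec("FLUO", "non-salt")
    train = generate_dataset(1, salt, non, seed=101)
    test = generate_dataset(20, salt, non, seed=202)
    model = train_ensemble(extract_labeled(train, fluo_config), subset="all", seed=7)
    predictions = classify_plates(model, extract_labeled(test, fluo_config))
    truth = {p.image.id: p.condition for p in test}
    return predictions, truth


@pytest.fixture(scope="session")
def kfold_records(fluo_config):
    """40 labeled synthetic plates (20 per class) as seed records."""
    salt = default_spec("FLUO", "salt")
    non = default_spec("FLUO", "non-salt")
    plates = generate_dataset(20, salt, non, seed=303)
    return extract_labeled(plates, fluo_config)
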