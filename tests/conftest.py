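"""Shared fixtures.

The expensive end-to-end phantom recovery (training on 120 volumes for
three seeds) is computed once per session and shared by the acceptance
tests that need a trained model.
"""

from __future__ import annotations

import numpy as np
import pytest

from msa3d import (PhantomSpec, TrainConfig, attention_mass, evaluate_model,
                   generate_dataset, train)

TINY_SHAPE = (12, 14, 12)


@pytest.fixture
def tiny_spec() -> PhantomSpec:
    """A fast phantom family for smoke tests."""
    return PhantomSpec(shape=TINY_SHAPE, lesion_radii=(2, 2, 2),
                       effect_size=0.8, noise_sd=0.05)


@pytest.fixture(scope="session")
def recovery_runs():
    """Train the desk-scale model for three seeds on the default phantom task.

    Returns a list of dicts with the trained model, its test metrics, the
    axial attention-mass ratio over lesioned test volumes, and the test set.
    """
    spec = PhantomSpec()  # (24, 28, 24), effect_size 0.8, noise_sd 0.05
    results = []
    for seed in (0, 1, 2):
        train_ds = generate_dataset(60, spec, seed=1000 + seed)
        test_ds = generate_dataset(30, spec, seed=2000 + seed)
        model, history = train(train_ds,
                               train_cfg=TrainConfig(seed=seed, max_epochs=25))
        report = evaluate_model(model, test_ds)
        x, y = test_ds.as_arrays()
        informative = sorted(test_ds.informative_slices["axial"])
        masses = [attention_mass(model.attention_matrices(x[i])["z"], informative)
                  for i in np.flatnonzero(y == 1)]
        baseline = len(informative) / spec.shape[2]
        results.append({
            "seed": seed,
            "model": model,
            "history": history,
            "report": report,
            "mass_ratio": float(np.mean(masses)) / baseline,
            "test_ds": test_ds,
        })
    return results
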