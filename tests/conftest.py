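import numpy as np
import pytest

from dceseg import (
    DynamicSeries,
    PhantomSpec,
    build_training_table,
    make_dataset,
    noiseless_archetypes,
    train_cascade,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_series(rng):
    """A random 6x5x3x65 dynamic series with positive intensities."""
    data = rng.uniform(50.0, 200.0, size=(6, 5, 3, 65))
    return DynamicSeries(data, n_pre=8)


@pytest.fixture(scope="session")
def noiseless_setup():
    """A tiny noiseless phantom world: train/test samples, table, model.

    Session-scoped because the cascade grid search is the slow part and the
    fixture is read-only.
    """
    spec = PhantomSpec(noise_sd_rel=0.0)
    train, test = make_dataset(
        6, 3, spec=spec, seed=7, archetypes=noiseless_archetypes(), vary_samples=False
    )
    table, basis = build_training_table((s.series, s.train_rois) for s in train)
    model = train_cascade(table, basis)
    return {"train": train, "test": test, "table": table, "basis": basis, "model": model}
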