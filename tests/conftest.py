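"""Shared fixtures: session-scoped synthetic datasets of the toy model.

Problem sizes are chosen so that Monte-Carlo noise sits well inside the
asserted tolerances (see docs/methods.md); seeds are fixed for determinism.
"""

import numpy as np
import pytest

from evbkit import (
    HarmonicDiabatModel,
    SamplingSpec,
    generate_dataset,
)


@pytest.fixture(scope="session")
def sym_model():
    """Symmetric charge-transfer preset: lambda_reorg = 148, crossing 37 kcal/mol."""
    return HarmonicDiabatModel.symmetric()


@pytest.fixture(scope="session")
def asym_model():
    """k2 = 2 k1 preset with h12 = 20: nonzero reaction entropy -(R/2) ln 2."""
    return HarmonicDiabatModel.asymmetric()


@pytest.fixture(scope="session")
def sym_windows_300(sym_model):
    """One replicate of the symmetric model at 300 K (21 windows)."""
    spec = SamplingSpec(
        temperatures=(300.0,), n_steps=60_000, n_burnin=6_000,
        n_replicates=1, seed=2026,
    )
    ds = generate_dataset(sym_model, spec)
    return ds.select(temperature=300.0, replicate=0)


@pytest.fixture(scope="session")
def sym_dataset_multi_t(sym_model):
    """Symmetric model over the full 280-320 K grid at the default chain length."""
    spec = SamplingSpec(n_steps=200_000, n_burnin=20_000, n_replicates=1, seed=4242)
    return generate_dataset(sym_model, spec)


@pytest.fixture(scope="session")
def asym_dataset(asym_model):
    """Asymmetric preset, 5 temperatures x 3 replicates (invariance-study size)."""
    spec = SamplingSpec(n_steps=150_000, n_burnin=15_000, n_replicates=3, seed=777)
    return generate_dataset(asym_model, spec)


def batch_sem(values, n_batches=50):
    """Standard error of the mean of a correlated series, by batch means."""
    values = np.asarray(values)
    usable = (len(values) // n_batches) * n_batches
    batches = values[:usable].reshape(n_batches, -1).mean(axis=1)
    return batches.std(ddof=1) / np.sqrt(n_batches)
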