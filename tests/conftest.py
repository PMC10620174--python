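"""Shared fixtures: small random lesion tables and a session-scoped default
synthetic cohort with its trained dual AD-AE (reused by the slower
end-to-end tests so the network is trained once per session)."""

import numpy as np
import pandas as pd
import pytest

from cloudharmony import (
    LesionTable,
    SimulationConfig,
    TrainingConfig,
    generate_cohort,
    standardize,
)
from cloudharmony.adae import ArchitectureSpec, init_model, train, encode


def random_lesion_table(
    n_patients: int = 5,
    lesions_per_patient: int = 3,
    d: int = 6,
    n_centers: int = 2,
    seed: int = 0,
) -> LesionTable:
    """Small random but structurally valid table for unit tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_patients):
        center = f"C{p % n_centers + 1}"
        scanner = f"S{p % n_centers + 1}"
        for l in range(lesions_per_patient):
            rows.append(
                [f"P{p}_L{l}", f"P{p}", center, scanner, *rng.standard_normal(d)]
            )
    cols = ["lesion_id", "patient_id", "center", "scanner"] + [f"f{i}" for i in range(1, d + 1)]
    return LesionTable(pd.DataFrame(rows, columns=cols))


@pytest.fixture
def small_table() -> LesionTable:
    return random_lesion_table()


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort, standardized, with survival and truth."""
    clean, confounded, survival, truth = generate_cohort(SimulationConfig(seed=1))
    std, params = standardize(confounded)
    return {
        "clean": clean,
        "confounded": confounded,
        "std": std,
        "survival": survival,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def trained_adae(default_cohort):
    """Dual AD-AE trained once on the standardized default cohort."""
    std = default_cohort["std"]
    model = init_model(ArchitectureSpec.for_data(std.d, 2, 5), 42)
    trained = train(model, std, TrainingConfig(seed=42))
    return {"model": trained, "embeddings": encode(trained, std)}
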