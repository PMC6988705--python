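import numpy as np
import pandas as pd
import pytest

from craniomirror.geometry import LandmarkConfiguration, feature_table
from craniomirror.schemes import (LandmarkScheme, human_face_scheme,
                                  rodent_dorsal_scheme)
from craniomirror.simulate import default_human_spec, generate_human_cohort


@pytest.fixture(scope="session")
def human_scheme():
    return human_face_scheme()


@pytest.fixture(scope="session")
def rodent_scheme():
    return rodent_dorsal_scheme()


@pytest.fixture(scope="session")
def human_cohort():
    """One default synthetic human cohort, shared across tests."""
    return generate_human_cohort(default_human_spec(seed=11))


@pytest.fixture(scope="session")
def human_features(human_cohort):
    return feature_table(human_cohort.configs, human_cohort.scheme)


def random_configuration(scheme: LandmarkScheme, rng, scale=30.0,
                         subject_id="s") -> LandmarkConfiguration:
    """A generic (asymmetric) configuration over a scheme's labels."""
    return LandmarkConfiguration(
        subject_id=subject_id,
        coords={lab: rng.normal(0, scale, 3) for lab in scheme.labels},
    )


def generic_scheme(m: int, p: int) -> LandmarkScheme:
    """A scheme with m midline landmarks and p bilateral pairs."""
    landmarks = (
        [(f"L{i}", "left") for i in range(p)]
        + [(f"R{i}", "right") for i in range(p)]
        + [(f"M{i}", "midline") for i in range(m)]
    )
    return LandmarkScheme(
        name=f"gen_{m}_{p}", landmarks=tuple(landmarks),
        pairing={f"L{i}": f"R{i}" for i in range(p)},
    )


def synthetic_covariates(rng, n=200, n_fam=60, p_carrier=0.33,
                         contrast="DEL"):
    """Minimal covariate table for mixed-model simulations."""
    fam = rng.integers(0, n_fam, n)
    return pd.DataFrame({
        "genotype": np.where(rng.random(n) < p_carrier, contrast, "CTRL"),
        "age": rng.uniform(3, 50, n),
        "sex": np.where(rng.random(n) < 0.5, "M", "F"),
        "head_circumference": 50 + rng.normal(0, 2, n),
        "bmi": 20 + rng.normal(0, 3, n),
        "PC1": rng.normal(size=n),
        "PC2": rng.normal(size=n),
        "family_id": [f"F{i}" for i in fam],
    }), fam
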