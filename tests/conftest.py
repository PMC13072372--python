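import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import rabi

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

GENERALIST = "wide-range generalist"


@pytest.fixture
def scheme():
    return rabi.DEFAULT_SCHEME


@pytest.fixture
def worked_site_traits():
    """Four widespread least-concern species whose indices are 1, 2, 1, 2."""
    return [
        rabi.SpeciesTraits("Amietia nutti", 5, False, "LC", GENERALIST),
        rabi.SpeciesTraits("Hyperolius glandicolor", 2, False, "LC", GENERALIST),
        rabi.SpeciesTraits("Sclerophrys gutturalis", 4, False, "LC", GENERALIST),
        rabi.SpeciesTraits("Sclerophrys kisoloensis", 3, False, "LC", GENERALIST),
    ]


@pytest.fixture
def inselberg_matrix(worked_site_traits):
    """One-site assemblage containing exactly the four worked-example species."""
    species = [t.species_id for t in worked_site_traits]
    frame = pd.DataFrame([[1] * len(species)], index=["site10"], columns=species)
    return rabi.OccurrenceMatrix(frame, {"site10": "EZ3"})


@pytest.fixture
def toy_matrix():
    """Hand-built 5-site x 6-species matrix over three ecozones.

    Zone species sets: Z1 = {s1, s2, s5}, Z2 = {s1, s3, s5, s6},
    Z3 = {s3, s4}; unique species: s2 (Z1), s6 (Z2), s4 (Z3).
    """
    frame = pd.DataFrame(
        [
            [1, 1, 0, 0, 0, 0],  # a1
            [1, 0, 0, 0, 1, 0],  # a2
            [1, 0, 1, 0, 0, 0],  # b1
            [0, 0, 1, 0, 1, 1],  # b2
            [0, 0, 1, 1, 0, 0],  # c1
        ],
        index=["a1", "a2", "b1", "b2", "c1"],
        columns=["s1", "s2", "s3", "s4", "s5", "s6"],
    )
    zones = {"a1": "Z1", "a2": "Z1", "b1": "Z2", "b2": "Z2", "c1": "Z3"}
    return rabi.OccurrenceMatrix(frame, zones)


def random_traits(rng: np.random.Generator, species_ids, scheme=rabi.DEFAULT_SCHEME):
    """Uniformly random valid trait records, for oracle-equivalence checks."""
    sens_labels = [lbl for lbl, _ in scheme.sbs_levels]
    cats = sorted(scheme.tbs_scores)
    out = []
    for sp in species_ids:
        occupancy = int(rng.integers(1, scheme.n_ecozones + 1))
        zones = frozenset(
            rng.choice(scheme.ecozone_labels, size=occupancy, replace=False)
        )
        endemic = occupancy == 1 and bool(rng.random() < 0.3)
        out.append(
            rabi.SpeciesTraits(
                sp,
                zones,
                endemic,
                str(rng.choice(cats)),
                str(rng.choice(sens_labels)),
            )
        )
    return out


def random_matrix(rng: np.random.Generator, n_sites, n_species, n_zones=3):
    sites = [f"st{i}" for i in range(n_sites)]
    species = [f"sp{i}" for i in range(n_species)]
    presence = rng.random((n_sites, n_species)) < 0.4
    zones = {s: f"EZ{int(rng.integers(1, n_zones + 1))}" for s in sites}
    frame = pd.DataFrame(presence, index=sites, columns=species)
    return rabi.OccurrenceMatrix(frame, zones)
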