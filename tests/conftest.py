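"""Shared fixtures: a seeded synthetic study and partition oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from strainteract import SimConfig, classify_at_threshold
from strainteract.simulate import (
    gen_amino_profiles,
    gen_ani_matrix,
    gen_design,
    gen_growth,
    gen_pathway_map,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def noise_free_config() -> SimConfig:
    return SimConfig(seed=1, growth_noise_sd=0.0, concentration_noise_cv=0.0)


@pytest.fixture(scope="session")
def study(sim_config):
    """One complete synthetic study shared across tests (seed 1)."""
    design = gen_design(sim_config)
    biomass = gen_growth(design, sim_config)
    amino, transcription = gen_amino_profiles(sim_config)
    return {
        "config": sim_config,
        "ani": gen_ani_matrix(sim_config),
        "design": design,
        "biomass": biomass,
        "amino": amino,
        "transcription": transcription,
        "pathway": gen_pathway_map(sim_config),
    }


@pytest.fixture(scope="session")
def scheme_995(study):
    return classify_at_threshold(study["ani"], 99.5)


def oracle_partition(values: np.ndarray, threshold: float) -> tuple[int, ...]:
    """Brute-force single-linkage oracle: transitive closure of the >=t relation.

    Independent of the production implementation: reachability is computed
    by iterated boolean matrix products; labels are canonicalised by first
    appearance so partitions compare as tuples.
    """
    adj = values >= threshold
    np.fill_diagonal(adj, True)
    reach = adj.copy()
    for _ in range(values.shape[0]):
        new = reach | (reach @ reach)
        if (new == reach).all():
            break
        reach = new
    raw = [int(np.flatnonzero(reach[i])[0]) for i in range(values.shape[0])]
    seen: dict[int, int] = {}
    return tuple(seen.setdefault(r, len(seen)) for r in raw)


def partition_tuple(assignment: dict[str, int], isolates) -> tuple[int, ...]:
    return tuple(assignment[i] for i in isolates)
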