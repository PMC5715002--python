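from __future__ import annotations

import numpy as np
import pytest

from pollinet import (
    CommunitySpec,
    ContaminationSpec,
    InteractionMatrix,
    generate_truth,
    simulate_pollen_loads,
    simulate_visits,
)


def im(
    values,
    level: str = "species",
    provenance: str = "obs",
    threshold: int | None = None,
) -> InteractionMatrix:
    """Build an InteractionMatrix with generated labels."""
    values = np.asarray(values)
    return InteractionMatrix(
        values=values,
        plant_labels=tuple(f"P{i}" for i in range(values.shape[0])),
        pollinator_labels=tuple(f"A{j}" for j in range(values.shape[1])),
        level=level,
        provenance=provenance,
        threshold=threshold,
    )


def random_count_matrix(rng: np.random.Generator, max_dim: int = 8) -> InteractionMatrix:
    """A random pruned count matrix with at least one link."""
    while True:
        p = int(rng.integers(2, max_dim + 1))
        a = int(rng.integers(2, max_dim + 1))
        vals = rng.poisson(1.2, size=(p, a))
        m = im(vals).pruned()
        if m.n_plants >= 2 and m.n_pollinators >= 2:
            return m


SMALL_KW = dict(
    n_plant_species=30,
    n_insect_species=25,
    n_insect_individuals=150,
    seed=7,
)


@pytest.fixture(scope="session")
def small_world():
    """A reduced community with contamination, shared across tests."""
    spec = CommunitySpec(**SMALL_KW)
    cont = ContaminationSpec()
    truth = generate_truth(spec)
    visits = simulate_visits(truth)
    counts = simulate_pollen_loads(truth, spec, cont)
    return {
        "spec": spec,
        "cont": cont,
        "truth": truth,
        "visits": visits,
        "counts": counts,
        "registry": truth.registry(cont),
    }


@pytest.fixture(scope="session")
def study_world():
    """The default study-scale scenario (402 captured individuals)."""
    spec = CommunitySpec(seed=11)
    cont = ContaminationSpec()
    truth = generate_truth(spec)
    visits = simulate_visits(truth)
    counts = simulate_pollen_loads(truth, spec, cont)
    return {
        "spec": spec,
        "cont": cont,
        "truth": truth,
        "visits": visits,
        "counts": counts,
        "registry": truth.registry(cont),
    }
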