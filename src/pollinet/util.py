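"""Small shared helpers."""

from __future__ import annotations

import numpy as np

from .matrix import InteractionMatrix


def bipartite_from_degrees(
    plant_degrees: list[int],
    pollinator_degrees: list[int],
    provenance: str = "obs",
) -> InteractionMatrix:
    """Realize a binary bipartite matrix with the given degree sequences.

    Greedy Gale-Ryser style construction: pollinators are processed from
    highest to lowest degree and connected to the plants with the most
    remaining stubs.  Raises if the sequences are not graphical as a
    simple bipartite graph.  Useful for reconstructing a network with
    published dimensions, link count and single-partner counts.
    """
    pd_ = np.asarray(plant_degrees, dtype=np.int64)
    ad = np.asarray(pollinator_degrees, dtype=np.int64)
    if pd_.sum() != ad.sum():
        raise ValueError("degree sequences must have equal sums")
    B = np.zeros((pd_.size, ad.size), dtype=np.int64)
    remaining = pd_.copy()
    for j in np.argsort(-ad, kind="stable"):
        k = int(ad[j])
        targets = np.argsort(-remaining, kind="stable")[:k]
        if k > 0 and remaining[targets[-1]] <= 0:
            raise ValueError("degree sequences are not bipartite-graphical")
        B[targets, j] = 1
        remaining[targets] -= 1
    if (remaining != 0).any():
        raise ValueError("degree sequences are not bipartite-graphical")
    return InteractionMatrix(
        values=B,
        plant_labels=tuple(f"plant_{i + 1:03d}" for i in range(pd_.size)),
        pollinator_labels=tuple(f"insect_{j + 1:03d}" for j in range(ad.size)),
        level="species",
        provenance=provenance,
    )
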