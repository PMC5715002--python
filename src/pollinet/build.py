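"""Construction of bipartite interaction matrices from raw tables.

Two entry points produce individual-level binary matrices: one from the
visit survey (every captured insect contributes the single visit it was
captured on) and one from the metabarcoding read-count table, where a
link is called when a plant's read count strictly exceeds a threshold
(default 1,000 reads).  Wind-pollinated taxa and taxa resolved above
genus are removed before thresholding, and insects with no
super-threshold plant are dropped from the sequence-based matrix.

Individual-level matrices are then aggregated to species level (cell =
number of linked individuals) or group level (plants collapsed to the
four floral-morphology groups, insects to the nine functional groups).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import InteractionMatrix, MatrixError, TaxonRegistry

DEFAULT_THRESHOLD = 1000

VISIT_COLUMNS = ("individual_id", "insect_species", "insect_group", "plant_taxon")


def _validate_counts(counts: pd.DataFrame, registry: TaxonRegistry) -> None:
    if counts.empty:
        raise MatrixError("empty sequence-count table")
    vals = counts.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise MatrixError("sequence counts must be numeric")
    if (vals < 0).any():
        bad = counts.columns[np.argwhere(vals < 0)[0][1]]
        raise MatrixError(f"negative read count in column {bad!r}")
    unknown = set(counts.columns) - set(registry.plants.index)
    if unknown:
        raise MatrixError(f"taxa absent from registry: {sorted(unknown)}")


def call_interactions(
    seq_table: pd.DataFrame,
    registry: TaxonRegistry,
    threshold: int = DEFAULT_THRESHOLD,
    extra_marker_tables: tuple[pd.DataFrame, ...] = (),
) -> InteractionMatrix:
    """Call individual-level links from read counts by strict thresholding.

    A link plant-*i* / insect-*j* is called when the read count of taxon
    *i* in the pollen load of individual *j* is strictly greater than
    ``threshold``.  When counts from several markers are supplied (e.g.
    trnL and ITS1 as separate tables in ``extra_marker_tables``), a link
    is called if **either** marker exceeds the threshold; counts are
    never summed across markers.

    Wind-pollinated taxa and taxa of rank above genus are removed before
    thresholding, and insects left without any super-threshold plant are
    excluded from the matrix.
    """
    if threshold < 0:
        raise MatrixError("threshold must be non-negative")
    _validate_counts(seq_table, registry)
    keep_taxa = [t for t in seq_table.columns if t in set(registry.network_plants())]
    present = seq_table[keep_taxa].to_numpy() > threshold
    for other in extra_marker_tables:
        _validate_counts(other, registry)
        aligned = other.reindex(index=seq_table.index, columns=keep_taxa).fillna(0)
        present |= aligned.to_numpy() > threshold
    frame = pd.DataFrame(
        present.astype(np.int64), index=seq_table.index, columns=keep_taxa
    )
    matrix = InteractionMatrix.from_frame(
        frame.T, level="individual", provenance="seq", threshold=threshold
    )
    return matrix.pruned()


def build_obs_matrix(visits: pd.DataFrame) -> InteractionMatrix:
    """Build the individual-level binary matrix from the visit survey.

    Rows from all communities are merged; each (plant, individual) pair
    observed at least once becomes a link.
    """
    if visits is None or len(visits) == 0:
        raise MatrixError("empty visit table")
    missing = set(VISIT_COLUMNS) - set(visits.columns)
    if missing:
        raise MatrixError(f"visit table missing columns {sorted(missing)}")
    cross = pd.crosstab(visits["plant_taxon"], visits["individual_id"])
    binary = (cross > 0).astype(np.int64)
    # keep individuals in first-appearance order, plants in taxon order
    ind_order = list(dict.fromkeys(visits["individual_id"]))
    binary = binary[ind_order]
    return InteractionMatrix.from_frame(
        binary, level="individual", provenance="obs"
    ).pruned()


def aggregate(
    matrix: InteractionMatrix,
    registry: TaxonRegistry,
    level: str,
) -> InteractionMatrix:
    """Aggregate an individual-level matrix to species or group level.

    At species level the cell (plant, insect species) counts the linked
    individuals of that species, so link counts become interaction
    frequencies.  At group level plants are additionally collapsed to
    their floral-morphology group and insects to their functional group.
    Totals are conserved in both cases.
    """
    if matrix.level != "individual":
        raise MatrixError("aggregation starts from an individual-level matrix")
    if level not in ("species", "group"):
        raise MatrixError(f"unknown aggregation level {level!r}")
    frame = matrix.to_frame()
    try:
        sp = [registry.species_of(ind) for ind in frame.columns]
    except KeyError as exc:
        raise MatrixError(f"individual {exc.args[0]!r} absent from registry") from exc
    out = frame.T.groupby(pd.Index(sp, name="species")).sum().T
    if level == "group":
        try:
            gr = [registry.group_of(s) for s in out.columns]
        except KeyError as exc:
            raise MatrixError(
                f"insect species {exc.args[0]!r} absent from registry"
            ) from exc
        out = out.T.groupby(pd.Index(gr, name="group")).sum().T
        try:
            morph = [registry.morph_of(t) for t in out.index]
        except KeyError as exc:
            raise MatrixError(f"plant {exc.args[0]!r} absent from registry") from exc
        out = out.groupby(pd.Index(morph, name="morph_group")).sum()
    return InteractionMatrix.from_frame(
        out, level=level, provenance=matrix.provenance, threshold=matrix.threshold
    ).pruned()


def per_species_individual_matrices(
    matrix: InteractionMatrix,
    registry: TaxonRegistry,
    min_individuals: int = 10,
) -> list[InteractionMatrix]:
    """Split an individual-level matrix into per-insect-species matrices.

    One matrix is returned for each insect species represented by at
    least ``min_individuals`` individuals in ``matrix``, restricted to
    the plants that species contacts.  Species are returned from most to
    least abundant.  At study scale (402 captured individuals) the
    default cutoff selects on the order of the eleven most abundant
    species.
    """
    if matrix.level != "individual":
        raise MatrixError("per-species split starts from an individual-level matrix")
    species = pd.Series(
        [registry.species_of(ind) for ind in matrix.pollinator_labels],
        index=list(matrix.pollinator_labels),
    )
    sizes = species.value_counts()
    out: list[InteractionMatrix] = []
    for sp in sizes[sizes >= min_individuals].index:
        cols = [c for c in matrix.pollinator_labels if species[c] == sp]
        out.append(matrix.subset(pollinators=cols).pruned())
    return out


@dataclass(frozen=True)
class ContaminationProfile:
    """Summary of grass background reads in a sequence-count table.

    Fractions are over all insects in the table; ``frac_below_100``
    is cumulative (it includes the zero-read insects).  Two removal
    measures are reported: ``reads_removed`` is the fraction of the total
    grass read volume sitting in sub-threshold cells, and
    ``insects_cleared`` the fraction of insects whose grass signal falls
    entirely below the threshold (i.e. carries no super-threshold grass
    link).  Both are ``None`` when the table contains no grass reads.
    """

    n_insects: int
    frac_zero: float
    frac_below_100: float
    frac_above_threshold: float
    reads_removed: float | None
    insects_cleared: float | None
    threshold: int


def contamination_profile(
    seq_table: pd.DataFrame,
    registry: TaxonRegistry,
    threshold: int = DEFAULT_THRESHOLD,
) -> ContaminationProfile:
    """Profile grass background contamination and its removal by thresholding."""
    _validate_counts(seq_table, registry)
    grass_taxa = [t for t in seq_table.columns if t in set(registry.wind_taxa())]
    n = len(seq_table)
    if not grass_taxa or n == 0:
        return ContaminationProfile(
            n_insects=n,
            frac_zero=0.0,
            frac_below_100=0.0,
            frac_above_threshold=0.0,
            reads_removed=None,
            insects_cleared=None,
            threshold=threshold,
        )
    grass = seq_table[grass_taxa].to_numpy()
    totals = grass.sum(axis=1)
    frac_zero = float((totals == 0).mean())
    frac_below = float((totals < 100).mean())
    frac_above = float((totals > threshold).mean())
    grand = grass.sum()
    if grand == 0:
        reads_removed = None
        insects_cleared = None
    else:
        super_cells = grass > threshold
        reads_removed = float(1.0 - grass[super_cells].sum() / grand)
        insects_cleared = float(1.0 - (super_cells.any(axis=1)).mean())
    return ContaminationProfile(
        n_insects=n,
        frac_zero=frac_zero,
        frac_below_100=frac_below,
        frac_above_threshold=frac_above,
        reads_removed=reads_removed,
        insects_cleared=insects_cleared,
        threshold=threshold,
    )


def threshold_sensitivity(
    seq_table: pd.DataFrame,
    registry: TaxonRegistry,
    thresholds: list[int],
) -> pd.DataFrame:
    """Re-call interactions at each threshold and tabulate network size.

    Returns one row per threshold with the number of links, plants and
    insects retained.  Link counts are non-increasing in the threshold.
    """
    if any(t < 0 for t in thresholds):
        raise MatrixError("thresholds must be non-negative")
    rows = []
    for t in thresholds:
        try:
            m = call_interactions(seq_table, registry, threshold=t)
            rows.append(
                {
                    "threshold": t,
                    "n_links": m.n_links,
                    "n_plants": m.n_plants,
                    "n_insects": m.n_pollinators,
                }
            )
        except MatrixError:
            rows.append(
                {"threshold": t, "n_links": 0, "n_plants": 0, "n_insects": 0}
            )
    return pd.DataFrame(rows)
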