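"""Core containers for bipartite plant-pollinator interaction data.

An :class:`InteractionMatrix` is the central object of the package: a
plant x pollinator matrix of non-negative integer link weights, oriented
plants-in-rows / pollinators-in-columns throughout, tagged with the
resolution level at which it was built (``individual``, ``species`` or
``group``) and the provenance of the underlying data (``obs`` for direct
visit surveys, ``seq`` for thresholded pollen-metabarcoding read counts).

A :class:`TaxonRegistry` holds the side information needed to filter and
aggregate matrices: plant taxonomic rank, pollination mode and floral
morphology group, plus the insect species -> functional-group mapping and
the captured-individual -> species mapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

LEVELS = ("individual", "species", "group")
PROVENANCES = ("obs", "seq")

#: the four floral-morphology groups, ordered by reward accessibility
#: (zygomorphic most restrictive, open actinomorphic least restrictive)
MORPH_GROUPS = ("zygomorphic", "tubular", "ligulate", "actinomorphic")

#: the nine pollinator functional groups used at the group-group level
INSECT_GROUPS = (
    "Apis mellifera",
    "bumblebees",
    "wild bees",
    "other Hymenoptera",
    "Syrphidae",
    "Empididae",
    "other Diptera",
    "Coleoptera",
    "Lepidoptera",
)

PLANT_RANKS = ("species", "genus", "higher")
POLLINATION_MODES = ("insect", "wind")


class MatrixError(ValueError):
    """Raised when an interaction matrix violates a structural invariant."""


@dataclass(frozen=True)
class InteractionMatrix:
    """Bipartite plant x pollinator matrix of non-negative link weights.

    Parameters
    ----------
    values
        2-D integer array, plants in rows, pollinators in columns.
    plant_labels, pollinator_labels
        Unique ordered names for rows and columns.
    level
        Resolution level: ``individual``, ``species`` or ``group``.
    provenance
        ``obs`` (visit survey) or ``seq`` (metabarcoding).
    threshold
        Read-count threshold used during interaction calling, or ``None``
        for matrices not derived from sequence counts.
    """

    values: np.ndarray
    plant_labels: tuple[str, ...]
    pollinator_labels: tuple[str, ...]
    level: str
    provenance: str
    threshold: int | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 2:
            raise MatrixError("values must be a 2-D array")
        if not np.issubdtype(vals.dtype, np.integer):
            if np.any(vals != np.round(vals)):
                raise MatrixError("link weights must be integers")
            vals = vals.astype(np.int64)
        if np.any(vals < 0):
            raise MatrixError("link weights must be non-negative")
        object.__setattr__(self, "values", np.ascontiguousarray(vals, dtype=np.int64))
        object.__setattr__(self, "plant_labels", tuple(map(str, self.plant_labels)))
        object.__setattr__(
            self, "pollinator_labels", tuple(map(str, self.pollinator_labels))
        )
        if vals.shape != (len(self.plant_labels), len(self.pollinator_labels)):
            raise MatrixError(
                f"shape {vals.shape} does not match labels "
                f"({len(self.plant_labels)} plants, "
                f"{len(self.pollinator_labels)} pollinators)"
            )
        if len(set(self.plant_labels)) != len(self.plant_labels):
            raise MatrixError("duplicate plant labels")
        if len(set(self.pollinator_labels)) != len(self.pollinator_labels):
            raise MatrixError("duplicate pollinator labels")
        if self.level not in LEVELS:
            raise MatrixError(f"level must be one of {LEVELS}, got {self.level!r}")
        if self.provenance not in PROVENANCES:
            raise MatrixError(
                f"provenance must be one of {PROVENANCES}, got {self.provenance!r}"
            )

    # -- basic geometry -------------------------------------------------

    @property
    def n_plants(self) -> int:
        """P, the number of plant rows."""
        return self.values.shape[0]

    @property
    def n_pollinators(self) -> int:
        """A, the number of pollinator columns."""
        return self.values.shape[1]

    @property
    def total(self) -> int:
        """F, the grand total of link weights."""
        return int(self.values.sum())

    @property
    def n_links(self) -> int:
        """I, the number of non-zero cells (realized links)."""
        return int(np.count_nonzero(self.values))

    @property
    def binary(self) -> np.ndarray:
        """Boolean presence/absence view of the matrix."""
        return self.values > 0

    # -- transformations -------------------------------------------------

    def pruned(self) -> "InteractionMatrix":
        """Return a copy with all-zero rows and columns removed."""
        keep_r = self.values.sum(axis=1) > 0
        keep_c = self.values.sum(axis=0) > 0
        return replace(
            self,
            values=self.values[np.ix_(keep_r, keep_c)],
            plant_labels=tuple(np.array(self.plant_labels)[keep_r]),
            pollinator_labels=tuple(np.array(self.pollinator_labels)[keep_c]),
        )

    def subset(
        self,
        plants: list[str] | None = None,
        pollinators: list[str] | None = None,
    ) -> "InteractionMatrix":
        """Restrict to the given plant/pollinator labels (order preserved)."""
        ridx = (
            [self.plant_labels.index(p) for p in plants]
            if plants is not None
            else list(range(self.n_plants))
        )
        cidx = (
            [self.pollinator_labels.index(a) for a in pollinators]
            if pollinators is not None
            else list(range(self.n_pollinators))
        )
        return replace(
            self,
            values=self.values[np.ix_(ridx, cidx)],
            plant_labels=tuple(self.plant_labels[i] for i in ridx),
            pollinator_labels=tuple(self.pollinator_labels[j] for j in cidx),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.plant_labels, name="plant"),
            columns=pd.Index(self.pollinator_labels, name="pollinator"),
        )

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        level: str,
        provenance: str,
        threshold: int | None = None,
    ) -> "InteractionMatrix":
        return cls(
            values=frame.to_numpy(),
            plant_labels=tuple(map(str, frame.index)),
            pollinator_labels=tuple(map(str, frame.columns)),
            level=level,
            provenance=provenance,
            threshold=threshold,
        )

    # -- persistence -----------------------------------------------------

    def write_tsv(self, path: str | Path) -> None:
        """Write the matrix as labelled TSV plus a JSON metadata sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "level": self.level,
                    "provenance": self.provenance,
                    "threshold": self.threshold,
                    "n_plants": self.n_plants,
                    "n_pollinators": self.n_pollinators,
                    "n_links": self.n_links,
                    "total": self.total,
                },
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "InteractionMatrix":
        path = Path(path)
        frame = pd.read_csv(path, sep="\t", index_col=0)
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text())
        return cls.from_frame(
            frame,
            level=meta["level"],
            provenance=meta["provenance"],
            threshold=meta["threshold"],
        )


@dataclass
class TaxonRegistry:
    """Side information about plant taxa and insects.

    ``plants`` is indexed by taxon name with columns ``rank``
    (species/genus/higher), ``pollination_mode`` (insect/wind),
    ``morph_group`` (one of the four morphology groups, or ``none`` for
    wind-pollinated taxa) and ``on_site`` (bool).  ``insects`` maps insect
    species to their functional group; ``individuals`` maps captured
    insect individuals to their species.
    """

    plants: pd.DataFrame
    insects: pd.DataFrame = field(default_factory=pd.DataFrame)
    individuals: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"rank", "pollination_mode", "morph_group", "on_site"}
        missing = required - set(self.plants.columns)
        if missing:
            raise MatrixError(f"plant registry missing columns {sorted(missing)}")
        bad_rank = set(self.plants["rank"]) - set(PLANT_RANKS)
        if bad_rank:
            raise MatrixError(f"unknown plant ranks {sorted(bad_rank)}")
        bad_mode = set(self.plants["pollination_mode"]) - set(POLLINATION_MODES)
        if bad_mode:
            raise MatrixError(f"unknown pollination modes {sorted(bad_mode)}")
        insect = self.plants["pollination_mode"] == "insect"
        bad_morph = set(self.plants.loc[insect, "morph_group"]) - set(MORPH_GROUPS)
        if bad_morph:
            raise MatrixError(f"unknown morphology groups {sorted(bad_morph)}")

    # -- lookups ----------------------------------------------------------

    def wind_taxa(self) -> list[str]:
        return list(self.plants.index[self.plants["pollination_mode"] == "wind"])

    def network_plants(self) -> list[str]:
        """Taxa eligible for networks: insect-pollinated, rank <= genus."""
        keep = (self.plants["pollination_mode"] == "insect") & (
            self.plants["rank"].isin(["species", "genus"])
        )
        return list(self.plants.index[keep])

    def morph_of(self, taxon: str) -> str:
        return str(self.plants.at[taxon, "morph_group"])

    def species_of(self, individual: str) -> str:
        return str(self.individuals.at[individual, "species"])

    def group_of(self, species: str) -> str:
        return str(self.insects.at[species, "group"])

    # -- persistence -------------------------------------------------------

    def write_tsv(self, path: str | Path) -> None:
        """Write the plant registry TSV (taxon, rank, mode, morph, on_site)."""
        out = self.plants.reset_index()
        out.columns = ["taxon", "rank", "pollination_mode", "morph_group", "on_site"]
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(
        cls, path: str | Path, visits: pd.DataFrame | None = None
    ) -> "TaxonRegistry":
        """Load the plant registry; insect mappings come from a visit table."""
        plants = pd.read_csv(path, sep="\t", dtype={"on_site": bool})
        plants = plants.set_index("taxon")
        insects = pd.DataFrame()
        individuals = pd.DataFrame()
        if visits is not None:
            insects = (
                visits[["insect_species", "insect_group"]]
                .drop_duplicates()
                .rename(columns={"insect_group": "group"})
                .set_index("insect_species")
            )
            individuals = (
                visits[["individual_id", "insect_species"]]
                .drop_duplicates()
                .rename(columns={"insect_species": "species"})
                .set_index("individual_id")
            )
        return cls(plants=plants, insects=insects, individuals=individuals)
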