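"""Synthetic paired visit-survey / pollen-metabarcoding data generator.

The generator emulates a subalpine heathland pollination study: a skewed
(lognormal rank-abundance) plant community with four floral-morphology
groups, nine insect functional groups with group-structured floral
preferences (bees concentrate on zygomorphic flowers, hoverflies on open
actinomorphic ones), one recorded visit per captured insect individual,
and a pollen load that accumulates over a latent multi-visit foraging
history.  Wind-pollinated grasses contribute a low-level airborne
background read count to most insects.

Both outputs share a common ground truth so that every downstream stage
(interaction calling, aggregation, indices, null models, rarefaction)
can be tested against known structure.  All randomness flows through
per-stage :class:`numpy.random.Generator` streams derived from a single
seed, so a fixed seed reproduces both tables bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import INSECT_GROUPS, MORPH_GROUPS, TaxonRegistry

# independent sub-streams per generation stage; the capture stream is
# shared by simulate_visits and simulate_pollen_loads so the recorded
# visit is the first entry of the latent foraging history
_STAGE_TRUTH = 1
_STAGE_CAPTURE = 2
_STAGE_VISITS = 3
_STAGE_POLLEN = 4

#: share of captured individuals per insect group (Diptera dominate the
#: assemblage, with Empididae and Syrphidae the two most abundant
#: families; bumblebees are the main bee contingent)
DEFAULT_GROUP_WEIGHTS: dict[str, float] = {
    "Apis mellifera": 0.04,
    "bumblebees": 0.26,
    "wild bees": 0.08,
    "other Hymenoptera": 0.05,
    "Syrphidae": 0.20,
    "Empididae": 0.24,
    "other Diptera": 0.05,
    "Coleoptera": 0.05,
    "Lepidoptera": 0.03,
}

#: visit propensity of each insect group toward each floral-morphology
#: group (rows sum to 1).  Bees put most mass on zygomorphic flowers;
#: hoverflies (Syrphidae) prefer open actinomorphic/ligulate flowers;
#: empidids split between zygomorphic and actinomorphic flowers.
DEFAULT_GROUP_PREFERENCES = pd.DataFrame(
    [
        [0.70, 0.10, 0.05, 0.15],  # Apis mellifera
        [0.72, 0.10, 0.04, 0.14],  # bumblebees
        [0.65, 0.10, 0.08, 0.17],  # wild bees
        [0.35, 0.15, 0.15, 0.35],  # other Hymenoptera
        [0.07, 0.08, 0.25, 0.60],  # Syrphidae
        [0.45, 0.08, 0.07, 0.40],  # Empididae
        [0.15, 0.10, 0.20, 0.55],  # other Diptera
        [0.10, 0.10, 0.25, 0.55],  # Coleoptera
        [0.30, 0.40, 0.10, 0.20],  # Lepidoptera
    ],
    index=list(INSECT_GROUPS),
    columns=list(MORPH_GROUPS),
)


@dataclass
class CommunitySpec:
    """Parameters of the simulated plant-pollinator community.

    Defaults are sized to the field study being emulated: 402 captured
    insect individuals sampled from four merged heathland communities,
    a plant pool large enough that a sizeable minority of pollen taxa
    grow outside the surveyed plots, and strongly skewed ("few abundant,
    many rare") abundance distributions on both sides.
    """

    n_plant_species: int = 90
    n_insect_species: int = 110
    n_insect_individuals: int = 402
    #: sigma of the lognormal plant rank-abundance curve
    plant_abundance_shape: float = 2.5
    #: sigma of the lognormal insect-species abundance curve
    insect_abundance_shape: float = 1.2
    group_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_WEIGHTS)
    )
    group_preference_matrix: pd.DataFrame = field(
        default_factory=lambda: DEFAULT_GROUP_PREFERENCES.copy()
    )
    #: relative frequency of the four morphology groups among plants
    morph_weights: tuple[float, ...] = (0.30, 0.15, 0.20, 0.35)
    #: proportion of plant taxa growing outside the surveyed plots
    #: (reachable by foraging insects but never recorded in the survey)
    off_site_fraction: float = 0.5
    n_communities: int = 4
    #: mean number of latent foraging visits beyond the capture visit;
    #: history length is 1 + Poisson(extra_visit_mean), i.e. the pollen
    #: load accumulates over a full foraging bout, not just the capture
    extra_visit_mean: float = 7.0
    #: read-count law for a plant that genuinely contributed pollen:
    #: count = reference_threshold + ceil(Lognormal(meanlog, sdlog)).
    #: meanlog is set so that roughly one fifth of super-threshold
    #: counts fall within a factor two of the threshold.
    reference_threshold: int = 1000
    read_meanlog: float = math.log(3500.0)
    read_sdlog: float = 1.5
    #: mean of the geometric law for sub-threshold carryover reads
    sub_read_mean: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_plant_species", "n_insect_species", "n_insect_individuals"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.off_site_fraction <= 1:
            raise ValueError("off_site_fraction must lie in [0, 1]")
        if self.plant_abundance_shape <= 0 or self.insect_abundance_shape <= 0:
            raise ValueError("abundance shape parameters must be positive")
        if self.extra_visit_mean < 0:
            raise ValueError("extra_visit_mean must be non-negative")
        prefs = self.group_preference_matrix
        if (prefs.to_numpy() < 0).any():
            raise ValueError("group preferences must be non-negative")
        if not np.allclose(prefs.sum(axis=1).to_numpy(), 1.0, atol=1e-8):
            raise ValueError("each group-preference row must sum to 1")
        wsum = sum(self.group_weights.values())
        if not math.isclose(wsum, 1.0, abs_tol=1e-8):
            raise ValueError(f"group weights must sum to 1 (got {wsum})")


@dataclass
class ContaminationSpec:
    """Airborne-grass background contamination and visit carryover.

    The grass read-count law for a contaminated insect is a lognormal
    whose parameters put roughly 38% of contaminated insects below 100
    reads and 18% above 1,000 reads; combined with ``p_zero_grass`` this
    reproduces the field profile in which about a third of insects carry
    no grass reads, three fifths fewer than 100, and about one in nine
    more than 1,000 (from resting or landing on grass inflorescences).
    """

    n_grass_taxa: int = 3
    p_zero_grass: float = 0.35
    grass_meanlog: float = 5.157
    grass_sdlog: float = 1.889
    #: cap on the grass read count of a single insect
    grass_max: int = 26_952
    #: probability that a genuine visit leaves only a sub-threshold trace
    carryover_rate: float = 0.10

    def __post_init__(self) -> None:
        if self.n_grass_taxa < 0:
            raise ValueError("n_grass_taxa must be non-negative")
        for name in ("p_zero_grass", "carryover_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.grass_sdlog <= 0:
            raise ValueError("grass_sdlog must be positive")
        if self.grass_max < 1:
            raise ValueError("grass_max must be at least 1")


#: disables grass background and carryover entirely
NO_CONTAMINATION = ContaminationSpec(
    n_grass_taxa=0, p_zero_grass=1.0, carryover_rate=0.0
)


@dataclass
class Truth:
    """Ground-truth community structure behind one simulated data set."""

    plants: pd.DataFrame  # taxon-indexed: morph_group, abundance, on_site, rank
    species: pd.DataFrame  # insect-species-indexed: group, abundance
    individuals: pd.DataFrame  # individual-indexed: species, group
    propensity: np.ndarray  # plants x individuals, columns sum to 1
    spec: CommunitySpec

    @property
    def plant_labels(self) -> tuple[str, ...]:
        return tuple(self.plants.index)

    def registry(
        self, contamination: ContaminationSpec | None = None
    ) -> TaxonRegistry:
        """Build the taxon registry, including any grass taxa."""
        plants = self.plants[["rank", "morph_group", "on_site"]].copy()
        plants["pollination_mode"] = "insect"
        if contamination is not None and contamination.n_grass_taxa > 0:
            grass = pd.DataFrame(
                {
                    "rank": "species",
                    "morph_group": "none",
                    "on_site": True,
                    "pollination_mode": "wind",
                },
                index=_grass_names(contamination.n_grass_taxa),
            )
            plants = pd.concat([plants, grass])
        plants = plants[["rank", "pollination_mode", "morph_group", "on_site"]]
        plants.index.name = "taxon"
        insects = self.species[["group"]].copy()
        individuals = self.individuals[["species"]].copy()
        return TaxonRegistry(plants=plants, insects=insects, individuals=individuals)


def _grass_names(n: int) -> list[str]:
    return [f"grass_{i + 1:02d}" for i in range(n)]


def _rng(spec: CommunitySpec, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed), stage]))


def generate_truth(spec: CommunitySpec) -> Truth:
    """Draw the ground-truth community behind one simulated data set.

    Each plant receives a lognormal abundance, a morphology group and an
    on/off-site flag; each insect species a functional group and a
    lognormal abundance; each captured individual a species.  The visit
    propensity of individual *j* toward plant *i* is its group's
    preference for the plant's morphology group, shared among the plants
    of that group in proportion to their abundance.
    """
    rng = _rng(spec, _STAGE_TRUTH)
    P = spec.n_plant_species

    plant_names = [f"plant_{i + 1:03d}" for i in range(P)]
    morph = rng.choice(MORPH_GROUPS, size=P, p=np.asarray(spec.morph_weights))
    abundance = rng.lognormal(mean=0.0, sigma=spec.plant_abundance_shape, size=P)
    on_site = rng.random(P) >= spec.off_site_fraction
    if not on_site.any():
        on_site[int(np.argmax(abundance))] = True
    # off-site pollen taxa are identified from sequences alone and may
    # only be resolvable to genus; a few remain above genus and are
    # discarded during network construction
    rank = np.where(on_site, "species", "species").astype(object)
    off_idx = np.flatnonzero(~on_site)
    if off_idx.size:
        rank[off_idx] = rng.choice(
            ["species", "genus", "higher"], size=off_idx.size, p=[0.6, 0.3, 0.1]
        )
    plants = pd.DataFrame(
        {
            "morph_group": morph,
            "abundance": abundance,
            "on_site": on_site,
            "rank": rank,
        },
        index=pd.Index(plant_names, name="taxon"),
    )

    groups = list(spec.group_weights)
    weights = np.array([spec.group_weights[g] for g in groups], dtype=float)
    S = spec.n_insect_species
    sp_names = [f"insect_sp_{i + 1:03d}" for i in range(S)]
    sp_group = rng.choice(groups, size=S, p=weights / weights.sum())
    sp_abund = rng.lognormal(mean=0.0, sigma=spec.insect_abundance_shape, size=S)
    species = pd.DataFrame(
        {"group": sp_group, "abundance": sp_abund},
        index=pd.Index(sp_names, name="species"),
    )

    # individuals drawn by species abundance weighted within group shares:
    # species abundance already carries the skew; group composition is
    # controlled by re-weighting species by their group's target share
    group_totals = species.groupby("group")["abundance"].sum()
    sp_weight = sp_abund * np.array(
        [spec.group_weights[g] / group_totals[g] for g in sp_group]
    )
    sp_weight = sp_weight / sp_weight.sum()
    N = spec.n_insect_individuals
    ind_species = rng.choice(sp_names, size=N, p=sp_weight)
    ind_names = [f"ind_{i + 1:04d}" for i in range(N)]
    individuals = pd.DataFrame(
        {
            "species": ind_species,
            "group": [species.at[s, "group"] for s in ind_species],
        },
        index=pd.Index(ind_names, name="individual_id"),
    )

    # plant share within its morphology group, proportional to abundance
    prefs = spec.group_preference_matrix
    morph_share = np.zeros(P)
    for m in MORPH_GROUPS:
        sel = morph == m
        if sel.any():
            morph_share[sel] = abundance[sel] / abundance[sel].sum()
    base = np.zeros((P, len(groups)))
    for gi, g in enumerate(groups):
        gp = np.array([prefs.at[g, m] for m in morph])
        base[:, gi] = gp * morph_share
        # renormalize: morphology groups with no plants lose their mass
        base[:, gi] /= base[:, gi].sum()
    gidx = {g: i for i, g in enumerate(groups)}
    propensity = base[:, [gidx[g] for g in individuals["group"]]]

    return Truth(
        plants=plants,
        species=species,
        individuals=individuals,
        propensity=propensity,
        spec=spec,
    )


def _capture_visits(truth: Truth) -> np.ndarray:
    """Plant index of each individual's capture visit (on-site plants only).

    Drawn from a dedicated random stream so the visit table and the
    pollen-load table agree on the visit during which each insect was
    captured.
    """
    spec = truth.spec
    rng = _rng(spec, _STAGE_CAPTURE)
    on = truth.plants["on_site"].to_numpy()
    if not on.any():
        raise ValueError("no on-site plants to observe visits on")
    probs = truth.propensity[on, :]
    probs = probs / probs.sum(axis=0, keepdims=True)
    cum = np.cumsum(probs, axis=0)
    u = rng.random(probs.shape[1])
    local = (u[None, :] < cum).argmax(axis=0)
    return np.flatnonzero(on)[local]


def simulate_visits(truth: Truth, spec: CommunitySpec | None = None) -> pd.DataFrame:
    """Simulate the field survey: one recorded visit per captured insect.

    Returns a long-format table with one row per individual: the plant it
    was captured on, its species and functional group, and the community
    (site) it was sampled in.
    """
    spec = spec or truth.spec
    rng = _rng(spec, _STAGE_VISITS)
    captured = _capture_visits(truth)
    plant_names = np.array(truth.plant_labels)
    community = rng.integers(1, spec.n_communities + 1, size=len(captured))
    return pd.DataFrame(
        {
            "individual_id": truth.individuals.index,
            "insect_species": truth.individuals["species"].to_numpy(),
            "insect_group": truth.individuals["group"].to_numpy(),
            "plant_taxon": plant_names[captured],
            "community": community,
        }
    ).reset_index(drop=True)


def simulate_pollen_loads(
    truth: Truth,
    spec: CommunitySpec | None = None,
    contamination: ContaminationSpec | None = None,
) -> pd.DataFrame:
    """Simulate the post-bioinformatics read-count table.

    Each insect's latent foraging history is its capture visit plus a
    Poisson number of additional visits drawn from its full preference
    vector (on- and off-site plants alike).  Every distinct visited plant
    contributes a super-threshold read count with probability
    ``1 - carryover_rate`` and a sub-threshold geometric count otherwise.
    Grass taxa then add airborne background reads per the contamination
    spec.  Returns an individuals x taxa integer DataFrame.
    """
    spec = spec or truth.spec
    contamination = contamination or ContaminationSpec()
    rng = _rng(spec, _STAGE_POLLEN)
    N = len(truth.individuals)
    P = len(truth.plants)
    captured = _capture_visits(truth)

    counts = np.zeros((N, P), dtype=np.int64)
    extra = rng.poisson(spec.extra_visit_mean, size=N)
    cum = np.cumsum(truth.propensity, axis=0)
    for j in range(N):
        visited = {int(captured[j])}
        if extra[j]:
            u = rng.random(extra[j])
            visited.update(np.searchsorted(cum[:, j], u).tolist())
        for i in visited:
            if rng.random() < contamination.carryover_rate:
                c = min(
                    int(rng.geometric(1.0 / spec.sub_read_mean)),
                    spec.reference_threshold,
                )
            else:
                c = spec.reference_threshold + int(
                    math.ceil(rng.lognormal(spec.read_meanlog, spec.read_sdlog))
                )
            counts[j, i] = c

    columns = list(truth.plant_labels)
    if contamination.n_grass_taxa > 0:
        grass = np.zeros((N, contamination.n_grass_taxa), dtype=np.int64)
        contaminated = rng.random(N) >= contamination.p_zero_grass
        n_cont = int(contaminated.sum())
        if n_cont:
            totals = np.clip(
                np.round(
                    rng.lognormal(
                        contamination.grass_meanlog,
                        contamination.grass_sdlog,
                        size=n_cont,
                    )
                ),
                1,
                contamination.grass_max,
            ).astype(np.int64)
            # all of an insect's background load is attributed to a single
            # grass taxon (airborne pollen is dominated by one or two
            # locally mass-flowering grasses at any one time)
            taxon = rng.integers(0, contamination.n_grass_taxa, size=n_cont)
            grass[np.flatnonzero(contaminated), taxon] = totals
        counts = np.hstack([counts, grass])
        columns = columns + _grass_names(contamination.n_grass_taxa)

    return pd.DataFrame(
        counts,
        index=truth.individuals.index.copy(),
        columns=columns,
    )


def write_tables(
    outdir: str | Path,
    visits: pd.DataFrame,
    counts: pd.DataFrame,
    registry: TaxonRegistry,
) -> dict[str, Path]:
    """Write the three TSV inputs of the pipeline to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "visits": outdir / "visits.tsv",
        "counts": outdir / "counts.tsv",
        "taxa": outdir / "taxa.tsv",
    }
    visits.to_csv(paths["visits"], sep="\t", index=False)
    counts.to_csv(paths["counts"], sep="\t", index_label="individual_id")
    registry.write_tsv(paths["taxa"])
    return paths


def read_tables(outdir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, TaxonRegistry]:
    """Load the three TSVs written by :func:`write_tables`."""
    outdir = Path(outdir)
    visits = pd.read_csv(outdir / "visits.tsv", sep="\t")
    counts = pd.read_csv(outdir / "counts.tsv", sep="\t", index_col="individual_id")
    registry = TaxonRegistry.read_tsv(outdir / "taxa.tsv", visits=visits)
    return visits, counts, registry
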