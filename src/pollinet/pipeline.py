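"""End-to-end pipeline: simulate -> build -> indices -> nulls -> compare.

Stages communicate through serialized intermediates (TSV matrices with
JSON sidecars) in the run's output directory, so any later stage can be
re-run from cached inputs and reproduce its outputs exactly.  A run log
records the seed, package versions and filter tallies.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .build import (
    DEFAULT_THRESHOLD,
    aggregate,
    build_obs_matrix,
    call_interactions,
    contamination_profile,
    per_species_individual_matrices,
    threshold_sensitivity,
)
from .indices import compute_index_report, degree_distribution_fit, f_s_regression
from .matrix import InteractionMatrix, TaxonRegistry
from .nulls import null_envelope
from .rarefy import compare_networks, comparison_table
from .report import render_side_by_side
from .synth import (
    CommunitySpec,
    ContaminationSpec,
    generate_truth,
    read_tables,
    simulate_pollen_loads,
    simulate_visits,
    write_tables,
)

log = logging.getLogger("pollinet")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str = "pollinet_run"
    seed: int = 0
    threshold: int = DEFAULT_THRESHOLD
    levels: tuple[str, ...] = ("group", "species", "individual")
    n_null: int = 100
    n_rarefy: int = 1000
    min_individuals: int = 10
    n_restarts: int = 20
    sensitivity_thresholds: tuple[int, ...] = (250, 500, 1000, 2000, 4000)
    community: dict = field(default_factory=dict)
    contamination: dict = field(default_factory=dict)
    #: directory with pre-existing visits.tsv / counts.tsv / taxa.tsv;
    #: when unset, the synthetic scenario in ``community`` is simulated
    input_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_null < 1 or self.n_rarefy < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")
        bad = set(self.levels) - {"group", "species", "individual"}
        if bad:
            raise ValueError(f"unknown levels {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        if "levels" in raw:
            raw["levels"] = tuple(raw["levels"])
        if "sensitivity_thresholds" in raw:
            raw["sensitivity_thresholds"] = tuple(raw["sensitivity_thresholds"])
        return cls(**raw)

    def community_spec(self) -> CommunitySpec:
        return CommunitySpec(seed=self.seed, **self.community)

    def contamination_spec(self) -> ContaminationSpec:
        return ContaminationSpec(**self.contamination)


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (
        logging.StreamHandler(sys.stderr),
        logging.FileHandler(outdir / "run.log"),
    ):
        handler.setFormatter(fmt)
        log.addHandler(handler)


def stage_simulate(config: RunConfig) -> dict[str, Path]:
    """Generate (or locate) the three input tables."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.input_dir is not None:
        src = Path(config.input_dir)
        paths = {k: src / f"{k}.tsv" for k in ("visits", "counts", "taxa")}
        missing = [str(p) for p in paths.values() if not p.exists()]
        if missing:
            raise FileNotFoundError(f"missing input tables: {missing}")
        return paths
    spec = config.community_spec()
    cont = config.contamination_spec()
    truth = generate_truth(spec)
    visits = simulate_visits(truth, spec)
    counts = simulate_pollen_loads(truth, spec, cont)
    registry = truth.registry(cont)
    paths = write_tables(outdir / "tables", visits, counts, registry)
    log.info(
        "simulated %d individuals, %d plant taxa (+%d grass), seed=%d",
        len(visits),
        len(truth.plants),
        cont.n_grass_taxa,
        spec.seed,
    )
    return paths


def _load_inputs(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, TaxonRegistry]:
    src = (
        Path(config.input_dir)
        if config.input_dir is not None
        else Path(config.outdir) / "tables"
    )
    return read_tables(src)


def stage_build(config: RunConfig) -> dict[str, InteractionMatrix]:
    """Build matrices at the requested levels and write them to disk."""
    outdir = Path(config.outdir) / "matrices"
    outdir.mkdir(parents=True, exist_ok=True)
    visits, counts, registry = _load_inputs(config)

    obs_ind = build_obs_matrix(visits)
    seq_ind = call_interactions(counts, registry, threshold=config.threshold)
    matrices = {"obs_individual": obs_ind, "seq_individual": seq_ind}
    tallies = {
        "insects_surveyed": int(counts.shape[0]),
        "insects_retained_seq": seq_ind.n_pollinators,
        "insects_excluded_seq": int(counts.shape[0]) - seq_ind.n_pollinators,
        "taxa_in_counts": int(counts.shape[1]),
        "taxa_eligible": len(registry.network_plants()),
    }
    for level in ("species", "group"):
        if level in config.levels:
            matrices[f"obs_{level}"] = aggregate(obs_ind, registry, level)
            matrices[f"seq_{level}"] = aggregate(seq_ind, registry, level)
    for name, m in matrices.items():
        m.write_tsv(outdir / f"{name}.tsv")
    if "individual" in config.levels:
        per_dir = outdir / "per_species"
        per_dir.mkdir(exist_ok=True)
        for prov, ind in (("obs", obs_ind), ("seq", seq_ind)):
            for sub in per_species_individual_matrices(
                ind, registry, config.min_individuals
            ):
                sp = registry.species_of(sub.pollinator_labels[0])
                sub.write_tsv(per_dir / f"{prov}_{sp}.tsv")

    profile = contamination_profile(counts, registry, config.threshold)
    (Path(config.outdir) / "contamination.json").write_text(
        json.dumps(asdict(profile), indent=2) + "\n"
    )
    sens = threshold_sensitivity(counts, registry, list(config.sensitivity_thresholds))
    sens.to_csv(Path(config.outdir) / "threshold_sensitivity.tsv", sep="\t", index=False)
    (Path(config.outdir) / "build_tallies.json").write_text(
        json.dumps(tallies, indent=2) + "\n"
    )
    log.info("built %d matrices; %s", len(matrices), tallies)
    return matrices


def _read_matrices(config: RunConfig) -> dict[str, InteractionMatrix]:
    outdir = Path(config.outdir) / "matrices"
    return {
        p.stem: InteractionMatrix.read_tsv(p)
        for p in sorted(outdir.glob("*.tsv"))
    }


def stage_indices(config: RunConfig) -> pd.DataFrame:
    """Index reports plus degree fits and f-s regressions for every matrix."""
    matrices = _read_matrices(config)
    rows, extras = {}, {}
    for name, m in matrices.items():
        rows[name] = compute_index_report(
            m, seed=config.seed, n_restarts=config.n_restarts
        ).as_dict()
        if m.level == "species":
            extra: dict[str, object] = {}
            for axis in ("pollinators", "plants"):
                extra[f"degree_fit_{axis}"] = degree_distribution_fit(m, axis)
                try:
                    extra[f"fs_regression_{axis}"] = f_s_regression(m, axis)
                except Exception as exc:  # noqa: BLE001
                    extra[f"fs_regression_{axis}"] = {"error": str(exc)}
            extras[name] = extra
    frame = pd.DataFrame(rows).T
    frame.to_csv(Path(config.outdir) / "index_reports.tsv", sep="\t")
    (Path(config.outdir) / "connectivity_fits.json").write_text(
        json.dumps(extras, indent=2, default=float) + "\n"
    )
    log.info("computed index reports for %s", sorted(rows))
    return frame


def _run_nulls(config: RunConfig, matrices: dict[str, InteractionMatrix]) -> dict:
    out = {}
    for name in ("obs_species", "seq_species"):
        if name not in matrices:
            continue
        env = null_envelope(
            matrices[name],
            n_replicates=config.n_null,
            seed=config.seed,
            n_restarts=config.n_restarts,
        )
        summary = env.summary()
        summary.to_csv(Path(config.outdir) / f"nulls_{name}.tsv", sep="\t")
        out[name] = env
        log.info(
            "null envelope for %s: %d/%d indices outside CI",
            name,
            int(summary["significant"].sum()),
            len(summary),
        )
    return out


def stage_nulls(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Null-model envelopes for the species-level obs and seq networks."""
    envs = _run_nulls(config, _read_matrices(config))
    return {name: env.summary() for name, env in envs.items()}


def _run_compare(config: RunConfig, matrices: dict[str, InteractionMatrix]):
    results = compare_networks(
        matrices["seq_species"],
        matrices["obs_species"],
        n_reps=config.n_rarefy,
        seed=config.seed,
        n_restarts=config.n_restarts,
    )
    table = comparison_table(results)
    table.to_csv(Path(config.outdir) / "comparison.tsv", sep="\t", index=False)
    log.info(
        "rarefaction comparison: %d/%d indices significant after Bonferroni",
        int(table["p_adj"].lt(0.05).sum()),
        len(table),
    )
    return results, table


def stage_compare(config: RunConfig) -> pd.DataFrame:
    """Rarefaction comparison of the species-level seq vs obs networks."""
    return _run_compare(config, _read_matrices(config))[1]


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Run every stage and emit the side-by-side report; returns a bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    t0 = time.time()
    stage_simulate(config)
    matrices = stage_build(config)
    reports = stage_indices(config)
    envs = _run_nulls(config, matrices)
    comp, comparison = _run_compare(config, matrices)

    obs = compute_index_report(
        matrices["obs_species"], seed=config.seed, n_restarts=config.n_restarts
    )
    seq = compute_index_report(
        matrices["seq_species"], seed=config.seed, n_restarts=config.n_restarts
    )
    table1 = render_side_by_side(
        obs, seq, envs.get("obs_species"), envs.get("seq_species"), comp
    )
    (outdir / "table1.txt").write_text(table1)

    runlog = {
        "seed": config.seed,
        "pollinet_version": __version__,
        "numpy_version": np.__version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "elapsed_s": round(time.time() - t0, 2),
    }
    (outdir / "run_info.json").write_text(json.dumps(runlog, indent=2) + "\n")
    log.info("pipeline finished in %.1fs", runlog["elapsed_s"])
    return {
        "matrices": matrices,
        "reports": reports,
        "comparison": comparison,
        "table1": table1,
        "run_info": runlog,
    }
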