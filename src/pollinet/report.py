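"""Report rendering: side-by-side index tables and a basic bipartite plot."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .indices import IndexReport
from .matrix import InteractionMatrix, MatrixError
from .nulls import NullEnsemble
from .rarefy import ComparisonResult

#: presentation order and labels of the side-by-side table rows
TABLE_ROWS: list[tuple[str, str]] = [
    ("n_pollinators", "No. insect species (A)"),
    ("n_plants", "No. plant species (P)"),
    ("size", "Network size (A x P)"),
    ("n_links", "No. links (I)"),
    ("connectance", "Connectance (C = I/(A x P))"),
    ("nestedness", "Nestedness (100-T)/100"),
    ("modularity", "Modularity (M)"),
    ("n_modules", "Number of modules"),
    ("interaction_density", "Interaction density I/(A+P)"),
    ("plant_linkage", "Mean plant linkage level (I/P)"),
    ("insect_linkage", "Mean insect linkage level (I/A)"),
    ("h2_prime", "Interaction diversity (H2')"),
    ("evenness", "Interaction evenness (E2)"),
    ("mean_plant_d", "Mean plant specialization index d'"),
    ("mean_insect_d", "Mean insect specialization index d'"),
    ("extreme_plant_pct", "Extreme plant specialization (%)"),
    ("extreme_insect_pct", "Extreme insect specialization (%)"),
]


def _fmt(v: float) -> str:
    if not np.isfinite(v):
        return "-"
    if float(v).is_integer() and abs(v) < 1e7:
        return str(int(v))
    return f"{v:.3g}" if abs(v) < 1 else f"{v:.4g}"


def render_side_by_side(
    obs_report: IndexReport,
    seq_report: IndexReport,
    obs_null: NullEnsemble | None = None,
    seq_null: NullEnsemble | None = None,
    comparison: list[ComparisonResult] | None = None,
) -> str:
    """Render the obs-vs-seq species-network summary as a fixed-width table.

    Each network column shows the index value, a star when it falls
    outside its null-model confidence interval, the CI itself, and a
    letter: networks sharing a letter on a row did not differ
    significantly in the size-matched rarefaction test.
    """
    obs = obs_report.as_dict()
    seq = seq_report.as_dict()
    for env, rep in ((obs_null, obs), (seq_null, seq)):
        if env is not None and set(env.observed) - set(rep):
            raise MatrixError("null ensemble does not match the index report")
    comp = {c.index: c for c in (comparison or [])}

    def cell(rep: dict, env: NullEnsemble | None, key: str, which: int) -> tuple[str, str]:
        star = ""
        ci = ""
        if env is not None and key in env.ci_low.index:
            star = "*" if bool(env.significant[key]) else "ns"
            ci = f"{_fmt(env.ci_low[key])}-{_fmt(env.ci_high[key])}"
        letter = comp[key].letters[which] if key in comp else ""
        return f"{_fmt(rep[key])}{star} {letter}".strip(), ci

    header = f"{'Index':40s} {'sp-sp N_obs':>16s} {'95% CI':>15s} {'sp-sp N_seq':>16s} {'95% CI':>15s}"
    lines = [header, "-" * len(header)]
    for key, label in TABLE_ROWS:
        o, oci = cell(obs, obs_null, key, 0)
        s, sci = cell(seq, seq_null, key, 1)
        lines.append(f"{label:40s} {o:>16s} {oci:>15s} {s:>16s} {sci:>15s}")
    return "\n".join(lines) + "\n"


def report_frame(reports: dict[str, IndexReport]) -> pd.DataFrame:
    """One row per network, one column per index."""
    return pd.DataFrame({name: rep.as_dict() for name, rep in reports.items()}).T


def plot_bipartite(m: InteractionMatrix, path: str | Path) -> None:
    """Save a basic two-column bipartite diagram of the matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, max(3, 0.14 * max(m.n_plants, m.n_pollinators))))
    py = np.linspace(0, 1, m.n_plants) if m.n_plants > 1 else np.array([0.5])
    ay = np.linspace(0, 1, m.n_pollinators) if m.n_pollinators > 1 else np.array([0.5])
    wmax = m.values.max() or 1
    for i in range(m.n_plants):
        for j in range(m.n_pollinators):
            w = m.values[i, j]
            if w:
                ax.plot([0, 1], [py[i], ay[j]], "-", color="0.4", lw=0.3 + 2.2 * w / wmax)
    ax.scatter(np.zeros_like(py), py, s=12, color="forestgreen", zorder=3)
    ax.scatter(np.ones_like(ay), ay, s=12, color="darkorange", zorder=3)
    for i, lab in enumerate(m.plant_labels):
        ax.annotate(lab, (0, py[i]), ha="right", va="center", fontsize=4, xytext=(-4, 0), textcoords="offset points")
    for j, lab in enumerate(m.pollinator_labels):
        ax.annotate(lab, (1, ay[j]), ha="left", va="center", fontsize=4, xytext=(4, 0), textcoords="offset points")
    ax.set_xlim(-0.45, 1.45)
    ax.axis("off")
    ax.set_title(f"{m.level} {m.provenance} network", fontsize=8)
    fig.savefig(path, dpi=200, bbox_inches="tight")
    plt.close(fig)
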