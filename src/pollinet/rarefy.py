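"""Size- and effort-matched comparison of metabarcoding vs visit networks.

A metabarcoding network typically contains far more species and
interactions than the visit-survey network built on the same insects,
which precludes direct index comparison (most network metrics depend on
size and sampling intensity).  The procedure implemented here matches
the two species-level networks before comparing:

1. both matrices are restricted to the insect and plant species present
   in both (so the networks have the same dimensions);
2. the metabarcoding matrix is repeatedly downsampled to the visit
   matrix's interaction total by a multinomial draw with cell
   probabilities proportional to its observed frequencies;
3. each index (and the f-s regression slopes) computed on the visit
   network is compared against its distribution over the rarefied
   replicates, yielding an empirical p-value, Bonferroni-corrected
   across the index family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .indices import compute_index_report, f_s_regression
from .matrix import InteractionMatrix, MatrixError


def shared_restriction(
    m_seq: InteractionMatrix, m_obs: InteractionMatrix
) -> tuple[InteractionMatrix, InteractionMatrix]:
    """Restrict both matrices to the species found in both.

    Plants and pollinators are intersected by label; species left
    without any link in either matrix after the restriction are dropped
    from both, iterating until the two matrices share an identical,
    fully connected label set.
    """
    plants = [p for p in m_seq.plant_labels if p in set(m_obs.plant_labels)]
    polls = [a for a in m_seq.pollinator_labels if a in set(m_obs.pollinator_labels)]
    if not plants or not polls:
        raise MatrixError("no shared species between the two matrices")
    while True:
        s = m_seq.subset(plants=plants, pollinators=polls)
        o = m_obs.subset(plants=plants, pollinators=polls)
        empty_p = (s.values.sum(axis=1) == 0) | (o.values.sum(axis=1) == 0)
        empty_a = (s.values.sum(axis=0) == 0) | (o.values.sum(axis=0) == 0)
        if not empty_p.any() and not empty_a.any():
            return s, o
        plants = [p for p, e in zip(plants, empty_p) if not e]
        polls = [a for a, e in zip(polls, empty_a) if not e]
        if not plants or not polls:
            raise MatrixError("shared restriction removed every species")


def rarefy_once(
    m: InteractionMatrix,
    target_total: int,
    rng: np.random.Generator | int = 0,
) -> InteractionMatrix:
    """One multinomial downsample of ``m`` to ``target_total`` interactions.

    Cells are drawn from a multinomial with probabilities a_ij / F, so
    every draw has grand total exactly ``target_total``.  The returned
    matrix may contain empty rows or columns by chance; callers drop
    them before computing indices.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    F = m.total
    if F == 0:
        raise MatrixError("zero-total matrix cannot be rarefied")
    if target_total < 0:
        raise MatrixError("target_total must be non-negative")
    probs = (m.values / F).ravel()
    draw = rng.multinomial(int(target_total), probs).reshape(m.values.shape)
    return InteractionMatrix(
        values=draw,
        plant_labels=m.plant_labels,
        pollinator_labels=m.pollinator_labels,
        level=m.level,
        provenance=m.provenance,
        threshold=m.threshold,
    )


@dataclass(frozen=True)
class ComparisonResult:
    """One index's observed-vs-rarefied comparison."""

    index: str
    observed: float  # value on the visit-survey network
    seq_value: float  # value on the unrarefied metabarcoding network
    rarefied: np.ndarray  # distribution over rarefied replicates
    rarefied_mean: float
    p_value: float
    p_adjusted: float
    direction: str  # 'above' if rarefied values sit above the observed
    significant: bool
    letters: tuple[str, str]  # Table-style letters for (obs, seq)
    n_replicates: int


def _suite(m: InteractionMatrix, seed: int, n_restarts: int) -> dict[str, float]:
    vals = compute_index_report(m, seed=seed, n_restarts=n_restarts).as_dict()
    for axis, name in (("pollinators", "insect_fs_slope"), ("plants", "plant_fs_slope")):
        try:
            vals[name] = f_s_regression(m, axis)["slope"]
        except MatrixError:
            vals[name] = np.nan
    return vals


def compare_networks(
    m_seq: InteractionMatrix,
    m_obs: InteractionMatrix,
    n_reps: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    n_restarts: int = 20,
    index_fn=None,
) -> list[ComparisonResult]:
    """Compare two species-level networks at matched size and effort.

    Empirical p-values use the add-one estimator
    ``p = (1 + #{replicates on the more extreme side}) / (n_valid + 1)``
    with the smaller one-sided tail, then Bonferroni correction over the
    family of indices compared.  Indices that fail on a replicate are
    excluded from that index's distribution with a warning.
    """
    if n_reps < 1:
        raise MatrixError("need at least one rarefied replicate")
    if index_fn is None:
        index_fn = lambda mat: _suite(mat, seed, n_restarts)  # noqa: E731

    s, o = shared_restriction(m_seq, m_obs)
    target = o.total
    observed = index_fn(o)
    seq_values = index_fn(s)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 202]))
    rows = []
    n_failed = 0
    for rep in range(n_reps):
        rare = rarefy_once(s, target, rng).pruned()
        try:
            rows.append(index_fn(rare))
        except Exception as exc:  # noqa: BLE001
            n_failed += 1
            warnings.warn(f"rarefied replicate {rep} failed: {exc}", stacklevel=2)
    reps = pd.DataFrame(rows)

    names = [n for n in observed if n in reps.columns]
    m_tests = len(names)
    results = []
    for name in names:
        dist = reps[name].to_numpy(dtype=float)
        dist = dist[np.isfinite(dist)]
        obs_val = float(observed[name])
        n_valid = dist.size
        if n_valid == 0 or not np.isfinite(obs_val):
            p = np.nan
            direction = "undefined"
        else:
            n_ge = int((dist >= obs_val).sum())
            n_le = int((dist <= obs_val).sum())
            p = (1 + min(n_ge, n_le)) / (n_valid + 1)
            direction = "above" if n_ge < n_le else "below"
        p_adj = min(1.0, m_tests * p) if np.isfinite(p) else np.nan
        sig = bool(np.isfinite(p_adj) and p_adj < alpha)
        results.append(
            ComparisonResult(
                index=name,
                observed=obs_val,
                seq_value=float(seq_values.get(name, np.nan)),
                rarefied=dist,
                rarefied_mean=float(dist.mean()) if n_valid else np.nan,
                p_value=float(p),
                p_adjusted=float(p_adj),
                direction=direction,
                significant=sig,
                letters=("a", "b") if sig else ("a", "a"),
                n_replicates=n_valid,
            )
        )
    return results


def comparison_table(results: list[ComparisonResult]) -> pd.DataFrame:
    """Machine-readable comparison table, one row per index."""
    return pd.DataFrame(
        [
            {
                "index": r.index,
                "obs_value": r.observed,
                "seq_value": r.seq_value,
                "rarefied_mean": r.rarefied_mean,
                "p": r.p_value,
                "p_adj": r.p_adjusted,
                "direction": r.direction,
                "obs_letter": r.letters[0],
                "seq_letter": r.letters[1],
            }
            for r in results
        ]
    )
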