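"""Fixed-marginal null models and confidence envelopes.

The null model holds every species' interaction total fixed (so null
matrices contain common and rare species exactly like the empirical
one) and randomizes only how interactions pair up.  Sampling follows
the Patefield scheme for r x c contingency tables with given margins:
each of the F interaction tokens is allocated conditionally uniformly,
which is realized here by randomly pairing the multiset of row tokens
with a shuffled multiset of column tokens.  The resulting table law is
the multivariate (Fisher) hypergeometric distribution conditional on
the margins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .indices import compute_index_report
from .matrix import InteractionMatrix, MatrixError


def patefield_sample(
    m: InteractionMatrix, rng: np.random.Generator | int = 0
) -> InteractionMatrix:
    """Draw one random matrix with exactly the observed margins."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    r = m.values.sum(axis=1)
    c = m.values.sum(axis=0)
    F = int(r.sum())
    if F == 0:
        raise MatrixError("zero-total matrix")
    rows = np.repeat(np.arange(m.n_plants), r)
    cols = np.repeat(np.arange(m.n_pollinators), c)
    rng.shuffle(cols)
    table = np.zeros_like(m.values)
    np.add.at(table, (rows, cols), 1)
    return InteractionMatrix(
        values=table,
        plant_labels=m.plant_labels,
        pollinator_labels=m.pollinator_labels,
        level=m.level,
        provenance=m.provenance,
        threshold=m.threshold,
    )


@dataclass
class NullEnsemble:
    """Null-model distribution of the index suite for one matrix."""

    observed: dict[str, float]
    replicates: pd.DataFrame  # one row per null network, one column per index
    mean: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    significant: pd.Series  # True where observed falls strictly outside the CI
    n_replicates: int
    n_failed: int
    seed: int
    ci_method: str = "percentile"
    failures: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Table-style summary: observed value, null mean, CI, flag."""
        return pd.DataFrame(
            {
                "observed": pd.Series(self.observed),
                "null_mean": self.mean,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "significant": self.significant,
            }
        )


def null_envelope(
    m: InteractionMatrix,
    n_replicates: int = 100,
    seed: int = 0,
    index_fn=None,
    ci_method: str = "percentile",
    ci_level: float = 95.0,
    n_restarts: int = 20,
) -> NullEnsemble:
    """Index suite on ``n_replicates`` fixed-marginal null networks.

    Each null network (exactly the observed row and column totals, cells
    Patefield-randomized) is scored with the full index suite; per-index
    95% confidence intervals are the 2.5-97.5 empirical percentiles
    (``ci_method='normal'`` switches to mean +/- 1.96 SD).  The observed
    index is flagged significant when it falls strictly outside the
    interval.  Replicates on which an index computation fails are
    excluded with a warning.
    """
    if n_replicates < 2:
        raise MatrixError("need at least two null replicates")
    if ci_method not in ("percentile", "normal"):
        raise MatrixError(f"unknown ci_method {ci_method!r}")
    if index_fn is None:
        index_fn = lambda mat: compute_index_report(  # noqa: E731
            mat, seed=seed, n_restarts=n_restarts
        ).as_dict()

    observed = index_fn(m)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    rows, failures = [], []
    for rep in range(n_replicates):
        null = patefield_sample(m, rng)
        assert (null.values.sum(axis=1) == m.values.sum(axis=1)).all()
        assert (null.values.sum(axis=0) == m.values.sum(axis=0)).all()
        try:
            rows.append(index_fn(null))
        except Exception as exc:  # noqa: BLE001 - record and move on
            failures.append(f"replicate {rep}: {exc}")
            warnings.warn(f"null replicate {rep} failed: {exc}", stacklevel=2)
    reps = pd.DataFrame(rows)
    alpha = (100.0 - ci_level) / 2.0
    if ci_method == "percentile":
        ci_low = reps.quantile(alpha / 100.0)
        ci_high = reps.quantile(1.0 - alpha / 100.0)
    else:
        z = 1.959963984540054
        ci_low = reps.mean() - z * reps.std(ddof=1)
        ci_high = reps.mean() + z * reps.std(ddof=1)
    obs = pd.Series(observed)
    significant = (obs < ci_low) | (obs > ci_high)
    return NullEnsemble(
        observed=observed,
        replicates=reps,
        mean=reps.mean(),
        ci_low=ci_low,
        ci_high=ci_high,
        significant=significant,
        n_replicates=len(rows),
        n_failed=len(failures),
        seed=int(seed),
        ci_method=ci_method,
        failures=failures,
    )
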