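"""Network-level and species-level indices for bipartite matrices.

All indices are implemented from their defining formulas on the
plant x pollinator count matrix ``a`` with row totals ``r`` (plants),
column totals ``c`` (pollinators) and grand total ``F``:

* connectance ``C = I / (A x P)`` where ``I`` counts non-zero cells;
* nestedness as ``(100 - T) / 100`` with ``T`` the matrix temperature
  of the packed binary matrix (0 = perfectly nested, 100 = chaos);
* Barber bipartite modularity ``Q = (1/F) sum_ij (a_ij - r_i c_j / F)
  delta(g_i, g_j)``, maximized by weighted label propagation with
  agglomerative merging and restarts;
* the network-level specialization ``H2' = (H2max - H2) / (H2max -
  H2min)`` based on the Shannon entropy of interaction frequencies with
  marginal-constrained integer extremes;
* the species-level specialization ``d'``, a standardized
  Kullback-Leibler divergence between a species' interaction profile and
  partner availability;
* interaction evenness ``E2 = H2 / ln(A x P)``;
* extreme specialization, the percentage of species with a single
  partner;
* cumulative degree-distribution fits (exponential, power law,
  truncated power law) and the log-log regression of links-per-species
  on interaction frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import optimize, special, stats

from .matrix import InteractionMatrix, MatrixError

# normalization constant of the classic matrix-temperature calculator:
# the expected squared relative unexpectedness of a maximally disordered
# matrix, so that T spans [0, 100]
_TEMPERATURE_NORM = 0.04145


# ---------------------------------------------------------------------------
# basic arithmetic indices
# ---------------------------------------------------------------------------


def basic_indices(m: InteractionMatrix) -> dict[str, float]:
    """Size, link count, connectance, interaction density, linkage levels."""
    if m.n_plants == 0 or m.n_pollinators == 0:
        raise MatrixError("empty matrix")
    A, P, I = m.n_pollinators, m.n_plants, m.n_links
    return {
        "n_pollinators": float(A),
        "n_plants": float(P),
        "size": float(A * P),
        "n_links": float(I),
        "connectance": I / (A * P),
        "interaction_density": I / (A + P),
        "plant_linkage": I / P,
        "insect_linkage": I / A,
    }


# ---------------------------------------------------------------------------
# nestedness temperature
# ---------------------------------------------------------------------------


def _isocline_exponent(fill: float) -> float:
    """Exponent p such that the area under x^p + y^p = 1 equals ``fill``.

    The area of the unit p-ball quadrant is Gamma(1+1/p)^2 / Gamma(1+2/p),
    which increases monotonically from 0 to 1 as p goes from 0 to inf.
    """

    def area(p: float) -> float:
        return float(
            np.exp(2 * special.gammaln(1 + 1 / p) - special.gammaln(1 + 2 / p))
        )

    lo, hi = 1e-3, 1e3
    if fill <= area(lo):
        return lo
    if fill >= area(hi):
        return hi
    return float(optimize.brentq(lambda p: area(p) - fill, lo, hi, xtol=1e-10))


def nestedness_temperature(m: InteractionMatrix) -> dict[str, float]:
    """Matrix temperature T of the packed binary matrix, and (100-T)/100.

    The binary matrix is packed by sorting rows and columns by descending
    marginal totals (ties broken by label).  Cell centers are mapped to
    the unit square with the most generalist corner at the origin; the
    isocline of perfect nestedness for the observed fill is the p-norm
    curve ``x^p + y^p = 1`` whose enclosed area equals the fill.
    Presences outside the isocline and absences inside it are
    "unexpected"; each contributes its squared distance to the isocline,
    measured along the diagonal through the cell and normalized by the
    diagonal's length inside the square.  T scales the mean contribution
    to [0, 100].
    """
    B = m.binary
    P, A = B.shape
    if P == 0 or A == 0:
        raise MatrixError("empty matrix")
    out = {"temperature": 0.0, "nestedness": 1.0}
    if P == 1 or A == 1:
        return out  # a single row/column is trivially nested
    fill = B.mean()
    if fill in (0.0, 1.0):
        return out

    # pack: descending marginals, ties broken lexicographically by label
    rsum, csum = B.sum(axis=1), B.sum(axis=0)
    ridx = np.lexsort((np.array(m.plant_labels), -rsum))
    cidx = np.lexsort((np.array(m.pollinator_labels), -csum))
    Bp = B[np.ix_(ridx, cidx)]

    p = _isocline_exponent(float(fill))
    y = (np.arange(P) + 0.5) / P  # row coordinate, 0 at the generalist top
    x = (np.arange(A) + 0.5) / A
    X, Y = np.meshgrid(x, y)
    inside = X**p + Y**p < 1.0
    unexpected = Bp != inside
    if not unexpected.any():
        return out

    ux, uy = X[unexpected], Y[unexpected]
    # diagonal through the cell with direction (1, 1): the isocline
    # crossing g(t) = (x+t)^p + (y+t)^p - 1 = 0 is unique since g is
    # increasing; solve for all unexpected cells by bisection at once
    t0 = -np.minimum(ux, uy)
    t1 = np.minimum(1 - ux, 1 - uy)
    lo, hi = t0.copy(), t1.copy()
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        g = (ux + mid) ** p + (uy + mid) ** p - 1.0
        lo = np.where(g < 0, mid, lo)
        hi = np.where(g >= 0, mid, hi)
    t_cross = 0.5 * (lo + hi)
    rel = t_cross / (t1 - t0)  # distance from cell (t=0), normalized
    u = np.zeros(B.shape, dtype=float)
    u[unexpected] = rel**2
    T = float(np.clip(100.0 * u.mean() / _TEMPERATURE_NORM, 0.0, 100.0))
    return {"temperature": T, "nestedness": (100.0 - T) / 100.0}


# ---------------------------------------------------------------------------
# Barber bipartite modularity
# ---------------------------------------------------------------------------


def barber_q(
    m: InteractionMatrix, row_labels: np.ndarray, col_labels: np.ndarray
) -> float:
    """Barber modularity of a given bipartite module assignment."""
    Aw = m.values.astype(float)
    F = Aw.sum()
    if F == 0:
        raise MatrixError("zero-total matrix")
    Bt = Aw - np.outer(Aw.sum(axis=1), Aw.sum(axis=0)) / F
    same = row_labels[:, None] == col_labels[None, :]
    return float(Bt[same].sum() / F)


def _lpa_once(
    Bt: np.ndarray, rng: np.random.Generator, max_iter: int = 200
) -> tuple[float, np.ndarray, np.ndarray]:
    """One label-propagation + agglomeration run on the modularity matrix."""
    P, A = Bt.shape
    col_labels = rng.permutation(A) % max(min(P, A), 1)
    row_labels = np.zeros(P, dtype=np.int64)

    def relabel() -> int:
        nonlocal row_labels, col_labels
        labels = np.unique(np.concatenate([row_labels, col_labels]))
        lut = np.zeros(labels.max() + 1, dtype=np.int64)
        lut[labels] = np.arange(labels.size)
        row_labels, col_labels = lut[row_labels], lut[col_labels]
        return labels.size

    best_q = -np.inf
    for _ in range(max_iter):
        K = relabel()
        onehot_c = np.zeros((A, K))
        onehot_c[np.arange(A), col_labels] = 1.0
        row_scores = Bt @ onehot_c  # P x K
        row_labels = row_scores.argmax(axis=1)
        onehot_r = np.zeros((P, K))
        onehot_r[np.arange(P), row_labels] = 1.0
        col_scores = Bt.T @ onehot_r
        col_labels = col_scores.argmax(axis=1)
        q = col_scores[np.arange(A), col_labels].sum()
        if q <= best_q + 1e-12:
            break
        best_q = q

    # agglomeration: greedily merge module pairs with positive gain
    while True:
        K = relabel()
        if K < 2:
            break
        onehot_r = np.zeros((P, K))
        onehot_r[np.arange(P), row_labels] = 1.0
        onehot_c = np.zeros((A, K))
        onehot_c[np.arange(A), col_labels] = 1.0
        S = onehot_r.T @ Bt @ onehot_c  # K x K module-pair weights
        gain = S + S.T
        np.fill_diagonal(gain, -np.inf)
        a, b = np.unravel_index(np.argmax(gain), gain.shape)
        if gain[a, b] <= 1e-12:
            break
        row_labels[row_labels == b] = a
        col_labels[col_labels == b] = a
    relabel()
    q = (Bt * (row_labels[:, None] == col_labels[None, :])).sum()
    return float(q), row_labels, col_labels


def modularity(
    m: InteractionMatrix, seed: int = 0, n_restarts: int = 20
) -> dict[str, object]:
    """Maximize Barber bipartite modularity Q.

    Runs weighted label propagation (rows and columns alternately adopt
    the module that maximizes their contribution to Q) followed by
    greedy agglomerative merging, from ``n_restarts`` random starts, and
    returns the best partition found.  Deterministic under a fixed seed.
    """
    Aw = m.values.astype(float)
    F = Aw.sum()
    if F == 0:
        raise MatrixError("zero-total matrix")
    Bt = Aw - np.outer(Aw.sum(axis=1), Aw.sum(axis=0)) / F
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 77]))
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(max(n_restarts, 1)):
        q, rl, cl = _lpa_once(Bt, rng)
        if best is None or q > best[0]:
            best = (q, rl, cl)
    q, rl, cl = best
    n_modules = int(np.unique(np.concatenate([rl, cl])).size)
    return {
        "modularity": q / F,
        "n_modules": n_modules,
        "plant_modules": dict(zip(m.plant_labels, rl.tolist())),
        "pollinator_modules": dict(zip(m.pollinator_labels, cl.tolist())),
    }


# ---------------------------------------------------------------------------
# H2', d', evenness, extreme specialization
# ---------------------------------------------------------------------------


def _shannon(a: np.ndarray) -> float:
    """Shannon entropy of the cell frequencies of a count matrix."""
    F = a.sum()
    p = a[a > 0] / F
    return float(-(p * np.log(p)).sum())


def _h2_max_heuristic(r: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Integer matrix with margins (r, c) of near-maximal entropy.

    Entropy is maximized (in the continuous relaxation) by the
    independence matrix r_i c_j / F; a largest-remainder rounding
    constrained by the margins gives an integer matrix close to it.
    """
    F = r.sum()
    E = np.outer(r, c) / F
    a = np.floor(E).astype(np.int64)
    dr = r - a.sum(axis=1)
    dc = c - a.sum(axis=0)
    frac = (E - np.floor(E)).ravel()
    ncol = len(c)
    for idx in np.argsort(-frac):
        if dr.sum() == 0:
            break
        i, j = divmod(int(idx), ncol)
        if dr[i] > 0 and dc[j] > 0:
            a[i, j] += 1
            dr[i] -= 1
            dc[j] -= 1
    while dr.sum() > 0:  # greedy got stuck; pair leftover deficits
        i = int(np.argmax(dr))
        j = int(np.argmax(dc))
        a[i, j] += 1
        dr[i] -= 1
        dc[j] -= 1
    return a


def _greedy_concentrate(
    r: np.ndarray, c: np.ndarray, first: tuple[int, int] | None = None
) -> np.ndarray:
    """Concentrate mass by repeatedly making the largest feasible allocation."""
    rr, cc = r.copy(), c.copy()
    a = np.zeros((len(r), len(c)), dtype=np.int64)

    def allocate(i: int, j: int) -> None:
        amount = min(rr[i], cc[j])
        a[i, j] += amount
        rr[i] -= amount
        cc[j] -= amount

    if first is not None:
        allocate(*first)
    while rr.sum() > 0:
        alloc = np.minimum.outer(rr, cc)
        i, j = np.unravel_index(int(np.argmax(alloc)), alloc.shape)
        allocate(int(i), int(j))
    return a


def _h2_min_heuristic(r: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Integer matrix with margins (r, c) of near-minimal entropy.

    Greedy concentration is sensitive to the first allocation on small
    matrices, so every feasible first pair is tried there and the lowest
    entropy kept.
    """
    best = _greedy_concentrate(r, c)
    if len(r) * len(c) <= 100 and r.sum() <= 64:
        best_h = _shannon(best)
        for i in range(len(r)):
            for j in range(len(c)):
                if r[i] == 0 or c[j] == 0:
                    continue
                cand = _greedy_concentrate(r, c, first=(i, j))
                h = _shannon(cand)
                if h < best_h:
                    best, best_h = cand, h
    return best


def _cycle_refine(a: np.ndarray, maximize: bool) -> np.ndarray:
    """Hill-climb entropy by 2x2 cycle moves that preserve the margins.

    Moving one unit from cells (i, j') and (i', j) to (i, j) and
    (i', j') keeps every row and column total.  Worth the quadratic cost
    only on small matrices, where the rounding heuristics can miss the
    discrete optimum by a visible amount.
    """
    a = a.copy()
    sign = 1.0 if maximize else -1.0
    while True:
        base = _shannon(a)
        best_gain, best = 1e-12, None
        donors = np.argwhere(a > 0)
        for i, jp in donors:
            for ip, j in donors:
                if i == ip or j == jp:
                    continue
                b = a.copy()
                b[i, jp] -= 1
                b[ip, j] -= 1
                b[i, j] += 1
                b[ip, jp] += 1
                gain = sign * (_shannon(b) - base)
                if gain > best_gain:
                    best_gain, best = gain, b
        if best is None:
            return a
        a = best


def h2_extremes(m: InteractionMatrix) -> tuple[float, float]:
    """(H2min, H2max) entropies attainable under the observed margins."""
    r = m.values.sum(axis=1)
    c = m.values.sum(axis=0)
    lo = _h2_min_heuristic(r, c)
    hi = _h2_max_heuristic(r, c)
    if m.values.size <= 100 and r.sum() <= 64:
        lo = _cycle_refine(lo, maximize=False)
        hi = _cycle_refine(hi, maximize=True)
    return _shannon(lo), _shannon(hi)


def h2_prime(m: InteractionMatrix) -> float:
    """Network-level specialization H2' in [0, 1].

    ``H2' = (H2max - H2) / (H2max - H2min)`` where H2 is the Shannon
    entropy of the interaction frequencies and H2max/H2min the extremes
    attainable with integer cells under the observed marginal totals.
    Returns 0 when the margins leave no freedom (H2max == H2min).
    """
    if m.total == 0:
        raise MatrixError("zero-total matrix")
    h2 = _shannon(m.values)
    h_min, h_max = h2_extremes(m)
    if h_max - h_min < 1e-12:
        return 0.0
    h2 = float(np.clip(h2, h_min, h_max))
    return (h_max - h2) / (h_max - h_min)


def d_prime(m: InteractionMatrix, axis: str = "plants") -> dict[str, object]:
    """Species-level specialization d' for one side of the network.

    For a species with interaction proportions ``p`` and partner
    availability ``q`` (the partners' marginal totals over F), the raw
    Kullback-Leibler specialization is ``d = sum p ln(p/q)``.  It is
    standardized to [0, 1] by the analytic bounds d_min = 0 (profile
    matching availability) and ``d_max = ln(F / f_species)`` (all
    interactions on a partner used by nobody else).
    """
    if axis not in ("plants", "pollinators"):
        raise MatrixError(f"axis must be 'plants' or 'pollinators', got {axis!r}")
    a = m.values.astype(float)
    if axis == "pollinators":
        a = a.T
        labels = m.pollinator_labels
    else:
        labels = m.plant_labels
    F = a.sum()
    if F == 0:
        raise MatrixError("zero-total matrix")
    avail = a.sum(axis=0) / F  # partner availability q_j
    totals = a.sum(axis=1)
    values: dict[str, float] = {}
    for i, lab in enumerate(labels):
        if totals[i] == 0:
            continue
        p = a[i] / totals[i]
        nz = p > 0
        d = float((p[nz] * np.log(p[nz] / avail[nz])).sum())
        d_max = float(np.log(F / totals[i]))
        values[lab] = float(np.clip(d / d_max, 0.0, 1.0)) if d_max > 1e-12 else 0.0
    mean = float(np.mean(list(values.values()))) if values else 0.0
    return {"values": values, "mean": mean}


def evenness(m: InteractionMatrix) -> float:
    """Interaction evenness E2 = H2 / ln(A x P), in [0, 1].

    The denominator is the entropy of a uniform distribution over all
    cells, so E2 = 1 only for the full uniform matrix.
    """
    if m.total == 0:
        raise MatrixError("zero-total matrix")
    hmax = np.log(m.n_plants * m.n_pollinators)
    if hmax <= 0:
        return 0.0
    return float(np.clip(_shannon(m.values) / hmax, 0.0, 1.0))


def extreme_specialization(m: InteractionMatrix, axis: str = "plants") -> float:
    """Percentage of species on one axis with exactly one partner."""
    B = m.binary
    degrees = B.sum(axis=1) if axis == "plants" else B.sum(axis=0)
    if degrees.size == 0:
        return 0.0
    return float(100.0 * (degrees == 1).mean())


# ---------------------------------------------------------------------------
# degree distributions and f-s regression
# ---------------------------------------------------------------------------


def _aic(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * k


def degree_distribution_fit(
    m: InteractionMatrix, axis: str = "pollinators"
) -> dict[str, object]:
    """Fit the cumulative degree distribution P(k >= s) by least squares.

    Three candidate laws are fitted on the distinct observed degrees:
    exponential ``exp(-s/gamma)``, power law ``s**-gamma`` and truncated
    power law ``s**-gamma * exp(-s/k_x)``.  Returns per-model parameters,
    R^2 and AIC, plus the AIC-best model name.  Requires at least five
    distinct degree values; otherwise ``fit_possible`` is False.
    """
    B = m.binary
    degrees = B.sum(axis=0) if axis == "pollinators" else B.sum(axis=1)
    degrees = degrees[degrees > 0]
    s = np.unique(degrees).astype(float)
    if s.size < 5:
        return {"fit_possible": False, "n_distinct": int(s.size)}
    cum = np.array([(degrees >= v).mean() for v in s])

    models = {
        "exponential": (lambda s, g: np.exp(-s / g), [float(degrees.mean())]),
        "power_law": (lambda s, g: s ** (-g), [1.0]),
        "truncated_power_law": (
            lambda s, g, kx: s ** (-g) * np.exp(-s / kx),
            [0.5, float(s.max())],
        ),
    }
    result: dict[str, object] = {"fit_possible": True, "n_distinct": int(s.size)}
    fits = {}
    for name, (fn, p0) in models.items():
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = optimize.curve_fit(
                    fn, s, cum, p0=p0, bounds=(1e-6, np.inf), maxfev=10_000
                )
            resid = cum - fn(s, *popt)
            rss = float((resid**2).sum())
            tss = float(((cum - cum.mean()) ** 2).sum())
            fits[name] = {
                "params": [float(v) for v in popt],
                "r2": 1.0 - rss / tss if tss > 0 else np.nan,
                "aic": _aic(rss, s.size, len(popt)),
            }
        except (RuntimeError, ValueError):
            fits[name] = {"params": None, "r2": np.nan, "aic": np.inf}
    result["fits"] = fits
    result["best_model"] = min(fits, key=lambda k: fits[k]["aic"])
    return result


def f_s_regression(m: InteractionMatrix, axis: str = "pollinators") -> dict[str, float]:
    """OLS of log10(links per species) on log10(interaction frequency).

    For each species on ``axis``, s is its number of partners and f its
    marginal interaction total.  Returns slope, intercept, the slope's
    standard error and p-value, and R^2.
    """
    a = m.values
    if axis == "pollinators":
        f = a.sum(axis=0).astype(float)
        s = (a > 0).sum(axis=0).astype(float)
    elif axis == "plants":
        f = a.sum(axis=1).astype(float)
        s = (a > 0).sum(axis=1).astype(float)
    else:
        raise MatrixError(f"axis must be 'plants' or 'pollinators', got {axis!r}")
    keep = (f > 0) & (s > 0)
    f, s = f[keep], s[keep]
    if f.size < 2:
        raise MatrixError("regression needs at least two species")
    if np.all(f == f[0]):
        raise MatrixError("regression undefined: constant interaction frequency")
    res = stats.linregress(np.log10(f), np.log10(s))
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "stderr": float(res.stderr),
        "p_value": float(res.pvalue),
        "r2": float(res.rvalue**2),
        "n": int(f.size),
    }


# ---------------------------------------------------------------------------
# the full report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IndexReport:
    """The standard vector of network indices for one matrix."""

    n_pollinators: float
    n_plants: float
    size: float
    n_links: float
    connectance: float
    nestedness: float
    temperature: float
    modularity: float
    n_modules: float
    interaction_density: float
    plant_linkage: float
    insect_linkage: float
    h2_prime: float
    evenness: float
    mean_plant_d: float
    mean_insect_d: float
    extreme_plant_pct: float
    extreme_insect_pct: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


#: report fields in presentation order
REPORT_FIELDS = tuple(IndexReport.__dataclass_fields__)


def compute_index_report(
    m: InteractionMatrix, seed: int = 0, n_restarts: int = 20
) -> IndexReport:
    """Compute the full index suite for one matrix."""
    vals = basic_indices(m)
    vals.update(nestedness_temperature(m))
    mod = modularity(m, seed=seed, n_restarts=n_restarts)
    vals["modularity"] = mod["modularity"]
    vals["n_modules"] = float(mod["n_modules"])
    vals["h2_prime"] = h2_prime(m)
    vals["evenness"] = evenness(m)
    vals["mean_plant_d"] = d_prime(m, "plants")["mean"]
    vals["mean_insect_d"] = d_prime(m, "pollinators")["mean"]
    vals["extreme_plant_pct"] = extreme_specialization(m, "plants")
    vals["extreme_insect_pct"] = extreme_specialization(m, "pollinators")
    return IndexReport(**{k: vals[k] for k in REPORT_FIELDS})
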