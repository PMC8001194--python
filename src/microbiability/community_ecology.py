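"""PRIMER-style community statistics: Bray-Curtis, PERMANOVA, NMDS, SIMPER.

Abundances are standardized by total (per-sample proportions) before the
Bray-Curtis coefficient is computed. Dissimilarities are stored in [0, 1]
(PRIMER reports similarity on a 0-100 scale; conversion is 100 * (1 - d)).

PERMANOVA partitions the Gower-centered dissimilarity matrix sequentially
over the model terms and obtains p-values by permutation of residuals under
the model reduced by the tested term (and those after it). NMDS is Kruskal
non-metric scaling (stress-1, multiple restarts). SIMPER decomposes the mean
between-group Bray-Curtis dissimilarity into per-OTU contributions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.manifold import MDS

from .otu_preprocess import OtuTable

EXACT_PERMUTATION_LIMIT = 10**5


def bray_curtis(table: OtuTable, standardize_total: bool = True) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between samples.

    d_ik = sum_j |x_ij - x_kj| / sum_j (x_ij + x_kj), computed on per-sample
    proportions when ``standardize_total`` is on (the PRIMER convention).
    """
    if standardize_total:
        data = table.relative_abundances().T  # samples x OTUs
    else:
        totals = table.sample_totals()
        if np.any(totals <= 0):
            bad = [s for s, t in zip(table.sample_ids, totals) if t <= 0]
            raise ValueError(f"zero-total samples: {bad}")
        data = table.counts.T
    d = squareform(pdist(data, metric="braycurtis"))
    return DistanceMatrix(d, ids=table.sample_ids)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    """Sequential (type-I) pseudo-F table with permutation p-values."""

    table: pd.DataFrame
    n_permutations: int
    permutation_scheme: str

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PermanovaResult(\n{self.table}\n)"


def _term_columns(term: str, factors: pd.DataFrame) -> np.ndarray:
    """One-hot columns for a main effect or a ':'-interaction of factors."""
    parts = term.split(":")
    for p in parts:
        if p not in factors.columns:
            raise ValueError(f"unknown factor {p!r} in term {term!r}")
        if factors[p].nunique() < 2:
            raise ValueError(f"factor {p!r} has a single level")
    combo = factors[parts[0]].astype(str)
    for p in parts[1:]:
        combo = combo + ":" + factors[p].astype(str)
    levels = sorted(combo.unique())
    return np.column_stack([(combo == lv).to_numpy(float) for lv in levels])


def _hat(design: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection onto the column space of the design; returns (H, rank)."""
    u = scipy.linalg.orth(design)
    return u @ u.T, u.shape[1]


def permanova(
    D: DistanceMatrix,
    factors: pd.DataFrame,
    terms: list[str],
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a dissimilarity matrix.

    Terms are fitted sequentially in the given order ("line",
    "section", "line:section", ...). For each term the null distribution of
    its pseudo-F comes from permuting the residuals of the model reduced to
    the terms preceding it. All n! arrangements are enumerated when feasible
    (<= 1e5), otherwise ``n_perm`` Monte-Carlo permutations are drawn.
    """
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    d = np.asarray(D.data, dtype=float)
    n = d.shape[0]
    if len(factors) != n:
        raise ValueError("factor table does not match distance matrix size")
    j = np.eye(n) - np.ones((n, n)) / n
    G = j @ (-0.5 * d**2) @ j
    ss_total = float(np.trace(G))

    # cumulative hat matrices H_0 (intercept) .. H_k (full model)
    design = np.ones((n, 1))
    hats = [_hat(design)]
    for term in terms:
        design = np.hstack([design, _term_columns(term, factors)])
        hats.append(_hat(design))
    h_full, rank_full = hats[-1]
    df_res = n - rank_full
    if df_res <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")
    ss_res = float(np.trace((np.eye(n) - h_full) @ G))
    r_full = np.eye(n) - h_full

    exact = math.factorial(n) <= EXACT_PERMUTATION_LIMIT
    rng = np.random.default_rng(seed)
    if exact:
        perms = list(itertools.permutations(range(n)))
        scheme = f"exact ({len(perms)} arrangements)"
    else:
        perms = [rng.permutation(n) for _ in range(n_perm)]
        scheme = f"monte-carlo ({n_perm} permutations)"

    rows = []
    for i, term in enumerate(terms):
        h_red, rank_red = hats[i]
        h_term_diff = hats[i + 1][0] - h_red
        df_term = hats[i + 1][1] - rank_red
        if df_term <= 0:
            raise ValueError(f"term {term!r} adds no degrees of freedom")
        ss_term = float(np.trace(h_term_diff @ G))
        f_obs = (ss_term / df_term) / (ss_res / df_res)

        # residuals of the reduced model, permuted
        r_red = np.eye(n) - h_red
        g_res = r_red @ G @ r_red
        count = 0
        total = 0
        for perm in perms:
            idx = np.asarray(perm)
            gp = g_res[np.ix_(idx, idx)]
            num = np.sum(h_term_diff * gp) / df_term
            den = np.sum(r_full * gp) / df_res
            if den <= 0:
                continue
            total += 1
            if num / den >= f_obs - 1e-12:
                count += 1
        if exact:
            p = count / total
        else:
            p = (count + 1) / (total + 1)
        rows.append(
            {"term": term, "df": df_term, "SS": ss_term,
             "pseudo_F": f_obs, "p_value": p}
        )
    rows.append({"term": "residual", "df": df_res, "SS": ss_res,
                 "pseudo_F": np.nan, "p_value": np.nan})
    rows.append({"term": "total", "df": n - 1, "SS": ss_total,
                 "pseudo_F": np.nan, "p_value": np.nan})
    return PermanovaResult(
        table=pd.DataFrame(rows).set_index("term"),
        n_permutations=len(perms),
        permutation_scheme=scheme,
    )


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------


@dataclass
class NmdsResult:
    coordinates: pd.DataFrame
    stress: float
    n_restarts: int
    converged: bool


def nmds(
    D: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    seed: int | None = None,
) -> NmdsResult:
    """Non-metric multidimensional scaling minimizing Kruskal stress-1.

    Runs ``n_restarts`` SMACOF starts and keeps the best configuration;
    stress-1 lies in [0, 1] and values below ~0.1 indicate a faithful
    ordination.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    import inspect

    params = inspect.signature(MDS.__init__).parameters
    kwargs = dict(
        n_components=k,
        n_init=n_restarts,
        max_iter=max_iter,
        random_state=None if seed is None else int(seed),
        normalized_stress=True,
        eps=1e-6,
    )
    if "metric_mds" in params:  # sklearn >= 1.9 naming
        kwargs.update(metric_mds=False, metric="precomputed", init="random")
    else:
        kwargs.update(metric=False, dissimilarity="precomputed")
    model = MDS(**kwargs)
    coords = model.fit_transform(np.asarray(D.data))
    return NmdsResult(
        coordinates=pd.DataFrame(
            coords, index=list(D.ids), columns=[f"NMDS{i+1}" for i in range(k)]
        ),
        stress=float(model.stress_),
        n_restarts=n_restarts,
        converged=bool(model.n_iter_ < max_iter),
    )


# ---------------------------------------------------------------------------
# SIMPER
# ---------------------------------------------------------------------------


@dataclass
class SimperResult:
    """Per-OTU contributions to the mean between-group dissimilarity."""

    table: pd.DataFrame  # ranked: contribution, pct, cumulative_pct
    overall_dissimilarity: float
    groups: tuple[str, str] = ("", "")


def simper(table: OtuTable, groups) -> SimperResult:
    """Similarity-percentage decomposition for a two-level grouping.

    Every between-group sample pair contributes |x_ij - x_kj| / sum_j (x_ij +
    x_kj) for OTU j (on proportions); contributions are averaged over pairs,
    so they sum exactly to the mean between-group Bray-Curtis dissimilarity.
    """
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"simper needs exactly two groups, got {levels}")
    rel = table.relative_abundances().T  # samples x OTUs
    idx_a = np.where(groups == levels[0])[0]
    idx_b = np.where(groups == levels[1])[0]
    contrib = np.zeros(table.n_otus)
    n_pairs = 0
    for i in idx_a:
        for kk in idx_b:
            denom = float(np.sum(rel[i] + rel[kk]))
            contrib += np.abs(rel[i] - rel[kk]) / denom
            n_pairs += 1
    contrib /= n_pairs
    overall = float(contrib.sum())
    df = pd.DataFrame(
        {"otu_id": table.otu_ids, "contribution": contrib}
    ).sort_values("contribution", ascending=False, kind="stable")
    df["pct"] = 100.0 * df["contribution"] / overall if overall > 0 else 0.0
    df["cumulative_pct"] = df["pct"].cumsum()
    return SimperResult(
        table=df.reset_index(drop=True),
        overall_dissimilarity=overall,
        groups=(str(levels[0]), str(levels[1])),
    )


def to_primer_similarity(D: DistanceMatrix) -> np.ndarray:
    """Convert stored dissimilarities to PRIMER's 0-100 similarity scale."""
    return 100.0 * (1.0 - np.asarray(D.data))
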