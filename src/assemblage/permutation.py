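"""Permutational multivariate tests, mixed models, and rank post-hocs.

``permanova`` partitions a distance matrix by an *ordered* list of design
terms (sequential, Type-I sums of squares via the Gower-centred inner
product matrix), matching the convention that each term is adjusted only
for the terms before it.  ``beta_dispersion_test`` is the multivariate
homogeneity-of-dispersion test: distances to group centroids in principal
coordinate space (negative axes retained), optionally bias-adjusted for
small groups, with permutation p-values.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import pcoa
from .io import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "permanova",
    "PermanovaResult",
    "beta_dispersion_test",
    "DispersionResult",
    "fit_lmm",
    "kruskal_dunn",
]

_RANK_TOL = 1e-8


# ---------------------------------------------------------------------------
# Sequential PERMANOVA
# ---------------------------------------------------------------------------

def _term_matrix(term: str, design: pd.DataFrame) -> np.ndarray:
    """Columns for one design term; ':' builds an interaction product."""
    parts = term.split(":")
    blocks = []
    for name in parts:
        if name not in design.columns:
            raise KeyError(f"term {name!r} not in design columns")
        col = design[name]
        if pd.api.types.is_numeric_dtype(col):
            blocks.append(col.to_numpy(dtype=float)[:, None])
        else:
            blocks.append(pd.get_dummies(col.astype(str)).to_numpy(dtype=float))
    out = blocks[0]
    for nxt in blocks[1:]:
        out = np.einsum("ij,ik->ijk", out, nxt).reshape(len(out), -1)
    return out


def _gower_center(dm_values: np.ndarray) -> np.ndarray:
    n = dm_values.shape[0]
    a = -0.5 * dm_values**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    return (g + g.T) / 2.0


@dataclass
class PermanovaResult:
    """Per-term ANOVA-style table from a sequential PERMANOVA."""

    table: pd.DataFrame
    n_permutations: int

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PermanovaResult(n_perm={self.n_permutations})\n{self.table}"


def permanova(
    dm: DistanceMatrix,
    design: pd.DataFrame,
    formula_terms: list[str],
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Sequential (Type-I) PERMANOVA over an ordered term list.

    Terms are fitted in the order given; a term whose columns are fully
    contained in the span of earlier terms is absorbed (df 0, SS 0) with a
    logged warning.  p-values use free permutation of sample identities:
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    design = design.loc[list(dm.ids)]
    n = dm.n
    g = _gower_center(dm.values)
    total_ss = float(np.trace(g))

    # orthonormal basis accumulation, starting from the intercept
    basis = np.ones((n, 1)) / np.sqrt(n)
    hats: list[np.ndarray] = []
    dfs: list[int] = []
    for term in formula_terms:
        x = _term_matrix(term, design)
        resid = x - basis @ (basis.T @ x)
        u, s, _ = np.linalg.svd(resid, full_matrices=False)
        keep = s > _RANK_TOL * max(s[0] if len(s) else 0.0, 1.0)
        q_new = u[:, keep]
        df = int(keep.sum())
        if df == 0:
            logger.warning("permanova: term %r absorbed by earlier terms (df 0)", term)
            hats.append(np.zeros((n, n)))
        else:
            hats.append(q_new @ q_new.T)
            basis = np.hstack([basis, q_new])
        dfs.append(df)

    df_res = n - basis.shape[1]
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    def _term_stats(gmat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ss = np.array([float(np.sum(h * gmat)) for h in hats])
        ss_res = total_ss - ss.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss / np.maximum(dfs, 1)) / (ss_res / df_res)
        f = np.where(np.array(dfs) > 0, f, np.nan)
        return ss, f

    ss_obs, f_obs = _term_stats(g)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(formula_terms))
    for _ in range(n_perm):
        p = rng.permutation(n)
        _, f_perm = _term_stats(g[np.ix_(p, p)])
        exceed += np.where(np.isnan(f_obs), 0, f_perm >= f_obs - 1e-12)
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    pvals = np.where(np.isnan(f_obs), np.nan, pvals)

    ss_res = total_ss - ss_obs.sum()
    rows = []
    for term, df, ss, f, p in zip(formula_terms, dfs, ss_obs, f_obs, pvals):
        rows.append(
            {"term": term, "df": df, "sum_of_squares": ss, "pseudo_F": f,
             "R2": ss / total_ss, "p": p}
        )
    rows.append(
        {"term": "Residual", "df": df_res, "sum_of_squares": ss_res,
         "pseudo_F": np.nan, "R2": ss_res / total_ss, "p": np.nan}
    )
    return PermanovaResult(pd.DataFrame(rows).set_index("term"), n_perm)


# ---------------------------------------------------------------------------
# Multivariate homogeneity of dispersion
# ---------------------------------------------------------------------------

@dataclass
class DispersionResult:
    """Distances to group centroids and permutation p-values."""

    distances: pd.Series  # per sample
    groups: pd.Series
    f_statistic: float
    p_value: float
    pairwise_p: dict[tuple[str, str], float] = field(default_factory=dict)
    bias_adjusted: bool = True

    def group_means(self) -> pd.Series:
        return self.distances.groupby(self.groups).mean()


def _centroid_distances(
    coords: np.ndarray, signs: np.ndarray, labels: np.ndarray, adjust: bool
) -> np.ndarray:
    d2 = np.empty(len(labels))
    for lab in np.unique(labels):
        m = labels == lab
        c = coords[m].mean(axis=0)
        delta2 = (coords[m] - c) ** 2
        d2[m] = delta2 @ signs
        if adjust:
            n_g = int(m.sum())
            d2[m] *= n_g / (n_g - 1)
    return np.sqrt(np.maximum(d2, 0.0))


def _anova_f(values: np.ndarray, labels: np.ndarray) -> float:
    grand = values.mean()
    ss_b = ss_w = 0.0
    k = 0
    for lab in np.unique(labels):
        m = labels == lab
        k += 1
        ss_b += m.sum() * (values[m].mean() - grand) ** 2
        ss_w += ((values[m] - values[m].mean()) ** 2).sum()
    df_b, df_w = k - 1, len(values) - k
    if ss_w <= 0:
        return np.inf if ss_b > 0 else 0.0
    return (ss_b / df_b) / (ss_w / df_w)


def beta_dispersion_test(
    dm: DistanceMatrix,
    groups: pd.Series,
    n_perm: int = 999,
    bias_adjust: bool = True,
    seed: int = 0,
    pairwise: bool = True,
) -> DispersionResult:
    """Permutation test of multivariate homogeneity of group dispersions.

    Samples are embedded by PCoA keeping negative-eigenvalue axes; each
    sample's squared distance to its group centroid subtracts the
    negative-axis contribution (floored at 0).  With ``bias_adjust``,
    squared distances are scaled by n_g/(n_g - 1) to counter the
    small-sample downward bias of distances to an estimated centroid.
    """
    groups = groups.loc[list(dm.ids)].astype(str)
    labels = groups.to_numpy()
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    for lab, c in zip(uniq, counts):
        if c < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 samples")

    coords, signs = pcoa(dm).axes_with_sign()
    dist_obs = _centroid_distances(coords, signs, labels, bias_adjust)
    f_obs = _anova_f(dist_obs, labels)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        f_p = _anova_f(_centroid_distances(coords, signs, perm, bias_adjust), perm)
        exceed += f_p >= f_obs - 1e-12
    p_global = (1 + exceed) / (1 + n_perm)

    pairwise_p: dict[tuple[str, str], float] = {}
    if pairwise:
        for a, b in itertools.combinations(uniq, 2):
            m = (labels == a) | (labels == b)
            sub_labels = labels[m]
            sub_coords = coords[m]
            d_obs = _centroid_distances(sub_coords, signs, sub_labels, bias_adjust)
            f_ab = _anova_f(d_obs, sub_labels)
            exc = 0
            for _ in range(n_perm):
                perm = rng.permutation(sub_labels)
                f_p = _anova_f(
                    _centroid_distances(sub_coords, signs, perm, bias_adjust), perm
                )
                exc += f_p >= f_ab - 1e-12
            pairwise_p[(a, b)] = (1 + exc) / (1 + n_perm)

    return DispersionResult(
        distances=pd.Series(dist_obs, index=pd.Index(dm.ids, name="sample_id")),
        groups=groups,
        f_statistic=f_obs,
        p_value=p_global,
        pairwise_p=pairwise_p,
        bias_adjusted=bias_adjust,
    )


# ---------------------------------------------------------------------------
# Linear mixed model (random intercept)
# ---------------------------------------------------------------------------

def fit_lmm(
    response,
    fixed_terms: list[str],
    random_intercept: str,
    frame: pd.DataFrame,
) -> pd.DataFrame:
    """Gaussian linear mixed model with one random intercept.

    Wraps ``statsmodels`` MixedLM:  response ~ fixed_terms + (1 | group).
    Returns the fixed-effect coefficient table (estimate, SE, t, p) with a
    ``converged`` flag column; non-convergence is flagged, never silent.
    """
    import statsmodels.formula.api as smf

    if frame[random_intercept].nunique() < 2:
        raise ValueError("random-intercept factor needs >= 2 levels")
    data = frame.copy()
    data["__response__"] = np.asarray(response, dtype=float)
    formula = "__response__ ~ " + (" + ".join(fixed_terms) if fixed_terms else "1")
    if np.allclose(data["__response__"], data["__response__"].iloc[0]):
        # degenerate constant response: slopes are exactly zero
        import patsy

        design = patsy.dmatrix(
            " + ".join(fixed_terms) if fixed_terms else "1", data, return_type="dataframe"
        )
        out = pd.DataFrame(
            {
                "estimate": 0.0,
                "se": 0.0,
                "t": np.nan,
                "p": np.nan,
                "converged": True,
            },
            index=design.columns,
        )
        out.loc["Intercept", "estimate"] = float(data["__response__"].iloc[0])
        return out

    model = smf.mixedlm(formula, data, groups=data[random_intercept])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True, method=["lbfgs", "powell"])
    fe = fit.fe_params
    out = pd.DataFrame(
        {
            "estimate": fe,
            "se": fit.bse_fe.loc[fe.index],
            "t": fit.tvalues.loc[fe.index],
            "p": fit.pvalues.loc[fe.index],
            "converged": bool(fit.converged),
        }
    )
    if not fit.converged:
        logger.warning("fit_lmm: optimizer did not converge; estimates flagged")
    return out


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn post-hocs
# ---------------------------------------------------------------------------

def kruskal_dunn(
    values,
    groups,
    p_adjust: str | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis test with Dunn's pairwise rank post-hocs.

    Returns ``(chi2, p, pairwise_table)``.  Dunn z-statistics use rank
    means with the tie-corrected variance; p-values are two-sided normal,
    unadjusted by default (``p_adjust="bh"`` applies Benjamini-Hochberg).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    split = [values[groups == g] for g in uniq]
    if any(len(s) == 0 for s in split):
        raise ValueError("empty group")

    if np.allclose(values, values[0]):
        chi2, p_kw = 0.0, 1.0
    else:
        chi2, p_kw = stats.kruskal(*split)

    n = len(values)
    ranks = stats.rankdata(values)
    # tie correction term for the Dunn variance
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    rank_means = {g: ranks[groups == g].mean() for g in uniq}
    sizes = {g: int((groups == g).sum()) for g in uniq}

    rows = []
    for a, b in itertools.combinations(uniq, 2):
        var = (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b])
        if var <= 0:
            z = 0.0
        else:
            z = (rank_means[a] - rank_means[b]) / np.sqrt(var)
        rows.append({"group1": a, "group2": b, "z": z,
                     "p": 2 * stats.norm.sf(abs(z))})
    pairwise = pd.DataFrame(rows)
    if p_adjust == "bh" and len(pairwise):
        from statsmodels.stats.multitest import multipletests

        pairwise["p_adjusted"] = multipletests(pairwise["p"], method="fdr_bh")[1]
    return float(chi2), float(p_kw), pairwise
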