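"""Iterative statistical screen selecting the mixing-model tracers.

Candidate variables are per-amino-acid isotope values (δ¹⁵N of each AA,
δ¹³C of essential AAs) measured on particle samples.  The screen:

1. drops any variable missing from at least ``max_missing`` (default 4)
   samples within any single size fraction;
2. keeps only variables that discriminate the three size fractions
   (one-way ANOVA, p < alpha);
3. checks, per fraction, that samples are homogeneous across site, cruise
   and depth (pairwise PERMANOVA on Euclidean distances over the selected
   tracers, Benjamini–Hochberg adjusted across pairs), supporting the
   decision to pool samples across those factors.

On data mimicking the study design this yields the two nitrogen source
amino acids (Phe, Lys) and the carbon essential amino acid (Leu).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TracerSet",
    "missingness_filter",
    "fraction_discrimination_screen",
    "permanova_pseudo_F",
    "within_fraction_homogeneity",
    "select_tracers",
    "METADATA_COLUMNS",
]

METADATA_COLUMNS = ("sample_id", "fraction", "site", "cruise", "depth", "seed")


def candidate_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in METADATA_COLUMNS]


def missingness_filter(table: pd.DataFrame, max_missing: int = 4,
                       candidates: list[str] | None = None,
                       per_fraction: bool = True) -> tuple[list[str], pd.DataFrame]:
    """Drop variables missing from >= ``max_missing`` samples.

    The strict reading is applied by default: a variable is dropped if its
    missing count reaches the threshold within ANY single size fraction
    (``per_fraction=False`` counts across the whole table instead).
    Returns (retained variables, per-variable missing-count evidence).
    """
    if len(table) == 0:
        raise ValueError("empty tracer table")
    if candidates is None:
        candidates = candidate_columns(table)
    if per_fraction:
        counts = table.groupby("fraction", observed=True)[candidates].apply(
            lambda g: g.isna().sum())
        worst = counts.max(axis=0)
    else:
        worst = table[candidates].isna().sum()
    retained = [c for c in candidates if worst[c] < max_missing]
    evidence = pd.DataFrame({"variable": candidates,
                             "max_missing_per_fraction": worst[candidates].to_numpy(),
                             "retained_missingness": [c in retained for c in candidates]})
    return retained, evidence


def fraction_discrimination_screen(table: pd.DataFrame, alpha: float = 0.05,
                                   candidates: list[str] | None = None,
                                   ) -> tuple[list[str], pd.DataFrame]:
    """Keep variables that differ between size fractions (one-way ANOVA p < alpha)."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if candidates is None:
        candidates = candidate_columns(table)
    retained, rows = [], []
    for var in candidates:
        groups = [g.dropna().to_numpy()
                  for _, g in table.groupby("fraction", observed=True)[var]]
        groups = [g for g in groups if len(g) > 0]
        if len(groups) < 2 or any(len(g) < 2 for g in groups):
            warnings.warn(f"variable {var!r}: insufficient replication; dropped")
            rows.append((var, np.nan, np.nan, False))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            F, p = stats.f_oneway(*groups)
        keep = bool(np.isfinite(p) and p < alpha)
        rows.append((var, float(F), float(p), keep))
        if keep:
            retained.append(var)
    evidence = pd.DataFrame(rows, columns=["variable", "anova_F", "anova_p",
                                           "retained_anova"])
    return retained, evidence


# --------------------------------------------------------------------------
# PERMANOVA


def _check_distance_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")
    if not np.allclose(np.diag(D), 0, atol=1e-10):
        raise ValueError("distance matrix must have zero diagonal")
    return D


def _pseudo_F_batch(D2: np.ndarray, label_matrix: np.ndarray,
                    group_ids: np.ndarray) -> np.ndarray:
    """Pseudo-F for each row of ``label_matrix`` (P, n) of integer labels.

    Uses the distance-based sums of squares: SS_total = sum_{i<j} d²/n,
    SS_within = sum_g sum_{i<j in g} d²/n_g; F = (SS_A/(a-1)) / (SS_W/(n-a)).
    Equivalent to the pseudo-F from the Gower-centred inner-product matrix.
    """
    n = D2.shape[0]
    ss_total = D2.sum() / (2 * n)
    a = len(group_ids)
    ss_within = np.zeros(label_matrix.shape[0])
    for g in group_ids:
        M = (label_matrix == g).astype(float)  # (P, n)
        n_g = M[0].sum()
        ss_within += np.einsum("pi,ij,pj->p", M, D2, M) / (2 * n_g)
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova_pseudo_F(distance_matrix: np.ndarray, labels,
                       n_perm: int = 999, seed: int = 0,
                       exhaustive: bool = False) -> tuple[float, float]:
    """Permutational multivariate ANOVA pseudo-F and permutation p-value.

    The pseudo-F compares among-group to within-group sums of squared
    distances.  The null distribution permutes the label vector; the
    Monte-Carlo p uses the add-one estimator
    ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)`` so p is never zero.  With
    ``exhaustive=True`` all label permutations are enumerated (feasible for
    small n) and the exact p is returned.
    """
    D = _check_distance_matrix(distance_matrix)
    labels = np.asarray(labels)
    n = len(labels)
    if D.shape[0] != n:
        raise ValueError("labels length must match distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2 or np.any(np.bincount(codes) < 2):
        raise ValueError("need >= 2 groups with >= 2 members each")
    D2 = D ** 2
    group_ids = np.arange(len(uniq))
    F_obs = float(_pseudo_F_batch(D2, codes[None, :], group_ids)[0])
    if exhaustive:
        perms = np.array(list(itertools.permutations(codes)))
        F_perm = _pseudo_F_batch(D2, perms, group_ids)
        p = float(np.mean(F_perm >= F_obs - 1e-12))
        return F_obs, p
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(codes) for _ in range(n_perm)])
    F_perm = _pseudo_F_batch(D2, perms, group_ids)
    p = float((1 + np.sum(F_perm >= F_obs - 1e-12)) / (1 + n_perm))
    return F_obs, p


def within_fraction_homogeneity(table: pd.DataFrame, tracers: list[str],
                                factors=("site", "cruise", "depth"),
                                n_perm: int = 999, seed: int = 0,
                                alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise PERMANOVA per size fraction and metadata factor.

    Euclidean distances over the tracer columns; raw p-values are
    Benjamini–Hochberg adjusted across the pairs of each fraction x factor
    cell.  A report with no adjusted p < alpha supports pooling samples
    across sites, cruises and depths within a fraction.  Pairs with a level
    of fewer than 2 samples are skipped and reported as such.
    """
    missing = [f for f in factors if f not in table.columns]
    if missing:
        raise ValueError(f"metadata columns missing: {missing}")
    rows = []
    for frac, sub in table.groupby("fraction", observed=True):
        X = sub[tracers].dropna()
        sub = sub.loc[X.index]
        D = squareform(pdist(X.to_numpy()))
        for factor in factors:
            levels = sub[factor].unique()
            pair_rows = []
            for a, b in itertools.combinations(sorted(levels, key=str), 2):
                mask = sub[factor].isin([a, b]).to_numpy()
                labs = sub.loc[mask, factor].to_numpy()
                if min((labs == a).sum(), (labs == b).sum()) < 2:
                    pair_rows.append((frac, factor, a, b, np.nan, np.nan, "skipped"))
                    continue
                F, p = permanova_pseudo_F(D[np.ix_(mask, mask)], labs,
                                          n_perm=n_perm, seed=seed)
                pair_rows.append((frac, factor, a, b, F, p, "tested"))
            tested = [r for r in pair_rows if r[6] == "tested"]
            if tested:
                p_adj = multipletests([r[5] for r in tested], method="fdr_bh")[1]
            padj_iter = iter(p_adj if tested else [])
            for r in pair_rows:
                adj = float(next(padj_iter)) if r[6] == "tested" else np.nan
                rows.append((*r[:6], adj, r[6]))
    report = pd.DataFrame(rows, columns=["fraction", "factor", "level_a", "level_b",
                                         "pseudo_F", "p_raw", "p_adj", "status"])
    report["significant"] = report["p_adj"] < alpha
    return report


@dataclass
class TracerSet:
    """Selected tracer variables plus the screening evidence."""

    selected: list[str]
    evidence: pd.DataFrame
    homogeneity: pd.DataFrame | None = None
    alpha: float = 0.05
    max_missing: int = 4

    def to_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "alpha": self.alpha,
            "max_missing": self.max_missing,
            "evidence": self.evidence.to_dict(orient="records"),
        }


def select_tracers(table: pd.DataFrame, alpha: float = 0.05,
                   max_missing: int = 4, n_perm: int = 999, seed: int = 0,
                   homogeneity: bool = True) -> TracerSet:
    """Chain the missingness filter and the fraction-discrimination screen.

    Deterministic given (data, alpha, max_missing, seed).  Raises if no
    variable survives both filters.
    """
    retained1, ev1 = missingness_filter(table, max_missing=max_missing)
    if retained1:
        retained2, ev2 = fraction_discrimination_screen(
            table, alpha=alpha, candidates=retained1)
    else:
        retained2, ev2 = [], pd.DataFrame(
            columns=["variable", "anova_F", "anova_p", "retained_anova"])
    evidence = ev1.merge(ev2, on="variable", how="left")
    evidence["selected"] = evidence["variable"].isin(retained2)
    if not retained2:
        raise ValueError("no usable tracers survive the screens")
    report = None
    if homogeneity:
        report = within_fraction_homogeneity(table, retained2,
                                             n_perm=n_perm, seed=seed)
    return TracerSet(retained2, evidence, report, alpha, max_missing)
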