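"""Tracer screening: missingness filter, ANOVA screen, PERMANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from midmix.synthetic import StudyConfig, generate_tracer_table
from midmix.tracer_selection import (fraction_discrimination_screen,
                                     missingness_filter, permanova_pseudo_F,
                                     select_tracers,
                                     within_fraction_homogeneity)


def _table(n_per_fraction=7, seed=0, extra=None):
    rng = np.random.default_rng(seed)
    rows = []
    for frac, shift in zip(("small", "medium", "large"), (0.0, 5.0, 10.0)):
        for i in range(n_per_fraction):
            row = {"sample_id": f"{frac}{i}", "fraction": frac,
                   "site": "A" if i % 2 else "B", "cruise": "c1", "depth": 1000.0,
                   "good": shift + rng.normal(), "flat": rng.normal()}
            rows.append(row)
    df = pd.DataFrame(rows)
    if extra:
        for k, v in extra.items():
            df[k] = v
    return df


class TestMissingness:
    def test_fully_observed_all_retained(self):
        retained, _ = missingness_filter(_table())
        assert set(retained) == {"good", "flat"}

    def test_threshold_boundary(self):
        df = _table()
        # 4 missing in one fraction -> dropped; 3 missing -> retained
        df.loc[df.index[df["fraction"] == "small"][:4], "good"] = np.nan
        df.loc[df.index[df["fraction"] == "medium"][:3], "flat"] = np.nan
        retained, ev = missingness_filter(df)
        assert retained == ["flat"]
        assert ev.set_index("variable").loc["good", "max_missing_per_fraction"] == 4

    def test_across_fraction_variant_is_laxer(self):
        df = _table()
        # 2 missing in each of two fractions: dropped per-fraction? no (max 2);
        # across-table count is 4 -> dropped only in the pooled reading
        idx_s = df.index[df["fraction"] == "small"][:2]
        idx_m = df.index[df["fraction"] == "medium"][:2]
        df.loc[idx_s.union(idx_m), "good"] = np.nan
        per_frac, _ = missingness_filter(df)
        pooled, _ = missingness_filter(df, per_fraction=False)
        assert "good" in per_frac and "good" not in pooled


class TestDiscriminationScreen:
    def test_flat_variable_dropped(self):
        retained, ev = fraction_discrimination_screen(_table())
        assert "good" in retained and "flat" not in retained

    def test_planted_separation_power(self):
        kept = sum("good" in fraction_discrimination_screen(_table(seed=s))[0]
                   for s in range(50))
        assert kept == 50  # 5 sd separation at n=7: essentially always retained

    def test_null_retention_rate_near_alpha(self):
        hits, total = 0, 300
        rng = np.random.default_rng(8)
        for _ in range(total):
            df = _table(seed=rng.integers(2 ** 31))
            df["nullvar"] = rng.normal(size=len(df))
            hits += "nullvar" in fraction_discrimination_screen(
                df, candidates=["nullvar"])[0]
        assert 0.02 < hits / total < 0.09

    def test_insufficient_replication_dropped_with_warning(self):
        df = _table(n_per_fraction=2)
        df.loc[df["fraction"] == "small", "good"] = np.nan
        df.loc[df.index[df["fraction"] == "medium"][0], "good"] = np.nan
        with pytest.warns(UserWarning, match="insufficient"):
            retained, _ = fraction_discrimination_screen(df, candidates=["good"])
        assert retained == []


def _brute_force_permanova(D, labels):
    """Independent oracle: pseudo-F from first principles + full enumeration."""
    labels = np.asarray(labels)
    n = len(labels)

    def F_of(labs):
        ss_t = (D ** 2).sum() / (2 * n)
        ss_w = 0.0
        for g in np.unique(labs):
            idx = np.flatnonzero(labs == g)
            ss_w += sum(D[i, j] ** 2 for i in idx for j in idx) / (2 * len(idx))
        a = len(np.unique(labs))
        return ((ss_t - ss_w) / (a - 1)) / (ss_w / (n - a))

    F_obs = F_of(labels)
    perms = [F_of(np.array(p)) for p in itertools.permutations(labels)]
    p = np.mean([f >= F_obs - 1e-12 for f in perms])
    return F_obs, p


class TestPermanova:
    def _cloud(self, seed=0, n=6, sep=3.0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 2))
        X[n // 2:] += sep
        D = squareform(pdist(X))
        labels = ["a"] * (n // 2) + ["b"] * (n - n // 2)
        return D, labels

    def test_exhaustive_matches_independent_enumeration(self):
        D, labels = self._cloud(seed=2)
        F, p = permanova_pseudo_F(D, labels, exhaustive=True)
        F_ref, p_ref = _brute_force_permanova(D, labels)
        assert F == pytest.approx(F_ref, rel=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_matches_scikit_bio_statistic(self):
        from skbio.stats.distance import DistanceMatrix, permanova
        D, labels = self._cloud(seed=5, n=8)
        F, _ = permanova_pseudo_F(D, labels, n_perm=99, seed=1)
        res = permanova(DistanceMatrix(D), grouping=labels, permutations=9)
        assert F == pytest.approx(res["test statistic"], rel=1e-10)

    def test_p_in_unit_interval_and_addone(self):
        D, labels = self._cloud(seed=3)
        _, p = permanova_pseudo_F(D, labels, n_perm=99, seed=0)
        assert 1 / 100 <= p <= 1.0

    def test_relabeling_within_groups_invariant(self):
        D, labels = self._cloud(seed=7, n=8)
        F1, _ = permanova_pseudo_F(D, labels, n_perm=9, seed=0)
        # swap two members of group a: statistic must not change
        order = [1, 0, 2, 3, 4, 5, 6, 7]
        F2, _ = permanova_pseudo_F(D[np.ix_(order, order)],
                                   np.asarray(labels)[order], n_perm=9, seed=0)
        assert F1 == pytest.approx(F2, rel=1e-12)

    def test_duplicated_points_keep_F_finite(self):
        D, labels = self._cloud(seed=9)
        n = len(labels)
        big = np.zeros((2 * n, 2 * n))
        big[:n, :n] = big[n:, n:] = D
        big[:n, n:] = big[n:, :n] = D  # duplicate cloud at distance D
        F, p = permanova_pseudo_F(big, labels * 2, n_perm=99, seed=0)
        assert np.isfinite(F) and 0 < p <= 1

    def test_invalid_inputs_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            permanova_pseudo_F(D, ["a", "b"])
        with pytest.raises(ValueError, match="groups"):
            permanova_pseudo_F(np.zeros((3, 3)), ["a", "a", "b"])


class TestHomogeneity:
    def test_exchangeable_data_rarely_flagged(self):
        flagged_runs = 0
        for seed in range(10):
            df = _table(n_per_fraction=8, seed=100 + seed)
            rep = within_fraction_homogeneity(df, ["good", "flat"],
                                              factors=("site",), seed=seed)
            flagged_runs += bool(rep["significant"].any())
        assert flagged_runs <= 2  # false-positive runs stay rare under the null

    def test_planted_site_shift_flagged(self):
        df = _table(n_per_fraction=8, seed=12)
        df.loc[df["site"] == "A", "good"] += 50.0  # huge planted shift
        rep = within_fraction_homogeneity(df, ["good"], factors=("site",), seed=0)
        assert rep["significant"].all()

    def test_single_level_factor_empty_report(self):
        df = _table()
        rep = within_fraction_homogeneity(df, ["good"], factors=("cruise",))
        assert len(rep) == 0

    def test_missing_metadata_rejected(self):
        df = _table().drop(columns="site")
        with pytest.raises(ValueError, match="site"):
            within_fraction_homogeneity(df, ["good"])


class TestSelectTracers:
    def test_planted_design_selects_exactly_three(self, study):
        ts = select_tracers(study.tracer_table, seed=0)
        assert set(ts.selected) == {"d15N_Phe", "d15N_Lys", "d13C_Leu"}

    def test_deterministic_across_generator_seeds(self):
        for seed in (1, 2, 3):
            tab = generate_tracer_table(StudyConfig(seed=seed))
            ts = select_tracers(tab, seed=0, homogeneity=False)
            assert set(ts.selected) == {"d15N_Phe", "d15N_Lys", "d13C_Leu"}

    def test_all_missing_errors(self):
        tab = generate_tracer_table(StudyConfig(seed=1))
        cols = [c for c in tab.columns if c.startswith("d1")]
        tab[cols] = np.nan
        with pytest.raises(ValueError, match="no usable tracers"):
            select_tracers(tab, homogeneity=False)

    def test_alpha_one_disables_discrimination_filter(self, study):
        ts = select_tracers(study.tracer_table, alpha=1.0, homogeneity=False)
        # every non-missing variable survives (decoys have p = 1 < alpha = 1? no:
        # p < 1 is false only for exactly-1 p-values; exchangeable decoys give F=0,
        # p=1, so alpha=1 keeps variables with p strictly below 1)
        assert set(ts.selected) >= {"d15N_Phe", "d15N_Lys", "d13C_Leu"}
        assert "d15N_Gly" not in ts.selected  # still removed by missingness

    def test_screen_order_independent_per_variable(self, study):
        tab = study.tracer_table
        r1, _ = missingness_filter(tab)
        r2, _ = fraction_discrimination_screen(tab, candidates=r1)
        r3, _ = fraction_discrimination_screen(tab)
        r4, _ = missingness_filter(tab, candidates=r3)
        assert set(r2) == set(r4)
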