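"""Conclusion-level statistics: the trophic-base census and guild structure.

From per-consumer mixing posteriors (pooled to small 0.7–6 µm vs large
>6 µm classes) this module counts, per depth stratum, how many consumers
draw at least half of their trophic base from large particles; summarises
mean ± SD contributions per consumer group; and computes feeding-guild
proportions (taxon-weighted and density-weighted) from the trait table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CensusReport",
    "threshold_census",
    "group_contributions",
    "guild_proportions",
    "build_report",
    "DEFAULT_STRATA",
]

#: half-open [lower, upper) depth strata in metres; half-open so a consumer
#: at exactly 1000 m is counted once in the discharge stratum.
DEFAULT_STRATA = {"700-1500": (700.0, 1500.0), "1000-1500": (1000.0, 1500.0)}


@dataclass
class CensusReport:
    threshold: float
    strata: dict
    counts: pd.DataFrame  # stratum, n, n_above, percent
    criterion: str = "posterior_mean"

    def to_dict(self) -> dict:
        return {"threshold": self.threshold, "criterion": self.criterion,
                "strata": {k: list(v) for k, v in self.strata.items()},
                "counts": self.counts.to_dict(orient="records")}


def threshold_census(results: pd.DataFrame, threshold: float = 0.5,
                     strata: dict = DEFAULT_STRATA,
                     value_col: str = "p_large_mean",
                     prob_col: str | None = "p_large_prob_ge_half",
                     ) -> CensusReport:
    """Count consumers whose pooled large-fraction posterior mean >= threshold.

    ``results`` is the per-consumer summary table with ``depth_m`` and the
    pooled large-fraction posterior mean.  If a posterior-probability
    column is present, the alternative criterion
    P(p_large >= 0.5) >= 0.5 is reported side by side.  Strata are
    half-open ``[lower, upper)`` depth windows; an empty stratum is
    reported with n = 0.
    """
    rows = []
    for name, (lo, hi) in strata.items():
        sub = results[(results["depth_m"] >= lo) & (results["depth_m"] < hi)]
        n = len(sub)
        n_above = int((sub[value_col] >= threshold).sum())
        row = {"stratum": name, "n": n, "n_above": n_above,
               "percent": 100.0 * n_above / n if n else np.nan}
        if prob_col and prob_col in results.columns:
            row["n_above_prob"] = int((sub[prob_col] >= 0.5).sum())
        rows.append(row)
    return CensusReport(threshold, dict(strata), pd.DataFrame(rows))


def group_contributions(results: pd.DataFrame,
                        group_col: str = "group",
                        small_col: str = "p_small_mean",
                        large_col: str = "p_large_mean",
                        threshold: float = 0.5) -> dict:
    """Mean ± SD of pooled contributions per consumer group.

    Every consumer must carry a group label; the summary also counts how
    many groups have a mean large-particle contribution above ``threshold``.
    """
    unassigned = results.loc[results[group_col].isna(), "consumer_id"].tolist() \
        if group_col in results.columns else []
    if group_col not in results.columns or unassigned:
        raise ValueError(f"consumers without group assignment: {unassigned or 'all'}")
    agg = results.groupby(group_col, observed=True).agg(
        n=("consumer_id", "size"),
        small_mean=(small_col, "mean"), small_sd=(small_col, "std"),
        large_mean=(large_col, "mean"), large_sd=(large_col, "std"),
    ).reset_index()
    n_above = int((agg["large_mean"] > threshold).sum())
    return {"table": agg, "n_groups": len(agg),
            "n_groups_large_dominant": n_above, "threshold": threshold}


def guild_proportions(trait_table: pd.DataFrame, weights: str | None = None,
                      ) -> pd.DataFrame:
    """Feeding-guild proportions per community group.

    ``weights=None`` gives taxon-count proportions; ``weights='density'``
    weights each taxon by its ``density_weight`` column (e.g. to express
    what share of micronekton density is zooplanktivorous).
    """
    if trait_table["guild"].isna().any():
        raise ValueError("trait table has taxa without guild labels")
    if weights not in (None, "density"):
        raise ValueError(f"unknown weighting {weights!r}")
    if weights == "density" and "density_weight" not in trait_table.columns:
        raise ValueError("density weighting requested but no density_weight column")
    w = (trait_table["density_weight"] if weights == "density"
         else pd.Series(1.0, index=trait_table.index))
    df = trait_table.assign(_w=w)
    out = (df.groupby(["group", "guild"], observed=True)["_w"].sum()
             .rename("weight").reset_index())
    totals = out.groupby("group")["weight"].transform("sum")
    out["percent"] = 100.0 * out["weight"] / totals
    out["weighting"] = weights or "taxon"
    return out


def build_report(census: CensusReport | None = None,
                 groups: dict | None = None,
                 guilds: pd.DataFrame | None = None,
                 aa_contrasts: list | None = None,
                 lisst_summary: dict | None = None,
                 seed: int | None = None) -> dict:
    """Assemble the machine-readable study report; empty sections are omitted."""
    report: dict = {}
    if seed is not None:
        report["seed"] = seed
    if census is not None:
        report["census"] = census.to_dict()
    if groups is not None:
        report["group_contributions"] = {
            "table": groups["table"].to_dict(orient="records"),
            "n_groups": groups["n_groups"],
            "n_groups_large_dominant": groups["n_groups_large_dominant"],
            "threshold": groups["threshold"],
        }
    if guilds is not None:
        report["guild_proportions"] = guilds.to_dict(orient="records")
    if aa_contrasts:
        report["aa_contrasts"] = [
            {"fraction": r.fraction, "F": r.F, "p": r.p,
             "df_between": r.df_between, "df_within": r.df_within,
             "group_sizes": list(r.group_sizes)}
            for r in aa_contrasts]
    if lisst_summary:
        report["lisst"] = lisst_summary
    return report


def render_report_md(report: dict) -> str:
    """Human-readable companion to the JSON report."""
    lines = ["# Midwater food-web report", ""]
    if "seed" in report:
        lines.append(f"Seed: {report['seed']}")
    if "census" in report:
        lines += ["", "## Trophic-base census",
                  f"Threshold: large-fraction posterior mean >= {report['census']['threshold']}"]
        for row in report["census"]["counts"]:
            pct = row["percent"]
            lines.append(f"- {row['stratum']} m: {row['n_above']}/{row['n']} consumers"
                         + (f" ({pct:.0f}%)" if row["n"] else " (empty stratum)"))
    if "group_contributions" in report:
        g = report["group_contributions"]
        lines += ["", "## Group contributions",
                  f"{g['n_groups_large_dominant']} of {g['n_groups']} groups have mean "
                  f"large-particle contribution > {g['threshold']}"]
    if "aa_contrasts" in report:
        lines += ["", "## Amino-acid concentration contrasts (one-way ANOVA)"]
        for r in report["aa_contrasts"]:
            lines.append(f"- {r['fraction']}: F = {r['F']:.3g}, p = {r['p']:.3g}")
    if "guild_proportions" in report:
        lines += ["", "## Feeding-guild proportions"]
        for row in report["guild_proportions"]:
            lines.append(f"- {row['group']} / {row['guild']} "
                         f"({row['weighting']}-weighted): {row['percent']:.1f}%")
    if "lisst" in report:
        lines += ["", "## Particle field", json.dumps(report["lisst"], indent=2)]
    return "\n".join(lines) + "\n"
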