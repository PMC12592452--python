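"""Seeded synthetic datasets with the statistical structure of the field study.

The generators emulate, fraction by fraction, the data the analysis chain
consumes:

* per-fraction source tracer samples (δ¹⁵N of Phe/Lys, δ¹³C of Leu) for the
  three particle size fractions (0.7–6, 6–53, >53 µm), 7 samples each;
* consumers whose tracer vectors are Dirichlet-style mixtures of the source
  means with mixture-propagated noise — exactly the generative model the
  mixing model inverts, so parameter recovery is a clean test of the sampler;
* amino-acid concentration records (ngN/µgPN) for background vs plume and
  discharge particles, lognormal with moment-matched group means/SDs;
* LISST casts with a quiescent deep baseline, a background offset per size
  class, and (for plume casts) a lognormal-shaped volume mode in the small
  size classes centred near the discharge depth;
* a taxon→feeding-guild trait table hitting configured guild proportions
  exactly by largest-remainder rounding, with density weights.

Every generator draws from its own stream derived from ``(seed, stream_id)``
so outputs are reproducible independently of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .particle_field import LisstCast, SizeBinGrid, DEFAULT_FRACTION_WINDOWS

__all__ = [
    "StudyConfig",
    "SyntheticStudy",
    "generate_source_samples",
    "generate_consumers",
    "generate_aa_concentration_table",
    "generate_lisst_casts",
    "generate_trait_table",
    "generate_tracer_table",
    "generate_study",
    "paperlike_mixtures",
    "largest_remainder_counts",
]

FRACTIONS = ("small", "medium", "large")
TRACERS = ("d15N_Phe", "d15N_Lys", "d13C_Leu")

# Default source signatures (per mil).  The deposited field data are not
# reproduced here; these are realistic CSIA-AA values for three mutually
# well-separated deep particle pools (5-8 within-fraction SDs apart,
# pairwise, and off-collinear): δ15N_Phe baseline rises with size, the
# medium fraction carries strongly elevated δ15N_Lys (heterotrophic
# microbial resynthesis) with the most depleted essential-AA δ13C, and the
# large fraction is the isotopically heaviest in both N tracers.  The
# off-axis medium pool keeps the source triangle well conditioned, matching
# the study premise that the screened tracers discriminate the fractions.
DEFAULT_SOURCE_MEANS = np.array([
    #  d15N_Phe  d15N_Lys  d13C_Leu
    [2.0, 4.0, -26.0],    # small  0.7–6 µm
    [5.0, 14.0, -28.0],   # medium 6–53 µm
    [10.0, 13.0, -19.0],  # large  >53 µm
])
DEFAULT_SOURCE_SDS = np.full((3, 3), 1.0)

# Amino-acid concentration targets, ngN/µgPN (mean, SD) per group x fraction.
AA_TARGETS = {
    "background": {"small": (4.7, 2.7), "medium": (41.1, 25.3), "large": (46.3, 34.7)},
    "plume": {"small": (3.8, 4.4), "medium": (1.7, 1.5), "large": (4.2, 4.7)},
    "discharge": {"small": (3.8, 4.4), "medium": (1.7, 1.5), "large": (4.2, 4.7)},
}
AA_GROUP_N = {"background": 7, "plume": 3, "discharge": 3}

# fixed per-generator stream ids so outputs are order-independent
_STREAMS = {"sources": 1, "consumers": 2, "aa": 3, "lisst": 4, "traits": 5,
            "tracer_table": 6}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass
class LisstConfig:
    """Synthetic cast geometry and amplitudes.

    Depths span the lower mesopelagic / upper bathypelagic habitat
    (700–1500 db) at 0.5-db raw sampling; the plume layer sits near the
    1250 m discharge depth.  ``plume_fraction_totals`` are the small/large
    fraction volume sums (µL/L) at the plume core after calibration;
    ``background_fraction_totals`` play the same role for the broad
    background enhancement.  The plume PSD mode defaults to 3.5 µm, inside
    the 2.6–4.3 µm band where plume maxima are observed.
    """

    depth_min: float = 700.0
    depth_max: float = 1500.0
    raw_sampling: float = 0.5  # db between raw samples (finer than 1-db bins)
    n_background: int = 3
    n_plume: int = 5
    plume_center: float = 1250.0
    plume_width: float = 60.0  # Gaussian SD of the plume layer, db
    plume_fraction_totals: dict = field(
        default_factory=lambda: {"small": 9.80, "large": 2.18})
    background_fraction_totals: dict = field(
        default_factory=lambda: {"small": 0.08, "large": 0.23})
    modal_diameter: float = 3.5  # µm, plume PSD mode
    psd_logsd: float = 0.35     # lognormal width of the plume PSD (log-µm)
    class_offset: float = 0.05  # per-class instrument offset, µL/L
    noise_sd: float = 0.002     # additive measurement noise, µL/L


@dataclass
class StudyConfig:
    """Parameters of a synthetic study; defaults are the study conditions."""

    n_sources: int = 3
    fraction_labels: tuple = FRACTIONS
    tracer_names: tuple = TRACERS
    source_means: np.ndarray = field(default_factory=lambda: DEFAULT_SOURCE_MEANS.copy())
    source_sds: np.ndarray = field(default_factory=lambda: DEFAULT_SOURCE_SDS.copy())
    n_source_samples: int = 7
    consumer_mixtures: np.ndarray | None = None  # (N, K); default paper-like set
    consumer_groups: list | None = None
    consumer_depths: np.ndarray | None = None
    measurement_sd: np.ndarray | float = 0.5  # ‰ per tracer
    mis_specified_noise_scale: float = 1.0  # >1 inflates generator noise vs model
    aa_targets: dict = field(default_factory=lambda: {g: dict(v) for g, v in AA_TARGETS.items()})
    aa_group_n: dict = field(default_factory=lambda: dict(AA_GROUP_N))
    aa_distribution: str = "lognormal"  # or "truncnorm"
    lisst: LisstConfig = field(default_factory=LisstConfig)
    zoop_guilds: dict = field(default_factory=lambda: {
        "particle_feeder": 0.53, "gelatinous": 0.20})
    zoop_n_taxa: int = 79
    micro_guilds: dict = field(default_factory=lambda: {
        "zooplanktivore": 0.60, "pelagic_micronektonivore": 0.375,
        "gelatinous_zooplanktivore": 0.0125, "pelagic_generalist": 0.0125})
    micro_n_taxa: int = 80
    micro_zoopl_density_share: float = 0.85
    seed: int = 0

    def __post_init__(self):
        self.source_means = np.asarray(self.source_means, dtype=float)
        self.source_sds = np.asarray(self.source_sds, dtype=float)
        K, J = len(self.fraction_labels), len(self.tracer_names)
        if self.source_means.shape != (K, J) or self.source_sds.shape != (K, J):
            raise ValueError("source_means/source_sds must be K x J")
        if np.any(self.source_sds < 0):
            raise ValueError("source_sds must be non-negative")
        self.measurement_sd = np.broadcast_to(
            np.asarray(self.measurement_sd, dtype=float), (J,)).copy()
        if np.any(self.measurement_sd < 0):
            raise ValueError("measurement_sd must be non-negative")
        if self.consumer_mixtures is None:
            mix, groups, depths = paperlike_mixtures(self.seed)
            self.consumer_mixtures = mix
            if self.consumer_groups is None:
                self.consumer_groups = groups
            if self.consumer_depths is None:
                self.consumer_depths = depths
        self.consumer_mixtures = np.asarray(self.consumer_mixtures, dtype=float)
        if self.consumer_mixtures.ndim != 2 or self.consumer_mixtures.shape[1] != K:
            raise ValueError("consumer_mixtures must be (N, K)")
        if (np.any(self.consumer_mixtures < 0)
                or np.any(np.abs(self.consumer_mixtures.sum(axis=1) - 1) > 1e-12)):
            raise ValueError("each mixture must be non-negative and sum to 1")
        n = len(self.consumer_mixtures)
        if self.consumer_groups is None:
            self.consumer_groups = [f"group_{i % 4}" for i in range(n)]
        if self.consumer_depths is None:
            self.consumer_depths = np.linspace(
                self.lisst.depth_min, self.lisst.depth_max - 1, n)
        self.consumer_depths = np.asarray(self.consumer_depths, dtype=float)


# --------------------------------------------------------------------------
# paper-like census structure

ZOOP_GROUPS = ("zoop_0.2-0.5mm", "zoop_0.5-1.0mm", "zoop_1.0-2.0mm", "zoop_2.0-5.0mm")
MICRO_GROUPS = ("A_brevicarinata", "Cyclothone_spp", "Japatella_spp", "Eucopia_spp")


def paperlike_mixtures(seed: int = 0):
    """Planted true mixtures reproducing the study's census regime.

    46 consumers in 8 groups (4 zooplankton size fractions + 4 micronekton
    taxa).  By construction: 30 of 46 consumers have pooled large-fraction
    (>6 µm = medium + large) truth above 0.5; 26 consumers sit in the
    discharge stratum (1000–1500 m), 16 of them above 0.5; 5 of the 8 groups
    are large-dominant on average.  Mixtures are kept well away from the 0.5
    boundary (pooled-large truth in 0.80-0.95 or 0.05-0.20, i.e. a margin of
    at least 0.30, about four posterior-mean error SDs under the default
    tracer noise) so the census tests the pipeline, not boundary shrinkage.

    Returns (mixtures (46,3), group labels, depths in m).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(17,)))
    groups8 = list(ZOOP_GROUPS + MICRO_GROUPS)
    sizes = [6, 6, 6, 6, 6, 6, 5, 5]
    large_dominant_groups = set(groups8[:5])  # 5 of 8 groups
    mixtures, labels, above = [], [], []
    for g, n in zip(groups8, sizes):
        for _ in range(n):
            if g in large_dominant_groups:
                large = rng.uniform(0.80, 0.95)
                above.append(True)
            else:
                large = rng.uniform(0.05, 0.20)
                above.append(False)
            medium_share = rng.uniform(0.35, 0.65)
            mixtures.append([1.0 - large, large * medium_share,
                             large * (1.0 - medium_share)])
            labels.append(g)
    mixtures = np.asarray(mixtures)
    above = np.asarray(above)
    assert above.sum() == 30 and len(above) == 46
    # depths: 16 of the 30 large-dominant and 10 of the 16 small-dominant
    # consumers in the discharge stratum [1000, 1500); the rest in [700, 1000)
    depths = np.empty(46)
    idx_above = np.flatnonzero(above)
    idx_below = np.flatnonzero(~above)
    depths[idx_above[:16]] = rng.uniform(1000, 1499, 16)
    depths[idx_above[16:]] = rng.uniform(700, 999, 14)
    depths[idx_below[:10]] = rng.uniform(1000, 1499, 10)
    depths[idx_below[10:]] = rng.uniform(700, 999, 6)
    return mixtures, labels, depths


# --------------------------------------------------------------------------
# generators


def generate_source_samples(config: StudyConfig) -> pd.DataFrame:
    """Draw ``n_source_samples`` tracer values per fraction from the source pools.

    Long format: sample_id, fraction, tracer, value_permil, seed.
    """
    rng = _rng(config.seed, "sources")
    rows = []
    for k, frac in enumerate(config.fraction_labels):
        for i in range(config.n_source_samples):
            sid = f"{frac}_{i + 1:02d}"
            for j, tr in enumerate(config.tracer_names):
                val = rng.normal(config.source_means[k, j], config.source_sds[k, j])
                rows.append((sid, frac, tr, val))
    df = pd.DataFrame(rows, columns=["sample_id", "fraction", "tracer", "value_permil"])
    df["seed"] = config.seed
    return df


def consumer_noise_sd(config: StudyConfig, p: np.ndarray) -> np.ndarray:
    """SD of a consumer tracer under mixture ``p`` — the model's own formula."""
    var = (p ** 2) @ (config.source_sds ** 2) + config.measurement_sd ** 2
    return config.mis_specified_noise_scale * np.sqrt(var)


def generate_consumers(config: StudyConfig) -> pd.DataFrame:
    """Consumers drawn from the mixing model's generative distribution.

    Tracer j of a consumer with true mixture p is
    Normal(Σ_k p_k·m_kj, sqrt(Σ_k p_k²·s_kj² + τ_j²)); the true p is stored
    alongside in ``true_p_*`` columns.
    """
    rng = _rng(config.seed, "consumers")
    P = config.consumer_mixtures
    rows = []
    for i, p in enumerate(P):
        mu = p @ config.source_means
        sd = consumer_noise_sd(config, p)
        x = rng.normal(mu, sd)
        rows.append(x)
    df = pd.DataFrame(rows, columns=list(config.tracer_names))
    df.insert(0, "consumer_id", [f"c{i + 1:03d}" for i in range(len(P))])
    df.insert(1, "group", list(config.consumer_groups))
    df.insert(2, "depth_m", config.consumer_depths)
    df.insert(3, "depth_stratum",
              np.where(config.consumer_depths >= 1000, "1000-1500", "700-1000"))
    for k, frac in enumerate(config.fraction_labels):
        df[f"true_p_{frac}"] = P[:, k]
    df["seed"] = config.seed
    return df


def _lognormal_params(mean: float, sd: float):
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return mu, np.sqrt(sigma2)


def generate_aa_concentration_table(config: StudyConfig) -> pd.DataFrame:
    """Amino-acid concentration records per group x size fraction.

    Draws are lognormal with moment-matched mean/SD by default (the targets
    have SD ≈ mean, so a normal would put mass below zero); a truncated
    normal is available via ``aa_distribution='truncnorm'``.  Subsample
    fractions and the implied raw masses are included so the normalization
    arithmetic is exercisable end to end.
    """
    from scipy import stats as sps

    rng = _rng(config.seed, "aa")
    rows = []
    i = 0
    for group, fracs in config.aa_targets.items():
        n = config.aa_group_n[group]
        for frac, (mean, sd) in fracs.items():
            if mean <= 0 or sd < 0:
                raise ValueError(f"invalid AA target for {group}/{frac}")
            for _ in range(n):
                i += 1
                if sd == 0:
                    conc = mean
                elif config.aa_distribution == "lognormal":
                    mu, sigma = _lognormal_params(mean, sd)
                    conc = float(rng.lognormal(mu, sigma))
                elif config.aa_distribution == "truncnorm":
                    a = (0.0 - mean) / sd
                    conc = float(sps.truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                                                   random_state=rng))
                else:
                    raise ValueError(f"unknown aa_distribution {config.aa_distribution!r}")
                # back out plausible raw subsample masses consistent with the record
                bulk_pn = float(rng.uniform(20.0, 120.0))  # µg N on whole filter
                f_bulk, f_csia = 0.5, 0.5
                rows.append((f"aa{i:03d}", group, frac,
                             conc * bulk_pn * f_csia, bulk_pn * f_bulk,
                             f_bulk, f_csia, conc))
    df = pd.DataFrame(rows, columns=[
        "sample_id", "sample_type", "size_fraction", "total_aa_N", "bulk_PN",
        "subsample_fraction_bulk", "subsample_fraction_csia", "normalized_conc"])
    df["seed"] = config.seed
    return df


def _plume_class_profile(cfg: LisstConfig, grid: SizeBinGrid,
                         windows=DEFAULT_FRACTION_WINDOWS) -> np.ndarray:
    """Per-class plume volumes (µL/L) at the plume core.

    Shape is a lognormal PSD over diameter peaking at ``modal_diameter``;
    each fraction window is rescaled so its class sum hits the configured
    core total exactly (before noise).
    """
    logd = np.log(grid.centers)
    shape = np.exp(-0.5 * ((logd - np.log(cfg.modal_diameter)) / cfg.psd_logsd) ** 2)
    vols = np.zeros(grid.n_bins)
    for name, (lo, hi) in windows.items():
        mask = (grid.centers >= lo) & (grid.centers < hi)
        target = cfg.plume_fraction_totals.get(name, 0.0)
        w = shape[mask]
        if w.sum() <= 0 and target > 0:
            raise ValueError(f"plume PSD has no mass in window {name}")
        if target > 0:
            vols[mask] = target * w / w.sum()
    return vols


def _background_class_profile(cfg: LisstConfig, grid: SizeBinGrid,
                              windows=DEFAULT_FRACTION_WINDOWS) -> np.ndarray:
    """Broad background particle enhancement per class at its core depth."""
    logd = np.log(grid.centers)
    shape = np.exp(-0.5 * ((logd - np.log(8.0)) / 1.0) ** 2)  # broad, gentle
    vols = np.zeros(grid.n_bins)
    for name, (lo, hi) in windows.items():
        mask = (grid.centers >= lo) & (grid.centers < hi)
        target = cfg.background_fraction_totals.get(name, 0.0)
        w = shape[mask]
        if target > 0:
            vols[mask] = target * w / w.sum()
    return vols


def generate_lisst_casts(config: StudyConfig) -> list[LisstCast]:
    """Raw (0.5-db sampled) background and plume casts.

    Every cast has a per-class constant instrument offset (removed by
    baseline calibration), a small additive noise floor, and a quiescent
    deepest-10 m segment carrying baseline only.  Plume casts add a
    lognormal-shaped volume mode in the small classes centred at the plume
    depth; background casts carry a broad, weak mid-depth enhancement.
    """
    cfg = config.lisst
    if cfg.depth_max - cfg.depth_min < 10:
        raise ValueError("depth range must span at least 10 m for calibration")
    rng = _rng(config.seed, "lisst")
    grid = SizeBinGrid.lisst_default()
    depths = np.arange(cfg.depth_min, cfg.depth_max + 1e-9, cfg.raw_sampling)
    quiescent = depths >= depths.max() - 10.0
    casts = []

    def make(cast_id, cast_type, core_profile, center, width):
        envelope = np.exp(-0.5 * ((depths - center) / width) ** 2)
        envelope[quiescent] = 0.0  # deepest 10 m stay at baseline
        vols = envelope[:, None] * core_profile[None, :]
        vols += cfg.class_offset
        vols += np.abs(rng.normal(0.0, cfg.noise_sd, vols.shape))
        df = pd.DataFrame(vols, columns=grid.bin_columns())
        df.insert(0, "depth_db", depths)
        return LisstCast(cast_id, cast_type, df, grid)

    bg_profile = _background_class_profile(cfg, grid)
    for i in range(cfg.n_background):
        casts.append(make(f"bg_{i + 1}", "background", bg_profile,
                          0.5 * (cfg.depth_min + cfg.depth_max), 250.0))
    plume_profile = _plume_class_profile(cfg, grid)
    for i in range(cfg.n_plume):
        casts.append(make(f"plume_{i + 1}", "plume", plume_profile,
                          cfg.plume_center, cfg.plume_width))
    return casts


def largest_remainder_counts(total: int, proportions: dict[str, float],
                             other_label: str = "other") -> dict[str, int]:
    """Integer counts hitting ``proportions`` of ``total`` by largest remainder.

    Proportions must sum to <= 1; any shortfall is assigned to
    ``other_label``.
    """
    props = dict(proportions)
    s = sum(props.values())
    if s > 1 + 1e-9 or any(v < 0 for v in props.values()):
        raise ValueError(f"infeasible guild proportions (sum {s:.4f})")
    if s < 1 - 1e-9:
        props[other_label] = 1.0 - s
    labels = list(props)
    raw = np.array([props[g] * total for g in labels])
    base = np.floor(raw + 1e-9).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base))
    for i in range(short):
        base[order[i]] += 1
    return dict(zip(labels, base.tolist()))


def generate_trait_table(config: StudyConfig) -> pd.DataFrame:
    """Taxon → feeding-guild table with density weights.

    Guild counts hit the configured proportions exactly by construction.
    Micronekton density weights are set so zooplanktivores carry the
    configured share (default 85%) of total micronekton density.
    """
    rng = _rng(config.seed, "traits")
    rows = []
    zoop_counts = largest_remainder_counts(config.zoop_n_taxa, config.zoop_guilds)
    i = 0
    for guild, n in zoop_counts.items():
        for _ in range(n):
            i += 1
            rows.append((f"zoop_taxon_{i:03d}", "zooplankton", guild, 1.0))
    micro_counts = largest_remainder_counts(config.micro_n_taxa, config.micro_guilds)
    n_zp = micro_counts.get("zooplanktivore", 0)
    n_other = config.micro_n_taxa - n_zp
    share = config.micro_zoopl_density_share
    if n_zp and n_other:
        # per-taxon weight ratio giving zooplanktivores `share` of density
        w_zp = share * n_other / ((1 - share) * n_zp)
    else:
        w_zp = 1.0
    i = 0
    for guild, n in micro_counts.items():
        w = w_zp if guild == "zooplanktivore" else 1.0
        for _ in range(n):
            i += 1
            rows.append((f"micro_taxon_{i:03d}", "micronekton", guild, w))
    df = pd.DataFrame(rows, columns=["taxon", "group", "guild", "density_weight"])
    df["depth_stratum"] = "1000-1500"
    df["seed"] = config.seed
    return df


def generate_tracer_table(config: StudyConfig, n_decoys: int = 12,
                          missing_var: str = "d15N_Gly",
                          n_missing: int = 4) -> pd.DataFrame:
    """A planted candidate-tracer table for the selection screen.

    The configured tracers discriminate between fractions (their means come
    from ``source_means``, separated by several SD); ``n_decoys`` additional
    amino-acid variables are exchangeable across fractions — the same sample
    values recur in every fraction, so their between-fraction variance is
    exactly zero and the discrimination screen rejects them deterministically
    under any seed.  One decoy is additionally missing from ``n_missing``
    samples of the small fraction, exercising the missingness filter.
    Site/cruise/depth metadata are exchangeable across samples.
    """
    rng = _rng(config.seed, "tracer_table")
    n = config.n_source_samples
    decoy_names = [missing_var] + [f"d15N_AA{i:02d}" for i in range(1, n_decoys)]
    decoy_vals = {name: rng.normal(5.0 + d, 1.5, n)
                  for d, name in enumerate(decoy_names)}
    rows = []
    sites = ["site_A", "site_B"]
    cruises = ["spring", "fall"]
    for k, frac in enumerate(config.fraction_labels):
        for i in range(n):
            row = {
                "sample_id": f"{frac}_{i + 1:02d}", "fraction": frac,
                "site": sites[i % 2], "cruise": cruises[(i // 2) % 2],
                "depth": [900.0, 1100.0, 1300.0][i % 3],
            }
            for j, tr in enumerate(config.tracer_names):
                row[tr] = rng.normal(config.source_means[k, j], config.source_sds[k, j])
            for name in decoy_names:
                row[name] = decoy_vals[name][i]
            rows.append(row)
    df = pd.DataFrame(rows)
    small_idx = df.index[df["fraction"] == "small"][:n_missing]
    df.loc[small_idx, missing_var] = np.nan
    df["seed"] = config.seed
    return df


def source_summary_from_config(config: StudyConfig):
    """A SourceSummary carrying the generating (true) source parameters.

    Useful for sampler-calibration studies where source-estimation noise
    should not enter; SDs are floored the same way `summarize_sources`
    floors them.
    """
    from .mixing_model import SD_FLOOR, SourceSummary

    return SourceSummary(
        list(config.fraction_labels), list(config.tracer_names),
        config.source_means.copy(),
        np.maximum(config.source_sds, SD_FLOOR),
        np.full(len(config.fraction_labels), config.n_source_samples),
    )


@dataclass
class SyntheticStudy:
    """Bundle of all generated tables for one seed."""

    config: StudyConfig
    source_table: pd.DataFrame
    consumer_table: pd.DataFrame
    aa_conc_table: pd.DataFrame
    lisst_casts: list[LisstCast]
    trait_table: pd.DataFrame
    tracer_table: pd.DataFrame


def generate_study(config: StudyConfig | None = None, seed: int | None = None,
                   ) -> SyntheticStudy:
    """Generate every table of a synthetic study under one seed."""
    if config is None:
        config = StudyConfig(seed=0 if seed is None else seed)
    elif seed is not None:
        config = replace(config, seed=seed)
    return SyntheticStudy(
        config=config,
        source_table=generate_source_samples(config),
        consumer_table=generate_consumers(config),
        aa_conc_table=generate_aa_concentration_table(config),
        lisst_casts=generate_lisst_casts(config),
        trait_table=generate_trait_table(config),
        tracer_table=generate_tracer_table(config),
    )
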