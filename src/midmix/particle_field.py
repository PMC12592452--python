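"""Processing of LISST-style particle size-distribution casts.

A laser-diffraction cast reports particle volume concentration (µL/L) in 32
logarithmically spaced size classes per depth sample.  The processing chain
is: bin to 1-db depth intervals, calibrate each size class against its
minimum over the deepest 10 m of the cast (the quiescent deep baseline),
then aggregate classes into the small (1.25–6 µm) and large (6–250 µm)
fractions and optionally convert volumes to number concentrations with a
spherical-particle model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SizeBinGrid",
    "LisstCast",
    "bin_to_depth",
    "baseline_calibrate",
    "aggregate_fractions",
    "volume_to_counts",
    "psd_maxima",
    "DEFAULT_FRACTION_WINDOWS",
]

#: fraction windows in µm; class membership is decided by bin centre.
DEFAULT_FRACTION_WINDOWS = {"small": (1.25, 6.0), "large": (6.0, 250.0)}

UL_PER_UM3 = 1e-12  # 1 µm³ = 1e-12 µL


@dataclass(frozen=True)
class SizeBinGrid:
    """Logarithmic size-class grid.

    The default mirrors the instrument: 32 classes with centres
    log-spaced from 1.36 to 230.14 µm (common ratio ≈ 1.18), giving
    bandwidths from about 0.22 to 38 µm.  Edges are reconstructed at the
    geometric half-step, so adjacent classes tile the size axis exactly.
    """

    centers: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.centers, dtype=float)
        object.__setattr__(self, "centers", c)
        if np.any(np.diff(c) <= 0):
            raise ValueError("bin centers must be strictly increasing")

    @classmethod
    def lisst_default(cls) -> "SizeBinGrid":
        return cls(np.geomspace(1.36, 230.14, 32))

    @property
    def ratio(self) -> float:
        return float(np.exp(np.mean(np.diff(np.log(self.centers)))))

    @property
    def lower_edges(self) -> np.ndarray:
        return self.centers / np.sqrt(self.ratio)

    @property
    def upper_edges(self) -> np.ndarray:
        return self.centers * np.sqrt(self.ratio)

    @property
    def bandwidths(self) -> np.ndarray:
        return self.upper_edges - self.lower_edges

    @property
    def n_bins(self) -> int:
        return len(self.centers)

    def bin_columns(self) -> list[str]:
        return [f"bin_{i + 1:02d}" for i in range(self.n_bins)]


@dataclass
class LisstCast:
    """One cast: depth series (db) x size-class volume concentrations (µL/L)."""

    cast_id: str
    cast_type: str  # background | plume
    data: pd.DataFrame  # columns: depth_db, bin_01..bin_NN
    grid: SizeBinGrid = field(default_factory=SizeBinGrid.lisst_default)
    calibrated: bool = False
    binned: bool = False

    def __post_init__(self):
        if self.cast_type not in ("background", "plume"):
            raise ValueError(f"unknown cast_type {self.cast_type!r}")
        missing = [c for c in ["depth_db", *self.grid.bin_columns()]
                   if c not in self.data.columns]
        if missing:
            raise ValueError(f"cast table missing columns {missing}")

    @property
    def volumes(self) -> np.ndarray:
        return self.data[self.grid.bin_columns()].to_numpy(dtype=float)

    @property
    def depths(self) -> np.ndarray:
        return self.data["depth_db"].to_numpy(dtype=float)


def bin_to_depth(cast: LisstCast, bin_size: float = 1.0) -> LisstCast:
    """Average each size class into depth bins (default 1 db).

    Unordered depths are sorted first; bins with no samples are absent from
    the output.  Bins are labelled by their centre depth.
    """
    if len(cast.data) == 0:
        raise ValueError("empty cast")
    df = cast.data.sort_values("depth_db")
    idx = np.floor(df["depth_db"].to_numpy() / bin_size).astype(int)
    binned = df.groupby(idx, sort=True).mean(numeric_only=True)
    binned["depth_db"] = (binned.index.to_numpy() + 0.5) * bin_size
    binned = binned.reset_index(drop=True)[cast.data.columns]
    return replace(cast, data=binned, binned=True)


def baseline_calibrate(cast: LisstCast, baseline_span: float = 10.0) -> LisstCast:
    """Subtract each size class's minimum over the deepest ``baseline_span`` db.

    The deepest segment of a cast is assumed particle-quiescent, so its
    per-class minima estimate the instrument/background offset.  Volumes are
    floored at zero.  Idempotent: the deep minima of a calibrated cast are
    zero.
    """
    depths = cast.depths
    span = depths.max() - depths.min()
    if span < baseline_span:
        raise ValueError(
            f"cast spans {span:.1f} db; need >= {baseline_span} db for the "
            "deep calibration segment")
    deep = depths >= depths.max() - baseline_span
    offsets = cast.volumes[deep].min(axis=0)
    vols = np.clip(cast.volumes - offsets, 0.0, None)
    data = cast.data.copy()
    data[cast.grid.bin_columns()] = vols
    return replace(cast, data=data, calibrated=True)


def _window_mask(grid: SizeBinGrid, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return (grid.centers >= lo) & (grid.centers < hi)


def aggregate_fractions(cast: LisstCast,
                        windows: dict[str, tuple[float, float]] = DEFAULT_FRACTION_WINDOWS,
                        ) -> pd.DataFrame:
    """Per-depth summed volume (µL/L) of classes whose centres fall in each window."""
    out = {"depth_db": cast.depths}
    vols = cast.volumes
    for name, window in windows.items():
        out[name] = vols[:, _window_mask(cast.grid, window)].sum(axis=1)
    return pd.DataFrame(out)


def volume_to_counts(cast: LisstCast,
                     windows: dict[str, tuple[float, float]] | None = DEFAULT_FRACTION_WINDOWS,
                     ) -> pd.DataFrame:
    """Convert class volumes to number concentrations (particles/L).

    Spherical-particle model: ``N_i = V_i / ((π/6) d_i³)`` with ``d_i`` the
    bin centre.  Returns per-class counts plus per-window totals.
    """
    d = cast.grid.centers
    per_particle_ul = (np.pi / 6.0) * d ** 3 * UL_PER_UM3
    counts = cast.volumes / per_particle_ul  # particles/L
    out = pd.DataFrame(counts, columns=[f"count_{c}" for c in cast.grid.bin_columns()])
    out.insert(0, "depth_db", cast.depths)
    if windows:
        for name, window in windows.items():
            out[name] = counts[:, _window_mask(cast.grid, window)].sum(axis=1)
    return out


def psd_maxima(cast: LisstCast, depth_window: tuple[float, float],
               rel_tol: float = 1e-9) -> np.ndarray:
    """Modal diameter(s) of the mean PSD within a depth window.

    Returns the bin centre(s) maximising mean volume concentration; exact
    ties are all reported.  An all-zero window yields an empty result.
    """
    lo, hi = depth_window
    sel = (cast.depths >= lo) & (cast.depths < hi)
    if not sel.any():
        raise ValueError(f"no samples in depth window {depth_window}")
    mean_psd = cast.volumes[sel].mean(axis=0)
    peak = mean_psd.max()
    if peak <= 0:
        return np.array([])
    ties = mean_psd >= peak * (1 - rel_tol)
    return cast.grid.centers[ties]
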