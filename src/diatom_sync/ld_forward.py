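"""Forward model from cell orientations to laser-diffraction size classes.

True inversion of ring-detector scattering is out of scope; instead each
cell deposits volume into the log-spaced size-class bin containing its
*apparent* (projected) major extent, and into the bin containing its minor
axis.  The Ratio of the minor-axis band (VD1) to the major-axis band (VD2)
volume concentrations is then a scalar proxy for population orientation.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError, ValidationError
from .population_sim import PopulationTrajectory

__all__ = [
    "CellGeometry",
    "SizeClassGrid",
    "SizeBand",
    "SizeClassSeries",
    "RatioSeries",
    "DEFAULT_VD1",
    "DEFAULT_VD2",
    "apparent_length",
    "observe",
    "ratio_series",
]

#: Size bands (µm) capturing the minor/major apparent cell dimensions.
DEFAULT_VD1 = None  # set below, after SizeBand is defined
DEFAULT_VD2 = None

# conversion: 1 µm³ per litre = 1e-9 µL L⁻¹
_UM3_TO_UL = 1.0e-9


@dataclass(frozen=True)
class CellGeometry:
    """Prolate-spheroid cell axes in µm (full axis lengths)."""

    major_axis_um: float = 10.5
    minor_axis_um: float = 3.0

    def __post_init__(self):
        if not self.major_axis_um > self.minor_axis_um > 0:
            raise ValidationError("cell axes must satisfy major > minor > 0")

    def volume_um3(self) -> float:
        """Spheroid volume (4/3)·π·(a/2)·(b/2)² with full axes a, b."""
        a = self.major_axis_um / 2.0
        b = self.minor_axis_um / 2.0
        return 4.0 / 3.0 * math.pi * a * b * b


class SizeClassGrid:
    """32 contiguous, logarithmically spaced size-class bins (µm)."""

    def __init__(self, lower_um: float = 1.25, upper_um: float = 250.0, n_classes: int = 32):
        if not 0 < lower_um < upper_um:
            raise ValidationError("grid edges must satisfy 0 < lower < upper")
        if n_classes < 1:
            raise ValidationError("need at least one size class")
        self.n_classes = int(n_classes)
        self.edges = np.geomspace(lower_um, upper_um, self.n_classes + 1)

    @property
    def centers(self) -> np.ndarray:
        """Geometric bin centers (µm)."""
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    def bin_index(self, length_um) -> np.ndarray:
        """Bin holding each length; lengths outside the range clip to the
        nearest edge bin (callers may count them via :meth:`out_of_range`)."""
        idx = np.searchsorted(self.edges, np.asarray(length_um, dtype=float), side="right") - 1
        return np.clip(idx, 0, self.n_classes - 1)

    def out_of_range(self, length_um) -> int:
        length_um = np.asarray(length_um, dtype=float)
        return int(np.sum((length_um < self.edges[0]) | (length_um >= self.edges[-1])))


@dataclass(frozen=True)
class SizeBand:
    """A [lo, hi] µm band of the size-class axis with a role label."""

    lo_um: float
    hi_um: float
    role: str

    def __post_init__(self):
        if not self.lo_um < self.hi_um:
            raise ValidationError("band requires lo < hi")
        if self.role not in ("VD1", "VD2"):
            raise ValidationError("band role must be VD1 or VD2")

    def mask(self, grid: SizeClassGrid) -> np.ndarray:
        """Band membership by bin *center* — stable under grid refinement."""
        c = grid.centers
        return (c >= self.lo_um) & (c <= self.hi_um)


DEFAULT_VD1 = SizeBand(2.5, 3.5, "VD1")
DEFAULT_VD2 = SizeBand(7.33, 14.0, "VD2")


@dataclass
class SizeClassSeries:
    """Time × size-class volume-concentration matrix (µL L⁻¹)."""

    times: np.ndarray
    volume_concentration: np.ndarray
    grid: SizeClassGrid
    n_clipped: int = 0

    def __post_init__(self):
        vc = np.asarray(self.volume_concentration, dtype=float)
        if vc.ndim != 2 or vc.shape[1] != self.grid.n_classes:
            raise ValidationError("volume matrix must be (n_times, n_classes)")
        if vc.shape[0] != len(self.times):
            raise ValidationError("times and volume matrix length mismatch")
        if np.any(vc < 0):
            raise ValidationError("volume concentrations must be nonnegative")

    def to_csv(self, path):
        buf = io.StringIO()
        edges = ",".join(f"{e:.6f}" for e in self.grid.edges)
        buf.write(f"# size_class_edges_um: {edges}\n")
        buf.write(f"# n_clipped: {self.n_clipped}\n")
        cols = {"time_s": self.times}
        cols.update(
            {f"vc_{i + 1:02d}": self.volume_concentration[:, i] for i in range(self.grid.n_classes)}
        )
        pd.DataFrame(cols).to_csv(buf, index=False, float_format="%.10g")
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def from_csv(cls, path) -> "SizeClassSeries":
        edges = None
        n_clipped = 0
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if "size_class_edges_um:" in line:
                    edges = np.array([float(x) for x in line.split(":", 1)[1].split(",")])
                elif "n_clipped:" in line:
                    n_clipped = int(line.split(":", 1)[1])
        df = pd.read_csv(path, comment="#")
        vc_cols = [c for c in df.columns if c.startswith("vc_")]
        if edges is None:
            raise AnalysisError("size-class CSV lacks the edge metadata header")
        grid = SizeClassGrid(edges[0], edges[-1], len(vc_cols))
        return cls(
            times=df["time_s"].to_numpy(),
            volume_concentration=df[vc_cols].to_numpy(),
            grid=grid,
            n_clipped=n_clipped,
        )


@dataclass
class RatioSeries:
    """The scalar orientation proxy Σ(VD1 band) / Σ(VD2 band) over time.

    ``valid`` flags samples where the VD2 band sum was positive; invalid
    samples carry NaN in ``ratio`` rather than being dropped.
    """

    times: np.ndarray
    ratio: np.ndarray
    valid: np.ndarray
    normalization: str = "none"

    def __post_init__(self):
        if not (len(self.times) == len(self.ratio) == len(self.valid)):
            raise ValidationError("ratio series arrays must share a length")

    def to_csv(self, path):
        pd.DataFrame(
            {"time_s": self.times, "ratio": self.ratio, "valid": self.valid.astype(int)}
        ).to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "RatioSeries":
        df = pd.read_csv(path, comment="#")
        return cls(
            times=df["time_s"].to_numpy(dtype=float),
            ratio=df["ratio"].to_numpy(dtype=float),
            valid=df["valid"].to_numpy().astype(bool),
        )


def apparent_length(geometry: CellGeometry, tilt_rad) -> np.ndarray | float:
    """Projected major extent of a prolate spheroid tilted out of the
    detector plane by angle β: √(r₁²·cos²β + r₂²·sin²β).

    Periodic in β; vectorized over ``tilt_rad``.
    """
    beta = np.asarray(tilt_rad, dtype=float)
    r1 = geometry.major_axis_um
    r2 = geometry.minor_axis_um
    out = np.sqrt(r1 * r1 * np.cos(beta) ** 2 + r2 * r2 * np.sin(beta) ** 2)
    return float(out) if out.ndim == 0 else out


def observe(
    trajectory: PopulationTrajectory,
    geometry: CellGeometry | None = None,
    grid: SizeClassGrid | None = None,
    noise_cv: float = 0.0,
    seed: int | None = None,
) -> SizeClassSeries:
    """Bin cell projections into size classes at every sample time.

    Each cell splits its volume between the bin containing its apparent
    major extent and the bin containing its minor axis, with weights linear
    in the apparent length: w_major = (L − r₂)/(r₁ − r₂), w_minor = 1 −
    w_major.  A face-on cell (L = r₁) registers entirely at its major
    extent, an end-on cell (L = r₂) entirely at its minor axis, and the
    smooth weighting makes the band signal respond to orientation even when
    the apparent length stays inside one band.  The total deposited volume
    per time step equals cell_density · cell_volume exactly (before noise).
    Multiplicative lognormal noise of coefficient of variation ``noise_cv``
    is applied per bin per time; its log-scale mean is chosen so the noise
    factor has unit expectation.
    """
    geometry = geometry or CellGeometry()
    grid = grid or SizeClassGrid()
    if noise_cv < 0:
        raise ValidationError("noise_cv must be ≥ 0")

    cfg = trajectory.config
    n_cells = cfg.n_cells
    total_volume_ul = cfg.cell_density_per_l * geometry.volume_um3() * _UM3_TO_UL
    unit = total_volume_ul / n_cells  # volume per cell

    lengths = apparent_length(geometry, trajectory.tilts())  # (T, N)
    n_times = lengths.shape[0]
    n_clipped = grid.out_of_range(lengths)

    major_idx = grid.bin_index(lengths)
    minor_idx = int(grid.bin_index(geometry.minor_axis_um))
    w_major = (lengths - geometry.minor_axis_um) / (
        geometry.major_axis_um - geometry.minor_axis_um
    )
    w_major = np.clip(w_major, 0.0, 1.0)

    flat = (np.arange(n_times)[:, None] * grid.n_classes + major_idx).ravel()
    vc = np.bincount(
        flat, weights=w_major.ravel(), minlength=n_times * grid.n_classes
    ).reshape(n_times, grid.n_classes)
    vc *= unit
    vc[:, minor_idx] += (1.0 - w_major).sum(axis=1) * unit

    if noise_cv > 0:
        rng = np.random.default_rng(cfg.seed + 0x5EED if seed is None else seed)
        sigma = math.sqrt(math.log1p(noise_cv * noise_cv))
        vc = vc * rng.lognormal(-0.5 * sigma * sigma, sigma, size=vc.shape)

    return SizeClassSeries(
        times=trajectory.times.copy(),
        volume_concentration=vc,
        grid=grid,
        n_clipped=n_clipped,
    )


def ratio_series(
    series: SizeClassSeries,
    vd1: SizeBand | None = None,
    vd2: SizeBand | None = None,
) -> RatioSeries:
    """Per-time quotient of VD1-band and VD2-band volume sums.

    Samples with a zero VD2 sum are flagged invalid (NaN ratio), never
    silently dropped; an all-invalid series is an error.
    """
    vd1 = vd1 or DEFAULT_VD1
    vd2 = vd2 or DEFAULT_VD2
    if vd1.hi_um > vd2.lo_um:
        raise ValidationError("VD1 band must lie entirely below VD2")
    m1 = vd1.mask(series.grid)
    m2 = vd2.mask(series.grid)
    if not m1.any() or not m2.any():
        raise ValidationError("a size band contains no bin centers")
    s1 = series.volume_concentration[:, m1].sum(axis=1)
    s2 = series.volume_concentration[:, m2].sum(axis=1)
    valid = s2 > 0
    if not valid.any():
        raise AnalysisError("VD2 band sum is zero at every time point")
    ratio = np.full_like(s1, np.nan)
    ratio[valid] = s1[valid] / s2[valid]
    return RatioSeries(times=series.times.copy(), ratio=ratio, valid=valid)
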