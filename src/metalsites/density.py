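"""Real-space density maps and anomalous-peak evidence for metal sites.

Peak heights are reported in map-sigma units: the voxel standard deviation
about the map mean, over all voxels.  Heights are therefore invariant under
linear rescaling of the map values.  CCP4/MRC files are read and written
through gemmi; interpolation and normalization are done here on the raw
grid so that synthetic in-memory maps behave identically to file-backed
ones.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .structure import UnitCell
from .sites import SiteReport

__all__ = ["DensityMap", "read_map", "write_map", "peak_height",
           "attach_evidence"]


@dataclass
class DensityMap:
    """A full-cell density grid indexed [ix, iy, iz] along fractional axes."""

    values: np.ndarray
    cell: UnitCell
    spacegroup: str = "P 1"
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("density grid must be 3-D with >= 2 points per axis")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density grid contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sigma(self) -> float:
        return float(self.values.std())

    def value_at_fractional(self, frac: np.ndarray) -> float:
        """Trilinear interpolation with periodic wrapping."""
        frac = np.asarray(frac, dtype=float) % 1.0
        n = np.array(self.shape)
        g = frac * n
        i0 = np.floor(g).astype(int) % n
        w = g - np.floor(g)
        val = 0.0
        for corner in itertools.product((0, 1), repeat=3):
            idx = tuple((i0 + corner) % n)
            weight = np.prod([w[k] if corner[k] else 1.0 - w[k]
                              for k in range(3)])
            val += weight * float(self.values[idx])
        return val


def read_map(path: str | Path) -> DensityMap:
    """Read a CCP4/MRC map (modes 0/1/2; axis permutations honored)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot read map {path}: {exc}") from exc
    m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    grid = m.grid
    arr = np.array(grid, copy=True)
    if np.isnan(arr).any():
        # portions outside the recorded extent: fill with the map mean
        arr = np.nan_to_num(arr, nan=float(np.nanmean(arr)))
    cell = UnitCell(grid.unit_cell.a, grid.unit_cell.b, grid.unit_cell.c,
                    grid.unit_cell.alpha, grid.unit_cell.beta,
                    grid.unit_cell.gamma)
    sg = grid.spacegroup.hm if grid.spacegroup else "P 1"
    return DensityMap(values=arr, cell=cell, spacegroup=sg, source=str(path))


def write_map(dmap: DensityMap, path: str | Path) -> Path:
    """Write a full-cell CCP4 map (mode 2, float32)."""
    path = Path(path)
    grid = gemmi.FloatGrid(*dmap.shape)
    grid.set_unit_cell(gemmi.UnitCell(*dmap.cell.parameters))
    sg = gemmi.find_spacegroup_by_name(dmap.spacegroup)
    grid.spacegroup = sg if sg is not None else gemmi.find_spacegroup_by_name("P 1")
    arr = np.array(grid, copy=False)
    arr[...] = dmap.values
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header(2, True)
    m.write_ccp4_map(str(path))
    return path


def peak_height(dmap: DensityMap, xyz: np.ndarray, mode: str = "local_max",
                radius: float = 0.75) -> float:
    """Normalized density height at a position, in map-sigma units.

    ``at_point`` evaluates the trilinear interpolant exactly at ``xyz``;
    ``local_max`` (default) takes the maximum grid value within ``radius``
    of the point, since a refined atom center rarely coincides with the peak
    voxel.  Points outside the cell are wrapped by lattice periodicity.
    """
    sigma = dmap.sigma
    if sigma <= 0:
        raise ValueError("map is constant; sigma normalization undefined")
    mean = dmap.mean
    frac = dmap.cell.fractionalize(np.asarray(xyz, dtype=float))
    if mode == "at_point":
        return (dmap.value_at_fractional(frac) - mean) / sigma
    if mode != "local_max":
        raise ValueError(f"unknown mode {mode!r}")
    if radius <= 0:
        raise ValueError("radius must be positive")
    n = np.array(dmap.shape)
    # conservative index window: radius over the smallest grid step per axis
    steps = np.array([dmap.cell.a, dmap.cell.b, dmap.cell.c]) / n
    half = np.maximum(np.ceil(radius / steps).astype(int) + 1, 1)
    center_idx = np.round((frac % 1.0) * n).astype(int)
    best = -np.inf
    offsets = np.stack(np.meshgrid(
        *[np.arange(-h, h + 1) for h in half], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    idx = (center_idx + offsets) % n
    frac_pts = (center_idx + offsets) / n
    xyz_pts = dmap.cell.orthogonalize(frac_pts)
    target = dmap.cell.orthogonalize(frac % 1.0)
    d = np.linalg.norm(xyz_pts - target, axis=1)
    mask = d <= radius
    if not mask.any():
        mask = d <= d.min() + 1e-9
    vals = dmap.values[idx[mask, 0], idx[mask, 1], idx[mask, 2]]
    best = float(vals.max())
    return (best - mean) / sigma


def attach_evidence(report: SiteReport, dmap: DensityMap,
                    threshold: float = 3.0, mode: str = "local_max",
                    radius: float = 0.75) -> SiteReport:
    """Annotate every site with its map peak height; flag weak evidence.

    The default 3.0 sigma threshold matches the customary contour level for
    displaying anomalous difference density.  The map and the report's
    structure must share the same unit cell to within 1%.
    """
    if report.cell is not None:
        if not dmap.cell.is_close(UnitCell(*report.cell), rtol=0.01):
            raise ValueError(
                f"map cell {dmap.cell.parameters} does not match structure "
                f"cell {report.cell} within 1%")
    for site in report.sites:
        h = peak_height(dmap, site.metal.xyz, mode=mode, radius=radius)
        site.evidence_sigma = h
        site.flags = [f for f in site.flags if f != "weak_evidence"]
        if h < threshold:
            site.flags.append("weak_evidence")
    report.settings = dict(report.settings)
    report.settings["evidence"] = {"threshold_sigma": threshold, "mode": mode,
                                   "radius": radius, "map": dmap.source}
    return report
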