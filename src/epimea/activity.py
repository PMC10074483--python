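"""Per-electrode FP-rate maps and automatic most-active-area selection.

The experimenters located the most active slice region by eye from the
activity map and raster plot; here that step is an explicit, parameterised
algorithm: threshold the rate grid at the 75th percentile of nonzero rates,
take 4-connected components, keep the component with the largest total rate
(ties: larger size, then smallest row-major index of its top-left electrode),
and dilate by one electrode ring until a minimum size is reached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .conditions import ArrayGeometry
from .detect import FPEvent
from .simulate import REGION_CODES, REGION_NAMES

__all__ = ["ActivityMap", "compute_map", "select_active_area", "build_activity_map"]


@dataclass
class ActivityMap:
    rates: np.ndarray  # (n_rows, n_cols) Hz
    area_mask: np.ndarray  # boolean grid, 4-connected
    area_region: str  # "HPC" | "CTX" | "unknown"
    window: tuple[float, float]


def compute_map(
    fps: list[FPEvent], geometry: ArrayGeometry, window: tuple[float, float]
) -> np.ndarray:
    """FP rate per electrode: count in the half-open window / window length."""
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("window must have positive length")
    rates = np.zeros((geometry.n_rows, geometry.n_cols))
    for fp in fps:
        if t0 <= fp.onset < t1:
            rates[fp.row, fp.col] += 1
    return rates / (t1 - t0)


_RING = np.ones((3, 3), dtype=bool)  # one-electrode ring = 8-neighbourhood


def select_active_area(
    rates: np.ndarray,
    region_labels: np.ndarray | None = None,
    min_size: int = 4,
    percentile: float = 75.0,
) -> np.ndarray:
    """Select the most active 4-connected electrode component.

    Raises ``ValueError("no activity")`` on an all-zero map.
    """
    rates = np.asarray(rates, dtype=float)
    nonzero = rates[rates > 0]
    if nonzero.size == 0:
        raise ValueError("no activity")
    on_slice = None
    if region_labels is not None:
        on_slice = np.asarray(region_labels) != REGION_CODES["off_slice"]

    thr = np.percentile(nonzero, percentile)
    # strictly above the percentile; on flat maps (nothing strictly above,
    # e.g. a uniform grid) fall back to >= so the plateau itself is selected
    mask = rates > thr
    if not mask.any():
        mask = rates >= thr
    mask &= rates > 0
    if on_slice is not None:
        mask &= on_slice
    labels, n_comp = ndimage.label(mask)  # default structure: 4-connectivity
    if n_comp == 0:
        raise ValueError("no activity")

    best = None
    for comp_id in range(1, n_comp + 1):
        comp = labels == comp_id
        total = float(rates[comp].sum())
        size = int(comp.sum())
        rr, cc = np.nonzero(comp)
        top_left = int(rr.min() * rates.shape[1] + cc[rr == rr.min()].min())
        key = (total, size, -top_left)
        if best is None or key > best[0]:
            best = (key, comp)
    area = best[1]

    while area.sum() < min_size:
        grown = ndimage.binary_dilation(area, structure=_RING)
        if on_slice is not None:
            grown &= on_slice
        if grown.sum() == area.sum():
            break  # cannot grow further inside the slice
        area = grown
    return area


def area_region(area_mask: np.ndarray, region_labels: np.ndarray | None) -> str:
    """Majority-vote HPC/CTX attribution of the selected area."""
    if region_labels is None:
        return "unknown"
    codes = np.asarray(region_labels)[area_mask]
    hpc = int((codes == REGION_CODES["HPC"]).sum())
    ctx = int((codes == REGION_CODES["CTX"]).sum())
    if hpc == ctx == 0:
        return "unknown"
    return REGION_NAMES[REGION_CODES["HPC"] if hpc >= ctx else REGION_CODES["CTX"]]


def build_activity_map(
    fps: list[FPEvent],
    geometry: ArrayGeometry,
    window: tuple[float, float],
    region_labels: np.ndarray | None = None,
    min_size: int = 4,
    percentile: float = 75.0,
) -> ActivityMap:
    rates = compute_map(fps, geometry, window)
    mask = select_active_area(rates, region_labels, min_size=min_size, percentile=percentile)
    return ActivityMap(rates, mask, area_region(mask, region_labels), window)


def plot_activity_map(amap: ActivityMap, path: str) -> None:
    """Optional PNG rendering (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(amap.rates, cmap="Greens", origin="upper")
    rr, cc = np.nonzero(amap.area_mask)
    ax.scatter(cc, rr, s=4, c="red", marker="s", label="active area")
    fig.colorbar(im, ax=ax, label="FP rate (Hz)")
    ax.set_title(f"most active area ({amap.area_region})")
    ax.legend(loc="lower right", fontsize=7)
    fig.savefig(path, dpi=120)
    plt.close(fig)
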