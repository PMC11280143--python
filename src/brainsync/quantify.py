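"""Atlas compartmentalization, AP binning, region filters, and densities.

Every positive pixel (axon channel) or detected spot (activity channel) is
assigned to the atlas region labeling its coordinate; per-slice counts are
accumulated into fixed-width bins along the anterior-posterior axis (a
slice's AP coordinate is its anterior face, bins are half-open
[start, start + width)).  Region-selection filters and volume-based density
normalization follow the published thresholds and are deterministic and
independent of sample ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "BinnedTrace",
    "DensityTable",
    "compartmentalize",
    "compartmentalize_spots",
    "bin_trace",
    "select_regions_ochief",
    "select_regions_cfos",
    "cfos_density",
]

BACKGROUND_LABEL = 0


@dataclass(frozen=True)
class BinnedTrace:
    region_id: int
    hemisphere: str
    bin_width_um: float
    bin_starts_um: np.ndarray
    values: np.ndarray  # counts per bin, >= 0


@dataclass(frozen=True)
class DensityTable:
    """Per-sample, per-region activity density and WT-ctrl-relative density."""

    density: pd.DataFrame  # samples x regions, cells/mm^3
    relative: pd.DataFrame  # samples x retained regions, unitless
    dropped_low_density: list
    dropped_zero_baseline: list


def compartmentalize(
    mask_stack: np.ndarray,
    binary_stack: np.ndarray,
) -> pd.DataFrame:
    """Count positive pixels per (region, slice); background counted apart.

    Returns a long table (region_id, slice, count) that includes a
    ``region_id == 0`` row per slice holding events falling outside any
    labeled region, so total counts are conserved exactly.
    """
    masks = np.asarray(mask_stack)
    sig = np.asarray(binary_stack, dtype=bool)
    if masks.shape != sig.shape:
        raise ValueError(
            f"mask stack {masks.shape} and signal stack {sig.shape} differ in shape"
        )
    if masks.ndim == 2:
        masks, sig = masks[None], sig[None]
    n_labels = int(masks.max()) + 1
    rows = []
    for z in range(masks.shape[0]):
        counts = np.bincount(masks[z][sig[z]].ravel(), minlength=n_labels)
        for rid in np.nonzero(counts)[0]:
            rows.append({"region_id": int(rid), "slice": z, "count": int(counts[rid])})
    return pd.DataFrame(rows, columns=["region_id", "slice", "count"])


def compartmentalize_spots(
    mask_stack: np.ndarray,
    spots: pd.DataFrame,
    pixel_um: float,
) -> pd.DataFrame:
    """Assign spot centers (slice, x_um, y_um) to region labels.

    A spot belongs to the region labeling the pixel containing its center;
    centers outside the image bounds raise an error.
    """
    masks = np.asarray(mask_stack)
    if masks.ndim == 2:
        masks = masks[None]
    rows = []
    counts: dict[tuple[int, int], int] = {}
    for _, s in spots.iterrows():
        z = int(s["slice"])
        r = int(np.floor(s["y_um"] / pixel_um))
        c = int(np.floor(s["x_um"] / pixel_um))
        if not (0 <= z < masks.shape[0] and 0 <= r < masks.shape[1] and 0 <= c < masks.shape[2]):
            raise ValueError(f"spot at slice={z}, ({s['x_um']}, {s['y_um']}) um is out of bounds")
        key = (int(masks[z, r, c]), z)
        counts[key] = counts.get(key, 0) + 1
    for (rid, z), n in sorted(counts.items()):
        rows.append({"region_id": rid, "slice": z, "count": n})
    return pd.DataFrame(rows, columns=["region_id", "slice", "count"])


def bin_trace(
    per_slice_counts: np.ndarray,
    slice_ap_um: np.ndarray,
    bin_width_um: float = 100.0,
    ap_origin_um: float = 0.0,
    n_bins: int | None = None,
    region_id: int = 0,
    hemisphere: str = "",
) -> BinnedTrace:
    """Accumulate per-slice counts into half-open AP bins.

    Each slice's count is added to the bin containing its AP coordinate
    (anterior face); the sum over bins equals the sum over slices.  Handles
    slice grids not aligned to bin boundaries.
    """
    counts = np.asarray(per_slice_counts, dtype=float)
    ap = np.asarray(slice_ap_um, dtype=float)
    if counts.shape != ap.shape:
        raise ValueError("counts and AP coordinates differ in length")
    idx = np.floor((ap - ap_origin_um) / bin_width_um).astype(int)
    if counts.size and idx.min() < 0:
        raise ValueError("slice AP coordinate precedes the bin origin")
    if n_bins is None:
        n_bins = int(idx.max()) + 1 if counts.size else 1
    values = np.zeros(n_bins)
    np.add.at(values, idx, counts)
    starts = ap_origin_um + bin_width_um * np.arange(n_bins)
    return BinnedTrace(region_id, hemisphere, bin_width_um, starts, values)


def select_regions_ochief(
    totals_wt: pd.Series,
    totals_mut: pd.Series,
    contra_totals_all: pd.Series | None = None,
    sd_multiplier: float = 13.0,
    percentile: float = 20.0,
) -> list:
    """Axon-label region filter.

    A region is kept iff the summed total over both genotype groups exceeds
    ``sd_multiplier`` times the SD of the per-region totals of the
    contralateral side (``contra_totals_all``; defaults to the totals of the
    side being filtered, and is reused verbatim when filtering the
    ipsilateral side) AND its mutant-group total strictly exceeds the
    ``percentile``-th percentile (linear interpolation) of the mutant
    per-region totals.
    """
    if not totals_wt.index.equals(totals_mut.index):
        raise ValueError("genotype total series are not aligned")
    ref = contra_totals_all if contra_totals_all is not None else totals_wt + totals_mut
    sd = float(np.asarray(ref, dtype=float).std())
    combined = totals_wt + totals_mut
    cut = float(np.percentile(totals_mut.to_numpy(dtype=float), percentile))
    keep = (combined > sd_multiplier * sd) & (totals_mut > cut)
    return list(totals_wt.index[keep])


def select_regions_cfos(totals_by_group: pd.DataFrame, min_cells: float = 100.0) -> list:
    """Activity-marker region filter: total over all groups strictly > min_cells."""
    total = totals_by_group.sum(axis=1)
    return list(total.index[total > min_cells])


def cfos_density(
    cell_counts: pd.DataFrame,
    volumes_mm3: pd.Series,
    baseline_samples: list,
    density_exclusion: float = 800.0,
) -> DensityTable:
    """Volume-based density, low-density exclusion, baseline normalization.

    ``cell_counts`` is samples x regions (total cells per region);
    ``volumes_mm3`` gives each region's volume.  Density = cells / volume.
    Regions whose density summed over all samples is below
    ``density_exclusion`` (cells/mm^3, strict <) are dropped; relative
    density divides by the mean over ``baseline_samples`` (the unstimulated
    wild-type group), and regions with a zero baseline mean are dropped with
    a logged warning instead of producing infinities.
    """
    missing = [r for r in cell_counts.columns if r not in volumes_mm3.index]
    if missing:
        raise ValueError(f"volumes missing for regions: {missing[:5]}")
    density = cell_counts.astype(float).div(volumes_mm3[cell_counts.columns], axis=1)

    total = density.sum(axis=0)
    low = list(total.index[total < density_exclusion])
    kept = density.drop(columns=low)

    base = kept.loc[baseline_samples].mean(axis=0)
    zero_base = list(base.index[base == 0.0])
    if zero_base:
        log.warning(
            "dropping %d region(s) with zero baseline mean density: %s",
            len(zero_base),
            zero_base[:5],
        )
    kept = kept.drop(columns=zero_base)
    relative = kept.div(base.drop(zero_base), axis=1)
    return DensityTable(density, relative, low, zero_base)
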