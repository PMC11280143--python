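"""Synthetic atlases, cohorts, section images, and behavior tables.

Everything downstream of raw imaging is exercisable on data generated here
with known ground truth: a toy labeled atlas (mirrored hemispheres,
rectangular region masks written as multi-page TIFF), cohorts of AP-binned
axon-label and activity-marker counts with planted genotype effects,
latent-factor correlation communities and rewiring-coupled regions, section
images with planted ridges and spots, and paired behavior durations.

Count noise is negative-binomial (gamma-Poisson mixture, dispersion
configurable) to keep the rank-based statistics honest; latent factors are
sample-level Gaussian scores entering the log-mean, the simplest mechanism
that produces rank-detectable co-fluctuation.  All outputs are bit-identical
for identical arguments and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi

from .behavior import BEHAVIOR_CLASSES

__all__ = [
    "Region",
    "RegionAtlas",
    "GroundTruth",
    "CohortDesign",
    "Cohort",
    "GROUPS",
    "make_atlas",
    "simulate_cohort",
    "render_section_image",
    "simulate_behavior",
]

#: the four experimental groups as (genotype, stimulation)
GROUPS = (
    ("WT", "ctrl"),
    ("WT", "TBS"),
    ("Tbr1het", "ctrl"),
    ("Tbr1het", "TBS"),
)

AREA_TAGS = ("isocortex", "TH", "HY", "MB")


@dataclass(frozen=True)
class Region:
    region_id: int
    acronym: str
    hemisphere: str  # "ipsi" | "contra"
    area: str
    ap_start_um: float
    ap_end_um: float
    volume_mm3: float


@dataclass
class RegionAtlas:
    """Toy labeled atlas: catalog plus a label-mask stack (0 = background)."""

    regions: list[Region]
    mask: np.ndarray  # (n_slices, H, W) uint16
    ap_step_um: float
    pixel_um: float
    mask_ref: Path | None = None

    @property
    def region_ids(self) -> np.ndarray:
        return np.array([r.region_id for r in self.regions])

    @property
    def n_slices(self) -> int:
        return self.mask.shape[0]

    @property
    def slice_ap_um(self) -> np.ndarray:
        """AP coordinate of each slice's anterior face."""
        return self.ap_step_um * np.arange(self.n_slices)

    @property
    def volumes(self) -> pd.Series:
        return pd.Series(
            {r.region_id: r.volume_mm3 for r in self.regions}, name="volume_mm3"
        )

    def region(self, region_id: int) -> Region:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        raise KeyError(region_id)

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        tiff = directory / "atlas_masks.tif"
        tifffile.imwrite(tiff, self.mask.astype(np.uint16))
        catalog = {
            "ap_step_um": self.ap_step_um,
            "pixel_um": self.pixel_um,
            "mask_ref": tiff.name,
            "regions": [vars(r) for r in self.regions],
        }
        (directory / "atlas_catalog.json").write_text(json.dumps(catalog, indent=1))
        self.mask_ref = tiff
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "RegionAtlas":
        directory = Path(directory)
        catalog = json.loads((directory / "atlas_catalog.json").read_text())
        mask = tifffile.imread(directory / catalog["mask_ref"])
        if mask.ndim == 2:
            mask = mask[None]
        regions = [Region(**r) for r in catalog["regions"]]
        return cls(
            regions,
            np.asarray(mask),
            catalog["ap_step_um"],
            catalog["pixel_um"],
            directory / catalog["mask_ref"],
        )


@dataclass
class GroundTruth:
    """Planted effects, fully describing what downstream stages should find."""

    ochief_multipliers: dict = field(default_factory=dict)  # region -> het multiplier
    cfos_log_effects: dict = field(default_factory=dict)  # region -> {group: logfc}
    communities: dict = field(default_factory=dict)  # name -> [region ids]
    loadings: dict = field(default_factory=dict)  # name -> loading
    coupled_regions: list = field(default_factory=list)
    coupled_amplitude: float = 0.0
    behavior_shift: dict = field(default_factory=dict)  # behavior -> seconds

    def validate(self) -> None:
        for name, members in self.communities.items():
            if len(members) < 3:
                raise ValueError(f"community {name!r} has fewer than 3 regions")
        for rid, m in self.ochief_multipliers.items():
            if m < 0:
                raise ValueError(f"negative multiplier for region {rid}")

    def community_of(self) -> dict:
        out = {}
        for name, members in self.communities.items():
            for rid in members:
                out[rid] = name
        return out


@dataclass
class CohortDesign:
    """Group sizes, effect parameters, and the latent-factor specification."""

    n_per_group: int | dict = 6
    baseline_ochief: float = 30.0
    baseline_cfos: float = 15.0
    dispersion: float = 2.0
    bin_width_um: float = 100.0
    ochief_multipliers: dict = field(default_factory=dict)
    cfos_log_effects: dict = field(default_factory=dict)
    communities: dict = field(default_factory=dict)
    loadings: dict = field(default_factory=dict)
    coupled_regions: list = field(default_factory=list)
    coupled_amplitude: float = 1.5
    profile_sigma_bins: float = 2.0  # smoothness of the per-region AP profile

    def group_sizes(self) -> dict:
        if isinstance(self.n_per_group, int):
            sizes = {f"{g}_{s}": self.n_per_group for g, s in GROUPS}
        else:
            sizes = dict(self.n_per_group)
        for key, n in sizes.items():
            if n < 3:
                raise ValueError(f"group {key!r} needs >= 3 samples (got {n})")
        return sizes


@dataclass
class Cohort:
    """Per-sample, per-region binned traces with group labels and truth."""

    sample_ids: list
    genotype: np.ndarray  # (S,) str
    stim: np.ndarray  # (S,) str
    region_ids: np.ndarray  # (R,)
    hemispheres: np.ndarray  # (R,) str
    areas: np.ndarray  # (R,) str
    volumes: pd.Series  # region_id -> mm^3
    bin_starts_um: np.ndarray  # (B,)
    bin_width_um: float
    ochief: np.ndarray  # (S, R, B) integer counts
    cfos: np.ndarray  # (S, R, B) integer counts
    truth: GroundTruth | None = None

    def sample_mask(self, genotype: str | None = None, stim: str | None = None) -> np.ndarray:
        keep = np.ones(len(self.sample_ids), dtype=bool)
        if genotype is not None:
            keep &= self.genotype == genotype
        if stim is not None:
            keep &= self.stim == stim
        return keep

    def density(self) -> pd.DataFrame:
        """Samples x regions table of activity density (cells/mm^3)."""
        totals = self.cfos.sum(axis=2).astype(float)
        vols = self.volumes[self.region_ids].to_numpy()
        return pd.DataFrame(
            totals / vols, index=self.sample_ids, columns=self.region_ids
        )

    def region_index(self, region_id: int) -> int:
        idx = np.nonzero(self.region_ids == region_id)[0]
        if idx.size == 0:
            raise KeyError(region_id)
        return int(idx[0])

    def group_key(self) -> np.ndarray:
        return np.array([f"{g}_{s}" for g, s in zip(self.genotype, self.stim)])

    def to_long_frame(self) -> pd.DataFrame:
        """Long CSV layout: one row per sample, region, and AP bin."""
        s_idx, r_idx, b_idx = np.meshgrid(
            np.arange(len(self.sample_ids)),
            np.arange(len(self.region_ids)),
            np.arange(len(self.bin_starts_um)),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "sample_id": np.asarray(self.sample_ids)[s_idx.ravel()],
                "region_id": self.region_ids[r_idx.ravel()],
                "hemisphere": self.hemispheres[r_idx.ravel()],
                "ap_bin_start_um": self.bin_starts_um[b_idx.ravel()],
                "ochief_pixels": self.ochief.ravel(),
                "cfos_cells": self.cfos.ravel(),
            }
        )


def make_atlas(
    n_regions_per_hemisphere: int,
    ap_span_um: float,
    seed: int = 0,
    slice_shape: tuple[int, int] = (64, 96),
    pixel_um: float = 25.0,
    ap_step_um: float = 60.0,
    out_dir: str | Path | None = None,
) -> RegionAtlas:
    """Build a mirrored two-hemisphere toy atlas of rectangular regions.

    The left half of every slice is the contralateral hemisphere, the right
    half ipsilateral; each half is tiled by ``n_regions_per_hemisphere``
    horizontal strips (contra labels 1..n, ipsi labels n+1..2n, 0 =
    background).  Volumes are voxel counts times the voxel volume.  The seed
    only affects the (deterministic) assignment of parent-area tags.
    """
    if n_regions_per_hemisphere < 4:
        raise ValueError("need at least 4 regions per hemisphere")
    if ap_span_um < 1000.0:
        raise ValueError("ap_span_um must cover at least 10 bins of 100 um")
    h, w = slice_shape
    strip = h // n_regions_per_hemisphere
    if strip < 1:
        raise ValueError(
            f"{n_regions_per_hemisphere} regions cannot tile {h} mask rows"
        )
    n_slices = int(round(ap_span_um / ap_step_um))
    half = w // 2

    labels = np.zeros((h, w), dtype=np.uint16)
    n = n_regions_per_hemisphere
    for k in range(n):
        r0, r1 = k * strip, (k + 1) * strip
        labels[r0:r1, :half] = k + 1  # contra
        labels[r0:r1, half:] = n + k + 1  # ipsi
    mask = np.broadcast_to(labels, (n_slices, h, w)).copy()

    rng = np.random.default_rng(seed)
    area_of = {k: AREA_TAGS[i % len(AREA_TAGS)] for i, k in enumerate(rng.permutation(n))}
    voxel_mm3 = (pixel_um**2 * ap_step_um) / 1e9
    regions = []
    for k in range(n):
        for hemi, rid in (("contra", k + 1), ("ipsi", n + k + 1)):
            count = int((mask == rid).sum())
            regions.append(
                Region(
                    region_id=rid,
                    acronym=f"R{k + 1:02d}",
                    hemisphere=hemi,
                    area=area_of[k],
                    ap_start_um=0.0,
                    ap_end_um=n_slices * ap_step_um,
                    volume_mm3=count * voxel_mm3,
                )
            )
    atlas = RegionAtlas(regions, mask, ap_step_um, pixel_um)
    if out_dir is not None:
        atlas.save(out_dir)
    return atlas


def _smooth_profiles(rng: np.random.Generator, n_regions: int, n_bins: int, sigma: float) -> np.ndarray:
    """Positive per-region AP profiles with mean 1 along bins."""
    g = ndi.gaussian_filter1d(rng.normal(size=(n_regions, n_bins)), sigma, axis=1)
    prof = np.exp(0.5 * g)
    return prof / prof.mean(axis=1, keepdims=True)


def _bump_profiles(rng: np.random.Generator, n_regions: int, n_bins: int) -> np.ndarray:
    """Unit-peak Gaussian bumps at random AP positions (one per region)."""
    centers = rng.uniform(0.2 * n_bins, 0.8 * n_bins, size=n_regions)
    width = max(1.5, n_bins / 8.0)
    bins = np.arange(n_bins)
    return np.exp(-0.5 * ((bins[None, :] - centers[:, None]) / width) ** 2)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    lam = rng.gamma(shape=dispersion, scale=np.maximum(mean, 1e-12) / dispersion)
    return rng.poisson(lam).astype(np.int64)


def simulate_cohort(
    atlas: RegionAtlas, design: CohortDesign, seed: int = 0
) -> Cohort:
    """Draw a four-group cohort of binned counts with planted structure.

    Axon-label means carry the genotype multipliers (and, for coupled
    regions, an AP bump added multiplicatively in the mutant genotype);
    activity means carry per-group log fold changes, sample-level community
    latent factors on the log scale, and — for coupled regions — the same AP
    bump in the mutant stimulated group, which couples the rewiring signal
    to the activity-modulation signal.  Counts are negative-binomial.
    """
    truth = GroundTruth(
        ochief_multipliers=dict(design.ochief_multipliers),
        cfos_log_effects={k: dict(v) for k, v in design.cfos_log_effects.items()},
        communities={k: list(v) for k, v in design.communities.items()},
        loadings=dict(design.loadings),
        coupled_regions=list(design.coupled_regions),
        coupled_amplitude=design.coupled_amplitude,
    )
    truth.validate()
    unknown = set().union(*truth.communities.values()) - set(atlas.region_ids.tolist()) if truth.communities else set()
    if unknown:
        raise ValueError(f"community regions not in atlas: {sorted(unknown)}")

    sizes = design.group_sizes()
    sample_ids, genotype, stim = [], [], []
    for g, s in GROUPS:
        key = f"{g}_{s}"
        for i in range(sizes.get(key, 0)):
            sample_ids.append(f"{key}_{i + 1:02d}")
            genotype.append(g)
            stim.append(s)
    genotype = np.array(genotype)
    stim = np.array(stim)

    region_ids = atlas.region_ids
    n_regions = len(region_ids)
    hemispheres = np.array([r.hemisphere for r in atlas.regions])
    areas = np.array([r.area for r in atlas.regions])
    span = float(max(r.ap_end_um for r in atlas.regions))
    n_bins = int(np.ceil(span / design.bin_width_um))
    bin_starts = design.bin_width_um * np.arange(n_bins)

    rng = np.random.default_rng(seed)
    prof_o = _smooth_profiles(rng, n_regions, n_bins, design.profile_sigma_bins)
    prof_c = _smooth_profiles(rng, n_regions, n_bins, design.profile_sigma_bins)
    bumps = _bump_profiles(rng, n_regions, n_bins)

    mult = np.array(
        [design.ochief_multipliers.get(int(rid), 1.0) for rid in region_ids]
    )
    coupled = np.isin(region_ids, np.asarray(design.coupled_regions, dtype=region_ids.dtype))
    comm_names = sorted(design.communities)
    member = np.zeros((len(comm_names), n_regions), dtype=bool)
    lam = np.zeros(len(comm_names))
    for ci, name in enumerate(comm_names):
        member[ci] = np.isin(region_ids, np.asarray(design.communities[name], dtype=region_ids.dtype))
        lam[ci] = design.loadings.get(name, 0.0)

    n_samples = len(sample_ids)
    z = rng.normal(size=(n_samples, len(comm_names)))

    mean_o = np.empty((n_samples, n_regions, n_bins))
    mean_c = np.empty((n_samples, n_regions, n_bins))
    for si in range(n_samples):
        het = genotype[si] == "Tbr1het"
        tbs = stim[si] == "TBS"
        gkey = f"{genotype[si]}_{stim[si]}"
        mo = design.baseline_ochief * prof_o * (mult[:, None] if het else 1.0)
        if het:
            mo = mo * np.where(
                coupled[:, None], 1.0 + design.coupled_amplitude * bumps, 1.0
            )
        logfc = np.array(
            [design.cfos_log_effects.get(int(rid), {}).get(gkey, 0.0) for rid in region_ids]
        )
        factor = np.ones(n_regions)
        for ci in range(len(comm_names)):
            factor = factor * np.where(
                member[ci], np.exp(lam[ci] * z[si, ci]), 1.0
            )
        mc = design.baseline_cfos * prof_c * (np.exp(logfc) * factor)[:, None]
        if het and tbs:
            mc = mc * np.where(
                coupled[:, None], 1.0 + design.coupled_amplitude * bumps, 1.0
            )
        mean_o[si] = mo
        mean_c[si] = mc
    if (mean_o < 0).any() or (mean_c < 0).any():
        raise ValueError("effect specification produced negative means")

    ochief = _nb_counts(rng, mean_o, design.dispersion)
    cfos = _nb_counts(rng, mean_c, design.dispersion)
    return Cohort(
        sample_ids=sample_ids,
        genotype=genotype,
        stim=stim,
        region_ids=region_ids,
        hemispheres=hemispheres,
        areas=areas,
        volumes=atlas.volumes,
        bin_starts_um=bin_starts,
        bin_width_um=design.bin_width_um,
        ochief=ochief,
        cfos=cfos,
        truth=truth,
    )


def render_section_image(
    spots: np.ndarray | list,
    ridges: list,
    shape: tuple[int, int] = (256, 256),
    pixel_um: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    spot_diameter_um: float = 10.0,
    spot_amplitude: float = 10.0,
    ridge_amplitude: float = 20.0,
    ridge_width_um: float = 4.0,
    background_amplitude: float = 2.0,
) -> tuple[np.ndarray, dict]:
    """Render a section image with planted spots and axon ridges.

    ``spots`` is a sequence of (x_um, y_um) centers; spots are rendered as
    Gaussian blobs whose sigma matches the Laplacian-of-Gaussian detection
    scale for ``spot_diameter_um``.  ``ridges`` is a sequence of segment
    endpoint pairs ((x0, y0), (x1, y1)) in micrometers, drawn at constant
    amplitude with the stated width.  A smooth background ramp plus Gaussian
    noise is added.  Returns (float32 image, truth) where truth holds the
    exact spot centers and the boolean ridge mask.
    """
    if pixel_um > spot_diameter_um / 3.0:
        raise ValueError("pixel_um must be <= spot_diameter_um / 3")
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    x_um = (xx + 0.5) * pixel_um
    y_um = (yy + 0.5) * pixel_um

    img = np.zeros(shape, dtype=float)
    # background drift: tilted plane plus broad dome
    gx, gy = rng.uniform(-1, 1, 2)
    img += background_amplitude * (gx * x_um / (w * pixel_um) + gy * y_um / (h * pixel_um))
    cx, cy = rng.uniform(0.3, 0.7, 2) * np.array([w, h]) * pixel_um
    dome_sigma = 0.5 * max(h, w) * pixel_um
    img += background_amplitude * np.exp(
        -((x_um - cx) ** 2 + (y_um - cy) ** 2) / (2 * dome_sigma**2)
    )

    sigma_um = spot_diameter_um / (2.0 * np.sqrt(2.0))
    spots = np.asarray(spots, dtype=float).reshape(-1, 2)
    for sx, sy in spots:
        img += spot_amplitude * np.exp(
            -((x_um - sx) ** 2 + (y_um - sy) ** 2) / (2 * sigma_um**2)
        )

    ridge_mask = np.zeros(shape, dtype=bool)
    for (x0, y0), (x1, y1) in ridges:
        px, py = x_um - x0, y_um - y0
        vx, vy = x1 - x0, y1 - y0
        norm2 = vx * vx + vy * vy
        t = np.clip((px * vx + py * vy) / norm2, 0.0, 1.0) if norm2 > 0 else 0.0
        dist = np.hypot(px - t * vx, py - t * vy)
        ridge_mask |= dist <= ridge_width_um / 2.0
    img[ridge_mask] += ridge_amplitude

    img += rng.normal(scale=noise_sd, size=shape)
    truth = {"spots": spots, "ridge_mask": ridge_mask}
    return img.astype(np.float32), truth


def simulate_behavior(
    n_mice: int,
    behaviors: tuple = BEHAVIOR_CLASSES,
    paired_shift: dict | None = None,
    seed: int = 0,
    base_mean_s: float = 60.0,
    noise_sd_s: float = 8.0,
) -> pd.DataFrame:
    """Paired ctrl/TBS behavior durations with an optional planted shift.

    Each mouse gets a latent per-behavior propensity (gamma distributed);
    both arms add independent Gaussian noise, and the TBS arm additionally
    receives the planted shift for its behavior.  Durations are clipped at
    zero.  With zero shift the two arms are exchangeable.
    """
    if n_mice < 5:
        raise ValueError("need at least 5 mice")
    paired_shift = paired_shift or {}
    rng = np.random.default_rng(seed)
    rows = []
    for m in range(n_mice):
        for b in behaviors:
            base = rng.gamma(shape=4.0, scale=base_mean_s / 4.0)
            ctrl = max(0.0, base + rng.normal(scale=noise_sd_s))
            tbs = max(0.0, base + paired_shift.get(b, 0.0) + rng.normal(scale=noise_sd_s))
            rows.append(
                {"mouse_id": f"m{m + 1:02d}", "behavior": b, "condition": "ctrl", "seconds": ctrl}
            )
            rows.append(
                {"mouse_id": f"m{m + 1:02d}", "behavior": b, "condition": "TBS", "seconds": tbs}
            )
    return pd.DataFrame(rows)
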