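"""Seeded synthetic screening-image generator.

Renders multi-channel fluorescence fields (nuclei / spot-marker / EGF cargo)
with per-cell ground truth, emulating a reverse-transfection cell-array or
multi-well RNAi screen: a Poisson number of HeLa-like nuclei per field, a
three-class mitotic phenotype mixture (normal interphase nuclei, condensed
bright "spindle"-arrest nuclei, multi-lobed "cytokinesis"-failure nuclei),
an optional Cy3-labelled transfection spot confining the cells, and an
optional perinuclear EGF-cargo ring per cell.

The defaults reproduce the cell-array study conditions: ~156 cells inside a
300 um spot, negative-control phenotype frequencies of roughly 10% spindle
and 8% cytokinesis, and 16-bit quantized output. Images are bit-identical
for a fixed seed.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

__all__ = [
    "CLASSES",
    "ClassGeometry",
    "CargoModel",
    "MarkerSpot",
    "NoiseModel",
    "SceneSpec",
    "FieldImage",
    "GroundTruth",
    "ConditionEffect",
    "render_field",
    "generate_screen",
    "make_array_layout",
    "make_plate_layout",
    "field_seed",
]

#: canonical phenotype class order (also the classifier tie-break order)
CLASSES = ("normal", "spindle", "cytokinesis")

#: 16-bit camera ceiling
INTENSITY_MAX = 65535


@dataclass(frozen=True)
class ClassGeometry:
    """Per-class nucleus shape and photometry model.

    Normal interphase nuclei are ellipses with semi-axes sampled around
    ``normal_semi_axes_um``.  Spindle-arrest nuclei are near-circular
    condensed nuclei at ``spindle_area_ratio`` of the normal area and
    ``spindle_intensity_ratio`` times the chromatin intensity.  Cytokinesis
    failure produces one connected multi-lobed footprint of 2-4 overlapping
    lobes totalling 1.5-2x the normal area.
    """

    normal_semi_axes_um: tuple[float, float] = (7.5, 5.5)
    axis_cv: float = 0.12
    spindle_area_ratio: float = 0.6
    spindle_intensity_ratio: float = 1.8
    cytokinesis_area_range: tuple[float, float] = (1.5, 2.0)
    cytokinesis_lobes: tuple[int, int] = (2, 4)
    base_intensity: float = 3000.0
    intensity_cv: float = 0.15
    texture_sd: float = 0.08


@dataclass(frozen=True)
class CargoModel:
    """Perinuclear EGF-cargo rendering model.

    Each cell receives a true ring intensity drawn from
    N(ring_mean, ring_sd^2), painted on a chessboard annulus of
    ``ring_render_width_px`` around its nucleus, plus a Poisson number of
    punctate endosomal granules inside the annulus.  ``scale`` multiplies
    every EGF-specific intensity (ring and granules) and models receptor
    knock-down; the additive camera/medium background does not scale.
    """

    ring_mean: float = 2000.0
    ring_sd: float = 600.0  # ~30% cell-to-cell CV of EGF uptake
    ring_render_width_px: int = 7
    granule_rate: float = 4.0
    granule_intensity: float = 2500.0
    granule_sigma_px: float = 1.2
    background: float = 60.0
    scale: float = 1.0

    def scaled(self, factor: float) -> "CargoModel":
        return replace(self, scale=self.scale * factor)


@dataclass(frozen=True)
class MarkerSpot:
    """Cy3 transfection-spot marker.  ``center``/``radius_px`` default to the
    field center and 150 um / pixel_size (300 um printed spot diameter)."""

    center: tuple[float, float] | None = None
    radius_px: float | None = None
    intensity: float = 6000.0


@dataclass(frozen=True)
class NoiseModel:
    """Acquisition noise: background plane (constant + linear gradient in
    counts/px) -> object rendering -> optional Poisson shot noise ->
    additive Gaussian read noise -> clip to [0, 65535] and round."""

    gaussian_sd: float = 40.0
    background: float = 100.0
    background_gradient: tuple[float, float] = (0.05, 0.02)
    poisson: bool = True


@dataclass(frozen=True)
class SceneSpec:
    """Full specification of one synthetic field."""

    field_shape: tuple[int, int] = (384, 384)
    pixel_size: float = 1.0  # um / px
    platform: str = "array_spot"
    expected_cells: float = 156.0
    phenotype_mix: tuple[float, float, float] = (0.823, 0.097, 0.080)
    class_geometry: ClassGeometry = field(default_factory=ClassGeometry)
    cargo_model: CargoModel | None = None
    marker_spot: MarkerSpot | None = field(default_factory=MarkerSpot)
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    allow_touching: bool = False
    max_place_attempts: int = 3000

    def marker_radius_px(self) -> float:
        if self.marker_spot is None:
            raise ValueError("spec has no marker spot")
        if self.marker_spot.radius_px is not None:
            return float(self.marker_spot.radius_px)
        return 150.0 / self.pixel_size

    def marker_center(self) -> tuple[float, float]:
        if self.marker_spot is None:
            raise ValueError("spec has no marker spot")
        if self.marker_spot.center is not None:
            return tuple(map(float, self.marker_spot.center))
        return ((self.field_shape[0] - 1) / 2.0, (self.field_shape[1] - 1) / 2.0)

    def validate(self) -> None:
        mix = np.asarray(self.phenotype_mix, dtype=float)
        if mix.shape != (3,):
            raise ValueError("phenotype_mix must have three entries")
        if np.any(mix < 0) or np.any(mix > 1):
            raise ValueError("phenotype_mix entries must lie in [0, 1]")
        if abs(mix.sum() - 1.0) > 1e-12:
            raise ValueError(
                f"phenotype_mix must sum to 1 (got {mix.sum()!r})"
            )
        if not self.expected_cells > 0:
            raise ValueError("expected_cells must be > 0")
        if len(self.field_shape) != 2 or min(self.field_shape) < 8:
            raise ValueError("field_shape must be a 2-D shape of at least 8 px")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.platform not in ("array_spot", "well96", "well384"):
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.marker_spot is not None:
            if self.marker_radius_px() > min(self.field_shape) / 2:
                raise ValueError("marker radius exceeds half the field size")


@dataclass
class FieldImage:
    """One imaged position: named 16-bit channel rasters plus metadata."""

    channels: dict[str, np.ndarray]
    platform: str = "array_spot"
    replicate: int = 0
    position: str = "pos0"
    subposition: int = 0
    condition: str = "NC"

    def __post_init__(self) -> None:
        if "nuclei" not in self.channels:
            raise ValueError("FieldImage requires a 'nuclei' channel")
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("all channels must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels["nuclei"].shape


@dataclass
class GroundTruth:
    """Generator-side truth: one row per rendered cell plus field totals."""

    cells: pd.DataFrame  # class, centroid_r, centroid_c, footprint_px, ring_mean
    n_dropped: int = 0

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def fractions(self) -> tuple[float, float, float]:
        if self.n_cells == 0:
            return (math.nan, math.nan, math.nan)
        counts = self.cells["class"].value_counts()
        return tuple(counts.get(c, 0) / self.n_cells for c in CLASSES)

    def mean_cargo(self) -> float:
        if self.n_cells == 0 or self.cells["ring_mean"].isna().all():
            return math.nan
        return float(self.cells["ring_mean"].mean())


# ---------------------------------------------------------------------------
# footprint sampling


def _ellipse_mask(a: float, b: float, theta: float) -> np.ndarray:
    """Boolean raster of an ellipse with semi-axes a, b rotated by theta."""
    a = max(a, 1.2)
    b = max(b, 1.0)
    half = int(math.ceil(max(a, b))) + 1
    rr, cc = np.mgrid[-half : half + 1, -half : half + 1]
    ct, st = math.cos(theta), math.sin(theta)
    u = cc * ct + rr * st
    v = -cc * st + rr * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _sample_footprint(
    cls: str, geom: ClassGeometry, pixel_size: float, rng: np.random.Generator
) -> np.ndarray:
    """One nucleus footprint (boolean mask in local coordinates)."""
    a_um, b_um = geom.normal_semi_axes_um
    a = rng.normal(a_um, geom.axis_cv * a_um) / pixel_size
    b = rng.normal(b_um, geom.axis_cv * b_um) / pixel_size
    theta = rng.uniform(0.0, math.pi)
    a, b = max(a, b), min(a, b)
    if cls == "normal":
        return _ellipse_mask(a, b, theta)
    if cls == "spindle":
        # condensed, near-circular, ~spindle_area_ratio of the normal area
        r = math.sqrt(geom.spindle_area_ratio * a * b)
        bb = r * rng.uniform(0.88, 1.0)
        aa = r * r / bb
        return _ellipse_mask(aa, bb, theta)
    if cls == "cytokinesis":
        # 2-4 overlapping lobes forming one connected multi-lobed footprint
        lo, hi = geom.cytokinesis_area_range
        target = rng.uniform(lo, hi) * math.pi * a * b
        m = int(rng.integers(geom.cytokinesis_lobes[0], geom.cytokinesis_lobes[1] + 1))
        # inflate lobes so the union area (after overlap) lands near target
        lobe_area = 1.25 * target / m
        radii = []
        masks = []
        for _ in range(m):
            area_i = lobe_area * rng.uniform(0.8, 1.2)
            ecc = rng.uniform(0.75, 0.95)
            bi = math.sqrt(area_i * ecc / math.pi)
            ai = area_i / (math.pi * bi)
            radii.append(min(ai, bi))
            masks.append(_ellipse_mask(ai, bi, rng.uniform(0, math.pi)))
        # place lobe centers sequentially with guaranteed overlap
        centers = [(0.0, 0.0)]
        for i in range(1, m):
            prev = centers[int(rng.integers(0, i))]
            ang = rng.uniform(0, 2 * math.pi)
            d = rng.uniform(0.7, 0.95) * (radii[i - 1] + radii[i])
            centers.append((prev[0] + d * math.sin(ang), prev[1] + d * math.cos(ang)))
        # rasterize the union on a common canvas
        halfs = [mk.shape[0] // 2 for mk in masks]
        rmin = min(c[0] - h for c, h in zip(centers, halfs))
        rmax = max(c[0] + h for c, h in zip(centers, halfs))
        cmin = min(c[1] - h for c, h in zip(centers, halfs))
        cmax = max(c[1] + h for c, h in zip(centers, halfs))
        H = int(math.ceil(rmax - rmin)) + 3
        W = int(math.ceil(cmax - cmin)) + 3
        canvas = np.zeros((H, W), bool)
        for (cr, cc_), mk, h in zip(centers, masks, halfs):
            r0 = int(round(cr - rmin)) + 1 - h
            c0 = int(round(cc_ - cmin)) + 1 - h
            canvas[r0 : r0 + mk.shape[0], c0 : c0 + mk.shape[1]] |= mk
        # crop to content
        rows = np.any(canvas, axis=1)
        cols = np.any(canvas, axis=0)
        return canvas[rows][:, cols]
    raise ValueError(f"unknown class {cls!r}")


# ---------------------------------------------------------------------------
# placement


class _Placer:
    """Reject-and-resample placement keeping footprints non-adjacent.

    ``blocked`` is the occupancy mask dilated by one pixel (8-neighbourhood),
    so a candidate is accepted iff none of its pixels is blocked -- distinct
    footprints then never touch, even diagonally.
    """

    _D3 = np.ones((3, 3), bool)

    def __init__(self, shape: tuple[int, int], allow_touching: bool) -> None:
        self.shape = shape
        self.allow_touching = allow_touching
        self.blocked = np.zeros(shape, bool)

    def try_place(
        self,
        footprint: np.ndarray,
        spot: tuple[tuple[float, float], float] | None,
        rng: np.random.Generator,
        max_attempts: int,
    ) -> tuple[np.ndarray, np.ndarray] | None:
        """Return absolute (rows, cols) of the placed footprint or None."""
        H, W = self.shape
        fh, fw = footprint.shape
        if fh + 4 > H or fw + 4 > W:
            raise ValueError(
                f"field {self.shape} too small to place a nucleus of size "
                f"{footprint.shape}"
            )
        fr, fc = np.nonzero(footprint)
        # local centroid, used to anchor the candidate center
        cr, cc = fr.mean(), fc.mean()
        for _ in range(max_attempts):
            if spot is not None:
                (sr, sc), rad = spot
                rho = rad * math.sqrt(rng.uniform())
                ang = rng.uniform(0, 2 * math.pi)
                pr, pc = sr + rho * math.sin(ang), sc + rho * math.cos(ang)
            else:
                pr = rng.uniform(cr + 2, H - (fh - cr) - 2)
                pc = rng.uniform(cc + 2, W - (fw - cc) - 2)
            r0 = int(round(pr - cr))
            c0 = int(round(pc - cc))
            if r0 < 2 or c0 < 2 or r0 + fh > H - 2 or c0 + fw > W - 2:
                continue
            rows, cols = fr + r0, fc + c0
            if not self.allow_touching and self.blocked[rows, cols].any():
                continue
            grown = ndi.binary_dilation(
                np.pad(footprint, 1), structure=self._D3
            )
            gr, gc = np.nonzero(grown)
            self.blocked[gr + r0 - 1, gc + c0 - 1] = True
            return rows, cols
        return None


# ---------------------------------------------------------------------------
# rendering


def _background_plane(shape: tuple[int, int], noise: NoiseModel) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    gr, gc = noise.background_gradient
    return noise.background + gr * rr + gc * cc


def _finalize(img: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    out = np.maximum(img, 0.0)
    if noise.poisson:
        out = rng.poisson(out).astype(float)
    out = out + rng.normal(0.0, noise.gaussian_sd, out.shape)
    return np.rint(np.clip(out, 0, INTENSITY_MAX)).astype(np.uint16)


def render_field(spec: SceneSpec) -> tuple[FieldImage, GroundTruth]:
    """Render one field and its ground truth; deterministic in ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    geom = spec.class_geometry
    H, W = spec.field_shape

    n = int(rng.poisson(spec.expected_cells)) if spec.expected_cells >= 1e-6 else 0
    class_idx = rng.choice(3, size=n, p=np.asarray(spec.phenotype_mix, float))

    spot = None
    if spec.marker_spot is not None:
        spot = (spec.marker_center(), spec.marker_radius_px())

    placer = _Placer(spec.field_shape, spec.allow_touching)
    nuclei = _background_plane(spec.field_shape, spec.noise)
    cargo = None
    if spec.cargo_model is not None:
        cargo = np.full(spec.field_shape, float(spec.cargo_model.background))

    records: list[dict] = []
    n_dropped = 0
    for ci in class_idx:
        cls = CLASSES[ci]
        footprint = _sample_footprint(cls, geom, spec.pixel_size, rng)
        placed = placer.try_place(footprint, spot, rng, spec.max_place_attempts)
        if placed is None:
            n_dropped += 1
            continue
        rows, cols = placed
        # chromatin photometry: class base level, cell-to-cell gain, texture
        ratio = geom.spindle_intensity_ratio if cls == "spindle" else 1.0
        gain = max(rng.normal(1.0, geom.intensity_cv), 0.3)
        level = geom.base_intensity * ratio * gain
        tex = ndi.gaussian_filter(rng.standard_normal(footprint.shape), 2.0)
        ts = tex.std()
        if ts > 0:
            tex /= ts
        values = level * (1.0 + geom.texture_sd * tex[footprint.astype(bool)])
        nuclei[rows, cols] += np.maximum(values, 0.0)

        ring_mean = math.nan
        if cargo is not None:
            cm = spec.cargo_model
            w = cm.ring_render_width_px
            ring_mean = max(rng.normal(cm.ring_mean, cm.ring_sd), 0.0) * cm.scale
            r0, c0 = rows.min() - w, cols.min() - w
            local = np.zeros(
                (rows.max() - rows.min() + 1 + 2 * w, cols.max() - cols.min() + 1 + 2 * w),
                bool,
            )
            local[rows - r0, cols - c0] = True
            annulus = ndi.binary_dilation(local, structure=np.ones((3, 3)), iterations=w)
            annulus &= ~local
            ar, ac = np.nonzero(annulus)
            ar, ac = ar + r0, ac + c0
            keep = (ar >= 0) & (ar < H) & (ac >= 0) & (ac < W)
            ar, ac = ar[keep], ac[keep]
            cargo[ar, ac] += ring_mean
            k = int(rng.poisson(cm.granule_rate))
            if k > 0 and len(ar) > 0:
                picks = rng.integers(0, len(ar), size=k)
                amp = cm.granule_intensity * cm.scale
                s = cm.granule_sigma_px
                half = int(math.ceil(3 * s))
                gy, gx = np.mgrid[-half : half + 1, -half : half + 1]
                blob = np.exp(-(gy**2 + gx**2) / (2 * s * s))
                for p in picks:
                    br, bc = ar[p] - half, ac[p] - half
                    rs, re = max(br, 0), min(br + blob.shape[0], H)
                    cs, ce = max(bc, 0), min(bc + blob.shape[1], W)
                    cargo[rs:re, cs:ce] += (
                        amp * blob[rs - br : re - br, cs - bc : ce - bc]
                    )

        records.append(
            {
                "class": cls,
                "centroid_r": rows.mean(),
                "centroid_c": cols.mean(),
                "footprint_px": len(rows),
                "ring_mean": ring_mean,
            }
        )

    channels: dict[str, np.ndarray] = {"nuclei": _finalize(nuclei, spec.noise, rng)}
    if spot is not None:
        marker = _background_plane(spec.field_shape, spec.noise).copy()
        (sr, sc), rad = spot
        rr, cc = np.mgrid[0:H, 0:W]
        marker[(rr - sr) ** 2 + (cc - sc) ** 2 <= rad * rad] += spec.marker_spot.intensity
        channels["marker"] = _finalize(marker, spec.noise, rng)
    if cargo is not None:
        channels["cargo"] = _finalize(cargo, spec.noise, rng)

    cells = pd.DataFrame(
        records,
        columns=["class", "centroid_r", "centroid_c", "footprint_px", "ring_mean"],
    )
    image = FieldImage(channels=channels, platform=spec.platform)
    return image, GroundTruth(cells=cells, n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# screen-level generation

SUBPOSITIONS = {"array_spot": 1, "well96": 25, "well384": 9}

LAYOUT_COLUMNS = ["replicate", "platform", "position", "subposition", "condition"]


@dataclass(frozen=True)
class ConditionEffect:
    """Per-siRNA effect: phenotype mixture, EGF-cargo scaling and relative
    cell density (fraction of remaining cells vs the negative control)."""

    phenotype_mix: tuple[float, float, float] | None = None
    cargo_scale: float = 1.0
    density_multiplier: float = 1.0


def make_array_layout(
    conditions: Iterable[str],
    spots_per_condition: int = 9,
    replicates: int = 3,
) -> pd.DataFrame:
    """Cell-array layout: each siRNA spotted ``spots_per_condition`` times,
    one image per spot, repeated over independent replicate arrays."""
    rows = [
        {
            "replicate": rep,
            "platform": "array_spot",
            "position": f"{cond}_s{j}",
            "subposition": 0,
            "condition": cond,
        }
        for rep in range(1, replicates + 1)
        for cond in conditions
        for j in range(1, spots_per_condition + 1)
    ]
    return pd.DataFrame(rows, columns=LAYOUT_COLUMNS)


def make_plate_layout(
    conditions: Iterable[str],
    wells_per_condition: int = 6,
    replicates: int = 3,
    platform: str = "well384",
    subpositions: int | None = None,
) -> pd.DataFrame:
    """Multi-well layout: several wells per siRNA, several camera
    subpositions imaged per well (9 for 384-well, 25 for 96-well)."""
    if subpositions is None:
        subpositions = SUBPOSITIONS[platform]
    rows = [
        {
            "replicate": rep,
            "platform": platform,
            "position": f"{cond}_w{j}",
            "subposition": s,
            "condition": cond,
        }
        for rep in range(1, replicates + 1)
        for cond in conditions
        for j in range(1, wells_per_condition + 1)
        for s in range(subpositions)
    ]
    return pd.DataFrame(rows, columns=LAYOUT_COLUMNS)


def field_seed(master_seed: int, replicate, position, subposition) -> int:
    """Stable per-field seed: master seed + CRC32 of the field key."""
    crc = zlib.crc32(f"{replicate}|{position}|{subposition}".encode())
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, crc])
    return int(ss.generate_state(1, np.uint64)[0] >> 1)


def generate_screen(
    layout: pd.DataFrame,
    condition_effects: Mapping[str, ConditionEffect],
    base_spec: SceneSpec,
    master_seed: int = 0,
) -> tuple[list[FieldImage], list[GroundTruth]]:
    """Render one field per layout row, applying per-condition effects.

    Per-field seeds derive deterministically from ``master_seed`` and the
    (replicate, position, subposition) key, so regeneration of any single
    field is reproducible independently of iteration order.
    """
    missing = sorted(set(layout["condition"]) - set(condition_effects))
    if missing:
        raise KeyError(f"no condition effect defined for {missing[0]!r}")
    fields: list[FieldImage] = []
    truths: list[GroundTruth] = []
    for row in layout.itertuples(index=False):
        eff = condition_effects[row.condition]
        mix = eff.phenotype_mix if eff.phenotype_mix is not None else base_spec.phenotype_mix
        cargo = base_spec.cargo_model
        if cargo is not None:
            cargo = cargo.scaled(eff.cargo_scale)
        marker = base_spec.marker_spot if row.platform == "array_spot" else None
        spec = replace(
            base_spec,
            platform=row.platform,
            phenotype_mix=tuple(mix),
            expected_cells=base_spec.expected_cells * eff.density_multiplier,
            cargo_model=cargo,
            marker_spot=marker,
            seed=field_seed(master_seed, row.replicate, row.position, row.subposition),
        )
        image, truth = render_field(spec)
        image.platform = row.platform
        image.replicate = int(row.replicate)
        image.position = str(row.position)
        image.subposition = int(row.subposition)
        image.condition = str(row.condition)
        fields.append(image)
        truths.append(truth)
    return fields, truths
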