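"""Synthetic two-channel micrographs of monocyte/macrophage populations.

Generates DAPI (nuclear) + phalloidin (f-actin) scenes for five phenotypes
-- M1, M2, naive macrophage, day-0 monocyte, day-6 monocyte -- with per-cell
ground-truth masks, so that segmentation, feature extraction and
classification can be exercised and calibrated without any microscopy data.

The cell outline is a low-order radial Fourier perturbation of an ellipse,

    r(theta) = R * (1 + sum_{k=2..6} a_k cos(k*theta + phi_k)),

with ``a_k`` drawn uniformly in ``±boundary_irregularity / k``; harmonics of
order 2..6 produce lamellar / spindle outlines without self-intersection.
The actin texture inside each cell is a Poisson spot process blurred with a
per-phenotype Gaussian sigma and normalised to unit variance, so phenotypes
differ in texture grain (dotted vs smooth) at matched mean brightness, plus
a multiplicative rim boost within 2 px of the cell edge.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage.draw import polygon as _draw_polygon

from .segment import TwoChannelImage

PHENOTYPES: tuple[str, ...] = ("M1", "M2", "naive_mac", "mono_d0", "mono_d6")

#: relative amplitude of the actin texture around the per-cell mean
_ACTIN_TEXTURE_CONTRAST = 0.35
#: rim thickness (px) over which edge_rim_gain applies
_RIM_WIDTH_PX = 2
#: clearance kept between any cell mask and the image border, px
_BORDER_MARGIN_PX = 3


class ArchetypeError(ValueError):
    """Raised when a phenotype archetype violates its physical bounds."""


@dataclass(frozen=True)
class PhenotypeArchetype:
    """Morphological population parameters for one phenotype.

    Lengths are in pixels; intensities in arbitrary fluorescence units added
    on top of the scene background.
    """

    name: str
    cell_radius_mean: float
    cell_radius_sd: float
    elongation_mean: float = 1.0       # major/minor axis ratio, >= 1
    elongation_sd: float = 0.0
    boundary_irregularity: float = 0.0  # radial Fourier amplitude, [0, 0.5]
    nucleus_radius_mean: float = 5.0
    nucleus_radius_sd: float = 0.0
    nucleus_offset_frac: float = 0.0    # centroid displacement / cell radius
    actin_spot_density: float = 1.0     # spots per 100 px^2
    actin_smoothness: float = 2.0       # Gaussian blur sigma, px
    edge_rim_gain: float = 1.0          # multiplicative rim boost, >= 1
    dna_intensity_scale: float = 140.0  # mean nuclear intensity per px
    actin_intensity_scale: float = 60.0  # mean cytoplasmic actin per px

    def validate(self) -> None:
        checks = [
            ("cell_radius_mean", self.cell_radius_mean > 0),
            ("cell_radius_sd", self.cell_radius_sd >= 0),
            ("elongation_mean", self.elongation_mean >= 1.0),
            ("elongation_sd", self.elongation_sd >= 0),
            ("boundary_irregularity", 0.0 <= self.boundary_irregularity <= 0.5),
            ("nucleus_radius_mean",
             0 < self.nucleus_radius_mean < self.cell_radius_mean),
            ("nucleus_radius_sd", self.nucleus_radius_sd >= 0),
            ("nucleus_offset_frac", 0.0 <= self.nucleus_offset_frac < 1.0),
            ("actin_spot_density", self.actin_spot_density >= 0),
            ("actin_smoothness", self.actin_smoothness >= 0),
            ("edge_rim_gain", self.edge_rim_gain >= 1.0),
            ("dna_intensity_scale", self.dna_intensity_scale > 0),
            ("actin_intensity_scale", self.actin_intensity_scale > 0),
        ]
        for fname, ok in checks:
            if not ok:
                raise ArchetypeError(
                    f"archetype {self.name!r}: invalid value for field "
                    f"{fname!r} ({getattr(self, fname)!r})"
                )


def default_archetypes() -> dict[str, PhenotypeArchetype]:
    """The five calibrated phenotype archetypes.

    Orderings emulated: M2 largest cells; day-6 monocytes largest nuclei;
    day-0 monocytes small, round and uniform; M1 smaller, elongated, with
    fine-grained ("dotted") actin; naive macrophages and day-6 monocytes
    share a near-identical cell-area distribution.
    """
    return {
        "mono_d0": PhenotypeArchetype(
            name="mono_d0", cell_radius_mean=9.0, cell_radius_sd=0.8,
            elongation_mean=1.05, elongation_sd=0.03,
            boundary_irregularity=0.05,
            nucleus_radius_mean=6.0, nucleus_radius_sd=0.6,
            nucleus_offset_frac=0.1,
            actin_spot_density=0.5, actin_smoothness=2.0,
            edge_rim_gain=1.0, dna_intensity_scale=145.0,
            actin_intensity_scale=42.0,
        ),
        "mono_d6": PhenotypeArchetype(
            name="mono_d6", cell_radius_mean=16.0, cell_radius_sd=2.5,
            elongation_mean=1.15, elongation_sd=0.1,
            boundary_irregularity=0.14,
            nucleus_radius_mean=10.4, nucleus_radius_sd=1.1,
            nucleus_offset_frac=0.15,
            actin_spot_density=0.7, actin_smoothness=2.4,
            edge_rim_gain=1.2, dna_intensity_scale=145.0,
            actin_intensity_scale=58.0,
        ),
        "naive_mac": PhenotypeArchetype(
            name="naive_mac", cell_radius_mean=17.0, cell_radius_sd=2.5,
            elongation_mean=1.35, elongation_sd=0.15,
            boundary_irregularity=0.25,
            nucleus_radius_mean=7.8, nucleus_radius_sd=0.8,
            nucleus_offset_frac=0.25,
            actin_spot_density=1.0, actin_smoothness=1.6,
            edge_rim_gain=1.45, dna_intensity_scale=145.0,
            actin_intensity_scale=62.0,
        ),
        "M1": PhenotypeArchetype(
            name="M1", cell_radius_mean=12.0, cell_radius_sd=1.5,
            elongation_mean=1.8, elongation_sd=0.25,
            boundary_irregularity=0.25,
            nucleus_radius_mean=7.0, nucleus_radius_sd=0.7,
            nucleus_offset_frac=0.25,
            actin_spot_density=12.0, actin_smoothness=0.8,
            edge_rim_gain=1.3, dna_intensity_scale=145.0,
            actin_intensity_scale=60.0,
        ),
        "M2": PhenotypeArchetype(
            name="M2", cell_radius_mean=24.0, cell_radius_sd=3.0,
            elongation_mean=1.2, elongation_sd=0.08,
            boundary_irregularity=0.30,
            nucleus_radius_mean=9.0, nucleus_radius_sd=0.9,
            nucleus_offset_frac=0.2,
            actin_spot_density=1.2, actin_smoothness=3.0,
            edge_rim_gain=1.8, dna_intensity_scale=145.0,
            actin_intensity_scale=72.0,
        ),
    }


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one rendered scene / dataset."""

    image_height: int = 512
    image_width: int = 512
    cells_per_image: int = 18
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: {c: 0.2 for c in PHENOTYPES})
    background_level: float = 100.0
    gaussian_noise_sd: float = 5.0
    poisson_noise: bool = True
    min_cell_separation: int = 2
    staining_cv: float = 0.12   # per-cell lognormal brightness variation
    texture_jitter: float = 0.2  # per-cell lognormal actin-smoothness variation
    outlier_frac: float = 0.18  # atypical cells among cultured classes
    rng_seed: int = 0

    def validate(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if self.cells_per_image < 0:
            raise ValueError("cells_per_image must be >= 0")
        mix = dict(self.class_mix)
        if any(v < 0 for v in mix.values()):
            raise ValueError("class_mix proportions must be >= 0")
        if self.staining_cv < 0 or self.texture_jitter < 0:
            raise ValueError("staining_cv and texture_jitter must be >= 0")
        if not 0 <= self.outlier_frac < 1:
            raise ValueError("outlier_frac must be in [0, 1)")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1 within 1e-9")
        unknown = set(mix) - set(PHENOTYPES)
        if unknown:
            raise ValueError(f"unknown phenotype(s) in class_mix: {sorted(unknown)}")


@dataclass
class CellGeometry:
    """A placement-free sampled cell: local boolean masks plus draws."""

    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    radius: float
    elongation: float
    nucleus_radius: float

    @property
    def cell_area(self) -> int:
        return int(self.cell_mask.sum())

    @property
    def nucleus_area(self) -> int:
        return int(self.nucleus_mask.sum())


@dataclass
class CellRecord:
    object_id: int
    phenotype: str
    area: int
    nucleus_area: int


@dataclass
class GroundTruth:
    """Per-scene ground truth: label maps plus per-cell records."""

    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    records: list[CellRecord]

    def __len__(self) -> int:
        return len(self.records)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, high: float | None = None) -> float:
    v = rng.normal(mean, sd) if sd > 0 else mean
    if high is not None:
        v = min(v, high)
    return max(v, low)


def sample_cell_geometry(archetype: PhenotypeArchetype,
                         rng: np.random.Generator) -> CellGeometry:
    """Draw one cell + nucleus mask pair from an archetype.

    The nucleus is a disc whose centre is displaced from the cell centroid by
    ``nucleus_offset_frac`` of the available clearance and snapped to the
    nearest position where the disc still fits strictly inside the cell.
    """
    archetype.validate()
    r = _truncated_normal(rng, archetype.cell_radius_mean,
                          archetype.cell_radius_sd, low=3.0)
    elong = _truncated_normal(rng, archetype.elongation_mean,
                              archetype.elongation_sd, low=1.0)
    r_nuc = _truncated_normal(rng, archetype.nucleus_radius_mean,
                              archetype.nucleus_radius_sd, low=2.0)

    ks = np.arange(2, 7)
    amps = rng.uniform(-1.0, 1.0, size=ks.size) * \
        archetype.boundary_irregularity / ks
    phases = rng.uniform(0.0, 2 * np.pi, size=ks.size)
    rot = rng.uniform(0.0, np.pi)
    offset_dir = rng.uniform(0.0, 2 * np.pi)

    theta = np.linspace(0.0, 2 * np.pi, 720, endpoint=False)
    radial = r * (1.0 + np.sum(amps[:, None] *
                               np.cos(ks[:, None] * theta[None, :] +
                                      phases[:, None]), axis=0))
    radial = np.clip(radial, 0.2 * r, None)
    # area-preserving elongation: semi-axes r*sqrt(e) and r/sqrt(e)
    x = radial * np.cos(theta) * np.sqrt(elong)
    y = radial * np.sin(theta) / np.sqrt(elong)
    xr = x * np.cos(rot) - y * np.sin(rot)
    yr = x * np.sin(rot) + y * np.cos(rot)

    half = int(np.ceil(max(np.abs(xr).max(), np.abs(yr).max()))) + 2
    size = 2 * half + 1
    rr, cc = _draw_polygon(yr + half, xr + half, shape=(size, size))
    cell = np.zeros((size, size), dtype=bool)
    cell[rr, cc] = True
    cell = ndi.binary_fill_holes(cell)
    # keep the largest connected component (razor-thin lobes may detach)
    lab, n = ndi.label(cell, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = ndi.sum_labels(cell, lab, index=np.arange(1, n + 1))
        cell = lab == (1 + int(np.argmax(sizes)))

    edt = ndi.distance_transform_edt(cell)
    max_clear = float(edt.max())
    if r_nuc + 1.0 > max_clear:
        r_nuc = max(2.0, max_clear - 1.5)
    valid = edt >= r_nuc + 1.0
    if not valid.any():
        valid = edt == max_clear

    coords = np.argwhere(cell)
    centroid = coords.mean(axis=0)
    ci = np.clip(np.round(centroid).astype(int), 0, size - 1)
    clearance = float(edt[ci[0], ci[1]]) - r_nuc
    if clearance < 0:
        anchor = np.unravel_index(np.argmax(edt), edt.shape)
        ci = np.array(anchor)
        clearance = max_clear - r_nuc
    shift = archetype.nucleus_offset_frac * max(clearance, 0.0)
    target = ci + shift * np.array([np.sin(offset_dir), np.cos(offset_dir)])
    vcoords = np.argwhere(valid)
    d2 = np.sum((vcoords - target[None, :]) ** 2, axis=1)
    nc = vcoords[int(np.argmin(d2))]

    yy, xx = np.mgrid[0:size, 0:size]
    nucleus = (yy - nc[0]) ** 2 + (xx - nc[1]) ** 2 <= r_nuc ** 2
    nucleus &= cell
    return CellGeometry(cell_mask=cell, nucleus_mask=nucleus, radius=r,
                        elongation=elong, nucleus_radius=r_nuc)


def _render_actin_field(geom: CellGeometry, arch: PhenotypeArchetype,
                        rng: np.random.Generator) -> np.ndarray:
    """Per-cell actin intensity field on the geometry's local patch."""
    mask = geom.cell_mask
    area = geom.cell_area
    n_spots = rng.poisson(arch.actin_spot_density * area / 100.0)
    spikes = np.zeros(mask.shape, dtype=float)
    if n_spots > 0:
        coords = np.argwhere(mask)
        idx = rng.integers(0, len(coords), size=n_spots)
        np.add.at(spikes, (coords[idx, 0], coords[idx, 1]), 1.0)
    tex = ndi.gaussian_filter(spikes, max(arch.actin_smoothness, 1e-6))
    inside = tex[mask]
    sd = inside.std()
    z = np.zeros_like(tex)
    if sd > 0:
        z[mask] = (inside - inside.mean()) / sd
    field = arch.actin_intensity_scale * (1.0 + _ACTIN_TEXTURE_CONTRAST * z)
    field = np.clip(field, 0.2 * arch.actin_intensity_scale, None)
    rim = mask & ~ndi.binary_erosion(mask, iterations=_RIM_WIDTH_PX)
    field[rim] *= arch.edge_rim_gain
    field[~mask] = 0.0
    return field


class PlacementError(RuntimeError):
    """Raised when the requested cell count cannot be placed without overlap."""

    def __init__(self, requested: int, achieved: int):
        super().__init__(
            f"could not place {requested} cells without overlap; "
            f"achieved {achieved}")
        self.requested = requested
        self.achieved = achieved


def render_scene(config: SceneConfig,
                 archetypes: Mapping[str, PhenotypeArchetype],
                 rng: np.random.Generator,
                 classes: Sequence[str] | None = None,
                 max_attempts: int = 1000,
                 ) -> tuple[TwoChannelImage, GroundTruth]:
    """Render one two-channel scene with non-overlapping cells.

    ``classes`` fixes the per-cell phenotype sequence; otherwise each cell's
    class is drawn from ``config.class_mix``. Noise (Poisson then additive
    Gaussian) is applied last.
    """
    config.validate()
    h, w = config.image_height, config.image_width
    if classes is None:
        mix = dict(config.class_mix)
        names = [c for c in PHENOTYPES if mix.get(c, 0) > 0]
        probs = np.array([mix[c] for c in names], dtype=float)
        probs /= probs.sum() if names else 1.0
        classes = [str(rng.choice(names, p=probs))
                   for _ in range(config.cells_per_image)]
    else:
        classes = list(classes)
        missing = set(classes) - set(archetypes)
        if missing:
            raise ValueError(f"no archetype for class(es): {sorted(missing)}")
    for name in set(classes):
        if name not in archetypes:
            raise ValueError(f"no archetype for class {name!r}")

    dapi = np.full((h, w), config.background_level, dtype=float)
    actin = np.full((h, w), config.background_level, dtype=float)
    cell_labels = np.zeros((h, w), dtype=np.int32)
    nucleus_labels = np.zeros((h, w), dtype=np.int32)
    forbidden = np.zeros((h, w), dtype=bool)
    records: list[CellRecord] = []

    def _lognormal_gain(cv: float) -> float:
        # unit-mean multiplicative gain; models cell-to-cell staining
        # efficiency so per-pixel intensity scales are not class oracles
        if cv <= 0:
            return 1.0
        sigma = np.sqrt(np.log1p(cv ** 2))
        return float(rng.lognormal(-0.5 * sigma ** 2, sigma))

    for i, cls in enumerate(classes, start=1):
        arch = archetypes[cls]
        arch = replace(
            arch,
            dna_intensity_scale=(arch.dna_intensity_scale *
                                 _lognormal_gain(config.staining_cv)),
            actin_intensity_scale=(arch.actin_intensity_scale *
                                   _lognormal_gain(config.staining_cv)),
            actin_smoothness=(arch.actin_smoothness *
                              _lognormal_gain(config.texture_jitter)),
        )
        # cultured populations carry atypical cells (mitotic, over-spread,
        # stacked); freshly isolated day-0 monocytes stay uniform
        if cls != "mono_d0" and rng.random() < config.outlier_frac:
            arch = replace(
                arch,
                cell_radius_mean=arch.cell_radius_mean *
                float(rng.uniform(1.15, 1.5)),
                elongation_mean=arch.elongation_mean *
                float(rng.uniform(1.3, 1.7)),
                boundary_irregularity=min(
                    0.45, arch.boundary_irregularity + 0.15),
            )
        geom = sample_cell_geometry(arch, rng)
        ph, pw = geom.cell_mask.shape
        if ph + 2 * _BORDER_MARGIN_PX > h or pw + 2 * _BORDER_MARGIN_PX > w:
            raise PlacementError(len(classes), len(records))
        placed = False
        for _ in range(max_attempts):
            r0 = int(rng.integers(_BORDER_MARGIN_PX,
                                  h - ph - _BORDER_MARGIN_PX + 1))
            c0 = int(rng.integers(_BORDER_MARGIN_PX,
                                  w - pw - _BORDER_MARGIN_PX + 1))
            sl = (slice(r0, r0 + ph), slice(c0, c0 + pw))
            if not (forbidden[sl] & geom.cell_mask).any():
                placed = True
                break
        if not placed:
            raise PlacementError(len(classes), len(records))

        field = _render_actin_field(geom, arch, rng)
        actin[sl][geom.cell_mask] += field[geom.cell_mask]
        dapi[sl][geom.nucleus_mask] += arch.dna_intensity_scale
        cell_labels[sl][geom.cell_mask] = i
        nucleus_labels[sl][geom.nucleus_mask] = i
        grown = geom.cell_mask
        if config.min_cell_separation > 0:
            grown = ndi.binary_dilation(
                geom.cell_mask, iterations=int(config.min_cell_separation))
        forbidden[sl] |= grown
        records.append(CellRecord(object_id=i, phenotype=cls,
                                  area=geom.cell_area,
                                  nucleus_area=geom.nucleus_area))

    for img in (dapi, actin):
        if config.poisson_noise:
            img[:] = rng.poisson(np.clip(img, 0, None)).astype(float)
        if config.gaussian_noise_sd > 0:
            img += rng.normal(0.0, config.gaussian_noise_sd, size=img.shape)
        np.clip(img, 0, None, out=img)

    image = TwoChannelImage(dapi=dapi, actin=actin)
    truth = GroundTruth(cell_labels=cell_labels,
                        nucleus_labels=nucleus_labels, records=records)
    return image, truth


def _allocate_image_classes(mix: Mapping[str, float], n_images: int,
                            ) -> list[str]:
    """Largest-remainder allocation of single-class images to phenotypes."""
    names = [c for c in PHENOTYPES if mix.get(c, 0) > 0]
    raw = np.array([mix[c] * n_images for c in names], dtype=float)
    counts = np.floor(raw).astype(int)
    rem = n_images - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for j in range(rem):
        counts[order[j % len(names)]] += 1
    out: list[str] = []
    for name, k in zip(names, counts):
        out.extend([name] * int(k))
    return out


def _to_uint16(img: np.ndarray) -> np.ndarray:
    return np.clip(np.round(img), 0, 65535).astype(np.uint16)


def generate_dataset(config: SceneConfig,
                     archetypes: Mapping[str, PhenotypeArchetype],
                     n_images: int,
                     out_dir: str | Path,
                     set_name: str = "synth") -> pd.DataFrame:
    """Write a reproducible dataset of single-class image pairs.

    Files follow ``<set>_<class>_<idx>_<channel>.tif`` (16-bit grayscale,
    channel in {dapi, actin}); ground-truth label maps go to ``truth/`` and a
    per-image manifest (image, class, n_cells, seed) to ``manifest.csv``.
    Fully reproducible from ``config.rng_seed``.
    """
    out_dir = Path(out_dir)
    truth_dir = out_dir / "truth"
    try:
        truth_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc

    image_classes = _allocate_image_classes(dict(config.class_mix), n_images)
    seeds = np.random.SeedSequence(config.rng_seed).generate_state(n_images)
    rows = []
    for idx, cls in enumerate(image_classes):
        seed = int(seeds[idx] % (2 ** 31))
        rng = np.random.default_rng(seed)
        image, truth = render_scene(
            config, archetypes, rng,
            classes=[cls] * config.cells_per_image)
        stem = f"{set_name}_{cls}_{idx:03d}"
        tifffile.imwrite(out_dir / f"{stem}_dapi.tif", _to_uint16(image.dapi))
        tifffile.imwrite(out_dir / f"{stem}_actin.tif", _to_uint16(image.actin))
        tifffile.imwrite(truth_dir / f"{stem}_celllabels.tif",
                         truth.cell_labels.astype(np.uint16))
        tifffile.imwrite(truth_dir / f"{stem}_nuclabels.tif",
                         truth.nucleus_labels.astype(np.uint16))
        rows.append({"image": stem, "class": cls,
                     "n_cells": len(truth), "seed": seed})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def dataset_checksum(manifest: pd.DataFrame) -> str:
    """Stable sha256 over the manifest contents."""
    return hashlib.sha256(
        manifest.to_csv(index=False).encode()).hexdigest()
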