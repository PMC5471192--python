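"""The per-cell "cytoprofile": a fixed, ordered vector of 228 measurements.

Composition (exactly 228, part of the public contract):

* shape, 14 per object x {nucleus, cell}                          =  28
* intensity, 12 per object x {dapi, actin}                        =  48
* radial distribution, 12 per object x channel                    =  48
* Haralick texture, 13 per object x channel x offset {3, 8} px    = 104

Degenerate values (empty radial bin, zero-variance GLCM correlation, ...)
are imputed as 0 so every profile stays finite for the classifiers.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import regionprops

from .segment import SegmentedObject, TwoChannelImage

log = logging.getLogger(__name__)

N_FEATURES = 228
HARALICK_SCALES = (3, 8)
N_GRAY_LEVELS = 8

SHAPE_NAMES = (
    "area", "perimeter", "form_factor", "compactness", "eccentricity",
    "solidity", "extent", "equivalent_diameter", "major_axis_length",
    "minor_axis_length", "orientation_deg", "radius_max", "radius_mean",
    "radius_median",
)
INTENSITY_NAMES = (
    "integrated", "mean", "median", "std", "mad", "min", "max",
    "quartile_lower", "quartile_upper", "edge_integrated", "edge_mean",
    "mass_displacement",
)
RADIAL_NAMES = tuple(
    f"{stat}_bin{b}" for stat in ("frac_at_d", "mean_frac", "radial_cv")
    for b in (1, 2, 3, 4)
)
HARALICK_NAMES = (
    "asm", "contrast", "correlation", "variance", "idm", "sum_average",
    "sum_variance", "sum_entropy", "entropy", "difference_variance",
    "difference_entropy", "imc1", "imc2",
)

_OBJECTS = ("nucleus", "cell")
_CHANNELS = ("dapi", "actin")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered 228-entry schema; the order is the public contract."""

    table: pd.DataFrame  # columns: name, object, channel, family, scale

    @property
    def names(self) -> list[str]:
        return list(self.table["name"])

    def __len__(self) -> int:
        return len(self.table)

    @property
    def hash(self) -> str:
        return hashlib.sha256("\n".join(self.names).encode()).hexdigest()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def build_schema() -> FeatureSchema:
    rows: list[dict] = []

    def add(name: str, obj: str, channel: str, family: str, scale=None):
        rows.append({"name": name, "object": obj, "channel": channel,
                     "family": family, "scale": scale})

    for obj in _OBJECTS:
        for feat in SHAPE_NAMES:
            add(f"{obj}_shape_{feat}", obj, "none", "shape")
    for obj in _OBJECTS:
        for ch in _CHANNELS:
            for feat in INTENSITY_NAMES:
                add(f"{obj}_{ch}_intensity_{feat}", obj, ch, "intensity")
    for obj in _OBJECTS:
        for ch in _CHANNELS:
            for feat in RADIAL_NAMES:
                add(f"{obj}_{ch}_radial_{feat}", obj, ch, "radial")
    for scale in HARALICK_SCALES:
        for obj in _OBJECTS:
            for ch in _CHANNELS:
                for feat in HARALICK_NAMES:
                    add(f"{obj}_{ch}_texture_{feat}_s{scale}",
                        obj, ch, "texture", scale)

    table = pd.DataFrame(rows)
    assert len(table) == N_FEATURES
    assert table["name"].is_unique
    return FeatureSchema(table=table)


# ---------------------------------------------------------------------------
# shape


def _boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Pixels of the mask with a 4-connected background neighbour."""
    inner = ndi.binary_erosion(
        mask, structure=ndi.generate_binary_structure(2, 1), border_value=0)
    return mask & ~inner


_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def _chain_perimeter(mask: np.ndarray) -> float:
    """Polygon length through 8-connected boundary pixel centres.

    Moore-neighbour boundary tracing with Jacob's stopping criterion;
    orthogonal steps count 1, diagonal steps sqrt(2).
    """
    pad = np.pad(mask, 1)
    coords = np.argwhere(pad)
    if len(coords) == 1:
        return 0.0
    # start: topmost-leftmost foreground pixel, entered from the left
    start = tuple(coords[np.lexsort((coords[:, 1], coords[:, 0]))[0]])
    boundary = [start]
    prev_dir = 6  # came from the west
    cur = start
    length = 0.0
    max_steps = 8 * int(pad.sum()) + 8
    for _ in range(max_steps):
        found = False
        for k in range(8):
            d = (prev_dir + 6 + k) % 8  # backtrack then clockwise sweep
            nr, nc = cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1]
            if pad[nr, nc]:
                step = np.sqrt(2.0) if d % 2 else 1.0
                nxt = (nr, nc)
                if nxt == start and len(boundary) > 1:
                    return length + step
                length += step
                boundary.append(nxt)
                cur = nxt
                prev_dir = d
                found = True
                break
        if not found:  # isolated pixel reached via a spur
            return length
    return length  # pragma: no cover - safety bound


def shape_features(mask: np.ndarray) -> dict[str, float]:
    """14 shape descriptors of a non-empty connected pixel set."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("shape_features: empty mask")
    props = regionprops(mask.astype(np.uint8))[0]
    area = float(props.area)
    perimeter = _chain_perimeter(mask)
    if perimeter <= 0:  # single pixel / degenerate: square-equivalent length
        perimeter = 4.0 * np.sqrt(area)
    form_factor = 4.0 * np.pi * area / perimeter ** 2
    compactness = 1.0 / form_factor
    edt = ndi.distance_transform_edt(mask)
    radii = edt[mask]
    orientation = np.degrees(props.orientation)
    if orientation <= -90.0:
        orientation += 180.0
    return {
        "area": area,
        "perimeter": perimeter,
        "form_factor": form_factor,
        "compactness": compactness,
        "eccentricity": float(props.eccentricity),
        "solidity": float(props.solidity),
        "extent": float(props.extent),
        "equivalent_diameter": 2.0 * np.sqrt(area / np.pi),
        "major_axis_length": float(props.axis_major_length),
        "minor_axis_length": float(props.axis_minor_length),
        "orientation_deg": float(orientation),
        "radius_max": float(radii.max()),
        "radius_mean": float(radii.mean()),
        "radius_median": float(np.median(radii)),
    }


# ---------------------------------------------------------------------------
# intensity


def intensity_features(mask: np.ndarray, image: np.ndarray) -> dict[str, float]:
    """12 intensity descriptors of one stain over one object mask.

    "Edge" statistics are taken over the boundary pixels; mass displacement
    is the distance between the binary and intensity-weighted centroids.
    """
    mask = np.asarray(mask, dtype=bool)
    image = np.asarray(image, dtype=float)
    if not mask.any():
        raise ValueError("intensity_features: empty mask")
    if mask.shape != image.shape:
        raise ValueError("mask and image shapes differ")
    v = image[mask]
    edge = _boundary_pixels(mask)
    ve = image[edge] if edge.any() else v
    coords = np.argwhere(mask)
    bc = coords.mean(axis=0)
    total = v.sum()
    wc = (coords * v[:, None]).sum(axis=0) / total if total > 0 else bc
    med = float(np.median(v))
    return {
        "integrated": float(v.sum()),
        "mean": float(v.mean()),
        "median": med,
        "std": float(v.std()),          # population (ddof=0)
        "mad": float(np.median(np.abs(v - med))),  # unscaled
        "min": float(v.min()),
        "max": float(v.max()),
        "quartile_lower": float(np.percentile(v, 25)),
        "quartile_upper": float(np.percentile(v, 75)),
        "edge_integrated": float(ve.sum()),
        "edge_mean": float(ve.mean()),
        "mass_displacement": float(np.linalg.norm(wc - bc)),
    }


# ---------------------------------------------------------------------------
# radial distribution


def radial_distribution(mask: np.ndarray, image: np.ndarray,
                        n_bins: int = 4, n_wedges: int = 8) -> dict[str, float]:
    """FracAtD / MeanFrac / RadialCV over concentric distance-from-edge bins.

    The normalised distance runs from the object edge (0) to the in-mask
    point farthest from the edge (1); bin 1 is the outermost ring, bin
    ``n_bins`` the innermost core. RadialCV is the coefficient of variation
    of mean intensity over angular wedges around the farthest point.
    Degenerate quantities (empty bin, zero totals) are imputed as 0.
    """
    mask = np.asarray(mask, dtype=bool)
    image = np.asarray(image, dtype=float)
    if not mask.any():
        raise ValueError("radial_distribution: empty mask")
    edt = ndi.distance_transform_edt(mask)
    dmax = edt.max()
    out: dict[str, float] = {}
    dn = np.zeros_like(edt)
    dn[mask] = edt[mask] / dmax if dmax > 0 else 1.0
    bins = np.zeros(mask.shape, dtype=int)
    bins[mask] = np.minimum(np.ceil(dn[mask] * n_bins).astype(int),
                            n_bins) - 1  # 0-based, 0 = outermost

    center = np.unravel_index(np.argmax(edt), edt.shape)
    yy, xx = np.mgrid[0:mask.shape[0], 0:mask.shape[1]]
    ang = np.arctan2(yy - center[0], xx - center[1])
    wedges = np.minimum((((ang + np.pi) / (2 * np.pi)) * n_wedges).astype(int),
                        n_wedges - 1)

    total = image[mask].sum()
    area = mask.sum()
    for b in range(n_bins):
        bmask = mask & (bins == b)
        bsum = image[bmask].sum() if bmask.any() else 0.0
        frac = bsum / total if total > 0 else 0.0
        area_frac = bmask.sum() / area
        mean_frac = frac / area_frac if area_frac > 0 else 0.0
        if bmask.any():
            wmeans = []
            for wdg in range(n_wedges):
                sel = bmask & (wedges == wdg)
                if sel.any():
                    wmeans.append(image[sel].mean())
            wmeans = np.array(wmeans)
            mu = wmeans.mean()
            cv = float(wmeans.std() / mu) if (len(wmeans) > 1 and mu > 0) else 0.0
        else:
            cv = 0.0
        out[f"frac_at_d_bin{b + 1}"] = float(frac)
        out[f"mean_frac_bin{b + 1}"] = float(mean_frac)
        out[f"radial_cv_bin{b + 1}"] = cv
    return {name: out[name] for name in RADIAL_NAMES}


# ---------------------------------------------------------------------------
# Haralick texture


def _glcm_one_direction(levels: np.ndarray, offset: tuple[int, int],
                        n_levels: int) -> np.ndarray | None:
    """Symmetric normalised GLCM for one offset; None if no valid pair.

    ``levels`` holds quantised gray levels with -1 outside the mask.
    """
    dr, dc = offset
    h, w = levels.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        return None
    a = levels[r0:r1, c0:c1]
    b = levels[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    valid = (a >= 0) & (b >= 0)
    if not valid.any():
        return None
    codes = a[valid] * n_levels + b[valid]
    counts = np.bincount(codes, minlength=n_levels * n_levels).astype(float)
    P = counts.reshape(n_levels, n_levels)
    P = P + P.T
    return P / P.sum()


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    np.log2(p, where=p > 0, out=out)
    return out


def haralick_from_glcm(P: np.ndarray) -> dict[str, float]:
    """Haralick's 13 statistics from a normalised symmetric GLCM.

    Zero-variance marginals impute correlation and IMC1 as 0.
    """
    n = P.shape[0]
    i = np.arange(n)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mx = (i * px).sum()
    my = (i * py).sum()
    sx = np.sqrt(((i - mx) ** 2 * px).sum())
    sy = np.sqrt(((i - my) ** 2 * py).sum())

    p_sum = np.zeros(2 * n - 1)
    np.add.at(p_sum, (ii + jj).ravel(), P.ravel())
    p_diff = np.zeros(n)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), P.ravel())
    k_sum = np.arange(2 * n - 1)
    k_diff = np.arange(n)

    asm = float((P ** 2).sum())
    contrast = float(((ii - jj) ** 2 * P).sum())
    corr = float(((ii * jj * P).sum() - mx * my) / (sx * sy)) \
        if sx > 0 and sy > 0 else 0.0
    variance = float(((ii - mx) ** 2 * P).sum())
    idm = float((P / (1.0 + (ii - jj) ** 2)).sum())
    sum_avg = float((k_sum * p_sum).sum())
    sum_var = float(((k_sum - sum_avg) ** 2 * p_sum).sum())
    sum_ent = float(-(p_sum * _xlog2(p_sum)).sum())
    entropy = float(-(P * _xlog2(P)).sum())
    diff_avg = float((k_diff * p_diff).sum())
    diff_var = float(((k_diff - diff_avg) ** 2 * p_diff).sum())
    diff_ent = float(-(p_diff * _xlog2(p_diff)).sum())

    hx = float(-(px * _xlog2(px)).sum())
    hy = float(-(py * _xlog2(py)).sum())
    pxy = np.outer(px, py)
    hxy1 = float(-(P * _xlog2(pxy)).sum())
    hxy2 = float(-(pxy * _xlog2(pxy)).sum())
    denom = max(hx, hy)
    imc1 = float((entropy - hxy1) / denom) if denom > 0 else 0.0
    imc2 = float(np.sqrt(1.0 - np.exp(-2.0 * max(hxy2 - entropy, 0.0))))

    return {
        "asm": asm, "contrast": contrast, "correlation": corr,
        "variance": variance, "idm": idm, "sum_average": sum_avg,
        "sum_variance": sum_var, "sum_entropy": sum_ent, "entropy": entropy,
        "difference_variance": diff_var, "difference_entropy": diff_ent,
        "imc1": imc1, "imc2": imc2,
    }


def haralick_features(mask: np.ndarray, image: np.ndarray, scale: int = 3,
                      n_levels: int = N_GRAY_LEVELS,
                      directions: bool = False) -> dict[str, float]:
    """Direction-averaged Haralick statistics over a masked region.

    In-mask intensities are quantised to ``n_levels`` equal-width bins
    between the in-mask min and max; co-occurrence pairs are restricted to
    pixel pairs both inside the mask, over the 4 standard directions at the
    given pixel offset. With ``directions=True`` the per-direction values
    are returned instead (keys suffixed ``_d0.._d3``).
    """
    mask = np.asarray(mask, dtype=bool)
    image = np.asarray(image, dtype=float)
    if mask.sum() < 2:
        raise ValueError("haralick_features: need >= 2 in-mask pixels")
    v = image[mask]
    vmin, vmax = v.min(), v.max()
    levels = np.full(mask.shape, -1, dtype=np.int64)
    if vmax > vmin:
        q = np.floor((image - vmin) / (vmax - vmin) * n_levels).astype(np.int64)
        levels[mask] = np.clip(q[mask], 0, n_levels - 1)
    else:
        levels[mask] = 0

    offsets = [(0, scale), (scale, 0), (scale, scale), (scale, -scale)]
    per_dir: list[dict[str, float]] = []
    for off in offsets:
        P = _glcm_one_direction(levels, off, n_levels)
        per_dir.append(haralick_from_glcm(P) if P is not None else None)

    if directions:
        out = {}
        for d, stats in enumerate(per_dir):
            for name in HARALICK_NAMES:
                out[f"{name}_d{d}"] = stats[name] if stats else 0.0
        return out

    computed = [s for s in per_dir if s is not None]
    if not computed:
        # no valid pair at this offset: constant-texture convention
        base = dict.fromkeys(HARALICK_NAMES, 0.0)
        base["asm"] = 1.0
        base["idm"] = 1.0
        return base
    return {name: float(np.mean([s[name] for s in computed]))
            for name in HARALICK_NAMES}


# ---------------------------------------------------------------------------
# assembly


class ProfileError(RuntimeError):
    """Raised when a cell's profile cannot be computed."""


def assemble_cytoprofile(obj: SegmentedObject, image: TwoChannelImage,
                         schema: FeatureSchema) -> np.ndarray:
    """Compute the full 228-vector for one segmented cell, schema-ordered."""
    if len(schema) != N_FEATURES:
        raise ValueError("schema must be the canonical 228-entry schema")
    pad = max(HARALICK_SCALES)
    rs, cs = obj.bbox
    h, w = image.dapi.shape
    r0, r1 = max(0, rs.start - pad), min(h, rs.stop + pad)
    c0, c1 = max(0, cs.start - pad), min(w, cs.stop + pad)
    local = (slice(rs.start - r0, rs.start - r0 + obj.cell_mask.shape[0]),
             slice(cs.start - c0, cs.start - c0 + obj.cell_mask.shape[1]))
    shape_ = (r1 - r0, c1 - c0)
    masks = {}
    for name, m in (("cell", obj.cell_mask), ("nucleus", obj.nucleus_mask)):
        full = np.zeros(shape_, dtype=bool)
        full[local] = m
        masks[name] = full
    channels = {"dapi": image.dapi[r0:r1, c0:c1],
                "actin": image.actin[r0:r1, c0:c1]}

    values: dict[str, float] = {}
    try:
        for objname in _OBJECTS:
            for feat, val in shape_features(masks[objname]).items():
                values[f"{objname}_shape_{feat}"] = val
        for objname in _OBJECTS:
            for ch in _CHANNELS:
                for feat, val in intensity_features(
                        masks[objname], channels[ch]).items():
                    values[f"{objname}_{ch}_intensity_{feat}"] = val
                for feat, val in radial_distribution(
                        masks[objname], channels[ch]).items():
                    values[f"{objname}_{ch}_radial_{feat}"] = val
        for scale in HARALICK_SCALES:
            for objname in _OBJECTS:
                for ch in _CHANNELS:
                    for feat, val in haralick_features(
                            masks[objname], channels[ch], scale=scale).items():
                        values[f"{objname}_{ch}_texture_{feat}_s{scale}"] = val
    except ValueError as exc:
        raise ProfileError(
            f"profile failed for {obj.image_id}/{obj.cell_id}: {exc}") from exc

    vec = np.array([values[name] for name in schema.names], dtype=float)
    bad = ~np.isfinite(vec)
    if bad.any():
        log.warning("imputing %d non-finite feature(s) for %s/%d",
                    int(bad.sum()), obj.image_id, obj.cell_id)
        vec[bad] = 0.0
    return vec


def edge_actin_intensity_per_area(profile: np.ndarray,
                                  schema: FeatureSchema) -> float:
    """Sum edge-actin intensity normalised to cell area (a key separator
    of the large, rim-bright phenotypes from small monocytes)."""
    names = schema.names
    edge = profile[names.index("cell_actin_intensity_edge_integrated")]
    area = profile[names.index("cell_shape_area")]
    return float(edge / area)


def profile_objects(objects: list[SegmentedObject], image: TwoChannelImage,
                    schema: FeatureSchema, class_label: str | None = None,
                    image_id: str = "") -> pd.DataFrame:
    """Feature table rows for all objects of one image; failures are logged
    and the cell excluded."""
    rows = []
    for obj in objects:
        try:
            vec = assemble_cytoprofile(obj, image, schema)
        except ProfileError as exc:
            log.warning("%s", exc)
            continue
        row = {"image_id": image_id or obj.image_id, "object_id": obj.cell_id,
               "class": class_label}
        row.update(zip(schema.names, vec))
        rows.append(row)
    cols = ["image_id", "object_id", "class"] + schema.names
    return pd.DataFrame(rows, columns=cols)
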