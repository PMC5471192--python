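"""File discovery and image I/O.

The phenotype class is encoded in the file name, convention
``<set>_<class>_<idx>_<channel>.<ext>`` with channel in {dapi, actin} and
class one of the five phenotype names or ``blind`` for unlabeled sets.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .segment import TwoChannelImage

log = logging.getLogger(__name__)

DEFAULT_PATTERN = (
    r"(?P<set>.+)_(?P<cls>M1|M2|naive_mac|mono_d0|mono_d6|blind)"
    r"_(?P<idx>\d+)_(?P<channel>dapi|actin)\.(tif|tiff|png)$"
)


@dataclass(frozen=True)
class ImageRecord:
    image_id: str
    label: str  # phenotype name or "blind"
    dapi_path: Path
    actin_path: Path
    checksum: str


def _file_sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def discover_images(input_dir: str | Path,
                    pattern: str = DEFAULT_PATTERN) -> list[ImageRecord]:
    """Pair channel files by shared stem and extract the class label.

    Files with a missing partner channel are excluded with a warning;
    zero matched pairs is an error.
    """
    input_dir = Path(input_dir)
    rx = re.compile(pattern)
    if not ({"cls", "channel"} <= set(rx.groupindex)):
        raise ValueError("pattern must contain 'cls' and 'channel' groups")
    groups: dict[str, dict] = {}
    for path in sorted(input_dir.iterdir()):
        m = rx.match(path.name)
        if not m:
            continue
        stem = path.name[:m.start("channel")].rstrip("_")
        rec = groups.setdefault(stem, {"cls": m.group("cls")})
        rec[m.group("channel")] = path
    records: list[ImageRecord] = []
    for stem, rec in sorted(groups.items()):
        if "dapi" not in rec or "actin" not in rec:
            have = [k for k in ("dapi", "actin") if k in rec]
            log.warning("excluding %s: only channel(s) %s present", stem, have)
            continue
        checksum = hashlib.sha256(
            (_file_sha256(rec["dapi"]) + _file_sha256(rec["actin"])).encode()
        ).hexdigest()
        records.append(ImageRecord(image_id=stem, label=rec["cls"],
                                   dapi_path=rec["dapi"],
                                   actin_path=rec["actin"],
                                   checksum=checksum))
    if not records:
        raise FileNotFoundError(
            f"no two-channel image pairs matching pattern in {input_dir}")
    return records


def _read_gray(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim == 3:  # collapse an RGB PNG to its first channel
        img = img[..., 0]
    return img.astype(float)


def read_two_channel(record: ImageRecord) -> TwoChannelImage:
    dapi = _read_gray(record.dapi_path)
    actin = _read_gray(record.actin_path)
    if dapi.shape != actin.shape:
        raise ValueError(
            f"{record.image_id}: channel shapes differ "
            f"({dapi.shape} vs {actin.shape})")
    return TwoChannelImage(dapi=dapi, actin=actin)
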