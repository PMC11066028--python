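"""Field-to-crop preprocessing.

Turns multi-channel fields into filtered, normalized, split 64x64 single-cell
crops: nuclear-channel watershed segmentation for cell centers, fixed-size
crops around the centers, a dataset-wide 5th-percentile intensity filter plus
a low-variance background filter, removal of proteins with fewer than 10
surviving cells, a per-protein stratified 8:1:1 train/val/test split, and
per-crop per-channel standardization (instance normalization).

Coordinate convention: 0-based pixel indices; a crop around center ``c`` spans
the half-open window ``[c - size//2, c + size//2)`` in each axis. Centers are
``(x, y)`` pairs with x = column, y = row.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.segmentation import watershed

log = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    crop_size: int = 64
    boundary_margin: int = 10
    intensity_percentile: float = 5.0
    min_cells_per_protein: int = 10
    split_ratios: tuple[int, int, int] = (8, 1, 1)
    variance_floor: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.intensity_percentile < 100:
            raise ValueError("intensity percentile must be in (0, 100)")
        if self.boundary_margin < 0 or any(r <= 0 for r in self.split_ratios):
            raise ValueError("margin must be >= 0 and split ratios positive")


@dataclass
class Crop:
    """One single-cell image patch with provenance."""

    pixels: np.ndarray  # (H, W, C); channel 0 = tagged protein
    protein_id: str
    center: tuple[int, int]  # (x, y) in the source field
    crop_id: str = ""
    replicate: int | None = None
    field_id: str | None = None
    stage: str | None = None
    archetype: str | None = None
    split: str | None = None
    mask: np.ndarray | None = None  # ground-truth foreground, when known


def detect_cell_centers(nuclear: np.ndarray, margin: int = 10) -> list[tuple[int, int]]:
    """Nucleus centers via Otsu threshold -> distance transform -> watershed.

    Returns ``(x, y)`` centroids of the watershed segments, discarding centers
    closer than ``margin`` pixels to the image border. A flat or empty image
    yields an empty list.
    """
    img = np.asarray(nuclear, dtype=np.float64)
    if img.ndim != 2 or np.any(img < 0):
        raise ValueError("nuclear channel must be a nonnegative 2-D image")
    if img.max() - img.min() < 1e-12:
        return []
    thresh = threshold_otsu(img)
    binary = img > thresh
    lbl = cc_label(binary)
    sizes = np.bincount(lbl.ravel())
    binary = sizes[lbl] >= 9
    binary[lbl == 0] = False
    if not binary.any():
        return []
    dist = ndimage.distance_transform_edt(binary)
    peaks = peak_local_max(dist, min_distance=6, labels=cc_label(binary))
    markers = np.zeros(img.shape, dtype=int)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        return []
    segments = watershed(-dist, markers, mask=binary)
    h, w = img.shape
    centers = []
    for prop in regionprops(segments):
        cy, cx = prop.centroid
        x, y = int(round(cx)), int(round(cy))
        if x < margin or y < margin or x >= w - margin or y >= h - margin:
            continue
        centers.append((x, y))
    return centers


def extract_crops(
    field: np.ndarray,
    centers: list[tuple[int, int]],
    crop_size: int = 64,
    protein_id: str = "",
    **provenance,
) -> list[Crop]:
    """Cut ``crop_size`` windows around centers; channel 0 is the tagged
    protein. ``field`` is (C, H, W); page 3, when present, is the noiseless
    foreground template and becomes the crop's ground-truth mask. Centers too
    close to the border for a full window are skipped with a log entry.
    """
    c, h, w = field.shape
    half = crop_size // 2
    crops = []
    for x, y in centers:
        r0, r1 = y - half, y + half
        c0, c1 = x - half, x + half
        if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
            log.info("skipping center (%d, %d): crop window outside field", x, y)
            continue
        window = field[:, r0:r1, c0:c1]
        mask = None
        pixels = window
        if c >= 4:
            tmpl = window[3]
            mask = tmpl > 0.05 * tmpl.max() if tmpl.max() > 0 else tmpl > 0
            pixels = window[:3]
        crops.append(
            Crop(
                pixels=np.ascontiguousarray(pixels.transpose(1, 2, 0)).copy(),
                protein_id=protein_id,
                center=(x, y),
                mask=mask,
                **provenance,
            )
        )
    return crops


def filter_crops(crops, config: PreprocessConfig | None = None):
    """Apply the dataset-wide low-intensity and background-variance filters.

    Intensity = sum of channel-0 pixels; crops strictly below the dataset's
    ``intensity_percentile`` are rejected (ties at the boundary are kept).
    Crops whose channel-0 variance is below ``variance_floor`` are rejected as
    background-dominated. Returns ``(kept, rejected)`` with rejection reasons.
    """
    config = config or PreprocessConfig()
    if not crops:
        raise ValueError("filter_crops needs at least one crop")
    intensities = np.array([float(c.pixels[..., 0].sum()) for c in crops])
    cutoff = np.percentile(intensities, config.intensity_percentile)
    kept, rejected = [], []
    for crop, inten in zip(crops, intensities):
        if inten < cutoff:
            rejected.append((crop, "low_intensity"))
        elif float(crop.pixels[..., 0].var()) < config.variance_floor:
            rejected.append((crop, "background_dominated"))
        else:
            kept.append(crop)
    for _, reason in rejected[:5]:
        log.debug("rejected crop: %s", reason)
    log.info("filter_crops kept %d / %d", len(kept), len(crops))
    return kept, rejected


def drop_sparse_proteins(crops, min_cells: int = 10):
    """Remove proteins with fewer than ``min_cells`` surviving crops."""
    counts: dict[str, int] = {}
    for c in crops:
        counts[c.protein_id] = counts.get(c.protein_id, 0) + 1
    keep = {p for p, n in counts.items() if n >= min_cells}
    dropped = sorted(set(counts) - keep)
    if dropped:
        log.info("dropping sparse proteins: %s", dropped)
    out = [c for c in crops if c.protein_id in keep]
    if not out:
        raise ValueError("all proteins dropped: empty dataset")
    return out


def split_dataset(crops, ratios=(8, 1, 1), seed: int = 0):
    """Per-protein stratified train/val/test split.

    Each protein's crops are shuffled with a protein-id-salted seed (so the
    assignment is independent of dataset ordering) and split by ``ratios``.
    """
    total = sum(ratios)
    by_protein: dict[str, list[Crop]] = {}
    for c in crops:
        by_protein.setdefault(c.protein_id, []).append(c)
    out = []
    for pid in sorted(by_protein):
        group = sorted(by_protein[pid], key=lambda c: c.crop_id)
        salt = zlib.crc32(pid.encode())
        rng = np.random.default_rng(np.random.SeedSequence([seed, salt]))
        order = rng.permutation(len(group))
        n = len(group)
        n_val = int(round(n * ratios[1] / total))
        n_test = int(round(n * ratios[2] / total))
        n_train = n - n_val - n_test
        for rank, gi in enumerate(order):
            if rank < n_train:
                split = "train"
            elif rank < n_train + n_val:
                split = "val"
            else:
                split = "test"
            out.append(replace(group[gi], split=split))
    return out


def normalize_crop(crop: Crop) -> Crop:
    """Instance normalization: per channel, mean 0 and variance 1.

    A constant channel cannot be standardized and becomes all zeros.
    """
    pixels = crop.pixels.astype(np.float64)
    out = np.zeros_like(pixels)
    for ch in range(pixels.shape[-1]):
        chan = pixels[..., ch]
        std = chan.std()
        if std < 1e-12:
            log.debug("constant channel %d in crop %s -> zeros", ch, crop.crop_id)
            continue
        out[..., ch] = (chan - chan.mean()) / std
    return replace(crop, pixels=out)


def dihedral(pixels: np.ndarray, k: int) -> np.ndarray:
    """Apply the k-th of the 8 square symmetries (4 rotations x optional flip)."""
    out = np.rot90(pixels, k % 4, axes=(0, 1))
    if k >= 4:
        out = out[:, ::-1]
    return np.ascontiguousarray(out)


def augment(crop: Crop, seed: int | np.random.Generator = 0) -> Crop:
    """Random flip (horizontal/vertical) and rotation by 0/90/180/270 degrees,
    drawn uniformly over the 8 dihedral transforms."""
    if crop.pixels.shape[0] != crop.pixels.shape[1]:
        raise ValueError("augmentation requires a square crop")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return replace(crop, pixels=dihedral(crop.pixels, int(rng.integers(8))))


def prepare_dataset(dataset, config: PreprocessConfig | None = None):
    """Full preprocessing pipeline on a synthetic (or loaded) dataset.

    Detects centers on each field's nuclear channel, extracts crops, matches
    each detected crop to the nearest manifest cell (for stage/archetype
    ground truth), filters, drops sparse proteins, splits and normalizes.
    Returns the normalized crops.
    """
    config = config or PreprocessConfig()
    crops = []
    counter = 0
    for key, field_arr in dataset.fields.items():
        sub = dataset.manifest[dataset.manifest.field_id == key]
        if sub.empty:
            continue
        protein_id = sub.protein_id.iloc[0]
        centers = detect_cell_centers(field_arr[1], margin=config.boundary_margin)
        extracted = extract_crops(
            field_arr, centers, config.crop_size, protein_id=protein_id, field_id=key
        )
        truth_xy = sub[["x", "y"]].to_numpy(dtype=float)
        for crop in extracted:
            counter += 1
            crop.crop_id = f"cell{counter:06d}"
            crop.replicate = int(sub.replicate.iloc[0])
            d = np.hypot(truth_xy[:, 0] - crop.center[0], truth_xy[:, 1] - crop.center[1])
            j = int(np.argmin(d))
            if d[j] <= 8:
                crop.stage = sub.stage.iloc[j]
                crop.archetype = sub.archetype.iloc[j]
            crops.append(crop)
    kept, _ = filter_crops(crops, config)
    kept = drop_sparse_proteins(kept, config.min_cells_per_protein)
    kept = split_dataset(kept, config.split_ratios, config.seed)
    return [normalize_crop(c) for c in kept]


def crops_to_arrays(crops, split: str | None = None, channel: int | None = 0):
    """Stack crops into arrays for model consumption.

    Returns ``(X, protein_ids, crop_ids)`` with X of shape (N, 1, H, W) for a
    single channel or (N, C, H, W) when ``channel`` is None.
    """
    sel = [c for c in crops if split is None or c.split == split]
    if channel is None:
        X = np.stack([c.pixels.transpose(2, 0, 1) for c in sel])
    else:
        X = np.stack([c.pixels[..., channel][None] for c in sel])
    ids = np.array([c.protein_id for c in sel])
    crop_ids = np.array([c.crop_id for c in sel])
    return X, ids, crop_ids
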