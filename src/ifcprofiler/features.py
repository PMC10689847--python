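"""Interpretable feature families for multichannel conjugate images.

Six families are computed per record, all from the intensity stack and the
per-channel segmentation masks:

* ``morphology`` — 30 shape descriptors of a channel mask (16 scalar
  descriptors, 7 Hu moments, 7 intensity-weighted Hu moments);
* ``intensity`` — 17 order/moment statistics of the masked intensities
  (8 statistics incl. Shannon entropy + the 10th..90th deciles);
* ``texture`` — 6 gray-level co-occurrence (GLCM) statistics on the masked,
  32-level quantized intensities;
* ``coloc`` — 17 co-localization measures for an unordered channel pair
  (mask-overlap distances, intensity agreement over the union pixel set,
  Manders/overlap/ICQ coefficients, structural similarity, Hausdorff);
* ``synaptic`` — 3 enrichment ratios of a channel inside the synapse mask
  relative to the whole cell;
* ``qc`` — per-channel background mean and Sobel gradient RMS.

The *fluorescent-relevant* preset emits exactly 27 per-channel and 17
per-pair features, which expands to 210 columns for a four-fluorochrome
panel and 132 for three — the feature spaces used for the antibody
mode-of-action comparisons.  Missing values are explicit NaN, never 0.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import stats
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import directed_hausdorff
from skimage import measure
from skimage.feature import graycomatrix
from skimage.filters import sobel
from skimage.metrics import structural_similarity
from skimage.morphology import dilation as binary_dilation, disk

from .core_data import BRIGHTFIELD, CellRecord, FLUORESCENT_CHANNELS

logger = logging.getLogger(__name__)

FAMILIES = ("morphology", "intensity", "texture", "coloc", "synaptic", "qc")

#: Default structuring-element radius for the synapse mask (pixels).
SYNAPSE_DILATION_RADIUS = 3

DECILES = tuple(range(10, 100, 10))

GLCM_LEVELS = 32
GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)

INTENSITY_RANGE = 65535.0  # 16-bit dynamic range used for entropy binning


# ---------------------------------------------------------------------------
# Synapse mask
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynapseMask:
    """Contact-zone mask: intersection of the dilated T- and B-cell masks."""

    mask: np.ndarray
    dilation_radius: int = SYNAPSE_DILATION_RADIUS

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def derive_synapse_mask(
    record: CellRecord,
    t_channel: str = "CD3",
    b_channel: str = "MHCII",
    dilation_radius: int = SYNAPSE_DILATION_RADIUS,
) -> SynapseMask:
    """Contact zone between the T-cell and B-cell masks.

    Each mask is dilated by a disk of the given radius and the two dilations
    are intersected; an empty result means no contact.  ``t_channel`` may be
    substituted (e.g. CD4 when an anti-CD3 therapeutic blocks the staining).
    """
    for name in (t_channel, b_channel):
        if name not in record.channels:
            raise KeyError(f"synapse mask requires channel {name!r}")
    selem = disk(dilation_radius)
    t = binary_dilation(record.channel_mask(t_channel), selem)
    b = binary_dilation(record.channel_mask(b_channel), selem)
    return SynapseMask(mask=t & b, dilation_radius=dilation_radius)


# ---------------------------------------------------------------------------
# Morphology (30 values)
# ---------------------------------------------------------------------------

MORPHOLOGY_SCALARS = (
    "area",
    "bounding box area",
    "convex area",
    "eccentricity",
    "equivalent diameter",
    "euler number",
    "extent",
    "max feret diameter",
    "min feret diameter",
    "filled area",
    "major axis length",
    "minor axis length",
    "orientation",
    "perimeter",
    "crofton perimeter",
    "solidity",
)
MORPHOLOGY_NAMES = (
    MORPHOLOGY_SCALARS
    + tuple(f"hu moment {i}" for i in range(1, 8))
    + tuple(f"weighted hu moment {i}" for i in range(1, 8))
)


def _min_feret(mask: np.ndarray) -> float:
    """Minimum caliper width of the pixelated region (pixel-corner hull)."""
    ys, xs = np.nonzero(mask)
    corners = np.concatenate(
        [
            np.stack([ys + dy, xs + dx], axis=1)
            for dy in (-0.5, 0.5)
            for dx in (-0.5, 0.5)
        ]
    ).astype(float)
    try:
        hull = ConvexHull(corners)
        pts = corners[hull.vertices]
    except QhullError:
        pts = corners
    # width orthogonal to each hull edge; the min over edges is the min feret
    edges = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    good = lengths > 0
    if not good.any():
        return 1.0
    normals = np.stack([-edges[good, 1], edges[good, 0]], axis=1) / lengths[
        good, None
    ]
    proj = normals @ pts.T
    return float((proj.max(axis=1) - proj.min(axis=1)).min())


def morphology_features(
    mask: np.ndarray, image: np.ndarray | None = None
) -> dict[str, float]:
    """30 shape descriptors of a (possibly disconnected) binary mask.

    The whole mask is treated as one region.  An empty mask yields all-NaN;
    the 7 weighted Hu moments require ``image`` and are NaN without it.
    """
    out = {name: np.nan for name in MORPHOLOGY_NAMES}
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return out
    label = mask.astype(np.uint8)
    if image is not None:
        props = measure.regionprops(label, intensity_image=np.asarray(image, float))[0]
    else:
        props = measure.regionprops(label)[0]
    out["area"] = float(props.area)
    out["bounding box area"] = float(props.area_bbox)
    out["convex area"] = float(props.area_convex)
    out["eccentricity"] = float(props.eccentricity)
    out["equivalent diameter"] = float(props.equivalent_diameter_area)
    out["euler number"] = float(props.euler_number)
    out["extent"] = float(props.extent)
    out["max feret diameter"] = float(props.feret_diameter_max)
    out["min feret diameter"] = _min_feret(mask)
    out["filled area"] = float(props.area_filled)
    out["major axis length"] = float(props.axis_major_length)
    out["minor axis length"] = float(props.axis_minor_length)
    out["orientation"] = float(props.orientation)
    out["perimeter"] = float(props.perimeter)
    out["crofton perimeter"] = float(props.perimeter_crofton)
    out["solidity"] = float(props.solidity)
    for i, v in enumerate(props.moments_hu, start=1):
        out[f"hu moment {i}"] = float(v)
    if image is not None:
        for i, v in enumerate(props.moments_weighted_hu, start=1):
            out[f"weighted hu moment {i}"] = float(v)
    return out


# ---------------------------------------------------------------------------
# Intensity (17 values)
# ---------------------------------------------------------------------------

INTENSITY_NAMES = (
    "min intensity",
    "max intensity",
    "sum intensity",
    "mean intensity",
    "std intensity",
    "skewness",
    "kurtosis",
    "entropy",
) + tuple(f"{p}th percentile" for p in DECILES)


def shannon_entropy(values: np.ndarray) -> float:
    """Shannon entropy (nats) of a 256-bin histogram over the 16-bit range."""
    hist, _ = np.histogram(
        np.asarray(values, float) / INTENSITY_RANGE, bins=256, range=(0.0, 1.0)
    )
    p = hist[hist > 0] / hist.sum()
    return float(-(p * np.log(p)).sum())


def intensity_features(image: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """17 statistics of the intensities under the mask (NaN if mask empty)."""
    out = {name: np.nan for name in INTENSITY_NAMES}
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return out
    vals = np.asarray(image, dtype=float)[mask]
    out["min intensity"] = float(vals.min())
    out["max intensity"] = float(vals.max())
    out["sum intensity"] = float(vals.sum())
    out["mean intensity"] = float(vals.mean())
    sd = float(vals.std())
    out["std intensity"] = sd
    # constant input: third/fourth moments are 0/0 -- define as 0
    out["skewness"] = float(stats.skew(vals)) if sd > 0 else 0.0
    out["kurtosis"] = float(stats.kurtosis(vals)) if sd > 0 else 0.0
    out["entropy"] = shannon_entropy(vals)
    pct = np.percentile(vals, DECILES)  # linear interpolation between ranks
    for p, v in zip(DECILES, pct):
        out[f"{p}th percentile"] = float(v)
    return out


# ---------------------------------------------------------------------------
# Texture (6 GLCM values)
# ---------------------------------------------------------------------------

TEXTURE_NAMES = (
    "contrast",
    "dissimilarity",
    "homogeneity",
    "ASM",
    "energy",
    "correlation",
)


def _masked_glcm(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Symmetric, normalized, angle-averaged GLCM of the masked intensities.

    Intensities under the mask are min-max rescaled and quantized to 32
    levels; pixels outside the mask are assigned a reserved level whose rows
    and columns are discarded, so co-occurrences never cross the mask edge.
    """
    img = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    vals = img[mask]
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        q = np.floor((img - lo) / (hi - lo) * GLCM_LEVELS).astype(np.intp)
        q = np.clip(q, 0, GLCM_LEVELS - 1)
    else:
        q = np.zeros_like(img, dtype=np.intp)
    coded = np.zeros(img.shape, dtype=np.uint8)  # 0 = outside mask
    coded[mask] = q[mask] + 1
    glcm = graycomatrix(
        coded,
        distances=[1],
        angles=list(GLCM_ANGLES),
        levels=GLCM_LEVELS + 1,
        symmetric=True,
        normed=False,
    )
    acc = np.zeros((GLCM_LEVELS, GLCM_LEVELS), dtype=float)
    for a in range(glcm.shape[3]):
        sub = glcm[1:, 1:, 0, a].astype(float)
        total = sub.sum()
        if total > 0:
            acc += sub / total
    s = acc.sum()
    return acc / s if s > 0 else acc


def texture_features(image: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """6 GLCM statistics (distance 1, four angles averaged, symmetric)."""
    out = {name: np.nan for name in TEXTURE_NAMES}
    if not np.asarray(mask, dtype=bool).any():
        return out
    P = _masked_glcm(image, mask)
    if P.sum() == 0:
        return out
    i, j = np.indices(P.shape)
    diff = i - j
    out["contrast"] = float((P * diff**2).sum())
    out["dissimilarity"] = float((P * np.abs(diff)).sum())
    out["homogeneity"] = float((P / (1.0 + diff**2)).sum())
    asm = float((P**2).sum())
    out["ASM"] = asm
    out["energy"] = float(np.sqrt(asm))
    mu_i = float((P * i).sum())
    mu_j = float((P * j).sum())
    var_i = float((P * (i - mu_i) ** 2).sum())
    var_j = float((P * (j - mu_j) ** 2).sum())
    if var_i > 0 and var_j > 0:
        out["correlation"] = float(
            (P * (i - mu_i) * (j - mu_j)).sum() / np.sqrt(var_i * var_j)
        )
    else:
        out["correlation"] = 1.0  # degenerate (zero-variance) matrix
    return out


# ---------------------------------------------------------------------------
# Co-localization (17 values)
# ---------------------------------------------------------------------------

COLOC_NAMES = (
    "dice distance",
    "jaccard distance",
    "intersection area",
    "union area",
    "overlap fraction",
    "correlation distance",
    "euclidean distance",
    "cosine distance",
    "pearson correlation",
    "spearman correlation",
    "mutual information",
    "manders M1",
    "manders M2",
    "overlap coefficient",
    "ICQ",
    "structural similarity",
    "hausdorff distance",
)


def _mutual_information(x: np.ndarray, y: np.ndarray, bins: int = 16) -> float:
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / (px @ py)[nz])).sum())


def colocalization_features(
    image_a: np.ndarray,
    mask_a: np.ndarray,
    image_b: np.ndarray,
    mask_b: np.ndarray,
) -> dict[str, float]:
    """17 co-localization measures for an unordered channel pair.

    Mask-overlap distances come from the two masks; intensity agreement is
    computed over the union-of-masks pixel set; structural similarity uses
    the full frame.  Both masks empty -> all NaN.
    """
    out = {name: np.nan for name in COLOC_NAMES}
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if not a.any() and not b.any():
        return out
    ia = np.asarray(image_a, dtype=float)
    ib = np.asarray(image_b, dtype=float)

    inter = a & b
    union = a | b
    n_inter = float(inter.sum())
    n_union = float(union.sum())
    out["intersection area"] = n_inter
    out["union area"] = n_union
    out["dice distance"] = 1.0 - 2.0 * n_inter / (a.sum() + b.sum())
    out["jaccard distance"] = 1.0 - n_inter / n_union
    min_area = float(min(a.sum(), b.sum()))
    if min_area > 0:
        out["overlap fraction"] = n_inter / min_area

    x = ia[union]
    y = ib[union]
    out["euclidean distance"] = float(np.sqrt(((x - y) ** 2).sum()))
    if x.std() > 0 and y.std() > 0:
        r = float(np.corrcoef(x, y)[0, 1])
        out["pearson correlation"] = r
        out["correlation distance"] = 1.0 - r
        rho = stats.spearmanr(x, y).statistic
        out["spearman correlation"] = float(rho)
    nx = float(np.linalg.norm(x))
    ny = float(np.linalg.norm(y))
    if nx > 0 and ny > 0:
        out["cosine distance"] = 1.0 - float(x @ y) / (nx * ny)
        out["overlap coefficient"] = float((x * y).sum()) / np.sqrt(
            float((x**2).sum()) * float((y**2).sum())
        )
    out["mutual information"] = _mutual_information(x, y)

    sum_a = float(ia[a].sum()) if a.any() else 0.0
    sum_b = float(ib[b].sum()) if b.any() else 0.0
    if sum_a > 0:
        out["manders M1"] = float(ia[inter].sum()) / sum_a
    if sum_b > 0:
        out["manders M2"] = float(ib[inter].sum()) / sum_b

    # intensity correlation quotient over the union pixel set
    prod = (x - x.mean()) * (y - y.mean())
    out["ICQ"] = float((prod > 0).mean()) - 0.5

    drange = max(float(max(ia.max(), ib.max()) - min(ia.min(), ib.min())), 1.0)
    side = min(ia.shape)
    win = min(7, side if side % 2 == 1 else side - 1)
    if win >= 3:
        out["structural similarity"] = float(
            structural_similarity(ia, ib, data_range=drange, win_size=win)
        )
    if a.any() and b.any():
        pa = np.argwhere(a)
        pb = np.argwhere(b)
        out["hausdorff distance"] = float(
            max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0])
        )
    return out


# ---------------------------------------------------------------------------
# Synaptic enrichment (3 values)
# ---------------------------------------------------------------------------

SYNAPTIC_NAMES = ("enrichment (mean)", "enrichment (sum)", "enrichment (max)")


def synaptic_features(
    image: np.ndarray, cell_mask: np.ndarray, synapse: SynapseMask
) -> dict[str, float]:
    """Enrichment of a channel inside the synapse relative to the whole cell.

    ``enrichment (mean) = mean(I in synapse) / mean(I in cell)``;
    ``enrichment (sum)`` uses sums; ``enrichment (max)`` divides the synapse
    maximum by the cell mean.  An empty synapse mask is a real "no contact"
    measurement and yields 0 for all three; a zero denominator yields NaN.
    """
    out = {name: np.nan for name in SYNAPTIC_NAMES}
    syn = np.asarray(synapse.mask, dtype=bool)
    if not syn.any():
        return {name: 0.0 for name in SYNAPTIC_NAMES}
    cell = np.asarray(cell_mask, dtype=bool)
    if not cell.any():
        return out
    img = np.asarray(image, dtype=float)
    cell_vals = img[cell]
    syn_vals = img[syn]
    cell_mean = float(cell_vals.mean())
    cell_sum = float(cell_vals.sum())
    if cell_mean > 0:
        out["enrichment (mean)"] = float(syn_vals.mean()) / cell_mean
        out["enrichment (max)"] = float(syn_vals.max()) / cell_mean
    if cell_sum > 0:
        out["enrichment (sum)"] = float(syn_vals.sum()) / cell_sum
    return out


# ---------------------------------------------------------------------------
# Quality control (2 values per channel)
# ---------------------------------------------------------------------------

QC_NAMES = ("background mean", "gradient RMS")


def qc_features(record: CellRecord) -> dict[str, float]:
    """Background mean and Sobel gradient RMS for every channel.

    Background = pixels outside the union of all channel masks (NaN when the
    union covers the frame).  Gradient RMS is the root-mean-square Sobel
    gradient magnitude within the channel's own mask, or over the whole
    frame when that mask is empty — a focus measure.
    """
    out: dict[str, float] = {}
    union = record.masks.any(axis=0)
    background = ~union
    for c, name in enumerate(record.channels):
        img = np.asarray(record.image[c], dtype=float)
        if background.any():
            out[f"background mean of {name}"] = float(img[background].mean())
        else:
            out[f"background mean of {name}"] = np.nan
        grad = sobel(img)
        mask = record.masks[c]
        sel = grad[mask] if mask.any() else grad
        out[f"gradient RMS of {name}"] = float(np.sqrt((sel**2).mean()))
    return out


# ---------------------------------------------------------------------------
# Feature inventory
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureDef:
    name: str
    family: str
    channels: tuple[str, ...]  # one channel, or an unordered pair
    computation: str  # key within the family block


@dataclass
class FeatureInventory:
    """Ordered, declarative list of feature definitions."""

    entries: list[FeatureDef] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate feature names in inventory: {dupes[:5]}")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def content_hash(self) -> str:
        blob = json.dumps(
            [(e.name, e.family, list(e.channels), e.computation) for e in self.entries]
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "version": 1,
            "entries": [
                {
                    "name": e.name,
                    "family": e.family,
                    "channels": list(e.channels),
                    "computation": e.computation,
                }
                for e in self.entries
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureInventory":
        payload = json.loads(Path(path).read_text())
        return cls(
            entries=[
                FeatureDef(
                    name=e["name"],
                    family=e["family"],
                    channels=tuple(e["channels"]),
                    computation=e["computation"],
                )
                for e in payload["entries"]
            ]
        )


def _per_channel_block(ch: str) -> list[FeatureDef]:
    """27 fluorescent-relevant entries for one channel."""
    entries = [
        FeatureDef(f"{stat} of {ch}", "intensity", (ch,), stat)
        for stat in INTENSITY_NAMES
    ]
    entries += [
        FeatureDef(f"{stat} of {ch}", "texture", (ch,), stat) for stat in TEXTURE_NAMES
    ]
    entries += [
        FeatureDef(
            f"enrichment of {ch} ({kind})", "synaptic", (ch,), f"enrichment ({kind})"
        )
        for kind in ("mean", "sum", "max")
    ]
    entries.append(FeatureDef(f"area of {ch}", "morphology", (ch,), "area"))
    return entries


def _per_pair_block(a: str, b: str) -> list[FeatureDef]:
    """17 co-localization entries for an unordered channel pair."""
    return [
        FeatureDef(f"{stat} of {a} & {b}", "coloc", (a, b), stat)
        for stat in COLOC_NAMES
    ]


def fluor_relevant_inventory(
    channels: Sequence[str] = FLUORESCENT_CHANNELS,
) -> FeatureInventory:
    """27 features per fluorescent channel + 17 per unordered pair.

    Four channels give 210 columns, three give 132 — the feature spaces used
    to compare antibody-treated and control synapses.
    """
    channels = list(channels)
    entries: list[FeatureDef] = []
    for ch in channels:
        entries.extend(_per_channel_block(ch))
    for i, a in enumerate(channels):
        for b in channels[i + 1 :]:
            entries.extend(_per_pair_block(a, b))
    return FeatureInventory(entries=entries)


def intensity_inventory(channels: Sequence[str]) -> FeatureInventory:
    """Intensity statistics only — the lean space for shift analyses."""
    return FeatureInventory(
        entries=[
            FeatureDef(f"{stat} of {ch}", "intensity", (ch,), stat)
            for ch in channels
            for stat in INTENSITY_NAMES
        ]
    )


def full_inventory(panel: Sequence[str], qc: bool = True) -> FeatureInventory:
    """Fluorescent-relevant block + brightfield morphology (+ QC).

    The full feature space is configurable by construction; its total column
    count depends on the panel and the enabled blocks.
    """
    fluor = [c for c in panel if c not in (BRIGHTFIELD, "Live/Dead")]
    inv = fluor_relevant_inventory(fluor)
    entries = list(inv.entries)
    if "Live/Dead" in panel:
        # viability stain: intensity statistics only (used by cleaning rule 1)
        entries.extend(
            FeatureDef(f"{stat} of Live/Dead", "intensity", ("Live/Dead",), stat)
            for stat in INTENSITY_NAMES
        )
    if BRIGHTFIELD in panel:
        entries.extend(
            FeatureDef(f"{name} of {BRIGHTFIELD}", "morphology", (BRIGHTFIELD,), name)
            for name in MORPHOLOGY_NAMES
        )
    if qc:
        for ch in panel:
            entries.append(
                FeatureDef(f"background mean of {ch}", "qc", (ch,), "background mean")
            )
            entries.append(
                FeatureDef(f"gradient RMS of {ch}", "qc", (ch,), "gradient RMS")
            )
    return FeatureInventory(entries=entries)


# ---------------------------------------------------------------------------
# Feature table + extraction
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """records x named-features matrix with explicit NaN for missing."""

    df: pd.DataFrame
    provenance: str = ""

    @property
    def feature_names(self) -> list[str]:
        return list(self.df.columns)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.df.to_csv(path, index_label="record_id")
        return path

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str = "") -> "FeatureTable":
        return cls(pd.read_csv(path, index_col="record_id"), provenance=provenance)


def compute_record_features(
    record: CellRecord,
    inventory: FeatureInventory,
    t_channel: str = "CD3",
    b_channel: str = "MHCII",
) -> dict[str, float]:
    """All inventory features for one record (shared blocks computed once)."""
    values: dict[str, float] = {}
    blocks: dict[tuple, dict[str, float]] = {}
    synapse: SynapseMask | None = None
    qc_block: dict[str, float] | None = None

    needs_synapse = any(e.family == "synaptic" for e in inventory.entries)
    if needs_synapse:
        synapse = derive_synapse_mask(record, t_channel=t_channel, b_channel=b_channel)

    for e in inventory.entries:
        key = (e.family, e.channels)
        if key not in blocks:
            if e.family == "morphology":
                ch = e.channels[0]
                blocks[key] = morphology_features(
                    record.channel_mask(ch), record.channel_image(ch)
                )
            elif e.family == "intensity":
                ch = e.channels[0]
                blocks[key] = intensity_features(
                    record.channel_image(ch), record.channel_mask(ch)
                )
            elif e.family == "texture":
                ch = e.channels[0]
                blocks[key] = texture_features(
                    record.channel_image(ch), record.channel_mask(ch)
                )
            elif e.family == "coloc":
                a, b = e.channels
                blocks[key] = colocalization_features(
                    record.channel_image(a),
                    record.channel_mask(a),
                    record.channel_image(b),
                    record.channel_mask(b),
                )
            elif e.family == "synaptic":
                ch = e.channels[0]
                blocks[key] = synaptic_features(
                    record.channel_image(ch), record.channel_mask(ch), synapse
                )
            elif e.family == "qc":
                if qc_block is None:
                    qc_block = qc_features(record)
                blocks[key] = {
                    comp: qc_block[f"{comp} of {e.channels[0]}"]
                    for comp in QC_NAMES
                }
            else:
                raise ValueError(f"unknown feature family {e.family!r}")
        values[e.name] = blocks[key].get(e.computation, np.nan)
    return values


def _safe_record_features(record, inventory, t_channel, b_channel):
    try:
        return record.record_id, compute_record_features(
            record, inventory, t_channel, b_channel
        )
    except Exception:  # per-record failure must not abort the batch
        logger.exception("feature extraction failed for record %s", record.record_id)
        return record.record_id, {name: np.nan for name in inventory.names}


def extract_features(
    records: Iterable[CellRecord],
    inventory: FeatureInventory,
    t_channel: str = "CD3",
    b_channel: str = "MHCII",
    n_jobs: int = 1,
) -> FeatureTable:
    """One row per record, columns in inventory order, deterministic.

    Chunked parallel execution (``n_jobs``) yields output identical to the
    serial run because rows are keyed by record id and reassembled in input
    order.
    """
    records = list(records)
    if n_jobs == 1:
        rows = [
            _safe_record_features(r, inventory, t_channel, b_channel) for r in records
        ]
    else:
        rows = Parallel(n_jobs=n_jobs)(
            delayed(_safe_record_features)(r, inventory, t_channel, b_channel)
            for r in records
        )
    df = pd.DataFrame.from_dict(
        {rid: vals for rid, vals in rows}, orient="index", columns=inventory.names
    )
    df = df.loc[[r.record_id for r in records]]
    df.index.name = "record_id"
    return FeatureTable(df=df, provenance=inventory.content_hash)
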