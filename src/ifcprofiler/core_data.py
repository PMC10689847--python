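"""Domain types and record I/O for imaging-flow-cytometry conjugate analysis.

A *record* is one imaging-flow-cytometry event: a C-channel intensity stack
(16-bit counts) with per-channel binary segmentation masks and acquisition
metadata (donor, experiment, condition, optional expert label).  Records are
stored one per HDF5 file so that cohorts can be processed embarrassingly in
parallel.  This module also holds the nine-class conjugate taxonomy and the
stratified train/test splitter shared by every downstream stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Canonical channel panel.  BF is stain-free; Live/Dead is optional and used
# only by the cleaning stage.
BRIGHTFIELD = "BF"
DEFAULT_PANEL = ("BF", "F-actin", "MHCII", "CD3", "P-CD3z")
VIABILITY_CHANNEL = "Live/Dead"

#: Fluorescent channels carrying targeted biological information.
FLUORESCENT_CHANNELS = ("F-actin", "MHCII", "CD3", "P-CD3z")


class ValidationError(ValueError):
    """A record or argument violates a structural invariant."""


class FormatError(IOError):
    """An on-disk record does not conform to the expected HDF5 layout."""


# ---------------------------------------------------------------------------
# CellRecord
# ---------------------------------------------------------------------------

@dataclass
class CellRecord:
    """One cell/conjugate event.

    Parameters
    ----------
    record_id:
        Opaque unique identifier.
    channels:
        Ordered channel names; must be unique.
    image:
        ``(C, H, W)`` non-negative intensity stack (16-bit dynamic range).
    masks:
        ``(C, H, W)`` boolean segmentation masks, one per channel
        (``True`` = inside cell).
    meta:
        Mapping with at least ``donor_id``, ``experiment_id``, ``condition``.
    label:
        Optional expert class name.
    probs:
        Optional classifier probability simplex over the nine classes.
    """

    record_id: str
    channels: Sequence[str]
    image: np.ndarray
    masks: np.ndarray
    meta: dict = field(default_factory=dict)
    label: str | None = None
    probs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.channels = tuple(str(c) for c in self.channels)
        self.image = np.asarray(self.image)
        self.masks = np.asarray(self.masks).astype(bool)
        self.validate()

    def validate(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValidationError(f"duplicate channel names: {self.channels}")
        if self.image.ndim != 3:
            raise ValidationError("image must be a C x H x W stack")
        if self.image.shape[0] != len(self.channels):
            raise ValidationError(
                f"image has {self.image.shape[0]} planes for "
                f"{len(self.channels)} channels"
            )
        if self.masks.shape != self.image.shape:
            raise ValidationError(
                f"masks shape {self.masks.shape} != image shape {self.image.shape}"
            )
        if np.any(np.asarray(self.image, dtype=np.float64) < 0):
            raise ValidationError("intensities must be non-negative")
        if self.probs is not None:
            self.probs = np.asarray(self.probs, dtype=np.float64)
            if abs(float(self.probs.sum()) - 1.0) > 1e-9:
                raise ValidationError("probs must sum to 1 within 1e-9")

    # convenience -----------------------------------------------------------
    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in panel {self.channels}") from None

    def channel_image(self, name: str) -> np.ndarray:
        return self.image[self.channel_index(name)]

    def channel_mask(self, name: str) -> np.ndarray:
        return self.masks[self.channel_index(name)]

    def with_channels(self, names: Sequence[str]) -> "CellRecord":
        """Restrict the record to a channel subset (order as given)."""
        idx = [self.channel_index(n) for n in names]
        return replace(
            self,
            channels=tuple(names),
            image=self.image[idx],
            masks=self.masks[idx],
        )


# ---------------------------------------------------------------------------
# Class taxonomy
# ---------------------------------------------------------------------------

SINGLET, DOUBLET, MULTIPLET = "singlet", "doublet", "multiplet"


@dataclass(frozen=True)
class ClassTaxonomy:
    """The nine conjugate classes, their grouping level and artifact flags.

    Two classes ('T cell w/ small B-LCL', 'no cell-cell interaction') are
    experimental artifacts: they are kept during classifier training to
    sharpen the decision boundary but excluded from every population-level
    analysis.
    """

    classes: tuple[str, ...]
    level1: Mapping[str, str]
    artifact: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.classes) != 9:
            raise ValidationError("taxonomy must contain exactly 9 classes")
        if not self.artifact <= set(self.classes):
            raise ValidationError("artifact classes must be taxonomy classes")

    @property
    def analysis_classes(self) -> tuple[str, ...]:
        """Classes retained for frequency/feature profiling (non-artifact)."""
        return tuple(c for c in self.classes if c not in self.artifact)


def default_taxonomy() -> ClassTaxonomy:
    classes = (
        "single B-LCL",
        "single T cell w/o signaling",
        "single T cell w/ signaling",
        "T cell w/ small B-LCL",
        "B-LCL and T cell in one layer",
        "synapse w/o signaling",
        "synapse w/ signaling",
        "no cell-cell interaction",
        "multi-synapse",
    )
    level1 = {
        "single B-LCL": SINGLET,
        "single T cell w/o signaling": SINGLET,
        "single T cell w/ signaling": SINGLET,
        "T cell w/ small B-LCL": DOUBLET,
        "B-LCL and T cell in one layer": DOUBLET,
        "synapse w/o signaling": DOUBLET,
        "synapse w/ signaling": DOUBLET,
        "no cell-cell interaction": DOUBLET,
        "multi-synapse": MULTIPLET,
    }
    artifact = frozenset({"T cell w/ small B-LCL", "no cell-cell interaction"})
    return ClassTaxonomy(classes=classes, level1=level1, artifact=artifact)


# ---------------------------------------------------------------------------
# HDF5 record I/O
# ---------------------------------------------------------------------------
# Layout (one record per file): datasets "image" (uint16), "masks" (uint8 0/1),
# "channels" (variable-length UTF-8), optional "probs" (float64); group "meta"
# with scalar attributes, plus optional "label" attribute on the root.

_KNOWN_DATASETS = {"image", "masks", "channels", "probs"}


def write_record(record: CellRecord, path: str | Path) -> Path:
    """Write a validated record to one HDF5 file; round-trips bit-exactly."""
    record.validate()
    path = Path(path)
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        f.create_dataset("image", data=np.asarray(record.image, dtype=np.uint16))
        f.create_dataset("masks", data=record.masks.astype(np.uint8))
        f.create_dataset("channels", data=np.array(record.channels, dtype=str_dt))
        if record.probs is not None:
            f.create_dataset("probs", data=np.asarray(record.probs, dtype=np.float64))
        f.attrs["record_id"] = record.record_id
        if record.label is not None:
            f.attrs["label"] = record.label
        meta = f.create_group("meta")
        for key, value in record.meta.items():
            meta.attrs[key] = value
    return path


def read_record(path: str | Path) -> CellRecord:
    """Read and validate a record written by :func:`write_record`.

    Unknown extra datasets are ignored with a logged warning; a missing
    required dataset raises :class:`FormatError` naming it.
    """
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            for name in ("image", "masks", "channels"):
                if name not in f:
                    raise FormatError(f"{path}: missing required dataset {name!r}")
            extra = sorted(set(f.keys()) - _KNOWN_DATASETS - {"meta"})
            if extra:
                logger.warning("%s: ignoring unknown datasets %s", path, extra)
            channels = [
                c.decode() if isinstance(c, bytes) else str(c) for c in f["channels"][()]
            ]
            probs = f["probs"][()] if "probs" in f else None
            meta = dict(f["meta"].attrs) if "meta" in f else {}
            meta = {
                k: (v.decode() if isinstance(v, bytes) else v) for k, v in meta.items()
            }
            label = f.attrs.get("label")
            if isinstance(label, bytes):
                label = label.decode()
            record_id = f.attrs.get("record_id", path.stem)
            if isinstance(record_id, bytes):
                record_id = record_id.decode()
            return CellRecord(
                record_id=str(record_id),
                channels=channels,
                image=f["image"][()],
                masks=f["masks"][()].astype(bool),
                meta=meta,
                label=None if label is None else str(label),
                probs=probs,
            )
    except OSError as exc:
        if isinstance(exc, FormatError):
            raise
        raise IOError(f"cannot read record at {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# DatasetIndex
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = (
    "record_id",
    "path",
    "donor_id",
    "experiment_id",
    "condition",
    "label",
)


@dataclass
class DatasetIndex:
    """Manifest of a record collection with grouping accessors.

    Backed by a DataFrame with columns ``record_id, path, donor_id,
    experiment_id, condition, label`` (label may be missing).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS[:-1] if c not in self.table.columns]
        if missing:
            raise ValidationError(f"manifest lacks columns {missing}")
        if "label" not in self.table.columns:
            self.table = self.table.assign(label=pd.NA)
        if self.table["record_id"].duplicated().any():
            dupes = self.table.loc[self.table["record_id"].duplicated(), "record_id"]
            raise ValidationError(f"duplicate record ids: {sorted(set(dupes))[:5]}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def record_ids(self) -> list[str]:
        return list(self.table["record_id"])

    @property
    def labels(self) -> pd.Series:
        return self.table.set_index("record_id")["label"]

    def by_donor(self) -> dict[str, "DatasetIndex"]:
        return {
            str(d): DatasetIndex(g.copy()) for d, g in self.table.groupby("donor_id")
        }

    def by_condition(self) -> dict[str, "DatasetIndex"]:
        return {
            str(c): DatasetIndex(g.copy()) for c, g in self.table.groupby("condition")
        }

    def by_experiment(self) -> dict[str, "DatasetIndex"]:
        return {
            str(e): DatasetIndex(g.copy())
            for e, g in self.table.groupby("experiment_id")
        }

    def subset(self, record_ids: Iterable[str]) -> "DatasetIndex":
        wanted = set(record_ids)
        return DatasetIndex(
            self.table[self.table["record_id"].isin(wanted)].copy()
        )

    def iter_records(self):
        """Yield :class:`CellRecord` objects, resolving each path lazily."""
        for _, row in self.table.iterrows():
            yield read_record(row["path"])

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "DatasetIndex":
        table = pd.read_csv(path, dtype={"record_id": str, "donor_id": str})
        if "path" in table.columns:
            table["path"] = table["path"].fillna("")
        return cls(table)

    @classmethod
    def from_rows(cls, rows: Sequence[Mapping]) -> "DatasetIndex":
        return cls(pd.DataFrame(list(rows)))


# ---------------------------------------------------------------------------
# Stratified split
# ---------------------------------------------------------------------------

def stratified_split(
    index: DatasetIndex,
    labels: Mapping[str, str] | pd.Series | None = None,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[DatasetIndex, DatasetIndex]:
    """Split a labeled index into train/test preserving class proportions.

    The train set totals ``floor(train_fraction * n)`` records: each class
    contributes ``floor(train_fraction * n_c)``, and the remaining slots are
    assigned to classes by largest fractional part (ties broken by class
    name).  Per-class train counts therefore differ from the exact
    proportional allocation by less than one record.  For the study's 5,221
    annotated conjugates at 70 % this yields 3,654 train / 1,567 test.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValidationError("train_fraction must lie strictly between 0 and 1")
    if labels is None:
        labels = index.labels
    lab = pd.Series({rid: labels[rid] for rid in index.record_ids})
    if lab.isna().any():
        missing = list(lab.index[lab.isna()])[:5]
        raise ValidationError(f"unlabeled records: {missing}")

    counts = lab.value_counts()
    small = sorted(counts.index[counts < 2])
    if small:
        raise ValidationError(f"classes with fewer than 2 records: {small}")

    eps = 1e-9  # guard against float floor of exact products (e.g. 0.7 * 5220)
    n_total = len(lab)
    train_total = int(np.floor(train_fraction * n_total + eps))
    quota = {c: train_fraction * n for c, n in counts.items()}
    base = {c: int(np.floor(q + eps)) for c, q in quota.items()}
    remainder = max(0, train_total - sum(base.values()))
    frac_order = sorted(
        counts.index, key=lambda c: (-(quota[c] - base[c]), str(c))
    )
    alloc = dict(base)
    for c in frac_order[:remainder]:
        alloc[c] += 1

    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    for c in sorted(counts.index, key=str):
        ids = sorted(lab.index[lab == c])
        rng.shuffle(ids)
        train_ids.extend(ids[: alloc[c]])
    train_set = set(train_ids)
    test_ids = [rid for rid in index.record_ids if rid not in train_set]
    return index.subset(train_set), index.subset(test_ids)
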