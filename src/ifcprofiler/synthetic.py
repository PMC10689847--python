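"""Synthetic conjugate-image generator.

Renders labeled multichannel cell records with the statistical structure the
downstream analyses assume: nine conjugate classes built from disk-shaped
cells (T cells carry CD3, B-LCLs carry MHCII, everything carries F-actin and
brightfield signal), synaptic enrichment of selected stains at the contact
zone, Poisson-Gaussian camera noise, optional defocus blur and a viability
stain.  Cohorts add donor random effects (shared log-normal gain per donor),
per-condition class-frequency simplexes, per-condition channel gain shifts
(the planted "feature differences") and a linear donor x condition
functional readout.

The generator is deliberately non-photorealistic: it reproduces the
*relationships* the pipeline measures (mask topology per class, enrichment
ratios, frequency shifts, linear functional structure), not the absolute
intensity distributions of a real imaging flow cytometer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk
from skimage.morphology import dilation as binary_dilation, disk as disk_selem

from .core_data import (
    CellRecord,
    DatasetIndex,
    VIABILITY_CHANNEL,
    default_taxonomy,
    write_record,
)
from .features import SYNAPSE_DILATION_RADIUS, DECILES

IMAGE_SIZE = 64
PANEL = ("BF", "F-actin", "MHCII", "CD3", "P-CD3z")

BACKGROUND_LEVEL = 100.0
#: Mean signal counts per channel on the supporting cell body.
DEFAULT_LEVELS = {
    "BF": 3000.0,
    "F-actin": 2200.0,
    "MHCII": 3000.0,
    "CD3": 3000.0,
    "P-CD3z": 2400.0,
    VIABILITY_CHANNEL: 150.0,
}
DEAD_VIABILITY_LEVEL = 4000.0
DEFAULT_NOISE_SD = 50.0

#: Synaptic enrichment factors (contact-zone mean / cell-body mean) applied
#: to stains that concentrate at a functional synapse.
DEFAULT_RHO = {"F-actin": 2.0, "MHCII": 1.5, "P-CD3z": 2.5}

CLASS_NAMES = default_taxonomy().classes


@dataclass
class SceneSpec:
    """Geometry and signal levels for one rendered record."""

    class_name: str
    t_radius: float = 8.0
    b_radius: float = 11.0
    radius_jitter: float = 1.0
    center_jitter: float = 2.0
    levels: dict = field(default_factory=lambda: dict(DEFAULT_LEVELS))
    noise_sd: float = DEFAULT_NOISE_SD
    rho: dict = field(default_factory=lambda: dict(DEFAULT_RHO))
    viability_level: float = DEFAULT_LEVELS[VIABILITY_CHANNEL]
    blur_sd: float = 0.0
    include_viability: bool = True

    def __post_init__(self) -> None:
        if self.class_name not in CLASS_NAMES:
            raise ValueError(f"unknown class name {self.class_name!r}")
        if self.t_radius <= 0 or self.b_radius <= 0:
            raise ValueError("radii must be positive")
        if any(v < 0 for v in self.levels.values()):
            raise ValueError("intensity levels must be non-negative")
        if any(r < 0 for r in self.rho.values()):
            raise ValueError("enrichment factors must be non-negative")


@dataclass(frozen=True)
class _Cell:
    kind: str  # "T" or "B"
    center: tuple[float, float]
    radius: float


def _disk_mask(center, radius, shape=(IMAGE_SIZE, IMAGE_SIZE)) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk(center, radius, shape=shape)
    mask[rr, cc] = True
    return mask


def _layout(spec: SceneSpec, rng: np.random.Generator) -> list[_Cell]:
    """Cell arrangement per class; distances control mask overlap topology."""
    j = spec.center_jitter
    cy, cx = 32.0 + rng.uniform(-j, j), 32.0 + rng.uniform(-j, j)
    rt = max(2.0, spec.t_radius + rng.uniform(-1, 1) * spec.radius_jitter)
    rb = max(2.0, spec.b_radius + rng.uniform(-1, 1) * spec.radius_jitter)
    name = spec.class_name
    theta = rng.uniform(0, 2 * np.pi)
    u = np.array([np.cos(theta), np.sin(theta)])

    def pair(gap: float) -> list[_Cell]:
        # centers separated so that the edge-to-edge distance equals `gap`
        d = rt + rb + gap
        c1 = np.array([cy, cx]) - u * d / 2
        c2 = np.array([cy, cx]) + u * d / 2
        return [_Cell("B", tuple(c1), rb), _Cell("T", tuple(c2), rt)]

    if name == "single B-LCL":
        return [_Cell("B", (cy, cx), rb)]
    if name in ("single T cell w/o signaling", "single T cell w/ signaling"):
        return [_Cell("T", (cy, cx), rt)]
    if name == "T cell w/ small B-LCL":
        small = max(2.0, 0.35 * rb)
        d = rt + small - 1.0
        return [
            _Cell("T", (cy, cx), rt),
            _Cell("B", tuple(np.array([cy, cx]) + u * d), small),
        ]
    if name == "B-LCL and T cell in one layer":
        return pair(-0.9 * min(rt, rb))  # heavy overlap: stacked cells
    if name in ("synapse w/o signaling", "synapse w/ signaling"):
        return pair(-2.0)  # touching with a small contact zone
    if name == "no cell-cell interaction":
        return pair(2.0 * SYNAPSE_DILATION_RADIUS + 3.0)  # beyond dilation reach
    if name == "multi-synapse":
        n_extra = int(rng.integers(1, 3))  # 3 or 4 cells
        cells = pair(-2.0)
        for k in range(n_extra):
            anchor = cells[-1]
            kind = "B" if anchor.kind == "T" else "T"
            r = rb if kind == "B" else rt
            phi = theta + (k + 1) * rng.uniform(0.6, 1.2)
            v = np.array([np.cos(phi), np.sin(phi)])
            c = np.array(anchor.center) + v * (anchor.radius + r - 2.0)
            c = np.clip(c, 6, IMAGE_SIZE - 6)
            cells.append(_Cell(kind, tuple(c), r))
        return cells
    raise ValueError(f"unknown class name {name!r}")


def render_record(
    spec: SceneSpec,
    rng: np.random.Generator,
    record_id: str = "synthetic",
    meta: Mapping | None = None,
) -> CellRecord:
    """Render one labeled record from a scene specification.

    Channel supports follow the class composition (e.g. a signaling synapse
    has touching CD3 and MHCII disks with P-CD3z concentrated at the contact
    zone by the factor ``rho``); masks match the rendered supports.
    """
    cells = _layout(spec, rng)
    name = spec.class_name
    shape = (IMAGE_SIZE, IMAGE_SIZE)
    t_mask = np.zeros(shape, bool)
    b_mask = np.zeros(shape, bool)
    for cell in cells:
        m = _disk_mask(cell.center, cell.radius)
        if cell.kind == "T":
            t_mask |= m
        else:
            b_mask |= m
    union = t_mask | b_mask

    signaling = name in (
        "single T cell w/ signaling",
        "synapse w/ signaling",
        "multi-synapse",
    )
    synaptic = name in ("synapse w/o signaling", "synapse w/ signaling", "multi-synapse")

    # contact zone as the feature engine will see it
    selem = disk_selem(SYNAPSE_DILATION_RADIUS)
    contact = binary_dilation(t_mask, selem) & binary_dilation(b_mask, selem)

    signal: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}

    def paint(support: np.ndarray, level: float, enrich: float | None) -> np.ndarray:
        img = np.zeros(shape, float)
        img[support] = level
        if enrich is not None and enrich != 1.0:
            # synaptic accumulation sits at the contact interface itself,
            # which straddles both cell bodies
            img[contact] = level * enrich
        return img

    lv = spec.levels
    signal["BF"] = paint(union, lv["BF"], None)
    masks["BF"] = union
    signal["F-actin"] = paint(
        union, lv["F-actin"], spec.rho.get("F-actin") if synaptic else None
    )
    masks["F-actin"] = union
    signal["MHCII"] = paint(
        b_mask, lv["MHCII"], spec.rho.get("MHCII") if synaptic else None
    )
    masks["MHCII"] = b_mask
    signal["CD3"] = paint(t_mask, lv["CD3"], None)
    masks["CD3"] = t_mask
    if signaling:
        enrich = spec.rho.get("P-CD3z") if synaptic else None
        signal["P-CD3z"] = paint(t_mask, lv["P-CD3z"], enrich)
        masks["P-CD3z"] = t_mask
    else:
        signal["P-CD3z"] = np.zeros(shape, float)
        masks["P-CD3z"] = np.zeros(shape, bool)

    channels = list(PANEL)
    if spec.include_viability:
        channels.append(VIABILITY_CHANNEL)
        signal[VIABILITY_CHANNEL] = paint(union, spec.viability_level, None)
        masks[VIABILITY_CHANNEL] = union

    stack = np.zeros((len(channels),) + shape, float)
    for c, ch in enumerate(channels):
        img = signal[ch] + BACKGROUND_LEVEL
        if spec.blur_sd > 0:
            img = gaussian_filter(img, spec.blur_sd)
        img = rng.poisson(img).astype(float)
        img += rng.normal(0.0, spec.noise_sd, shape)
        stack[c] = np.clip(img, 0, 65535)

    return CellRecord(
        record_id=record_id,
        channels=channels,
        image=np.round(stack).astype(np.uint16),
        masks=np.stack([masks[ch] for ch in channels]),
        meta=dict(meta or {}),
        label=name,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Intensity statistics that scale monotonically with a channel gain; used
#: to derive the expected sign of a planted per-channel shift.
SCALE_EQUIVARIANT_STATS = (
    "min intensity",
    "max intensity",
    "sum intensity",
    "mean intensity",
    "std intensity",
) + tuple(f"{p}th percentile" for p in DECILES)


@dataclass
class ConditionSpec:
    """One experimental arm: class mixture + planted channel gain shifts."""

    class_frequencies: dict
    channel_scale: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = float(sum(self.class_frequencies.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class frequencies sum to {total}, expected 1")
        unknown = set(self.class_frequencies) - set(CLASS_NAMES)
        if unknown:
            raise ValueError(f"unknown classes in frequency simplex: {unknown}")


@dataclass
class CohortSpec:
    """Donors x conditions sampling plan with planted ground truth."""

    donors: Sequence[str]
    conditions: Mapping[str, ConditionSpec]
    records_per_group: int = 100
    donor_effect_sd: float = 0.15
    dead_fraction: float = 0.0
    scene_overrides: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.donors:
            raise ValueError("at least one donor required")
        if not self.conditions:
            raise ValueError("at least one condition required")
        if self.records_per_group < 1:
            raise ValueError("records_per_group must be >= 1")


@dataclass
class CohortResult:
    records: list
    index: DatasetIndex
    true_frequencies: pd.DataFrame  # rows donor x condition, cols classes
    shift_signs: pd.DataFrame  # feature, condition, expected sign


def expected_shift_signs(conditions: Mapping[str, ConditionSpec]) -> pd.DataFrame:
    """Expected {-1,+1} direction per scale-equivariant intensity feature for
    every condition whose channel gain differs from 1."""
    rows = []
    for cond, cspec in conditions.items():
        for ch, scale in cspec.channel_scale.items():
            if scale == 1.0:
                continue
            sign = 1 if scale > 1.0 else -1
            for stat in SCALE_EQUIVARIANT_STATS:
                rows.append(
                    {"condition": cond, "feature": f"{stat} of {ch}", "sign": sign}
                )
    return pd.DataFrame(rows, columns=["condition", "feature", "sign"])


def generate_cohort(
    spec: CohortSpec, out_dir: str | Path | None = None
) -> CohortResult:
    """Draw a full donor x condition cohort, reproducibly from ``spec.seed``.

    Classes are sampled per record from the condition's frequency simplex;
    donor effects multiply all channel gains by a shared log-normal factor;
    condition channel scales plant known feature shifts.  With ``out_dir``
    records are written one-per-file as HDF5 and the index points at them.
    """
    rng = np.random.default_rng(spec.seed)
    donor_gain = {
        d: float(np.exp(rng.normal(0.0, spec.donor_effect_sd))) for d in spec.donors
    }
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    records = []
    rows = []
    freq_rows = []
    counter = 0
    for donor in spec.donors:
        for cond, cspec in spec.conditions.items():
            classes = sorted(cspec.class_frequencies)
            probs = np.array([cspec.class_frequencies[c] for c in classes])
            freq_rows.append(
                {"donor_id": donor, "condition": cond}
                | {c: cspec.class_frequencies.get(c, 0.0) for c in CLASS_NAMES}
            )
            drawn = rng.choice(len(classes), size=spec.records_per_group, p=probs)
            for k in drawn:
                cls = classes[int(k)]
                levels = {
                    ch: v * donor_gain[donor] * cspec.channel_scale.get(ch, 1.0)
                    for ch, v in DEFAULT_LEVELS.items()
                }
                scene_kwargs = dict(spec.scene_overrides)
                dead = rng.random() < spec.dead_fraction
                scene = SceneSpec(
                    class_name=cls,
                    levels=levels,
                    viability_level=(
                        DEAD_VIABILITY_LEVEL if dead else levels[VIABILITY_CHANNEL]
                    ),
                    **scene_kwargs,
                )
                rid = f"{donor}-{cond}-{counter:06d}"
                counter += 1
                meta = {
                    "donor_id": donor,
                    "experiment_id": "sim",
                    "condition": cond,
                }
                rec = render_record(scene, rng, record_id=rid, meta=meta)
                path = ""
                if out_path is not None:
                    path = str(write_record(rec, out_path / f"{rid}.h5"))
                records.append(rec)
                rows.append(
                    {
                        "record_id": rid,
                        "path": path,
                        "donor_id": donor,
                        "experiment_id": "sim",
                        "condition": cond,
                        "label": cls,
                    }
                )
    index = DatasetIndex(pd.DataFrame(rows))
    return CohortResult(
        records=records,
        index=index,
        true_frequencies=pd.DataFrame(freq_rows),
        shift_signs=expected_shift_signs(spec.conditions),
    )


def functional_readout(
    profile: pd.DataFrame,
    coefficients: Mapping[str, float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.Series:
    """Linear donor x condition readout ``y = sum(beta * column) + noise``.

    ``profile`` is an aggregated feature matrix (rows = donor x condition);
    the coefficient map names its columns.  Emulates a downstream functional
    measurement (e.g. a cytotoxicity marker frequency) that is linear in
    aggregated synapse morphology.
    """
    missing = [c for c in coefficients if c not in profile.columns]
    if missing:
        raise KeyError(f"coefficient columns not in profile: {missing}")
    rng = np.random.default_rng(seed)
    y = pd.Series(0.0, index=profile.index, name="readout")
    for col, beta in coefficients.items():
        y = y + beta * profile[col].astype(float)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, len(y))
    return y


def balanced_cohort_spec(
    n_donors: int = 3,
    records_per_group: int = 300,
    conditions: Mapping[str, ConditionSpec] | None = None,
    seed: int = 0,
    **kwargs,
) -> CohortSpec:
    """Convenience spec: uniform 9-class mixture, one 'control' condition."""
    if conditions is None:
        uniform = {c: 1.0 / 9.0 for c in CLASS_NAMES}
        conditions = {"control": ConditionSpec(class_frequencies=uniform)}
    donors = [f"donor{i+1}" for i in range(n_donors)]
    return CohortSpec(
        donors=donors,
        conditions=dict(conditions),
        records_per_group=records_per_group,
        seed=seed,
        **kwargs,
    )
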