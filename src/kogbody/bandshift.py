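"""Position-weighted scoring of phosphorylation band shifts.

Phosphorylated protein species migrate more slowly on SDS-PAGE and so sit
nearer the top of the gel.  Each lane is reduced to a 1-D intensity profile
(mean across the lane width), total-signal normalized against a reference
lane, and scored with a linear position weighting that calls the first pixel
of the gel 100% phosphorylated and the last pixel 0%.  Raw scores are in
arbitrary weight units; a two-anchor affine transform maps a designated
high-phosphorylation lane to 1.0 and a low one to 0.0, and the same constants
rescale every other lane in the batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class EmptyLaneError(ValueError):
    """Lane carries no signal (all-zero intensities)."""


class DegenerateAnchorError(ValueError):
    """High and low anchor lanes have equal raw scores."""


@dataclass
class LaneProfile:
    """1-D intensity trace along a lane's migration axis.

    Index 0 is the top of the gel (slowest migration, most phosphorylated).
    """

    intensities: np.ndarray
    lane_id: str = ""
    condition: str = ""
    strain: str = ""
    time_min: float | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1 or self.intensities.size < 2:
            raise ValueError("profile must be 1-D with length >= 2")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        if not np.any(self.intensities > 0):
            raise EmptyLaneError(f"lane {self.lane_id!r} has no signal")

    @property
    def total(self) -> float:
        return float(self.intensities.sum())


@dataclass(frozen=True)
class ScoreConfig:
    """Endpoint weights for the linear position weighting."""

    weight_top: float = 100.0
    weight_bottom: float = 0.0

    def __post_init__(self) -> None:
        if self.weight_top == self.weight_bottom:
            raise ValueError("weight_top and weight_bottom must differ")

    def weights(self, n_pixels: int) -> np.ndarray:
        return np.linspace(self.weight_top, self.weight_bottom, n_pixels)


@dataclass(frozen=True)
class AnchorTransform:
    """Affine rescaling normalized = scale * raw + offset."""

    scale: float
    offset: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.scale) or self.scale == 0:
            raise DegenerateAnchorError("anchor transform scale must be finite and nonzero")

    def __call__(self, raw: float) -> float:
        return self.scale * raw + self.offset


@dataclass(frozen=True)
class BandshiftScore:
    lane_id: str
    raw: float
    normalized: float


def extract_lane_profile(
    lane_image: np.ndarray, migration_axis: int = 0, **meta
) -> LaneProfile:
    """Collapse a 2-D lane image to a profile by averaging across the width.

    ``migration_axis`` is the axis along which the protein migrated; the
    perpendicular axis is averaged out.
    """
    img = np.asarray(lane_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("lane_image must be 2-D")
    if img.shape[migration_axis] < 2:
        raise ValueError("need >= 2 positions along the migration axis")
    profile = img.mean(axis=1 - migration_axis)
    return LaneProfile(profile, **meta)


def normalize_total(profile: LaneProfile, reference: LaneProfile) -> LaneProfile:
    """Scale ``profile`` so its total signal matches the reference lane."""
    if len(profile.intensities) != len(reference.intensities):
        raise ValueError("profile and reference must have the same length")
    if profile.total <= 0 or reference.total <= 0:
        raise EmptyLaneError("cannot total-normalize a zero-total lane")
    scale = reference.total / profile.total
    return replace(profile, intensities=profile.intensities * scale)


def position_weighted_score(
    profile: LaneProfile, config: ScoreConfig = ScoreConfig()
) -> float:
    """Sum of intensities weighted linearly from weight_top to weight_bottom.

    With the defaults, a lane whose signal all sits at the first pixel scores
    100 per unit of signal and one at the last pixel scores 0.
    """
    w = config.weights(len(profile.intensities))
    return float(np.dot(w, profile.intensities))


def fit_anchor_transform(raw_ref_high: float, raw_ref_low: float) -> AnchorTransform:
    """Affine map sending the high anchor's raw score to 1.0 and the low to 0.0."""
    if raw_ref_high == raw_ref_low:
        raise DegenerateAnchorError("anchor lanes have identical raw scores")
    scale = 1.0 / (raw_ref_high - raw_ref_low)
    offset = -scale * raw_ref_low
    return AnchorTransform(scale=scale, offset=offset)


@dataclass
class BatchResult:
    scores: list[BandshiftScore]
    transform: AnchorTransform

    def by_id(self, lane_id: str) -> BandshiftScore:
        for s in self.scores:
            if s.lane_id == lane_id:
                return s
        raise KeyError(lane_id)


def score_batch(
    profiles: list[LaneProfile],
    reference_lane_id: str,
    anchor_high_id: str,
    anchor_low_id: str,
    config: ScoreConfig = ScoreConfig(),
    subtract_background: bool = False,
) -> BatchResult:
    """Score a batch of lanes and anchor-normalize against two named lanes.

    Pipeline per lane: optional constant background subtraction (minimum
    pixel), total normalization to the reference lane, position-weighted raw
    score; then the affine transform fit on the two anchors is applied to
    every lane, so the anchors come out exactly 1.0 and 0.0 and every other
    lane (including replicates of other strains) is rescaled with the same
    constants.
    """
    ids = [p.lane_id for p in profiles]
    for needed in (reference_lane_id, anchor_high_id, anchor_low_id):
        if needed not in ids:
            raise KeyError(f"lane {needed!r} missing from batch")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate lane ids in batch")

    prepared = {}
    for p in profiles:
        if subtract_background:
            p = replace(p, intensities=p.intensities - p.intensities.min())
        prepared[p.lane_id] = p
    reference = prepared[reference_lane_id]
    raw = {
        lane_id: position_weighted_score(normalize_total(p, reference), config)
        for lane_id, p in prepared.items()
    }
    transform = fit_anchor_transform(raw[anchor_high_id], raw[anchor_low_id])
    scores = [
        BandshiftScore(lane_id=i, raw=raw[i], normalized=transform(raw[i]))
        for i in ids
    ]
    return BatchResult(scores=scores, transform=transform)
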