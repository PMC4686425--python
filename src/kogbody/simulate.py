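"""Synthetic data with known ground truth for every pipeline stage.

Four generators emulate the raw material of a Kog1-body study so the whole
pipeline is testable without any deposited data:

* two-band gel lanes whose band-intensity split encodes a known
  phosphorylated fraction (band near the top of the gel = phosphorylated,
  slower-migrating species);
* per-timepoint binomial sampling of body-positive cell counts from the
  exponential formation/dissociation models;
* protein sequences with planted Q/N-rich motifs on a Q/N-free background;
* two/three-channel 3-D cell fields: a membrane-ring channel, a punctate
  focus channel with bodies planted in an annulus just outside the ring
  (near the vacuole edge), and a marker channel for co-localization
  experiments.

Every generator is reproducible (same spec + seed -> bitwise-identical
output) and emits its ground truth alongside the data.  Seeding is
hierarchical: each replicate/cell derives its stream from (seed, index), so
adding replicates never perturbs earlier ones.

Noise is additive Gaussian truncated at zero — the simplest model consistent
with non-negative intensities.  There is no point-spread-function realism,
photobleaching or camera-noise modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bandshift import LaneProfile
from .kinetics import TimecourseDataset, TimecoursePoint
from .prilm import AMINO_ACIDS, MotifInterval, ProteinSequence
from .foci import ImageStack

_DEF_BG_WEIGHTS = {aa: 1.0 for aa in sorted(AMINO_ACIDS - {"Q", "N"})}


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(s) for s in stream])


# ---------------------------------------------------------------------------
# gel lanes


@dataclass(frozen=True)
class LaneSimSpec:
    """Two-Gaussian-band gel lane with a known phosphorylated fraction."""

    n_pixels: int = 100
    phospho_fraction: float = 0.5
    band_top_center: float = 30.0     # phosphorylated (slower) band
    band_bottom_center: float = 70.0  # unphosphorylated band
    band_sigma: float = 3.0
    total_signal: float = 1000.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pixels < 2:
            raise ValueError("n_pixels must be >= 2")
        if not 0.0 <= self.phospho_fraction <= 1.0:
            raise ValueError("phospho_fraction must be in [0, 1]")
        for c in (self.band_top_center, self.band_bottom_center):
            if not 0 <= c < self.n_pixels:
                raise ValueError("band centers must lie within the lane")
        if self.band_top_center >= self.band_bottom_center:
            raise ValueError(
                "band_top_center must be above (smaller index than) band_bottom_center"
            )
        if self.band_sigma <= 0 or self.total_signal <= 0 or self.noise_sd < 0:
            raise ValueError("band_sigma/total_signal must be > 0, noise_sd >= 0")


def simulate_lane(spec: LaneSimSpec, lane_id: str = "", **meta) -> LaneProfile:
    """Render a lane profile: two Gaussian bands plus truncated noise.

    Band areas are phospho_fraction*total_signal (top band) and the
    complement (bottom band); each band is normalized on the pixel grid so
    the noiseless lane integral equals total_signal exactly.
    """
    x = np.arange(spec.n_pixels, dtype=float)
    profile = np.zeros(spec.n_pixels)
    for center, area in (
        (spec.band_top_center, spec.phospho_fraction * spec.total_signal),
        (spec.band_bottom_center, (1.0 - spec.phospho_fraction) * spec.total_signal),
    ):
        if area <= 0:
            continue
        g = np.exp(-0.5 * ((x - center) / spec.band_sigma) ** 2)
        profile += area * g / g.sum()
    if spec.noise_sd > 0:
        profile = profile + _rng(spec.seed, 0).normal(0.0, spec.noise_sd, spec.n_pixels)
        profile = np.clip(profile, 0.0, None)
    return LaneProfile(profile, lane_id=lane_id, **meta)


def render_lane_image(
    profile: LaneProfile, width: int = 10, noise_sd: float = 0.0, seed: int = 0
) -> np.ndarray:
    """Replicate a 1-D profile across a lane width with optional pixel noise.

    Rows are the migration axis; useful for testing profile extraction from
    2-D gel images.
    """
    img = np.tile(profile.intensities[:, None], (1, width))
    if noise_sd > 0:
        img = np.clip(img + _rng(seed, 1).normal(0.0, noise_sd, img.shape), 0.0, None)
    return img


# ---------------------------------------------------------------------------
# time courses


@dataclass(frozen=True)
class TimecourseSimSpec:
    """Binomial body-count sampling from an exponential kinetic model.

    p(t) = A*(1 - e^(-t/tau)) + c  (formation),
           A*e^(-t/tau) + c        (dissociation), or
           c                       (flat).
    """

    model: str = "formation"
    A: float = 0.49
    tau: float = 11.0
    c: float = 0.08
    timepoints: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 20.0, 30.0, 45.0, 60.0)
    n_cells_per_timepoint: int = 200
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("formation", "dissociation", "flat"):
            raise ValueError(f"unknown model {self.model!r}")
        if not (0.0 <= self.A <= 1.0 and 0.0 <= self.c <= 1.0):
            raise ValueError("A and c must be in [0, 1]")
        if self.A + self.c > 1.0 + 1e-12:
            raise ValueError("A + c must be <= 1 (p(t) would exceed 1)")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        tp = np.asarray(self.timepoints, float)
        if np.any(tp < 0) or np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints must be non-negative and strictly increasing")
        if self.n_cells_per_timepoint < 1 or self.n_replicates < 1:
            raise ValueError("n_cells_per_timepoint and n_replicates must be >= 1")

    def p(self, t) -> np.ndarray:
        t = np.asarray(t, float)
        if self.model == "formation":
            return self.A * (1.0 - np.exp(-t / self.tau)) + self.c
        if self.model == "dissociation":
            return self.A * np.exp(-t / self.tau) + self.c
        return np.full_like(t, self.c)


def simulate_timecourse(
    spec: TimecourseSimSpec, condition: str = "", strain: str = ""
) -> TimecourseDataset:
    """Draw body-positive counts ~ Binomial(n, p(t)) per replicate and timepoint.

    The returned dataset carries the generating spec in its ``truth`` field.
    """
    replicates = []
    for r in range(spec.n_replicates):
        rng = _rng(spec.seed, 2, r)
        points = [
            TimecoursePoint(
                time_min=float(t),
                n_cells=spec.n_cells_per_timepoint,
                n_with_bodies=int(rng.binomial(spec.n_cells_per_timepoint, p)),
            )
            for t, p in zip(spec.timepoints, spec.p(spec.timepoints))
        ]
        replicates.append(points)
    return TimecourseDataset(
        replicates=replicates, condition=condition, strain=strain, truth=spec
    )


# ---------------------------------------------------------------------------
# protein sequences


@dataclass(frozen=True)
class SequenceSimSpec:
    """Background sequence with planted Q/N-rich motif insertions.

    Each insertion is (position, motif_length, qn_fraction); exactly
    round(qn_fraction * motif_length) of its residues are Q or N.  The
    default background excludes Q and N so planted motifs are the only
    Q/N signal.
    """

    length: int = 500
    motif_insertions: tuple[tuple[int, int, float], ...] = ()
    background_alphabet_weights: tuple[tuple[str, float], ...] = tuple(
        _DEF_BG_WEIGHTS.items()
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        spans = []
        for pos, mlen, qn in self.motif_insertions:
            if mlen < 1 or pos < 0 or pos + mlen > self.length:
                raise ValueError(f"insertion ({pos}, {mlen}) does not fit in sequence")
            if not 0.0 <= qn <= 1.0:
                raise ValueError("qn_fraction must be in [0, 1]")
            spans.append((pos, pos + mlen))
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("motif insertions must not overlap")


@dataclass
class SimulatedSequence:
    sequence: ProteinSequence
    motifs: list[MotifInterval]  # ground truth planted intervals


def simulate_sequence(spec: SequenceSimSpec, seq_id: str = "synthetic") -> SimulatedSequence:
    letters = [w[0] for w in spec.background_alphabet_weights]
    weights = np.array([w[1] for w in spec.background_alphabet_weights], float)
    if weights.sum() <= 0:
        raise ValueError("background weights must have positive total")
    weights = weights / weights.sum()
    rng = _rng(spec.seed, 3)
    residues = list(rng.choice(letters, size=spec.length, p=weights))
    motifs = []
    for idx, (pos, mlen, qn_fraction) in enumerate(spec.motif_insertions):
        n_qn = round(qn_fraction * mlen)
        qn_sites = rng.choice(mlen, size=n_qn, replace=False)
        motif = list(rng.choice(letters, size=mlen, p=weights))
        for site in qn_sites:
            motif[site] = "Q" if rng.random() < 0.5 else "N"
        residues[pos : pos + mlen] = motif
        motifs.append(MotifInterval(seq_id, pos, pos + mlen, label=f"motif{idx + 1}"))
    return SimulatedSequence(
        sequence=ProteinSequence(id=seq_id, residues="".join(residues)), motifs=motifs
    )


# ---------------------------------------------------------------------------
# cell image fields


@dataclass(frozen=True)
class CellImageSimSpec:
    """Field of cells: membrane rings plus punctate bodies near the ring.

    Cells sit on a square grid; each is a membrane ring (emulating a
    vacuolar-membrane marker) and, with probability ``body_probability``,
    carries k foci (k drawn from ``bodies_per_cell_weights``) rendered as 3-D
    Gaussian spots in the focus channel, planted in a narrow annulus just
    outside the ring.  With probability ``colocalization_probability`` a
    body-positive cell additionally gets a marker-channel focus coincident
    with one of its bodies.
    """

    n_cells: int = 100
    body_probability: float = 0.57
    bodies_per_cell_weights: tuple[tuple[int, float], ...] = ((1, 0.90), (2, 0.08), (3, 0.02))
    n_z: int = 5
    cell_pitch_px: int = 28
    focus_intensity: float = 150.0
    focus_sigma: float = 1.3
    membrane_ring_radius: float = 6.0
    membrane_intensity: float = 80.0
    background_sd: float = 2.0
    colocalization_probability: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for p in (self.body_probability, self.colocalization_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        ks = [k for k, _ in self.bodies_per_cell_weights]
        if not ks or any(k < 1 for k in ks):
            raise ValueError("bodies_per_cell_weights must cover counts >= 1")
        if self.n_z < 1 or self.cell_pitch_px < 20:
            raise ValueError("need n_z >= 1 and cell_pitch_px >= 20")
        if self.membrane_ring_radius + 3.5 >= self.cell_pitch_px / 2 - 2:
            raise ValueError("focus annulus must fit inside the cell footprint")


@dataclass
class SimulatedCellField:
    stack: ImageStack                 # channels: foci, membrane, marker
    cell_map: np.ndarray              # labeled 2-D image, 0 = background
    truth: pd.DataFrame               # planted foci: cell_id, channel, z, y, x
    n_body_positive: int

    @property
    def planted_fraction(self) -> float:
        return self.n_body_positive / int(self.cell_map.max())


_MIN_FOCUS_SEPARATION = 12.0  # px; keeps noiseless detection components disjoint
_RENDER_TRUNC_SIGMA = 3.0


def _render_spot(vol: np.ndarray, z0: float, y0: float, x0: float,
                 peak: float, sigma: float, sigma_z: float = 0.8) -> None:
    nz, ny, nx = vol.shape
    r = int(np.ceil(_RENDER_TRUNC_SIGMA * sigma))
    rz = int(np.ceil(_RENDER_TRUNC_SIGMA * sigma_z))
    zs = np.arange(max(0, int(z0) - rz), min(nz, int(z0) + rz + 1))
    ys = np.arange(max(0, int(y0) - r), min(ny, int(y0) + r + 1))
    xs = np.arange(max(0, int(x0) - r), min(nx, int(x0) + r + 1))
    dz = ((zs - z0) / sigma_z) ** 2
    dy = ((ys - y0) / sigma) ** 2
    dx = ((xs - x0) / sigma) ** 2
    spot = peak * np.exp(-0.5 * (dz[:, None, None] + dy[None, :, None] + dx[None, None, :]))
    vol[np.ix_(zs, ys, xs)] += spot


def simulate_cell_stack(spec: CellImageSimSpec) -> SimulatedCellField:
    """Render a cell field and return stack, labeled cell map and ground truth.

    Foci that would violate placement constraints (outside the annulus or too
    close to an earlier focus in the same cell) are re-drawn, never clipped.
    """
    n_side = int(np.ceil(np.sqrt(spec.n_cells)))
    pitch = spec.cell_pitch_px
    ny = nx = n_side * pitch
    nz = spec.n_z
    foci_ch = np.zeros((nz, ny, nx))
    mem_ch = np.zeros((nz, ny, nx))
    marker_ch = np.zeros((nz, ny, nx))
    cell_map = np.zeros((ny, nx), dtype=np.int32)

    ks = np.array([k for k, _ in spec.bodies_per_cell_weights])
    kw = np.array([w for _, w in spec.bodies_per_cell_weights], float)
    kw = kw / kw.sum()

    cell_radius = pitch // 2 - 2
    yy, xx = np.mgrid[0:ny, 0:nx]
    z_mid = (nz - 1) / 2.0

    truth_rows = []
    n_body_positive = 0
    for cid in range(1, spec.n_cells + 1):
        row, col = divmod(cid - 1, n_side)
        cy = row * pitch + pitch / 2.0
        cx = col * pitch + pitch / 2.0
        # cell footprint
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        cell_map[r2 <= cell_radius**2] = cid
        # membrane ring, attenuated away from the mid z-plane
        ring_mask = np.abs(np.sqrt(r2) - spec.membrane_ring_radius) <= 2.5
        ys, xs = np.nonzero(ring_mask)
        ring_vals = spec.membrane_intensity * np.exp(
            -0.5 * ((np.sqrt(r2[ys, xs]) - spec.membrane_ring_radius) / 0.8) ** 2
        )
        for z in range(nz):
            mem_ch[z, ys, xs] += ring_vals * np.exp(-0.5 * ((z - z_mid) / 1.5) ** 2)

        rng = _rng(spec.seed, 4, cid)
        if rng.random() >= spec.body_probability:
            continue
        n_body_positive += 1
        k = int(rng.choice(ks, p=kw))
        placed: list[tuple[float, float, float]] = []
        for _ in range(k):
            for _attempt in range(200):
                radius = spec.membrane_ring_radius + 1.5 + 2.0 * rng.random()
                angle = 2 * np.pi * rng.random()
                fy = cy + radius * np.sin(angle)
                fx = cx + radius * np.cos(angle)
                fz = z_mid + rng.uniform(-1.0, 1.0) if nz > 1 else 0.0
                if all(
                    np.hypot(fy - py, fx - px) >= _MIN_FOCUS_SEPARATION
                    for _, py, px in placed
                ):
                    break
            else:
                raise RuntimeError(
                    f"could not place {k} separated foci in cell {cid}"
                )
            placed.append((fz, fy, fx))
            _render_spot(foci_ch, fz, fy, fx, spec.focus_intensity, spec.focus_sigma)
            truth_rows.append(
                {"cell_id": cid, "channel": "foci", "z": fz, "y": fy, "x": fx,
                 "colocalized": False}
            )
        if spec.colocalization_probability > 0 and rng.random() < spec.colocalization_probability:
            fz, fy, fx = placed[0]
            _render_spot(marker_ch, fz, fy, fx, spec.focus_intensity, spec.focus_sigma)
            truth_rows.append(
                {"cell_id": cid, "channel": "marker", "z": fz, "y": fy, "x": fx,
                 "colocalized": True}
            )
            truth_rows[-(len(placed) + 1)]["colocalized"] = True

    if spec.background_sd > 0:
        noise_rng = _rng(spec.seed, 5)
        for ch in (foci_ch, mem_ch, marker_ch):
            ch += noise_rng.normal(0.0, spec.background_sd, ch.shape)
            np.clip(ch, 0.0, None, out=ch)

    stack = ImageStack(
        voxels=np.stack([foci_ch, mem_ch, marker_ch]).astype(np.float32),
        channel_names=("foci", "membrane", "marker"),
    )
    truth = pd.DataFrame(
        truth_rows, columns=["cell_id", "channel", "z", "y", "x", "colocalized"]
    )
    return SimulatedCellField(
        stack=stack, cell_map=cell_map, truth=truth, n_body_positive=n_body_positive
    )
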