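"""Readers and writers for the pipeline's on-disk formats.

Formats: lane profiles as CSV (lane_id, pixel, intensity), time courses as
TSV (condition, strain, replicate, time_min, n_cells, n_with_bodies),
sequences as FASTA, image stacks as multi-page TIFF with a sidecar YAML
documenting the channel axis, interval manifests as TSV with 1-based
inclusive coordinates.  Tabular outputs may carry provenance comment
headers (``# key=value``); readers skip them.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .bandshift import LaneProfile
from .foci import ImageStack
from .kinetics import TimecourseDataset, TimecoursePoint
from .prilm import MotifInterval, ProteinSequence


def provenance_header(seed: int | None = None, config: dict | None = None) -> list[str]:
    """Comment lines recording version, seed and a config digest.

    Contains nothing run-dependent beyond the config itself, so identical
    runs produce byte-identical files.
    """
    lines = [f"# kogbody {__version__}"]
    parts = []
    if seed is not None:
        parts.append(f"seed={seed}")
    if config is not None:
        digest = hashlib.sha256(
            yaml.safe_dump(config, sort_keys=True).encode()
        ).hexdigest()[:16]
        parts.append(f"config_sha256={digest}")
    if parts:
        lines.append("# " + " ".join(parts))
    return lines


def _write_table(df: pd.DataFrame, path, sep: str, header_lines: list[str] | None) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        for line in header_lines or []:
            fh.write(line + "\n")
        df.to_csv(fh, sep=sep, index=False, lineterminator="\n")


# --- lane profiles ---------------------------------------------------------


def write_profiles_csv(profiles: list[LaneProfile], path, header_lines=None) -> None:
    rows = [
        {"lane_id": p.lane_id, "pixel": i, "intensity": v,
         "condition": p.condition, "strain": p.strain,
         "time_min": "" if p.time_min is None else p.time_min}
        for p in profiles
        for i, v in enumerate(p.intensities)
    ]
    _write_table(pd.DataFrame(rows), path, ",", header_lines)


def read_profiles_csv(path) -> list[LaneProfile]:
    df = pd.read_csv(path, comment="#")
    profiles = []
    for lane_id, grp in df.groupby("lane_id", sort=False):
        grp = grp.sort_values("pixel")
        t = grp["time_min"].iloc[0] if "time_min" in grp else None
        profiles.append(
            LaneProfile(
                grp["intensity"].to_numpy(),
                lane_id=str(lane_id),
                condition=str(grp["condition"].iloc[0]) if "condition" in grp else "",
                strain=str(grp["strain"].iloc[0]) if "strain" in grp else "",
                time_min=None if t is None or pd.isna(t) else float(t),
            )
        )
    return profiles


# --- time courses ----------------------------------------------------------


def write_timecourse_tsv(dataset: TimecourseDataset, path, header_lines=None) -> None:
    rows = [
        {"condition": dataset.condition, "strain": dataset.strain,
         "replicate": r, "time_min": p.time_min,
         "n_cells": p.n_cells, "n_with_bodies": p.n_with_bodies}
        for r, rep in enumerate(dataset.replicates)
        for p in rep
    ]
    _write_table(pd.DataFrame(rows), path, "\t", header_lines)


def read_timecourse_tsv(path) -> list[TimecourseDataset]:
    """One dataset per (condition, strain) group in the file."""
    df = pd.read_csv(path, sep="\t", comment="#")
    datasets = []
    for (cond, strain), grp in df.groupby(["condition", "strain"], sort=False, dropna=False):
        replicates = []
        for _, rep in grp.groupby("replicate", sort=True):
            rep = rep.sort_values("time_min")
            replicates.append(
                [
                    TimecoursePoint(float(r.time_min), int(r.n_cells), int(r.n_with_bodies))
                    for r in rep.itertuples()
                ]
            )
        datasets.append(
            TimecourseDataset(
                replicates=replicates,
                condition="" if pd.isna(cond) else str(cond),
                strain="" if pd.isna(strain) else str(strain),
            )
        )
    return datasets


# --- sequences and intervals ----------------------------------------------


def write_fasta(sequences: list[ProteinSequence], path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[ProteinSequence]:
    return [
        ProteinSequence(id=rec.id, residues=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_interval_manifest(intervals: list[MotifInterval], path, header_lines=None) -> None:
    """1-based inclusive coordinates at the file boundary."""
    rows = [
        {"seq_id": iv.seq_id, "label": iv.label,
         "start_1based": iv.start + 1, "end_1based": iv.end}
        for iv in intervals
    ]
    hdr = list(header_lines or []) + ["# coordinates: 1-based inclusive"]
    _write_table(pd.DataFrame(rows, columns=["seq_id", "label", "start_1based", "end_1based"]),
                 path, "\t", hdr)


def read_interval_manifest(path) -> list[MotifInterval]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        MotifInterval(
            seq_id=str(r.seq_id), start=int(r.start_1based) - 1,
            end=int(r.end_1based), label=str(r.label),
        )
        for r in df.itertuples()
    ]


# --- image stacks ----------------------------------------------------------


def write_stack_tiff(stack: ImageStack, path) -> None:
    """Multi-page TIFF (channel, z, y, x) plus a sidecar YAML naming the axes."""
    path = Path(path)
    tifffile.imwrite(str(path), np.asarray(stack.voxels), photometric="minisblack")
    sidecar = {
        "axes": "CZYX",
        "channels": list(stack.channel_names),
        "voxel_size_um": None if stack.voxel_size_um is None else list(stack.voxel_size_um),
    }
    with open(path.with_suffix(path.suffix + ".yaml"), "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)


def read_stack_tiff(path) -> ImageStack:
    path = Path(path)
    voxels = tifffile.imread(str(path))
    with open(path.with_suffix(path.suffix + ".yaml")) as fh:
        sidecar = yaml.safe_load(fh)
    vs = sidecar.get("voxel_size_um")
    return ImageStack(
        voxels=voxels,
        channel_names=tuple(sidecar["channels"]),
        voxel_size_um=None if vs is None else tuple(vs),
    )


def write_cell_map_tiff(cell_map: np.ndarray, path) -> None:
    tifffile.imwrite(str(path), np.asarray(cell_map, dtype=np.int32),
                     photometric="minisblack")


def read_cell_map_tiff(path) -> np.ndarray:
    return tifffile.imread(str(path))
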