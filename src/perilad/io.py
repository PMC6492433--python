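"""Reading and writing the on-disk formats used by the pipeline.

Nucleus stacks are TIFFs (one file per channel, one page per z-slice) with a
JSON sidecar carrying the mandatory voxel size; contact matrices are sparse
upper-triangle triplet text plus a bins BED; tracks are bedGraph; intervals
are BED.  All tabular reading/writing goes through pandas and tifffile.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .domains import SignalTrack
from .hic import ContactMatrix
from .imaging import NucleusImage

__all__ = [
    "write_nucleus", "read_nucleus",
    "write_contact_matrix", "read_contact_matrix",
    "write_bedgraph", "read_bedgraph",
    "track_to_bedgraph", "bedgraph_to_track",
    "read_feature_table", "read_qpcr_table",
]


# ------------------------------------------------------------------- nucleus

def write_nucleus(img: NucleusImage, prefix) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    for name, data in img.channels.items():
        tifffile.imwrite(f"{prefix}_{name}.tif", data.astype(np.float32))
    meta = {"voxel_size_um": list(img.voxel_size_um),
            "channels": sorted(img.channels)}
    Path(f"{prefix}.json").write_text(json.dumps(meta, indent=1))


def read_nucleus(prefix) -> NucleusImage:
    prefix = Path(prefix)
    meta = json.loads(Path(f"{prefix}.json").read_text())
    if "voxel_size_um" not in meta:
        raise ValueError(f"{prefix}.json lacks mandatory voxel_size_um")
    channels = {name: tifffile.imread(f"{prefix}_{name}.tif").astype(float)
                for name in meta["channels"]}
    return NucleusImage(voxel_size_um=tuple(meta["voxel_size_um"]), channels=channels)


# -------------------------------------------------------------- contact maps

def write_contact_matrix(m: ContactMatrix, matrix_path, bins_path) -> None:
    """Sparse 0-based upper-triangle triplets (bin_i TAB bin_j TAB count) + bins BED."""
    iu, ju = np.triu_indices(m.n_bins)
    vals = m.counts[iu, ju]
    nz = vals != 0
    pd.DataFrame({"i": iu[nz], "j": ju[nz], "count": vals[nz]}).to_csv(
        matrix_path, sep="\t", header=False, index=False)
    bins = pd.DataFrame({
        "chrom": m.chroms, "start": m.starts,
        "end": np.asarray(m.starts) + m.bin_size_bp,
        "bin_id": np.arange(m.n_bins),
    })
    bins.to_csv(bins_path, sep="\t", header=False, index=False)


def read_contact_matrix(matrix_path, bins_path) -> ContactMatrix:
    bins = pd.read_csv(bins_path, sep="\t", header=None,
                       names=["chrom", "start", "end", "bin_id"])
    n = len(bins)
    bin_size = int((bins["end"] - bins["start"]).iloc[0])
    counts = np.zeros((n, n))
    trip = pd.read_csv(matrix_path, sep="\t", header=None, names=["i", "j", "count"])
    counts[trip["i"], trip["j"]] = trip["count"]
    counts[trip["j"], trip["i"]] = trip["count"]
    return ContactMatrix(counts=counts, bin_size_bp=bin_size,
                         chroms=bins["chrom"].to_numpy(),
                         starts=bins["start"].to_numpy())


# ------------------------------------------------------------------- tracks

def write_bedgraph(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "value"])


def track_to_bedgraph(track: SignalTrack) -> pd.DataFrame:
    starts = track.start_bp + np.arange(track.n_windows) * track.window_bp
    return pd.DataFrame({"chrom": track.chrom, "start": starts,
                         "end": starts + track.window_bp, "value": track.values})


def bedgraph_to_track(df: pd.DataFrame, chrom: str | None = None) -> SignalTrack:
    if chrom is not None:
        df = df[df["chrom"] == chrom]
    else:
        chrom = df["chrom"].iloc[0]
    widths = (df["end"] - df["start"]).unique()
    if len(widths) != 1:
        raise ValueError("bedGraph is not a fixed-width window track")
    df = df.sort_values("start")
    return SignalTrack(chrom=str(chrom), window_bp=int(widths[0]),
                       values=df["value"].to_numpy(dtype=float),
                       start_bp=int(df["start"].iloc[0]))


# ------------------------------------------------------------------- tables

def read_feature_table(path):
    """Delimited feature table with header (chrom, start, end, feature...)."""
    df = pd.read_csv(path, sep="\t")
    meta = df[["chrom", "start", "end"]]
    X = df.drop(columns=["chrom", "start", "end"])
    return meta, X


def read_qpcr_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"locus", "template", "Ct"}
    if not required.issubset(df.columns):
        raise ValueError(f"qPCR table needs columns {sorted(required)}")
    return df
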