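"""File formats and round-trip helpers.

Genome coordinates are 0-based half-open internally; GFF3 (1-based
inclusive) and BED (0-based half-open) are both normalized on load, and all
emitted annotation coordinates are 1-based inclusive with labelled columns.
TIFF is the only supported image container.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "load_gene_annotation",
    "write_gff3",
    "load_trajectories",
    "write_trajectories",
    "write_counts",
    "load_counts",
    "write_reads",
    "load_reads",
    "write_tiff",
    "read_tiff",
]

TRAJECTORY_COLUMNS = ("track_id", "frame", "x_um", "y_um")


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------


def load_gene_annotation(path: str | Path, feature_types: tuple[str, ...] = ("gene",)) -> pd.DataFrame:
    """Gene table (gene_id, contig, start, end, strand; 1-based inclusive).

    Accepts GFF3 (``.gff``/``.gff3``, 1-based inclusive) or BED
    (``.bed``, 0-based half-open, converted).  Malformed lines raise with
    the line number.
    """
    path = Path(path)
    rows = []
    if path.suffix.lower() in {".gff", ".gff3"}:
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 9:
                    raise ValueError(f"{path}:{ln}: expected 9 GFF3 columns, got {len(parts)}")
                contig, _src, ftype, start, end, _score, strand, _phase, attrs = parts
                if ftype not in feature_types:
                    continue
                try:
                    start_i, end_i = int(start), int(end)
                except ValueError as e:
                    raise ValueError(f"{path}:{ln}: non-integer coordinates") from e
                if strand not in "+-":
                    raise ValueError(f"{path}:{ln}: invalid strand {strand!r}")
                gene_id = None
                for kv in attrs.split(";"):
                    if "=" in kv:
                        key, val = kv.split("=", 1)
                        if key.strip() in ("ID", "gene_id", "Name"):
                            gene_id = val.strip()
                            break
                if gene_id is None:
                    raise ValueError(f"{path}:{ln}: no ID/gene_id/Name attribute")
                rows.append((gene_id, contig, start_i, end_i, strand))
    elif path.suffix.lower() == ".bed":
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split()
                if len(parts) < 6:
                    raise ValueError(f"{path}:{ln}: BED line needs >= 6 fields for strand")
                contig, start, end, name, _score, strand = parts[:6]
                rows.append((name, contig, int(start) + 1, int(end), strand))
    else:
        raise ValueError(f"unsupported annotation format: {path.suffix}")
    return pd.DataFrame(rows, columns=["gene_id", "contig", "start", "end", "strand"])


def write_gff3(annotation: pd.DataFrame, path: str | Path) -> None:
    """Write a gene table (1-based inclusive coords) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation.itertuples(index=False):
            fh.write(
                f"{g.contig}\tcondensate_kit\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


def write_trajectories(tracks: pd.DataFrame, path: str | Path) -> None:
    tracks.loc[:, list(TRAJECTORY_COLUMNS)].to_csv(path, index=False)


def load_trajectories(path: str | Path) -> pd.DataFrame:
    """Trajectory CSV (track_id, frame, x_um, y_um) with validation.

    Rows may arrive in any order; they are sorted per track.  Duplicate
    (track, frame) pairs are an error naming the offending track.
    """
    df = pd.read_csv(path)
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory file missing columns: {sorted(missing)}")
    if not np.isfinite(df[["x_um", "y_um"]].to_numpy()).all():
        raise ValueError("non-finite positions in trajectory file")
    dup = df.duplicated(subset=["track_id", "frame"])
    if dup.any():
        tid = df.loc[dup, "track_id"].iloc[0]
        raise ValueError(f"duplicate (track, frame) row in track {tid}")
    return df.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# count matrices / read records
# ---------------------------------------------------------------------------


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.rename_axis("gene").to_csv(path, sep="\t")


def load_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_reads(reads: pd.DataFrame, path: str | Path) -> None:
    """Read-record TSV: read_id, contig, start, end (0-based half-open),
    strand, sequence + any extra columns."""
    reads.to_csv(path, sep="\t", index=False)


def load_reads(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"contig", "start", "end", "strand", "sequence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"read-record file missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


def write_tiff(image: np.ndarray, path: str | Path, as_uint16: bool = True) -> None:
    """Write an image (or channel stack) as TIFF; 16-bit by default."""
    import tifffile

    arr = np.asarray(image)
    if as_uint16:
        arr = np.clip(arr, 0, None)
        peak = arr.max() if arr.size else 0
        if peak > 65535:
            arr = arr / peak * 65535.0
        arr = arr.astype(np.uint16)
    tifffile.imwrite(path, arr)


def read_tiff(path: str | Path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)
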