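"""Coverage tracks, anchored regions, and per-region profile extraction.

Coordinates are 0-based half-open throughout (BED convention).  An anchor
is a single base; the analysis window is [anchor - flank, anchor + flank).
For minus-strand regions the extracted bin sequence is reversed so that the
functional coordinate runs in transcription orientation: t = -flank is
always upstream of the anchor.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "CoverageTrack",
    "RegionSet",
    "ProfileMatrix",
    "read_chrom_sizes",
    "read_bedgraph",
    "write_bedgraph",
    "normalize_track",
    "read_regions",
    "read_blacklist",
    "filter_blacklist",
    "extract_profiles",
    "write_profiles",
    "read_profiles",
]

_FLOAT_FMT = "%.17g"


@dataclass
class CoverageTrack:
    """Sparse per-base signal: sorted non-overlapping intervals per chromosome.

    Bases not covered by any interval carry implicit value 0, the bedGraph
    convention.  `wigsum` is the genome-wide total signal
    sum(value * (end - start)).
    """

    chrom_sizes: dict
    data: dict = field(default_factory=dict)  # chrom -> (starts, ends, values)

    def __post_init__(self):
        for chrom, (s, e, v) in self.data.items():
            if chrom not in self.chrom_sizes:
                raise ValueError(f"unknown chromosome {chrom!r}")
            s, e, v = (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64),
                       np.asarray(v, dtype=float))
            if np.any(s >= e):
                raise ValueError(f"empty or inverted interval on {chrom}")
            if np.any(e > self.chrom_sizes[chrom]):
                raise ValueError(f"interval beyond end of {chrom}")
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"overlapping intervals on {chrom}")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite value on {chrom}")
            self.data[chrom] = (s, e, v)
        self.wigsum = float(
            sum(((e - s) * v).sum() for s, e, v in self.data.values())
        )

    @property
    def n_intervals(self) -> int:
        return sum(len(s) for s, _, _ in self.data.values())

    def intervals(self):
        """Yield (chrom, start, end, value) in chromosome-name order."""
        for chrom in sorted(self.data):
            s, e, v = self.data[chrom]
            for i in range(len(s)):
                yield chrom, int(s[i]), int(e[i]), float(v[i])


@dataclass
class RegionSet:
    """Anchored, stranded, fixed-width windows with unique ids.

    `entries` is a DataFrame with columns region_id, chrom, anchor, strand,
    class_label; the window of each entry is [anchor - flank, anchor + flank).
    """

    entries: pd.DataFrame
    flank: int

    def __post_init__(self):
        required = ["region_id", "chrom", "anchor", "strand", "class_label"]
        missing = [c for c in required if c not in self.entries.columns]
        if missing:
            raise ValueError(f"missing RegionSet columns: {missing}")
        self.entries = self.entries.reset_index(drop=True)
        ids = self.entries["region_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate region_id {dup!r}")
        bad = ~self.entries["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError(
                f"malformed strand {self.entries['strand'][bad].iloc[0]!r}"
            )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def region_ids(self) -> list[str]:
        return self.entries["region_id"].tolist()

    def windows(self) -> pd.DataFrame:
        """DataFrame with window start/end columns added."""
        w = self.entries.copy()
        w["start"] = w["anchor"] - self.flank
        w["end"] = w["anchor"] + self.flank
        return w


@dataclass
class ProfileMatrix:
    """L x G matrix of binned mean signal on a common relative grid."""

    region_ids: list
    grid: np.ndarray  # G bin centers in [-flank, +flank), equidistant
    values: np.ndarray  # (L, G)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        d = np.diff(self.grid)
        if self.grid.size > 1 and not (
            np.all(d > 0) and np.allclose(d, d[0], rtol=1e-9, atol=1e-9)
        ):
            raise ValueError("grid must be strictly increasing and equidistant")
        if self.values.shape != (len(self.region_ids), self.grid.size):
            raise ValueError("values shape must be (L, G)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite profile values")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def read_chrom_sizes(path) -> dict:
    """Two-column TSV: chromosome name, length in bp."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"],
                     dtype={"chrom": str, "size": np.int64})
    return dict(zip(df["chrom"], df["size"]))


def read_bedgraph(path, chrom_sizes: dict) -> CoverageTrack:
    """Parse a 4-column bedGraph into a CoverageTrack.

    Track/browser definition lines and comments are tolerated and skipped.
    Book-ended intervals with equal value are merged.  Overlapping intervals,
    unknown chromosomes and non-numeric values are errors that name the
    offending line.
    """
    kept_lines: list[str] = []
    kept_nums: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            kept_lines.append(stripped)
            kept_nums.append(lineno)
    if not kept_lines:
        return CoverageTrack(chrom_sizes=dict(chrom_sizes), data={})
    try:
        df = pd.read_csv(
            io.StringIO("\n".join(kept_lines)), sep=r"\s+", header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64,
                   "value": float}, float_precision="round_trip",
        )
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: malformed bedGraph ({exc})") from exc
    df["lineno"] = kept_nums
    unknown = ~df["chrom"].isin(chrom_sizes)
    if unknown.any():
        row = df[unknown].iloc[0]
        raise ValueError(
            f"{path}:{row.lineno}: unknown chromosome {row.chrom!r}"
        )
    data = {}
    for chrom, grp in df.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"], kind="mergesort")
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        v = grp["value"].to_numpy()
        ln = grp["lineno"].to_numpy()
        if np.any(s >= e):
            i = int(np.nonzero(s >= e)[0][0])
            raise ValueError(f"{path}:{ln[i]}: empty or inverted interval")
        overlap = s[1:] < e[:-1]
        if np.any(overlap):
            i = int(np.nonzero(overlap)[0][0]) + 1
            raise ValueError(
                f"{path}:{ln[i]}: interval overlaps the previous one on {chrom}"
            )
        if np.any(e > chrom_sizes[chrom]):
            i = int(np.nonzero(e > chrom_sizes[chrom])[0][0])
            raise ValueError(
                f"{path}:{ln[i]}: interval beyond end of {chrom} "
                f"({chrom_sizes[chrom]} bp)"
            )
        # merge book-ended runs of equal value
        boundary = np.nonzero((s[1:] != e[:-1]) | (v[1:] != v[:-1]))[0] + 1
        starts_idx = np.concatenate([[0], boundary])
        ends_idx = np.concatenate([boundary, [len(s)]]) - 1
        data[chrom] = (s[starts_idx], e[ends_idx], v[starts_idx])
    return CoverageTrack(chrom_sizes=dict(chrom_sizes), data=data)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a CoverageTrack as 4-column bedGraph (full float precision)."""
    with open(path, "w") as fh:
        for chrom, start, end, value in track.intervals():
            fh.write(f"{chrom}\t{start}\t{end}\t{_FLOAT_FMT % value}\n")


def normalize_track(track: CoverageTrack,
                    target_wigsum: float = 1e8) -> CoverageTrack:
    """Scale all values so the total signal equals `target_wigsum`.

    This is the "wigsum" normalization used for read-depth correction of
    coverage tracks (default target 10^8).
    """
    if track.wigsum == 0:
        raise ValueError("cannot normalize empty track")
    scale = target_wigsum / track.wigsum
    data = {c: (s, e, v * scale) for c, (s, e, v) in track.data.items()}
    return CoverageTrack(chrom_sizes=dict(track.chrom_sizes), data=data)


def read_regions(path, flank: int, chrom_sizes: dict) -> RegionSet:
    """Read anchored regions from BED6 (+ optional 7th class-label column).

    The anchor (e.g. a TSS) is the BED start for '+' strand features and
    end - 1 for '-' strand.  Entries whose window [anchor-flank, anchor+flank)
    exceeds chromosome bounds are dropped (count logged); duplicate
    (chrom, anchor, strand) triples keep the first occurrence.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 6:
        raise ValueError(f"{path}: BED6 requires at least 6 columns")
    cols = ["chrom", "start", "end", "region_id", "score", "strand"]
    df = df.rename(columns=dict(enumerate(cols)))
    df["class_label"] = df[6].astype(str) if df.shape[1] > 6 else ""
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(
            f"{path}: malformed strand {df['strand'][bad].iloc[0]!r}"
        )
    if df["region_id"].duplicated().any():
        dup = df["region_id"][df["region_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate region_id {dup!r}")
    df["anchor"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    n0 = len(df)
    df = df.drop_duplicates(subset=["chrom", "anchor", "strand"], keep="first")
    n_dup = n0 - len(df)
    sizes = df["chrom"].map(chrom_sizes)
    in_bounds = (
        sizes.notna()
        & (df["anchor"] - flank >= 0)
        & (df["anchor"] + flank <= sizes.fillna(0).astype(np.int64))
    )
    n_oob = int((~in_bounds).sum())
    if n_dup or n_oob:
        log.info("read_regions: dropped %d duplicate-anchor and %d "
                 "out-of-bounds entries", n_dup, n_oob)
    df = df[in_bounds]
    entries = df[["region_id", "chrom", "anchor", "strand",
                  "class_label"]].reset_index(drop=True)
    return RegionSet(entries=entries, flank=int(flank))


def read_blacklist(path) -> list:
    """BED3 artifact intervals as a list of (chrom, start, end)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={"chrom": str, "start": np.int64, "end": np.int64})
    return list(df.itertuples(index=False, name=None))


def filter_blacklist(regions: RegionSet, blacklist,
                     exclude_ids=None) -> RegionSet:
    """Drop regions overlapping artifact intervals or named in exclude_ids.

    A region is removed when its window overlaps any blacklist interval by
    at least 1 bp (half-open semantics).  Input order is preserved.
    """
    exclude = set(exclude_ids) if exclude_ids else set()
    w = regions.windows()
    keep = np.ones(len(w), dtype=bool)
    if exclude:
        keep &= ~w["region_id"].isin(exclude).to_numpy()
    for chrom, bstart, bend in blacklist:
        hit = (
            (w["chrom"] == chrom)
            & (w["start"] < bend)
            & (w["end"] > bstart)
        ).to_numpy()
        keep &= ~hit
    entries = regions.entries[keep].reset_index(drop=True)
    return RegionSet(entries=entries, flank=regions.flank)


def extract_profiles(track: CoverageTrack, regions: RegionSet,
                     bin_size: int = 10,
                     reverse_minus: bool = True) -> ProfileMatrix:
    """Mean binned signal in each region window, transcription-oriented.

    Each of the G = 2*flank/bin_size cells is the mean per-base signal over
    its bin; uncovered bases contribute 0.  For minus-strand regions the
    bin sequence is reversed (unless `reverse_minus=False`, which keeps
    genome orientation as used by the ordinary coverage-correlation
    baseline).  Regions on chromosomes absent from the track produce a
    zero row and a logged warning.
    """
    flank = regions.flank
    if (2 * flank) % bin_size != 0:
        raise ValueError("2*flank must be divisible by bin_size")
    G = (2 * flank) // bin_size
    grid = -flank + bin_size * (np.arange(G) + 0.5)
    L = len(regions)
    values = np.zeros((L, G))
    missing = 0
    for i, row in enumerate(regions.entries.itertuples(index=False)):
        chrom = row.chrom
        if chrom not in track.data:
            if chrom not in track.chrom_sizes:
                missing += 1
            continue  # zero row: chromosome uncovered or absent
        s, e, v = track.data[chrom]
        w0 = row.anchor - flank
        w1 = row.anchor + flank
        i0 = np.searchsorted(e, w0, side="right")
        i1 = np.searchsorted(s, w1, side="left")
        buf = np.zeros(2 * flank)
        for j in range(i0, i1):
            lo = max(int(s[j]), w0) - w0
            hi = min(int(e[j]), w1) - w0
            buf[lo:hi] = v[j]
        prof = buf.reshape(G, bin_size).mean(axis=1)
        if reverse_minus and row.strand == "-":
            prof = prof[::-1]
        values[i] = prof
    if missing:
        log.warning("extract_profiles: %d regions on chromosomes absent "
                    "from the track; rows filled with 0", missing)
    return ProfileMatrix(region_ids=regions.region_ids, grid=grid,
                         values=values)


def write_profiles(profiles: ProfileMatrix, path) -> None:
    """TSV serialization: header of grid coordinates, first column region_id."""
    with open(path, "w") as fh:
        fh.write("region_id\t" + "\t".join(_FLOAT_FMT % g for g in profiles.grid)
                 + "\n")
        for rid, row in zip(profiles.region_ids, profiles.values):
            fh.write(str(rid) + "\t"
                     + "\t".join(_FLOAT_FMT % x for x in row) + "\n")


def read_profiles(path) -> ProfileMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip")
    grid = np.array([float(c) for c in df.columns])
    return ProfileMatrix(region_ids=[str(i) for i in df.index], grid=grid,
                         values=df.to_numpy(dtype=float))
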