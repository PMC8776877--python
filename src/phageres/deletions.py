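"""Large-deletion calling from per-base coverage and cohort interval statistics.

Phage-resistant clones frequently lose a large (tens to hundreds of kbp)
chromosomal segment; on a read-mapping coverage track such a deletion shows
as a long run of (near-)zero depth. This module calls those runs as
half-open 0-based intervals, then summarises a cohort of deletion-bearing
clones by the *core element* (the interval every clone's deletion contains)
and the *cumulated range* (total bases deleted in at least one clone), and
extracts the flanking sequences used for downstream motif scans.

Coordinates are 0-based half-open throughout; 1-based conventions appear
only at I/O boundaries (depth TSV input, VCF).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d


@dataclass(frozen=True)
class CoverageTrack:
    """Per-base read depth over one contig."""

    contig: str
    depths: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.depths, dtype=np.int64)
        object.__setattr__(self, "depths", d)
        if d.ndim != 1 or d.size == 0:
            raise ValueError("depths must be a nonempty 1-D array")
        if (d < 0).any():
            raise ValueError("depths must be non-negative")

    def __len__(self):
        return self.depths.size

    @classmethod
    def from_tsv(cls, path, reference_length: int | None = None) -> "CoverageTrack":
        """Read a samtools-depth-style TSV (contig, 1-based pos, depth).

        Positions absent from the file get depth 0; ``reference_length``
        extends the track beyond the last listed position when given.
        """
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["contig", "pos", "depth"])
        if df.empty:
            raise ValueError(f"{path}: empty coverage file")
        contigs = df["contig"].unique()
        if len(contigs) > 1:
            raise ValueError(f"{path}: multiple contigs {list(contigs)}")
        length = reference_length or int(df["pos"].max())
        depths = np.zeros(length, dtype=np.int64)
        depths[df["pos"].to_numpy() - 1] = df["depth"].to_numpy()
        return cls(contig=str(contigs[0]), depths=depths)

    @classmethod
    def from_bedgraph(cls, path, reference_length: int | None = None) -> "CoverageTrack":
        """Read a 4-column bedGraph (contig, start, end, depth; 0-based half-open)."""
        df = pd.read_csv(path, sep="\t", header=None, comment="t",
                         names=["contig", "start", "end", "depth"])
        if df.empty:
            raise ValueError(f"{path}: empty bedGraph")
        contigs = df["contig"].unique()
        if len(contigs) > 1:
            raise ValueError(f"{path}: multiple contigs {list(contigs)}")
        length = reference_length or int(df["end"].max())
        depths = np.zeros(length, dtype=np.int64)
        for s, e, d in zip(df["start"], df["end"], df["depth"]):
            depths[s:e] = d
        return cls(contig=str(contigs[0]), depths=depths)


@dataclass(frozen=True)
class DeletionCall:
    """One called deletion: 0-based half-open interval on the reference.

    ``label`` distinguishes true chromosomal deletions from coverage gaps
    that coincide with an annotated resident-prophage locus (a zero-depth
    region there reflects prophage induction, not genome loss).
    """

    clone_id: str
    start: int
    end: int
    label: str = "deletion"

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def interval(self):
        return (self.start, self.end)


@dataclass(frozen=True)
class DeletionSummary:
    """Cohort statistics over deletion-bearing clones."""

    core_intervals: tuple
    core_length: int
    union_length: int
    per_clone_sizes: dict
    core_gene_hits: tuple = ()
    n_clones: int = 0


# ---------------------------------------------------------------------------
# interval algebra (0-based half-open)

def merge_intervals(intervals):
    """Sort and merge overlapping/adjacent intervals into a disjoint list."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def intersect_interval_lists(a, b):
    """Intersection of two disjoint sorted interval lists."""
    out = []
    i = j = 0
    a, b = list(a), list(b)
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def total_length(intervals) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


# ---------------------------------------------------------------------------
# calling

def call_deletions(
    track: CoverageTrack,
    depth_max: int = 0,
    min_len: int = 10_000,
    clone_id: str = "",
    mode: str = "strict",
    window: int = 500,
    prophage_intervals=None,
) -> list:
    """Call large deletions as long low-depth runs.

    Parameters
    ----------
    depth_max : int
        A position belongs to a run when its depth is <= ``depth_max``
        (strict mode). Default 0: complete absence of coverage.
    min_len : int
        Minimum run length in bp to report; default 10 kbp, below the
        smallest deletion of interest but above short mapping dropouts.
    mode : {"strict", "windowed"}
        ``windowed`` tolerates sporadic stray reads: positions qualify when
        the centred ``window``-bp mean depth is <= 5% of the genome-wide
        median depth.
    prophage_intervals : list of (start, end), optional
        Annotated resident-prophage loci; a call whose majority overlaps one
        is labelled ``prophage_induction`` instead of ``deletion``.

    Returns disjoint, sorted :class:`DeletionCall` objects.
    """
    if min_len <= 0:
        raise ValueError("min_len must be > 0")
    d = track.depths
    if mode == "strict":
        low = d <= depth_max
    elif mode == "windowed":
        med = np.median(d)
        smooth = uniform_filter1d(d.astype(float), size=window, mode="nearest")
        low = smooth <= 0.05 * med
    else:
        raise ValueError(f"unknown mode {mode!r}")

    calls = []
    # run-length encode the boolean mask
    padded = np.diff(np.concatenate(([0], low.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    for s, e in zip(starts, ends):
        if e - s >= min_len:
            calls.append(DeletionCall(clone_id=clone_id, start=int(s), end=int(e)))
    if prophage_intervals:
        calls = [_maybe_prophage(c, prophage_intervals) for c in calls]
    return calls


def _maybe_prophage(call: DeletionCall, prophage_intervals) -> DeletionCall:
    overlap = total_length(
        intersect_interval_lists(
            [call.interval], merge_intervals(prophage_intervals)
        )
    )
    if overlap >= 0.5 * call.size:
        return DeletionCall(call.clone_id, call.start, call.end,
                            label="prophage_induction")
    return call


# ---------------------------------------------------------------------------
# cohort statistics

def _group_by_clone(calls) -> dict:
    grouped: dict = {}
    for c in calls:
        grouped.setdefault(c.clone_id, []).append(c.interval)
    return {cid: merge_intervals(ivs) for cid, ivs in grouped.items()}


def core_element(calls, genes=None) -> DeletionSummary:
    """Cohort core/union statistics over deletion calls.

    Each clone contributes the union of its own calls; the core is the
    intersection of those per-clone regions across all deletion-bearing
    clones (possibly empty, possibly several intervals). ``genes`` (from
    :func:`phageres.annotations.read_gff3`) restricts ``core_gene_hits`` to
    genes lying fully inside the core.
    """
    grouped = _group_by_clone(calls)
    if not grouped:
        return DeletionSummary(
            core_intervals=(), core_length=0, union_length=0,
            per_clone_sizes={}, core_gene_hits=(), n_clones=0,
        )
    clones = sorted(grouped)
    core = grouped[clones[0]]
    for cid in clones[1:]:
        core = intersect_interval_lists(core, grouped[cid])
    union_len = total_length([iv for ivs in grouped.values() for iv in ivs])
    sizes = {cid: total_length(ivs) for cid, ivs in grouped.items()}
    hits = ()
    if genes is not None:
        hits = tuple(
            g.gene_id
            for g in genes
            if any(s <= g.start and g.end <= e for s, e in core)
        )
    return DeletionSummary(
        core_intervals=tuple(core),
        core_length=total_length(core),
        union_length=union_len,
        per_clone_sizes=sizes,
        core_gene_hits=hits,
        n_clones=len(clones),
    )


def cumulated_range(calls) -> int:
    """Total bases covered by at least one deletion call (union length)."""
    return total_length([c.interval for c in calls])


# ---------------------------------------------------------------------------
# flank extraction

@dataclass(frozen=True)
class FlankPair:
    """Sequences immediately flanking a deletion, clipped at genome edges."""

    left: str
    right: str
    left_clipped: bool = False
    right_clipped: bool = False


def extract_flanks(reference: str, interval, flank_len: int = 500) -> FlankPair:
    """Extract ``flank_len`` bp either side of a deletion interval.

    ``reference`` is the contig sequence; ``interval`` a 0-based half-open
    (start, end) within it. Flanks truncated by a genome edge are returned
    shortened with the corresponding clip flag set.
    """
    if flank_len <= 0:
        raise ValueError("flank_len must be > 0")
    start, end = int(interval[0]), int(interval[1])
    n = len(reference)
    if not (0 <= start < end <= n):
        raise ValueError(f"interval [{start}, {end}) outside reference of length {n}")
    left_start = max(0, start - flank_len)
    right_end = min(n, end + flank_len)
    return FlankPair(
        left=reference[left_start:start],
        right=reference[end:right_end],
        left_clipped=left_start > start - flank_len,
        right_clipped=right_end < end + flank_len,
    )


def calls_to_bed(calls, path) -> None:
    """Write deletion calls as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for c in sorted(calls, key=lambda c: (c.clone_id, c.start)):
            fh.write(f"{c.clone_id}\t{c.start}\t{c.end}\t{c.label}\n")
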