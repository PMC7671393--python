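"""Decompose a chain set into gap-category tracks.

Relative to the source assembly, every base falls in exactly one of three
categories: UNGAPPED (inside an aligned block), GAPPED_IN_SOURCE (source
sequence with no target counterpart: dt>0/dq=0 gaps plus chain-uncovered
sequence) or GAPPED_IN_BOTH (dt>0/dq>0 gaps, where both assemblies carry
unaligned sequence at the same junction).  GAPPED_IN_TARGET is target
sequence inserted relative to the source (dt=0/dq>0): it has zero width in
source coordinates and is localized there by 2 bp midpoint intervals around
the insertion junction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .chain import Chain, forwardize
from .intervals import merge_intervals, subtract_intervals, total_length

__all__ = [
    "GapCategory",
    "RegionTrack",
    "TrackStats",
    "classify_blocks",
    "detect_target_insertions",
    "strand_change_summary",
    "write_tracks_bed",
    "read_chrom_sizes",
]


class GapCategory(str, enum.Enum):
    UNGAPPED = "ungapped"
    GAPPED_IN_SOURCE = "gapped_in_source"
    GAPPED_IN_TARGET = "gapped_in_target"
    GAPPED_IN_BOTH = "gapped_in_both"


@dataclass
class RegionTrack:
    """Intervals of one gap category in one coordinate space.

    ``space`` is ``"source"`` or ``"target"``.  Each interval is
    ``(chrom, start, end, annotation)``; the annotation carries the
    insertion size ``dq`` for target-insertion intervals and is ``None``
    otherwise.
    """

    category: GapCategory
    space: str
    intervals: list[tuple[str, int, int, int | None]] = field(default_factory=list)

    def by_chrom(self) -> dict[str, list[tuple[int, int]]]:
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e, _ in self.intervals:
            out.setdefault(chrom, []).append((s, e))
        return out

    def merged(self) -> dict[str, list[tuple[int, int]]]:
        return {c: merge_intervals(v) for c, v in self.by_chrom().items()}

    def total_length(self) -> int:
        return sum(total_length(v) for v in self.by_chrom().values())

    def sort(self) -> None:
        self.intervals.sort(key=lambda r: (r[0], r[1], r[2]))


@dataclass
class TrackStats:
    """Per-category interval counts, lengths and fractions.

    ``pct_length`` for the three source-space categories is relative to the
    summed source chromosome sizes, so those three percentages total 100.
    The target-insertion category is measured by its inserted length (sum of
    dq) on the same denominator for comparability.  ``n_blocks`` counts raw
    (unmerged) intervals, ``n_merged`` the merged ones; both are reported
    because either convention is defensible for "number of blocks".
    """

    table: pd.DataFrame
    genome_size: int
    strand_change_fraction: float

    def __str__(self) -> str:
        return (
            self.table.to_string()
            + f"\nsource genome size: {self.genome_size} bp"
            + f"\nstrand-change fraction of ungapped length: "
            f"{100 * self.strand_change_fraction:.2f}%"
        )


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column (name, length) chromosome-sizes file."""
    sizes: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        name, length = line.split()[:2]
        sizes[name] = int(length)
    return sizes


def _chain_source_tracks(
    chain: Chain,
) -> dict[GapCategory, list[tuple[int, int]]]:
    """Raw per-category source-space intervals of one chain's walk."""
    out: dict[GapCategory, list[tuple[int, int]]] = {
        GapCategory.UNGAPPED: [],
        GapCategory.GAPPED_IN_SOURCE: [],
        GapCategory.GAPPED_IN_BOTH: [],
    }
    for t0, _q0, b in chain.walk():
        out[GapCategory.UNGAPPED].append((t0, t0 + b.size))
        gap_start = t0 + b.size
        if b.dt > 0 and b.dq == 0:
            out[GapCategory.GAPPED_IN_SOURCE].append((gap_start, gap_start + b.dt))
        elif b.dt > 0 and b.dq > 0:
            out[GapCategory.GAPPED_IN_BOTH].append((gap_start, gap_start + b.dt))
    return out


def _chain_target_insert_spans(
    chain: Chain, want: GapCategory
) -> list[tuple[str, int, int, int | None]]:
    """Target-space forward-strand spans of dq>0 gaps of one category."""
    h = chain.header
    out = []
    for _t0, q0, b in chain.walk():
        if b.dq <= 0:
            continue
        cat = (
            GapCategory.GAPPED_IN_BOTH if b.dt > 0 else GapCategory.GAPPED_IN_TARGET
        )
        if cat is not want:
            continue
        qs = q0 + b.size
        s, e, _ = forwardize(h.q_size, h.q_strand, qs, qs + b.dq)
        out.append((h.q_name, s, e, b.dq))
    return out


def classify_blocks(
    chains: Iterable[Chain],
    source_chrom_sizes: Mapping[str, int],
    cross_chain_contiguity: bool = False,
) -> tuple[dict[tuple[GapCategory, str], RegionTrack], TrackStats]:
    """Partition the source genome into gap-category tracks.

    Where chains overlap in source coordinates, each base is classified by
    the highest-score chain covering it (ties: lowest chain id), so the
    three source-space categories always tile the genome exactly.  Source
    bases covered by no chain are appended to GAPPED_IN_SOURCE.  dq>0 gap
    spans are additionally emitted in target space, and target insertions
    (dt=0/dq>0) as 2 bp source-space midpoints via
    :func:`detect_target_insertions`.
    """
    chains = list(chains)
    unknown = sorted(
        {c.header.chain_id for c in chains if c.header.t_name not in source_chrom_sizes}
    )
    if unknown:
        raise ValueError(
            f"chains {unknown} reference chromosomes absent from the "
            "chromosome-sizes table"
        )

    src_tracks: dict[GapCategory, dict[str, list[tuple[int, int]]]] = {
        cat: {} for cat in (
            GapCategory.UNGAPPED,
            GapCategory.GAPPED_IN_SOURCE,
            GapCategory.GAPPED_IN_BOTH,
        )
    }
    raw_counts = {cat: 0 for cat in GapCategory}
    claimed: dict[str, list[tuple[int, int]]] = {}

    for chain in sorted(chains, key=lambda c: (-c.header.score, c.header.chain_id)):
        chrom = chain.header.t_name
        already = claimed.setdefault(chrom, [])
        for cat, ivs in _chain_source_tracks(chain).items():
            raw_counts[cat] += len(ivs)
            free = subtract_intervals(ivs, already)
            if free:
                src_tracks[cat].setdefault(chrom, []).extend(free)
        claimed[chrom] = merge_intervals(
            already + [(chain.header.t_start, chain.header.t_end)]
        )

    # sequence covered by no chain has no target counterpart
    for chrom, size in source_chrom_sizes.items():
        uncovered = subtract_intervals([(0, size)], claimed.get(chrom, []))
        if uncovered:
            raw_counts[GapCategory.GAPPED_IN_SOURCE] += len(uncovered)
            src_tracks[GapCategory.GAPPED_IN_SOURCE].setdefault(chrom, []).extend(
                uncovered
            )

    tracks: dict[tuple[GapCategory, str], RegionTrack] = {}
    for cat, per_chrom in src_tracks.items():
        tr = RegionTrack(category=cat, space="source")
        for chrom in sorted(per_chrom):
            for s, e in merge_intervals(per_chrom[chrom]):
                tr.intervals.append((chrom, s, e, None))
        tracks[(cat, "source")] = tr

    for cat in (GapCategory.GAPPED_IN_BOTH, GapCategory.GAPPED_IN_TARGET):
        tr = RegionTrack(category=cat, space="target")
        for chain in chains:
            tr.intervals.extend(_chain_target_insert_spans(chain, cat))
        tr.sort()
        tracks[(cat, "target")] = tr
    raw_counts[GapCategory.GAPPED_IN_TARGET] = len(
        tracks[(GapCategory.GAPPED_IN_TARGET, "target")].intervals
    )

    tracks[(GapCategory.GAPPED_IN_TARGET, "source")] = detect_target_insertions(
        chains, cross_chain_contiguity=cross_chain_contiguity
    )

    genome_size = sum(source_chrom_sizes.values())
    rows = []
    for cat in GapCategory:
        if cat is GapCategory.GAPPED_IN_TARGET:
            track = tracks[(cat, "target")]
            length = sum(iv[3] or 0 for iv in track.intervals)
        else:
            track = tracks[(cat, "source")]
            length = track.total_length()
        rows.append(
            {
                "category": cat.value,
                "n_blocks": raw_counts[cat],
                "n_merged": len(track.intervals),
                "length_bp": length,
                "pct_length": 100 * length / genome_size if genome_size else 0.0,
            }
        )
    table = pd.DataFrame(rows).set_index("category")
    total_blocks = table["n_blocks"].sum()
    table["pct_blocks"] = (
        100 * table["n_blocks"] / total_blocks if total_blocks else 0.0
    )
    stats = TrackStats(
        table=table,
        genome_size=genome_size,
        strand_change_fraction=strand_change_summary(chains),
    )
    return tracks, stats


def detect_target_insertions(
    chains: Iterable[Chain], cross_chain_contiguity: bool = False
) -> RegionTrack:
    """2 bp source-space midpoints flanking each target insertion.

    A dt=0/dq>0 gap means target sequence will be inserted between two
    source bases that sit next to each other: the junction at source
    position ``p`` is widened by 1 bp in both directions to the interval
    ``[p-1, p+1)``, annotated with the inserted length ``dq``.  Junctions at
    a chromosome edge are clamped to 1 bp.  With ``cross_chain_contiguity``
    two *different* chains abutting in source coordinates also count as a
    junction (the inserted length is then unknown and annotated 0).
    """
    track = RegionTrack(category=GapCategory.GAPPED_IN_TARGET, space="source")
    chains = list(chains)
    for chain in chains:
        h = chain.header
        t = h.t_start
        for b in chain.blocks:
            t += b.size
            if b.dt == 0 and b.dq > 0:
                lo = max(t - 1, 0)
                hi = min(t + 1, h.t_size)
                track.intervals.append((h.t_name, lo, hi, b.dq))
            t += b.dt
    if cross_chain_contiguity:
        ends: dict[tuple[str, int], bool] = {}
        for c in chains:
            ends[(c.header.t_name, c.header.t_end)] = True
        for c in chains:
            key = (c.header.t_name, c.header.t_start)
            if key in ends and c.header.t_start > 0:
                p = c.header.t_start
                track.intervals.append((c.header.t_name, p - 1, p + 1, 0))
    track.sort()
    return track


def strand_change_summary(chains: Iterable[Chain]) -> float:
    """Fraction of aligned (ungapped) source length carried by minus-strand
    chains."""
    minus = plus = 0
    for c in chains:
        if c.header.q_strand == "-":
            minus += c.aligned_length
        else:
            plus += c.aligned_length
    total = minus + plus
    return minus / total if total else 0.0


def write_tracks_bed(
    tracks: Mapping[tuple[GapCategory, str], RegionTrack], outdir
) -> dict[tuple[GapCategory, str], Path]:
    """Write one BED file per (category, space); name column carries the
    category and, for insertions, the ``dq`` annotation."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for (cat, space), track in tracks.items():
        path = outdir / f"{cat.value}.{space}.bed"
        with open(path, "w") as fh:
            for chrom, s, e, ann in sorted(track.intervals):
                name = cat.value if ann is None else f"{cat.value};dq={ann}"
                fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")
        paths[(cat, space)] = path
    return paths
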