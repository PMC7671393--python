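"""Three-step filtering guideline around liftover.

Step 1 removes input records overlapping regions that cannot convert
cleanly (gapped-in-source, gapped-in-both) or the blacklist.  Step 2 is the
conversion itself.  Step 3 deals with target insertions — either
*conservative* (drop every output overlapping the target-space insertion
track) or *split* (cut the 2 bp insertion midpoints out of the inputs
before lifting) — then removes duplications, alternative-chromosome hits
and, for CpG data, positions whose target dinucleotide is no longer CG.

Each record ends in exactly one terminal tally; removal-reason precedence
is fixed (prefilter tracks in order gapped_in_source, gapped_in_both,
blacklist; post-filters in order target-gap overlap, duplication,
alternative chromosome, not-CG).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .chain import Chain
from .engine import (
    BedRecord,
    LiftConfig,
    build_index,
    lift_bed,
)
from .regions import GapCategory, RegionTrack, classify_blocks

__all__ = [
    "GuidelineConfig",
    "FilterReport",
    "prefilter",
    "split_at_insertions",
    "postfilter_conservative",
    "postfilter_duplication",
    "postfilter_alt_chrom",
    "postfilter_not_cg",
    "run_guideline",
    "CANONICAL_HUMAN",
]

CANONICAL_HUMAN = r"^chr(\d+|X|Y|M)$"


@dataclass(frozen=True)
class GuidelineConfig:
    """Guideline options.

    ``mode`` is ``conservative`` (exclude outputs overlapping target
    insertions) or ``split`` (cut insertion midpoints out of inputs).
    ``canonical_pattern`` decides which target chromosomes count as
    primary.  ``cpg_check`` requires ``target_fasta`` (a path or a
    chromosome→sequence mapping) and treats records as 1 bp C positions.
    """

    mode: str = "conservative"
    blacklist: Sequence[BedRecord] | None = None
    canonical_pattern: str = CANONICAL_HUMAN
    cpg_check: bool = False
    target_fasta: object | None = None
    engine_mode: str = "span"
    lift: LiftConfig = field(default_factory=LiftConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("conservative", "split"):
            raise ValueError(f"unknown guideline mode {self.mode!r}")
        if self.cpg_check and self.target_fasta is None:
            raise ValueError("cpg_check requires target_fasta")


@dataclass
class FilterReport:
    """Full accounting of where every input record ended up.

    Records removed before lifting are tallied per prefilter track; in
    split mode ``n_split_added`` is the net change in record count from
    cutting midpoints out (pieces added minus parents consumed, negative
    when records fall entirely inside midpoints).  The terminal tallies
    satisfy ``n_unlifted + n_removed_* + n_filtered_final =
    n_input - prefilter removals + n_split_added``.
    """

    n_input: int = 0
    n_removed_prefilter: dict[str, int] = field(default_factory=dict)
    n_split_added: int = 0
    n_raw_lifted: int = 0
    n_unlifted: int = 0
    n_removed_target_gap_overlap: int = 0
    n_removed_duplication: int = 0
    n_removed_alt_chrom: int = 0
    n_removed_not_cg: int = 0
    n_filtered_final: int = 0

    def check_accounting(self) -> None:
        entering = (
            self.n_input
            - sum(self.n_removed_prefilter.values())
            + self.n_split_added
        )
        terminal = (
            self.n_unlifted
            + self.n_removed_target_gap_overlap
            + self.n_removed_duplication
            + self.n_removed_alt_chrom
            + self.n_removed_not_cg
            + self.n_filtered_final
        )
        if entering != terminal:
            raise AssertionError(
                f"accounting violated: {entering} records entered the lift "
                f"stage but {terminal} are tallied"
            )

    def to_dict(self) -> dict[str, int]:
        d = {
            "n_input": self.n_input,
            "n_split_added": self.n_split_added,
            "n_raw_lifted": self.n_raw_lifted,
            "n_unlifted": self.n_unlifted,
            "n_removed_target_gap_overlap": self.n_removed_target_gap_overlap,
            "n_removed_duplication": self.n_removed_duplication,
            "n_removed_alt_chrom": self.n_removed_alt_chrom,
            "n_removed_not_cg": self.n_removed_not_cg,
            "n_filtered_final": self.n_filtered_final,
        }
        for k, v in self.n_removed_prefilter.items():
            d[f"n_removed_prefilter_{k}"] = v
        return d

    def __str__(self) -> str:
        lines = [f"{k}\t{v}" for k, v in self.to_dict().items()]
        return "\n".join(lines)


def _tree_of(records: Iterable) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for rec in records:
        if isinstance(rec, BedRecord):
            chrom, s, e = rec.chrom, rec.start, rec.end
        else:
            chrom, s, e = rec[0], rec[1], rec[2]
        if e > s:
            trees.setdefault(chrom, IntervalTree()).addi(s, e)
    return trees


def _track_tree(track: RegionTrack, space: str) -> dict[str, IntervalTree]:
    if track.space != space:
        raise ValueError(
            f"track {track.category.value} is in {track.space} space, "
            f"expected {space}"
        )
    return _tree_of(track.intervals)


def _hits(trees: dict[str, IntervalTree], rec: BedRecord) -> bool:
    tree = trees.get(rec.chrom)
    return tree is not None and bool(tree.overlap(rec.start, rec.end))


def prefilter(
    records: Sequence[BedRecord],
    tracks: Mapping[tuple[GapCategory, str], RegionTrack],
    blacklist: Sequence[BedRecord] | None = None,
) -> tuple[list[BedRecord], list[tuple[BedRecord, str]]]:
    """Remove records overlapping (>=1 bp) gapped-in-source, gapped-in-both
    or the blacklist, in that reason order."""
    stages = [
        ("gapped_in_source",
         _track_tree(tracks[(GapCategory.GAPPED_IN_SOURCE, "source")], "source")),
        ("gapped_in_both",
         _track_tree(tracks[(GapCategory.GAPPED_IN_BOTH, "source")], "source")),
        ("blacklist", _tree_of(blacklist or [])),
    ]
    kept, removed = [], []
    for rec in records:
        for reason, trees in stages:
            if _hits(trees, rec):
                removed.append((rec, reason))
                break
        else:
            kept.append(rec)
    return kept, removed


def split_at_insertions(
    records: Sequence[BedRecord], midpoint_track: RegionTrack
) -> list[BedRecord]:
    """Cut the 2 bp insertion midpoints out of each record before lifting.

    Pieces inherit the parent name with ``/s<i>`` suffixes; empty pieces
    are dropped; untouched records pass through unchanged.
    """
    if midpoint_track.space != "source":
        raise ValueError("midpoint track must be in source space")
    trees = _tree_of(midpoint_track.intervals)
    out: list[BedRecord] = []
    for rec in records:
        tree = trees.get(rec.chrom)
        hits = sorted(tree.overlap(rec.start, rec.end)) if tree else []
        if not hits:
            out.append(rec)
            continue
        pieces = []
        cur = rec.start
        for iv in hits:
            if iv.begin > cur:
                pieces.append((cur, min(iv.begin, rec.end)))
            cur = max(cur, iv.end)
        if cur < rec.end:
            pieces.append((cur, rec.end))
        for i, (s, e) in enumerate(pieces):
            out.append(replace(rec, start=s, end=e, name=f"{rec.name}/s{i}"))
    return out


def postfilter_conservative(
    records: Sequence[BedRecord], target_gap_track: RegionTrack
) -> tuple[list[BedRecord], list[BedRecord]]:
    """Drop lifted records overlapping the target-space insertion track."""
    trees = _track_tree(target_gap_track, "target")
    kept, removed = [], []
    for rec in records:
        (removed if _hits(trees, rec) else kept).append(rec)
    return kept, removed


def postfilter_duplication(
    records: Sequence[BedRecord],
) -> tuple[list[BedRecord], list[BedRecord]]:
    """Remove whole collision groups.

    A record is removed when its source produced more than one output
    (one-to-many; only possible in diagnostic pieces mode, whose outputs
    carry ``/<i>`` suffixes) or when two different sources landed on an
    identical target interval (many-to-one).  Pieces cut deliberately by
    :func:`split_at_insertions` (``/s<i>`` suffixes) count as distinct
    sources — splitting is the point of that mode, not a duplication.
    """
    def source_key(r: BedRecord) -> str:
        stem, _, suffix = r.name.rpartition("/")
        if stem and suffix.isdigit():
            return stem
        return r.name

    by_source: dict[str, int] = {}
    by_target: dict[tuple[str, int, int], set[str]] = {}
    for r in records:
        by_source[source_key(r)] = by_source.get(source_key(r), 0) + 1
        by_target.setdefault((r.chrom, r.start, r.end), set()).add(source_key(r))
    kept, removed = [], []
    for r in records:
        if by_source[source_key(r)] > 1 or len(
            by_target[(r.chrom, r.start, r.end)]
        ) > 1:
            removed.append(r)
        else:
            kept.append(r)
    return kept, removed


def postfilter_alt_chrom(
    records: Sequence[BedRecord], canonical_pattern: str = CANONICAL_HUMAN
) -> tuple[list[BedRecord], list[BedRecord]]:
    """Keep records on chromosomes matching the canonical-name rule."""
    pat = re.compile(canonical_pattern)
    kept, removed = [], []
    for r in records:
        (kept if pat.match(r.chrom) else removed).append(r)
    return kept, removed


def _fetch(fasta, chrom: str, start: int, end: int) -> str | None:
    """Slice [start,end) out of a pyfaidx Fasta or a plain mapping; None at
    edges / missing span."""
    if start < 0:
        return None
    if isinstance(fasta, Mapping):
        seq = fasta.get(chrom)
        if seq is None:
            raise KeyError(f"chromosome {chrom} not in target sequences")
        if end > len(seq):
            return None
        return seq[start:end]
    rec = fasta[chrom]
    if end > len(rec):
        return None
    return str(rec[start:end])


def postfilter_not_cg(
    records: Sequence[BedRecord], target_fasta
) -> tuple[list[BedRecord], list[tuple[BedRecord, str]]]:
    """Keep 1 bp C positions whose target context is still a CG.

    A plus-strand C at position p must read CG over [p, p+2); a
    minus-strand C maps onto the forward-strand G of the pair, so the
    check window is [p-1, p+1).  Records at sequence edges are removed
    with reason ``edge``.
    """
    kept, removed = [], []
    for r in records:
        if r.strand == "-":
            ctx = _fetch(target_fasta, r.chrom, r.start - 1, r.start + 1)
        else:
            ctx = _fetch(target_fasta, r.chrom, r.start, r.start + 2)
        if ctx is None:
            removed.append((r, "edge"))
        elif ctx.upper() == "CG":
            kept.append(r)
        else:
            removed.append((r, "not_cg"))
    return kept, removed


def run_guideline(
    records: Sequence[BedRecord],
    chains: Sequence[Chain],
    config: GuidelineConfig,
    source_chrom_sizes: Mapping[str, int] | None = None,
    tracks: Mapping[tuple[GapCategory, str], RegionTrack] | None = None,
) -> tuple[list[BedRecord], FilterReport]:
    """Run prefilter → (split) → lift → (conservative) → duplication →
    alt-chromosome → optional not-CG, with full accounting."""
    if tracks is None:
        if source_chrom_sizes is None:
            source_chrom_sizes = {}
            for c in chains:
                h = c.header
                source_chrom_sizes.setdefault(h.t_name, h.t_size)
        tracks, _ = classify_blocks(chains, source_chrom_sizes)

    report = FilterReport(n_input=len(records))

    kept, removed_pre = prefilter(records, tracks, config.blacklist)
    # names need not be unique (methylome files often reuse columns), so
    # tag every surviving record with a unique source key for duplication
    # detection; stripped again before returning
    kept = [replace(r, name=f"{i}|{r.name}") for i, r in enumerate(kept)]
    for _rec, reason in removed_pre:
        report.n_removed_prefilter[reason] = (
            report.n_removed_prefilter.get(reason, 0) + 1
        )

    if config.mode == "split":
        before = len(kept)
        kept = split_at_insertions(
            kept, tracks[(GapCategory.GAPPED_IN_TARGET, "source")]
        )
        report.n_split_added = len(kept) - before

    index = build_index(chains)
    lifted, unlifted, _tally = lift_bed(
        index, kept, mode=config.engine_mode, config=config.lift
    )
    report.n_raw_lifted = len(lifted)
    report.n_unlifted = len(unlifted)
    # diagnostic pieces mode can emit several outputs per input; fold the
    # extra records into the split-added tally so accounting stays exact
    report.n_split_added += len(lifted) - (len(kept) - len(unlifted))

    if config.mode == "conservative":
        lifted, removed = postfilter_conservative(
            lifted, tracks[(GapCategory.GAPPED_IN_TARGET, "target")]
        )
        report.n_removed_target_gap_overlap = len(removed)

    lifted, removed = postfilter_duplication(lifted)
    report.n_removed_duplication = len(removed)

    lifted, removed = postfilter_alt_chrom(lifted, config.canonical_pattern)
    report.n_removed_alt_chrom = len(removed)

    if config.cpg_check:
        lifted, removed_cg = postfilter_not_cg(lifted, config.target_fasta)
        report.n_removed_not_cg = len(removed_cg)

    lifted = [replace(r, name=r.name.partition("|")[2]) for r in lifted]
    report.n_filtered_final = len(lifted)
    report.check_accounting()
    return lifted, report
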