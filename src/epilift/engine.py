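"""Point and interval coordinate conversion through a chain set.

Two interval algorithms are provided.  *Span* mode mirrors the UCSC-style
split-and-merge strategy: the interval's mappable bases are projected
through the chosen chain and a single spanning target interval is reported
when at least ``min_match`` of the bases map; target insertions inside the
span stretch the output without counting against ``min_match``.
*Integrity* mode mirrors segment_liftover: the same spanning interval is
accepted only if the before/after width ratio lies within ``[1/n, n]`` and
the target chromosome matches the expected name, with no minimum-match
requirement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

from intervaltree import IntervalTree

from .chain import Chain, forwardize

__all__ = [
    "LiftConfig",
    "LiftOutcome",
    "BedRecord",
    "MapIndex",
    "build_index",
    "lift_point",
    "lift_interval_span",
    "lift_interval_integrity",
    "lift_bed",
    "read_bed",
    "write_bed",
]


@dataclass(frozen=True)
class LiftConfig:
    """Tunables of the conversion algorithms.

    ``min_match`` is the minimum mappable fraction for span mode (0.95, the
    documented UCSC liftOver default); ``ratio_bound`` is the integrity-mode
    width-ratio bound n (2.0); ``chrom_map`` renames source chromosomes to
    their expected target names for the integrity same-chromosome test
    (identity when empty).
    """

    min_match: float = 0.95
    ratio_bound: float = 2.0
    chain_choice: str = "best-score"
    chrom_map: Mapping[str, str] | None = None
    emit_pieces: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.min_match <= 1):
            raise ValueError("min_match must be in (0, 1]")
        if self.ratio_bound <= 1:
            raise ValueError("ratio_bound must be > 1")
        if self.chain_choice not in ("best-score", "error-on-ambiguity"):
            raise ValueError(f"unknown chain_choice {self.chain_choice!r}")


@dataclass(frozen=True)
class BedRecord:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: str = "."
    strand: str = "."

    def to_line(self, extra: str | None = None) -> str:
        fields = [self.chrom, str(self.start), str(self.end), self.name,
                  self.score, self.strand]
        if extra is not None:
            fields.append(extra)
        return "\t".join(fields)


@dataclass
class LiftOutcome:
    """Result of converting one point or interval.

    ``status`` is LIFTED or UNLIFTED; ``reason`` one of ok, no_chain, gap,
    low_match, ratio_violation, chrom_violation, ambiguous.  ``targets``
    holds ``(chrom, start, end, strand)`` tuples (non-empty iff LIFTED);
    ``mapped_fraction`` is the fraction of source bases inside aligned
    blocks of the chosen chain.
    """

    status: str
    reason: str
    targets: list[tuple[str, int, int, str]] = field(default_factory=list)
    mapped_fraction: float = 0.0
    source: BedRecord | None = None

    @property
    def lifted(self) -> bool:
        return self.status == "LIFTED"


_UNLIFTED = "UNLIFTED"
_LIFTED = "LIFTED"


@dataclass
class MapIndex:
    """Searchable per-chromosome view of a chain set.

    ``blocks[chrom]`` stabs aligned blocks: each entry's data is
    ``(chain, t_block_start, q_block_start)``.  ``spans[chrom]`` stabs whole
    chain source spans for distinguishing "inside a gap" from "no chain".
    """

    blocks: dict[str, IntervalTree] = field(default_factory=dict)
    spans: dict[str, IntervalTree] = field(default_factory=dict)

    @property
    def n_entries(self) -> int:
        return sum(len(t) for t in self.blocks.values())


def build_index(chains: Iterable[Chain]) -> MapIndex:
    index = MapIndex()
    for chain in chains:
        chrom = chain.header.t_name
        btree = index.blocks.setdefault(chrom, IntervalTree())
        stree = index.spans.setdefault(chrom, IntervalTree())
        stree.addi(chain.header.t_start, chain.header.t_end, chain)
        for t0, q0, b in chain.walk():
            btree.addi(t0, t0 + b.size, (chain, t0, q0))
    return index


def _best(chains: Iterable[Chain]) -> Chain | None:
    best = None
    for c in chains:
        if best is None or (-c.header.score, c.header.chain_id) < (
            -best.header.score, best.header.chain_id
        ):
            best = c
    return best


def _select_chain(
    index: MapIndex, chrom: str, start: int, end: int, config: LiftConfig
) -> Chain | None:
    """Highest-score chain whose source span covers ``start``; if none,
    highest-score chain overlapping the interval; ties by lowest id."""
    stree = index.spans.get(chrom)
    if stree is None:
        return None
    covering = [iv.data for iv in stree.at(start)]
    if config.chain_choice == "error-on-ambiguity" and len(covering) > 1:
        raise ValueError(
            f"{chrom}:{start}-{end} is covered by {len(covering)} chains"
        )
    if covering:
        return _best(covering)
    overlapping = [iv.data for iv in stree.overlap(start, end)]
    return _best(overlapping)


def _mapped_runs(
    chain: Chain, start: int, end: int
) -> list[tuple[int, int, int, int]]:
    """Aligned sub-runs of [start,end): (src_s, src_e, q_s, q_e) with q on
    the q-strand-oriented sequence."""
    runs = []
    for t0, q0, b in chain.walk():
        s = max(start, t0)
        e = min(end, t0 + b.size)
        if s < e:
            runs.append((s, e, q0 + (s - t0), q0 + (e - t0)))
    return runs


def lift_point(
    index: MapIndex, chrom: str, pos: int, config: LiftConfig | None = None
) -> LiftOutcome:
    """Convert a single position; at most one target under best-score
    chain choice."""
    config = config or LiftConfig()
    if pos < 0:
        raise ValueError("position must be non-negative")
    btree = index.blocks.get(chrom)
    hits = list(btree.at(pos)) if btree is not None else []
    if not hits:
        stree = index.spans.get(chrom)
        in_span = stree is not None and bool(stree.at(pos))
        return LiftOutcome(_UNLIFTED, "gap" if in_span else "no_chain")
    chain = _best(h.data[0] for h in hits)
    for h in hits:
        c, t0, q0 = h.data
        if c is chain:
            q = q0 + (pos - t0)
            hh = c.header
            fwd = q if hh.q_strand == "+" else hh.q_size - 1 - q
            return LiftOutcome(
                _LIFTED, "ok",
                targets=[(hh.q_name, fwd, fwd + 1, hh.q_strand)],
                mapped_fraction=1.0,
            )
    raise AssertionError("unreachable")


def _span_outcome(
    index: MapIndex, chrom: str, start: int, end: int, config: LiftConfig
) -> tuple[LiftOutcome, Chain | None]:
    if start >= end:
        raise ValueError(f"inverted or empty interval [{start},{end})")
    chain = _select_chain(index, chrom, start, end, config)
    if chain is None:
        return LiftOutcome(_UNLIFTED, "no_chain"), None
    runs = _mapped_runs(chain, start, end)
    mapped = sum(e - s for s, e, _, _ in runs)
    fraction = mapped / (end - start)
    if mapped == 0:
        return LiftOutcome(_UNLIFTED, "gap"), chain
    h = chain.header
    q_lo = min(r[2] for r in runs)
    q_hi = max(r[3] for r in runs)
    f_s, f_e, strand = forwardize(h.q_size, h.q_strand, q_lo, q_hi)
    out = LiftOutcome(
        _LIFTED, "ok",
        targets=[(h.q_name, f_s, f_e, strand)],
        mapped_fraction=fraction,
    )
    if config.emit_pieces:
        pieces = []
        for s, e, qs, qe in runs:
            ps, pe, st = forwardize(h.q_size, h.q_strand, qs, qe)
            pieces.append((h.q_name, ps, pe, st))
        out.targets = pieces
    return out, chain


def lift_interval_span(
    index: MapIndex, chrom: str, start: int, end: int,
    config: LiftConfig | None = None,
) -> LiftOutcome:
    """Split-and-merge conversion: single spanning target interval,
    accepted when mapped_fraction >= min_match."""
    config = config or LiftConfig()
    out, _chain = _span_outcome(index, chrom, start, end, config)
    if not out.lifted:
        return out
    if out.mapped_fraction < config.min_match:
        return LiftOutcome(
            _UNLIFTED, "low_match", mapped_fraction=out.mapped_fraction
        )
    return out


def lift_interval_integrity(
    index: MapIndex, chrom: str, start: int, end: int,
    config: LiftConfig | None = None,
) -> LiftOutcome:
    """Integrity-preserving conversion: the spanning interval is accepted
    only when width_before/width_after is within [1/n, n] and the target
    chromosome matches the expected name (min_match is waived)."""
    config = config or LiftConfig()
    cfg = replace(config, emit_pieces=False)
    out, _chain = _span_outcome(index, chrom, start, end, cfg)
    if not out.lifted:
        return out
    t_chrom, t_s, t_e, _strand = out.targets[0]
    expected = (config.chrom_map or {}).get(chrom, chrom)
    if t_chrom != expected:
        return LiftOutcome(
            _UNLIFTED, "chrom_violation", mapped_fraction=out.mapped_fraction
        )
    n = config.ratio_bound
    ratio = (end - start) / (t_e - t_s)
    if not (1 / n <= ratio <= n):
        return LiftOutcome(
            _UNLIFTED, "ratio_violation", mapped_fraction=out.mapped_fraction
        )
    return out


def read_bed(source) -> list[BedRecord]:
    """Read BED3/BED6 from a path or line iterable."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    elif isinstance(source, (list, tuple)):
        lines = list(source)
    else:
        from pathlib import Path

        lines = Path(source).read_text().splitlines()
    records = []
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"BED line {lineno}: fewer than 3 columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ValueError(f"BED line {lineno}: {exc}") from exc
        if start < 0 or end <= start:
            raise ValueError(f"BED line {lineno}: bad interval {start}-{end}")
        records.append(
            BedRecord(
                chrom=fields[0], start=start, end=end,
                name=fields[3] if len(fields) > 3 else ".",
                score=fields[4] if len(fields) > 4 else ".",
                strand=fields[5] if len(fields) > 5 else ".",
            )
        )
    return records


def write_bed(records: Iterable[BedRecord], dest, reasons=None) -> None:
    from pathlib import Path

    reasons = list(reasons) if reasons is not None else None
    lines = []
    for i, r in enumerate(records):
        extra = reasons[i] if reasons is not None else None
        lines.append(r.to_line(extra))
    text = "\n".join(lines) + ("\n" if lines else "")
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)


def lift_bed(
    index: MapIndex,
    records: Sequence[BedRecord],
    mode: str = "span",
    config: LiftConfig | None = None,
) -> tuple[list[BedRecord], list[tuple[BedRecord, str]], dict[str, int]]:
    """Convert a batch of BED records.

    Returns (lifted records in target coordinates, unlifted records paired
    with their reason code, per-reason tally).  Record counts are conserved:
    lifted + unlifted = input.
    """
    config = config or LiftConfig()
    if mode not in ("span", "integrity"):
        raise ValueError(f"unknown mode {mode!r}")
    fn = lift_interval_span if mode == "span" else lift_interval_integrity
    lifted: list[BedRecord] = []
    unlifted: list[tuple[BedRecord, str]] = []
    tally: dict[str, int] = {}
    for rec in records:
        out = fn(index, rec.chrom, rec.start, rec.end, config)
        tally[out.reason] = tally.get(out.reason, 0) + 1
        if out.lifted:
            for j, (c, s, e, st) in enumerate(out.targets):
                name = rec.name if len(out.targets) == 1 else f"{rec.name}/{j}"
                lifted.append(replace(rec, chrom=c, start=s, end=e,
                                      name=name, strand=st))
        else:
            unlifted.append((rec, out.reason))
    return lifted, unlifted, tally
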