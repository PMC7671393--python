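"""UCSC chain file parsing, validation, inversion and writing.

A chain describes one pairwise alignment between a *source* (``t``) and a
*target* (``q``) chromosome as a run of ungapped aligned blocks separated by
gaps.  Each gap advances the source by ``dt`` bases and the target by ``dq``
bases without aligning them.  All coordinates are 0-based half-open.  Target
coordinates are stored exactly as the format gives them: on the
``q_strand``-oriented sequence.  Use :func:`forwardize_target` to express a
target interval on the forward strand.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator

import pandas as pd

__all__ = [
    "AlignedBlock",
    "ChainHeader",
    "Chain",
    "ChainParseError",
    "ChainValidationError",
    "parse_chain_file",
    "write_chain_file",
    "chain_summary",
    "forwardize_target",
    "forwardize",
    "invert_chain",
    "per_base_map",
]


class ChainParseError(ValueError):
    """Raised when a chain file cannot be tokenized into chains."""


class ChainValidationError(ValueError):
    """Raised when a parsed chain violates the format invariants."""


@dataclass(frozen=True)
class AlignedBlock:
    """One ungapped aligned block and the gap that follows it.

    ``size`` is the aligned length; ``dt``/``dq`` are the unaligned advances
    in source/target after the block.  The last block of a chain has
    ``dt == dq == 0``.
    """

    size: int
    dt: int = 0
    dq: int = 0


@dataclass(frozen=True)
class ChainHeader:
    score: float
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: int


@dataclass
class Chain:
    """A chain header plus its ordered aligned blocks."""

    header: ChainHeader
    blocks: list[AlignedBlock] = field(default_factory=list)

    def validate(self) -> None:
        h = self.header
        if h.t_strand != "+":
            raise ChainValidationError(
                f"chain {h.chain_id}: t_strand must be '+', got {h.t_strand!r}"
            )
        if h.q_strand not in ("+", "-"):
            raise ChainValidationError(
                f"chain {h.chain_id}: q_strand must be '+' or '-'"
            )
        if not (0 <= h.t_start < h.t_end <= h.t_size):
            raise ChainValidationError(
                f"chain {h.chain_id}: bad source span {h.t_start}-{h.t_end} "
                f"on size {h.t_size}"
            )
        if not (0 <= h.q_start < h.q_end <= h.q_size):
            raise ChainValidationError(
                f"chain {h.chain_id}: bad target span {h.q_start}-{h.q_end} "
                f"on size {h.q_size}"
            )
        if not self.blocks:
            raise ChainValidationError(f"chain {h.chain_id}: no blocks")
        for b in self.blocks:
            if b.size <= 0 or b.dt < 0 or b.dq < 0:
                raise ChainValidationError(
                    f"chain {h.chain_id}: negative or zero block field {b}"
                )
        last = self.blocks[-1]
        if last.dt != 0 or last.dq != 0:
            raise ChainValidationError(
                f"chain {h.chain_id}: final block must have dt=dq=0"
            )
        t_sum = sum(b.size + b.dt for b in self.blocks)
        q_sum = sum(b.size + b.dq for b in self.blocks)
        if t_sum != h.t_end - h.t_start:
            raise ChainValidationError(
                f"chain {h.chain_id}: block sums ({t_sum}) do not match "
                f"source span ({h.t_end - h.t_start})"
            )
        if q_sum != h.q_end - h.q_start:
            raise ChainValidationError(
                f"chain {h.chain_id}: block sums ({q_sum}) do not match "
                f"target span ({h.q_end - h.q_start})"
            )

    def walk(self) -> Iterator[tuple[int, int, AlignedBlock]]:
        """Yield ``(t_pos, q_pos, block)`` for each aligned block.

        ``t_pos`` is the source start of the block; ``q_pos`` its start on
        the q-strand-oriented target sequence.
        """
        t = self.header.t_start
        q = self.header.q_start
        for b in self.blocks:
            yield t, q, b
            t += b.size + b.dt
            q += b.size + b.dq

    @property
    def aligned_length(self) -> int:
        return sum(b.size for b in self.blocks)


def _open_maybe_gzip(source) -> IO[str]:
    if isinstance(source, (str, Path)):
        raw: IO[bytes] = open(source, "rb")
    elif isinstance(source, io.TextIOBase):
        return source
    else:
        raw = source
    head = raw.read(2)
    raw.seek(0)
    if head == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(raw, "rb"))
    return io.TextIOWrapper(raw)


def parse_chain_file(source) -> list[Chain]:
    """Parse a UCSC chain file (path, text stream or binary stream).

    Gzip input is detected from the magic bytes, not the file name.  Every
    returned chain has been validated against the format invariants.
    """
    fh = _open_maybe_gzip(source)
    chains: list[Chain] = []
    current: Chain | None = None
    pending: list[tuple[int, int, int]] = []

    def finish(chain: Chain) -> None:
        chain.blocks = [AlignedBlock(*t) for t in pending]
        chain.validate()
        chains.append(chain)

    for lineno, line in enumerate(fh, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("chain"):
            if current is not None:
                raise ChainParseError(
                    f"line {lineno}: new chain before previous one ended"
                )
            fields = line.split()
            if len(fields) != 13:
                raise ChainParseError(
                    f"line {lineno}: chain header has {len(fields)} fields, "
                    "expected 13"
                )
            try:
                header = ChainHeader(
                    score=float(fields[1]),
                    t_name=fields[2],
                    t_size=int(fields[3]),
                    t_strand=fields[4],
                    t_start=int(fields[5]),
                    t_end=int(fields[6]),
                    q_name=fields[7],
                    q_size=int(fields[8]),
                    q_strand=fields[9],
                    q_start=int(fields[10]),
                    q_end=int(fields[11]),
                    chain_id=int(fields[12]),
                )
            except ValueError as exc:
                raise ChainParseError(f"line {lineno}: {exc}") from exc
            current = Chain(header=header)
            pending = []
            continue
        parts = line.split()
        if current is None:
            raise ChainParseError(f"line {lineno}: data line outside a chain")
        try:
            nums = [int(p) for p in parts]
        except ValueError as exc:
            raise ChainParseError(f"line {lineno}: {exc}") from exc
        if len(nums) == 3:
            pending.append((nums[0], nums[1], nums[2]))
        elif len(nums) == 1:
            pending.append((nums[0], 0, 0))
            finish(current)
            current = None
        else:
            raise ChainParseError(
                f"line {lineno}: expected 1 or 3 integers, got {len(nums)}"
            )
    if current is not None:
        raise ChainParseError("unexpected end of file inside a chain stanza")
    return chains


def write_chain_file(chains: Iterable[Chain], dest=None) -> str:
    """Serialize chains in UCSC chain format; write to ``dest`` if given."""
    out = io.StringIO()
    for c in chains:
        h = c.header
        score = int(h.score) if float(h.score).is_integer() else h.score
        out.write(
            f"chain {score} {h.t_name} {h.t_size} {h.t_strand} "
            f"{h.t_start} {h.t_end} {h.q_name} {h.q_size} {h.q_strand} "
            f"{h.q_start} {h.q_end} {h.chain_id}\n"
        )
        for b in c.blocks[:-1]:
            out.write(f"{b.size} {b.dt} {b.dq}\n")
        out.write(f"{c.blocks[-1].size}\n\n")
    text = out.getvalue()
    if dest is not None:
        if isinstance(dest, (str, Path)):
            Path(dest).write_text(text)
        else:
            dest.write(text)
    return text


def chain_summary(chains: Iterable[Chain]) -> pd.DataFrame:
    """One row per chain: identifiers, spans, strand, score, aligned length."""
    rows = []
    for c in chains:
        h = c.header
        rows.append(
            {
                "chain_id": h.chain_id,
                "score": h.score,
                "t_name": h.t_name,
                "t_start": h.t_start,
                "t_end": h.t_end,
                "q_name": h.q_name,
                "q_strand": h.q_strand,
                "q_start": h.q_start,
                "q_end": h.q_end,
                "n_blocks": len(c.blocks),
                "aligned_bp": c.aligned_length,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chain_id", "score", "t_name", "t_start", "t_end",
            "q_name", "q_strand", "q_start", "q_end", "n_blocks", "aligned_bp",
        ],
    )


def forwardize(q_size: int, q_strand: str, start: int, end: int) -> tuple[int, int, str]:
    """Express a q-strand-oriented interval on the target forward strand."""
    if q_strand == "+":
        return start, end, "+"
    return q_size - end, q_size - start, "-"


def forwardize_target(chain: Chain, interval: tuple[int, int]) -> tuple[tuple[int, int], str]:
    """Map a q-oriented interval of ``chain`` to forward-strand coordinates."""
    start, end = interval
    h = chain.header
    if not (h.q_start <= start < end <= h.q_end):
        raise ValueError(
            f"interval [{start},{end}) outside chain {h.chain_id} target "
            f"span [{h.q_start},{h.q_end})"
        )
    s, e, strand = forwardize(h.q_size, h.q_strand, start, end)
    return (s, e), strand


def invert_chain(chain: Chain) -> Chain:
    """Swap the source and target roles of a chain.

    The returned chain maps target coordinates back to source coordinates
    and always has ``t_strand='+'``: for a minus-strand chain the block list
    is reversed and both coordinate spans are re-expressed so the new source
    runs along the target forward strand while the new target (the old
    source) is read on its minus strand.  Inverting twice reproduces the
    original per-base map.
    """
    h = chain.header
    blocks = chain.blocks
    if h.q_strand == "+":
        new_header = ChainHeader(
            score=h.score,
            t_name=h.q_name, t_size=h.q_size, t_strand="+",
            t_start=h.q_start, t_end=h.q_end,
            q_name=h.t_name, q_size=h.t_size, q_strand="+",
            q_start=h.t_start, q_end=h.t_end,
            chain_id=h.chain_id,
        )
        new_blocks = [AlignedBlock(b.size, b.dq, b.dt) for b in blocks]
    else:
        # Reverse block order; the gap after reversed block i is the gap
        # that preceded the original block, with dt/dq swapped.
        sizes = [b.size for b in reversed(blocks)]
        gaps = [(b.dq, b.dt) for b in reversed(blocks[:-1])] + [(0, 0)]
        new_blocks = [AlignedBlock(s, g[0], g[1]) for s, g in zip(sizes, gaps)]
        new_header = ChainHeader(
            score=h.score,
            t_name=h.q_name, t_size=h.q_size, t_strand="+",
            t_start=h.q_size - h.q_end, t_end=h.q_size - h.q_start,
            q_name=h.t_name, q_size=h.t_size, q_strand="-",
            q_start=h.t_size - h.t_end, q_end=h.t_size - h.t_start,
            chain_id=h.chain_id,
        )
    inv = Chain(header=new_header, blocks=new_blocks)
    inv.validate()
    return inv


def per_base_map(chain: Chain) -> dict[int, tuple[str, int, str]]:
    """Brute-force enumeration of the chain's per-base source→target map.

    Returns ``{source_pos: (target_chrom, target_forward_pos, strand)}`` for
    every aligned base.  Intended for validation and small fixtures only.
    """
    h = chain.header
    out: dict[int, tuple[str, int, str]] = {}
    for t0, q0, b in chain.walk():
        for i in range(b.size):
            q = q0 + i
            if h.q_strand == "+":
                fwd = q
            else:
                fwd = h.q_size - 1 - q
            out[t0 + i] = (h.q_name, fwd, h.q_strand)
    return out
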