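"""Synthetic assembly pairs with a known truth alignment.

The simulator emulates how one reference assembly evolves into the next:
segments deleted from the source, new sequence inserted in the target,
segments replaced by unrelated sequence of a different length, and segments
inverted (which real chain files represent as separate minus-strand
chains).  It emits both FASTA sequences, the truth chain linking them, and
a brute-force per-base :class:`TruthMap` that serves as the independent
oracle for the lift engine and the gap-region decomposition.

Optionally a fraction of CpG dinucleotides is mutated in the target
sequence so the "not CG" post-filter has known positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .chain import AlignedBlock, Chain, ChainHeader
from .engine import BedRecord

__all__ = [
    "RearrangementSpec",
    "TruthMap",
    "AssemblyPair",
    "simulate_assembly_pair",
    "oracle_lift_point",
    "oracle_span",
    "simulate_methylome",
    "simulate_peaks",
    "default_fixture_suite",
    "write_fasta",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# unmapped-category codes in TruthMap arrays
MAPPED = 0
CAT_GAPPED_IN_SOURCE = 1
CAT_GAPPED_IN_BOTH = 2


@dataclass(frozen=True)
class RearrangementSpec:
    """What to simulate per chromosome.

    Event counts apply to every chromosome; sizes are drawn uniformly from
    the inclusive ranges.  ``cpg_mutation_rate`` is the per-CpG probability
    that the target copy of an aligned CpG is mutated so it is no longer CG.
    Events are placed without overlap (minimum 2 bp apart) and away from
    chromosome ends.
    """

    chrom_lengths: Mapping[str, int]
    n_deletions: int = 4
    deletion_size: tuple[int, int] = (20, 200)
    n_insertions: int = 4
    insertion_size: tuple[int, int] = (50, 500)
    n_replacements: int = 2
    replacement_src_size: tuple[int, int] = (30, 150)
    replacement_tgt_size: tuple[int, int] = (30, 150)
    n_inversions: int = 1
    inversion_size: tuple[int, int] = (200, 1000)
    cpg_mutation_rate: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class Event:
    kind: str  # deletion | insertion | replacement | inversion
    pos: int
    length: int  # source length (0 for insertion)
    tgt_length: int  # target length (0 for deletion)


@dataclass
class TruthMap:
    """Per-base source→target map: the brute-force oracle.

    For each source chromosome: the target chromosome name, an int64 array
    of target forward positions (−1 where unmapped), a unit array of strand
    (+1/−1, 0 where unmapped) and an unmapped-category code array.
    """

    tgt_chrom: dict[str, str] = field(default_factory=dict)
    tgt_pos: dict[str, np.ndarray] = field(default_factory=dict)
    strand: dict[str, np.ndarray] = field(default_factory=dict)
    category: dict[str, np.ndarray] = field(default_factory=dict)

    def total_size(self) -> int:
        return sum(a.size for a in self.tgt_pos.values())


@dataclass
class AssemblyPair:
    """Everything one simulation run produces."""

    spec: RearrangementSpec
    source: dict[str, str]
    target: dict[str, str]
    chains: list[Chain]
    truth: TruthMap
    events: dict[str, list[Event]]
    mutated_cpgs: dict[str, set[int]]  # source C positions whose target CG was broken

    def source_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.source.items()}

    def target_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.target.items()}


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    """Uppercase ACGT array with CpGs planted roughly every 25 bp so CpG
    filters have material to work on."""
    seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length)
    pos = 0
    while pos + 2 < length:
        pos += int(rng.integers(10, 41))
        if pos + 1 >= length:
            break
        seq[pos] = b"C"
        seq[pos + 1] = b"G"
        pos += 2
    return seq


def _place_events(rng: np.random.Generator, spec: RearrangementSpec,
                  length: int) -> list[Event]:
    wanted: list[tuple[str, int, int]] = []
    for _ in range(spec.n_deletions):
        n = int(rng.integers(spec.deletion_size[0], spec.deletion_size[1] + 1))
        wanted.append(("deletion", n, 0))
    for _ in range(spec.n_insertions):
        n = int(rng.integers(spec.insertion_size[0], spec.insertion_size[1] + 1))
        wanted.append(("insertion", 0, n))
    for _ in range(spec.n_replacements):
        s = int(rng.integers(spec.replacement_src_size[0],
                             spec.replacement_src_size[1] + 1))
        t = int(rng.integers(spec.replacement_tgt_size[0],
                             spec.replacement_tgt_size[1] + 1))
        wanted.append(("replacement", s, t))
    for _ in range(spec.n_inversions):
        n = int(rng.integers(spec.inversion_size[0], spec.inversion_size[1] + 1))
        wanted.append(("inversion", n, n))
    events: list[Event] = []
    occupied: list[tuple[int, int]] = []
    for kind, slen, tlen in wanted:
        placed = False
        for _attempt in range(200):
            pos = int(rng.integers(2, max(3, length - slen - 2)))
            lo, hi = pos - 2, pos + max(slen, 1) + 2
            if all(hi <= s or lo >= e for s, e in occupied):
                occupied.append((lo, hi))
                events.append(Event(kind, pos, slen, tlen))
                placed = True
                break
        if not placed:
            raise RuntimeError(
                "could not place all rearrangement events without overlap; "
                "reduce event counts or sizes"
            )
    events.sort(key=lambda e: e.pos)
    return events


def simulate_assembly_pair(spec: RearrangementSpec) -> AssemblyPair:
    """Simulate the pair, its truth chain file and the per-base oracle."""
    rng = np.random.default_rng(spec.seed)
    source: dict[str, str] = {}
    target: dict[str, str] = {}
    chains: list[Chain] = []
    truth = TruthMap()
    all_events: dict[str, list[Event]] = {}
    mutated: dict[str, set[int]] = {}
    chain_id = 1

    for chrom in spec.chrom_lengths:
        length = spec.chrom_lengths[chrom]
        src = _random_sequence(rng, length)
        events = _place_events(rng, spec, length)
        all_events[chrom] = events

        tgt_parts: list[np.ndarray] = []
        tpos = np.full(length, -1, dtype=np.int64)
        strand = np.zeros(length, dtype=np.int8)
        category = np.zeros(length, dtype=np.uint8)

        # chain pieces gathered as (t_start, t_end, q_fwd_start, q_fwd_end,
        # strand, blocks); q coords fixed up once the target length is known
        pieces: list[tuple[int, int, int, int, str, list[AlignedBlock]]] = []

        t = 0  # source cursor
        q = 0  # target cursor (forward build coordinates)
        fwd_blocks: list[AlignedBlock] = []
        fwd_t0 = 0
        fwd_q0 = 0

        def close_forward(t_end: int, q_end: int) -> None:
            nonlocal fwd_blocks
            if fwd_blocks:
                # strip the trailing gap of the final block
                last = fwd_blocks[-1]
                fwd_blocks[-1] = AlignedBlock(last.size, 0, 0)
                pieces.append((fwd_t0, t_end, fwd_q0, q_end, "+", fwd_blocks))
            fwd_blocks = []

        def aligned_segment(m: int) -> None:
            nonlocal t, q, fwd_blocks, fwd_t0, fwd_q0
            if m <= 0:
                return
            if not fwd_blocks:
                fwd_t0, fwd_q0 = t, q
            tgt_parts.append(src[t:t + m])
            tpos[t:t + m] = np.arange(q, q + m)
            strand[t:t + m] = 1
            fwd_blocks.append(AlignedBlock(m, 0, 0))
            t += m
            q += m

        def add_gap(dt: int, dq: int) -> None:
            # attach to the current open block (there must be one)
            last = fwd_blocks[-1]
            fwd_blocks[-1] = AlignedBlock(last.size, last.dt + dt, last.dq + dq)

        for ev in events:
            aligned_segment(ev.pos - t)
            if ev.kind == "deletion":
                category[t:t + ev.length] = CAT_GAPPED_IN_SOURCE
                add_gap(ev.length, 0)
                t += ev.length
            elif ev.kind == "insertion":
                tgt_parts.append(_random_sequence(rng, ev.tgt_length))
                add_gap(0, ev.tgt_length)
                q += ev.tgt_length
            elif ev.kind == "replacement":
                category[t:t + ev.length] = CAT_GAPPED_IN_BOTH
                tgt_parts.append(_random_sequence(rng, ev.tgt_length))
                add_gap(ev.length, ev.tgt_length)
                t += ev.length
                q += ev.tgt_length
            elif ev.kind == "inversion":
                close_forward(t, q)
                seg = src[t:t + ev.length]
                rc = np.frombuffer(
                    seg.tobytes().decode().translate(_COMPLEMENT)[::-1].encode(),
                    dtype="S1",
                ).copy()
                tgt_parts.append(rc)
                tpos[t:t + ev.length] = np.arange(
                    q + ev.length - 1, q - 1, -1
                )
                strand[t:t + ev.length] = -1
                pieces.append(
                    (t, t + ev.length, q, q + ev.length, "-",
                     [AlignedBlock(ev.length, 0, 0)])
                )
                t += ev.length
                q += ev.length
            else:  # pragma: no cover
                raise AssertionError(ev.kind)
        aligned_segment(length - t)
        close_forward(t, q)

        tgt = np.concatenate(tgt_parts) if tgt_parts else np.empty(0, dtype="S1")
        q_size = len(tgt)

        # optional CpG corruption in the target copy of aligned plus-strand CpGs
        mut: set[int] = set()
        if spec.cpg_mutation_rate > 0:
            s_bytes = src.tobytes()
            p = s_bytes.find(b"CG")
            while p != -1:
                if (
                    strand[p] == 1 and strand[p + 1] == 1
                    and tpos[p + 1] == tpos[p] + 1
                    and rng.random() < spec.cpg_mutation_rate
                ):
                    tgt[tpos[p + 1]] = b"A"  # break the G of the pair
                    mut.add(p)
                p = s_bytes.find(b"CG", p + 1)
        mutated[chrom] = mut

        for t_start, t_end, qf_s, qf_e, st, blocks in pieces:
            if st == "+":
                q_start, q_end = qf_s, qf_e
            else:
                q_start, q_end = q_size - qf_e, q_size - qf_s
            header = ChainHeader(
                score=float(sum(b.size for b in blocks)),
                t_name=chrom, t_size=length, t_strand="+",
                t_start=t_start, t_end=t_end,
                q_name=chrom, q_size=q_size, q_strand=st,
                q_start=q_start, q_end=q_end,
                chain_id=chain_id,
            )
            chain = Chain(header=header, blocks=blocks)
            chain.validate()
            chains.append(chain)
            chain_id += 1

        source[chrom] = src.tobytes().decode()
        target[chrom] = tgt.tobytes().decode()
        truth.tgt_chrom[chrom] = chrom
        truth.tgt_pos[chrom] = tpos
        truth.strand[chrom] = strand
        truth.category[chrom] = category

    return AssemblyPair(
        spec=spec, source=source, target=target, chains=chains,
        truth=truth, events=all_events, mutated_cpgs=mutated,
    )


def oracle_lift_point(
    truth: TruthMap, chrom: str, pos: int
) -> tuple[str, int, str] | None:
    """Look up one source base in the truth map; None when unmapped."""
    arr = truth.tgt_pos[chrom]
    if not (0 <= pos < arr.size):
        raise IndexError(f"{chrom}:{pos} outside simulated chromosome")
    if arr[pos] < 0:
        return None
    st = "+" if truth.strand[chrom][pos] > 0 else "-"
    return truth.tgt_chrom[chrom], int(arr[pos]), st


def oracle_span(
    truth: TruthMap, chrom: str, start: int, end: int
) -> tuple[tuple[str, int, int, str] | None, float]:
    """Spanning target interval of the mapped bases of [start,end) on the
    majority strand, plus the mapped fraction."""
    pos = truth.tgt_pos[chrom][start:end]
    st = truth.strand[chrom][start:end]
    mask = pos >= 0
    fraction = mask.mean() if end > start else 0.0
    if not mask.any():
        return None, 0.0
    majority = 1 if (st[mask] > 0).sum() * 2 >= mask.sum() else -1
    sel = pos[mask & (st == majority)]
    lo, hi = int(sel.min()), int(sel.max()) + 1
    return (
        (truth.tgt_chrom[chrom], lo, hi, "+" if majority > 0 else "-"),
        float(fraction),
    )


def find_cpgs(seq: str) -> list[int]:
    """0-based C positions of every CG dinucleotide."""
    out = []
    p = seq.find("CG")
    while p != -1:
        out.append(p)
        p = seq.find("CG", p + 1)
    return out


def simulate_methylome(
    sequences: Mapping[str, str],
    seed: int = 0,
    coverage_mean: float = 20.0,
    beta_mix: tuple[float, float, float] = (0.4, 0.5, 0.1),
) -> list[tuple[str, int, int, float]]:
    """One record per CpG: (chrom, C position, coverage, methylation beta).

    Coverage is Poisson with the given mean; beta comes from the bimodal
    mixture typical of WGBS (Beta(0.5,8) low, Beta(8,0.5) high, uniform
    middle, with the supplied weights).
    """
    rng = np.random.default_rng(seed)
    records = []
    w_low, w_high, w_mid = beta_mix
    for chrom in sequences:
        for pos in find_cpgs(sequences[chrom]):
            cov = int(rng.poisson(coverage_mean))
            u = rng.random()
            if u < w_low:
                beta = float(rng.beta(0.5, 8))
            elif u < w_low + w_high:
                beta = float(rng.beta(8, 0.5))
            else:
                beta = float(rng.random())
            records.append((chrom, pos, cov, beta))
    return records


def simulate_peaks(
    chrom_sizes: Mapping[str, int],
    seed: int = 0,
    n: int = 100,
    width_range: tuple[int, int] = (150, 2000),
) -> list[BedRecord]:
    """n ChIP-seq-like intervals with uniform widths, uniformly placed."""
    lo, hi = width_range
    if hi > min(chrom_sizes.values()):
        raise ValueError("width range exceeds the shortest chromosome")
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    out = []
    for i in range(n):
        ci = int(rng.choice(len(chroms), p=probs))
        w = int(rng.integers(lo, hi + 1))
        s = int(rng.integers(0, chrom_sizes[chroms[ci]] - w + 1))
        out.append(BedRecord(chroms[ci], s, s + w, name=f"peak{i}"))
    return out


def default_fixture_suite(base_seed: int = 12345) -> list[AssemblyPair]:
    """The package's standard synthetic test conditions.

    One full genome of three chromosomes (50-100 kb) carrying every event
    type including inversions and CpG corruption, plus a smaller plus-only
    genome; 300 kb of source sequence in total so exhaustive per-base
    checks stay cheap.
    """
    specs = [
        RearrangementSpec(
            chrom_lengths={"chr1": 100_000, "chr2": 80_000, "chr3": 50_000},
            n_inversions=2,
            cpg_mutation_rate=0.02,
            seed=base_seed,
        ),
        RearrangementSpec(
            chrom_lengths={"chr1": 40_000, "chr2": 30_000},
            n_inversions=0,
            seed=base_seed + 1,
        ),
    ]
    return [simulate_assembly_pair(s) for s in specs]


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    return path
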