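"""Concordance and QC statistics between two coordinate/annotation sets.

These are the measures used to compare a lifted dataset against an
independently aligned one: interval Jaccard similarity, gain/loss/overlap
counts, shrink/equal/extend width classification, Cohen's kappa on binned
coverage or methylation, per-CpG methylation deltas, a randomization-based
Fisher enrichment test, nearest-feature distance preservation and Pearson
correlation of interval widths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .engine import BedRecord
from .intervals import intersect_length, merge_intervals, total_length

__all__ = [
    "jaccard",
    "gain_loss_overlap",
    "width_change_classify",
    "bin_coverage",
    "bin_beta",
    "cohen_kappa",
    "KappaResult",
    "delta_methylation",
    "Contingency2x2",
    "EnrichmentResult",
    "fisher_one_sided",
    "enrichment_test",
    "NearestFeatureResult",
    "nearest_feature_delta",
    "pearson_width_correlation",
]

IntervalSet = Mapping[str, Sequence[tuple[int, int]]]


def _as_per_chrom(intervals) -> dict[str, list[tuple[int, int]]]:
    """Accept BedRecord lists, (chrom,start,end) tuples, or per-chromosome
    dicts."""
    if isinstance(intervals, Mapping):
        return {c: list(v) for c, v in intervals.items()}
    out: dict[str, list[tuple[int, int]]] = {}
    for rec in intervals:
        if isinstance(rec, BedRecord):
            out.setdefault(rec.chrom, []).append((rec.start, rec.end))
        else:
            out.setdefault(rec[0], []).append((rec[1], rec[2]))
    return out


def jaccard(set_a, set_b) -> float:
    """length(A∩B) / length(A∪B) over merged interval sets."""
    a = _as_per_chrom(set_a)
    b = _as_per_chrom(set_b)
    inter = sum(
        intersect_length(a.get(c, []), b.get(c, [])) for c in set(a) | set(b)
    )
    len_a = sum(total_length(v) for v in a.values())
    len_b = sum(total_length(v) for v in b.values())
    union = len_a + len_b - inter
    if union == 0:
        raise ValueError("Jaccard undefined: both interval sets are empty")
    return inter / union


def gain_loss_overlap(
    alignment_set, liftover_set, min_overlap: int = 1
) -> dict[str, float]:
    """Classify each interval by whether it overlaps the other set.

    loss: in the alignment output only; gain: in the liftover output only;
    overlapping: present (>= min_overlap bp) in both, counted once per
    interval on each side.  Percentages are over the union of counts.
    """
    a = _as_per_chrom(alignment_set)
    b = _as_per_chrom(liftover_set)
    merged_a = {c: merge_intervals(v) for c, v in a.items()}
    merged_b = {c: merge_intervals(v) for c, v in b.items()}

    def overlaps(iv, track) -> bool:
        s, e = iv
        return any(
            min(e, te) - max(s, ts) >= min_overlap for ts, te in track
        )

    loss = gain = overlap_align = overlap_lift = 0
    for c, ivs in a.items():
        for iv in ivs:
            if overlaps(iv, merged_b.get(c, [])):
                overlap_align += 1
            else:
                loss += 1
    for c, ivs in b.items():
        for iv in ivs:
            if overlaps(iv, merged_a.get(c, [])):
                overlap_lift += 1
            else:
                gain += 1
    total = loss + gain + overlap_align + overlap_lift
    pct = (lambda x: 100 * x / total if total else 0.0)
    return {
        "loss": loss,
        "gain": gain,
        "overlap_align": overlap_align,
        "overlap_lift": overlap_lift,
        "pct_loss": pct(loss),
        "pct_gain": pct(gain),
        "pct_overlap": pct(overlap_align + overlap_lift),
    }


def width_change_classify(
    pairs: Iterable[tuple[float, float]], n: float = 2.0
) -> dict[str, int]:
    """shrink/equal/extend counts from (width_before, width_after) pairs.

    equal iff 1/n < B/A < n (strict); B/A >= n is shrink, B/A <= 1/n is
    extend, so the boundary ratios fall in the changed classes.
    """
    if n <= 1:
        raise ValueError("ratio bound n must be > 1")
    counts = {"shrink": 0, "equal": 0, "extend": 0}
    for before, after in pairs:
        if before <= 0 or after <= 0:
            raise ValueError("widths must be positive")
        ratio = before / after
        if ratio >= n:
            counts["shrink"] += 1
        elif ratio <= 1 / n:
            counts["extend"] += 1
        else:
            counts["equal"] += 1
    return counts


_COVERAGE_EDGES = (0, 6, 12, 18, 24, 32)
_BETA_EDGES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


def _bin(v: float, edges: Sequence[float], top_open: bool, what: str) -> int:
    if v < edges[0]:
        raise ValueError(f"negative {what} value {v}")
    if v > edges[-1]:
        if not top_open:
            raise ValueError(f"{what} value {v} above {edges[-1]}")
        warnings.warn(
            f"{what} value {v} above {edges[-1]}; assigned to the top bin",
            stacklevel=3,
        )
        return len(edges) - 2
    for i in range(len(edges) - 2):
        if v < edges[i + 1]:
            return i
    return len(edges) - 2  # top bin is closed


def bin_coverage(v: float) -> int:
    """Five coverage bins [0,6), [6,12), [12,18), [18,24), [24,32]; values
    above 32 are top-binned with a warning."""
    return _bin(v, _COVERAGE_EDGES, top_open=True, what="coverage")


def bin_beta(v: float) -> int:
    """Five methylation bins [0,0.2), ..., [0.8,1.0]."""
    return _bin(v, _BETA_EDGES, top_open=False, what="beta")


_KAPPA_BANDS = (
    (0.0, "no agreement"),
    (0.20, "slight agreement"),
    (0.40, "fair agreement"),
    (0.60, "moderate agreement"),
    (0.80, "substantial agreement"),
    (1.0, "perfect agreement"),
)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    interpretation: str

    def __float__(self) -> float:
        return self.kappa


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> KappaResult:
    """Unweighted Cohen's kappa, κ = (p_o − p_e)/(1 − p_e), with the
    conventional verbal agreement band."""
    if len(labels_a) != len(labels_b):
        raise ValueError("label sequences must have equal length")
    if not labels_a:
        raise ValueError("empty label sequences")
    n = len(labels_a)
    cats = sorted(set(labels_a) | set(labels_b), key=str)
    idx = {c: i for i, c in enumerate(cats)}
    table = np.zeros((len(cats), len(cats)))
    for x, y in zip(labels_a, labels_b):
        table[idx[x], idx[y]] += 1
    p_o = np.trace(table) / n
    p_e = float((table.sum(axis=1) / n) @ (table.sum(axis=0) / n))
    kappa = 1.0 if p_e == 1.0 else (p_o - p_e) / (1 - p_e)
    interp = "no agreement"
    if kappa >= 0:
        for hi, name in _KAPPA_BANDS[1:]:
            if kappa <= hi:
                interp = name
                break
        else:
            interp = _KAPPA_BANDS[-1][1]
    return KappaResult(float(kappa), interp)


def delta_methylation(
    lift_records: Iterable[tuple[str, int, float]],
    align_records: Iterable[tuple[str, int, float]],
    threshold: float = 0.2,
) -> dict:
    """Per-site methylation delta (liftover minus alignment) on sites
    present in both; |delta| >= threshold flags a significant difference.

    Records are (chrom, pos, beta) or (chrom, pos, coverage, beta) tuples.
    """
    def as_map(records):
        out = {}
        for r in records:
            out[(r[0], r[1])] = float(r[-1])
        return out

    lift = as_map(lift_records)
    align = as_map(align_records)
    common = sorted(set(lift) & set(align))
    deltas = {k: lift[k] - align[k] for k in common}
    # tolerance keeps boundary deltas like 0.1 - 0.3 significant despite
    # binary floating point
    significant = {
        k for k, d in deltas.items() if abs(d) >= threshold - 1e-12
    }
    return {
        "deltas": deltas,
        "significant": significant,
        "n_common": len(common),
        "n_lift_only": len(lift) - len(common),
        "n_align_only": len(align) - len(common),
        "fraction_zero": (
            sum(1 for d in deltas.values() if d == 0.0) / len(common)
            if common else float("nan")
        ),
    }


def recurrence_counter(
    per_sample_significant: Sequence[set], direction_maps: Sequence[dict] | None = None,
    same_direction: bool = False,
) -> dict[int, int]:
    """How often the same significant site recurs across sample pairs.

    Returns {k: number of sites significant in exactly k samples}.  With
    ``same_direction`` a site only accumulates across samples whose delta
    sign agrees with its first occurrence.
    """
    counts: dict[tuple, int] = {}
    sign: dict[tuple, int] = {}
    for i, sites in enumerate(per_sample_significant):
        for site in sites:
            if same_direction and direction_maps is not None:
                s = 1 if direction_maps[i][site] >= 0 else -1
                if site in sign and sign[site] != s:
                    continue
                sign.setdefault(site, s)
            counts[site] = counts.get(site, 0) + 1
    out: dict[int, int] = {}
    for k in counts.values():
        out[k] = out.get(k, 0) + 1
    return out


@dataclass(frozen=True)
class Contingency2x2:
    """Counts (query overlapping, query not, random overlapping, random
    not) for one annotation."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")


@dataclass(frozen=True)
class EnrichmentResult:
    feature: str
    odds_ratio: float
    p_value: float
    significant: bool
    table: Contingency2x2
    continuity_corrected: bool = False


def fisher_one_sided(table: Contingency2x2) -> float:
    """One-sided (greater) Fisher exact p: the hypergeometric upper tail
    P(X >= a) with margins fixed."""
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    if n == 0:
        return 1.0
    # X ~ Hypergeom(N=n, K=a+b draws of the first row, n1=a+c successes)
    return float(stats.hypergeom.sf(a - 1, n, a + c, a + b))


def odds_ratio(table: Contingency2x2) -> tuple[float, bool]:
    """Cross-product OR; zero cells get the Haldane–Anscombe 0.5
    correction and a flag."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if 0 in (a, b, c, d):
        return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5)), True
    return (a * d) / (b * c), False


def enrichment_test(
    query,
    annotations: Mapping[str, object],
    universe,
    n_rand: int = 1,
    seed: int = 0,
    or_threshold: float = 5.0,
    p_threshold: float = 0.001,
) -> list[EnrichmentResult]:
    """Randomization enrichment of a query set in each annotation track.

    The query's overlap counts are compared with those of an equally sized
    random draw: for point queries the draw is a without-replacement sample
    from the universe points; for interval queries each interval is placed
    uniformly (width-preserving) on its own chromosome, with ``universe``
    a chromosome-sizes mapping.  A one-sided Fisher test on the resulting
    2×2 table flags features with OR >= ``or_threshold`` and
    p < ``p_threshold``.  With ``n_rand`` > 1 the random overlap count is
    the rounded mean over replicates.
    """
    rng = np.random.default_rng(seed)
    q = _as_per_chrom(query)
    q_items = [(c, s, e) for c, ivs in q.items() for s, e in sorted(ivs)]
    n_query = len(q_items)
    is_points = all(e - s == 1 for _c, s, e in q_items)

    ann_merged: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for name, track in annotations.items():
        per = {}
        for c, v in _as_per_chrom(track).items():
            m = merge_intervals(v)
            per[c] = (np.array([t[0] for t in m]), np.array([t[1] for t in m]))
        ann_merged[name] = per

    def count_overlaps(items) -> dict[str, int]:
        counts = {}
        for name, merged in ann_merged.items():
            total = 0
            for c, s, e in items:
                if c not in merged:
                    continue
                ts, te = merged[c]
                j = int(np.searchsorted(ts, s, side="right")) - 1
                hit = (j >= 0 and te[j] > s) or (
                    j + 1 < len(ts) and ts[j + 1] < e
                )
                total += bool(hit)
            counts[name] = total
        return counts

    def random_items():
        if is_points:
            upts = [(c, p) for c, ps in _universe_points(universe).items()
                    for p in ps]
            if len(upts) < n_query:
                raise ValueError("universe smaller than the query")
            pick = rng.choice(len(upts), size=n_query, replace=False)
            return [(upts[i][0], upts[i][1], upts[i][1] + 1) for i in pick]
        sizes = dict(universe)
        out = []
        for c, s, e in q_items:
            w = e - s
            limit = sizes[c] - w
            pos = int(rng.integers(0, limit + 1))
            out.append((c, pos, pos + w))
        return out

    q_counts = count_overlaps(q_items)
    rand_counts_reps = [count_overlaps(random_items()) for _ in range(n_rand)]

    results = []
    for name in annotations:
        a = q_counts[name]
        b = n_query - a
        c = int(round(np.mean([r[name] for r in rand_counts_reps])))
        d = n_query - c
        table = Contingency2x2(a, b, c, d)
        p = fisher_one_sided(table)
        orr, corrected = odds_ratio(table)
        results.append(
            EnrichmentResult(
                feature=name,
                odds_ratio=orr,
                p_value=p,
                significant=(orr >= or_threshold and p < p_threshold),
                table=table,
                continuity_corrected=corrected,
            )
        )
    return results


def _universe_points(universe) -> dict[str, np.ndarray]:
    if isinstance(universe, Mapping) and all(
        np.isscalar(v) for v in universe.values()
    ):
        raise ValueError(
            "point queries need a point universe, not chromosome sizes"
        )
    out: dict[str, list[int]] = {}
    if isinstance(universe, Mapping):
        return {c: np.asarray(v) for c, v in universe.items()}
    for rec in universe:
        if isinstance(rec, BedRecord):
            out.setdefault(rec.chrom, []).append(rec.start)
        else:
            out.setdefault(rec[0], []).append(rec[1])
    return {c: np.array(v) for c, v in out.items()}


@dataclass(frozen=True)
class NearestFeatureResult:
    chrom: str
    point: int
    feature: tuple[int, int]
    d1: int
    d2: int

    @property
    def delta(self) -> int:
        return self.d1 - self.d2


def _edge_distance(p: int, s: int, e: int) -> int | None:
    """bp gap between a point and a feature edge; None when covered."""
    if s <= p < e:
        return None
    return s - p if p < s else p - e + 1


def nearest_feature_delta(
    points_src: Sequence[tuple[str, int]],
    features_src: Sequence[tuple[str, int, int]],
    points_lifted: Sequence[tuple[str, int] | None],
    features_tgt: Sequence[tuple[str, int, int]],
) -> tuple[list[NearestFeatureResult], float, int]:
    """Does liftover preserve each feature's distance to its nearest point?

    ``features_tgt`` is index-paired with ``features_src`` (the same
    features in target coordinates); ``points_lifted`` is index-paired
    with ``points_src`` (None where the point failed to lift).  For every
    feature, the nearest non-covering source point is found (d1), the pair
    is deduplicated to unique (feature, point) pairs, and the distance is
    re-measured after liftover (d2).  Returns the per-pair results, the
    fraction with delta == 0, and the number of skipped pairs (covered
    points or unlifted points).
    """
    if len(features_src) != len(features_tgt):
        raise ValueError("source/target feature lists must be index-paired")
    results: list[NearestFeatureResult] = []
    skipped = 0
    for fi, (fchrom, fs, fe) in enumerate(features_src):
        best: tuple[int, int] | None = None  # (d1, point index)
        for pi, (pchrom, p) in enumerate(points_src):
            if pchrom != fchrom:
                continue
            d = _edge_distance(p, fs, fe)
            if d is None:
                continue
            if best is None or d < best[0]:
                best = (d, pi)
        if best is None:
            skipped += 1
            continue
        d1, pi = best
        lifted = points_lifted[pi]
        if lifted is None:
            skipped += 1
            continue
        lchrom, lp = lifted
        tchrom, ts, te = features_tgt[fi]
        if lchrom != tchrom:
            skipped += 1
            continue
        d2 = _edge_distance(lp, ts, te)
        if d2 is None:
            skipped += 1
            continue
        results.append(
            NearestFeatureResult(fchrom, points_src[pi][1], (fs, fe), d1, d2)
        )
    zero_fraction = (
        sum(1 for r in results if r.delta == 0) / len(results)
        if results else float("nan")
    )
    return results, zero_fraction, skipped


def pearson_width_correlation(
    pairs: Iterable[tuple[float, float]]
) -> float:
    """Pearson r of paired interval widths."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least two width pairs")
    if arr[:, 0].std() == 0 or arr[:, 1].std() == 0:
        raise ValueError("degenerate width variance")
    return float(stats.pearsonr(arr[:, 0], arr[:, 1])[0])
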