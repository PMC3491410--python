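"""k-mismatch occurrence counting on converted references.

The mapping pipeline never aligns reads directly; it counts, per
orientation, every locus where a (converted) query occurs within a Hamming
distance budget k, grouped by mismatch count.  The contract is the hit set,
not the data structure: ``find_hits`` uses a q-gram seed index with
pigeonhole seeding (a hit with <= k mismatches leaves at least one of k+1
query parts exact) and a vectorized Hamming verifier, falling back to a
full scan when the query is too short to seed.  ``brute_force_hits`` is the
definitional sliding-window oracle used to test it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reference_prep import (
    BASE_SPACE,
    ConvertedReference,
    colors_to_codes,
    seq_to_codes,
)


@dataclass(frozen=True)
class Hit:
    """One candidate locus: 0-based offset into the searched reference text."""

    chrom: str
    pos: int
    mismatches: int


@dataclass
class HitList:
    """Per-orientation candidate loci grouped by mismatch count."""

    orientation: str
    groups: dict[int, list[Hit]] = field(default_factory=dict)

    def total(self) -> int:
        return sum(len(g) for g in self.groups.values())

    def max_group_size(self) -> int:
        return max((len(g) for g in self.groups.values()), default=0)

    def all_hits(self) -> list[Hit]:
        return [h for _, g in sorted(self.groups.items()) for h in g]


class SeedIndex:
    """Sorted q-gram index over one encoded reference chromosome."""

    def __init__(self, arr: np.ndarray, q: int):
        self.q = q
        n = arr.size
        if n < q:
            self.sorted_codes = None
            self.positions = None
            return
        code = np.zeros(n - q + 1, dtype=np.int64)
        for j in range(q):
            code = code * 4 + arr[j : n - q + 1 + j]
        order = np.argsort(code, kind="stable")
        self.sorted_codes = code[order]
        self.positions = order.astype(np.int64)

    def lookup(self, code: int) -> np.ndarray:
        if self.sorted_codes is None:
            return np.empty(0, dtype=np.int64)
        lo = np.searchsorted(self.sorted_codes, code, side="left")
        hi = np.searchsorted(self.sorted_codes, code, side="right")
        return self.positions[lo:hi]


def _encode_query(ref: ConvertedReference, query) -> np.ndarray:
    if isinstance(query, np.ndarray):
        return query.astype(np.uint8, copy=False)
    if ref.space == BASE_SPACE:
        return seq_to_codes(query)
    return colors_to_codes(query)


def _chrom_index(ref: ConvertedReference, chrom: str) -> SeedIndex:
    idx = ref._indexes.get(chrom)
    if idx is None:
        idx = SeedIndex(ref.arr(chrom), ref.seed_q)
        ref._indexes[chrom] = idx
    return idx


def _part_starts(m: int, k: int) -> list[int]:
    nparts = k + 1
    base, extra = divmod(m, nparts)
    starts, s = [], 0
    for i in range(nparts):
        starts.append(s)
        s += base + (1 if i < extra else 0)
    return starts


def _gram_code(q: np.ndarray, start: int, length: int) -> int:
    code = 0
    for v in q[start : start + length]:
        code = code * 4 + int(v)
    return code


def find_hits(ref: ConvertedReference, query, k: int) -> dict[int, list[Hit]]:
    """All loci of ``query`` in ``ref`` within Hamming distance k.

    Returns {mismatch_count: [Hit, ...]} with each group sorted by
    (chrom, pos).  A query longer than a chromosome yields no hits on that
    chromosome; hits never span chromosomes.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    q = _encode_query(ref, query)
    m = q.size
    groups: dict[int, list[Hit]] = {}
    if m == 0:
        return groups
    offsets = np.arange(m)
    for chrom in ref.chroms:
        arr = ref.arr(chrom)
        n = arr.size
        if m > n:
            continue
        seed_len = ref.seed_q
        use_index = n >= seed_len and (m // (k + 1)) >= seed_len
        if use_index:
            idx = _chrom_index(ref, chrom)
            cand_parts = []
            for s in _part_starts(m, k):
                code = _gram_code(q, s, seed_len)
                cand_parts.append(idx.lookup(code) - s)
            cands = np.unique(np.concatenate(cand_parts))
            cands = cands[(cands >= 0) & (cands <= n - m)]
        else:
            cands = np.arange(n - m + 1, dtype=np.int64)
        if cands.size == 0:
            continue
        windows = arr[cands[:, None] + offsets]
        mm = (windows != q).sum(axis=1)
        keep = mm <= k
        for p, c in zip(cands[keep].tolist(), mm[keep].tolist()):
            groups.setdefault(int(c), []).append(Hit(chrom, int(p), int(c)))
    for g in groups.values():
        g.sort(key=lambda h: (h.chrom, h.pos))
    return dict(sorted(groups.items()))


def brute_force_hits(ref: ConvertedReference, query, k: int) -> dict[int, list[Hit]]:
    """Definitional oracle: per-position Hamming scan in pure Python."""
    if k < 0:
        raise ValueError("k must be >= 0")
    q = _encode_query(ref, query).tolist()
    m = len(q)
    groups: dict[int, list[Hit]] = {}
    if m == 0:
        return groups
    for chrom in ref.chroms:
        text = ref.arr(chrom).tolist()
        for pos in range(len(text) - m + 1):
            d = 0
            for a, b in zip(q, text[pos : pos + m]):
                if a != b:
                    d += 1
                    if d > k:
                        break
            if d <= k:
                groups.setdefault(d, []).append(Hit(chrom, pos, d))
    for g in groups.values():
        g.sort(key=lambda h: (h.chrom, h.pos))
    return dict(sorted(groups.items()))
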