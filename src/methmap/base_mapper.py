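"""Base-space (Illumina) bisulfite read mapping.

Pipeline per read: low-complexity (entropy) filter -> in-silico C->T
conversion of the read -> hit counting in the four read/reference
orientation combinations on the fully converted references -> list
filtering (an orientation's whole candidate list is discarded when one of
its mismatch levels holds at least the cutoff number of hits) ->
bisulfite-aware verification of the surviving candidates against the
original genome -> unique-hit resolution (report the single locus with the
strictly lowest number of non-bisulfite mismatches).

A bisulfite (BS) mismatch is read T over reference C (equivalently read A
over reference G on the minus strand after coordinate normalization): it is
evidence of an unmethylated cytosine, not an error, and is never counted
against a hit.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .io_formats import BaseRead, RunConfig
from .reference_prep import (
    A,
    C,
    FULL,
    G,
    PLUS,
    RC,
    T,
    Genome,
    ReferenceSet,
    fully_convert,
    reverse_complement,
    sanitize,
    seq_to_codes,
)
from .search_engine import Hit, HitList, find_hits

# Table of the four orientations: (name, query source, reference orientation).
# The strand flag reported for a hit equals the strand whose cytosines the
# aligned read measures (the "bisulfite strand").
ORIENT_READ_PLUS = "read_vs_plus"
ORIENT_READ_RC = "read_vs_rc"
ORIENT_RCREAD_PLUS = "rcread_vs_plus"
ORIENT_RCREAD_RC = "rcread_vs_rc"

_ORIENTATIONS = (
    (ORIENT_READ_PLUS, "read", PLUS),
    (ORIENT_READ_RC, "read", RC),
    (ORIENT_RCREAD_PLUS, "rcread", PLUS),
    (ORIENT_RCREAD_RC, "rcread", RC),
)

STATUS_UNIQUE = "unique"
STATUS_AMBIGUOUS = "ambiguous"
STATUS_UNMAPPED = "unmapped"
STATUS_LIST_FILTERED = "list_filtered"
STATUS_ENTROPY_FILTERED = "entropy_filtered"


@dataclass
class MappingResult:
    """A resolved unique alignment in original-genome plus-strand coordinates.

    ``aligned_seq`` is the read (or decoded color read) oriented to the plus
    strand; ``strand`` identifies which strand's cytosines it measures.
    """

    read_id: str
    chrom: str
    pos: int  # 0-based plus-strand coordinate of the leftmost aligned base
    strand: str  # '+' or '-'
    non_bs_mismatches: int
    bs_mismatches: int
    reference_label: str  # FULL | NONCPG
    aligned_seq: str
    space: str = "base"
    unique: bool = True
    color_mismatches: int | None = None


@dataclass
class MapOutcome:
    status: str
    result: MappingResult | None = None


def shannon_entropy(seq: str) -> float:
    """Discrete Shannon entropy of the A/C/G/T histogram, normalized to [0,1].

    Ns (and other ambiguity codes) are excluded from the histogram.  The
    normalization by log2(4) makes the low-complexity cutoff of 0.25
    scale-meaningful: a single-letter read scores 0, a two-letter read with
    equal counts scores 0.5, a balanced four-letter read scores 1.
    """
    counts = Counter(b for b in seq.upper() if b in "ACGT")
    total = sum(counts.values())
    if total == 0:
        return 0.0
    h = 0.0
    for n in counts.values():
        p = n / total
        h -= p * math.log2(p)
    return h / 2.0


def convert_read(seq: str) -> str:
    """In-silico bisulfite conversion of a read: every C becomes T."""
    return fully_convert(seq)


def count_orientations(
    seq: str, refset: ReferenceSet, k: int
) -> list[HitList]:
    """Hit counts for the four orientation combinations (Counts 1..4).

    The reverse complement is taken on the raw (unconverted) read before the
    C->T conversion of the query.
    """
    conv_read = convert_read(seq)
    conv_rcread = convert_read(reverse_complement(seq))
    out = []
    for name, source, ref_orient in _ORIENTATIONS:
        query = conv_read if source == "read" else conv_rcread
        ref = refset.get(FULL, ref_orient)
        out.append(HitList(name, find_hits(ref, query, k)))
    return out


def list_filter(hitlists: list[HitList], cutoff: int) -> list[HitList]:
    """Discard every list in which some mismatch level holds >= cutoff hits.

    A read that is repetitive on one strand can still be unique on the
    other; dropping the repetitive list both avoids rendering all hits
    ambiguous and shrinks the verification work.
    """
    return [hl for hl in hitlists if hl.max_group_size() < cutoff]


@dataclass
class _Candidate:
    chrom: str
    pos: int
    strand: str
    non_bs: int
    bs: int
    aligned_seq: str
    orientation: str
    orient_rank: int = 0


def _normalize_hit(
    orientation: str, hit: Hit, read_len: int, chrom_len: int
) -> tuple[int, str]:
    """Map a hit on a converted reference back to plus-strand coordinates."""
    if orientation in (ORIENT_READ_PLUS, ORIENT_RCREAD_PLUS):
        pos = hit.pos
    else:
        pos = chrom_len - hit.pos - read_len
    strand = "+" if orientation in (ORIENT_READ_PLUS, ORIENT_RCREAD_PLUS) else "-"
    return pos, strand


def _aligned_plus_seq(orientation: str, seq: str, rc_seq: str) -> str:
    """The read oriented along the plus strand of the original genome."""
    if orientation in (ORIENT_READ_PLUS, ORIENT_RCREAD_PLUS):
        return seq if orientation == ORIENT_READ_PLUS else rc_seq
    return rc_seq if orientation == ORIENT_READ_RC else seq


def bs_aware_mismatches(
    aligned: np.ndarray, ref_window: np.ndarray, strand: str
) -> tuple[int, int]:
    """(non-bisulfite, bisulfite) mismatch counts for a plus-oriented alignment."""
    mm = aligned != ref_window
    if strand == "+":
        bs = mm & (ref_window == C) & (aligned == T)
    else:
        bs = mm & (ref_window == G) & (aligned == A)
    n_bs = int(bs.sum())
    return int(mm.sum()) - n_bs, n_bs


def verify_bs_mismatches(
    read_seq: str, hit: Hit, orientation: str, genome: Genome
) -> tuple[int, int]:
    """Recount mismatches of the ORIGINAL (unconverted) read at a hit locus.

    The hit's converted-space coordinates are normalized to the plus strand
    of the original genome first.
    """
    seq = sanitize(read_seq)
    rc_seq = reverse_complement(seq)
    chrom_len = len(genome[hit.chrom])
    pos, strand = _normalize_hit(orientation, hit, len(seq), chrom_len)
    if pos < 0 or pos + len(seq) > chrom_len:
        raise ValueError("hit locus out of chromosome range")
    aligned = seq_to_codes(_aligned_plus_seq(orientation, seq, rc_seq))
    window = genome.arr(hit.chrom)[pos : pos + len(seq)]
    return bs_aware_mismatches(aligned, window, strand)


def resolve_unique(candidates: list[_Candidate]) -> _Candidate | None:
    """The single candidate with strictly minimal non-BS mismatches, if any."""
    if not candidates:
        return None
    best = min(c.non_bs for c in candidates)
    winners = [c for c in candidates if c.non_bs == best]
    return winners[0] if len(winners) == 1 else None


def map_read(read: BaseRead, refset: ReferenceSet, config: RunConfig) -> MapOutcome:
    """Run the full base-space pipeline on one read."""
    if shannon_entropy(read.seq) < config.entropy_cutoff:
        return MapOutcome(STATUS_ENTROPY_FILTERED)
    seq = sanitize(read.seq)
    rc_seq = reverse_complement(seq)
    m = len(seq)
    k = config.resolve_k_base(m)
    hitlists = count_orientations(seq, refset, k)
    any_hits = any(hl.total() for hl in hitlists)
    retained = list_filter(hitlists, config.list_cutoff_base)
    if not any_hits:
        return MapOutcome(STATUS_UNMAPPED)
    if not any(hl.total() for hl in retained):
        return MapOutcome(STATUS_LIST_FILTERED)

    genome = refset.genome
    rank = {name: i for i, (name, _, _) in enumerate(_ORIENTATIONS)}
    # candidates are keyed by genomic LOCATION: an unconverted read matches
    # the same locus under both strand interpretations (e.g. Count 1 and
    # Count 4), which is one unique location, not an ambiguity; ties at a
    # location break toward the earlier orientation, which preserves the
    # natural strand assignment
    candidates: dict[tuple[str, int], _Candidate] = {}
    for hl in retained:
        for hit in hl.all_hits():
            chrom_len = len(genome[hit.chrom])
            pos, strand = _normalize_hit(hl.orientation, hit, m, chrom_len)
            aligned_seq = _aligned_plus_seq(hl.orientation, seq, rc_seq)
            aligned = seq_to_codes(aligned_seq)
            window = genome.arr(hit.chrom)[pos : pos + m]
            non_bs, bs = bs_aware_mismatches(aligned, window, strand)
            if non_bs > k:
                continue
            key = (hit.chrom, pos)
            prev = candidates.get(key)
            r = rank[hl.orientation]
            if (
                prev is None
                or non_bs < prev.non_bs
                or (non_bs == prev.non_bs and r < prev.orient_rank)
            ):
                candidates[key] = _Candidate(
                    hit.chrom, pos, strand, non_bs, bs, aligned_seq, hl.orientation, r
                )
    winner = resolve_unique(list(candidates.values()))
    if winner is None:
        return MapOutcome(STATUS_AMBIGUOUS if candidates else STATUS_UNMAPPED)
    return MapOutcome(
        STATUS_UNIQUE,
        MappingResult(
            read_id=read.read_id,
            chrom=winner.chrom,
            pos=winner.pos,
            strand=winner.strand,
            non_bs_mismatches=winner.non_bs,
            bs_mismatches=winner.bs,
            reference_label=FULL,
            aligned_seq=winner.aligned_seq,
            space="base",
        ),
    )


def map_reads(
    reads, refset: ReferenceSet, config: RunConfig
) -> tuple[list[MappingResult], dict]:
    """Map a read stream; returns unique results and a run report."""
    counts = {
        "total": 0,
        STATUS_ENTROPY_FILTERED: 0,
        STATUS_LIST_FILTERED: 0,
        STATUS_UNIQUE: 0,
        STATUS_AMBIGUOUS: 0,
        STATUS_UNMAPPED: 0,
    }
    by_label: dict[str, int] = {}
    results: list[MappingResult] = []
    for read in reads:
        outcome = map_read(read, refset, config)
        counts["total"] += 1
        counts[outcome.status] += 1
        if outcome.result is not None:
            results.append(outcome.result)
            label = outcome.result.reference_label
            by_label[label] = by_label.get(label, 0) + 1
    report = dict(counts)
    report["unique_by_label"] = by_label
    return results, report
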