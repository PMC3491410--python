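"""SOLiD color-space bisulfite read mapping.

Color reads cannot be C->T converted before mapping (the nucleotides are
unknown and a single color error would cascade through a naive decoding),
so the pipeline works directly in color space:

1. count hits of the read's color string (primer-transition color excluded)
   in the two valid orientations on a pair of converted color references —
   the directional SOLiD protocol sequences only the original
   bisulfite-treated strands, so matches corresponding to
   reverse-complemented reads are invalid;
2. list filtering (color cutoff: a list is dropped when some mismatch level
   holds strictly more than 10 hits) at an enlarged mismatch budget
   (default 4), since one bisulfite conversion appears as two adjacent
   color mismatches against the fully converted reference;
3. mismatch stage filtering: candidates are bucket-grouped by color-space
   mismatch count and examined in ascending order; each examined hit is
   decoded to bases by dynamic programming against the original genome
   (bisulfite-induced mismatches cost zero when the reference is C and the
   decoded base is T) and its non-bisulfite base mismatches recounted; the
   first hit that is unique at the strictly minimal base-mismatch count
   among all hits examined so far is reported (capped at 3 non-BS
   mismatches);
4. dual-index mapping: the fully converted references (budget M1) model
   hypomethylated DNA and are scanned first; reads without a unique hit
   there are rescanned on the non-CpG converted references (budget M2),
   which retain CpG cytosines and so model CpG-methylated DNA.  Hits are
   labeled with the reference type they came from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ColorRead, RunConfig
from .reference_prep import (
    C,
    FULL,
    NONCPG,
    PLUS,
    RC,
    T,
    ReferenceSet,
    _BASE_LUT,
    codes_to_seq,
    colors_to_codes,
    reverse_complement,
    sanitize,
    sanitize_colors,
    seq_to_codes,
)
from .base_mapper import (
    MapOutcome,
    MappingResult,
    STATUS_AMBIGUOUS,
    STATUS_LIST_FILTERED,
    STATUS_UNIQUE,
    STATUS_UNMAPPED,
)
from .search_engine import Hit, HitList, find_hits

ORIENT_COLOR_PLUS = "colors_vs_plus"
ORIENT_COLOR_RC = "colors_vs_rc"

_XOR44 = np.arange(4, dtype=np.uint8)[:, None] ^ np.arange(4, dtype=np.uint8)[None, :]


@dataclass
class DecodedRead:
    """Most-likely base translation of a color read against a reference window.

    ``full_bases`` covers every color transition (length L for L colors);
    ``bases`` drops the final base, whose single flanking color cannot
    distinguish a substitution from a color error.
    """

    source: ColorRead
    bases: str
    full_bases: str
    dp_cost: int


@dataclass
class StagedHits:
    """Candidate hits bucket-sorted by ascending color-mismatch count."""

    groups: dict[int, list[tuple[str, Hit]]]  # (orientation, hit)


def _color_query(cread: ColorRead) -> np.ndarray:
    """Searchable color query: sanitized colors minus the primer transition."""
    return colors_to_codes(sanitize_colors(cread.colors))[1:]


def count_color_orientations(
    cread: ColorRead, refset: ReferenceSet, k: int, conversion: str = FULL
) -> list[HitList]:
    """Hit counts in the two valid orientations on one converted color genome.

    A plus-strand read matches the plus reference forward; a minus-strand
    read matches the reverse-complement reference forward (conversion is
    applied per strand before encoding).  The two reverse-complement-read
    combinations are invalid under the directional protocol and are never
    searched here; they are only probed by :func:`estimate_noise`.
    """
    query = _color_query(cread)
    return [
        HitList(ORIENT_COLOR_PLUS, find_hits(refset.get(conversion, PLUS), query, k)),
        HitList(ORIENT_COLOR_RC, find_hits(refset.get(conversion, RC), query, k)),
    ]


def color_list_filter(hitlists: list[HitList], cutoff: int = 10) -> list[HitList]:
    """Drop lists in which some mismatch level holds strictly more than
    ``cutoff`` hits."""
    return [hl for hl in hitlists if hl.max_group_size() <= cutoff]


def decode_color_read(cread: ColorRead, ref_window: str) -> DecodedRead:
    """Optimal DP conversion of a color read to bases against a genome window.

    ``ref_window`` is the ORIGINAL (unconverted) genome at the candidate
    locus, in alignment orientation, length >= the number of colors L.  The
    DP chooses one base per color transition minimizing transition cost
    (0 when the color matches the di-base code of the adjacent base pair,
    else 1) plus emission cost (0 when the base equals the reference base,
    or when the reference is C and the base is T — a bisulfite conversion —
    else 1).  The primer base anchors the first transition.  Cost ties are
    broken toward reference-matching bases, so an isolated color mismatch
    is resolved as a sequencing error rather than a substitution.
    """
    colors = colors_to_codes(sanitize_colors(cread.colors))
    L = colors.size
    if len(ref_window) < L:
        raise ValueError("reference window shorter than the read")
    w = seq_to_codes(sanitize(ref_window[:L]))
    scale = 4 * (L + 1)  # dominates the accumulated tie-break term (< L)
    emis = np.ones((L, 4), dtype=np.int64)
    emis[np.arange(L), w] = 0
    emis[w == C, T] = 0  # bisulfite-induced mismatch costs nothing
    pref = np.ones((L, 4), dtype=np.int64)
    pref[np.arange(L), w] = 0
    primer = int(_BASE_LUT[ord(cread.primer_base)])
    cost = (
        scale
        * (
            (primer ^ np.arange(4) != colors[0]).astype(np.int64)
            + emis[0]
        )
        + pref[0]
    )
    back = np.zeros((L, 4), dtype=np.int8)
    for i in range(1, L):
        trans = (_XOR44 != colors[i]).astype(np.int64)  # (prev base, base)
        total = cost[:, None] + scale * trans
        back[i] = np.argmin(total, axis=0)
        cost = total[back[i], np.arange(4)] + scale * emis[i] + pref[i]
    b = int(np.argmin(cost))
    dp_cost = int(cost[b]) // scale
    decoded = np.empty(L, dtype=np.uint8)
    for i in range(L - 1, -1, -1):
        decoded[i] = b
        b = int(back[i, b])
    full = codes_to_seq(decoded)
    return DecodedRead(cread, full[:-1], full, dp_cost)


def color_mismatch_count(
    cread: ColorRead, decoded: DecodedRead, ref_window: str
) -> int:
    """Non-bisulfite base mismatches of a decoded color read.

    A decoded base is charged one mismatch when both of its flanking colors
    mismatch the reference colors AND the base itself mismatches the
    reference non-bisulfitically (reference C with decoded T is free).  A
    single mismatching color — a sequencing error — is never charged.  The
    first base, whose left flank is the non-genomic primer transition, and
    the final base, whose right flanking color does not exist, are charged
    on their single available flank.
    """
    colors = colors_to_codes(sanitize_colors(cread.colors))
    L = colors.size
    w = seq_to_codes(sanitize(ref_window[:L]))
    d = seq_to_codes(decoded.full_bases)
    ref_colors = w[:-1] ^ w[1:]  # pairs with read colors[1:]
    cmm = np.zeros(L, dtype=bool)
    cmm[1:] = colors[1:] != ref_colors
    non_bs = (d != w) & ~((w == C) & (d == T))
    flank = np.empty(L, dtype=bool)
    flank[0] = cmm[1]
    flank[1 : L - 1] = cmm[1 : L - 1] & cmm[2:L]
    flank[L - 1] = cmm[L - 1]
    return int((non_bs & flank).sum())


@dataclass
class _ColorCandidate:
    chrom: str
    pos: int  # plus-strand leftmost coordinate of the aligned window
    strand: str
    color_mm: int
    base_mm: int
    decoded: DecodedRead
    window: str  # alignment-orientation window (original genome)


def _window_for_hit(
    refset: ReferenceSet, orientation: str, hit: Hit, n_colors: int
) -> tuple[int, str, str]:
    """(plus pos, strand, alignment-orientation original-genome window)."""
    genome = refset.genome
    chrom_len = len(genome[hit.chrom])
    if orientation == ORIENT_COLOR_PLUS:
        pos = hit.pos
        window = genome[hit.chrom][pos : pos + n_colors]
        return pos, "+", window
    pos = chrom_len - hit.pos - n_colors
    window = reverse_complement(genome[hit.chrom][pos : pos + n_colors])
    return pos, "-", window


def stage_hits(hitlists: list[HitList]) -> StagedHits:
    """Bucket-sort retained hits from both orientations by color mismatches."""
    groups: dict[int, list[tuple[str, Hit]]] = {}
    for hl in hitlists:
        for level, hits in hl.groups.items():
            groups.setdefault(level, []).extend((hl.orientation, h) for h in hits)
    return StagedHits(dict(sorted(groups.items())))


def mismatch_stage_filter(
    staged: StagedHits, refset: ReferenceSet, cread: ColorRead, config: RunConfig
) -> _ColorCandidate | None:
    """Examine color-mismatch groups in ascending order; report the first hit
    unique at the strictly minimal base-mismatch count among all hits
    examined so far.  Hits in later groups are never decoded once a unique
    winner exists.  A winner with more than the resultant mismatch cap
    (default 3 non-BS mismatches) is rejected."""
    L = len(cread.colors)
    examined: list[_ColorCandidate] = []
    for level in sorted(staged.groups):
        for orientation, hit in staged.groups[level]:
            pos, strand, window = _window_for_hit(refset, orientation, hit, L)
            decoded = decode_color_read(cread, window)
            base_mm = color_mismatch_count(cread, decoded, window)
            examined.append(
                _ColorCandidate(hit.chrom, pos, strand, level, base_mm, decoded, window)
            )
        best = min(c.base_mm for c in examined)
        winners = [c for c in examined if c.base_mm == best]
        if len(winners) == 1:
            winner = winners[0]
            if winner.base_mm > config.max_resultant_mismatches:
                return None
            return winner
    return None


def _bs_count(decoded_full: str, window: str) -> int:
    d = seq_to_codes(decoded_full)
    w = seq_to_codes(sanitize(window[: len(decoded_full)]))
    return int(((w == C) & (d == T)).sum())


def _result_from_candidate(
    cread: ColorRead, cand: _ColorCandidate, label: str
) -> MappingResult:
    full = cand.decoded.full_bases
    aligned_plus = full if cand.strand == "+" else reverse_complement(full)
    return MappingResult(
        read_id=cread.read_id,
        chrom=cand.chrom,
        pos=cand.pos,
        strand=cand.strand,
        non_bs_mismatches=cand.base_mm,
        bs_mismatches=_bs_count(full, cand.window),
        reference_label=label,
        aligned_seq=aligned_plus,
        space="color",
        color_mismatches=cand.color_mm,
    )


def _pipeline_on_conversion(
    cread: ColorRead, refset: ReferenceSet, conversion: str, k: int, config: RunConfig
) -> tuple[str, _ColorCandidate | None]:
    hitlists = count_color_orientations(cread, refset, k, conversion)
    any_hits = any(hl.total() for hl in hitlists)
    retained = color_list_filter(hitlists, config.list_cutoff_color)
    if not any_hits:
        return STATUS_UNMAPPED, None
    if not any(hl.total() for hl in retained):
        return STATUS_LIST_FILTERED, None
    cand = mismatch_stage_filter(stage_hits(retained), refset, cread, config)
    if cand is None:
        return STATUS_AMBIGUOUS, None
    return STATUS_UNIQUE, cand


def dual_index_map(
    cread: ColorRead, refset: ReferenceSet, M1: int, M2: int, config: RunConfig
) -> MapOutcome:
    """Scan the fully converted references at budget M1; when that yields no
    unique hit, rescan the non-CpG converted references at budget M2.  The
    result is labeled with the reference type that produced it."""
    status1, cand = _pipeline_on_conversion(cread, refset, FULL, M1, config)
    if cand is not None:
        return MapOutcome(STATUS_UNIQUE, _result_from_candidate(cread, cand, FULL))
    status2, cand = _pipeline_on_conversion(cread, refset, NONCPG, M2, config)
    if cand is not None:
        return MapOutcome(STATUS_UNIQUE, _result_from_candidate(cread, cand, NONCPG))
    for status in (STATUS_AMBIGUOUS, STATUS_LIST_FILTERED):
        if status in (status1, status2):
            return MapOutcome(status)
    return MapOutcome(STATUS_UNMAPPED)


def map_color_read(
    cread: ColorRead, refset: ReferenceSet, config: RunConfig
) -> MapOutcome:
    """Map one color read under the configured mode's (M1, M2) scan plan."""
    last = MapOutcome(STATUS_UNMAPPED)
    for m1, m2 in config.scan_plan():
        outcome = dual_index_map(cread, refset, m1, m2, config)
        if outcome.status == STATUS_UNIQUE:
            return outcome
        if outcome.status == STATUS_AMBIGUOUS or (
            outcome.status == STATUS_LIST_FILTERED and last.status == STATUS_UNMAPPED
        ):
            last = outcome
    return last


def map_color_reads(
    creads, refset: ReferenceSet, config: RunConfig
) -> tuple[list[MappingResult], dict]:
    counts = {
        "total": 0,
        STATUS_LIST_FILTERED: 0,
        STATUS_UNIQUE: 0,
        STATUS_AMBIGUOUS: 0,
        STATUS_UNMAPPED: 0,
    }
    by_label: dict[str, int] = {}
    results: list[MappingResult] = []
    for cread in creads:
        outcome = map_color_read(cread, refset, config)
        counts["total"] += 1
        counts[outcome.status] += 1
        if outcome.result is not None:
            results.append(outcome.result)
            label = outcome.result.reference_label
            by_label[label] = by_label.get(label, 0) + 1
    report = dict(counts)
    report["unique_by_label"] = by_label
    return results, report


@dataclass
class NoiseEstimate:
    err: float | None  # reverse-complement mappings / mappings
    n_mapped: int
    n_marked: int


def _invalid_orientation_best(
    cread: ColorRead, refset: ReferenceSet, k: int
) -> tuple[int | None, bool]:
    """Best hit of the read in the two INVALID (reverse-complement read)
    orientations: (minimal color mismatch count, unique at that minimum)."""
    query = _color_query(cread)[::-1].copy()
    # mirror the dual-index order: the fully converted references first,
    # the non-CpG converted ones only when those yield nothing
    for conversion in (FULL, NONCPG):
        best: int | None = None
        n_at_best = 0
        for orientation in (PLUS, RC):
            groups = find_hits(refset.get(conversion, orientation), query, k)
            for level, hits in groups.items():
                if best is None or level < best:
                    best, n_at_best = level, len(hits)
                elif level == best:
                    n_at_best += len(hits)
        if best is not None:
            return best, n_at_best == 1
    return None, False


def estimate_noise(
    creads, refset: ReferenceSet, config: RunConfig
) -> NoiseEstimate:
    """Directionality-based noise estimate.

    The directional protocol cannot produce reverse-complement reads, so any
    read whose best alignment lies in an invalid orientation is noise.  Each
    read is mapped in the valid orientations; the invalid orientations are
    then probed, and the read is marked when a strictly lower-mismatch hit
    exists there (or when it maps uniquely ONLY in the invalid
    orientations).  err = marked reverse-complement mappings / all mappings;
    undefined (None) when nothing maps.
    """
    k = max(m for pair in config.scan_plan() for m in pair)
    n_mapped = 0
    n_marked = 0
    for cread in creads:
        outcome = map_color_read(cread, refset, config)
        inv_best, inv_unique = _invalid_orientation_best(cread, refset, k)
        if outcome.result is not None:
            n_mapped += 1
            if inv_best is not None and inv_best < (
                outcome.result.color_mismatches or 0
            ):
                n_marked += 1
        elif inv_best is not None and inv_unique:
            n_mapped += 1
            n_marked += 1
    err = (n_marked / n_mapped) if n_mapped else None
    return NoiseEstimate(err, n_mapped, n_marked)
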