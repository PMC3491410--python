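"""Color-space pipeline: DP decoding, the bisulfite-aware color mismatch
count, list and stage filtering, dual-index mapping and noise estimation."""

import numpy as np
import pytest

from methmap import (
    ColorRead,
    RunConfig,
    color_list_filter,
    color_mismatch_count,
    decode_color,
    decode_color_read,
    encode_color,
    fully_convert,
    map_color_read,
    map_color_reads,
    noncpg_convert,
    reverse_complement,
    simulate_color_reads,
    simulate_genome,
    estimate_noise,
)
from methmap.base_mapper import STATUS_UNIQUE
from methmap.color_mapper import (
    ORIENT_COLOR_PLUS,
    ORIENT_COLOR_RC,
    _invalid_orientation_best,
    count_color_orientations,
)
from methmap.reference_prep import FULL, NONCPG, Genome
from methmap import build_reference_set
from methmap.search_engine import Hit, HitList
from .oracles import color_of, encode, min_decoding_cost


def _cread(bases: str, primer: str = "T") -> ColorRead:
    return ColorRead("r", primer, encode(primer + bases))


def test_decode_bisulfite_site_costs_zero():
    # reference ACG, read ATG (bisulfite conversion at the C): two adjacent
    # color mismatches, but the decode charges nothing for the C->T site
    decoded = decode_color_read(_cread("ATG"), "ACG")
    assert decoded.full_bases == "ATG"
    assert decoded.dp_cost == 0
    assert color_mismatch_count(_cread("ATG"), decoded, "ACG") == 0


def test_decode_error_free_unmethylated_read():
    window = "TAGGATTCAG"
    read = fully_convert(window)
    decoded = decode_color_read(_cread(read), window)
    assert decoded.full_bases == read
    assert decoded.dp_cost == 0
    assert len(decoded.bases) == len(read) - 1


def test_decode_single_isolated_color_error_recovers_reference():
    window = "TAGGATTCAG"
    colors = list(encode("T" + window))
    colors[4] = {"0": "1", "1": "0", "2": "3", "3": "2"}[colors[4]]
    cread = ColorRead("r", "T", "".join(colors))
    decoded = decode_color_read(cread, window)
    assert decoded.full_bases == window
    assert decoded.dp_cost == 1
    assert color_mismatch_count(cread, decoded, window) == 0


def test_decode_matches_exhaustive_minimum():
    rng = np.random.default_rng(5)
    bases = "ACGT"
    for _ in range(120):
        L = int(rng.integers(2, 7))
        window = "".join(bases[i] for i in rng.integers(0, 4, L))
        colors = "".join("0123"[i] for i in rng.integers(0, 4, L))
        primer = bases[int(rng.integers(0, 4))]
        cread = ColorRead("r", primer, colors)
        decoded = decode_color_read(cread, window)
        expected = min_decoding_cost(primer, colors, window)
        assert decoded.dp_cost == expected
        # the reported translation itself achieves the optimum
        from .oracles import decoding_cost

        assert decoding_cost(primer, colors, window, decoded.full_bases) == expected


def test_decode_window_shorter_than_read_rejected():
    with pytest.raises(ValueError):
        decode_color_read(_cread("ACGT"), "AC")


def test_color_mismatch_count_snp_charges_one():
    # a true substitution (ref A -> read G) flips both flanking colors and
    # the decoded base mismatches non-bisulfitically
    window = "TAGAATTCAG"
    read = window[:4] + "G" + window[5:]
    cread = _cread(read)
    decoded = decode_color_read(cread, window)
    assert decoded.full_bases == read
    assert color_mismatch_count(cread, decoded, window) == 1


def test_color_mismatch_count_exact_read_is_zero():
    window = "TAGGATTCAG"
    cread = _cread(window)
    decoded = decode_color_read(cread, window)
    assert color_mismatch_count(cread, decoded, window) == 0


def _mk_color_lists(sizes, level=1):
    out = []
    for name, size in zip((ORIENT_COLOR_PLUS, ORIENT_COLOR_RC), sizes):
        groups = {level: [Hit("c", p, level) for p in range(size)]} if size else {}
        out.append(HitList(name, groups))
    return out


def test_color_list_filter_strictly_more_than_cutoff():
    retained = color_list_filter(_mk_color_lists((3, 11)), cutoff=10)
    assert [hl.orientation for hl in retained] == [ORIENT_COLOR_PLUS]
    assert len(color_list_filter(_mk_color_lists((10, 10)), cutoff=10)) == 2
    assert sum(hl.total() for hl in color_list_filter(_mk_color_lists((0, 0)))) == 0


@pytest.fixture(scope="module")
def color_genome():
    return simulate_genome(20000, gc=0.4, seed=7)


@pytest.fixture(scope="module")
def crefset(color_genome):
    return build_reference_set(color_genome, "color")


def test_valid_orientations_cover_both_strands(color_genome, crefset):
    window = color_genome["chr1"][800:850]
    plus_read = _cread(fully_convert(window))
    lists = {hl.orientation: hl for hl in count_color_orientations(plus_read, crefset, 0)}
    assert [h.pos for h in lists[ORIENT_COLOR_PLUS].groups[0]] == [800]
    assert lists[ORIENT_COLOR_RC].total() == 0

    minus_read = _cread(fully_convert(reverse_complement(window)))
    lists = {hl.orientation: hl for hl in count_color_orientations(minus_read, crefset, 0)}
    assert lists[ORIENT_COLOR_PLUS].total() == 0
    assert lists[ORIENT_COLOR_RC].total() == 1


def test_empty_chromosome_yields_zero_counts():
    genome = Genome({"c": "A"})
    refset = build_reference_set(genome, "color")
    lists = count_color_orientations(_cread("ATGTTG"), refset, 2)
    assert all(hl.total() == 0 for hl in lists)


def test_unmethylated_read_resolves_on_full_reference(color_genome, crefset):
    window = color_genome["chr1"][800:850]
    outcome = map_color_read(_cread(fully_convert(window)), crefset, RunConfig())
    assert outcome.status == STATUS_UNIQUE
    assert outcome.result.reference_label == FULL
    assert (outcome.result.pos, outcome.result.strand) == (800, "+")


def _cpg_methylated_read(genome, pos, length):
    """Bases of a read retaining exactly the CpG cytosines (genomic context)."""
    return noncpg_convert(genome["chr1"][pos : pos + length + 1])[:length]


def test_cpg_dense_methylated_read_falls_through_to_noncpg(color_genome, crefset):
    # find a window with >= 3 CpGs: on the FULL reference each retained CpG C
    # costs two color mismatches, exceeding M1=4
    seq = color_genome["chr1"]
    pos = next(
        p for p in range(0, len(seq) - 51) if seq[p : p + 51].count("CG") >= 3
    )
    read = _cpg_methylated_read(color_genome, pos, 50)
    outcome = map_color_read(_cread(read), crefset, RunConfig())
    assert outcome.status == STATUS_UNIQUE
    assert outcome.result.reference_label == NONCPG
    assert (outcome.result.pos, outcome.result.strand) == (pos, "+")
    assert outcome.result.non_bs_mismatches == 0


def test_zero_m1_with_color_error_falls_through_to_noncpg(color_genome, crefset):
    # a CpG-free window: the NONCPG and FULL texts coincide there, so the
    # single color error is simply beyond the M1=0 budget
    seq = color_genome["chr1"]
    pos = next(
        p for p in range(0, len(seq) - 51) if "CG" not in seq[p : p + 51]
    )
    colors = list(encode("T" + fully_convert(seq[pos : pos + 50])))
    colors[20] = {"0": "1", "1": "0", "2": "3", "3": "2"}[colors[20]]
    cread = ColorRead("r", "T", "".join(colors))
    outcome = map_color_read(cread, crefset, RunConfig(M1=0, M2=3))
    assert outcome.status == STATUS_UNIQUE
    assert outcome.result.reference_label == NONCPG


def test_resultant_mismatch_cap_rejects_unique_hit(color_genome, crefset):
    window = color_genome["chr1"][900:950]
    read = window[:10] + ("G" if window[10] != "G" else "A") + window[11:]
    cread = _cread(fully_convert(read))
    ok = map_color_read(cread, crefset, RunConfig())
    assert ok.status == STATUS_UNIQUE and ok.result.non_bs_mismatches >= 1
    capped = map_color_read(cread, crefset, RunConfig(max_resultant_mismatches=0))
    assert capped.result is None


def test_single_color_error_counts_zero_base_mismatches(color_genome, crefset):
    window = color_genome["chr1"][800:850]
    colors = list(encode("T" + fully_convert(window)))
    colors[25] = {"0": "2", "1": "3", "2": "0", "3": "1"}[colors[25]]
    outcome = map_color_read(ColorRead("r", "T", "".join(colors)), crefset, RunConfig())
    assert outcome.status == STATUS_UNIQUE
    assert outcome.result.color_mismatches == 1
    assert outcome.result.non_bs_mismatches == 0


def test_mode_ordering_on_fixed_simulation(color_genome, crefset):
    creads, _ = simulate_color_reads(
        color_genome, 250, read_len=50, meth_prob=0.03, max_snps=2,
        color_error_rate=0.05, seed=23
    )
    uniques = {}
    for mode in ("fast", "default", "sensitive"):
        _, report = map_color_reads(creads, crefset, RunConfig(mode=mode))
        uniques[mode] = report[STATUS_UNIQUE]
    assert uniques["fast"] <= uniques["default"] <= uniques["sensitive"]


def test_reverse_complement_read_found_only_by_invalid_probe(color_genome, crefset):
    window = color_genome["chr1"][1200:1250]
    valid = fully_convert(window)  # an error-free plus-strand read
    rc_read = _cread(reverse_complement(valid))
    outcome = map_color_read(rc_read, crefset, RunConfig())
    assert outcome.result is None
    best, unique = _invalid_orientation_best(rc_read, crefset, 4)
    assert best == 0 and unique


def test_noise_zero_on_valid_only_reads(color_genome, crefset):
    creads, _ = simulate_color_reads(
        color_genome, 150, read_len=50, meth_prob=0.03, max_snps=0,
        color_error_rate=0.02, seed=29
    )
    est = estimate_noise(creads, crefset, RunConfig())
    assert est.n_mapped > 100
    assert est.err == 0.0


def test_full_noncpg_hit_overlap_on_partially_methylated_reads(color_genome, crefset):
    """Loci found on the fully converted and the non-CpG converted references
    coincide for reads mapped by both."""
    from methmap.color_mapper import _pipeline_on_conversion

    creads, _ = simulate_color_reads(
        color_genome, 400, read_len=50, meth_prob=0.1, max_snps=0,
        color_error_rate=0.0, seed=31
    )
    cfg = RunConfig()
    both = agree = 0
    for cread in creads:
        _, full_cand = _pipeline_on_conversion(cread, crefset, FULL, 4, cfg)
        _, non_cand = _pipeline_on_conversion(cread, crefset, NONCPG, 4, cfg)
        if full_cand is not None and non_cand is not None:
            both += 1
            if (full_cand.chrom, full_cand.pos, full_cand.strand) == (
                non_cand.chrom, non_cand.pos, non_cand.strand
            ):
                agree += 1
    assert both > 20
    assert agree / both > 0.8
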