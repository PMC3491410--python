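"""Bisulfite read simulation with known truth, and mapping evaluation.

The simulator emulates the standard whole-genome bisulfite protocols on a
random reference: reads are drawn uniformly over positions and strands;
each cytosine of a read is retained (methylated) with probability
``meth_prob``, independent of context, and otherwise written as T; a
uniform number of non-bisulfite substitutions may be injected; color reads
are then di-base encoded behind a primer base and per-color sequencing
errors applied at a uniform rate (order matters: a bisulfite conversion
flips two adjacent colors, a color error flips one).  Truth records the
exact origin of each read, so mapping recovery and accuracy are measured by
exact (chrom, pos, strand) comparison.

All randomness flows through ``numpy.random.default_rng`` on explicit
integer seeds, so a fixed seed reproduces reads byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .io_formats import BaseRead, ColorRead
from .base_mapper import MappingResult
from .reference_prep import (
    BASE_ORDER,
    C,
    Genome,
    T,
    codes_to_colors,
    codes_to_seq,
    reverse_complement,
    seq_to_codes,
)

DEFAULT_PRIMER = "T"


@dataclass
class SimTruth:
    """Ground truth for one simulated read (plus-strand, 0-based, leftmost)."""

    read_id: str
    chrom: str
    pos: int
    strand: str
    converted_positions: list[int] = field(default_factory=list)
    injected_snp_positions: list[int] = field(default_factory=list)
    injected_color_error_positions: list[int] = field(default_factory=list)


def simulate_genome(length: int, gc: float = 0.4, seed: int = 0) -> Genome:
    """A single-chromosome random genome with the requested GC fraction."""
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc) / 2.0
    p = [at, gc / 2.0, gc / 2.0, at]  # A C G T
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    return Genome({"chr1": codes_to_seq(codes)})


def _choose_windows(genome: Genome, n: int, read_len: int, rng) -> list[tuple[str, int, str]]:
    chroms = [c for c, s in genome.entries.items() if len(s) >= read_len]
    if not chroms:
        raise ValueError("read length exceeds every chromosome")
    weights = np.array(
        [len(genome[c]) - read_len + 1 for c in chroms], dtype=np.float64
    )
    weights /= weights.sum()
    chrom_idx = rng.choice(len(chroms), size=n, p=weights)
    strands = rng.integers(0, 2, size=n)
    out = []
    for i in range(n):
        chrom = chroms[int(chrom_idx[i])]
        pos = int(rng.integers(0, len(genome[chrom]) - read_len + 1))
        out.append((chrom, pos, "+" if strands[i] == 0 else "-"))
    return out


def _bisulfite_and_snps(
    window_codes: np.ndarray, meth_prob: float, max_snps: int, rng
) -> tuple[np.ndarray, list[int], list[int]]:
    """Apply uniform bisulfite conversion, then inject non-BS substitutions."""
    read = window_codes.copy()
    c_pos = np.nonzero(read == C)[0]
    converted: list[int] = []
    if c_pos.size:
        keep = rng.random(c_pos.size) < meth_prob
        converted = [int(i) for i in c_pos[~keep]]
        read[c_pos[~keep]] = T
    snps: list[int] = []
    if max_snps > 0:
        n_snps = int(rng.integers(0, max_snps + 1))  # uniform over {0..max}
        if n_snps:
            sites = rng.choice(read.size, size=n_snps, replace=False)
            for site in sorted(int(s) for s in sites):
                ref = int(window_codes[site])
                cur = int(read[site])
                # a non-BS mismatch: not the reference base, not the current
                # read base, and never ref C -> read T (that mimics conversion)
                banned = {ref, cur}
                if ref == C:
                    banned.add(T)
                choices = [b for b in range(4) if b not in banned]
                if not choices:
                    continue
                read[site] = choices[int(rng.integers(0, len(choices)))]
                snps.append(site)
    return read, converted, snps


def simulate_base_reads(
    genome: Genome,
    n: int,
    read_len: int = 75,
    meth_prob: float = 0.5,
    max_snps: int = 0,
    seed: int = 0,
) -> tuple[list[BaseRead], dict[str, SimTruth]]:
    """Simulate Illumina-style bisulfite reads with truth.

    ``meth_prob`` is the per-cytosine retention (methylation) probability,
    uniform across contexts; the bisulfite conversion rate is 1-meth_prob.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= meth_prob <= 1.0:
        raise ValueError("meth_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    reads: list[BaseRead] = []
    truths: dict[str, SimTruth] = {}
    for idx, (chrom, pos, strand) in enumerate(
        _choose_windows(genome, n, read_len, rng)
    ):
        window = genome[chrom][pos : pos + read_len]
        if strand == "-":
            window = reverse_complement(window)
        codes, converted, snps = _bisulfite_and_snps(
            seq_to_codes(window), meth_prob, max_snps, rng
        )
        read_id = f"r{idx:07d}"
        reads.append(BaseRead(read_id, codes_to_seq(codes), "I" * read_len))
        truths[read_id] = SimTruth(read_id, chrom, pos, strand, converted, snps)
    return reads, truths


def simulate_color_reads(
    genome: Genome,
    n: int,
    read_len: int = 50,
    meth_prob: float = 0.5,
    max_snps: int = 2,
    color_error_rate: float = 0.05,
    seed: int = 0,
) -> tuple[list[ColorRead], dict[str, SimTruth]]:
    """Simulate directional SOLiD bisulfite color reads with truth.

    Bisulfite conversion and substitutions are applied in base space first,
    the read is then encoded into color space behind the primer base, and
    per-color sequencing errors are injected last at ``color_error_rate``.
    Only the two valid orientations of a directional library are produced.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= meth_prob <= 1.0:
        raise ValueError("meth_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    primer_code = seq_to_codes(DEFAULT_PRIMER)[0]
    reads: list[ColorRead] = []
    truths: dict[str, SimTruth] = {}
    for idx, (chrom, pos, strand) in enumerate(
        _choose_windows(genome, n, read_len, rng)
    ):
        window = genome[chrom][pos : pos + read_len]
        if strand == "-":
            window = reverse_complement(window)
        codes, converted, snps = _bisulfite_and_snps(
            seq_to_codes(window), meth_prob, max_snps, rng
        )
        with_primer = np.concatenate(([primer_code], codes))
        colors = with_primer[:-1] ^ with_primer[1:]
        err_sites: list[int] = []
        if color_error_rate > 0:
            mask = rng.random(colors.size) < color_error_rate
            for site in np.nonzero(mask)[0]:
                colors[site] = (colors[site] + rng.integers(1, 4)) % 4
                err_sites.append(int(site))
        read_id = f"c{idx:07d}"
        reads.append(ColorRead(read_id, DEFAULT_PRIMER, codes_to_colors(colors)))
        truths[read_id] = SimTruth(
            read_id, chrom, pos, strand, converted, snps, err_sites
        )
    return reads, truths


def evaluate(
    results: Iterable[MappingResult], truths: dict[str, SimTruth]
) -> dict:
    """Recovery and accuracy of unique mappings against simulation truth.

    A result is correct iff (chrom, pos, strand) matches the truth exactly.
    recovery = unique results / total reads; accuracy = correct / unique.
    """
    results = list(results)
    n_total = len(truths)
    n_unique = len(results)
    n_correct = 0
    for r in results:
        t = truths.get(r.read_id)
        if t is not None and (r.chrom, r.pos, r.strand) == (t.chrom, t.pos, t.strand):
            n_correct += 1
    return {
        "total": n_total,
        "unique": n_unique,
        "correct": n_correct,
        "false_positives": n_unique - n_correct,
        "recovery": n_unique / n_total if n_total else 0.0,
        "accuracy": n_correct / n_unique if n_unique else None,
    }
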