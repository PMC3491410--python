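"""Per-cytosine methylation calling from unique alignments.

For every strandwise reference cytosine covered by a uniquely aligned read,
the aligned read base votes: C (conversion-protected, i.e. methylated) or
T (converted, unmethylated); any other base is treated as a sequencing
error or SNP and ignored.  On the minus strand the same comparison appears
as reference G versus read G/A after plus-strand coordinate normalization.
Contexts (CG, CHG, CHH with H in {A,C,T}) are classified from the ORIGINAL
genome, read strandwise from the cytosine.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .base_mapper import MappingResult
from .reference_prep import Genome

CONTEXTS = ("CG", "CHG", "CHH")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class MethylationCall:
    """Methylation tally for one cytosine (0-based position on its strand's
    plus-coordinate projection)."""

    chrom: str
    pos: int
    strand: str
    context: str
    n_methylated: int
    n_unmethylated: int

    @property
    def level(self) -> float | None:
        total = self.n_methylated + self.n_unmethylated
        if total == 0:
            return None
        return 100.0 * self.n_methylated / total


def classify_context(genome: Genome, chrom: str, pos: int, strand: str) -> str:
    """CG / CHG / CHH context of the cytosine at (chrom, pos, strand).

    On the minus strand the plus-coordinate base is G and the strandwise
    downstream bases run leftward, complemented.  A cytosine too close to
    the strandwise end to complete the trinucleotide is classified from the
    available bases: CG when the next base is G, else CHH.
    """
    seq = genome[chrom]
    if strand == "+":
        if seq[pos] != "C":
            raise ValueError(f"{chrom}:{pos}(+) is not a C")
        nxt = seq[pos + 1] if pos + 1 < len(seq) else None
        nxt2 = seq[pos + 2] if pos + 2 < len(seq) else None
    else:
        if seq[pos] != "G":
            raise ValueError(f"{chrom}:{pos}(-) is not a strandwise C")
        nxt = _COMPLEMENT[seq[pos - 1]] if pos - 1 >= 0 else None
        nxt2 = _COMPLEMENT[seq[pos - 2]] if pos - 2 >= 0 else None
    if nxt == "G":
        return "CG"
    if nxt is None or nxt2 is None:
        return "CHH"
    return "CHG" if nxt2 == "G" else "CHH"


def call_methylation(
    alignments: Iterable[MappingResult], genome: Genome
) -> list[MethylationCall]:
    """Tally methylated/unmethylated read bases over every covered cytosine.

    Only unique alignments should be supplied.  Reference positions that
    originally held an ambiguous base (sanitized to A) are excluded.
    """
    tallies: dict[tuple[str, int, str], list[int]] = {}
    for aln in alignments:
        seq = genome[aln.chrom]
        amb = genome.ambiguous.get(aln.chrom, frozenset())
        start = aln.pos
        if aln.strand == "+":
            ref_c, meth_base, unmeth_base = "C", "C", "T"
        else:
            ref_c, meth_base, unmeth_base = "G", "G", "A"
        for i, read_base in enumerate(aln.aligned_seq):
            pos = start + i
            if seq[pos] != ref_c or pos in amb:
                continue
            if read_base == meth_base:
                bucket = 0
            elif read_base == unmeth_base:
                bucket = 1
            else:
                continue
            key = (aln.chrom, pos, aln.strand)
            t = tallies.get(key)
            if t is None:
                t = [0, 0]
                tallies[key] = t
            t[bucket] += 1
    calls = []
    for (chrom, pos, strand), (n_meth, n_unmeth) in sorted(tallies.items()):
        context = classify_context(genome, chrom, pos, strand)
        calls.append(MethylationCall(chrom, pos, strand, context, n_meth, n_unmeth))
    return calls


def level_by_context(calls: Iterable[MethylationCall]) -> dict[str, float | None]:
    """Percent methylation per context: 100 * sum(meth) / sum(meth + unmeth).

    A context with no covered cytosines reports None.
    """
    meth = {ctx: 0 for ctx in CONTEXTS}
    total = {ctx: 0 for ctx in CONTEXTS}
    for call in calls:
        meth[call.context] += call.n_methylated
        total[call.context] += call.n_methylated + call.n_unmethylated
    return {
        ctx: (100.0 * meth[ctx] / total[ctx]) if total[ctx] else None
        for ctx in CONTEXTS
    }


def write_methylation(calls: Iterable[MethylationCall], path: str | Path) -> None:
    """BED-like TSV: chrom, 0-based pos, strand, context, n_meth, n_unmeth, level."""
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tstrand\tcontext\tn_methylated\tn_unmethylated\tlevel\n")
        for c in calls:
            level = "NA" if c.level is None else f"{c.level:.4f}"
            fh.write(
                f"{c.chrom}\t{c.pos}\t{c.strand}\t{c.context}\t"
                f"{c.n_methylated}\t{c.n_unmethylated}\t{level}\n"
            )
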