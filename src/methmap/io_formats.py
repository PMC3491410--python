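"""Readers and writers for the formats the pipeline touches.

FASTA references and FASTQ base reads go through Biopython; CSFASTA color
reads (a primer base followed by color digits, optionally with a parallel
.qual file) use a small parser since no standard library covers them.
Alignments are written as a SAM-flavoured TSV: positions are 1-based in
files (SAM convention) while every internal coordinate is 0-based.
Quality strings are parsed and carried but unused by the algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Iterable, TextIO

from Bio import SeqIO

from .reference_prep import Genome

PRIMER_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass
class BaseRead:
    """A base-space sequencing read."""

    read_id: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise FormatError(f"read {self.read_id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise FormatError(
                f"read {self.read_id!r}: quality length != sequence length"
            )


@dataclass
class ColorRead:
    """A SOLiD color-space read: a primer base plus color digits.

    ``colors`` may contain ambiguity codes (e.g. '.'); they are sanitized to
    '0' at mapping time.  The first color is the primer transition.
    """

    read_id: str
    primer_base: str
    colors: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if self.primer_base not in PRIMER_BASES:
            raise FormatError(
                f"read {self.read_id!r}: primer base {self.primer_base!r} not in A/C/G/T"
            )
        if len(self.colors) < 2:
            raise FormatError(f"read {self.read_id!r}: fewer than 2 colors")


MODES = ("fast", "default", "sensitive")


@dataclass
class RunConfig:
    """Tunable mapping parameters with their pipeline defaults.

    k_base          mismatch budget on the converted genome for base reads
                    (None: 2 for reads <= 51 bp, else 3)
    primary_color_k mismatch budget for the primary color-space scan
    list_cutoff_base   a base-space orientation list is discarded when some
                       mismatch level holds >= this many hits
    list_cutoff_color  a color-space list is discarded when some level holds
                       strictly more than this many hits
    entropy_cutoff  reads with normalized Shannon entropy below this are
                    discarded as low-complexity
    M1, M2          color-space scan budgets on the fully converted and the
                    non-CpG converted references (each capped at 5)
    mode            fast | default | sensitive (sets the (M1, M2) scan plan)
    max_resultant_mismatches  cap on non-bisulfite mismatches of a reported
                    unique color-space hit
    """

    k_base: int | None = None
    primary_color_k: int = 4
    list_cutoff_base: int = 40
    list_cutoff_color: int = 10
    entropy_cutoff: float = 0.25
    M1: int = 4
    M2: int = 4
    mode: str = "default"
    max_resultant_mismatches: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.M1 <= 5 and 0 <= self.M2 <= 5):
            raise ValueError("M1 and M2 must be in 0..5")
        if self.list_cutoff_base <= 0 or self.list_cutoff_color <= 0:
            raise ValueError("list cutoffs must be positive")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    def scan_plan(self) -> list[tuple[int, int]]:
        """(M1, M2) pairs tried in order for color-space mapping."""
        if self.mode == "fast":
            return [(0, 3), (3, 0)]
        if self.mode == "sensitive":
            return [(5, 5)]
        return [(self.M1, self.M2)]

    def resolve_k_base(self, read_len: int) -> int:
        if self.k_base is not None:
            return self.k_base
        return 2 if read_len <= 51 else 3

    def as_dict(self) -> dict:
        return {
            "k_base": self.k_base,
            "primary_color_k": self.primary_color_k,
            "list_cutoff_base": self.list_cutoff_base,
            "list_cutoff_color": self.list_cutoff_color,
            "entropy_cutoff": self.entropy_cutoff,
            "M1": self.M1,
            "M2": self.M2,
            "mode": self.mode,
            "max_resultant_mismatches": self.max_resultant_mismatches,
            "seed": self.seed,
        }


def read_fasta(path: str | Path) -> Genome:
    """Load a FASTA reference; sequences are uppercased and sanitized, with
    the positions of ambiguous letters recorded for the methylation caller."""
    raw: dict[str, str] = {}
    try:
        for record in SeqIO.parse(str(path), "fasta"):
            seq = str(record.seq)
            if not record.id:
                raise FormatError(f"{path}: FASTA record with empty header")
            if not seq:
                raise FormatError(f"{path}: record {record.id!r} has empty sequence")
            if record.id in raw:
                raise FormatError(f"{path}: duplicate record {record.id!r}")
            raw[record.id] = seq
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if not raw:
        raise FormatError(f"{path}: no FASTA records")
    return Genome.from_raw(raw)


def read_fastq(path: str | Path) -> Iterator[BaseRead]:
    """Stream 4-line FASTQ records in file order."""
    it = SeqIO.parse(str(path), "fastq")
    i = 0
    while True:
        try:
            record = next(it)
        except StopIteration:
            return
        except ValueError as exc:
            raise FormatError(f"{path}: record {i}: {exc}") from exc
        qual = "".join(
            chr(q + 33) for q in record.letter_annotations["phred_quality"]
        )
        yield BaseRead(record.id, str(record.seq).upper(), qual)
        i += 1


def _read_qual_file(path: str | Path) -> dict[str, str]:
    quals: dict[str, str] = {}
    name = None
    for line in open(path):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            name = line[1:].split()[0]
        elif name is not None:
            quals[name] = line
            name = None
    return quals


def read_csfasta(
    path: str | Path, qual_path: str | Path | None = None
) -> Iterator[ColorRead]:
    """Stream CSFASTA records (``>id`` then ``<primer base><color digits>``)."""
    quals = _read_qual_file(qual_path) if qual_path is not None else {}
    name = None
    i = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                if name is not None:
                    raise FormatError(f"{path}: record {i}: header without sequence")
                name = line[1:].split()[0]
                continue
            if name is None:
                raise FormatError(f"{path}: record {i}: sequence without header")
            if line[0] not in PRIMER_BASES:
                raise FormatError(
                    f"{path}: record {i} ({name!r}): first character {line[0]!r} "
                    "is not a primer base"
                )
            yield ColorRead(name, line[0], line[1:], quals.get(name))
            name = None
            i += 1
    if name is not None:
        raise FormatError(f"{path}: record {i}: header without sequence")


_ALIGNMENT_COLUMNS = (
    "read_id",
    "chrom",
    "pos",
    "strand",
    "non_bs_mismatches",
    "bs_mismatches",
    "reference_label",
    "space",
    "aligned_seq",
)


def write_alignments(
    results: Iterable, path: str | Path, config: RunConfig | None = None
) -> None:
    """Write unique alignments as a SAM-flavoured TSV (1-based positions).

    ``aligned_seq`` is the read oriented to the plus strand of the original
    genome (for color reads, the decoded base sequence); the reference label
    records which converted reference produced the hit.
    """
    with open(path, "w") as fh:
        fh.write("#methmap\talignments\n")
        if config is not None:
            pairs = "\t".join(f"{k}={v}" for k, v in config.as_dict().items())
            fh.write(f"#config\t{pairs}\n")
        fh.write("#columns\t" + "\t".join(_ALIGNMENT_COLUMNS) + "\n")
        for r in results:
            fh.write(
                f"{r.read_id}\t{r.chrom}\t{r.pos + 1}\t{r.strand}\t"
                f"{r.non_bs_mismatches}\t{r.bs_mismatches}\t{r.reference_label}\t"
                f"{r.space}\t{r.aligned_seq}\n"
            )


def read_alignments(path: str | Path) -> list:
    """Re-read an alignment TSV into MappingResult objects (round-trip)."""
    from .base_mapper import MappingResult

    out = []
    for line in open(path):
        if line.startswith("#") or not line.strip():
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) != len(_ALIGNMENT_COLUMNS):
            raise FormatError(f"{path}: bad alignment line: {line!r}")
        out.append(
            MappingResult(
                read_id=f[0],
                chrom=f[1],
                pos=int(f[2]) - 1,
                strand=f[3],
                non_bs_mismatches=int(f[4]),
                bs_mismatches=int(f[5]),
                reference_label=f[6],
                space=f[7],
                aligned_seq=f[8],
            )
        )
    return out
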