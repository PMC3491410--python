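"""Reference preparation for bisulfite mapping.

Bisulfite treatment converts unmethylated cytosine to uracil, which is read
as thymine after PCR.  Because the two genomic strands are no longer
complementary after an in-silico C->T conversion, a separate converted
reference is required per strand.  This module builds:

* base space: the fully converted (every C -> T) plus-strand and
  reverse-complement references;
* color space: the fully converted and the non-CpG converted (C retained
  only in CpG dinucleotides, modelling CpG methylation) references for both
  strands, each encoded into SOLiD di-base color space.

Conversion order is fixed: reverse-complement first, then C->T conversion,
then (color space only) di-base encoding.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

# Integer base codes; the XOR of two base codes is exactly the SOLiD color
# of the di-base pair (0:{AA,CC,GG,TT} 1:{AC,CA,GT,TG} 2:{AG,GA,CT,TC}
# 3:{AT,TA,CG,GC}).
BASE_ORDER = "ACGT"
A, C, G, T = 0, 1, 2, 3

FULL = "FULL"
NONCPG = "NONCPG"
PLUS = "PLUS"
RC = "RC"
BASE_SPACE = "base"
COLOR_SPACE = "color"

_BASE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASE_ORDER):
    _BASE_LUT[ord(_b)] = _i
_COLOR_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _d in enumerate("0123"):
    _COLOR_LUT[ord(_d)] = _i
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COLOR_BYTES = np.frombuffer(b"0123", dtype=np.uint8)

_RC_TABLE = str.maketrans("ACGT", "TGCA")
_NON_BASE_RE = re.compile(r"[^ACGT]")
_NON_COLOR_RE = re.compile(r"[^0123]")
_NONCPG_RE = re.compile(r"C(?!G)")


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string as a uint8 array (A=0 C=1 G=2 T=3)."""
    arr = _BASE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() == 255:
        raise ValueError("sequence contains non-A/C/G/T characters")
    return arr


def codes_to_seq(codes: np.ndarray) -> str:
    return _BASE_BYTES[codes].tobytes().decode("ascii")


def colors_to_codes(colors: str) -> np.ndarray:
    arr = _COLOR_LUT[np.frombuffer(colors.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() == 255:
        raise ValueError("color string contains non-0/1/2/3 characters")
    return arr


def codes_to_colors(codes: np.ndarray) -> str:
    return _COLOR_BYTES[codes].tobytes().decode("ascii")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


def sanitize(seq: str) -> str:
    """Replace every non-A/C/G/T symbol by A (applied to references and base reads)."""
    return _NON_BASE_RE.sub("A", seq.upper())


def sanitize_colors(colors: str) -> str:
    """Replace every non-{0,1,2,3} symbol (ambiguity codes such as '.') by 0."""
    return _NON_COLOR_RE.sub("0", colors)


def fully_convert(seq: str) -> str:
    """Bisulfite-convert in silico: every C becomes T (idempotent)."""
    return seq.replace("C", "T")


def noncpg_convert(seq: str) -> str:
    """Convert C -> T except when the C is immediately followed by G.

    Models a genome whose CpG cytosines are methylated (protected) while all
    other cytosines are converted.  A trailing C (no following base) is
    converted.
    """
    return _NONCPG_RE.sub("T", seq)


def encode_color(seq: str) -> str:
    """SOLiD di-base encoding: one color digit per adjacent base pair."""
    if len(seq) < 2:
        raise ValueError("color encoding requires a sequence of length >= 2")
    codes = seq_to_codes(seq)
    return codes_to_colors(codes[:-1] ^ codes[1:])


def decode_color(primer_base: str, colors: str) -> str:
    """Naive cumulative decoding of a color string anchored on a primer base.

    Each decoded base is the XOR-accumulation of the primer code with the
    color digits; a single color error therefore corrupts every downstream
    base, which is why mapping never relies on this decoding.
    """
    p = int(_BASE_LUT[ord(primer_base)])
    if p == 255:
        raise ValueError("primer base must be one of A/C/G/T")
    cc = colors_to_codes(colors)
    run = np.bitwise_xor.accumulate(np.concatenate(([np.uint8(p)], cc)))
    return codes_to_seq(run[1:])


@dataclass
class Genome:
    """Named chromosome sequences, sanitized to the A/C/G/T alphabet.

    ``ambiguous`` records the 0-based positions that originally held a
    non-A/C/G/T symbol (replaced by A); methylation calling excludes them.
    """

    entries: dict[str, str]
    ambiguous: dict[str, frozenset[int]] = field(default_factory=dict)
    _arrays: dict[str, np.ndarray] = field(
        default_factory=dict, repr=False, compare=False
    )

    @classmethod
    def from_raw(cls, raw: dict[str, str]) -> "Genome":
        entries: dict[str, str] = {}
        amb: dict[str, frozenset[int]] = {}
        for name, seq in raw.items():
            up = seq.upper()
            mask = _BASE_LUT[np.frombuffer(up.encode("ascii"), dtype=np.uint8)] == 255
            entries[name] = sanitize(up)
            amb[name] = frozenset(int(i) for i in np.nonzero(mask)[0])
        return cls(entries, amb)

    def arr(self, chrom: str) -> np.ndarray:
        cached = self._arrays.get(chrom)
        if cached is None:
            cached = seq_to_codes(self.entries[chrom])
            self._arrays[chrom] = cached
        return cached

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.entries

    def __getitem__(self, chrom: str) -> str:
        return self.entries[chrom]

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.entries.items()}


@dataclass
class ConvertedReference:
    """One converted reference text (per strand/conversion/space) plus caches.

    The search index (a q-gram seed index, see :mod:`methmap.search_engine`)
    is built lazily per chromosome and cached on the object; ``seed_q`` is
    the q-gram length it uses.
    """

    conversion: str  # FULL | NONCPG
    orientation: str  # PLUS | RC
    space: str  # base | color
    chroms: dict[str, str]
    seed_q: int
    _arrays: dict[str, np.ndarray] = field(
        default_factory=dict, repr=False, compare=False
    )
    _indexes: dict[str, object] = field(
        default_factory=dict, repr=False, compare=False
    )

    def arr(self, chrom: str) -> np.ndarray:
        cached = self._arrays.get(chrom)
        if cached is None:
            text = self.chroms[chrom]
            cached = (
                seq_to_codes(text) if self.space == BASE_SPACE else colors_to_codes(text)
            )
            self._arrays[chrom] = cached
        return cached


@dataclass
class ReferenceSet:
    """All converted references for one genome in one space.

    base space: {FULL} x {PLUS, RC}; color space: {FULL, NONCPG} x {PLUS, RC}.
    """

    genome: Genome
    space: str
    refs: dict[tuple[str, str], ConvertedReference]

    def get(self, conversion: str, orientation: str) -> ConvertedReference:
        return self.refs[(conversion, orientation)]


def build_reference_set(
    genome: Genome, space: str = BASE_SPACE, seed_q: int | None = None
) -> ReferenceSet:
    """Build every converted reference (and color encoding) for ``genome``.

    Conversion is applied to each strand before color encoding, so a read
    simulated from the minus strand matches the RC reference directly.
    """
    if not genome.entries:
        raise ValueError("empty genome")
    if space not in (BASE_SPACE, COLOR_SPACE):
        raise ValueError(f"unknown space {space!r}")
    if seed_q is None:
        seed_q = 12 if space == BASE_SPACE else 8
    conversions = (FULL,) if space == BASE_SPACE else (FULL, NONCPG)
    refs: dict[tuple[str, str], ConvertedReference] = {}
    for conversion in conversions:
        convert = fully_convert if conversion == FULL else noncpg_convert
        for orientation in (PLUS, RC):
            texts: dict[str, str] = {}
            for name, seq in genome.entries.items():
                strand_seq = seq if orientation == PLUS else reverse_complement(seq)
                text = convert(strand_seq)
                if space == COLOR_SPACE:
                    text = encode_color(text) if len(text) >= 2 else ""
                texts[name] = text
            refs[(conversion, orientation)] = ConvertedReference(
                conversion, orientation, space, texts, seed_q
            )
    return ReferenceSet(genome, space, refs)


_INDEX_FORMAT_VERSION = 1


def save_reference_set(refset: ReferenceSet, outdir: str | Path) -> None:
    """Serialize a reference set as plain text (sanitized FASTA + metadata).

    The converted texts are deterministic functions of the genome and are
    rebuilt on load; only the genome, the ambiguity mask and the build
    parameters are stored.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "genome.fa", "w") as fh:
        for name, seq in refset.genome.entries.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    amb = {name: sorted(pos) for name, pos in refset.genome.ambiguous.items()}
    (out / "ambiguous.json").write_text(json.dumps(amb))
    q = next(iter(refset.refs.values())).seed_q
    meta = {"format_version": _INDEX_FORMAT_VERSION, "space": refset.space, "seed_q": q}
    (out / "meta.json").write_text(json.dumps(meta))


def load_reference_set(indir: str | Path) -> ReferenceSet:
    indir = Path(indir)
    meta = json.loads((indir / "meta.json").read_text())
    if meta.get("format_version") != _INDEX_FORMAT_VERSION:
        raise ValueError("unsupported index format version")
    entries: dict[str, str] = {}
    name = None
    parts: list[str] = []
    for line in (indir / "genome.fa").read_text().splitlines():
        if line.startswith(">"):
            if name is not None:
                entries[name] = "".join(parts)
            name = line[1:].split()[0]
            parts = []
        else:
            parts.append(line.strip())
    if name is not None:
        entries[name] = "".join(parts)
    amb_raw = json.loads((indir / "ambiguous.json").read_text())
    ambiguous = {n: frozenset(v) for n, v in amb_raw.items()}
    genome = Genome(entries, ambiguous)
    return build_reference_set(genome, meta["space"], meta["seed_q"])
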