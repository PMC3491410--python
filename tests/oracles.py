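"""Independent oracles for color-space operations.

These deliberately avoid the package's XOR-based encoding: the di-base code
is written out as a literal table and the decoding cost is minimized by
exhaustive enumeration over all base strings, so the oracles share no code
path with the implementation they check.
"""

import itertools

DIBASE_CODE = {
    "AA": "0", "CC": "0", "GG": "0", "TT": "0",
    "AC": "1", "CA": "1", "GT": "1", "TG": "1",
    "AG": "2", "GA": "2", "CT": "2", "TC": "2",
    "AT": "3", "TA": "3", "CG": "3", "GC": "3",
}


def color_of(a: str, b: str) -> str:
    return DIBASE_CODE[a + b]


def encode(seq: str) -> str:
    return "".join(color_of(a, b) for a, b in zip(seq, seq[1:]))


def decoding_cost(primer: str, colors: str, window: str, bases: str) -> int:
    """Transition + emission cost of one candidate base translation."""
    prev = primer
    cost = 0
    for i, b in enumerate(bases):
        if color_of(prev, b) != colors[i]:
            cost += 1
        ref = window[i]
        if not (b == ref or (ref == "C" and b == "T")):
            cost += 1
        prev = b
    return cost


def min_decoding_cost(primer: str, colors: str, window: str) -> int:
    """Exhaustive minimum over all 4^L base strings."""
    L = len(colors)
    return min(
        decoding_cost(primer, colors, window, "".join(c))
        for c in itertools.product("ACGT", repeat=L)
    )
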