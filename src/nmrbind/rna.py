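"""Terminal stem-loop detection for short RNA hairpins.

Short synthetic RNAs designed as hairpins pair their 5' and 3' ends into a
contiguous terminal stem enclosing an unpaired loop.  This module detects
that maximal terminal stem by zipping complementary ends inward — no bulges,
no internal loops, no thermodynamic folding — and predicts the number of
imino-proton resonances the hairpin should show in a 1D 1H spectrum (one
protected imino per Watson-Crick pair, two per G·U wobble).

Positions are 1-based throughout, matching conventional nucleotide numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

WATSON_CRICK = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "U"), ("U", "G")}
COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

MIN_LOOP = 3


@dataclass(frozen=True)
class RNASequence:
    """An RNA oligonucleotide over the alphabet {A, C, G, U}."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError("empty RNA sequence")
        bad = set(self.bases) - set("ACGU")
        if bad:
            raise ValueError(f"invalid RNA bases: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self) -> "RNASequence":
        rc = "".join(COMPLEMENT[b] for b in reversed(self.bases))
        return RNASequence(id=f"{self.id}_rc", bases=rc)


@dataclass
class StemLoop:
    """A terminal-stem hairpin: nested (i, j) pairs plus the unpaired loop."""

    pairs: list[tuple[int, int]] = field(default_factory=list)
    loop_range: tuple[int, int] = (0, 0)  # 1-based inclusive
    dot_bracket: str = ""
    folded: bool = True  # False when no terminal pairs could be formed

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def loop_length(self) -> int:
        lo, hi = self.loop_range
        return hi - lo + 1 if hi >= lo else 0


def fold_terminal_stem(seq: RNASequence | str, allow_gu: bool = False) -> StemLoop:
    """Zip the maximal contiguous terminal stem of a hairpin candidate.

    Pairs position k with L+1-k for k = 1, 2, ... while the bases are
    Watson-Crick complementary (or G·U when ``allow_gu``) and at least
    ``MIN_LOOP`` unpaired bases remain in the middle; stops at the first
    non-pairing position.

    Returns a flagged (``folded=False``) structure with an empty pair list
    and a full-length loop when not even the terminal bases pair.
    """
    if isinstance(seq, str):
        seq = RNASequence(id="rna", bases=seq)
    L = len(seq)
    if L < 2 * 1 + MIN_LOOP + 2:  # minimal 2-bp stem + 3-nt loop
        raise ValueError(f"sequence too short to form a stem-loop (length {L})")

    allowed = WATSON_CRICK | (WOBBLE if allow_gu else set())
    pairs: list[tuple[int, int]] = []
    k = 1
    while True:
        i, j = k, L + 1 - k
        if j - i - 1 < MIN_LOOP:
            break
        if (seq.bases[i - 1], seq.bases[j - 1]) not in allowed:
            break
        pairs.append((i, j))
        k += 1

    if pairs:
        inner_i, inner_j = pairs[-1]
        loop = (inner_i + 1, inner_j - 1)
        ss = StemLoop(pairs=pairs, loop_range=loop, folded=True)
    else:
        ss = StemLoop(pairs=[], loop_range=(1, L), folded=False)
    ss.dot_bracket = to_dot_bracket(ss, L)
    return ss


def expected_imino_count(ss: StemLoop, seq: RNASequence | str) -> int:
    """Predicted number of observable imino-proton resonances.

    Each A-U pair protects one U H3, each G-C pair one G H1, and each G·U
    wobble protects both G H1 and U H3 (two resonances).  Unpaired bases
    contribute nothing: their iminos exchange too fast with water.
    """
    if isinstance(seq, str):
        seq = RNASequence(id="rna", bases=seq)
    count = 0
    for i, j in ss.pairs:
        bp = (seq.bases[i - 1], seq.bases[j - 1])
        if bp in WATSON_CRICK:
            count += 1
        elif bp in WOBBLE:
            count += 2
        else:
            raise ValueError(f"pair ({i},{j}) {bp[0]}-{bp[1]} is not complementary")
    return count


def to_dot_bracket(ss: StemLoop, length: int) -> str:
    """Render nested pairs as dot-bracket notation."""
    chars = ["."] * length
    for i, j in ss.pairs:
        if not (1 <= i < j <= length):
            raise ValueError(f"pair ({i},{j}) outside sequence of length {length}")
    for (i1, j1) in ss.pairs:
        for (i2, j2) in ss.pairs:
            if i1 < i2 < j1 < j2:
                raise ValueError(f"crossing pairs ({i1},{j1}) and ({i2},{j2})")
    for i, j in ss.pairs:
        if chars[i - 1] != "." or chars[j - 1] != ".":
            raise ValueError(f"position reused by pair ({i},{j})")
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)
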