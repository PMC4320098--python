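"""Seven-motif metallophosphoesterase signature scanning.

Class III phosphodiesterases carry a bimetal catalytic core built from seven
short conserved motifs, D(X)H(X)nGD(X)nGNHD(X)nH(X)nGH(X)H, where (X)n is a
stretch of n arbitrary residues (a *spacer*).  The first and last spacers are
fixed at exactly one residue by the signature itself; the four inner spacers
vary between subclasses and are the classification signal.

This module locates every minimal-penalty placement of the seven elements in
a protein sequence.  The penalty of a placement is the summed distance of the
four variable spacers to their reference intervals (zero inside the interval,
one unit per residue outside), so a penalty of 0 means a textbook-spaced
architecture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InputError, IntegrityError

#: canonical 20-letter amino-acid alphabet
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: accepted but never matching a motif position (IUPAC ambiguity / rare codes)
AMBIGUOUS = "BZJUOX"

#: residue lengths of the seven signature elements
ELEMENT_LENGTHS = (1, 1, 2, 4, 1, 2, 1)

#: admissible variants of the fourth motif; GNCD marks subclass IIIC
MOTIF4_VARIANTS = ("GNHD", "GNHE", "GNCD")


@dataclass(frozen=True)
class MotifElement:
    """One element of the signature: an index 1..7 and its alternative
    residue strings (all alternatives share one length)."""

    index: int
    alternatives: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= self.index <= 7:
            raise ValueError(f"element index {self.index} outside 1..7")
        if not self.alternatives:
            raise ValueError("element needs at least one alternative")
        lengths = {len(a) for a in self.alternatives}
        if len(lengths) != 1:
            raise ValueError("alternatives of one element must share a length")
        for alt in self.alternatives:
            if not alt or any(c not in AMINO_ACIDS for c in alt):
                raise ValueError(f"pattern {alt!r} not over the 20-letter alphabet")

    @property
    def length(self) -> int:
        return len(self.alternatives[0])


@dataclass(frozen=True)
class SignatureDefinition:
    """The seven elements plus six reference spacer intervals.

    ``spacer_bounds[i]`` is the (min, max) reference range for the spacer
    between elements i+1 and i+2.  Bounds 0 and 5 are pinned to (1, 1) by the
    D(X)H and GH(X)H parts of the signature; only the four inner spacers
    contribute to the penalty.
    """

    elements: tuple[MotifElement, ...]
    spacer_bounds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.elements) != 7:
            raise ValueError("signature must have exactly 7 elements")
        if tuple(e.index for e in self.elements) != tuple(range(1, 8)):
            raise ValueError("element indices must be 1..7 in order")
        if len(self.spacer_bounds) != 6:
            raise ValueError("signature must have exactly 6 spacer intervals")
        for lo, hi in self.spacer_bounds:
            if lo > hi or lo < 0:
                raise ValueError(f"bad spacer interval ({lo}, {hi})")
        if self.spacer_bounds[0] != (1, 1) or self.spacer_bounds[5] != (1, 1):
            raise ValueError("spacers 1->2 and 6->7 are fixed at exactly 1")

    @property
    def element_lengths(self) -> tuple[int, ...]:
        return tuple(e.length for e in self.elements)

    @property
    def min_span(self) -> int:
        """Residues of the shortest conceivable placement (all spacers at
        their lower reference bound)."""
        return sum(self.element_lengths) + sum(lo for lo, _ in self.spacer_bounds)


def class_iii_signature(
    spacer_bounds: tuple[tuple[int, int], ...] | None = None,
) -> SignatureDefinition:
    """The class III PDE signature D-H-GD-GNH[D/E]|GNCD-H-GH-H.

    Default reference intervals for the four variable spacers are the
    subclass IIIA values 37-38, 28-32, 68-70 and 35-37.
    """
    if spacer_bounds is None:
        spacer_bounds = ((1, 1), (37, 38), (28, 32), (68, 70), (35, 37), (1, 1))
    elements = (
        MotifElement(1, ("D",)),
        MotifElement(2, ("H",)),
        MotifElement(3, ("GD",)),
        MotifElement(4, MOTIF4_VARIANTS),
        MotifElement(5, ("H",)),
        MotifElement(6, ("GH",)),
        MotifElement(7, ("H",)),
    )
    return SignatureDefinition(elements, tuple(spacer_bounds))


@dataclass(frozen=True)
class ArchitectureMatch:
    """A placement of the seven elements.

    positions are 0-based first-residue indices; spacers count residues
    strictly between consecutive elements; penalty is the summed
    distance-to-interval of the four variable spacers.
    """

    positions: tuple[int, ...]
    spacers: tuple[int, ...]
    motif4_variant: str
    penalty: float


@dataclass(frozen=True)
class SpacerProfile:
    """The six spacers of a match plus the full sequence length."""

    spacers: tuple[int, ...]
    sequence_length: int


def interval_distance(value: float, interval: tuple[float, float]) -> float:
    """Linear distance from ``value`` to the closed interval (0 inside)."""
    lo, hi = interval
    if value < lo:
        return lo - value
    if value > hi:
        return value - hi
    return 0.0


def validate_sequence(sequence: str) -> str:
    """Upper-case and validate a protein sequence.

    Ambiguity codes (B, Z, J, U, O, X) are accepted but never match a motif
    position; anything else raises :class:`InputError` naming the offender.
    """
    if not sequence:
        raise InputError("empty sequence")
    seq = sequence.upper()
    allowed = set(AMINO_ACIDS) | set(AMBIGUOUS)
    for i, c in enumerate(seq):
        if c not in allowed:
            raise InputError(f"invalid residue {c!r} at position {i}")
    return seq


def _occurrences(seq: str, element: MotifElement) -> list[tuple[int, str]]:
    """All (position, matched-alternative) pairs for one element."""
    out = []
    n, k = len(seq), element.length
    for pos in range(n - k + 1):
        window = seq[pos : pos + k]
        for alt in element.alternatives:
            if window == alt:
                out.append((pos, alt))
                break
    return out


def _spacer_ok(i: int, spacer: int, max_spacer: int) -> bool:
    # spacers 0 and 5 are fixed at exactly 1; inner spacers bounded above
    if i in (0, 5):
        return spacer == 1
    return 0 <= spacer <= max_spacer


def scan_architecture(
    sequence: str,
    signature: SignatureDefinition | None = None,
    max_spacer: int = 150,
) -> list[ArchitectureMatch]:
    """Find all minimal-penalty placements of the signature in ``sequence``.

    Dynamic programming over candidate element occurrences: for each
    occurrence of element i the minimal achievable penalty of the suffix
    i..7 is tabulated, then every optimal path is reconstructed.  Placements
    are returned sorted by ascending penalty (all equal at the minimum) and
    lexicographically smallest position vector first.  Empty list if the
    signature cannot be placed at all.
    """
    if signature is None:
        signature = class_iii_signature()
    seq = validate_sequence(sequence)
    lens = signature.element_lengths

    occ = [_occurrences(seq, e) for e in signature.elements]
    if any(not o for o in occ):
        return []

    INF = float("inf")
    # best[i][j] = minimal penalty of suffix starting with occurrence j of element i
    best: list[dict[int, float]] = [dict() for _ in range(7)]
    for j in range(len(occ[6])):
        best[6][j] = 0.0
    for i in range(5, -1, -1):
        for j, (pos, _alt) in enumerate(occ[i]):
            lo = INF
            for k, (npos, _nalt) in enumerate(occ[i + 1]):
                spacer = npos - (pos + lens[i])
                if spacer < 0:
                    continue
                if not _spacer_ok(i, spacer, max_spacer):
                    continue
                nxt = best[i + 1].get(k, INF)
                if nxt is INF:
                    continue
                cand = nxt + interval_distance(spacer, signature.spacer_bounds[i])
                if cand < lo:
                    lo = cand
            if lo is not INF:
                best[i][j] = lo

    if not best[0]:
        return []
    overall = min(best[0].values())

    # reconstruct every optimal path
    matches: list[ArchitectureMatch] = []

    def walk(i: int, j: int, positions: list[int], remaining: float) -> None:
        pos, alt = occ[i][j]
        positions.append(pos)
        if i == 6:
            spacers = tuple(
                positions[t + 1] - (positions[t] + lens[t]) for t in range(6)
            )
            variant = seq[positions[3] : positions[3] + lens[3]]
            penalty = sum(
                interval_distance(s, signature.spacer_bounds[t])
                for t, s in enumerate(spacers)
            )
            matches.append(
                ArchitectureMatch(tuple(positions), spacers, variant, penalty)
            )
        else:
            for k, (npos, _na) in enumerate(occ[i + 1]):
                spacer = npos - (pos + lens[i])
                if spacer < 0 or not _spacer_ok(i, spacer, max_spacer):
                    continue
                nxt = best[i + 1].get(k)
                if nxt is None:
                    continue
                cost = interval_distance(spacer, signature.spacer_bounds[i])
                if abs(cost + nxt - remaining) < 1e-9:
                    walk(i + 1, k, positions, remaining - cost)
        positions.pop()

    for j, sub in best[0].items():
        if abs(sub - overall) < 1e-9:
            walk(0, j, [], sub)

    matches.sort(key=lambda m: (m.penalty, m.positions))
    return matches


def extract_spacer_profile(
    match: ArchitectureMatch, sequence_length: int
) -> SpacerProfile:
    """Book-keeping: the six spacers of a match plus the sequence length.

    Raises :class:`IntegrityError` if the match does not fit in a sequence
    of the given length or its spacers do not recompute from its positions.
    """
    span_end = match.positions[6] + ELEMENT_LENGTHS[6]
    if sequence_length < span_end:
        raise IntegrityError(
            f"match ends at {span_end} but sequence length is {sequence_length}"
        )
    recomputed = tuple(
        match.positions[i + 1] - (match.positions[i] + ELEMENT_LENGTHS[i])
        for i in range(6)
    )
    if recomputed != tuple(match.spacers):
        raise IntegrityError(
            f"spacers {match.spacers} do not recompute from positions ({recomputed})"
        )
    return SpacerProfile(tuple(match.spacers), sequence_length)
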