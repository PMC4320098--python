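"""Scanner correctness: planted architectures, oracle equivalence,
re-validation of reported matches."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pdekit.errors import InputError, IntegrityError
from pdekit.motifs import (
    ArchitectureMatch,
    ELEMENT_LENGTHS,
    SpacerProfile,
    class_iii_signature,
    extract_spacer_profile,
    interval_distance,
    scan_architecture,
)

from _oracles import brute_force_scan
from conftest import make_iiia_sequence

#: compact signature for oracle-equivalence tests on short sequences
SMALL_SIG = class_iii_signature(
    ((1, 1), (3, 6), (2, 5), (5, 9), (3, 6), (1, 1))
)


def test_planted_iiia_architecture_unique_zero_penalty_match():
    seq = make_iiia_sequence()
    matches = scan_architecture(seq)
    assert len(matches) == 1
    m = matches[0]
    assert m.spacers == (1, 37, 30, 69, 36, 1)
    assert m.penalty == 0
    assert m.motif4_variant == "GNHD"
    assert len(m.positions) == 7


def test_no_signature_elements_no_match():
    assert scan_architecture("A" * 300) == []


def test_two_candidate_fifth_histidines_in_interval_wins():
    # plant an extra H giving an out-of-interval spacer for element 5; the
    # scanner must pick the in-interval one, agreeing with full enumeration
    spacers = (1, 37, 30, 69, 36, 1)
    seq = list(make_iiia_sequence(spacers))
    assert seq[185] == "H"  # the planted element-5 histidine
    seq[150] = "H"  # decoy inside the 69-residue spacer
    seq = "".join(seq)
    matches = scan_architecture(seq)
    oracle = brute_force_scan(seq, class_iii_signature(), 150)
    assert [(m.positions, m.penalty) for m in matches] == oracle
    assert matches[0].penalty == 0
    assert matches[0].spacers == spacers


@pytest.mark.parametrize("bad, pos", [("DAH1GD", 3), ("D*H", 1)])
def test_invalid_residue_error_names_position(bad, pos):
    with pytest.raises(InputError, match=f"position {pos}"):
        scan_architecture(bad)


def test_empty_sequence_rejected():
    with pytest.raises(InputError):
        scan_architecture("")


def test_ambiguous_letters_never_match_motifs():
    # X in place of the element-1 aspartate must kill the only placement
    seq = list(make_iiia_sequence())
    assert seq[40] == "D"  # the planted element-1 aspartate
    seq[40] = "X"
    assert scan_architecture("".join(seq)) == []


_BOOSTED = np.array(list("DHGNECADHG"))


def _random_case(rng):
    """Sequence <= 120 aa; half the cases carry a planted architecture with
    random (often out-of-interval) spacers, sometimes corrupted, over a
    background dense in motif letters -- so decoys and near-misses abound."""
    if rng.random() < 0.5:
        return "".join(rng.choice(_BOOSTED, size=int(rng.integers(25, 121))))
    variant = ("GNHD", "GNHE", "GNCD")[rng.integers(0, 3)]
    parts = []
    for i, text in enumerate(("D", "H", "GD", variant, "H", "GH", "H")):
        parts.append(text)
        if i < 6:
            spacer = 1 if i in (0, 5) and rng.random() < 0.7 else int(
                rng.integers(0, 13)
            )
            parts.append("".join(rng.choice(_BOOSTED, size=spacer)))
    seq = "".join(parts)
    if rng.random() < 0.3:  # corrupt one residue
        k = int(rng.integers(0, len(seq)))
        seq = seq[:k] + "A" + seq[k + 1 :]
    pad = int(rng.integers(0, max(1, 121 - len(seq))))
    return ("".join(rng.choice(_BOOSTED, size=pad)) + seq)[:120]


def test_scanner_equals_bruteforce_500_seeded_cases():
    rng = np.random.default_rng(2024)
    n_with_match = 0
    for _ in range(500):
        seq = _random_case(rng)
        got = scan_architecture(seq, SMALL_SIG, max_spacer=15)
        want = brute_force_scan(seq, SMALL_SIG, max_spacer=15)
        assert [(m.positions, m.penalty) for m in got] == want
        n_with_match += bool(want)
    assert n_with_match > 100  # the suite genuinely exercises placements


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_scanner_oracle_equivalence_property(seed):
    rng = np.random.default_rng(seed)
    seq = _random_case(rng)
    got = scan_architecture(seq, SMALL_SIG, max_spacer=15)
    want = brute_force_scan(seq, SMALL_SIG, max_spacer=15)
    assert [(m.positions, m.penalty) for m in got] == want


def test_reported_matches_revalidate(benchmark60):
    records, _ = benchmark60
    sig = class_iii_signature()
    checked = 0
    for rec in records[:10]:
        for m in scan_architecture(str(rec.seq), sig):
            seq = str(rec.seq)
            for el, pos in zip(sig.elements, m.positions):
                assert seq[pos : pos + el.length] in el.alternatives
            spacers = tuple(
                m.positions[i + 1] - (m.positions[i] + ELEMENT_LENGTHS[i])
                for i in range(6)
            )
            assert spacers == m.spacers
            assert m.spacers[0] == 1 and m.spacers[5] == 1
            penalty = sum(
                interval_distance(s, sig.spacer_bounds[i])
                for i, s in enumerate(m.spacers)
            )
            assert penalty == pytest.approx(m.penalty)
            checked += 1
    assert checked >= 10


def test_extract_spacer_profile_from_positions():
    m = ArchitectureMatch(
        positions=(0, 2, 40, 72, 145, 182, 185),
        spacers=(1, 37, 30, 69, 36, 1),
        motif4_variant="GNHD",
        penalty=0.0,
    )
    profile = extract_spacer_profile(m, 186)
    assert profile.spacers == (1, 37, 30, 69, 36, 1)
    assert profile.sequence_length == 186


def test_extract_spacer_profile_integrity_checks():
    m = ArchitectureMatch(
        positions=(0, 2, 40, 72, 145, 182, 185),
        spacers=(1, 37, 30, 69, 36, 1),
        motif4_variant="GNHD",
        penalty=0.0,
    )
    with pytest.raises(IntegrityError):
        extract_spacer_profile(m, 100)  # shorter than the match span
    bad = ArchitectureMatch(m.positions, (2, 37, 30, 69, 36, 1), "GNHD", 0.0)
    with pytest.raises(IntegrityError):
        extract_spacer_profile(bad, 186)


def test_zero_length_spacer_allowed_between_inner_elements():
    # adjacency between GD and the motif-IV block gives spacer 0
    seq = make_iiia_sequence(spacers=(1, 37, 0, 69, 36, 1))
    matches = scan_architecture(seq)
    assert matches[0].spacers[2] == 0
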