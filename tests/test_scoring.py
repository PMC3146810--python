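import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dsqm import (
    AMINO_ACIDS,
    ConfigurationError,
    DsqmError,
    ModelParseError,
    PeptideWindow,
    QuantMatrix,
    enumerate_windows,
    identify_core,
    parse_model,
    scan_protein,
    score_window,
)

# ---------------------------------------------------------------------------
# Model grammar
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "spec, positions, cross",
    [
        ("p1p6", ("p1", "p6"), ()),
        ("p1p2p6", ("p1", "p2", "p6"), ()),
        ("p1p6crossp1p6", ("p1", "p6"), (("p1", "p6"),)),
        ("p1p4p6p9", ("p1", "p4", "p6", "p9"), ()),
        ("p1p4p6p7p9", ("p1", "p4", "p6", "p7", "p9"), ()),
        ("all9", tuple(f"p{i}" for i in range(1, 10)), ()),
        ("all13", ("p-2", "p-1") + tuple(f"p{i}" for i in range(1, 10)) + ("p+1", "p+2"), ()),
        ("core9+p-1", ("p-1",) + tuple(f"p{i}" for i in range(1, 10)), ()),
        ("core9+flanks", ("p-2", "p-1") + tuple(f"p{i}" for i in range(1, 10)) + ("p+1", "p+2"), ()),
        ("p-2p1p+2", ("p-2", "p1", "p+2"), ()),
    ],
)
def test_parse_model(spec, positions, cross):
    model = parse_model(spec)
    assert model.positions == positions
    assert model.cross_terms == cross
    # canonical ids are a fixed point of parsing
    assert parse_model(model.id) == model


@pytest.mark.parametrize(
    "bad", ["p1p0", "p10", "q1", "", "crossp1p6", "p1p6crossp1", "p1xp6", "core9+x"]
)
def test_parse_model_rejects_malformed(bad):
    with pytest.raises(ModelParseError):
        parse_model(bad)


# ---------------------------------------------------------------------------
# Window scoring
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "sequence, model, expected",
    [
        ("FHYLPFLPS", "p1p6", 0.314),
        ("KFHYLPFLP", "p1p6", -10.183),
        ("FHYLPFLPS", "all9", 1.413),
        ("FHYLPFLPS", "p1p6crossp1p6", 0.314 + 0.157 * 0.157),
    ],
)
def test_score_window_reference_values(nap, sequence, model, expected):
    ws = score_window(PeptideWindow("q", 0, sequence), nap, parse_model(model))
    assert ws.scorable
    assert ws.score == pytest.approx(expected, abs=1e-9)


def test_13mer_core_coordinates(nap):
    """In a 13-mer the core occupies window indices 2..10, so the p1p6 score
    of RKFHYLPFLPSTG equals that of its centre 9-mer FHYLPFLPS."""
    w13 = PeptideWindow("q", 0, "RKFHYLPFLPSTG")
    assert w13.core9 == "FHYLPFLPS"
    assert score_window(w13, nap, parse_model("p1p6")).score == pytest.approx(0.314)


def test_flank_position_needs_13mer_window():
    from dsqm import ALL_POSITIONS_13, FbeSimConfig, gen_fbe_table, normalize

    wide = normalize(
        gen_fbe_table(FbeSimConfig(seed=0, positions=ALL_POSITIONS_13)), "npp"
    )
    model = parse_model("core9+p-1")
    with pytest.raises(ConfigurationError, match="9-mer"):
        score_window(PeptideWindow("q", 0, "FHYLPFLPS"), wide, model)


def test_model_position_absent_from_matrix(nap):
    # the packaged matrices cover p1..p9 only; p-1 is not a column
    model = parse_model("core9+p-1")
    with pytest.raises(ConfigurationError, match="absent from matrix"):
        score_window(PeptideWindow("q", 0, "RKFHYLPFLPSTG"), nap, model)


def test_noncanonical_residue_at_model_position_unscorable(nap, p1p6):
    ws = score_window(PeptideWindow("q", 0, "XHYLPFLPS"), nap, p1p6)
    assert not ws.scorable and ws.score is None
    # X away from every model position leaves the window scorable
    ws = score_window(PeptideWindow("q", 0, "FHXLPFLPS"), nap, p1p6)
    assert ws.scorable and ws.score == pytest.approx(0.314)


# ---------------------------------------------------------------------------
# Window enumeration and scanning
# ---------------------------------------------------------------------------


def test_enumerate_windows_overlapping_registers():
    wins = enumerate_windows("3lqz", "RKFHYLPFLPSTGGS", 9)
    assert len(wins) == 7
    assert wins[0].sequence == "RKFHYLPFL" and wins[0].offset == 0
    assert wins[-1].sequence == "PFLPSTGGS" and wins[-1].offset == 6


def test_enumerate_windows_edge_lengths():
    assert len(enumerate_windows("x", "FHYLPFLPS", 9)) == 1
    assert enumerate_windows("x", "FHYLPFLP", 9) == []


def test_scan_matches_brute_force_double_loop(nap):
    """scan_protein equals an index-arithmetic-free double loop over
    offsets and model positions, on random sequences up to length 50."""
    rng = np.random.default_rng(7)
    model = parse_model("p1p2p6p9")
    core_index = {"p1": 0, "p2": 1, "p6": 5, "p9": 8}
    for _ in range(25):
        n = int(rng.integers(9, 51))
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=n))
        got = scan_protein("r", seq, nap, model, 9)
        assert len(got) == n - 8
        for i, ws in enumerate(got):
            expected = sum(
                float(nap.weights.at[seq[i + core_index[p]], p])
                for p in model.positions
            )
            assert ws.window.offset == i
            assert ws.score == pytest.approx(expected, abs=1e-12)


def test_scan_flags_unscorable_windows(nap, p1p6):
    scores = scan_protein("q", "XFHYLPFLPS", nap, p1p6, 9)
    assert not scores[0].scorable  # X sits at p1 of the first register
    assert scores[1].scorable


def test_homopolymer_windows_score_equally(nap, p1p6):
    scores = scan_protein("q", "A" * 10, nap, p1p6, 9)
    assert len(scores) == 2
    assert scores[0].score == scores[1].score


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------

windows9 = st.text(alphabet=sorted(AMINO_ACIDS), min_size=9, max_size=9)


@given(windows9)
def test_additivity_over_disjoint_position_sets(nap, seq):
    """For disjoint linear models A and B, score(A u B) = score(A) + score(B)."""
    w = PeptideWindow("q", 0, seq)
    a = score_window(w, nap, parse_model("p1p6")).score
    b = score_window(w, nap, parse_model("p2p9")).score
    ab = score_window(w, nap, parse_model("p1p2p6p9")).score
    assert ab == pytest.approx(a + b, abs=1e-12)


@given(windows9, st.sampled_from(sorted(AMINO_ACIDS)))
def test_monotone_substitution(nap, seq, replacement):
    """Swapping the p6 residue for one with strictly larger weight strictly
    increases any linear score involving p6."""
    model = parse_model("p1p6")
    old_w = nap.weight("p6", seq[5])
    new_w = nap.weight("p6", replacement)
    if new_w <= old_w:
        return
    before = score_window(PeptideWindow("q", 0, seq), nap, model).score
    after = score_window(
        PeptideWindow("q", 0, seq[:5] + replacement + seq[6:]), nap, model
    ).score
    assert after > before


def test_identify_core_tie_breaks_to_smallest_offset():
    flat = QuantMatrix(
        pd.DataFrame(
            np.zeros((20, 9)),
            index=list(AMINO_ACIDS),
            columns=[f"p{i}" for i in range(1, 10)],
        ),
        mode="nap",
    )
    best = identify_core("ACDEFGHIKLMNPQRSTVWY", flat, parse_model("p1p6"))
    assert best.window.offset == 0


def test_identify_core_requires_scorable_window(nap, p1p6):
    with pytest.raises(DsqmError, match="no scorable"):
        identify_core("XXXXXXXXX", nap, p1p6)


def test_identify_core_recovers_known_cores(nap, p1p6, known_core_peptides):
    """The argmax register under p1p6/QMnap is the experimentally known
    binding core for all six reference peptides."""
    for name, entry in known_core_peptides.items():
        best = identify_core(entry["sequence"], nap, p1p6, parent_id=name)
        assert best.window.offset == entry["core_offset"], name
        assert best.window.sequence == entry["core"], name
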