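"""Window scoring, protein scanning and binding-core identification.

A protein (or long peptide) is decomposed into overlapping windows of
length 9 (the binding core alone) or 13 (core plus two flanking residues
on each side).  Each window is scored against a quantitative matrix
under a *position model* -- the subset of positions whose weights are
summed, optionally with pairwise interaction (cross) terms:

    score = sum_p w(p, residue at p) + sum_(a,b) w(a, res a) * w(b, res b)

The binding core of a peptide is the window (register) with the maximal
score; for HLA-DP2 the two-anchor model ``p1p6`` with the nap-normalized
matrix discriminates the core sharply, because the deep hydrophobic p1
and p6 pockets dominate binding.

Model grammar
-------------
A model string is a concatenation of position tokens (``p1``...``p9``,
``p-2``, ``p-1``, ``p+1``, ``p+2``) followed by zero or more
``cross<pos><pos>`` suffixes, e.g. ``p1p6``, ``p1p2p6``,
``p1p6crossp1p6``.  Aliases: ``all9`` (the nine core positions),
``all13`` (core plus flanks), and ``core9`` optionally extended with
``+<pos>`` segments or ``+flanks`` (e.g. ``core9+p-1``, ``core9+flanks``).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable

from .errors import ConfigurationError, DsqmError, ModelParseError
from .matrices import (
    ALL_POSITIONS_13,
    AMINO_ACIDS,
    CORE_POSITIONS,
    QuantMatrix,
    _POSITION_RANK,
    sort_positions,
)

logger = logging.getLogger(__name__)

_AA_SET = frozenset(AMINO_ACIDS)
_TOKEN_RE = re.compile(r"p(?:-[12]|\+[12]|[1-9])")


@dataclass(frozen=True)
class PositionModel:
    """A subset of positions to sum, plus optional pairwise cross terms."""

    positions: tuple[str, ...]
    cross_terms: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.positions:
            raise ModelParseError("a position model needs at least one position")
        object.__setattr__(self, "positions", sort_positions(self.positions))
        for a, b in self.cross_terms:
            sort_positions((a, b))  # validates the labels

    @property
    def id(self) -> str:
        """Canonical model string; ``parse_model(model.id) == model``."""
        if not self.cross_terms:
            if self.positions == CORE_POSITIONS:
                return "all9"
            if self.positions == ALL_POSITIONS_13:
                return "all13"
        base = "".join(self.positions)
        return base + "".join(f"cross{a}{b}" for a, b in self.cross_terms)

    def required_positions(self) -> tuple[str, ...]:
        """All positions the model reads, including cross-term members."""
        seen = set(self.positions)
        for a, b in self.cross_terms:
            seen.update((a, b))
        return sort_positions(seen)


def _parse_position_run(fragment: str, context: str) -> tuple[str, ...]:
    """Parse a fragment that must tile exactly into position tokens."""
    tokens: list[str] = []
    i = 0
    while i < len(fragment):
        m = _TOKEN_RE.match(fragment, i)
        if m is None:
            raise ModelParseError(
                f"cannot parse {context!r}: unexpected fragment {fragment[i:]!r}"
            )
        tokens.append(m.group(0))
        i = m.end()
    if not tokens:
        raise ModelParseError(f"cannot parse {context!r}: no position tokens")
    return tuple(tokens)


def parse_model(spec: str) -> PositionModel:
    """Parse a model string (see module docstring for the grammar)."""
    s = spec.strip()
    if s == "all9":
        return PositionModel(CORE_POSITIONS)
    if s in ("all13", "core9+flanks"):
        return PositionModel(ALL_POSITIONS_13)
    if s == "core9" or s.startswith("core9+"):
        extras: tuple[str, ...] = ()
        rest = s[len("core9"):]
        if rest:
            extras = _parse_position_run(rest.replace("+p", "p"), spec)
            # every extra must have been introduced by a '+'
            if rest != "".join("+" + t for t in extras):
                raise ModelParseError(f"cannot parse {spec!r}: bad flank extension")
        return PositionModel(CORE_POSITIONS + extras)

    parts = s.split("cross")
    positions = _parse_position_run(parts[0], spec)
    if len(set(positions)) != len(positions):
        raise ModelParseError(f"cannot parse {spec!r}: repeated position")
    cross: list[tuple[str, str]] = []
    for part in parts[1:]:
        pair = _parse_position_run(part, spec)
        if len(pair) != 2:
            raise ModelParseError(
                f"cannot parse {spec!r}: cross term {part!r} must name exactly "
                f"two positions"
            )
        cross.append((pair[0], pair[1]))
    return PositionModel(positions, tuple(cross))


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

#: Window indices of each position label for the two window lengths.
#: In a 13-mer the core p1..p9 sits at indices 2..10, flanks at 0,1,11,12.
_INDEX_13 = dict(_POSITION_RANK)
_INDEX_9 = {p: i for i, p in enumerate(CORE_POSITIONS)}


def position_index(position: str, length: int) -> int:
    """0-based index of *position* within a window of *length* (9 or 13)."""
    table = {9: _INDEX_9, 13: _INDEX_13}.get(length)
    if table is None:
        raise ConfigurationError(f"window length must be 9 or 13, not {length}")
    try:
        return table[position]
    except KeyError:
        raise ConfigurationError(
            f"position {position} does not exist in a {length}-mer window"
        ) from None


@dataclass(frozen=True)
class PeptideWindow:
    """One register: a fixed-length subsequence of a parent sequence."""

    parent_id: str
    offset: int
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def core9(self) -> str:
        """The 9-mer binding core (the window itself, or the centre of a 13-mer)."""
        if self.length == 9:
            return self.sequence
        if self.length == 13:
            return self.sequence[2:11]
        raise ConfigurationError(f"window length {self.length} has no defined core")


@dataclass(frozen=True)
class WindowScore:
    """A window with its model score; unscorable windows carry no score."""

    window: PeptideWindow
    model_id: str
    score: float | None
    scorable: bool


def score_window(
    window: PeptideWindow, matrix: QuantMatrix, model: PositionModel
) -> WindowScore:
    """Score one window against *matrix* under *model*.

    A window is unscorable (``scorable=False``, ``score=None``) when a
    residue outside the 20-letter alphabet sits at any position the model
    reads.  Model positions missing from the matrix or not addressable in
    a window of this length raise :class:`ConfigurationError`.
    """
    needed = model.required_positions()
    missing = [p for p in needed if p not in matrix.positions]
    if missing:
        raise ConfigurationError(
            f"model {model.id!r} needs position(s) {missing} absent from matrix "
            f"{matrix.provenance or '<anonymous>'}"
        )
    residues: dict[str, str] = {}
    for p in needed:
        aa = window.sequence[position_index(p, window.length)]
        if aa not in _AA_SET:
            return WindowScore(window, model.id, None, False)
        residues[p] = aa
    total = sum(matrix.weight(p, residues[p]) for p in model.positions)
    total += sum(
        matrix.weight(a, residues[a]) * matrix.weight(b, residues[b])
        for a, b in model.cross_terms
    )
    return WindowScore(window, model.id, float(total), True)


def enumerate_windows(
    parent_id: str, sequence: str, length: int = 9
) -> list[PeptideWindow]:
    """All overlapping windows of *length*, N->C; empty if the sequence is shorter."""
    if length not in (9, 13):
        raise ConfigurationError(f"window length must be 9 or 13, not {length}")
    sequence = sequence.upper()
    n = len(sequence) - length + 1
    if n <= 0:
        logger.warning(
            "sequence %s (%d aa) is shorter than the %d-mer window; no windows",
            parent_id, len(sequence), length,
        )
        return []
    return [
        PeptideWindow(parent_id, i, sequence[i : i + length]) for i in range(n)
    ]


def scan_protein(
    parent_id: str,
    sequence: str,
    matrix: QuantMatrix,
    model: PositionModel,
    length: int = 9,
) -> list[WindowScore]:
    """Score every overlapping window of a protein, in sequence order."""
    return [
        score_window(w, matrix, model)
        for w in enumerate_windows(parent_id, sequence, length)
    ]


def identify_core(
    sequence: str,
    matrix: QuantMatrix,
    model: PositionModel,
    length: int = 9,
    parent_id: str = "query",
) -> WindowScore:
    """The best-scoring register of a peptide: its predicted binding core.

    Ties are broken towards the smallest offset.  Raises
    :class:`DsqmError` when no window is scorable.
    """
    scored = [s for s in scan_protein(parent_id, sequence, matrix, model, length) if s.scorable]
    if not scored:
        raise DsqmError(f"no scorable {length}-mer window in sequence {parent_id!r}")
    return max(scored, key=lambda s: (s.score, -s.window.offset))


def scores_to_rows(scored: Iterable[WindowScore]) -> list[dict]:
    """Flatten window scores to plain dicts for tabular output."""
    rows = []
    for s in scored:
        rows.append(
            {
                "parent_id": s.window.parent_id,
                "offset": s.window.offset,
                "window": s.window.sequence,
                "core": s.window.core9 if s.window.length == 13 else s.window.sequence,
                "model_id": s.model_id,
                "score": "" if s.score is None else f"{s.score:.3f}",
                "scorable": int(s.scorable),
            }
        )
    return rows
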