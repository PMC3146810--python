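"""Quantitative matrices for peptide--MHC class II binding prediction.

A quantitative matrix (QM) assigns every (binding-groove position, amino
acid) pair a dimensionless weight derived from normalized docking free
binding energies.  Peptide windows are scored by summing weights over a
chosen subset of positions; residues predicted not to bind at all carry a
large negative penalty (default -10.000) so that a single disallowed
anchor residue dominates any additive score.

Two normalization modes exist and are tagged on the matrix:

``npp`` (normalized position-per-position)
    statistics taken separately per position, so each column has zero
    mean and unit range over its non-penalty cells.
``nap`` (normalized over all positions)
    statistics taken over all positions jointly, so the zero-mean /
    unit-range structure holds globally rather than per column.

The packaged matrices ``DP2-QMnpp-9`` and ``DP2-QMnap-9`` cover the nine
binding-core positions p1..p9 of the human class II allele HLA-DP2
(DPA*0103 / DPB1*0201).
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, TextIO

import numpy as np
import pandas as pd
from Bio.SeqUtils import IUPACData
from scipy import stats

from .errors import ConfigurationError, MatrixFormatError, MatrixLookupError

#: Canonical one-letter residue codes, ordered as in standard QM tables
#: (alphabetical by three-letter name).
AMINO_ACIDS: tuple[str, ...] = tuple("ARNDCQEGHILKMFPSTWYV")

#: Three-letter -> one-letter residue code map (e.g. "Ala" -> "A").
THREE_TO_ONE: dict[str, str] = {
    three: one
    for three, one in IUPACData.protein_letters_3to1.items()
    if one in AMINO_ACIDS
}
ONE_TO_THREE: dict[str, str] = {one: three for three, one in THREE_TO_ONE.items()}

#: The nine binding-core positions, N->C.
CORE_POSITIONS: tuple[str, ...] = tuple(f"p{i}" for i in range(1, 10))
#: Flanking positions outside the core, two on each side.
FLANK_POSITIONS_N: tuple[str, ...] = ("p-2", "p-1")
FLANK_POSITIONS_C: tuple[str, ...] = ("p+1", "p+2")
#: All thirteen positions of a flank-extended window, N->C.
ALL_POSITIONS_13: tuple[str, ...] = FLANK_POSITIONS_N + CORE_POSITIONS + FLANK_POSITIONS_C

_POSITION_RANK: dict[str, int] = {p: i for i, p in enumerate(ALL_POSITIONS_13)}

DEFAULT_PENALTY = -10.0


def is_position(label: str) -> bool:
    """True if *label* is one of the 13 recognised position labels."""
    return label in _POSITION_RANK


def sort_positions(labels: Iterable[str]) -> tuple[str, ...]:
    """Order position labels N->C (p-2 < p-1 < p1 < ... < p9 < p+1 < p+2)."""
    labels = tuple(labels)
    for lab in labels:
        if lab not in _POSITION_RANK:
            raise ConfigurationError(f"unknown position label {lab!r}")
    return tuple(sorted(labels, key=_POSITION_RANK.__getitem__))


def to_one_letter(code: str) -> str:
    """Normalise a one- or three-letter residue code to canonical one-letter.

    Raises ``KeyError`` for codes outside the 20 canonical amino acids.
    """
    code = code.strip()
    if len(code) == 1:
        up = code.upper()
        if up in AMINO_ACIDS:
            return up
        raise KeyError(code)
    return THREE_TO_ONE[code.capitalize()]


@dataclass(eq=False)
class QuantMatrix:
    """A (position x amino acid) table of dimensionless binding weights.

    Parameters
    ----------
    weights
        DataFrame with index = the 20 one-letter residue codes and one
        column per position label; every cell defined.
    penalty_value
        The score assigned to residues predicted not to bind at the
        position; any cell equal to it is a *penalty cell*.
    mode
        Normalization mode tag, ``"npp"`` or ``"nap"``.
    provenance
        Free-text origin tag (builtin name, source file, simulation...).
    """

    weights: pd.DataFrame
    penalty_value: float = DEFAULT_PENALTY
    mode: str = "nap"
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("npp", "nap"):
            raise ConfigurationError(f"unknown normalization mode {self.mode!r}")
        cols = sort_positions(self.weights.columns)
        if set(self.weights.index) != set(AMINO_ACIDS):
            missing = sorted(set(AMINO_ACIDS) - set(self.weights.index))
            extra = sorted(set(self.weights.index) - set(AMINO_ACIDS))
            raise ConfigurationError(
                f"matrix rows must be the 20 amino acids "
                f"(missing {missing}, unexpected {extra})"
            )
        self.weights = self.weights.reindex(index=list(AMINO_ACIDS), columns=list(cols))
        self.weights = self.weights.astype(float)
        if self.weights.isna().any().any():
            raise ConfigurationError("matrix contains undefined cells")

    # -- access ---------------------------------------------------------

    @property
    def positions(self) -> tuple[str, ...]:
        return tuple(self.weights.columns)

    def weight(self, position: str, residue: str) -> float:
        """Weight of *residue* (one- or three-letter code) at *position*."""
        return float(self.weights.at[to_one_letter(residue), position])

    def is_penalty(self, position: str, residue: str) -> bool:
        return self.weight(position, residue) == self.penalty_value

    def penalty_mask(self) -> pd.DataFrame:
        """Boolean frame marking cells that hold the penalty value."""
        return self.weights == self.penalty_value

    def penalty_cells(self) -> list[tuple[str, str]]:
        """(position, residue) coordinates of penalty cells, column-major."""
        mask = self.penalty_mask()
        return [
            (pos, aa)
            for pos in self.positions
            for aa in AMINO_ACIDS
            if mask.at[aa, pos]
        ]

    def nonpenalty_values(self, position: str | None = None) -> np.ndarray:
        """Non-penalty weights, for one column or the whole matrix."""
        if position is None:
            vals = self.weights.values.ravel()
        else:
            vals = self.weights[position].values
        return vals[vals != self.penalty_value]

    # -- validation -----------------------------------------------------

    def validate(self, tol: float = 0.01) -> list[str]:
        """Check the value-range and mode invariants, warning on violations.

        Non-penalty cells must lie in [-1, 1]; npp matrices must have zero
        mean and unit range per position, nap matrices globally, within
        *tol* (the packaged tables are printed to 3 decimals, so their
        statistics close only approximately).  Returns the messages.
        """
        problems: list[str] = []
        vals = self.weights.values.ravel()
        out = vals[(vals != self.penalty_value) & ((vals < -1.0) | (vals > 1.0))]
        if out.size:
            problems.append(
                f"{out.size} non-penalty cell(s) outside [-1, 1], e.g. {out[0]:g}"
            )
        if self.mode == "npp":
            for pos in self.positions:
                v = self.nonpenalty_values(pos)
                if v.size < 2:
                    problems.append(f"{pos}: fewer than 2 non-penalty cells")
                    continue
                if abs(v.mean()) > tol:
                    problems.append(f"{pos}: non-penalty mean {v.mean():.4f} not 0")
                if abs((v.max() - v.min()) - 1.0) > tol:
                    problems.append(
                        f"{pos}: non-penalty range {v.max() - v.min():.4f} not 1"
                    )
        else:
            v = self.nonpenalty_values()
            if abs(v.mean()) > tol:
                problems.append(f"global non-penalty mean {v.mean():.4f} not 0")
            if abs((v.max() - v.min()) - 1.0) > tol:
                problems.append(f"global non-penalty range {v.max() - v.min():.4f} not 1")
        for msg in problems:
            warnings.warn(f"matrix {self.provenance or '<anonymous>'}: {msg}", stacklevel=2)
        return problems

    # -- comparison -----------------------------------------------------

    def equal_to(self, other: "QuantMatrix", decimals: int = 3) -> bool:
        """Equality of positions, mode, penalty and weights at *decimals* d.p."""
        return (
            self.positions == other.positions
            and self.mode == other.mode
            and math.isclose(self.penalty_value, other.penalty_value, abs_tol=10 ** -decimals)
            and bool(
                np.all(
                    self.weights.round(decimals).values
                    == other.weights.round(decimals).values
                )
            )
        )

    def __repr__(self) -> str:
        return (
            f"QuantMatrix(mode={self.mode!r}, positions={len(self.positions)}, "
            f"penalty={self.penalty_value:g}, provenance={self.provenance!r})"
        )


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------
# #mode: nap|npp
# #penalty: -10.000
# #provenance: free text            (optional)
# AA <TAB> p1 <TAB> ... positions
# Ala <TAB> cell ...                one row per residue, 1- or 3-letter code


def write_matrix(matrix: QuantMatrix, dest: TextIO | str | Path | None = None) -> str:
    """Serialise *matrix* to the TSV dialect; weights printed to 3 decimals.

    Writes to *dest* (stream or path) when given; always returns the text.
    """
    buf = io.StringIO()
    buf.write(f"#mode: {matrix.mode}\n")
    buf.write(f"#penalty: {matrix.penalty_value:.3f}\n")
    if matrix.provenance:
        buf.write(f"#provenance: {matrix.provenance}\n")
    buf.write("AA\t" + "\t".join(matrix.positions) + "\n")
    for aa in AMINO_ACIDS:
        cells = "\t".join(f"{matrix.weights.at[aa, pos]:.3f}" for pos in matrix.positions)
        buf.write(f"{ONE_TO_THREE[aa]}\t{cells}\n")
    text = buf.getvalue()
    if dest is not None:
        if hasattr(dest, "write"):
            dest.write(text)  # type: ignore[union-attr]
        else:
            Path(dest).write_text(text)
    return text


def read_matrix(source: TextIO | str | Path) -> QuantMatrix:
    """Parse the matrix TSV dialect into a :class:`QuantMatrix`.

    *source* may be an open text stream, a path, or the raw text itself
    (anything containing a newline is treated as text).  Structural
    problems raise :class:`MatrixFormatError` with the offending line
    number; invariant violations (e.g. a non-penalty cell outside
    [-1, 1]) only warn, via :meth:`QuantMatrix.validate`.
    """
    if hasattr(source, "read"):
        text = source.read()  # type: ignore[union-attr]
    else:
        s = str(source)
        text = s if "\n" in s else Path(s).read_text()

    mode = "nap"
    penalty = DEFAULT_PENALTY
    provenance = ""
    header: list[str] | None = None
    rows: dict[str, list[float]] = {}

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                key, val = key.strip().lower(), val.strip()
                if key == "mode":
                    if val not in ("npp", "nap"):
                        raise MatrixFormatError(f"unknown mode {val!r}", lineno)
                    mode = val
                elif key == "penalty":
                    try:
                        penalty = float(val)
                    except ValueError:
                        raise MatrixFormatError(f"bad penalty {val!r}", lineno) from None
                elif key == "provenance":
                    provenance = val
            continue
        fields = line.split("\t")
        if header is None:
            if fields[0].strip().upper() != "AA":
                raise MatrixFormatError("expected header starting with 'AA'", lineno)
            header = [f.strip() for f in fields[1:]]
            if not header:
                raise MatrixFormatError("header lists no positions", lineno)
            for pos in header:
                if not is_position(pos):
                    raise MatrixFormatError(f"unknown position label {pos!r}", lineno)
            if len(set(header)) != len(header):
                raise MatrixFormatError("duplicate position column", lineno)
            continue
        try:
            aa = to_one_letter(fields[0])
        except KeyError:
            raise MatrixFormatError(
                f"unknown residue code {fields[0]!r}", lineno
            ) from None
        if aa in rows:
            raise MatrixFormatError(f"duplicate row for residue {fields[0]!r}", lineno)
        cells = fields[1:]
        if len(cells) != len(header):
            raise MatrixFormatError(
                f"expected {len(header)} cells, found {len(cells)}", lineno
            )
        try:
            rows[aa] = [float(c) for c in cells]
        except ValueError:
            raise MatrixFormatError("non-numeric cell", lineno) from None

    if header is None:
        raise MatrixFormatError("no header line found")
    missing = [ONE_TO_THREE[aa] for aa in AMINO_ACIDS if aa not in rows]
    if missing:
        raise MatrixFormatError(f"missing row(s) for {', '.join(missing)}")

    frame = pd.DataFrame.from_dict(rows, orient="index", columns=header)
    matrix = QuantMatrix(frame, penalty_value=penalty, mode=mode, provenance=provenance)
    matrix.validate()
    return matrix


# ---------------------------------------------------------------------------
# Builtin matrices
# ---------------------------------------------------------------------------

#: name -> (data file, description)
BUILTIN_MATRICES: dict[str, tuple[str, str]] = {
    "DP2-QMnpp-9": (
        "DP2-QMnpp-9.tsv",
        "HLA-DP2 9-mer core, normalized position-per-position",
    ),
    "DP2-QMnap-9": (
        "DP2-QMnap-9.tsv",
        "HLA-DP2 9-mer core, normalized over all positions",
    ),
}


@lru_cache(maxsize=None)
def builtin_matrix(name: str) -> QuantMatrix:
    """Load a packaged matrix by registered name.

    Available names are the keys of :data:`BUILTIN_MATRICES`; an unknown
    name raises :class:`MatrixLookupError` listing them.
    """
    if name not in BUILTIN_MATRICES:
        raise MatrixLookupError(
            f"unknown builtin matrix {name!r}; available: "
            + ", ".join(sorted(BUILTIN_MATRICES))
        )
    filename, _ = BUILTIN_MATRICES[name]
    text = resources.files("dsqm.data").joinpath(filename).read_text()
    with warnings.catch_warnings():
        # packaged tables are printed to 3 d.p.; their invariants close
        # within the documented +/-0.01 and need not re-warn on every load
        warnings.simplefilter("ignore")
        matrix = read_matrix(text)
    matrix.provenance = name
    return matrix


def matrix_correlation(
    a: QuantMatrix, b: QuantMatrix, include_penalty_cells: bool = True
) -> float:
    """Pearson correlation between the paired cells of two matrices.

    The matrices must share the same position set.  With
    ``include_penalty_cells=False``, pairs where either matrix holds its
    penalty value are dropped; fewer than 3 remaining pairs is an error.
    The default includes penalty cells: the two packaged HLA-DP2 matrices
    correlate at r = 0.997 over all 180 cells.
    """
    if set(a.positions) != set(b.positions):
        raise ConfigurationError(
            f"position sets differ: {a.positions} vs {b.positions}"
        )
    cols = list(a.positions)
    x = a.weights[cols].values.ravel()
    y = b.weights.reindex(columns=cols).values.ravel()
    if not include_penalty_cells:
        keep = (x != a.penalty_value) & (y != b.penalty_value)
        x, y = x[keep], y[keep]
    if x.size < 3:
        raise ConfigurationError("fewer than 3 paired cells after filtering")
    return float(stats.pearsonr(x, y).statistic)
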