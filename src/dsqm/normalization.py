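"""Normalization of docking free binding energies into quantitative matrices.

A docking run over a single-substitution peptide library yields one free
binding energy (FBE, kcal/mol) per (position, residue) pair: the lowest
energy over the engine's independent runs for that variant.  Negative
FBEs mean predicted binding; positive (and zero) FBEs mean no binding.

Binding energies are turned into dimensionless matrix weights by

    w = -(FBE_i - FBE_avg) / (FBE_max - FBE_min)

where the statistics are taken over the binding (negative-FBE) records
of the scope: each position separately (``npp``) or all positions jointly
(``nap``).  The sign flip makes higher affinity (more negative energy)
score higher.  Non-binding records never enter the statistics; their
cells receive the penalty score (default -10.000) directly.

By construction each scope's weights have zero mean and unit range, and
every non-penalty weight lies in [-1, 1].
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, TextIO

import numpy as np
import pandas as pd

from .errors import DegenerateScopeError, FbeFormatError
from .matrices import (
    AMINO_ACIDS,
    DEFAULT_PENALTY,
    QuantMatrix,
    sort_positions,
    to_one_letter,
)

_COLUMNS = ("position", "residue", "fbe_kcal_mol")


@dataclass
class FbeTable:
    """Raw free binding energies for every (position, residue) pair.

    ``data`` holds columns ``position``, ``residue`` (one-letter) and
    ``fbe_kcal_mol``; exactly one record per pair over the declared
    position set.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise FbeFormatError(f"missing column(s): {', '.join(missing)}")
        df["residue"] = [to_one_letter(r) for r in df["residue"]]
        df["fbe_kcal_mol"] = df["fbe_kcal_mol"].astype(float)
        if not np.isfinite(df["fbe_kcal_mol"]).all():
            raise FbeFormatError("non-finite FBE value")
        positions = sort_positions(df["position"].unique())
        dup = df.duplicated(subset=["position", "residue"])
        if dup.any():
            first = df[dup].iloc[0]
            raise FbeFormatError(
                f"duplicate record for ({first['position']}, {first['residue']})"
            )
        expected = len(positions) * len(AMINO_ACIDS)
        if len(df) != expected:
            raise FbeFormatError(
                f"expected {expected} records ({len(positions)} positions x 20 "
                f"residues), found {len(df)}"
            )
        df["position"] = pd.Categorical(df["position"], categories=positions, ordered=True)
        self.data = df.sort_values(["position", "residue"]).reset_index(drop=True)

    @property
    def positions(self) -> tuple[str, ...]:
        return tuple(self.data["position"].cat.categories)

    def pivot(self) -> pd.DataFrame:
        """(residue x position) frame of FBE values."""
        wide = self.data.pivot(index="residue", columns="position", values="fbe_kcal_mol")
        return wide.reindex(index=list(AMINO_ACIDS), columns=list(self.positions))

    # -- I/O ------------------------------------------------------------

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, float]]
    ) -> "FbeTable":
        """Build from (position, residue, fbe) triples."""
        return cls(pd.DataFrame(records, columns=list(_COLUMNS)))

    @classmethod
    def from_tsv(cls, source: TextIO | str | Path) -> "FbeTable":
        """Read the FBE TSV dialect: header ``position  residue  fbe_kcal_mol``."""
        if hasattr(source, "read"):
            buf: TextIO = source  # type: ignore[assignment]
        else:
            s = str(source)
            buf = io.StringIO(s) if "\n" in s else io.StringIO(Path(s).read_text())
        try:
            df = pd.read_csv(buf, sep="\t", comment="#")
        except Exception as exc:
            raise FbeFormatError(f"unreadable FBE table: {exc}") from exc
        return cls(df)

    def to_tsv(self, dest: TextIO | str | Path | None = None) -> str:
        out = io.StringIO()
        out.write("\t".join(_COLUMNS) + "\n")
        for _, row in self.data.iterrows():
            out.write(f"{row['position']}\t{row['residue']}\t{row['fbe_kcal_mol']:.3f}\n")
        text = out.getvalue()
        if dest is not None:
            if hasattr(dest, "write"):
                dest.write(text)  # type: ignore[union-attr]
            else:
                Path(dest).write_text(text)
        return text


def partition_binders(table: FbeTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into (binding, non-binding) by the sign of the FBE.

    Binding means strictly negative energy; an FBE of exactly zero counts
    as non-binding.
    """
    neg = table.data["fbe_kcal_mol"] < 0
    return (
        table.data[neg].reset_index(drop=True),
        table.data[~neg].reset_index(drop=True),
    )


def normalize(
    table: FbeTable, mode: str = "nap", penalty: float = DEFAULT_PENALTY
) -> QuantMatrix:
    """Normalize an FBE table into a :class:`QuantMatrix`.

    Each scope (one position for ``npp``; the whole table for ``nap``)
    needs at least two binding records with distinct energies, otherwise
    :class:`DegenerateScopeError` is raised naming the scope.
    """
    if mode not in ("npp", "nap"):
        raise FbeFormatError(f"unknown normalization mode {mode!r}")
    wide = table.pivot()
    binding = wide.values < 0

    def scope_stats(values: np.ndarray, scope: str) -> tuple[float, float, float]:
        values = values[values < 0]
        if values.size < 2 or values.max() == values.min():
            raise DegenerateScopeError(
                f"scope {scope!r}: need >= 2 binding records with distinct "
                f"FBEs to normalize (found {values.size})"
            )
        return float(values.mean()), float(values.max()), float(values.min())

    weights = np.full(wide.shape, float(penalty))
    if mode == "npp":
        for j, pos in enumerate(wide.columns):
            col = wide.values[:, j]
            avg, hi, lo = scope_stats(col, str(pos))
            mask = binding[:, j]
            weights[mask, j] = -(col[mask] - avg) / (hi - lo)
    else:
        avg, hi, lo = scope_stats(wide.values.ravel(), "all positions")
        weights[binding] = -(wide.values[binding] - avg) / (hi - lo)

    frame = pd.DataFrame(weights, index=wide.index, columns=[str(c) for c in wide.columns])
    return QuantMatrix(
        frame, penalty_value=float(penalty), mode=mode, provenance=f"normalize({mode})"
    )
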