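"""Benchmark protocol: per-protein ranking, top-k% selection, sensitivity.

Known binders to an MHC allele are variable-length peptides, each a
substring of a parent protein.  To benchmark a matrix/model pair, each
parent protein is decomposed into overlapping windows which are scored
and ranked in descending order *within that protein*; the top k% are the
predicted binders.  A known binder is a true prediction if at least one
selected window's 9-mer core is a substring of the binder.  Sensitivity
at a cut-off is the fraction of known binders so recovered; binders are
counted once regardless of how many windows hit them.

Selection size is ceil(k/100 * n) over the n scorable windows, so the
selections at increasing cut-offs are nested and sensitivity is
non-decreasing in k.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import pandas as pd
from Bio import SeqIO

from .errors import ConfigurationError, TestSetError
from .matrices import QuantMatrix
from .scoring import PositionModel, WindowScore, scan_protein

DEFAULT_THRESHOLDS: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 25.0)


@dataclass(frozen=True)
class TestProtein:
    __test__ = False  # domain object, not a pytest case

    id: str
    sequence: str


@dataclass(frozen=True)
class KnownBinder:
    """A peptide known to bind, tied to its parent protein by id."""

    protein_id: str
    sequence: str
    ic50_nm: float | None = None


@dataclass
class TestSet:
    """Parent proteins plus the known binders originating from them."""

    __test__ = False  # domain object, not a pytest case

    proteins: dict[str, str]
    binders: list[KnownBinder]

    def __post_init__(self) -> None:
        for b in self.binders:
            if b.protein_id not in self.proteins:
                raise TestSetError(
                    f"binder {b.sequence!r} references unknown protein {b.protein_id!r}"
                )
            if len(b.sequence) < 9:
                raise TestSetError(
                    f"binder {b.sequence!r} is shorter than the 9-mer binding core"
                )
            if b.sequence not in self.proteins[b.protein_id]:
                warnings.warn(
                    f"binder {b.sequence!r} is not a substring of protein "
                    f"{b.protein_id!r}; kept (matching is by sequence only)",
                    stacklevel=2,
                )

    def binders_of(self, protein_id: str) -> list[KnownBinder]:
        return [b for b in self.binders if b.protein_id == protein_id]


def load_proteins_fasta(source: TextIO | str | Path) -> dict[str, str]:
    """Read parent proteins from FASTA; record ids become protein ids."""
    if hasattr(source, "read"):
        handle: TextIO = source  # type: ignore[assignment]
    else:
        handle = io.StringIO(Path(source).read_text())
    proteins: dict[str, str] = {}
    for rec in SeqIO.parse(handle, "fasta"):
        if rec.id in proteins:
            raise TestSetError(f"duplicate protein id {rec.id!r} in FASTA")
        proteins[rec.id] = str(rec.seq).upper()
    return proteins


def load_binders_tsv(source: TextIO | str | Path) -> list[KnownBinder]:
    """Read binders from TSV: protein_id, binder_sequence[, ic50_nM]."""
    if hasattr(source, "read"):
        buf: TextIO = source  # type: ignore[assignment]
    else:
        s = str(source)
        buf = io.StringIO(s) if "\n" in s else io.StringIO(Path(s).read_text())
    df = pd.read_csv(buf, sep="\t", comment="#")
    required = {"protein_id", "binder_sequence"}
    if not required.issubset(df.columns):
        raise TestSetError(
            f"binder TSV needs columns {sorted(required)}, found {list(df.columns)}"
        )
    binders = []
    for _, row in df.iterrows():
        ic50 = row.get("ic50_nM")
        binders.append(
            KnownBinder(
                str(row["protein_id"]),
                str(row["binder_sequence"]).upper(),
                None if ic50 is None or pd.isna(ic50) else float(ic50),
            )
        )
    return binders


def load_testset(
    proteins_fasta: TextIO | str | Path, binders_tsv: TextIO | str | Path
) -> TestSet:
    return TestSet(load_proteins_fasta(proteins_fasta), load_binders_tsv(binders_tsv))


def resolve_gi_numbers(*gi_numbers: str) -> None:
    """Placeholder for NCBI GI -> sequence resolution.

    Published benchmark sets often identify parent proteins by NCBI GI
    number.  Resolving those requires a network query (e.g. NCBI E-utilities
    ``efetch`` with ``db=protein``), which this package deliberately does
    not perform; supply the parent proteins as FASTA instead.
    """
    raise NotImplementedError(
        "GI resolution requires a network query; provide proteins as FASTA"
    )


# ---------------------------------------------------------------------------
# Selection and matching
# ---------------------------------------------------------------------------


def select_top(scored: Sequence[WindowScore], pct: float) -> list[WindowScore]:
    """The ceil(pct/100 * n) best of one protein's n scorable windows.

    Ordering is by descending score, ties towards the smaller offset, so
    selection is deterministic and selections at increasing pct nest.
    """
    if not 0 < pct <= 100:
        raise ConfigurationError(f"threshold must be in (0, 100], not {pct}")
    scorable = [s for s in scored if s.scorable]
    if not scorable:
        warnings.warn("no scorable windows; empty selection", stacklevel=2)
        return []
    k = math.ceil(pct / 100.0 * len(scorable))
    ranked = sorted(scorable, key=lambda s: (-s.score, s.window.offset))
    return ranked[:k]


def matches_binder(window_score: WindowScore, binder: KnownBinder) -> bool:
    """True if the window's 9-mer core is contained in the binder sequence.

    Windows from a different parent protein never match.
    """
    w = window_score.window
    if w.parent_id != binder.protein_id:
        return False
    return w.core9 in binder.sequence


# ---------------------------------------------------------------------------
# Sensitivity
# ---------------------------------------------------------------------------


@dataclass
class SensitivityResult:
    """Sensitivity of a matrix/model pair at each top-k% cut-off."""

    model_id: str
    matrix_id: str
    thresholds: tuple[float, ...]
    sensitivity: dict[float, float] = field(default_factory=dict)
    counts: dict[float, tuple[int, int]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "model_id": self.model_id,
                "matrix": self.matrix_id,
                "threshold_pct": t,
                "true_predicted": self.counts[t][0],
                "total_binders": self.counts[t][1],
                "sensitivity": self.sensitivity[t],
            }
            for t in self.thresholds
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, dest: TextIO | str | Path | None = None) -> str:
        frame = self.to_frame()
        text = frame.to_csv(sep="\t", index=False, float_format="%.4f")
        if dest is not None:
            if hasattr(dest, "write"):
                dest.write(text)  # type: ignore[union-attr]
            else:
                Path(dest).write_text(text)
        return text


def sensitivity(
    testset: TestSet,
    matrix: QuantMatrix,
    model: PositionModel,
    length: int = 9,
    thresholds: Iterable[float] = DEFAULT_THRESHOLDS,
) -> SensitivityResult:
    """Run the full benchmark protocol at each threshold.

    Every protein is scanned once; per threshold the top k% windows per
    protein are selected and each known binder is marked recovered if any
    selected window of its protein matches it.
    """
    thresholds = tuple(float(t) for t in thresholds)
    for t in thresholds:
        if not 0 < t <= 100:
            raise ConfigurationError(f"threshold must be in (0, 100], not {t}")
    scans = {
        pid: scan_protein(pid, seq, matrix, model, length)
        for pid, seq in testset.proteins.items()
    }
    result = SensitivityResult(
        model.id, matrix.provenance or "<matrix>", thresholds
    )
    total = len(testset.binders)
    for t in thresholds:
        selected = {pid: select_top(scans[pid], t) for pid in scans}
        hit = sum(
            1
            for b in testset.binders
            if any(matches_binder(s, b) for s in selected[b.protein_id])
        )
        result.counts[t] = (hit, total)
        result.sensitivity[t] = hit / total if total else 0.0
    return result
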