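"""Synthetic docking outputs and planted-motif benchmark sets.

Two generators make every stage of the pipeline testable without any
docking engine or database download:

* :func:`gen_fbe_table` emulates the summary a docking run produces for
  a single-substitution peptide library -- one lowest free binding
  energy per (position, residue) cell, mostly negative (binding) with a
  small fraction of positive, non-binding cells.
* :func:`gen_testset` builds random background proteins with planted
  high-scoring 9-mer cores and reports the binders (core +/- 3 residues
  of context) plus the ground-truth core coordinates.

Defaults mirror the scale of the HLA-DP2 benchmark this package targets:
24 parent proteins with 19 binders each (457 binders arose from 24
proteins in the original set), docking energies centred near -5 kcal/mol
with ~3% non-binding cells (6 of the 180 cells of each packaged 9-mer
matrix are penalty cells).  Background residues are drawn uniformly
over the 20 amino acids; a frequency-table hook is provided.

All randomness flows from the single seed in the config via
``numpy.random.default_rng``; identical configs give identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DsqmError
from .matrices import AMINO_ACIDS, CORE_POSITIONS, QuantMatrix
from .normalization import FbeTable
from .evaluation import KnownBinder, TestSet
from .scoring import PositionModel, parse_model


@dataclass(frozen=True)
class FbeSimConfig:
    """Configuration for a synthetic free-binding-energy table.

    ``fbe_mean``/``fbe_sd`` parameterise the normal the binding
    (negative) energies are truncated from, in kcal/mol;
    ``positive_fraction`` is the probability a cell is non-binding.
    """

    seed: int = 0
    positions: tuple[str, ...] = CORE_POSITIONS
    fbe_mean: float = -5.0
    fbe_sd: float = 2.0
    positive_fraction: float = 6 / 180


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int, negative: bool
) -> np.ndarray:
    """Rejection-sample a normal truncated to one sign."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled))
        keep = draw[draw < 0] if negative else draw[draw > 0]
        take = keep[: size - filled]
        out[filled : filled + take.size] = take
        filled += take.size
    return out


def gen_fbe_table(cfg: FbeSimConfig, max_retries: int = 10) -> FbeTable:
    """Draw one FBE record per (position, residue) cell.

    Binding cells come from a negative-truncated normal(``fbe_mean``,
    ``fbe_sd``); non-binding cells from the mirrored positive-truncated
    normal.  A position left with fewer than two binding cells (possible
    at high ``positive_fraction``) is redrawn with a warning, and after
    ``max_retries`` failures an error is raised.
    """
    if cfg.fbe_sd <= 0:
        raise DsqmError("fbe_sd must be positive")
    if not 0 <= cfg.positive_fraction < 1:
        raise DsqmError("positive_fraction must lie in [0, 1)")
    rng = np.random.default_rng(cfg.seed)
    n_aa = len(AMINO_ACIDS)
    records: list[tuple[str, str, float]] = []
    for pos in cfg.positions:
        for attempt in range(max_retries):
            nonbind = rng.random(n_aa) < cfg.positive_fraction
            if n_aa - int(nonbind.sum()) >= 2:
                break
            warnings.warn(
                f"position {pos}: fewer than 2 binding cells drawn; redrawing",
                stacklevel=2,
            )
        else:
            raise DsqmError(
                f"position {pos}: could not draw >= 2 binding cells in "
                f"{max_retries} attempts (positive_fraction too high)"
            )
        neg = _truncated_normal(rng, cfg.fbe_mean, cfg.fbe_sd, n_aa, negative=True)
        pos_vals = _truncated_normal(rng, -cfg.fbe_mean, cfg.fbe_sd, n_aa, negative=False)
        for i, aa in enumerate(AMINO_ACIDS):
            records.append((pos, aa, float(pos_vals[i] if nonbind[i] else neg[i])))
    return FbeTable.from_records(records)


@dataclass(frozen=True)
class TestSetSimConfig:
    """Configuration for a planted-motif benchmark test set.

    ``plant_strength`` is the probability that each planted-core position
    named by ``planted_model`` carries the matrix's top-weight residue
    for that position; the remaining residues are background.
    """

    __test__ = False  # config object, not a pytest case

    seed: int = 0
    n_proteins: int = 24
    protein_length: int = 400
    binders_per_protein: int = 19
    planted_model: str = "p1p6"
    plant_strength: float = 1.0
    background_freqs: tuple[float, ...] | None = None

    def model(self) -> PositionModel:
        return parse_model(self.planted_model)


def top_weight_residue(matrix: QuantMatrix, position: str) -> str:
    """The residue with the maximal (non-penalty) weight at *position*."""
    col = matrix.weights[position]
    col = col[col != matrix.penalty_value]
    return str(col.idxmax())


def gen_testset(
    cfg: TestSetSimConfig, matrix: QuantMatrix
) -> tuple[TestSet, list[tuple[str, int]]]:
    """Generate proteins with planted cores; return the set and ground truth.

    Each protein is cut into ``binders_per_protein`` equal segments and
    one 9-mer core is planted per segment (segments must hold the core
    plus +/-3 context, i.e. be >= 15 residues, else the geometry is
    infeasible and an error is raised).  Binders are the planted cores
    extended by three residues of context on each side, clipped to the
    protein.  Ground truth is the list of (protein_id, core_offset).
    """
    if cfg.n_proteins < 0 or cfg.binders_per_protein < 0:
        raise DsqmError("counts must be non-negative")
    if not 0 <= cfg.plant_strength <= 1:
        raise DsqmError("plant_strength must lie in [0, 1]")
    rng = np.random.default_rng(cfg.seed)
    model = cfg.model()
    core_len, pad = 9, 3
    if cfg.binders_per_protein:
        seg = cfg.protein_length // cfg.binders_per_protein
        if seg < core_len + 2 * pad:
            raise DsqmError(
                f"infeasible geometry: {cfg.binders_per_protein} binders need "
                f"segments of >= {core_len + 2 * pad} residues, got {seg}"
            )
    freqs = None
    if cfg.background_freqs is not None:
        freqs = np.asarray(cfg.background_freqs, dtype=float)
        if freqs.size != len(AMINO_ACIDS) or not np.isclose(freqs.sum(), 1.0):
            raise DsqmError("background_freqs must be 20 probabilities summing to 1")

    aa = np.array(list(AMINO_ACIDS))
    plant_positions = {p: i for i, p in enumerate(CORE_POSITIONS)}
    proteins: dict[str, str] = {}
    binders: list[KnownBinder] = []
    truth: list[tuple[str, int]] = []

    for k in range(cfg.n_proteins):
        pid = f"synth{k:03d}"
        seq = list(rng.choice(aa, size=cfg.protein_length, p=freqs))
        for j in range(cfg.binders_per_protein):
            lo, hi = j * seg, (j + 1) * seg
            start = int(rng.integers(lo + pad, hi - core_len - pad + 1))
            core = rng.choice(aa, size=core_len, p=freqs)
            for p in model.positions:
                if p in plant_positions and rng.random() < cfg.plant_strength:
                    core[plant_positions[p]] = top_weight_residue(matrix, p)
            seq[start : start + core_len] = core
            truth.append((pid, start))
        proteins[pid] = "".join(seq)
        for pid_t, start in truth[-cfg.binders_per_protein:] if cfg.binders_per_protein else []:
            b_lo = max(0, start - pad)
            b_hi = min(cfg.protein_length, start + core_len + pad)
            binders.append(KnownBinder(pid, proteins[pid][b_lo:b_hi]))
    return TestSet(proteins, binders), truth


def shuffle_matrix(matrix: QuantMatrix, seed: int = 0) -> QuantMatrix:
    """Null control: permute residue labels independently within each position.

    Destroys the residue-to-weight association while preserving each
    column's value distribution (penalty cells move with their values).
    """
    rng = np.random.default_rng(seed)
    shuffled = matrix.weights.copy()
    for pos in matrix.positions:
        shuffled[pos] = rng.permutation(shuffled[pos].values)
    return QuantMatrix(
        shuffled,
        penalty_value=matrix.penalty_value,
        mode=matrix.mode,
        provenance=f"shuffled({matrix.provenance})",
    )
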