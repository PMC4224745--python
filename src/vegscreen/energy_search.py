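"""Hill-climbing over the constrained sequence space against a binding-energy oracle.

Energies are docking-style free-energy estimates in kcal/mol: lower is
stronger predicted binding. The oracle is pluggable — a precomputed table
read from TSV, or the deterministic composition surrogate shipped here for
desk-scale testing; the toolkit never invokes a docking binary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .peptide_space import (
    STANDARD_AMINO_ACIDS,
    MutableTemplate,
    PeptideSequence,
    enumerate_variants,
    parse_peptide,
)

# An energy oracle is any deterministic PeptideSequence -> kcal/mol mapping.
EnergyOracle = Callable[[PeptideSequence], float]


class OracleError(RuntimeError):
    """Oracle failed on a sequence; names the offending sequence."""

    def __init__(self, sequence: PeptideSequence, cause: Exception):
        self.sequence = sequence
        super().__init__(f"energy oracle failed on {sequence.residues!r}: {cause}")


@dataclass(frozen=True)
class EnergyRecord:
    """A (sequence, binding energy kcal/mol) pair; energy must be finite."""

    sequence: PeptideSequence
    energy: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.energy):
            raise ValueError(f"non-finite energy for {self.sequence.residues!r}")


@dataclass(frozen=True)
class HillClimbConfig:
    """Restart count, iteration cap, and seed for the steepest-descent search."""

    restarts: int = 8
    max_iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass(frozen=True)
class HillClimbResult:
    """Best record found plus the per-restart descent trajectories."""

    best: EnergyRecord
    trajectories: tuple[tuple[EnergyRecord, ...], ...]
    oracle_calls: int


def _evaluate(oracle: EnergyOracle, seq: PeptideSequence) -> float:
    try:
        energy = float(oracle(seq))
    except Exception as exc:  # noqa: BLE001 - contract: name the sequence
        raise OracleError(seq, exc) from exc
    if not math.isfinite(energy):
        raise OracleError(seq, ValueError(f"non-finite energy {energy}"))
    return energy


def _descend(
    start: PeptideSequence,
    template: MutableTemplate,
    alphabet: Sequence[str],
    oracle: EnergyOracle,
    max_iterations: int,
) -> tuple[list[EnergyRecord], int]:
    """Steepest descent from one start; returns (trajectory, oracle calls)."""
    positions = sorted(template.mutable_positions)
    letters = sorted(set(alphabet))
    current = start
    current_e = _evaluate(oracle, current)
    calls = 1
    trajectory = [EnergyRecord(current, current_e)]
    for _ in range(max_iterations):
        best_neighbor: PeptideSequence | None = None
        best_e = current_e
        chars = list(current.residues)
        for pos in positions:
            original = chars[pos - 1]
            for res in letters:
                if res == original:
                    continue
                chars[pos - 1] = res
                neighbor = PeptideSequence("".join(chars))
                e = _evaluate(oracle, neighbor)
                calls += 1
                # strict improvement; ties among equal improvements go to the
                # lexicographically smallest sequence for determinism
                if e < best_e or (
                    e == best_e
                    and best_neighbor is not None
                    and neighbor.residues < best_neighbor.residues
                ):
                    best_neighbor = neighbor
                    best_e = e
            chars[pos - 1] = original
        if best_neighbor is None:
            break
        current, current_e = best_neighbor, best_e
        trajectory.append(EnergyRecord(current, current_e))
    return trajectory, calls


def hill_climb(
    template: MutableTemplate,
    oracle: EnergyOracle,
    config: HillClimbConfig = HillClimbConfig(),
    alphabet: Sequence[str] = STANDARD_AMINO_ACIDS,
) -> HillClimbResult:
    """Multi-restart steepest-descent search for the lowest-energy variant.

    Each restart evaluates every single-position substitution at the mutable
    positions and moves to the best strictly improving neighbor until a local
    optimum or the iteration cap. Restart 1 starts from the template base;
    further restarts start from uniformly sampled variants. When
    ``config.restarts`` covers the whole variant space the starts are instead
    the full enumeration, making the search exhaustive. Deterministic given
    the seed; the core motif is untouched by construction of the neighborhood.
    """
    letters = sorted(set(alphabet))
    positions = sorted(template.mutable_positions)
    space = len(letters) ** len(positions)

    starts: list[PeptideSequence]
    if config.restarts >= space:
        starts = list(enumerate_variants(template, letters))
    else:
        rng = np.random.default_rng(config.seed)
        starts = [template.base]
        base_chars = list(template.base.residues)
        for _ in range(config.restarts - 1):
            chars = base_chars.copy()
            for pos in positions:
                chars[pos - 1] = letters[int(rng.integers(len(letters)))]
            starts.append(PeptideSequence("".join(chars)))

    trajectories: list[tuple[EnergyRecord, ...]] = []
    total_calls = 0
    best: EnergyRecord | None = None
    for start in starts:
        traj, calls = _descend(start, template, letters, oracle, config.max_iterations)
        trajectories.append(tuple(traj))
        total_calls += calls
        final = traj[-1]
        if (
            best is None
            or final.energy < best.energy
            or (final.energy == best.energy and final.sequence.residues < best.sequence.residues)
        ):
            best = final
    assert best is not None
    return HillClimbResult(best, tuple(trajectories), total_calls)


def best_of_replicates(energies: Sequence[float]) -> float:
    """Collapse replicate docking energies to the lowest (strongest) value."""
    if len(energies) == 0:
        raise ValueError("no replicate energies provided")
    return min(energies)


def filter_by_energy(
    records: Iterable[EnergyRecord], threshold: float
) -> list[EnergyRecord]:
    """Keep records with energy <= threshold (inclusive), preserving order.

    Inclusive on purpose: the motivating screen's table of hits contains
    entries at exactly the stated cutoff, so "lower than" is read as <=.
    """
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return [r for r in records if r.energy <= threshold]


# ---------------------------------------------------------------------------
# Surrogate oracle
# ---------------------------------------------------------------------------

#: Fixed per-residue weights for the surrogate oracle (kcal/mol contributions).
#: Basic and aromatic residues are favourable (negative), mirroring the
#: electrostatics-dominated receptor interface the screen targets; values are
#: arbitrary but fixed, documented constants.
SURROGATE_WEIGHTS: Mapping[str, float] = {
    "A": 0.05, "C": 0.00, "D": 0.45, "E": 0.40, "F": -0.35,
    "G": 0.10, "H": -0.25, "I": -0.15, "K": -0.40, "L": -0.10,
    "M": -0.05, "N": 0.15, "P": 0.20, "Q": 0.05, "R": -0.45,
    "S": 0.10, "T": 0.05, "V": -0.10, "W": -0.30, "Y": -0.20,
}


def surrogate_energy(sequence: PeptideSequence) -> float:
    """Deterministic composition-based stand-in for a docking oracle.

    Sums fixed per-residue weights and offsets by −3.0 kcal/mol so typical
    basic peptides land in the docking-score range (around −5 kcal/mol).
    Purely compositional: same residues in any order give the same energy.
    """
    return -3.0 + sum(SURROGATE_WEIGHTS[ch] for ch in sequence.residues)


class TableOracle:
    """Energy oracle backed by a precomputed (sequence -> energy) table."""

    def __init__(self, table: Mapping[str, float]):
        self._table = dict(table)

    def __call__(self, sequence: PeptideSequence) -> float:
        try:
            return self._table[sequence.residues]
        except KeyError:
            raise KeyError(f"no precomputed energy for {sequence.residues!r}") from None

    def __len__(self) -> int:
        return len(self._table)


# ---------------------------------------------------------------------------
# Energy-table TSV I/O
# ---------------------------------------------------------------------------

def read_energy_table(path: str | Path) -> list[EnergyRecord]:
    """Read an energy table TSV with columns ``sequence``, ``energy_kcal_mol``.

    An optional ``replicate`` column is collapsed per sequence via
    :func:`best_of_replicates` (the lowest replicate energy wins).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sequence", "energy_kcal_mol"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"energy table missing columns: {sorted(missing)}")
    if "replicate" in df.columns:
        collapsed = df.groupby("sequence", sort=False)["energy_kcal_mol"].min()
        pairs = list(collapsed.items())
    else:
        pairs = list(zip(df["sequence"], df["energy_kcal_mol"]))
    return [EnergyRecord(parse_peptide(seq), float(e)) for seq, e in pairs]


def write_energy_table(path: str | Path, records: Iterable[EnergyRecord]) -> None:
    rows = list(records)
    df = pd.DataFrame(
        {
            "sequence": [r.sequence.residues for r in rows],
            "energy_kcal_mol": [r.energy for r in rows],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def table_oracle_from_tsv(path: str | Path) -> TableOracle:
    """Load a TSV energy table as a pluggable oracle."""
    return TableOracle({r.sequence.residues: r.energy for r in read_energy_table(path)})
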