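"""Sliding-window binding-site scoring over a pluggable per-window p-value provider.

A peptide is cut into overlapping windows of length L (L <= 10, the length
cap of the PEPSITE binding-site predictor whose tabular output this module
consumes). Each window k gets a binding score

    S_k = sum_i 1 / p_i            over the top-n site p-values of the window,

and the whole peptide is aggregated relative to the fixed core motif's score
S_core as

    S_total = (1/m) * sum_k  S_k * (1 + log(S_k / S_core)),

so windows scoring above the core are up-weighted and windows scoring far
below it contribute negatively. The log base is configurable (natural log by
default). Higher S_total predicts stronger receptor binding.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .peptide_space import PeptideSequence, parse_peptide

#: Window-length cap imposed by the upstream binding-site predictor.
MAX_WINDOW_LENGTH = 10

#: Number of top predicted sites summed per window.
DEFAULT_TOP_N = 10


class ScoringError(ValueError):
    """Validation failure in the window-scoring pipeline."""


class ProviderError(RuntimeError):
    """P-value provider failed on a window; names the window."""

    def __init__(self, window: str, cause: Exception):
        self.window = window
        super().__init__(f"p-value provider failed on window {window!r}: {cause}")


@dataclass(frozen=True)
class WindowDecomposition:
    """Ordered windows of a parent sequence with their 1-based start offsets."""

    parent: PeptideSequence
    window_length: int
    stride: int
    windows: tuple[tuple[int, PeptideSequence], ...]

    @property
    def m(self) -> int:
        return len(self.windows)


@dataclass(frozen=True)
class PValueSet:
    """Top-n binding-site p-values for one window, best (smallest) first."""

    window: PeptideSequence
    pvalues: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.pvalues:
            raise ScoringError(f"empty p-value set for window {self.window.residues!r}")
        for p in self.pvalues:
            if not (0.0 < p <= 1.0):
                raise ScoringError(
                    f"p-value {p} for window {self.window.residues!r} outside (0, 1]"
                )
        object.__setattr__(self, "pvalues", tuple(sorted(self.pvalues)))

    @property
    def n(self) -> int:
        return len(self.pvalues)


@dataclass(frozen=True)
class BindingScore:
    """The reciprocal-p-value sum S for one window; S >= n by construction."""

    window: PeptideSequence
    S: float


@dataclass(frozen=True)
class TotalScore:
    """The window-averaged, core-referenced aggregate score for a peptide."""

    S_total: float
    S_core: float
    m: int


# A provider maps a window sequence to its PValueSet, deterministically.
PValueProvider = Callable[[PeptideSequence], PValueSet]


def decompose(
    sequence: PeptideSequence, window_length: int = MAX_WINDOW_LENGTH, stride: int = 1
) -> WindowDecomposition:
    """Slide a window of ``window_length`` over ``sequence``.

    With stride 1 this yields m = len - L + 1 windows; a sequence shorter
    than the window is returned as a single whole-sequence window. Window
    lengths above 10 are rejected (predictor limit).
    """
    if window_length < 1:
        raise ScoringError("window length must be >= 1")
    if window_length > MAX_WINDOW_LENGTH:
        raise ScoringError(
            f"window length {window_length} exceeds the {MAX_WINDOW_LENGTH}-residue "
            "limit of the binding-site predictor"
        )
    if stride < 1:
        raise ScoringError("stride must be >= 1")
    n = sequence.length
    if n <= window_length:
        windows = ((1, sequence),)
    else:
        starts = list(range(0, n - window_length + 1, stride))
        # ensure the tail is covered when the stride overshoots it
        if starts[-1] != n - window_length:
            starts.append(n - window_length)
        windows = tuple(
            (s + 1, PeptideSequence(sequence.residues[s : s + window_length]))
            for s in starts
        )
    return WindowDecomposition(sequence, window_length, stride, windows)


def binding_score(pset: PValueSet) -> BindingScore:
    """Reciprocal-p-value sum over the provided top sites."""
    return BindingScore(pset.window, float(sum(1.0 / p for p in pset.pvalues)))


def total_score(
    sub_scores: Sequence[BindingScore],
    S_core: float,
    log_base: float | str = "e",
) -> TotalScore:
    """Aggregate per-window scores relative to the core motif's score.

    ``log_base`` accepts "e"/"natural" (default), 10, 2, or any base > 1.
    Every sub-score and the core score must be positive.
    """
    if not sub_scores:
        raise ScoringError("no sub-sequence scores to aggregate")
    if S_core <= 0:
        raise ScoringError(f"core score must be positive, got {S_core}")
    if isinstance(log_base, str):
        if log_base not in ("e", "natural"):
            raise ScoringError(f"unknown log base {log_base!r}")
        log = math.log
    else:
        if log_base <= 1:
            raise ScoringError("numeric log base must exceed 1")
        base = float(log_base)
        log = lambda x: math.log(x, base)  # noqa: E731
    total = 0.0
    for bs in sub_scores:
        if bs.S <= 0:
            raise ScoringError(f"sub-sequence score must be positive, got {bs.S}")
        total += bs.S * (1.0 + log(bs.S / S_core))
    m = len(sub_scores)
    return TotalScore(total / m, S_core, m)


def score_peptide(
    sequence: PeptideSequence,
    provider: PValueProvider,
    core: PeptideSequence,
    window_length: int = MAX_WINDOW_LENGTH,
    top_n: int = DEFAULT_TOP_N,
    log_base: float | str = "e",
    stride: int = 1,
) -> TotalScore:
    """Decompose, score each window, and aggregate against the core's score.

    The core motif (7 residues in the motivating screen, shorter than the
    window) is scored as a single whole-sequence window. When the provider
    returns more than ``top_n`` sites only the best ``top_n`` are summed;
    fewer sites are summed as-is.
    """

    def call(window: PeptideSequence) -> PValueSet:
        try:
            pset = provider(window)
        except Exception as exc:  # noqa: BLE001 - contract: name the window
            raise ProviderError(window.residues, exc) from exc
        if pset.n > top_n:
            pset = PValueSet(pset.window, pset.pvalues[:top_n])
        return pset

    decomposition = decompose(sequence, window_length, stride)
    sub_scores = [binding_score(call(win)) for _, win in decomposition.windows]
    core_score = binding_score(call(core))
    return total_score(sub_scores, core_score.S, log_base)


def rank_candidates(
    scored: Sequence[tuple[PeptideSequence, TotalScore | float]],
) -> list[tuple[PeptideSequence, float]]:
    """Order candidates by descending total score, ties lexicographic.

    Accepts either :class:`TotalScore` objects or bare floats; returns
    (sequence, score) pairs. Stable and deterministic.
    """
    pairs = [
        (seq, s.S_total if isinstance(s, TotalScore) else float(s))
        for seq, s in scored
    ]
    return sorted(pairs, key=lambda item: (-item[1], item[0].residues))


# ---------------------------------------------------------------------------
# Providers: TSV-backed (real predictor output) and a deterministic surrogate
# ---------------------------------------------------------------------------

class TableProvider:
    """P-value provider backed by tabular predictor output."""

    def __init__(self, table: Mapping[str, Sequence[float]]):
        self._table = {
            seq: PValueSet(parse_peptide(seq), tuple(ps)) for seq, ps in table.items()
        }

    def __call__(self, window: PeptideSequence) -> PValueSet:
        try:
            return self._table[window.residues]
        except KeyError:
            raise KeyError(f"no p-values for window {window.residues!r}") from None


def read_pvalue_table(path: str | Path) -> TableProvider:
    """Read a p-value TSV: columns ``window_sequence``, ``rank``, ``p_value``.

    One row per predicted site; rows are grouped by window and sorted by rank.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"window_sequence", "rank", "p_value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"p-value table missing columns: {sorted(missing)}")
    table = {
        str(seq): list(grp.sort_values("rank")["p_value"].astype(float))
        for seq, grp in df.groupby("window_sequence", sort=False)
    }
    return TableProvider(table)


class SurrogateProvider:
    """Deterministic composition-hash p-value provider for desk-scale runs.

    Each window's sequence is hashed (MD5, stable across processes) to seed a
    random generator that draws ``n_sites`` p-values uniformly from (0, 1].
    Basic residues (R, K, H) shift the draw toward smaller p-values, loosely
    mimicking the electrostatics-driven site predictions of the real
    predictor on an acidic receptor surface.
    """

    def __init__(self, n_sites: int = DEFAULT_TOP_N, seed: int = 0):
        if n_sites < 1:
            raise ScoringError("n_sites must be >= 1")
        self.n_sites = n_sites
        self.seed = seed

    def __call__(self, window: PeptideSequence) -> PValueSet:
        digest = hashlib.md5(
            f"{self.seed}:{window.residues}".encode()
        ).digest()
        rng = np.random.default_rng(int.from_bytes(digest[:8], "big"))
        basic_frac = sum(window.residues.count(r) for r in "RKH") / window.length
        # uniform draws sharpened by basic-residue content; exponent in [1, 3]
        draws = rng.uniform(size=self.n_sites) ** (1.0 + 2.0 * basic_frac)
        pvalues = tuple(float(min(max(p, 1e-6), 1.0)) for p in draws)
        return PValueSet(window, pvalues)
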