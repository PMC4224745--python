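"""Peptide sequences, constrained mutation spaces, and rule-based candidate generators.

The search space is anchored on a template peptide (the VEGF exon-6 fragment
QKRKRKKSRYKS in the motivating application) whose receptor-contact core motif
(RKRKKSR) is held fixed while flanking positions are mutated or extended.
Positions are 1-based and inclusive throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino acids, one-letter codes, alphabetical.
STANDARD_AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

_AA_SET = frozenset(STANDARD_AMINO_ACIDS)

#: Hydrophilic basic residues used by the basic-augmentation generator rule.
BASIC_RESIDUES: frozenset[str] = frozenset("RKH")

#: Strongly hydrophobic residues used by the hydrophobic-augmentation rule.
HYDROPHOBIC_RESIDUES: frozenset[str] = frozenset("ILVF")


class PeptideError(ValueError):
    """Base error for peptide-space validation failures."""


class InvalidResidueError(PeptideError):
    """A character outside the 20 standard one-letter codes."""

    def __init__(self, residue: str, position: int):
        self.residue = residue
        self.position = position
        super().__init__(
            f"invalid residue {residue!r} at position {position} "
            f"(expected one of {STANDARD_AMINO_ACIDS})"
        )


class MotifNotFoundError(PeptideError):
    """The core motif does not occur in the base sequence."""


class AmbiguousMotifError(PeptideError):
    """The core motif occurs more than once in the base sequence."""

    def __init__(self, motif: str, spans: list[tuple[int, int]]):
        self.spans = spans
        super().__init__(
            f"motif {motif!r} occurs at multiple spans: "
            + ", ".join(f"[{a},{b}]" for a, b in spans)
        )


@dataclass(frozen=True)
class PeptideSequence:
    """A validated peptide over the 20 standard one-letter amino-acid codes.

    Immutable and hashable; compares by residue string.
    """

    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise PeptideError("peptide must contain at least one residue")
        for i, ch in enumerate(self.residues, start=1):
            if ch not in _AA_SET:
                raise InvalidResidueError(ch, i)

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def __getitem__(self, item) -> str:
        return self.residues[item]


def parse_peptide(text: str) -> PeptideSequence:
    """Parse free text into a validated, upper-cased :class:`PeptideSequence`.

    Raises :class:`InvalidResidueError` naming the offending character and its
    1-based position, and :class:`PeptideError` on empty input.
    """
    cleaned = text.strip().upper()
    if not cleaned:
        raise PeptideError("empty peptide string")
    return PeptideSequence(cleaned)


def locate_core(base: PeptideSequence, motif: PeptideSequence) -> tuple[int, int]:
    """Locate the single exact occurrence of ``motif`` in ``base``.

    Returns the 1-based inclusive span ``(start, end)``. Raises
    :class:`MotifNotFoundError` if absent and :class:`AmbiguousMotifError`
    (listing every span) if the motif occurs more than once.
    """
    if motif.length > base.length:
        raise MotifNotFoundError(
            f"motif {motif.residues!r} longer than base {base.residues!r}"
        )
    spans: list[tuple[int, int]] = []
    start = base.residues.find(motif.residues)
    while start != -1:
        spans.append((start + 1, start + motif.length))
        start = base.residues.find(motif.residues, start + 1)
    if not spans:
        raise MotifNotFoundError(
            f"motif {motif.residues!r} not found in {base.residues!r}"
        )
    if len(spans) > 1:
        raise AmbiguousMotifError(motif.residues, spans)
    return spans[0]


@dataclass(frozen=True)
class MutableTemplate:
    """A base peptide with an immutable core span and a set of mutable positions.

    Invariants checked at construction: the base restricted to ``core_span``
    equals ``core_motif`` exactly; mutable positions are in range and disjoint
    from the core span.
    """

    base: PeptideSequence
    core_motif: PeptideSequence
    core_span: tuple[int, int]
    mutable_positions: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        start, end = self.core_span
        if not (1 <= start <= end <= self.base.length):
            raise PeptideError(f"core span [{start},{end}] out of range")
        if self.base.residues[start - 1 : end] != self.core_motif.residues:
            raise PeptideError(
                f"base[{start}:{end}] = {self.base.residues[start - 1:end]!r} "
                f"does not equal core motif {self.core_motif.residues!r}"
            )
        core_positions = set(range(start, end + 1))
        object.__setattr__(self, "mutable_positions", frozenset(self.mutable_positions))
        overlap = core_positions & self.mutable_positions
        if overlap:
            raise PeptideError(f"mutable positions {sorted(overlap)} overlap the core span")
        out_of_range = [p for p in self.mutable_positions if not 1 <= p <= self.base.length]
        if out_of_range:
            raise PeptideError(f"mutable positions {sorted(out_of_range)} out of range")

    @classmethod
    def from_sequences(
        cls,
        base: PeptideSequence | str,
        core: PeptideSequence | str,
        mutable_positions: Iterable[int],
    ) -> "MutableTemplate":
        """Build a template, locating the core automatically (must be unique)."""
        base_pep = base if isinstance(base, PeptideSequence) else parse_peptide(base)
        core_pep = core if isinstance(core, PeptideSequence) else parse_peptide(core)
        span = locate_core(base_pep, core_pep)
        return cls(base_pep, core_pep, span, frozenset(mutable_positions))

    def space_size(self, alphabet: Sequence[str] = STANDARD_AMINO_ACIDS) -> int:
        """|alphabet| ** |mutable positions| — the full variant count."""
        return len(alphabet) ** len(self.mutable_positions)


def enumerate_variants(
    template: MutableTemplate,
    alphabet: Sequence[str] = STANDARD_AMINO_ACIDS,
) -> Iterator[PeptideSequence]:
    """Lazily yield every variant of the template over ``alphabet``.

    All ``|alphabet| ** k`` combinations of the ``k`` mutable positions are
    produced in lexicographic order of the mutable-position residue tuple
    (positions sorted ascending). The core span is identical in every variant.
    An empty mutable set yields exactly the base sequence.
    """
    letters = sorted(set(alphabet))
    if not letters:
        raise PeptideError("alphabet must be non-empty")
    for ch in letters:
        if ch not in _AA_SET:
            raise InvalidResidueError(ch, 0)
    positions = sorted(template.mutable_positions)
    base = list(template.base.residues)
    if not positions:
        yield template.base
        return
    for combo in itertools.product(letters, repeat=len(positions)):
        seq = base.copy()
        for pos, res in zip(positions, combo):
            seq[pos - 1] = res
        yield PeptideSequence("".join(seq))


@dataclass(frozen=True)
class GeneratorRule:
    """A bounded terminal-augmentation rule around a fixed core.

    ``basic_augment`` grows hydrophilic basic flanks ({R,K,H}); the
    ``hydrophobic_augment`` mode appends strongly hydrophobic residues
    ({I,L,V,F}) at either terminus. Generation is made finite by
    ``max_insertions`` (total residues added across both termini) and capped
    at ``max_length`` residues overall (default 14).
    """

    mode: str
    terminal_alphabet: frozenset[str]
    max_length: int = 14
    max_insertions: int = 4

    def __post_init__(self) -> None:
        if self.mode not in ("basic_augment", "hydrophobic_augment"):
            raise PeptideError(f"unknown generator mode {self.mode!r}")
        alpha = frozenset(self.terminal_alphabet)
        object.__setattr__(self, "terminal_alphabet", alpha)
        if not alpha:
            raise PeptideError("terminal alphabet must be non-empty")
        bad = alpha - _AA_SET
        if bad:
            raise PeptideError(f"terminal alphabet contains non-standard residues {sorted(bad)}")
        if self.max_insertions < 0:
            raise PeptideError("max_insertions must be >= 0")

    @classmethod
    def basic(cls, max_length: int = 14, max_insertions: int = 4) -> "GeneratorRule":
        return cls("basic_augment", BASIC_RESIDUES, max_length, max_insertions)

    @classmethod
    def hydrophobic(cls, max_length: int = 14, max_insertions: int = 4) -> "GeneratorRule":
        return cls("hydrophobic_augment", HYDROPHOBIC_RESIDUES, max_length, max_insertions)


def generate_candidates(core: PeptideSequence, rule: GeneratorRule) -> list[PeptideSequence]:
    """Generate every flank-augmented candidate around ``core`` under ``rule``.

    Candidates are the core with an N-terminal flank of length ``a`` and a
    C-terminal flank of length ``b``, ``a + b <= max_insertions``, every flank
    residue drawn from ``rule.terminal_alphabet``, and total length capped at
    ``rule.max_length``. The output is deduplicated and returned in a
    deterministic order (ascending length, then lexicographic).
    """
    if rule.max_length < core.length:
        raise PeptideError(
            f"max_length {rule.max_length} shorter than core ({core.length} residues)"
        )
    letters = sorted(rule.terminal_alphabet)
    budget = min(rule.max_insertions, rule.max_length - core.length)
    seen: set[str] = set()
    out: list[PeptideSequence] = []
    for total in range(budget + 1):
        for n_len in range(total + 1):
            c_len = total - n_len
            for nflank in itertools.product(letters, repeat=n_len):
                for cflank in itertools.product(letters, repeat=c_len):
                    seq = "".join(nflank) + core.residues + "".join(cflank)
                    if seq not in seen:
                        seen.add(seq)
                        out.append(PeptideSequence(seq))
    out.sort(key=lambda p: (p.length, p.residues))
    return out


# ---------------------------------------------------------------------------
# Library I/O: FASTA and one-sequence-per-line plain text
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, PeptideSequence]]:
    """Read a peptide library from FASTA; returns (record id, sequence) pairs."""
    return [
        (rec.id, parse_peptide(str(rec.seq)))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(
    path: str | Path,
    peptides: Iterable[PeptideSequence],
    ids: Iterable[str] | None = None,
) -> int:
    """Write peptides to single-line FASTA; ids default to 1-based ranks."""
    peptides = list(peptides)
    if ids is None:
        ids = [str(i) for i in range(1, len(peptides) + 1)]
    records = [
        SeqRecord(Seq(p.residues), id=name, description="")
        for name, p in zip(ids, peptides, strict=True)
    ]
    with open(path, "w") as handle:
        return SeqIO.write(records, handle, "fasta-2line")


def read_plain(path: str | Path) -> list[PeptideSequence]:
    """Read one peptide per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(parse_peptide(line))
    return out
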