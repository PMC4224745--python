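"""End-to-end screen orchestration: candidates → energy triage → window scoring → report.

The screen mirrors the published workflow: constrained mutants and
flank-augmented candidates are triaged by a binding-energy oracle
(docking-style, kcal/mol), scored by the sliding-window binding-site
statistic, and reported side by side. Selection of a final shortlist
combines both metrics as a configurable union of top-k by each — the two
in-silico metrics are not commensurable, so neither is collapsed into the
other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .energy_search import (
    EnergyOracle,
    EnergyRecord,
    surrogate_energy,
    table_oracle_from_tsv,
)
from .fixtures import load_fixtures
from .peptide_space import (
    GeneratorRule,
    MutableTemplate,
    PeptideSequence,
    generate_candidates,
    parse_peptide,
    read_fasta,
    read_plain,
)
from .window_scoring import (
    PValueProvider,
    SurrogateProvider,
    read_pvalue_table,
    score_peptide,
)

logger = logging.getLogger("vegscreen")

#: Screen-wide defaults mirroring the published protocol.
DEFAULT_TEMPLATE = "QKRKRKKSRYKS"
DEFAULT_CORE = "RKRKKSR"
DEFAULT_MUTABLE_POSITIONS = (1, 2, 10, 11, 12)
DEFAULT_WINDOW_LENGTH = 10
DEFAULT_TOP_N = 10
DEFAULT_ENERGY_THRESHOLD = -5.2
DEFAULT_REFERENCE_IC50 = 464.0


@dataclass(frozen=True)
class ScreenConfig:
    """Flat configuration for a full screen run."""

    base: str = DEFAULT_TEMPLATE
    core: str = DEFAULT_CORE
    mutable_positions: tuple[int, ...] = DEFAULT_MUTABLE_POSITIONS
    candidate_source: str = "generate"  # "generate" | "fixtures" | file path
    oracle_source: str = "surrogate"  # "surrogate" | energy-table TSV path
    pvalue_source: str = "surrogate"  # "surrogate" | p-value TSV path
    window_length: int = DEFAULT_WINDOW_LENGTH
    log_base: str = "e"
    energy_threshold: float = DEFAULT_ENERGY_THRESHOLD
    reference_ic50: float = DEFAULT_REFERENCE_IC50
    top_k: int = 10
    max_insertions: int = 2
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "ScreenConfig":
        """Parse a flat ``key = value`` config file ('#' comments allowed)."""
        values: dict[str, object] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key == "mutable_positions":
                values[key] = tuple(int(p) for p in raw.split(",") if p.strip())
            elif key in ("window_length", "top_k", "seed", "max_insertions"):
                values[key] = int(raw)
            elif key in ("energy_threshold", "reference_ic50"):
                values[key] = float(raw)
            else:
                values[key] = raw
        return cls(**values)  # type: ignore[arg-type]


def _resolve_oracle(source: str) -> EnergyOracle:
    if source == "surrogate":
        return surrogate_energy
    return table_oracle_from_tsv(source)


def _resolve_provider(source: str, seed: int) -> PValueProvider:
    if source == "surrogate":
        return SurrogateProvider(seed=seed)
    return read_pvalue_table(source)


def _resolve_candidates(config: ScreenConfig) -> list[PeptideSequence]:
    src = config.candidate_source
    if src == "fixtures":
        fx = load_fixtures()
        seqs = (
            [r.sequence.residues for r in fx.table1]
            + [s.sequence for s in fx.table2]
            + [s.sequence for s in fx.table3]
        )
        out, seen = [], set()
        for s in seqs:
            if s not in seen:
                seen.add(s)
                out.append(parse_peptide(s))
        return out
    if src == "generate":
        core = parse_peptide(config.core)
        basic = generate_candidates(
            core, GeneratorRule.basic(max_insertions=config.max_insertions)
        )
        hydrophobic = generate_candidates(
            core, GeneratorRule.hydrophobic(max_insertions=config.max_insertions)
        )
        seen: set[str] = set()
        out = []
        for p in basic + hydrophobic:
            if p.residues not in seen:
                seen.add(p.residues)
                out.append(p)
        return out
    path = Path(src)
    if path.suffix.lower() in (".fasta", ".fa", ".faa"):
        return [seq for _, seq in read_fasta(path)]
    return read_plain(path)


def run_screen(config: ScreenConfig) -> pd.DataFrame:
    """Run the full screen and return the joined report.

    Columns: ``sequence``, ``energy_kcal_mol``, ``passes_energy``,
    ``total_score``, ``selected``, ``flag``. Candidates for which an oracle
    or provider lookup fails are flagged (flag names the failing stage),
    never silently dropped. Sorted by total score descending, then energy
    ascending, then sequence. Deterministic given the config and seed.
    """
    oracle = _resolve_oracle(config.oracle_source)
    provider = _resolve_provider(config.pvalue_source, config.seed)
    core = parse_peptide(config.core)
    candidates = _resolve_candidates(config)
    logger.info("screen: %d candidates (source=%s, seed=%d)",
                len(candidates), config.candidate_source, config.seed)

    rows = []
    n_flagged = 0
    for pep in candidates:
        row: dict[str, object] = {"sequence": pep.residues, "flag": ""}
        try:
            row["energy_kcal_mol"] = float(oracle(pep))
        except Exception as exc:  # noqa: BLE001 - flag, do not drop
            row["energy_kcal_mol"] = float("nan")
            row["flag"] = f"energy:{exc}"
        try:
            row["total_score"] = score_peptide(
                pep, provider, core,
                window_length=config.window_length,
                log_base=config.log_base if config.log_base == "e" else float(config.log_base),
            ).S_total
        except Exception as exc:  # noqa: BLE001
            row["total_score"] = float("nan")
            row["flag"] = (row["flag"] + ";" if row["flag"] else "") + f"score:{exc}"
        if row["flag"]:
            n_flagged += 1
        rows.append(row)

    report = pd.DataFrame(rows, columns=["sequence", "energy_kcal_mol", "total_score", "flag"])
    report["passes_energy"] = report["energy_kcal_mol"] <= config.energy_threshold
    # shortlist: union of top-k by each metric (metrics are incommensurable)
    by_energy = set(
        report.dropna(subset=["energy_kcal_mol"])
        .sort_values(["energy_kcal_mol", "sequence"])
        .head(config.top_k)["sequence"]
    )
    by_score = set(
        report.dropna(subset=["total_score"])
        .sort_values(["total_score", "sequence"], ascending=[False, True])
        .head(config.top_k)["sequence"]
    )
    report["selected"] = report["sequence"].isin(by_energy | by_score)
    report = report.sort_values(
        ["total_score", "energy_kcal_mol", "sequence"],
        ascending=[False, True, True],
        na_position="last",
    ).reset_index(drop=True)

    n_pass = int(report["passes_energy"].sum())
    logger.info(
        "screen: %d in = %d flagged + %d clean; %d pass energy <= %.2f; %d selected",
        len(report), n_flagged, len(report) - n_flagged, n_pass,
        config.energy_threshold, int(report["selected"].sum()),
    )
    return report


def fixtures_report() -> pd.DataFrame:
    """Fixtures-only report: the packaged energy and score tables joined.

    Reproduces the printed rankings — no oracle or provider is consulted.
    """
    fx = load_fixtures()
    energy = {r.sequence.residues: r.energy for r in fx.table1}
    energy[fx.table1_reference.sequence.residues] = fx.table1_reference.energy
    rows = []
    for table, label in ((fx.table2, "basic"), (fx.table3, "hydrophobic")):
        for s in table:
            rows.append(
                {
                    "sequence": s.sequence,
                    "design": label,
                    "number": s.number,
                    "total_score": s.score,
                    "energy_kcal_mol": energy.get(s.sequence),
                }
            )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["total_score", "sequence"], ascending=[False, True]
    ).reset_index(drop=True)


def energy_triage(records: list[EnergyRecord] | None = None,
                  threshold: float = DEFAULT_ENERGY_THRESHOLD) -> pd.DataFrame:
    """Inclusive energy filter over records (packaged table by default)."""
    from .energy_search import filter_by_energy

    if records is None:
        fx = load_fixtures()
        records = list(fx.table1) + [fx.table1_reference]
    kept = filter_by_energy(records, threshold)
    return pd.DataFrame(
        {
            "sequence": [r.sequence.residues for r in kept],
            "energy_kcal_mol": [r.energy for r in kept],
        }
    )
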