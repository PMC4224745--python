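"""One-site competition dose–response modelling and IC50 estimation.

Models a radioligand competition assay: a fixed tracer (e.g. 125I-labelled
VEGF) binds its receptor while an unlabelled competitor peptide at
concentration c displaces it. Bound signal follows the four-parameter
log-logistic competition curve

    y(c) = bottom + (top - bottom) / (1 + (c / IC50)^h),

with ``top`` the signal at zero competitor, ``bottom`` the non-specific
signal, ``IC50`` the half-maximal inhibitory concentration (nmol/L) and
``h`` the Hill slope. Lower IC50 means higher competitor affinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

#: The assay's competitor concentration series, nmol/L.
ASSAY_CONCENTRATIONS_NMOL_L: tuple[float, ...] = (0.0, 1.3, 6.5, 32.5, 65.0, 650.0, 6500.0)


class AssayError(ValueError):
    """Validation failure in assay simulation or fitting."""


@dataclass(frozen=True)
class ConcentrationSeries:
    """Ordered competitor concentrations (nmol/L); >= 4 points for fitting."""

    concentrations: tuple[float, ...] = ASSAY_CONCENTRATIONS_NMOL_L

    def __post_init__(self) -> None:
        c = self.concentrations
        if len(c) < 4:
            raise AssayError("need at least 4 concentrations for curve fitting")
        if any(x < 0 for x in c):
            raise AssayError("concentrations must be non-negative")
        nonzero = [x for x in c if x > 0]
        if any(b <= a for a, b in zip(nonzero, nonzero[1:])):
            raise AssayError("concentrations must be strictly increasing after zero")


@dataclass(frozen=True)
class DoseResponse:
    """Measured (concentration, bound signal) points, possibly replicated."""

    points: tuple[tuple[float, float], ...]
    replicates: int = 1

    def __post_init__(self) -> None:
        if not self.points:
            raise AssayError("empty dose-response data")
        if any(signal < 0 for _, signal in self.points):
            raise AssayError("signals must be non-negative")

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        arr = np.asarray(self.points, dtype=float)
        return arr[:, 0], arr[:, 1]

    def mean_by_concentration(self) -> tuple[np.ndarray, np.ndarray]:
        c, y = self.as_arrays()
        uniq = np.unique(c)
        means = np.array([y[c == u].mean() for u in uniq])
        return uniq, means


@dataclass(frozen=True)
class CompetitionModel:
    """Four-parameter one-site competition curve."""

    top: float
    bottom: float
    ic50: float
    hill: float = 1.0

    def __post_init__(self) -> None:
        if not self.top > self.bottom >= 0:
            raise AssayError(f"need top > bottom >= 0, got top={self.top}, bottom={self.bottom}")
        if self.ic50 <= 0:
            raise AssayError("IC50 must be positive")
        if self.hill <= 0:
            raise AssayError("Hill slope must be positive")

    def predict(self, concentrations: Sequence[float] | np.ndarray) -> np.ndarray:
        c = np.asarray(concentrations, dtype=float)
        return _competition_curve(c, self.top, self.bottom, self.ic50, self.hill)


def _competition_curve(
    c: np.ndarray, top: float, bottom: float, ic50: float, hill: float
) -> np.ndarray:
    # (0 / ic50)^h = 0, so the zero-concentration point pins y = top directly
    with np.errstate(divide="ignore"):
        ratio = np.where(c > 0, (c / ic50) ** hill, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio)


@dataclass(frozen=True)
class IC50Estimate:
    """Fitted IC50 with its standard error and an honest convergence flag."""

    ic50: float
    standard_error: float
    converged: bool
    residual_norm: float
    model: CompetitionModel | None = field(default=None, compare=False)


def simulate_competition(
    model: CompetitionModel,
    series: ConcentrationSeries = ConcentrationSeries(),
    noise_cv: float = 0.05,
    replicates: int = 2,
    seed: int = 0,
) -> DoseResponse:
    """Simulate a competition assay run with multiplicative Gaussian noise.

    Each replicate signal at concentration c is the model mean times
    ``(1 + noise_cv * N(0,1))``, truncated at zero (counts cannot go
    negative). ``noise_cv = 0`` puts every point exactly on the curve.
    Reproducible given the seed.
    """
    if noise_cv < 0:
        raise AssayError("noise_cv must be >= 0")
    if replicates < 1:
        raise AssayError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    points: list[tuple[float, float]] = []
    for c in series.concentrations:
        mean = float(model.predict([c])[0])
        for _ in range(replicates):
            signal = mean * (1.0 + noise_cv * rng.standard_normal()) if noise_cv > 0 else mean
            points.append((c, max(signal, 0.0)))
    return DoseResponse(tuple(points), replicates)


def fit_ic50(data: DoseResponse) -> IC50Estimate:
    """Least-squares fit of the four-parameter competition model.

    Initialisation: top = max mean signal, bottom = min mean signal, IC50 =
    geometric mid-concentration, Hill slope 1; bounds keep IC50 and the slope
    positive and ``bottom`` non-negative. Flat data (no dose-dependent
    inhibition) is flagged as non-converged with no IC50 reported.
    """
    c, y = data.as_arrays()
    if len(np.unique(c)) < 4:
        raise AssayError("need at least 4 distinct concentrations to fit")

    uniq, means = data.mean_by_concentration()
    span = means.max() - means.min()
    if span <= 0 or (means.max() > 0 and span / means.max() < 1e-6):
        return IC50Estimate(math.nan, math.nan, False, float(np.linalg.norm(y - y.mean())))

    nonzero = uniq[uniq > 0]
    ic50_init = float(np.exp(np.mean(np.log(nonzero))))
    p0 = [float(means.max()), float(means.min()), ic50_init, 1.0]
    lower = [0.0, 0.0, 1e-9, 1e-3]
    upper = [np.inf, np.inf, np.inf, 50.0]
    try:
        popt, pcov = curve_fit(
            _competition_curve, c, y, p0=p0, bounds=(lower, upper), maxfev=20000
        )
    except (RuntimeError, ValueError):
        return IC50Estimate(math.nan, math.nan, False, math.nan)

    top, bottom, ic50, hill = (float(v) for v in popt)
    residual = float(np.linalg.norm(y - _competition_curve(c, *popt)))
    se = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else math.nan
    converged = ic50 > 0 and top > bottom and np.isfinite(ic50)
    model = CompetitionModel(top, bottom, ic50, hill) if converged else None
    return IC50Estimate(ic50 if converged else math.nan, se, converged, residual, model)


def fold_affinity(reference_ic50: float, ic50: float) -> dict[str, float]:
    """Affinity fold-change of a candidate relative to the reference peptide.

    Returns the raw ratio reference/candidate plus one-decimal and
    nearest-integer roundings. A ratio above 1 means the candidate binds more
    strongly (lower IC50) than the reference.
    """
    if reference_ic50 <= 0 or ic50 <= 0:
        raise AssayError("IC50 values must be positive")
    ratio = reference_ic50 / ic50
    return {
        "fold": ratio,
        "fold_1dp": round(ratio, 1),
        "fold_int": int(round(ratio)),
    }


def count_better_than_reference(
    records: Iterable[tuple[str, float]], reference: float
) -> int:
    """Count candidates with IC50 strictly below the reference IC50."""
    if reference <= 0:
        raise AssayError("reference IC50 must be positive")
    return sum(1 for _, ic50 in records if ic50 < reference)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_dose_response(path: str | Path) -> DoseResponse:
    """Read a dose-response TSV: ``concentration_nmol_l``, ``signal``
    and an optional ``replicate`` column."""
    df = pd.read_csv(path, sep="\t")
    required = {"concentration_nmol_l", "signal"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dose-response table missing columns: {sorted(missing)}")
    points = tuple(
        (float(c), float(s)) for c, s in zip(df["concentration_nmol_l"], df["signal"])
    )
    replicates = (
        int(df.groupby("concentration_nmol_l").size().max())
        if "replicate" in df.columns
        else 1
    )
    return DoseResponse(points, replicates)


def write_dose_response(path: str | Path, data: DoseResponse) -> None:
    c, y = data.as_arrays()
    pd.DataFrame({"concentration_nmol_l": c, "signal": y}).to_csv(
        path, sep="\t", index=False
    )


def write_ic50_report(
    path: str | Path,
    rows: Iterable[tuple[str, IC50Estimate]],
    reference_ic50: float | None = None,
) -> None:
    """Write an IC50 report TSV: sequence, ic50_nmol_l, se, converged,
    fold_vs_reference (blank when no reference is given or the fit failed)."""
    out = []
    for seq, est in rows:
        fold = (
            fold_affinity(reference_ic50, est.ic50)["fold_1dp"]
            if reference_ic50 is not None and est.converged
            else math.nan
        )
        out.append(
            {
                "sequence": seq,
                "ic50_nmol_l": est.ic50,
                "se": est.standard_error,
                "converged": est.converged,
                "fold_vs_reference": fold,
            }
        )
    pd.DataFrame(out).to_csv(path, sep="\t", index=False)
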