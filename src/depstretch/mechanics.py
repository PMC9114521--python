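"""Strain and Young's-modulus analysis of per-cell length traces.

A trapped cell is imaged at fixed frame rate while a DEP stress stretches
it.  The detector reports a feature length L(t); the strain of a cell is

    strain = (Lmax - L0) / L0

with L0 = min L(t) and Lmax = max L(t) over the trace (the min/max rule:
the smallest detected length is the initial length, the largest the final
stretched length, regardless of when they occur).  Young's modulus is
stress / strain with a single stretching stress shared by all cells.

The stress can come from two places:

* calibration mode (default): from a reference (E_ref, strain_ref) pair,
  sigma = E_ref * strain_ref — the only mode with printed ground truth;
* physics mode: from the DEP stress relation in
  :mod:`depstretch.dielectrics` with a geometric constant from
  :mod:`depstretch.fieldsolver`.

Quality control: traces whose length collapses below a configurable
fraction of the starting value are flagged broken (lysed in the trap) and
excluded, as are non-positive/non-finite lengths and zero-strain cells;
exclusions are itemised, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InvalidTraceError",
    "LengthTrace",
    "StrainResult",
    "ModulusResult",
    "strain_from_trace",
    "calibrate_stress",
    "modulus_from_strain",
    "strain_interval_proportions",
    "population_summary",
    "analyze_traces",
    "DEFAULT_BROKEN_FRACTION",
]

#: A trace whose minimum length falls below this fraction of its starting
#: length is classified as a broken (lysed) cell.
DEFAULT_BROKEN_FRACTION = 0.5


class InvalidTraceError(ValueError):
    """Raised for traces that cannot define a strain at all."""


@dataclass(frozen=True)
class LengthTrace:
    """Detected length of one cell over time.

    ``times`` in seconds (strictly increasing), ``lengths`` in μm.
    ``group`` and ``batch_id`` are optional labels carried through the
    pipeline (e.g. "normal" / "treated", cycle number).
    """

    cell_id: str
    times: np.ndarray
    lengths: np.ndarray
    group: str | None = None
    batch_id: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        L = np.asarray(self.lengths, dtype=float)
        if t.ndim != 1 or L.ndim != 1 or t.size != L.size:
            raise InvalidTraceError("times and lengths must be 1D and equal length")
        if t.size and not np.all(np.diff(t) > 0):
            raise InvalidTraceError(f"times not strictly increasing for {self.cell_id}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "lengths", L)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class StrainResult:
    """Per-cell strain with QC verdict.

    ``qc_flag`` is one of ``ok``, ``null_strain``, ``broken``,
    ``nonfinite_length``, ``nonpositive_length``; ``valid`` means the cell
    enters group statistics (only ``ok``).
    """

    cell_id: str
    l0: float
    lmax: float
    strain: float
    valid: bool
    qc_flag: str
    group: str | None = None
    batch_id: str | None = None


@dataclass(frozen=True)
class ModulusResult:
    """Per-cell Young's modulus at a shared stretching stress."""

    cell_id: str
    strain: float
    stress: float
    modulus: float

    def __post_init__(self) -> None:
        if abs(self.modulus * self.strain - self.stress) > 1e-9 * max(
            abs(self.stress), 1.0
        ):
            raise ValueError("modulus * strain must recover stress")


def strain_from_trace(
    trace: LengthTrace, broken_fraction: float = DEFAULT_BROKEN_FRACTION
) -> StrainResult:
    """Strain of one trace by the min/max rule, with QC classification.

    L0 = min length, Lmax = max length; sample order is irrelevant.
    Fewer than two samples cannot define a stretch and raise
    :class:`InvalidTraceError`; other defects are returned as invalid
    results with a reason, so batch processing can tally them.
    """
    L = trace.lengths
    if L.size < 2:
        raise InvalidTraceError(
            f"trace {trace.cell_id}: need >= 2 samples, got {L.size}"
        )

    def _invalid(flag: str) -> StrainResult:
        return StrainResult(
            cell_id=trace.cell_id, l0=np.nan, lmax=np.nan, strain=np.nan,
            valid=False, qc_flag=flag, group=trace.group, batch_id=trace.batch_id,
        )

    if not np.all(np.isfinite(L)):
        return _invalid("nonfinite_length")
    if np.any(L <= 0):
        return _invalid("nonpositive_length")
    l0 = float(L.min())
    lmax = float(L.max())
    if l0 < broken_fraction * float(L[0]):
        return _invalid("broken")
    strain = (lmax - l0) / l0
    null = strain <= 0.0
    return StrainResult(
        cell_id=trace.cell_id, l0=l0, lmax=lmax, strain=strain,
        valid=not null, qc_flag="null_strain" if null else "ok",
        group=trace.group, batch_id=trace.batch_id,
    )


def calibrate_stress(e_ref: float, strain_ref: float) -> float:
    """Stretching stress (Pa) implied by a reference (modulus, strain) pair.

    Inverts E = sigma / strain: sigma = E_ref * strain_ref.
    """
    if not strain_ref > 0:
        raise ValueError(f"reference strain must be > 0, got {strain_ref}")
    return e_ref * strain_ref


def modulus_from_strain(
    strain: float, stress: float, cell_id: str = ""
) -> ModulusResult:
    """Per-cell Young's modulus at the shared stress: E = stress/strain."""
    if not strain > 0:
        raise ValueError(
            f"cell {cell_id or '<anon>'} unmeasurable: strain {strain} <= 0"
        )
    return ModulusResult(
        cell_id=cell_id, strain=strain, stress=stress, modulus=stress / strain
    )


def strain_interval_proportions(
    strains: Sequence[float],
    bin_width: float = 0.03,
    upper: float = 0.09,
) -> pd.Series:
    """Fraction of cells per half-open strain interval [lo, lo+width).

    Bins run from 0 to ``upper``; strains >= ``upper`` land in a final
    overflow bin.  Proportions sum to 1.  Mirrors interval-proportion
    histograms used to compare soft/stiff subpopulations.
    """
    s = np.asarray(strains, dtype=float)
    if s.size == 0:
        raise ValueError("no strains given")
    n_bins = int(round(upper / bin_width))
    if n_bins < 1 or abs(n_bins * bin_width - upper) > 1e-9:
        raise ValueError("upper must be a positive multiple of bin_width")
    edges = np.arange(n_bins + 1) * bin_width
    # half-open bins: index i for edges[i] <= s < edges[i+1]
    idx = np.searchsorted(edges, s, side="right") - 1
    counts = np.zeros(n_bins + 1, dtype=float)
    for i in idx:
        counts[min(max(i, 0), n_bins)] += 1
    labels = [f"[{edges[i]:g}, {edges[i+1]:g})" for i in range(n_bins)]
    labels.append(f">= {upper:g}")
    return pd.Series(counts / s.size, index=labels, name="proportion")


@dataclass(frozen=True)
class PopulationSummary:
    """n, mean, median and central-75% interval of a sample."""

    n: int
    mean: float
    median: float
    ci_low: float
    ci_high: float


def population_summary(values: Sequence[float]) -> PopulationSummary:
    """Summary statistics matching box-plot reporting: median with a
    central 75% interval (12.5th–87.5th percentiles) plus mean and n."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values given")
    lo, hi = np.percentile(v, [12.5, 87.5])
    return PopulationSummary(
        n=int(v.size), mean=float(v.mean()), median=float(np.median(v)),
        ci_low=float(lo), ci_high=float(hi),
    )


def analyze_traces(
    traces: Iterable[LengthTrace],
    stress: float,
    broken_fraction: float = DEFAULT_BROKEN_FRACTION,
) -> pd.DataFrame:
    """Run the strain → modulus pipeline over a set of traces.

    Returns one row per cell with columns cell_id, group, batch_id, l0_um,
    lmax_um, strain, stress_pa, modulus_pa, qc_flag.  Invalid cells keep
    their QC flag and carry NaN modulus; downstream statistics must filter
    on ``qc_flag == "ok"``.
    """
    rows = []
    for tr in traces:
        sr = strain_from_trace(tr, broken_fraction=broken_fraction)
        if sr.valid:
            modulus = stress / sr.strain
        else:
            modulus = np.nan
        rows.append(
            {
                "cell_id": sr.cell_id,
                "group": sr.group,
                "batch_id": sr.batch_id,
                "l0_um": sr.l0,
                "lmax_um": sr.lmax,
                "strain": sr.strain,
                "stress_pa": stress if sr.valid else np.nan,
                "modulus_pa": modulus,
                "qc_flag": sr.qc_flag,
            }
        )
    if not rows:
        raise ValueError("no traces to analyze")
    return pd.DataFrame(rows)
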