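"""Two-group comparison reports for strain/modulus populations.

Produces the descriptive comparison used to contrast a normal and a
drug-treated population: per-group n (after QC exclusions, itemised),
mean and median strain with a central-75% interval, a group Young's
modulus (stress over mean strain), the deltas, and an interval-proportion table
(fraction of cells per strain bin).  Inference is deliberately absent:
no hypothesis test is implied; callers may apply their own test to the
underlying per-cell tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .mechanics import population_summary, strain_interval_proportions

__all__ = ["GroupSummary", "ComparisonReport", "compare_groups"]


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n_input: int
    n_valid: int
    exclusions: dict
    mean_strain: float
    median_strain: float
    strain_ci_low: float
    strain_ci_high: float
    modulus_pa: float  # group modulus stress / mean strain


@dataclass(frozen=True)
class ComparisonReport:
    """Descriptive comparison of two analysed groups."""

    group_a: GroupSummary
    group_b: GroupSummary
    mean_strain_delta: float
    median_strain_delta: float
    modulus_delta_pa: float
    proportions: pd.DataFrame  # one column per group, bins as index

    def to_text(self) -> str:
        a, b = self.group_a, self.group_b
        lines = [
            f"{'':24s}{a.label:>14s}{b.label:>14s}",
            f"{'n (valid/input)':24s}{f'{a.n_valid}/{a.n_input}':>14s}"
            f"{f'{b.n_valid}/{b.n_input}':>14s}",
            f"{'mean strain':24s}{a.mean_strain:>14.4f}{b.mean_strain:>14.4f}",
            f"{'median strain':24s}{a.median_strain:>14.4f}{b.median_strain:>14.4f}",
            f"{'central 75% interval':24s}"
            f"{f'[{a.strain_ci_low:.4f},{a.strain_ci_high:.4f}]':>14s}"
            f"{f'[{b.strain_ci_low:.4f},{b.strain_ci_high:.4f}]':>14s}",
            f"{'group modulus (Pa)':24s}{a.modulus_pa:>14.1f}{b.modulus_pa:>14.1f}",
            "",
            f"delta mean strain   {self.mean_strain_delta:+.4f}",
            f"delta median strain {self.median_strain_delta:+.4f}",
            f"delta group modulus {self.modulus_delta_pa:+.1f} Pa",
            "",
            "strain-interval proportions:",
            self.proportions.to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


def _summarise(results: pd.DataFrame, label: str) -> GroupSummary:
    flags = results.qc_flag.value_counts().to_dict()
    ok = results[results.qc_flag == "ok"]
    if len(ok) == 0:
        raise ValueError(
            f"group {label!r} empty after QC; exclusions: {flags}"
        )
    s = population_summary(ok.strain.to_numpy())
    return GroupSummary(
        label=label,
        n_input=int(len(results)),
        n_valid=int(len(ok)),
        exclusions={k: int(v) for k, v in flags.items() if k != "ok"},
        mean_strain=s.mean,
        median_strain=s.median,
        strain_ci_low=s.ci_low,
        strain_ci_high=s.ci_high,
        modulus_pa=float(ok.stress_pa.iloc[0]) / s.mean,
    )


def compare_groups(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    bin_width: float = 0.03,
    upper: float = 0.09,
    labels: tuple[str, str] = ("a", "b"),
) -> ComparisonReport:
    """Compare two per-cell results tables (output of ``analyze_traces``).

    Both tables must retain at least one QC-passing cell; otherwise the
    error lists the exclusion tallies.
    """
    la = results_a.group.dropna().iloc[0] if results_a.group.notna().any() else labels[0]
    lb = results_b.group.dropna().iloc[0] if results_b.group.notna().any() else labels[1]
    ga = _summarise(results_a, str(la))
    gb = _summarise(results_b, str(lb))
    props = pd.DataFrame(
        {
            ga.label: strain_interval_proportions(
                results_a[results_a.qc_flag == "ok"].strain.to_numpy(),
                bin_width, upper,
            ),
            gb.label: strain_interval_proportions(
                results_b[results_b.qc_flag == "ok"].strain.to_numpy(),
                bin_width, upper,
            ),
        }
    )
    return ComparisonReport(
        group_a=ga,
        group_b=gb,
        mean_strain_delta=gb.mean_strain - ga.mean_strain,
        median_strain_delta=gb.median_strain - ga.median_strain,
        modulus_delta_pa=gb.modulus_pa - ga.modulus_pa,
        proportions=props,
    )
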