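"""Evaluation of computed vs experimental CCS.

Per-peptide percent errors, the 3%-threshold success classification, per-method
aggregates, best-of-dispersion-variant selection, signed overestimation and
the N-to-C-terminal compactness metric.  Statistics are always recomputed
from raw CCS values; rounding to the tables' one-decimal precision happens
only when classifying success (a value that prints as 3.0 counts as meeting a
3.0% threshold) and at presentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reference_data import ReferenceRecord
from .structures import Geometry

__all__ = [
    "EvaluationSummary",
    "percent_error",
    "signed_percent_deviation",
    "classify_success",
    "evaluate_method",
    "select_best_variant",
    "aggregate_best_variant",
    "dispersion_inflation",
    "n_to_c_distance",
]

#: Percent errors are classified at the precision experimental tables print.
_CLASSIFY_DECIMALS = 1


@dataclass(frozen=True)
class EvaluationSummary:
    """Aggregated accuracy of one CCS method over a reference set."""

    method: str
    per_peptide_errors: dict[str, float]  # absolute %, unrounded
    per_peptide_signed: dict[str, float]  # signed %, positive = overestimate
    mean_abs_error: float
    sd_abs_error: float  # sample SD (n-1)
    mean_signed_deviation: float
    sd_signed_deviation: float
    success_count: int
    n: int
    threshold: float

    @property
    def success_rate(self) -> float:
        return self.success_count / self.n


def percent_error(calc: float, exp: float) -> float:
    """Absolute percent error 100 |calc - exp| / exp."""
    if exp <= 0:
        raise ValueError("experimental CCS must be positive")
    return 100.0 * abs(calc - exp) / exp


def signed_percent_deviation(calc: float, exp: float) -> float:
    """Signed percent deviation 100 (calc - exp) / exp; positive means the
    computed CCS overestimates experiment."""
    if exp <= 0:
        raise ValueError("experimental CCS must be positive")
    return 100.0 * (calc - exp) / exp


def classify_success(error: float, threshold: float = 3.0) -> bool:
    """Whether a percent error meets the success threshold (inclusive).

    The error is first rounded to the tables' printed precision (1 decimal),
    so e.g. 3.04% prints as 3.0 and counts as a success at a 3% threshold.
    """
    if error < 0:
        raise ValueError("percent error must be nonnegative")
    return round(error, _CLASSIFY_DECIMALS) <= threshold


def _summary(
    method: str, peptides: list[str], calc: np.ndarray, exp: np.ndarray, threshold: float
) -> EvaluationSummary:
    errors = 100.0 * np.abs(calc - exp) / exp
    signed = 100.0 * (calc - exp) / exp
    successes = sum(classify_success(e, threshold) for e in errors)
    n = len(peptides)
    return EvaluationSummary(
        method=method,
        per_peptide_errors=dict(zip(peptides, errors.tolist())),
        per_peptide_signed=dict(zip(peptides, signed.tolist())),
        mean_abs_error=float(errors.mean()),
        sd_abs_error=float(errors.std(ddof=1)) if n > 1 else 0.0,
        mean_signed_deviation=float(signed.mean()),
        sd_signed_deviation=float(signed.std(ddof=1)) if n > 1 else 0.0,
        success_count=int(successes),
        n=n,
        threshold=threshold,
    )


def evaluate_method(
    records: list[ReferenceRecord], method: str, threshold: float = 3.0
) -> EvaluationSummary:
    """Accuracy summary of one method's CCS column against experiment."""
    for r in records:
        if method not in r.method_ccs:
            raise KeyError(f"record {r.peptide!r} has no method {method!r}")
    peptides = [r.peptide for r in records]
    calc = np.array([r.method_ccs[method] for r in records])
    exp = np.array([r.exp_ccs for r in records])
    return _summary(method, peptides, calc, exp, threshold)


def select_best_variant(
    record: ReferenceRecord, variant_a: str, variant_b: str
) -> tuple[str, float]:
    """The dispersion variant whose CCS better agrees with experiment.

    Ties go to ``variant_a`` (first listed)."""
    for v in (variant_a, variant_b):
        if v not in record.method_ccs:
            raise KeyError(f"record {record.peptide!r} has no method {v!r}")
    ea = percent_error(record.method_ccs[variant_a], record.exp_ccs)
    eb = percent_error(record.method_ccs[variant_b], record.exp_ccs)
    best = variant_a if ea <= eb else variant_b
    return best, record.method_ccs[best]


def aggregate_best_variant(
    records: list[ReferenceRecord],
    variant_a: str,
    variant_b: str,
    threshold: float = 3.0,
) -> EvaluationSummary:
    """Per-peptide best-of-two-variants selection, then method-style summary."""
    peptides = [r.peptide for r in records]
    calc = np.array(
        [select_best_variant(r, variant_a, variant_b)[1] for r in records]
    )
    exp = np.array([r.exp_ccs for r in records])
    return _summary(f"best({variant_a}, {variant_b})", peptides, calc, exp, threshold)


def dispersion_inflation(
    record: ReferenceRecord,
    uncorrected_method: str,
    dispersion_methods: tuple[str, str],
) -> float:
    """Percent CCS inflation of a dispersion-uncorrected structure.

    Compares the uncorrected method's CCS against the mean CCS of the two
    dispersion-corrected variants: 100 (CCS_uncorr - mean) / mean.
    """
    for m in (uncorrected_method, *dispersion_methods):
        if m not in record.method_ccs:
            raise KeyError(f"record {record.peptide!r} has no method {m!r}")
    disp = float(np.mean([record.method_ccs[m] for m in dispersion_methods]))
    return 100.0 * (record.method_ccs[uncorrected_method] - disp) / disp


def n_to_c_distance(
    geometry: Geometry, n_terminal_atom: int, c_alpha_atom: int
) -> float:
    """Distance (A) between the N-terminal amine nitrogen and the C-terminal
    Calpha — a compactness proxy for peptide ions."""
    n = len(geometry)
    for idx in (n_terminal_atom, c_alpha_atom):
        if not (0 <= idx < n):
            raise IndexError(f"atom index {idx} out of range for {n} atoms")
    d = geometry.positions[n_terminal_atom] - geometry.positions[c_alpha_atom]
    return float(np.linalg.norm(d))
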