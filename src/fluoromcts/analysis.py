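"""Post-run screening and statistics for generated candidates.

Three concerns:

* the three-way photophysics filter used to shortlist synthesizable
  fluorophores — bright absorption, visible-or-redder fluorescence of
  nonzero intensity, and a Stokes shift large enough to distinguish the
  emitted from the absorbed light;
* Pearson correlations between the structural descriptors (aromatic ring
  count, conjugate length) and the four photophysical quantities;
* run summaries: pass fraction, median generation order of the shortlist,
  and binned wavelength/intensity distributions stratified by structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import FilterInapplicableError, InputError, UndefinedCorrelationError
from .mcts import CandidateRecord
from .reward import PhotophysicalProfile

CRITERION_ABS_OS = "absorption_os"          # (i)
CRITERION_FL_WAVELENGTH = "fl_wavelength"   # (ii) wavelength part
CRITERION_FL_OS = "fl_os"                   # (ii) OS part
CRITERION_SHIFT = "stokes_shift"            # (iii)


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds of the candidate shortlist filter.

    Defaults: absorption OS > 0.1; fluorescence wavelength > 400 nm with
    OS > 0.01; absorption-to-fluorescence shift > 100 nm.  ``strict``
    controls whether boundary values fail (default) or pass.
    """

    min_abs_os: float = 0.1
    min_fl_wavelength: float = 400.0
    min_fl_os: float = 0.01
    min_shift: float = 100.0
    strict: bool = True

    def __post_init__(self) -> None:
        if min(self.min_abs_os, self.min_fl_wavelength,
               self.min_fl_os, self.min_shift) < 0:
            raise InputError("filter thresholds must be nonnegative")


def passes_filter(profile: PhotophysicalProfile,
                  criteria: FilterCriteria = FilterCriteria()
                  ) -> tuple[bool, list[str]]:
    """Apply the three filter conditions; returns (verdict, failed criteria)."""
    if not profile.ok:
        raise FilterInapplicableError("cannot filter a failed evaluation")
    exceeds = (lambda x, t: x > t) if criteria.strict else (lambda x, t: x >= t)
    failed = []
    if not exceeds(profile.a_i, criteria.min_abs_os):
        failed.append(CRITERION_ABS_OS)
    if not exceeds(profile.f_w, criteria.min_fl_wavelength):
        failed.append(CRITERION_FL_WAVELENGTH)
    if not exceeds(profile.f_i, criteria.min_fl_os):
        failed.append(CRITERION_FL_OS)
    if not exceeds(profile.f_w - profile.a_w, criteria.min_shift):
        failed.append(CRITERION_SHIFT)
    return not failed, failed


def percentage(count: int, total: int) -> float:
    """count/total as a percentage, rounded half-up to 2 decimals."""
    if total == 0:
        return 0.0
    frac = Decimal(count) * 100 / Decimal(total)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FilterSummary:
    n_pass: int
    n_total: int
    pass_percent: float  # 2-decimal half-up rounding


def filter_candidates(records: list[CandidateRecord],
                      criteria: FilterCriteria = FilterCriteria()
                      ) -> tuple[list[CandidateRecord], FilterSummary]:
    """Filter a run ledger, preserving generation order.

    Records whose evaluation failed cannot pass; they still count in the
    denominator (every produced candidate does).
    """
    if not records:
        raise InputError("empty record list")
    passed = [
        rec for rec in records
        if rec.profile.ok and passes_filter(rec.profile, criteria)[0]
    ]
    summary = FilterSummary(
        n_pass=len(passed), n_total=len(records),
        pass_percent=percentage(len(passed), len(records)))
    return passed, summary


def pearson_correlation(x, y) -> float:
    """Product-moment correlation coefficient in [-1, 1].

    Computed from centered sums directly; zero variance in either vector
    raises :class:`UndefinedCorrelationError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise InputError("need at least 3 observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        raise UndefinedCorrelationError("zero variance in input vector")
    r = float(dx @ dy) / np.sqrt(sxx * syy)
    return max(-1.0, min(1.0, r))


STRUCTURE_ROWS = ("n_aromatic_rings", "conjugate_length")
PROFILE_COLUMNS = ("a_w", "a_i", "f_w", "f_i")


def correlation_table(records: list[CandidateRecord]) -> pd.DataFrame:
    """2x4 table of Pearson R: structure descriptors vs photophysics.

    Rows: aromatic ring count, conjugate length.  Columns: absorption
    wavelength/OS, fluorescence wavelength/OS.
    """
    ok = [r for r in records if r.profile.ok]
    if len(ok) < 3:
        raise InputError("need at least 3 records with ok status")
    struct = {
        "n_aromatic_rings": [r.molecule.n_aromatic_rings for r in ok],
        "conjugate_length": [r.molecule.conjugate_length for r in ok],
    }
    photo = {c: [getattr(r.profile, c) for r in ok] for c in PROFILE_COLUMNS}
    table = pd.DataFrame(index=list(STRUCTURE_ROWS),
                         columns=list(PROFILE_COLUMNS), dtype=float)
    for row in STRUCTURE_ROWS:
        for col in PROFILE_COLUMNS:
            table.loc[row, col] = pearson_correlation(struct[row], photo[col])
    return table


@dataclass(frozen=True)
class RunSummary:
    n_total: int
    n_pass: int
    pass_percent: float
    median_generation_index: int | None  # lower median; None for empty subset
    binned: dict = field(hash=False, default_factory=dict)


def _lower_median(values: list[int]) -> int:
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def _wavelength_edges(w: np.ndarray) -> np.ndarray:
    top = max(1500.0, (float(w.max()) // 100.0 + 1.0) * 100.0) if len(w) else 1500.0
    return np.arange(0.0, top + 1e-9, 100.0)


def _os_edges(os_values: np.ndarray) -> np.ndarray:
    top = max(1.0, float(os_values.max()) + 1e-9) if len(os_values) else 1.0
    return np.linspace(0.0, top, 11)


def summarize_run(records: list[CandidateRecord],
                  filtered: list[CandidateRecord]) -> RunSummary:
    """Totals, pass fraction, median generation order of the shortlist, and
    binned (wavelength, OS) distributions stratified by structure.

    The binned structure maps mode ('absorption' | 'fluorescence') →
    stratifier ('n_aromatic_rings' | 'conjugate_length') → stratum value →
    2D count array over (wavelength, OS) bins.  Within each stratifier the
    counts sum to the number of ok records.
    """
    filtered_keys = {r.molecule.smiles_canonical for r in filtered}
    record_keys = {r.molecule.smiles_canonical for r in records}
    if not filtered_keys <= record_keys:
        raise InputError("filtered subset is not a subset of records")

    ok = [r for r in records if r.profile.ok]
    binned: dict = {}
    for mode, (w_attr, i_attr) in (("absorption", ("a_w", "a_i")),
                                   ("fluorescence", ("f_w", "f_i"))):
        binned[mode] = {}
        w = np.array([getattr(r.profile, w_attr) for r in ok])
        o = np.array([getattr(r.profile, i_attr) for r in ok])
        for strat in STRUCTURE_ROWS:
            values = np.array([getattr(r.molecule, strat) for r in ok])
            strata = {}
            for v in sorted(set(values.tolist())):
                mask = values == v
                counts, _, _ = np.histogram2d(
                    w[mask], o[mask], bins=[_wavelength_edges(w), _os_edges(o)])
                strata[int(v)] = counts
            binned[mode][strat] = strata

    median = _lower_median([r.generation_index for r in filtered]) if filtered else None
    return RunSummary(
        n_total=len(records), n_pass=len(filtered),
        pass_percent=percentage(len(filtered), len(records)),
        median_generation_index=median, binned=binned)
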