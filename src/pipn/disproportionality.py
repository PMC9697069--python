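"""Case/non-case disproportionality analysis of spontaneous-report data.

Within the stratum of reports listing a target drug (here paclitaxel), a
report is a *case* if it lists any term of the case definition (for PIPN:
peripheral neuropathy, peripheral sensory neuropathy, peripheral
sensorimotor neuropathy) and a *non-case* otherwise; it is *exposed* if it
also lists any member of a concomitant drug group.  The four cells are

====  ======================================
n11   exposed cases
n12   exposed non-cases
n21   unexposed cases
n22   unexposed non-cases
====  ======================================

The reporting odds ratio and its Woolf (log-normal) confidence interval are

    ROR = (n11/n21) / (n12/n22) = n11*n22 / (n12*n21)
    CI  = exp[ ln ROR  ±  z * sqrt(1/n11 + 1/n12 + 1/n21 + 1/n22) ]

with z = 1.96 for a 95% interval; the log is natural.  Association is also
tested with the 1-df Pearson chi-squared statistic, with Yates' continuity
correction applied when any cell count is below 5 (the default policy; the
textbook expected-count rule is available via ``yates_policy``).

Zero cells leave the ROR and CI undefined; by default this raises
:class:`~pipn.errors.UndefinedResultError`, and the opt-in Haldane–Anscombe
correction (+0.5 to every cell) is flagged in the result rather than applied
silently.

:func:`invert_counts` is a verification oracle for published analyses whose
2x2 cells were never printed: it enumerates the integer tables compatible
with a rounded ROR, a rounded CI and the printed margins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from pipn.errors import EmptyStratumError, UndefinedResultError, ValidationError
from pipn.report_model import AdverseEventReport, CaseDefinition, DrugGroup, ReportSet

logger = logging.getLogger(__name__)

#: The PIPN case definition: three preferred terms, matched exactly.
PIPN_CASE_DEFINITION = CaseDefinition(
    "pipn",
    frozenset(
        {
            "peripheral neuropathy",
            "peripheral sensory neuropathy",
            "peripheral sensorimotor neuropathy",
        }
    ),
)

#: Default pooled exposure class of alpha-1 adrenergic receptor antagonists.
ALPHA1_ANTAGONISTS = DrugGroup(
    "alpha1_antagonists",
    frozenset(
        {
            "tamsulosin",
            "doxazosin",
            "alfuzosin",
            "silodosin",
            "terazosin",
            "prazosin",
            "urapidil",
            "naftopidil",
        }
    ),
)


@dataclass(frozen=True)
class ContingencyTable:
    """The four cells of a case/non-case x exposed/unexposed 2x2 table."""

    n11: int  # exposed cases
    n12: int  # exposed non-cases
    n21: int  # unexposed cases
    n22: int  # unexposed non-cases

    def __post_init__(self) -> None:
        for name in ("n11", "n12", "n21", "n22"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValidationError(f"{name}={v!r} is not a non-negative integer")
            object.__setattr__(self, name, int(v))
        if self.total < 1:
            raise ValidationError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.n11 + self.n12 + self.n21 + self.n22

    @property
    def cases(self) -> int:
        return self.n11 + self.n21

    @property
    def exposed(self) -> int:
        return self.n11 + self.n12

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n11, self.n12, self.n21, self.n22)


@dataclass(frozen=True)
class SignalResult:
    """ROR, CI, chi-squared and reporting rates for one exposure group."""

    group_name: str
    table: ContingencyTable
    ror: float
    ci_low: float
    ci_high: float
    z: float
    chi2: float
    p_value: float
    yates_applied: bool
    haldane_applied: bool
    reporting_rate_exposed: float  # proportion of exposed reports that are cases
    reporting_rate_unexposed: float


def is_case(report: AdverseEventReport, cd: CaseDefinition) -> bool:
    """True iff the report lists any term of the case definition."""
    return not cd.terms.isdisjoint(report.events)


def select_target_reports(rs: ReportSet, target_drug: str) -> ReportSet:
    """Restrict a report set to the reports listing ``target_drug``."""
    subset = [r for r in rs if target_drug in r.drugs]
    if not subset:
        logger.warning("no report lists target drug %r", target_drug)
    return ReportSet(subset, provenance=f"{rs.provenance} | target={target_drug}")


def build_contingency(
    target_rs: ReportSet, group: DrugGroup, cd: CaseDefinition
) -> ContingencyTable:
    """Cross-classify a target-drug stratum by case status and exposure.

    ``target_rs`` must already be restricted to the target drug (the table
    always sums to ``len(target_rs)``).
    """
    if len(target_rs) == 0:
        raise EmptyStratumError("cannot build a contingency table on an empty stratum")
    n11 = n12 = n21 = n22 = 0
    for r in target_rs:
        exposed = not group.members.isdisjoint(r.drugs)
        case = is_case(r, cd)
        if exposed:
            n11 += case
            n12 += not case
        else:
            n21 += case
            n22 += not case
    return ContingencyTable(n11, n12, n21, n22)


def _cells(t: ContingencyTable, haldane: bool) -> tuple[float, float, float, float]:
    a, b, c, d = t.as_tuple()
    if haldane:
        return (a + 0.5, b + 0.5, c + 0.5, d + 0.5)
    if min(a, b, c, d) == 0:
        raise UndefinedResultError(
            f"ROR/CI undefined for zero cell in {t.as_tuple()}; "
            "pass haldane=True to apply the +0.5 Haldane-Anscombe correction"
        )
    return (float(a), float(b), float(c), float(d))


def ror(t: ContingencyTable, haldane: bool = False) -> float:
    """Reporting odds ratio (n11*n22)/(n12*n21), optionally Haldane-corrected."""
    a, b, c, d = _cells(t, haldane)
    return (a * d) / (b * c)


def ror_ci(
    t: ContingencyTable, z: float = 1.96, haldane: bool = False
) -> tuple[float, float]:
    """Woolf confidence interval exp(ln ROR ± z*SE), SE = sqrt(sum of 1/cell)."""
    a, b, c, d = _cells(t, haldane)
    log_ror = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (math.exp(log_ror - z * se), math.exp(log_ror + z * se))


def chi_squared(
    t: ContingencyTable, yates_policy: str = "observed"
) -> tuple[float, float, bool]:
    """1-df Pearson chi-squared for a 2x2 table with a Yates trigger policy.

    chi2 = N(|ad-bc|)^2 / (r1 r2 c1 c2); with Yates' correction |ad-bc| is
    reduced by N/2 (floored at zero).  ``yates_policy``:

    * ``"observed"`` (default) — correct when any observed cell is < 5;
    * ``"expected"`` — correct when any expected cell is < 5;
    * ``"always"`` / ``"never"`` — force the choice.

    A zero row or column margin yields (0.0, 1.0, False) — the degenerate
    table carries no association information.
    """
    a, b, c, d = (float(x) for x in t.as_tuple())
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return (0.0, 1.0, False)
    expected = np.array([r1 * c1, r1 * c2, r2 * c1, r2 * c2]) / n
    if yates_policy == "observed":
        yates = min(t.as_tuple()) < 5
    elif yates_policy == "expected":
        yates = bool(expected.min() < 5)
    elif yates_policy == "always":
        yates = True
    elif yates_policy == "never":
        yates = False
    else:
        raise ValidationError(f"unknown yates_policy {yates_policy!r}")
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2, 0.0)
    chi2 = n * diff**2 / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(chi2, df=1))
    return (float(chi2), p, yates)


def reporting_rate(rs: ReportSet, cd: CaseDefinition) -> float:
    """Proportion of reports in ``rs`` that are cases under ``cd``."""
    if len(rs) == 0:
        raise ValidationError("reporting rate undefined for an empty report set")
    return sum(is_case(r, cd) for r in rs) / len(rs)


def format_rate_pct(rate: float, decimals: int = 2) -> float:
    """Rate as a percentage rounded half-up to ``decimals`` (display rule)."""
    scale = 10**decimals
    return math.floor(rate * 100 * scale + 0.5) / scale


def signal_table(
    target_rs: ReportSet,
    groups: list[DrugGroup],
    cd: CaseDefinition,
    z: float = 1.96,
    yates_policy: str = "observed",
    haldane: bool = False,
) -> list[SignalResult]:
    """One :class:`SignalResult` per drug group, sorted by group name.

    A group whose table leaves the ROR undefined (zero cell, no Haldane) is
    reported with NaN ROR/CI rather than aborting the other groups.
    """
    if len(target_rs) == 0:
        raise EmptyStratumError("signal table requested on an empty stratum")
    results = []
    for group in sorted(groups, key=lambda g: g.name):
        t = build_contingency(target_rs, group, cd)
        try:
            r = ror(t, haldane)
            lo, hi = ror_ci(t, z, haldane)
        except UndefinedResultError:
            logger.warning("ROR undefined for group %r, table %s", group.name, t.as_tuple())
            r, lo, hi = math.nan, math.nan, math.nan
        chi2, p, yates = chi_squared(t, yates_policy)
        rate_exp = t.n11 / t.exposed if t.exposed else math.nan
        rate_unexp = t.n21 / (t.n21 + t.n22) if (t.n21 + t.n22) else math.nan
        results.append(
            SignalResult(
                group_name=group.name,
                table=t,
                ror=r,
                ci_low=lo,
                ci_high=hi,
                z=z,
                chi2=chi2,
                p_value=p,
                yates_applied=yates,
                haldane_applied=haldane and not math.isnan(r),
                reporting_rate_exposed=rate_exp,
                reporting_rate_unexposed=rate_unexp,
            )
        )
    return results


def invert_counts(
    ror_printed: float,
    ci_printed: tuple[float, float],
    total_reports: int,
    total_cases: int,
    decimals: int = 2,
) -> list[ContingencyTable]:
    """Enumerate the all-positive integer 2x2 tables consistent with a
    printed (rounded) ROR, a printed CI and the printed margins.

    The search fixes ``n11 + n21 = total_cases`` and the grand total, scans
    ``n11``, and for each ``n11`` bounds ``n12`` by inverting the ROR
    relation over the rounding interval of ``ror_printed``.  Every candidate
    whose recomputed ROR and CI round (half-up) to the printed values is
    returned; no match returns an empty list.
    """
    lo_p, hi_p = ci_printed
    if total_reports <= 0 or total_cases <= 0 or decimals < 1:
        raise ValidationError("totals must be positive and decimals >= 1")
    # a printed lower bound of 0.00 is legal (it rounds up from below 0.005)
    if lo_p > hi_p or ror_printed <= 0 or lo_p < 0:
        return []
    noncases = total_reports - total_cases
    if noncases <= 0:
        return []
    half = 0.5 * 10**-decimals
    matches: list[ContingencyTable] = []

    def _round(x: np.ndarray) -> np.ndarray:
        # round half up, matching the display rule
        return np.floor(x * 10**decimals + 0.5) / 10**decimals

    for n11 in range(1, total_cases):
        n21 = total_cases - n11
        # invert ror = n11*(noncases - n12) / (n12*n21) over the rounding interval
        lo_b, hi_b = [], []
        for r in (ror_printed - half, ror_printed + half):
            if r <= 0:
                continue
            n12_star = n11 * noncases / (r * n21 + n11)
            lo_b.append(n12_star)
            hi_b.append(n12_star)
        if not lo_b:
            continue
        n12_min = max(1, math.floor(min(lo_b)) - 2)
        n12_max = min(noncases - 1, math.ceil(max(hi_b)) + 2)
        if n12_min > n12_max:
            continue
        n12 = np.arange(n12_min, n12_max + 1)
        n22 = noncases - n12
        ror_v = (n11 * n22) / (n12 * n21)
        log_ror = np.log(ror_v)
        se = np.sqrt(1 / n11 + 1 / n12 + 1 / n21 + 1 / n22)
        ci_lo = np.exp(log_ror - 1.96 * se)
        ci_hi = np.exp(log_ror + 1.96 * se)
        ok = (
            (_round(ror_v) == round(ror_printed, decimals))
            & (_round(ci_lo) == round(lo_p, decimals))
            & (_round(ci_hi) == round(hi_p, decimals))
        )
        for m in n12[ok]:
            matches.append(ContingencyTable(n11, int(m), n21, int(noncases - m)))
    return matches
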