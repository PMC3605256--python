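"""Exact 2x2 case-control association from carrier tables.

Given carrier counts at a locus (case carriers / case non-carriers /
control carriers / control non-carriers) this module computes:

* Fisher exact p-values (two-sided by the minimum-likelihood rule,
  one-sided for carrier enrichment in cases),
* odds ratios, either the sample (cross-product) OR or the conditional
  maximum-likelihood OR of the noncentral hypergeometric model, and
* confidence intervals, either Woolf (log-OR +/- 1.96 SE) or the exact
  conditional interval obtained by inverting the exact test.

Tables with a zero cell have an undefined or infinite sample OR; the
``zero_policy`` argument selects between raising, Haldane-Anscombe
correction (+0.5 to every cell) and reporting an infinite OR with its
exact conditional lower bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

__all__ = [
    "CarrierTable",
    "AssociationResult",
    "carrier_table",
    "fisher_exact",
    "odds_ratio",
    "combine_counts",
]


@dataclass(frozen=True)
class CarrierTable:
    """2x2 carrier-by-status table."""

    case_carriers: int
    case_noncarriers: int
    control_carriers: int
    control_noncarriers: int

    def __post_init__(self):
        cells = self.as_tuple()
        if any(c < 0 for c in cells):
            raise ValueError("carrier table cells must be non-negative")
        if sum(cells) == 0:
            raise ValueError("carrier table is all zero")

    def as_tuple(self):
        return (
            self.case_carriers,
            self.case_noncarriers,
            self.control_carriers,
            self.control_noncarriers,
        )

    def as_matrix(self):
        a, b, c, d = self.as_tuple()
        return [[a, b], [c, d]]

    @property
    def n_cases(self) -> int:
        return self.case_carriers + self.case_noncarriers

    @property
    def n_controls(self) -> int:
        return self.control_carriers + self.control_noncarriers

    @property
    def case_frequency(self) -> float:
        """Carrier frequency among cases (fraction, not percent)."""
        return self.case_carriers / self.n_cases

    @property
    def control_frequency(self) -> float:
        return self.control_carriers / self.n_controls


@dataclass
class AssociationResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_two_sided: float
    p_one_sided: float
    method: str  # sample | conditional_mle
    ci_method: str  # woolf | exact_conditional


def carrier_table(carriers, samples) -> CarrierTable:
    """Build a carrier table from a carrier set (or CNVRegion) and a sample sheet.

    ``carriers`` may be a set of sample ids or any object with a
    ``carrier_samples`` attribute.  Every carrier id must be present in the
    sheet; the four counts partition the sheet by status x carriage.
    """
    ids = getattr(carriers, "carrier_samples", carriers)
    ids = set(ids)
    sheet_ids = set(samples.sample_ids)
    missing = ids - sheet_ids
    if missing:
        raise KeyError(f"carrier ids absent from sample sheet: {sorted(missing)[:5]}")
    df = samples.df
    is_carrier = df["sample_id"].isin(ids)
    is_case = df["status"] == "case"
    return CarrierTable(
        case_carriers=int((is_case & is_carrier).sum()),
        case_noncarriers=int((is_case & ~is_carrier).sum()),
        control_carriers=int((~is_case & is_carrier).sum()),
        control_noncarriers=int((~is_case & ~is_carrier).sum()),
    )


def fisher_exact(table: CarrierTable) -> tuple:
    """Fisher exact p-values for a carrier table.

    Returns ``(p_two_sided, p_one_sided)``.  The two-sided p sums the
    probabilities of all tables with the observed margins whose point
    probability does not exceed the observed table's; the one-sided p sums
    the case-enrichment tail.
    """
    m = table.as_matrix()
    p_two = float(stats.fisher_exact(m, alternative="two-sided")[1])
    p_one = float(stats.fisher_exact(m, alternative="greater")[1])
    return (min(p_two, 1.0), min(p_one, 1.0))


def _woolf_ci(a, b, c, d, level=0.95):
    z = stats.norm.ppf(0.5 + level / 2)
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def odds_ratio(
    table: CarrierTable,
    method: str = "conditional_mle",
    ci_method: str = "exact_conditional",
    zero_policy: str = "infinite",
    level: float = 0.95,
) -> AssociationResult:
    """Odds ratio with confidence interval and Fisher exact p-values.

    ``method='sample'`` gives the cross-product (a*d)/(b*c);
    ``method='conditional_mle'`` maximizes the noncentral hypergeometric
    likelihood given the table margins (the estimate printed by exact
    tests).  ``ci_method`` is ``'woolf'`` or ``'exact_conditional'``.

    When a zero cell makes the sample OR undefined/infinite:
    ``zero_policy='strict'`` raises; ``'haldane'`` adds 0.5 to every cell
    (sample method only); ``'infinite'`` reports ``inf`` (or 0) with the
    exact conditional interval, whose finite bound is still informative.
    """
    if method not in ("sample", "conditional_mle"):
        raise ValueError(f"unknown OR method {method!r}")
    if ci_method not in ("woolf", "exact_conditional"):
        raise ValueError(f"unknown CI method {ci_method!r}")
    a, b, c, d = table.as_tuple()
    p_two, p_one = fisher_exact(table)
    has_zero = 0 in (a, b, c, d)

    if method == "sample":
        if has_zero:
            if zero_policy == "strict":
                raise ZeroDivisionError("sample OR undefined for table with a zero cell")
            if zero_policy == "haldane":
                a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
                or_ = (a2 * d2) / (b2 * c2)
            else:  # infinite
                or_ = math.inf if b * c == 0 else 0.0
        else:
            or_ = (a * d) / (b * c)
    else:
        res = _scipy_odds_ratio(table.as_matrix(), kind="conditional")
        or_ = float(res.statistic)

    if ci_method == "woolf":
        if has_zero:
            if zero_policy == "haldane":
                lo, hi = _woolf_ci(a + 0.5, b + 0.5, c + 0.5, d + 0.5, level)
            elif zero_policy == "strict":
                raise ZeroDivisionError("Woolf CI undefined for table with a zero cell")
            else:
                lo, hi = 0.0, math.inf
        else:
            lo, hi = _woolf_ci(a, b, c, d, level)
    else:
        res = _scipy_odds_ratio(table.as_matrix(), kind="conditional")
        ci = res.confidence_interval(confidence_level=level)
        lo, hi = float(ci.low), float(ci.high)

    return AssociationResult(
        odds_ratio=or_,
        ci_low=lo,
        ci_high=hi,
        p_two_sided=p_two,
        p_one_sided=p_one,
        method=method,
        ci_method=ci_method,
    )


def combine_counts(tables: list) -> CarrierTable:
    """Cellwise sum of carrier tables (combining cohorts)."""
    if not tables:
        raise ValueError("combine_counts requires at least one table")
    a = sum(t.case_carriers for t in tables)
    b = sum(t.case_noncarriers for t in tables)
    c = sum(t.control_carriers for t in tables)
    d = sum(t.control_noncarriers for t in tables)
    return CarrierTable(a, b, c, d)
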