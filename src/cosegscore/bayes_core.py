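"""Closed-form arithmetic of the points-based Bayesian variant-classification
framework.

Evidence for or against pathogenicity is expressed on a log-odds "points"
scale: +1 point is supporting, +2 moderate, +4 strong and +8 very strong
evidence.  A piece of evidence worth ``p`` points carries conditional odds of
pathogenicity of ``base ** (p / 6)`` with ``base = 81``, and the posterior
probability of pathogenicity follows from combining those odds with a prior
of 0.102 in a naive Bayesian classifier:

    posterior(p) = prior_odds * 81**(p/6) / (1 + prior_odds * 81**(p/6))

Diagnostic yield (the fraction of phenotype-matched probands in whom a
causative variant is found in a given gene) is treated as a hypothetical
posterior probability and converted back to points on a half-point grid,
always rounding *down* so the evidence strength is never overstated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "BayesConfig",
    "StrengthLabel",
    "DEFAULT_CONFIG",
    "odds_from_points",
    "points_from_odds",
    "posterior_from_points",
    "yield_to_points",
    "generate_table2",
    "classify_points",
    "strength_label",
    "POINTS_GRID",
    "STRENGTH_BANDS",
]


@dataclass(frozen=True)
class BayesConfig:
    """Numeric basis of the points framework.

    prior_probability
        Prior probability that a rare variant in an established disease gene
        is pathogenic (0.102 in the points framework this package follows).
    odds_per_point_base, points_per_exponent_unit
        Conditional odds for ``p`` points are
        ``odds_per_point_base ** (p / points_per_exponent_unit)``.  The
        defaults (81, 6) make +6 points worth odds of exactly 81:1.  An
        alternative basis (e.g. supporting odds 2.0:1 with prior 0.125,
        i.e. base 256, exponent unit 8 -- 2**p) may be supplied here.
    """

    prior_probability: float = 0.102
    odds_per_point_base: float = 81.0
    points_per_exponent_unit: float = 6.0

    def __post_init__(self) -> None:
        if not (0.0 < self.prior_probability < 1.0):
            raise ValueError("prior_probability must lie strictly in (0, 1)")
        if not (self.odds_per_point_base > 1.0):
            raise ValueError("odds_per_point_base must exceed 1")
        if not (self.points_per_exponent_unit > 0.0):
            raise ValueError("points_per_exponent_unit must be positive")

    @property
    def prior_odds(self) -> float:
        return self.prior_probability / (1.0 - self.prior_probability)


DEFAULT_CONFIG = BayesConfig()

#: Half-point lookup grid used for yield -> points conversion.  The printed
#: conversion table starts at +1.0; the grid additionally carries +0.5 so
#: that evidence divided across many variants still lands on a defined row.
POINTS_GRID: tuple[float, ...] = tuple(0.5 * k for k in range(1, 25))


def _require_finite(value: float, name: str) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


def odds_from_points(p: float, cfg: BayesConfig = DEFAULT_CONFIG) -> float:
    """Conditional odds of pathogenicity for an evidence weight of ``p`` points.

    ``odds_from_points(6.0)`` is exactly 81.0 under the default basis and
    ``odds_from_points(0.0)`` is 1.0 (no evidence).
    """
    p = _require_finite(p, "points")
    return cfg.odds_per_point_base ** (p / cfg.points_per_exponent_unit)


def points_from_odds(odds: float, cfg: BayesConfig = DEFAULT_CONFIG) -> float:
    """Inverse of :func:`odds_from_points`."""
    odds = _require_finite(odds, "odds")
    if odds <= 0.0:
        raise ValueError("odds must be positive")
    return math.log(odds) / math.log(cfg.odds_per_point_base) * cfg.points_per_exponent_unit


def posterior_from_points(p: float, cfg: BayesConfig = DEFAULT_CONFIG) -> float:
    """Posterior probability of pathogenicity after ``p`` points of evidence.

    Combines the prior odds with the conditional odds multiplicatively;
    ``posterior_from_points(0.0)`` recovers the prior.
    """
    joint = cfg.prior_odds * odds_from_points(p, cfg)
    return joint / (1.0 + joint)


def _printed_percent(probability: float) -> float:
    """Round a probability to the table's printed precision (0.1%)."""
    return round(probability * 100.0, 1)


def yield_to_points(
    diagnostic_yield: float,
    cfg: BayesConfig = DEFAULT_CONFIG,
    min_yield: float = 0.20,
) -> float:
    """Convert a diagnostic yield (hypothetical posterior) to evidence points.

    Returns the largest grid value ``p`` (0.5 ... 12.0, half-point steps)
    whose posterior, at the table's printed precision of 0.1 percentage
    point, does not exceed the yield -- i.e. the yield is rounded *down* to
    the nearest table row.  Yields below ``min_yield`` (default 20%, the
    recommended floor for phenotype-specificity evidence, equivalent to a
    minimum of +1.0 points) return 0.  Pass ``min_yield=0.0`` when
    converting posterior shares of an allele divided across variants.
    """
    diagnostic_yield = float(diagnostic_yield)
    if not (0.0 <= diagnostic_yield <= 1.0):
        raise ValueError(f"diagnostic yield must lie in [0, 1], got {diagnostic_yield!r}")
    if diagnostic_yield < min_yield:
        return 0.0
    target = _printed_percent(diagnostic_yield)
    best = 0.0
    for p in POINTS_GRID:
        if _printed_percent(posterior_from_points(p, cfg)) <= target + 1e-9:
            best = p
        else:
            break
    return best


def generate_table2(cfg: BayesConfig = DEFAULT_CONFIG) -> list[tuple[float, float]]:
    """Regenerate the diagnostic-yield -> points conversion table.

    Returns ``(yield_percent, points)`` pairs for points 12.0 down to 1.0 in
    half-point steps (23 rows), with yields rounded to one decimal percent,
    matching the published table row for row.
    """
    rows = []
    for k in range(24, 1, -1):  # 12.0 down to 1.0
        p = 0.5 * k
        rows.append((_printed_percent(posterior_from_points(p, cfg)), p))
    return rows


def classify_points(total_points: float) -> str:
    """Five-tier classification from the summed evidence points.

    >= +10 pathogenic, +6..+9.9 likely pathogenic, above -1 uncertain,
    -1..-6.9 likely benign, <= -7 benign.
    """
    total_points = _require_finite(total_points, "total_points")
    if total_points >= 10.0:
        return "Pathogenic"
    if total_points >= 6.0:
        return "Likely pathogenic"
    if total_points > -1.0:
        return "Uncertain significance"
    if total_points > -7.0:
        return "Likely benign"
    return "Benign"


@dataclass(frozen=True)
class StrengthLabel:
    """A combined PP1/PP4 strength band: the point interval and the maximum
    allowable combination of criterion strengths for curation platforms that
    do not accommodate raw points."""

    combined_code: str
    point_band: tuple[float, float] = field(default=(0.0, math.inf))


#: (lower bound, upper bound, maximum allowable strength of combined codes).
STRENGTH_BANDS: tuple[tuple[float, float, str], ...] = (
    (0.0, 1.0, "not applicable"),
    (1.0, 2.0, "PP1_Supporting or PP4_Supporting"),
    (2.0, 3.0, "PP1_Moderate or PP4_Moderate or PP1_Supporting + PP4_Supporting"),
    (3.0, 4.0, "PP1_Supporting + PP4_Moderate or PP4_Supporting + PP1_Moderate"),
    (4.0, 5.0, "PP1_Strong or PP4_Strong or PP1_Moderate + PP4_Moderate"),
    (5.0, math.inf, "PP1_Strong + PP4_Supporting or PP4_Strong + PP1_Supporting"),
)


def strength_label(combined_pp1_pp4_points: float) -> StrengthLabel:
    """Map capped, non-negative combined PP1+PP4 points to the strength band
    usable on code-based curation platforms."""
    p = _require_finite(combined_pp1_pp4_points, "combined points")
    if p < 0.0:
        raise ValueError(
            "combined PP1/PP4 points must be non-negative; "
            "non-segregation evidence (BS4) is labeled separately"
        )
    for lo, hi, code in STRENGTH_BANDS:
        if lo <= p < hi:
            return StrengthLabel(combined_code=code, point_band=(lo, hi))
    raise AssertionError("strength bands must cover [0, inf)")
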