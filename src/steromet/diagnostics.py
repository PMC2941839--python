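"""Diagnostic ratio evaluation, disorder calling, and group totals.

A ratio is the sum of measured numerator analytes over the sum of measured
denominator analytes.  Analytes absent from a profile contribute nothing
(they are recorded); a ratio whose denominator analytes are all absent, or
sum to zero, is *undefined* — undefined is a value, not an error.

A disorder is called positive only when **all** of its ratios are flagged
high and none is undefined.  Positive calls are ranked by the geometric
mean of ``value / p95`` across the disorder's ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .profile_io import SteroidProfile
from .reference import Flag, ReferenceSet, flag_value
from .registry import GROUPS, RatioDefinition, Registry

__all__ = [
    "RatioResult",
    "DisorderCall",
    "ratio_value",
    "compute_ratio",
    "evaluate_panel",
    "group_totals",
]


@dataclass(frozen=True)
class RatioResult:
    ratio_id: str
    disorder: str
    value: float | None
    numerator_sum: float
    denominator_sum: float
    flag: Flag = Flag.UNDEFINED
    centile_excess: float | None = None  # value / p95, for ranking
    missing: tuple[str, ...] = ()


@dataclass(frozen=True)
class DisorderCall:
    disorder: str
    gene: str
    n_ratios: int
    n_high: int
    n_undefined: int
    positive: bool
    rank_score: float | None

    def __post_init__(self) -> None:
        assert self.positive == (self.n_high == self.n_ratios and self.n_undefined == 0)


def ratio_value(profile: SteroidProfile, definition: RatioDefinition) -> float | None:
    """Bare ratio value, or ``None`` when the denominator is undefined."""
    den = [profile.amounts[a] for a in definition.denominator if a in profile.amounts]
    if not den or sum(den) == 0:
        return None
    num = sum(profile.amounts.get(a, 0.0) for a in definition.numerator)
    return num / sum(den)


def compute_ratio(
    profile: SteroidProfile,
    definition: RatioDefinition,
    reference: ReferenceSet | None = None,
) -> RatioResult:
    """Evaluate one diagnostic ratio on a profile.

    When a reference set is given and holds a range for the ratio, the
    result carries a flag and a ``value / p95`` centile excess.
    """
    num_present = [a for a in definition.numerator if a in profile.amounts]
    den_present = [a for a in definition.denominator if a in profile.amounts]
    missing = tuple(
        a
        for a in (*definition.numerator, *definition.denominator)
        if a not in profile.amounts
    )
    numerator_sum = sum(profile.amounts[a] for a in num_present)
    denominator_sum = sum(profile.amounts[a] for a in den_present)
    value = None if (not den_present or denominator_sum == 0) else numerator_sum / denominator_sum

    flag = Flag.UNDEFINED
    excess = None
    if reference is not None:
        rng = reference.get(definition.id)
        if rng is not None:
            flag = flag_value(value, rng)
            if value is not None and rng.p95 > 0:
                excess = value / rng.p95
    return RatioResult(
        ratio_id=definition.id,
        disorder=definition.disorder,
        value=value,
        numerator_sum=numerator_sum,
        denominator_sum=denominator_sum,
        flag=flag,
        centile_excess=excess,
        missing=missing,
    )


def evaluate_panel(
    profile: SteroidProfile,
    registry: Registry,
    reference: ReferenceSet,
) -> tuple[list[RatioResult], list[DisorderCall]]:
    """Evaluate the full ratio panel and derive one call per disorder.

    Returns one :class:`RatioResult` per registry ratio (panel order) and
    one :class:`DisorderCall` per disorder, positives first in descending
    rank order.
    """
    reference.require_version(registry)
    results = [compute_ratio(profile, rd, reference) for rd in registry.ratios]
    by_disorder: dict[str, list[RatioResult]] = {}
    for r in results:
        by_disorder.setdefault(r.disorder, []).append(r)

    calls: list[DisorderCall] = []
    for disorder in registry.disorders:
        rs = by_disorder[disorder]
        gene = registry.ratios_for(disorder)[0].gene
        n_high = sum(1 for r in rs if r.flag is Flag.HIGH)
        n_undefined = sum(1 for r in rs if r.value is None)
        positive = n_high == len(rs) and n_undefined == 0
        excesses = [r.centile_excess for r in rs]
        if any(e is None or e <= 0 for e in excesses):
            rank = None
        else:
            rank = math.exp(sum(math.log(e) for e in excesses) / len(excesses))
        calls.append(
            DisorderCall(
                disorder=disorder,
                gene=gene,
                n_ratios=len(rs),
                n_high=n_high,
                n_undefined=n_undefined,
                positive=positive,
                rank_score=rank,
            )
        )
    calls.sort(key=lambda c: (not c.positive, -(c.rank_score if c.rank_score is not None else -math.inf)))
    return results, calls


def group_totals(profile: SteroidProfile, registry: Registry) -> dict[str, float]:
    """Sum each analyte into its (single) report group; requires 24-h urine."""
    if profile.collection != "24h":
        raise ValueError(
            "quantitative grouping requires a 24-h collection; "
            f"profile {profile.sample_id!r} is {profile.collection!r}"
        )
    totals = {group: 0.0 for group in GROUPS}
    for abbr, amount in profile.amounts.items():
        totals[registry.group_of(abbr)] += amount
    return totals
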