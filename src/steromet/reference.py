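"""Reference ranges (mean, 5th and 95th centiles) from a normal cohort.

Ranges are built for every analyte, every report group, and every
diagnostic ratio that is evaluable in enough cohort profiles.  Centiles
are empirical: linear interpolation between order statistics at plotting
position ``(n - 1) * p + 1`` on the natural (untransformed) scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np

from .profile_io import SteroidProfile
from .registry import GROUPS, Registry

__all__ = [
    "Flag",
    "ReferenceRange",
    "ReferenceSet",
    "ReferenceError",
    "build_reference",
    "flag_value",
]

DEFAULT_MIN_COHORT = 20


class ReferenceError(ValueError):
    """Cohort too small, or a reference set applied under the wrong registry."""


class Flag(str, Enum):
    LOW = "low"
    NORMAL = "normal"
    HIGH = "high"
    UNDEFINED = "undefined"


@dataclass(frozen=True)
class ReferenceRange:
    """Cohort summary for one key (analyte abbr, group label, or ratio id)."""

    key: str
    n: int
    mean: float
    p5: float
    p95: float

    def __post_init__(self) -> None:
        if self.p5 > self.p95:
            raise ReferenceError(f"range for {self.key!r}: p5 > p95")


def _centiles(values: np.ndarray) -> tuple[float, float, float]:
    return (
        float(np.mean(values)),
        float(np.quantile(values, 0.05)),
        float(np.quantile(values, 0.95)),
    )


def flag_value(value: float | None, range: ReferenceRange) -> Flag:
    """Flag an observation against a range.

    ``None`` (not computable) maps to ``undefined``; values equal to either
    boundary are ``normal`` (conservative convention).
    """
    if value is None:
        return Flag.UNDEFINED
    if value < range.p5:
        return Flag.LOW
    if value > range.p95:
        return Flag.HIGH
    return Flag.NORMAL


@dataclass
class ReferenceSet:
    """Mapping key → :class:`ReferenceRange`, tied to a registry version."""

    registry_version: str
    ranges: dict[str, ReferenceRange]
    min_n: int = DEFAULT_MIN_COHORT

    def get(self, key: str) -> ReferenceRange | None:
        return self.ranges.get(key)

    def require_version(self, registry: Registry) -> None:
        if registry.version != self.registry_version:
            raise ReferenceError(
                f"reference set was built under registry {self.registry_version!r}, "
                f"refusing to apply it under {registry.version!r}"
            )

    # -- serialization ---------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "registry_version": self.registry_version,
            "min_n": self.min_n,
            "ranges": {
                k: {"n": r.n, "mean": r.mean, "p5": r.p5, "p95": r.p95}
                for k, r in sorted(self.ranges.items())
            },
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ReferenceSet":
        doc = json.loads(text)
        ranges = {
            k: ReferenceRange(key=k, n=int(v["n"]), mean=v["mean"], p5=v["p5"], p95=v["p95"])
            for k, v in doc["ranges"].items()
        }
        return cls(
            registry_version=doc["registry_version"],
            ranges=ranges,
            min_n=int(doc.get("min_n", DEFAULT_MIN_COHORT)),
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json(), encoding="utf-8")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceSet":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def build_reference(
    cohort: list[SteroidProfile],
    registry: Registry,
    min_n: int = DEFAULT_MIN_COHORT,
) -> ReferenceSet:
    """Build per-analyte, per-group and per-ratio ranges from 24-h profiles.

    A range is emitted for each analyte measured in at least ``min_n``
    profiles, each report group, and each registry ratio evaluable in at
    least ``min_n`` profiles.  Profiles from spot collections are rejected.
    """
    from .diagnostics import group_totals, ratio_value  # deferred: two-way module use

    if len(cohort) < min_n:
        raise ReferenceError(
            f"cohort of {len(cohort)} profiles is below the minimum of {min_n} (key: cohort)"
        )
    for p in cohort:
        if p.collection != "24h":
            raise ReferenceError(
                f"profile {p.sample_id!r} is a spot collection; reference ranges "
                "require 24-h collections"
            )

    ranges: dict[str, ReferenceRange] = {}

    for abbr in registry.abbrs:
        values = np.array(
            [p.amounts[abbr] for p in cohort if abbr in p.amounts], dtype=float
        )
        if values.size >= min_n:
            mean, p5, p95 = _centiles(values)
            ranges[abbr] = ReferenceRange(key=abbr, n=values.size, mean=mean, p5=p5, p95=p95)

    totals = [group_totals(p, registry) for p in cohort]
    for group in GROUPS:
        values = np.array([t[group] for t in totals], dtype=float)
        mean, p5, p95 = _centiles(values)
        ranges[group] = ReferenceRange(key=group, n=values.size, mean=mean, p5=p5, p95=p95)

    for rd in registry.ratios:
        values = np.array(
            [v for p in cohort if (v := ratio_value(p, rd)) is not None], dtype=float
        )
        if values.size >= min_n:
            mean, p5, p95 = _centiles(values)
            ranges[rd.id] = ReferenceRange(key=rd.id, n=values.size, mean=mean, p5=p5, p95=p95)

    return ReferenceSet(registry_version=registry.version, ranges=ranges, min_n=min_n)
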