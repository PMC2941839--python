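"""Read and write quantified urinary steroid profiles.

Two tabular dialects are supported, both UTF-8 with a mandatory header and
a sniffed tab/comma delimiter:

long
    columns ``sample_id``, ``metabolite``, ``amount_ug_per_24h`` — one row
    per measurement.
wide
    ``sample_id`` plus one column per canonical analyte abbreviation.

A missing analyte means *not measured* and stays absent from the profile
map; an explicit ``0`` means *measured, below detection*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .registry import Registry, RegistryError

__all__ = ["SteroidProfile", "ProfileValidationError", "read_profiles", "write_profiles"]

LONG_COLUMNS = ("sample_id", "metabolite", "amount_ug_per_24h")


class ProfileValidationError(ValueError):
    """A profile file or profile object violates the format contract."""


@dataclass
class SteroidProfile:
    """Per-sample analyte → excretion map (µg/24 h for 24-h collections)."""

    sample_id: str
    amounts: dict[str, float]
    collection: str = "24h"
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ProfileValidationError("sample_id must be non-empty")
        if self.collection not in ("24h", "spot"):
            raise ProfileValidationError(
                f"collection must be '24h' or 'spot', got {self.collection!r}"
            )
        for abbr, value in self.amounts.items():
            if not math.isfinite(value) or value < 0:
                raise ProfileValidationError(
                    f"amount for {abbr!r} in sample {self.sample_id!r} must be "
                    f"finite and >= 0, got {value!r}"
                )

    def get(self, abbr: str) -> float | None:
        return self.amounts.get(abbr)


def _sniff_sep(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _canonicalize(profile_amounts: dict[str, float], registry: Registry) -> dict[str, float]:
    return {registry.canonical(k): v for k, v in profile_amounts.items()}


def read_profiles(path: str | Path, registry: Registry) -> list[SteroidProfile]:
    """Parse a long- or wide-format profile table (dialect auto-detected).

    Unknown analyte columns raise; negative, non-finite or duplicate
    measurements raise :class:`ProfileValidationError` naming the row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_sep(path)
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    cols = list(frame.columns)
    if not cols or cols[0] != "sample_id":
        raise ProfileValidationError(
            f"first column must be 'sample_id', got {cols[:1] or 'nothing'}"
        )
    if [c for c in cols[:3]] == list(LONG_COLUMNS):
        return _read_long(frame, registry)
    return _read_wide(frame, registry)


def _parse_amount(raw: str, row: int) -> float:
    try:
        value = float(raw)
    except ValueError:
        raise ProfileValidationError(f"row {row}: non-numeric amount {raw!r}") from None
    if not math.isfinite(value) or value < 0:
        raise ProfileValidationError(f"row {row}: amount must be finite and >= 0, got {raw!r}")
    return value


def _read_long(frame: pd.DataFrame, registry: Registry) -> list[SteroidProfile]:
    profiles: dict[str, dict[str, float]] = {}
    for i, rec in enumerate(frame.itertuples(index=False), start=2):
        sample_id = str(rec.sample_id)
        abbr = registry.canonical(str(rec.metabolite))
        value = _parse_amount(str(rec.amount_ug_per_24h), i)
        amounts = profiles.setdefault(sample_id, {})
        if abbr in amounts:
            raise ProfileValidationError(
                f"row {i}: duplicate measurement of {abbr!r} for sample {sample_id!r}"
            )
        amounts[abbr] = value
    return [SteroidProfile(sample_id=s, amounts=a) for s, a in profiles.items()]


def _read_wide(frame: pd.DataFrame, registry: Registry) -> list[SteroidProfile]:
    analyte_cols = [c for c in frame.columns if c != "sample_id"]
    unknown = []
    canonical: dict[str, str] = {}
    for col in analyte_cols:
        try:
            canonical[col] = registry.canonical(col)
        except RegistryError:
            unknown.append(col)
    if unknown:
        raise ProfileValidationError(f"unknown analyte columns: {unknown}")
    if len(set(canonical.values())) != len(canonical):
        raise ProfileValidationError("duplicate analyte columns after canonicalization")
    profiles: list[SteroidProfile] = []
    seen: set[str] = set()
    for i, rec in enumerate(frame.itertuples(index=False), start=2):
        row = dict(zip(frame.columns, rec))
        sample_id = str(row["sample_id"])
        if sample_id in seen:
            raise ProfileValidationError(f"row {i}: duplicate sample_id {sample_id!r}")
        seen.add(sample_id)
        amounts: dict[str, float] = {}
        for col in analyte_cols:
            raw = str(row[col]).strip()
            if raw == "":  # not measured
                continue
            amounts[canonical[col]] = _parse_amount(raw, i)
        profiles.append(SteroidProfile(sample_id=sample_id, amounts=amounts))
    return profiles


def write_profiles(
    profiles: list[SteroidProfile],
    path: str | Path,
    format: str = "long",
    registry: Registry | None = None,
) -> Path:
    """Serialize profiles; ``read_profiles(write_profiles(x)) == x``.

    Wide output orders columns by registry order when a registry is given,
    otherwise by first appearance across profiles.
    """
    path = Path(path)
    if format == "long":
        rows = [
            {
                "sample_id": p.sample_id,
                "metabolite": abbr,
                "amount_ug_per_24h": repr(value),
            }
            for p in profiles
            for abbr, value in p.amounts.items()
        ]
        frame = pd.DataFrame(rows, columns=list(LONG_COLUMNS))
    elif format == "wide":
        if registry is not None:
            present = {a for p in profiles for a in p.amounts}
            columns = [a for a in registry.abbrs if a in present]
        else:
            columns = list(dict.fromkeys(a for p in profiles for a in p.amounts))
        rows = []
        for p in profiles:
            row: dict[str, str] = {"sample_id": p.sample_id}
            for abbr in columns:
                value = p.amounts.get(abbr)
                row[abbr] = "" if value is None else repr(value)
            rows.append(row)
        frame = pd.DataFrame(rows, columns=["sample_id", *columns])
    else:
        raise ValueError(f"format must be 'long' or 'wide', got {format!r}")
    frame.to_csv(path, sep="\t", index=False)
    return path
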