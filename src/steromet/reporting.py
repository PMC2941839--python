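"""Structured quantitative and ratio-panel reports, plus thin graphics.

Reports are primarily structured documents (JSON / TSV); the figures are a
rendering layer over them — dots for observations on a log axis, a shaded
band between the 5th and 95th centiles.  Zero or undefined observations
are drawn as annotated floor markers, never dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .diagnostics import DisorderCall, RatioResult, evaluate_panel, group_totals
from .profile_io import SteroidProfile
from .reference import Flag, ReferenceSet, flag_value
from .registry import GROUPS, Registry

__all__ = [
    "QuantRow",
    "QuantReport",
    "RatioPanelReport",
    "render_quant_report",
    "render_ratio_panel",
    "plot_reports",
]


@dataclass(frozen=True)
class QuantRow:
    key: str  # analyte abbr or group label
    group: str
    amount: float | None
    ref_mean: float | None
    ref_p5: float | None
    ref_p95: float | None
    flag: Flag


@dataclass(frozen=True)
class QuantReport:
    """Grouped per-analyte quantitation against reference centiles."""

    sample_id: str
    rows: tuple[QuantRow, ...]
    group_rows: tuple[QuantRow, ...]

    def to_dict(self) -> dict:
        def row(r: QuantRow) -> dict:
            return {
                "key": r.key,
                "group": r.group,
                "amount": r.amount,
                "mean": r.ref_mean,
                "p5": r.ref_p5,
                "p95": r.ref_p95,
                "flag": r.flag.value,
            }

        return {
            "sample_id": self.sample_id,
            "kind": "quant",
            "rows": [row(r) for r in self.rows],
            "groups": [row(r) for r in self.group_rows],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    def to_tsv(self) -> str:
        lines = ["key\tgroup\tamount\tmean\tp5\tp95\tflag"]
        for r in (*self.rows, *self.group_rows):
            lines.append(
                "\t".join(
                    [
                        r.key,
                        r.group,
                        _fmt(r.amount),
                        _fmt(r.ref_mean),
                        _fmt(r.ref_p5),
                        _fmt(r.ref_p95),
                        r.flag.value,
                    ]
                )
            )
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class RatioSection:
    disorder: str
    gene: str
    ratios: tuple[RatioResult, ...]
    call: DisorderCall


@dataclass(frozen=True)
class RatioPanelReport:
    """Per-disorder diagnostic ratio sections with the derived calls."""

    sample_id: str
    sections: tuple[RatioSection, ...]
    p95: dict[str, float | None]

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "kind": "panel",
            "ratios": [
                {
                    "id": r.ratio_id,
                    "disorder": r.disorder,
                    "value": r.value,
                    "p95": self.p95.get(r.ratio_id),
                    "flag": r.flag.value,
                }
                for s in self.sections
                for r in s.ratios
            ],
            "calls": [
                {
                    "disorder": s.call.disorder,
                    "gene": s.call.gene,
                    "positive": s.call.positive,
                    "n_high": s.call.n_high,
                    "n_ratios": s.call.n_ratios,
                    "n_undefined": s.call.n_undefined,
                    "rank_score": s.call.rank_score,
                }
                for s in sorted(
                    self.sections,
                    key=lambda s: (
                        not s.call.positive,
                        -(s.call.rank_score if s.call.rank_score is not None else float("-inf")),
                    ),
                )
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    def to_tsv(self) -> str:
        lines = ["ratio_id\tdisorder\tvalue\tp95\tflag"]
        for s in self.sections:
            for r in s.ratios:
                lines.append(
                    "\t".join(
                        [
                            r.ratio_id,
                            r.disorder,
                            _fmt(r.value),
                            _fmt(self.p95.get(r.ratio_id)),
                            r.flag.value,
                        ]
                    )
                )
        return "\n".join(lines) + "\n"


def _fmt(v: float | None) -> str:
    return "" if v is None else repr(float(v))


def render_quant_report(
    profile: SteroidProfile, reference: ReferenceSet, registry: Registry
) -> QuantReport:
    """Grouped quantitative report: one row per registry analyte plus group totals.

    Analytes lacking a reference range (or missing from the profile) are
    still listed, flagged ``undefined`` where no comparison is possible.
    """
    if profile.collection != "24h":
        raise ValueError("quantitative reporting requires a 24-h collection")
    reference.require_version(registry)

    rows: list[QuantRow] = []
    for group in GROUPS:
        for m in registry.metabolites:
            if m.group != group:
                continue
            amount = profile.amounts.get(m.abbr)
            rng = reference.get(m.abbr)
            flag = flag_value(amount, rng) if rng is not None else Flag.UNDEFINED
            rows.append(
                QuantRow(
                    key=m.abbr,
                    group=group,
                    amount=amount,
                    ref_mean=rng.mean if rng else None,
                    ref_p5=rng.p5 if rng else None,
                    ref_p95=rng.p95 if rng else None,
                    flag=flag,
                )
            )

    totals = group_totals(profile, registry)
    group_rows: list[QuantRow] = []
    for group in GROUPS:
        rng = reference.get(group)
        amount = totals[group] if profile.amounts else None
        flag = flag_value(amount, rng) if rng is not None else Flag.UNDEFINED
        group_rows.append(
            QuantRow(
                key=group,
                group=group,
                amount=amount,
                ref_mean=rng.mean if rng else None,
                ref_p5=rng.p5 if rng else None,
                ref_p95=rng.p95 if rng else None,
                flag=flag,
            )
        )
    return QuantReport(sample_id=profile.sample_id, rows=tuple(rows), group_rows=tuple(group_rows))


def render_ratio_panel(
    profile: SteroidProfile, reference: ReferenceSet, registry: Registry
) -> RatioPanelReport:
    """Diagnostic ratio panel report: one section per disorder with its call."""
    results, calls = evaluate_panel(profile, registry, reference)
    by_disorder: dict[str, list[RatioResult]] = {}
    for r in results:
        by_disorder.setdefault(r.disorder, []).append(r)
    call_map = {c.disorder: c for c in calls}
    sections = tuple(
        RatioSection(
            disorder=d,
            gene=call_map[d].gene,
            ratios=tuple(by_disorder[d]),
            call=call_map[d],
        )
        for d in registry.disorders
    )
    p95 = {
        rd.id: (reference.get(rd.id).p95 if reference.get(rd.id) else None)
        for rd in registry.ratios
    }
    return RatioPanelReport(sample_id=profile.sample_id, sections=sections, p95=p95)


_GROUP_COLORS = {
    "androgens": "#3b4cc0",
    "androgen_precursors": "#9ecae1",
    "mineralocorticoids_and_precursors": "#41ab5d",
    "glucocorticoid_precursors": "#fec44f",
    "glucocorticoids": "#f16913",
}


def plot_reports(
    report: QuantReport | RatioPanelReport,
    out_path: str | Path,
    format: str = "svg",
) -> Path:
    """Render a report as a figure plus a deterministic JSON metadata sidecar.

    Observations are dots on a log value axis over a shaded p5–p95 band;
    zero/undefined values become annotated markers at the axis floor.
    """
    if format not in ("svg", "png"):
        raise ValueError(f"unknown format {format!r}; use 'svg' or 'png'")
    out_path = Path(out_path)

    if isinstance(report, QuantReport):
        entries = [
            (r.key, _GROUP_COLORS[r.group], r.amount, r.ref_p5, r.ref_p95) for r in report.rows
        ]
        title = f"Urinary steroid quantitation (ug/24 h) — {report.sample_id}"
        ylabel = "excretion (ug/24 h)"
    else:
        entries = [
            (r.ratio_id, "#555555", r.value, None, report.p95.get(r.ratio_id))
            for s in report.sections
            for r in s.ratios
        ]
        title = f"Diagnostic ratio panel — {report.sample_id}"
        ylabel = "ratio"

    positives = [v for _, _, v, _, _ in entries if v is not None and v > 0]
    floors = [p for *_, p5, p in entries for p in (p5, p) if p is not None and p > 0]
    floor = min(positives + floors, default=1.0) / 10.0

    fig, ax = plt.subplots(figsize=(max(8.0, 0.35 * len(entries)), 4.5))
    for i, (key, color, value, p5, p95) in enumerate(entries):
        if p95 is not None:
            lo = p5 if (p5 is not None and p5 > 0) else floor
            ax.fill_between([i - 0.35, i + 0.35], [lo, lo], [max(p95, floor)] * 2,
                            color=color, alpha=0.25, linewidth=0)
        if value is None or value <= 0:
            ax.plot(i, floor, marker="v", color="#aaaaaa")
        else:
            ax.plot(i, value, marker="o", color=color)
    ax.set_yscale("log")
    ax.set_xticks(range(len(entries)))
    ax.set_xticklabels([e[0] for e in entries], rotation=90, fontsize=7)
    ax.set_ylabel(ylabel)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, format=format)
    plt.close(fig)

    sidecar = out_path.with_suffix(out_path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"figure": out_path.name, "report": report.to_dict(), "markers": len(entries)},
                   indent=1, sort_keys=True),
        encoding="utf-8",
    )
    return out_path
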