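"""Synthetic urinary steroid profiles from steady-state pathway flux.

The generative model, in order:

1. **Flux propagation.**  A fixed production flux enters at pregnenolone
   and splits at every hormone node among its outgoing enzymatic edges and
   a per-node excretion sink, in proportion to ``base_rate x activity``.
   Edges whose enzyme depends on the POR electron donor are additionally
   scaled by ``por_activity`` (twice for the b5-assisted lyase steps, which
   are disproportionately sensitive to POR loss).  The system is linear and
   solved exactly.
2. **Compensatory drive (optional, used by the disorder presets).**  A
   one-shot ACTH-like feedback rescales the input flux to restore cortisol
   output, and an LH-like feedback upweights the gonadal
   DHEA -> androstenedione step when testosterone output is low.  Both are
   off by default, so plain scenarios conserve ``input_flux`` exactly.
3. **Excretion yields.**  Each hormone's sink flux is distributed over its
   urinary metabolites.  Cortisol is handled as a pool: a free-hormone
   fraction (cortisol F / cortisone E) and a metabolite fraction, both
   partitioned between 11-hydroxy and 11-oxo forms by ``beta_11oxo``.
4. **Post-synthesis partitions.**  5alpha/5beta metabolite pairs are
   re-split by ``rho_5alpha``.
5. **Noise.**  Independent multiplicative log-normal noise per analyte,
   with a deterministic per-sample substream of the scenario seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .profile_io import SteroidProfile
from .registry import PathwayGraph, Registry

__all__ = [
    "SimulationScenario",
    "FluxState",
    "ScenarioError",
    "steady_state_flux",
    "excrete",
    "simulate_cohort",
    "scenario_preset",
    "PRESET_NAMES",
]


class ScenarioError(ValueError):
    """Invalid scenario parameters or an unknown preset/enzyme."""


@dataclass(frozen=True)
class SimulationScenario:
    """Parameters of one simulated condition.

    ``activities`` maps enzyme id to a residual-activity fraction in [0, 1]
    (enzymes not listed are fully active).  ``por_activity`` applies
    multiplicatively to every POR-dependent reaction.  Feedback switches
    are off by default and enabled by the disorder presets.
    """

    name: str = "custom"
    activities: dict[str, float] = field(default_factory=dict)
    por_activity: float = 1.0
    rho_5alpha: float = 0.4
    beta_11oxo: float = 0.55
    enable_backdoor: bool = False
    input_flux: float = 10000.0
    noise_sigma: float = 0.3
    seed: int = 0
    acth_feedback: bool = False
    lh_feedback: bool = False
    sink_weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for enzyme, a in self.activities.items():
            if not 0.0 <= a <= 1.0:
                raise ScenarioError(f"activity for {enzyme!r} must be in [0, 1], got {a}")
        for label, v in (
            ("por_activity", self.por_activity),
            ("rho_5alpha", self.rho_5alpha),
            ("beta_11oxo", self.beta_11oxo),
        ):
            if not 0.0 <= v <= 1.0:
                raise ScenarioError(f"{label} must be in [0, 1], got {v}")
        if not self.input_flux > 0:
            raise ScenarioError(f"input_flux must be > 0, got {self.input_flux}")
        if self.noise_sigma < 0:
            raise ScenarioError(f"noise_sigma must be >= 0, got {self.noise_sigma}")


@dataclass(frozen=True)
class FluxState:
    """Exact steady-state solution: per-hormone inflow and excretion-sink flux."""

    synthesis: dict[str, float]
    sink: dict[str, float]
    input_flux_effective: float
    acth_multiplier: float = 1.0
    lh_multiplier: float = 1.0


#: Root node receiving the production flux.
INPUT_HORMONE = "pregnenolone"
#: Gonadal-axis edge upweighted by the LH-like feedback.
_LH_EDGES = frozenset({("DHEA", "androstenedione", "HSD3B2")})
_LH_CAP = 25.0
_ACTH_CAP = 1000.0

#: Default per-node excretion-sink weights (1.0 when unlisted); scenario
#: ``sink_weights`` override these.  DHEA holds a large directly-excreted
#: pool; 17OH-progesterone metabolites are kept moderate so precursor
#: build-up, not baseline leak, dominates its diagnostic ratios.
DEFAULT_SINK_WEIGHTS: dict[str, float] = {
    "17OH-progesterone": 0.3,
    "progesterone": 2.0,
    "11-deoxycortisol": 0.3,
    "DHEA": 5.0,
}

#: Hormone sink flux -> urinary analyte yield weights (each row sums to 1).
#: Cortisol is absent here; its pool is partitioned by `_excrete_cortisol_pool`.
YIELDS: dict[str, tuple[tuple[str, float], ...]] = {
    "pregnenolone": (("5PD", 0.8), ("Pregnadienol", 0.2)),
    "17OH-pregnenolone": (("5PT", 1.0),),
    "progesterone": (("PD", 1.0),),
    "11-deoxycorticosterone": (("PD", 1 / 3), ("THDOC", 1 / 3), ("5aTHDOC", 1 / 3)),
    "17OH-progesterone": (("17HP", 1 / 3), ("3a5a17HP", 1 / 3), ("PT", 1 / 3)),
    "21-deoxycortisol": (("PTONE", 1.0),),
    "11-deoxycortisol": (("THS", 1.0),),
    "corticosterone": (("THA", 0.25), ("5aTHA", 0.25), ("THB", 0.25), ("5aTHB", 0.25)),
    "aldosterone": (("THALDO", 1.0),),
    "DHEA": (("DHEA", 0.57), ("16a-DHEA", 0.37), ("An", 0.03), ("Et", 0.03)),
    "androstenedione": (("An", 1.0),),
    "testosterone": (("An", 0.5), ("Et", 0.5)),
    "5a-dihydrotestosterone": (("An", 1.0),),
    "11b-OH-androstenedione": (("11b-OH-An", 1.0),),
    "5a-17OH-pregnanolone": (("3a5a17HP", 1.0),),
    "androsterone": (("An", 1.0),),
}

#: Fraction of cortisol output excreted as 11beta-hydroxy-androsterone.
_CORTISOL_11OHAN_FRACTION = 0.08
#: 11-oxo (cortisone-side) and 11-hydroxy (cortisol-side) metabolite sets.
_OXO_METS = ("THE", "a-Cortolone", "b-Cortolone", "11-OXO-Et")
_OH_METS = ("THF", "5aTHF", "a-Cortol", "b-Cortol", "11b-OH-Et", "6b-OH-cortisol")

#: (5alpha analyte, 5beta analyte) pairs re-partitioned by rho_5alpha.
_RHO_PAIRS = (
    ("An", "Et"),
    ("5aTHF", "THF"),
    ("5aTHB", "THB"),
    ("5aTHA", "THA"),
    ("5aTHDOC", "THDOC"),
)


def _free_fraction(beta_11oxo: float) -> float:
    # Share of the cortisol pool excreted as free F/E rather than as ring-A
    # reduced metabolites; rises when 11-oxo conversion fails (low beta), so
    # the free/metabolite panel ratio moves with the disease.
    return 0.05 + 0.45 * (1.0 - beta_11oxo) ** 2


def _edge_weight(
    reaction, scenario: SimulationScenario, lh_multiplier: float
) -> float:
    if reaction.backdoor and not scenario.enable_backdoor:
        return 0.0
    w = reaction.base_rate * scenario.activities.get(reaction.enzyme, 1.0)
    if "POR" in reaction.cofactors:
        w *= scenario.por_activity
        if "b5" in reaction.cofactors:
            w *= scenario.por_activity  # lyase loses function ~quadratically
    if reaction.key in _LH_EDGES:
        w *= lh_multiplier
    return w


def _solve(
    pathway: PathwayGraph, scenario: SimulationScenario, lh_multiplier: float
) -> tuple[dict[str, float], dict[str, float]]:
    """Exact linear steady state: inflow and sink flux per hormone node."""
    nodes = [h.id for h in pathway.hormones]
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)

    out_weights: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for r in pathway.flux_reactions():
        w = _edge_weight(r, scenario, lh_multiplier)
        if w > 0:
            out_weights[index[r.substrate]].append((index[r.product], w))

    # share matrix: P[i, j] = fraction of node i's inflow routed to node j
    P = np.zeros((n, n))
    sink_share = np.ones(n)
    for i in range(n):
        ws = scenario.sink_weights.get(
            nodes[i], DEFAULT_SINK_WEIGHTS.get(nodes[i], 1.0)
        )
        total = ws + sum(w for _, w in out_weights[i])
        if total <= 0:
            continue
        sink_share[i] = ws / total
        for j, w in out_weights[i]:
            P[i, j] = w / total

    b = np.zeros(n)
    b[index[INPUT_HORMONE]] = scenario.input_flux
    inflow = np.linalg.solve(np.eye(n) - P.T, b)
    sinks = inflow * sink_share
    return (
        {node: float(inflow[i]) for node, i in index.items()},
        {node: float(sinks[i]) for node, i in index.items()},
    )


def steady_state_flux(pathway: PathwayGraph, scenario: SimulationScenario) -> FluxState:
    """Solve the branch-competition flux model for one scenario.

    Mass balance holds exactly: total sink flux equals the (feedback
    adjusted) input flux.  Raises :class:`ScenarioError` for activities
    naming enzymes absent from the pathway.
    """
    known = {r.enzyme for r in pathway.reactions}
    unknown = set(scenario.activities) - known
    if unknown:
        raise ScenarioError(f"scenario references unknown enzymes: {sorted(unknown)}")
    if INPUT_HORMONE not in {h.id for h in pathway.hormones}:
        raise ScenarioError(f"pathway lacks the input node {INPUT_HORMONE!r}")

    lh_mult = 1.0
    acth_mult = 1.0
    if scenario.lh_feedback or scenario.acth_feedback:
        baseline = replace(
            scenario,
            activities={},
            por_activity=1.0,
            enable_backdoor=False,
            lh_feedback=False,
            acth_feedback=False,
        )
        _, sink_ref = _solve(pathway, baseline, 1.0)
        _, sink_0 = _solve(pathway, scenario, 1.0)
        if scenario.lh_feedback:
            t_ref = sink_ref["testosterone"] + sink_ref["5a-dihydrotestosterone"]
            t_0 = sink_0["testosterone"] + sink_0["5a-dihydrotestosterone"]
            lh_mult = _LH_CAP if t_0 <= 0 else min(max(t_ref / t_0, 1.0), _LH_CAP)

    inflow, sinks = _solve(pathway, scenario, lh_mult)

    if scenario.acth_feedback:
        f_ref_inflow, f_ref_sinks = _solve(
            pathway,
            replace(
                scenario,
                activities={},
                por_activity=1.0,
                enable_backdoor=False,
                lh_feedback=False,
                acth_feedback=False,
            ),
            1.0,
        )
        f_ref = f_ref_sinks["cortisol"]
        f_now = sinks["cortisol"]
        acth_mult = _ACTH_CAP if f_now <= 0 else min(max(f_ref / f_now, 1.0), _ACTH_CAP)
        inflow = {k: v * acth_mult for k, v in inflow.items()}
        sinks = {k: v * acth_mult for k, v in sinks.items()}

    return FluxState(
        synthesis=inflow,
        sink=sinks,
        input_flux_effective=scenario.input_flux * acth_mult,
        acth_multiplier=acth_mult,
        lh_multiplier=lh_mult,
    )


def _excrete_cortisol_pool(amounts: dict[str, float], cortisol_flux: float, beta: float) -> None:
    amounts["11b-OH-An"] = amounts.get("11b-OH-An", 0.0) + cortisol_flux * _CORTISOL_11OHAN_FRACTION
    pool = cortisol_flux * (1.0 - _CORTISOL_11OHAN_FRACTION)
    phi = _free_fraction(beta)
    amounts["F"] = amounts.get("F", 0.0) + pool * phi * (1.0 - beta)
    amounts["E"] = amounts.get("E", 0.0) + pool * phi * beta
    mets = pool * (1.0 - phi)
    for abbr in _OH_METS:
        amounts[abbr] = amounts.get(abbr, 0.0) + mets * (1.0 - beta) / len(_OH_METS)
    for abbr in _OXO_METS:
        amounts[abbr] = amounts.get(abbr, 0.0) + mets * beta / len(_OXO_METS)


def excrete(
    flux: FluxState,
    scenario: SimulationScenario,
    registry: Registry,
    sample_id: str = "sim",
) -> SteroidProfile:
    """Map sink fluxes to a noise-free urinary profile (µg/24 h).

    Total analyte mass equals the effective input flux exactly; estrogen
    sink flux cannot be carried (no estrogen analytes are quantified) and
    raises if a scenario routes mass there.
    """
    for estrogen in ("estrone", "estradiol"):
        if flux.sink.get(estrogen, 0.0) > 0:
            raise ScenarioError(
                f"scenario routes flux to {estrogen}, which carries no quantified analyte"
            )
    amounts: dict[str, float] = {}
    for hormone, sink_flux in flux.sink.items():
        if sink_flux <= 0:
            continue
        if hormone == "cortisol":
            _excrete_cortisol_pool(amounts, sink_flux, scenario.beta_11oxo)
            continue
        try:
            rows = YIELDS[hormone]
        except KeyError:
            raise ScenarioError(f"no excretion yields defined for hormone {hormone!r}") from None
        for abbr, weight in rows:
            amounts[abbr] = amounts.get(abbr, 0.0) + sink_flux * weight

    rho = scenario.rho_5alpha
    for alpha_abbr, beta_abbr in _RHO_PAIRS:
        total = amounts.get(alpha_abbr, 0.0) + amounts.get(beta_abbr, 0.0)
        if total > 0:
            amounts[alpha_abbr] = total * rho
            amounts[beta_abbr] = total * (1.0 - rho)

    amounts = {registry.canonical(a): v for a, v in amounts.items()}
    return SteroidProfile(sample_id=sample_id, amounts=amounts, collection="24h")


def simulate_cohort(
    scenario: SimulationScenario,
    n: int,
    seed: int | None = None,
    registry: Registry | None = None,
) -> list[SteroidProfile]:
    """Generate ``n`` noisy profiles, bit-reproducible for (scenario, n, seed).

    Each profile is the noise-free excretion profile multiplied per analyte
    by ``exp(Normal(0, noise_sigma))`` drawn from a per-sample substream.
    """
    if n < 1:
        raise ScenarioError(f"cohort size must be >= 1, got {n}")
    if registry is None:
        from .registry import load_registry

        registry = load_registry()
    flux = steady_state_flux(registry.pathway, scenario)
    base = excrete(flux, scenario, registry)
    abbrs = sorted(base.amounts)
    values = np.array([base.amounts[a] for a in abbrs])

    streams = np.random.SeedSequence(scenario.seed if seed is None else seed).spawn(n)
    cohort: list[SteroidProfile] = []
    for i, ss in enumerate(streams, start=1):
        rng = np.random.default_rng(ss)
        noise = np.exp(rng.normal(0.0, scenario.noise_sigma, size=values.size))
        amounts = dict(zip(abbrs, (values * noise).tolist()))
        cohort.append(
            SteroidProfile(
                sample_id=f"{scenario.name}_{i:04d}",
                amounts=amounts,
                collection="24h",
                meta={"scenario": scenario.name},
            )
        )
    return cohort


_DISEASE_RESIDUAL = 0.05

_PRESETS: dict[str, dict] = {
    "normal": {},
    "21OHD": {"activities": {"CYP21A2": _DISEASE_RESIDUAL}},
    "11bOHD": {"activities": {"CYP11B1": _DISEASE_RESIDUAL}},
    "17aOHD": {
        "activities": {
            "CYP17A1_hydroxylase": _DISEASE_RESIDUAL,
            "CYP17A1_lyase": _DISEASE_RESIDUAL,
        }
    },
    "HSD3B2": {"activities": {"HSD3B2": _DISEASE_RESIDUAL}},
    "ORD": {"por_activity": _DISEASE_RESIDUAL},
    "ORD_pregnancy": {"por_activity": _DISEASE_RESIDUAL, "enable_backdoor": True},
    "AME": {"beta_11oxo": 0.15},
    "ACRD": {"beta_11oxo": 0.95},
    "SRD5A2": {"rho_5alpha": _DISEASE_RESIDUAL},
    "HSD17B3": {"activities": {"HSD17B3": _DISEASE_RESIDUAL}},
}

PRESET_NAMES: tuple[str, ...] = tuple(_PRESETS)


def scenario_preset(name: str, **overrides) -> SimulationScenario:
    """Named scenario for each disorder the ratio panel covers.

    Enzymatic disorders retain 5% residual activity so every ratio stays
    finite.  Disorder presets enable the compensatory ACTH/LH drive (a
    no-op for ``normal``, which keeps plain defaults).
    """
    try:
        params = dict(_PRESETS[name])
    except KeyError:
        raise ScenarioError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        ) from None
    if name != "normal":
        params.setdefault("acth_feedback", True)
        params.setdefault("lh_feedback", True)
    params.update(overrides)
    return SimulationScenario(name=name, **params)
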