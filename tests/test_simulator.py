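import numpy as np
import pytest

from steromet.diagnostics import group_totals, ratio_value
from steromet.simulator import (
    PRESET_NAMES,
    DEFAULT_SINK_WEIGHTS,
    ScenarioError,
    SimulationScenario,
    excrete,
    scenario_preset,
    simulate_cohort,
    steady_state_flux,
)


def iterative_flux_oracle(pathway, scenario, tol=1e-14, max_iter=100_000):
    """Independent fixed-point propagation: push inflow through node shares
    until residual mass is negligible.  No linear algebra."""
    from steromet.simulator import DEFAULT_SINK_WEIGHTS, _edge_weight

    nodes = [h.id for h in pathway.hormones]
    shares = {}
    for node in nodes:
        out = [
            (r.product, _edge_weight(r, scenario, 1.0))
            for r in pathway.flux_reactions()
            if r.substrate == node
        ]
        ws = scenario.sink_weights.get(node, DEFAULT_SINK_WEIGHTS.get(node, 1.0))
        total = ws + sum(w for _, w in out)
        shares[node] = (ws / total, [(p, w / total) for p, w in out if w > 0])

    pending = {node: 0.0 for node in nodes}
    pending["pregnenolone"] = scenario.input_flux
    inflow = {node: 0.0 for node in nodes}
    sink = {node: 0.0 for node in nodes}
    for _ in range(max_iter):
        moved = 0.0
        nxt = {node: 0.0 for node in nodes}
        for node, mass in pending.items():
            if mass <= 0:
                continue
            inflow[node] += mass
            sink_share, out = shares[node]
            sink[node] += mass * sink_share
            for product, share in out:
                nxt[product] += mass * share
            moved += mass
        pending = nxt
        if moved < tol * scenario.input_flux:
            break
    return inflow, sink


def _noise_free(registry, name, **overrides):
    scenario = scenario_preset(name, **overrides)
    flux = steady_state_flux(registry.pathway, scenario)
    return excrete(flux, scenario, registry, sample_id=name)


class TestSteadyStateFlux:
    def test_mass_balance_default(self, registry):
        scenario = SimulationScenario()
        flux = steady_state_flux(registry.pathway, scenario)
        assert sum(flux.sink.values()) == pytest.approx(scenario.input_flux, rel=1e-9)
        assert flux.input_flux_effective == scenario.input_flux

    def test_blocked_cyp21a2(self, registry):
        blocked = SimulationScenario(activities={"CYP21A2": 0.0})
        open_ = SimulationScenario()
        fb = steady_state_flux(registry.pathway, blocked)
        fo = steady_state_flux(registry.pathway, open_)
        assert fb.synthesis["11-deoxycortisol"] == 0.0
        assert fb.synthesis["11-deoxycorticosterone"] == 0.0
        assert fb.sink["17OH-progesterone"] > fo.sink["17OH-progesterone"]

    def test_matches_iterative_oracle_on_random_scenarios(self, registry):
        rng = np.random.default_rng(7)
        enzymes = sorted({r.enzyme for r in registry.pathway.flux_reactions()})
        for _ in range(10):
            scenario = SimulationScenario(
                activities={e: float(rng.uniform(0.01, 1.0)) for e in enzymes},
                por_activity=float(rng.uniform(0.01, 1.0)),
            )
            flux = steady_state_flux(registry.pathway, scenario)
            inflow_o, sink_o = iterative_flux_oracle(registry.pathway, scenario)
            for node in flux.sink:
                assert flux.sink[node] == pytest.approx(
                    sink_o[node], rel=1e-9, abs=1e-9
                ), node

    def test_unknown_enzyme_rejected(self, registry):
        with pytest.raises(ScenarioError, match="unknown enzymes"):
            steady_state_flux(
                registry.pathway, SimulationScenario(activities={"CYP99": 0.5})
            )

    def test_deterministic(self, registry):
        scenario = scenario_preset("ORD")
        a = steady_state_flux(registry.pathway, scenario)
        b = steady_state_flux(registry.pathway, scenario)
        assert a == b


class TestExcrete:
    def test_conservation(self, registry):
        scenario = SimulationScenario()
        flux = steady_state_flux(registry.pathway, scenario)
        profile = excrete(flux, scenario, registry)
        assert sum(profile.amounts.values()) == pytest.approx(
            scenario.input_flux, rel=1e-9
        )

    def test_beta_one_extreme(self, registry):
        scenario = SimulationScenario(beta_11oxo=1.0)
        flux = steady_state_flux(registry.pathway, scenario)
        profile = excrete(flux, scenario, registry)
        for abbr in ("THF", "5aTHF", "a-Cortol", "b-Cortol", "F"):
            assert profile.amounts[abbr] == 0.0
        assert profile.amounts["THE"] > 0
        assert profile.amounts["a-Cortolone"] > 0

    def test_rho_zero_extreme(self, registry):
        scenario = SimulationScenario(rho_5alpha=0.0)
        flux = steady_state_flux(registry.pathway, scenario)
        profile = excrete(flux, scenario, registry)
        assert profile.amounts["An"] == 0.0
        assert profile.amounts["Et"] > 0
        assert profile.amounts["5aTHF"] == 0.0

    def test_estrogen_flux_rejected(self, registry):
        flux = steady_state_flux(registry.pathway, SimulationScenario())
        leaky = type(flux)(
            synthesis=flux.synthesis,
            sink={**flux.sink, "estrone": 5.0},
            input_flux_effective=flux.input_flux_effective,
        )
        with pytest.raises(ScenarioError, match="estrone"):
            excrete(leaky, SimulationScenario(), registry)


class TestSimulateCohort:
    def test_zero_noise_identical(self, registry):
        scenario = SimulationScenario(noise_sigma=0.0)
        cohort = simulate_cohort(scenario, 5, seed=1, registry=registry)
        flux = steady_state_flux(registry.pathway, scenario)
        base = excrete(flux, scenario, registry)
        for p in cohort:
            assert p.amounts == pytest.approx(base.amounts)

    def test_same_seed_identical(self, registry):
        a = simulate_cohort(scenario_preset("normal"), 10, seed=5, registry=registry)
        b = simulate_cohort(scenario_preset("normal"), 10, seed=5, registry=registry)
        assert [p.amounts for p in a] == [p.amounts for p in b]

    def test_different_seed_differs(self, registry):
        a = simulate_cohort(scenario_preset("normal"), 2, seed=5, registry=registry)
        b = simulate_cohort(scenario_preset("normal"), 2, seed=6, registry=registry)
        assert a[0].amounts != b[0].amounts

    def test_lognormal_median_property(self, registry):
        scenario = scenario_preset("normal")
        cohort = simulate_cohort(scenario, 1000, seed=2, registry=registry)
        flux = steady_state_flux(registry.pathway, scenario)
        base = excrete(flux, scenario, registry)
        abbrs = sorted(base.amounts)
        samples = np.array([[p.amounts[a] for a in abbrs] for p in cohort])
        medians = np.median(samples, axis=0)
        # SE of the sample median of a log-normal ~ 1.2533 * sigma / sqrt(n) on log scale
        se_log = 1.2533 * scenario.noise_sigma / np.sqrt(1000)
        for j, abbr in enumerate(abbrs):
            if base.amounts[abbr] == 0:
                assert medians[j] == 0
            else:
                assert abs(np.log(medians[j] / base.amounts[abbr])) < 3 * se_log, abbr

    def test_bad_n(self, registry):
        with pytest.raises(ScenarioError):
            simulate_cohort(scenario_preset("normal"), 0, registry=registry)


class TestPresets:
    def test_normal_is_default(self):
        scenario = scenario_preset("normal")
        assert scenario == SimulationScenario(name="normal")

    def test_acrd(self):
        scenario = scenario_preset("ACRD")
        assert scenario.beta_11oxo == 0.95
        assert scenario.activities == {}

    def test_ame(self):
        assert scenario_preset("AME").beta_11oxo == 0.15

    def test_srd5a2(self):
        assert scenario_preset("SRD5A2").rho_5alpha == 0.05

    def test_ord_leaves_mitochondrial_enzymes_untouched(self):
        scenario = scenario_preset("ORD")
        assert scenario.por_activity == 0.05
        assert "CYP11B1" not in scenario.activities
        assert "CYP11B2" not in scenario.activities

    def test_ord_pregnancy_enables_backdoor(self):
        assert scenario_preset("ORD_pregnancy").enable_backdoor
        assert not scenario_preset("ORD").enable_backdoor

    def test_unknown_preset_lists_names(self):
        with pytest.raises(ScenarioError, match="normal"):
            scenario_preset("nope")

    def test_all_presets_construct(self, registry):
        for name in PRESET_NAMES:
            scenario = scenario_preset(name)
            flux = steady_state_flux(registry.pathway, scenario)
            profile = excrete(flux, scenario, registry)
            assert sum(profile.amounts.values()) == pytest.approx(
                flux.input_flux_effective, rel=1e-9
            )


class TestScenarioValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"por_activity": 1.5},
            {"rho_5alpha": -0.1},
            {"beta_11oxo": 2.0},
            {"input_flux": 0.0},
            {"noise_sigma": -1.0},
            {"activities": {"CYP21A2": 1.2}},
        ],
    )
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ScenarioError):
            SimulationScenario(**kwargs)


class TestDiseaseDirections:
    def test_21ohd_precursor_ratio_monotone_in_activity(self, registry):
        values = []
        for a in np.linspace(0.01, 1.0, 11):
            profile = _noise_free(
                registry, "21OHD", activities={"CYP21A2": float(a)}
            )
            values.append(
                profile.amounts["17HP"]
                / (profile.amounts["THE"] + profile.amounts["THF"] + profile.amounts["5aTHF"])
            )
        assert all(values[i] >= values[i + 1] - 1e-12 for i in range(10))

    def test_acrd_raises_both_ratios(self, registry):
        normal = _noise_free(registry, "normal")
        acrd = _noise_free(registry, "ACRD")
        for ratio_id in ("ACRD_1", "ACRD_2"):
            rd = next(r for r in registry.ratios if r.id == ratio_id)
            assert ratio_value(acrd, rd) > ratio_value(normal, rd)

    def test_ord_signature(self, registry):
        normal = _noise_free(registry, "normal")
        ord_ = _noise_free(registry, "ORD")
        for rd in registry.ratios_for("ORD"):
            assert ratio_value(ord_, rd) > ratio_value(normal, rd), rd.id
        assert (
            group_totals(ord_, registry)["androgens"]
            < group_totals(normal, registry)["androgens"]
        )

    def test_backdoor_raises_androsterone(self, registry):
        ord_ = _noise_free(registry, "ORD")
        ordp = _noise_free(registry, "ORD_pregnancy")
        assert ordp.amounts["An"] > ord_.amounts["An"]
        assert ordp.amounts["3a5a17HP"] > ord_.amounts["3a5a17HP"]


def test_parameter_recovery_smoke(registry, reference_set):
    """Single-disorder scenarios produce the correct top-ranked positive call.

    (The full 9 x 50 sweep runs in the acceptance suite; this is a spot
    check on three mechanistically distinct disorders.)
    """
    from steromet.diagnostics import evaluate_panel

    for disorder in ("21OHD", "ACRD", "SRD5A2"):
        cases = simulate_cohort(scenario_preset(disorder), 10, seed=13, registry=registry)
        hits = 0
        for case in cases:
            _, calls = evaluate_panel(case, registry, reference_set)
            if calls[0].positive and calls[0].disorder == disorder:
                hits += 1
        assert hits >= 9, disorder
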