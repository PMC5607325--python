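"""Constraint compilation: mass balance, physiology, isotopes, site rows."""

import numpy as np
import pytest

import ventlim as vl
from ventlim.compile import (
    CompileError,
    IsotopeOptions,
    compile_isotope_constraints,
    compile_mass_balance,
    compile_physiological_constraints,
    compile_site_constraints,
)
from ventlim.model import Compartment, SiteEnvironment, build_topology
from ventlim.synthetic import standard_compartments


def _row_by_tag(rows, tag_fragment):
    hits = [r for r in rows if tag_fragment in r.tag]
    assert hits, f"no row tagged with {tag_fragment!r}"
    return hits


class TestMassBalance:
    def test_single_compartment_signs(self):
        comps = [
            Compartment("B", "b", "internal", "detritus"),
            Compartment("In", "i", "external", "detritus"),
            Compartment("Out1", "o1", "external", "dissolved"),
            Compartment("Out2", "o2", "external", "dissolved"),
        ]
        model = build_topology(comps, flow_list=[("In", "B"), ("B", "Out1"), ("B", "Out2")])
        (row,) = compile_mass_balance(model)
        assert row.coeffs == {"In->B": 1.0, "B->Out1": -1.0, "B->Out2": -1.0}
        assert row.rhs == 0.0

    def test_site_row_counts(self, fixtures_by_site):
        expected = {"BOV": 9, "HR1": 10, "HR2": 9}
        for site, n in expected.items():
            assert len(compile_mass_balance(fixtures_by_site[site])) == n

    def test_no_internals_is_an_error(self):
        comps = [
            Compartment("A", "a", "external", "detritus"),
            Compartment("B", "b", "internal", "detritus"),
        ]
        model = build_topology(comps, flow_list=[("A", "B"), ("B", "A")])
        model.compartments = [c for c in model.compartments if not c.is_internal]
        with pytest.raises(CompileError):
            compile_mass_balance(model)


class TestPhysiology:
    @pytest.fixture()
    def vent_model(self):
        comps = []
        for c in standard_compartments():
            if c.is_internal and c.taxon_class in ("bacteria", "macrofauna", "megafauna"):
                c = vl.Compartment(c.id, c.name, c.locality, c.taxon_class,
                                   biomass=10.0, feeding_modes=c.feeding_modes)
            comps.append(c)
        env = SiteEnvironment("V", 1000.0, 24.0, scoc_range=(1.62, 2.86),
                              poc_range=(0.70, 27.17))
        return build_topology(comps, environment=env)

    def test_macrofaunal_maintenance_bound(self, vent_model):
        # biomass 10 at rounded Tlim 1.3: lower respiration bound 0.13
        rows = compile_physiological_constraints(vent_model, tlim_mode="rounded")
        (row,) = _row_by_tag(rows, "maintenance_respiration:MacDF")
        assert row.coeffs == {"MacDF->DIC": 1.0}
        assert row.rhs == pytest.approx(0.13)

    def test_megafaunal_maintenance_bound(self, vent_model):
        rows = compile_physiological_constraints(vent_model, tlim_mode="rounded")
        (row,) = _row_by_tag(rows, "maintenance_respiration:MegDF")
        assert row.rhs == pytest.approx(0.013)

    def test_bacterial_growth_efficiency_window(self, vent_model):
        rows = compile_physiological_constraints(vent_model)
        lo_row, hi_row = _row_by_tag(rows, "bge:Bac")
        labels = vent_model.flow_labels
        x = np.zeros(len(labels))

        def set_flow(lab, v):
            x[labels.index(lab)] = v

        def sat(row):
            return bool(sum(c * x[labels.index(l)] for l, c in row.coeffs.items()) >= row.rhs - 1e-12)

        # uptake 1.0: production must lie in [0.05, 0.45]
        set_flow("Det->Bac", 1.0)
        for production, ok in [(0.2, True), (0.04, False), (0.5, False)]:
            set_flow("Bac->DIC", 1.0 - production)
            assert (sat(lo_row) and sat(hi_row)) == ok

    def test_missing_biomass_names_compartment(self, vent_model):
        broken = build_topology(
            [vl.Compartment(c.id, c.name, c.locality, c.taxon_class,
                            biomass=None if c.id == "MacSF" else c.biomass,
                            feeding_modes=c.feeding_modes)
             for c in vent_model.compartments],
            flow_list=[(f.source, f.sink) for f in vent_model.flows],
            environment=vent_model.environment,
        )
        with pytest.raises(CompileError, match="MacSF"):
            compile_physiological_constraints(broken)


class TestIsotopes:
    def _two_source_model(self, consumer_mean, consumer_sd=1.0):
        comps = [
            Compartment("Det", "det", "internal", "detritus", d13c_mean=-20.0),
            Compartment("Bac", "bac", "internal", "bacteria", biomass=1.0,
                        d13c_mean=-30.0, feeding_modes=frozenset({"heterotrophy"})),
            Compartment("MacDF", "df", "internal", "macrofauna", biomass=1.0,
                        d13c_mean=consumer_mean, d13c_sd=consumer_sd,
                        feeding_modes=frozenset({"deposit"})),
            Compartment("Det_w", "w", "external", "detritus", d13c_mean=-20.0),
            Compartment("DIC", "dic", "external", "dissolved"),
            Compartment("Predation", "p", "external", "megafauna"),
        ]
        flows = [("Det_w", "Det"), ("Det", "Bac"), ("Det", "MacDF"), ("Bac", "MacDF"),
                 ("Bac", "DIC"), ("Bac", "Det"), ("MacDF", "DIC"), ("MacDF", "Det"),
                 ("MacDF", "Predation")]
        return build_topology(comps, flow_list=flows)

    def test_balanced_mixture_accepted(self):
        # sources -20 and -30 with discrimination 1: equal flows mix to -24
        model = self._two_source_model(consumer_mean=-24.0)
        rows = [r for r in compile_isotope_constraints(model, discrimination=1.0)
                if "MacDF" in r.tag]
        assert len(rows) == 2
        x = {"Det->MacDF": 1.0, "Bac->MacDF": 1.0}
        for row in rows:
            val = sum(c * x.get(l, 0.0) for l, c in row.coeffs.items())
            assert val >= row.rhs - 1e-12

    def test_unreachable_signature_rejected_for_any_intake(self):
        # single food source at -30 cannot produce a -25 +- 2 consumer
        comps = [
            Compartment("Det", "det", "internal", "detritus", d13c_mean=-30.0),
            Compartment("MacDF", "df", "internal", "macrofauna", biomass=1.0,
                        d13c_mean=-25.0, d13c_sd=1.0, feeding_modes=frozenset({"deposit"})),
            Compartment("Det_w", "w", "external", "detritus", d13c_mean=-30.0),
            Compartment("DIC", "dic", "external", "dissolved"),
        ]
        model = build_topology(comps, flow_list=[
            ("Det_w", "Det"), ("Det", "MacDF"), ("MacDF", "DIC"), ("MacDF", "Det")])
        rows = compile_isotope_constraints(model, discrimination=1.0, tolerance_sd=2.0)
        upper = [r for r in rows if r.coeffs.get("Det->MacDF", 0.0) < 0]
        assert upper  # the mismatch makes one side strictly negative per unit intake

    def test_consumer_without_data_contributes_no_rows(self):
        model = self._two_source_model(consumer_mean=-24.0)
        stripped = build_topology(
            [Compartment(c.id, c.name, c.locality, c.taxon_class, biomass=c.biomass,
                         d13c_mean=None if c.id == "MacDF" else c.d13c_mean,
                         d13c_sd=None, feeding_modes=c.feeding_modes)
             for c in model.compartments],
            flow_list=[(f.source, f.sink) for f in model.flows],
        )
        assert compile_isotope_constraints(stripped) == []

    def test_consumer_with_data_but_no_food_is_an_error(self):
        comps = [
            Compartment("Det", "det", "internal", "detritus", d13c_mean=-25.0),
            Compartment("MacDF", "df", "internal", "macrofauna", biomass=1.0,
                        d13c_mean=-24.0, d13c_sd=1.0, feeding_modes=frozenset({"deposit"})),
            Compartment("Det_w", "w", "external", "detritus", d13c_mean=-25.0),
            Compartment("DIC", "dic", "external", "dissolved"),
        ]
        model = build_topology(comps, flow_list=[
            ("Det_w", "Det"), ("Det", "Det_w"), ("DIC", "MacDF"), ("MacDF", "DIC")])
        with pytest.raises(CompileError, match="MacDF"):
            compile_isotope_constraints(model)


class TestSiteRows:
    @pytest.mark.parametrize("site,expected", [("HR1", (1.62, 2.86)), ("BOV", (0.81, 2.86))])
    def test_scoc_bounds(self, fixtures_by_site, site, expected):
        rows = compile_site_constraints(fixtures_by_site[site])
        scoc = [r for r in rows if r.tag == "scoc"]
        assert len(scoc) == 2
        lo = [r.rhs for r in scoc if all(c > 0 for c in r.coeffs.values())]
        hi = [-r.rhs for r in scoc if all(c < 0 for c in r.coeffs.values())]
        assert lo == [pytest.approx(expected[0])]
        assert hi == [pytest.approx(expected[1])]

    def test_poc_rows_bound_deposition(self, hr1_model):
        rows = [r for r in compile_site_constraints(hr1_model) if r.tag == "poc"]
        assert len(rows) == 2
        assert {tuple(r.coeffs.items()) for r in rows} == {
            (("Det_w->Det", 1.0),), (("Det_w->Det", -1.0),)
        }
        assert sorted(abs(r.rhs) for r in rows) == [pytest.approx(0.70), pytest.approx(27.17)]

    def test_missing_ranges_are_errors(self, hr1_model):
        import dataclasses
        env = dataclasses.replace(hr1_model.environment, scoc_range=None)
        broken = hr1_model.with_environment(env)
        with pytest.raises(CompileError, match="scoc"):
            compile_site_constraints(broken)


class TestFullCompile:
    def test_every_flow_has_a_nonnegativity_row(self, hr1_system, hr1_model):
        tags = set(hr1_system.ineq_provenance)
        for lab in hr1_model.flow_labels:
            assert f"nonnegativity:{lab}" in tags

    def test_rows_reference_only_declared_flows_and_are_nonzero(self, hr1_system):
        # enforced by construction; assert the invariant on the built arrays
        assert hr1_system.E.shape[1] == hr1_system.G.shape[1] == hr1_system.n_flows
        assert (np.abs(hr1_system.E).max(axis=1) > 0).all()
        assert (np.abs(hr1_system.G).max(axis=1) > 0).all()

    def test_compile_is_deterministic(self, hr1_model):
        a = vl.compile(hr1_model)
        b = vl.compile(hr1_model)
        assert np.array_equal(a.E, b.E) and np.array_equal(a.G, b.G)
        assert np.array_equal(a.f, b.f) and np.array_equal(a.h, b.h)
        assert a.row_provenance == b.row_provenance

    def test_temperature_change_touches_only_tlim_rows(self, hr1_model):
        import dataclasses
        warm = hr1_model.with_environment(
            dataclasses.replace(hr1_model.environment, temperature=30.0))
        a, b = vl.compile(hr1_model), vl.compile(warm)
        assert a.row_provenance == b.row_provenance
        changed = [
            tag for i, tag in enumerate(a.ineq_provenance)
            if not (np.array_equal(a.G[i], b.G[i]) and a.h[i] == b.h[i])
        ]
        assert changed and all("[Tlim]" in tag for tag in changed)

    def test_removing_a_compartment_removes_exactly_its_rows_and_columns(self, hr1_model):
        reduced = build_topology(
            [c for c in hr1_model.compartments],
            site_absences={"MacES"},
            flow_list=[(f.source, f.sink) for f in hr1_model.flows],
            environment=hr1_model.environment,
            rules=hr1_model.rules,
        )
        a = vl.compile(hr1_model)
        b = vl.compile(reduced)
        dropped_rows = set(a.row_provenance) - set(b.row_provenance)
        assert all("MacES" in tag for tag in dropped_rows)
        dropped_cols = set(a.flow_labels) - set(b.flow_labels)
        assert dropped_cols == {l for l in a.flow_labels if "MacES" in l}
        # surviving rows keep identical coefficients on the surviving flows
        keep = [a.flow_labels.index(l) for l in b.flow_labels]
        for tag in set(b.ineq_provenance):
            rows_a = sorted(
                tuple(a.G[i, keep]) + (a.h[i],)
                for i, t in enumerate(a.ineq_provenance) if t == tag)
            rows_b = sorted(
                tuple(b.G[i]) + (b.h[i],)
                for i, t in enumerate(b.ineq_provenance) if t == tag)
            assert rows_a == rows_b

    def test_custom_constraints_enter_with_provenance(self):
        comps = [
            Compartment("A", "a", "internal", "detritus"),
            Compartment("In", "i", "external", "detritus"),
            Compartment("Out", "o", "external", "dissolved"),
        ]
        model = build_topology(
            comps, flow_list=[("In", "A"), ("A", "Out")],
            extra_constraints=[({"In->A": 1.0}, "<", 2.0)],
        )
        system = vl.compile(model, IsotopeOptions(enabled=False),
                            include_physiology=False, include_site=False)
        assert "custom:0" in system.ineq_provenance
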