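"""Network indices: closed forms, scale invariance, capacity bounds."""

import numpy as np
import pytest

import ventlim as vl
from ventlim.errors import VentlimError
from ventlim.indices import (
    FlowMatrix,
    average_mutual_information,
    compartmentalisation,
    ensemble_indices,
    finn_cycling_index,
    n_links,
    to_flow_matrix,
    total_system_throughflow,
)


def fm(labels, T, imports=None, exports=None, respiration=None):
    n = len(labels)
    z = np.zeros(n)
    return FlowMatrix(labels, np.asarray(T, dtype=float),
                      imports if imports is not None else z.copy(),
                      exports if exports is not None else z.copy(),
                      respiration if respiration is not None else z.copy())


@pytest.fixture()
def loop():
    """import 1 -> A, A->B 1, B->A 0.5, B->export 0.5 (hand-workable cycle)."""
    return fm(["A", "B"], [[0.0, 1.0], [0.5, 0.0]],
              imports=np.array([1.0, 0.0]), exports=np.array([0.0, 0.5]))


class TestFlowMatrix:
    def test_single_flow_placement(self, hr1_model):
        x = np.zeros(hr1_model.n_flows)
        x[hr1_model.flow_index("Det->Bac")] = 1.0
        m = to_flow_matrix(hr1_model, x)
        i, j = m.labels.index("Det"), m.labels.index("Bac")
        assert m.T[i, j] == 1.0
        assert m.T.sum() == 1.0

    def test_balanced_solution_balances_per_compartment(self, hr1_model, hr1_ensemble):
        m = to_flow_matrix(hr1_model, hr1_ensemble.samples[0])
        assert m.max_imbalance() <= 1e-8

    def test_negative_entry_rejected(self, hr1_model):
        x = np.zeros(hr1_model.n_flows)
        x[0] = -0.1
        with pytest.raises(VentlimError, match="negative"):
            to_flow_matrix(hr1_model, x)

    def test_length_mismatch_rejected(self, hr1_model):
        with pytest.raises(VentlimError, match="length"):
            to_flow_matrix(hr1_model, np.zeros(3))

    def test_respiration_separated_from_exports(self, hr1_model, hr1_ensemble):
        m = to_flow_matrix(hr1_model, hr1_ensemble.samples[0])
        resp_cols = [fl for fl in hr1_model.flows if fl.sink == "DIC"
                     and hr1_model.compartment(fl.source).is_internal]
        total_resp = sum(hr1_ensemble.samples[0][fl.index] for fl in resp_cols)
        assert m.respiration.sum() == pytest.approx(total_resp, abs=1e-12)


class TestTST:
    def test_single_pass_through(self):
        m = fm(["A"], [[0.0]], imports=np.array([1.0]), exports=np.array([1.0]))
        assert total_system_throughflow(m) == pytest.approx(1.0, abs=1e-12)

    def test_loop_throughflows_sum(self, loop):
        assert total_system_throughflow(loop) == pytest.approx(2.5, abs=1e-12)

    def test_empty_network(self):
        assert total_system_throughflow(fm(["A", "B"], np.zeros((2, 2)))) == 0.0


class TestFCI:
    def test_acyclic_chain_has_no_cycling(self):
        chain = fm(["A", "B"], [[0.0, 1.0], [0.0, 0.0]],
                   imports=np.array([1.0, 0.0]), exports=np.array([0.0, 1.0]))
        assert finn_cycling_index(chain) == pytest.approx(0.0, abs=1e-12)

    def test_hand_inverted_loop(self, loop):
        # N = [[1.5, 1.0], [0.75, 1.5]] by hand; FCI = 1/3
        assert finn_cycling_index(loop) == pytest.approx(1 / 3, abs=1e-12)

    def test_corrected_variant_rescales_denominator(self, loop):
        tc_over_tst = finn_cycling_index(loop)
        corrected = finn_cycling_index(loop, corrected=True)
        assert corrected == pytest.approx(tc_over_tst / (1 - tc_over_tst), abs=1e-12)

    def test_removed_return_flow_zeroes_index(self):
        m = fm(["A", "B"], [[0.0, 1.0], [0.0, 0.0]],
               imports=np.array([1.0, 0.0]), exports=np.array([0.0, 1.0]))
        assert finn_cycling_index(m) == 0.0

    def test_fully_cyclic_component_rejected(self):
        # a closed A<->B loop with no exports retains carbon forever
        m = fm(["A", "B"], [[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(VentlimError, match="cyclic"):
            finn_cycling_index(m)

    def test_scale_invariance(self, loop):
        scaled = fm(loop.labels, loop.T * 7.3, loop.imports * 7.3,
                    loop.exports * 7.3, loop.respiration * 7.3)
        assert finn_cycling_index(scaled) == pytest.approx(finn_cycling_index(loop), abs=1e-12)
        assert total_system_throughflow(scaled) == pytest.approx(
            7.3 * total_system_throughflow(loop), abs=1e-9)


class TestAMI:
    def test_single_flow_carries_no_information(self):
        m = fm(["A", "B"], [[0.0, 1.0], [0.0, 0.0]])
        assert average_mutual_information(m) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("k", [2, 4, 8])
    def test_parallel_deterministic_transfers(self, k):
        labels = [f"c{i}" for i in range(2 * k)]
        T = np.zeros((2 * k, 2 * k))
        for i in range(k):
            T[2 * i, 2 * i + 1] = 1.0
        assert average_mutual_information(fm(labels, T)) == pytest.approx(
            np.log2(k), abs=1e-12)

    def test_fully_mixed_two_by_two_is_independent(self):
        m = fm(["a", "b", "c", "d"], [
            [0, 0, 1, 1],
            [0, 0, 1, 1],
            [0, 0, 0, 0],
            [0, 0, 0, 0],
        ])
        assert average_mutual_information(m) == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance(self, loop):
        scaled = fm(loop.labels, loop.T * 3.1, loop.imports * 3.1,
                    loop.exports * 3.1, loop.respiration * 3.1)
        assert average_mutual_information(scaled) == pytest.approx(
            average_mutual_information(loop), abs=1e-12)

    def test_capacity_bound(self, hr1_model, hr1_ensemble):
        for row in hr1_ensemble.samples[:20]:
            m = to_flow_matrix(hr1_model, row)
            # extended matrix has n internal + import row / export+resp columns
            assert average_mutual_information(m) <= np.log2(len(m.labels) + 2)

    def test_parallel_duplicate_path_never_increases_ami(self):
        single = fm(["A", "B", "C"], [[0, 1, 0], [0, 0, 1], [0, 0, 0]],
                    imports=np.array([1.0, 0, 0]), exports=np.array([0, 0, 1.0]))
        # the A->B->C path split over a parallel duplicate conduit B2
        dup = fm(["A", "B", "C", "B2"],
                 [[0, 0.5, 0, 0.5], [0, 0, 0.5, 0], [0, 0, 0, 0], [0, 0, 0.5, 0]],
                 imports=np.array([1.0, 0, 0, 0]), exports=np.array([0, 0, 1.0, 0]))
        assert average_mutual_information(dup) <= average_mutual_information(single) + 1e-12
        # merging the duplicate back into shared sinks strictly mixes
        mixed = fm(["A", "B", "C", "B2"],
                   [[0, 0.5, 0, 0.5], [0, 0, 0.25, 0], [0, 0, 0, 0], [0, 0.25, 0.25, 0]],
                   imports=np.array([1.0, 0, 0, 0]),
                   exports=np.array([0, 0.25, 0.75, 0]))
        assert average_mutual_information(mixed) < average_mutual_information(single)


class TestCompartmentalisation:
    def test_complete_graph(self):
        T = np.ones((3, 3)) - np.eye(3)
        assert compartmentalisation(fm(["a", "b", "c"], T)) == pytest.approx(1.0, abs=1e-12)

    def test_two_disjoint_dyads(self):
        T = np.zeros((4, 4))
        T[0, 1] = T[2, 3] = 1.0
        assert compartmentalisation(fm(list("abcd"), T)) == pytest.approx(1 / 3, abs=1e-12)

    def test_edgeless_graph(self):
        assert compartmentalisation(fm(list("abc"), np.zeros((3, 3)))) == 0.0

    def test_needs_two_compartments(self):
        with pytest.raises(VentlimError):
            compartmentalisation(fm(["a"], np.zeros((1, 1))))


class TestEnsembleIndices:
    def test_identical_rows_have_zero_sd(self, hr1_model, hr1_ensemble):
        row = hr1_ensemble.samples[0]
        ens = vl.FlowEnsemble(np.tile(row, (3, 1)), hr1_ensemble.flow_labels,
                              0, 0, 1.0, 3)
        rep = ensemble_indices(hr1_model, ens)
        assert all(sd == pytest.approx(0.0, abs=1e-12) for _, sd in rep.values())

    def test_two_row_mean_is_midpoint(self, hr1_model, hr1_ensemble):
        two = vl.FlowEnsemble(hr1_ensemble.samples[:2], hr1_ensemble.flow_labels,
                              0, 0, 1.0, 2)
        rep = ensemble_indices(hr1_model, two)
        from ventlim.indices import network_indices
        r0 = network_indices(hr1_model, two.samples[0]).as_dict()
        r1 = network_indices(hr1_model, two.samples[1]).as_dict()
        for key, (mean, _) in rep.items():
            assert mean == pytest.approx((r0[key] + r1[key]) / 2, rel=1e-12)

    def test_fci_stays_in_unit_interval(self, hr1_model, hr1_ensemble):
        rep = ensemble_indices(hr1_model, vl.FlowEnsemble(
            hr1_ensemble.samples[:50], hr1_ensemble.flow_labels, 0, 0, 1.0, 50))
        mean, _ = rep["fci"]
        assert 0.0 <= mean <= 1.0

    def test_links_count_positive_flows(self, hr1_model, hr1_ensemble):
        m = to_flow_matrix(hr1_model, hr1_ensemble.samples[0])
        assert n_links(m, tol=1e-10) <= hr1_model.n_flows
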