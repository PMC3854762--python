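import numpy as np
import pytest

from ccdock.config import Config, DEFAULTS
from ccdock.propensity import (boltzmann_weights, combine, fir_predicted,
                               interaction_propensity, jet_frequency,
                               nip_interface, normalize_nip, retain)
from conftest import make_decoys, rid

RT = DEFAULTS.gas_constant * DEFAULTS.temperature


class TestBoltzmann:
    def test_best_energy_weight_one(self):
        ds = make_decoys("a", "b", [(-5.0, set(), set()), (-3.0, set(), set())])
        bw = boltzmann_weights(ds)
        assert bw.weights[0] == 1.0
        assert bw.e_min == -5.0

    def test_half_weight_at_rt_ln2(self):
        ds = make_decoys("a", "b", [(-5.0, set(), set()),
                                    (-5.0 + RT * np.log(2), set(), set())])
        bw = boltzmann_weights(ds)
        assert bw.weights[1] == pytest.approx(0.5, rel=1e-12)

    def test_weights_decrease_with_energy(self):
        ds = make_decoys("a", "b", [(e, set(), set())
                                    for e in (-9.0, -7.0, -4.0)])
        w = boltzmann_weights(ds).weights
        assert w[0] > w[1] > w[2] > 0

    def test_retention_thresholds(self):
        energies = [-5.0, -5.0 + RT * np.log(2), -5.0 + RT * np.log(100)]
        ds = make_decoys("a", "b", [(e, set(), set()) for e in energies])
        assert len(retain(ds, min_weight=0.1)) == 2
        assert len(retain(ds, min_weight=1e-9)) == 3
        assert len(retain(ds, min_weight=1.0)) == 1

    def test_invalid_inputs(self):
        ds = make_decoys("a", "b", [(-1.0, set(), set())])
        with pytest.raises(ValueError):
            boltzmann_weights(ds, temperature=-1.0)
        with pytest.raises(ValueError):
            retain(ds, min_weight=0.0)


class TestInteractionPropensity:
    def test_pooled_counting(self):
        # 3 partners with (2, 3, 5) conformations, all retained (equal E);
        # residue 1 present in (1, 0, 4) of them -> ip = 5/10
        surface = frozenset(rid(i) for i in range(1, 6))
        sets = [
            make_decoys("p", "q", [(-1.0, {rid(1)}, set()),
                                   (-1.0, {rid(2)}, set())]),
            make_decoys("p", "r", [(-1.0, {rid(3)}, set())] * 3),
            make_decoys("s", "p", [(-1.0, set(), {rid(1)})] * 4
                        + [(-1.0, set(), {rid(5)})]),
        ]
        ip = interaction_propensity("p", sets, surface)
        assert ip[rid(1)] == pytest.approx(0.5)
        assert ip[rid(4)] == 0.0

    def test_residue_in_every_interface(self):
        surface = frozenset({rid(1), rid(2)})
        sets = [make_decoys("p", "q", [(-1.0, {rid(1)}, set())] * 3)]
        ip = interaction_propensity("p", sets, surface)
        assert ip[rid(1)] == 1.0 and ip[rid(2)] == 0.0

    def test_shift_invariance(self):
        surface = frozenset({rid(1), rid(2)})
        confs = [(-8.0, {rid(1)}, set()), (-7.5, {rid(2)}, set()),
                 (-3.0, {rid(1)}, set())]
        shifted = [(e + 123.4, ir, il) for e, ir, il in confs]
        ip1 = interaction_propensity("p", [make_decoys("p", "q", confs)], surface)
        ip2 = interaction_propensity("p", [make_decoys("p", "q", shifted)], surface)
        assert ip1 == ip2

    def test_wrong_pair_rejected(self):
        with pytest.raises(ValueError):
            interaction_propensity("x", [make_decoys("a", "b", [(-1.0, set(),
                                                                 set())])],
                                   frozenset({rid(1)}))


class TestNIP:
    def test_arithmetic(self):
        # ip {0.1, 0.2, 0.7}: mean 1/3, max 0.7
        # nip = (ip - 1/3) / (0.7 - 1/3) -> exactly {-7/11, -4/11, 1}
        surface = frozenset({rid(1), rid(2), rid(3)})
        ip = {rid(1): 0.1, rid(2): 0.2, rid(3): 0.7}
        nip = normalize_nip(ip, surface)
        assert nip[rid(1)] == pytest.approx(-7 / 11)
        assert nip[rid(2)] == pytest.approx(-4 / 11)
        assert nip[rid(3)] == pytest.approx(1.0)

    def test_constant_profile_warns_and_zeroes(self):
        surface = frozenset({rid(1), rid(2)})
        nip = normalize_nip({rid(1): 0.4, rid(2): 0.4}, surface)
        assert nip == {rid(1): 0.0, rid(2): 0.0}

    def test_interface_cutoffs(self):
        nip = {rid(1): -0.6, rid(2): -0.3, rid(3): 1.0}
        assert nip_interface(nip, "p", cutoff=0.0).residues == {rid(3)}
        assert nip_interface(nip, "p", cutoff=1.5).residues == frozenset()
        assert nip_interface(nip, "p", cutoff=-np.inf).residues == set(nip)
        assert nip_interface(nip, "p", cutoff=0.0).provenance == "predicted"


class TestJetAndCombine:
    def test_jet_frequency_counts(self):
        surface = frozenset({rid(1), rid(2), rid(3)})
        runs = [{rid(1)}] * 7 + [{rid(2)}] * 3
        jet = jet_frequency(runs, surface)
        assert jet[rid(1)] == pytest.approx(0.7)
        assert jet[rid(2)] == pytest.approx(0.3)
        assert jet[rid(3)] == 0.0

    def test_combine_weights(self):
        nip = {rid(1): 0.5}
        jet = {rid(1): 1.0}
        assert combine(nip, jet, 0.4, 0.6)[rid(1)] == pytest.approx(0.8)
        assert combine(nip, jet, 1.0, 0.0)[rid(1)] == 0.5
        assert combine(nip, jet, 0.0, 1.0)[rid(1)] == 1.0

    def test_invalid_weights(self):
        with pytest.raises(ValueError):
            combine({rid(1): 0.0}, {}, 0.5, 0.6)
        with pytest.raises(ValueError):
            combine({rid(1): 0.0}, {}, -0.2, 1.2)


class TestFirPredicted:
    def test_threshold_counting(self):
        ds = make_decoys("a", "b",
                         [(-1.0, {rid(i) for i in range(1, 5)}, {rid(1)})])
        scores_r = {rid(1): 0.9, rid(2): 0.6, rid(3): 0.4, rid(4): 0.1}
        f = fir_predicted(ds.conformations[0], scores_r, {rid(1): 1.0}, tau=0.5)
        assert f.fir_receptor == 0.5
        assert f.fir_ligand == 1.0

    def test_all_or_none(self):
        ds = make_decoys("a", "b", [(-1.0, {rid(1)}, {rid(2)})])
        c = ds.conformations[0]
        assert fir_predicted(c, {rid(1): 0.9}, {rid(2): 0.9},
                             tau=0.5).fir_overall == 1.0
        assert fir_predicted(c, {rid(1): 0.1}, {rid(2): 0.1},
                             tau=0.5).fir_overall == 0.0

    def test_pipeline_identity_single_conformation(self):
        # one partner, one retained conformation, reference = its interface:
        # every interface residue scores above any tau <= its combined score
        surface = frozenset({rid(1), rid(2)})
        ds = make_decoys("a", "b", [(-1.0, {rid(1)}, {rid(2)})])
        ip = interaction_propensity("a", [ds], surface)
        nip = normalize_nip(ip, surface)
        jet = {rid(1): 1.0, rid(2): 1.0}
        comb = combine(nip, jet, 0.4, 0.6)
        f = fir_predicted(ds.conformations[0], comb, {rid(2): 1.0},
                          tau=min(comb[rid(1)], 1.0))
        assert f.fir_receptor == 1.0
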