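"""Decoding motifs: threshold gates, coherent/incoherent FFLs, exclusivity."""

import numpy as np
import pytest

from p53decode.containers import OSCILLATORY, RISING, KineticParams, TimeCourse, TimeGrid
from p53decode.expression_io import fold_change, max_fold_change
from p53decode.kinetic_model import sample_at, simulate_mrna, simulate_protein
from p53decode.motif_models import (FFLSpec, ThresholdSpec, exclusivity_index,
                                    hill, null_spec, simulate_cffl,
                                    simulate_iffl, simulate_threshold,
                                    simulate_y)
from p53decode.synthetic import (OSC_P53_SPEC, RISING_P53_SPEC, archetype,
                                 hourly_p53, load_motif_preset, simulate_clean)

KIN = KineticParams(1.0, 0.5, 1.0, 0.5, 0.0)


def simple_traces(p53, kin=KIN):
    mrna = simulate_mrna(p53, kin.kp_mrna, kin.kd_mrna)
    prot = simulate_protein(mrna, kin.kp_prot, kin.kd_prot, tdel=kin.tdel)
    return mrna, prot


class TestReduction:
    """Nulling each motif's distinguishing parameter recovers simple regulation."""

    def test_threshold_zero_theta(self, p53_osc):
        for level in ("transcriptional", "translational"):
            spec = ThresholdSpec(theta=0.0, level=level)
            tr = simulate_threshold(p53_osc, spec, KIN)
            mrna, prot = simple_traces(p53_osc)
            np.testing.assert_allclose(tr.mrna.levels, mrna.levels, atol=1e-9)
            np.testing.assert_allclose(tr.protein.levels, prot.levels, atol=1e-9)

    def test_cffl_zero_y_threshold(self, p53_osc):
        for level in ("transcriptional", "posttranscriptional"):
            spec = FFLSpec(topology="coherent", level=level, y_threshold=0.0)
            tr = simulate_cffl(p53_osc, spec, KIN)
            mrna, prot = simple_traces(p53_osc)
            np.testing.assert_allclose(tr.mrna.levels, mrna.levels, atol=1e-9)
            np.testing.assert_allclose(tr.protein.levels, prot.levels, atol=1e-9)

    def test_iffl_zero_repression(self, p53_rise):
        spec = FFLSpec(topology="incoherent", repression=0.0)
        tr = simulate_iffl(p53_rise, spec, KIN)
        mrna, prot = simple_traces(p53_rise)
        np.testing.assert_allclose(tr.protein.levels, prot.levels, atol=1e-9)

    @pytest.mark.parametrize("name", ["SESN1-like", "RAD51C-like", "HSPG2-like",
                                      "HOXC13-like", "BAX-like"])
    def test_all_preset_nulled_variants_reduce(self, name, p53_osc, p53_rise):
        mech = load_motif_preset(name)
        kin = mech.kinetics
        for p53 in (p53_osc, p53_rise):
            mrna, prot = simple_traces(p53, kin)
            if mech.threshold is not None:
                tr = simulate_threshold(p53, null_spec(mech.threshold), kin)
            elif mech.ffl.topology == "coherent":
                tr = simulate_cffl(p53, null_spec(mech.ffl), kin)
            else:
                tr = simulate_iffl(p53, null_spec(mech.ffl), kin)
            np.testing.assert_allclose(tr.protein.levels, prot.levels, atol=1e-9)


class TestThresholdGate:
    def test_theta_above_both_regimes_never_induces(self, p53_osc, p53_rise, grid):
        mech = archetype("k")  # high translational threshold
        for p53 in (p53_osc, p53_rise):
            tr = simulate_clean(mech, p53)
            fc = max_fold_change(fold_change(sample_at(tr.protein, grid)))
            assert fc < 1.15

    def test_medium_theta_induces_under_rising_only(self, p53_osc, p53_rise, grid):
        """A threshold between the regimes' mRNA maxima gates the protein
        open only when p53 keeps rising."""
        mech = archetype("g")
        fcs = {}
        for cond, p53 in ((OSCILLATORY, p53_osc), (RISING, p53_rise)):
            tr = simulate_clean(mech, p53)
            fcs[cond] = max_fold_change(fold_change(sample_at(tr.protein, grid)))
        assert fcs[RISING] > 1.15 > fcs[OSCILLATORY]

    def test_negative_theta_rejected(self):
        with pytest.raises(ValueError):
            ThresholdSpec(theta=-1.0)

    def test_hill_basic_values(self):
        assert hill(2.0, 2.0, 4.0) == pytest.approx(0.5)
        assert float(hill(5.0, 0.0, 4.0)) == 1.0


class TestCFFL:
    def test_broken_and_gate_never_induces(self, p53_rise, grid):
        spec = FFLSpec(topology="coherent", level="posttranscriptional",
                       y_production=0.0, y_threshold=1.0)
        tr = simulate_cffl(p53_rise, spec, KIN)
        fc = max_fold_change(fold_change(sample_at(tr.protein, grid)))
        assert fc < 1.15

    def _pulse_input(self, width, amp=2.5):
        g = TimeGrid(tuple(np.arange(0.0, 25.0, 1.0)))
        t = g.array
        levels = 0.2 + amp * ((t >= 2) & (t < 2 + width))
        return TimeCourse("x", RISING, 1, g, levels.astype(float))

    def test_persistence_detection(self, grid):
        """A brief input pulse leaves Z uninduced; a sustained one induces it."""
        spec = FFLSpec(topology="coherent", level="posttranscriptional",
                       y_production=0.5, y_degradation=0.05, y_delay=0.5,
                       y_threshold=1.0, x_half=1.4)
        for width, expect_induced in ((1.0, False), (12.0, True)):
            tr = simulate_cffl(self._pulse_input(width), spec, KIN)
            fc = max_fold_change(fold_change(sample_at(tr.protein, grid)),
                                 window=(1, 24))
            assert (fc > 1.15) == expect_induced

    def test_minimum_pulse_width_grows_with_y_delay(self):
        """Swept property: the shortest inducing pulse gets longer as the
        intermediate's delay increases."""
        def min_width(y_delay):
            spec = FFLSpec(topology="coherent", level="posttranscriptional",
                           y_production=0.5, y_degradation=0.05, y_delay=y_delay,
                           y_threshold=1.0, x_half=1.4)
            for width in np.arange(1.0, 20.1, 1.0):
                tr = simulate_cffl(self._pulse_input(width), spec, KIN)
                fc = fold_change(tr.protein)
                if float(np.max(fc.values)) > 1.15:
                    return width
            return np.inf
        widths = [min_width(d) for d in (0.0, 2.0, 4.0)]
        assert widths[0] <= widths[1] <= widths[2]
        assert widths[0] < widths[2]

    def test_incoherent_spec_rejected(self, p53_rise):
        with pytest.raises(ValueError):
            simulate_cffl(p53_rise, FFLSpec(topology="incoherent"), KIN)

    def test_cffl_presets_rising_exclusive(self, p53_osc, p53_rise, grid):
        for name in ("SESN1-like", "RAD51C-like"):
            mech = load_motif_preset(name)
            prot = {}
            for cond, p53 in ((OSCILLATORY, p53_osc), (RISING, p53_rise)):
                prot[cond] = sample_at(simulate_clean(mech, p53).protein, grid)
            label, margin = exclusivity_index(prot[OSCILLATORY], prot[RISING])
            assert label == "rising_only"
            assert margin < 0


class TestIFFL:
    def test_iffl_preset_oscillatory_exclusive(self, p53_osc, p53_rise, grid):
        mech = load_motif_preset("HSPG2-like")
        prot = {}
        for cond, p53 in ((OSCILLATORY, p53_osc), (RISING, p53_rise)):
            prot[cond] = sample_at(simulate_clean(mech, p53).protein, grid)
        label, margin = exclusivity_index(prot[OSCILLATORY], prot[RISING])
        assert label == "osc_only"
        assert margin > 0

    def test_mrna_protein_ordering_inverted(self, p53_osc, p53_rise, grid):
        """mRNA is induced more under rising while the protein shows the
        reverse ordering (the repressor is epistatic under sustained input)."""
        mech = load_motif_preset("HSPG2-like")
        out = {}
        for cond, p53 in ((OSCILLATORY, p53_osc), (RISING, p53_rise)):
            tr = simulate_clean(mech, p53)
            out[cond] = (
                max_fold_change(fold_change(sample_at(tr.mrna, grid))),
                max_fold_change(fold_change(sample_at(tr.protein, grid))),
            )
        assert out[RISING][0] > out[OSCILLATORY][0]      # mRNA higher under rising
        assert out[OSCILLATORY][1] > out[RISING][1]      # protein ordering inverted

    def test_coherent_spec_rejected(self, p53_rise):
        with pytest.raises(ValueError):
            simulate_iffl(p53_rise, FFLSpec(topology="coherent"), KIN)

    def test_stability_variant_attenuates_rising_protein(self, p53_rise, grid):
        """Destabilization by Y suppresses the rising-condition protein
        relative to the unrepressed loop (the degradation rate is bounded by
        1 per step, so suppression is partial rather than exclusive)."""
        from dataclasses import replace
        mech = load_motif_preset("HSPG2-like")
        spec = replace(mech.ffl, target="stability")
        repressed = sample_at(simulate_iffl(p53_rise, spec, mech.kinetics).protein, grid)
        free = sample_at(simulate_iffl(p53_rise, replace(spec, repression=0.0),
                                       mech.kinetics).protein, grid)
        fc_rep = max_fold_change(fold_change(repressed))
        fc_free = max_fold_change(fold_change(free))
        # full repression pins kd at the cap, so the induced excess shrinks
        # toward kd0/kd_cap = 0.7 of the free response
        assert fc_rep < 0.8 * fc_free


class TestExclusivityIndex:
    def test_identical_traces_none_margin_zero(self, grid, rng):
        levels = rng.uniform(0.5, 2.0, 11)
        a = TimeCourse("g", OSCILLATORY, 1, grid, levels)
        b = TimeCourse("g", RISING, 1, grid, levels)
        label, margin = exclusivity_index(a, b)
        assert label == "none"
        assert margin == pytest.approx(0.0)

    def test_zero_basal_rejected(self, grid):
        a = TimeCourse("g", OSCILLATORY, 1, grid, np.r_[0.0, np.ones(10)])
        b = TimeCourse("g", RISING, 1, grid, np.ones(11))
        with pytest.raises(ValueError):
            exclusivity_index(a, b)


class TestY:
    def test_y_accumulates_under_sustained_input_only(self, p53_osc, p53_rise):
        spec = FFLSpec(topology="coherent", level="posttranscriptional",
                       y_production=0.5, y_degradation=0.05, y_delay=0.5,
                       x_half=1.4)
        y_osc = simulate_y(p53_osc, spec)
        y_rise = simulate_y(p53_rise, spec)
        assert y_rise.levels.max() > 5 * max(y_osc.levels.max(), 1e-6)
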