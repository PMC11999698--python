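import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from octosim.morphology import build_octopus_morphology, surface_areas
from octosim.synapses import (
    AMPA_DEFAULT,
    GLYCINE_DEFAULT,
    DensityTable,
    SynapseKinetics,
    conductance_waveform,
    derive_ia_density,
    place_synapses,
    synapse_count_report,
    waveform_peak_time,
)


class TestWaveform:
    def test_zero_at_and_before_onset(self):
        kin = SynapseKinetics("AMPA", 0.3, 3.0)
        assert conductance_waveform(kin, 0.0) == 0.0
        assert conductance_waveform(kin, -1.0) == 0.0

    def test_peak_equals_gmax_by_normalization(self):
        for kin in (
            SynapseKinetics("AMPA", 0.3, 3.0, gmax=5.0),
            AMPA_DEFAULT,
            GLYCINE_DEFAULT,
        ):
            tp = waveform_peak_time(kin)
            assert conductance_waveform(kin, tp) == pytest.approx(kin.gmax)

    def test_double_exponential_peak_time_closed_form(self):
        """argmax = tr*td/(td-tr) * ln(td/tr) = 0.7675 ms for 0.3/3 ms."""
        kin = SynapseKinetics("AMPA", 0.3, 3.0)
        expected = 0.3 * 3.0 / (3.0 - 0.3) * math.log(10.0)
        assert expected == pytest.approx(0.7675, abs=5e-4)
        assert waveform_peak_time(kin) == pytest.approx(expected)
        t = np.linspace(0.0, 5.0, 50001)
        g = conductance_waveform(kin, t)
        assert t[np.argmax(g)] == pytest.approx(expected, abs=1e-3)

    def test_alpha_limit_peaks_at_tau(self):
        kin = SynapseKinetics("glycine", 3.0, 3.0, gmax=2.0)
        assert waveform_peak_time(kin) == 3.0
        assert conductance_waveform(kin, 3.0) == pytest.approx(2.0)

    def test_invalid_time_constants_rejected(self):
        with pytest.raises(ValueError):
            SynapseKinetics("AMPA", 3.0, 0.3)

    @given(
        tr=st.floats(0.05, 2.0),
        ratio=st.floats(1.0, 20.0),
        t=st.floats(0.0, 50.0),
    )
    def test_nonnegative_everywhere(self, tr, ratio, t):
        kin = SynapseKinetics("AMPA", tr, tr * ratio, gmax=1.0)
        assert conductance_waveform(kin, t) >= 0.0

    def test_unimodal_for_positive_time(self):
        t = np.linspace(1e-4, 30.0, 20000)
        for kin in (AMPA_DEFAULT, SynapseKinetics("x", 0.3, 3.0)):
            g = conductance_waveform(kin, t)
            k = np.argmax(g)
            assert np.all(np.diff(g[: k + 1]) >= -1e-12)
            assert np.all(np.diff(g[k:]) <= 1e-12)


class TestDensityTable:
    def test_ia_by_subtraction(self, density_table):
        ia = derive_ia_density(density_table)
        assert ia["dendrite"] == pytest.approx(10.7 - 4.1)
        assert ia["soma"] == pytest.approx(13.3 - 4.9)

    def test_packaged_ia_matches_subtraction(self, density_table):
        ia = derive_ia_density(density_table)
        assert density_table.density("SGN_Ia", "dendrite") == pytest.approx(
            ia["dendrite"], abs=0.05
        )
        assert density_table.density("SGN_Ia", "soma") == pytest.approx(
            ia["soma"], abs=0.05
        )

    def test_subtraction_of_equal_densities_is_zero(self):
        table = DensityTable(
            {
                ("SGN_total", "soma"): 5.0,
                ("SGN_total", "dendrite"): 5.0,
                ("SGN_Ibc", "soma"): 5.0,
                ("SGN_Ibc", "dendrite"): 5.0,
            }
        )
        ia = derive_ia_density(table)
        assert ia == {"soma": 0.0, "dendrite": 0.0}

    def test_inconsistent_table_rejected(self):
        table = DensityTable(
            {
                ("SGN_total", "soma"): 1.0,
                ("SGN_total", "dendrite"): 1.0,
                ("SGN_Ibc", "soma"): 2.0,
                ("SGN_Ibc", "dendrite"): 1.0,
            }
        )
        with pytest.raises(ValueError):
            derive_ia_density(table)


class TestPlacement:
    def test_expected_mode_reproduces_measured_budget(
        self, default_morphology, density_table
    ):
        pop = place_synapses(
            default_morphology, density_table, ["SGN_total"], seed=0, mode="expected"
        )
        counts = {
            (r["compartment"]): r["n"] for r in pop.counts().to_dict("records")
        }
        assert counts["soma"] == 203
        assert counts["dendrite"] == 832
        gly = place_synapses(
            default_morphology, density_table, ["glycinergic"], seed=0
        )
        assert len(gly) == 354

    def test_zero_density_gives_empty_population(self, default_morphology):
        table = DensityTable(
            {("glycinergic", "soma"): 0.0, ("glycinergic", "dendrite"): 0.0}
        )
        pop = place_synapses(default_morphology, table, ["glycinergic"], seed=0)
        assert len(pop) == 0

    def test_identical_seed_identical_population(
        self, default_morphology, density_table
    ):
        a = place_synapses(default_morphology, density_table, ["SGN_total"], seed=7)
        b = place_synapses(default_morphology, density_table, ["SGN_total"], seed=7)
        assert a.to_frame().equals(b.to_frame())

    def test_subtype_additivity_in_expected_mode(
        self, default_morphology, density_table
    ):
        """Ia + Ib/c counts match SGN_total within 1 per compartment."""
        total = place_synapses(default_morphology, density_table, ["SGN_total"])
        parts = place_synapses(
            default_morphology, density_table, ["SGN_Ia", "SGN_Ibc"]
        )
        tc = total.counts().groupby("compartment")["n"].sum()
        pc = parts.counts().groupby("compartment")["n"].sum()
        for comp in ("soma", "dendrite"):
            assert abs(int(tc[comp]) - int(pc[comp])) <= 1

    def test_tonotopic_rank_increases_with_distance(
        self, default_morphology, density_table
    ):
        from octosim.morphology import path_distance

        pop = place_synapses(default_morphology, density_table, ["SGN_total"], seed=3)
        ranked = sorted(
            (p for p in pop.placements if p.tonotopic_rank is not None),
            key=lambda p: p.tonotopic_rank,
        )
        dists = [path_distance(default_morphology, p.location) for p in ranked]
        assert all(b >= a - 1e-9 for a, b in zip(dists, dists[1:]))

    def test_poisson_mode_statistics(self, default_morphology, density_table):
        """Across seeded draws the counts behave like a Poisson sample."""
        areas = surface_areas(default_morphology)
        mean_expected = (
            density_table.density("glycinergic", "soma") * areas.soma_area
            + density_table.density("glycinergic", "dendrite") * areas.dendrite_area
        ) / 100.0
        counts = np.array(
            [
                len(
                    place_synapses(
                        default_morphology, density_table, ["glycinergic"],
                        seed=s, mode="poisson",
                    )
                )
                for s in range(1000)
            ]
        )
        assert abs(counts.mean() - mean_expected) / mean_expected < 0.05
        assert 0.8 < counts.var() / counts.mean() < 1.2

    def test_unknown_population_rejected(self, default_morphology, density_table):
        with pytest.raises(KeyError):
            place_synapses(default_morphology, density_table, ["GABAergic"])


class TestCountReport:
    def test_budget_and_shares(self, default_morphology, density_table):
        rep = synapse_count_report(density_table, surface_areas(default_morphology))
        assert rep.totals["SGN_total"] == 1035
        assert rep.totals["glycinergic"] == 354
        assert rep.dendritic_fraction == pytest.approx(83.0, abs=1.0)
        assert rep.ia_fraction_of_sgn == pytest.approx(62.0, abs=1.0)

    def test_density_ratios(self, default_morphology, density_table):
        rep = synapse_count_report(density_table, surface_areas(default_morphology))
        assert rep.e_i_ratio_soma == pytest.approx(13.3 / 1.8)
        assert rep.e_i_ratio_dendrite == pytest.approx(10.7 / 4.2)

    def test_equal_densities_give_unit_ratios(self, default_morphology):
        table = DensityTable(
            {
                ("SGN_total", "soma"): 3.0,
                ("SGN_total", "dendrite"): 3.0,
                ("glycinergic", "soma"): 3.0,
                ("glycinergic", "dendrite"): 3.0,
            }
        )
        rep = synapse_count_report(table, surface_areas(default_morphology))
        assert rep.e_i_ratio_soma == 1.0
        assert rep.e_i_ratio_dendrite == 1.0

    def test_zero_inhibition_flagged_infinite(self, default_morphology):
        table = DensityTable(
            {
                ("SGN_total", "soma"): 3.0,
                ("SGN_total", "dendrite"): 3.0,
                ("glycinergic", "soma"): 0.0,
                ("glycinergic", "dendrite"): 0.0,
            }
        )
        rep = synapse_count_report(table, surface_areas(default_morphology))
        assert math.isinf(rep.e_i_ratio_soma)
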