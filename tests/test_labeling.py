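"""Labeling kinetics simulator and synthetic dataset generators."""

import numpy as np
import pytest

from nitromet.calibration import fit_ngam
from nitromet.isotope import enrichment
from nitromet.labeling import (
    OUT,
    TRACER,
    ChannelingConfig,
    Flow,
    LabelingError,
    LabelingNetwork,
    Pool,
    generate_chemostat_dataset,
    generate_formate_batch,
    rtca_labeling_network,
    simulate_labeling,
)


def one_pool_network(flux=0.3, size=2.0, a=0.65):
    return LabelingNetwork(
        [Pool("x", size, 3)],
        [Flow(TRACER, "x", flux), Flow("x", OUT, flux)],
        tracer_enrichment=a,
    )


class TestSimulator:
    def test_one_pool_matches_closed_form(self):
        """e(t) = a (1 - exp(-F t / P)) for a single washed-through pool."""
        F, P, a = 0.3, 2.0, 0.65
        times = [0, 1, 2, 5, 10, 20, 40]
        res = simulate_labeling(one_pool_network(F, P, a), times=times)
        expected = a * (1 - np.exp(-(F * 1000 / 60) * np.asarray(times, float) / P))
        assert np.max(np.abs(res.series["x"].enrichment - expected)) < 1e-6

    def test_steady_state_reaches_tracer_enrichment(self):
        res = simulate_labeling(one_pool_network(), times=[0, 500, 1000])
        assert res.series["x"].enrichment[-1] == pytest.approx(0.65, abs=1e-6)

    def test_monotone_labeling_without_inactive_pools(self):
        net = rtca_labeling_network()
        res = simulate_labeling(net, times=list(np.linspace(0, 120, 25)))
        for pid, series in res.series.items():
            diffs = np.diff(series.enrichment)
            # non-decreasing up to the integrator's relative tolerance
            assert np.all(diffs >= -1e-6), pid

    def test_channeling_downstream_labels_faster_than_precursor(self):
        """With an inactive aKG sub-pool and the pathway running through
        the active sub-pool, glutamate leads measured aKG at early times."""
        net = rtca_labeling_network()
        cfg = ChannelingConfig(inactive_fraction={"akg": 0.5}, exchange_rate=0.05)
        res = simulate_labeling(net, cfg, times=[0, 5, 10, 20])
        akg = res.series["akg"].enrichment
        glu = res.series["glu"].enrichment
        assert np.all(glu[1:] > akg[1:])

    def test_no_channeling_precursor_leads(self):
        net = rtca_labeling_network()
        res = simulate_labeling(net, times=[0, 5, 10, 20])
        akg = res.series["akg"].enrichment
        glu = res.series["glu"].enrichment
        assert np.all(glu[1:] <= akg[1:] + 1e-12)

    def test_carbon_conservation(self):
        """Labeled carbon in pools plus labeled efflux equals the
        integrated labeled inflow (trapezoidal within solver tolerance)."""
        F, P, a = 0.3, 2.0, 0.65
        times = np.linspace(0, 30, 601)
        res = simulate_labeling(one_pool_network(F, P, a), times=list(times))
        e = res.series["x"].enrichment
        rate = F * 1000 / 60 * 3  # umol C per min
        inflow = rate * a * times[-1]
        outflow = np.trapezoid(rate * e, times)
        stored = e[-1] * P * 3
        # tolerance dominated by the test's own trapezoidal quadrature
        assert inflow == pytest.approx(outflow + stored, rel=1e-4)

    def test_mids_binomial_consistent_with_enrichment(self):
        res = simulate_labeling(one_pool_network(), times=[0, 5, 10])
        for e_t, mid in zip(res.series["x"].enrichment, res.mids["x"]):
            assert enrichment(mid) == pytest.approx(e_t, abs=1e-9)

    def test_unbalanced_network_rejected_before_integration(self):
        net = LabelingNetwork(
            [Pool("x", 1.0, 2)], [Flow(TRACER, "x", 1.0)], 0.5
        )
        with pytest.raises(LabelingError, match="not flux-balanced"):
            simulate_labeling(net, times=[0, 1])

    def test_times_must_start_at_zero(self):
        with pytest.raises(LabelingError, match="start at 0"):
            simulate_labeling(one_pool_network(), times=[1, 2])


class TestChemostatGenerator:
    def test_noise_free_pairs_recover_exactly(self):
        ds = generate_chemostat_dataset(
            535.0, 0.90, 1.0, (0.002, 0.006, 0.010), 0.0, seed=1, slope=1266.67
        )
        ngam, *_ = fit_ngam(ds.pairs, 1.0)
        assert ngam == pytest.approx(0.90, abs=1e-9)

    def test_seeded_tsv_is_byte_identical(self):
        kw = dict(
            gam=535.0, ngam=0.90, atp_yield=1.0,
            dilution_rates=tuple(np.linspace(0.002, 0.012, 20)),
            noise_sd=0.02, seed=7, slope=1266.67,
        )
        assert (
            generate_chemostat_dataset(**kw).to_tsv()
            == generate_chemostat_dataset(**kw).to_tsv()
        )

    def test_monte_carlo_recovery_rate(self):
        """NGAM recovered within 10% in >= 95% of 200 seeded replicates
        at the chemostat measurement precision (n = 20)."""
        rates = np.linspace(0.002, 0.012, 20)
        ok = 0
        for seed in range(200):
            ds = generate_chemostat_dataset(
                535.0, 0.90, 1.0, rates, 0.02, seed, slope=1266.67
            )
            ngam, *_ = fit_ngam(ds.pairs, 1.0)
            ok += abs(ngam - 0.90) / 0.90 <= 0.10
        assert ok >= 190

    def test_negative_noise_rejected(self):
        with pytest.raises(LabelingError):
            generate_chemostat_dataset(
                535.0, 0.9, 1.0, (0.002, 0.006), -0.1, 1, slope=1000.0
            )

    def test_duplicate_rates_rejected(self):
        with pytest.raises(LabelingError):
            generate_chemostat_dataset(
                535.0, 0.9, 1.0, (0.002, 0.002), 0.0, 1, slope=1000.0
            )


class TestFormateBatch:
    def test_headspace_monotone_increasing(self):
        fb = generate_formate_batch(6.0, 0.35, rgp_active=False)
        assert np.all(np.diff(fb.headspace_13c.enrichment) >= -1e-12)

    def test_zero_oxidation_headspace_constant(self):
        fb = generate_formate_batch(0.0, 0.0, rgp_active=False)
        assert np.allclose(fb.headspace_13c.enrichment, 0.0)

    def test_formate_pool_mixing_two_thirds(self):
        """0.5 mM unlabeled + 1 mM labeled formate: the intracellular
        pool approaches 2/3 enrichment."""
        fb = generate_formate_batch(6.0, 0.35, rgp_active=False)
        assert fb.formate_enrichment.enrichment[-1] == pytest.approx(
            2.0 / 3.0, abs=1e-4
        )

    def test_serine_lags_co2_without_rgp(self):
        fb = generate_formate_batch(6.0, 0.35, rgp_active=False)
        ser = fb.series["ser"].enrichment
        co2 = fb.series["co2"].enrichment
        assert np.all(ser[1:] <= co2[1:] + 1e-12)
        assert ser[1] < co2[1]

    def test_rgp_routes_label_ahead_of_co2(self):
        with_rgp = generate_formate_batch(6.0, 0.35, rgp_active=True)
        without = generate_formate_batch(6.0, 0.35, rgp_active=False)
        assert with_rgp.series["ser"].enrichment[1] > without.series["ser"].enrichment[1]
        assert with_rgp.series["ser"].enrichment[1] > with_rgp.series["co2"].enrichment[1]

    def test_extracellular_dilution_lowers_plateau(self):
        fb = generate_formate_batch(
            6.0, 0.35, rgp_active=False, extracellular_dilution=0.6
        )
        assert fb.formate_enrichment.enrichment[-1] == pytest.approx(
            0.6 * 2.0 / 3.0, abs=1e-4
        )

    def test_zero_headspace_volume_rejected(self):
        with pytest.raises(LabelingError):
            generate_formate_batch(6.0, 0.35, rgp_active=False, headspace_volume_ml=0.0)

    def test_seeded_mids_deterministic(self):
        a = generate_formate_batch(6.0, 0.35, rgp_active=False, seed=5, noise_sd=0.01)
        b = generate_formate_batch(6.0, 0.35, rgp_active=False, seed=5, noise_sd=0.01)
        for k in a.mids:
            for ma, mb in zip(a.mids[k], b.mids[k]):
                assert np.array_equal(ma.fractions, mb.fractions)
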