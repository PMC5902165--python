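"""Generator determinism, kinetic coupling against an ODE oracle, archetypes."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from circamyo import annotation as an
from circamyo import rhythm as rh
from circamyo import simulate as sim


class TestDeterminism:
    def test_in_vivo_byte_identical(self):
        a = sim.gen_in_vivo(40, rng_seed=3)
        b = sim.gen_in_vivo(40, rng_seed=3)
        pd.testing.assert_frame_equal(a.exonic_counts, b.exonic_counts)
        pd.testing.assert_frame_equal(a.intronic_log2, b.intronic_log2)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_in_vitro_byte_identical(self):
        a = sim.gen_in_vitro(30, rng_seed=3)
        b = sim.gen_in_vitro(30, rng_seed=3)
        pd.testing.assert_frame_equal(a.expr, b.expr)
        pd.testing.assert_frame_equal(a.truth, b.truth)


class TestKineticCoupling:
    def test_attenuation_at_matched_rates(self):
        # k = w: gain 1/sqrt(2), delay 3 h for a 24-h period
        hl = 24 * np.log(2) / (2 * np.pi)
        g, d = sim.attenuation(hl)
        assert g == pytest.approx(1 / np.sqrt(2), rel=1e-12)
        assert d == pytest.approx(3.0, rel=1e-12)

    def test_closed_form_matches_ode_oracle(self):
        """The periodic solution of dm/dt = 2^p(t) - k m carries the harmonic
        of the forcing attenuated by k/sqrt(k^2+w^2) and delayed by
        atan2(w,k)/w, because the ODE is linear in m."""
        period = 24.0
        w = 2 * np.pi / period
        for half_life in (1.0, 6.0, 24.0):
            k = np.log(2) / half_life
            forcing = lambda t: 2.0 ** (1.0 + 0.4 * np.cos(w * t))
            sol = solve_ivp(
                lambda t, m: forcing(t) - k * m,
                (0, 40 * period),
                [forcing(0) / k],
                dense_output=True,
                rtol=1e-10,
                atol=1e-12,
                max_step=0.5,
            )
            t = np.linspace(39 * period, 40 * period, 4001)[:-1]
            m = sol.sol(t)[0]
            f = forcing(t)
            # relative amplitude of the fundamental: mode-w coefficient over
            # the mean level, in response vs forcing
            cm = np.mean(m * np.exp(-1j * w * t)) / np.mean(m)
            cf = np.mean(f * np.exp(-1j * w * t)) / np.mean(f)
            ratio = cm / cf
            g, delay = sim.attenuation(half_life, period)
            assert abs(ratio) == pytest.approx(g, rel=1e-6)
            assert -np.angle(ratio) / w % period == pytest.approx(delay, abs=1e-4)

    def test_flat_gene_has_no_oscillation(self):
        d = sim.gen_in_vivo(30, rhythmic_frac=0.0, sigma_e=0.0, donor_sd=0.0, rng_seed=1)
        assert np.allclose(d.intronic_signal.std(axis=1), 0.0)
        assert np.allclose(d.exonic_signal.std(axis=1), 0.0)

    def test_measured_attenuation_matches_closed_form(self):
        d = sim.gen_in_vivo(40, rhythmic_frac=1.0, sigma_e=0.0, rng_seed=6)
        f_in = rh.fit_layer(d.intronic_signal, d.samples)
        f_ex = rh.fit_layer(d.exonic_signal, d.samples)
        ratio = f_ex["amplitude"] / f_in["amplitude"]
        rel = np.abs(ratio - d.truth["truth_attenuation"]) / d.truth["truth_attenuation"]
        assert rel.max() < 0.05

    def test_proxy_monotone_in_half_life_noiseless(self):
        from scipy.stats import spearmanr

        d = sim.gen_in_vivo(100, rhythmic_frac=0.5, sigma_e=0.0, rng_seed=7)
        proxy = d.exonic_signal.mean(axis=1) - d.intronic_signal.mean(axis=1)
        assert spearmanr(proxy, d.truth["truth_half_life"]).statistic > 0.95


class TestInVitroGenerator:
    def test_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            sim.gen_in_vitro(50, mix=(0.5, 0.5, 0.5, 0.5), rng_seed=0)

    def test_null_knockdown_preserves_signal(self):
        d = sim.gen_in_vitro(40, kd_amp_factor=1.0, sigma=0.0, rng_seed=2,
                             mix=(0.4, 0.3, 0.3, 0.0))
        sheet = d.samples
        for donor in ("donorA", "donorB"):
            ctrl = sheet.index[(sheet.donor_id == donor) & (sheet.condition == "siControl")]
            kd = sheet.index[(sheet.donor_id == donor) & (sheet.condition == "siCLOCK")]
            assert np.allclose(d.expr[ctrl].to_numpy(), d.expr[kd].to_numpy())

    def test_undamped_noiseless_clock_gene_is_exact_cosine(self):
        d = sim.gen_in_vitro(20, sigma=0.0, tau_h=1e12, rng_seed=2)
        sheet = d.samples
        ids = sheet.index[
            (sheet.donor_id == "donorA")
            & (sheet.condition == "siControl")
            & (sheet.replicate == 1)
        ]
        t = sheet.loc[ids, "time_h"].to_numpy()
        row = d.expr.loc["ARNTL", ids].to_numpy()
        amp = d.truth.loc["ARNTL", "truth_amp"]
        phase = d.truth.loc["ARNTL", "truth_phase"]
        centred = row - row.mean()
        expected = (amp / 2) * np.cos(2 * np.pi / 24 * (t - phase))
        assert np.allclose(centred, expected - expected.mean(), atol=1e-9)

    def test_archetype_proportions_match_mix(self):
        mix = (0.10, 0.10, 0.10, 0.70)
        d = sim.gen_in_vitro(2000, mix=mix, rng_seed=11)
        free = d.truth[~d.truth["truth_clock_gene"]]
        counts = free["truth_archetype"].value_counts(normalize=True)
        for cls, frac in zip(("circadian", "one_peak", "linear", "cloud"), mix):
            se = np.sqrt(frac * (1 - frac) / len(free))
            assert abs(counts[cls] - frac) < 4 * se


class TestToyAnnotation:
    def test_single_exon_gene_has_no_introns(self):
        transcripts, truth = sim.gen_toy_annotation(1, rng_seed=0, max_transcripts=1, max_exons=1)
        gid = transcripts[0].gene_id
        assert truth[gid].intronic == ()

    def test_truth_agrees_with_region_builder(self):
        transcripts, truth = sim.gen_toy_annotation(30, rng_seed=4)
        by_gene = {}
        for t in transcripts:
            by_gene.setdefault(t.gene_id, []).append(t)
        for gid, ts in by_gene.items():
            r = an.build_gene_regions(ts)
            assert r.exonic == truth[gid].exonic
            assert r.intronic == truth[gid].intronic

    def test_gtf_round_trip_preserves_truth(self, tmp_path):
        transcripts, truth = sim.gen_toy_annotation(10, rng_seed=5)
        an.write_gtf(transcripts, tmp_path / "t.gtf")
        parsed = an.read_gtf(tmp_path / "t.gtf")
        by_gene = {}
        for t in parsed:
            by_gene.setdefault(t.gene_id, []).append(t)
        for gid, ts in by_gene.items():
            r = an.build_gene_regions(ts)
            assert r.exonic == truth[gid].exonic and r.intronic == truth[gid].intronic


class TestMotifGenerator:
    def test_extreme_enrichment(self, rng):
        genes = [f"g{i}" for i in range(60)]
        phases = pd.Series(np.r_[np.full(20, 2.0), rng.uniform(8, 24, 40)], index=genes)
        members, _ = sim.gen_motif_memberships(
            phases, enriched_bin=0, p_in=1.0, p_out=0.0, n_decoys=0, rng_seed=0
        )
        assert members["MOTIF_PLANTED"] == set(genes[:20])

    def test_null_motif_has_no_bin_preference(self):
        genes = [f"g{i}" for i in range(2000)]
        phases = pd.Series(np.linspace(0, 24, 2000, endpoint=False), index=genes)
        members, _ = sim.gen_motif_memberships(
            phases, enriched_bin=0, p_in=0.3, p_out=0.3, n_decoys=0, rng_seed=1
        )
        hit = members["MOTIF_PLANTED"]
        bins = (np.floor(phases / 4) % 6).astype(int)
        rates = [np.mean([g in hit for g in phases.index[bins == b]]) for b in range(6)]
        assert max(rates) - min(rates) < 0.12
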