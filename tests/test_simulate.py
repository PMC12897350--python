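"""Synthetic study generator: design counts, marker laws, spectra structure."""

import numpy as np
import pytest

from nirselect import (
    STUDY_GRID,
    SimConfig,
    average_replicates,
    default_design,
    generate_study,
    simulate_markers,
    simulate_spectra,
)


class TestDesign:
    def test_counts_match_study(self):
        d = default_design()
        samples = d.samples()
        assert len(samples) == 142
        olive = [s for s in samples if d.category(s.category).oil_class == "olive"]
        from collections import Counter

        per_cat = Counter(s.category for s in olive)
        assert len(per_cat) == 12 and set(per_cat.values()) == {11}
        sun = [s for s in samples if s.category in ("SO", "SOHO")]
        assert len(sun) == 10

    def test_triplicate_spectra_count(self, study):
        assert study.spectra.n_spectra == 3 * 142 == 426

    def test_supplementation_coding(self):
        for s in default_design().samples():
            if s.treatment in ("E5", "E6", "E7", "E8"):
                assert s.supplemented
            if s.treatment in ("E1", "E2", "E3", "E4"):
                assert not s.supplemented
            if s.is_control:
                assert s.temperature_C is None and s.duration_h is None


class TestMarkers:
    def test_totox_exact_identity(self, study):
        m = study.markers
        np.testing.assert_array_equal(m["totox"].to_numpy(),
                                      2.0 * m["pv"].to_numpy()
                                      + m["anv"].to_numpy())

    def test_zero_noise_monotone_in_duration(self):
        cfg = SimConfig(seed=3, marker_noise_sd=0.0)
        m, _ = simulate_markers(default_design(), cfg)
        m = m.set_index("sample_id")
        for cat in ("PC", "HB", "SO"):
            for marker in ("pv", "anv", "k232"):
                # same temperature, longer frying -> strictly more oxidation
                assert m.loc[f"{cat}_E2", marker] > m.loc[f"{cat}_E1", marker]
                assert m.loc[f"{cat}_E4", marker] > m.loc[f"{cat}_E3", marker]

    def test_stress_and_supplementation_orderings(self):
        """E4 (210 degC / 6 h) exceeds controls, and unsupplemented frying
        (E1-E4) exceeds supplemented (E5-E8), for every marker over seeds."""
        from nirselect.spectra import MARKER_NAMES

        design = default_design()
        wins_e4 = {m: 0 for m in MARKER_NAMES}
        wins_sup = {m: 0 for m in MARKER_NAMES}
        n_seeds = 20
        for seed in range(n_seeds):
            m, _ = simulate_markers(design, SimConfig(seed=seed))
            t = m["sample_id"].str.rsplit("_", n=1).str[1]
            for marker in MARKER_NAMES:
                e4 = m.loc[t == "E4", marker].mean()
                ctrl = m.loc[t.isin(["C", "C1", "C2", "S"]), marker].mean()
                uns = m.loc[t.isin(["E1", "E2", "E3", "E4"]), marker].mean()
                sup = m.loc[t.isin(["E5", "E6", "E7", "E8"]), marker].mean()
                wins_e4[marker] += e4 > ctrl
                wins_sup[marker] += uns > sup
        for marker in MARKER_NAMES:
            assert wins_e4[marker] == n_seeds
            assert wins_sup[marker] == n_seeds

    def test_no_supplementation_effect_when_factor_is_one(self):
        """With suppl_factor = 1 the supplemented/unsupplemented growth laws
        coincide, so the noise-free group means match exactly."""
        cfg = SimConfig(seed=5, suppl_factor=1.0, marker_noise_sd=0.0)
        m, _ = simulate_markers(default_design(), cfg)
        t = m["sample_id"].str.rsplit("_", n=1).str[1]
        olive = ~m["sample_id"].str.split("_").str[0].isin(["SO", "SOHO"])
        for marker in ("pv", "anv"):
            uns = m.loc[olive & t.isin(["E1", "E2", "E3", "E4"]), marker]
            sup = m.loc[olive & t.isin(["E5", "E6", "E7", "E8"]), marker]
            assert uns.mean() == pytest.approx(sup.mean(), rel=1e-12)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="suppl_factor"):
            SimConfig(suppl_factor=0.0)
        with pytest.raises(ValueError, match="noise"):
            SimConfig(marker_noise_sd=-0.1)


class TestSpectra:
    def test_zero_slopes_zero_noise_gives_category_baseline(self):
        from dataclasses import replace

        cfg = SimConfig(seed=2, replicate_noise_sd=0.0)
        cfg.band_table = [replace(b, slope=0.0) for b in cfg.band_table]
        design = default_design()
        markers, _ = simulate_markers(design, cfg)
        spectra = simulate_spectra(markers, design, cfg)
        by_sample = {}
        for sid, row in zip(spectra.sample_ids, spectra.absorbance):
            by_sample.setdefault(sid.split("_")[0], []).append(row)
        for cat, rows in by_sample.items():
            rows = np.asarray(rows)
            assert np.abs(rows - rows[0]).max() <= 1e-12

    def test_band_sign_correlations(self, study):
        """Across samples, absorbance at 1392 nm falls with K232 and at
        2114 nm rises with K270 (the generating band signs)."""
        avg = average_replicates(study.spectra)
        m = study.markers.set_index("sample_id").loc[avg.sample_ids]
        a1392 = avg.absorbance[:, STUDY_GRID.wavelength_to_index(1392) - 1]
        a2114 = avg.absorbance[:, STUDY_GRID.wavelength_to_index(2114) - 1]
        assert np.corrcoef(a1392, m["k232"])[0, 1] < -0.5
        assert np.corrcoef(a2114, m["k270"])[0, 1] > 0.5

    def test_absorbance_envelopes(self, study):
        """Baseline anchoring keeps absorbance near the observed levels."""
        avg = average_replicates(study.spectra)
        a1392 = avg.absorbance[:, STUDY_GRID.wavelength_to_index(1392) - 1]
        a2114 = avg.absorbance[:, STUDY_GRID.wavelength_to_index(2114) - 1]
        assert 0.33 < a1392.min() and a1392.max() < 0.46
        assert 1.0 < a2114.min() and a2114.max() < 1.25
        assert (study.spectra.absorbance > 0).all()

    def test_replicate_averaging_cuts_noise_by_three(self):
        """Var of the averaged replicate noise is ~1/3 of a single one."""
        design = default_design()
        cfg = SimConfig(seed=4)
        markers, _ = simulate_markers(design, cfg)
        spectra = simulate_spectra(markers, design, cfg)
        # per-sample channel variance across replicates estimates noise^2
        resid = []
        for sid in set(spectra.sample_ids):
            rows = spectra.absorbance[
                [i for i, s in enumerate(spectra.sample_ids) if s == sid]]
            resid.append(rows.var(axis=0, ddof=1).mean())
        noise_var = float(np.mean(resid))
        assert noise_var == pytest.approx(cfg.replicate_noise_sd ** 2, rel=0.1)

    def test_off_grid_band_center_rejected(self):
        from nirselect import BandSpec

        with pytest.raises(ValueError, match="grid"):
            SimConfig(band_table=[BandSpec(1393.0, 12.0, "k232", -0.01)])


class TestReproducibility:
    def test_same_seed_bit_identical(self):
        a = generate_study(SimConfig(seed=11))
        b = generate_study(SimConfig(seed=11))
        np.testing.assert_array_equal(a.spectra.absorbance, b.spectra.absorbance)
        assert a.markers.equals(b.markers)

    def test_different_seeds_differ_but_same_skeleton(self):
        a = generate_study(SimConfig(seed=11))
        b = generate_study(SimConfig(seed=12))
        assert a.spectra.sample_ids == b.spectra.sample_ids
        assert not np.array_equal(a.spectra.absorbance, b.spectra.absorbance)

    def test_written_study_roundtrips_into_pipeline(self, tmp_path, study):
        from nirselect import read_markers, read_spectra

        study.write(tmp_path)
        spectra = read_spectra(tmp_path / "spectra.csv")
        markers = read_markers(tmp_path / "markers.csv")
        assert spectra.n_spectra == 426
        assert len(markers) == 142
        np.testing.assert_allclose(spectra.absorbance,
                                   study.spectra.absorbance, rtol=1e-9)
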