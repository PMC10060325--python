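"""Generator contracts: determinism, degenerate cases, ground-truth recovery."""

import numpy as np
import pytest

from mitothermics.calorimetry import circadian_phase_summary, derive_metabolic_series
from mitothermics.flux_assay import extract_states, normalize_states
from mitothermics.omics_enrichment import de_filter, mtdna_ratio
from mitothermics.synthetic_data import (
    GeneratorConfig,
    gen_abundance_table,
    gen_cage_trace,
    gen_flux_plate,
    gen_qpcr,
)


class TestDeterminism:
    def test_flux_plate_byte_identical(self, default_config):
        p1, t1 = gen_flux_plate(default_config, "coupling-CI")
        p2, t2 = gen_flux_plate(GeneratorConfig(seed=1), "coupling-CI")
        assert p1.data.to_csv(index=False) == p2.data.to_csv(index=False)
        assert t1 == t2

    def test_all_generators_reproducible(self, default_config):
        other = GeneratorConfig(seed=1)
        assert gen_cage_trace(default_config)[0].data.equals(gen_cage_trace(other)[0].data)
        assert gen_abundance_table(default_config)[0].values.equals(
            gen_abundance_table(other)[0].values
        )
        assert gen_qpcr(default_config)[0].data.equals(gen_qpcr(other)[0].data)

    def test_streams_independent_across_generators(self, default_config):
        """Consuming one generator does not shift another's draws."""
        fresh = gen_cage_trace(GeneratorConfig(seed=1))[0].data
        gen_flux_plate(default_config, "coupling-CII")
        after = gen_cage_trace(default_config)[0].data
        assert fresh.equals(after)

    def test_different_seeds_differ(self):
        a = gen_flux_plate(GeneratorConfig(seed=1), "coupling-CI")[0].data
        b = gen_flux_plate(GeneratorConfig(seed=2), "coupling-CI")[0].data
        assert not a["ocr_pmol_min"].equals(b["ocr_pmol_min"])


class TestFluxGenerator:
    def test_zero_noise_ticks_equal_phase_means(self, quiet_config):
        plate, truth = gen_flux_plate(quiet_config, "coupling-CI")
        means = truth["state_means"]
        for (group, phase), sub in plate.data.groupby(["group", "phase"]):
            if phase == "equilibration":
                continue
            np.testing.assert_allclose(sub["ocr_pmol_min"], means[group][phase])

    def test_unknown_assay_kind_lists_protocols(self, default_config):
        with pytest.raises(ValueError, match="coupling-CII"):
            gen_flux_plate(default_config, "not-an-assay")

    def test_state3_reduction_recovered_downstream(self):
        """Cvs state 3 configured to 0.45x Ctrl; the pipeline's group means
        land within 10% of the configured truth."""
        cfg = GeneratorConfig(seed=42)
        for g in ("Ctrl", "Cvs"):
            cfg.flux.state_means["coupling-CI"][g] = dict(
                cfg.flux.state_means["coupling-CI"][g]
            )
        cfg.flux.state_means["coupling-CI"]["Cvs"]["state3"] = (
            0.45 * cfg.flux.state_means["coupling-CI"]["Ctrl"]["state3"]
        )
        plate, truth = gen_flux_plate(cfg, "coupling-CI")
        table = normalize_states(extract_states(plate), plate).table
        for group in ("Ctrl", "Cvs"):
            got = table.loc[table["group"] == group, "state3"].mean()
            want = truth["state_means"][group]["state3"]
            assert got == pytest.approx(want, rel=0.10)

    def test_nonmito_subtraction_can_go_negative(self, quiet_config):
        quiet_config.flux.nonmito_subtract = True
        cfg = quiet_config
        cfg.flux.state_means["coupling-CII"]["Cvs"]["state4o"] = 5.0
        plate, _ = gen_flux_plate(cfg, "coupling-CII")
        s4 = plate.data[(plate.data["phase"] == "state4o") & (plate.data["group"] == "Cvs")]
        assert np.all(s4["ocr_pmol_min"] < 0)  # 5 - 25 residual

    def test_triplicate_wells_per_animal(self, default_config):
        plate, _ = gen_flux_plate(default_config, "coupling-CI")
        wells = plate.wells
        assert wells.groupby("animal_id").size().eq(3).all()
        assert wells["animal_id"].nunique() == 12


class TestCageGenerator:
    def test_rer_one_flat_gives_pure_carbohydrate(self, quiet_config):
        cfg = quiet_config
        for g in ("Ctrl", "Cvs"):
            cfg.cage.rer_light[g] = 1.0
            cfg.cage.rer_dark[g] = 1.0
        trace, _ = gen_cage_trace(cfg)
        d = derive_metabolic_series(trace)
        assert np.all(d["cho_mg_min"] > 0)
        assert np.all(d["fao_mg_min"] == 0.0)

    def test_dark_dominant_vo2_gives_dark_dominant_ee(self, quiet_config):
        trace, _ = gen_cage_trace(quiet_config)  # defaults: dark EE > light EE
        t = circadian_phase_summary(trace).table
        for _, sub in t.groupby("animal_id"):
            s = sub.set_index("phase")
            assert s.loc["dark", "ee"] > s.loc["light", "ee"]

    def test_vco2_equals_rer_times_vo2(self, quiet_config):
        trace, truth = gen_cage_trace(quiet_config)
        d = trace.data
        light = trace.is_light(d["timestamp"])
        for g in ("Ctrl", "Cvs"):
            sel = (d["group"] == g) & light
            np.testing.assert_allclose(
                d.loc[sel, "vco2_ml_min"] / d.loc[sel, "vo2_ml_min"],
                truth["rer_light"][g],
            )

    def test_group_rer_difference_recovered(self):
        """Ctrl 0.95 vs Cvs 0.89 (difference 0.06) recovered within 0.01."""
        cfg = GeneratorConfig(seed=9)
        trace, truth = gen_cage_trace(cfg)
        t = circadian_phase_summary(trace).table
        tot = t[t["phase"] == "total"]
        diff = (tot.loc[tot["group"] == "Ctrl", "rer"].mean()
                - tot.loc[tot["group"] == "Cvs", "rer"].mean())
        want = truth["rer_total"]["Ctrl"] - truth["rer_total"]["Cvs"]
        assert want == pytest.approx(0.06, abs=1e-12)
        assert diff == pytest.approx(want, abs=0.01)

    def test_bad_bin_width_rejected(self):
        cfg = GeneratorConfig(seed=0)
        cfg.cage.bin_minutes = 7.0  # does not divide the 24-h light/dark period
        with pytest.raises(ValueError, match="divide"):
            gen_cage_trace(cfg)


class TestOmicsGenerator:
    def test_no_noise_no_de_gives_unit_folds(self, quiet_config):
        cfg = quiet_config
        cfg.omics.n_proteins = 50
        cfg.omics.n_de_up = 0
        cfg.omics.n_de_down = 0
        table, _ = gen_abundance_table(cfg)
        ctrl = table.values[table.group_columns("Ctrl")].mean(axis=1)
        cvs = table.values[table.group_columns("Cvs")].mean(axis=1)
        np.testing.assert_allclose(cvs / ctrl, 1.0)

    def test_planted_fold_change_applied(self, quiet_config):
        cfg = quiet_config
        cfg.omics.n_proteins = 30
        cfg.omics.n_de_up = 5
        cfg.omics.n_de_down = 2
        table, truth = gen_abundance_table(cfg)
        cvs = table.values[table.group_columns("Cvs")].mean(axis=1)
        ctrl = table.values[table.group_columns("Ctrl")].mean(axis=1)
        ratio = cvs / ctrl
        np.testing.assert_allclose(ratio[truth["de_up"]], 2.0)
        np.testing.assert_allclose(ratio[truth["de_down"]], 0.5)

    def test_null_false_positive_rate_matches_alpha_without_fold_gate(self):
        """With no planted effects and the fold gate disabled, the p<0.05
        gate fires at ~alpha per protein."""
        hits = total = 0
        for seed in range(40):
            cfg = GeneratorConfig(seed=seed)
            cfg.omics.n_proteins = 200
            cfg.omics.n_de_up = 0
            cfg.omics.n_de_down = 0
            table, _ = gen_abundance_table(cfg)
            res = de_filter(table, "Ctrl", "Cvs", fold_threshold=1.0)
            hits += res.n_up + res.n_down
            total += res.n_tested
        assert hits / total == pytest.approx(0.05, abs=0.015)

    def test_default_fold_gate_suppresses_null_hits(self):
        cfg = GeneratorConfig(seed=0)
        cfg.omics.n_proteins = 500
        cfg.omics.n_de_up = 0
        cfg.omics.n_de_down = 0
        table, _ = gen_abundance_table(cfg)
        res = de_filter(table, "Ctrl", "Cvs")
        assert res.n_up + res.n_down <= 2

    def test_power_on_planted_two_fold(self):
        cfg = GeneratorConfig(seed=7)
        cfg.omics.n_proteins = 200
        cfg.omics.n_de_up = 20
        cfg.omics.n_de_down = 0
        cfg.omics.log2_noise_sd = 0.15
        table, truth = gen_abundance_table(cfg)
        res = de_filter(table, "Ctrl", "Cvs")
        recovered = len(res.significant.index.intersection(truth["de_up"]))
        assert recovered >= 18

    def test_oversized_de_set_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            cfg = GeneratorConfig(seed=0)
            cfg.omics.model_validate({**cfg.omics.model_dump(), "n_proteins": 10,
                                      "n_de_up": 8, "n_de_down": 8})

    def test_nonpositive_fold_rejected(self):
        cfg = GeneratorConfig(seed=0)
        with pytest.raises(ValueError):
            cfg.omics.model_validate({**cfg.omics.model_dump(), "fold_change": 0.0})


class TestQpcrGenerator:
    def test_unit_ratio_exact_without_noise(self, quiet_config):
        quiet_config.qpcr.true_ratio = {"Ctrl": 1.0, "Cvs": 1.0}
        records, _ = gen_qpcr(quiet_config)
        ratios = mtdna_ratio(records)
        np.testing.assert_allclose(ratios["ratio"], 1.0)

    def test_ratio_two_is_one_ct_cycle(self, quiet_config):
        quiet_config.qpcr.true_ratio = {"Ctrl": 2.0, "Cvs": 2.0}
        records, _ = gen_qpcr(quiet_config)
        mean_ct = records.data.groupby(["animal_id", "gene"])["ct"].mean().unstack()
        np.testing.assert_allclose(mean_ct["Lpl"] - mean_ct["Nd1"], 1.0)

    def test_group_ratio_recovered_under_noise(self):
        """Replicate SD 0.2, n=5: group mean ratio within 15% of truth
        across 100 seeds."""
        errs = []
        for seed in range(100):
            cfg = GeneratorConfig(seed=seed)
            cfg.qpcr.replicate_sd = 0.2
            records, truth = gen_qpcr(cfg)
            ratios = mtdna_ratio(records)
            for g in ("Ctrl", "Cvs"):
                got = ratios.loc[ratios["group"] == g, "ratio"].mean()
                errs.append(abs(got / truth["true_ratio"][g] - 1))
        errs = np.asarray(errs)
        # per-seed group means concentrate within the band; the seed-average
        # is far inside it
        assert np.quantile(errs, 0.95) < 0.15
        assert errs.mean() < 0.15
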