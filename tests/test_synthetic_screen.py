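"""Generator contracts: determinism, spiking, rendering geometry, closure."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from rncfret import bead_imaging as bi
from rncfret import synthetic_screen as sy
from rncfret.fret_engine import compute_efret
from rncfret.plate_model import default_layout_1536

from conftest import pair_layout


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [dict(imaged_fraction=0.0), dict(imaged_fraction=1.2),
         dict(beads_per_well=-1), dict(brightness_cv=1.5),
         dict(bead_diameter_limits=(20.0, 16.0)), dict(baseline_efret=100.0),
         dict(illumination_amplitude=1.0), dict(noise_model="salt")],
    )
    def test_invariant_violations_rejected(self, kw):
        with pytest.raises(sy.ConfigurationError):
            sy.SimulationConfig(**kw)

    def test_expected_beads_per_image(self):
        cfg = sy.SimulationConfig()
        assert cfg.expected_beads_per_image == pytest.approx(600 * 0.19)


class TestDeterminism:
    def test_same_seed_identical_truth_and_image_bytes(self, fast_cfg):
        layout = pair_layout(2)
        t1 = sy.draw_screen_truth(layout, fast_cfg, seed=5)
        t2 = sy.draw_screen_truth(layout, fast_cfg, seed=5)
        pd.testing.assert_frame_equal(t1.wells, t2.wells)
        pd.testing.assert_frame_equal(t1.beads, t2.beads)
        pd.testing.assert_frame_equal(t1.compounds, t2.compounds)
        well = layout.dmso_pairs[0][0]
        img1 = sy.render_well_image(t1, well)
        img2 = sy.render_well_image(t2, well)
        assert img1.pixels.tobytes() == img2.pixels.tobytes()

    def test_different_seed_differs(self, fast_cfg):
        layout = pair_layout(1)
        well = layout.dmso_pairs[0][0]
        t1 = sy.draw_screen_truth(layout, fast_cfg, seed=1)
        t2 = sy.draw_screen_truth(layout, fast_cfg, seed=2)
        assert not np.array_equal(
            sy.render_well_image(t1, well).pixels, sy.render_well_image(t2, well).pixels
        )

    def test_wells_reproducible_in_isolation(self, fast_cfg):
        # a well's substream does not depend on which other wells were drawn
        big = default_layout_1536(n_compounds=4, n_dmso_pairs=2, plate_id="t")
        small = default_layout_1536(n_compounds=1, n_dmso_pairs=2, plate_id="t")
        tb = sy.draw_screen_truth(big, fast_cfg, seed=3)
        ts = sy.draw_screen_truth(small, fast_cfg, seed=3)
        np.testing.assert_array_equal(
            sy.render_well_image(tb, "A01").pixels,
            sy.render_well_image(ts, "A01").pixels,
        )


class TestSpikeHits:
    def test_empty_spike_is_identity(self, fast_cfg):
        layout = default_layout_1536(n_compounds=3, n_dmso_pairs=2)
        truth = sy.draw_screen_truth(layout, fast_cfg, seed=1)
        spiked = sy.spike_hits(truth, {})
        pd.testing.assert_frame_equal(spiked.wells, truth.wells)
        pd.testing.assert_frame_equal(spiked.compounds, truth.compounds)

    def test_spike_is_local_to_listed_compounds(self, fast_cfg):
        layout = default_layout_1536(n_compounds=3, n_dmso_pairs=2)
        truth = sy.draw_screen_truth(layout, fast_cfg, seed=1)
        cid = sorted(layout.compound_quartets)[0]
        spiked = sy.spike_hits(truth, {cid: 6.0})
        changed = spiked.wells["efret_true"] != truth.wells["efret_true"]
        assert set(spiked.wells.loc[changed, "compound_id"]) == {cid}
        assert (
            spiked.wells.loc[changed, "efret_true"]
            - truth.wells.loc[changed, "efret_true"]
        ).eq(6.0).all()
        assert truth.wells["efret_true"].equals(
            sy.draw_screen_truth(layout, fast_cfg, seed=1).wells["efret_true"]
        )  # input not mutated

    def test_unknown_compound_rejected(self, fast_cfg):
        truth = sy.draw_screen_truth(
            default_layout_1536(n_compounds=1, n_dmso_pairs=2), fast_cfg, seed=1
        )
        with pytest.raises(KeyError, match="nope"):
            sy.spike_hits(truth, {"nope": 3.0})


class TestRendering:
    def test_empty_well_is_background_times_field(self, fast_cfg):
        cfg = dataclasses.replace(fast_cfg, beads_per_well=0, read_noise_sd=0.0)
        layout = pair_layout(1)
        truth = sy.draw_screen_truth(layout, cfg, seed=2)
        well = layout.dmso_pairs[0][0]
        img = sy.render_well_image(truth, well)
        field = sy._field_surface(cfg.image_shape, truth.field_params)
        expected = np.clip(np.round(cfg.background_level * field), 0, 65535)
        np.testing.assert_array_equal(img.pixels, expected.astype(np.uint16))

    def test_17um_disk_pixel_area(self, fast_cfg):
        cfg = dataclasses.replace(
            fast_cfg, read_noise_sd=0.0, illumination_amplitude=0.0,
            defocus_fraction=0.0, artifact_rate=0.0,
        )
        layout = pair_layout(1)
        well = layout.dmso_pairs[0][0]
        truth = sy.draw_screen_truth(layout, cfg, seed=4)
        truth.beads = pd.DataFrame(
            [{"well": well, "x_um": 83.2, "y_um": 83.2, "diameter_um": 17.0,
              "brightness": 1.0, "kind": "bead", "axis_ratio": 1.0, "angle": 0.0}]
        )
        img = sy.render_well_image(truth, well)
        # pixels with at least half-covered area: the π(8.5)²/0.325² disk
        mask = img.pixels > cfg.background_level + truth.well_amplitude(well) / 2
        expected = math.pi * 8.5 ** 2 / 0.325 ** 2  # ~2,149 px
        assert abs(mask.sum() - expected) / expected < 0.02

    def test_zero_fret_pair_conserves_total_signal(self):
        cfg = sy.SimulationConfig(
            image_shape=(512, 512), beads_per_well=30, imaged_fraction=1.0,
            baseline_efret=0.0, brightness_cv=0.0, bead_diameter_sd=1e-9,
            defocus_fraction=0.0, artifact_rate=0.0, read_noise_sd=0.0,
            illumination_amplitude=0.0,
        )
        layout = pair_layout(1)
        d_well, da_well = layout.dmso_pairs[0]
        truth = sy.draw_screen_truth(layout, cfg, seed=6)
        means = []
        for well in (d_well, da_well):
            img = sy.render_well_image(truth, well)
            m, _ = bi.analyze_well(img)
            means.append(m.mean_intensity)
        # no quench at E = 0: identical per-bead signal in both channels
        assert abs(means[0] - means[1]) / means[0] < 0.002

    def test_artifact_rendered_elongated_and_rejected(self, fast_cfg):
        cfg = dataclasses.replace(fast_cfg, artifact_rate=0.5)
        layout = pair_layout(1)
        well = layout.dmso_pairs[0][0]
        truth = sy.draw_screen_truth(layout, cfg, seed=8)
        assert (truth.beads["kind"] == "artifact").any()
        img = sy.render_well_image(truth, well)
        _, dets = bi.analyze_well(img)
        arts = truth.beads[
            (truth.beads["kind"] == "artifact") & (truth.beads["well"] == well)
        ]
        assert len(arts)
        for art in arts.itertuples(index=False):
            for det in dets:
                dist = math.hypot(det.centroid_um[0] - art.x_um,
                                  det.centroid_um[1] - art.y_um)
                if dist < 5.0:
                    assert not det.passed


class TestNoiseFreeClosure:
    def test_spiked_delta_recovered_without_noise(self):
        cfg = sy.SimulationConfig(
            image_shape=(1024, 1024), beads_per_well=250,
            brightness_cv=0.0, defocus_fraction=0.0, artifact_rate=0.0,
            read_noise_sd=0.0, compound_artifact_fraction=0.0,
        )
        layout = default_layout_1536(n_compounds=1, n_dmso_pairs=2)
        cid = sorted(layout.compound_quartets)[0]

        def measure(truth):
            images = sy.WellImageSet(truth, cfg)
            wells, _ = bi.analyze_plate(images, plate_id="t")
            by_well = wells.set_index("well")["mean_intensity"]
            es = [
                compute_efret(by_well[d], by_well[da])
                for d, da in layout.compound_pairs(cid)
            ]
            return float(np.mean(es))

        truth = sy.draw_screen_truth(layout, cfg, seed=11)
        e0 = measure(truth)
        e1 = measure(sy.spike_hits(truth, {cid: 6.0}))
        assert e1 - e0 == pytest.approx(6.0, abs=0.2)


class TestStatisticalFastPath:
    def test_sample_measurements_deterministic_and_calibrated(self):
        cfg = sy.SimulationConfig()
        layout = pair_layout(24)
        truth = sy.draw_screen_truth(layout, cfg, seed=13, place_beads=False)
        m1 = sy.sample_measurements(truth)
        m2 = sy.sample_measurements(truth)
        pd.testing.assert_frame_equal(m1, m2)
        d_wells = [d for d, _ in layout.dmso_pairs]
        per_area = cfg.donor_amplitude / cfg.pixel_area
        got = m1.set_index("well").loc[d_wells, "mean_intensity"].mean()
        assert got == pytest.approx(per_area, rel=0.01)

    def test_statistical_screen_artifact_fraction_and_spike(self):
        cfg = sy.SimulationConfig()
        comp, dmso = sy.simulate_screen_statistical(5000, cfg, seed=21)
        frac = (
            (comp["donor_multiplier"] != 1.0) | (comp["background_multiplier"] != 1.0)
        ).mean()
        assert 0.07 <= frac <= 0.13
        assert len(dmso) == 32
        delta = np.zeros(200)
        delta[:5] = 6.0
        spiked, _ = sy.simulate_screen_statistical(200, cfg, seed=22, delta_efret=delta)
        avg = (spiked["efret_1"] + spiked["efret_2"]) / 2
        assert (avg[:5] - cfg.baseline_efret).mean() == pytest.approx(6.0, abs=0.8)

    def test_well_level_recovery_with_noise_over_400_beads(self):
        # pooling 4 pairs (~456 beads/channel) recovers true E within 2%
        # absolute in >= 95% of seeded replicates
        cfg = sy.SimulationConfig()
        layout = pair_layout(5)
        ok = 0
        n_rep = 100
        for seed in range(n_rep):
            truth = sy.draw_screen_truth(layout, cfg, seed=seed, place_beads=False)
            m = sy.sample_measurements(truth).set_index("well")
            f = {}
            for side, wells in (
                ("d", [p[0] for p in layout.dmso_pairs]),
                ("da", [p[1] for p in layout.dmso_pairs]),
            ):
                sub = m.loc[wells]
                assert sub["n_beads"].sum() >= 400
                f[side] = np.average(sub["mean_intensity"], weights=sub["n_beads"])
            if abs(compute_efret(f["d"], f["da"]) - cfg.baseline_efret) < 2.0:
                ok += 1
        assert ok >= 0.95 * n_rep
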