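import numpy as np
import pytest
from scipy import stats

from miml import features as feat
from miml import synthetic as syn


def two_class_pop(n=10, seed=0, **kw):
    defaults = dict(diameter_mean=14.0, diameter_sd=1.0)
    defaults.update(kw)
    return syn.PopulationConfig(
        classes=(
            syn.ClassConfig(name="soft", n=n, stiffness_mean=1.0, stiffness_sd=0.2, **defaults),
            syn.ClassConfig(name="stiff", n=n, stiffness_mean=10.0, stiffness_sd=2.0, **defaults),
        ),
        seed=seed,
    )


class TestSamplePopulation:
    def test_empty_population_rejected(self):
        with pytest.raises(syn.ConfigurationError):
            syn.ClassConfig(name="soft", n=0, stiffness_mean=1.0)

    def test_negative_sd_rejected(self):
        with pytest.raises(syn.ConfigurationError):
            syn.ClassConfig(name="soft", n=5, stiffness_mean=1.0, diameter_sd=-1.0)

    def test_determinism(self):
        pop = two_class_pop(n=25, seed=3)
        a = syn.sample_population(pop)
        b = syn.sample_population(pop)
        assert a == b

    def test_counts_match_config(self):
        cells = syn.sample_population(two_class_pop(n=7))
        by_class = {}
        for c in cells:
            by_class[c.class_label] = by_class.get(c.class_label, 0) + 1
        assert by_class == {"soft": 7, "stiff": 7}

    def test_sample_means_within_3_se(self):
        # oracle: sampling distribution of the mean of the configured normals
        pop = two_class_pop(n=100, seed=7)
        cells = syn.sample_population(pop)
        for cls_cfg in pop.classes:
            s = np.array([c.stiffness for c in cells if c.class_label == cls_cfg.name])
            se = cls_cfg.stiffness_sd / np.sqrt(cls_cfg.n)
            assert abs(s.mean() - cls_cfg.stiffness_mean) < 3 * se
            d = np.array([c.diameter for c in cells if c.class_label == cls_cfg.name])
            se_d = cls_cfg.diameter_sd / np.sqrt(cls_cfg.n)
            assert abs(d.mean() - cls_cfg.diameter_mean) < 3 * se_d

    def test_diameters_positive(self):
        pop = syn.PopulationConfig(
            classes=(
                syn.ClassConfig(name="a", n=200, diameter_mean=2.0, diameter_sd=1.5, stiffness_mean=1.0),
                syn.ClassConfig(name="b", n=1, stiffness_mean=1.0),
            ),
            seed=0,
        )
        assert all(c.diameter > 0.5 for c in syn.sample_population(pop))


def cell(diameter=14.0, stiffness=2.0, **kw):
    return syn.CellSpec(cell_id="c0", class_label="soft", diameter=diameter,
                        stiffness=stiffness, texture_seed=5, **kw)


class TestSimulateTransit:
    def test_small_cell_undeformed(self, geometry):
        trace = syn.simulate_transit(cell(diameter=4.0), geometry)
        assert trace.max_di < 0.05

    def test_bad_dt_rejected(self, geometry):
        with pytest.raises(ValueError, match="dt"):
            syn.simulate_transit(cell(), geometry, dt=0.0)

    def test_soft_deforms_more_and_transits_faster(self, geometry):
        soft = syn.simulate_transit(cell(stiffness=1.0), geometry)
        stiff = syn.simulate_transit(cell(stiffness=10.0), geometry)
        assert soft.max_di > stiff.max_di
        assert feat.compute_transition_time(soft) < feat.compute_transition_time(stiff)

    def test_rigid_limit_via_closed_form_oracle(self, geometry):
        # oracle: g_eff(s) closed form predicts the fully relaxed DI; as
        # s -> inf, g_eff -> D so DI -> 0 while duration keeps growing
        d = 14.0
        grid = [1.0, 10.0, 100.0, 1e4]
        dis, durations = [], []
        for s in grid:
            # coarsen dt for very stiff cells: transit time grows ~ linearly
            # with stiffness, so a fixed dt would need millions of steps
            dt = max(0.5, s / 2000.0)
            tr = syn.simulate_transit(cell(diameter=d, stiffness=s), geometry, dt=dt)
            dis.append(tr.max_di)
            durations.append(feat.compute_transition_time(tr))
            g_eff = syn.effective_gap(d, s, geometry.gap)
            di_pred = (d**2 - g_eff**2) / (d**2 + g_eff**2)
            assert tr.max_di <= di_pred + 1e-9
        assert all(x > y for x, y in zip(dis, dis[1:]))
        assert all(x < y for x, y in zip(durations, durations[1:]))
        assert dis[-1] < 1e-3
        # rigid limit via the closed-form gap: DI(s=1e6) is numerically zero
        g_inf = syn.effective_gap(d, 1e6, geometry.gap)
        assert (d**2 - g_inf**2) / (d**2 + g_inf**2) < 1e-4

    def test_trace_invariants(self, geometry):
        tr = syn.simulate_transit(cell(), geometry)
        assert np.all(tr.major_axis >= tr.minor_axis)
        assert np.all(tr.minor_axis > 0)
        assert np.all(tr.velocity >= 0)
        assert tr.entry_index < tr.exit_index

    def test_geometry_limit_diameter_to_gap(self, geometry):
        # as diameter -> gap from above, max DI -> 0
        dis = [
            syn.simulate_transit(cell(diameter=geometry.gap + eps), geometry).max_di
            for eps in (2.0, 1.0, 0.5, 0.1, 0.01)
        ]
        assert all(x > y for x, y in zip(dis, dis[1:]))
        assert dis[-1] < 2e-3


class TestRenderFrames:
    def test_circle_round_trip(self, geometry):
        c = cell(diameter=4.0)  # never deforms: a == b throughout
        tr = syn.simulate_transit(c, geometry)
        spec = syn.ImageSpec(pixel_scale=0.15)  # ~27 px circle
        seq = syn.render_frames(tr, c, which="squeezed", spec=spec, seed=1)
        mask = feat.segment_cell(seq.frames[0])
        fit = feat.fit_ellipse(mask)
        assert fit.a / fit.b < 1.02

    def test_determinism_bit_identical(self, geometry):
        c = cell()
        tr = syn.simulate_transit(c, geometry)
        f1 = syn.render_frames(tr, c, which="squeezed", seed=9).frames[0]
        f2 = syn.render_frames(tr, c, which="squeezed", seed=9).frames[0]
        np.testing.assert_array_equal(f1, f2)

    def test_different_seed_differs(self, geometry):
        c = cell()
        tr = syn.simulate_transit(c, geometry)
        f1 = syn.render_frames(tr, c, which="squeezed", seed=1).frames[0]
        f2 = syn.render_frames(tr, c, which="squeezed", seed=2).frames[0]
        assert not np.array_equal(f1, f2)

    def test_out_of_bounds_names_frame(self, geometry):
        c = cell(diameter=30.0, stiffness=0.5)
        tr = syn.simulate_transit(c, geometry)
        small = syn.ImageSpec(height=32, width=32, pixel_scale=0.5)
        with pytest.raises(syn.RenderError, match="c0"):
            syn.render_frames(tr, c, which="squeezed", spec=small, seed=0)

    def test_pixel_range(self, geometry):
        c = cell()
        tr = syn.simulate_transit(c, geometry)
        for frame in syn.render_frames(tr, c, which="entry", seed=0).frames:
            assert frame.min() >= 0.0 and frame.max() <= 1.0

    def test_area_conservation(self, geometry):
        # noise-free, texture-free rendering: coverage recovers pi*a*b/4 +-3%
        c = syn.CellSpec(cell_id="c1", class_label="soft", diameter=12.0, stiffness=2.0,
                         texture_seed=1, texture_amp=0.0)
        tr = syn.simulate_transit(c, geometry)
        spec = syn.ImageSpec(noise_sd=0.0)
        for which in ("entry", "squeezed"):
            seq = syn.render_frames(tr, c, which=which, spec=spec, seed=0)
            img = seq.frames[0]
            coverage = (img - spec.background) / (c.brightness - spec.background)
            area_um2 = coverage.sum() * spec.pixel_scale**2
            idx = seq.frame_indices[0]
            expected = np.pi * tr.major_axis[idx] * tr.minor_axis[idx] / 4.0
            assert area_um2 == pytest.approx(expected, rel=0.03)

    def test_overlap_one_classes_indistinguishable(self, geometry):
        # two-sample KS on pooled pixel intensities, n=50 cells per class
        pop = two_class_pop(n=50, seed=21)
        pop = syn.PopulationConfig(classes=pop.classes, texture_overlap=1.0, seed=21)
        cells = syn.sample_population(pop)
        hists = {"soft": [], "stiff": []}
        for c in cells:
            tr = syn.simulate_transit(c, geometry)
            img = syn.render_frames(tr, c, which="entry", seed=0).frames[0]
            hists[c.class_label].append(img.mean())
        p = stats.ks_2samp(hists["soft"], hists["stiff"]).pvalue
        assert p > 0.01


class TestMakeDataset:
    def test_counts_and_images(self, small_dataset_dir):
        out, summary = small_dataset_dir
        assert summary["counts"] == {"soft": 10, "stiff": 10}
        manifest = (out / "manifest.csv").read_text().strip().splitlines()
        assert len(manifest) == 21  # header + 20 rows
        assert len(list((out / "images").glob("*.png"))) == 40

    def test_manifest_determinism(self, small_dataset_dir, tmp_path):
        out, _ = small_dataset_dir
        pop = syn.default_population(n_per_class=10, texture_overlap=0.5, seed=11)
        syn.make_dataset(pop, out_dir=tmp_path)
        assert (tmp_path / "manifest.csv").read_text() == (out / "manifest.csv").read_text()

    def test_manifest_di_matches_trace(self, small_dataset_dir, geometry):
        import pandas as pd

        out, summary = small_dataset_dir
        df = pd.read_csv(summary["manifest"])
        pop = syn.default_population(n_per_class=10, texture_overlap=0.5, seed=11)
        cells = {c.cell_id: c for c in syn.sample_population(pop)}
        for _, row in df.iterrows():
            tr = syn.simulate_transit(cells[row["cell_id"]], geometry)
            sq = tr.squeezed_step()
            di = feat.compute_di(float(tr.major_axis[sq]), float(tr.minor_axis[sq]))
            assert abs(di - row["di"]) < 1e-12

    def test_manifest_columns_exact_order(self, small_dataset_dir):
        out, _ = small_dataset_dir
        header = (out / "manifest.csv").read_text().splitlines()[0]
        assert header == "cell_id,class,di,tt_ms,vmax_norm,dir_per_ms,img_entry,img_squeezed"


class TestMonotonicityProperty:
    def test_population_monotonicity_over_stiffness_grid(self, geometry):
        levels = [1.0, 2.0, 4.0, 8.0, 16.0]
        means = {"di": [], "tt": [], "vmax": []}
        for s in levels:
            pop = syn.PopulationConfig(
                classes=(
                    syn.ClassConfig(name="a", n=50, diameter_mean=14.0, diameter_sd=1.0,
                                    stiffness_mean=s, stiffness_sd=0.1 * s),
                    syn.ClassConfig(name="b", n=1, stiffness_mean=1.0),
                ),
                seed=42,
            )
            cells = [c for c in syn.sample_population(pop) if c.class_label == "a"]
            di, tt, vm = [], [], []
            for c in cells:
                tr = syn.simulate_transit(c, geometry)
                di.append(tr.max_di)
                tt.append(feat.compute_transition_time(tr))
                vm.append(feat.compute_vmax(tr, geometry.flow_velocity))
            means["di"].append(np.mean(di))
            means["tt"].append(np.mean(tt))
            means["vmax"].append(np.mean(vm))
        assert all(x > y for x, y in zip(means["di"], means["di"][1:]))
        assert all(x < y for x, y in zip(means["tt"], means["tt"][1:]))
        assert all(x > y for x, y in zip(means["vmax"], means["vmax"][1:]))
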