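"""Generator: library drawing, study-design grid, peak-table simulation."""

import numpy as np
import pandas as pd
import pytest

import dims_stability as ds
from dims_stability.synthetic import DEFAULT_GRID

from conftest import annotate_study


class TestGenerateLibrary:
    def test_empty_library(self):
        lib = ds.generate_library(0, (70, 600), 0, seed=1)
        assert len(lib) == 0

    def test_deterministic_for_fixed_seed(self):
        a = ds.generate_library(100, (70, 600), 17, seed=7)
        b = ds.generate_library(100, (70, 600), 17, seed=7)
        pd.testing.assert_frame_equal(a.entries, b.entries)

    def test_pairwise_ppm_separation_bruteforce(self):
        lib = ds.generate_library(100, (70, 600), 17, seed=7)
        m = lib.entries["monoisotopic_mass"].to_numpy()
        for i in range(len(m)):
            for j in range(i + 1, len(m)):
                sep = abs(m[i] - m[j]) / min(m[i], m[j]) * 1e6
                assert sep > 4.0

    def test_silc_count_and_mass_bounds(self):
        lib = ds.generate_library(50, (80, 500), 5, seed=2)
        assert len(lib.silc_names) == 5
        masses = lib.entries["monoisotopic_mass"]
        assert masses.between(80, 500).all()

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_metabolites=10, mass_range=(300, 300), n_silc=0),
            dict(n_metabolites=10, mass_range=(70, 600), n_silc=11),
            dict(n_metabolites=-1, mass_range=(70, 600), n_silc=0),
            dict(n_metabolites=10, mass_range=(10, 600), n_silc=0),
        ],
    )
    def test_invalid_arguments_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ds.generate_library(seed=1, **kwargs)


class TestGenerateDesign:
    def test_default_grid_gives_69_design_samples(self):
        design = ds.generate_design(3, None, 1)
        assert len(design.samples) == 69  # 3 pools x (1 reference + 22 conditions)
        assert sum(len(v) for v in DEFAULT_GRID.values()) == 22

    def test_reference_only_design(self):
        design = ds.generate_design(1, {}, 1)
        assert len(design.samples) == 1
        assert design.samples["series"].iloc[0] == ds.REFERENCE_SERIES

    def test_replicate_expansion_multiplies_rows(self):
        design = ds.generate_design(3, None, 3)
        assert len(design.samples) == 207  # 69 x 3
        assert len(design.base_samples()) == 69

    def test_one_reference_per_pool_and_monotone_levels(self):
        design = ds.generate_design(4, None, 2)
        base = design.base_samples()
        refs = base[base["series"] == ds.REFERENCE_SERIES]
        assert refs.groupby("pool").size().eq(1).all()
        for (_, _), grp in base[base["series"] != ds.REFERENCE_SERIES].groupby(
            ["pool", "series"]
        ):
            assert (np.diff(grp["level"]) > 0).all()

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            ds.generate_design(0, None, 1)
        with pytest.raises(ValueError):
            ds.generate_design(1, {"room": [2, 2, 8]}, 1)

    def test_exclusion_flags_rows(self):
        design = ds.generate_design(2, {"room": [2]}, 2)
        sid = design.samples["sample_id"].iloc[-1]
        out = design.exclude([sid])
        assert out.samples.loc[out.samples["sample_id"] == sid, "excluded"].all()
        assert not design.samples["excluded"].any()  # original untouched


class TestSimulatePeakTables:
    def test_zero_noise_identity_across_samples(self, tiny_library, small_design):
        ann = annotate_study(tiny_library, small_design, ds.EffectSpec(seed=5))
        # no drift, no noise, equal pool factors: every row is constant
        assert np.allclose(ann.values.to_numpy(), ann.values.to_numpy()[:, [0]])

    def test_forced_drift_appears_as_exact_fold_change(self, tiny_library, small_design):
        met = [n for n in tiny_library.names if not n.startswith("silc")][0]
        eff = ds.EffectSpec(drifts={met: {"freeze_thaw": {7: 2.0}}}, seed=5)
        ann = annotate_study(tiny_library, small_design, eff)
        meta = ann.sample_meta
        ref = meta[meta["series"] == ds.REFERENCE_SERIES].index[0]
        cond = meta[(meta["series"] == "freeze_thaw") & (meta["level"] == 7)].index[0]
        fc = ann.values.loc[met, cond] / ann.values.loc[met, ref]
        assert fc == pytest.approx(2.0, abs=1e-12)

    def test_lognormal_noise_cv_matches_closed_form(self, tiny_library):
        # one sILC, many replicate draws: CV -> sqrt(exp(sigma^2) - 1)
        sigma = 0.15
        design = ds.generate_design(1, {}, replicates=10_000)
        eff = ds.EffectSpec(noise_sigma=sigma, seed=42)
        peaks = ds.simulate_peak_tables(tiny_library, design, eff)
        silc = tiny_library.silc_names[0]
        matches = ds.match_peaks(peaks, tiny_library)
        sums = (
            matches[matches["metabolite"] == silc]
            .groupby("replicate")["intensity"]
            .sum()
        )
        cv = sums.std(ddof=1) / sums.mean()
        expected = np.sqrt(np.exp(sigma**2) - 1.0)  # ~0.1508
        n = len(sums)
        se = expected / np.sqrt(2 * (n - 1))  # rough SE of a CV estimate
        assert abs(cv - expected) < 3 * se

    def test_determinism_bit_identical(self, tiny_library, small_design):
        eff = ds.EffectSpec(noise_sigma=0.1, seed=9)
        a = ds.simulate_peak_tables(tiny_library, small_design, eff)
        b = ds.simulate_peak_tables(tiny_library, small_design, eff)
        pd.testing.assert_frame_equal(a, b)

    def test_silc_fold_change_exactly_one_without_noise(self, tiny_library, small_design):
        ann = annotate_study(tiny_library, small_design, ds.EffectSpec(seed=5))
        meta = ann.sample_meta
        ref = meta[meta["series"] == ds.REFERENCE_SERIES].index[0]
        for silc in tiny_library.silc_names:
            fcs = ann.values.loc[silc] / ann.values.loc[silc, ref]
            assert np.allclose(fcs, 1.0)

    def test_baseline_scaling_leaves_fold_changes_unchanged(self, tiny_library, small_design):
        eff1 = ds.EffectSpec(noise_sigma=0.05, seed=4, baseline_log10_range=(5.0, 7.0))
        eff2 = ds.EffectSpec(noise_sigma=0.05, seed=4, baseline_log10_range=(7.0, 9.0))
        a = annotate_study(tiny_library, small_design, eff1)
        b = annotate_study(tiny_library, small_design, eff2)
        ref_a = a.values.iloc[:, 0]
        ref_b = b.values.iloc[:, 0]
        np.testing.assert_allclose(
            a.values.div(ref_a, axis=0), b.values.div(ref_b, axis=0), rtol=1e-9
        )

    def test_silc_ignores_pool_scale_factors(self, tiny_library, small_design):
        # spike-ins are added at fixed concentration: with zero noise their
        # intensity is identical across pools even when pools are scaled
        eff = ds.EffectSpec(pool_factors=(1.0, 2.0, 0.5), seed=4)
        ann = annotate_study(tiny_library, small_design, eff)
        silc = tiny_library.silc_names[0]
        met = [n for n in tiny_library.names if not n.startswith("silc")][0]
        assert np.allclose(
            ann.values.loc[silc], ann.values.loc[silc].iloc[0]
        )
        meta = ann.sample_meta
        refs = {
            p: meta[(meta["pool"] == p) & (meta["series"] == ds.REFERENCE_SERIES)].index[0]
            for p in (1, 2, 3)
        }
        assert ann.values.loc[met, refs[2]] == pytest.approx(
            2.0 * ann.values.loc[met, refs[1]]
        )

    def test_silc_drift_rejected(self, tiny_library, small_design):
        silc = tiny_library.silc_names[0]
        eff = ds.EffectSpec(drifts={silc: {"room": 2.0}}, seed=1)
        with pytest.raises(ValueError):
            ds.simulate_peak_tables(tiny_library, small_design, eff)

    def test_unknown_metabolite_rejected(self, tiny_library, small_design):
        eff = ds.EffectSpec(drifts={"nope": {"room": 2.0}}, seed=1)
        with pytest.raises(KeyError):
            ds.simulate_peak_tables(tiny_library, small_design, eff)
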