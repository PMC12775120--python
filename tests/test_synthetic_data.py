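"""Generator contracts: profile shapes, exposures, dataset structure, variants."""

import numpy as np
import pytest

import sbspca
from sbspca import GeneratorConfig, generate_dataset, generate_profile
from sbspca.datasets import _blocks_of


class TestProfiles:
    @pytest.mark.parametrize(
        "kind,n,exposure,expected_support,expected_pct",
        [
            ("spill_left", 52, 0.38, 20, 38),
            ("episodic", 52, 0.13, 7, 13),
            ("spill_right", 52, 0.25, 13, 25),
            ("spill_wide", 52, 0.52, 27, 52),
        ],
    )
    def test_support_size_and_reported_exposure(
        self, kind, n, exposure, expected_support, expected_pct
    ):
        p = generate_profile(kind, n, exposure, amplitude=2.0, seed=1)
        assert len(p.support) == expected_support
        assert p.exposure == len(p.support) / n
        assert p.exposure_percent == expected_pct

    def test_left_right_wide_placement(self):
        left = generate_profile("spill_left", 52, 0.38)
        assert left.support[0] == 0 and _blocks_of(left.support) == [(0, 20)]
        right = generate_profile("spill_right", 52, 0.25)
        assert right.support[-1] == 51 and len(_blocks_of(right.support)) == 1
        wide = generate_profile("spill_wide", 52, 0.52)
        blocks = _blocks_of(wide.support)
        assert len(blocks) == 1
        assert blocks[0][0] > 0 and blocks[0][1] < 52  # interior block

    def test_episodic_is_disjoint_short_blocks(self):
        p = generate_profile("episodic", 52, 0.13, seed=5)
        blocks = _blocks_of(p.support)
        assert len(blocks) >= 2
        assert all(b - a <= 5 for a, b in blocks)
        # disjoint with at least one gap between consecutive blocks
        for (a1, b1), (a2, b2) in zip(blocks[:-1], blocks[1:]):
            assert a2 > b1

    def test_monotone_and_stable_profiles(self):
        inc = generate_profile("increasing", 53, 1.0, amplitude=3.0)
        assert np.all(np.diff(inc.as_array()) > 0)
        dec = generate_profile("decreasing", 53, 1.0, amplitude=3.0)
        assert np.all(np.diff(dec.as_array()) < 0)
        stable = generate_profile("stable", 53, 1.0, amplitude=3.0)
        assert np.allclose(stable.as_array(), 3.0)
        assert stable.exposure == 1.0

    def test_spill_short_length_cap(self):
        p = generate_profile("spill_short", 52, 0.08)
        assert len(p.support) <= 5
        with pytest.raises(ValueError, match="<= 5"):
            generate_profile("spill_short", 52, 0.3)

    def test_rejections(self):
        with pytest.raises(ValueError, match="unknown profile kind"):
            generate_profile("volcano", 52, 0.5)
        with pytest.raises(ValueError, match="empty support"):
            generate_profile("spill_short", 52, 0.001)
        with pytest.raises(ValueError, match="full support"):
            generate_profile("stable", 52, 0.5)


class TestDatasetGeneration:
    def test_dataset_ii_shape_and_registry(self, dataset_ii):
        table, registry = dataset_ii
        assert table.n_samples == 52
        assert len(registry.entries) == 9
        assert registry.dataset_label == "II"
        # every registry feature exists in the table
        ids = set(table.feature_ids)
        assert all(e.feature_id in ids for e in registry.entries)
        # the designed left-sided / episodic exposures reproduce
        kinds = {e.profile.kind: e for e in registry.entries}
        assert kinds["spill_left"].profile.exposure_percent in (33, 38)
        assert kinds["episodic"].profile.exposure_percent == 13

    def test_dataset_i_registry(self):
        cfg = GeneratorConfig(n_times=53, seed=3)
        table, registry = generate_dataset(cfg, "I")
        assert table.n_samples == 53
        assert len(registry.entries) == 8
        assert {e.profile.kind for e in registry.entries} >= {
            "increasing",
            "decreasing",
            "fluctuating",
            "stable",
        }

    def test_exposure_conservation(self, dataset_ii):
        _, registry = dataset_ii
        for e in registry.entries:
            vals = np.asarray(e.concentration)
            assert np.count_nonzero(vals) / len(vals) == e.profile.exposure

    def test_noiseless_limit_is_exact(self):
        cfg = GeneratorConfig(
            n_times=20,
            n_background_features=20,
            noise_cv=1e-9,
            spike_noise_cv=0.0,
            zero_rate=0.0,
            drift_magnitude=0.0,
            n_artifact_features=0,
            seed=4,
        )
        spec = [{"kind": "spill_left", "exposure": 0.4, "amplitude": 100.0}]
        table, registry = generate_dataset(cfg, spec)
        e = registry.entries[0]
        row = table.column(e.feature_id)
        baseline = row - np.asarray(e.profile.values)
        # baseline collapses to a constant and the spike adds exactly the profile
        assert np.allclose(baseline, baseline[0], rtol=1e-5)
        corr = np.corrcoef(row - baseline[0], e.profile.as_array())[0, 1]
        assert corr > 1 - 1e-9

    def test_seed_determinism_bytes(self, tmp_path):
        cfg = GeneratorConfig(seed=9, n_background_features=40)
        a, _ = generate_dataset(cfg, "II")
        b, _ = generate_dataset(cfg, "II")
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        sbspca.write_feature_table(a, pa)
        sbspca.write_feature_table(b, pb)
        assert pa.read_bytes() == pb.read_bytes()
        c, _ = generate_dataset(GeneratorConfig(seed=10, n_background_features=40), "II")
        assert not np.array_equal(a.X, c.X)

    def test_background_lag1_autocorrelation(self):
        cfg = GeneratorConfig(
            n_times=52,
            n_background_features=300,
            ar_coefficient=0.5,
            zero_rate=0.0,
            drift_magnitude=0.0,
            n_artifact_features=0,
            seed=21,
        )
        table, _ = generate_dataset(cfg, [])
        logs = np.log(table.X[:, :300])
        acs = []
        for j in range(300):
            x = logs[:, j] - logs[:, j].mean()
            acs.append((x[1:] * x[:-1]).sum() / (x * x).sum())
        assert abs(np.mean(acs) - 0.5) < 0.1

    def test_registry_capacity_rejected(self):
        cfg = GeneratorConfig(n_background_features=5)
        with pytest.raises(ValueError, match="capacity"):
            generate_dataset(cfg, "II")

    def test_roundtrip_io(self, dataset_ii, tmp_path):
        table, registry = dataset_ii
        path = tmp_path / "t.csv"
        sbspca.write_feature_table(table, path)
        back = sbspca.read_feature_table(path)
        assert back.X.shape == table.X.shape
        np.testing.assert_allclose(back.X, table.X, rtol=1e-12)
        rpath = tmp_path / "r.json"
        sbspca.write_registry_json(registry, rpath)
        reg2 = sbspca.read_registry_json(rpath)
        assert [e.feature_id for e in reg2.entries] == registry.feature_ids


class TestToolVariants:
    def test_identity_variant(self, dataset_ii):
        table, registry = dataset_ii
        params = dict(
            dropout_rate=0.0,
            duplicate_rate=0.0,
            satellite_rate=0.0,
            rescale_sd=0.0,
            missed_rate=0.0,
            mz_jitter_ppm=0.0,
            rt_jitter=0.0,
        )
        variants = sbspca.emulate_tool_variants(table, registry, [params, params], seed=1)
        v = variants[0]
        np.testing.assert_allclose(v.table.X, table.X)
        assert v.provenance == {f: f for f in table.feature_ids}

    def test_duplicates_map_to_parent(self, dataset_ii):
        table, registry = dataset_ii
        params = dict(dropout_rate=0.0, duplicate_rate=0.3, satellite_rate=0.0)
        variants = sbspca.emulate_tool_variants(table, registry, [params, params], seed=2)
        v = variants[0]
        assert v.table.n_features > table.n_features
        dups = [f for f in v.table.feature_ids if f.endswith("_dup")]
        assert dups
        for d in dups:
            assert v.provenance[d] == d[: -len("_dup")]

    def test_missed_detections_reduce_exposure(self, dataset_ii):
        table, registry = dataset_ii
        target = registry.ids_of_kinds(["spill_left"])[0]
        true_exp = registry.entry(target).profile.exposure
        params = dict(
            dropout_rate=0.0,
            duplicate_rate=0.0,
            satellite_rate=0.0,
            missed_rate=0.0,
            missed_rate_overrides={target: 0.4},
        )
        variants = sbspca.emulate_tool_variants(table, registry, [params, params], seed=3)
        row = variants[0].table.column(target)
        spike = registry.entry(target).profile.as_array() > 0
        detected = np.count_nonzero(row[spike]) / len(row)
        assert detected < true_exp

    def test_full_dropout_rejected(self, dataset_ii):
        table, registry = dataset_ii
        with pytest.raises(ValueError, match="dropout"):
            sbspca.emulate_tool_variants(
                table, registry, [{"dropout_rate": 1.0}, {"dropout_rate": 0.0}], seed=1
            )

    def test_fewer_than_two_variants_rejected(self, dataset_ii):
        table, registry = dataset_ii
        with pytest.raises(ValueError, match="at least 2"):
            sbspca.emulate_tool_variants(table, registry, [{}], seed=1)
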