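"""Split planning, augmentation planning/execution, and transforms."""

import hashlib

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_manifest
from lpc_sononet import datapipe as dp


def blank_manifest(counts: dict) -> pd.DataFrame:
    rows = [{"path": f"{cat}/{i:05d}.png", "category": cat, "split": "",
             "provenance": "original"}
            for cat, n in counts.items() for i in range(n)]
    return pd.DataFrame(rows, columns=dp.MANIFEST_COLUMNS)


class TestSplit:
    @pytest.mark.parametrize("n,expected", [
        (1040, (832, 104, 104)),   # femur row of the six-class table
        (711, (568, 72, 71)),      # abdomen row
        (10, (8, 1, 1)),
        (143, (114, 15, 14)),
    ])
    def test_ratio_rounding_rule(self, n, expected):
        assert dp._split_counts(n, (8, 1, 1)) == expected

    def test_split_is_partition_and_deterministic(self):
        m = blank_manifest({"femur": 57, "thorax": 23, "other": 11})
        plan, out = dp.make_split(m, seed=5)
        plan2, out2 = dp.make_split(m, seed=5)
        pd.testing.assert_frame_equal(out, out2)
        assert set(out["split"]) <= set(dp.SPLITS)
        for cat, (tr, va, te) in plan.per_category.items():
            sub = out[out["category"] == cat]
            assert (tr, va, te) == tuple(
                (sub["split"] == s).sum() for s in dp.SPLITS)
            assert tr + va + te == len(sub)

    @given(st.dictionaries(
        st.sampled_from(["a", "b", "c", "d"]),
        st.integers(min_value=1, max_value=60),
        min_size=1),
        st.integers(min_value=0, max_value=2 ** 20))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_partition_property(self, counts, seed):
        """Splits are disjoint and exhaustive per category, any seed."""
        plan, out = dp.make_split(blank_manifest(counts), seed=seed)
        assert (out["split"] != "").all()
        for cat, n in counts.items():
            assert sum(plan.per_category[cat]) == n

    def test_explicit_counts_mirror_table_rows(self):
        # brain row (3092 -> 2472/310/310) deviates from the ratio rule by
        # one; explicit counts reproduce the published table verbatim
        m = blank_manifest({"brain": 3092})
        plan, out = dp.make_split(
            m, counts_table={"brain": dp.SIX_CLASS_COUNTS["brain"]})
        assert plan.per_category["brain"] == (2472, 310, 310)

    def test_explicit_counts_must_sum(self):
        with pytest.raises(dp.ManifestError, match="sum"):
            dp.make_split(blank_manifest({"femur": 10}),
                          counts_table={"femur": (8, 1, 2)})

    def test_unlabeled_record_rejected(self):
        m = blank_manifest({"femur": 3})
        m.loc[1, "category"] = ""
        with pytest.raises(dp.ManifestError, match="lack a category"):
            dp.make_split(m)


class TestPlanAugmentation:
    def make_train(self, counts):
        m = blank_manifest(counts)
        m["split"] = "train"
        return m

    def test_round_robin_exact_eleven_each(self):
        # 114 originals to 1368: deficit 1254 = 11 per source exactly
        m = self.make_train({"other_brain": 114})
        plan = dp.plan_augmentation(m, {"other_brain": 1368}, seed=0)
        assert len(plan.jobs) == 1254
        per_source = pd.Series([j[0] for j in plan.jobs]).value_counts()
        assert (per_source == 11).all() and len(per_source) == 114

    def test_round_robin_remainder_split(self):
        # 568 -> 1300: deficit 732 = 164 sources x 2 + 404 sources x 1
        m = self.make_train({"abdomen": 568})
        plan = dp.plan_augmentation(m, {"abdomen": 1300}, seed=1)
        per_source = pd.Series([j[0] for j in plan.jobs]).value_counts()
        assert len(plan.jobs) == 732
        assert (per_source.value_counts().sort_index()
                == pd.Series({1: 404, 2: 164})).all()

    def test_zero_deficit_zero_jobs(self):
        m = self.make_train({"thorax": 25})
        assert dp.plan_augmentation(m, {"thorax": 25}, seed=0).jobs == ()

    def test_target_below_originals_names_category(self):
        m = self.make_train({"cervix": 30})
        with pytest.raises(dp.ManifestError, match="cervix"):
            dp.plan_augmentation(m, {"cervix": 29}, seed=0)

    def test_no_duplicate_spec_per_source(self):
        m = self.make_train({"femur": 5})
        plan = dp.plan_augmentation(m, {"femur": 60}, seed=3)
        seen = {}
        for src, _, spec in plan.jobs:
            assert spec not in seen.setdefault(src, set())
            seen[src].add(spec)

    def test_plan_is_seed_deterministic_and_seed_sensitive(self):
        m = self.make_train({"femur": 7, "other": 4})
        targets = {"femur": 20, "other": 12}
        p1 = dp.plan_augmentation(m, targets, seed=4)
        p2 = dp.plan_augmentation(m, targets, seed=4)
        assert p1.jobs == p2.jobs
        others = [dp.plan_augmentation(m, targets, seed=s).jobs
                  for s in range(10)]
        assert any(o != p1.jobs for o in others)

    def test_only_original_train_records_are_sources(self):
        m = pd.concat([self.make_train({"femur": 4}),
                       blank_manifest({"femur": 6})])  # unsplit records
        plan = dp.plan_augmentation(m, {"femur": 8}, seed=0)
        sources = {j[0] for j in plan.jobs}
        assert sources <= set(m[m["split"] == "train"]["path"])


class TestTransforms:
    rng = np.random.default_rng(0)
    img = rng.random((24, 32))

    def test_hflip_is_involution(self):
        spec = dp.TransformSpec("hflip")
        twice = dp.apply_transform(dp.apply_transform(self.img, spec), spec)
        np.testing.assert_array_equal(twice, self.img)

    def test_rotate_zero_is_identity(self):
        out = dp.apply_transform(self.img, dp.TransformSpec("rotate", 0.0))
        np.testing.assert_array_equal(out, self.img)

    def test_rotation_fills_corners_with_zero(self):
        img = np.ones((33, 33))
        out = dp.apply_transform(img, dp.TransformSpec("rotate", 15.0))
        assert out[0, 0] == 0.0 and out.shape == img.shape

    def test_blur_preserves_constant_images(self):
        const = np.full((20, 20), 0.37)
        out = dp.apply_transform(const,
                                 dp.TransformSpec("gaussian_blur", 1.0))
        np.testing.assert_allclose(out, const, atol=1e-6)

    @pytest.mark.parametrize("spec", [
        dp.TransformSpec("rotate", -12.5),
        dp.TransformSpec("brightness", 1.3),
        dp.TransformSpec("contrast", 0.7),
        dp.TransformSpec("gaussian_blur", 0.5),
        dp.TransformSpec("hflip"),
    ])
    def test_output_shape_and_range(self, spec):
        out = dp.apply_transform(self.img, spec)
        assert out.shape == self.img.shape
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(dp.ManifestError):
            dp.TransformSpec("vflip")
        with pytest.raises(dp.ManifestError):
            dp.TransformSpec("rotate", 90.0)  # outside the pinned range


class TestExecutePlan:
    def test_counts_equal_targets_and_isolation(self, tmp_path):
        rng = np.random.default_rng(1)
        train = make_manifest(tmp_path, {"femur": 4, "thorax": 3}, rng)
        (tmp_path / "v").mkdir(exist_ok=True)
        val = make_manifest(tmp_path / "v", {"femur": 2}, rng, split="val")
        manifest = pd.concat([train, val], ignore_index=True)
        targets = {"femur": 11, "thorax": 7}
        plan = dp.plan_augmentation(manifest, targets, seed=2)
        out = dp.execute_plan(manifest, plan, tmp_path / "aug")
        tr = out[out["split"] == "train"]
        for cat, t in targets.items():
            assert (tr["category"] == cat).sum() == t
        # originals and val untouched
        pd.testing.assert_frame_equal(
            out[out["provenance"] == "original"].reset_index(drop=True),
            manifest.reset_index(drop=True))
        pd.testing.assert_frame_equal(
            out[out["split"] == "val"].reset_index(drop=True),
            val.reset_index(drop=True))
        # every augmented file exists and differs from its source
        for _, rec in out[out["provenance"] != "original"].iterrows():
            src_stem = rec["provenance"].split(":")[1]
            src = train.loc[train["path"].str.contains(src_stem), "path"]
            aug_bytes = open(rec["path"], "rb").read()
            src_bytes = open(src.iloc[0], "rb").read()
            assert hashlib.sha256(aug_bytes).digest() != \
                hashlib.sha256(src_bytes).digest()

    def test_rerun_is_byte_identical(self, tmp_path):
        rng = np.random.default_rng(2)
        manifest = make_manifest(tmp_path, {"abdomen": 3}, rng)
        plan = dp.plan_augmentation(manifest, {"abdomen": 9}, seed=7)
        out1 = dp.execute_plan(manifest, plan, tmp_path / "a")
        files1 = {p: open(p, "rb").read()
                  for p in out1[out1["provenance"] != "original"]["path"]}
        plan2 = dp.plan_augmentation(manifest, {"abdomen": 9}, seed=7)
        out2 = dp.execute_plan(manifest, plan2, tmp_path / "a")
        pd.testing.assert_frame_equal(out1, out2)
        for p, b in files1.items():
            assert open(p, "rb").read() == b

    def test_empty_plan_leaves_manifest_unchanged(self, tmp_path):
        rng = np.random.default_rng(3)
        manifest = make_manifest(tmp_path, {"other": 2}, rng)
        plan = dp.plan_augmentation(manifest, {"other": 2}, seed=0)
        out = dp.execute_plan(manifest, plan, tmp_path / "a")
        pd.testing.assert_frame_equal(out, manifest)


class TestManifestIO:
    def test_round_trip(self, tmp_path):
        m = blank_manifest({"femur": 3, "other": 2})
        dp.write_manifest(m, tmp_path / "m.csv")
        back = dp.read_manifest(tmp_path / "m.csv")
        pd.testing.assert_frame_equal(back, m)

    def test_missing_column_rejected(self, tmp_path):
        (tmp_path / "bad.csv").write_text("path,category\na.png,femur\n")
        with pytest.raises(dp.ManifestError, match="split"):
            dp.read_manifest(tmp_path / "bad.csv")


def test_shipped_target_tables_are_consistent():
    """The shipped six-/nine-class target tables exceed their training
    counts and sum to the documented totals (16,448 and 13,922)."""
    for counts, targets, total in [
            (dp.SIX_CLASS_COUNTS, dp.SIX_CLASS_TARGETS, 16448),
            (dp.NINE_CLASS_COUNTS, dp.NINE_CLASS_TARGETS, 13922)]:
        assert set(counts) == set(targets)
        for cat in counts:
            assert targets[cat] >= counts[cat][0]
        assert sum(targets.values()) == total
        assert sum(c[0] for c in counts.values()) == 9916
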