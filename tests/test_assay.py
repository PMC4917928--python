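"""Degeneration assay: sampling, profiles, determinism, resolution."""

import numpy as np
import pandas as pd
import pytest

from funcoh import (
    AssayConfig,
    ICTable,
    ProteinSet,
    degenerate,
    make_pool,
    planted_core_fixture,
    register_metric,
    resolution,
    run_assay,
    score_set,
)
from funcoh.assay import EXTRA_METRICS, PoolError, replacement_count


@pytest.fixture(scope="module")
def planted():
    return planted_core_fixture(seed=2)


def rng(seed=0):
    return np.random.default_rng(seed)


class TestDegenerate:
    def setup_method(self):
        self.family = ProteinSet.from_ids([f"F{i}" for i in range(10)], label="fam")
        self.pool = ProteinSet.from_ids([f"Q{i}" for i in range(30)], label="pool")

    def test_fraction_zero_returns_family_itself(self):
        assert degenerate(self.family, self.pool, 0.0, rng()) is self.family

    def test_fraction_one_fully_disjoint(self):
        out = degenerate(self.family, self.pool, 1.0, rng())
        assert set(out.members) & set(self.family.members) == set()
        assert len(out) == 10

    def test_fraction_point_three_keeps_seven(self):
        out = degenerate(self.family, self.pool, 0.3, rng())
        kept = set(out.members) & set(self.family.members)
        drawn = set(out.members) - set(self.family.members)
        assert (len(kept), len(drawn)) == (7, 3)

    def test_round_half_up(self):
        assert replacement_count(0.25, 10) == 3  # 2.5 rounds up
        assert replacement_count(0.1, 5) == 1
        assert replacement_count(0.0, 7) == 0

    def test_no_duplicates_in_output(self):
        for fraction in (0.2, 0.5, 0.9):
            out = degenerate(self.family, self.pool, fraction, rng(3))
            assert len(set(out.members)) == len(out)

    def test_overlapping_pool_rejected(self):
        bad_pool = ProteinSet.from_ids(["F0", "Q1", "Q2"])
        with pytest.raises(PoolError):
            degenerate(self.family, bad_pool, 0.5, rng())

    def test_undersized_pool_rejected(self):
        small = ProteinSet.from_ids(["Q1", "Q2"])
        with pytest.raises(PoolError):
            degenerate(self.family, small, 0.5, rng())


class TestRunAssay:
    def make_config(self, **kw):
        base = dict(
            levels=(0.0, 0.5, 1.0), iterations=3, seed=42,
            min_family_size=5, metrics=("agreement", "ui", "gic"),
        )
        base.update(kw)
        return AssayConfig(**base)

    def test_level_zero_mean_is_undegenerated_score_sd_zero(self, planted):
        onto, corpus, families, _ = planted
        ic = ICTable.from_corpus(corpus)
        pool = make_pool(families, "FAM")
        profile = run_assay(families["FAM"], pool, corpus, onto, ic, self.make_config())
        at_zero = profile.table[profile.table["level"] == 0.0].set_index("metric")
        direct = score_set(families["FAM"], corpus, onto, ic, ("agreement", "ui", "gic"))
        for metric, expected in direct.items():
            assert at_zero.loc[metric, "mean"] == pytest.approx(expected)
            assert at_zero.loc[metric, "sd"] == 0.0

    def test_reproducible_from_seed(self, planted):
        onto, corpus, families, _ = planted
        ic = ICTable.from_corpus(corpus)
        pool = make_pool(families, "FAM")
        config = self.make_config(iterations=2)
        p1 = run_assay(families["FAM"], pool, corpus, onto, ic, config)
        p2 = run_assay(families["FAM"], pool, corpus, onto, ic, config)
        pd.testing.assert_frame_equal(p1.table, p2.table)

    def test_cohesive_family_degrades(self, planted):
        onto, corpus, families, _ = planted
        ic = ICTable.from_corpus(corpus)
        pool = make_pool(families, "FAM")
        profile = run_assay(families["FAM"], pool, corpus, onto, ic, self.make_config())
        for metric in ("agreement", "ui", "gic"):
            means = profile.mean_by_level(metric)
            assert means[1.0] < means[0.0]

    def test_small_family_skipped(self, planted):
        onto, corpus, families, _ = planted
        ic = ICTable.from_corpus(corpus)
        pool = make_pool(families, "FAM")
        tiny = ProteinSet.from_ids(families["FAM"].members[:3], label="tiny")
        config = self.make_config(min_family_size=20)
        assert run_assay(tiny, pool, corpus, onto, ic, config) is None

    def test_plugin_metric_hook(self, planted):
        onto, corpus, families, _ = planted
        ic = ICTable.from_corpus(corpus)
        register_metric("const", lambda pset, corpus, ctx: 0.75)
        try:
            scores = score_set(families["FAM"], corpus, onto, ic, ("const",))
            assert scores["const"] == 0.75
        finally:
            EXTRA_METRICS.pop("const", None)


class TestAssayConfig:
    def test_unsorted_levels_rejected(self):
        with pytest.raises(ValueError):
            AssayConfig(levels=(0.5, 0.1))

    def test_out_of_range_level_rejected(self):
        with pytest.raises(ValueError):
            AssayConfig(levels=(0.0, 1.5))


class TestResolution:
    def test_constant_profile_zero(self):
        assert resolution([{0.0: 0.4, 0.5: 0.4, 1.0: 0.4}]) == 0.0

    def test_average_over_families(self):
        fams = [{0.0: 0.9, 1.0: 0.1}, {0.0: 0.6, 1.0: 0.4}]
        assert resolution(fams) == pytest.approx((0.8 + 0.2) / 2)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            resolution([])

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            resolution([{0.0: 0.5}])
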