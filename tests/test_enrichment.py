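"""Disynthon aggregation, enrichment z-scores, and class assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from delscreen import del_decode as dd
from delscreen import enrichment as en
from delscreen import synthetic_del as sd


def _count_table(rows):
    df = pd.DataFrame(rows, columns=["library_id", "blocks", "condition", "raw_count", "unique_count"])
    df["norm_rpm"] = 0.0
    return dd.CountTable(df=df, totals=None)


class TestAggregateDisynthons:
    def test_two_cycle_aggregation_is_identity(self):
        ct = _count_table(
            [("L", "a|b", "target", 5, 5), ("L", "a|c", "target", 7, 7)]
        )
        out = en.aggregate_disynthons(ct, n_cycles=2)
        assert len(out) == 2
        assert set(out["disynthon"]) == {"1,2:a|b", "1,2:a|c"}
        assert out["unique_count"].sum() == 12

    def test_three_cycle_member_feeds_three_views(self):
        ct = _count_table([("L", "a|b|c", "target", 5, 5)])
        out = en.aggregate_disynthons(ct, n_cycles=3)
        assert len(out) == 3
        assert set(out["disynthon"]) == {"1,2:a|b", "1,3:a|c", "2,3:b|c"}
        assert (out["unique_count"] == 5).all()

    def test_matches_brute_force_groupby(self, rng):
        # independent oracle: enumerate cycle pairs per member and groupby-sum
        blocks = [f"{a}|{b}|{c}" for a in "xyz" for b in "pq" for c in "mn"]
        rows = [
            ("L", bl, cond, int(k), int(k))
            for bl in blocks
            for cond in ("target", "no_target")
            for k in [rng.integers(0, 50)]
        ]
        ct = _count_table(rows)
        out = en.aggregate_disynthons(ct, 3)
        expected = {}
        for _, r in ct.df.iterrows():
            parts = r["blocks"].split("|")
            for i, j in [(0, 1), (0, 2), (1, 2)]:
                key = (f"{i+1},{j+1}:{parts[i]}|{parts[j]}", r["condition"])
                expected[key] = expected.get(key, 0) + r["unique_count"]
        observed = {
            (r["disynthon"], r["condition"]): r["unique_count"] for _, r in out.iterrows()
        }
        assert observed == expected


class TestEnrichmentStatistic:
    def test_equal_proportions_give_zero(self):
        assert en.enrichment_statistic(50, 1000, 50, 1000) == pytest.approx(0.0)

    def test_reference_value(self):
        # frozen from direct evaluation of the pseudocounted two-proportion
        # formula: p=(k+0.5)/(N+0.5), pooled pbar, z = dp / sqrt(pbar(1-pbar)(1/N1+1/N2))
        z = en.enrichment_statistic(100, 10_000, 10, 10_000, pseudocount=0.5)
        assert z == pytest.approx(8.566, abs=0.05)

    def test_sign_and_antisymmetry(self):
        z = en.enrichment_statistic(0, 10_000, 10, 10_000)
        assert z < 0
        fwd = en.enrichment_statistic(37, 5000, 12, 8000)
        rev = en.enrichment_statistic(12, 8000, 37, 5000)
        assert fwd == pytest.approx(-rev)

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            en.enrichment_statistic(0, 0, 1, 100)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        k=st.integers(0, 500),
        extra=st.integers(1, 200),
        n=st.integers(1000, 100_000),
    )
    def test_monotone_in_selected_count(self, k, extra, n):
        lo = en.enrichment_statistic(k, n, 50, n)
        hi = en.enrichment_statistic(k + extra, n, 50, n)
        assert hi > lo


class TestAssignClasses:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["library_id", "disynthon", "condition", "unique_count"]
        )

    def test_rule_table(self):
        # competitive: huge target enrichment, relieved by competitor;
        # noncompetitive: enriched in both; matrix: enriched in control;
        # null: flat everywhere
        rows = []
        n = 10_000
        cases = {
            "comp": {"no_target": 10, "target": 500, "target_plus_competitor": 12},
            "noncomp": {"no_target": 10, "target": 500, "target_plus_competitor": 480},
            "matrix": {"no_target": 5000, "target": 300, "target_plus_competitor": 300},
            "null": {"no_target": 10, "target": 10, "target_plus_competitor": 10},
        }
        # pad so condition totals are comparable
        for name, counts in cases.items():
            for cond, k in counts.items():
                rows.append(("L", f"1,2:{name}|x", cond, k))
        for i in range(400):
            for cond in ("no_target", "target", "target_plus_competitor"):
                rows.append(("L", f"1,2:pad{i}|x", cond, 10))
        labels = en.assign_classes(self._table(rows))
        got = dict(zip(labels["disynthon"], labels["label"]))
        assert got["1,2:comp|x"] == "competitive_hit"
        assert got["1,2:noncomp|x"] == "noncompetitive_hit"
        assert got["1,2:matrix|x"] == "matrix_binder"
        assert got["1,2:null|x"] == "non_hit"

    def test_matrix_precedence_over_hits(self):
        rows = []
        for i in range(200):
            for cond in ("no_target", "target", "target_plus_competitor"):
                rows.append(("L", f"1,2:pad{i}|x", cond, 10))
        # enriched in no_target AND in target: matrix wins by precedence
        rows += [
            ("L", "1,2:both|x", "no_target", 3000),
            ("L", "1,2:both|x", "target", 3000),
            ("L", "1,2:both|x", "target_plus_competitor", 10),
        ]
        labels = en.assign_classes(self._table(rows))
        got = dict(zip(labels["disynthon"], labels["label"]))
        assert got["1,2:both|x"] == "matrix_binder"

    def test_all_flat_is_non_hit(self):
        rows = [
            ("L", f"1,2:d{i}|x", cond, 20)
            for i in range(50)
            for cond in ("no_target", "target")
        ]
        labels = en.assign_classes(self._table(rows))
        assert (labels["label"] == "non_hit").all()

    def test_missing_no_target_raises(self):
        rows = [("L", "1,2:a|b", "target", 5)]
        with pytest.raises(ValueError, match="no_target"):
            en.assign_classes(self._table(rows))

    def test_without_competitor_hits_merge_to_target_hit(self):
        rows = []
        for i in range(200):
            for cond in ("no_target", "target"):
                rows.append(("L", f"1,2:pad{i}|x", cond, 10))
        rows += [("L", "1,2:hit|x", "no_target", 10), ("L", "1,2:hit|x", "target", 500)]
        labels = en.assign_classes(self._table(rows))
        got = dict(zip(labels["disynthon"], labels["label"]))
        assert got["1,2:hit|x"] == "target_hit"
        assert labels.loc[labels["disynthon"] == "1,2:hit|x", "is_pte"].all()

    def test_every_disynthon_gets_exactly_one_class(self, screen_library):
        conds = sd.standard_conditions()
        decoded = {}
        schema = dd.TagSchema.from_libraries([screen_library])
        for i, c in enumerate(conds):
            rs = sd.simulate_selection(screen_library, c, 30_000, 0.1, 0.001, seed=60 + i)
            decoded[c.kind], _ = dd.decode_reads(rs, schema)
        ct = dd.build_count_table(decoded)
        dis = en.aggregate_disynthons(ct, 2)
        labels = en.assign_classes(dis, all_keys=en.all_disynthon_keys(screen_library))
        assert len(labels) == screen_library.n_members  # 2-cycle: one view each
        assert labels["label"].isin(en.CLASSES).all()

    def test_promiscuity_requires_panel(self):
        rows = []
        for i in range(100):
            for cond in ("no_target", "target"):
                rows.append(("L", f"1,2:pad{i}|x", cond, 10))
        rows += [("L", "1,2:sticky|x", "no_target", 10), ("L", "1,2:sticky|x", "target", 800)]
        table = self._table(rows)
        alone = en.assign_classes(table)
        got = dict(zip(alone["disynthon"], alone["label"]))
        assert got["1,2:sticky|x"] == "target_hit"  # unreachable without a panel
        panel = {"t2": table.copy(), "t3": table.copy()}
        with_panel = en.assign_classes(table, panel=panel)
        got = dict(zip(with_panel["disynthon"], with_panel["label"]))
        assert got["1,2:sticky|x"] == "promiscuous_binder"


class TestSelectPtes:
    def test_competitive_class_is_pte_with_competitor(self, screen_library):
        labels = pd.DataFrame(
            {
                "library_id": ["L01", "L01"],
                "disynthon": [
                    f"1,2:{screen_library.members[0].block_ids[0]}|{screen_library.members[0].block_ids[1]}",
                    f"1,2:{screen_library.members[1].block_ids[0]}|{screen_library.members[1].block_ids[1]}",
                ],
                "label": ["competitive_hit", "noncompetitive_hit"],
                "z_competitor": [0.1, 9.0],
            }
        )
        ptes = en.select_ptes(labels, screen_library)
        assert len(ptes) == 1
        assert ptes.loc[0, "smiles"] == screen_library.members[0].smiles

    def test_without_competitor_target_hits_are_ptes(self, screen_library):
        m0, m1 = screen_library.members[0], screen_library.members[1]
        labels = pd.DataFrame(
            {
                "library_id": ["L01", "L01"],
                "disynthon": [
                    f"1,2:{m0.block_ids[0]}|{m0.block_ids[1]}",
                    f"1,2:{m1.block_ids[0]}|{m1.block_ids[1]}",
                ],
                "label": ["target_hit", "target_hit"],
            }
        )
        ptes = en.select_ptes(labels, screen_library, competitor_present=False)
        assert len(ptes) == 2

    def test_empty_pte_set_warns(self, screen_library):
        labels = pd.DataFrame(
            {"library_id": ["L01"], "disynthon": ["1,2:a|b"], "label": ["non_hit"],
             "z_competitor": [0.0]}
        )
        with pytest.warns(UserWarning, match="empty PTE"):
            ptes = en.select_ptes(labels, screen_library)
        assert ptes.empty
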