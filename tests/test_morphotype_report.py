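import itertools

import numpy as np
import pytest

import scalemorph as sm
from scalemorph.clustering import Partition
from scalemorph.errors import MapLookupError, UndefinedRatioError
from scalemorph.morphotype_report import (
    REFERENCE_GROUP_SIZES,
    REFERENCE_MORPHOTYPES,
    GroupSummary,
    MorphotypeSummary,
    build_squamation_map,
)

from conftest import make_table


def as_partition(labels, table):
    labels = np.asarray(labels)
    return Partition(
        labels=labels, k=len(np.unique(labels)), scale_ids=tuple(table.scale_ids)
    )


def test_single_scale_group_has_zero_sd():
    table = make_table([[3.35, 5.66], [1.0, 2.0], [1.2, 2.2]], ("L5", "L6"))
    summary = sm.summarize_groups(table, as_partition([1, 0, 0], table))
    singleton = [g for g in summary.groups if g.n == 1][0]
    assert singleton.L5_sd == 0.0
    assert singleton.L6_sd == 0.0
    assert singleton.L6_over_L5_sd == 0.0


def test_ratio_stats_are_per_scale_then_averaged():
    # ratios 2 and 4 -> mean 3.0, population SD 1.0 (not ratio of means)
    table = make_table([[1.0, 2.0], [1.0, 4.0]], ("L5", "L6"))
    summary = sm.summarize_groups(table, as_partition([0, 0], table))
    g = summary.groups[0]
    assert g.L6_over_L5_mean == pytest.approx(3.0)
    assert g.L6_over_L5_sd == pytest.approx(1.0)


def test_published_convention_reproduces_reference_ratio_column():
    # with the ratio-of-means convention the first reference row would give
    # 8.25/1.75 = 4.714, not the printed 4.75: the per-scale mean is required
    ref = REFERENCE_MORPHOTYPES[1]
    ratio_of_means = ref["L6"][0] / ref["L5"][0]
    assert ratio_of_means != pytest.approx(ref["L6_over_L5"][0], abs=0.02)


def test_group_sizes_sum_and_invariance_to_row_order(rng, default_sample):
    table = default_sample.table
    labels = default_sample.true_labels
    part = as_partition(labels, table)
    summary = sm.summarize_groups(table, part)
    assert sum(g.n for g in summary.groups) == len(table) == 226
    perm = rng.permutation(len(table))
    table_p = type(table)(
        records=[table.records[i] for i in perm], variable_names=table.variable_names
    )
    summary_p = sm.summarize_groups(table_p, as_partition(labels[perm], table_p))
    for a, b in zip(summary.groups, summary_p.groups):
        assert a.n == b.n
        assert a.L5_mean == pytest.approx(b.L5_mean, abs=1e-12)
        assert a.L6_over_L5_mean == pytest.approx(b.L6_over_L5_mean, abs=1e-12)


def test_concealed_field_percent_reported_when_l7_present(default_sample):
    table = default_sample.table  # includes L7 by default
    part = as_partition(default_sample.true_labels, table)
    summary = sm.summarize_groups(table, part)
    mapping, _ = sm.match_to_reference(summary)
    for g in summary.groups:
        mt = mapping[g.group]
        pct = REFERENCE_MORPHOTYPES[mt].get("concealed_pct")
        if pct and g.n >= 10:
            assert g.concealed_pct_mean == pytest.approx(pct, abs=2.0)


def test_zero_length_scale_raises_undefined_ratio():
    table = make_table([[0.0, 2.0], [1.0, 2.0]], ("L5", "L6"))
    with pytest.raises(UndefinedRatioError):
        sm.summarize_groups(table, as_partition([0, 0], table))


def reference_summary():
    """A summary identical to the reference parameters."""
    groups = []
    for i, mt in enumerate(sorted(REFERENCE_MORPHOTYPES)):
        ref = REFERENCE_MORPHOTYPES[mt]
        groups.append(GroupSummary(
            group=i, n=REFERENCE_GROUP_SIZES[mt],
            L5_mean=ref["L5"][0], L5_sd=ref["L5"][1] if REFERENCE_GROUP_SIZES[mt] > 1 else 0.0,
            L6_mean=ref["L6"][0], L6_sd=ref["L6"][1] if REFERENCE_GROUP_SIZES[mt] > 1 else 0.0,
            L6_over_L5_mean=ref["L6_over_L5"][0], L6_over_L5_sd=ref["L6_over_L5"][1],
            L1_over_L6_mean=ref["L1_over_L6"][0], L1_over_L6_sd=ref["L1_over_L6"][1],
            L3_over_L6_mean=ref["L3_over_L6"][0], L3_over_L6_sd=ref["L3_over_L6"][1],
        ))
    return MorphotypeSummary(groups=groups, total_n=226)


def test_match_identity_on_reference_itself():
    summary = reference_summary()
    mapping, cost = sm.match_to_reference(summary)
    assert cost == pytest.approx(0.0, abs=1e-12)
    assert mapping == {i: mt for i, mt in enumerate(sorted(REFERENCE_MORPHOTYPES))}


def test_match_is_order_free():
    summary = reference_summary()
    swapped = MorphotypeSummary(
        groups=[summary.groups[1], summary.groups[0]] + summary.groups[2:],
        total_n=226,
    )
    mapping, _ = sm.match_to_reference(swapped)
    assert mapping == {g.group: mt for g, mt in zip(
        sorted(swapped.groups, key=lambda g: g.group),
        sorted(REFERENCE_MORPHOTYPES),
    )}


def test_match_equals_exhaustive_permutation_minimum(default_sample):
    table = default_sample.table
    part = as_partition(default_sample.true_labels, table)
    summary = sm.summarize_groups(table, part)
    mapping, cost = sm.match_to_reference(summary)
    # exhaustive 8! oracle
    mts = sorted(REFERENCE_MORPHOTYPES)
    vecs = [np.array([g.L5_mean, g.L6_mean, g.L6_over_L5_mean]) for g in summary.groups]
    refs = {mt: np.array([REFERENCE_MORPHOTYPES[mt]["L5"][0],
                          REFERENCE_MORPHOTYPES[mt]["L6"][0],
                          REFERENCE_MORPHOTYPES[mt]["L6_over_L5"][0]]) for mt in mts}
    best = min(
        (sum(np.linalg.norm(v - refs[p[i]]) for i, v in enumerate(vecs)), p)
        for p in itertools.permutations(mts)
    )
    assert cost == pytest.approx(best[0], rel=1e-12)
    assert [mapping[g.group] for g in summary.groups] == list(best[1])


def test_singleton_cluster_maps_to_morphotype_12(default_sample):
    table = default_sample.table
    part = as_partition(default_sample.true_labels, table)
    summary = sm.summarize_groups(table, part)
    mapping, _ = sm.match_to_reference(summary)
    singleton_group = [g.group for g in summary.groups if g.n == 1][0]
    assert mapping[singleton_group] == 12


def test_squamation_map_structure():
    smap = build_squamation_map()
    assert len(smap.areas) == 16
    belts = {}
    for a in smap.areas.values():
        belts[a.belt] = belts.get(a.belt, 0) + 1
    assert belts == {"dorsal": 3, "middle": 5, "ventral": 6, "unpaired": 2}
    assert smap.areas["M5"].morphotype is None
    assert not smap.areas["M5"].preserved


@pytest.mark.parametrize(
    "query, expect",
    [
        ("D2", {"morphotype": 6, "belt": "dorsal"}),
        ("Mt2", {"areas": [("M2", "middle")]}),
        ("M5", {"morphotype": None}),
    ],
)
def test_squamation_lookup(query, expect):
    entry = sm.squamation_lookup(query)
    if "areas" in expect:
        got = [(a["area"], a["belt"]) for a in entry["areas"]]
        assert got == expect["areas"]
    else:
        for key, val in expect.items():
            assert entry[key] == val


def test_squamation_lookup_unknown_lists_valid_ids():
    with pytest.raises(MapLookupError, match="D1"):
        sm.squamation_lookup("Z9")


def test_lateral_line_modifier_covers_morphotypes_1_to_4():
    smap = build_squamation_map()
    assert smap.lateral_line_morphotypes == (1, 2, 3, 4)
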