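"""Cohort tabulation: printed-table reproduction, statistics oracle, MAF."""

import numpy as np
import pytest

from canalmorph.pipeline import ToothReport
from canalmorph.report import recommend_maf, round_half_up, tabulate_cohort


def make_record(tooth_id, codes, foramina=(), accessory=(), connecting=(),
                root_count=1):
    return ToothReport(
        tooth_id=tooth_id,
        root_count=root_count,
        bifurcation_third="middle" if root_count == 2 else None,
        codes=dict(codes),
        digits={k: [int(c) for c in v.split("/")[0].split("-")] for k, v in codes.items()},
        foramina=list(foramina),
        accessory_canals=list(accessory),
        connecting_canals=list(connecting),
        landmarks={}, flags=[], config={},
    )


def make_foramen(root="single", shape="oval", W=0.40, N=0.28, D=0.45):
    return {"exit_id": 0, "class": "physiological", "shape": shape, "root": root,
            "W_mm": W, "N_mm": N, "D_mm": D, "third": "apical", "flags": []}


def reference_cohort():
    """Per-tooth records constructed from the published per-table counts."""
    records = []
    singles = {
        "1-1-1/1": 73, "1-1-1/2": 14, "1-1-1/3": 1, "1-1-1/4": 2, "1-1-2/1": 1,
        "1-2-1/1": 4, "1-2-1/2": 1, "1-2-2/2": 1, "2-3-1/1": 1,
    }
    shapes = ["round"] * 6 + ["irregular"] + ["oval"] * 72      # one-foramen teeth
    acc = [{"third": "middle", "n_foramina": 1, "opening_diameters_mm": [0.1]}] * 7 + \
          [{"third": "apical", "n_foramina": 1, "opening_diameters_mm": [0.1]}] * 6
    i = s = a = 0
    for code, n in singles.items():
        f = int(code.split("/")[1])
        for _ in range(n):
            if f == 1:
                foramina = [make_foramen(shape=shapes[s])]
                s += 1
            else:
                foramina = [make_foramen(W=0.38, N=0.22, D=0.16) for _ in range(f)]
            accessory = []
            if code == "1-1-1/1" and shapes[s - 1] == "oval" and a < 13:
                accessory = [acc[a]]
                a += 1
            connecting = []
            if code == "1-2-1/1" and not any(
                r.codes.get("single") == "1-2-1/1" for r in records
            ):
                connecting = [{"type": "L", "third": "middle"}]
            if code == "2-3-1/1":
                connecting = [{"type": "C", "third": "middle"}]
            records.append(make_record(f"s{i}", {"single": code}, foramina,
                                       accessory, connecting))
            i += 1
    two = [("1-1-1/1", "1-1-1/1"), ("1-1-1/1", "1-1-1/2"), ("1-2-1/1", "1-1-1/1")]
    for j, (cb, cl) in enumerate(two):
        foramina = [make_foramen("buccal")]
        for _ in range(int(cl.split("/")[1])):
            foramina.append(make_foramen("lingual"))
        accessory = []
        if j == 0:
            accessory = [{"third": "middle", "n_foramina": 1, "root": "buccal",
                          "opening_diameters_mm": [0.1]}]
        records.append(make_record(f"t{j}", {"buccal": cb, "lingual": cl},
                                   foramina, accessory, root_count=2))
    assert len(records) == 101
    return records


@pytest.fixture(scope="module")
def summary():
    return tabulate_cohort(reference_cohort())


def cell(df, **filters):
    m = np.ones(len(df), dtype=bool)
    for k, v in filters.items():
        m &= df[k] == v
    rows = df[m]
    assert len(rows) == 1, f"{filters} -> {len(rows)} rows"
    return rows.iloc[0]


def test_rcc_table_reproduces_reference_cells(summary):
    t = summary.rcc
    assert cell(t, rcc="1-1-1/1", group="single-rooted")["n"] == 73
    assert cell(t, rcc="1-1-1/1", group="single-rooted")["percent"] == 74.5
    assert cell(t, rcc="1-1-1/2", group="single-rooted")["percent"] == 14.3
    assert cell(t, rcc="1-2-1/1", group="single-rooted")["percent"] == 4.1
    assert cell(t, rcc="1-1-1/3", group="single-rooted")["percent"] == 1.0
    assert cell(t, rcc="1-1-1/1", root="buccal")["n"] == 2
    assert cell(t, rcc="1-2-1/1", root="buccal")["percent"] == 33.3


def test_foramen_count_table_reproduces_reference_cells(summary):
    t = summary.foramen_counts
    assert cell(t, frequency=1)["1R-Ph_n"] == 79
    assert cell(t, frequency=1)["1R-Ph_pct"] == 80.6
    assert cell(t, frequency=2)["1R-Ph_pct"] == 16.3
    assert cell(t, frequency=3)["1R-Ph_pct"] == 1.0
    assert cell(t, frequency=4)["1R-Ph_pct"] == 2.0
    assert cell(t, frequency=0)["1R-Ac_n"] == 85     # 98 - 13 with accessory canals
    assert cell(t, frequency=1)["2R-Ph/B_pct"] == 100.0


def test_canal_location_table_reproduces_reference_cells(summary):
    t = summary.canal_locations
    single = t[t.group == "single-rooted"]
    assert cell(single, feature="accessory", location="middle")["n"] == 7
    assert cell(single, feature="accessory", location="middle")["percent"] == 6.9
    assert cell(single, feature="accessory", location="apical")["percent"] == 5.9
    assert cell(single, feature="accessory", location="coronal")["n"] == 0
    assert cell(single, feature="connecting", location="none")["percent"] == 98.0
    assert cell(single, feature="connecting", type="L")["n"] == 1
    assert cell(single, feature="connecting", type="C")["n"] == 1


def test_shape_table_reproduces_reference_cells(summary):
    t = summary.shapes
    one = cell(t, foramina=1)
    assert one["n"] == 79
    assert one["oval_n"] == 72 and one["oval_pct"] == 91.1
    assert one["round_n"] == 6 and one["round_pct"] == 7.6
    assert one["irregular_n"] == 1 and one["irregular_pct"] == 1.3
    assert cell(t, foramina=2)["oval_pct"] == 100.0


def test_metrology_table_against_brute_force_statistics(summary):
    row = cell(summary.metrology, foramina=1)
    assert row["W_mean"] == 0.40 and row["N_mean"] == 0.28 and row["D_mean"] == 0.45
    assert row["MAF"] == "45/50"
    # independent recomputation over random cohorts
    rng = np.random.default_rng(5)
    values = rng.uniform(0.2, 0.9, size=25)
    records = [make_record(f"r{i}", {"single": "1-1-1/1"},
                           [make_foramen(W=w, N=w * 0.7, D=w * 0.5)])
               for i, w in enumerate(values)]
    table = tabulate_cohort(records).metrology
    row = table[table.foramina == 1].iloc[0]
    assert row["W_mean"] == round_half_up(float(np.mean(values)), 2)
    assert row["W_sd"] == round_half_up(float(np.std(values, ddof=1)), 2)
    assert row["W_max"] == round_half_up(float(np.max(values)), 2)
    assert row["W_min"] == round_half_up(float(np.min(values)), 2)


def test_singleton_stratum_statistics():
    records = [make_record("only", {"single": "1-1-1/1"}, [make_foramen(W=0.33)])]
    row = tabulate_cohort(records).metrology.iloc[0]
    assert row["W_mean"] == row["W_max"] == row["W_min"] == 0.33
    assert row["W_sd"] == 0.0


def test_percentages_sum_to_100_within_rounding(summary):
    pct = summary.rcc[summary.rcc.group == "single-rooted"]["percent"].sum()
    assert abs(pct - 100.0) <= 0.2


def test_empty_cohort_rejected():
    with pytest.raises(ValueError):
        tabulate_cohort([])


def test_round_half_up_is_not_bankers():
    assert round_half_up(74.45, 1) == 74.5
    assert round_half_up(2.05, 1) == 2.1
    assert round_half_up(0.125, 2) == 0.13


def test_maf_policies():
    label, flags = recommend_maf(1, 0.40)
    assert label == "45/50" and "HEURISTIC" in flags
    assert recommend_maf(3, 0.32)[0] == "40"
    # ISO ceiling: strictly greater than the mean wide diameter
    assert recommend_maf(1, 0.40, policy="iso-ceiling")[0] == "45"
    assert recommend_maf(1, 0.32, policy="iso-ceiling")[0] == "35"
    label, flags = recommend_maf(2, None, policy="iso-ceiling")
    assert label == "" and flags
    with pytest.raises(ValueError):
        recommend_maf(1, 0.4, policy="nope")
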