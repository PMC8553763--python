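"""Cohort-level tabulation of per-tooth reports.

Produces the five standard summary tables of a root-canal-configuration
study:

1. RCC frequency (single-rooted; two-rooted per root), absolute n and
   relative % of the group;
2. physiological foramen and accessory canal count frequencies, by root
   group;
3. accessory/connecting canal locations by root third, with L/C typing;
4. foramen metrology per foramen-count stratum: mean, SD (sample, n-1),
   max, min of the wide (W) and narrow (N) diameters and the
   physiological-to-anatomical distance (D), plus a master-apical-file (MAF)
   recommendation;
5. foramen shape distribution per foramen-count stratum.

Percentage denominators follow the conventions of the printed literature
tables this layout mirrors (logged per table in the metadata): RCC and
foramen-count tables use the size of the root group; accessory locations use
the whole cohort.  Percentages are printed half-up to one decimal, lengths
to two decimals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .pipeline import ToothReport

__all__ = [
    "CohortSummary",
    "tabulate_cohort",
    "recommend_maf",
    "MAF_POLICIES",
    "round_half_up",
]

ISO_SIZES = (6, 8, 10, 15, 20, 25, 30, 35, 40, 45, 50, 55, 60, 70, 80, 90, 100, 110, 120, 130, 140)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (what printed tables use), not banker's."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _pct(n: int, denom: int) -> float:
    return round_half_up(100.0 * n / denom, 1) if denom else float("nan")


# -- MAF policies ----------------------------------------------------------

def _maf_table_lookup(stratum: int, mean_wide_mm: float | None) -> str:
    """Documented lookup keyed by foramen count (HEURISTIC: the derivation of
    the published pairs is not stated, so they are reproduced, not derived)."""
    table = {1: "45/50", 2: "40/45", 3: "40", 4: "40"}
    return table.get(stratum, "40")


def _maf_iso_ceiling(stratum: int, mean_wide_mm: float | None) -> str:
    """Smallest ISO size strictly greater than the mean wide diameter
    (ISO size = tip diameter in hundredths of a mm)."""
    if mean_wide_mm is None or not np.isfinite(mean_wide_mm):
        return ""
    hundredths = mean_wide_mm * 100.0
    for size in ISO_SIZES:
        if size > hundredths + 1e-9:
            return str(size)
    return str(ISO_SIZES[-1])


MAF_POLICIES = {
    "table-lookup": _maf_table_lookup,
    "iso-ceiling": _maf_iso_ceiling,
}


def recommend_maf(
    stratum: int, mean_wide_mm: float | None, policy: str = "table-lookup"
) -> tuple[str, list[str]]:
    """MAF (ISO tip size) label for a metrology stratum, with flags."""
    flags = []
    if mean_wide_mm is None or not np.isfinite(mean_wide_mm):
        flags.append("no-wide-diameter-mean")
        if policy != "table-lookup":
            return "", flags
    if policy == "table-lookup":
        flags.append("HEURISTIC")
    try:
        label = MAF_POLICIES[policy](stratum, mean_wide_mm)
    except KeyError:
        raise ValueError(f"unknown MAF policy {policy!r}") from None
    return label, flags


# -- cohort summary --------------------------------------------------------

@dataclass
class CohortSummary:
    rcc: pd.DataFrame
    foramen_counts: pd.DataFrame
    canal_locations: pd.DataFrame
    metrology: pd.DataFrame
    shapes: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "rcc": self.rcc,
            "foramen_counts": self.foramen_counts,
            "canal_locations": self.canal_locations,
            "metrology": self.metrology,
            "shapes": self.shapes,
        }

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables().items():
            table.to_csv(directory / f"table_{name}.csv", index=False)
            table.to_json(directory / f"table_{name}.json", orient="records", indent=1)
        (directory / "tables_meta.json").write_text(json.dumps(self.meta, indent=1))


def _single_and_two_rooted(records: list[ToothReport]):
    singles = [r for r in records if r.root_count == 1]
    twos = [r for r in records if r.root_count == 2]
    return singles, twos


def tabulate_cohort(records: list[ToothReport], maf_policy: str = "table-lookup") -> CohortSummary:
    """Aggregate per-tooth reports into the five summary tables."""
    if not records:
        raise ValueError("empty cohort: nothing to tabulate")
    singles, twos = _single_and_two_rooted(records)
    n_total, n_single, n_two = len(records), len(singles), len(twos)
    meta = {
        "n_total": n_total,
        "n_single_rooted": n_single,
        "n_two_rooted": n_two,
        "denominators": {
            "rcc_single": n_single,
            "rcc_two_rooted": n_two,
            "accessory_locations": n_total,
            "connecting_single": n_single,
            "foramen_counts": "per root group",
        },
        "percent_convention": "per-tooth, half-up to one decimal",
        "maf_policy": maf_policy,
    }

    # ---- table 1: RCC frequencies ---------------------------------------
    rows = []
    codes_single = [r.codes["single"] for r in singles]
    for code in sorted(set(codes_single)):
        n = codes_single.count(code)
        rows.append({"group": "single-rooted", "root": "single", "rcc": code,
                     "n": n, "percent": _pct(n, n_single)})
    for label in ("buccal", "lingual"):
        codes_two = [r.codes.get(label) for r in twos if label in r.codes]
        for code in sorted(set(codes_two)):
            n = codes_two.count(code)
            rows.append({"group": "two-rooted", "root": label, "rcc": code,
                         "n": n, "percent": _pct(n, n_two)})
    rcc_table = pd.DataFrame(rows, columns=["group", "root", "rcc", "n", "percent"])

    # ---- table 2: foramen / accessory canal count frequencies -----------
    def count_hist(values: list[int]) -> dict[int, int]:
        hist: dict[int, int] = {}
        for v in values:
            hist[v] = hist.get(v, 0) + 1
        return hist

    rows = []
    col_defs: list[tuple[str, list[int], int]] = [
        ("1R-Ph", [r.n_physiological["single"] for r in singles], n_single),
        ("1R-Ac", [sum(a["n_foramina"] for a in r.accessory_canals) for r in singles],
         n_single),
        ("2R-Ph/B", [r.n_physiological.get("buccal", 0) for r in twos], n_two),
        ("2R-Ph/L", [r.n_physiological.get("lingual", 0) for r in twos], n_two),
        ("2R-Ac/B", [sum(a["n_foramina"] for a in r.accessory_canals
                         if a.get("root") == "buccal") for r in twos], n_two),
        ("2R-Ac/L", [sum(a["n_foramina"] for a in r.accessory_canals
                         if a.get("root") == "lingual") for r in twos], n_two),
    ]
    freqs = sorted({v for _, vals, _ in col_defs for v in vals} | {0, 1})
    for f_ in freqs:
        row = {"frequency": f_}
        for name, vals, denom in col_defs:
            n = vals.count(f_)
            row[f"{name}_n"] = n
            row[f"{name}_pct"] = _pct(n, denom) if denom else float("nan")
        rows.append(row)
    foramen_counts = pd.DataFrame(rows)

    # ---- table 3: accessory / connecting canal locations ----------------
    rows = []
    for group, group_records in (("single-rooted", singles), ("two-rooted", twos)):
        acc_thirds = [a["third"] for r in group_records for a in r.accessory_canals]
        none_n = sum(1 for r in group_records if not r.accessory_canals)
        rows.append({"group": group, "feature": "accessory", "location": "none",
                     "type": "", "n": none_n, "percent": _pct(none_n, n_total)})
        for third in ("coronal", "middle", "apical"):
            n = acc_thirds.count(third)
            rows.append({"group": group, "feature": "accessory", "location": third,
                         "type": "", "n": n, "percent": _pct(n, n_total)})
        con_none = sum(1 for r in group_records if not r.connecting_canals)
        denom_con = len(group_records) or 1
        rows.append({"group": group, "feature": "connecting", "location": "none",
                     "type": "", "n": con_none, "percent": _pct(con_none, denom_con)})
        con = [(c["third"], c["type"], r.codes[next(iter(r.codes))])
               for r in group_records for c in r.connecting_canals]
        for third, ctype, code in sorted(set(con)):
            n = con.count((third, ctype, code))
            rows.append({"group": group, "feature": "connecting", "location": third,
                         "type": ctype, "n": n, "percent": _pct(n, n_total)})
    canal_locations = pd.DataFrame(rows)

    # ---- tables 4 + 5: metrology and shape per foramen-count stratum ----
    met_rows, shape_rows = [], []
    strata: dict[int, list[dict]] = {}
    for r in singles:
        n_ph = r.n_physiological["single"]
        if n_ph >= 1:
            phys = [f_ for f_ in r.foramina if f_["class"] == "physiological"]
            strata.setdefault(n_ph, []).extend(phys)
    for stratum in sorted(strata):
        phys = strata[stratum]
        n_teeth = sum(
            1 for r in singles if r.n_physiological["single"] == stratum
        )
        stats = {}
        for key, col in (("W", "W_mm"), ("N", "N_mm"), ("D", "D_mm")):
            vals = np.array([f_[col] for f_ in phys], dtype=float)
            vals = vals[np.isfinite(vals)]
            stats[key] = vals
        mean_w = float(np.mean(stats["W"])) if stats["W"].size else None
        maf, maf_flags = recommend_maf(stratum, mean_w, maf_policy)
        row = {"foramina": stratum, "n_teeth": n_teeth, "MAF": maf,
               "flags": ";".join(maf_flags)}
        for key in ("W", "N", "D"):
            vals = stats[key]
            if vals.size:
                row[f"{key}_mean"] = round_half_up(float(np.mean(vals)), 2)
                row[f"{key}_sd"] = round_half_up(float(np.std(vals, ddof=1)), 2) if vals.size > 1 else 0.0
                row[f"{key}_max"] = round_half_up(float(np.max(vals)), 2)
                row[f"{key}_min"] = round_half_up(float(np.min(vals)), 2)
            else:
                row.update({f"{key}_mean": None, f"{key}_sd": None,
                            f"{key}_max": None, f"{key}_min": None})
        met_rows.append(row)

        shapes = [f_["shape"] for f_ in phys if f_["shape"]]
        denom = len(shapes) or 1
        srow = {"foramina": stratum, "n": len(shapes)}
        for shape in ("oval", "round", "irregular"):
            n = shapes.count(shape)
            srow[f"{shape}_n"] = n
            srow[f"{shape}_pct"] = _pct(n, denom)
        shape_rows.append(srow)

    metrology = pd.DataFrame(met_rows)
    shapes_table = pd.DataFrame(shape_rows)

    return CohortSummary(
        rcc=rcc_table,
        foramen_counts=foramen_counts,
        canal_locations=canal_locations,
        metrology=metrology,
        shapes=shapes_table,
        meta=meta,
    )
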