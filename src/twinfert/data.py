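"""Parish-register data handling: per-child records to analysis tables.

The raw unit is one child: population, maternal identity, the mother's birth
year/month, and the child's birth year/month (day optional).  From these the
module identifies multiple births (twins/triplets), applies the family-wise
selection filters of the study design, and derives the two analysis tables:

* birth level — one row per delivery, with maternal age in months, parity,
  twin status, parity progression (PP: a later birth exists) and the
  interbirth interval to the next birth (IBI, months; absent for the last
  birth of each mother);
* mother level — one row per mother, with total births, twin and singleton
  birth counts, lifetime twinner status, and age at first birth (AFB,
  months).

Twins are identified by date proximity: exact dates no more than one day
apart, or, when days are unrecorded, an identical birth year and month.  A
delivery of more than three children is treated as a data error.  Selection
is family-wise: a mother is kept only if her own birth month is known, her
life course is traced to at least age 45, all her children's birth months are
known, and all consecutive deliveries are at least nine months apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_COLUMN_MAP",
    "read_children",
    "identify_twin_births",
    "apply_selection_filters",
    "derive_tables",
    "summarize_populations",
    "Dataset",
]

DEFAULT_COLUMN_MAP = {
    "population_id": "population_id",
    "maternal_id": "maternal_id",
    "maternal_birth_year": "maternal_birth_year",
    "maternal_birth_month": "maternal_birth_month",
    "child_birth_year": "child_birth_year",
    "child_birth_month": "child_birth_month",
    "child_birth_day": "child_birth_day",
    "followup_to_45": "followup_to_45",
}

_MANDATORY = ["population_id", "maternal_id", "maternal_birth_year",
              "maternal_birth_month", "child_birth_year"]

MIN_IBI_MONTHS = 9
FOLLOWUP_AGE_YEARS = 45
MAX_MULTIPLE = 3


class FormatError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclass
class Dataset:
    """Filtered dataset: derived tables plus the exclusion log."""

    births: pd.DataFrame
    mothers: pd.DataFrame
    exclusions: pd.DataFrame

    def check_invariants(self):
        b, m = self.births, self.mothers
        if not (m["twin_total"] + m["singleton_total"]).equals(m["births_total"]):
            raise DataError("twin_total + singleton_total != births_total")
        if len(b) != int(m["births_total"].sum()):
            raise DataError("birth rows != sum of births_total")
        n_ibi = int(b["IBI_months"].notna().sum())
        if n_ibi != len(b) - len(m):
            raise DataError("IBI-present rows != birth rows - mothers")
        last = b.groupby("maternal_id")["PP"].apply(lambda s: (s == 0).sum())
        if not (last == 1).all():
            raise DataError("each mother must have exactly one terminal birth")
        return True


def read_children(path, column_map=None) -> pd.DataFrame:
    """Read a per-child CSV into the canonical children table.

    ``column_map`` maps canonical names to the file's column names (see
    ``DEFAULT_COLUMN_MAP``).  Missing birth months are retained as <NA> and
    flagged (they are handled at filtering, not at parsing); a missing
    mandatory column raises :class:`FormatError`, an unparseable date raises
    :class:`DataError` naming the row.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path) if not isinstance(path, pd.DataFrame) else path.copy()

    for key in _MANDATORY:
        if cmap[key] not in raw.columns:
            raise FormatError(f"missing mandatory column {cmap[key]!r}")

    out = pd.DataFrame({
        "population_id": raw[cmap["population_id"]].astype(str),
        "maternal_id": raw[cmap["maternal_id"]].astype(str),
    })
    for key in ("maternal_birth_year", "maternal_birth_month",
                "child_birth_year", "child_birth_month", "child_birth_day"):
        col = cmap[key]
        if col in raw.columns:
            vals = pd.to_numeric(raw[col], errors="coerce")
            bad = vals.isna() & raw[col].notna() & (raw[col].astype(str).str.strip() != "")
            if bad.any():
                raise DataError(f"unparseable value in {col!r} at row "
                                f"{int(np.flatnonzero(bad)[0])}")
            out[key] = vals.astype("Int64")
        else:
            out[key] = pd.array([pd.NA] * len(raw), dtype="Int64")
    for key in ("maternal_birth_year", "child_birth_year"):
        if out[key].isna().any():
            raise DataError(f"missing {key} in some rows")

    fcol = cmap["followup_to_45"]
    if fcol in raw.columns:
        out["followup_to_45"] = raw[fcol].astype(bool)
    else:
        out["followup_to_45"] = True

    out["month_known"] = out["child_birth_month"].notna()
    order_month = out["child_birth_month"].fillna(1)
    order_day = out["child_birth_day"].fillna(15)
    out = (out.assign(_m=order_month, _d=order_day)
              .sort_values(["population_id", "maternal_id",
                            "child_birth_year", "_m", "_d"],
                           kind="mergesort")
              .drop(columns=["_m", "_d"])
              .reset_index(drop=True))
    return out


def write_children(children: pd.DataFrame, path):
    children.drop(columns=["month_known"], errors="ignore").to_csv(path, index=False)


def _age_months(row_year, row_month, mat_year, mat_month):
    return (row_year - mat_year) * 12 + (row_month - mat_month)


def identify_twin_births(children: pd.DataFrame) -> pd.DataFrame:
    """Merge same-delivery children into birth events.

    Children of one mother belong to the same delivery when their exact
    dates differ by at most one day or, if any day is unrecorded, their birth
    year and month coincide.  A group larger than three children raises
    :class:`DataError`.  Returns one row per birth event with ``n_offspring``
    and ``twin`` (n_offspring >= 2).
    """
    events = []
    for (pop, mid), grp in children.groupby(["population_id", "maternal_id"],
                                            sort=True):
        grp = grp.reset_index(drop=True)
        cur = None  # (year, month, day, count, month_known)
        rows = []
        for _, ch in grp.iterrows():
            y = int(ch["child_birth_year"])
            mo = int(ch["child_birth_month"]) if pd.notna(ch["child_birth_month"]) else None
            d = int(ch["child_birth_day"]) if pd.notna(ch["child_birth_day"]) else None
            if cur is not None and _same_delivery(cur, (y, mo, d)):
                cur["count"] += 1
            else:
                if cur is not None:
                    rows.append(cur)
                cur = {"year": y, "month": mo, "day": d, "count": 1}
            if cur["count"] > MAX_MULTIPLE:
                raise DataError(
                    f"mother {mid}: more than {MAX_MULTIPLE} children in one "
                    "delivery")
        if cur is not None:
            rows.append(cur)

        mat_y = int(grp["maternal_birth_year"].iloc[0])
        mat_m = (int(grp["maternal_birth_month"].iloc[0])
                 if pd.notna(grp["maternal_birth_month"].iloc[0]) else None)
        followup = bool(grp["followup_to_45"].all())
        for k, ev in enumerate(rows):
            if ev["month"] is not None and mat_m is not None:
                age = _age_months(ev["year"], ev["month"], mat_y, mat_m)
            else:
                age = None
            events.append({
                "population_id": pop, "maternal_id": mid,
                "year": ev["year"], "month": ev["month"], "day": ev["day"],
                "parity": k + 1, "n_offspring": ev["count"],
                "twin": ev["count"] >= 2, "age_months": age,
                "followup_to_45": followup,
                "maternal_month_known": mat_m is not None,
            })
    ev = pd.DataFrame(events)
    if len(ev):
        ev["age_months"] = ev["age_months"].astype("Int64")
    return ev


def _same_delivery(cur, nxt):
    y, mo, d = nxt
    if cur["year"] != y:
        # Dec 31 / Jan 1 adjacency with exact dates
        if cur["day"] is not None and d is not None and cur["month"] is not None \
                and mo is not None:
            return abs(_to_ordinal(cur) - _to_ordinal({"year": y, "month": mo,
                                                       "day": d})) <= 1
        return False
    if cur["month"] is None or mo is None:
        return False
    if cur["day"] is None or d is None:
        return cur["month"] == mo
    return abs(_to_ordinal(cur) - _to_ordinal({"year": y, "month": mo, "day": d})) <= 1


def _to_ordinal(ev):
    import calendar
    import datetime
    last = calendar.monthrange(ev["year"], ev["month"])[1]
    return datetime.date(ev["year"], ev["month"],
                         min(ev["day"], last)).toordinal()


def apply_selection_filters(events: pd.DataFrame):
    """Family-wise selection: returns ``(kept_events, exclusion_log)``.

    A mother is dropped entirely if any criterion fails: her own birth month
    unknown, not followed to age 45, any child's birth month unknown, or any
    consecutive interbirth gap below nine months.  The log records one row
    per excluded mother with the first failing reason.
    """
    kept, log = [], []
    for mid, grp in events.groupby("maternal_id", sort=True):
        reason = None
        if not grp["maternal_month_known"].all():
            reason = "maternal_birth_month_unknown"
        elif not grp["followup_to_45"].all():
            reason = "not_traced_to_45"
        elif grp["month"].isna().any():
            reason = "child_birth_month_unknown"
        else:
            ages = grp.sort_values("parity")["age_months"].to_numpy(dtype=float)
            gaps = np.diff(ages)
            if len(gaps) and (gaps < MIN_IBI_MONTHS).any():
                reason = "interbirth_gap_below_9_months"
        if reason is None:
            kept.append(grp)
        else:
            log.append({"maternal_id": mid,
                        "population_id": grp["population_id"].iloc[0],
                        "reason": reason, "n_births": len(grp)})
    kept_df = (pd.concat(kept, ignore_index=True) if kept
               else events.iloc[0:0].copy())
    log_df = pd.DataFrame(log, columns=["maternal_id", "population_id",
                                        "reason", "n_births"])
    return kept_df, log_df


def derive_tables(events: pd.DataFrame) -> Dataset:
    """Build birth-level and mother-level tables from filtered events."""
    ev = events.sort_values(["population_id", "maternal_id", "parity"]).copy()
    grp = ev.groupby("maternal_id", sort=False)
    ev["births_total"] = grp["parity"].transform("max")
    ev["PP"] = (ev["parity"] < ev["births_total"]).astype(int)
    age = ev["age_months"].astype(float)
    nxt = grp["age_months"].shift(-1).astype(float)
    ev["IBI_months"] = nxt - age

    births = ev[["maternal_id", "population_id", "age_months", "parity",
                 "n_offspring", "twin", "PP", "IBI_months"]].copy()
    births["twin"] = births["twin"].astype(int)
    births["age_months"] = births["age_months"].astype(float)

    mothers = (ev.groupby(["maternal_id", "population_id"], sort=True)
               .agg(births_total=("parity", "max"),
                    twin_total=("twin", "sum"),
                    AFB_months=("age_months", "min"))
               .reset_index())
    mothers["twin_total"] = mothers["twin_total"].astype(int)
    mothers["singleton_total"] = mothers["births_total"] - mothers["twin_total"]
    mothers["twinner"] = (mothers["twin_total"] >= 1).astype(int)
    mothers["AFB_months"] = mothers["AFB_months"].astype(float)

    excl = pd.DataFrame(columns=["maternal_id", "population_id", "reason",
                                 "n_births"])
    ds = Dataset(births=births.reset_index(drop=True), mothers=mothers,
                 exclusions=excl)
    ds.check_invariants()
    return ds


def summarize_populations(dataset: Dataset) -> pd.DataFrame:
    """Per-population and pooled summary: mother and birth counts, twinner
    and twinning rates in permille (2 decimals), births min/median/max."""
    rows = []
    m, b = dataset.mothers, dataset.births
    pops = sorted(m["population_id"].unique())
    for pop in pops + ["all"]:
        mm = m if pop == "all" else m[m["population_id"] == pop]
        bb = b if pop == "all" else b[b["population_id"] == pop]
        if len(mm) == 0:
            import warnings
            warnings.warn(f"population {pop!r} empty; omitted")
            continue
        rows.append({
            "population_id": pop,
            "n_mothers": len(mm),
            "n_twinners": int(mm["twinner"].sum()),
            "twinner_rate_permille": round(1000 * mm["twinner"].mean(), 2),
            "n_births": len(bb),
            "n_twin_births": int(bb["twin"].sum()),
            "twinning_rate_permille": round(1000 * bb["twin"].mean(), 2),
            "births_min": int(mm["births_total"].min()),
            "births_median": float(mm["births_total"].median()),
            "births_max": int(mm["births_total"].max()),
        })
    return pd.DataFrame(rows)


def load_and_prepare(path, column_map=None):
    """Full ingestion pipeline: read, identify twins, filter, derive tables.

    Returns a :class:`Dataset` whose ``exclusions`` carries the filter log so
    the selection is auditable.
    """
    children = read_children(path, column_map)
    events = identify_twin_births(children)
    kept, log = apply_selection_filters(events)
    if len(kept) == 0:
        raise DataError("no families survived the selection filters")
    ds = derive_tables(kept)
    ds.exclusions = log
    return ds
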