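"""Contribution ledger lambda_E * E and its aggregations.

The contribution of each (species, detailed sector, month, fine cell) entry is
the first-order product of the adjoint sensitivity (deaths per kg) and the
emitted mass (kg); marginals over species, sectors, countries and months all
close on the same anthropogenic total, which is the bookkeeping every share
and ranking below relies on.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .adjoint import SensitivityField
from .grids import CountryMask, EmissionInventory, GridError
from .report import round_half_up

DJF = (12, 1, 2)
JJA = (6, 7, 8)
SEASONS = {"DJF": DJF, "JJA": JJA, "MAM": (3, 4, 5), "SON": (9, 10, 11)}

GROUPINGS = ("species", "main_sector", "detailed_sector", "country", "month",
             "country_x_sector", "sector_x_species")


class AttributionError(ValueError):
    pass


@dataclasses.dataclass
class ContributionLedger:
    """Deaths contributed per (species, detailed sector, month, fine cell)."""

    inventory: EmissionInventory
    data: dict[tuple[str, str], np.ndarray]     # (species, sector) -> (12, nlat, nlon)
    signed: bool = False                        # True for difference ledgers

    def __post_init__(self) -> None:
        for key, arr in self.data.items():
            if arr.shape != (12,) + self.inventory.grid.shape:
                raise AttributionError(f"ledger entry {key} has shape {arr.shape}")
        if not self.signed:
            for key, arr in self.data.items():
                if np.any(arr < 0):
                    raise AttributionError(f"negative contribution in {key}")

    @property
    def grid(self):
        return self.inventory.grid

    @property
    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))

    # -- marginals -----------------------------------------------------------
    def by_species(self) -> pd.Series:
        out: dict[str, float] = {sp: 0.0 for sp in self.inventory.species}
        for (sp, _), arr in self.data.items():
            out[sp] += float(arr.sum())
        return pd.Series(out)

    def by_detailed_sector(self) -> pd.Series:
        out: dict[str, float] = {sec: 0.0 for sec in self.inventory.sectors}
        for (_, sec), arr in self.data.items():
            out[sec] += float(arr.sum())
        return pd.Series(out)

    def by_main_sector(self) -> pd.Series:
        det = self.by_detailed_sector()
        mains = sorted(set(self.inventory.sector_to_main.values()))
        out = {m: 0.0 for m in mains}
        for sec, v in det.items():
            out[self.inventory.sector_to_main[sec]] += v
        return pd.Series(out)

    def by_month(self) -> pd.Series:
        tot = np.zeros(12)
        for arr in self.data.values():
            tot += arr.sum(axis=(1, 2))
        return pd.Series(tot, index=np.arange(1, 13))

    def by_country(self, mask: CountryMask) -> pd.Series:
        if not mask.grid.equals(self.grid):
            raise GridError("mask grid does not match the ledger grid")
        percell = self.per_cell()
        ids = mask.ids.ravel()
        agg = np.bincount(ids, weights=percell.ravel(), minlength=int(ids.max()) + 1)
        index = [mask.name_of(int(cid)) for cid in range(len(agg))
                 if (agg[cid] != 0 or cid in mask.country_ids or cid == 0)]
        values = [agg[cid] for cid in range(len(agg))
                  if (agg[cid] != 0 or cid in mask.country_ids or cid == 0)]
        return pd.Series(values, index=index)

    def per_cell(self, species: str | None = None, sector: str | None = None) -> np.ndarray:
        """Deaths contributed by each source cell (summed over months)."""
        out = np.zeros(self.grid.shape)
        for (sp, sec), arr in self.data.items():
            if species is not None and sp != species:
                continue
            if sector is not None and sec != sector:
                continue
            out += arr.sum(axis=0)
        return out


def compute_contributions(lam: SensitivityField, inv: EmissionInventory,
                          renormalize_to: float | None = None) -> ContributionLedger:
    """ledger[s, k, m, i] = lambda[s, m, i] * E[s, k, m, i].

    The sensitivity must already live on the inventory's (fine) grid -- use
    ``SensitivityField.to_fine``; replication, not pattern scaling, because
    sensitivity is intensive.  ``renormalize_to`` optionally rescales the whole
    ledger so its total equals a given J (off by default).
    """
    if not lam.grid.equals(inv.grid):
        raise GridError("sensitivity grid does not match the inventory grid "
                        "(disaggregate with to_fine first)")
    missing = set(sp for sp, _ in inv.data) - set(lam.species)
    if missing:
        raise AttributionError(f"sensitivity lacks species {sorted(missing)}")
    data = {
        (sp, sec): lam.values[sp] * arr
        for (sp, sec), arr in inv.data.items()
    }
    ledger = ContributionLedger(inv, data)
    if renormalize_to is not None and ledger.total > 0:
        f = renormalize_to / ledger.total
        ledger = ContributionLedger(inv, {k: v * f for k, v in ledger.data.items()})
    return ledger


def aggregate_ledger(ledger: ContributionLedger, by: str,
                     mask: CountryMask | None = None) -> pd.DataFrame:
    """Group sums with percentage shares of the anthropogenic total, ranked in
    descending order (ties broken by label)."""
    if by not in GROUPINGS:
        raise AttributionError(f"unknown grouping {by!r}; use one of {GROUPINGS}")
    if by == "species":
        ser = ledger.by_species()
    elif by == "main_sector":
        ser = ledger.by_main_sector()
    elif by == "detailed_sector":
        ser = ledger.by_detailed_sector()
    elif by == "month":
        ser = ledger.by_month()
    elif by == "country":
        if mask is None:
            raise AttributionError("country grouping needs a mask")
        ser = ledger.by_country(mask)
    elif by == "country_x_sector":
        if mask is None:
            raise AttributionError("country grouping needs a mask")
        rows = {}
        for sec in ledger.inventory.sectors:
            sub = ContributionLedger(ledger.inventory,
                                     {k: v for k, v in ledger.data.items() if k[1] == sec},
                                     signed=ledger.signed)
            for country, v in sub.by_country(mask).items():
                rows[(country, sec)] = rows.get((country, sec), 0.0) + v
        ser = pd.Series(rows)
    else:  # sector_x_species
        rows = {}
        for (sp, sec), arr in ledger.data.items():
            key = (ledger.inventory.sector_to_main[sec], sp)
            rows[key] = rows.get(key, 0.0) + float(arr.sum())
        ser = pd.Series(rows)
    total = ledger.total
    df = ser.rename("deaths").to_frame().reset_index()
    if df.shape[1] == 2:
        df.columns = [by, "deaths"]
        sort_labels = df[by].astype(str)
    else:
        sort_labels = df.iloc[:, 0].astype(str) + "|" + df.iloc[:, 1].astype(str)
    df["share_pct"] = 100.0 * df["deaths"] / total if total != 0 else np.nan
    df["share_str"] = [f"{round_half_up(s, 1)}%" if np.isfinite(s) else ""
                       for s in df["share_pct"]]
    df = (df.assign(_lbl=sort_labels.values)
            .sort_values(["deaths", "_lbl"], ascending=[False, True])
            .drop(columns="_lbl").reset_index(drop=True))
    return df


def monthly_shares(ledger: ContributionLedger, by: str = "species",
                   mask: CountryMask | None = None) -> pd.DataFrame:
    """Per-month category fractions of that month's anthropogenic total.

    Rows are months 1..12; a month with zero total gets NaN fractions.
    """
    if by == "species":
        cats = {sp: np.zeros(12) for sp in ledger.inventory.species}
        for (sp, _), arr in ledger.data.items():
            cats[sp] += arr.sum(axis=(1, 2))
    elif by == "main_sector":
        mains = sorted(set(ledger.inventory.sector_to_main.values()))
        cats = {mname: np.zeros(12) for mname in mains}
        for (_, sec), arr in ledger.data.items():
            cats[ledger.inventory.sector_to_main[sec]] += arr.sum(axis=(1, 2))
    elif by == "detailed_sector":
        cats = {sec: np.zeros(12) for sec in ledger.inventory.sectors}
        for (_, sec), arr in ledger.data.items():
            cats[sec] += arr.sum(axis=(1, 2))
    else:
        raise AttributionError(f"unsupported monthly grouping {by!r}")
    df = pd.DataFrame(cats, index=np.arange(1, 13))
    totals = df.sum(axis=1)
    out = df.divide(totals, axis=0)
    out[totals == 0] = np.nan
    return out


def seasonal_ratio(ledger: ContributionLedger, season_a: str = "DJF",
                   season_b: str = "JJA", species: str | None = None,
                   sector: str | None = None, main_sector: str | None = None) -> float:
    """Ratio of summed contributions in season_a vs season_b for a category
    (winter DJF = Dec/Jan/Feb, summer JJA = Jun/Jul/Aug)."""
    months = np.zeros(12)
    for (sp, sec), arr in ledger.data.items():
        if species is not None and sp != species:
            continue
        if sector is not None and sec != sector:
            continue
        if main_sector is not None and ledger.inventory.sector_to_main[sec] != main_sector:
            continue
        months += arr.sum(axis=(1, 2))
    a = sum(months[m - 1] for m in SEASONS[season_a])
    b = sum(months[m - 1] for m in SEASONS[season_b])
    if b == 0:
        raise AttributionError(f"zero {season_b} total; seasonal ratio undefined")
    return float(a / b)
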