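"""Cost updating across years and countries (the medical basket approach).

A cost observed in a source country and year is moved to target-country
euros of a target year in two steps:

1. **inflate** within the source economy with its consumer price index
   (CPI), then
2. **convert** between economies with purchasing-power-parity (PPP)
   factors for the *hospital services* basket, which equalise the price of
   a fixed bundle of hospital care across countries.

Formally, with the default ``inflate_first`` order::

    updated = amount * CPI_src[target_year] / CPI_src[source_year]
                     * PPP_tgt[target_year] / PPP_src[target_year]

The reverse order (convert at the source year with the hospital basket,
then inflate with the target country's CPI) is available as
``order="convert_first"``; the two differ whenever the PPP series moves
over time, and the choice is a documented modelling convention, not a fact
the method dictates.

Index tables are supplied by the user as CSV files with columns
``country, year, value``; missing (country, year) entries raise
:class:`~ocudelay.errors.IndexLookupError` and are never interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Union

import pandas as pd

from .errors import IndexLookupError

__all__ = ["PriceIndexTables", "update_cost"]

Key = tuple[str, int]


def _read_index_csv(path: Union[str, Path]) -> dict[Key, float]:
    df = pd.read_csv(path)
    required = {"country", "year", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(
            f"index table {path} lacks columns {sorted(missing)}; "
            "expected country, year, value"
        )
    return {
        (str(r.country), int(r.year)): float(r.value)
        for r in df.itertuples(index=False)
    }


@dataclass(frozen=True)
class PriceIndexTables:
    """CPI series and hospital-services PPP factors.

    ``cpi`` maps (country, year) to a dimensionless index level;
    ``ppp_hospital`` maps (country, year) to national currency units per
    reference unit for the hospital-services basket.  All values must be
    positive.
    """

    cpi: Mapping[Key, float] = field(default_factory=dict)
    ppp_hospital: Mapping[Key, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, table in (("cpi", self.cpi), ("ppp_hospital", self.ppp_hospital)):
            bad = {k: v for k, v in table.items() if not v > 0}
            if bad:
                raise ValueError(f"{label} index values must be > 0, got {bad}")

    @classmethod
    def from_csv(
        cls, cpi_path: Union[str, Path], ppp_path: Union[str, Path]
    ) -> "PriceIndexTables":
        """Read both tables from CSV files (columns country, year, value)."""
        return cls(cpi=_read_index_csv(cpi_path), ppp_hospital=_read_index_csv(ppp_path))

    def _lookup(self, series: str, country: str, year: int) -> float:
        table = self.cpi if series == "cpi" else self.ppp_hospital
        try:
            return table[(country, int(year))]
        except KeyError:
            raise IndexLookupError(
                f"no {series} entry for country '{country}', year {year}"
            ) from None


def update_cost(
    amount: float,
    source_country: str,
    source_year: int,
    tables: PriceIndexTables,
    target_country: str = "NLD",
    target_year: int = 2023,
    order: str = "inflate_first",
) -> float:
    """Update ``amount`` from source-country/source-year prices to
    target-country currency of the target year.

    ``amount`` may be negative (a saving).  ``order`` selects the
    convention: ``"inflate_first"`` (default; CPI within the source
    economy, then hospital-basket PPP at the target year) or
    ``"convert_first"`` (PPP at the source year, then the target
    country's CPI).
    """
    if order == "inflate_first":
        inflation = tables._lookup("cpi", source_country, target_year) / tables._lookup(
            "cpi", source_country, source_year
        )
        conversion = tables._lookup(
            "ppp_hospital", target_country, target_year
        ) / tables._lookup("ppp_hospital", source_country, target_year)
    elif order == "convert_first":
        conversion = tables._lookup(
            "ppp_hospital", target_country, source_year
        ) / tables._lookup("ppp_hospital", source_country, source_year)
        inflation = tables._lookup("cpi", target_country, target_year) / tables._lookup(
            "cpi", target_country, source_year
        )
    else:
        raise ValueError(
            f"order must be 'inflate_first' or 'convert_first', got {order!r}"
        )
    return amount * inflation * conversion
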