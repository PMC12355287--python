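"""Link area-level annual constituent panels to transplant recipients.

The exposure of record is the calendar-weighted moving average of each
PM2.5 constituent over the 12 months preceding transplantation.  For a
transplant in month ``m`` of year ``y`` the average puts weight ``m/12``
on the annual mean of year ``y`` and ``(12 - m)/12`` on year ``y - 1``
(a July transplant therefore weights the transplant year 7/12 and the
prior year 5/12).  Panels are annual means per (zip, year), so no
sub-annual information is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The 15 PM2.5 constituents, by conventional abbreviation.  EC, NH4, NO3,
#: OC and SO4 are reported in ug/m3; the ten trace constituents in ng/m3.
CONSTITUENTS = (
    "Br", "Ca", "Cu", "EC", "Fe", "K", "NH4", "Ni",
    "NO3", "OC", "Pb", "Si", "SO4", "V", "Zn",
)


class MissingExposureError(KeyError):
    """A required (zip, year) row is absent from the constituent panel."""

    def __init__(self, zip_code: str, year: int):
        self.zip = zip_code
        self.year = year
        super().__init__(f"no panel row for zip {zip_code!r}, year {year}")

    def __str__(self) -> str:  # KeyError quotes its arg; keep message readable
        return f"no panel row for zip {self.zip!r}, year {self.year}"


class PanelSchemaError(ValueError):
    """Panel rows do not share a single, complete constituent set."""


@dataclass
class ConstituentPanel:
    """Annual mean constituent concentrations per (zip, year).

    Parameters
    ----------
    data : pandas.DataFrame
        Columns ``zip`` (string, leading zeros preserved), ``year`` (int)
        and one numeric column per constituent.
    constituents : tuple of str
        Constituent column names, identical across all rows.
    """

    data: pd.DataFrame
    constituents: tuple[str, ...] = CONSTITUENTS
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in ("zip", "year", *self.constituents) if c not in df.columns]
        if missing:
            raise PanelSchemaError(f"panel is missing columns: {missing}")
        df = df.copy()
        df["zip"] = df["zip"].astype(str)
        df["year"] = df["year"].astype(int)
        levels = df[list(self.constituents)].to_numpy(dtype=float)
        if not np.all(np.isfinite(levels)) or (levels < 0).any():
            raise PanelSchemaError("constituent concentrations must be finite and >= 0")
        if df.duplicated(subset=["zip", "year"]).any():
            dup = df[df.duplicated(subset=["zip", "year"])].iloc[0]
            raise PanelSchemaError(
                f"duplicate panel row for zip {dup['zip']!r}, year {int(dup['year'])}"
            )
        self.data = df
        self._index = {
            (z, y): row
            for (z, y), row in zip(
                zip(df["zip"].to_numpy(), df["year"].to_numpy()), levels
            )
        }

    @classmethod
    def from_csv(cls, path, constituents: tuple[str, ...] = CONSTITUENTS) -> "ConstituentPanel":
        """Read a panel CSV with columns zip, year, then one per constituent."""
        df = pd.read_csv(path, dtype={"zip": str})
        return cls(df, constituents)

    def levels(self, zip_code: str, year: int) -> np.ndarray:
        """Annual mean vector for one (zip, year); raises MissingExposureError."""
        try:
            return self._index[(str(zip_code), int(year))]
        except KeyError:
            raise MissingExposureError(str(zip_code), int(year)) from None


def compute_moving_average(
    panel: ConstituentPanel, zip_code: str, tx_year: int, tx_month: int
) -> pd.Series:
    """Pre-transplant 1-year moving average of each constituent.

    Returns ``(m/12) * level(tx_year) + ((12-m)/12) * level(tx_year - 1)``
    with ``m = tx_month``, as a Series indexed by constituent.  The result
    is a convex combination, so it always lies between the two annual
    values it averages.
    """
    if not 1 <= tx_month <= 12:
        raise ValueError(f"tx_month must be in 1..12, got {tx_month}")
    w = tx_month / 12.0
    current = panel.levels(zip_code, tx_year)
    prior = panel.levels(zip_code, tx_year - 1)
    values = w * current + (1.0 - w) * prior
    return pd.Series(values, index=list(panel.constituents), name=str(zip_code))


def link_cohort(
    panel: ConstituentPanel,
    recipients: pd.DataFrame,
    policy: str = "drop",
    id_col: str = "id",
) -> pd.DataFrame:
    """Compute one exposure row per recipient by panel linkage.

    Parameters
    ----------
    recipients : DataFrame with columns ``id``, ``zip``, ``tx_year``, ``tx_month``.
    policy : "drop" logs and excludes recipients whose (zip, tx_year) or
        (zip, tx_year - 1) panel row is missing; "strict" raises on the first.

    Returns
    -------
    DataFrame indexed by recipient id with one column per constituent.
    """
    if policy not in ("drop", "strict"):
        raise ValueError(f"policy must be 'drop' or 'strict', got {policy!r}")
    rows, ids, n_dropped = [], [], 0
    for rec in recipients.itertuples(index=False):
        try:
            exp = compute_moving_average(
                panel, str(rec.zip), int(rec.tx_year), int(rec.tx_month)
            )
        except MissingExposureError as err:
            if policy == "strict":
                raise
            n_dropped += 1
            logger.info("dropping recipient %s: %s", getattr(rec, id_col), err)
            continue
        rows.append(exp.to_numpy())
        ids.append(getattr(rec, id_col))
    if n_dropped:
        logger.warning("linkage dropped %d of %d recipients (missing panel rows)",
                       n_dropped, len(recipients))
    out = pd.DataFrame(
        np.asarray(rows, dtype=float).reshape(len(ids), len(panel.constituents)),
        index=pd.Index(ids, name=id_col),
        columns=list(panel.constituents),
    )
    out.attrs["n_dropped"] = n_dropped
    return out
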