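"""Derivation of the six sow reproduction traits from litter-level records.

Traits (one aggregated record per sow, as analyzed in the pipeline):

* PWL   -- pigs weaned per litter: total pigs weaned / number of litters
* BAL   -- born alive per litter: total born alive / number of litters
* W2CL  -- wean-to-conception interval per litter (days); an open last
  litter with no recorded interval is excluded from numerator and
  denominator
* LSY   -- litters per sow per year:
  (total gestation days / 115) / (days in breeding herd / 365)
* PWSY  -- pigs weaned per sow per year: LSY * PWL (an identity the output
  table satisfies exactly)
* NPD   -- non-productive days.  The defining sentence is ambiguous; the
  default reading is 365 - (mean productive days per litter) * LSY, where
  productive days are gestating + lactating days.  This keeps NPD inside
  [0, 365] for plausible records and is consistent with
  LSY ~ (365 - NPD) / cycle length.  The literal left-to-right reading
  (365 - total productive days) * LSY is available via
  ``npd_formula="literal"``.  Neither is asserted as canonical.

Fixed-effect levels (farm, last parity, last farrow month/year) are taken
from each sow's last litter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

TRAIT_NAMES = ("PWL", "BAL", "W2CL", "LSY", "PWSY", "NPD")

LITTER_COLUMNS = [
    "sow",
    "parity",
    "pigs_weaned",
    "born_alive",
    "w2c_days",
    "gestation_days",
    "lactation_days",
    "farrow_month",
    "farrow_year",
    "farm",
]

__all__ = ["SowRecordSet", "TRAIT_NAMES", "derive_traits", "summary_statistics"]


@dataclass
class SowRecordSet:
    """Litter records plus days-in-breeding-herd per sow.

    ``litters`` columns: sow, parity (1-10), pigs_weaned, born_alive,
    w2c_days (NaN allowed for an open last litter), gestation_days,
    lactation_days, farrow_month, farrow_year, farm.
    ``herd_days`` is a Series indexed by sow id.
    """

    litters: pd.DataFrame
    herd_days: pd.Series

    def __post_init__(self) -> None:
        missing = set(LITTER_COLUMNS) - set(self.litters.columns)
        if missing:
            raise ValueError(f"litter records missing columns: {sorted(missing)}")
        if (self.litters["parity"] > 10).any() or (self.litters["parity"] < 1).any():
            raise ValueError("parity must be within 1..10")
        counts = self.litters[
            ["pigs_weaned", "born_alive", "gestation_days", "lactation_days"]
        ]
        if (counts < 0).any().any():
            raise ValueError("litter counts and day totals must be >= 0")


def derive_traits(
    records: SowRecordSet, npd_formula: str = "per-litter"
) -> pd.DataFrame:
    """Per-sow trait table with fixed-effect levels from the last litter.

    Sows with zero litters or zero herd days are skipped with a logged
    reason column in ``attrs['skipped']``.  NPD values outside [0, 365] are
    kept and listed in ``attrs['npd_flags']`` -- they flag data issues
    rather than being clamped.
    """
    if npd_formula not in ("per-litter", "literal"):
        raise ValueError(f"unknown npd_formula {npd_formula!r}")
    rows = []
    skipped = []
    for sow, grp in records.litters.groupby("sow", sort=False):
        n_litters = len(grp)
        herd = float(records.herd_days.get(sow, np.nan))
        if n_litters == 0 or not herd > 0:
            skipped.append({"sow": sow, "reason": "no litters or no herd days"})
            continue
        grp = grp.sort_values("parity")
        pwl = grp["pigs_weaned"].sum() / n_litters
        bal = grp["born_alive"].sum() / n_litters
        w2c = grp["w2c_days"].dropna()
        w2cl = w2c.sum() / len(w2c) if len(w2c) else np.nan
        lsy = (grp["gestation_days"].sum() / 115.0) / (herd / 365.0)
        pwsy = lsy * pwl
        productive = (grp["gestation_days"] + grp["lactation_days"]).sum()
        if npd_formula == "per-litter":
            npd = 365.0 - (productive / n_litters) * lsy
        else:
            npd = (365.0 - productive) * lsy
        last = grp.iloc[-1]
        rows.append(
            {
                "animal": sow,
                "PWL": pwl,
                "BAL": bal,
                "W2CL": w2cl,
                "LSY": lsy,
                "PWSY": pwsy,
                "NPD": npd,
                "farm": str(last["farm"]),
                "last_parity": int(last["parity"]),
                "last_farrow_month": str(last["farrow_month"]),
                "last_farrow_year": str(last["farrow_year"]),
            }
        )
    out = pd.DataFrame(rows).set_index("animal") if rows else pd.DataFrame()
    out.attrs["skipped"] = pd.DataFrame(skipped, columns=["sow", "reason"])
    if len(out):
        flagged = out.index[(out["NPD"] < 0) | (out["NPD"] > 365)]
        out.attrs["npd_flags"] = list(flagged)
    else:
        out.attrs["npd_flags"] = []
    return out


def summary_statistics(traits: pd.DataFrame, columns=TRAIT_NAMES) -> pd.DataFrame:
    """Descriptive statistics per trait: n, mean, sd, cv, skewness and
    excess kurtosis (the normality diagnostic).  cv is flagged NaN when the
    mean is numerically zero; skewness/kurtosis are NaN for constant data.
    """
    rows = []
    for trait in columns:
        x = traits[trait].dropna().to_numpy(dtype=float)
        if len(x) < 2:
            raise ValueError(f"trait {trait!r} has fewer than 2 values")
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
        if sd == 0.0:
            cv = 0.0
            skw = kurt = np.nan
        else:
            cv = sd / mean if abs(mean) > 1e-12 else np.nan
            skw = float(stats.skew(x, bias=False))
            kurt = float(stats.kurtosis(x, bias=False))
        rows.append(
            {
                "trait": trait,
                "n": len(x),
                "mean": mean,
                "sd": sd,
                "cv": cv,
                "skewness": skw,
                "excess_kurtosis": kurt,
            }
        )
    return pd.DataFrame(rows).set_index("trait")
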