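"""Female lifetables: all-cause annual death probability and injury share.

Stored on a single-age × single-year grid covering the simulated age range
(10–59) and year range.  The synthetic generator produces a Gompertz-like
adult schedule with a secular decline, emulating the shape of national
female lifetables without reproducing any real country's values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

AGE_LO, AGE_HI = 10, 60  # simulated age support [10, 60)


@dataclass
class LifeTable:
    country: str
    years: np.ndarray           # [n_years], consecutive calendar years
    q_annual: np.ndarray        # [n_ages, n_years], annual death probability
    p_injury: np.ndarray        # [n_ages, n_years], share of deaths from injury

    def __post_init__(self) -> None:
        n_ages = AGE_HI - AGE_LO
        if self.q_annual.shape != (n_ages, len(self.years)):
            raise ValueError("q_annual shape does not match ages × years")
        if self.p_injury.shape != self.q_annual.shape:
            raise ValueError("p_injury shape does not match q_annual")
        if np.any((self.q_annual < 0) | (self.q_annual > 1)):
            raise ValueError("q_annual outside [0, 1]")
        if np.any((self.p_injury < 0) | (self.p_injury > 1)):
            raise ValueError("p_injury outside [0, 1]")

    def year_col(self, year: int) -> int:
        j = year - int(self.years[0])
        if not (0 <= j < len(self.years)):
            raise KeyError(f"year {year} outside lifetable range for {self.country}")
        return j

    def q_for(self, age_years: np.ndarray, year: int) -> np.ndarray:
        """Annual q at single ages (clipped to the table's support)."""
        j = self.year_col(year)
        i = np.clip(np.asarray(age_years, dtype=int) - AGE_LO, 0, AGE_HI - AGE_LO - 1)
        return self.q_annual[i, j]

    def p_injury_for(self, age_years: np.ndarray, year: int) -> np.ndarray:
        j = self.year_col(year)
        i = np.clip(np.asarray(age_years, dtype=int) - AGE_LO, 0, AGE_HI - AGE_LO - 1)
        return self.p_injury[i, j]

    def extend_to(self, year: int) -> "LifeTable":
        """Pad the table forward by carrying the last year's column
        (used for projection beyond the fitted range)."""
        last = int(self.years[-1])
        if year <= last:
            return self
        extra = year - last
        return LifeTable(
            self.country,
            np.arange(int(self.years[0]), year + 1),
            np.concatenate([self.q_annual, np.repeat(self.q_annual[:, -1:], extra, 1)], 1),
            np.concatenate([self.p_injury, np.repeat(self.p_injury[:, -1:], extra, 1)], 1),
        )

    def to_frame(self) -> pd.DataFrame:
        ages = np.arange(AGE_LO, AGE_HI)
        rec = []
        for j, year in enumerate(self.years):
            for i, age in enumerate(ages):
                rec.append((self.country, int(year), int(age),
                            float(self.q_annual[i, j]), float(self.p_injury[i, j])))
        return pd.DataFrame(rec, columns=["country", "year", "age", "q_annual", "p_injury"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, country: str) -> "LifeTable":
        sub = df[df["country"] == country]
        if sub.empty:
            raise KeyError(f"no lifetable rows for {country}")
        years = np.sort(sub["year"].unique())
        n_ages = AGE_HI - AGE_LO
        q = np.zeros((n_ages, len(years)))
        pi = np.zeros_like(q)
        piv_q = sub.pivot_table(index="age", columns="year", values="q_annual")
        piv_i = sub.pivot_table(index="age", columns="year", values="p_injury")
        ages = np.arange(AGE_LO, AGE_HI)
        q[:, :] = piv_q.reindex(ages).to_numpy()
        pi[:, :] = piv_i.reindex(ages).to_numpy()
        return cls(country, years, q, pi)


def synthetic_lifetable(
    country: str,
    years: tuple[int, int],
    level: float = 1.0,
    decline: float = 0.01,
    p_injury: float = 0.08,
) -> LifeTable:
    """Plausible female adult mortality schedule.

    ``level`` scales the whole schedule (1.0 ≈ a high-mortality setting
    with q(15) ≈ 1.5 per 1,000 and q(50) ≈ 8 per 1,000 in the reference
    year); ``decline`` is the proportional annual improvement.
    """
    yr = np.arange(years[0], years[1] + 1)
    ages = np.arange(AGE_LO, AGE_HI)
    base = 0.0012 * np.exp(0.04 * (ages - 15.0)) + 0.0003  # Gompertz-ish
    trend = np.exp(-decline * (yr - 2000))
    q = np.clip(level * base[:, None] * trend[None, :], 0.0, 1.0)
    pi = np.full_like(q, p_injury)
    return LifeTable(country, yr, q, pi)
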