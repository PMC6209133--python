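"""Age-bin scheme for discrete-time child survival analysis.

Under-5 age is partitioned into half-open day intervals [start, end).  The
default scheme follows the convention used in complete-birth-history (CBH)
surveys, where age at death is reported in days under 1 month, in months under
2 years, and in completed years thereafter: NN (0-28 days), PNN1 (29 days to
5 months), PNN2 (6-11 months), then single-year bins 1yr-4yr.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Sentinel returned for ages at or beyond the last bin boundary (>= 5 years).
BEYOND_UNDER5 = -1

#: Mean synodic-ish month length used to convert coded months to days.
DAYS_PER_MONTH = 30.44
#: Mean calendar year length used to convert coded years to days.
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class AgeBinScheme:
    """Ordered, contiguous, half-open age bins in days.

    Parameters
    ----------
    bins
        Tuple of ``(label, start_day, end_day)`` with ``start`` inclusive and
        ``end`` exclusive.  Bins must start at 0, be contiguous, and carry
        unique labels.
    """

    bins: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        if not self.bins:
            raise ValueError("scheme needs at least one bin")
        labels = [b[0] for b in self.bins]
        if len(set(labels)) != len(labels):
            raise ValueError("bin labels must be unique")
        if self.bins[0][1] != 0:
            raise ValueError("first bin must start at age 0")
        for (_, s, e), (_, s2, _) in zip(self.bins, self.bins[1:]):
            if e != s2:
                raise ValueError("bins must be contiguous and non-overlapping")
        for _, s, e in self.bins:
            if e <= s:
                raise ValueError("bin end must exceed bin start")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.bins)

    @property
    def starts(self) -> np.ndarray:
        return np.array([b[1] for b in self.bins])

    @property
    def ends(self) -> np.ndarray:
        return np.array([b[2] for b in self.bins])

    @property
    def max_age_days(self) -> int:
        return self.bins[-1][2]

    def index_for_days(self, age_days):
        """Bin index containing an age in days (vectorized).

        Returns :data:`BEYOND_UNDER5` for ages at or past the last boundary.
        Negative ages raise ``ValueError``.
        """
        age = np.asarray(age_days)
        if np.any(age < 0):
            raise ValueError("negative age at death")
        idx = np.searchsorted(self.ends, age, side="right")
        out = np.where(age >= self.max_age_days, BEYOND_UNDER5, idx)
        if np.isscalar(age_days) or out.ndim == 0:
            return int(out)
        return out.astype(int)

    def label_of(self, index: int) -> str:
        return self.bins[index][0]


#: The 7-bin scheme: NN, PNN1, PNN2, 1yr..4yr.
DEFAULT_SCHEME = AgeBinScheme(
    bins=(
        ("NN", 0, 29),
        ("PNN1", 29, 183),
        ("PNN2", 183, 365),
        ("1yr", 365, 730),
        ("2yr", 730, 1095),
        ("3yr", 1095, 1460),
        ("4yr", 1460, 1825),
    )
)


def coded_age_to_days(unit, value):
    """Convert a coded age at death to integer days (vectorized).

    Months convert at ``round(30.44 * m)`` and years at ``round(365.25 * y)``;
    the conversion is centralized here so it can be swapped in one place.
    """
    unit_arr = np.asarray(unit)
    val = np.asarray(value, dtype=float)
    if np.any(val < 0):
        raise ValueError("negative age at death")
    days = np.where(
        unit_arr == "days",
        val,
        np.where(
            unit_arr == "months",
            np.rint(DAYS_PER_MONTH * val),
            np.rint(DAYS_PER_YEAR * val),
        ),
    )
    known = np.isin(unit_arr, ("days", "months", "years"))
    if not np.all(known):
        bad = np.unique(unit_arr[~known])
        raise ValueError(f"unknown age-at-death unit(s): {list(bad)}")
    if np.isscalar(value) and days.ndim == 0:
        return int(days)
    return days.astype(int)


def assign_age_bin(age_at_death_coded, scheme: AgeBinScheme = DEFAULT_SCHEME):
    """Map a coded age at death ``(unit, value)`` to a bin index.

    Returns :data:`BEYOND_UNDER5` for deaths at age 5 or older.
    """
    unit, value = age_at_death_coded
    return scheme.index_for_days(coded_age_to_days(unit, value))


def months_to_days(months):
    """Completed-month age to days, using the scheme's central conversion."""
    return coded_age_to_days(
        np.broadcast_to("months", np.shape(months)) if not np.isscalar(months) else "months",
        months,
    )
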