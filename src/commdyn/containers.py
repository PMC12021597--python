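"""Core in-memory containers shared across the package.

The central object is :class:`CommunityTimeSeries`, a taxa-by-time abundance
matrix with monthly time stamps.  Columns are community states; column ``n``
is the state vector consumed by the locally weighted regressions in
:mod:`commdyn.smap`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

VALID_DOMAINS = ("eukaryote", "prokaryote", "virus")


@dataclass
class CommunityTimeSeries:
    """Taxa-by-time abundance matrix with monthly time stamps.

    Parameters
    ----------
    abundances : ndarray of shape (n_taxa, n_time)
        Strictly non-negative abundance values; column ``n`` is the community
        state at month ``n``.
    time_stamps : ndarray of int
        Monthly indices (0, 1, 2, ...), one per column.
    taxon_ids : list of str
        Row labels.
    domain_labels : list of str, optional
        Per-taxon domain tag (eukaryote / prokaryote / virus).
    """

    abundances: np.ndarray
    time_stamps: np.ndarray
    taxon_ids: list[str]
    domain_labels: list[str] | None = None
    #: z-scored series (e.g. from smap.standardize_series) legitimately hold
    #: negative values; raw abundance series must not.
    standardized: bool = False

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        self.time_stamps = np.asarray(self.time_stamps)
        if self.abundances.ndim != 2:
            raise ValueError("abundances must be a 2-D taxa-by-time matrix")
        n_taxa, n_time = self.abundances.shape
        if n_time < 2:
            raise ValueError("a community time series needs at least 2 time points")
        if len(self.time_stamps) != n_time:
            raise ValueError("time_stamps length must match the number of columns")
        if len(self.taxon_ids) != n_taxa:
            raise ValueError("taxon_ids length must match the number of rows")
        if np.isnan(self.abundances).any():
            raise ValueError("abundances contain missing values")
        if not self.standardized and (self.abundances < 0).any():
            raise ValueError("abundances must be non-negative")
        if self.domain_labels is not None:
            if len(self.domain_labels) != n_taxa:
                raise ValueError("domain_labels length must equal n_taxa")
            bad = set(self.domain_labels) - set(VALID_DOMAINS)
            if bad:
                raise ValueError(f"unknown domain labels: {sorted(bad)}")

    @property
    def n_taxa(self) -> int:
        return self.abundances.shape[0]

    @property
    def n_time(self) -> int:
        return self.abundances.shape[1]

    def sample_ids(self, start_year: int = 2007, start_month: int = 6) -> list[str]:
        """Render time stamps as YYYY-MM sample identifiers."""
        ids = []
        for t in np.asarray(self.time_stamps, dtype=int):
            month0 = (start_year * 12 + (start_month - 1)) + int(t)
            ids.append(f"{month0 // 12:04d}-{month0 % 12 + 1:02d}")
        return ids

    def to_frame(self, yyyymm: bool = True) -> pd.DataFrame:
        """Return a taxa-by-sample DataFrame (columns = YYYY-MM ids)."""
        cols = self.sample_ids() if yyyymm else [str(t) for t in self.time_stamps]
        return pd.DataFrame(self.abundances, index=self.taxon_ids, columns=cols)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, domain_labels: list[str] | None = None
    ) -> "CommunityTimeSeries":
        return cls(
            abundances=frame.to_numpy(dtype=float),
            time_stamps=np.arange(frame.shape[1]),
            taxon_ids=[str(i) for i in frame.index],
            domain_labels=domain_labels,
        )

    def copy(self) -> "CommunityTimeSeries":
        return replace(
            self,
            abundances=self.abundances.copy(),
            time_stamps=self.time_stamps.copy(),
            taxon_ids=list(self.taxon_ids),
            domain_labels=None if self.domain_labels is None else list(self.domain_labels),
        )
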