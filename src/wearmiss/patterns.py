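"""Descriptive missingness-pattern enumeration and rate tables.

A participant's missingness pattern is the binary vector of their per-night
missing flags (1 = night missing).  Patterns are tabulated most-common
first, with lexicographic tie-breaking, mirroring the usual
pattern-visualization ordering.  Rate tables give missing/total nights and a
rounded percentage per level of a grouping variable (night index, study
site, covariate levels, or no grouping for the overall rate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import LongitudinalDataset

GROUPINGS = (
    "night_index",
    "site",
    "n_children",
    "household_size",
    "employed",
    "married",
    "education_level",
    "none",
)


@dataclass
class PatternTable:
    """Distinct per-participant missingness patterns, most common first."""

    patterns: list[tuple[tuple[int, ...], int]]
    n_participants: int
    n_nights: int

    @property
    def n_patterns(self) -> int:
        return len(self.patterns)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"pattern": "".join(map(str, vec)), "count": cnt}
                for vec, cnt in self.patterns
            ]
        )


@dataclass
class RateTable:
    """Missing-night rates per level of a grouping variable, plus overall."""

    by: str
    table: pd.DataFrame  # columns: level, missing, total, percent, fraction

    @property
    def overall(self) -> pd.Series:
        return self.table[self.table["level"] == "overall"].iloc[0]


def enumerate_patterns(ds: LongitudinalDataset) -> PatternTable:
    """Tabulate each participant's 0/1 missingness vector across nights.

    Ordering is by descending count, ties broken lexicographically on the
    pattern vector, and is invariant to participant order in the input.
    """
    mat = (
        ds.nights.pivot(index="participant_id", columns="night_index", values="missing")
        .sort_index(axis=1)
        .to_numpy()
        .astype(int)
    )
    uniq, counts = np.unique(mat, axis=0, return_counts=True)
    entries = sorted(
        zip(map(tuple, uniq), counts.tolist()), key=lambda e: (-e[1], e[0])
    )
    return PatternTable(
        patterns=entries, n_participants=ds.n_participants, n_nights=ds.n_nights
    )


def missingness_rates(ds: LongitudinalDataset, by: str = "none") -> RateTable:
    """Missing/total nights and percent per level of ``by``, plus an overall row.

    Percentages are rounded to the nearest integer for display; the exact
    fraction is retained alongside.
    """
    if by not in GROUPINGS:
        raise ValueError(f"unknown grouping {by!r}; expected one of {GROUPINGS}")
    merged = ds.merged()
    rows = []
    if by != "none":
        grouped = merged.groupby(by, sort=True)["missing"]
        for level, g in grouped:
            rows.append(
                {"level": level, "missing": int(g.sum()), "total": int(g.count())}
            )
    total = len(merged)
    miss = int(merged["missing"].sum())
    rows.append({"level": "overall", "missing": miss, "total": total})
    table = pd.DataFrame(rows)
    table["fraction"] = table["missing"] / table["total"]
    table["percent"] = (100.0 * table["fraction"]).round().astype(int)
    return RateTable(by=by, table=table)


def plot_patterns(pt: PatternTable, ax=None):
    """Observed/missing grid of patterns ordered by frequency (optional).

    Requires matplotlib; rows are patterns (most common at the top), columns
    are nights, cell shading distinguishes observed from missing, with the
    count annotated at the right.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 0.35 * pt.n_patterns + 1))
    grid = np.array([vec for vec, _ in pt.patterns], dtype=float)
    ax.imshow(grid, cmap="Greys", aspect="auto", vmin=0, vmax=1)
    for i, (_, cnt) in enumerate(pt.patterns):
        ax.text(pt.n_nights - 0.35, i, str(cnt), va="center", fontsize=8)
    ax.set_xticks(range(pt.n_nights), [f"night {t+1}" for t in range(pt.n_nights)])
    ax.set_yticks([])
    ax.set_xlabel("night")
    ax.set_title(f"{pt.n_patterns} missingness patterns ({pt.n_participants} participants)")
    return ax
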