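"""Domain types, validation, CSV I/O and long<->wide reshaping.

The unit of observation is the participant-night: five sleep-stage durations
(deep, light, REM, awake, "unmeasurable" seconds the device could not
classify), a night index 1..n_nights, and a binary indicator of whether
heart-rate data were present for the day *before* the night.  Per-participant
covariates (household size, education level, employment, marital status,
number of children, study site) are constant across nights and never missing.

A night is either fully observed (all five stages recorded) or fully missing
(no stage recorded); partially missing nights are a data error and are
rejected on ingest.  Zero seconds in a stage on an observed night is valid
data — it means the participant recorded no time in that stage — with the
single exception that zero light sleep on an observed night is implausible
and triggers a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sleep-stage duration columns, in canonical order.
SLEEP_STAGES = ["deep_s", "light_s", "rem_s", "awake_s", "unmeasurable_s"]

#: Per-participant covariate columns, in canonical order.
COVARIATES = [
    "household_size",
    "education_level",
    "employed",
    "married",
    "n_children",
    "site",
]

#: The four covariates entered alongside the sleep variables in the wide table
#: used by Little's test.
WIDE_COVARIATES = ["married", "household_size", "education_level", "employed"]

#: Canonical long-format column order.
LONG_COLUMNS = (
    ["participant_id", "night_index"]
    + SLEEP_STAGES
    + ["hr_present_prior_day", "missing"]
    + COVARIATES
)


class SchemaError(ValueError):
    """A required column is absent or has the wrong type."""


class ValidationError(ValueError):
    """The data violate a structural invariant (e.g. a partially missing night)."""


@dataclass
class LongitudinalDataset:
    """A validated long-format repeated-measures sleep dataset.

    Attributes
    ----------
    nights : pandas.DataFrame
        One row per participant-night with columns ``participant_id``,
        ``night_index``, the five stage durations, ``hr_present_prior_day``
        and the derived ``missing`` flag.  Sorted by participant then night.
    covariates : pandas.DataFrame
        One row per participant, indexed by ``participant_id``, with the six
        covariate columns.
    """

    nights: pd.DataFrame
    covariates: pd.DataFrame
    n_nights: int = 5
    meta: dict = field(default_factory=dict)

    @property
    def participants(self) -> pd.Index:
        return self.covariates.index

    @property
    def n_participants(self) -> int:
        return len(self.covariates)

    @property
    def n_missing_nights(self) -> int:
        return int(self.nights["missing"].sum())

    @property
    def n_total_nights(self) -> int:
        return len(self.nights)

    def total_sleep_s(self) -> pd.Series:
        """Total sleep seconds per observed night (deep+light+REM+unmeasurable).

        Awake seconds are excluded: they are time within the sleep window the
        wearer spent awake, not sleep.  NaN on missing nights.
        """
        obs = self.nights
        return obs["deep_s"] + obs["light_s"] + obs["rem_s"] + obs["unmeasurable_s"]

    def merged(self) -> pd.DataFrame:
        """Night rows joined with their participant covariates."""
        return self.nights.merge(
            self.covariates, left_on="participant_id", right_index=True, how="left"
        )

    def validate(self) -> "LongitudinalDataset":
        """Check every structural invariant; raise ``ValidationError`` on failure."""
        nights, cov = self.nights, self.covariates
        dup = nights.duplicated(subset=["participant_id", "night_index"])
        if dup.any():
            bad = nights.loc[dup, ["participant_id", "night_index"]].iloc[0]
            raise ValidationError(
                f"duplicate (participant, night): "
                f"({bad['participant_id']}, {bad['night_index']})"
            )
        counts = nights.groupby("participant_id", sort=False)["night_index"].agg(
            ["count", "min", "max", "nunique"]
        )
        bad = counts[
            (counts["count"] != self.n_nights)
            | (counts["min"] != 1)
            | (counts["max"] != self.n_nights)
            | (counts["nunique"] != self.n_nights)
        ]
        if len(bad):
            raise ValidationError(
                f"participant {bad.index[0]!r} does not have night_index "
                f"1..{self.n_nights} exactly once"
            )
        no_cov = set(nights["participant_id"]) - set(cov.index)
        if no_cov:
            raise ValidationError(f"participants without covariates: {sorted(no_cov)[:5]}")
        if cov[[c for c in COVARIATES if c != "site"]].isna().any().any():
            raise ValidationError("missing covariate values are not allowed")

        stage = nights[SLEEP_STAGES]
        n_absent = stage.isna().sum(axis=1)
        mixed = (n_absent > 0) & (n_absent < len(SLEEP_STAGES))
        if mixed.any():
            bad = nights.loc[mixed].iloc[0]
            raise ValidationError(
                "partially missing night (stages must be all present or all "
                f"absent): participant {bad['participant_id']!r} night "
                f"{int(bad['night_index'])}"
            )
        derived = n_absent == len(SLEEP_STAGES)
        if not (nights["missing"].astype(bool) == derived).all():
            raise ValidationError("missing flag inconsistent with stage absence")
        neg = (stage < 0).any(axis=1)
        if neg.any():
            bad = nights.loc[neg].iloc[0]
            raise ValidationError(
                f"negative stage duration: participant {bad['participant_id']!r} "
                f"night {int(bad['night_index'])}"
            )
        zero_light = (~derived) & (nights["light_s"] == 0)
        if zero_light.any():
            warnings.warn(
                f"{int(zero_light.sum())} observed night(s) report 0 s of light "
                "sleep; observed nights are expected to contain some light sleep",
                UserWarning,
                stacklevel=2,
            )
        return self


def _derive_missing(nights: pd.DataFrame) -> pd.Series:
    """Night-level missingness: all five stage durations absent."""
    return nights[SLEEP_STAGES].isna().all(axis=1).astype(np.int8)


def make_dataset(
    nights: pd.DataFrame, covariates: pd.DataFrame, n_nights: int = 5
) -> LongitudinalDataset:
    """Assemble and validate a :class:`LongitudinalDataset` from raw frames."""
    nights = nights.copy()
    nights["missing"] = _derive_missing(nights)
    nights = nights.sort_values(["participant_id", "night_index"], kind="stable")
    nights = nights.reset_index(drop=True)
    covariates = covariates.copy()
    if covariates.index.name != "participant_id":
        covariates = covariates.set_index("participant_id")
    ds = LongitudinalDataset(nights=nights, covariates=covariates, n_nights=n_nights)
    return ds.validate()


DEFAULT_SCHEMA = {c: c for c in LONG_COLUMNS if c != "missing"}


def read_long_csv(
    path, schema: dict[str, str] | None = None, n_nights: int = 5
) -> LongitudinalDataset:
    """Read a long-format CSV (one row per participant-night) and validate it.

    Parameters
    ----------
    path : str or file-like
        CSV with a header row; UTF-8.
    schema : dict, optional
        Map from canonical column name to the column name used in the file.
        Defaults to the canonical names themselves.  The ``missing`` column is
        always derived, never read.
    n_nights : int
        Nights per participant (5 for the study design emulated here).

    Returns
    -------
    LongitudinalDataset

    Raises
    ------
    SchemaError
        A required column is absent.
    ValidationError
        Structural invariants are violated (mixed nights, duplicates, ...).
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    schema.pop("missing", None)
    df = pd.read_csv(path)
    missing_cols = [v for v in schema.values() if v not in df.columns]
    if missing_cols:
        raise SchemaError(f"required column(s) not in file: {missing_cols}")
    df = df.rename(columns={v: k for k, v in schema.items()})
    night_cols = ["participant_id", "night_index"] + SLEEP_STAGES + [
        "hr_present_prior_day"
    ]
    cov = (
        df[["participant_id"] + COVARIATES]
        .drop_duplicates()
        .set_index("participant_id")
    )
    if cov.index.has_duplicates:
        bad = cov.index[cov.index.duplicated()][0]
        raise ValidationError(
            f"covariates vary within participant {bad!r}; they must be constant"
        )
    ds = make_dataset(df[night_cols], cov, n_nights=n_nights)
    logger.info(
        "read %d participants, %d nights, %d missing nights",
        ds.n_participants,
        ds.n_total_nights,
        ds.n_missing_nights,
    )
    return ds


def write_long_csv(ds: LongitudinalDataset, path) -> None:
    """Write the canonical long-format CSV (covariates repeated per row)."""
    ds.merged()[LONG_COLUMNS].to_csv(path, index=False)


def to_wide(
    ds: LongitudinalDataset, variables: list[str] | None = None
) -> pd.DataFrame:
    """Reshape to one row per participant.

    Columns are ``<stage>_n<night>`` for each requested stage and night
    (missing nights yield NaN cells) followed by the four covariates entered
    in the normal-theory analysis: marital status, household size, education
    level, employment status.  With all five stages and five nights this is
    the 25 + 4 = 29-column table.
    """
    variables = list(SLEEP_STAGES) if variables is None else list(variables)
    unknown = [v for v in variables if v not in SLEEP_STAGES]
    if unknown:
        raise ValueError(f"unknown stage variable(s): {unknown}; valid: {SLEEP_STAGES}")
    wide = ds.nights.pivot(
        index="participant_id", columns="night_index", values=variables
    )
    wide.columns = [f"{stage}_n{night}" for stage, night in wide.columns]
    order = [f"{v}_n{t}" for v in variables for t in range(1, ds.n_nights + 1)]
    wide = wide[order]
    wide = wide.join(ds.covariates[WIDE_COVARIATES])
    return wide


def wide_to_long(wide: pd.DataFrame, n_nights: int = 5) -> pd.DataFrame:
    """Inverse of :func:`to_wide` for the sleep columns (used for round-trips)."""
    stages = sorted({c.rsplit("_n", 1)[0] for c in wide.columns if "_n" in c})
    rows = []
    for pid, row in wide.iterrows():
        for t in range(1, n_nights + 1):
            rec = {"participant_id": pid, "night_index": t}
            for s in stages:
                rec[s] = row.get(f"{s}_n{t}", np.nan)
            rows.append(rec)
    return pd.DataFrame(rows)
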