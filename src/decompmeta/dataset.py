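"""Dataset schema, validation and delimited-table I/O.

The unit of observation is a *treatment summary*: the reported mean and
dispersion of decay (mass loss as % of initial mass, or cumulative CO2-C
in mg per g litter) for one inoculum treatment at one study x litter x
time cell.  Study-level covariates (setting, environment, inoculum
complexity and taxa, litter chemistry, diversity-gradient length) live in
a separate moderator table keyed by study.

Dispersion is stored canonically as the within-treatment SD across
replicates; input files may declare it as SE, in which case it is
converted on read (``se_to_sd``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

RESPONSE_TYPES = ("mass_loss_pct", "co2_cum_mg_per_g")
SETTINGS = ("field", "laboratory")
ENVIRONMENTS = ("terrestrial", "freshwater")
COMPLEXITIES = ("reduced", "whole_community")
TAXA = ("bacteria", "fungi", "both")

#: canonical column order of the summaries table
SUMMARY_COLUMNS = [
    "study_id",
    "litter_id",
    "time_days",
    "treatment_id",
    "response_type",
    "mean",
    "sd",
    "n",
]

#: canonical column order of the moderator table
MODERATOR_COLUMNS = [
    "study_id",
    "setting",
    "environment",
    "inoculum_complexity",
    "inoculum_taxa",
    "max_richness",
    "litter_cn",
    "litter_lignin_pct",
    "n_inoculum_treatments",
]

#: key identifying one study x litter x time x response cell
CELL_KEY = ["study_id", "litter_id", "time_days", "response_type"]


def se_to_sd(se: float, n: int) -> float:
    """Convert a standard error of the mean to the replicate SD.

    ``sd = se * sqrt(n)``.  Identity for ``n == 1``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if se < 0:
        raise ValueError(f"se must be >= 0, got {se}")
    return se * math.sqrt(n)


@dataclass(frozen=True)
class TreatmentSummary:
    """Decay summary of one inoculum treatment at one cell."""

    study_id: str
    litter_id: str
    time_days: float
    treatment_id: str
    response_type: str
    mean_response: float
    sd_response: float
    n_replicates: int


@dataclass(frozen=True)
class StudyModerators:
    """Study-level covariates used in subgroup and moderator analyses."""

    study_id: str
    setting: str
    environment: str
    inoculum_complexity: str
    inoculum_taxa: str
    n_inoculum_treatments: int
    max_richness: float = float("nan")
    litter_cn: float = float("nan")
    litter_lignin_pct: float = float("nan")


@dataclass
class ExperimentDataset:
    """A validated pair of (summaries, moderators) tables.

    ``summaries`` uses :data:`SUMMARY_COLUMNS`, ``moderators``
    :data:`MODERATOR_COLUMNS`.  Construction via :meth:`from_frames`
    enforces all invariants; the plain constructor trusts its input.
    """

    summaries: pd.DataFrame
    moderators: pd.DataFrame

    # ------------------------------------------------------------------
    @classmethod
    def from_frames(
        cls,
        summaries: pd.DataFrame,
        moderators: pd.DataFrame,
        *,
        drop_single_treatment_cells: bool = True,
    ) -> "ExperimentDataset":
        """Validate and normalise the two tables.

        Cells (study x litter x time x response) with a single treatment
        carry no information about inoculum effects; they are dropped
        with a warning when ``drop_single_treatment_cells`` is true,
        otherwise they raise.
        """
        summaries = summaries.copy().reset_index(drop=True)
        moderators = moderators.copy().reset_index(drop=True)
        _check_columns(summaries, SUMMARY_COLUMNS, "summaries")
        _check_columns(moderators, MODERATOR_COLUMNS, "moderators")
        summaries = summaries[SUMMARY_COLUMNS]
        moderators = moderators[MODERATOR_COLUMNS]

        diagnostics = []
        diagnostics += _validate_summary_rows(summaries)
        diagnostics += _validate_moderator_rows(moderators)

        key = SUMMARY_COLUMNS[:5]  # study, litter, time, treatment, response
        dup = summaries.duplicated(subset=key, keep=False)
        if dup.any():
            for i in summaries.index[dup]:
                diagnostics.append(
                    f"summaries row {i}: duplicate key "
                    f"{tuple(summaries.loc[i, key])}"
                )

        missing_mod = set(summaries["study_id"]) - set(moderators["study_id"])
        if missing_mod:
            diagnostics.append(
                f"studies without moderator rows: {sorted(missing_mod)}"
            )
        if diagnostics:
            shown = "; ".join(diagnostics[:20])
            raise ValidationError(
                f"{len(diagnostics)} validation problem(s): {shown}",
                diagnostics,
            )

        n_treat = summaries.groupby(CELL_KEY, sort=False)["treatment_id"].transform(
            "nunique"
        )
        single = n_treat < 2
        if single.any():
            cells = (
                summaries.loc[single, CELL_KEY].drop_duplicates().to_records(index=False)
            )
            msg = f"{len(cells)} cell(s) with a single treatment excluded: " + ", ".join(
                map(str, cells[:10])
            )
            if not drop_single_treatment_cells:
                raise ValidationError(msg, [str(c) for c in cells])
            warnings.warn(msg, stacklevel=2)
            summaries = summaries.loc[~single].reset_index(drop=True)

        return cls(summaries=summaries, moderators=moderators)

    # ------------------------------------------------------------------
    def cells(self):
        """Iterate over (cell key tuple, sub-frame) pairs."""
        return self.summaries.groupby(CELL_KEY, sort=True)

    @property
    def study_ids(self):
        return list(pd.unique(self.summaries["study_id"]))

    def moderators_for(self, study_id) -> pd.Series:
        m = self.moderators
        row = m.loc[m["study_id"] == study_id]
        if row.empty:
            raise KeyError(study_id)
        return row.iloc[0]

    def equals(self, other: "ExperimentDataset") -> bool:
        """Field-by-field equality after canonical sorting."""
        a, b = _canon(self.summaries), _canon(other.summaries)
        c, d = _canon(self.moderators), _canon(other.moderators)
        return a.equals(b) and c.equals(d)


def _canon(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(list(df.columns)).reset_index(drop=True)


def _check_columns(df, expected, name):
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table is missing column(s): {missing}")


def _validate_summary_rows(df: pd.DataFrame):
    diags = []
    for i, row in df.iterrows():
        if row["response_type"] not in RESPONSE_TYPES:
            diags.append(
                f"summaries row {i}: unknown response_type {row['response_type']!r}"
            )
            continue
        if not (row["time_days"] > 0):
            diags.append(f"summaries row {i}: time_days must be > 0")
        if not (row["n"] >= 1):
            diags.append(f"summaries row {i}: n must be >= 1")
        if not (row["sd"] >= 0):
            diags.append(f"summaries row {i}: sd must be >= 0")
        if row["response_type"] == "mass_loss_pct":
            if not (0 <= row["mean"] <= 100):
                diags.append(
                    f"summaries row {i}: mass_loss_pct mean {row['mean']} "
                    "outside [0, 100]"
                )
        else:
            if not (row["mean"] >= 0):
                diags.append(f"summaries row {i}: CO2 mean must be >= 0")
    return diags


def _validate_moderator_rows(df: pd.DataFrame):
    diags = []
    if df["study_id"].duplicated().any():
        dups = sorted(df.loc[df["study_id"].duplicated(), "study_id"])
        diags.append(f"moderators: duplicate study_id rows {dups}")
    for i, row in df.iterrows():
        for col, allowed in [
            ("setting", SETTINGS),
            ("environment", ENVIRONMENTS),
            ("inoculum_complexity", COMPLEXITIES),
            ("inoculum_taxa", TAXA),
        ]:
            if row[col] not in allowed:
                diags.append(f"moderators row {i}: {col}={row[col]!r} not in {allowed}")
        if not (row["n_inoculum_treatments"] >= 2):
            diags.append(f"moderators row {i}: n_inoculum_treatments must be >= 2")
        rich = row["max_richness"]
        if row.get("inoculum_complexity") == "whole_community" and not pd.isna(rich):
            diags.append(
                f"moderators row {i}: max_richness only applies to reduced-"
                "complexity inocula"
            )
        if not pd.isna(rich) and not rich >= 1:
            diags.append(f"moderators row {i}: max_richness must be >= 1")
    return diags


# ----------------------------------------------------------------------
# delimited-table I/O
# ----------------------------------------------------------------------

#: default column mapping of the on-disk summaries file.  A schema config
#: may override any entry; ``dispersion_kind`` selects how the dispersion
#: column is interpreted: "from_column" (a dispersion_type column holds
#: "sd" or "se" per row), or a constant "sd" / "se" for the whole file.
DEFAULT_SCHEMA = {
    "study_id": "study_id",
    "litter_id": "litter_id",
    "time_days": "time_days",
    "treatment_id": "treatment_id",
    "response_type": "response_type",
    "mean": "mean",
    "dispersion": "dispersion",
    "dispersion_type": "dispersion_type",
    "n": "n",
    "dispersion_kind": "from_column",
}


def read_dataset(
    summaries_path,
    moderators_path,
    schema: dict | None = None,
    *,
    drop_single_treatment_cells: bool = True,
) -> ExperimentDataset:
    """Read and validate the canonical CSV pair.

    ``schema`` maps canonical field names to the file's column names and
    may set ``dispersion_kind`` (see :data:`DEFAULT_SCHEMA`).  SE
    dispersions are converted to SD before storage.
    """
    cfg = dict(DEFAULT_SCHEMA)
    if schema:
        unknown = set(schema) - set(cfg)
        if unknown:
            raise SchemaError(f"unknown schema key(s): {sorted(unknown)}")
        cfg.update(schema)

    raw = pd.read_csv(summaries_path)
    kind = cfg["dispersion_kind"]
    needed = [
        cfg[k]
        for k in (
            "study_id",
            "litter_id",
            "time_days",
            "treatment_id",
            "response_type",
            "mean",
            "dispersion",
            "n",
        )
    ]
    if kind == "from_column":
        needed.append(cfg["dispersion_type"])
    missing = [c for c in needed if c not in raw.columns]
    if missing:
        raise SchemaError(f"summaries file is missing column(s): {missing}")

    if kind == "from_column":
        dtypes = raw[cfg["dispersion_type"]].astype(str).str.lower()
        bad = ~dtypes.isin(["sd", "se"])
        if bad.any():
            raise ValidationError(
                "dispersion_type must be 'sd' or 'se'",
                [f"row {i}: {v!r}" for i, v in dtypes[bad].items()],
            )
    elif kind in ("sd", "se"):
        dtypes = pd.Series(kind, index=raw.index)
    else:
        raise SchemaError(f"dispersion_kind must be 'from_column', 'sd' or 'se'")

    n = pd.to_numeric(raw[cfg["n"]])
    disp = pd.to_numeric(raw[cfg["dispersion"]])
    sd = disp.where(dtypes == "sd", disp * np.sqrt(n))

    summaries = pd.DataFrame(
        {
            "study_id": raw[cfg["study_id"]].astype(str),
            "litter_id": raw[cfg["litter_id"]].astype(str),
            "time_days": pd.to_numeric(raw[cfg["time_days"]]).astype(float),
            "treatment_id": raw[cfg["treatment_id"]].astype(str),
            "response_type": raw[cfg["response_type"]].astype(str),
            "mean": pd.to_numeric(raw[cfg["mean"]]).astype(float),
            "sd": sd.astype(float),
            "n": n.astype(int),
        }
    )

    mod_raw = pd.read_csv(moderators_path)
    _check_columns(mod_raw, MODERATOR_COLUMNS, "moderators")
    moderators = pd.DataFrame(
        {
            "study_id": mod_raw["study_id"].astype(str),
            "setting": mod_raw["setting"].astype(str),
            "environment": mod_raw["environment"].astype(str),
            "inoculum_complexity": mod_raw["inoculum_complexity"].astype(str),
            "inoculum_taxa": mod_raw["inoculum_taxa"].astype(str),
            "max_richness": pd.to_numeric(mod_raw["max_richness"]).astype(float),
            "litter_cn": pd.to_numeric(mod_raw["litter_cn"]).astype(float),
            "litter_lignin_pct": pd.to_numeric(mod_raw["litter_lignin_pct"]).astype(
                float
            ),
            "n_inoculum_treatments": pd.to_numeric(
                mod_raw["n_inoculum_treatments"]
            ).astype(int),
        }
    )
    return ExperimentDataset.from_frames(
        summaries, moderators, drop_single_treatment_cells=drop_single_treatment_cells
    )


def write_dataset(dataset: ExperimentDataset, directory) -> tuple[Path, Path]:
    """Write the canonical CSV pair into ``directory``.

    Dispersion is emitted as SD (``dispersion_type`` = "sd") so that a
    read of the written files reproduces the dataset exactly.
    Returns the two file paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spath = directory / "summaries.csv"
    mpath = directory / "moderators.csv"

    out = dataset.summaries.rename(columns={"sd": "dispersion"}).copy()
    out["dispersion_type"] = "sd"
    out = out[
        [
            "study_id",
            "litter_id",
            "time_days",
            "treatment_id",
            "response_type",
            "mean",
            "dispersion",
            "dispersion_type",
            "n",
        ]
    ]
    out.to_csv(spath, index=False)
    dataset.moderators.to_csv(mpath, index=False)
    return spath, mpath
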