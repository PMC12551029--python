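"""Tabular I/O for beta matrices, EWAS weight tables and sample sheets.

All formats are delimited text (TSV by default, CSV accepted) with a
header row.  Observations are keyed as ``"<person_id>@<wave>"`` so a
beta matrix is joinable to a sample sheet without a third mapping file.
Probe identifiers are case-sensitive and are not validated against any
array manifest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Separator joining person id and wave into an observation key.
OBS_SEP = "@"


class FormatError(ValueError):
    """A file violates the expected tabular layout or value domain."""


class IntegrityError(ValueError):
    """A table violates a structural invariant (keys, couple membership)."""


def obs_key(person_id: str, wave: int) -> str:
    """Observation key for one person-wave, ``"<person>@<wave>"``."""
    return f"{person_id}{OBS_SEP}{wave}"


def split_obs_key(key: str) -> tuple[str, int]:
    person, _, wave = key.rpartition(OBS_SEP)
    if not person:
        raise FormatError(f"observation key {key!r} lacks the {OBS_SEP!r} separator")
    return person, int(wave)


@dataclass
class BetaMatrix:
    """Probe x sample matrix of methylation beta fractions.

    ``values[i, j]`` is the methylation fraction of probe ``probe_ids[i]``
    in observation ``sample_ids[j]``; missing entries are NaN.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise FormatError(
                f"beta matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.probe_ids, "probe")
        _check_unique(self.sample_ids, "sample")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise FormatError("beta values outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    def subset_probes(self, probes: list[str]) -> "BetaMatrix":
        idx = {p: i for i, p in enumerate(self.probe_ids)}
        rows = [idx[p] for p in probes]
        return BetaMatrix(list(probes), list(self.sample_ids), self.values[rows])


@dataclass
class WeightTable:
    """CpG identifier -> EWAS effect-size coefficient (unitless)."""

    entries: dict[str, float]
    score_name: str = ""
    citation: str = ""

    def __post_init__(self) -> None:
        coefs = np.array(list(self.entries.values()), dtype=float)
        if coefs.size and not np.all(np.isfinite(coefs)):
            raise FormatError("weight table contains non-finite coefficients")

    @property
    def probes(self) -> list[str]:
        return list(self.entries.keys())

    @property
    def coefficients(self) -> np.ndarray:
        return np.array(list(self.entries.values()), dtype=float)


SAMPLE_SHEET_COLUMNS = ["person_id", "couple_id", "wave", "age", "sex", "binge"]
ATS_ASSAY_COLUMNS = ["ats1", "ats2", "ats3", "ats4"]


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} id {x!r}")
        seen.add(x)


def _read_delimited(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_beta_matrix(path, orientation: str = "probes-in-rows", strict: bool = True) -> BetaMatrix:
    """Read a beta-value matrix from delimited text.

    Parameters
    ----------
    path : str or Path
        TSV (or ``.csv``) file with a header row; the first column holds
        the row keys (probes or samples depending on ``orientation``).
    orientation : {"probes-in-rows", "samples-in-rows"}
        Layout of the file; the returned matrix is always probe x sample.
    strict : bool
        If true, any non-numeric or out-of-range cell raises
        :class:`FormatError`; if false such cells become missing (NaN)
        and the count is logged.
    """
    if orientation not in ("probes-in-rows", "samples-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = _read_delimited(path)
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: expected a key column plus data columns")
    keys = raw.iloc[:, 0].tolist()
    cols = list(raw.columns[1:])
    cells = raw.iloc[:, 1:].to_numpy(dtype=object)
    values = np.empty(cells.shape, dtype=float)
    n_missing = 0
    for i in range(cells.shape[0]):
        for j in range(cells.shape[1]):
            cell = str(cells[i, j]).strip()
            if cell in ("", "NA", "NaN", "nan"):
                values[i, j] = np.nan
                n_missing += 1
                continue
            try:
                v = float(cell)
            except ValueError:
                if strict:
                    raise FormatError(
                        f"{path}: non-numeric cell {cell!r} at row {keys[i]!r}, column {cols[j]!r}"
                    ) from None
                values[i, j] = np.nan
                n_missing += 1
                continue
            if not 0.0 <= v <= 1.0:
                if strict:
                    raise FormatError(
                        f"{path}: beta value {v} outside [0, 1] at row {keys[i]!r}, "
                        f"column {cols[j]!r}"
                    )
                values[i, j] = np.nan
                n_missing += 1
            else:
                values[i, j] = v
    if n_missing:
        logger.info("%s: %d missing/invalid cells set to NaN", path, n_missing)
    if orientation == "samples-in-rows":
        return BetaMatrix(cols, keys, values.T)
    return BetaMatrix(keys, cols, values)


def write_beta_matrix(bm: BetaMatrix, path) -> None:
    df = bm.to_frame()
    df.index.name = "cpg"
    sep = "," if str(path).endswith(".csv") else "\t"
    df.to_csv(path, sep=sep, na_rep="NA", float_format="%.17g")


def read_weight_table(path, score_name: str = "", citation: str = "") -> WeightTable:
    """Read a CpG -> coefficient table (columns ``cpg``, ``coefficient``)."""
    raw = _read_delimited(path)
    for col in ("cpg", "coefficient"):
        if col not in raw.columns:
            raise FormatError(f"{path}: weight table lacks required column {col!r}")
    _check_unique(raw["cpg"].tolist(), "CpG")
    entries = {
        cpg: float(coef) for cpg, coef in zip(raw["cpg"], raw["coefficient"])
    }
    return WeightTable(entries, score_name=score_name, citation=citation)


def write_weight_table(wt: WeightTable, path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    pd.DataFrame({"cpg": wt.probes, "coefficient": wt.coefficients}).to_csv(
        path, sep=sep, index=False, float_format="%.17g"
    )


def align_probes(bm: BetaMatrix, wt: WeightTable) -> tuple[BetaMatrix, dict]:
    """Restrict a beta matrix to the probes of a weight table.

    Returns the restricted matrix (probe order follows the weight table)
    and a coverage report ``{n_requested, n_found, fraction}``.
    Idempotent: aligning the result again is a no-op.
    """
    have = set(bm.probe_ids)
    shared = [p for p in wt.probes if p in have]
    n_req = len(wt.probes)
    report = {
        "n_requested": n_req,
        "n_found": len(shared),
        "fraction": len(shared) / n_req if n_req else 0.0,
    }
    if not shared:
        raise FormatError("no scoreable probes: weight table and beta matrix are disjoint")
    return bm.subset_probes(shared), report


def validate_sample_sheet(df: pd.DataFrame) -> pd.DataFrame:
    """Check structural invariants of a long-format sample sheet."""
    missing_cols = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"sample sheet lacks columns {missing_cols}")
    dup = df.duplicated(subset=["person_id", "wave"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise IntegrityError(
            f"duplicated (person, wave) row: ({row['person_id']!r}, {row['wave']})"
        )
    couples_per_person = df.groupby("person_id")["couple_id"].nunique()
    bad = couples_per_person[couples_per_person > 1]
    if len(bad):
        raise IntegrityError(f"person {bad.index[0]!r} appears in more than one couple")
    partners = df.groupby("couple_id")["person_id"].nunique()
    crowded = partners[partners > 2]
    if len(crowded):
        raise IntegrityError(f"couple {crowded.index[0]!r} has more than 2 partners")
    return df


def read_sample_sheet(path) -> pd.DataFrame:
    """Read and validate a long-format sample sheet (one row per person-wave)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    df["person_id"] = df["person_id"].astype(str)
    df["couple_id"] = df["couple_id"].astype(str)
    df["wave"] = df["wave"].astype(int)
    return validate_sample_sheet(df)


def write_sample_sheet(df: pd.DataFrame, path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    df.to_csv(path, sep=sep, index=False, na_rep="NA", float_format="%.17g")


def write_scores(panel: pd.DataFrame, path) -> None:
    """Write a score panel (one row per person-wave) as delimited text."""
    sep = "," if str(path).endswith(".csv") else "\t"
    panel.to_csv(path, sep=sep, index=False, na_rep="NA", float_format="%.17g")


def read_scores(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if "person_id" in df.columns:
        df["person_id"] = df["person_id"].astype(str)
    if "couple_id" in df.columns:
        df["couple_id"] = df["couple_id"].astype(str)
    return df
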