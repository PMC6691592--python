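"""Reading, validating, describing and writing longitudinal score tables.

The package works on wide-format person x (wave x domain) tables of test
scores — here vocabulary and matrix reasoning measured at three occasions —
with missing entries allowed.  Columns are mapped to (wave, domain) cells by
a user-supplied column map, since deposited datasets rarely share a naming
scheme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

DEFAULT_MISSING_TOKENS = ("", "NA")


class DataError(Exception):
    """Malformed input table or configuration."""


def _canon(domain: str, wave: str) -> str:
    return f"{domain}_{wave}"


@dataclass
class LongitudinalDataset:
    """Wide table of scores: one row per person, one column per (domain, wave).

    ``scores`` holds floats with NaN for missing entries, columns named
    ``{domain}_{wave}`` ordered domain-major (all waves of the first domain,
    then the second).  ``group`` is an optional per-person categorical.
    """

    scores: pd.DataFrame
    wave_labels: tuple[str, ...]
    domain_labels: tuple[str, ...]
    group: pd.Series | None = None
    all_missing_ids: tuple = ()

    def __post_init__(self):
        expected = self.variable_names()
        if list(self.scores.columns) != expected:
            missing = set(expected) - set(self.scores.columns)
            if missing:
                raise DataError(f"score table lacks columns {sorted(missing)}")
            self.scores = self.scores[expected]
        empties = self.scores.index[self.scores.isna().all(axis=1)]
        if len(empties) and not self.all_missing_ids:
            self.all_missing_ids = tuple(empties)
            logger.warning(
                "%d person(s) have no observed scores: %s", len(empties), list(empties)
            )

    def variable_names(self) -> list[str]:
        return [_canon(d, w) for d in self.domain_labels for w in self.wave_labels]

    @property
    def n(self) -> int:
        return len(self.scores)

    @property
    def n_variables(self) -> int:
        return self.scores.shape[1]

    def to_matrix(self, columns: Sequence[str] | None = None) -> np.ndarray:
        cols = list(columns) if columns is not None else self.variable_names()
        return self.scores[cols].to_numpy(dtype=float)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.scores.isna()

    def split_by_group(self) -> dict[str, "LongitudinalDataset"]:
        if self.group is None:
            raise DataError("dataset has no grouping variable")
        out = {}
        for g, idx in self.group.groupby(self.group).groups.items():
            out[str(g)] = LongitudinalDataset(
                self.scores.loc[idx].copy(),
                self.wave_labels,
                self.domain_labels,
                group=None,
            )
        return out

    def sample_variances(self) -> dict[str, float]:
        return {c: float(self.scores[c].var()) for c in self.scores.columns}

    def sample_means(self) -> dict[str, float]:
        return {c: float(self.scores[c].mean()) for c in self.scores.columns}


@dataclass
class ValidationReport:
    n_persons: int
    n_variables: int
    observed_counts: dict[str, int]
    missing_counts: dict[str, int]
    all_missing_persons: tuple = ()

    def to_markdown(self) -> str:
        lines = [
            "## Data validation",
            f"- persons: {self.n_persons}",
            f"- score variables: {self.n_variables}",
            f"- persons with no observed scores: {len(self.all_missing_persons)}",
            "",
            "| variable | observed | missing |",
            "| --- | --- | --- |",
        ]
        for v in self.observed_counts:
            lines.append(f"| {v} | {self.observed_counts[v]} | {self.missing_counts[v]} |")
        return "\n".join(lines)


def read_wide_csv(
    path: str | Path,
    column_map: Mapping[str, tuple[str, str]],
    *,
    wave_labels: Sequence[str] | None = None,
    domain_labels: Sequence[str] | None = None,
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
    person_id_column: str | None = None,
    group_column: str | None = None,
) -> tuple[LongitudinalDataset, ValidationReport]:
    """Read a wide CSV into a LongitudinalDataset.

    ``column_map`` maps a CSV column name to a (wave, domain) pair.  Cells
    equal to one of ``missing_tokens`` (after stripping whitespace) become
    missing; any other non-numeric cell raises a parse error naming the
    offending row and column.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if raw.empty:
        raise DataError(f"{path} contains no data rows")

    unmapped = [c for c in column_map if c not in raw.columns]
    if unmapped:
        raise DataError(
            f"column map names column(s) {unmapped} absent from {path.name}; "
            f"file has {list(raw.columns)}"
        )

    if wave_labels is None:
        wave_labels = tuple(dict.fromkeys(w for w, _ in column_map.values()))
    if domain_labels is None:
        domain_labels = tuple(dict.fromkeys(d for _, d in column_map.values()))

    tokens = {t.strip() for t in missing_tokens}
    data = {}
    for col, (wave, dom) in column_map.items():
        cells = raw[col].str.strip()
        is_missing = cells.isin(tokens)
        numeric = pd.to_numeric(cells.where(~is_missing), errors="coerce")
        bad = numeric.isna() & ~is_missing
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataError(
                f"cannot parse cell at row {i + 2} (1-based, incl. header), "
                f"column {col!r}: {raw[col].iloc[i]!r} is neither numeric nor a "
                f"missing token {sorted(tokens)}"
            )
        data[_canon(dom, wave)] = numeric

    scores = pd.DataFrame(data)
    if person_id_column is not None:
        scores.index = pd.Index(raw[person_id_column], name=person_id_column)
    group = None
    if group_column is not None:
        if group_column not in raw.columns:
            raise DataError(f"group column {group_column!r} not in {path.name}")
        group = pd.Series(raw[group_column].to_numpy(), index=scores.index, name=group_column)

    ds = LongitudinalDataset(scores, tuple(wave_labels), tuple(domain_labels), group=group)
    report = ValidationReport(
        n_persons=ds.n,
        n_variables=ds.n_variables,
        observed_counts={c: int(ds.scores[c].notna().sum()) for c in ds.scores.columns},
        missing_counts={c: int(ds.scores[c].isna().sum()) for c in ds.scores.columns},
        all_missing_persons=ds.all_missing_ids,
    )
    return ds, report


def write_wide_csv(data: LongitudinalDataset, path: str | Path, missing_token: str = "NA") -> None:
    """Write the dataset in the same wide dialect ``read_wide_csv`` accepts."""
    out = data.scores.copy()
    if data.group is not None:
        out[data.group.name or "group"] = data.group.to_numpy()
    out.to_csv(path, index=False, na_rep=missing_token)


def column_map_for(data: LongitudinalDataset) -> dict[str, tuple[str, str]]:
    """The column map matching files produced by :func:`write_wide_csv`."""
    return {
        _canon(d, w): (w, d)
        for d in data.domain_labels
        for w in data.wave_labels
    }


def describe(data: LongitudinalDataset) -> dict:
    """Per-variable summary and pairwise-complete covariance matrix.

    Variances and covariances use the n-1 divisor (sample convention);
    variables with fewer than two observations get NaN variance and are
    listed under ``flagged``.
    """
    if data.n == 0:
        raise DataError("empty dataset")
    df = data.scores
    counts = df.notna().sum()
    summary = pd.DataFrame(
        {
            "n": counts,
            "mean": df.mean(),
            "variance": df.var(),  # pandas: ddof=1, skipna
            "missing": df.isna().sum(),
        }
    )
    flagged = [c for c in df.columns if counts[c] < 2]
    return {
        "summary": summary,
        "covariance": df.cov(),  # pairwise complete, ddof=1
        "flagged": flagged,
    }


# ---------------------------------------------------------------------------
# Study configuration files
# ---------------------------------------------------------------------------


@dataclass
class StudyConfig:
    """Analysis configuration loaded from YAML.

    Keys: ``column_map`` (column -> [wave, domain]), optional ``reliabilities``
    (domain -> wave -> Rxx), ``missing_tokens``, ``group_column``,
    ``person_id_column`` and free-form ``options``.
    """

    column_map: dict[str, tuple[str, str]]
    reliabilities: dict[str, dict[str, float]] | None = None
    missing_tokens: tuple[str, ...] = DEFAULT_MISSING_TOKENS
    group_column: str | None = None
    person_id_column: str | None = None
    options: dict = field(default_factory=dict)


def load_config(path: str | Path) -> StudyConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "column_map" not in raw:
        raise DataError(f"config {path} must define a column_map")
    cmap = {
        str(col): (str(wd[0]), str(wd[1])) for col, wd in raw["column_map"].items()
    }
    return StudyConfig(
        column_map=cmap,
        reliabilities=raw.get("reliabilities"),
        missing_tokens=tuple(raw.get("missing_tokens", DEFAULT_MISSING_TOKENS)),
        group_column=raw.get("group_column"),
        person_id_column=raw.get("person_id_column"),
        options=raw.get("options", {}),
    )
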