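"""Reading, validation and prevalence filtering of merged abundance tables.

The on-disk dialect is the MetaPhlAn2 merged table: a TSV whose first column
holds a ``|``-separated clade lineage (``k__``, ``p__``, ``c__``, ``o__``,
``f__``, ``g__``, ``s__`` prefixes) and whose remaining columns hold per-sample
percent abundances.  Only species-level rows (lineages terminating in an
``s__`` segment) enter the analysis; percentages are converted to fractions.

Sample metadata is a TSV with columns ``sample_id``, ``cohort`` and either a
pre-assigned ``group`` (``obese`` / ``healthy``) or a numeric ``bmi`` that is
binarised as obese (BMI >= 30) vs healthy (BMI < 25); samples in between are
excluded from analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ContractError, DataError, FormatError

logger = logging.getLogger(__name__)

OBESE = "obese"
HEALTHY = "healthy"
EXCLUDED = "excluded"

#: BMI cut points of the binary design.
BMI_OBESE = 30.0
BMI_HEALTHY = 25.0

_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__", "t__")


@dataclass
class AbundanceTable:
    """Samples x species relative abundances with cohort/group metadata.

    ``values`` is a DataFrame indexed by sample id with species-id columns,
    entries are relative-abundance *fractions* (not percent).  ``cohort`` and
    ``group`` are Series aligned to the sample index.
    """

    values: pd.DataFrame
    cohort: pd.Series
    group: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise FormatError("duplicate sample ids")
        if v.columns.has_duplicates:
            raise FormatError("duplicate species ids")
        arr = v.to_numpy(dtype=float)
        if np.any(arr < 0):
            raise FormatError("negative abundance values")
        row_sums = arr.sum(axis=1)
        if np.any(row_sums > 1.0 + 1e-6):
            raise FormatError("sample abundance sums exceed 1")
        self.cohort = self.cohort.reindex(v.index)
        self.group = self.group.reindex(v.index)
        if self.cohort.isna().any():
            missing = list(v.index[self.cohort.isna()])[:5]
            raise DataError(f"samples without cohort label: {missing}")
        if self.group.isna().any():
            missing = list(v.index[self.group.isna()])[:5]
            raise DataError(f"samples without group label: {missing}")

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_species(self) -> int:
        return self.values.shape[1]

    def cohorts(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.cohort:
            seen.setdefault(c, None)
        return list(seen)

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def group_labels(self, positive: str = OBESE) -> np.ndarray:
        """Binary labels: 1 for ``positive`` group, 0 otherwise."""
        return (self.group.to_numpy() == positive).astype(int)

    # -- subsetting ------------------------------------------------------
    def subset_samples(self, sample_ids: Iterable[str]) -> "AbundanceTable":
        idx = list(sample_ids)
        return AbundanceTable(
            self.values.loc[idx], self.cohort.loc[idx], self.group.loc[idx]
        )

    def subset_cohort(self, cohort: str) -> "AbundanceTable":
        mask = self.cohort == cohort
        if not mask.any():
            raise DataError(f"unknown cohort: {cohort}")
        return self.subset_samples(self.values.index[mask])

    def select_species(self, species_ids: Iterable[str]) -> "AbundanceTable":
        cols = list(species_ids)
        unknown = [s for s in cols if s not in self.values.columns]
        if unknown:
            raise ContractError(f"unknown species: {unknown[:5]}")
        return AbundanceTable(self.values[cols], self.cohort, self.group)


def assign_groups(bmi: Mapping[str, float]) -> dict[str, str]:
    """Binarise BMI: >= 30 obese, < 25 healthy, in-between excluded."""
    out: dict[str, str] = {}
    for sample, value in bmi.items():
        v = float(value)
        if not np.isfinite(v) or v <= 0:
            raise DataError(f"non-positive BMI for sample {sample!r}: {value}")
        if v >= BMI_OBESE:
            out[sample] = OBESE
        elif v < BMI_HEALTHY:
            out[sample] = HEALTHY
        else:
            out[sample] = EXCLUDED
    return out


def _species_name(lineage: str) -> str | None:
    """Species name if the lineage terminates at species rank, else None."""
    segments = lineage.strip().split("|")
    last = segments[-1]
    if not last.startswith("s__"):
        return None
    return last[3:]


def read_merged_profile(table_path: str | Path, metadata_path: str | Path) -> AbundanceTable:
    """Read a MetaPhlAn2-style merged table plus metadata into an AbundanceTable.

    Keeps only species-level rows, converts percent to fractions, and drops
    (with a logged warning) samples that are absent from the metadata or whose
    BMI falls in the excluded band.
    """
    table_path, metadata_path = Path(table_path), Path(metadata_path)
    with open(table_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise FormatError("merged table needs a lineage column and >=1 sample column")
    sample_cols = header[1:]
    if len(set(sample_cols)) != len(sample_cols):
        dupes = sorted({s for s in sample_cols if sample_cols.count(s) > 1})
        raise FormatError(f"duplicate sample columns: {dupes}")

    raw = pd.read_csv(table_path, sep="\t", index_col=0, header=0)
    species_rows = {}
    for lineage, row in raw.iterrows():
        name = _species_name(str(lineage))
        if name is None:
            continue
        if name in species_rows:
            raise FormatError(f"duplicate species-level lineage for {name!r}")
        species_rows[name] = row.to_numpy(dtype=float)
    if not species_rows:
        raise FormatError("no species-level rows in merged table")

    values = pd.DataFrame(species_rows, index=sample_cols)
    if (values.to_numpy() < 0).any():
        raise FormatError("negative abundance in merged table")
    values = values / 100.0  # percent -> fraction

    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in meta.columns or "cohort" not in meta.columns:
        raise FormatError("metadata must have sample_id and cohort columns")
    meta = meta.set_index("sample_id")
    if meta.index.has_duplicates:
        raise FormatError("duplicate sample_id in metadata")
    if "group" in meta.columns:
        group = meta["group"].astype(str)
    elif "bmi" in meta.columns:
        group = pd.Series(assign_groups(meta["bmi"].to_dict()))
    else:
        raise FormatError("metadata must have a group or bmi column")

    keep = [s for s in sample_cols if s in meta.index and group.get(s) != EXCLUDED]
    dropped = [s for s in sample_cols if s not in meta.index]
    if dropped:
        logger.warning("dropping %d samples absent from metadata: %s",
                       len(dropped), dropped[:5])
    excluded = [s for s in sample_cols if s in meta.index and group.get(s) == EXCLUDED]
    if excluded:
        logger.warning("dropping %d samples with BMI in the excluded band", len(excluded))
    if not keep:
        raise DataError("no samples left after metadata matching")
    return AbundanceTable(values.loc[keep], meta["cohort"].astype(str).loc[keep],
                          group.loc[keep])


def write_merged_profile(table: AbundanceTable, path: str | Path) -> None:
    """Write the species-level matrix in the merged-table dialect (percent)."""
    out = (table.values * 100.0).T
    out.index = [f"k__Bacteria|s__{s}" for s in out.index]
    out.index.name = "clade_name"
    out.to_csv(path, sep="\t", float_format="%.17g")


def write_metadata(table: AbundanceTable, path: str | Path) -> None:
    meta = pd.DataFrame({
        "sample_id": table.sample_ids,
        "cohort": table.cohort.to_numpy(),
        "group": table.group.to_numpy(),
    })
    meta.to_csv(path, sep="\t", index=False)


def _cell_prevalence(table: AbundanceTable, per_group: bool = True) -> pd.DataFrame:
    """Prevalence (fraction of samples with abundance > 0) per cell x species.

    Cells are cohort x group when ``per_group``, else whole cohorts.
    """
    present = table.values > 0
    if per_group:
        keys = pd.MultiIndex.from_arrays([table.cohort, table.group])
        return present.groupby(keys).mean()
    return present.groupby(table.cohort.to_numpy()).mean()


def filter_low_prevalence(table: AbundanceTable, threshold: float = 0.10,
                          per_group: bool = True) -> AbundanceTable:
    """Remove species whose prevalence is <= threshold in *every* cell.

    A species survives as soon as its prevalence strictly exceeds the
    threshold in any one cohort x group cell ("not more than 10%" reads as
    the removal condition).  Sample set is preserved.
    """
    if per_group:
        for cohort in table.cohorts():
            groups = set(table.group[table.cohort == cohort])
            if not {OBESE, HEALTHY} <= groups:
                raise DataError(f"cohort {cohort!r} is missing a group")
    prev = _cell_prevalence(table, per_group=per_group)
    keep = (prev > threshold).any(axis=0)
    kept = [s for s in table.species_ids if keep[s]]
    return table.select_species(kept)


def shared_species(table: AbundanceTable, threshold: float = 0.10,
                   per_group: bool = True) -> set[str]:
    """Species surviving the prevalence filter in every cohort (intersection)."""
    cohorts = table.cohorts()
    if len(cohorts) < 2:
        raise DataError("shared_species needs >=2 cohorts")
    surviving: list[set[str]] = []
    for cohort in cohorts:
        sub = table.subset_cohort(cohort)
        kept = filter_low_prevalence(sub, threshold=threshold, per_group=per_group)
        surviving.append(set(kept.species_ids))
    return set.intersection(*surviving)
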