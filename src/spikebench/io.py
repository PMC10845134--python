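"""Reading, validating and annotating DIA-NN-style quantification matrices.

The expected input is the wide matrix DIA-NN writes (``pg_matrix.tsv`` /
``pr_matrix.tsv``): one row per protein group or precursor, one numeric
column per run.  A separate run-design table maps run columns to the two
benchmark conditions and replicate indices.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RunDesign",
    "QuantMatrix",
    "read_run_design",
    "read_quant_matrix",
    "write_quant_matrix",
    "assign_species",
    "remove_contaminants",
    "read_contaminant_list",
    "AMBIGUOUS",
    "UNKNOWN",
]

logger = logging.getLogger("spikebench")

AMBIGUOUS = "ambiguous"
UNKNOWN = "unknown"

# Candidate entry-identifier columns, tried in order (DIA-NN dialects).
ID_COLUMN_CANDIDATES = ("Protein.Group", "Precursor.Id", "Protein.Ids", "entry_id")

DEFAULT_SUFFIX_MAP = {
    "_HUMAN": "human",
    "_YEAST": "yeast",
    "_ECOLI": "ecoli",
}


@dataclass(frozen=True)
class RunDesign:
    """Maps matrix run columns to benchmark conditions A/B.

    ``run_ids`` is the column order expected in the matrix; ``condition``
    holds "A" or "B" per run; ``replicate_index`` is a positive integer
    per run.  Both conditions must be present with at least 2 replicates
    each (needed for CVs and the two-group test).
    """

    run_ids: tuple[str, ...]
    condition: tuple[str, ...]
    replicate_index: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.run_ids) == len(self.condition) == len(self.replicate_index)):
            raise ValueError("run_ids, condition and replicate_index must align")
        if len(set(self.run_ids)) != len(self.run_ids):
            raise ValueError("duplicate run ids in design")
        conds = set(self.condition)
        if not conds <= {"A", "B"}:
            raise ValueError(f"conditions must be 'A' or 'B', got {sorted(conds)}")
        if conds != {"A", "B"}:
            raise ValueError("both conditions A and B must be present")
        for cond in ("A", "B"):
            if self.n_replicates(cond) < 2:
                raise ValueError(f"condition {cond} needs >=2 replicates")
        if any(r < 1 for r in self.replicate_index):
            raise ValueError("replicate indices must be positive")

    def runs(self, cond: str) -> tuple[str, ...]:
        return tuple(r for r, c in zip(self.run_ids, self.condition) if c == cond)

    def n_replicates(self, cond: str) -> int:
        return sum(1 for c in self.condition if c == cond)


def read_run_design(path: str | Path) -> RunDesign:
    """Read a run-design TSV with columns run_id, condition, replicate."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("run_id", "condition", "replicate"):
        if col not in table.columns:
            raise ValueError(f"run design missing column {col!r}")
    return RunDesign(
        tuple(table["run_id"]),
        tuple(table["condition"]),
        tuple(int(r) for r in table["replicate"]),
    )


@dataclass
class QuantMatrix:
    """An entries x runs intensity table with species annotations.

    ``intensities`` is a DataFrame indexed by entry id with one float
    column per run (NaN = missing; zeros are mapped to missing on read by
    default since a zero intensity is not a valid measurement).
    ``species`` and ``is_contaminant`` are aligned to the index; species
    is a design species name or ``ambiguous``/``unknown``.
    """

    intensities: pd.DataFrame
    level: str = "protein_group"
    species: pd.Series | None = None
    is_contaminant: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.level not in {"protein_group", "precursor"}:
            raise ValueError("level must be 'protein_group' or 'precursor'")
        if self.intensities.index.has_duplicates:
            dupes = self.intensities.index[self.intensities.index.duplicated()]
            raise ValueError(f"duplicate entry ids: {sorted(set(dupes))[:5]}")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise ValueError("negative intensities are invalid")
        if self.species is None:
            self.species = pd.Series(UNKNOWN, index=self.intensities.index)
        if self.is_contaminant is None:
            self.is_contaminant = pd.Series(False, index=self.intensities.index)

    @property
    def entry_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def n_entries(self) -> int:
        return len(self.intensities)

    def subset(self, keep: pd.Series | np.ndarray) -> "QuantMatrix":
        return QuantMatrix(
            self.intensities.loc[keep],
            level=self.level,
            species=self.species.loc[keep],
            is_contaminant=self.is_contaminant.loc[keep],
        )


def read_quant_matrix(
    path: str | Path,
    level: str,
    run_design: RunDesign,
    *,
    id_column: str | None = None,
    zero_is_missing: bool = True,
) -> QuantMatrix:
    """Parse a wide DIA-NN-style TSV into a :class:`QuantMatrix`.

    Columns are re-ordered to match ``run_design.run_ids``; annotation
    columns other than the identifier are ignored (a ``species`` column,
    if present, is carried through for :func:`assign_species`).  Empty
    cells and non-numeric tokens parse as missing; literal ``0`` is
    treated as missing unless ``zero_is_missing=False``.
    """
    header = pd.read_csv(path, sep="\t", nrows=0).columns
    if id_column is None:
        for cand in ID_COLUMN_CANDIDATES:
            if cand in header:
                id_column = cand
                break
        else:
            id_column = header[0]
    elif id_column not in header:
        raise ValueError(f"identifier column {id_column!r} not found")

    for run in run_design.run_ids:
        if run not in header:
            raise ValueError(f"run column not found: {run!r}")

    # round_trip parsing keeps write->read bit-identical
    table = pd.read_csv(
        path, sep="\t", dtype={id_column: str}, float_precision="round_trip"
    )
    ids = table[id_column]
    if ids.duplicated().any():
        dupes = sorted(set(ids[ids.duplicated()]))
        raise ValueError(f"duplicate entry ids: {dupes[:5]}")

    inten = table[list(run_design.run_ids)].apply(_as_float_exact)
    if zero_is_missing:
        inten = inten.mask(inten == 0)
    inten.index = pd.Index(ids, name=id_column)

    species = None
    if "species" in table.columns:
        species = pd.Series(table["species"].to_numpy(), index=inten.index)

    matrix = QuantMatrix(inten, level=level, species=species)
    logger.info("read %d %s entries x %d runs from %s",
                matrix.n_entries, level, len(run_design.run_ids), path)
    return matrix


def _as_float_exact(col: pd.Series) -> pd.Series:
    """Column to float64; non-numeric tokens -> NaN, exact parsing.

    Python's float() round-trips the 17-significant-digit decimals the
    writer emits, unlike pandas' fast to_numeric parser.
    """
    if pd.api.types.is_numeric_dtype(col):
        return col.astype(float)

    def conv(v):
        try:
            return float(v)
        except (TypeError, ValueError):
            return np.nan

    return col.map(conv, na_action="ignore").astype(float)


def write_quant_matrix(matrix: QuantMatrix, path: str | Path) -> None:
    """Write a matrix as UTF-8 TSV (missing values as empty cells).

    Together with :func:`read_quant_matrix` this round-trips values and
    missingness exactly (floats serialized with repr precision).
    """
    out = matrix.intensities.copy()
    out.insert(0, "species", matrix.species)
    out.to_csv(path, sep="\t", index=True, float_format="%.17g", na_rep="")


def assign_species(
    matrix: QuantMatrix,
    suffix_map: Mapping[str, str] | None = None,
    *,
    prefer_species_column: bool = True,
) -> QuantMatrix:
    """Annotate each entry with its species from identifier suffixes.

    A protein-group id may contain several ``;``-separated accessions; if
    all map to one species the group gets it, mixed groups become
    ``ambiguous`` and unmatched ids ``unknown``.  If the matrix already
    carries an explicit species column (DIA-NN ``--species-genes`` style)
    and ``prefer_species_column`` is set, it is kept where non-null.
    """
    if suffix_map is None:
        suffix_map = DEFAULT_SUFFIX_MAP
    if not suffix_map:
        raise ValueError("suffix_map must not be empty")

    existing = matrix.species if prefer_species_column else None

    def classify(entry_id: str) -> str:
        hits = set()
        for part in str(entry_id).split(";"):
            part = part.strip()
            matched = None
            for suffix, sp in suffix_map.items():
                if suffix in part:
                    matched = sp
                    break
            hits.add(matched if matched is not None else UNKNOWN)
        if len(hits) == 1:
            return hits.pop()
        hits.discard(UNKNOWN)
        return hits.pop() if len(hits) == 1 else AMBIGUOUS

    assigned = pd.Series(
        [classify(eid) for eid in matrix.entry_ids], index=matrix.entry_ids
    )
    if existing is not None:
        known = existing.notna() & ~existing.isin([UNKNOWN])
        assigned = assigned.where(~known, existing)
    return QuantMatrix(
        matrix.intensities,
        level=matrix.level,
        species=assigned,
        is_contaminant=matrix.is_contaminant,
    )


def read_contaminant_list(path: str | Path) -> list[str]:
    """Plain-text contaminant identifiers, one per line ('#' comments)."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def remove_contaminants(
    matrix: QuantMatrix,
    contaminant_ids: Iterable[str] = (),
    *,
    marker_prefix: str = "CON__",
) -> QuantMatrix:
    """Drop entries matching a contaminant list or marker prefix.

    Contaminants carry no ground-truth fold change, so they are removed
    before any benchmark statistic.  An entry is contaminant if any of
    its ``;``-separated accessions is in ``contaminant_ids`` or starts
    with ``marker_prefix``.
    """
    con_set = set(contaminant_ids)

    def is_con(entry_id: str) -> bool:
        return any(
            part.strip() in con_set or part.strip().startswith(marker_prefix)
            for part in str(entry_id).split(";")
        )

    flags = np.array([is_con(eid) for eid in matrix.entry_ids])
    removed = int(flags.sum())
    logger.info("removed %d contaminant entries of %d", removed, matrix.n_entries)
    result = matrix.subset(~flags)
    if result.n_entries == 0:
        warnings.warn("all entries were contaminants; matrix is empty")
    n_unannotated = int(result.species.isin([AMBIGUOUS, UNKNOWN]).sum())
    if n_unannotated:
        warnings.warn(
            f"{n_unannotated} entries are ambiguous/unknown species; they are "
            "kept in identification counts but excluded from ground-truth statistics"
        )
    return result
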