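"""Reading and validating MaxQuant-dialect peptide tables, experimental
designs and proteome FASTA files, and building the log2 intensity matrix.

The quantification input is a tab-separated "modification-specific peptide"
table: one row per (sequence, modification-set) species with one raw MS1
intensity column per LC-MS run.  Semantic columns (sequence, modifications,
decoy/contaminant flags, per-run intensities) are mapped onto header names
through a :class:`TableDialect`, defaulting to MaxQuant 1.6 conventions.
Raw intensity 0 is the MaxQuant encoding for "not quantified" and becomes an
explicit missing marker (NaN) on the log2 scale.

The modifications cell is a semicolon-separated list of ``Name@position``
tokens with 1-based peptide positions, e.g. ``Phospho (STY)@3``; an empty
cell or the literal ``Unmodified`` means no variable modification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ConfigError, DataError, DialectError

DEFAULT_STRAINS = ("wt_as", "pka_as", "sch9_as", "pka_sch9_as", "ypk1_as")
TREATMENTS = ("drug", "mock")

PHOSPHO_MOD = "Phospho (STY)"


@dataclass(frozen=True)
class TableDialect:
    """Mapping of semantic columns onto header names (MaxQuant 1.6 defaults)."""

    sequence: str = "Sequence"
    modifications: str = "Modifications"
    proteins: str = "Proteins"
    leading_protein: str = "Leading razor protein"
    localization: str = "Localization prob"
    reverse: str = "Reverse"
    contaminant: str = "Potential contaminant"
    intensity_prefix: str = "Intensity "

    def intensity_column(self, run_id: str) -> str:
        return f"{self.intensity_prefix}{run_id}"


DEFAULT_DIALECT = TableDialect()


@dataclass
class PeptideRecord:
    """One modification-specific peptide species with per-run intensities."""

    peptide_id: str
    sequence: str
    modifications: tuple[tuple[str, int], ...]
    n_phospho: int
    proteins: tuple[str, ...]
    leading_protein: str
    localization_score: float
    is_reverse: bool
    is_contaminant: bool
    intensities: dict[str, float]

    def __post_init__(self) -> None:
        for name, pos in self.modifications:
            if not (1 <= pos <= len(self.sequence)):
                raise DataError(
                    f"modification {name}@{pos} outside peptide "
                    f"{self.peptide_id!r} of length {len(self.sequence)}"
                )
        n_ph = sum(1 for name, _ in self.modifications if "Phospho" in name)
        if self.n_phospho != n_ph:
            raise DataError(
                f"peptide {self.peptide_id!r}: n_phospho={self.n_phospho} "
                f"but {n_ph} phospho modifications declared"
            )

    @property
    def phospho_positions(self) -> tuple[int, ...]:
        return tuple(
            pos for name, pos in self.modifications if "Phospho" in name
        )


def format_modifications(mods: Iterable[tuple[str, int]]) -> str:
    toks = [f"{name}@{pos}" for name, pos in mods]
    return ";".join(toks) if toks else "Unmodified"


def parse_modifications(cell: object) -> tuple[tuple[str, int], ...]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return ()
    text = str(cell).strip()
    if not text or text == "Unmodified":
        return ()
    mods = []
    for tok in text.split(";"):
        tok = tok.strip()
        if not tok:
            continue
        name, _, pos = tok.rpartition("@")
        if not name:
            raise DataError(f"malformed modification token {tok!r}")
        mods.append((name, int(pos)))
    return tuple(mods)


# ---------------------------------------------------------------------------
# experimental design


def make_design(
    strains: Sequence[str] = DEFAULT_STRAINS,
    treatments: Sequence[str] = TREATMENTS,
    replicates: int = 3,
) -> pd.DataFrame:
    """Build a fully crossed run design (strain x treatment x replicate)."""
    rows = []
    for strain in strains:
        for treatment in treatments:
            for rep in range(1, replicates + 1):
                rows.append(
                    {
                        "run_id": f"{strain}_{treatment}_{rep}",
                        "strain": strain,
                        "treatment": treatment,
                        "replicate": rep,
                        "batch": rep,
                    }
                )
    return pd.DataFrame(rows)


def validate_design(design: pd.DataFrame, replicates: int = 3) -> pd.DataFrame:
    required = {"run_id", "strain", "treatment", "replicate"}
    missing = required - set(design.columns)
    if missing:
        raise ConfigError(f"design lacks columns: {sorted(missing)}")
    design = design.copy()
    if "batch" not in design.columns:
        design["batch"] = design["replicate"]
    triples = design[["strain", "treatment", "replicate"]]
    if triples.duplicated().any():
        raise ConfigError("duplicate (strain, treatment, replicate) in design")
    counts = design.groupby(["strain", "treatment"], sort=False).size()
    bad = counts[counts != replicates]
    if len(bad):
        raise ConfigError(
            f"groups without exactly {replicates} replicates: "
            f"{list(bad.index)}"
        )
    return design


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_design(df)


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# peptide table


def read_peptide_table(
    path,
    design: pd.DataFrame,
    dialect: TableDialect = DEFAULT_DIALECT,
) -> list[PeptideRecord]:
    """Parse a MaxQuant-dialect modification-specific peptide table.

    Raw intensity cells that are empty are read as 0 (MaxQuant's "not
    quantified"); the 0 -> missing conversion happens in
    :func:`build_log2_matrix`, keeping this parse lossless.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    run_ids = list(design["run_id"])
    needed = {
        "sequence": dialect.sequence,
        "modifications": dialect.modifications,
        "reverse": dialect.reverse,
        "contaminant": dialect.contaminant,
    }
    for semantic, col in needed.items():
        if col not in df.columns:
            raise DialectError(
                f"table lacks the {semantic!r} column mapped to {col!r}"
            )
    for run in run_ids:
        if dialect.intensity_column(run) not in df.columns:
            raise DialectError(
                f"table lacks the intensity column "
                f"{dialect.intensity_column(run)!r} for run {run!r}"
            )

    records = []
    for idx, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        intensities = {}
        for run in run_ids:
            cell = row[dialect.intensity_column(run)].strip()
            if cell == "":
                value = 0.0
            else:
                try:
                    value = float(cell)
                except ValueError:
                    raise DataError(
                        f"non-numeric intensity {cell!r} in row {idx} "
                        f"(run {run})"
                    ) from None
            intensities[run] = value
        mods = parse_modifications(row[dialect.modifications])
        proteins_cell = row.get(dialect.proteins, "")
        proteins = tuple(p for p in proteins_cell.split(";") if p)
        leading = row.get(dialect.leading_protein, "") or (
            proteins[0] if proteins else ""
        )
        loc_cell = row.get(dialect.localization, "")
        loc = float(loc_cell) if loc_cell not in ("", "NA") else float("nan")
        pid = row.get("id", "") or f"row{idx}"
        records.append(
            PeptideRecord(
                peptide_id=pid,
                sequence=row[dialect.sequence],
                modifications=mods,
                n_phospho=sum(1 for n, _ in mods if "Phospho" in n),
                proteins=proteins,
                leading_protein=leading,
                localization_score=loc,
                is_reverse=row[dialect.reverse].strip() == "+",
                is_contaminant=row[dialect.contaminant].strip() == "+",
                intensities=intensities,
            )
        )
    return records


def write_peptide_table(
    records: Sequence[PeptideRecord],
    design: pd.DataFrame,
    path,
    dialect: TableDialect = DEFAULT_DIALECT,
) -> None:
    """Serialize records back to the tab-separated dialect (round-trip safe)."""
    run_ids = list(design["run_id"])
    rows = []
    for r in records:
        row = {
            "id": r.peptide_id,
            dialect.sequence: r.sequence,
            dialect.modifications: format_modifications(r.modifications),
            dialect.proteins: ";".join(r.proteins),
            dialect.leading_protein: r.leading_protein,
            dialect.localization: (
                "" if math.isnan(r.localization_score)
                else repr(r.localization_score)
            ),
            dialect.reverse: "+" if r.is_reverse else "",
            dialect.contaminant: "+" if r.is_contaminant else "",
        }
        for run in run_ids:
            v = r.intensities.get(run, 0.0)
            row[dialect.intensity_column(run)] = (
                str(int(v)) if float(v).is_integer() else repr(float(v))
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def filter_contaminants_decoys(
    records: Sequence[PeptideRecord],
) -> list[PeptideRecord]:
    """Drop decoy (reverse) and contaminant entries, preserving order."""
    return [r for r in records if not (r.is_reverse or r.is_contaminant)]


def select_phospho(records: Sequence[PeptideRecord]) -> list[PeptideRecord]:
    """Keep peptides carrying at least one phosphorylation."""
    return [r for r in records if r.n_phospho >= 1]


# ---------------------------------------------------------------------------
# intensity matrix


@dataclass
class LogIntensityMatrix:
    """log2 MS1 intensities, peptides x runs; NaN marks a missing value."""

    values: pd.DataFrame  # index: peptide_id, columns: run_id
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.design["run_id"]):
            raise ConfigError("matrix columns do not follow the design runs")

    def group_columns(self) -> dict[tuple[str, str], list[str]]:
        """Run ids per (strain, treatment) group, ordered by replicate."""
        out: dict[tuple[str, str], list[str]] = {}
        d = self.design.sort_values("replicate", kind="mergesort")
        for row in d.itertuples(index=False):
            out.setdefault((row.strain, row.treatment), []).append(row.run_id)
        return out

    def copy(self) -> "LogIntensityMatrix":
        return LogIntensityMatrix(self.values.copy(), self.design)


def build_log2_matrix(
    records: Sequence[PeptideRecord], design: pd.DataFrame
) -> LogIntensityMatrix:
    """log2-transform raw intensities; 0 or absent becomes missing (NaN)."""
    run_ids = list(design["run_id"])
    data = np.empty((len(records), len(run_ids)))
    ids = []
    for i, r in enumerate(records):
        ids.append(r.peptide_id)
        for j, run in enumerate(run_ids):
            v = r.intensities.get(run, 0.0)
            if v < 0:
                raise DataError(
                    f"negative intensity {v} for peptide {r.peptide_id!r}"
                )
            data[i, j] = np.log2(v) if v > 0 else np.nan
    values = pd.DataFrame(data, index=pd.Index(ids, name="peptide_id"),
                          columns=run_ids)
    if values.index.duplicated().any():
        raise DataError("duplicate peptide ids in records")
    return LogIntensityMatrix(values, design)


# ---------------------------------------------------------------------------
# FASTA and result tables


def read_proteome_fasta(path) -> dict[str, str]:
    """Read a proteome FASTA into {accession: uppercase sequence}.

    The accession is the first whitespace-delimited token of the header.
    """
    proteome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        if acc in proteome:
            raise DataError(f"duplicate accession {acc!r} in FASTA")
        proteome[acc] = str(rec.seq).upper()
    if not proteome:
        raise DataError(f"no FASTA records found in {path}")
    return proteome


def write_proteome_fasta(proteome: Mapping[str, str], path, width=60) -> None:
    with open(path, "w") as fh:
        for acc, seq in proteome.items():
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_results_tsv(table: pd.DataFrame, path) -> None:
    """Write a rectangular result table as TSV; missing rendered as ``NA``.

    Floats use Python repr, which round-trips at full precision.
    """
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
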