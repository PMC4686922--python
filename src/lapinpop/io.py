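"""Readers and writers for multilocus genotype files.

Supported formats
-----------------
``genepop``
    GenePop text with zero-padded fixed-width alleles (3 digits per
    allele by default, i.e. 6-digit genotypes; 2-digit alleles are
    accepted on input).  Hierarchy labels are carried in the individual
    name as ``group|unit|subunit|id`` so that round-trips are lossless;
    plain GenePop files whose names lack the ``|`` separators are read
    with each ``pop`` block becoming one domestic unit.
``structure``
    Whitespace table, two rows per individual, missing allele ``-9``,
    with leading label columns ``id group unit subunit`` and a header
    row of locus names (STRUCTURE-compatible via its extra-columns
    options).
``csv_two_column``
    CSV with label columns ``id,group,unit,subunit,sex`` followed by two
    columns per locus (``NAME`` and ``NAME.2``); 0 encodes missing.
``xlsx_table``
    The same table as ``csv_two_column`` in the first worksheet of an
    XLSX workbook.
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .genotypes import (
    MISSING,
    GenotypeDataset,
    Individual,
    Locus,
    ValidationError,
)

__all__ = ["read_genotypes", "write_genotypes", "ParseError", "FORMATS"]

FORMATS = ("genepop", "structure", "csv_two_column", "xlsx_table")

LABEL_COLS = ["id", "group", "unit", "subunit", "sex"]


class ParseError(ValueError):
    """A genotype file does not parse in the declared dialect."""


# ---------------------------------------------------------------------
# dispatch


def read_genotypes(path: str | Path, format: str) -> GenotypeDataset:
    """Read a genotype file and return a validated :class:`GenotypeDataset`.

    The returned dataset preserves the file's locus and individual order
    and carries a ``load_report`` dict with per-locus missing-call counts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    readers: dict[str, Callable[[Path], GenotypeDataset]] = {
        "genepop": _read_genepop,
        "structure": _read_structure,
        "csv_two_column": _read_csv,
        "xlsx_table": _read_xlsx,
    }
    if format not in readers:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    ds = readers[format](path)
    ds.load_report["path"] = str(path)
    ds.load_report["format"] = format
    ds.load_report["missing_per_locus"] = ds.missing_per_locus()
    return ds


def write_genotypes(dataset: GenotypeDataset, path: str | Path, format: str) -> None:
    """Write *dataset* so that :func:`read_genotypes` recovers it exactly."""
    writers: dict[str, Callable[[GenotypeDataset, Path], None]] = {
        "genepop": _write_genepop,
        "structure": _write_structure,
        "csv_two_column": _write_csv,
        "xlsx_table": _write_xlsx,
    }
    if format not in writers:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    writers[format](dataset, Path(path))


# ---------------------------------------------------------------------
# tabular dialect (CSV / XLSX)


def _frame_to_dataset(df: pd.DataFrame, where: str) -> GenotypeDataset:
    cols = list(df.columns)
    for c in ("id", "group", "unit"):
        if c not in cols:
            raise ParseError(f"{where}: missing required column {c!r}")
    allele_cols = [c for c in cols if c not in LABEL_COLS]
    if len(allele_cols) % 2:
        raise ParseError(f"{where}: odd number of allele columns")
    locus_names = []
    for k in range(0, len(allele_cols), 2):
        a, b = allele_cols[k], allele_cols[k + 1]
        if b not in (f"{a}.2", f"{a}.1"):  # pandas mangles duplicates to NAME.1
            raise ParseError(f"{where}: columns {a!r}/{b!r} are not a locus pair")
        locus_names.append(a)
    individuals = []
    for r, row in df.iterrows():
        sub = row.get("subunit")
        sex = row.get("sex")
        sub = None if pd.isna(sub) or sub in ("", None) else str(sub)
        sex = None if pd.isna(sex) or sex in ("", None) else str(sex)
        try:
            individuals.append(
                Individual(str(row["id"]), str(row["group"]), str(row["unit"]),
                           sub, sex)
            )
        except ValidationError as e:
            raise ParseError(f"{where}: row {r}: {e}") from e
    try:
        calls = (
            df[allele_cols].to_numpy(dtype=np.int64).reshape(len(df), -1, 2)
        )
    except (TypeError, ValueError) as e:
        raise ParseError(f"{where}: malformed allele token ({e})") from e
    loci = [Locus(n) for n in locus_names]
    return GenotypeDataset(loci, individuals, calls)


def _dataset_to_frame(dataset: GenotypeDataset) -> pd.DataFrame:
    data: dict[str, list] = {
        "id": [i.id for i in dataset.individuals],
        "group": [i.group for i in dataset.individuals],
        "unit": [i.unit for i in dataset.individuals],
        "subunit": [i.subunit or "" for i in dataset.individuals],
        "sex": [i.sex or "" for i in dataset.individuals],
    }
    df = pd.DataFrame(data)
    for j, loc in enumerate(dataset.loci):
        df[loc.name] = dataset.calls[:, j, 0]
        df[f"{loc.name}.2"] = dataset.calls[:, j, 1]
    return df


def _read_csv(path: Path) -> GenotypeDataset:
    df = pd.read_csv(path, dtype={"id": str})
    return _frame_to_dataset(df, str(path))


def _write_csv(dataset: GenotypeDataset, path: Path) -> None:
    _dataset_to_frame(dataset).to_csv(path, index=False)


def _read_xlsx(path: Path) -> GenotypeDataset:
    df = pd.read_excel(path, sheet_name=0, dtype={"id": str})
    return _frame_to_dataset(df, str(path))


def _write_xlsx(dataset: GenotypeDataset, path: Path) -> None:
    _dataset_to_frame(dataset).to_excel(path, index=False)


# ---------------------------------------------------------------------
# GenePop


def _genepop_name(ind: Individual) -> str:
    return "|".join([ind.group, ind.unit, ind.subunit or "", ind.id])


def _parse_genepop_name(name: str, pop_index: int) -> Individual:
    if "|" in name:
        parts = name.split("|")
        if len(parts) != 4:
            raise ParseError(f"bad individual name {name!r}")
        group, unit, sub, iid = parts
        return Individual(iid, group, unit, sub or None)
    return Individual(name, "domestic", f"pop{pop_index}")


def _read_genepop(path: Path) -> GenotypeDataset:
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    body = lines[1:]  # first line is a free-text title
    locus_names: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        chunk = body[i].strip()
        if chunk:
            locus_names.extend(n.strip() for n in chunk.split(",") if n.strip())
        i += 1
    if i == len(body):
        raise ParseError(f"{path}: no 'pop' line found")
    individuals: list[Individual] = []
    rows: list[list[int]] = []
    pop_index = 0
    for lineno, line in enumerate(body[i:], start=i + 2):
        if not line.strip():
            continue
        if line.strip().lower() == "pop":
            pop_index += 1
            continue
        if "," not in line:
            raise ParseError(f"{path}: line {lineno}: expected 'name , genotypes'")
        name, geno = line.split(",", 1)
        tokens = geno.split()
        if len(tokens) != len(locus_names):
            raise ParseError(
                f"{path}: line {lineno}: {len(tokens)} genotypes for "
                f"{len(locus_names)} loci"
            )
        alleles: list[int] = []
        for col, tok in enumerate(tokens):
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise ParseError(
                    f"{path}: line {lineno}, locus {locus_names[col]!r}: "
                    f"malformed allele token {tok!r}"
                )
            w = len(tok) // 2
            alleles.extend([int(tok[:w]), int(tok[w:])])
        individuals.append(_parse_genepop_name(name.strip(), pop_index))
        rows.append(alleles)
    calls = np.asarray(rows, dtype=np.int64).reshape(len(rows), len(locus_names), 2)
    return GenotypeDataset([Locus(n) for n in locus_names], individuals, calls)


def _write_genepop(dataset: GenotypeDataset, path: Path) -> None:
    if int(dataset.calls.max(initial=0)) > 999:
        raise ValidationError("allele codes above 999 cannot be written as GenePop")
    out = ["genotypes exported by lapinpop"]
    out.extend(dataset.locus_names)
    # one pop block per unit, preserving first-appearance order
    for unit, idx in dataset.partition("unit").items():
        out.append("pop")
        for i in idx:
            ind = dataset.individuals[i]
            toks = [
                f"{a:03d}{b:03d}" for a, b in dataset.calls[i]
            ]
            out.append(f"{_genepop_name(ind)} ,  " + " ".join(toks))
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------
# STRUCTURE (two rows per individual)

_STRUCT_MISSING = -9


def _read_structure(path: Path) -> GenotypeDataset:
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if len(lines) < 3:
        raise ParseError(f"{path}: too short for a two-row STRUCTURE table")
    locus_names = lines[0].split()
    n_label = 4  # id group unit subunit
    individuals: list[Individual] = []
    rows: list[np.ndarray] = []
    if (len(lines) - 1) % 2:
        raise ParseError(f"{path}: odd number of genotype rows")
    for k in range(1, len(lines), 2):
        r1, r2 = lines[k].split(), lines[k + 1].split()
        if len(r1) != n_label + len(locus_names) or len(r1) != len(r2):
            raise ParseError(f"{path}: line {k + 1}: wrong field count")
        if r1[:n_label] != r2[:n_label]:
            raise ParseError(f"{path}: line {k + 1}: row pair labels differ")
        iid, group, unit, sub = r1[:n_label]
        individuals.append(Individual(iid, group, unit, None if sub == "." else sub))
        try:
            a1 = np.array([int(x) for x in r1[n_label:]], dtype=np.int64)
            a2 = np.array([int(x) for x in r2[n_label:]], dtype=np.int64)
        except ValueError as e:
            raise ParseError(f"{path}: line {k + 1}: malformed allele token ({e})")
        rows.append(np.stack([a1, a2], axis=1))
    calls = np.stack(rows, axis=0)
    calls[calls == _STRUCT_MISSING] = MISSING
    return GenotypeDataset([Locus(n) for n in locus_names], individuals, calls)


def _write_structure(dataset: GenotypeDataset, path: Path) -> None:
    out = [" ".join(dataset.locus_names)]
    for i, ind in enumerate(dataset.individuals):
        labels = [ind.id, ind.group, ind.unit, ind.subunit or "."]
        calls = dataset.calls[i].copy()
        calls[calls == MISSING] = _STRUCT_MISSING
        for c in range(2):
            out.append(" ".join(labels + [str(a) for a in calls[:, c]]))
    path.write_text("\n".join(out) + "\n")
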