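"""Reading, validation and canonicalization of molecule tables.

Input tables are CSV (header with at least ``mol_id`` and ``smiles``
columns, recognized case-insensitively) or ``.smi`` (whitespace-delimited
SMILES plus optional identifier per line).  SMILES are canonicalized at
ingest with stereochemistry retained, so stereoisomers remain distinct
compounds.  Rows whose SMILES do not parse to a molecule with at least one
heavy atom are skipped with a warning and collected in a rejects list;
duplicate identifiers are an error.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

# RDKit logs every parse failure to stderr on its own; we report rejects
# through the logging module instead.
RDLogger.DisableLog("rdApp.error")

#: CSV column aliases, matched case-insensitively.
_ID_COLUMNS = ("mol_id", "id", "no", "no.")
_SMILES_COLUMNS = ("smiles", "smi")
_NAME_COLUMNS = ("name", "compound", "compound_name")
_FAMILY_COLUMNS = ("family", "family_label", "group", "label")


@dataclass(frozen=True)
class MoleculeRecord:
    """One input compound.

    Attributes
    ----------
    mol_id:
        Unique key within a collection; kept as the string read from the
        table (opaque — it is never interpreted chemically).
    name:
        Free-text compound name.
    smiles:
        Canonical isomeric SMILES.
    family_label:
        Optional ground-truth family for synthetic benchmark sets; absent
        (``None``) for real data.
    """

    mol_id: str
    name: str
    smiles: str
    family_label: str | None = None


@dataclass
class RejectedRow:
    """A skipped input row and the reason it was skipped."""

    row_number: int
    mol_id: str | None
    smiles: str | None
    reason: str


@dataclass
class MoleculeTable:
    """Ordered collection of validated records plus the rejects list."""

    records: list[MoleculeRecord]
    rejects: list[RejectedRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.mol_id for r in self.records]


def canonical_smiles(smiles: str) -> str | None:
    """Canonical isomeric SMILES, or ``None`` if the input is invalid.

    A molecule must have at least one heavy atom to be accepted.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumHeavyAtoms() < 1:
        return None
    return Chem.MolToSmiles(mol, isomericSmiles=True)


def _find_column(header: Sequence[str], aliases: Sequence[str]) -> int | None:
    lowered = [h.strip().lower() for h in header]
    for alias in aliases:
        if alias in lowered:
            return lowered.index(alias)
    return None


def _validate(rows: Iterable[tuple[int, str, str, str, str | None]]) -> MoleculeTable:
    """Canonicalize and de-duplicate parsed raw rows.

    ``rows`` yields ``(row_number, mol_id, name, smiles, family)``.
    """
    records: list[MoleculeRecord] = []
    rejects: list[RejectedRow] = []
    seen: set[str] = set()
    for row_number, mol_id, name, smiles, family in rows:
        if not smiles:
            rejects.append(RejectedRow(row_number, mol_id, smiles, "empty SMILES"))
            logger.warning("row %d (%s): empty SMILES, skipped", row_number, mol_id)
            continue
        canonical = canonical_smiles(smiles)
        if canonical is None:
            rejects.append(RejectedRow(row_number, mol_id, smiles, "unparseable SMILES"))
            logger.warning(
                "row %d (%s): unparseable SMILES %r, skipped", row_number, mol_id, smiles
            )
            continue
        if mol_id in seen:
            raise ValueError(f"duplicate mol_id {mol_id!r} at row {row_number}")
        seen.add(mol_id)
        records.append(MoleculeRecord(mol_id, name, canonical, family))
    return MoleculeTable(records=records, rejects=rejects)


def read_molecule_table(path: str | Path, format: str | None = None) -> MoleculeTable:
    """Read a molecule table from CSV or ``.smi``.

    Parameters
    ----------
    path:
        Input file.  The format is inferred from the suffix when ``format``
        is not given (``.smi``/``.smiles`` → smi, anything else → csv).
    format:
        ``"csv"`` or ``"smi"``.

    Returns
    -------
    MoleculeTable
        Records in file order with canonical SMILES; rows with invalid
        SMILES appear in ``rejects`` instead.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ValueError
        On a missing required column, a duplicate identifier, or an
        unknown format.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format is None:
        format = "smi" if path.suffix.lower() in (".smi", ".smiles") else "csv"
    if format == "csv":
        return _read_csv(path)
    if format == "smi":
        return _read_smi(path)
    raise ValueError(f"unknown molecule table format {format!r}")


def _read_csv(path: Path) -> MoleculeTable:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, header required") from None
        id_col = _find_column(header, _ID_COLUMNS)
        smiles_col = _find_column(header, _SMILES_COLUMNS)
        if id_col is None or smiles_col is None:
            raise ValueError(
                f"{path}: header must contain id and smiles columns, got {header!r}"
            )
        name_col = _find_column(header, _NAME_COLUMNS)
        family_col = _find_column(header, _FAMILY_COLUMNS)

        def rows():
            for i, row in enumerate(reader, start=2):
                if not row or all(not cell.strip() for cell in row):
                    continue
                mol_id = row[id_col].strip()
                smiles = row[smiles_col].strip() if smiles_col < len(row) else ""
                name = row[name_col].strip() if name_col is not None and name_col < len(row) else mol_id
                family = None
                if family_col is not None and family_col < len(row):
                    family = row[family_col].strip() or None
                yield i, mol_id, name, smiles, family

        return _validate(rows())


def _read_smi(path: Path) -> MoleculeTable:
    with open(path, encoding="utf-8") as fh:
        def rows():
            counter = 0
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                counter += 1
                smiles = parts[0]
                mol_id = parts[1] if len(parts) > 1 else str(counter)
                yield i, mol_id, mol_id, smiles, None

        return _validate(rows())


def write_molecule_table(table: MoleculeTable | Sequence[MoleculeRecord], path: str | Path) -> None:
    """Write records as CSV (columns mol_id, name, smiles, family)."""
    records = list(table)
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["mol_id", "name", "smiles", "family"])
        for r in records:
            writer.writerow([r.mol_id, r.name, r.smiles, r.family_label or ""])


def write_rejects(table: MoleculeTable, path: str | Path) -> None:
    """Write the rejects list as a JSON log."""
    payload = [
        {"row_number": r.row_number, "mol_id": r.mol_id, "smiles": r.smiles, "reason": r.reason}
        for r in table.rejects
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def write_group_report(groups, path: str | Path, names: dict[str, str] | None = None) -> None:
    """Write a TSV group report.

    One row per group member with columns ``group_id``, ``mol_id``,
    ``name``, ``mwgs``, ``is_representative``.  Rows are ordered by
    group_id, then descending MWGS, then mol_id, so reruns are
    byte-identical.

    Parameters
    ----------
    groups:
        Non-empty collection of :class:`csnkit.grouping.CompoundGroup`.
    path:
        Output file.
    names:
        Optional ``mol_id -> name`` mapping; ids are used as names when
        absent.
    """
    groups = list(groups)
    if not groups:
        raise ValueError("groups collection is empty")
    names = names or {}
    with open(Path(path), "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["group_id", "mol_id", "name", "mwgs", "is_representative"])
        for group in sorted(groups, key=lambda g: g.group_id):
            members = sorted(
                group.member_ids,
                key=lambda m: (-group.mwgs_by_member.get(m, 0.0), sort_key(m)),
            )
            for m in members:
                writer.writerow(
                    [
                        group.group_id,
                        m,
                        names.get(m, m),
                        f"{group.mwgs_by_member.get(m, float('nan')):.6f}",
                        "true" if m == group.representative_id else "false",
                    ]
                )


def sort_key(mol_id: str) -> tuple:
    """Deterministic ordering key for molecule identifiers.

    Purely numeric ids sort numerically (so "2" < "10"); everything else
    sorts lexically after the numeric block.
    """
    s = str(mol_id)
    try:
        return (0, int(s), "")
    except ValueError:
        return (1, 0, s)
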