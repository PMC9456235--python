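"""Binary protein–ligand interaction-fingerprint (IFP) tables.

An IFP table records, for each compound of a group docked into one
binding pocket, the presence (1) or absence (0) of specific residue-level
contacts.  Contact types form a closed vocabulary:

    PO  pi-orbital        Ak  alkyl-pi          HD  H-bond donor
    HA  H-bond acceptor   SF  sulfur bond

Column headers are ``RESIDUE:TYPE`` (e.g. ``F36:PO``), the first column
is the compound number (``No.``).  This module summarizes such tables:
per-column contact frequencies, consensus key-residue calling (residues
contacted by a strict majority of the group by default), and side-by-side
comparison of two groups.  It consumes already-extracted tables; docking
and pose analysis are out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

CONTACT_TYPES = ("PO", "Ak", "HD", "HA", "SF")

_RESIDUE_RE = re.compile(r"^([A-Za-z]+)(\d+)$")


class ResidueContact(NamedTuple):
    """A residue label (one-letter amino acid + sequence number) and contact type."""

    residue: str
    contact_type: str

    def __str__(self) -> str:
        return f"{self.residue}:{self.contact_type}"

    @property
    def residue_number(self) -> int:
        match = _RESIDUE_RE.match(self.residue)
        if match is None:
            raise ValueError(f"malformed residue label {self.residue!r}")
        return int(match.group(2))


def parse_residue_contact(label: str) -> ResidueContact:
    """Parse a ``RESIDUE:TYPE`` header cell, validating the contact type."""
    parts = label.strip().split(":")
    if len(parts) != 2:
        raise ValueError(f"malformed residue:type column {label!r}")
    residue, contact_type = parts[0].strip(), parts[1].strip()
    if contact_type not in CONTACT_TYPES:
        raise ValueError(
            f"unknown contact type {contact_type!r} in column {label!r}; "
            f"expected one of {CONTACT_TYPES}"
        )
    if _RESIDUE_RE.match(residue) is None:
        raise ValueError(f"malformed residue label {residue!r} in column {label!r}")
    return ResidueContact(residue=residue, contact_type=contact_type)


@dataclass
class InteractionFingerprintTable:
    """Compounds × residue-contacts binary matrix."""

    compound_ids: list[str]
    columns: list[ResidueContact]
    bits: np.ndarray  # shape (n_compounds, n_columns), values in {0, 1}

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.int64)
        if self.bits.shape != (len(self.compound_ids), len(self.columns)):
            raise ValueError("bit matrix shape does not match ids/columns")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("IFP entries must be 0 or 1")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("duplicate residue:type columns")
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise ValueError("duplicate compound ids")

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.bits, index=self.compound_ids, columns=[str(c) for c in self.columns]
        )
        frame.index.name = "No."
        return frame

    def to_csv(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(Path(path), sep=sep)


def parse_ifp_table(path: str | Path, sep: str | None = None) -> InteractionFingerprintTable:
    """Read an IFP table from CSV or TSV.

    The header row is ``No.`` followed by ``RESIDUE:TYPE`` columns; body
    rows hold strictly binary cells.  The delimiter is inferred from the
    file suffix when not given (``.tsv``/``.txt`` → tab, else comma).

    Raises
    ------
    ValueError
        On an unknown contact-type suffix, a non-binary cell, or a
        duplicate compound id.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    frame = pd.read_csv(path, sep=sep, dtype=str).dropna(how="all")
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected a 'No.' column plus residue:type columns")
    first = frame.columns[0].strip().lower()
    if first not in ("no.", "no", "id", "mol_id", "compound"):
        raise ValueError(f"{path}: first column must be 'No.', got {frame.columns[0]!r}")
    columns = [parse_residue_contact(c) for c in frame.columns[1:]]
    compound_ids = [str(v).strip() for v in frame.iloc[:, 0]]
    body = frame.iloc[:, 1:]
    bits = np.empty(body.shape, dtype=np.int64)
    for j, col in enumerate(body.columns):
        for i, cell in enumerate(body[col]):
            cell = str(cell).strip()
            if cell not in ("0", "1"):
                raise ValueError(
                    f"{path}: non-binary cell {cell!r} at row {compound_ids[i]}, "
                    f"column {col!r}"
                )
            bits[i, j] = int(cell)
    return InteractionFingerprintTable(compound_ids=compound_ids, columns=columns, bits=bits)


def contact_frequency(
    t: InteractionFingerprintTable,
) -> dict[ResidueContact, tuple[int, float]]:
    """Per-column contact counts and fractions.

    Returns ``{ResidueContact: (count, count / n_compounds)}`` ordered by
    descending fraction, then residue number, then contact type.
    """
    if t.n_compounds == 0 or t.n_columns == 0:
        raise ValueError("empty interaction-fingerprint table")
    counts = t.bits.sum(axis=0)
    items = [
        (col, (int(c), float(c) / t.n_compounds)) for col, c in zip(t.columns, counts)
    ]
    items.sort(key=lambda kv: (-kv[1][1], kv[0].residue_number, kv[0].contact_type))
    return dict(items)


def contact_frequency_frame(t: InteractionFingerprintTable) -> pd.DataFrame:
    """Contact frequencies as a tidy DataFrame (for the TSV report)."""
    freq = contact_frequency(t)
    return pd.DataFrame(
        [
            {
                "residue": rc.residue,
                "contact_type": rc.contact_type,
                "count": count,
                "fraction": fraction,
            }
            for rc, (count, fraction) in freq.items()
        ]
    )


def key_residues(
    t: InteractionFingerprintTable, min_fraction: float = 0.5
) -> dict[str, tuple[float, tuple[str, ...]]]:
    """Residues contacted by more than ``min_fraction`` of the compounds.

    Contact types of one residue are aggregated by the maximum column
    fraction (residues, not residue:type pairs, are what binding-site
    analysis names as important).  Returns
    ``{residue: (max_fraction, supporting contact types)}`` ordered by
    descending fraction then residue number.  The default 0.5 with a
    strict ``>`` operationalizes "contacted by most of the group".
    """
    if not 0.0 <= min_fraction < 1.0:
        raise ValueError("min_fraction must be in [0, 1)")
    freq = contact_frequency(t)
    per_residue: dict[str, dict[str, float]] = {}
    for rc, (_, fraction) in freq.items():
        per_residue.setdefault(rc.residue, {})[rc.contact_type] = fraction
    out: list[tuple[str, tuple[float, tuple[str, ...]]]] = []
    for residue, fractions in per_residue.items():
        best = max(fractions.values())
        if best > min_fraction:
            support = tuple(
                ct for ct in CONTACT_TYPES if fractions.get(ct) == best
            )
            out.append((residue, (best, support)))
    out.sort(key=lambda kv: (-kv[1][0], ResidueContact(kv[0], "PO").residue_number))
    return dict(out)


def compare_groups(
    t1: InteractionFingerprintTable, t2: InteractionFingerprintTable
) -> pd.DataFrame:
    """Outer-join contact-fraction comparison of two groups.

    One row per residue:type column present in either table, with the
    fraction in each group (0 where the column is absent) and the delta
    ``fraction_a − fraction_b``.  Ordered by residue number, then contact
    type, then table of origin.
    """
    f1 = {rc: frac for rc, (_, frac) in contact_frequency(t1).items()}
    f2 = {rc: frac for rc, (_, frac) in contact_frequency(t2).items()}
    all_columns = sorted(
        set(f1) | set(f2), key=lambda rc: (rc.residue_number, rc.residue, rc.contact_type)
    )
    rows = [
        {
            "residue": rc.residue,
            "contact_type": rc.contact_type,
            "fraction_a": f1.get(rc, 0.0),
            "fraction_b": f2.get(rc, 0.0),
            "delta": f1.get(rc, 0.0) - f2.get(rc, 0.0),
        }
        for rc in all_columns
    ]
    return pd.DataFrame(rows)


def plot_contact_frequencies(
    t: InteractionFingerprintTable, path: str | Path, title: str | None = None
) -> None:
    """Bar chart of per-column contact fractions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    freq = contact_frequency(t)
    labels = [str(rc) for rc in freq]
    fractions = [frac for _, frac in freq.values()]
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(labels)), 4))
    ax.bar(range(len(labels)), fractions, color="steelblue")
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=7)
    ax.set_ylabel("fraction of compounds")
    ax.set_ylim(0, 1.05)
    ax.axhline(0.5, color="0.5", ls="--", lw=0.8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)
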