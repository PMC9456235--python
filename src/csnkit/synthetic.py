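"""Seeded generators for every input the pipeline consumes.

Molecule fixtures are built from scaffold templates plus enumerated
substituent decorations, not from random SMILES mutation: a shared large
scaffold guarantees a controllable high within-family similarity band
while chemically distinct scaffolds keep between-family similarity low.
The built-in three-family preset emulates the kinds of structural classes
seen in essential-oil inventories — long aliphatic chains, fused-aromatic
derivatives, and fused-ring (terpene-like) aliphatics — with within-family
Dice ≥ 0.6 and between-family Dice ≤ 0.3, verified at generation time.

Interaction-fingerprint fixtures are Bernoulli matrices with planted
high-frequency columns (bit probability 1 − noise_rate) against a sparse
noise background (probability noise_rate).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fingerprints import compute_fingerprint, dice_similarity
from .ifp import CONTACT_TYPES, InteractionFingerprintTable, ResidueContact
from .io import MoleculeRecord, canonical_smiles

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FamilySpec:
    """Recipe for one synthetic compound family.

    ``scaffold`` is a SMILES template containing a single ``{}``
    placeholder; each member is the template with one decoration from
    ``decorations`` substituted (the empty string is a valid decoration
    and yields the bare scaffold).
    """

    family_id: str
    scaffold: str
    decorations: tuple[str, ...]
    n_members: int

    def member_smiles(self, decoration: str) -> str:
        return self.scaffold.format(decoration)


#: Default three-family preset: aliphatic chain homologs, methoxy-naphthalene
#: ethers, and a decalin-based terpene-like scaffold.  Pools are larger than
#: the default member counts so different seeds draw different subsets.
THREE_FAMILY_SPECS = (
    FamilySpec(
        family_id="chain",
        scaffold="CCCCCCCCCCCC{}",
        decorations=("C", "CC", "CCC", "CCCC", "CCCCC", "O", "CO", "CCO"),
        n_members=7,
    ),
    FamilySpec(
        family_id="aromatic",
        scaffold="COc1ccc2cc({})ccc2c1",
        decorations=("C", "CC", "CCC", "O", "OC", "CO", "CCO", "C(C)C"),
        n_members=6,
    ),
    FamilySpec(
        family_id="terpene",
        scaffold="CC1CCC(C(C)C)C2CCC(C{})CC12",
        decorations=("", "C", "CC", "O", "CO", "OC", "C(C)C", "C(C)(C)C"),
        n_members=6,
    ),
)

WITHIN_FAMILY_MIN_DICE = 0.6
BETWEEN_FAMILY_MAX_DICE = 0.3


def _similarity_bands(
    records: Sequence[MoleculeRecord],
) -> tuple[float, float]:
    """(min within-family, max between-family) Dice over a labelled set."""
    fps = {r.mol_id: compute_fingerprint(r) for r in records}
    within = []
    between = []
    for a, b in itertools.combinations(records, 2):
        s = dice_similarity(fps[a.mol_id], fps[b.mol_id])
        (within if a.family_label == b.family_label else between).append(s)
    return (min(within) if within else 1.0, max(between) if between else 0.0)


def generate_families(
    specs: Sequence[FamilySpec] = THREE_FAMILY_SPECS,
    seed: int = 0,
    within_min: float = WITHIN_FAMILY_MIN_DICE,
    between_max: float = BETWEEN_FAMILY_MAX_DICE,
    max_attempts: int = 10,
) -> list[MoleculeRecord]:
    """Deterministic labelled molecule set from family recipes.

    For each family the RNG draws ``n_members`` decorations from the
    spec's pool (without replacement when the pool is large enough).  The
    generated set is checked against the similarity bands; on a violation
    it is regenerated with a warning, up to ``max_attempts`` times.

    Raises
    ------
    ValueError
        If a spec is infeasible (no decorations, non-positive member
        count) or the bands cannot be met.
    """
    for spec in specs:
        if spec.n_members < 1:
            raise ValueError(f"family {spec.family_id!r}: n_members must be >= 1")
        if not spec.decorations:
            raise ValueError(f"family {spec.family_id!r}: empty decoration pool")
    for attempt in range(max_attempts):
        rng = np.random.default_rng(seed + 7919 * attempt)
        records: list[MoleculeRecord] = []
        counter = 0
        for spec in specs:
            pool = list(spec.decorations)
            if spec.n_members <= len(pool):
                chosen = rng.choice(len(pool), size=spec.n_members, replace=False)
                decorations = [pool[i] for i in sorted(chosen)]
            else:
                # repeat decorations only when asked for more members than the pool
                reps = -(-spec.n_members // len(pool))
                decorations = (pool * reps)[: spec.n_members]
            for k, d in enumerate(decorations, start=1):
                counter += 1
                smiles = canonical_smiles(spec.member_smiles(d))
                if smiles is None:
                    raise ValueError(
                        f"family {spec.family_id!r}: decoration {d!r} yields "
                        f"invalid SMILES {spec.member_smiles(d)!r}"
                    )
                records.append(
                    MoleculeRecord(
                        mol_id=str(counter),
                        name=f"{spec.family_id}-{k}",
                        smiles=smiles,
                        family_label=spec.family_id,
                    )
                )
        ids = [r.mol_id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("generated duplicate mol_ids")
        smiles_seen = [r.smiles for r in records]
        if len(set(smiles_seen)) != len(smiles_seen):
            logger.warning("duplicate structures in attempt %d; regenerating", attempt)
            continue
        lo, hi = _similarity_bands(records)
        if lo >= within_min and hi <= between_max:
            return records
        logger.warning(
            "similarity bands violated (within min %.3f, between max %.3f) "
            "in attempt %d; regenerating",
            lo,
            hi,
            attempt,
        )
    raise ValueError(
        f"could not generate families meeting similarity bands after {max_attempts} attempts"
    )


#: Residue letters used when synthesizing pocket column labels.
_RESIDUE_LETTERS = "FLVMPHYSAICERT"


def _synthetic_columns(n_columns: int, rng: np.random.Generator) -> list[ResidueContact]:
    columns: list[ResidueContact] = []
    number = 20
    for j in range(n_columns):
        number += int(rng.integers(3, 15))
        letter = _RESIDUE_LETTERS[int(rng.integers(len(_RESIDUE_LETTERS)))]
        contact = CONTACT_TYPES[j % len(CONTACT_TYPES)]
        columns.append(ResidueContact(f"{letter}{number}", contact))
    return columns


def generate_ifp_matrix(
    n_compounds: int,
    n_columns: int,
    planted_high_columns: int,
    noise_rate: float,
    seed: int = 0,
) -> tuple[InteractionFingerprintTable, list[ResidueContact]]:
    """Binary IFP fixture with planted consensus contacts.

    ``planted_high_columns`` columns (chosen by the seeded RNG) have bit
    probability ``1 − noise_rate``; all other cells are 1 with
    probability ``noise_rate``.  Returns the table together with the
    planted column list so recovery can be scored.
    """
    if not 0 <= planted_high_columns <= n_columns:
        raise ValueError("planted_high_columns must be between 0 and n_columns")
    if not 0.0 <= noise_rate < 0.5:
        raise ValueError("noise_rate must be in [0, 0.5)")
    if n_compounds < 1 or n_columns < 1:
        raise ValueError("n_compounds and n_columns must be >= 1")
    rng = np.random.default_rng(seed)
    columns = _synthetic_columns(n_columns, rng)
    planted_idx = sorted(
        rng.choice(n_columns, size=planted_high_columns, replace=False).tolist()
    )
    probs = np.full(n_columns, noise_rate)
    probs[planted_idx] = 1.0 - noise_rate
    bits = (rng.random((n_compounds, n_columns)) < probs[None, :]).astype(np.int64)
    table = InteractionFingerprintTable(
        compound_ids=[str(i + 1) for i in range(n_compounds)],
        columns=columns,
        bits=bits,
    )
    return table, [columns[i] for i in planted_idx]
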