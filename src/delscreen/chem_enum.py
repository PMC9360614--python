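"""Combinatorial enumeration of trisynthon products and circular fingerprints.

A trisynthon DEL member is assembled from three building blocks in two
sequential coupling steps: the step-1 reaction joins the cycle-1 and cycle-2
blocks, and the step-2 reaction joins that intermediate with the cycle-3
block.  Reactions are expressed as reaction SMARTS and applied with RDKit;
products are stored as canonical SMILES.

Molecules are featurised as binary extended-connectivity (Morgan) fingerprints
hashed to a fixed width, with an optional map from each set bit back to the
atom environments that fired it (needed for atom-level attribution).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, rdFingerprintGenerator

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

#: Generic amide coupling: carboxylic acid + primary amine -> amide.
#: Works for both steps of a tripeptide-style library: the cycle-2 amino acid
#: contributes its amine in step 1 and its acid in step 2 (the newly formed
#: amide N-H no longer matches the primary-amine pattern).
AMIDE_COUPLING_SMARTS = "[CX3:1](=[O:2])[OX2H1].[NX3;H2:3]>>[CX3:1](=[O:2])[N:3]"


class InputError(ValueError):
    """Raised for unparseable or inconsistent user-supplied records."""


@dataclass(frozen=True)
class BuildingBlock:
    """One monomeric reagent used in a single cycle of library construction."""

    block_id: str
    cycle: int
    smiles: str

    def __post_init__(self) -> None:
        if self.cycle not in (1, 2, 3):
            raise InputError(f"block {self.block_id!r}: cycle must be 1, 2 or 3")


@dataclass(frozen=True)
class ReactionTemplate:
    """A reaction SMARTS for one coupling step (1 joins cycles 1+2, 2 adds cycle 3)."""

    template_id: str
    step: int
    smarts: str

    def __post_init__(self) -> None:
        if self.step not in (1, 2):
            raise InputError(f"template {self.template_id!r}: step must be 1 or 2")


@dataclass(frozen=True)
class Trisynthon:
    """A fully assembled library member and the blocks it came from."""

    compound_id: str
    block_ids: tuple[str, str, str]
    product_smiles: str


@dataclass(frozen=True)
class EnumerationFailure:
    """A block combination for which a template did not apply."""

    block_ids: tuple[str, str, str]
    step: int
    reason: str


@dataclass
class EnumerationResult:
    products: list[Trisynthon]
    failures: list[EnumerationFailure] = field(default_factory=list)

    def __iter__(self):
        return iter(self.products)

    def __len__(self) -> int:
        return len(self.products)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound_id": [t.compound_id for t in self.products],
                "block1": [t.block_ids[0] for t in self.products],
                "block2": [t.block_ids[1] for t in self.products],
                "block3": [t.block_ids[2] for t in self.products],
                "smiles": [t.product_smiles for t in self.products],
            }
        )


_ALLOWED_FP = {(1024, 2), (1024, 3), (2048, 2), (2048, 3)}


@dataclass(frozen=True)
class FingerprintConfig:
    """Width and radius of the circular fingerprint.

    The standard pairings are 1024/2048 bits with radius 2 or 3; other values
    are accepted but flagged via :attr:`is_standard`.
    """

    n_bits: int = 2048
    radius: int = 3

    def __post_init__(self) -> None:
        if self.n_bits <= 0 or self.radius < 1:
            raise InputError("n_bits must be > 0 and radius >= 1")

    @property
    def is_standard(self) -> bool:
        return (self.n_bits, self.radius) in _ALLOWED_FP


@dataclass
class Fingerprint:
    """A binary circular fingerprint with an optional bit -> environment map.

    ``bit_atoms`` maps each set-bit index to the list of
    ``(center_atom_index, environment_radius)`` pairs that hashed to it.  It is
    ``None`` for synthetic (bit-perturbed) fingerprints that do not correspond
    to a real molecule.
    """

    bits: np.ndarray
    bit_atoms: dict[int, list[tuple[int, int]]] | None = None
    smiles: str | None = None

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bit_atoms is not None:
            on = set(np.flatnonzero(self.bits).tolist())
            if not set(self.bit_atoms) <= on:
                raise InputError("bit_atoms contains keys that are not set bits")

    @property
    def n_bits(self) -> int:
        return int(self.bits.shape[0])

    def on_bits(self) -> np.ndarray:
        return np.flatnonzero(self.bits)


def _mol_from_smiles(smiles: str, what: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"unparseable SMILES for {what}: {smiles!r}")
    return mol


def _rxn_from_smarts(template: ReactionTemplate) -> AllChem.ChemicalReaction:
    rxn = AllChem.ReactionFromSmarts(template.smarts)
    if rxn is None or rxn.GetNumReactantTemplates() != 2 or rxn.GetNumProductTemplates() != 1:
        raise InputError(
            f"template {template.template_id!r}: SMARTS must be a valid "
            f"two-reactant, one-product reaction: {template.smarts!r}"
        )
    rxn.Initialize()
    return rxn


def _apply(rxn: AllChem.ChemicalReaction, left: Chem.Mol, right: Chem.Mol) -> list[str]:
    """Run a two-component reaction, returning sorted unique canonical products."""
    out = set()
    for prod_set in rxn.RunReactants((left, right)):
        mol = prod_set[0]
        try:
            Chem.SanitizeMol(mol)
        except Exception:  # pragma: no cover - unsanitisable product
            continue
        out.add(Chem.MolToSmiles(mol))
    return sorted(out)


def enumerate_trisynthons(
    blocks: Sequence[BuildingBlock],
    templates: Sequence[ReactionTemplate],
    on_ambiguous: str = "first",
) -> EnumerationResult:
    """Enumerate one product per (cycle-1, cycle-2, cycle-3) block combination.

    Combinations where a template fails to match are recorded in
    ``result.failures`` rather than silently dropped.  When a template matches
    at more than one site the first product after canonical sorting is kept
    and a warning is logged (``on_ambiguous="first"``), or an
    :class:`InputError` is raised (``on_ambiguous="error"``).
    """
    if on_ambiguous not in ("first", "error"):
        raise InputError("on_ambiguous must be 'first' or 'error'")
    by_cycle: dict[int, list[BuildingBlock]] = {1: [], 2: [], 3: []}
    mols: dict[str, Chem.Mol] = {}
    for blk in blocks:
        if blk.block_id in mols:
            raise InputError(f"duplicate block_id {blk.block_id!r}")
        mols[blk.block_id] = _mol_from_smiles(blk.smiles, f"block {blk.block_id!r}")
        by_cycle[blk.cycle].append(blk)
    for cyc in (1, 2, 3):
        if not by_cycle[cyc]:
            raise InputError(f"no building blocks supplied for cycle {cyc}")
    step1 = [t for t in templates if t.step == 1]
    step2 = [t for t in templates if t.step == 2]
    if len(step1) != 1 or len(step2) != 1:
        raise InputError("exactly one step-1 and one step-2 template required")
    rxn1 = _rxn_from_smarts(step1[0])
    rxn2 = _rxn_from_smarts(step2[0])

    products: list[Trisynthon] = []
    failures: list[EnumerationFailure] = []
    cycle3 = by_cycle[3]
    for b1 in by_cycle[1]:
        for b2 in by_cycle[2]:
            inter = _apply(rxn1, mols[b1.block_id], mols[b2.block_id])
            if not inter:
                failures.extend(
                    EnumerationFailure((b1.block_id, b2.block_id, b3.block_id), 1,
                                       "step-1 template did not match")
                    for b3 in cycle3
                )
                continue
            if len(inter) > 1:
                if on_ambiguous == "error":
                    raise InputError(
                        f"step-1 template ambiguous for ({b1.block_id}, {b2.block_id}): "
                        f"{len(inter)} distinct products"
                    )
                logger.warning(
                    "step-1 template matched %d sites for (%s, %s); keeping first "
                    "canonical product", len(inter), b1.block_id, b2.block_id
                )
            inter_mol = Chem.MolFromSmiles(inter[0])
            for b3 in cycle3:
                final = _apply(rxn2, inter_mol, mols[b3.block_id])
                if not final:
                    failures.append(
                        EnumerationFailure((b1.block_id, b2.block_id, b3.block_id), 2,
                                           "step-2 template did not match")
                    )
                    continue
                if len(final) > 1:
                    if on_ambiguous == "error":
                        raise InputError(
                            f"step-2 template ambiguous for ({b1.block_id}, "
                            f"{b2.block_id}, {b3.block_id}): {len(final)} products"
                        )
                    logger.warning(
                        "step-2 template matched %d sites for (%s, %s, %s); keeping "
                        "first", len(final), b1.block_id, b2.block_id, b3.block_id
                    )
                products.append(
                    Trisynthon(
                        compound_id=f"{b1.block_id}.{b2.block_id}.{b3.block_id}",
                        block_ids=(b1.block_id, b2.block_id, b3.block_id),
                        product_smiles=final[0],
                    )
                )
    return EnumerationResult(products=products, failures=failures)


def compute_fingerprint(
    smiles: str,
    config: FingerprintConfig = FingerprintConfig(),
    with_atom_map: bool = True,
) -> Fingerprint:
    """Binary Morgan fingerprint of one molecule, with bit -> atom environments.

    Deterministic for a given canonical structure and config: two SMILES
    spellings of the same molecule give identical bit vectors.
    """
    mol = _mol_from_smiles(smiles, "fingerprint input")
    gen = _generator(config)
    bits = np.zeros(config.n_bits, dtype=np.uint8)
    if with_atom_map:
        ao = rdFingerprintGenerator.AdditionalOutput()
        ao.AllocateBitInfoMap()
        bv = gen.GetFingerprint(mol, additionalOutput=ao)
        bit_atoms = {int(b): [tuple(map(int, e)) for e in envs]
                     for b, envs in ao.GetBitInfoMap().items()}
    else:
        bv = gen.GetFingerprint(mol)
        bit_atoms = None
    bits[list(bv.GetOnBits())] = 1
    return Fingerprint(bits=bits, bit_atoms=bit_atoms, smiles=Chem.MolToSmiles(mol))


def fingerprint_matrix(
    smiles_list: Iterable[str],
    config: FingerprintConfig = FingerprintConfig(),
) -> np.ndarray:
    """Stacked binary fingerprints, shape ``(n_molecules, n_bits)`` (uint8)."""
    gen = _generator(config)
    rows = []
    for smi in smiles_list:
        mol = _mol_from_smiles(smi, "fingerprint input")
        rows.append(gen.GetFingerprintAsNumPy(mol))
    return np.asarray(rows, dtype=np.uint8)


def _generator(config: FingerprintConfig):
    return rdFingerprintGenerator.GetMorganGenerator(
        radius=config.radius, fpSize=config.n_bits
    )


# ---------------------------------------------------------------------------
# CSV interfaces


def read_building_blocks(path) -> list[BuildingBlock]:
    df = pd.read_csv(path, dtype={"block_id": str})
    missing = {"block_id", "cycle", "smiles"} - set(df.columns)
    if missing:
        raise InputError(f"building-block table missing columns {sorted(missing)}")
    return [
        BuildingBlock(row.block_id, int(row.cycle), row.smiles)
        for row in df.itertuples()
    ]


def read_templates(path) -> list[ReactionTemplate]:
    df = pd.read_csv(path, dtype={"template_id": str})
    missing = {"template_id", "step", "smarts"} - set(df.columns)
    if missing:
        raise InputError(f"template table missing columns {sorted(missing)}")
    return [
        ReactionTemplate(row.template_id, int(row.step), row.smarts)
        for row in df.itertuples()
    ]


def default_templates() -> list[ReactionTemplate]:
    """Generic peptide-coupling templates used when none are supplied."""
    return [
        ReactionTemplate("amide-step1", 1, AMIDE_COUPLING_SMARTS),
        ReactionTemplate("amide-step2", 2, AMIDE_COUPLING_SMARTS),
    ]
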