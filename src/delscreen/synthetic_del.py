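"""Synthetic DEL selection data: simulated sequencing counts and a derivative panel.

Real DEL screens of protein-protein-interaction targets produce per-compound
sequencing counts under three conditions — target-on-beads (signal), blank
beads (matrix background) and target-with-DNA-tag-only (tag background) — with
an extremely skewed count distribution and, in the hard case modelled here, a
single true binder.  This module emulates exactly that regime:

* a deterministic catalogue of peptide-coupling building blocks, one of which
  carries a naphthalene pharmacophore that defines the planted binder;
* a multinomial sequencing model: each condition distributes a fixed read
  depth over the library, with the binder's sampling weight multiplied by an
  enrichment factor in the target condition only;
* a synthetic analogue panel around the hit: single-site R-group edits that
  keep the pharmacophore (actives, IC50 < 50 µM) and pharmacophore-destroying
  multi-site edits (inactives, censored IC50 > 50 µM).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem_enum import BuildingBlock, InputError, Trisynthon

#: Substructure that defines binding in the synthetic affinity landscape.
PHARMACOPHORE_SMARTS = "c1ccc2ccccc2c1"  # naphthalene core

#: Censored-IC50 sentinel: "> 50 µM" stored as 51.0 with censored=True.
CENSORED_IC50 = 51.0

# Deterministic building-block catalogues (tripeptide-style chemistry).
# Cycle 1: carboxylic acids (exactly one COOH, no primary amine).  The first
# entry carries the naphthalene pharmacophore, so small libraries always
# contain the planted binder's block.
_ACIDS = [
    "OC(=O)Cc1ccc2cc(OC)ccc2c1",  # pharmacophore block (methoxy-naphthalene)
    "CC(=O)O", "CCC(=O)O", "CCCC(=O)O", "CCCCC(=O)O", "CC(C)C(=O)O",
    "CC(C)CC(=O)O", "OC(=O)C1CC1", "OC(=O)C1CCC1", "OC(=O)C1CCCC1",
    "OC(=O)C1CCCCC1", "OC(=O)CC1CCCCC1", "OC(=O)C1CCOCC1",
    "OC(=O)c1ccccc1", "OC(=O)Cc1ccccc1", "OC(=O)CCc1ccccc1",
    "OC(=O)c1ccc(C)cc1", "OC(=O)c1ccc(F)cc1", "OC(=O)c1ccc(Cl)cc1",
    "OC(=O)c1ccc(OC)cc1", "OC(=O)c1ccc(CC)cc1",
    "OC(=O)Cc1ccc(F)cc1", "OC(=O)Cc1ccc(Cl)cc1", "OC(=O)Cc1ccc(OC)cc1",
    "OC(=O)Cc1ccc(C)cc1", "OC(=O)c1cccc(F)c1", "OC(=O)c1cccc(Cl)c1",
    "OC(=O)c1cccc(C)c1", "OC(=O)c1cccs1", "OC(=O)c1ccco1",
    "OC(=O)Cc1cccs1", "OC(=O)c1ccncc1", "OC(=O)c1cccnc1",
    "OC(=O)COC", "OC(=O)CCOC", "OC(=O)C(C)CC", "OC(=O)CC(C)C",
    "OC(=O)CCCOC", "OC(=O)C(C)c1ccccc1", "OC(=O)CCSC",
]
# Cycle 2: amino acids (one primary amine + one COOH).
_AMINO_ACIDS = [
    "NC(Cc1ccccc1)C(=O)O",  # phenylalanine: part of the default planted binder
    "NCC(=O)O", "NC(C)C(=O)O", "NC(CC)C(=O)O", "NC(CCC)C(=O)O",
    "NC(C(C)C)C(=O)O", "NC(CC(C)C)C(=O)O", "NC(C)(C)C(=O)O",
    "NC(CCc1ccccc1)C(=O)O", "NC(Cc1ccc(F)cc1)C(=O)O",
    "NC(Cc1ccc(Cl)cc1)C(=O)O", "NC(Cc1ccc(OC)cc1)C(=O)O",
    "NC(Cc1ccc(C)cc1)C(=O)O", "NC(CO)C(=O)O", "NC(CCO)C(=O)O",
    "NC(CSC)C(=O)O", "NC(CCSC)C(=O)O", "NC(C1CCCCC1)C(=O)O",
    "NC(CC1CCCCC1)C(=O)O", "NC(Cc1cccs1)C(=O)O", "NC(Cc1ccco1)C(=O)O",
    "NC(Cc1ccncc1)C(=O)O", "NC(Cc1cccnc1)C(=O)O", "NCCC(=O)O",
    "NCCCC(=O)O", "NC1CCC(C(=O)O)CC1", "NCc1ccc(C(=O)O)cc1",
    "NCc1cccc(C(=O)O)c1", "NC(COC)C(=O)O", "NC(CCOC)C(=O)O",
    "NC(C1CCC1)C(=O)O", "NC(C1CCCC1)C(=O)O", "NC(Cc1cccc(F)c1)C(=O)O",
    "NC(Cc1cccc(C)c1)C(=O)O", "NC(CCCC)C(=O)O", "NC(C(C)CC)C(=O)O",
    "NC(Cc1cccc(Cl)c1)C(=O)O", "NC(CC(C)(C)C)C(=O)O", "NC(CCCOC)C(=O)O",
]
# Cycle 3: primary amines (no COOH).
_AMINES = [
    "NCc1ccccc1",  # benzylamine: part of the default planted binder
    "NC", "NCC", "NCCC", "NCCCC", "NCCCCC", "NC(C)C", "NCC(C)C",
    "NC(C)CC", "NCC(C)(C)C", "NCCO", "NCCOC", "NCCCOC", "NCCSC",
    "NCCc1ccccc1", "NCc1ccc(F)cc1", "NCc1ccc(Cl)cc1", "NCc1ccc(OC)cc1",
    "NCc1ccc(C)cc1", "NCc1cccc(F)c1", "NCc1cccc(C)c1", "NCc1cccc(Cl)c1",
    "NC1CCC1", "NC1CCCC1", "NC1CCCCC1", "NCC1CCCCC1", "NC1CCOCC1",
    "NCc1cccs1", "NCc1ccco1", "NCc1ccncc1", "NCc1cccnc1",
    "NCCc1ccc(F)cc1", "NCCc1ccc(OC)cc1", "NCCC(C)C", "NCCCC(C)C",
    "NCC(C)CC", "NCCc1cccs1", "NCC1CCC1", "NCC1CCCC1",
]

_CYCLE_PREFIX = {1: "A", 2: "B", 3: "C"}


def generate_building_blocks(n_per_cycle: int | tuple[int, int, int] = 37) -> list[BuildingBlock]:
    """Deterministic building-block catalogue for the synthetic study.

    ``n_per_cycle`` may be one integer or a per-cycle triple.  The first block
    of each cycle is part of the default planted binder (the cycle-1 block
    carries the naphthalene pharmacophore), so any catalogue slice contains it.
    """
    if isinstance(n_per_cycle, int):
        n_per_cycle = (n_per_cycle, n_per_cycle, n_per_cycle)
    catalogues = {1: _ACIDS, 2: _AMINO_ACIDS, 3: _AMINES}
    blocks: list[BuildingBlock] = []
    for cycle, n in zip((1, 2, 3), n_per_cycle):
        cat = catalogues[cycle]
        if not 1 <= n <= len(cat):
            raise InputError(
                f"cycle {cycle}: n_per_cycle must be in [1, {len(cat)}], got {n}"
            )
        prefix = _CYCLE_PREFIX[cycle]
        blocks.extend(
            BuildingBlock(f"{prefix}{i + 1:02d}", cycle, smi)
            for i, smi in enumerate(cat[:n])
        )
    return blocks


#: compound_id of the planted binder assembled from the first block of each cycle.
DEFAULT_BINDER_ID = "A01.B01.C01"


@dataclass(frozen=True)
class AffinityLandscape:
    """Which library members bind, and how strongly selection favours them.

    Binders are named either explicitly (``binder_ids``) or structurally
    (``pharmacophore_smarts``, every library member matching the pattern).
    ``enrichment_multiplier`` scales a binder's sampling weight in the target
    condition only.  A small "sticky" population binds the bead matrix itself
    and is enriched in *all three* conditions — this is the background the
    tag/beads subtractions of the scoring step are designed to remove.
    """

    binder_ids: frozenset[str] = frozenset({DEFAULT_BINDER_ID})
    enrichment_multiplier: float = 1000.0
    pharmacophore_smarts: str | None = None
    sticky_fraction: float = 0.02
    sticky_multiplier: float = 20.0

    def __post_init__(self) -> None:
        if self.enrichment_multiplier < 1:
            raise InputError("enrichment_multiplier must be >= 1")
        if not self.binder_ids and self.pharmacophore_smarts is None:
            raise InputError("binder set must be non-empty in planted mode")
        if not 0 <= self.sticky_fraction < 1 or self.sticky_multiplier < 1:
            raise InputError("sticky_fraction in [0,1), sticky_multiplier >= 1")


CONDITIONS = ("target", "beads", "tag")


@dataclass
class SelectionRecord:
    """Pre/post sequencing counts and enrichment folds for one compound."""

    compound_id: str
    pre_target: int
    post_target: int
    pre_beads: int
    post_beads: int
    pre_tag: int
    post_tag: int
    ef_target: float
    ef_beads: float
    ef_tag: float


def enrichment_fold(pre: np.ndarray, post: np.ndarray) -> np.ndarray:
    """EF = (post-selection count share) / (pre-selection count share).

    For compounds with a zero pre-count (where the ratio is undefined) the
    pre-count is replaced by a pseudo-count of 1; compounds observed before
    selection keep the exact ratio.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    pre_depth, post_depth = pre.sum(), post.sum()
    if pre_depth <= 0 or post_depth <= 0:
        raise InputError("both pre and post counts must have positive depth")
    pre_eff = np.maximum(pre, 1.0)
    return (post / post_depth) / (pre_eff / pre_depth)


def simulate_selection(
    library: Sequence[Trisynthon] | Sequence[str],
    landscape: AffinityLandscape = AffinityLandscape(),
    depth_per_condition: int = 1_000_000,
    seed: int = 0,
) -> list[SelectionRecord]:
    """Simulate one selection experiment over the three count channels.

    Each condition draws ``depth_per_condition`` reads multinomially, pre and
    post, so reads are a conserved budget.  Post-selection weights are uniform
    except for binders (×``enrichment_multiplier``, target condition only) and
    sticky matrix binders (×``sticky_multiplier`` in every condition).
    Fully reproducible from ``seed``.
    """
    if depth_per_condition <= 0:
        raise InputError("depth_per_condition must be > 0")
    if len(library) == 0:
        raise InputError("library must be non-empty")
    ids = [t.compound_id if isinstance(t, Trisynthon) else str(t) for t in library]
    n = len(ids)

    binder_mask = np.zeros(n, dtype=bool)
    if landscape.pharmacophore_smarts is not None:
        query = Chem.MolFromSmarts(landscape.pharmacophore_smarts)
        if query is None:
            raise InputError(
                f"unparseable pharmacophore SMARTS: {landscape.pharmacophore_smarts!r}"
            )
        for i, t in enumerate(library):
            if not isinstance(t, Trisynthon):
                raise InputError("pharmacophore mode requires Trisynthon inputs")
            mol = Chem.MolFromSmiles(t.product_smiles)
            binder_mask[i] = mol is not None and mol.HasSubstructMatch(query)
    id_index = {cid: i for i, cid in enumerate(ids)}
    for cid in landscape.binder_ids:
        if cid in id_index:
            binder_mask[id_index[cid]] = True

    rng = np.random.default_rng(seed)
    sticky = rng.random(n) < landscape.sticky_fraction

    base = np.ones(n)
    base[sticky] *= landscape.sticky_multiplier
    target_w = base.copy()
    target_w[binder_mask] *= landscape.enrichment_multiplier

    pre_p = np.full(n, 1.0 / n)
    counts: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for cond, w in (("target", target_w), ("beads", base), ("tag", base)):
        pre = rng.multinomial(depth_per_condition, pre_p)
        post = rng.multinomial(depth_per_condition, w / w.sum())
        counts[cond] = (pre, post)

    efs = {cond: enrichment_fold(pre, post) for cond, (pre, post) in counts.items()}
    return [
        SelectionRecord(
            compound_id=ids[i],
            pre_target=int(counts["target"][0][i]),
            post_target=int(counts["target"][1][i]),
            pre_beads=int(counts["beads"][0][i]),
            post_beads=int(counts["beads"][1][i]),
            pre_tag=int(counts["tag"][0][i]),
            post_tag=int(counts["tag"][1][i]),
            ef_target=float(efs["target"][i]),
            ef_beads=float(efs["beads"][i]),
            ef_tag=float(efs["tag"][i]),
        )
        for i in range(n)
    ]


def records_to_frame(records: Sequence[SelectionRecord]) -> pd.DataFrame:
    cols = ["compound_id", "pre_target", "post_target", "pre_beads",
            "post_beads", "pre_tag", "post_tag"]
    return pd.DataFrame({c: [getattr(r, c) for r in records] for c in cols})


def records_from_frame(df: pd.DataFrame) -> list[SelectionRecord]:
    """Rebuild selection records (and their EFs) from a count-table."""
    need = {"compound_id", "pre_target", "post_target", "pre_beads",
            "post_beads", "pre_tag", "post_tag"}
    missing = need - set(df.columns)
    if missing:
        raise InputError(f"count table missing columns {sorted(missing)}")
    efs = {
        cond: enrichment_fold(df[f"pre_{cond}"].to_numpy(), df[f"post_{cond}"].to_numpy())
        for cond in CONDITIONS
    }
    return [
        SelectionRecord(
            compound_id=str(row.compound_id),
            pre_target=int(row.pre_target), post_target=int(row.post_target),
            pre_beads=int(row.pre_beads), post_beads=int(row.post_beads),
            pre_tag=int(row.pre_tag), post_tag=int(row.post_tag),
            ef_target=float(efs["target"][i]),
            ef_beads=float(efs["beads"][i]),
            ef_tag=float(efs["tag"][i]),
        )
        for i, row in enumerate(df.itertuples())
    ]


# ---------------------------------------------------------------------------
# Derivative panel


@dataclass(frozen=True)
class DerivativeRecord:
    derivative_id: str
    smiles: str
    ic50_uM: float
    censored: bool = False

    @property
    def active(self) -> bool:
        return not self.censored and self.ic50_uM < 50.0


@dataclass
class DerivativePanel:
    """A small structure-activity panel of analogues around one hit compound."""

    records: list[DerivativeRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def n_active(self) -> int:
        return sum(r.active for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "derivative_id": [r.derivative_id for r in self.records],
                "smiles": [r.smiles for r in self.records],
                "ic50_uM": [r.ic50_uM for r in self.records],
                "censored": [r.censored for r in self.records],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DerivativePanel":
        return cls(
            records=[
                DerivativeRecord(
                    str(row.derivative_id), row.smiles,
                    float(row.ic50_uM), bool(row.censored),
                )
                for row in df.itertuples()
            ]
        )


_SMALL_R_GROUPS = ["C", "F", "Cl", "O", "OC", "N", "CC"]
_LARGE_R_GROUPS = ["CC", "CCC", "C(C)C", "OCC", "CCO", "c1ccccc1", "C1CCCCC1"]


def _attachment_sites(mol: Chem.Mol) -> list[int]:
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetSymbol() == "C" and a.GetTotalNumHs() >= 1
    ]


def _attach(mol: Chem.Mol, site: int, frag_smiles: str) -> Chem.Mol | None:
    frag = Chem.MolFromSmiles(frag_smiles)
    combo = Chem.RWMol(Chem.CombineMols(mol, frag))
    combo.AddBond(site, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    try:
        out = combo.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def _random_edit(mol: Chem.Mol, rng: np.random.Generator, frags: list[str]) -> Chem.Mol | None:
    sites = _attachment_sites(mol)
    if not sites:
        return None
    site = int(rng.choice(sites))
    frag = frags[int(rng.integers(len(frags)))]
    return _attach(mol, site, frag)


def _strip_pharmacophore(mol: Chem.Mol, query: Chem.Mol) -> Chem.Mol | None:
    repl = Chem.MolFromSmiles("C1CCCCC1")
    try:
        out = AllChem.ReplaceSubstructs(mol, query, repl, replaceAll=True)[0]
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def generate_derivative_panel(
    hit_smiles: str,
    n: int = 34,
    seed: int = 0,
    active_fraction: float = 7 / 34,
    pharmacophore_smarts: str = PHARMACOPHORE_SMARTS,
    keep_pharmacophore_inactive_prob: float = 0.15,
) -> DerivativePanel:
    """Enumerate ``n`` R-group analogues of a hit with planted activities.

    Actives (fraction ``active_fraction``, default 7/34) are single-site
    additions of a small substituent that leave the pharmacophore intact;
    their IC50s are drawn log-uniformly over 3-48 µM with one forced below
    10 µM.  Inactives are censored at > 50 µM and are built, with high
    probability, by replacing the pharmacophore ring system and adding one or
    two substituents — so activity is (noisily) aligned with pharmacophore
    retention, never perfectly confounded with it.
    """
    if n < 2:
        raise InputError("panel size must be >= 2")
    mol = Chem.MolFromSmiles(hit_smiles)
    if mol is None:
        raise InputError(f"unparseable hit SMILES: {hit_smiles!r}")
    if not _attachment_sites(mol):
        raise InputError("hit scaffold has no modifiable C-H sites")
    query = Chem.MolFromSmarts(pharmacophore_smarts)
    has_pharm = query is not None and mol.HasSubstructMatch(query)

    rng = np.random.default_rng(seed)
    n_active = int(round(active_fraction * n))
    seen: set[str] = {Chem.MolToSmiles(mol)}
    entries: list[tuple[str, float, bool]] = []  # (smiles, ic50, censored)

    def _unique_edit(base: Chem.Mol, n_edits: int, frags: list[str]) -> str:
        for _ in range(80):
            cur = base
            ok = True
            for _ in range(n_edits):
                nxt = _random_edit(cur, rng, frags)
                if nxt is None:
                    ok = False
                    break
                cur = nxt
            if not ok:
                continue
            smi = Chem.MolToSmiles(cur)
            if smi not in seen:
                seen.add(smi)
                return smi
        raise InputError("could not generate enough unique derivatives")

    for i in range(n_active):
        smi = _unique_edit(mol, 1, _SMALL_R_GROUPS)
        if i == 0:
            ic50 = float(np.exp(rng.uniform(np.log(3.0), np.log(9.5))))
        else:
            ic50 = float(np.exp(rng.uniform(np.log(3.0), np.log(48.0))))
        entries.append((smi, ic50, False))

    for _ in range(n - n_active):
        strip = has_pharm and rng.random() >= keep_pharmacophore_inactive_prob
        if strip:
            base = _strip_pharmacophore(mol, query)
            if base is None:
                base, strip = mol, False
        else:
            base = mol
        n_edits = int(rng.integers(1, 3)) if strip else int(rng.integers(3, 5))
        smi = _unique_edit(base, n_edits, _LARGE_R_GROUPS)
        entries.append((smi, CENSORED_IC50, True))

    order = rng.permutation(len(entries))
    records = [
        DerivativeRecord(f"a{rank + 1}", *entries[idx])
        for rank, idx in enumerate(order)
    ]
    return DerivativePanel(records=records)
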