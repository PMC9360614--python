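"""The end-to-end planted-signal benchmark study, scaled to desk size.

The full-scale screen this package models — a 30-million-member trisynthon
library reduced to ~1.1 million decoded count records with one true hit — is
not reproducible on a workstation, so the package ships a scaled replica:
a 37×37×37 combinatorial library (50,653 trisynthons), one planted binder at
enrichment multiplier 1000 selected at 10⁶ reads per condition, and a
34-member derivative panel with 7 actives sharing the binder's pharmacophore.
Undersampling interval and split sizes are scaled proportionally (see
docs/methods.md).

`build_library_artifacts` performs the seed-independent work (enumeration and
fingerprinting) once; `run_study` runs selection, scoring, splitting,
training and evaluation for one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .chem_enum import (
    FingerprintConfig,
    Trisynthon,
    default_templates,
    enumerate_trisynthons,
    fingerprint_matrix,
)
from .dataset_builder import SamplingConfig, SplitBundle, build_splits
from .del_scoring import ScoreWeights, compute_scores
from .modeling import EvalReport, GBMConfig, evaluate_model, train_model
from .synthetic_del import (
    DEFAULT_BINDER_ID,
    AffinityLandscape,
    generate_building_blocks,
    generate_derivative_panel,
    simulate_selection,
)


@dataclass(frozen=True)
class StudyConfig:
    """Scaled study conditions (defaults reproduce the shipped benchmark)."""

    n_per_cycle: int = 37              # 37^3 = 50,653 trisynthons
    depth_per_condition: int = 1_000_000
    enrichment_multiplier: float = 1000.0
    panel_size: int = 34
    active_fraction: float = 7 / 34
    undersample_interval_n: int = 8
    oversample_multiple: int = 800
    oversample_top_k: int = 100
    valid1_size: int = 5_000
    test1_size: int = 5_000
    fingerprint: FingerprintConfig = field(default_factory=FingerprintConfig)
    threshold: float = 0.5


@dataclass
class LibraryArtifacts:
    """Seed-independent pieces of the study: products and fingerprints."""

    products: list[Trisynthon]
    fingerprints: Mapping[str, np.ndarray]
    hit_id: str
    hit_smiles: str
    fp_config: FingerprintConfig


def build_library_artifacts(
    config: StudyConfig = StudyConfig(),
) -> LibraryArtifacts:
    """Enumerate the combinatorial library and fingerprint every product."""
    blocks = generate_building_blocks(config.n_per_cycle)
    result = enumerate_trisynthons(blocks, default_templates())
    products = result.products
    by_id = {t.compound_id: t for t in products}
    if DEFAULT_BINDER_ID not in by_id:
        raise RuntimeError("planted binder missing from enumerated library")
    X = fingerprint_matrix((t.product_smiles for t in products), config.fingerprint)
    fps = {t.compound_id: X[i] for i, t in enumerate(products)}
    return LibraryArtifacts(
        products=products,
        fingerprints=fps,
        hit_id=DEFAULT_BINDER_ID,
        hit_smiles=by_id[DEFAULT_BINDER_ID].product_smiles,
        fp_config=config.fingerprint,
    )


def run_study(
    artifacts: LibraryArtifacts,
    seed: int,
    config: StudyConfig = StudyConfig(),
    augment: bool = False,
    modify_type: int = 1,
    modify_bit: int = 2,
    gbm_config: GBMConfig | None = None,
) -> tuple[EvalReport, SplitBundle]:
    """One seeded selection -> scoring -> split -> GBM -> evaluation run."""
    landscape = AffinityLandscape(
        binder_ids=frozenset({artifacts.hit_id}),
        enrichment_multiplier=config.enrichment_multiplier,
    )
    records = simulate_selection(
        artifacts.products, landscape, config.depth_per_condition, seed=seed
    )
    scored = compute_scores(records, ScoreWeights())
    panel = generate_derivative_panel(
        artifacts.hit_smiles,
        n=config.panel_size,
        seed=seed,
        active_fraction=config.active_fraction,
    )
    sampling = SamplingConfig(
        undersample_interval_n=config.undersample_interval_n,
        oversample_multiple=config.oversample_multiple,
        oversample_top_k=config.oversample_top_k,
        modify_bit=modify_bit,
        modify_type=modify_type,
        augment=augment,
        seed=seed,
    )
    bundle = build_splits(
        scored, panel, sampling, artifacts.fingerprints,
        valid1_size=config.valid1_size, test1_size=config.test1_size,
        fp_config=artifacts.fp_config,
    )
    model = train_model(
        "gbm", gbm_config or GBMConfig(seed=seed),
        bundle.X_train, bundle.y_train,
        valid=(bundle.X_valid1, bundle.y_valid1),
    )
    report = evaluate_model(
        model, bundle, config.threshold,
        hyperparameters={
            "model": "gbm",
            "undersample_interval_n": config.undersample_interval_n,
            "oversample_multiple": config.oversample_multiple,
            "augment": augment,
            "modify_type": modify_type if augment else None,
            "seed": seed,
        },
    )
    return report, bundle
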