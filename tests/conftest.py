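"""Shared fixtures: the full study-mirror dataset (generated once per
session) and a factory for small, fast synthetic configurations."""
from __future__ import annotations

import numpy as np
import pytest

from phx import (
    PlantedPair,
    SyntheticConfig,
    generate_expression,
    paper_mirror_config,
)
from phx.ingest import log_fold_change, normalize_to_reference
from phx.syndata import orf_id


@pytest.fixture(scope="session")
def mirror_config():
    return paper_mirror_config(seed=0)


@pytest.fixture(scope="session")
def mirror_normalized(mirror_config):
    m = generate_expression(mirror_config, "infected")
    return normalize_to_reference(m, mirror_config.reference_feature)


@pytest.fixture(scope="session")
def mirror_fc(mirror_normalized):
    return log_fold_change(mirror_normalized)


def _small_config(
    seed: int = 0,
    host_gene_count: int = 120,
    n_orfs_per_class: int = 4,
    deg_plan: dict | None = None,
    tr_pairs: list | None = None,
    merged_pairs: list | None = None,
    tr_genes: tuple = (),
    noise_sigma: float = 0.1,
) -> SyntheticConfig:
    """A reduced dual-organism design: 3 x n ORFs, a small host genome."""
    class_map = {}
    n = 1
    for cls in ("late", "middle", "early"):
        for _ in range(n_orfs_per_class):
            class_map[orf_id(n)] = cls
            n += 1
    cfg = SyntheticConfig(
        phage_class_map=class_map,
        host_gene_count=host_gene_count,
        deg_plan=deg_plan or {},
        tr_pair_plan=tr_pairs or [],
        merged_pair_plan=merged_pairs or [],
        tr_genes=tr_genes,
        noise_sigma=noise_sigma,
        seed=seed,
    )
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def small_config_factory():
    return _small_config
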