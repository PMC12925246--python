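"""Synthetic multi-omics generator with known module structure.

Each planted module m draws a latent factor z_m ~ N(0, 1) over samples;
member features follow the rank-1 block model

    x_f = sqrt(w) * z_m + sqrt(1 - w) * noise_sd * eps,   eps ~ N(0, 1),

so with noise_sd = 1 the expected within-module pairwise correlation is
exactly w (= ``within_module_cor``) and the module has a meaningful first
principal component.  Selected module pairs across datasets share their
latents up to ``cross_link_strength`` (the correlation between the two
latents).  Background features are independent noise; missingness is
completely at random.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .io import AbundanceMatrix, SampleMetadata
from .tom_cluster import ModuleAssignment
import pandas as pd


@dataclass
class SimConfig:
    """Generator settings; defaults define the standard two-layer fixture
    (6 modules of 30 features per layer, w = 0.6, two cross-layer links of
    strength 0.9, unit noise, 100 samples, ~18% background features)."""

    n_samples: int = 100
    n_datasets: int = 2
    n_modules: int = 6
    module_size: int | list[int] = 30
    background_features: int = 40
    within_module_cor: float = 0.6
    n_cross_links: int = 2
    cross_link_strength: float = 0.9
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    group_effect: float = 0.8
    seed: int = 42
    dataset_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 < self.within_module_cor < 1.0:
            raise ValueError("within_module_cor must be in (0, 1)")
        if not 0.0 < self.cross_link_strength <= 1.0:
            raise ValueError("cross_link_strength must be in (0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        sizes = self.sizes()
        if min(sizes) < 2:
            raise ValueError("module sizes must be >= 2")
        if self.n_cross_links > self.n_modules:
            raise ValueError("more cross links than modules")
        if not self.dataset_names:
            self.dataset_names = [f"omics{i + 1}" for i in range(self.n_datasets)]

    def sizes(self) -> list[int]:
        if isinstance(self.module_size, int):
            return [self.module_size] * self.n_modules
        if len(self.module_size) != self.n_modules:
            raise ValueError("module_size list length must equal n_modules")
        return list(self.module_size)


@dataclass
class GroundTruth:
    """What the generator planted: per-dataset feature -> module maps,
    cross-layer latent couplings, latent factors and group labels."""

    true_modules: dict[str, dict[str, int]]  # dataset -> feature -> module (0 = background)
    cross_links: list[tuple[str, int, str, int, float]]  # (ds_a, mod_a, ds_b, mod_b, strength)
    latents: dict[str, np.ndarray]  # dataset -> n_modules x n_samples
    group_labels: list[str]
    affected_modules: dict[str, list[int]]  # dataset -> modules carrying the group effect


def generate_multiomics(cfg: SimConfig) -> tuple[list[AbundanceMatrix], SampleMetadata, GroundTruth]:
    """Draw the multi-layer fixture described by ``cfg``."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    sizes = cfg.sizes()
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    groups = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))

    # Latents per dataset; cross-linked pairs share correlated latents.
    latents = {name: rng.standard_normal((cfg.n_modules, n)) for name in cfg.dataset_names}
    cross_links: list[tuple[str, int, str, int, float]] = []
    if cfg.n_datasets >= 2 and cfg.n_cross_links > 0:
        ds_a, ds_b = cfg.dataset_names[0], cfg.dataset_names[1]
        s = cfg.cross_link_strength
        for li in range(cfg.n_cross_links):
            za = latents[ds_a][li]
            latents[ds_b][li] = s * za + np.sqrt(1.0 - s ** 2) * rng.standard_normal(n)
            cross_links.append((ds_a, li + 1, ds_b, li + 1, s))

    # Group effect: the first module of each dataset shifts between groups.
    affected = {name: [1] for name in cfg.dataset_names} if cfg.group_effect else \
               {name: [] for name in cfg.dataset_names}
    shift = (groups == "B").astype(float) - 0.5

    matrices: list[AbundanceMatrix] = []
    true_modules: dict[str, dict[str, int]] = {}
    w = cfg.within_module_cor
    for name in cfg.dataset_names:
        rows, fids, labels = [], [], []
        for mod in range(cfg.n_modules):
            z = latents[name][mod].copy()
            if (mod + 1) in affected[name]:
                z = z + cfg.group_effect * shift
            eps = rng.standard_normal((sizes[mod], n))
            block = np.sqrt(w) * z + np.sqrt(1.0 - w) * cfg.noise_sd * eps
            rows.append(block)
            for j in range(sizes[mod]):
                fids.append(f"{name}_M{mod + 1}_F{j + 1}")
                labels.append(mod + 1)
        if cfg.background_features:
            rows.append(rng.standard_normal((cfg.background_features, n)) * cfg.noise_sd)
            for j in range(cfg.background_features):
                fids.append(f"{name}_BG_F{j + 1}")
                labels.append(0)
        values = np.vstack(rows)
        if cfg.missing_rate > 0:
            mask = rng.random(values.shape) < cfg.missing_rate
            # keep every feature observed at least once
            all_gone = mask.all(axis=1)
            mask[all_gone, 0] = False
            values = np.where(mask, np.nan, values)
        matrices.append(AbundanceMatrix(fids, sample_ids, values, name))
        true_modules[name] = dict(zip(fids, labels))

    meta = SampleMetadata(sample_ids, pd.DataFrame({"group": pd.Categorical(groups)},
                                                   index=pd.Index(sample_ids)))
    truth = GroundTruth(true_modules=true_modules, cross_links=cross_links,
                        latents=latents, group_labels=list(groups),
                        affected_modules=affected)
    return matrices, meta, truth


def evaluate_recovery(assign: ModuleAssignment, truth: GroundTruth, dataset: str) -> dict:
    """Score a module assignment against the planted truth.

    ARI is computed over planted (non-background) features only; background
    features contribute to the reported unassigned fraction instead.
    """
    tm = truth.true_modules[dataset]
    true_labels = np.array([tm[f] for f in assign.feature_ids])
    planted = true_labels > 0
    ari = float(adjusted_rand_score(true_labels[planted], assign.labels[planted])) \
        if planted.any() else float("nan")
    sizes = np.array(sorted(assign.module_sizes.values()), dtype=float)
    return {
        "ari": ari,
        "n_modules": int(sizes.size),
        "mean_size": float(sizes.mean()) if sizes.size else 0.0,
        "sd_size": float(sizes.std(ddof=1)) if sizes.size > 1 else 0.0,
        "frac_unassigned": float((assign.labels == 0).mean()),
    }
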