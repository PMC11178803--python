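"""Synthetic reaction grids with known yield structure.

The generator emulates the structure of a combinatorial high-throughput
cross-coupling screen: a Cartesian grid over per-role component sets
(default 15 aryl halides × 4 ligands × 3 bases × 23 additives = 4140
combinations), with percent yield built from a base level, additive
per-component main effects, pairwise aryl-halide × additive interactions
(echoing additive poisoning of specific substrates) and Gaussian noise,
clipped to [0, 100].  Component SMILES come from fixed packaged toy
vocabularies of simple substituted aromatics, amines and phosphines.

Also provides exact draws from a GP prior (:func:`gp_draw_dataset`) for
oracle-equivalence and parameter-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky

from .featurize import DEFAULT_ROLES, Reaction
from .gp import KernelParams, matern52_gram

__all__ = ["TOY_VOCABULARIES", "GridSpec", "synth_reaction_grid", "gp_draw_dataset"]

#: fixed toy SMILES vocabularies, one list per role (all parse under rdkit)
TOY_VOCABULARIES = {
    "aryl_halide": (
        "Brc1ccccc1", "Clc1ccccc1", "Ic1ccccc1",
        "Brc1ccc(C)cc1", "Clc1ccc(C)cc1", "Ic1ccc(C)cc1",
        "Brc1ccc(OC)cc1", "Clc1ccc(OC)cc1",
        "Brc1ccc(F)cc1", "Clc1ccc(F)cc1",
        "Brc1ccc(C(F)(F)F)cc1", "Brc1cccnc1", "Clc1cccnc1",
        "Brc1ccncc1", "Clc1ccncc1", "Brc1ccc(C#N)cc1",
    ),
    "ligand": (
        "CP(C)C", "CCP(CC)CC", "CC(C)P(C(C)C)C(C)C",
        "c1ccc(P(c2ccccc2)c2ccccc2)cc1",
        "CC(C)(C)P(C(C)(C)C)C(C)(C)C",
        "C1CCC(P(C2CCCCC2)C2CCCCC2)CC1",
    ),
    "base": (
        "CCN(CC)CC", "CN(C)C", "C1CCNCC1", "C1COCCN1", "CN1CCCC1",
    ),
    "additive": (
        "c1ccoc1", "Cc1ccco1", "c1ccsc1", "Cc1cccs1",
        "c1cc[nH]c1", "Cc1ccc[nH]1", "c1ccncc1", "Cc1ccncc1",
        "c1ccnnc1", "c1cnccn1", "c1ccc2ccccc2c1", "c1ccc2[nH]ccc2c1",
        "c1ccc2occc2c1", "c1ccc2sccc2c1", "CC(=O)c1ccccc1", "COc1ccccc1",
        "Cc1ccccc1C", "N#Cc1ccccc1", "O=Cc1ccccc1", "CC(C)c1ccccc1",
        "Fc1ccccc1", "c1ocnc1", "CCOC(=O)c1ccccc1", "CN(C)c1ccccc1",
    ),
}

#: half-width of the uniform main-effect distribution, in yield points
_DEFAULT_EFFECT_RANGES = {"aryl_halide": 15.0, "ligand": 10.0, "base": 8.0, "additive": 15.0}


@dataclass(frozen=True)
class GridSpec:
    """Specification of a synthetic reaction grid.

    ``counts`` are the per-role component counts in the fixed role order;
    ``interaction_strength`` is the standard deviation (yield points) of the
    sampled aryl-halide × additive interaction terms; ``noise_sd`` the
    observation noise; ``subsample`` the kept fraction of the full grid.
    """

    counts: tuple = (15, 4, 3, 23)
    roles: tuple = DEFAULT_ROLES
    base_yield: float = 50.0
    effect_ranges: dict = field(default_factory=lambda: dict(_DEFAULT_EFFECT_RANGES))
    interaction_strength: float = 10.0
    noise_sd: float = 5.0
    subsample: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if len(self.counts) != len(self.roles):
            raise ValueError("counts and roles length mismatch")
        if any(c < 1 for c in self.counts):
            raise ValueError("component counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not (0.0 < self.subsample <= 1.0):
            raise ValueError("subsample must be in (0, 1]")
        for role, count in zip(self.roles, self.counts):
            if count > len(TOY_VOCABULARIES.get(role, ())):
                raise ValueError(
                    f"toy vocabulary for role {role!r} has only "
                    f"{len(TOY_VOCABULARIES.get(role, ()))} entries, {count} requested"
                )


def synth_reaction_grid(spec: GridSpec = GridSpec()) -> list:
    """Generate the full (optionally subsampled) grid of synthetic reactions.

    Yield model per combination (i, j, k, l):

        y = clip(base + Σ_role effect_role + I[aryl, additive] + ε, 0, 100)

    with effect_role ~ U(−range, range) per component, interaction
    I ~ N(0, interaction_strength²) per (aryl halide, additive) pair and
    ε ~ N(0, noise_sd²) per reaction.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    vocabs = [TOY_VOCABULARIES[role][: count] for role, count in zip(spec.roles, spec.counts)]
    effects = [
        rng.uniform(-spec.effect_ranges.get(role, 10.0), spec.effect_ranges.get(role, 10.0), size=count)
        for role, count in zip(spec.roles, spec.counts)
    ]
    inter = np.zeros((spec.counts[0], spec.counts[-1]))
    if spec.interaction_strength > 0:
        inter = rng.normal(0.0, spec.interaction_strength, size=inter.shape)
    idx_grid = np.stack(
        np.meshgrid(*[np.arange(c) for c in spec.counts], indexing="ij"), axis=-1
    ).reshape(-1, len(spec.counts))
    n = idx_grid.shape[0]
    keep = np.arange(n)
    if spec.subsample < 1.0:
        keep = np.sort(rng.choice(n, size=int(round(n * spec.subsample)), replace=False))
    noise = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else np.zeros(n)
    reactions = []
    for row in keep:
        idx = idx_grid[row]
        y = spec.base_yield + sum(eff[i] for eff, i in zip(effects, idx))
        y += inter[idx[0], idx[-1]] + noise[row]
        reactions.append(
            Reaction(
                components={role: vocab[i] for role, vocab, i in zip(spec.roles, vocabs, idx)},
                yield_=float(np.clip(y, 0.0, 100.0)),
                id=f"rxn-{row:05d}",
            )
        )
    return reactions


def gp_draw_dataset(features, params: KernelParams, seed: int = 0) -> np.ndarray:
    """One exact draw from N(0, K + σ²I) over the given feature rows."""
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    params.validate()
    n = X.shape[0]
    K = matern52_gram(X, X, params) + params.noise * np.eye(n)
    if params.outputscale == 0.0 and params.noise == 0.0:
        return np.zeros(n)
    L = cholesky(K + 1e-10 * np.eye(n), lower=True)
    rng = np.random.default_rng(seed)
    return L @ rng.standard_normal(n)
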