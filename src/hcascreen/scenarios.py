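"""Canonical synthetic study conditions with recoverable ground truth.

Each function builds a :class:`~hcascreen.synthetic_screen.SimulationConfig`
for one calibration or recovery experiment:

* :func:`null_screen` — zero effect sizes everywhere; every downstream
  SimIdx has null expectation ``1 - alpha``.
* :func:`recovery_screen` — one MoA shifting *k* of *F* features by a
  fixed effect; in the power-1 regime SimIdx concentrates at
  ``(F - k)(1 - alpha) / F``.
* :func:`er_dominated_screen` — MoAs drawing their affected features per
  channel with ER-dominated weights, so the most-targeted organelle and
  the best predictive organelle subsets are known by construction.
* :func:`overlap_grid_config` — one multi-compound MoA at a given
  compound-to-compound overlap, for PSI heterogeneity calibration.
* :func:`target_switch_config` — an agonist/antagonist pair with
  organelle-resolved (optionally disjoint) footprints.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .profiles_io import CHANNELS, FeatureSchema
from .synthetic_screen import (
    EffectSpec,
    SimulationConfig,
    make_pair_scenario,
)

_SEED_MASK = 0x7FFFFFFF

#: Per-channel (mean, half-width) of the per-MoA fraction of the channel's
#: features that a treatment affects in the ER-dominated scenario.  ER is
#: hit in nearly every treatment (mean 0.90) and with the widest
#: MoA-to-MoA spread, so it is both the most-targeted organelle and the
#: dominant source of between-MoA variance in the whole-cell response;
#: mitochondria are barely touched.
ER_DOMINATED_WEIGHTS: dict[str, tuple[float, float]] = {
    "ER": (0.90, 0.10),
    "Golgi": (0.45, 0.05),
    "Hoechst": (0.25, 0.04),
    "Syto": (0.12, 0.03),
    "Mito": (0.04, 0.02),
}


def null_screen(
    seed: int,
    n_moas: int = 20,
    n_features: int = 824,
    n_cells: int = 100,
    k_affected: int = 100,
) -> SimulationConfig:
    """A screen whose treatments are distributionally identical to DMSO."""
    rng = np.random.default_rng([seed & _SEED_MASK, 21])
    effects = tuple(
        EffectSpec(
            moa_label=f"null-moa-{i:02d}",
            affected_features=frozenset(
                rng.choice(n_features, size=k_affected, replace=False).tolist()
            ),
            effect_size_sd=0.0,
            n_compounds=1,
        )
        for i in range(n_moas)
    )
    return SimulationConfig(
        n_features=n_features,
        n_dmso_cells=n_cells,
        n_cells_per_compound=n_cells,
        effects=effects,
        seed=seed & _SEED_MASK,
    )


def recovery_screen(
    seed: int,
    k_affected: int = 200,
    n_features: int = 824,
    effect_size_sd: float = 2.0,
    n_cells: int = 200,
) -> SimulationConfig:
    """One MoA with a fixed affected set, in the near-certain-detection regime."""
    rng = np.random.default_rng([seed & _SEED_MASK, 22])
    affected = frozenset(
        rng.choice(n_features, size=k_affected, replace=False).tolist()
    )
    return SimulationConfig(
        n_features=n_features,
        n_dmso_cells=n_cells,
        n_cells_per_compound=n_cells,
        effects=(
            EffectSpec(
                moa_label="recovery-moa",
                affected_features=affected,
                effect_size_sd=effect_size_sd,
                n_compounds=1,
                overlap_fraction=1.0,
            ),
        ),
        seed=seed & _SEED_MASK,
    )


def expected_recovery_sim_idx(
    k_affected: int = 200, n_features: int = 824, alpha: float = 0.05
) -> float:
    """SimIdx expectation when all k affected features are detected."""
    return (n_features - k_affected) * (1.0 - alpha) / n_features


def er_dominated_screen(
    seed: int,
    n_moas: int = 20,
    n_features: int = 824,
    n_cells: int = 60,
    n_dmso_cells: int = 150,
    n_unannotated: int = 30,
    effect_size_sd: float = 2.0,
    channel_weights: Mapping[str, tuple[float, float]] | None = None,
) -> SimulationConfig:
    """MoAs whose affected features land predominantly in the ER block.

    Per MoA and channel, the affected fraction of the channel's block is
    drawn uniformly from ``mean ± half_width`` (independently across
    channels), so each organelle's mean targeting rate and its
    between-MoA variance both follow the channel weights.
    """
    weights = dict(channel_weights or ER_DOMINATED_WEIGHTS)
    config = SimulationConfig(n_features=n_features, seed=seed & _SEED_MASK)
    layout = config.channel_layout
    rng = np.random.default_rng([seed & _SEED_MASK, 23])
    effects = []
    for i in range(n_moas):
        affected: set[int] = set()
        for ch in CHANNELS:
            block = np.fromiter(layout[ch], dtype=int)
            mean, half = weights.get(ch, (0.0, 0.0))
            frac = float(np.clip(rng.uniform(mean - half, mean + half), 0.0, 1.0))
            k = int(round(frac * block.size))
            if k:
                affected |= set(rng.choice(block, size=k, replace=False).tolist())
        effects.append(
            EffectSpec(
                moa_label=f"er-moa-{i:02d}",
                affected_features=frozenset(affected),
                effect_size_sd=effect_size_sd,
                n_compounds=1,
                overlap_fraction=1.0,
            )
        )
    return SimulationConfig(
        n_features=n_features,
        n_dmso_cells=n_dmso_cells,
        n_cells_per_compound=n_cells,
        effects=tuple(effects),
        n_unannotated=n_unannotated,
        seed=seed & _SEED_MASK,
    )


def overlap_grid_config(
    seed: int,
    overlap_fraction: float,
    n_features: int = 824,
    affected_fraction: float = 0.8,
    n_compounds: int = 4,
    n_cells: int = 100,
    effect_size_sd: float = 2.0,
) -> SimulationConfig:
    """One multi-compound MoA with a large affected pool at a given overlap."""
    rng = np.random.default_rng([seed & _SEED_MASK, 24])
    k = int(round(affected_fraction * n_features))
    affected = frozenset(rng.choice(n_features, size=k, replace=False).tolist())
    return SimulationConfig(
        n_features=n_features,
        n_dmso_cells=n_cells,
        n_cells_per_compound=n_cells,
        effects=(
            EffectSpec(
                moa_label=f"grid-moa-ov{overlap_fraction:.2f}",
                affected_features=affected,
                effect_size_sd=effect_size_sd,
                n_compounds=n_compounds,
                overlap_fraction=overlap_fraction,
            ),
        ),
        seed=seed & _SEED_MASK,
    )


def target_switch_config(
    seed: int,
    agonist_channels: set[str] = frozenset({"Golgi", "Mito"}),
    antagonist_channels: set[str] = frozenset({"Hoechst", "ER"}),
    n_features: int = 824,
    n_cells: int = 100,
    n_dmso_cells: int = 150,
) -> SimulationConfig:
    """Agonist/antagonist pair whose organelle footprints may differ."""
    base = SimulationConfig(
        n_features=n_features,
        n_dmso_cells=n_dmso_cells,
        n_cells_per_compound=n_cells,
        seed=seed & _SEED_MASK,
    )
    return make_pair_scenario(
        base, set(agonist_channels), set(antagonist_channels)
    )


def channel_target_frequency(
    truth: Mapping[str, frozenset[int]],
    schema: FeatureSchema,
    compounds: list[str] | None = None,
) -> dict[str, float]:
    """Realized ground truth: mean fraction of each channel's features affected."""
    ids = list(truth) if compounds is None else compounds
    out: dict[str, float] = {}
    for ch in CHANNELS:
        idx = set(schema.features_for(ch).tolist())
        if not idx or not ids:
            out[ch] = float("nan")
            continue
        out[ch] = float(
            np.mean([len(truth[c] & idx) / len(idx) for c in ids])
        )
    return out
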