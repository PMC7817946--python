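"""End-to-end orchestration of the screen analysis.

``run_pipeline`` executes similarity -> impact -> response models ->
heterogeneity over either an input screen (profile + annotation tables)
or a simulated one, writes every stage's table, and emits a JSON run
report.  The pipeline is a pure function of (inputs, config, seed): a
rerun with the same config is bit-identical, so no timestamps appear in
any output.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import AnalysisError, ConfigError, InputError
from .heterogeneity import (
    flag_low_psi,
    pair_contrast,
    psi_matrix,
    select_multi_compound_moas,
)
from .impact import build_impact, default_threshold, organelle_impact_fraction
from .profiles_io import (
    CHANNELS,
    attribute_channels,
    read_annotation,
    read_profiles,
)
from .response_models import (
    RESPONSE_COLUMN,
    fit_and_score,
    fit_response_curve,
    models_to_frame,
    occurrence_analysis,
    sensitivity,
)
from .similarity import screen_similarity
from .synthetic_screen import EffectSpec, SimulationConfig, simulate_screen

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on.

    Either ``profiles_path``/``annotation_path`` or ``simulation`` must be
    given.  Defaults mirror the screen's canonical operating point:
    per-feature alpha 0.05, high-impact threshold at 90% of the MoA count,
    top/bottom 5 models, PSI cutoff 0.3, PSI selection strictly more than
    3 compounds.
    """

    profiles_path: str | None = None
    annotation_path: str | None = None
    simulation: SimulationConfig | None = None
    treatment_column: str = "treatment"
    alpha: float = 0.05
    variance_mode: str = "pooled"
    attribution_mode: str = "multi"
    mahalanobis_shrinkage: float = 0.1
    outlier_quantile: float = 0.99
    impact_threshold_quantile: float = 0.9
    top_k: int = 5
    bottom_k: int = 5
    psi_min_compounds: int = 3
    psi_cutoff: float = 0.3
    seed: int = 0
    output_dir: str = "hca-output"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")
        has_files = self.profiles_path is not None and self.annotation_path is not None
        if has_files == (self.simulation is not None):
            raise ConfigError(
                "give either profiles_path+annotation_path or a simulation config"
            )
        for path in (self.profiles_path, self.annotation_path):
            if path is not None and not Path(path).exists():
                raise InputError(f"input path does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} is not a mapping")
        sim = raw.pop("simulation", None)
        if sim is not None:
            effects = [EffectSpec(**e) for e in sim.pop("effects", [])]
            layout = sim.pop("channel_layout", None)
            if layout is not None:
                layout = {ch: range(b[0], b[1]) for ch, b in layout.items()}
            sim = SimulationConfig(effects=tuple(effects), channel_layout=layout, **sim)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(simulation=sim, **raw)

    def describe(self) -> dict[str, Any]:
        out = {
            k: v
            for k, v in self.__dict__.items()
            if k != "simulation"
        }
        if self.simulation is not None:
            sim = self.simulation
            out["simulation"] = {
                "n_features": sim.n_features,
                "n_dmso_cells": sim.n_dmso_cells,
                "n_cells_per_compound": sim.n_cells_per_compound,
                "n_unannotated": sim.n_unannotated,
                "block_correlation": sim.block_correlation,
                "seed": sim.seed,
                "effects": [
                    {
                        "moa_label": e.moa_label,
                        "n_affected": len(e.affected_features),
                        "effect_size_sd": e.effect_size_sd,
                        "n_compounds": e.n_compounds,
                        "overlap_fraction": e.overlap_fraction,
                    }
                    for e in sim.effects
                ],
            }
        return out


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except AnalysisError as exc:
                raise AnalysisError(f"[stage {name}] {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all four stages and write outputs under ``config.output_dir``.

    Returns the run report (also written as ``report.json``).
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    collected_warnings: list[str] = []

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        report = _run(config, out_dir)
        collected_warnings = sorted({str(w.message) for w in caught})

    report["warnings"] = collected_warnings
    payload = json.dumps(report, indent=1, sort_keys=True)
    (out_dir / "report.json").write_text(payload)
    return report


def _run(config: RunConfig, out_dir: Path) -> dict[str, Any]:
    # ---- inputs -------------------------------------------------------
    if config.simulation is not None:
        profiles, annotation, truth = simulate_screen(config.simulation)
        schema = next(iter(profiles.values())).schema
        truth_json = {cid: sorted(fs) for cid, fs in truth.items()}
        (out_dir / "ground_truth.json").write_text(
            json.dumps(truth_json, indent=1, sort_keys=True)
        )
    else:
        profiles = read_profiles(config.profiles_path, config.treatment_column)
        annotation = read_annotation(config.annotation_path)
        schema = next(iter(profiles.values())).schema
    schema = attribute_channels(schema, mode=config.attribution_mode)
    schema.to_json(out_dir / "feature_schema.json")

    report: dict[str, Any] = {
        "package_version": __version__,
        "config": config.describe(),
        "n_treatments": len(profiles) - 1,
        "n_moas": len(annotation.moa_labels()),
        "n_unannotated": len(annotation.unannotated_compounds()),
    }

    # ---- stage 1: similarity -----------------------------------------
    screen = _stage("similarity")(screen_similarity)(
        profiles,
        annotation,
        alpha=config.alpha,
        variance_mode=config.variance_mode,
        schema=schema,
        regularization=config.mahalanobis_shrinkage,
        outlier_quantile=config.outlier_quantile,
    )
    screen.table.to_csv(out_dir / "similarity_moa.csv", index=False)
    screen.compound_table.to_csv(out_dir / "similarity_compound.csv", index=False)
    report["similarity"] = {
        "mean_sim_idx": float(screen.table["sim_idx"].mean()),
        "min_sim_idx": float(screen.table["sim_idx"].min()),
        "max_sim_idx": float(screen.table["sim_idx"].max()),
        "median_mahalanobis": float(screen.table["mahalanobis"].median()),
    }

    # ---- stage 2: impact ---------------------------------------------
    impact = _stage("impact")(build_impact)(screen.sig_vectors)
    threshold = default_threshold(impact.n_moas, config.impact_threshold_quantile)
    fractions = _stage("impact")(organelle_impact_fraction)(impact, schema, threshold)
    impact.to_frame(schema).to_csv(out_dir / "impact_index.csv", index=False)
    pd.DataFrame(
        [{"channel": ch, "fraction_high_impact": fr} for ch, fr in fractions.items()]
    ).to_csv(out_dir / "organelle_fractions.csv", index=False)
    finite = {ch: fr for ch, fr in fractions.items() if np.isfinite(fr)}
    report["impact"] = {
        "threshold": threshold,
        "n_moas": impact.n_moas,
        "organelle_fractions": fractions,
        "top_organelle": max(finite, key=finite.get) if finite else None,
    }

    # ---- stage 3: response models ------------------------------------
    curves = []
    for ch in CHANNELS:
        col = f"sim_idx_{ch}"
        try:
            curve = fit_response_curve(
                screen.table[col], screen.table["sim_idx"], channel=ch
            )
            curves.append(curve)
        except AnalysisError as exc:
            warnings.warn(f"response curve for {ch} skipped: {exc}")
    curve_rows = [
        {
            "channel": c.channel,
            "a": c.coefficients[0],
            "b": c.coefficients[1],
            "c": c.coefficients[2],
            "n_points": c.n_points,
            "residual_ss": c.fit_residual_ss,
            "sensitivity_at_0.5": sensitivity(c, 0.5),
        }
        for c in curves
    ]
    pd.DataFrame(curve_rows).to_csv(out_dir / "response_curves.csv", index=False)

    train = _design_table(screen.table)
    unannotated = set(annotation.unannotated_compounds())
    test_rows = screen.compound_table[
        screen.compound_table["treatment_id"].isin(unannotated)
    ]
    if test_rows.empty:
        test_rows = screen.compound_table
        warnings.warn(
            "no unannotated test compounds; scoring prediction models on the "
            "annotated per-compound rows"
        )
    test = _design_table(test_rows)

    report["response_models"] = {}
    try:
        models = _stage("response_models")(fit_and_score)(train, test)
        models_to_frame(models).to_csv(out_dir / "prediction_models.csv", index=False)
        occurrence = occurrence_analysis(models, config.top_k, config.bottom_k)
        occ_payload = {
            "counts": {
                ch: {"top": t, "bottom": b} for ch, (t, b) in occurrence.counts.items()
            },
            "top_instances": occurrence.top_instances,
            "bottom_instances": occurrence.bottom_instances,
        }
        (out_dir / "occurrence.json").write_text(
            json.dumps(occ_payload, indent=1, sort_keys=True)
        )
        report["response_models"] = {
            "best_subset": "+".join(models[0].organelle_subset),
            "best_test_r2": models[0].test_r2,
            "occurrence": occ_payload,
        }
    except AnalysisError as exc:
        warnings.warn(f"prediction stage skipped: {exc}")

    # ---- stage 4: heterogeneity --------------------------------------
    moas = select_multi_compound_moas(annotation, profiles, config.psi_min_compounds)
    matrices = []
    for moa in moas:
        compound_profiles = {
            c: profiles[c] for c in annotation.compounds_for(moa) if c in profiles
        }
        psi = _stage("heterogeneity")(psi_matrix)(
            compound_profiles,
            schema,
            alpha=config.alpha,
            moa_label=moa,
            variance_mode=config.variance_mode,
        )
        matrices.append(psi)
        pd.DataFrame(
            psi.matrix, index=psi.compound_ids, columns=psi.compound_ids
        ).to_csv(out_dir / f"psi_{_slug(moa)}.csv")
    flagged = flag_low_psi(matrices, config.psi_cutoff)
    pd.DataFrame(
        [
            {"moa": m.moa_label, "mean_psi": m.summary, "n_compounds": len(m.compound_ids)}
            for m in matrices
        ]
    ).to_csv(out_dir / "psi_summary.csv", index=False)

    contrasts = {}
    by_label = {m.moa_label: m for m in matrices}
    for ag, ant in annotation.pair_registry:
        if ag in by_label and ant in by_label:
            table = pair_contrast(by_label[ag], by_label[ant])
            table.to_csv(out_dir / f"pair_contrast_{_slug(ag)}.csv", index=False)
            contrasts[f"{ag} / {ant}"] = {
                "agonist_top": str(
                    table.loc[table["agonist_rank"] == 1, "channel"].iloc[0]
                ),
                "antagonist_top": str(
                    table.loc[table["antagonist_rank"] == 1, "channel"].iloc[0]
                ),
            }
    report["heterogeneity"] = {
        "n_moas_tested": len(matrices),
        "mean_psi": {m.moa_label: m.summary for m in matrices},
        "flagged_low_psi": flagged,
        "pair_contrasts": contrasts,
    }
    return report


def _design_table(table: pd.DataFrame) -> pd.DataFrame:
    cols = {f"sim_idx_{ch}": ch for ch in CHANNELS}
    out = table[["sim_idx", *cols]].rename(columns={"sim_idx": RESPONSE_COLUMN, **cols})
    return out.dropna()


def _slug(label: str) -> str:
    return "".join(c if c.isalnum() else "-" for c in label).strip("-")
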