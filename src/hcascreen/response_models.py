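"""Organelle -> whole-cell response modelling.

Two layers: (i) per-organelle quadratic response curves ``overall SimIdx
= a x^2 + b x + c`` with the organelle SimIdx as the regressor, whose
first derivative ``2 a x + b`` is the sensitivity of the cellular
response to that organelle; (ii) exhaustive multivariate linear
regressions over every 2- and 3-organelle subset (C(5,2) + C(5,3) = 20
models), trained on MoA-level rows and scored on held-out per-compound
rows with the goodness of prediction ``R^2 = 1 - SSE/SST``.  Ranking the
models and counting organelle occurrences among the top/bottom five of
each size identifies the channels that carry (or lack) predictive
signal.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import AnalysisError
from .profiles_io import CHANNELS

logger = logging.getLogger(__name__)

#: Column holding the whole-cell response in design tables.
RESPONSE_COLUMN = "overall"


@dataclass(frozen=True)
class ResponseCurve:
    """Quadratic organelle->cell response fit for one channel."""

    channel: str
    coefficients: tuple[float, float, float]  # (a, b, c), highest power first
    n_points: int
    fit_residual_ss: float

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise AnalysisError("a quadratic fit needs at least 3 points")


@dataclass(frozen=True)
class PredictionModel:
    """One organelle-subset linear model with its held-out score."""

    organelle_subset: tuple[str, ...]
    coefficients: dict[str, float]  # "const" plus one slope per channel
    train_n: int
    test_r2: float

    def __post_init__(self) -> None:
        if len(self.organelle_subset) not in (2, 3):
            raise AnalysisError("organelle subsets must have 2 or 3 channels")
        if self.test_r2 > 1.0 + 1e-12:
            raise AnalysisError("test R^2 cannot exceed 1")


def fit_response_curve(x, y, channel: str) -> ResponseCurve:
    """Ordinary least-squares quadratic fit of overall vs organelle SimIdx."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise AnalysisError(f"channel {channel}: need >= 3 points for a quadratic fit")
    if np.unique(x).size < 3:
        raise AnalysisError(f"channel {channel}: design is rank deficient (x values repeat)")
    coeffs = np.polyfit(x, y, 2)
    resid = y - np.polyval(coeffs, x)
    return ResponseCurve(
        channel=channel,
        coefficients=(float(coeffs[0]), float(coeffs[1]), float(coeffs[2])),
        n_points=int(x.size),
        fit_residual_ss=float(np.sum(resid**2)),
    )


def sensitivity(curve: ResponseCurve, x: float) -> float:
    """First derivative of the response curve at *x*: ``2 a x + b``."""
    a, b, _ = curve.coefficients
    return 2.0 * a * x + b


def enumerate_models(channels: set[str] | tuple[str, ...] = CHANNELS) -> list[tuple[str, ...]]:
    """All 2- and 3-channel subsets, lexicographically ordered (pairs first)."""
    tags = sorted(channels)
    if len(tags) != 5 or len(set(tags)) != 5:
        raise AnalysisError("expected exactly 5 distinct channel tags")
    return [
        tuple(c)
        for size in (2, 3)
        for c in itertools.combinations(tags, size)
    ]


def _r_squared(actual: np.ndarray, predicted: np.ndarray, center: float) -> float:
    sse = float(np.sum((actual - predicted) ** 2))
    sst = float(np.sum((actual - center) ** 2))
    if sst == 0:
        raise AnalysisError("test responses are constant; R^2 undefined")
    return 1.0 - sse / sst


def fit_and_score(
    train: pd.DataFrame,
    test: pd.DataFrame,
    subsets: list[tuple[str, ...]] | None = None,
    response: str = RESPONSE_COLUMN,
    sst_about: str = "test",
) -> list[PredictionModel]:
    """Fit every organelle-subset OLS model on *train*, score R^2 on *test*.

    Both tables need one column per channel tag plus the *response*
    column; train rows are typically MoA-level aggregates and test rows
    per-compound readouts.  ``SST`` is taken about the test-set mean by
    default (``sst_about="train"`` switches to the training mean for
    sensitivity analysis).  Models are returned sorted by test R^2
    descending with lexicographic subset tie-break; negative R^2 is
    reported as-is.  Subsets with collinear predictors are skipped with a
    warning.
    """
    if subsets is None:
        subsets = enumerate_models()
    if sst_about not in ("test", "train"):
        raise AnalysisError(f"unknown sst_about {sst_about!r}")
    max_size = max(len(s) for s in subsets)
    if len(train) <= max_size + 1:
        raise AnalysisError("train table too small for the requested subsets")
    if len(test) == 0:
        raise AnalysisError("test table is empty")
    needed = {response} | {c for s in subsets for c in s}
    for frame, name in ((train, "train"), (test, "test")):
        missing = needed - set(frame.columns)
        if missing:
            raise AnalysisError(f"{name} table lacks columns {sorted(missing)}")

    y_train = train[response].to_numpy(dtype=float)
    y_test = test[response].to_numpy(dtype=float)
    center = float(np.mean(y_test if sst_about == "test" else y_train))

    models: list[PredictionModel] = []
    for subset in subsets:
        x_train = sm.add_constant(train[list(subset)].to_numpy(dtype=float))
        if np.linalg.matrix_rank(x_train) < x_train.shape[1]:
            logger.warning("skipping collinear subset %s", subset)
            continue
        fit = sm.OLS(y_train, x_train).fit()
        x_test = sm.add_constant(
            test[list(subset)].to_numpy(dtype=float), has_constant="add"
        )
        predicted = x_test @ fit.params
        r2 = _r_squared(y_test, predicted, center)
        coefficients = {"const": float(fit.params[0])}
        coefficients.update(
            {ch: float(v) for ch, v in zip(subset, fit.params[1:])}
        )
        models.append(
            PredictionModel(
                organelle_subset=tuple(subset),
                coefficients=coefficients,
                train_n=len(train),
                test_r2=float(r2),
            )
        )
    models.sort(key=lambda m: (-m.test_r2, m.organelle_subset))
    return models


@dataclass(frozen=True)
class OccurrenceCounts:
    """Channel occurrence tallies across the best and worst subset models."""

    counts: dict[str, tuple[int, int]]  # channel -> (top_count, bottom_count)
    top_instances: int
    bottom_instances: int

    def fractions(self) -> dict[str, tuple[float, float]]:
        return {
            ch: (top / self.top_instances, bot / self.bottom_instances)
            for ch, (top, bot) in self.counts.items()
        }


def occurrence_analysis(
    models: list[PredictionModel], top_k: int = 5, bottom_k: int = 5
) -> OccurrenceCounts:
    """Count channel appearances in the top/bottom-k models per subset size.

    With k = 5 over the 20 canonical models each side selects 5 pairs and
    5 triples, i.e. 5*2 + 5*3 = 25 organelle instances.
    """
    by_size: dict[int, list[PredictionModel]] = {}
    for m in models:
        by_size.setdefault(len(m.organelle_subset), []).append(m)
    if set(by_size) != {2, 3}:
        raise AnalysisError("models must cover both subset sizes 2 and 3")
    for size, group in by_size.items():
        if len(group) < max(top_k, bottom_k):
            raise AnalysisError(
                f"only {len(group)} size-{size} models for k={max(top_k, bottom_k)}"
            )

    top: dict[str, int] = {ch: 0 for ch in CHANNELS}
    bottom: dict[str, int] = {ch: 0 for ch in CHANNELS}
    top_instances = bottom_instances = 0
    for size in sorted(by_size):
        ranked = sorted(by_size[size], key=lambda m: (-m.test_r2, m.organelle_subset))
        for m in ranked[:top_k]:
            top_instances += size
            for ch in m.organelle_subset:
                top[ch] += 1
        for m in ranked[-bottom_k:]:
            bottom_instances += size
            for ch in m.organelle_subset:
                bottom[ch] += 1
    return OccurrenceCounts(
        counts={ch: (top[ch], bottom[ch]) for ch in CHANNELS},
        top_instances=top_instances,
        bottom_instances=bottom_instances,
    )


def models_to_frame(models: list[PredictionModel]) -> pd.DataFrame:
    rows = []
    for rank, m in enumerate(models, start=1):
        rows.append(
            {
                "rank": rank,
                "subset": "+".join(m.organelle_subset),
                "n_channels": len(m.organelle_subset),
                "train_n": m.train_n,
                "test_r2": m.test_r2,
                **{f"coef_{k}": v for k, v in m.coefficients.items()},
            }
        )
    return pd.DataFrame(rows)
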