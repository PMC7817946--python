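"""Similarity statistics between treatment populations and the DMSO control.

The central quantity is the similarity index (SimIdx): each of the
screen's features is tested with a per-feature two-sided two-sample
t-test at level ``alpha`` between the treatment population and DMSO,
yielding a binary significance array ``h`` (1 = changed); SimIdx is the
fraction of features that did *not* change.  Restricting the fraction to
the features of one fluorescent channel gives the organelle SimIdx, and
replacing DMSO by a second compound gives the pairwise similarity index
(PSI).  Because the test level is alpha with no multiplicity correction,
the null expectation of SimIdx is ``1 - alpha``, not 1.

A complementary whole-profile measure is the Mahalanobis distance of each
treatment cell from the DMSO distribution, with covariance shrinkage
toward the diagonal (the feature count typically exceeds the DMSO cell
count) and quantile-based outlier filtering before aggregation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .exceptions import AnalysisError
from .profiles_io import (
    CHANNELS,
    FeatureSchema,
    ProfileTable,
    ScreenAnnotation,
    pool_profiles,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignificanceVector:
    """Per-feature test outcome of one population comparison.

    ``h[x] = 1`` iff feature ``x`` differs significantly (p < alpha).
    ``usable`` marks features with >= 2 non-missing cells in both groups;
    ``degenerate`` marks zero-variance-equal-mean features, which are
    forced to ``h = 0`` and excluded from SimIdx denominators so constant
    dummy columns cannot inflate similarity.
    """

    schema: FeatureSchema
    h: np.ndarray
    p_values: np.ndarray
    alpha: float
    n_a: int
    n_b: int
    usable: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    degenerate: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = self.schema.n_features
        for name in ("h", "p_values", "usable", "degenerate"):
            arr = getattr(self, name)
            if arr is None or np.shape(arr) != (n,):
                raise AnalysisError(f"{name} must have one entry per feature")
        if np.any((self.h == 1) & ~self.usable):
            raise AnalysisError("unusable features cannot be significant")

    @property
    def countable(self) -> np.ndarray:
        """Features entering SimIdx denominators: usable and non-degenerate."""
        return self.usable & ~self.degenerate


def feature_significance(
    a: ProfileTable,
    b: ProfileTable,
    alpha: float = 0.05,
    variance_mode: str = "pooled",
    correction: str | None = None,
) -> SignificanceVector:
    """Two-sided two-sample t-test per feature between populations *a* and *b*.

    ``variance_mode="pooled"`` is the classical equal-variance test (the
    default two-sample test of the original analysis environment);
    ``"welch"`` drops the equal-variance assumption.  ``correction="bh"``
    optionally applies Benjamini-Hochberg across usable features (off by
    default: the screen's operating point is a raw per-feature alpha).
    Missing entries are dropped pairwise per feature.
    """
    if a.schema.feature_names != b.schema.feature_names:
        raise AnalysisError("profiles do not share a feature schema")
    if variance_mode not in ("pooled", "welch"):
        raise AnalysisError(f"unknown variance_mode {variance_mode!r}")
    if not 0.0 < alpha < 1.0:
        raise AnalysisError("alpha must lie in (0, 1)")

    xa, xb = a.values, b.values
    na = np.sum(~np.isnan(xa), axis=0)
    nb = np.sum(~np.isnan(xb), axis=0)
    usable = (na >= 2) & (nb >= 2)
    if not usable.any():
        raise AnalysisError(
            f"no usable features comparing {a.treatment_id!r} and {b.treatment_id!r}"
        )
    n_unusable = int((~usable).sum())
    if n_unusable:
        logger.warning(
            "%d features unusable (fewer than 2 cells) comparing %s vs %s",
            n_unusable,
            a.treatment_id,
            b.treatment_id,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_a = np.nanmean(np.where(usable, xa, np.nan), axis=0)
        mean_b = np.nanmean(np.where(usable, xb, np.nan), axis=0)
        var_a = np.nanvar(np.where(usable, xa, np.nan), axis=0, ddof=1)
        var_b = np.nanvar(np.where(usable, xb, np.nan), axis=0, ddof=1)
        res = stats.ttest_ind(
            xa,
            xb,
            axis=0,
            equal_var=(variance_mode == "pooled"),
            nan_policy="omit",
        )
        p = np.asarray(res.pvalue, dtype=float)

    degenerate = usable & (var_a == 0) & (var_b == 0) & (mean_a == mean_b)
    # both groups constant but different: t is infinite, the difference is
    # certain at any level
    certain = usable & (var_a == 0) & (var_b == 0) & (mean_a != mean_b)
    p = np.where(certain, 0.0, p)
    p = np.where(~usable | degenerate, np.nan, p)

    if correction == "bh":
        from statsmodels.stats.multitest import multipletests

        mask = np.isfinite(p)
        if mask.any():
            p_adj = p.copy()
            p_adj[mask] = multipletests(p[mask], method="fdr_bh")[1]
            p = p_adj
    elif correction is not None:
        raise AnalysisError(f"unknown correction {correction!r}")

    h = np.where(np.isfinite(p) & (p < alpha), 1, 0).astype(np.int8)
    return SignificanceVector(
        schema=a.schema,
        h=h,
        p_values=p,
        alpha=alpha,
        n_a=a.n_cells,
        n_b=b.n_cells,
        usable=usable,
        degenerate=degenerate,
    )


def _subset_mask(sig: SignificanceVector, feature_subset: Iterable[int] | None) -> np.ndarray:
    mask = sig.countable.copy()
    if feature_subset is not None:
        sel = np.zeros(sig.schema.n_features, dtype=bool)
        sel[np.fromiter((int(i) for i in feature_subset), dtype=int)] = True
        mask &= sel
    return mask


def sim_idx(
    sig: SignificanceVector, feature_subset: Iterable[int] | None = None
) -> float:
    """Fraction of (usable, non-degenerate) features with ``h = 0``."""
    mask = _subset_mask(sig, feature_subset)
    denom = int(mask.sum())
    if denom == 0:
        raise AnalysisError("no usable features in the requested subset")
    return float((sig.h[mask] == 0).sum() / denom)


def organelle_sim_idx(
    sig: SignificanceVector, schema: FeatureSchema | None = None
) -> dict[str, float]:
    """SimIdx restricted to each channel's attributed features.

    Channels with no usable attributed feature are reported as ``nan``.
    """
    schema = schema or sig.schema
    out: dict[str, float] = {}
    for ch in CHANNELS:
        idx = schema.features_for(ch)
        try:
            out[ch] = sim_idx(sig, idx) if idx.size else float("nan")
        except AnalysisError:
            out[ch] = float("nan")
    return out


def pairwise_sim_idx(
    a: ProfileTable,
    b: ProfileTable,
    alpha: float = 0.05,
    feature_subset: Iterable[int] | None = None,
    variance_mode: str = "pooled",
) -> float:
    """PSI: SimIdx comparing two compounds directly (no DMSO involved)."""
    sig = feature_significance(a, b, alpha=alpha, variance_mode=variance_mode)
    return sim_idx(sig, feature_subset)


def mahalanobis_profile(
    reference: ProfileTable,
    query: ProfileTable,
    regularization: float = 0.1,
    outlier_quantile: float = 0.99,
    aggregate: str = "median",
) -> tuple[float, np.ndarray, int]:
    """Mahalanobis distance of every query cell from the reference cloud.

    The reference (DMSO) covariance is shrunk toward its own diagonal with
    weight ``regularization`` — with more features than reference cells the
    raw covariance is singular, and diagonal (rather than identity)
    shrinkage keeps the distance invariant under per-feature rescaling.
    Query cells above the ``outlier_quantile`` of their own distance
    distribution are dropped before aggregation (median by default).

    Returns ``(summary, per_cell_distances, n_outliers_removed)``; the
    per-cell array covers *all* query cells, pre-filtering.
    """
    if reference.n_cells < 2:
        raise AnalysisError("reference needs at least 2 cells")
    if aggregate not in ("median", "mean"):
        raise AnalysisError(f"unknown aggregate {aggregate!r}")
    if not 0.0 <= regularization <= 1.0:
        raise AnalysisError("regularization must lie in [0, 1]")
    if not 0.0 < outlier_quantile <= 1.0:
        raise AnalysisError("outlier_quantile must lie in (0, 1]")

    ref = reference.values[~np.isnan(reference.values).any(axis=1)]
    qry = query.values[~np.isnan(query.values).any(axis=1)]
    if ref.shape[0] < 2 or qry.shape[0] < 1:
        raise AnalysisError("too few complete cells for a Mahalanobis profile")

    mu = ref.mean(axis=0)
    cov = np.cov(ref, rowvar=False)
    cov = np.atleast_2d(cov)
    shrunk = (1.0 - regularization) * cov + regularization * np.diag(np.diag(cov))
    try:
        chol = linalg.cho_factor(shrunk, lower=True)
    except linalg.LinAlgError as exc:
        raise AnalysisError(
            "regularized covariance is not invertible; increase regularization"
        ) from exc

    centered = (qry - mu).T
    solved = linalg.cho_solve(chol, centered)
    d2 = np.einsum("ij,ij->j", centered, solved)
    per_cell = np.sqrt(np.maximum(d2, 0.0))

    cutoff = np.quantile(per_cell, outlier_quantile)
    keep = per_cell <= cutoff
    n_outliers = int((~keep).sum())
    kept = per_cell[keep]
    summary = float(np.median(kept) if aggregate == "median" else np.mean(kept))
    return summary, per_cell, n_outliers


def dynamic_range(values: Sequence[float]) -> float:
    """Maximum over minimum of the finite values (metric resolving power)."""
    arr = np.asarray(list(values), dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise AnalysisError("no finite values for a dynamic range")
    if np.any(arr <= 0):
        raise AnalysisError("dynamic range undefined for non-positive values")
    return float(arr.max() / arr.min())


@dataclass(frozen=True)
class SimilarityResult:
    """Per-treatment summary of the similarity stage."""

    treatment_id: str
    sim_idx: float
    organelle_sim_idx: dict[str, float]
    mahalanobis_summary: float
    n_outliers_removed: int
    n_cells: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.sim_idx <= 1.0:
            raise AnalysisError("sim_idx out of [0, 1]")


@dataclass
class ScreenSimilarity:
    """Output of :func:`screen_similarity`.

    ``table`` has one row per MoA (cells pooled across the MoA's
    compounds); ``compound_table`` one row per individual compound.  The
    per-MoA significance vectors feed the impact stage; the table columns
    are the vectors behind the cumulative-histogram figures.
    """

    table: pd.DataFrame
    compound_table: pd.DataFrame
    sig_vectors: dict[str, SignificanceVector]
    results: list[SimilarityResult]


def _similarity_row(
    treatment: ProfileTable,
    control: ProfileTable,
    alpha: float,
    variance_mode: str,
    schema: FeatureSchema,
    mahalanobis: bool,
    regularization: float,
    outlier_quantile: float,
    aggregate: str,
) -> tuple[SimilarityResult, SignificanceVector]:
    sig = feature_significance(treatment, control, alpha=alpha, variance_mode=variance_mode)
    overall = sim_idx(sig)
    per_channel = organelle_sim_idx(sig, schema)
    if mahalanobis:
        summary, _, n_out = mahalanobis_profile(
            control,
            treatment,
            regularization=regularization,
            outlier_quantile=outlier_quantile,
            aggregate=aggregate,
        )
    else:
        summary, n_out = float("nan"), 0
    result = SimilarityResult(
        treatment_id=treatment.treatment_id,
        sim_idx=overall,
        organelle_sim_idx=per_channel,
        mahalanobis_summary=summary,
        n_outliers_removed=n_out,
        n_cells=treatment.n_cells,
    )
    return result, sig


def _to_frame(results: list[SimilarityResult], extra: Mapping[str, list] | None = None) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "treatment_id": r.treatment_id,
            "n_cells": r.n_cells,
            "sim_idx": r.sim_idx,
            "mahalanobis": r.mahalanobis_summary,
            "n_outliers_removed": r.n_outliers_removed,
        }
        for ch in CHANNELS:
            row[f"sim_idx_{ch}"] = r.organelle_sim_idx.get(ch, float("nan"))
        rows.append(row)
    df = pd.DataFrame(rows)
    if extra:
        for k, v in extra.items():
            df[k] = v
    return df


def screen_similarity(
    profiles: Mapping[str, ProfileTable],
    annotation: ScreenAnnotation,
    alpha: float = 0.05,
    variance_mode: str = "pooled",
    schema: FeatureSchema | None = None,
    compute_mahalanobis: bool = True,
    regularization: float = 0.1,
    outlier_quantile: float = 0.99,
    aggregate: str = "median",
    per_compound: bool = True,
) -> ScreenSimilarity:
    """Run the similarity stage over a whole screen.

    Every annotated MoA is compared against DMSO with its compounds'
    cells pooled into one population (the MoA-level readout); individual
    compounds — including unannotated test compounds — are additionally
    compared one by one when ``per_compound`` is set (these rows feed the
    PSI stage and the prediction test set).
    """
    control = profiles.get(annotation.control_id)
    if control is None:
        raise AnalysisError(f"control {annotation.control_id!r} missing from profiles")
    schema = schema or control.schema

    moa_results: list[SimilarityResult] = []
    sig_vectors: dict[str, SignificanceVector] = {}
    for moa in annotation.moa_labels():
        compounds = [c for c in annotation.compounds_for(moa) if c in profiles]
        if not compounds:
            continue
        pooled = pool_profiles([profiles[c] for c in compounds], moa)
        result, sig = _similarity_row(
            pooled, control, alpha, variance_mode, schema,
            compute_mahalanobis, regularization, outlier_quantile, aggregate,
        )
        moa_results.append(result)
        sig_vectors[moa] = sig

    if not moa_results:
        raise AnalysisError("no annotated MoA has profiles in this screen")

    compound_results: list[SimilarityResult] = []
    moa_col: list[str] = []
    if per_compound:
        for cid, table in profiles.items():
            if cid == annotation.control_id:
                continue
            result, _ = _similarity_row(
                table, control, alpha, variance_mode, schema,
                False, regularization, outlier_quantile, aggregate,
            )
            compound_results.append(result)
            moa = annotation.moa_of(cid)
            moa_col.append("" if moa is None else moa)

    return ScreenSimilarity(
        table=_to_frame(moa_results),
        compound_table=_to_frame(compound_results, {"moa": moa_col} if compound_results else None),
        sig_vectors=sig_vectors,
        results=moa_results + compound_results,
    )
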