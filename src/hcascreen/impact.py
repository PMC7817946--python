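"""Impact Index: how often each feature (and organelle) is hit by treatments.

For feature *f*, the screen's significance vectors are collated into a
binary row ``SimVal_f`` over MoAs (1 = the MoA changed the feature) and
the Impact Index is its sum, ``ImpIdx_f = sum(SimVal_f)`` — an integer
between 0 and the number of MoAs.  The most-targeted organelle is then
read off the fraction of each channel's features whose ImpIdx exceeds a
high threshold (by default 90% of the maximum possible value, i.e.
``round(0.9 * n_moas)``, 243 for a 270-MoA screen).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import AnalysisError
from .profiles_io import CHANNELS, FeatureSchema
from .similarity import SignificanceVector

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImpactProfile:
    """Binary features x MoAs affect matrix plus per-feature ImpIdx.

    ``sim_val`` is float with ``NaN`` marking features unusable for a
    given MoA comparison (never silently zero); ``imp_idx`` sums over the
    usable entries and is ``NaN`` for features usable in no MoA.
    """

    moa_labels: tuple[str, ...]
    sim_val: np.ndarray
    imp_idx: np.ndarray

    @property
    def n_moas(self) -> int:
        return len(self.moa_labels)

    def to_frame(self, schema: FeatureSchema) -> pd.DataFrame:
        df = pd.DataFrame(self.sim_val, columns=list(self.moa_labels))
        df.insert(0, "feature", list(schema.feature_names))
        df["imp_idx"] = self.imp_idx
        return df


def build_impact(sig_vectors: dict[str, SignificanceVector]) -> ImpactProfile:
    """Assemble the SimVal matrix column-per-MoA and row-sum it to ImpIdx.

    Asserts the conservation identity on every run: the total ImpIdx mass
    equals the total count of significant features across MoAs, i.e.
    ``sum_f ImpIdx_f = sum_moa usable_moa * (1 - SimIdx_moa)``.
    """
    if not sig_vectors:
        raise AnalysisError("need at least one MoA significance vector")
    labels = tuple(sig_vectors)
    first = sig_vectors[labels[0]]
    n_features = first.schema.n_features
    for moa in labels[1:]:
        if sig_vectors[moa].schema.feature_names != first.schema.feature_names:
            raise AnalysisError(f"significance vector for {moa!r} has a different schema")

    sim_val = np.full((n_features, len(labels)), np.nan)
    for j, moa in enumerate(labels):
        sig = sig_vectors[moa]
        col = np.where(sig.countable, sig.h.astype(float), np.nan)
        sim_val[:, j] = col

    ever_usable = np.isfinite(sim_val).any(axis=1)
    imp_idx = np.where(ever_usable, np.nansum(sim_val, axis=1), np.nan)

    total = float(np.nansum(imp_idx))
    per_moa = float(
        sum(
            int(sig_vectors[m].countable.sum())
            - int((sig_vectors[m].h[sig_vectors[m].countable] == 0).sum())
            for m in labels
        )
    )
    assert total == per_moa, (
        f"ImpIdx conservation violated: {total} != {per_moa}"
    )
    return ImpactProfile(moa_labels=labels, sim_val=sim_val, imp_idx=imp_idx)


def default_threshold(n_moas: int, quantile: float = 0.9) -> int:
    """High-impact cutoff: ``round(quantile * n_moas)``, half away from zero."""
    if not 0.0 < quantile <= 1.0:
        raise AnalysisError("quantile must lie in (0, 1]")
    return int(math.floor(quantile * n_moas + 0.5))


def organelle_impact_fraction(
    profile: ImpactProfile,
    schema: FeatureSchema,
    threshold: int | None = None,
) -> dict[str, float]:
    """Per channel: fraction of usable attributed features with ImpIdx > threshold.

    Strict inequality; channels with no usable attributed feature are
    reported as ``nan`` with a warning.
    """
    if threshold is None:
        threshold = default_threshold(profile.n_moas)
    if not 0 <= threshold <= profile.n_moas:
        raise AnalysisError("threshold must lie in [0, n_moas]")
    out: dict[str, float] = {}
    for ch in CHANNELS:
        idx = schema.features_for(ch)
        usable = idx[np.isfinite(profile.imp_idx[idx])] if idx.size else idx
        if usable.size == 0:
            logger.warning("channel %s has no usable attributed features", ch)
            out[ch] = float("nan")
            continue
        out[ch] = float((profile.imp_idx[usable] > threshold).mean())
    return out
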