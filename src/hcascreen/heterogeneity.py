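"""Response heterogeneity across compounds sharing a mechanism of action.

For each MoA treated with more than ``min_compounds`` distinct compounds,
all unordered compound pairs are compared directly with the pairwise
similarity index (PSI, the SimIdx of a compound-vs-compound test).  A
low mean off-diagonal PSI means the compounds — despite a conserved
annotated outcome — change different features: response heterogeneity.
Restricting PSI to one channel's features gives the organelle PSI used to
contrast agonist and antagonist arms of a receptor pair: the organelle
with the highest PSI behaves concordantly across the arm's compounds and
is read as the arm's most likely target, so differing top organelles
between arms signal a target switch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import AnalysisError
from .profiles_io import CHANNELS, FeatureSchema, ProfileTable, ScreenAnnotation
from .similarity import feature_significance, sim_idx

_SYM_TOL = 1e-12


@dataclass(frozen=True)
class PsiMatrix:
    """Symmetric compound-by-compound PSI matrix for one MoA."""

    moa_label: str
    compound_ids: tuple[str, ...]
    matrix: np.ndarray
    organelle_summaries: dict[str, float]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.compound_ids),) * 2:
            raise AnalysisError("PSI matrix shape does not match compound list")
        if np.nanmax(np.abs(m - m.T)) > _SYM_TOL:
            raise AnalysisError("PSI matrix is not symmetric")
        off = m[~np.eye(len(self.compound_ids), dtype=bool)]
        if off.size and (np.nanmin(off) < 0 or np.nanmax(off) > 1):
            raise AnalysisError("PSI values out of [0, 1]")
        if not np.allclose(np.diag(m), 1.0):
            raise AnalysisError("PSI diagonal must be 1 by convention")
        object.__setattr__(self, "matrix", m)

    @property
    def summary(self) -> float:
        """Mean off-diagonal PSI (the MoA's scalar heterogeneity readout)."""
        return self._reduce("mean")

    def _reduce(self, how: str) -> float:
        mask = ~np.eye(len(self.compound_ids), dtype=bool)
        off = self.matrix[mask]
        fn = {"mean": np.mean, "median": np.median, "min": np.min}[how]
        return float(fn(off))

    def reduced(self, how: str = "mean") -> float:
        if how not in ("mean", "median", "min"):
            raise AnalysisError(f"unknown PSI reduction {how!r}")
        return self._reduce(how)


def psi_matrix(
    profiles: Mapping[str, ProfileTable],
    schema: FeatureSchema,
    alpha: float = 0.05,
    channel: str | None = None,
    moa_label: str = "",
    variance_mode: str = "pooled",
) -> PsiMatrix:
    """All-pairs PSI among a set of compound profiles.

    Each pair's per-feature test is run once; the full-feature PSI fills
    the matrix (or the channel-restricted PSI when *channel* is given)
    and, for the unrestricted case, per-channel PSIs averaged over pairs
    fill ``organelle_summaries``.  The diagonal is 1 by convention and
    excluded from every summary.
    """
    ids = tuple(profiles)
    if len(ids) < 2:
        raise AnalysisError("PSI needs at least 2 compounds")
    subset = schema.features_for(channel) if channel is not None else None
    if subset is not None and subset.size == 0:
        raise AnalysisError(f"channel {channel!r} has no attributed features")

    n = len(ids)
    matrix = np.eye(n)
    channel_accum = {ch: [] for ch in CHANNELS}
    for i in range(n):
        for j in range(i + 1, n):
            sig = feature_significance(
                profiles[ids[i]], profiles[ids[j]], alpha=alpha, variance_mode=variance_mode
            )
            value = sim_idx(sig, subset)
            matrix[i, j] = matrix[j, i] = value
            if channel is None:
                for ch in CHANNELS:
                    idx = schema.features_for(ch)
                    if idx.size:
                        try:
                            channel_accum[ch].append(sim_idx(sig, idx))
                        except AnalysisError:
                            pass
    organelle_summaries = {
        ch: (float(np.mean(v)) if v else float("nan"))
        for ch, v in channel_accum.items()
    }
    return PsiMatrix(
        moa_label=moa_label,
        compound_ids=ids,
        matrix=matrix,
        organelle_summaries=organelle_summaries,
    )


def select_multi_compound_moas(
    annotation: ScreenAnnotation,
    profiles: Mapping[str, ProfileTable],
    min_compounds: int = 3,
) -> list[str]:
    """MoAs with strictly more than *min_compounds* profiled compounds."""
    out = []
    for moa in annotation.moa_labels():
        n = sum(1 for c in annotation.compounds_for(moa) if c in profiles)
        if n > min_compounds:
            out.append(moa)
    return sorted(out)


def flag_low_psi(matrices: list[PsiMatrix], cutoff: float = 0.3) -> list[str]:
    """MoAs whose mean off-diagonal PSI falls strictly below *cutoff*."""
    if not 0.0 < cutoff <= 1.0:
        raise AnalysisError("cutoff must lie in (0, 1]")
    return [m.moa_label for m in matrices if m.summary < cutoff]


def pair_contrast(agonist: PsiMatrix, antagonist: PsiMatrix) -> pd.DataFrame:
    """Per-channel agonist vs antagonist organelle PSI with within-arm ranks.

    Rank 1 is the channel with the highest organelle PSI in that arm (its
    most concordantly affected — "most likely targeted" — organelle).
    """
    ch_a = {c for c, v in agonist.organelle_summaries.items() if np.isfinite(v)}
    ch_b = {c for c, v in antagonist.organelle_summaries.items() if np.isfinite(v)}
    if ch_a != ch_b:
        raise AnalysisError("agonist and antagonist carry different channel sets")
    if not ch_a:
        raise AnalysisError("no organelle summaries to contrast")
    channels = [c for c in CHANNELS if c in ch_a]
    ag = np.array([agonist.organelle_summaries[c] for c in channels])
    an = np.array([antagonist.organelle_summaries[c] for c in channels])

    def ranks(values: np.ndarray) -> np.ndarray:
        order = np.lexsort((np.arange(values.size), -values))
        r = np.empty(values.size, dtype=int)
        r[order] = np.arange(1, values.size + 1)
        return r

    return pd.DataFrame(
        {
            "channel": channels,
            "agonist_psi": ag,
            "antagonist_psi": an,
            "agonist_rank": ranks(ag),
            "antagonist_rank": ranks(an),
            "delta": ag - an,
        }
    )


def top_channel(contrast: pd.DataFrame, arm: str) -> str:
    """The rank-1 channel of ``arm`` ('agonist' or 'antagonist')."""
    if arm not in ("agonist", "antagonist"):
        raise AnalysisError(f"unknown arm {arm!r}")
    row = contrast.loc[contrast[f"{arm}_rank"] == 1]
    return str(row["channel"].iloc[0])
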