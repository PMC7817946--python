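"""Reading and writing single-cell feature tables and screen annotations.

A cell-painting screen is delivered as a long table with one row per
segmented cell and one column per CellProfiler morphology feature, plus a
column naming the treatment (a compound/BroadID or the DMSO vehicle
control).  Feature labels embed the fluorescent-channel acronyms
``Golgi``, ``ER``, ``Hoechst``, ``Syto`` and ``Mito``; those acronyms are
the only organelle attribution available, so channel membership is
recovered by substring search on the labels.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError

#: The five fluorescent channels of the cell-painting assay, in the fixed
#: order used for first-match attribution.
CHANNELS: tuple[str, ...] = ("Golgi", "ER", "Hoechst", "Syto", "Mito")

#: Default identifier of the vehicle-control condition.
DEFAULT_CONTROL_ID = "DMSO"


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature labels plus per-feature organelle attribution.

    Parameters
    ----------
    feature_names
        Unique, non-empty feature labels, in column order.
    channel_map
        Feature index -> set of channel tags.  A feature may carry zero
        tags (e.g. ``Cells_AreaShape_Compactness``) or several (cross-
        channel correlation features).
    """

    feature_names: tuple[str, ...]
    channel_map: dict[int, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = tuple(self.feature_names)
        object.__setattr__(self, "feature_names", names)
        if len(set(names)) != len(names):
            raise InputError("feature names must be unique")
        if any(not n for n in names):
            raise InputError("feature names must be non-empty")
        for idx, tags in self.channel_map.items():
            if not 0 <= idx < len(names):
                raise InputError(f"channel_map index {idx} out of range")
            bad = set(tags) - set(CHANNELS)
            if bad:
                raise InputError(f"unknown channel tags {sorted(bad)}")
        # normalise to frozensets
        object.__setattr__(
            self,
            "channel_map",
            {i: frozenset(t) for i, t in self.channel_map.items() if t},
        )

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def channels_of(self, index: int) -> frozenset[str]:
        return self.channel_map.get(index, frozenset())

    def features_for(self, channel: str) -> np.ndarray:
        """Indices of the features attributed to *channel*."""
        if channel not in CHANNELS:
            raise InputError(f"unknown channel {channel!r}")
        return np.array(
            sorted(i for i, t in self.channel_map.items() if channel in t),
            dtype=int,
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": list(self.feature_names),
            "channel_map": {str(i): sorted(t) for i, t in self.channel_map.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureSchema":
        payload = json.loads(Path(path).read_text())
        return cls(
            feature_names=tuple(payload["feature_names"]),
            channel_map={
                int(i): frozenset(t) for i, t in payload["channel_map"].items()
            },
        )


@dataclass(frozen=True)
class ProfileTable:
    """Single-cell feature matrix (cells x features) for one treatment.

    ``values`` is a float matrix; missing measurements are ``NaN`` and are
    never imputed — downstream tests drop them pairwise.  Row order carries
    no meaning (cells within a treatment are unordered).
    """

    treatment_id: str
    schema: FeatureSchema
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise InputError("profile values must be a 2-D matrix")
        if values.shape[1] != self.schema.n_features:
            raise InputError(
                f"profile for {self.treatment_id!r} has {values.shape[1]} columns, "
                f"schema has {self.schema.n_features} features"
            )
        if values.shape[0] < 1:
            raise InputError(f"profile for {self.treatment_id!r} has no cells")
        if np.isnan(values).all(axis=1).any():
            raise InputError(
                f"profile for {self.treatment_id!r} contains an entirely missing row"
            )
        object.__setattr__(self, "values", values)

    @property
    def n_cells(self) -> int:
        return int(self.values.shape[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.schema.feature_names))


def pool_profiles(tables: Sequence[ProfileTable], treatment_id: str) -> ProfileTable:
    """Stack several compound tables into one pooled population."""
    if not tables:
        raise InputError("cannot pool an empty list of profiles")
    schema = tables[0].schema
    for t in tables[1:]:
        if t.schema.feature_names != schema.feature_names:
            raise InputError("cannot pool profiles with differing schemas")
    return ProfileTable(
        treatment_id=treatment_id,
        schema=schema,
        values=np.vstack([t.values for t in tables]),
    )


_UNANNOTATED = ("", "unannotated", "na", "nan", "none")

_PAIR_RE = re.compile(r"^(?P<stem>.*?)[\s_]?(?P<role>agonist|antagonist)$", re.I)


@dataclass(frozen=True)
class ScreenAnnotation:
    """Compound -> MoA map plus control id and agonist/antagonist pairs.

    ``compound_to_moa`` maps every non-control compound to its MoA label or
    to ``None`` when the compound is unannotated (a test compound).
    ``pair_registry`` lists ``(agonist_moa, antagonist_moa)`` label pairs.
    """

    compound_to_moa: dict[str, str | None]
    control_id: str = DEFAULT_CONTROL_ID
    pair_registry: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.compound_to_moa.get(self.control_id) is not None:
            raise InputError(
                f"control {self.control_id!r} must not carry an MoA label"
            )
        moas = set(self.moa_labels())
        for ag, ant in self.pair_registry:
            if ag not in moas or ant not in moas:
                raise InputError(
                    f"pair ({ag!r}, {ant!r}) references MoAs absent from the map"
                )
        object.__setattr__(self, "pair_registry", tuple(self.pair_registry))

    def moa_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for cid, moa in self.compound_to_moa.items():
            if cid != self.control_id and moa is not None:
                seen.setdefault(moa)
        return list(seen)

    def compounds_for(self, moa: str) -> list[str]:
        return [
            cid
            for cid, m in self.compound_to_moa.items()
            if m == moa and cid != self.control_id
        ]

    def unannotated_compounds(self) -> list[str]:
        return [
            cid
            for cid, m in self.compound_to_moa.items()
            if m is None and cid != self.control_id
        ]

    def moa_of(self, compound: str) -> str | None:
        return self.compound_to_moa.get(compound)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    # round_trip parsing keeps finite values bit-identical across write/read
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_profiles(
    path: str | Path,
    treatment_column: str = "treatment",
    value_columns: Sequence[str] | None = None,
) -> dict[str, ProfileTable]:
    """Read a long single-cell table and split it per treatment.

    Feature columns are every column other than ``treatment_column`` unless
    ``value_columns`` narrows them.  Column order is preserved; the returned
    tables all share a single :class:`FeatureSchema` (without channel
    attribution — see :func:`attribute_channels`).
    """
    df = _read_table(path)
    if treatment_column not in df.columns:
        raise InputError(
            f"treatment column {treatment_column!r} not found in {path}"
        )
    if value_columns is None:
        value_columns = [c for c in df.columns if c != treatment_column]
    else:
        missing = [c for c in value_columns if c not in df.columns]
        if missing:
            raise InputError(f"feature columns not found: {missing}")
    if not value_columns:
        raise InputError(f"no feature columns in {path}")

    numeric = {}
    for col in value_columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise InputError(
                f"non-numeric value {df[col].iloc[row]!r} at row {row}, "
                f"column {col!r} in {path}"
            )
        numeric[col] = coerced.to_numpy(dtype=float)

    schema = FeatureSchema(feature_names=tuple(value_columns))
    matrix = np.column_stack([numeric[c] for c in value_columns])
    out: dict[str, ProfileTable] = {}
    treatments = df[treatment_column].astype(str)
    for tid in treatments.unique():
        mask = (treatments == tid).to_numpy()
        out[tid] = ProfileTable(treatment_id=tid, schema=schema, values=matrix[mask])
    return out


def write_profiles(
    profiles: Mapping[str, ProfileTable],
    path: str | Path,
    treatment_column: str = "treatment",
) -> None:
    """Write profiles back to one long CSV/TSV (inverse of read_profiles)."""
    frames = []
    for tid in profiles:
        frame = profiles[tid].to_frame()
        frame.insert(0, treatment_column, tid)
        frames.append(frame)
    df = pd.concat(frames, ignore_index=True)
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    # %.17g guarantees float64 entries survive the text round trip bit-exactly
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def attribute_channels(schema: FeatureSchema, mode: str = "multi") -> FeatureSchema:
    """Attribute every feature to organelle channels by acronym matching.

    Matching is case-insensitive substring search of each channel acronym
    in the full feature label (CellProfiler labels concatenate tokens with
    underscores inconsistently, so token boundaries are not required).

    ``mode="multi"`` assigns all matching tags; ``mode="first-match"``
    assigns only the first acronym found when scanning the fixed order
    Golgi, ER, Hoechst, Syto, Mito, which yields disjoint channel sets.
    """
    if mode not in ("multi", "first-match"):
        raise InputError(f"unknown attribution mode {mode!r}")
    channel_map: dict[int, frozenset[str]] = {}
    for idx, name in enumerate(schema.feature_names):
        low = name.lower()
        hits = [ch for ch in CHANNELS if ch.lower() in low]
        if not hits:
            continue
        if mode == "first-match":
            hits = hits[:1]
        channel_map[idx] = frozenset(hits)
    return replace(schema, channel_map=channel_map)


def _pairs_from_labels(moas: Iterable[str]) -> tuple[tuple[str, str], ...]:
    """Auto-detect agonist/antagonist pairs from MoA label stems."""
    stems: dict[str, dict[str, str]] = {}
    for moa in moas:
        m = _PAIR_RE.match(moa.strip())
        if m:
            stems.setdefault(m.group("stem").strip().lower(), {})[
                m.group("role").lower()
            ] = moa
    registry = []
    for stem in sorted(stems):
        roles = stems[stem]
        if "agonist" in roles and "antagonist" in roles:
            registry.append((roles["agonist"], roles["antagonist"]))
    return tuple(registry)


def read_annotation(
    path: str | Path, control_id: str = DEFAULT_CONTROL_ID
) -> ScreenAnnotation:
    """Read a compound -> MoA annotation table.

    Expects columns ``compound`` and ``moa`` (first two columns are used if
    those names are absent).  Compounds with an empty/"unannotated" MoA are
    recorded as unannotated test compounds.  Agonist/antagonist pairs are
    auto-detected from MoA labels of the form ``"<stem> agonist"`` /
    ``"<stem> antagonist"``.
    """
    df = _read_table(path)
    if df.shape[1] < 2:
        raise InputError(f"annotation {path} needs at least two columns")
    cols = list(df.columns)
    comp_col = "compound" if "compound" in cols else cols[0]
    moa_col = "moa" if "moa" in cols else cols[1]

    mapping: dict[str, str | None] = {}
    for row_idx, row in df.iterrows():
        cid = str(row[comp_col]).strip()
        raw = row[moa_col]
        moa = None if pd.isna(raw) else str(raw).strip()
        if moa is not None and moa.lower() in _UNANNOTATED:
            moa = None
        if cid == control_id and moa is not None:
            raise InputError(
                f"control {control_id!r} carries MoA {moa!r} (row {row_idx})"
            )
        if cid in mapping and mapping[cid] != moa:
            raise InputError(
                f"compound {cid!r} annotated with conflicting MoAs "
                f"{mapping[cid]!r} and {moa!r}"
            )
        mapping[cid] = moa

    moas = [m for m in mapping.values() if m is not None]
    return ScreenAnnotation(
        compound_to_moa=mapping,
        control_id=control_id,
        pair_registry=_pairs_from_labels(moas),
    )


def write_annotation(annotation: ScreenAnnotation, path: str | Path) -> None:
    rows = [
        {"compound": cid, "moa": "" if moa is None else moa}
        for cid, moa in annotation.compound_to_moa.items()
    ]
    if annotation.control_id not in annotation.compound_to_moa:
        rows.insert(0, {"compound": annotation.control_id, "moa": ""})
    pd.DataFrame(rows).to_csv(Path(path), index=False)
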