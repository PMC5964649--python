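"""Lineage data model and the tabular lineage dialect.

A lineage file holds one row per detected nucleus per timestep:

    node_id,predecessor_id,timestep,time_hp,x,y,z,validated,identity,death

``node_id`` is unique; ``predecessor_id`` links to the same cell (or the
mother's last nucleus) one timestep earlier and is empty for roots.
``time_hp`` is hours post fertilization (wild type) or post activation
(clones).  ``identity`` is ``inner``/``outer`` or empty when unannotated;
``validated`` and ``death`` are 0/1 flags.  A *track* is a maximal chain of
nodes between divisions: it starts at a graph root or just after a division
and ends where the cell divides, dies, or leaves the observation window.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import LineageFormatError

__all__ = [
    "COLUMNS",
    "IDENTITY_INNER",
    "IDENTITY_OUTER",
    "IDENTITY_UNSET",
    "LineageMetadata",
    "CellTrack",
    "EmbryoLineage",
    "ValidationReport",
    "read_lineage_table",
    "write_lineage_table",
    "build_tracks",
    "validate_lineage",
]

COLUMNS = [
    "node_id",
    "predecessor_id",
    "timestep",
    "time_hp",
    "x",
    "y",
    "z",
    "validated",
    "identity",
    "death",
]

IDENTITY_INNER = "inner"
IDENTITY_OUTER = "outer"
IDENTITY_UNSET = ""

_VALID_IDENTITIES = {IDENTITY_INNER, IDENTITY_OUTER, IDENTITY_UNSET}

FATE_DIVIDES = "divides"
FATE_DIES = "dies"
FATE_CENSORED = "censored"


@dataclass(frozen=True)
class LineageMetadata:
    """Per-embryo metadata block accompanying a lineage table.

    ``fertilization_offset_h`` is the estimated delay between coitum and
    fertilization for wild-type embryos (8 h by convention); for clones the
    time origin is the activation pulse and the offset is 0.
    """

    embryo_id: str
    group: str = "wild_type"  # "wild_type" | "clone"
    time_origin: str = "fertilization"  # "fertilization" | "activation"
    fertilization_offset_h: float = 8.0
    frame_interval_min: float = 15.0

    def __post_init__(self) -> None:
        if self.group not in ("wild_type", "clone"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.time_origin not in ("fertilization", "activation"):
            raise ValueError(f"unknown time origin {self.time_origin!r}")

    @property
    def frame_interval_h(self) -> float:
        return self.frame_interval_min / 60.0


@dataclass
class CellTrack:
    """A maximal division-to-division chain of nuclei (one cell's lifetime)."""

    track_id: int
    node_ids: list[int]
    mother_track_id: int | None = None
    daughter_track_ids: tuple[int, ...] = ()
    birth_timestep: int = 0
    last_timestep: int = 0
    fate: str = FATE_CENSORED

    def __len__(self) -> int:
        return len(self.node_ids)

    @property
    def first_node(self) -> int:
        return self.node_ids[0]

    @property
    def last_node(self) -> int:
        return self.node_ids[-1]


@dataclass
class EmbryoLineage:
    """An embryo's full nucleus graph plus derived cell tracks.

    ``nodes`` is a DataFrame indexed by ``node_id`` with the dialect columns
    (minus ``node_id``); ``tracks`` maps track id to :class:`CellTrack`.
    """

    metadata: LineageMetadata
    nodes: pd.DataFrame
    tracks: dict[int, CellTrack] = field(default_factory=dict)
    node_track: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.tracks and len(self.nodes):
            self.tracks, self.node_track = build_tracks(self.nodes)

    # -- convenience accessors -------------------------------------------------

    @property
    def timesteps(self) -> np.ndarray:
        """Sorted timesteps that contain at least one validated node."""
        mask = self.nodes["validated"].to_numpy(bool)
        return np.unique(self.nodes.loc[mask, "timestep"].to_numpy())

    def frame_nodes(self, timestep: int, validated_only: bool = True) -> pd.DataFrame:
        sel = self.nodes["timestep"] == timestep
        if validated_only:
            sel &= self.nodes["validated"].astype(bool)
        return self.nodes.loc[sel]

    def frame_positions(self, timestep: int, validated_only: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """(node_ids, (n,3) positions) for one timestep."""
        frame = self.frame_nodes(timestep, validated_only)
        return frame.index.to_numpy(), frame[["x", "y", "z"]].to_numpy(float)

    def time_of_timestep(self, timestep: int) -> float:
        sel = self.nodes.index[self.nodes["timestep"] == timestep]
        if len(sel) == 0:
            raise KeyError(f"no nodes at timestep {timestep}")
        return float(self.nodes.at[sel[0], "time_hp"])

    def track_is_validated(self, track_id: int) -> bool:
        t = self.tracks[track_id]
        return bool(self.nodes.loc[t.node_ids, "validated"].all())

    @property
    def validated_tracks(self) -> list[CellTrack]:
        return [t for t in self.tracks.values() if self.track_is_validated(t.track_id)]

    def root_tracks(self) -> list[CellTrack]:
        return [t for t in self.tracks.values() if t.mother_track_id is None]

    def n_divisions(self) -> int:
        return sum(1 for t in self.tracks.values() if t.fate == FATE_DIVIDES)


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_lineage`: errors fail, warnings do not."""

    errors: list[tuple[str, object, str]] = field(default_factory=list)
    warnings: list[tuple[str, object, str]] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.errors

    def add_error(self, code: str, ref: object, message: str) -> None:
        self.errors.append((code, ref, message))

    def add_warning(self, code: str, ref: object, message: str) -> None:
        self.warnings.append((code, ref, message))

    def summary(self) -> str:
        lines = [f"validation {'PASS' if self.passed else 'FAIL'}: "
                 f"{len(self.errors)} error(s), {len(self.warnings)} warning(s)"]
        for code, ref, msg in self.errors:
            lines.append(f"  ERROR [{code}] ({ref}): {msg}")
        for code, ref, msg in self.warnings:
            lines.append(f"  WARN  [{code}] ({ref}): {msg}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

def _parse_flag(values: pd.Series, column: str) -> pd.Series:
    """Accept 0/1 and true/false spellings for boolean columns."""
    mapping = {"0": False, "1": True, "false": False, "true": True,
               "False": False, "True": True}
    as_str = values.astype(str).str.strip()
    out = as_str.map(mapping)
    if out.isna().any():
        bad = as_str[out.isna()].iloc[0]
        raise LineageFormatError(f"column {column!r}: unparseable flag {bad!r}")
    return out.astype(bool)


def read_lineage_table(path: str | Path, metadata: LineageMetadata) -> EmbryoLineage:
    """Read a lineage CSV file in the package dialect.

    Raises :class:`LineageFormatError` on a missing column, duplicate
    ``node_id``, dangling predecessor, or a predecessor whose timestep is not
    exactly one less than its successor's.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise LineageFormatError(f"{path.name}: missing required column(s) {missing}")

    try:
        nodes = pd.DataFrame({
            "predecessor_id": pd.to_numeric(
                raw["predecessor_id"].where(raw["predecessor_id"] != "", np.nan),
                errors="raise",
            ).astype("Int64"),
            "timestep": pd.to_numeric(raw["timestep"], errors="raise").astype(int),
            # float() round-trips repr output exactly; pd.to_numeric does not
            "time_hp": raw["time_hp"].map(float),
            "x": raw["x"].map(float),
            "y": raw["y"].map(float),
            "z": raw["z"].map(float),
            "validated": _parse_flag(raw["validated"], "validated"),
            "identity": raw["identity"].astype(str).str.strip(),
            "death": _parse_flag(raw["death"], "death"),
        }, index=pd.to_numeric(raw["node_id"], errors="raise").astype(int))
    except (ValueError, TypeError) as exc:
        raise LineageFormatError(f"{path.name}: unparseable value ({exc})") from exc
    nodes.index.name = "node_id"

    if nodes.index.has_duplicates:
        dup = int(nodes.index[nodes.index.duplicated()][0])
        raise LineageFormatError(f"{path.name}: duplicate node_id {dup}")
    bad_identity = ~nodes["identity"].isin(_VALID_IDENTITIES)
    if bad_identity.any():
        val = nodes.loc[bad_identity, "identity"].iloc[0]
        raise LineageFormatError(f"{path.name}: unknown identity label {val!r}")

    _check_links(nodes, source=path.name)
    return EmbryoLineage(metadata=metadata, nodes=nodes)


def _check_links(nodes: pd.DataFrame, source: str = "<table>") -> None:
    pred = nodes["predecessor_id"]
    linked = pred.notna()
    if linked.any():
        targets = pred[linked].astype(int)
        missing = ~targets.isin(nodes.index)
        if missing.any():
            nid = int(targets.index[missing][0])
            raise LineageFormatError(
                f"{source}: node {nid} links to nonexistent predecessor "
                f"{int(targets[missing].iloc[0])}")
        dt = nodes.loc[targets.index, "timestep"].to_numpy() - \
            nodes.loc[targets.to_numpy(), "timestep"].to_numpy()
        bad = dt != 1
        if bad.any():
            nid = int(targets.index[bad][0])
            raise LineageFormatError(
                f"{source}: node {nid} has predecessor at timestep offset "
                f"{int(dt[bad][0])} (must be exactly 1)")


def write_lineage_table(lineage: EmbryoLineage, path: str | Path) -> None:
    """Write the node table in the dialect; inverse of :func:`read_lineage_table`.

    Unset identities become empty fields and flags are written as 0/1, so the
    round trip is exact field for field.
    """
    nodes = lineage.nodes
    out = pd.DataFrame({
        "node_id": nodes.index.to_numpy(),
        "predecessor_id": nodes["predecessor_id"].map(
            lambda v: "" if pd.isna(v) else str(int(v))),
        "timestep": nodes["timestep"].to_numpy(),
        "time_hp": [repr(float(v)) for v in nodes["time_hp"]],
        "x": [repr(float(v)) for v in nodes["x"]],
        "y": [repr(float(v)) for v in nodes["y"]],
        "z": [repr(float(v)) for v in nodes["z"]],
        "validated": nodes["validated"].astype(int).to_numpy(),
        "identity": nodes["identity"].to_numpy(),
        "death": nodes["death"].astype(int).to_numpy(),
    })
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Track construction
# ---------------------------------------------------------------------------

def build_tracks(nodes: pd.DataFrame) -> tuple[dict[int, CellTrack], dict[int, int]]:
    """Partition the node graph into maximal division-to-division chains.

    Returns ``(tracks, node_track)`` where ``node_track`` maps every node id
    to its track id.  Track boundaries occur exactly at graph roots and at
    divisions (nodes with two successors).  A node with three or more
    successors is a format error.
    """
    successors: dict[int, list[int]] = {}
    for nid, pred in nodes["predecessor_id"].items():
        if pd.notna(pred):
            successors.setdefault(int(pred), []).append(int(nid))
    for nid, succ in successors.items():
        if len(succ) > 2:
            raise LineageFormatError(
                f"node {nid} has {len(succ)} successors (max 2)")
        succ.sort()

    timestep = nodes["timestep"].to_dict()
    roots = [int(n) for n, p in nodes["predecessor_id"].items() if pd.isna(p)]
    roots.sort(key=lambda n: (timestep[n], n))

    tracks: dict[int, CellTrack] = {}
    node_track: dict[int, int] = {}
    # (first node, mother track id) pairs seed a breadth-first chain walk
    queue: list[tuple[int, int | None]] = [(r, None) for r in roots]
    next_id = 0
    while queue:
        head, mother = queue.pop(0)
        chain = [head]
        while True:
            succ = successors.get(chain[-1], [])
            if len(succ) == 1:
                chain.append(succ[0])
            else:
                break
        tid = next_id
        next_id += 1
        succ = successors.get(chain[-1], [])
        if len(succ) == 2:
            fate = FATE_DIVIDES
        elif bool(nodes.at[chain[-1], "death"]):
            fate = FATE_DIES
        else:
            fate = FATE_CENSORED
        tracks[tid] = CellTrack(
            track_id=tid,
            node_ids=chain,
            mother_track_id=mother,
            birth_timestep=int(timestep[chain[0]]),
            last_timestep=int(timestep[chain[-1]]),
            fate=fate,
        )
        for n in chain:
            node_track[n] = tid
        for s in succ:
            queue.append((s, tid))

    # second pass: daughter links (daughters always get larger ids than mothers)
    for tid, tr in tracks.items():
        if tr.fate == FATE_DIVIDES:
            daughters = tuple(sorted(
                node_track[s] for s in successors[tr.last_node]))
            tr.daughter_track_ids = daughters
    return tracks, node_track


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_lineage(lineage: EmbryoLineage) -> ValidationReport:
    """Semantic validation of a parsed lineage.

    Checks: at most two successors per node (enforced structurally by
    :func:`build_tracks`), death-flagged nodes are terminal, timesteps within
    a track are consecutive, and ``time_hp`` spacing is consistent with the
    metadata frame interval.
    """
    report = ValidationReport()
    nodes = lineage.nodes
    dt_h = lineage.metadata.frame_interval_h

    successors: dict[int, int] = {}
    for nid, pred in nodes["predecessor_id"].items():
        if pd.notna(pred):
            successors[int(pred)] = successors.get(int(pred), 0) + 1

    for nid in nodes.index[nodes["death"].astype(bool)]:
        if successors.get(int(nid), 0) > 0:
            report.add_error("death_not_terminal", int(nid),
                             "death-flagged node has a successor")

    for tid, track in lineage.tracks.items():
        steps = nodes.loc[track.node_ids, "timestep"].to_numpy()
        if len(steps) > 1 and not np.all(np.diff(steps) == 1):
            report.add_error("gap_in_track", tid,
                             "track timesteps are not consecutive")
        times = nodes.loc[track.node_ids, "time_hp"].to_numpy(float)
        if len(times) > 1:
            spacing = np.diff(times)
            if not np.allclose(spacing, dt_h, atol=1e-6):
                report.add_error(
                    "inconsistent_time", tid,
                    f"time_hp spacing deviates from frame interval {dt_h:g} h")

    # global timestep/time consistency: same timestep => same time_hp
    per_step = nodes.groupby("timestep")["time_hp"].nunique()
    for step, n in per_step.items():
        if n > 1:
            report.add_error("inconsistent_time", int(step),
                             "nodes at one timestep carry different time_hp")

    if len(nodes) and not nodes["validated"].any():
        report.add_warning("no_validated_nodes", None,
                           "lineage has no validated nodes")
    return report


def lineage_from_records(records: Iterable[dict], metadata: LineageMetadata) -> EmbryoLineage:
    """Build a lineage from an iterable of dialect-keyed dicts (mainly for
    tests and the simulator)."""
    rows = list(records)
    if rows:
        df = pd.DataFrame(rows)
    else:
        df = pd.DataFrame(columns=COLUMNS)
    df = df.reindex(columns=COLUMNS)
    if df["identity"].isna().any():
        df["identity"] = df["identity"].fillna(IDENTITY_UNSET)
    nodes = pd.DataFrame({
        "predecessor_id": pd.array(
            [np.nan if (v is None or (isinstance(v, float) and math.isnan(v)))
             else int(v) for v in df["predecessor_id"]], dtype="Int64"),
        "timestep": df["timestep"].astype(int).to_numpy(),
        "time_hp": df["time_hp"].astype(float).to_numpy(),
        "x": df["x"].astype(float).to_numpy(),
        "y": df["y"].astype(float).to_numpy(),
        "z": df["z"].astype(float).to_numpy(),
        "validated": df["validated"].astype(bool).to_numpy(),
        "identity": df["identity"].astype(str).to_numpy(),
        "death": df["death"].astype(bool).to_numpy(),
    }, index=pd.Index(df["node_id"].astype(int), name="node_id"))
    _check_links(nodes)
    return EmbryoLineage(metadata=metadata, nodes=nodes)


def copy_lineage(lineage: EmbryoLineage) -> EmbryoLineage:
    """Deep-ish copy (nodes copied; tracks rebuilt)."""
    return EmbryoLineage(
        metadata=dataclasses.replace(lineage.metadata),
        nodes=lineage.nodes.copy(),
    )
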