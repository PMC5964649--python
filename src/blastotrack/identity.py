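"""Inner/outer identity annotation and division-type classification.

The blastocyst segregates two populations: outer cells (trophectoderm,
forming the embryo's surface) and inner cells (inner cell mass).  Identity is
assigned geometrically at a cell's last observed timestep — a nucleus is
*outer* when it sits on, or within a tolerance of, the convex hull of all
nuclei in that frame — and then propagated backward along the lineage.  A
mitosis whose daughters end up in different compartments is an *asymmetric*
division; identical compartments make it *symmetric*.

Identity is a per-track attribute, constant between divisions, so the rule
"identity prior to the next mitosis" reduces to the daughter track's
identity; a daughter that never divides before the end of the recording uses
its identity at the last observed timestep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .errors import DegenerateGeometryError, LineageValidationError
from .lineage_io import (
    FATE_DIES,
    FATE_DIVIDES,
    IDENTITY_INNER,
    IDENTITY_OUTER,
    IDENTITY_UNSET,
    CellTrack,
    EmbryoLineage,
)

__all__ = [
    "DivisionRecord",
    "DeathRecord",
    "AnnotatedLineage",
    "classify_frame_by_position",
    "propagate_identities_backward",
    "resolve_mother_identity",
    "classify_divisions",
    "annotate_lineage",
]

DEFAULT_SHELL_TOLERANCE = 0.5  # fraction of mean nearest-neighbor distance


@dataclass(frozen=True)
class DivisionRecord:
    """One mitosis: mother track, timing, and the identity outcome."""

    mother_track_id: int
    time_hp: float
    mother_identity: str
    daughter_identities: tuple[str, str]
    daughter_track_ids: tuple[int, int]
    division_type: str  # "symmetric" | "asymmetric"
    time_na: float | None = None

    @property
    def is_asymmetric(self) -> bool:
        return self.division_type == "asymmetric"


@dataclass(frozen=True)
class DeathRecord:
    """One cell death: the dying track, its identity and timing."""

    track_id: int
    time_hp: float
    identity: str
    time_na: float | None = None


@dataclass
class AnnotatedLineage:
    """Lineage plus per-track identity and division/death records."""

    lineage: EmbryoLineage
    identities: dict[int, str]
    divisions: list[DivisionRecord] = field(default_factory=list)
    deaths: list[DeathRecord] = field(default_factory=list)

    def identity_of(self, track_id: int) -> str:
        return self.identities[track_id]

    def with_identities(self, identities: dict[int, str]) -> "AnnotatedLineage":
        """Same lineage, different identity assignment (records recomputed)."""
        divisions = classify_divisions(self.lineage, identities)
        deaths = collect_deaths(self.lineage, identities)
        return AnnotatedLineage(self.lineage, dict(identities), divisions, deaths)


# ---------------------------------------------------------------------------
# Geometric classification
# ---------------------------------------------------------------------------

def classify_frame_by_position(
    positions: np.ndarray,
    shell_tolerance: float = DEFAULT_SHELL_TOLERANCE,
) -> np.ndarray:
    """Classify every nucleus of one frame as outer (True) or inner (False).

    A nucleus is outer iff it is a vertex of the frame's 3D convex hull, or
    its distance to the nearest hull facet plane is at most
    ``shell_tolerance`` times the frame's mean nearest-neighbor distance.
    Ties at the tolerance are classified outer.

    Raises :class:`DegenerateGeometryError` for < 5 points or coplanar
    geometry.
    """
    pts = np.asarray(positions, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("positions must be an (n, 3) array")
    n = len(pts)
    if n < 5:
        raise DegenerateGeometryError(f"need >=5 nuclei, got {n}")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate frame geometry: {exc}") from exc

    outer = np.zeros(n, dtype=bool)
    outer[hull.vertices] = True

    interior = ~outer
    if interior.any():
        # hull.equations rows are (normal | offset) with unit outward normals,
        # so |A.p + b| is the distance to each facet plane
        planes = hull.equations
        d = pts[interior] @ planes[:, :3].T + planes[:, 3]
        facet_dist = np.min(np.abs(d), axis=1)
        tree = cKDTree(pts)
        nn_dist, _ = tree.query(pts, k=2)
        mean_nn = float(np.mean(nn_dist[:, 1]))
        outer[np.flatnonzero(interior)[facet_dist <= shell_tolerance * mean_nn]] = True
    return outer


class _FrameClassifier:
    """Memoized per-timestep geometric classification of a lineage."""

    def __init__(self, lineage: EmbryoLineage, shell_tolerance: float):
        self.lineage = lineage
        self.shell_tolerance = shell_tolerance
        self._cache: dict[int, dict[int, str]] = {}

    def identity_at(self, node_id: int, timestep: int) -> str:
        if timestep not in self._cache:
            ids, pts = self.lineage.frame_positions(timestep)
            outer = classify_frame_by_position(pts, self.shell_tolerance)
            self._cache[timestep] = {
                int(i): (IDENTITY_OUTER if o else IDENTITY_INNER)
                for i, o in zip(ids, outer)
            }
        return self._cache[timestep][int(node_id)]


# ---------------------------------------------------------------------------
# Backward propagation
# ---------------------------------------------------------------------------

def resolve_mother_identity(
    lineage: EmbryoLineage,
    mother: CellTrack,
    frame_classifier: Callable[[int, int], str] | None = None,
    curated: str | None = None,
    shell_tolerance: float = DEFAULT_SHELL_TOLERANCE,
) -> str:
    """Identity of a mother whose daughters disagree (asymmetric division).

    A curated annotation (from the input file) takes precedence; otherwise
    the mother's last nucleus position is classified geometrically within its
    own frame.
    """
    if curated in (IDENTITY_INNER, IDENTITY_OUTER):
        return curated
    file_identity = str(lineage.nodes.at[mother.last_node, "identity"])
    if file_identity in (IDENTITY_INNER, IDENTITY_OUTER):
        return file_identity
    if frame_classifier is None:
        frame_classifier = _FrameClassifier(lineage, shell_tolerance).identity_at
    return frame_classifier(mother.last_node, mother.last_timestep)


def propagate_identities_backward(
    lineage: EmbryoLineage,
    leaf_identities: dict[int, str],
    shell_tolerance: float = DEFAULT_SHELL_TOLERANCE,
    frame_classifier: Callable[[int, int], str] | None = None,
) -> dict[int, str]:
    """Propagate leaf-track identities back to the roots.

    Tracks are processed leaves-to-roots: a mother whose two daughters agree
    inherits their identity; disagreeing daughters mark an asymmetric
    division and the mother is resolved by :func:`resolve_mother_identity`.
    Every validated leaf track must appear in ``leaf_identities``.
    """
    if frame_classifier is None:
        frame_classifier = _FrameClassifier(lineage, shell_tolerance).identity_at

    identities: dict[int, str] = {}
    validated = {t.track_id for t in lineage.validated_tracks}
    order = sorted(
        (t for t in lineage.tracks.values() if t.track_id in validated),
        key=lambda t: t.last_timestep, reverse=True)
    for track in order:
        if track.fate != FATE_DIVIDES:
            ident = leaf_identities.get(track.track_id, IDENTITY_UNSET)
            if ident not in (IDENTITY_INNER, IDENTITY_OUTER):
                raise LineageValidationError(
                    f"leaf track {track.track_id} has no identity")
            identities[track.track_id] = ident
            continue
        d1, d2 = track.daughter_track_ids
        if d1 not in identities or d2 not in identities:
            # daughters not validated: fall back to geometry at last timestep
            identities[track.track_id] = frame_classifier(
                track.last_node, track.last_timestep)
            continue
        if identities[d1] == identities[d2]:
            identities[track.track_id] = identities[d1]
        else:
            identities[track.track_id] = resolve_mother_identity(
                lineage, track, frame_classifier)
    return identities


# ---------------------------------------------------------------------------
# Division and death records
# ---------------------------------------------------------------------------

def classify_divisions(
    lineage: EmbryoLineage, identities: dict[int, str]
) -> list[DivisionRecord]:
    """One record per division; asymmetric iff the daughters' track
    identities differ.  Division time is the frame at which the daughters
    first appear."""
    records = []
    for track in sorted(lineage.tracks.values(), key=lambda t: t.track_id):
        if track.fate != FATE_DIVIDES or track.track_id not in identities:
            continue
        d1, d2 = track.daughter_track_ids
        if d1 not in identities or d2 not in identities:
            continue
        ids = (identities[d1], identities[d2])
        first_daughter_node = lineage.tracks[d1].first_node
        time_hp = float(lineage.nodes.at[first_daughter_node, "time_hp"])
        records.append(DivisionRecord(
            mother_track_id=track.track_id,
            time_hp=time_hp,
            mother_identity=identities[track.track_id],
            daughter_identities=ids,
            daughter_track_ids=(d1, d2),
            division_type="asymmetric" if ids[0] != ids[1] else "symmetric",
        ))
    return records


def collect_deaths(
    lineage: EmbryoLineage, identities: dict[int, str]
) -> list[DeathRecord]:
    """One record per dying track, inheriting the track's identity."""
    records = []
    for track in sorted(lineage.tracks.values(), key=lambda t: t.track_id):
        if track.fate != FATE_DIES or track.track_id not in identities:
            continue
        records.append(DeathRecord(
            track_id=track.track_id,
            time_hp=float(lineage.nodes.at[track.last_node, "time_hp"]),
            identity=identities[track.track_id],
        ))
    return records


def annotate_lineage(
    lineage: EmbryoLineage,
    shell_tolerance: float = DEFAULT_SHELL_TOLERANCE,
    leaf_identities: dict[int, str] | None = None,
    prefer_file_identities: bool = True,
) -> AnnotatedLineage:
    """Full annotation pass: leaf identities, backward propagation, records.

    Leaf identities come, in order of precedence, from ``leaf_identities``
    (e.g. a simulator's ground truth), from the file's ``identity`` column on
    the leaf's last node (curation), or from geometric classification of the
    leaf's last observed frame.
    """
    classifier = _FrameClassifier(lineage, shell_tolerance)
    leaves: dict[int, str] = {}
    for track in lineage.validated_tracks:
        if track.fate == FATE_DIVIDES:
            continue
        tid = track.track_id
        if leaf_identities and tid in leaf_identities:
            leaves[tid] = leaf_identities[tid]
            continue
        file_identity = str(lineage.nodes.at[track.last_node, "identity"])
        if prefer_file_identities and file_identity in (IDENTITY_INNER, IDENTITY_OUTER):
            leaves[tid] = file_identity
        else:
            leaves[tid] = classifier.identity_at(track.last_node, track.last_timestep)

    identities = propagate_identities_backward(
        lineage, leaves, shell_tolerance, classifier.identity_at)
    return AnnotatedLineage(
        lineage=lineage,
        identities=identities,
        divisions=classify_divisions(lineage, identities),
        deaths=collect_deaths(lineage, identities),
    )
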