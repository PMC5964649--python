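"""In silico transformation of asymmetric divisions into symmetric divisions.

The experiment asks how much of the inner-cell-population robustness is owed
to asymmetric divisions.  Keeping the tree topology, timestamps and
positions fixed, identities are replayed root-to-leaf from a *division
program* (per division: symmetric/asymmetric and which daughter is the
off-type one).  A transformation then forces divisions of a target mother
type (inner or outer) to be symmetric — daughters inherit the mother's
identity — and population statistics are recomputed on the counterfactual
identities.

By default the target-type test uses the mother's identity under the
*transformed* replay (recursive): this is the only reading after which no
target-type asymmetric division remains, and under ``target="outer"`` every
inner cell descends from an inner root.  A sensitivity mode evaluates the
selection on the original annotation instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import StatisticsError
from .identity import AnnotatedLineage
from .lineage_io import FATE_DIVIDES, IDENTITY_INNER, IDENTITY_OUTER, EmbryoLineage
from .stats import coefficient_of_variation, counts_by_type, counts_on_grid
from .timescale import TimeScale

__all__ = [
    "DivisionProgram",
    "ConditionResult",
    "extract_program",
    "forward_identity_replay",
    "transform_asymmetric_to_symmetric",
    "condition_comparison",
    "CONDITION_OBSERVED",
    "CONDITION_OUTER_SYM",
    "CONDITION_INNER_SYM",
]

CONDITION_OBSERVED = "observed"
CONDITION_OUTER_SYM = "outer_symmetrized"
CONDITION_INNER_SYM = "inner_symmetrized"

_OPPOSITE = {IDENTITY_INNER: IDENTITY_OUTER, IDENTITY_OUTER: IDENTITY_INNER}


@dataclass
class DivisionProgram:
    """Forward description of a lineage's identity dynamics.

    ``asymmetric`` maps a dividing mother track to the off-type daughter
    track id, or to ``None`` for a symmetric division.  ``root_identities``
    fixes the identities at the window onset.  Replaying the program on the
    untransformed lineage reproduces the annotated identities exactly.
    """

    root_identities: dict[int, str]
    asymmetric: dict[int, int | None] = field(default_factory=dict)

    def covers(self, lineage: EmbryoLineage) -> bool:
        return all(t.track_id in self.asymmetric
                   for t in lineage.tracks.values() if t.fate == FATE_DIVIDES)


@dataclass
class ConditionResult:
    """Identities recomputed under one experimental condition.

    Topology, timestamps and positions are those of the untouched lineage;
    only the per-track identity differs between conditions.
    """

    condition: str
    annotated: AnnotatedLineage

    @property
    def identities(self) -> dict[int, str]:
        return self.annotated.identities


def extract_program(annotated: AnnotatedLineage) -> DivisionProgram:
    """Division program implied by an annotated lineage."""
    roots = {
        t.track_id: annotated.identities[t.track_id]
        for t in annotated.lineage.root_tracks()
        if t.track_id in annotated.identities
    }
    asym: dict[int, int | None] = {}
    for div in annotated.divisions:
        if not div.is_asymmetric:
            asym[div.mother_track_id] = None
        else:
            d1, d2 = div.daughter_track_ids
            off = d1 if annotated.identities[d1] != div.mother_identity else d2
            asym[div.mother_track_id] = off
    return DivisionProgram(root_identities=roots, asymmetric=asym)


def forward_identity_replay(
    lineage: EmbryoLineage,
    program: DivisionProgram,
    symmetrize_type: str | None = None,
    selection_identities: dict[int, str] | None = None,
) -> dict[int, str]:
    """Replay identities root-to-leaf under a division program.

    Roots keep their program identities.  At each division the daughters
    inherit the mother's current identity, except at a division flagged
    asymmetric, where the designated off-type daughter takes the opposite
    identity.  When ``symmetrize_type`` is given, an asymmetric division is
    treated as symmetric whenever the mother's identity equals that type —
    the mother identity being taken from the running (recursive) replay, or
    from ``selection_identities`` when provided (sensitivity mode).
    """
    identities: dict[int, str] = {}
    queue: list[int] = []
    for tid, ident in program.root_identities.items():
        identities[tid] = ident
        queue.append(tid)
    while queue:
        tid = queue.pop()
        track = lineage.tracks[tid]
        if track.fate != FATE_DIVIDES:
            continue
        if tid not in program.asymmetric:
            raise StatisticsError(f"division program does not cover track {tid}")
        mother_ident = identities[tid]
        off = program.asymmetric[tid]
        if off is not None and symmetrize_type is not None:
            selector = (selection_identities[tid] if selection_identities
                        else mother_ident)
            if selector == symmetrize_type:
                off = None
        for d in track.daughter_track_ids:
            if d == off:
                identities[d] = _OPPOSITE[mother_ident]
            else:
                identities[d] = mother_ident
            queue.append(d)
    return identities


def transform_asymmetric_to_symmetric(
    annotated: AnnotatedLineage,
    target_type: str,
    program: DivisionProgram | None = None,
    recursive_selection: bool = True,
) -> ConditionResult:
    """Turn asymmetric divisions of ``target_type`` mothers into symmetric
    ones and recompute all identities.

    Only identities change; the returned condition shares the lineage object
    (topology, positions, times) with the input.
    """
    if target_type not in (IDENTITY_INNER, IDENTITY_OUTER):
        raise ValueError(f"target_type must be inner or outer, got {target_type!r}")
    if program is None:
        program = extract_program(annotated)
    identities = forward_identity_replay(
        annotated.lineage, program,
        symmetrize_type=target_type,
        selection_identities=None if recursive_selection else annotated.identities,
    )
    name = CONDITION_OUTER_SYM if target_type == IDENTITY_OUTER else CONDITION_INNER_SYM
    return ConditionResult(condition=name, annotated=annotated.with_identities(identities))


def run_conditions(
    annotated: AnnotatedLineage,
    conditions: list[str] | None = None,
) -> dict[str, ConditionResult]:
    """Observed plus requested counterfactual conditions for one embryo."""
    if conditions is None:
        conditions = [CONDITION_OBSERVED, CONDITION_OUTER_SYM, CONDITION_INNER_SYM]
    program = extract_program(annotated)
    out: dict[str, ConditionResult] = {}
    for cond in conditions:
        if cond == CONDITION_OBSERVED:
            out[cond] = ConditionResult(cond, annotated)
        elif cond == CONDITION_OUTER_SYM:
            out[cond] = transform_asymmetric_to_symmetric(
                annotated, IDENTITY_OUTER, program)
        elif cond == CONDITION_INNER_SYM:
            out[cond] = transform_asymmetric_to_symmetric(
                annotated, IDENTITY_INNER, program)
        else:
            raise ValueError(f"unknown condition {cond!r}")
    return out


def condition_comparison(
    cohort: list[tuple[AnnotatedLineage, TimeScale]],
    grid_na: np.ndarray,
    conditions: list[str] | None = None,
) -> pd.DataFrame:
    """Cross-embryo variability of inner and outer counts per condition.

    For each condition, per-embryo counts are recomputed on the transformed
    identities, evaluated on the common n.a. grid, and summarized as a
    coefficient of variation across embryos.  Returns a tidy frame with
    columns ``condition, na, cell_type, mean_count, cv``.
    """
    if conditions is None:
        conditions = [CONDITION_OBSERVED, CONDITION_OUTER_SYM, CONDITION_INNER_SYM]
    rows = []
    for cond in conditions:
        per_embryo = {IDENTITY_INNER: [], IDENTITY_OUTER: []}
        for annotated, ts in cohort:
            result = run_conditions(annotated, [cond])[cond]
            counts = counts_by_type(result.annotated, ts)
            on_grid = counts_on_grid(counts, grid_na)
            per_embryo[IDENTITY_INNER].append(on_grid["n_inner"].to_numpy(float))
            per_embryo[IDENTITY_OUTER].append(on_grid["n_outer"].to_numpy(float))
        for cell_type, series in per_embryo.items():
            mat = np.vstack(series)
            cv = coefficient_of_variation(mat)
            mean = mat.mean(axis=0)
            for i, na in enumerate(np.asarray(grid_na, dtype=float)):
                rows.append({
                    "condition": cond,
                    "na": na,
                    "cell_type": cell_type,
                    "mean_count": mean[i],
                    "cv": cv[i],
                })
    return pd.DataFrame(rows)
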