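"""Population statistics of annotated embryo lineages.

All statistics operate on validated tracks only and, where time enters, on
normalized age (n.a.).  Group-level statistics average per-embryo values
(unweighted) and report both the sample standard deviation and the standard
error of the mean.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import StatisticsError
from .identity import AnnotatedLineage, DivisionRecord
from .lineage_io import FATE_DIES, FATE_DIVIDES, IDENTITY_INNER, IDENTITY_OUTER
from .timescale import TimeScale

__all__ = [
    "GroupStat",
    "BinnedSeries",
    "FounderSummary",
    "attach_normalized_age",
    "counts_by_type",
    "counts_on_grid",
    "proportion_inner",
    "asymmetric_division_proportion",
    "normalized_death_ratio",
    "group_normalized_death_ratio",
    "coefficient_of_variation",
    "neighborhood_composition",
    "founder_clone_summary",
    "relative_developmental_speed",
    "make_bins",
]

DEFAULT_BIN_WIDTH = 0.05  # n.a. (~4.3 h for an 86 h collapse time)
DEFAULT_K_NEIGHBORS = 8


@dataclass
class GroupStat:
    """Per-embryo values with group mean and dispersion.

    Both the sample standard deviation and the standard error are reported;
    dispersion is undefined (NaN) for a single embryo.
    """

    values: list[float]
    labels: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if self.values else float("nan")

    @property
    def sd(self) -> float:
        if self.n < 2:
            return float("nan")
        return float(np.std(self.values, ddof=1))

    @property
    def se(self) -> float:
        return self.sd / np.sqrt(self.n) if self.n >= 2 else float("nan")


@dataclass
class BinnedSeries:
    """A proportion per n.a. bin with its event counts.

    Bins are half-open ``[lo, hi)``; a bin with an empty denominator is
    flagged (proportion NaN), never zero-filled.
    """

    bin_edges: np.ndarray
    numerator: np.ndarray
    denominator: np.ndarray

    @property
    def proportion(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.numerator / self.denominator.astype(float)
        out[self.denominator == 0] = np.nan
        return out

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_lo_na": self.bin_edges[:-1],
            "bin_hi_na": self.bin_edges[1:],
            "n_events": self.numerator,
            "n_total": self.denominator,
            "proportion": self.proportion,
        })


@dataclass
class FounderSummary:
    """A founder cell (present at the window onset) and its clone's outcome.

    For a binary tree rooted at the founder, the number of mitoses satisfies
    ``n_mitoses = n_final + n_dead - 1``.
    """

    founder_track_id: int
    founder_identity: str
    n_mitoses: int
    n_final_inner: int
    n_final_outer: int
    n_dead: int

    @property
    def n_final(self) -> int:
        return self.n_final_inner + self.n_final_outer


# ---------------------------------------------------------------------------
# Time attachment
# ---------------------------------------------------------------------------

def attach_normalized_age(annotated: AnnotatedLineage, timescale: TimeScale) -> AnnotatedLineage:
    """Return a copy whose division and death records carry ``time_na``."""
    divisions = [dataclasses.replace(d, time_na=timescale.to_na(d.time_hp))
                 for d in annotated.divisions]
    deaths = [dataclasses.replace(d, time_na=timescale.to_na(d.time_hp))
              for d in annotated.deaths]
    return AnnotatedLineage(annotated.lineage, annotated.identities, divisions, deaths)


# ---------------------------------------------------------------------------
# Counts and proportions
# ---------------------------------------------------------------------------

def counts_by_type(
    annotated: AnnotatedLineage,
    timescale: TimeScale | None = None,
) -> pd.DataFrame:
    """Validated-cell counts by identity, per timestep.

    Returns a frame with columns ``timestep, time_hp, n_inner, n_outer,
    n_total`` (plus ``na`` when a timescale is given); at every timestep
    ``n_inner + n_outer = n_total``.
    """
    lineage = annotated.lineage
    nodes = lineage.nodes
    validated = nodes["validated"].to_numpy(bool)
    track_of = lineage.node_track
    identity = np.array([
        annotated.identities.get(track_of[int(nid)], "")
        for nid in nodes.index
    ])
    keep = validated & np.isin(identity, [IDENTITY_INNER, IDENTITY_OUTER])
    df = pd.DataFrame({
        "timestep": nodes["timestep"].to_numpy()[keep],
        "time_hp": nodes["time_hp"].to_numpy()[keep],
        "inner": identity[keep] == IDENTITY_INNER,
    })
    grouped = df.groupby("timestep").agg(
        time_hp=("time_hp", "first"),
        n_inner=("inner", "sum"),
        n_total=("inner", "size"),
    ).reset_index()
    grouped["n_outer"] = grouped["n_total"] - grouped["n_inner"]
    grouped = grouped[["timestep", "time_hp", "n_inner", "n_outer", "n_total"]]
    if timescale is not None:
        grouped["na"] = timescale.to_na(grouped["time_hp"].to_numpy())
    return grouped


def counts_on_grid(counts: pd.DataFrame, grid_na: np.ndarray) -> pd.DataFrame:
    """Evaluate the per-timestep count step functions on an n.a. grid.

    Counts are piecewise constant between frames; each grid point takes the
    counts of the latest frame at or before it.  The grid must lie within
    the observed n.a. range.
    """
    if "na" not in counts.columns:
        raise ValueError("counts frame lacks an 'na' column; pass a timescale")
    na = counts["na"].to_numpy(float)
    grid = np.asarray(grid_na, dtype=float)
    if np.any(grid < na[0] - 1e-9) or np.any(grid > na[-1] + 1e-9):
        raise ValueError("grid outside the embryo's observed window")
    idx = np.clip(np.searchsorted(na, grid + 1e-12) - 1, 0, len(na) - 1)
    return pd.DataFrame({
        "na": grid,
        "n_inner": counts["n_inner"].to_numpy()[idx],
        "n_outer": counts["n_outer"].to_numpy()[idx],
        "n_total": counts["n_total"].to_numpy()[idx],
    })


def proportion_inner(counts: pd.DataFrame) -> np.ndarray:
    """PIC = inner / (inner + outer) per row; NaN-flagged where total is 0."""
    total = counts["n_total"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pic = counts["n_inner"].to_numpy(float) / total
    pic[total == 0] = np.nan
    return pic


def group_mean_series(per_embryo: list[np.ndarray]) -> GroupStat | pd.DataFrame:
    """Unweighted mean (and dispersion) of per-embryo series on a common grid."""
    arr = np.vstack(per_embryo)
    return pd.DataFrame({
        "mean": np.nanmean(arr, axis=0),
        "sd": np.nanstd(arr, axis=0, ddof=1) if len(arr) > 1 else np.nan,
        "se": (np.nanstd(arr, axis=0, ddof=1) / np.sqrt(len(arr))
               if len(arr) > 1 else np.nan),
    })


# ---------------------------------------------------------------------------
# Asymmetric-division proportions (OAD / IAD)
# ---------------------------------------------------------------------------

def make_bins(lo_na: float, hi_na: float, width: float = DEFAULT_BIN_WIDTH) -> np.ndarray:
    """Half-open bins of the given width starting at the window lower bound.

    The last bin is extended to cover ``hi_na`` when the window length is not
    an exact multiple of the width.
    """
    n = int(np.ceil((hi_na - lo_na) / width - 1e-9))
    return lo_na + width * np.arange(max(n, 1) + 1)


def asymmetric_division_proportion(
    divisions: list[DivisionRecord],
    mother_type: str,
    bin_edges: np.ndarray,
) -> BinnedSeries:
    """Per-bin proportion of asymmetric divisions among divisions whose
    mother has the given identity (OAD for outer mothers, IAD for inner).

    Divisions must carry ``time_na``; a division exactly on a bin edge
    belongs to the right bin.  Divisions outside the binned range are
    ignored.
    """
    edges = np.asarray(bin_edges, dtype=float)
    n_bins = len(edges) - 1
    num = np.zeros(n_bins, dtype=int)
    den = np.zeros(n_bins, dtype=int)
    for d in divisions:
        if d.mother_identity != mother_type:
            continue
        if d.time_na is None:
            raise StatisticsError("division lacks time_na; attach a timescale")
        b = int(np.searchsorted(edges, d.time_na, side="right")) - 1
        if b < 0 or b >= n_bins:
            continue
        den[b] += 1
        if d.is_asymmetric:
            num[b] += 1
    return BinnedSeries(bin_edges=edges, numerator=num, denominator=den)


# ---------------------------------------------------------------------------
# Normalized death ratio
# ---------------------------------------------------------------------------

def _tracks_alive_in_window(
    annotated: AnnotatedLineage, timescale: TimeScale, lo_na: float, hi_na: float
) -> list[int]:
    lineage = annotated.lineage
    out = []
    for track in lineage.validated_tracks:
        tid = track.track_id
        if tid not in annotated.identities:
            continue
        t0 = timescale.to_na(float(lineage.nodes.at[track.first_node, "time_hp"]))
        t1 = timescale.to_na(float(lineage.nodes.at[track.last_node, "time_hp"]))
        if t0 <= hi_na and t1 >= lo_na:
            out.append(tid)
    return out


def normalized_death_ratio(
    annotated: AnnotatedLineage,
    timescale: TimeScale,
    identity: str,
    window: tuple[float, float],
) -> dict:
    """Death enrichment of one cell type in one embryo.

    r_T = (D_T / D) / (N_T / N), where D_T counts deaths of identity T within
    the n.a. window, D all deaths in the window, N_T distinct validated
    tracks of identity T alive at any point in the window, and N all such
    tracks.  r_T = 1 when death is independent of cell type.

    Raises :class:`StatisticsError` when the embryo has no deaths in the
    window (the caller excludes it with a warning).
    """
    lo, hi = window
    deaths = [d for d in annotated.deaths
              if d.time_na is not None and lo <= d.time_na <= hi]
    if not deaths:
        deaths = [dataclasses.replace(d, time_na=timescale.to_na(d.time_hp))
                  for d in annotated.deaths]
        deaths = [d for d in deaths if lo <= d.time_na <= hi]
    n_deaths = len(deaths)
    if n_deaths == 0:
        raise StatisticsError("no deaths in window; embryo excluded")
    n_deaths_t = sum(1 for d in deaths if d.identity == identity)
    alive = _tracks_alive_in_window(annotated, timescale, lo, hi)
    n_tracks = len(alive)
    n_tracks_t = sum(1 for tid in alive if annotated.identities[tid] == identity)
    if n_tracks == 0 or n_tracks_t == 0:
        raise StatisticsError(f"no {identity} tracks alive in window")
    value = (n_deaths_t / n_deaths) / (n_tracks_t / n_tracks)
    return {
        "value": value,
        "n_deaths_type": n_deaths_t,
        "n_deaths": n_deaths,
        "n_tracks_type": n_tracks_t,
        "n_tracks": n_tracks,
    }


def group_normalized_death_ratio(
    cohort: list[tuple[AnnotatedLineage, TimeScale]],
    identity: str,
    window: tuple[float, float],
) -> tuple[GroupStat, list[str]]:
    """Group mean/dispersion of the per-embryo normalized death ratio.

    Embryos without deaths in the window are excluded; their labels are
    returned as warnings.
    """
    values, labels, excluded = [], [], []
    for annotated, ts in cohort:
        embryo_id = annotated.lineage.metadata.embryo_id
        try:
            res = normalized_death_ratio(annotated, ts, identity, window)
        except StatisticsError as exc:
            excluded.append(f"{embryo_id}: {exc}")
            continue
        values.append(res["value"])
        labels.append(embryo_id)
    return GroupStat(values=values, labels=labels), excluded


# ---------------------------------------------------------------------------
# Variability
# ---------------------------------------------------------------------------

def coefficient_of_variation(count_matrix: np.ndarray) -> np.ndarray:
    """CV across embryos per grid point: sample s.d. (n-1) over mean.

    ``count_matrix`` is (n_embryos, n_grid); requires >= 2 embryos.  Grid
    points with zero mean are flagged NaN.
    """
    arr = np.asarray(count_matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise StatisticsError("coefficient of variation needs >=2 embryos")
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = sd / mean
    cv[mean == 0] = np.nan
    return cv


# ---------------------------------------------------------------------------
# Neighborhood composition around dividing cells
# ---------------------------------------------------------------------------

def neighborhood_composition(
    annotated: AnnotatedLineage,
    k: int = DEFAULT_K_NEIGHBORS,
) -> pd.DataFrame:
    """Fraction of other-type cells among the k nearest neighbors of each
    dividing mother, measured at the mother's last timestep (the frame
    immediately before the daughters appear).

    Returns one row per division with columns ``mother_track_id,
    division_type, mother_identity, frac_other_type, n_neighbors, flagged``
    (flagged when fewer than k neighbors were available).
    """
    lineage = annotated.lineage
    rows = []
    frames: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for div in annotated.divisions:
        mother = lineage.tracks[div.mother_track_id]
        step = mother.last_timestep
        if step not in frames:
            ids, pts = lineage.frame_positions(step)
            idents = np.array([
                annotated.identities.get(lineage.node_track[int(i)], "")
                for i in ids])
            frames[step] = (ids, pts, idents)
        ids, pts, idents = frames[step]
        self_mask = ids == mother.last_node
        others = ~self_mask
        n_avail = int(others.sum())
        if n_avail == 0:
            continue
        kk = min(k, n_avail)
        mother_pos = pts[self_mask][0]
        dist = np.linalg.norm(pts[others] - mother_pos, axis=1)
        order = np.argsort(dist, kind="stable")[:kk]
        neighbor_idents = idents[others][order]
        frac = float(np.mean(neighbor_idents != div.mother_identity))
        rows.append({
            "mother_track_id": div.mother_track_id,
            "division_type": div.division_type,
            "mother_identity": div.mother_identity,
            "frac_other_type": frac,
            "n_neighbors": kk,
            "flagged": kk < k,
        })
    return pd.DataFrame(rows, columns=[
        "mother_track_id", "division_type", "mother_identity",
        "frac_other_type", "n_neighbors", "flagged"])


# ---------------------------------------------------------------------------
# Founder clones
# ---------------------------------------------------------------------------

def founder_clone_summary(annotated: AnnotatedLineage) -> list[FounderSummary]:
    """One summary per validated cell present at the first validated
    timestep: mitoses in its subtree and the final composition of its clone
    (censored leaves by identity, plus deaths)."""
    lineage = annotated.lineage
    steps = lineage.timesteps
    if len(steps) == 0:
        return []
    first_step = int(steps[0])
    founders = [
        t for t in lineage.validated_tracks
        if t.birth_timestep <= first_step <= t.last_timestep
        and t.track_id in annotated.identities
    ]
    summaries = []
    for founder in sorted(founders, key=lambda t: t.track_id):
        n_mit = n_dead = n_inner = n_outer = 0
        stack = [founder.track_id]
        while stack:
            tid = stack.pop()
            track = lineage.tracks[tid]
            if track.fate == FATE_DIVIDES:
                n_mit += 1
                stack.extend(track.daughter_track_ids)
            elif track.fate == FATE_DIES:
                n_dead += 1
            else:
                ident = annotated.identities.get(tid)
                if ident == IDENTITY_INNER:
                    n_inner += 1
                elif ident == IDENTITY_OUTER:
                    n_outer += 1
        summaries.append(FounderSummary(
            founder_track_id=founder.track_id,
            founder_identity=annotated.identities[founder.track_id],
            n_mitoses=n_mit,
            n_final_inner=n_inner,
            n_final_outer=n_outer,
            n_dead=n_dead,
        ))
    return summaries


# ---------------------------------------------------------------------------
# Developmental speed
# ---------------------------------------------------------------------------

def relative_developmental_speed(
    clone_t_collapse_hp: float,
    wild_type_t_collapse_hp: list[float],
) -> float:
    """Percent slowdown of a clone relative to the wild-type mean:
    100 * (t_collapse(clone) / mean(t_collapse(wt)) - 1)."""
    if not wild_type_t_collapse_hp:
        raise StatisticsError("empty wild-type reference set")
    ref = float(np.mean(wild_type_t_collapse_hp))
    return 100.0 * (clone_t_collapse_hp / ref - 1.0)
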