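"""Stochastic generator of synthetic pre-implantation embryo lineages.

The generator emulates the structure of curated 3D+time lineage data from
rabbit pre-implantation embryos observed from the ~32-cell stage to
hatching: two compartments (outer/trophectoderm on the embryo surface,
inner cells in the interior), cell-cycle-timed divisions with time-varying
asymmetric-division probabilities, type-biased exponential death hazards,
and an embryo radius trajectory with a scripted blastocoel collapse.  It
emits a lineage in the tabular dialect of :mod:`blastotrack.lineage_io`
together with a ground-truth sidecar (per-track identity, per-division type
and off-type daughter, deaths), so every pipeline stage can be checked
against the simulated truth.

Positions are phenomenological: outer cells sit on a sphere of radius
``R(t)`` (linear growth, multiplicative drop at the collapse time), inner
cells at a fractional radius, both with Gaussian jitter.  There is no
mechanics and no cell-cell exclusion beyond jitter; the geometry is
sufficient for convex-hull, shell-classification and nearest-neighbor
operations, not for morphology.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lineage_io import (
    IDENTITY_INNER,
    IDENTITY_OUTER,
    EmbryoLineage,
    LineageMetadata,
    lineage_from_records,
)

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "generate_embryo",
    "generate_cohort",
    "wt_like_params",
    "clone_like_params",
    "embryo_seed",
]


@dataclass
class SimulationParams:
    """Full parameterization of one synthetic embryo.

    Times are hours post fertilization/activation; lengths are µm.  The
    asymmetric-division probability of outer mothers follows a Gaussian bump
    in normalized age (the wave of asymmetric divisions around the 32- to
    64-cell stage); inner mothers use one of three modes: ``constant``,
    ``late_step`` (zero before ``p_asym_inner_step_na``, emulating the
    delayed and scarce inner asymmetric divisions seen in clones), or
    ``feedback`` (probability rises when the proportion of inner cells
    exceeds its target, a testable version of the regulation hypothesis).
    ``collapse_volume_drop`` is the fractional hull-volume drop scripted at
    ``t_collapse_h`` (radius is multiplied by its cube root).
    """

    # cohort bookkeeping
    embryo_id: str = "sim"
    group: str = "wild_type"
    time_origin: str = "fertilization"

    # observation window; inner founder counts vary strongly between real
    # embryos, so the realized count is Poisson(n_initial_inner) clamped >= 1
    # unless vary_inner_founders is off
    n_initial_outer: int = 23
    n_initial_inner: int = 9
    vary_inner_founders: bool = True
    t_start_h: float = 61.5
    t_end_h: float = 86.0
    frame_interval_min: float = 15.0

    # cell cycle (log-normal)
    cycle_mean_h: float = 13.0
    cycle_cv: float = 0.2

    # asymmetric-division probabilities
    p_asym_outer_peak: float = 0.25
    p_asym_outer_center_na: float = 0.85
    p_asym_outer_sigma_na: float = 0.10
    p_asym_inner_mode: str = "constant"  # constant | late_step | feedback
    p_asym_inner: float = 0.05
    p_asym_inner_step_na: float = 0.95
    feedback_target_pic: float = 0.25
    feedback_base: float = 0.30
    feedback_gain: float = 3.0
    feedback_max: float = 0.80

    # death hazards (per cell-hour); h_inner = death_bias_beta * h_outer
    h_outer_per_h: float = 0.0015
    death_bias_beta: float = 1.0

    # geometry
    initial_radius_um: float = 55.0
    growth_um_per_h: float = 0.4
    inner_radius_frac: float = 0.5
    jitter_um: float = 1.0
    direction_dispersion: float = 0.15

    # scripted blastocoel collapse
    t_collapse_h: float = 80.0
    collapse_volume_drop: float = 0.15

    def __post_init__(self) -> None:
        if not 0 <= self.p_asym_outer_peak <= 1 or not 0 <= self.p_asym_inner <= 1:
            raise ValueError("asymmetry probabilities must lie in [0, 1]")
        if self.h_outer_per_h < 0 or self.death_bias_beta < 0:
            raise ValueError("death hazards must be non-negative")
        if not 0 <= self.collapse_volume_drop < 1:
            raise ValueError("collapse_volume_drop must lie in [0, 1)")
        if self.t_end_h <= self.t_start_h:
            raise ValueError("empty observation window")

    @property
    def frame_interval_h(self) -> float:
        return self.frame_interval_min / 60.0

    @property
    def h_inner_per_h(self) -> float:
        return self.death_bias_beta * self.h_outer_per_h

    @property
    def n_frames(self) -> int:
        return int(np.floor((self.t_end_h - self.t_start_h) / self.frame_interval_h + 1e-9)) + 1

    @property
    def collapse_frame(self) -> int:
        """First frame at or after the scripted collapse time."""
        return int(np.ceil((self.t_collapse_h - self.t_start_h) / self.frame_interval_h - 1e-9))

    def radius_at(self, t_h: float) -> float:
        r = self.initial_radius_um + self.growth_um_per_h * (t_h - self.t_start_h)
        frame = round((t_h - self.t_start_h) / self.frame_interval_h)
        if frame >= self.collapse_frame:
            r *= (1.0 - self.collapse_volume_drop) ** (1.0 / 3.0)
        return r

    def p_asym(self, identity: str, t_h: float, current_pic: float) -> float:
        na = t_h / self.t_collapse_h
        if identity == IDENTITY_OUTER:
            z = (na - self.p_asym_outer_center_na) / self.p_asym_outer_sigma_na
            return self.p_asym_outer_peak * float(np.exp(-0.5 * z * z))
        if self.p_asym_inner_mode == "constant":
            return self.p_asym_inner
        if self.p_asym_inner_mode == "late_step":
            return self.p_asym_inner if na >= self.p_asym_inner_step_na else 0.0
        if self.p_asym_inner_mode == "feedback":
            p = self.feedback_base + self.feedback_gain * (current_pic - self.feedback_target_pic)
            return float(np.clip(p, 0.0, self.feedback_max))
        raise ValueError(f"unknown inner asymmetry mode {self.p_asym_inner_mode!r}")

    def metadata(self) -> LineageMetadata:
        return LineageMetadata(
            embryo_id=self.embryo_id,
            group=self.group,
            time_origin=self.time_origin,
            fertilization_offset_h=8.0 if self.time_origin == "fertilization" else 0.0,
            frame_interval_min=self.frame_interval_min,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def wt_like_params(**overrides) -> SimulationParams:
    """Wild-type-like preset: 23 outer + 9 inner founders, unbiased death."""
    return SimulationParams(group="wild_type", time_origin="fertilization",
                            **overrides)


def clone_like_params(**overrides) -> SimulationParams:
    """Clone-like preset: few inner founders, inner-biased death, slower
    development, and late/scarce inner asymmetric divisions."""
    defaults = dict(
        group="clone",
        time_origin="activation",
        n_initial_outer=23,
        n_initial_inner=3,
        t_start_h=72.0,
        t_end_h=101.0,
        t_collapse_h=94.0,
        h_outer_per_h=0.002,
        death_bias_beta=4.0,
        p_asym_inner_mode="late_step",
        p_asym_inner=0.08,
        p_asym_inner_step_na=0.95,
    )
    defaults.update(overrides)
    return SimulationParams(**defaults)


@dataclass
class GroundTruth:
    """Generator-side record of what the pipeline should recover."""

    identities: dict[int, str]
    divisions: list[dict] = field(default_factory=list)
    deaths: list[dict] = field(default_factory=list)
    extinct: bool = False

    def division_types(self) -> dict[int, str]:
        return {d["mother_track_id"]: d["division_type"] for d in self.divisions}

    def offtype_daughters(self) -> dict[int, int | None]:
        return {d["mother_track_id"]: d["offtype_daughter_track_id"]
                for d in self.divisions}

    def to_frame(self) -> pd.DataFrame:
        div = self.division_types()
        off = self.offtype_daughters()
        rows = [{
            "track_id": tid,
            "identity": ident,
            "division_type": div.get(tid, ""),
            "offtype_daughter": ("" if off.get(tid) is None else off.get(tid)),
        } for tid, ident in sorted(self.identities.items())]
        return pd.DataFrame(rows, columns=[
            "track_id", "identity", "division_type", "offtype_daughter"])


# ---------------------------------------------------------------------------
# Simulation internals
# ---------------------------------------------------------------------------

@dataclass
class _Cell:
    identity: str
    birth_time_h: float
    cycle_h: float
    direction: np.ndarray
    radial_frac: float
    first_node_id: int | None = None
    prev_node_id: int | None = None
    node_count: int = 0


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n roughly evenly spaced unit vectors (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _draw_cycle(rng: np.random.Generator, params: SimulationParams) -> float:
    cv = max(params.cycle_cv, 1e-6)
    sigma = float(np.sqrt(np.log(1 + cv * cv)))
    mu = float(np.log(params.cycle_mean_h)) - 0.5 * sigma * sigma
    return float(rng.lognormal(mean=mu, sigma=sigma))


def _daughter_direction(rng: np.random.Generator, mother_dir: np.ndarray,
                        dispersion: float) -> np.ndarray:
    d = mother_dir + dispersion * rng.normal(size=3)
    return d / np.linalg.norm(d)


def generate_embryo(
    params: SimulationParams, seed: int
) -> tuple[EmbryoLineage, GroundTruth]:
    """Simulate one embryo at frame resolution.

    The clock advances in frames of ``frame_interval_min``; deaths and
    divisions are binned to frames.  Reproducible: identical ``(params,
    seed)`` yield identical output.  Total extinction is flagged on the
    ground truth; the (truncated) lineage is still emitted.
    """
    rng = np.random.default_rng(seed)
    dt = params.frame_interval_h

    # founders: outer on a jittered golden-spiral lattice (even epithelial
    # spacing keeps the hull volume stable), inner on random interior sites
    rot = _random_rotation(rng)
    outer_dirs = _fibonacci_sphere(params.n_initial_outer) @ rot.T
    cells: list[_Cell] = []
    for i in range(params.n_initial_outer):
        d = _daughter_direction(rng, outer_dirs[i], 0.05)
        cells.append(_Cell(IDENTITY_OUTER, params.t_start_h, 0.0, d, 1.0))
    n_inner = params.n_initial_inner
    if params.vary_inner_founders:
        n_inner = max(1, int(rng.poisson(params.n_initial_inner)))
    for _ in range(n_inner):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        cells.append(_Cell(IDENTITY_INNER, params.t_start_h, 0.0, d,
                           params.inner_radius_frac))
    # desynchronized founders: age at window start is uniform over the cycle
    for c in cells:
        c.cycle_h = _draw_cycle(rng, params)
        c.birth_time_h = params.t_start_h - rng.uniform(0, c.cycle_h)

    rows: list[dict] = []
    sim_divisions: list[dict] = []  # keyed by mother first_node_id
    sim_deaths: list[dict] = []
    sim_cells: list[_Cell] = list(cells)  # every cell ever alive
    next_node_id = 0

    p_death = {
        IDENTITY_OUTER: 1.0 - np.exp(-params.h_outer_per_h * dt),
        IDENTITY_INNER: 1.0 - np.exp(-params.h_inner_per_h * dt),
    }

    for frame in range(params.n_frames):
        t = params.t_start_h + frame * dt
        dying: list[_Cell] = []
        if frame > 0 and cells:
            # deaths (exponential hazard, binned to the frame)
            survivors: list[_Cell] = []
            for c in cells:
                if rng.random() < p_death[c.identity]:
                    dying.append(c)
                else:
                    survivors.append(c)
            # divisions between frame-1 and frame
            n_inner = sum(1 for c in survivors if c.identity == IDENTITY_INNER)
            pic = n_inner / len(survivors) if survivors else 0.0
            cells = []
            for c in survivors:
                if t - c.birth_time_h < c.cycle_h:
                    cells.append(c)
                    continue
                p = params.p_asym(c.identity, t, pic)
                asym = rng.random() < p
                daughters = []
                for j in range(2):
                    ident = c.identity
                    frac = c.radial_frac
                    if asym and j == 1:
                        ident = (IDENTITY_INNER if c.identity == IDENTITY_OUTER
                                 else IDENTITY_OUTER)
                        frac = (params.inner_radius_frac
                                if ident == IDENTITY_INNER else 1.0)
                    elif ident == IDENTITY_OUTER:
                        frac = 1.0
                    d = _Cell(
                        identity=ident,
                        birth_time_h=t,
                        cycle_h=_draw_cycle(rng, params),
                        direction=_daughter_direction(
                            rng, c.direction, params.direction_dispersion),
                        radial_frac=frac,
                        prev_node_id=c.prev_node_id,  # link to mother's last node
                    )
                    daughters.append(d)
                sim_divisions.append({
                    "mother_cell": c,
                    "daughter_cells": tuple(daughters),
                    "offtype_cell": daughters[1] if asym else None,
                    "timestep": frame,
                    "time_hp": t,
                    "division_type": "asymmetric" if asym else "symmetric",
                })
                cells.extend(daughters)
                sim_cells.extend(daughters)

        radius = params.radius_at(t)
        for c in dying + cells:
            pos = c.direction * (radius * c.radial_frac) \
                + params.jitter_um * rng.normal(size=3)
            node_id = next_node_id
            next_node_id += 1
            rows.append({
                "node_id": node_id,
                "predecessor_id": c.prev_node_id,
                "timestep": frame,
                "time_hp": t,
                "x": float(pos[0]), "y": float(pos[1]), "z": float(pos[2]),
                "validated": True,
                "identity": "",
                "death": c in dying,
            })
            if c.first_node_id is None:
                c.first_node_id = node_id
            c.prev_node_id = node_id
            c.node_count += 1
        for c in dying:
            sim_deaths.append({
                "cell": c, "timestep": frame, "time_hp": t,
                "identity": c.identity,
            })
        if not cells:
            break

    metadata = params.metadata()
    lineage = lineage_from_records(rows, metadata)

    # map simulator cells to the track ids the parser assigns
    def _tid(cell: _Cell) -> int:
        return lineage.node_track[cell.first_node_id]

    identities = {_tid(c): c.identity for c in sim_cells
                  if c.first_node_id is not None}
    divisions = [{
        "mother_track_id": _tid(d["mother_cell"]),
        "timestep": d["timestep"],
        "time_hp": d["time_hp"],
        "division_type": d["division_type"],
        "offtype_daughter_track_id": (
            None if d["offtype_cell"] is None else _tid(d["offtype_cell"])),
        "daughter_track_ids": tuple(sorted(_tid(c) for c in d["daughter_cells"])),
    } for d in sim_divisions
        if all(c.first_node_id is not None for c in d["daughter_cells"])]
    deaths = [{
        "track_id": _tid(d["cell"]),
        "timestep": d["timestep"],
        "time_hp": d["time_hp"],
        "identity": d["identity"],
    } for d in sim_deaths]

    truth = GroundTruth(
        identities=identities,
        divisions=divisions,
        deaths=deaths,
        extinct=not cells,
    )
    return lineage, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

_PRESETS = {"wt_like": wt_like_params, "clone_like": clone_like_params}


def embryo_seed(master_seed: int, index: int) -> int:
    """Deterministic per-embryo seed derived from the master seed."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_cohort(
    preset: str,
    n_embryos: int,
    seed: int,
    **overrides,
) -> list[tuple[EmbryoLineage, GroundTruth, SimulationParams]]:
    """Independent embryos from a named preset with derived per-embryo seeds.

    ``overrides`` are applied to every embryo's parameters (the embryo id is
    always overwritten with ``<preset><index>``).
    """
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
    out = []
    for i in range(n_embryos):
        params = _PRESETS[preset](**overrides)
        params = dataclasses.replace(params, embryo_id=f"{preset}_{i:02d}")
        lineage, truth = generate_embryo(params, embryo_seed(seed, i))
        out.append((lineage, truth, params))
    return out
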