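"""Independent brute-force oracles for the stochastic model.

These re-implement the generator's event rules (frame-binned divisions,
Bernoulli deaths, Poisson inner founders) at the level of counts only — no
geometry, no lineage tables, none of the package's annotation or statistics
code — so they can serve as an independent reference for population-level
expectations.
"""

import numpy as np

from blastotrack.synthetic import SimulationParams


def _founders(params: SimulationParams, rng: np.random.Generator):
    """(identity, birth_time, cycle) triples for the starting population."""
    cv = max(params.cycle_cv, 1e-6)
    sigma = float(np.sqrt(np.log(1 + cv * cv)))
    mu = float(np.log(params.cycle_mean_h)) - 0.5 * sigma * sigma

    def cycle():
        return float(rng.lognormal(mu, sigma))

    n_inner = params.n_initial_inner
    if params.vary_inner_founders:
        n_inner = max(1, int(rng.poisson(params.n_initial_inner)))
    cells = []
    for ident, n in (("outer", params.n_initial_outer), ("inner", n_inner)):
        for _ in range(n):
            c = cycle()
            cells.append([ident, params.t_start_h - rng.uniform(0, c), c])
    return cells, cycle


def branching_process_replicate(params: SimulationParams, rng: np.random.Generator):
    """One replicate of the count-level branching process.

    Returns (final_count, n_tracks_by_type, n_deaths_by_type) where a
    "track" is any cell that ever existed during the observation window.
    """
    dt = params.frame_interval_h
    p_death = {
        "outer": 1.0 - np.exp(-params.h_outer_per_h * dt),
        "inner": 1.0 - np.exp(-params.h_inner_per_h * dt),
    }
    cells, cycle = _founders(params, rng)
    n_tracks = {"inner": 0, "outer": 0}
    n_deaths = {"inner": 0, "outer": 0}
    for ident, _, _ in cells:
        n_tracks[ident] += 1
    for frame in range(1, params.n_frames):
        t = params.t_start_h + frame * dt
        survivors = []
        for cell in cells:
            if rng.random() < p_death[cell[0]]:
                n_deaths[cell[0]] += 1
            else:
                survivors.append(cell)
        n_inner_now = sum(1 for c in survivors if c[0] == "inner")
        pic = n_inner_now / len(survivors) if survivors else 0.0
        cells = []
        for cell in survivors:
            ident, birth, cyc = cell
            if t - birth < cyc:
                cells.append(cell)
                continue
            p = params.p_asym(ident, t, pic)
            asym = rng.random() < p
            for j in range(2):
                d_ident = ident
                if asym and j == 1:
                    d_ident = "inner" if ident == "outer" else "outer"
                n_tracks[d_ident] += 1
                cells.append([d_ident, t, cycle()])
        if not cells:
            break
    return len(cells), n_tracks, n_deaths


def death_ratio_replicate(params: SimulationParams, rng: np.random.Generator,
                          identity: str = "inner"):
    """Normalized death ratio of one replicate over the full window, or
    None when the replicate has no deaths (excluded, as in the pipeline)."""
    _, n_tracks, n_deaths = branching_process_replicate(params, rng)
    d = n_deaths["inner"] + n_deaths["outer"]
    n = n_tracks["inner"] + n_tracks["outer"]
    if d == 0 or n_tracks[identity] == 0:
        return None
    return (n_deaths[identity] / d) / (n_tracks[identity] / n)


def mc_mean_se(values):
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(len(arr)))
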