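import pytest

from blastotrack.lineage_io import LineageMetadata, lineage_from_records
from blastotrack.synthetic import generate_embryo, wt_like_params


@pytest.fixture
def metadata():
    return LineageMetadata(embryo_id="toy", frame_interval_min=15.0)


def node(nid, pred, step, x=0.0, y=0.0, z=0.0, validated=True, identity="",
         death=False, dt_h=0.25, t0_h=0.0):
    """One dialect row; time_hp is derived from the timestep."""
    return {
        "node_id": nid, "predecessor_id": pred, "timestep": step,
        "time_hp": t0_h + step * dt_h, "x": x, "y": y, "z": z,
        "validated": validated, "identity": identity, "death": death,
    }


@pytest.fixture
def make_lineage(metadata):
    def _make(rows, meta=None):
        return lineage_from_records(rows, meta or metadata)
    return _make


def fast_params(**overrides):
    """A small, short embryo for bulk property tests (seconds, not minutes)."""
    defaults = dict(
        n_initial_outer=12,
        n_initial_inner=4,
        t_start_h=61.5,
        t_end_h=75.0,
        t_collapse_h=80.0,
        cycle_mean_h=9.0,
    )
    defaults.update(overrides)
    return wt_like_params(**defaults)


@pytest.fixture(scope="session")
def wt_embryo():
    """One wild-type-like embryo with its ground truth (shared, read-only)."""
    params = wt_like_params()
    lineage, truth = generate_embryo(params, 42)
    return lineage, truth, params
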