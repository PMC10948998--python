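import numpy as np
import pandas as pd
import pytest

from stripedyn import RunConfig
from stripedyn.simgen import EmbryoGeometry, make_embryo, simulate_traces


@pytest.fixture
def rng():
    return np.random.default_rng(20261002)


@pytest.fixture(scope="session")
def small_geometry():
    """A trunk-scale embryo small enough for per-test simulation."""
    return EmbryoGeometry(ap_length_um=120, n_ap_nuclei=12, n_dv_nuclei=4,
                          dv_window_um=66, nc14_duration_s=600)


@pytest.fixture(scope="session")
def ideal_embryo_traces():
    """Noise-free, step-edged, always-on embryo plus its trace table."""
    emb = make_embryo("wt", preset="ideal", seed=11)
    return emb, simulate_traces(emb)


@pytest.fixture(scope="session")
def default_wt_analysis():
    """One default-preset wild-type embryo run through the full chain."""
    from stripedyn.pipeline import analyze_embryo

    emb = make_embryo("wt", preset="default", seed=7)
    tr = simulate_traces(emb)
    return emb, analyze_embryo(tr, RunConfig(), genotype="wt")


def random_trace_table(rng, n_nuclei=6, n_frames=12, dt=61.0):
    """Small random trace table on a shared frame grid."""
    rows = []
    for nid in range(n_nuclei):
        el = rng.uniform(0, 100)
        dv = rng.uniform(-100, 100)
        for f in range(n_frames):
            rows.append({
                "nucleus_id": nid, "frame": f, "t_seconds": f * dt,
                "ap_um": el * 5.0, "dv_um": dv, "el_pct": el,
                "fluor_ms2": rng.uniform(0, 400),
                "fluor_pp7": rng.uniform(0, 50),
                "true_state": 0,
            })
    return pd.DataFrame(rows)
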