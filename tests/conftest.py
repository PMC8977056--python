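import numpy as np
import pandas as pd
import pytest

from ktrquant import pipeline, synth


@pytest.fixture(scope="session")
def toy_points():
    """The 1-D four-point instance {0, 1, 10, 11} with its true 2-split."""
    X = np.array([[0.0], [1.0], [10.0], [11.0]])
    true = np.array([1, 1, 2, 2])
    crossed = np.array([1, 2, 1, 2])
    return X, true, crossed


@pytest.fixture(scope="session")
def rendered_pipeline():
    """A noiseless 50-cell transient render run through the full extraction.

    Shared across tests because rendering plus extraction is the most
    expensive fixture in the suite.
    """
    sc = synth.SynthConfig(n_cells=50, noise_sd=0.0, amplitude_cv=0.2, seed=3)
    truth = synth.generate_trajectories(
        sc, [synth.default_archetypes()["transient"]])
    render = synth.render_timelapse(truth, seed=3)
    cn = pipeline.extract_trajectories(render.stack)
    return truth, render, cn


def match_to_truth(cn: pd.DataFrame, render, truth: pd.DataFrame, tol_px: float = 3.0):
    """Map measured track ids to planted cell ids via first-frame centroids."""
    t0 = render.centroids[0]
    truth_ids = truth["cell_id"].unique()
    meas0 = cn.groupby("cell_id")[["x0", "y0"]].first()
    mapping = {}
    for cid, row in meas0.iterrows():
        d = np.hypot(t0[:, 0] - row["y0"], t0[:, 1] - row["x0"])
        j = int(d.argmin())
        if d[j] <= tol_px:
            mapping[cid] = truth_ids[j]
    return mapping
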