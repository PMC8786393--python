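"""Shared fixtures: the desk-scale phantom, and one full pipeline run."""

from __future__ import annotations

import numpy as np
import pytest

from dotkit import synthetic
from dotkit.pipeline import PipelineConfig, run_pipeline

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def phantom_bundle():
    """Phantom head, probe, vectorized sensitivity model (no recording)."""
    phantom = synthetic.PhantomSpec()
    probe = synthetic.ProbeSpec()
    model, head, vols = synthetic.generate_sensitivity_model(phantom, probe)
    return {"phantom": phantom, "probe": probe, "model": model,
            "head": head, "volumes": vols}


@pytest.fixture(scope="session")
def pipeline_workdir(tmp_path_factory):
    """One full file-based pipeline run on the seeded synthetic fixture."""
    workdir = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(seed=FIXTURE_SEED)
    run_pipeline(cfg, workdir)
    return workdir


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rigid_transform(rng: np.random.Generator):
    """A uniformly random proper rotation and a modest translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(
        rng.integers(2**31))).as_matrix()
    trans = rng.normal(scale=5.0, size=3)
    return rot, trans
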