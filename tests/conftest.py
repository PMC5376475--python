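import numpy as np
import pytest

import phaseflow as pf


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_grid():
    return pf.GridSpec(16, 12)  # 10x10 px cells on 160x120 frames


@pytest.fixture(scope="session")
def tiny_workflows():
    """Three small single-camera workflows with 3 phases, for fast pipeline tests.

    40x60 frames, 3 fps, 4-6 s phases: extraction runs in a couple of seconds
    while still producing enough words per second to featurize.
    """
    workflows = []
    for w in range(3):
        script = pf.default_script(
            n_phases=3, cameras=1, duration_range=(4, 6), fps=3,
            frame_size=(60, 80), speed=3.0, noise_sigma=1.0,
            seed=100 + w, workflow_id=f"tiny{w}")
        seqs, ann = pf.generate_phase_videos(script)
        workflows.append(pf.Workflow(f"tiny{w}", seqs, ann))
    return workflows


@pytest.fixture(scope="session")
def tiny_config():
    return pf.PipelineConfig(
        foreground="framediff", extraction="gridblock", normalizer="top",
        K=4, grid=pf.GridSpec(8, 6), o_count=3, seed=0, lda_iterations=30)
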