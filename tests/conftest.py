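import numpy as np
import pytest

from mosquant.feature_extraction import IsotopologueTrace


def make_trace(intensities, index=0, rts=None, target_mz=500.0, ppm_tol=10.0):
    intensities = np.asarray(intensities, dtype=float)
    if rts is None:
        rts = np.arange(len(intensities), dtype=float)
    return IsotopologueTrace(
        index=index,
        retention_times=np.asarray(rts, dtype=float),
        intensities=intensities,
        target_mz=target_mz,
        ppm_tol=ppm_tol,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def noiseless_single_run():
    """One noiseless run at t=0.10 with a grid of true in vivo MOS values."""
    from mosquant.synth_data import NoiseSpec, build_design, make_ground_truth, simulate_ms1_run

    design = build_design(
        t_points=(0.10,), n_technical=1, n_biological=1, age_groups=("young",)
    )
    truths = np.array([0.0, 0.05, 0.25, 0.5, 1.0])
    truth = make_ground_truth(
        5, mos=truths, design=design, noise=NoiseSpec(0.0), seed=42
    )
    run = truth.design.runs()[0]
    ms1, evidence = simulate_ms1_run(truth, run)
    return truth, run, ms1, evidence
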