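import numpy as np
import pytest

from calfmolli.ecv import cohort_ecv
from calfmolli.phantom import PAPER_TI_MS, CohortConfig, PhantomConfig, generate_cohort, generate_phantom
from calfmolli.pipeline import analyze_cohort

TI = np.asarray(PAPER_TI_MS)


@pytest.fixture(scope="session")
def ti():
    return TI.copy()


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Small noiseless textured phantom with masks and ground truth."""
    cfg = PhantomConfig(grid_size=64, pixel_spacing_mm=3.0,
                        noise_sigma=0.0, noise_model="none", seed=5)
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def cohort_run():
    """The study-condition synthetic cohort run end to end.

    50 claudicants + 50 controls, bilateral 64x64 legs at SNR 50, ground
    truth calibrated to the reported group medians; shared across the
    recovery tests because a single full-pipeline pass is the expensive
    part of the suite.
    """
    cfg = CohortConfig(n_pad=50, n_control=50, seed=20240614)
    bundles, truth = generate_cohort(cfg)
    res = analyze_cohort(bundles)
    ecv_df, n_excluded = cohort_ecv(res["metrics"], res["blood"], res["subjects"])
    return {"config": cfg, "bundles": bundles, "truth": truth,
            "ecv": ecv_df, "n_excluded": n_excluded, **res}
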