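import numpy as np
import pytest

import restaq


@pytest.fixture(scope="session")
def square_wave_params():
    """Noiseless square-wave actigraphy: RA is analytically 2/3."""
    return restaq.ActigraphyParams(
        rest_level=20.0, active_level=100.0, noise_cv=0.0, missing_rate=0.0,
        dst_rate=0.0, size_flag_rate=0.0, calibration_flag_rate=0.0, seed=0,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """n=300 samples x 50 variants with covariates, for scan unit tests."""
    g = restaq.gen_genotypes(300, 50, (0.1, 0.5), seed=42)
    cov = restaq.gen_covariates(300, seed=43)
    return g, cov


def brute_force_m10_l5(bin_means, bin_valid, w10, w5):
    """Exhaustive enumeration over all window start positions."""
    def scan(width, pick):
        best_val, best_idx = None, None
        for s in range(len(bin_means) - width + 1):
            chunk = bin_means[s : s + width]
            ok = bin_valid[s : s + width]
            if not ok.any():
                continue
            val = np.where(ok, chunk, 0.0).sum() / ok.sum()
            if best_val is None or pick(val, best_val):
                best_val, best_idx = val, s
        return best_val, best_idx

    m10, i10 = scan(w10, lambda a, b: a > b)
    l5, i5 = scan(w5, lambda a, b: a < b)
    return m10, l5, i10, i5
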