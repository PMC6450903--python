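import numpy as np
import pandas as pd
import pytest

INCIDENCE_TXT = """\
SNP EA OA BETA SE EAF INFO
rs1 A G 0.10 0.020 0.30 0.995
rs2 C T -0.05 0.015 0.10 0.999
rs3 G A 0.02 0.010 0.45 0.991
rs4 A T 0.07 0.030 0.20 0.990
rs5 C G -0.01 0.012 0.40 0.992
rs6 A C 0.03 0.025 0.15 0.950
"""

PROGNOSIS_TXT = """\
SNP EA OA BETA SE EAF INFO
rs1 A G 0.30 0.040 0.31 0.992
rs2 T C 0.08 0.030 0.89 0.998
rs3 G A -0.02 0.020 0.44 0.995
rs4 A T 0.05 0.060 0.21 0.991
rs5 C G 0.02 0.025 0.39 0.993
rs6 C A -0.06 0.050 0.84 0.990
rs7 A G 0.11 0.020 0.25 0.990
"""


@pytest.fixture
def sumstats_files(tmp_path):
    inc = tmp_path / "incidence.txt"
    pro = tmp_path / "prognosis.txt"
    inc.write_text(INCIDENCE_TXT)
    pro.write_text(PROGNOSIS_TXT)
    return inc, pro


def make_pairs(m=2000, b=-0.4, se_x=0.02, se_y=0.03, sd_bx=0.05, seed=0,
               frac_causal_y=0.0, sd_by=0.05):
    """Synthetic harmonized pairs with a known confounding slope.

    True incidence effects N(0, sd_bx^2); observed effects add classical
    measurement error with the stated standard errors; conditional
    prognosis effects are b * beta_gx (+ optional direct effects) plus
    noise.
    """
    rng = np.random.default_rng(seed)
    bx = rng.normal(0.0, sd_bx, m)
    by = np.zeros(m)
    n_causal = int(frac_causal_y * m)
    by[:n_causal] = rng.normal(0.0, sd_by, n_causal)
    bx_hat = bx + rng.normal(0.0, se_x, m)
    by_hat = by + b * bx + rng.normal(0.0, se_y, m)
    return pd.DataFrame(
        {
            "variant_id": [f"rs{i}" for i in range(m)],
            "beta_gx": bx_hat,
            "se_gx": se_x,
            "beta_gy_prime": by_hat,
            "se_gy": se_y,
            "pruned": True,
        }
    )


@pytest.fixture
def known_slope_pairs():
    return make_pairs()
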