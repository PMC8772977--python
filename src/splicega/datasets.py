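"""Small published benchmark grids shipped with the package."""

from __future__ import annotations

import pandas as pd

#: Test-set MSE of eight feature-selection methods on the three Hu-sheep
#: body-weight traits (birth, six-month, weaning weight; 240 animals,
#: 54,183 gene probes).  Rows are methods — the splicing-based memetic
#: algorithm this package implements ("MA-splicing"), five heuristic
#: wrappers, plain GA, and adaptive best-subset selection (ABSS); lower
#: is better.  This grid is the standard input of the rank-based
#: comparison pipeline in :mod:`splicega.stats_eval`.
_BW_MSE = {
    "method": [
        "MA-splicing",
        "SWA",
        "ABC",
        "SCA",
        "GA",
        "BPSO",
        "beta-hill-climbing",
        "ABSS",
    ],
    "birth_weight": [0.2213, 0.2392, 0.2390, 0.2391, 0.2393, 0.2392, 0.2389, 0.2292],
    "six_month_weight": [5.4026, 5.6424, 5.6264, 5.6433, 5.6470, 5.6464, 5.6385, 5.8182],
    "weaning_weight": [
        15.7727,
        15.8819,
        15.8762,
        15.8815,
        15.8831,
        15.8835,
        15.8799,
        15.8993,
    ],
}


def bodyweight_mse_benchmark() -> pd.DataFrame:
    """Methods x traits MSE grid of the sheep body-weight benchmark."""
    df = pd.DataFrame(_BW_MSE).set_index("method")
    df.index.name = "method"
    return df
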