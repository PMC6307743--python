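"""Shared helpers for the test suite."""

import numpy as np
import pandas as pd


def make_truth_frame(n, snow=True, patchiness=0.8, site_id="s0", bad=False):
    """Homogeneous truth table for marginal-rate checks."""
    return pd.DataFrame(
        {
            "image_id": [f"img{i:05d}" for i in range(n)],
            "site_id": site_id,
            "snow": snow,
            "patchiness": patchiness if snow else np.nan,
            "snow_on_trees": None,
            "bad": bad,
        }
    )
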