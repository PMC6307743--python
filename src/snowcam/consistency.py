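"""Arithmetic consistency checks of the full-scale campaign's headline rates.

The pipeline mirrors a continental camera-network snow-labeling campaign
(133 sites, 184,453 midday images, three crowd votes each, paired daily
satellite snow-cover extractions).  The campaign's headline percentages are
all derivable from its printed counts and rates; these checks recompute each
one from its inputs and compare at the printed rounding.  They are pure
arithmetic — no data files are read.
"""

from __future__ import annotations

import pandas as pd

#: Image counts of the full-scale campaign.
CAMPAIGN_COUNTS = {
    "total_images": 184_453,
    "usable_images": 172_927,  # after removing bad-consensus images
    "snow_images": 38_727,
    "modis_classified": 96_151,
}

#: Sensitivity/specificity of the transfer-learned classifier at full scale
#: (whole-set fit and the site-grouped cross-validation), against crowd
#: consensus, full dataset.
CAMPAIGN_RATES = {
    "overfit_sensitivity": 0.893,
    "overfit_specificity": 0.994,
    "by_site_sensitivity": 0.833,
    "by_site_specificity": 0.940,
}

#: The printed headline values the recomputations must reproduce.
REPORTED = {
    "snow_prevalence_pct": (21.0, 1),
    "bad_image_pct": (6.2, 1),
    "modis_coverage_pct": (56.0, 0),
    "overfit_accuracy_pct": (97.1, 1),
    "by_site_accuracy_pct": (91.6, 1),
}


def recompute_reported_rates() -> dict:
    """Each headline value recomputed from its printed inputs (unrounded)."""
    c, r = CAMPAIGN_COUNTS, CAMPAIGN_RATES
    prevalence = c["snow_images"] / c["usable_images"]
    return {
        "snow_prevalence_pct": 100.0 * c["snow_images"] / c["total_images"],
        "bad_image_pct": 100.0
        * (c["total_images"] - c["usable_images"])
        / c["total_images"],
        "modis_coverage_pct": 100.0 * c["modis_classified"] / c["usable_images"],
        "overfit_accuracy_pct": 100.0
        * (
            r["overfit_sensitivity"] * prevalence
            + r["overfit_specificity"] * (1.0 - prevalence)
        ),
        "by_site_accuracy_pct": 100.0
        * (
            r["by_site_sensitivity"] * prevalence
            + r["by_site_specificity"] * (1.0 - prevalence)
        ),
    }


def consistency_report() -> pd.DataFrame:
    """Table: recomputed value vs reported value, matched at the reported
    rounding."""
    recomputed = recompute_reported_rates()
    rows = []
    for name, (reported, digits) in REPORTED.items():
        value = recomputed[name]
        rows.append(
            {
                "quantity": name,
                "recomputed": value,
                "reported": reported,
                "digits": digits,
                "match": round(value, digits) == reported,
            }
        )
    return pd.DataFrame(rows)
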