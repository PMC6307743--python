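"""Satellite fractional-snow-cover binarization, validation and OR-fusion.

The two daily 500 m products (Terra- and Aqua-borne sensors) are binarized
jointly: snow if either reports a fractional cover greater than zero,
missing only when neither product reported.  Validation treats SNOW as the
positive class; fusion declares snow when either the satellite or the
camera classifier does, which can only raise sensitivity and only lower
specificity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .metrics import ConfusionCounts, UndefinedMetricError
from .types import BinaryOutcome, ModisObservation


def _coerce_fraction(value: Optional[float]) -> Optional[float]:
    """Out-of-range codes (cloud, fill) count as missing."""
    if value is None:
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    if np.isnan(v) or not 0.0 <= v <= 100.0:
        return None
    return v


def binarize_modis(obs: ModisObservation) -> BinaryOutcome:
    """Snow if either product reports cover > 0; missing iff both missing."""
    terra = _coerce_fraction(obs.terra_fraction)
    aqua = _coerce_fraction(obs.aqua_fraction)
    if terra is None and aqua is None:
        return BinaryOutcome.MISSING
    if (terra or 0.0) > 0.0 or (aqua or 0.0) > 0.0:
        return BinaryOutcome.SNOW
    return BinaryOutcome.NO_SNOW


def binarize_modis_table(modis: pd.DataFrame) -> pd.Series:
    """Vectorized binarization of a modis manifest → Series of
    :class:`BinaryOutcome` values keyed by image_id."""
    terra = pd.to_numeric(modis["terra_fraction"], errors="coerce")
    aqua = pd.to_numeric(modis["aqua_fraction"], errors="coerce")
    terra = terra.where((terra >= 0) & (terra <= 100))
    aqua = aqua.where((aqua >= 0) & (aqua <= 100))
    missing = terra.isna() & aqua.isna()
    snow = (terra.fillna(0) > 0) | (aqua.fillna(0) > 0)
    out = np.where(
        missing,
        BinaryOutcome.MISSING.value,
        np.where(snow, BinaryOutcome.SNOW.value, BinaryOutcome.NO_SNOW.value),
    )
    return pd.Series(out, index=pd.Index(modis["image_id"], name="image_id"), name="modis")


def _align(
    outcomes: pd.Series, reference: pd.Series
) -> Tuple[pd.Series, pd.Series]:
    shared = outcomes.index.intersection(reference.index)
    return outcomes.loc[shared], reference.loc[shared]


def validate_binary(outcomes: pd.Series, reference: pd.Series) -> ConfusionCounts:
    """Confusion of binarized satellite outcomes against reference binary
    labels.  MISSING outcomes are excluded first; positive class is SNOW."""
    outcomes, reference = _align(outcomes, reference)
    keep = outcomes != BinaryOutcome.MISSING.value
    outcomes, reference = outcomes[keep], reference[keep]
    if len(outcomes) == 0:
        raise UndefinedMetricError("no evaluable images (all missing)")
    pred = outcomes == BinaryOutcome.SNOW.value
    return ConfusionCounts.from_labels(reference.astype(bool), pred)


def combine_or(modis: BinaryOutcome, classifier_snow: bool) -> bool:
    """OR-fusion for one image: snow iff either detector says snow.

    MISSING satellite outcomes are excluded from fusion metrics and are a
    caller error here.
    """
    modis = BinaryOutcome(modis)
    if modis is BinaryOutcome.MISSING:
        raise ValueError("cannot fuse a MISSING satellite outcome")
    return modis is BinaryOutcome.SNOW or bool(classifier_snow)


def combine_or_table(outcomes: pd.Series, classifier: pd.Series) -> pd.Series:
    """Vectorized OR-fusion over the shared, non-missing image set."""
    shared = outcomes.index.intersection(classifier.index)
    o = outcomes.loc[shared]
    keep = o != BinaryOutcome.MISSING.value
    o = o[keep]
    c = classifier.loc[o.index].astype(bool)
    return (o == BinaryOutcome.SNOW.value) | c


def stratified_metrics(
    outcomes: pd.Series,
    reference: pd.Series,
    strata: Mapping[str, str],
) -> Dict[str, ConfusionCounts]:
    """:func:`validate_binary` within each stratum.

    Every evaluated image must carry a stratum; strata typically derive
    from the tree sub-labels (trees vs no trees; snow on foliage vs ground
    only under the canopy).
    """
    outcomes, reference = _align(outcomes, reference)
    keep = outcomes != BinaryOutcome.MISSING.value
    outcomes, reference = outcomes[keep], reference[keep]
    strata_s = pd.Series(dict(strata))
    missing_strata = outcomes.index.difference(strata_s.index)
    if len(missing_strata) > 0:
        raise ValueError(
            f"{len(missing_strata)} evaluated images lack a stratum"
        )
    out: Dict[str, ConfusionCounts] = {}
    for stratum in sorted(set(strata_s.loc[outcomes.index])):
        ids = outcomes.index[strata_s.loc[outcomes.index] == stratum]
        out[stratum] = validate_binary(outcomes.loc[ids], reference.loc[ids])
    return out


def seasonal_sensitivity(
    outcomes: pd.Series,
    reference: pd.Series,
    dates: pd.Series,
    min_images: int = 5,
) -> pd.Series:
    """Day-of-year sensitivity series, pooling sites and years.

    For each day of year the sensitivity is computed over reference-snow
    images with a non-missing satellite outcome; days with fewer than
    ``min_images`` such images are reported missing (NaN).
    """
    outcomes, reference = _align(outcomes, reference)
    dates = pd.to_datetime(dates.loc[outcomes.index])
    keep = (outcomes != BinaryOutcome.MISSING.value) & reference.astype(bool)
    doy = dates.dt.dayofyear[keep]
    detected = (outcomes[keep] == BinaryOutcome.SNOW.value).groupby(doy).sum()
    n = outcomes[keep].groupby(doy).size()
    sens = (detected / n).where(n >= min_images)
    return sens.reindex(range(1, 367)).rename("sensitivity")


@dataclass(frozen=True)
class SiteSummary:
    site_id: str
    n_images: int
    n_snow_images: int
    fraction_snow_days: float
    sensitivity: Optional[float]
    missed_snow_count: int


def site_sensitivity_summary(
    outcomes: pd.Series,
    reference: pd.Series,
    records: pd.DataFrame,
) -> pd.DataFrame:
    """Per-site snow fraction, satellite sensitivity and missed-snow count.

    ``fraction_snow_days`` comes from the reference labels over all images
    of the site; sensitivity and missed counts only use images with a
    non-missing satellite outcome.  Sites with no evaluable snow images
    carry a missing sensitivity.  Also reports ``missed_per_year``, the raw
    missed count scaled by 365 / n_images.
    """
    outcomes, reference = _align(outcomes, reference)
    rec = records.set_index("image_id").loc[outcomes.index]
    rows = []
    for site_id, ids in rec.groupby("site_id").groups.items():
        ref = reference.loc[ids].astype(bool)
        out = outcomes.loc[ids]
        evaluable = out != BinaryOutcome.MISSING.value
        snow_eval = ref & evaluable
        n_snow_eval = int(snow_eval.sum())
        detected = int(((out == BinaryOutcome.SNOW.value) & ref).sum())
        missed = n_snow_eval - detected
        n_images = len(ids)
        rows.append(
            {
                "site_id": site_id,
                "n_images": n_images,
                "n_snow_images": int(ref.sum()),
                "fraction_snow_days": float(ref.mean()),
                "sensitivity": (detected / n_snow_eval) if n_snow_eval else np.nan,
                "missed_snow_count": missed,
                "missed_per_year": 365.0 * missed / n_images if n_images else np.nan,
            }
        )
    return pd.DataFrame(rows).sort_values("site_id").reset_index(drop=True)


def fit_log_curve(
    x: Sequence[float], y: Sequence[float]
) -> Tuple[float, float, float]:
    """Least squares of y on ln x: returns (intercept, slope, r_squared).

    r_squared is 1 − SSE/SST of the fitted curve.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.any(x <= 0):
        raise ValueError("all x must be > 0 for a logarithmic fit")
    if np.allclose(x, x[0]):
        raise ValueError("x values are degenerate (all equal)")
    res = linregress(np.log(x), y)
    yhat = res.intercept + res.slope * np.log(x)
    sse = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return float(res.intercept), float(res.slope), r2
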