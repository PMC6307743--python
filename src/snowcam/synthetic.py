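"""Synthetic camera-network generator.

Builds a network of camera sites with one midday image per site per day and
everything downstream stages consume: daily snow truth from a seasonal
two-state Markov chain, three crowd votes per image, class-conditional
Gaussian feature vectors with per-site appearance offsets, paired satellite
fractional-snow-cover readings with canopy- and patchiness-dependent misses,
and small rendered RGB scenes for the image path.

Every generator is a pure function of its inputs and a seed.  Default rates
are calibrated to the marginal statistics of the full-scale deployment the
pipeline mirrors: ~21% snow prevalence, ~6.2% bad images, ~56% satellite
coverage.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from .types import (
    Canopy,
    ModisObservation,
    SimulationConfig,
    SiteConfig,
    SiteType,
    SnowLabel,
    TrueState,
)

START_DATE = "2013-01-01"  # two default years avoid leap days

# Seasonal Markov-chain shape constants (see docs/methods.md).
PEAK_DOY = 15  # mid-January snow-onset peak, northern hemisphere
ONSET_BASE = 0.15
ONSET_SHAPE = 3
MELT_BASE = 0.015
MELT_SCALE = 0.45
MELT_SHAPE = 2
PATCHINESS_CONCENTRATION = 6.0

_SNOW_SUBLABEL_VALUES = np.array(
    [
        SnowLabel.SNOW_TREELESS.value,
        SnowLabel.SNOW_ON_TREES.value,
        SnowLabel.SNOW_GROUND_ONLY.value,
    ]
)


def _tristate(col: pd.Series) -> Tuple[np.ndarray, np.ndarray]:
    """Split an object column of {True, False, None/NaN} into (is_na, is_true)."""
    vals = col.to_numpy(dtype=object)
    is_na = np.fromiter(
        (v is None or (isinstance(v, float) and np.isnan(v)) for v in vals),
        bool,
        len(vals),
    )
    is_true = np.fromiter(
        (not na and bool(v) for v, na in zip(vals, is_na)), bool, len(vals)
    )
    return is_na, is_true


def _key_int(key: object) -> int:
    return int.from_bytes(hashlib.sha256(str(key).encode()).digest()[:4], "big")


def stable_rng(seed: int, *keys: object) -> np.random.Generator:
    """Generator seeded from a root seed plus stable string/int keys."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed)] + [_key_int(k) for k in keys])
    )


def _ensure_rng(seed: Union[int, np.random.Generator], *keys: object):
    if isinstance(seed, np.random.Generator):
        return seed
    return stable_rng(seed, *keys)


def season_intensity(doy: np.ndarray) -> np.ndarray:
    """Winter intensity in [0, 1], peaking at ``PEAK_DOY``."""
    return 0.5 * (1.0 + np.cos(2.0 * np.pi * (np.asarray(doy) - PEAK_DOY) / 365.25))


def _onset_prob(s, severity, multiplier):
    return np.clip(multiplier * ONSET_BASE * severity * s**ONSET_SHAPE, 0.0, 1.0)


def _melt_prob(s):
    return np.clip(MELT_BASE + MELT_SCALE * (1.0 - s) ** MELT_SHAPE, 0.0, 1.0)


def _dates(years: int) -> pd.DatetimeIndex:
    return pd.date_range(START_DATE, periods=365 * years, freq="D")


def patchiness_mean(s: np.ndarray) -> np.ndarray:
    """Expected ground-cover fraction given winter intensity ``s``.

    Mid-season snow tends to blanket the ground; transition-season snow is
    patchy.
    """
    return np.clip(0.08 + 0.87 * np.asarray(s) ** 1.5, 0.05, 0.95)


def expected_prevalence(
    severities: np.ndarray, years: int, multiplier: float
) -> float:
    """Deterministic mean snow fraction of the chain across sites.

    Propagates the one-day marginal P(snow) recursion (one warm-up year,
    then the recorded years) — the calibration oracle for the sampler.
    """
    severities = np.asarray(severities, dtype=float)
    doy_warm = _dates(1).dayofyear.to_numpy()
    doy_run = _dates(years).dayofyear.to_numpy()
    p = np.zeros_like(severities)
    total = np.zeros_like(severities)
    for phase, doys in (("warm", doy_warm), ("run", doy_run)):
        s = season_intensity(doys)
        for i in range(len(doys)):
            on = _onset_prob(s[i], severities, multiplier)
            off = _melt_prob(s[i])
            p = p * (1.0 - off) + (1.0 - p) * on
            if phase == "run":
                total += p
    return float(np.mean(total / len(doy_run)))


def calibrate_onset_multiplier(
    severities: Sequence[float], years: int, target: float
) -> float:
    """Tune the network-wide onset multiplier so the chain's expected snow
    fraction matches ``target``."""
    severities = np.asarray(severities, dtype=float)
    if target <= 0 or not np.any(severities > 0):
        return 0.0

    def f(m):
        return expected_prevalence(severities, years, m) - target

    lo, hi = 1e-4, 1.0
    while f(hi) < 0 and hi < 512:
        hi *= 2.0
    if f(hi) < 0:  # target unreachable (melt-limited); saturate
        return hi
    return float(brentq(f, lo, hi, xtol=1e-4))


def simulate_snow_series(
    site: SiteConfig,
    years: int,
    seed: int,
    *,
    onset_multiplier: float = 1.0,
    onset_rate: Optional[float] = None,
    melt_rate: Optional[float] = None,
    bad_image_prob: float = 0.0,
) -> List[TrueState]:
    """Daily snow truth for one site: one :class:`TrueState` per day.

    ``onset_rate`` / ``melt_rate`` override the seasonal transition
    probabilities with constants (useful for degenerate-limit checks).
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    rng = stable_rng(seed, "truth", site.site_id)
    dates = _dates(years)
    doys = dates.dayofyear.to_numpy()
    s = season_intensity(doys)
    p_on = (
        np.full_like(s, onset_rate)
        if onset_rate is not None
        else _onset_prob(s, site.winter_severity, onset_multiplier)
    )
    p_off = np.full_like(s, melt_rate) if melt_rate is not None else _melt_prob(s)

    u = rng.random(len(dates))
    m = patchiness_mean(s)
    a = m * PATCHINESS_CONCENTRATION
    b = (1.0 - m) * PATCHINESS_CONCENTRATION
    patch_draws = np.clip(rng.beta(a, b), 0.01, 1.0)
    tree_draws = rng.random(len(dates))
    bad_draws = rng.random(len(dates))

    # warm-start: one deterministic year of the marginal recursion so the
    # Jan-1 initial state sits at the chain's mid-winter level
    p0 = 0.0
    warm_doys = _dates(1).dayofyear.to_numpy()
    s_warm = season_intensity(warm_doys)
    p_on_warm = (
        np.full_like(s_warm, onset_rate)
        if onset_rate is not None
        else _onset_prob(s_warm, site.winter_severity, onset_multiplier)
    )
    p_off_warm = (
        np.full_like(s_warm, melt_rate) if melt_rate is not None else _melt_prob(s_warm)
    )
    for i in range(len(warm_doys)):
        p0 = p0 * (1.0 - p_off_warm[i]) + (1.0 - p0) * p_on_warm[i]

    states: List[TrueState] = []
    snow = bool(rng.random() < p0)
    for i, date in enumerate(dates):
        snow = (u[i] >= p_off[i]) if snow else (u[i] < p_on[i])
        image_id = f"{site.site_id}_{date:%Y%m%d}"
        if snow:
            patchiness = float(patch_draws[i])
            if site.canopy is Canopy.NONE:
                on_trees: Optional[bool] = None
            else:
                on_trees = bool(tree_draws[i] < 0.25 + 0.55 * patchiness)
            states.append(
                TrueState(
                    image_id=image_id,
                    snow=True,
                    patchiness=patchiness,
                    snow_on_trees=on_trees,
                    bad=bool(bad_draws[i] < bad_image_prob),
                )
            )
        else:
            states.append(
                TrueState(
                    image_id=image_id,
                    snow=False,
                    bad=bool(bad_draws[i] < bad_image_prob),
                )
            )
    return states


# ---------------------------------------------------------------------------
# crowd votes
# ---------------------------------------------------------------------------


def _vote_error(truth: TrueState, config: SimulationConfig) -> float:
    e = config.annotator_error_base
    if truth.snow:
        e += config.annotator_error_patchy * (1.0 - truth.patchiness)
    return min(e, 1.0)


def simulate_votes(
    truth: TrueState,
    config: SimulationConfig,
    seed: Union[int, np.random.Generator],
) -> Tuple[SnowLabel, SnowLabel, SnowLabel]:
    """Three independent crowd votes for one image.

    Bad images draw BAD_IMAGE votes with high probability.  For usable
    images each vote is correct with probability 1 − e, where e grows as
    snow gets patchier; wrong votes flip across the snow/no-snow boundary.
    """
    rng = _ensure_rng(seed, "votes", truth.image_id)
    e = _vote_error(truth, config)
    votes = []
    for _ in range(3):
        if truth.bad:
            votes.append(
                SnowLabel.BAD_IMAGE
                if rng.random() < config.bad_vote_prob
                else truth.true_label
            )
            continue
        if rng.random() < config.spurious_bad_prob:
            votes.append(SnowLabel.BAD_IMAGE)
        elif rng.random() < e:
            if truth.snow:
                votes.append(SnowLabel.NO_SNOW)
            else:
                votes.append(SnowLabel(rng.choice(_SNOW_SUBLABEL_VALUES)))
        else:
            votes.append(truth.true_label)
    return tuple(votes)


def simulate_votes_table(
    truth: pd.DataFrame, config: SimulationConfig, seed: Union[int, np.random.Generator]
) -> pd.DataFrame:
    """Vectorized votes for a whole truth table.

    Statistically identical to :func:`simulate_votes` applied per image.
    Returns long-format ``image_id, annotator_index, label``.
    """
    rng = _ensure_rng(seed, "votes_table")
    n = len(truth)
    snow = truth["snow"].to_numpy(dtype=bool)
    bad = truth["bad"].to_numpy(dtype=bool)
    patch = truth["patchiness"].to_numpy(dtype=float)
    e = np.full(n, config.annotator_error_base)
    e[snow] += config.annotator_error_patchy * (1.0 - patch[snow])
    e = np.clip(e, 0.0, 1.0)

    trees_na, trees_true = _tristate(truth["snow_on_trees"])
    true_lab = np.where(
        ~snow,
        SnowLabel.NO_SNOW.value,
        np.where(
            trees_na,
            SnowLabel.SNOW_TREELESS.value,
            np.where(
                trees_true,
                SnowLabel.SNOW_ON_TREES.value,
                SnowLabel.SNOW_GROUND_ONLY.value,
            ),
        ),
    )

    labels = np.empty((n, 3), dtype=object)
    for j in range(3):
        lab = true_lab.copy()
        err = rng.random(n) < e
        # wrong votes flip across the binary boundary
        lab[err & snow] = SnowLabel.NO_SNOW.value
        n_fp = int(np.sum(err & ~snow))
        lab[err & ~snow] = rng.choice(_SNOW_SUBLABEL_VALUES, size=n_fp)
        spurious = rng.random(n) < config.spurious_bad_prob
        lab[spurious] = SnowLabel.BAD_IMAGE.value
        # bad images: annotators mostly agree the image is unusable
        bad_vote = bad & (rng.random(n) < config.bad_vote_prob)
        lab[bad_vote] = SnowLabel.BAD_IMAGE.value
        labels[:, j] = lab

    out = pd.DataFrame(
        {
            "image_id": np.repeat(truth["image_id"].to_numpy(), 3),
            "annotator_index": np.tile([1, 2, 3], n),
            "label": labels.reshape(-1),
        }
    )
    return out


# ---------------------------------------------------------------------------
# feature vectors
# ---------------------------------------------------------------------------


def class_direction(d: int) -> np.ndarray:
    """Unit vector along which the snow / no-snow class means separate."""
    return np.ones(d) / np.sqrt(d)


def site_offset(site: SiteConfig, config: SimulationConfig) -> np.ndarray:
    """Fixed per-site appearance shift of magnitude ``site_offset_scale``.

    Derived from the network seed and site id only, so it is shared by
    every image of the site.
    """
    rng = stable_rng(config.seed, "site_offset", site.site_id)
    v = rng.standard_normal(config.feature_dim)
    norm = np.linalg.norm(v)
    if norm == 0 or site.site_offset_scale == 0:
        return np.zeros(config.feature_dim)
    return site.site_offset_scale * v / norm


def _feature_mean(
    truth: TrueState, site: SiteConfig, config: SimulationConfig
) -> np.ndarray:
    d = config.feature_dim
    u = class_direction(d)
    mean = np.zeros(d)
    if truth.snow:
        # patchy snow shrinks toward the no-snow mean
        mean += truth.patchiness * config.class_separation * u
    elif site.white_object:
        mean += config.white_object_shift * config.class_separation * u
    return mean + site_offset(site, config)


def simulate_features(
    truth: TrueState,
    site: SiteConfig,
    config: SimulationConfig,
    seed: Union[int, np.random.Generator],
) -> np.ndarray:
    """One class-conditional Gaussian feature vector (unit noise)."""
    if config.feature_dim < 2:
        raise ValueError("feature_dim must be >= 2")
    rng = _ensure_rng(seed, "features", truth.image_id)
    noise = rng.standard_normal(config.feature_dim)
    if truth.bad:
        return 2.0 * noise  # uninformative content
    return _feature_mean(truth, site, config) + noise


def simulate_features_table(
    truth: pd.DataFrame,
    sites: Sequence[SiteConfig],
    config: SimulationConfig,
    seed: Union[int, np.random.Generator],
) -> pd.DataFrame:
    """Vectorized feature matrix for a whole truth table (image_id index)."""
    rng = _ensure_rng(seed, "features_table")
    d = config.feature_dim
    u = class_direction(d)
    by_id = {s.site_id: s for s in sites}
    n = len(truth)
    means = np.zeros((n, d))
    snow = truth["snow"].to_numpy(dtype=bool)
    bad = truth["bad"].to_numpy(dtype=bool)
    patch = np.nan_to_num(truth["patchiness"].to_numpy(dtype=float))
    site_ids = truth["site_id"].to_numpy()

    means[snow] += (patch[snow, None] * config.class_separation) * u
    for sid, site in by_id.items():
        rows = site_ids == sid
        if site.white_object:
            means[rows & ~snow] += (
                config.white_object_shift * config.class_separation
            ) * u
        means[rows] += site_offset(site, config)
    noise = rng.standard_normal((n, d))
    X = means + noise
    X[bad] = 2.0 * noise[bad]
    cols = [f"f{i:02d}" for i in range(d)]
    return pd.DataFrame(X, index=pd.Index(truth["image_id"], name="image_id"), columns=cols)


# ---------------------------------------------------------------------------
# satellite observations
# ---------------------------------------------------------------------------


def _miss_prob(truth: TrueState, site: SiteConfig, config: SimulationConfig) -> float:
    p = config.modis_miss_base
    if site.canopy is Canopy.DENSE and truth.snow_on_trees is False:
        p += config.modis_miss_canopy_penalty
    p += config.modis_miss_patchy * (1.0 - truth.patchiness)
    return min(p, 1.0)


def simulate_modis(
    truth: TrueState,
    site: SiteConfig,
    config: SimulationConfig,
    seed: Union[int, np.random.Generator],
) -> ModisObservation:
    """Paired fractional-snow-cover readings for one image.

    Cloud-type dropout removes both products together.  Snow can be missed
    (reported as 0) with probability rising for patchy snow and for
    ground-only snow under dense canopy; detected snow reports a fraction
    near ``patchiness`` in percent.
    """
    rng = _ensure_rng(seed, "modis", truth.image_id)
    if rng.random() < config.modis_missing_prob:
        return ModisObservation(truth.image_id, None, None)
    if truth.snow:
        if rng.random() < _miss_prob(truth, site, config):
            return ModisObservation(truth.image_id, 0.0, 0.0)
        base = truth.patchiness * 100.0
        terra = float(np.clip(base + 8.0 * rng.standard_normal(), 1.0, 100.0))
        aqua = float(np.clip(base + 8.0 * rng.standard_normal(), 1.0, 100.0))
        return ModisObservation(truth.image_id, terra, aqua)
    if rng.random() < config.modis_false_pos_prob:
        return ModisObservation(truth.image_id, float(rng.uniform(1.0, 15.0)), 0.0)
    return ModisObservation(truth.image_id, 0.0, 0.0)


def simulate_modis_table(
    truth: pd.DataFrame,
    sites: Sequence[SiteConfig],
    config: SimulationConfig,
    seed: Union[int, np.random.Generator],
) -> pd.DataFrame:
    """Vectorized satellite observations for a whole truth table."""
    rng = _ensure_rng(seed, "modis_table")
    n = len(truth)
    snow = truth["snow"].to_numpy(dtype=bool)
    patch = np.nan_to_num(truth["patchiness"].to_numpy(dtype=float))
    site_ids = truth["site_id"].to_numpy()
    trees_na, trees_true = _tristate(truth["snow_on_trees"])
    on_trees_false = ~trees_na & ~trees_true

    dense = np.zeros(n, dtype=bool)
    for s in sites:
        if s.canopy is Canopy.DENSE:
            dense |= site_ids == s.site_id

    p_miss = np.full(n, config.modis_miss_base)
    p_miss[dense & on_trees_false] += config.modis_miss_canopy_penalty
    p_miss += config.modis_miss_patchy * (1.0 - patch)
    p_miss = np.clip(p_miss, 0.0, 1.0)

    missing = rng.random(n) < config.modis_missing_prob
    miss = rng.random(n) < p_miss
    fp = rng.random(n) < config.modis_false_pos_prob
    terra = np.zeros(n)
    aqua = np.zeros(n)
    detected = snow & ~miss
    base = patch * 100.0
    terra[detected] = np.clip(
        base[detected] + 8.0 * rng.standard_normal(int(detected.sum())), 1.0, 100.0
    )
    aqua[detected] = np.clip(
        base[detected] + 8.0 * rng.standard_normal(int(detected.sum())), 1.0, 100.0
    )
    fp_rows = ~snow & fp
    terra[fp_rows] = rng.uniform(1.0, 15.0, int(fp_rows.sum()))
    terra[missing] = np.nan
    aqua[missing] = np.nan
    return pd.DataFrame(
        {
            "image_id": truth["image_id"].to_numpy(),
            "terra_fraction": terra,
            "aqua_fraction": aqua,
        }
    )


# ---------------------------------------------------------------------------
# toy rendering
# ---------------------------------------------------------------------------


def render_toy_image(
    truth: TrueState,
    site: SiteConfig,
    seed: Union[int, np.random.Generator],
    size: Tuple[int, int] = (64, 64),
) -> np.ndarray:
    """Small deterministic RGB scene for one image (uint8, H×W×3).

    Sky above, textured green/brown ground below, an optional tree band,
    white patches covering roughly ``patchiness`` of the ground when snow is
    present, an optional white structure, and pure noise for bad images.
    """
    h, w = size
    if h < 32 or w < 32:
        raise ValueError("raster must be at least 32x32")
    rng = _ensure_rng(seed, "render", truth.image_id)
    if truth.bad:
        return rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)

    img = np.zeros((h, w, 3), dtype=float)
    horizon = int(0.4 * h)
    img[:horizon] = np.array([135.0, 170.0, 220.0])  # sky
    img[horizon:] = np.array([70.0, 115.0, 55.0])  # ground
    img += rng.normal(0.0, 6.0, size=(h, w, 3))

    tree_top, tree_bot = horizon, int(0.55 * h)
    if site.canopy is not Canopy.NONE:
        img[tree_top:tree_bot] = np.array([35.0, 70.0, 35.0]) + rng.normal(
            0.0, 5.0, size=(tree_bot - tree_top, w, 3)
        )

    ground_top = tree_bot if site.canopy is not Canopy.NONE else horizon
    if truth.snow:
        gh = h - ground_top
        field = gaussian_filter(rng.standard_normal((gh, w)), sigma=4.0)
        thresh = np.quantile(field, 1.0 - truth.patchiness)
        mask = field >= thresh
        ground = img[ground_top:]
        ground[mask] = 240.0 + rng.normal(0.0, 4.0, size=(int(mask.sum()), 3))
        if truth.snow_on_trees:
            band = img[tree_top:tree_bot]
            tf = gaussian_filter(rng.standard_normal(band.shape[:2]), sigma=2.0)
            tmask = tf >= np.quantile(tf, 0.4)
            band[tmask] = 235.0 + rng.normal(0.0, 4.0, size=(int(tmask.sum()), 3))

    if site.white_object:
        r0, r1 = int(0.45 * h), int(0.58 * h)
        c0, c1 = int(0.10 * w), int(0.26 * w)
        img[r0:r1, c0:c1] = 245.0

    return np.clip(img, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------


def generate_sites(config: SimulationConfig) -> List[SiteConfig]:
    """Draw the site roster: types, latitude-driven severity, canopy,
    white structures."""
    rng = stable_rng(config.seed, "sites")
    sites = []
    for i in range(config.n_sites):
        lat = float(rng.uniform(28.0, 68.0))
        severity = float(np.clip((lat - 25.0) / 45.0, 0.0, 0.98))
        site_type = SiteType(rng.choice(["I", "II", "III"], p=[0.48, 0.26, 0.26]))
        canopy = Canopy(rng.choice(["none", "open", "dense"], p=[0.30, 0.35, 0.35]))
        sites.append(
            SiteConfig(
                site_id=f"site{i:03d}",
                site_type=site_type,
                winter_severity=severity,
                latitude_proxy=lat,
                canopy=canopy,
                white_object=bool(rng.random() < 0.10),
                site_offset_scale=config.site_offset_scale,
            )
        )
    return sites


def truth_to_frame(
    states: Iterable[TrueState], site: SiteConfig, dates: pd.DatetimeIndex
) -> pd.DataFrame:
    rows = []
    for st, date in zip(states, dates):
        rows.append(
            {
                "image_id": st.image_id,
                "site_id": site.site_id,
                "date": f"{date:%Y-%m-%d}",
                "site_type": site.site_type.value,
                "snow": st.snow,
                "patchiness": st.patchiness if st.snow else np.nan,
                "snow_on_trees": st.snow_on_trees,
                "bad": st.bad,
            }
        )
    return pd.DataFrame(rows)


def simulate_truth_table(
    sites: Sequence[SiteConfig], config: SimulationConfig
) -> pd.DataFrame:
    """Daily truth for all sites, with the network-level prevalence
    calibration applied."""
    multiplier = calibrate_onset_multiplier(
        [s.winter_severity for s in sites], config.years, config.target_snow_prevalence
    )
    dates = _dates(config.years)
    frames = []
    for site in sites:
        states = simulate_snow_series(
            site,
            config.years,
            config.seed,
            onset_multiplier=multiplier,
            bad_image_prob=config.bad_image_prob,
        )
        frames.append(truth_to_frame(states, site, dates))
    return pd.concat(frames, ignore_index=True)


@dataclass
class NetworkBundle:
    """All manifests of one synthetic network, keyed by image_id."""

    config: SimulationConfig
    sites: List[SiteConfig]
    records: pd.DataFrame  # image_id, site_id, date, site_type
    truth: pd.DataFrame  # image_id, snow, patchiness, snow_on_trees, bad
    votes: pd.DataFrame  # image_id, annotator_index, label
    features: pd.DataFrame  # image_id index, f00..fNN
    modis: pd.DataFrame  # image_id, terra_fraction, aqua_fraction

    @property
    def true_binary(self) -> pd.Series:
        """Ground-truth snow/no-snow keyed by image_id."""
        return pd.Series(
            self.truth["snow"].to_numpy(dtype=bool),
            index=self.truth["image_id"],
            name="snow",
        )

    @property
    def true_labels(self) -> pd.Series:
        """Ground-truth five-way labels keyed by image_id (ignores bad)."""
        snow = self.truth["snow"].to_numpy(dtype=bool)
        trees_na, trees_true = _tristate(self.truth["snow_on_trees"])
        lab = np.where(
            ~snow,
            SnowLabel.NO_SNOW.value,
            np.where(
                trees_na,
                SnowLabel.SNOW_TREELESS.value,
                np.where(
                    trees_true,
                    SnowLabel.SNOW_ON_TREES.value,
                    SnowLabel.SNOW_GROUND_ONLY.value,
                ),
            ),
        )
        return pd.Series(lab, index=self.truth["image_id"], name="label")

    def sites_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "site_id": s.site_id,
                    "site_type": s.site_type.value,
                    "winter_severity": s.winter_severity,
                    "latitude_proxy": s.latitude_proxy,
                    "canopy": s.canopy.value,
                    "white_object": s.white_object,
                    "site_offset_scale": s.site_offset_scale,
                }
                for s in self.sites
            ]
        )

    def write_csv(self, outdir: Union[str, Path]) -> None:
        """Write all manifests as headered CSV (deterministic bytes)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        kw = {"index": False, "float_format": "%.6f"}
        self.sites_frame().to_csv(outdir / "sites.csv", **kw)
        self.records.to_csv(outdir / "records.csv", **kw)
        self.truth.to_csv(outdir / "truth.csv", **kw)
        self.votes.to_csv(outdir / "votes.csv", **kw)
        self.features.to_csv(outdir / "features.csv", index=True, float_format="%.6f")
        self.modis.to_csv(outdir / "modis.csv", **kw)


def simulate_network(config: SimulationConfig) -> NetworkBundle:
    """Generate the full synthetic network: records, truth, votes, features
    and satellite observations, fully reproducible from the config seed."""
    sites = generate_sites(config)
    truth = simulate_truth_table(sites, config)
    records = truth[["image_id", "site_id", "date", "site_type"]].copy()
    truth_cols = truth[
        ["image_id", "site_id", "snow", "patchiness", "snow_on_trees", "bad"]
    ].copy()
    votes = simulate_votes_table(truth_cols, config, stable_rng(config.seed, "votes"))
    features = simulate_features_table(
        truth_cols, sites, config, stable_rng(config.seed, "features")
    )
    modis = simulate_modis_table(
        truth_cols, sites, config, stable_rng(config.seed, "modis")
    )
    return NetworkBundle(
        config=config,
        sites=sites,
        records=records,
        truth=truth_cols.drop(columns=["site_id"]),
        votes=votes,
        features=features,
        modis=modis,
    )
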