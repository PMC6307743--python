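"""Crowd-vote aggregation and gold-standard evaluation.

Each image receives three independent five-way votes.  Consensus is
hierarchical: the binary projections (bad / no-snow / snow) are majority-
voted first; only when the snow class wins is a snow sub-category (treeless,
on trees, ground only) resolved by majority among the snow votes.  A
three-way top-level split has no majority and is queued for manual
adjudication.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .metrics import ConfusionCounts, UndefinedMetricError
from .types import ConsensusResult, SnowLabel, TopLevel

logger = logging.getLogger(__name__)


def _top_class(label: SnowLabel) -> TopLevel:
    if label is SnowLabel.BAD_IMAGE:
        return TopLevel.BAD
    return TopLevel.SNOW if label.is_snow else TopLevel.NO_SNOW


def aggregate_votes(
    image_id: str, votes: Sequence[SnowLabel], n_votes: int = 3
) -> ConsensusResult:
    """Majority consensus for one image from exactly ``n_votes`` votes.

    The top-level class (BAD / NO_SNOW / SNOW on the binary projection)
    needs at least two votes; with no two votes agreeing at top level the
    result is UNRESOLVED.  Snow sub-label ties leave the sub-label absent.
    """
    votes = [SnowLabel(v) for v in votes]
    if len(votes) != n_votes:
        raise ValueError(f"expected exactly {n_votes} votes, got {len(votes)}")
    top_counts = Counter(_top_class(v) for v in votes)
    top, count = top_counts.most_common(1)[0]
    if count < 2:
        return ConsensusResult(image_id, TopLevel.UNRESOLVED)

    unanimous: Optional[bool] = None
    if top_counts[TopLevel.BAD] == 0:
        projections = {v.is_snow for v in votes}
        unanimous = len(projections) == 1

    sub_label: Optional[SnowLabel] = None
    if top is TopLevel.SNOW:
        snow_votes = Counter(v for v in votes if v.is_snow)
        ranked = snow_votes.most_common()
        if len(ranked) == 1 or ranked[0][1] > ranked[1][1]:
            sub_label = ranked[0][0]
    return ConsensusResult(image_id, top, sub_label=sub_label, unanimous=unanimous)


def aggregate_votes_table(votes: pd.DataFrame) -> pd.DataFrame:
    """Consensus for a long-format votes table (image_id, annotator_index,
    label) → one row per image: top_level, sub_label, unanimous.

    Vectorized equivalent of :func:`aggregate_votes` applied per image
    (asserted against it in the test suite).
    """
    wide = votes.pivot(index="image_id", columns="annotator_index", values="label")
    wide = wide.sort_index()
    lab = wide.to_numpy(dtype=object)
    n = lab.shape[0]
    is_bad = lab == SnowLabel.BAD_IMAGE.value
    is_no = lab == SnowLabel.NO_SNOW.value
    is_snow = ~is_bad & ~is_no

    bad_n = is_bad.sum(axis=1)
    no_n = is_no.sum(axis=1)
    snow_n = is_snow.sum(axis=1)

    top = np.full(n, TopLevel.UNRESOLVED.value, dtype=object)
    top[bad_n >= 2] = TopLevel.BAD.value
    top[no_n >= 2] = TopLevel.NO_SNOW.value
    top[snow_n >= 2] = TopLevel.SNOW.value

    # snow sub-label: strict majority among the snow votes
    sub = np.full(n, "", dtype=object)
    for sub_value in _SNOW_VALUES:
        cnt = ((lab == sub_value) & is_snow).sum(axis=1)
        other = snow_n - cnt
        win = (cnt >= 2) | ((cnt == 1) & (other == 0))
        sub[win & (snow_n >= 2)] = sub_value
    # three distinct snow votes or a 1-1 split among two snow votes → no majority
    sub[snow_n < 2] = ""

    unanimous = np.full(n, "", dtype=object)
    eligible = bad_n == 0
    unanimous[eligible] = (snow_n[eligible] == 0) | (snow_n[eligible] == 3)

    out = pd.DataFrame(
        {
            "image_id": wide.index.to_numpy(),
            "top_level": top,
            "sub_label": sub,
            "unanimous": unanimous,
        }
    )
    return out


_SNOW_VALUES = (
    SnowLabel.SNOW_TREELESS.value,
    SnowLabel.SNOW_ON_TREES.value,
    SnowLabel.SNOW_GROUND_ONLY.value,
)


def unresolved_queue(results: Iterable[ConsensusResult]) -> List[str]:
    """Image ids with no top-level majority, for manual adjudication."""
    return [r.image_id for r in results if r.top_level is TopLevel.UNRESOLVED]


def apply_adjudication(
    results: Sequence[ConsensusResult], adjudication: Mapping[str, SnowLabel]
) -> List[ConsensusResult]:
    """Override consensus with authoritative labels.

    Adjudicating a non-UNRESOLVED image is allowed but logged as a warning.
    """
    by_id = {r.image_id: r for r in results}
    out = []
    for r in results:
        if r.image_id not in adjudication:
            out.append(r)
            continue
        label = SnowLabel(adjudication[r.image_id])
        if r.top_level is not TopLevel.UNRESOLVED:
            warnings.warn(
                f"adjudication overrides a resolved consensus for {r.image_id}",
                stacklevel=2,
            )
            logger.warning("adjudication override for resolved image %s", r.image_id)
        top = _top_class(label)
        sub = label if label.is_snow else None
        out.append(ConsensusResult(r.image_id, top, sub_label=sub, unanimous=r.unanimous))
    return out


def unanimity_rate(
    votes_by_image: Mapping[str, Sequence[SnowLabel]],
    exclude: str = "any_bad",
    consensus: Optional[Mapping[str, TopLevel]] = None,
) -> float:
    """Fraction of qualifying images whose three binary projections agree.

    ``exclude='any_bad'`` drops images with any BAD vote (default);
    ``exclude='consensus_bad'`` drops only images whose consensus is BAD
    (requires ``consensus``); BAD votes then don't count toward agreement.
    """
    if exclude not in {"any_bad", "consensus_bad"}:
        raise ValueError("exclude must be 'any_bad' or 'consensus_bad'")
    n = agree = 0
    for image_id, votes in votes_by_image.items():
        votes = [SnowLabel(v) for v in votes]
        if exclude == "any_bad":
            if any(v is SnowLabel.BAD_IMAGE for v in votes):
                continue
            proj = [v.is_snow for v in votes]
        else:
            if consensus is None:
                raise ValueError("consensus required for exclude='consensus_bad'")
            if TopLevel(consensus[image_id]) is TopLevel.BAD:
                continue
            proj = [v.is_snow for v in votes if v is not SnowLabel.BAD_IMAGE]
            if not proj:
                continue
        n += 1
        agree += int(len(set(proj)) == 1)
    if n == 0:
        raise UndefinedMetricError("no qualifying images for unanimity rate")
    return agree / n


def unanimity_rate_table(votes: pd.DataFrame, exclude: str = "any_bad") -> float:
    """Vectorized :func:`unanimity_rate` over a long-format votes table.

    Only the default ``exclude='any_bad'`` denominator is supported here;
    use :func:`unanimity_rate` for the consensus-BAD denominator.
    """
    if exclude != "any_bad":
        raise ValueError("unanimity_rate_table supports exclude='any_bad' only")
    wide = votes.pivot(index="image_id", columns="annotator_index", values="label")
    lab = wide.to_numpy(dtype=object)
    is_bad = lab == SnowLabel.BAD_IMAGE.value
    is_no = lab == SnowLabel.NO_SNOW.value
    is_snow = ~is_bad & ~is_no
    eligible = is_bad.sum(axis=1) == 0
    if not eligible.any():
        raise UndefinedMetricError("no qualifying images for unanimity rate")
    snow_n = is_snow[eligible].sum(axis=1)
    return float(((snow_n == 0) | (snow_n == 3)).mean())


def expected_unanimity(e: float) -> float:
    """Closed form: P(three independent binary votes agree) at error ``e``."""
    return (1.0 - e) ** 3 + e**3


def annotator_error_from_unanimity(rate: float) -> float:
    """Invert :func:`expected_unanimity` on e ∈ [0, 0.5]."""
    if not 0.25 <= rate <= 1.0:
        raise ValueError("unanimity rate must be in [0.25, 1]")
    if rate >= 1.0:
        return 0.0
    return float(brentq(lambda e: expected_unanimity(e) - rate, 0.0, 0.5))


def expected_consensus_error(e: float) -> float:
    """Closed form: majority-of-three binary error, 3e² − 2e³."""
    return 3.0 * e**2 - 2.0 * e**3


def compare_to_gold(
    consensus: Mapping[str, ConsensusResult],
    gold: Mapping[str, SnowLabel],
) -> Tuple[ConfusionCounts, pd.DataFrame]:
    """Binary confusion of consensus vs gold plus a five-way cross-table.

    Images whose consensus is BAD (or UNRESOLVED) are excluded from the
    binary comparison; positive class is SNOW.
    """
    shared = sorted(set(consensus) & set(gold))
    if not shared:
        raise ValueError("no overlapping image_ids between consensus and gold")
    y_true, y_pred = [], []
    cross_rows = []
    for image_id in shared:
        res = consensus[image_id]
        g = SnowLabel(gold[image_id])
        cons_label = _consensus_five_way(res)
        cross_rows.append({"gold": g.value, "consensus": cons_label})
        if res.top_level in (TopLevel.BAD, TopLevel.UNRESOLVED):
            continue
        if g is SnowLabel.BAD_IMAGE:
            continue
        y_true.append(g.is_snow)
        y_pred.append(res.top_level is TopLevel.SNOW)
    counts = ConfusionCounts.from_labels(y_true, y_pred)
    cross = pd.crosstab(
        pd.Series([r["gold"] for r in cross_rows], name="gold"),
        pd.Series([r["consensus"] for r in cross_rows], name="consensus"),
    )
    return counts, cross


def _consensus_five_way(res: ConsensusResult) -> str:
    if res.top_level is TopLevel.BAD:
        return SnowLabel.BAD_IMAGE.value
    if res.top_level is TopLevel.NO_SNOW:
        return SnowLabel.NO_SNOW.value
    if res.top_level is TopLevel.SNOW:
        return res.sub_label.value if res.sub_label else "snow_unspecified"
    return "unresolved"


def consensus_frame_to_results(frame: pd.DataFrame) -> Dict[str, ConsensusResult]:
    """Rebuild :class:`ConsensusResult` objects from a consensus CSV frame."""
    out = {}
    for row in frame.itertuples(index=False):
        sub = SnowLabel(row.sub_label) if getattr(row, "sub_label", "") else None
        unan = row.unanimous
        if isinstance(unan, str):
            unan = None if unan == "" else unan.lower() == "true"
        elif pd.isna(unan):
            unan = None
        out[row.image_id] = ConsensusResult(
            row.image_id, TopLevel(row.top_level), sub_label=sub, unanimous=unan
        )
    return out
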