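"""Enzyme-level clash scores, ensemble Z statistics and cleavage prediction.

For one enzyme-substrate complex the enzyme-level score is the maximum
per-graft clash over the recognition-site nucleotides (both strands, before
strand averaging); the ``exclude_outermost`` variant drops the first and
last site base pair first.  Across an ensemble of enzymes the scores are
standardized (sample standard deviation, n-1) and converted to lower-tail
and two-sided normal probabilities; empirical ranks r/(n+1) are reported
alongside because a rank test is an equally valid reading of a one-sided
tail.

An enzyme is predicted to cleave RNA/DNA heteroduplexes when it binds its
site in a sufficiently A-like conformation (fraction of A-classified site
steps >= ``a_fraction_min``) and the grafted hydroxyls fit (site score <=
``clash_threshold``).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = ["EnzymeScore", "enzyme_score", "zscores", "predict_cleaver",
           "EnzymeStatsError", "DegenerateEnsembleError", "NoSiteError",
           "DEFAULT_A_FRACTION_MIN"]

DEFAULT_A_FRACTION_MIN = 0.5
DEFAULT_CLASH_THRESHOLD = 1.1


class EnzymeStatsError(ValueError):
    pass


class DegenerateEnsembleError(EnzymeStatsError):
    pass


class NoSiteError(EnzymeStatsError):
    pass


@dataclass
class EnzymeScore:
    enzyme_id: str = ""
    structure_id: str = ""
    site_pattern: str = ""
    n_site_steps: int = 0
    n_a_steps: int = 0
    max_clash_site: float = float("nan")
    variant: str = "include_outermost"
    z: float = float("nan")
    p_one_sided: float = float("nan")
    p_two_sided: float = float("nan")
    empirical_rank: float = float("nan")
    predicted_cleaver: Optional[bool] = None


def enzyme_score(per_position: pd.DataFrame, site_span: Optional[tuple],
                 variant: str = "include_outermost") -> float:
    """Enzyme-level maximal clash over the recognition site.

    ``per_position`` is a :func:`~ribograft.clash_scoring.score_duplex`
    table; the maximum is taken over the per-graft maxima of both strands
    (columns ``max_s1`` / ``max_s2``), not over strand-averaged values.
    """
    if variant not in ("include_outermost", "exclude_outermost"):
        raise EnzymeStatsError(f"unknown variant {variant!r}")
    if site_span is None:
        raise NoSiteError("no recognition site annotated")
    lo, hi = site_span
    if hi < lo:
        raise NoSiteError("empty recognition site")
    if variant == "exclude_outermost":
        lo, hi = lo + 1, hi - 1
        if hi < lo:
            raise NoSiteError("site too short after dropping outermost pairs")
    sel = per_position[(per_position["position"] >= lo) &
                       (per_position["position"] <= hi)]
    if sel.empty:
        raise NoSiteError(f"no positions within site span {site_span}")
    vals = pd.concat([sel["max_s1"], sel["max_s2"]]).dropna()
    if vals.empty:
        raise EnzymeStatsError("all site grafts undefined")
    return float(vals.max())


def zscores(scores: Sequence[float]) -> pd.DataFrame:
    """Standardize an ensemble of enzyme-level scores.

    Returns a frame with z, normal-theory one-sided (lower tail) and
    two-sided probabilities, and the empirical rank probability r/(n+1).
    """
    x = np.asarray(list(scores), float)
    if x.size < 2:
        raise EnzymeStatsError("need at least two scores")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateEnsembleError("all scores identical: zero variance")
    z = (x - x.mean()) / sd
    ranks = pd.Series(x).rank(method="average").to_numpy()
    return pd.DataFrame({
        "score": x,
        "z": z,
        "p_one_sided": norm.cdf(z),
        "p_two_sided": 2.0 * norm.cdf(-np.abs(z)),
        "empirical_rank": ranks / (x.size + 1.0),
    })


def predict_cleaver(score: EnzymeScore,
                    a_fraction_min: float = DEFAULT_A_FRACTION_MIN,
                    clash_threshold: float = DEFAULT_CLASH_THRESHOLD) -> bool:
    """Conjunction rule: A-like site binding AND accommodable hydroxyls."""
    if score.n_site_steps <= 0:
        return False
    a_fraction = score.n_a_steps / score.n_site_steps
    return bool(a_fraction >= a_fraction_min and
                score.max_clash_site <= clash_threshold)
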