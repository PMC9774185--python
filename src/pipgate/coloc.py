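"""Two-channel colocalization statistics with automatic threshold selection.

Implements the intensity-correlation statistic set reported by the standard
ImageJ/FIJI colocalization-threshold workflow on registered two-channel
images: Pearson correlation (whole image, above- and below-threshold),
intensity-ratio coefficients m1/m2 and their thresholded counterparts k1/k2,
the overlap coefficient R, automatic (Costes-style) threshold determination
from the channel-channel regression, and a colocalized-pixel mask restricted
to pixels whose two intensities are within a factor ``ratio_min`` of each
other (the pixels conventionally recolored white).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ColocResult",
    "pearson_coefficient",
    "intensity_ratio_coefficients",
    "manders_split_fractions",
    "costes_thresholds",
    "overlap_and_counts",
    "coloc_report",
]


def _channels(pair_or_ch1, ch2=None):
    if ch2 is None:
        ch1, ch2 = pair_or_ch1.channel1, pair_or_ch1.channel2
    else:
        ch1 = pair_or_ch1
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    if ch1.shape != ch2.shape:
        raise ValueError("channels must have identical shapes")
    return ch1.ravel(), ch2.ravel()


def pearson_coefficient(pair_or_ch1, ch2=None, region: str = "all",
                        thresholds: tuple[float, float] | None = None) -> float:
    """Product-moment correlation of the two channels over a pixel region.

    region : 'all', 'above' (both channels above their thresholds) or
        'below' (both strictly below); 'above'/'below' require ``thresholds``.
    """
    s1, s2 = _channels(pair_or_ch1, ch2)
    if region != "all":
        if thresholds is None:
            raise ValueError("thresholds required for region selection")
        t1, t2 = thresholds
        mask = (s1 > t1) & (s2 > t2) if region == "above" else (s1 < t1) & (s2 < t2)
        s1, s2 = s1[mask], s2[mask]
    if s1.size < 2:
        raise ValueError(f"region {region!r} selects fewer than 2 pixels")
    if np.ptp(s1) == 0 or np.ptp(s2) == 0:
        raise ValueError("zero-variance channel in selected region")
    return float(np.corrcoef(s1, s2)[0, 1])


def intensity_ratio_coefficients(pair_or_ch1, ch2=None) -> tuple[float, float]:
    """Intensity-ratio colocalization coefficients.

    m1 = sum(s1*s2)/sum(s1^2) and m2 = sum(s1*s2)/sum(s2^2).  These are the
    overlap-style (k-type) forms; they are not bounded by 1 and obey the exact
    scaling laws m1(a*s1, s2) = m1/a and m2(s1, b*s2) = m2/b.
    """
    s1, s2 = _channels(pair_or_ch1, ch2)
    d1, d2 = float(s1 @ s1), float(s2 @ s2)
    if d1 == 0 or d2 == 0:
        raise ValueError("all-zero channel")
    num = float(s1 @ s2)
    return num / d1, num / d2


def manders_split_fractions(pair_or_ch1, ch2=None,
                            thresholds: tuple[float, float] = (0.0, 0.0)) -> tuple[float, float]:
    """Classical split colocalization fractions (bounded by 1).

    M1 = fraction of channel-1 intensity in pixels where channel 2 is above
    its threshold, and vice versa for M2.
    """
    s1, s2 = _channels(pair_or_ch1, ch2)
    t1, t2 = thresholds
    tot1, tot2 = float(s1.sum()), float(s2.sum())
    if tot1 == 0 or tot2 == 0:
        raise ValueError("all-zero channel")
    return float(s1[s2 > t2].sum()) / tot1, float(s2[s1 > t1].sum()) / tot2


def costes_thresholds(pair_or_ch1, ch2=None, step: float = 1.0):
    """Automatic unbiased threshold pair from the channel-channel regression.

    An ordinary least-squares line ch2 = slope*ch1 + intercept is fitted over
    all pixels.  Candidate pairs (t, slope*t + intercept) are scanned downward
    from the channel-1 maximum in steps of one intensity unit; the returned
    pair is the first at which the Pearson correlation of the pixels with
    BOTH channels below their thresholds reaches <= 0.  If no candidate
    achieves that, the minimum intensity is returned with a warning.

    Returns (threshold_ch1, threshold_ch2, slope, intercept).
    """
    s1, s2 = _channels(pair_or_ch1, ch2)
    if np.ptp(s1) == 0 or np.ptp(s2) == 0:
        raise ValueError("zero-variance channel")
    slope, intercept = np.polyfit(s1, s2, 1)
    if slope <= 0 or np.corrcoef(s1, s2)[0, 1] <= 0:
        # no positive overall correlation: the scan is inapplicable, every
        # pixel is treated as significant
        warnings.warn("channels show no positive correlation; thresholds collapse to minimum",
                      stacklevel=2)
        return float(s1.min()), float(s2.min()), float(slope), float(intercept)

    # pixel i is in the below-both region at threshold t iff t > crit_i where
    # crit_i = max(s1_i, (s2_i - intercept)/slope); as t decreases pixels only
    # ever leave the region, so the scan runs on incrementally updated sums.
    crit = np.maximum(s1, (s2 - intercept) / slope)
    order = np.argsort(crit)[::-1]  # pixels in order of leaving
    s1o, s2o = s1[order], s2[order]
    crit_o = crit[order]

    n = s1.size
    sums = np.array([s1o.sum(), s2o.sum(), s1o @ s1o, s2o @ s2o, s1o @ s2o], dtype=float)
    count = n
    ptr = 0  # pixels [0, ptr) have left the region

    t = float(np.ceil(s1.max()))
    t_min = float(s1.min())
    found = None
    seen_positive = False  # the crossing only counts once the scan has entered
    # the positively correlated zone; a shallow regression slope can make the
    # topmost candidate regions spuriously anti-correlated
    while t > t_min:
        while ptr < n and crit_o[ptr] >= t:
            x, y = s1o[ptr], s2o[ptr]
            sums -= (x, y, x * x, y * y, x * y)
            count -= 1
            ptr += 1
        if count >= 2:
            sx, sy, sxx, syy, sxy = sums
            var1 = sxx - sx * sx / count
            var2 = syy - sy * sy / count
            if var1 > 1e-12 * max(sxx, 1.0) and var2 > 1e-12 * max(syy, 1.0):
                r = (sxy - sx * sy / count) / np.sqrt(var1 * var2)
                if r > 0:
                    seen_positive = True
                elif seen_positive:
                    found = t
                    break
        t -= step
    if found is None:
        warnings.warn("no threshold yields non-positive below-threshold correlation; "
                      "using minimum intensity", stacklevel=2)
        found = t_min
    return float(found), float(slope * found + intercept), float(slope), float(intercept)


@dataclass
class ColocResult:
    """Full colocalization statistic set for a registered image pair."""

    pearson: float
    m1: float
    m2: float
    k1: float
    k2: float
    overlap_R_above: float
    overlap_R_below: float
    threshold_ch1: float
    threshold_ch2: float
    regression_slope: float
    regression_intercept: float
    n_coloc_pixels: int
    n_ch1_above: int
    n_ch2_above: int
    mask: np.ndarray

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "mask"}
        return d


def overlap_and_counts(pair_or_ch1, ch2=None, thresholds: tuple[float, float] = (0.0, 0.0),
                       ratio_min: float = 0.1):
    """Thresholded overlap statistics, pixel counts and the colocalized mask.

    Over the pixels with both channels above threshold: overlap coefficient
    R = sum(s1*s2)/sqrt(sum(s1^2)*sum(s2^2)) and the per-channel coefficients
    k1 = sum(s1*s2)/sum(s1^2), k2 = sum(s1*s2)/sum(s2^2).  R is also reported
    over the both-below region.  A pixel is colocalized when both channels are
    above threshold AND min(s1,s2)/max(s1,s2) > ratio_min; the boolean mask of
    those pixels is returned together with per-channel above-threshold counts.
    """
    if ch2 is None:
        shape = pair_or_ch1.channel1.shape
    else:
        shape = np.asarray(pair_or_ch1).shape
    s1, s2 = _channels(pair_or_ch1, ch2)
    t1, t2 = thresholds
    if not (s1 > t1).any() and not (s2 > t2).any():
        raise ValueError("no pixels above threshold in either channel")
    above = (s1 > t1) & (s2 > t2)

    def overlap_r(m):
        d = float(np.sqrt((s1[m] @ s1[m]) * (s2[m] @ s2[m])))
        return float(s1[m] @ s2[m]) / d if d > 0 else 0.0

    if above.any():
        a1, a2 = s1[above], s2[above]
        num = float(a1 @ a2)
        k1, k2 = num / float(a1 @ a1), num / float(a2 @ a2)
        r_above = overlap_r(above)
    else:
        # channels overlap nowhere above threshold: zero overlap by definition
        k1 = k2 = r_above = 0.0
    below = (s1 < t1) & (s2 < t2)
    r_below = overlap_r(below) if below.any() else 0.0
    hi = np.maximum(s1, s2)
    ratio = np.divide(np.minimum(s1, s2), hi, out=np.zeros_like(hi), where=hi > 0)
    mask = above & (ratio > ratio_min)
    return {
        "overlap_R_above": r_above,
        "overlap_R_below": r_below,
        "k1": k1,
        "k2": k2,
        "n_coloc_pixels": int(mask.sum()),
        "n_ch1_above": int((s1 > t1).sum()),
        "n_ch2_above": int((s2 > t2).sum()),
        "mask": mask.reshape(shape),
    }


def coloc_report(pair, ratio_min: float = 0.1) -> ColocResult:
    """Run the full statistic set with automatic thresholds."""
    t1, t2, slope, intercept = costes_thresholds(pair)
    m1, m2 = intensity_ratio_coefficients(pair)
    stats = overlap_and_counts(pair, thresholds=(t1, t2), ratio_min=ratio_min)
    return ColocResult(
        pearson=pearson_coefficient(pair),
        m1=m1, m2=m2,
        k1=stats["k1"], k2=stats["k2"],
        overlap_R_above=stats["overlap_R_above"],
        overlap_R_below=stats["overlap_R_below"],
        threshold_ch1=t1, threshold_ch2=t2,
        regression_slope=slope, regression_intercept=intercept,
        n_coloc_pixels=stats["n_coloc_pixels"],
        n_ch1_above=stats["n_ch1_above"],
        n_ch2_above=stats["n_ch2_above"],
        mask=stats["mask"],
    )
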