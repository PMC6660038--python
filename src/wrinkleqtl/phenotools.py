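"""Computable parts of the wrinkle-phenotype protocol.

The pixel-ratio phenotype is the count of traced-wrinkle pixels over the
count of facial-contour pixels; the score phenotype is a three-scorer
consensus on a 1-5 half-point grid, rescored while the scorer range exceeds
one point.  ``describe`` supplies the descriptive statistics the pipeline
reports per trait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

SCORE_MIN, SCORE_MAX, SCORE_STEP = 1.0, 5.0, 0.5
MAX_SCORER_RANGE = 1.0

__all__ = ["pixel_ratio", "load_mask", "consensus_score", "ConsensusResult",
           "describe"]


def load_mask(path) -> np.ndarray:
    """Binary mask from a text 0/1 grid or an image file (nonzero = set)."""
    path = str(path)
    if path.endswith((".txt", ".dat")):
        return np.loadtxt(path, dtype=int) != 0
    import imageio.v3 as iio

    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., :3].max(axis=2)
    return img > 0


def pixel_ratio(trace_mask: np.ndarray, contour_mask: np.ndarray) -> float:
    """Traced-wrinkle pixels over facial-contour pixels (TFW/BFC)."""
    trace = np.asarray(trace_mask).astype(bool)
    contour = np.asarray(contour_mask).astype(bool)
    if trace.shape != contour.shape:
        raise ValueError("masks must share dimensions")
    bfc = int(contour.sum())
    if bfc == 0:
        raise ValueError("empty facial contour")
    outside = int((trace & ~contour).sum())
    if outside:
        log.warning("%d trace pixels fall outside the contour", outside)
    return float(trace.sum()) / bfc


@dataclass
class ConsensusResult:
    accepted: bool
    mean: float | None


def _validate_score(s: float) -> None:
    if not SCORE_MIN <= s <= SCORE_MAX:
        raise ValueError(f"score {s} outside [{SCORE_MIN}, {SCORE_MAX}]")
    if abs(round(s / SCORE_STEP) * SCORE_STEP - s) > 1e-9:
        raise ValueError(f"score {s} not on the {SCORE_STEP} grid")


def consensus_score(scores) -> ConsensusResult:
    """Three-scorer consensus: accept the mean when the range is <= 1,
    otherwise flag the sample for rescoring."""
    scores = tuple(float(s) for s in scores)
    if len(scores) != 3:
        raise ValueError("need exactly three scores")
    for s in scores:
        _validate_score(s)
    if max(scores) - min(scores) > MAX_SCORER_RANGE:
        return ConsensusResult(accepted=False, mean=None)
    return ConsensusResult(accepted=True, mean=float(np.mean(scores)))


def describe(values, sex=None, other=None) -> dict:
    """Descriptive summary of one trait: n, range, mean, SD, SE, CV, plus the
    Pearson correlation with ``other`` and a Welch t-test between sexes.

    CV is SD/mean (flagged None when the SD is zero or the mean is zero).
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 values")
    sd = float(np.std(v, ddof=1))
    mean = float(np.mean(v))
    out = {
        "n": int(len(v)),
        "min": float(v.min()),
        "max": float(v.max()),
        "mean": mean,
        "sd": sd,
        "se": sd / np.sqrt(len(v)),
        "cv": (sd / mean if sd > 0 and mean != 0 else None),
    }
    if out["cv"] is None:
        log.warning("CV undefined (zero variance or zero mean)")
    if other is not None:
        out["correlation"] = float(np.corrcoef(v, np.asarray(other, float))[0, 1])
    if sex is not None:
        sex = np.asarray(sex)
        m, f = v[sex == "M"], v[sex == "F"]
        if len(m) >= 2 and len(f) >= 2:
            t, p = stats.ttest_ind(f, m, equal_var=False)
            out["sex_means"] = {"M": float(m.mean()), "F": float(f.mean())}
            out["sex_welch_t"] = float(t)
            out["sex_welch_p"] = float(p)
    return out
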