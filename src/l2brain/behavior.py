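"""Behavioral scoring: L2 test percentiles, composite proficiency and the
corrected-progress (CorP) learning gain.

Learners sit three L2 tests (a C-test, a course-book assessment and a
listening-comprehension test) before (T1) and after (T2) the training.
Each raw score is expressed as a percentile of its maximum, proficiency is
the unweighted mean of the three percentiles, and the learning gain is the
corrected progress

    CorP = (T2 - T1) * max / (max - T1)

i.e. the achieved improvement as a percentage of the improvement that was
still attainable at T1.  A learner moving 30 -> 50 on a 0-100 scale earns
CorP = 28.57, while 0 -> 20 earns only 20.00: gains from a higher starting
point count for more, compensating the logarithmic shape of adult L2
learning trajectories.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

TESTS = ("c_test", "course_test", "listening")


def percentile_score(raw: float, max_raw: float) -> float:
    """Score as a percentage of the maximum (0-100)."""
    if max_raw <= 0:
        raise ValueError("max_raw must be positive")
    if raw < 0 or raw > max_raw:
        raise ValueError(f"raw score {raw} outside [0, {max_raw}]")
    return 100.0 * raw / max_raw


def composite(percentiles: Sequence[float]) -> float:
    """Unweighted mean of the three test percentiles."""
    vals = np.asarray(percentiles, float)
    if vals.size != len(TESTS) or np.isnan(vals).any():
        raise ValueError(f"need {len(TESTS)} percentiles, got {percentiles!r}")
    return float(vals.mean())


def corrected_progress(t1: float, t2: float, max_score: float = 100.0) -> float:
    """Corrected progress: gain as a percentage of attainable improvement.

    Strictly increasing in ``t2`` and, for a fixed positive gain, in ``t1``;
    negative when the learner regresses.  Undefined at ``t1 == max_score``.
    """
    if t1 > max_score or t1 < 0 or t2 < 0 or t2 > max_score:
        raise ValueError("scores must lie in [0, max_score]")
    if t1 == max_score:
        raise ZeroDivisionError("CorP undefined when the T1 score is already maximal")
    return (t2 - t1) * max_score / (max_score - t1)


def first_pc_variance_share(scores: np.ndarray | pd.DataFrame) -> float:
    """Variance share (%) of the first principal component of a score matrix.

    Computed on the correlation matrix, so the share is the largest
    eigenvalue divided by the number of tests.  Used to justify collapsing
    the three L2 tests into one composite (the study reports 82%).
    """
    x = np.asarray(scores, float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a (subjects x tests) matrix with >= 2 of each")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant test column: correlation undefined")
    corr = np.corrcoef(x, rowvar=False)
    eigvals = np.linalg.eigvalsh(corr)
    return float(eigvals.max() / x.shape[1] * 100.0)


def assessment_table(
    t1: pd.DataFrame, t2: pd.DataFrame, max_score: float = 100.0
) -> pd.DataFrame:
    """Assemble the per-subject assessment table.

    ``t1``/``t2`` carry one row per subject with columns ``subject`` plus the
    three test percentiles.  Returns composites and CorP (computed on the
    composite percentile with ``max_score`` = 100).
    """
    for df, name in ((t1, "t1"), (t2, "t2")):
        missing = {"subject", *TESTS} - set(df.columns)
        if missing:
            raise ValueError(f"{name} table missing columns {sorted(missing)}")
    merged = t1.merge(t2, on="subject", suffixes=("_T1", "_T2"), validate="1:1")
    out = merged[["subject"]].copy()
    for sess in ("T1", "T2"):
        cols = [f"{t}_{sess}" for t in TESTS]
        vals = merged[cols].to_numpy(float)
        if ((vals < 0) | (vals > 100)).any():
            raise ValueError("percentiles must lie in [0, 100]")
        out[[f"{t}_{sess}" for t in TESTS]] = vals
        out[f"composite_{sess}"] = vals.mean(axis=1)
    out["corp"] = [
        corrected_progress(a, b, max_score)
        for a, b in zip(out["composite_T1"], out["composite_T2"])
    ]
    return out
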