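"""Observer-score evaluation: tie-corrected Spearman rank correlation,
median-threshold visibility classification, and a synthetic mean-opinion-
score (MOS) generator.

The study compares each metric's 21 scores per (case, noise, property)
group against the group's MOS by Spearman's ρ.  Two tie policies are
provided: the printed difference-of-ranks formula with the (m³−m)/12 tie
correction added for every tie group of either variable, and the exact
Pearson-correlation-of-average-ranks form used as its oracle.  The two
coincide when there are no ties.

No human observer data ships with the package; ``synth_mos`` generates a
synthetic observer panel whose latent detectability grows logistically
with inclusion radius × optical contrast, standing in for the 20-subject
experiment so the evaluation stage is fully testable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "rank_with_ties",
    "spearman_rho",
    "correlation_table",
    "median_threshold_classify",
    "synth_mos",
    "mos_means",
    "N_SUBJECTS",
]

N_SUBJECTS = 20
GROUP_KEYS = ["case", "noise", "property"]


def rank_with_ties(values) -> np.ndarray:
    """Ranks 1..n; tied values get the mean of their positional ranks."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot rank an empty list")
    return rankdata(values, method="average")


def _tie_correction(ranks: np.ndarray) -> float:
    """Sum of (m³ − m)/12 over the tie groups of one variable."""
    _, counts = np.unique(ranks, return_counts=True)
    m = counts[counts > 1].astype(float)
    return float(np.sum((m ** 3 - m) / 12.0))


def spearman_rho(a, b, tie_policy: str = "printed") -> float:
    """Spearman rank correlation between two equally long score lists.

    tie_policy "printed" uses the difference-of-ranks formula, adding the
    (m³−m)/12 correction terms of both variables to the Σd² sum when ties
    exist; "rank_pearson" is the exact Pearson correlation of average
    ranks.  A zero-variance rank vector makes ρ undefined and raises.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be two equal-length 1-D lists")
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 observations")
    ra = rank_with_ties(a)
    rb = rank_with_ties(b)
    if np.ptp(ra) == 0 or np.ptp(rb) == 0:
        raise ValueError("rank vector has zero variance; rho is undefined")

    if tie_policy == "rank_pearson":
        return float(np.corrcoef(ra, rb)[0, 1])
    if tie_policy == "printed":
        d2 = float(np.sum((ra - rb) ** 2))
        cf = _tie_correction(ra) + _tie_correction(rb)
        return 1.0 - 6.0 * (d2 + cf) / (n * (n ** 2 - 1))
    raise ValueError(f"unknown tie_policy {tie_policy!r}")


def correlation_table(scores: pd.DataFrame, mos: pd.DataFrame,
                      metric_columns=None,
                      tie_policy: str = "printed") -> pd.DataFrame:
    """Per-group Spearman ρ of every metric against the mean opinion score.

    ``scores`` needs columns image_id, case, noise, property plus one column
    per metric; ``mos`` needs image_id and subject_* columns (or a
    ready-made ``mos`` column).  Returns one row per (case, noise, property)
    group plus an ``Average`` row of per-metric means across groups.
    """
    if metric_columns is None:
        metric_columns = [c for c in scores.columns
                          if c not in {"image_id", *GROUP_KEYS}]
    mos = mos.copy()
    if "mos" not in mos.columns:
        mos["mos"] = mos_means(mos)
    if set(scores["image_id"]) != set(mos["image_id"]):
        raise ValueError("scores and MOS tables cover different image sets")
    merged = scores.merge(mos[["image_id", "mos"]], on="image_id",
                          validate="one_to_one")

    rows = []
    for keys, grp in merged.groupby(GROUP_KEYS, sort=True):
        row = dict(zip(GROUP_KEYS, keys), n=len(grp))
        for m in metric_columns:
            row[m] = spearman_rho(grp[m].to_numpy(), grp["mos"].to_numpy(),
                                  tie_policy=tie_policy)
        rows.append(row)
    table = pd.DataFrame(rows)
    avg = {k: "Average" for k in GROUP_KEYS}
    avg["n"] = int(table["n"].sum())
    for m in metric_columns:
        avg[m] = float(table[m].mean())
    return pd.concat([table, pd.DataFrame([avg])], ignore_index=True)


@dataclass
class VisibilityPartition:
    """Median-threshold split of similarity scores into visible/invisible."""

    threshold: float
    visible_ids: list
    invisible_ids: list


def median_threshold_classify(scores, image_ids=None) -> VisibilityPartition:
    """Classify images by their similarity to the homogeneous reference.

    Scores strictly below the group median indicate low similarity to the
    homogeneous reference, i.e. a *visible* inclusion; scores at or above
    the median are classified invisible (ties at the median deliberately
    fall on the invisible side).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 scores to classify")
    if image_ids is None:
        image_ids = list(range(len(scores)))
    med = float(np.median(scores))
    visible = [i for i, s in zip(image_ids, scores) if s < med]
    invisible = [i for i, s in zip(image_ids, scores) if s >= med]
    return VisibilityPartition(threshold=med, visible_ids=visible,
                               invisible_ids=invisible)


def synth_mos(grid, n_subjects: int = N_SUBJECTS, seed: int = 0
              ) -> pd.DataFrame:
    """Synthetic observer panel (stand-in for human MOS data).

    ``grid`` is a list of (image_id, inclusion_radius_mm, contrast) tuples,
    where contrast is the relative optical deviation of the inclusion from
    background (``PhantomSpec.contrast``).  Latent detectability follows a
    logistic curve in radius × contrast, mapped onto the 1 (not detectable)
    … 5 (very detectable) opinion scale; each subject adds integer jitter
    in {-1, 0, +1}.  A zero-detectability image scores exactly 1 from every
    subject.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for image_id, radius, contrast in grid:
        x = float(radius) * float(contrast)
        if x == 0:
            scores = np.ones(n_subjects, dtype=int)
        else:
            latent = 1.0 + 4.0 / (1.0 + np.exp(-(x - 6.0) / 2.0))
            jitter = rng.choice([-1, 0, 1], size=n_subjects,
                                p=[0.2, 0.6, 0.2])
            scores = np.clip(int(round(latent)) + jitter, 1, 5)
        rows.append({"image_id": image_id,
                     **{f"subject_{i + 1}": int(s)
                        for i, s in enumerate(scores)}})
    return pd.DataFrame(rows)


def mos_means(mos: pd.DataFrame) -> np.ndarray:
    """Mean opinion score per image from the subject columns (unrounded)."""
    subj = [c for c in mos.columns if c.startswith("subject_")]
    if not subj:
        raise ValueError("MOS table has no subject_* columns")
    vals = mos[subj].to_numpy(float)
    if vals.min() < 1 or vals.max() > 5:
        raise ValueError("opinion scores must lie in [1, 5]")
    return vals.mean(axis=1)
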