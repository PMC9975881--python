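"""Correlation analysis of movement features against activity-level scores.

Covers the redundancy screen (Pearson correlations between features, with a
prune that keeps only the neck variant of blocks that are near-duplicates
across body keypoints), the Spearman correlation of each retained feature
with the ordinal clinician score including Benjamini–Hochberg correction
within each activity family, descriptive feature characteristics, and the
correlation power analysis used to justify the cohort size.

The power computation uses the Fisher-z approximation with the small-sample
bias correction ``z_r = atanh(r) + r / (2 (n - 1))`` and a critical
correlation derived from the two-sided t critical value at ``n - 2`` degrees
of freedom — the standard approximation implemented by the common power
calculators for correlation tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .features import FEATURE_NAMES
from .io import KEYPOINT_NAMES, NECK

NECK_NAME = KEYPOINT_NAMES[NECK]

PCC_GROUPINGS = (
    "within-activity-across-MFs",
    "across-activities-same-MF",
    "across-keypoints-same-MF-same-activity",
)


def _pairwise_pearson(df: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson matrix; constant columns give NaN cells."""
    df = pd.DataFrame(df)
    out = df.corr(method="pearson", min_periods=min_pairs)
    # A constant column has no defined correlation, including with itself.
    constant = (df.std(skipna=True) == 0) | (df.notna().sum() < min_pairs)
    out.loc[constant, :] = np.nan
    out.loc[:, constant] = np.nan
    return out


def pearson_matrix(
    fm: pd.DataFrame,
    grouping: str,
    activity: str | None = None,
    keypoint: str | None = None,
    feature: str | None = None,
) -> pd.DataFrame:
    """Pearson correlations between feature columns under one of the three
    study groupings.

    ``fm`` is the children x (activity, keypoint, feature) matrix.  The
    grouping fixes two of the three column levels and correlates across the
    third:

    * ``within-activity-across-MFs`` — fix (activity, keypoint), correlate
      the four movement features with each other;
    * ``across-activities-same-MF`` — fix (keypoint, feature), correlate an
      activity with every other activity;
    * ``across-keypoints-same-MF-same-activity`` — fix (activity, feature),
      correlate the body keypoints with each other.
    """
    if grouping not in PCC_GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}; expected one of {PCC_GROUPINGS}")
    if grouping == "within-activity-across-MFs":
        if activity is None or keypoint is None:
            raise ValueError("grouping requires activity and keypoint")
        sub = fm.loc[:, (activity, keypoint)]
    elif grouping == "across-activities-same-MF":
        if keypoint is None or feature is None:
            raise ValueError("grouping requires keypoint and feature")
        sub = fm.xs((keypoint, feature), axis=1, level=("keypoint", "feature"))
        sub.columns = [c for c in sub.columns]
    else:
        if activity is None or feature is None:
            raise ValueError("grouping requires activity and feature")
        sub = fm.loc[:, activity].xs(feature, axis=1, level="feature")
    return _pairwise_pearson(pd.DataFrame(sub))


def spearman_vs_scores(
    feature_column: Sequence[float], scores: Sequence[int]
) -> tuple[float, float]:
    """Spearman rho (average ranks over ties) of a feature against the
    ordinal score, with a two-sided p-value from the t approximation.

    Missing feature values are dropped pairwise; at least 4 complete pairs
    are required and the scores must not be constant on them.
    """
    x = np.asarray(feature_column, dtype=float)
    s = np.asarray(scores, dtype=float)
    if x.shape != s.shape:
        raise ValueError("feature column and scores must align")
    mask = ~np.isnan(x) & ~np.isnan(s)
    x, s = x[mask], s[mask]
    if x.size < 4:
        raise ValueError(f"need >= 4 complete pairs, got {x.size}")
    if np.all(s == s[0]):
        raise ValueError("scores are constant; correlation undefined")
    res = sps.spearmanr(x, s)  # average ranks for ties; t-approximation p
    return float(res.statistic), float(res.pvalue)


def bh_adjust(
    p_values: Sequence[float], families: Sequence[str] | None = None
) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, within each family.

    ``families`` labels each p-value (e.g. by activity); adjustment is
    applied separately per family.  Without labels the whole vector is one
    family.  Adjusted values are monotone in the order statistics and capped
    at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if families is None:
        families = np.zeros(p.size)
    fam = np.asarray(families)
    if fam.shape != p.shape:
        raise ValueError("families must align with p_values")
    for f in pd.unique(fam):
        idx = np.flatnonzero(fam == f)
        valid = idx[~np.isnan(p[idx])]
        if valid.size == 0:
            continue
        out[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return out


def redundancy_prune(
    fm: pd.DataFrame, threshold: float = 0.95, neck: str = NECK_NAME
) -> list[tuple[str, str, str]]:
    """Drop near-duplicate keypoint variants of each feature.

    For each (activity, feature) block, the Pearson correlations between the
    body keypoints are computed; if every pairwise value reaches
    ``threshold`` the variants are interchangeable and only the neck one is
    retained (the neck being the most reliably visible keypoint).  If any
    pair falls below the threshold all keypoints are kept.  Returns the
    retained (activity, keypoint, feature) triples.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    retained: list[tuple[str, str, str]] = []
    activities = fm.columns.get_level_values("activity").unique()
    for activity in activities:
        block = fm.loc[:, activity]
        keypoints = list(block.columns.get_level_values("keypoint").unique())
        for feat in FEATURE_NAMES:
            present = [k for k in keypoints if (k, feat) in block.columns]
            if not present:
                continue
            if len(present) == 1:
                retained.append((activity, present[0], feat))
                continue
            pcc = _pairwise_pearson(block.xs(feat, axis=1, level="feature")[present])
            off = pcc.to_numpy()[~np.eye(len(present), dtype=bool)]
            if np.all(~np.isnan(off)) and np.all(off >= threshold):
                keep = [neck] if neck in present else [present[0]]
            else:
                keep = present
            retained.extend((activity, k, feat) for k in keep)
    return retained


def alpha_for_planned_comparisons(family_alpha: float, k: int) -> float:
    """Bonferroni-style split of a family-wise level over k planned tests."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0.0 < family_alpha < 1.0:
        raise ValueError("family_alpha must lie in (0, 1)")
    return family_alpha / k


def correlation_power(
    n: int, r: float, alpha: float, two_sided: bool = True
) -> float:
    """Power of the test that a Pearson correlation of size ``r`` is nonzero
    at level ``alpha`` with ``n`` paired observations.

    Fisher-z approximation with small-sample bias correction: the effect is
    ``z_r = atanh(r) + r / (2 (n - 1))``; the rejection region comes from the
    t critical value at ``n - 2`` df mapped to a critical correlation
    ``r_c = sqrt(t^2 / (t^2 + n - 2))``; power is the normal probability that
    the observed z statistic (SD ``1 / sqrt(n - 3)``) falls beyond it.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    if not 0.0 < r < 1.0:
        raise ValueError("r must lie in (0, 1)")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    df = n - 2
    tail = alpha / 2 if two_sided else alpha
    t_crit = sps.t.ppf(1.0 - tail, df)
    r_crit = np.sqrt(t_crit**2 / (t_crit**2 + df))
    z_r = np.arctanh(r) + r / (2.0 * (n - 1))
    z_crit = np.arctanh(r_crit)
    scale = np.sqrt(n - 3)
    power = sps.norm.cdf((z_r - z_crit) * scale)
    if two_sided:
        power += sps.norm.cdf(-(z_r + z_crit) * scale)
    return float(power)


def feature_characteristics(values: Sequence[float]) -> dict[str, float]:
    """Descriptive summary of one feature column: range, centre, spread.

    SD uses the sample (n-1) divisor; quartiles use linear interpolation.
    Missing values are dropped; at least 2 observations are required.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise ValueError("need >= 2 values for a summary")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {
        "n": int(x.size),
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "mean": float(np.mean(x)),
        "median": float(med),
        "sd": float(np.std(x, ddof=1)),
        "q1": float(q1),
        "q3": float(q3),
    }


@dataclass
class CorrelationReport:
    """Bundle of the correlation-analysis outputs for one cohort.

    ``scc`` is a long-form table (activity, keypoint, feature, scc, p_raw,
    p_bh, retained); ``pcc`` maps activity -> per-feature keypoint PCC
    matrices; ``power`` records the power-analysis inputs and result.
    """

    scc: pd.DataFrame
    pcc: dict[str, dict[str, pd.DataFrame]]
    retained: list[tuple[str, str, str]]
    power: dict[str, float]
    characteristics: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "meta": self.meta,
            "power": self.power,
            "retained": [list(t) for t in self.retained],
            "scc": self.scc.to_dict(orient="records"),
            "pcc": {
                act: {feat: m.round(6).to_dict() for feat, m in feats.items()}
                for act, feats in self.pcc.items()
            },
        }


def correlation_report(
    fm: pd.DataFrame,
    scores: Mapping[str, int],
    redundancy_threshold: float = 0.95,
    family_alpha: float = 0.05,
    planned_comparisons: int = 4,
    power_r: float = 0.5,
) -> CorrelationReport:
    """Run the full statistical stage on a feature matrix.

    Computes the keypoint-redundancy PCC matrices and prune per activity, the
    Spearman correlation of every feature column with the activity-level
    score with BH adjustment within each activity, descriptive
    characteristics per column, and the correlation power analysis at the
    planned-comparison level ``family_alpha / planned_comparisons``.
    """
    score_vec = np.array([scores[c] for c in fm.index], dtype=float)
    activities = list(fm.columns.get_level_values("activity").unique())

    pcc: dict[str, dict[str, pd.DataFrame]] = {}
    for activity in activities:
        pcc[activity] = {}
        for feat in FEATURE_NAMES:
            try:
                pcc[activity][feat] = pearson_matrix(
                    fm, "across-keypoints-same-MF-same-activity",
                    activity=activity, feature=feat,
                )
            except (KeyError, ValueError):
                continue
    retained = redundancy_prune(fm, threshold=redundancy_threshold)
    retained_set = set(retained)

    rows = []
    for activity, keypoint, feat in fm.columns:
        col = fm[(activity, keypoint, feat)].to_numpy(dtype=float)
        try:
            rho, p = spearman_vs_scores(col, score_vec)
        except ValueError:
            rho, p = np.nan, np.nan
        rows.append(
            {
                "activity": activity,
                "keypoint": keypoint,
                "feature": feat,
                "scc": rho,
                "p_raw": p,
                "retained": (activity, keypoint, feat) in retained_set,
            }
        )
    scc = pd.DataFrame(rows)
    scc["p_bh"] = bh_adjust(scc["p_raw"].to_numpy(), scc["activity"].to_numpy())

    characteristics = pd.DataFrame(
        [
            {"activity": a, "keypoint": k, "feature": f,
             **feature_characteristics(fm[(a, k, f)])}
            for (a, k, f) in fm.columns
            if fm[(a, k, f)].notna().sum() >= 2
        ]
    )

    alpha = alpha_for_planned_comparisons(family_alpha, planned_comparisons)
    n = int(fm.shape[0])
    power = {
        "n": n,
        "r": power_r,
        "alpha": alpha,
        "power": correlation_power(n, power_r, alpha, two_sided=True),
    }
    return CorrelationReport(
        scc=scc,
        pcc=pcc,
        retained=retained,
        power=power,
        characteristics=characteristics,
    )
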