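"""Data-driven sleep phenotyping: Ward clustering and group comparisons.

The cohort is dichotomized by agglomerative hierarchical clustering (Ward
criterion on Euclidean distances in the standardized six-feature space) cut
at two clusters.  The cluster with the larger mean standardized sleep-hour
variability is labelled group B -- the "unstable sleep" phenotype -- which
makes the labelling deterministic rather than dependent on dendrogram
orientation.  Groups are then characterized feature by feature with Welch
(unequal-variance) t tests and Hedges g (small-sample corrected), with the
IIV features log-transformed first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage

from .habitual_stats import (
    FEATURE_COLUMNS,
    IIV_COLUMNS,
    IntraindividualStats,
    log_transform_iiv,
)

GROUP_A = "A"
GROUP_B = "B"


@dataclass
class ClusterAssignment:
    participant_id: str
    group_label: str  # "A" (stable) | "B" (unstable)
    linkage_height: float  # merge height at the 2-cluster cut


@dataclass
class GroupComparison:
    feature: str
    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float
    hedges_g: float  # signed, B minus A

    def __post_init__(self) -> None:
        if not np.isfinite(self.hedges_g):
            raise ValueError("Hedges g must be finite")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p value must lie in [0, 1]")


def ward_dichotomize(features: pd.DataFrame) -> list[ClusterAssignment]:
    """Cut a Ward dendrogram on the standardized feature matrix at k=2.

    ``features`` is the output of :func:`~sleepjitai.habitual_stats.feature_matrix`
    (participants in the index, the six standardized columns).  Uses the
    Ward criterion on Euclidean distances (the ``ward.D2`` convention).
    Group B is the cluster with the larger mean standardized ``iiv_sh``.
    """
    if features.shape[0] < 4:
        raise ValueError("clustering requires at least 4 participants")
    if list(features.columns) != list(FEATURE_COLUMNS):
        raise ValueError(f"expected feature columns {FEATURE_COLUMNS}")
    z = linkage(features.to_numpy(), method="ward")
    labels = fcluster(z, t=2, criterion="maxclust")
    height = float(z[-1, 2])
    mean_iiv = {k: features["iiv_sh"].to_numpy()[labels == k].mean() for k in (1, 2)}
    b_cluster = max(mean_iiv, key=mean_iiv.get)
    return [
        ClusterAssignment(
            participant_id=pid,
            group_label=GROUP_B if lab == b_cluster else GROUP_A,
            linkage_height=height,
        )
        for pid, lab in zip(features.index, labels)
    ]


def assignments_to_frame(assignments: Sequence[ClusterAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [a.participant_id for a in assignments],
            "group_label": [a.group_label for a in assignments],
            "linkage_height": [a.linkage_height for a in assignments],
        }
    )


def hedges_g(x: np.ndarray, y: np.ndarray) -> float:
    """Standardized mean difference of y vs x with small-sample correction.

    g = J * (mean(y) - mean(x)) / s_pooled,  J = 1 - 3 / (4 df - 1),
    df = n_x + n_y - 2, pooled SD with n-1 weights.
    """
    nx, ny = len(x), len(y)
    df = nx + ny - 2
    if df <= 0:
        raise ValueError("each group needs at least 2 members")
    s_pooled = np.sqrt(((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / df)
    if s_pooled == 0:
        raise ValueError("pooled SD is 0; effect size undefined")
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    return float(j * (np.mean(y) - np.mean(x)) / s_pooled)


def compare_groups(
    stats: Sequence[IntraindividualStats],
    assignments: Sequence[ClusterAssignment],
) -> list[GroupComparison]:
    """Welch t tests and Hedges g per feature between groups A and B.

    IIV features are log-transformed before testing (normality); means are
    reported on the transformed scale for those features.  Effects are
    signed B minus A, so a positive g on an IIV feature means group B is
    more variable.
    """
    group_of = {a.participant_id: a.group_label for a in assignments}
    groups = {GROUP_A: [], GROUP_B: []}
    for s in stats:
        if s.participant_id in group_of:
            groups[group_of[s.participant_id]].append(s)
    if min(len(groups[GROUP_A]), len(groups[GROUP_B])) < 2:
        raise ValueError("both groups need at least 2 members")

    def values(feature: str, members: list[IntraindividualStats]) -> np.ndarray:
        if feature == "iim_mid":
            v = np.array([m.iim_mid_since_noon for m in members])
        else:
            v = np.array([getattr(m, feature) for m in members])
        if feature in IIV_COLUMNS:
            v = log_transform_iiv(v)
        return v

    out = []
    for feature in FEATURE_COLUMNS:
        a = values(feature, groups[GROUP_A])
        b = values(feature, groups[GROUP_B])
        t, p = sps.ttest_ind(b, a, equal_var=False)
        out.append(
            GroupComparison(
                feature=feature,
                mean_a=float(a.mean()),
                mean_b=float(b.mean()),
                t_statistic=float(t),
                p_value=float(p),
                hedges_g=hedges_g(a, b),
            )
        )
    return out


def comparisons_to_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": [c.feature for c in comparisons],
            "mean_a": [c.mean_a for c in comparisons],
            "mean_b": [c.mean_b for c in comparisons],
            "t": [c.t_statistic for c in comparisons],
            "p": [c.p_value for c in comparisons],
            "hedges_g": [c.hedges_g for c in comparisons],
        }
    )
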