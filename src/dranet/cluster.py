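"""Sample grouping by DRA-gene expression and by sensitivity thresholds.

Two complementary groupings of a cell-line panel:

* :func:`cluster_samples` — agglomerative Ward clustering (Euclidean
  distance between sample expression profiles over the DRA genes), cut into
  two clusters; the cluster with the higher mean sensitivity is labelled
  the "sensitive group", the other "non-sensitive".
* :func:`trichotomize` — a mean ± k·SD rule (default k = 0.8) splitting
  samples into sensitive / indeterminate / resistant classes; the
  indeterminate window spans 2k standard deviations around the mean and
  those samples are excluded from connectivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .exceptions import DegenerateInputError, InputError

__all__ = ["GroupAssignment", "cluster_samples", "compare_groups",
           "ResponseClasses", "trichotomize"]

SENSITIVE = "sensitive"
NON_SENSITIVE = "non_sensitive"
RESISTANT = "resistant"
INDETERMINATE = "indeterminate"


@dataclass
class GroupAssignment:
    """Two-group Ward partition of samples with its linkage record."""

    labels: pd.Series            # sample id -> {sensitive, non_sensitive}
    linkage_matrix: np.ndarray   # scipy condensed linkage of the agglomeration
    order: list[str]             # dendrogram leaf order of sample ids

    def members(self, label: str) -> list[str]:
        return self.labels.index[self.labels == label].tolist()


def cluster_samples(expr: pd.DataFrame, sensitivity: pd.Series) -> GroupAssignment:
    """Ward/Euclidean clustering of samples on their expression profiles.

    ``expr`` is genes × samples, usually restricted to the DRA genes of one
    drug.  The two-cluster cut is labelled by mean sensitivity: the cluster
    whose members have the larger mean is the sensitive group.
    """
    if expr.shape[1] < 2:
        raise InputError("need at least 2 samples to cluster")
    if expr.shape[0] < 1:
        raise InputError("need at least 1 gene to cluster")
    profiles = expr.to_numpy(dtype=float).T  # samples × genes
    Z = linkage(profiles, method="ward", metric="euclidean")
    cut = fcluster(Z, t=2, criterion="maxclust")
    sens = sensitivity.reindex(expr.columns).astype(float)
    means = {c: sens[cut == c].mean() for c in np.unique(cut)}
    if len(means) < 2:
        raise InputError("clustering produced a single group")
    sensitive_cluster = max(means, key=lambda c: means[c])
    labels = pd.Series(
        np.where(cut == sensitive_cluster, SENSITIVE, NON_SENSITIVE),
        index=expr.columns, name="group",
    )
    from scipy.cluster.hierarchy import leaves_list
    order = [expr.columns[i] for i in leaves_list(Z)]
    return GroupAssignment(labels=labels, linkage_matrix=Z, order=order)


def compare_groups(sensitivity: pd.Series, assignment: GroupAssignment):
    """Two-sample Student's t-test (pooled variance) between the groups.

    Returns ``(t_statistic, p_value, (n_sensitive, n_non_sensitive))`` with a
    two-sided p.  The statistic is oriented as sensitive minus non-sensitive.
    """
    sens = sensitivity.astype(float)
    a = sens[assignment.members(SENSITIVE)].dropna()
    b = sens[assignment.members(NON_SENSITIVE)].dropna()
    if len(a) < 2 or len(b) < 2:
        raise DegenerateInputError("both groups need >= 2 members for the t-test")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p), (len(a), len(b))


@dataclass
class ResponseClasses:
    """Sensitive / indeterminate / resistant partition by the ±k·SD rule."""

    classes: pd.Series   # sample id -> class label
    mean: float
    sd: float
    k: float

    def members(self, label: str) -> list[str]:
        return self.classes.index[self.classes == label].tolist()

    @property
    def counts(self) -> dict[str, int]:
        return {lab: int((self.classes == lab).sum())
                for lab in (SENSITIVE, INDETERMINATE, RESISTANT)}


def trichotomize(sensitivity: pd.Series, k: float = 0.8,
                 invert_labels: bool = False) -> ResponseClasses:
    """Split samples into resistant / sensitive / indeterminate classes.

    Samples at least ``k`` sample standard deviations (n−1 denominator)
    above the mean are resistant, at least ``k`` SD below are sensitive, and
    the window of 2k SD around the mean is indeterminate.  Boundary values
    exactly at mean ± k·SD land in the extreme classes.  ``invert_labels``
    swaps the resistant/sensitive names for conventions where a high
    activity area means a responsive line.
    """
    sens = pd.Series(sensitivity).astype(float).dropna()
    if len(sens) < 3:
        raise DegenerateInputError("need >= 3 finite sensitivity values")
    mean = float(sens.mean())
    sd = float(sens.std(ddof=1))
    if sd == 0:
        raise DegenerateInputError("zero standard deviation: all values identical")
    hi, lo = (SENSITIVE, RESISTANT) if invert_labels else (RESISTANT, SENSITIVE)
    classes = pd.Series(
        np.where(sens >= mean + k * sd, hi,
                 np.where(sens <= mean - k * sd, lo, INDETERMINATE)),
        index=sens.index, name="response_class",
    )
    return ResponseClasses(classes=classes, mean=mean, sd=sd, k=float(k))
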