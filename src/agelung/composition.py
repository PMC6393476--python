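"""Compositional analysis of cell-type frequencies across mice.

Cell-type proportions are compositional: an increase of one type is
indistinguishable from a decrease of another.  The pipeline therefore
tests a global composition difference — shrinkage transform, mouse-wise
euclidean distances, non-metric MDS to 2 dimensions, and a rank-sum test
of coordinate 1 against age — and summarizes per-type shifts descriptively
as old-mouse proportions minus the young median.  A binomial GLM handles
single-cluster membership fractions (e.g. the proliferative cluster).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.spatial.distance as ssd
import statsmodels.api as sm

from ._stats import rank_sum_test


@dataclass
class CompositionReport:
    coordinates: pd.DataFrame  # mice x 2 MDS coordinates + age
    stress: float
    coord1_p: float
    relative_change: pd.Series  # per cell type, median over old mice


def proportions_from_annotation(annotation: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Mice x cell-types proportion table plus per-mouse age labels."""
    cells = annotation.dropna(subset=["cell_type"])
    counts = cells.pivot_table(
        index="mouse_id", columns="cell_type", values="barcode", aggfunc="count", fill_value=0
    )
    props = counts.div(counts.sum(axis=1), axis=0)
    ages = cells.groupby("mouse_id")["age"].first().reindex(props.index)
    return props, ages


def shrink_proportions(props: pd.DataFrame) -> pd.DataFrame:
    """Compress proportions away from 0 and 1: y' = (y (n-1) + 1/K) / n.

    n is the number of mice and K the number of cell types; row sums are
    conserved and 1/K is a fixed point.
    """
    n, K = props.shape
    if n < 2:
        raise ValueError("shrinkage needs at least two mice")
    values = props.to_numpy(dtype=float)
    if np.any(values < 0) or np.any(np.abs(values.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("rows must be probability vectors before shrinkage")
    return pd.DataFrame(
        (values * (n - 1) + 1.0 / K) / n, index=props.index, columns=props.columns
    )


def classical_mds(dist: np.ndarray, k: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS via double-centered eigendecomposition."""
    d2 = np.asarray(dist, dtype=float) ** 2
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:k]
    coords = eigvec[:, order] * np.sqrt(np.maximum(eigval[order], 0.0))
    return coords


def mds_age_test(
    transformed: pd.DataFrame,
    age: pd.Series,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> CompositionReport:
    """Non-metric MDS of mouse-wise distances plus a coordinate-1 age test.

    Kruskal MDS is initialized from the classical solution; the exact
    two-sided rank-sum test compares coordinate 1 between age groups.
    Coordinate 1 is oriented so that the young mean is <= the old mean.
    """
    age = age.reindex(transformed.index)
    n_young = int((age == "young").sum())
    n_old = int((age == "old").sum())
    if min(n_young, n_old) < 3:
        raise ValueError("need at least three mice per age group")
    dist = ssd.squareform(ssd.pdist(transformed.to_numpy(dtype=float)))
    init = classical_mds(dist, k=2)
    coords, stress = _nonmetric_mds(dist, init, max_iter=max_iter, tol=tol)
    # orient: young mean <= old mean on coordinate 1
    young_mask = (age == "young").to_numpy()
    if coords[young_mask, 0].mean() > coords[~young_mask, 0].mean():
        coords[:, 0] *= -1.0
    _, p = rank_sum_test(coords[~young_mask, 0], coords[young_mask, 0])
    frame = pd.DataFrame(coords, index=transformed.index, columns=["coord1", "coord2"])
    frame["age"] = age
    return CompositionReport(
        coordinates=frame,
        stress=float(stress),
        coord1_p=float(p),
        relative_change=pd.Series(dtype=float),
    )


def _nonmetric_mds(dist, init, max_iter, tol):
    from sklearn.manifold import MDS

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mds = MDS(
                n_components=2,
                metric=False,
                dissimilarity="precomputed",
                max_iter=max_iter,
                eps=tol,
                n_init=1,
                normalized_stress=True,
                random_state=0,
            )
            coords = mds.fit_transform(dist, init=init)
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite MDS solution")
        return coords, mds.stress_
    except Exception as exc:  # fall back to the classical embedding
        warnings.warn(f"non-metric MDS failed ({exc}); using classical solution")
        return init.copy(), np.nan


def relative_change(props: pd.DataFrame, age: pd.Series) -> tuple[pd.DataFrame, pd.Series]:
    """Old-mouse proportions minus the young median, per cell type.

    Returns the per-(old mouse, type) delta table and its median-over-old-
    mice summary.
    """
    age = age.reindex(props.index)
    if (age == "young").sum() < 1 or (age == "old").sum() < 1:
        raise ValueError("need at least one mouse per age")
    young_median = props.loc[age == "young"].median(axis=0)
    deltas = props.loc[age == "old"].sub(young_median, axis=1)
    return deltas, deltas.median(axis=0)


def cluster_fraction_test(
    membership: np.ndarray,
    age: np.ndarray,
    mouse: np.ndarray | None = None,
) -> tuple[float, float, bool]:
    """Binomial GLM of cluster membership on age (logit link).

    Returns (log odds ratio of membership in old vs young, two-sided p,
    separation flag).  With complete separation the Wald test is
    uninformative, so p falls back to Fisher's exact test on the 2x2
    counts and the flag is set.
    """
    membership = np.asarray(membership, dtype=bool)
    age = np.asarray(age, dtype=object)
    present = set(age.tolist())
    if not {"young", "old"} <= present:
        raise ValueError("both ages must be present")
    is_old = (age == "old").astype(float)
    k_young = int(membership[age == "young"].sum())
    n_young = int((age == "young").sum())
    k_old = int(membership[age == "old"].sum())
    n_old = int((age == "old").sum())
    separated = k_young in (0, n_young) or k_old in (0, n_old)
    if separated:
        import scipy.stats as st

        table = [[k_old, n_old - k_old], [k_young, n_young - k_young]]
        _, p = st.fisher_exact(table, alternative="two-sided")
        with np.errstate(divide="ignore"):
            log_odds = float(
                np.log((k_old / max(n_old - k_old, 1e-12)) / max(k_young / max(n_young - k_young, 1e-12), 1e-12))
            )
        return log_odds, float(p), True
    exog = sm.add_constant(is_old)
    model = sm.GLM(membership.astype(float), exog, family=sm.families.Binomial())
    fit = model.fit()
    return float(fit.params[1]), float(fit.pvalues[1]), False
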