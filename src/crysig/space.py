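"""Low-dimensional acoustic space of cry MPS and between-baby shrinkage statistics.

Each cry's modulation power spectrum is flattened to a vector and reduced by
PCA.  A 2D map of per-baby average positions (PC1, PC2) visualizes the spread
of individual vocal signatures per condition; the shrinkage of that spread in
the pain condition is quantified as the drop in mean distance-to-centroid,
tested with a paired t across babies.  A two-class linear discriminant on the
20-PC projections yields the single axis that best separates discomfort from
pain cries, and trajectory correlations relate that axis to the identity-
bearing principal components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = [
    "SpaceError",
    "PCBasis",
    "AcousticMap",
    "ShrinkageResult",
    "DiscriminantAxis",
    "TrajectoryStats",
    "fit_mps_pca",
    "project",
    "per_group_average",
    "map_babies",
    "centroid_shrinkage_test",
    "condition_discriminant",
    "trajectory_correlation",
]


class SpaceError(ValueError):
    """Invalid input to an acoustic-space computation."""


@dataclass
class PCBasis:
    """Centered PCA basis with a reproducible sign convention (the largest-
    magnitude loading of each component is positive)."""

    mean: np.ndarray
    components: np.ndarray  # (n_components, n_features), orthonormal rows
    explained_variance_ratio: np.ndarray
    fitted_on: str


@dataclass
class AcousticMap:
    """Per baby x condition coordinates in the (PC1, PC2) plane."""

    coords: pd.DataFrame  # columns: baby_id, condition, PC1, PC2
    centroids: dict  # condition -> (2,) array
    dispersions: dict  # condition -> mean distance to centroid


@dataclass
class ShrinkageResult:
    distances_a: np.ndarray
    distances_b: np.ndarray
    mean_a: float
    mean_a_2se: float
    mean_b: float
    mean_b_2se: float
    mean_difference: float
    t_statistic: float
    df: int
    p_value: float


@dataclass
class DiscriminantAxis:
    """Unit-norm axis in PC space separating the two conditions, oriented so
    the pain class projects positive relative to discomfort."""

    loading: np.ndarray
    per_cry_projection: np.ndarray
    class_means: dict
    conditions: np.ndarray


@dataclass
class TrajectoryStats:
    r_discomfort: float
    p_discomfort: float
    r_pain: float
    p_pain: float
    r_difference: float
    p_difference: float
    arrows: pd.DataFrame  # baby_id, x_discomfort, y_discomfort, x_pain, y_pain


def fit_mps_pca(vectors: np.ndarray, n_components: int, fitted_on: str = "") -> PCBasis:
    """Centered PCA of flattened MPS vectors.

    Components are sign-fixed so that the largest-magnitude loading of each is
    positive, making maps and correlations reproducible across refits.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2:
        raise SpaceError("vectors must be a 2D array (n_samples x n_features)")
    if X.shape[0] < n_components + 1:
        raise SpaceError(
            f"need more than {n_components} samples to fit {n_components} components; got {X.shape[0]}"
        )
    pca = PCA(n_components=n_components, svd_solver="auto", random_state=0)
    pca.fit(X)
    comps = pca.components_.copy()
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return PCBasis(
        mean=pca.mean_,
        components=comps,
        explained_variance_ratio=pca.explained_variance_ratio_,
        fitted_on=fitted_on,
    )


def project(basis: PCBasis, vectors: np.ndarray) -> np.ndarray:
    """Coordinates of vectors in the PC basis."""
    X = np.atleast_2d(np.asarray(vectors, dtype=float))
    return (X - basis.mean) @ basis.components.T


def per_group_average(
    vectors: np.ndarray, baby_ids, conditions
) -> tuple[np.ndarray, pd.DataFrame]:
    """Average vector per (baby, condition); returns the matrix and its labels."""
    df = pd.DataFrame({"baby_id": baby_ids, "condition": conditions})
    groups = df.groupby(["baby_id", "condition"], sort=True).indices
    labels, rows = [], []
    for (baby, cond), idx in groups.items():
        labels.append({"baby_id": baby, "condition": cond})
        rows.append(np.asarray(vectors)[idx].mean(axis=0))
    return np.vstack(rows), pd.DataFrame(labels)


def map_babies(vectors: np.ndarray, baby_ids, conditions, basis: PCBasis) -> AcousticMap:
    """Project per-baby average MPS per condition onto (PC1, PC2).

    Babies lacking one of the two conditions are excluded with a warning.
    """
    avg, labels = per_group_average(vectors, baby_ids, conditions)
    coords2 = project(basis, avg)[:, :2]
    df = labels.copy()
    df["PC1"] = coords2[:, 0]
    df["PC2"] = coords2[:, 1]
    counts = df.groupby("baby_id")["condition"].nunique()
    incomplete = counts[counts < 2].index.tolist()
    if incomplete:
        warnings.warn(f"babies missing a condition excluded from map: {incomplete}")
        df = df[~df["baby_id"].isin(incomplete)].reset_index(drop=True)
    centroids, dispersions = {}, {}
    for cond, sub in df.groupby("condition"):
        c = sub[["PC1", "PC2"]].to_numpy().mean(axis=0)
        centroids[cond] = c
        dispersions[cond] = float(
            np.linalg.norm(sub[["PC1", "PC2"]].to_numpy() - c, axis=1).mean()
        )
    return AcousticMap(coords=df, centroids=centroids, dispersions=dispersions)


def centroid_shrinkage_test(
    amap: AcousticMap, condition_a: str = "discomfort", condition_b: str = "pain"
) -> ShrinkageResult:
    """Paired t test of per-baby distance-to-centroid between conditions.

    Distances are Euclidean in the (PC1, PC2) plane, each condition measured
    against its own centroid; a positive mean difference (a minus b) with small
    p indicates shrinkage of the acoustic space in condition b.
    """
    df = amap.coords
    babies = sorted(set(df["baby_id"]))
    if len(babies) < 3:
        raise SpaceError("paired centroid test requires at least 3 babies")
    dist = {}
    for cond in (condition_a, condition_b):
        sub = df[df["condition"] == cond].set_index("baby_id")
        if not set(babies) <= set(sub.index):
            raise SpaceError(f"every baby must have condition {cond!r}")
        xy = sub.loc[babies, ["PC1", "PC2"]].to_numpy()
        dist[cond] = np.linalg.norm(xy - amap.centroids[cond], axis=1)
    da, db_ = dist[condition_a], dist[condition_b]
    n = len(babies)
    diff = da - db_
    if np.std(diff, ddof=1) == 0:
        # degenerate: identical per-baby differences
        t_stat, p = (0.0, 1.0) if diff.mean() == 0 else (np.inf * np.sign(diff.mean()), 0.0)
    else:
        t_stat, p = stats.ttest_rel(da, db_)
    return ShrinkageResult(
        distances_a=da,
        distances_b=db_,
        mean_a=float(da.mean()),
        mean_a_2se=float(2 * da.std(ddof=1) / np.sqrt(n)),
        mean_b=float(db_.mean()),
        mean_b_2se=float(2 * db_.std(ddof=1) / np.sqrt(n)),
        mean_difference=float(da.mean() - db_.mean()),
        t_statistic=float(t_stat),
        df=n - 1,
        p_value=float(p),
    )


def condition_discriminant(projections: np.ndarray, conditions) -> DiscriminantAxis:
    """Single linear-discriminant axis separating the two conditions in PC space."""
    X = np.asarray(projections, dtype=float)
    cond = np.asarray(conditions)
    classes = sorted(set(cond))
    if len(classes) != 2:
        raise SpaceError("condition discriminant requires exactly two classes")
    lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage="auto")
    lda.fit(X, cond)
    w = lda.coef_[0] if lda.coef_.ndim > 1 else lda.coef_
    w = w / np.linalg.norm(w)
    proj = X @ w
    means = {c: float(proj[cond == c].mean()) for c in classes}
    if "pain" in means and "discomfort" in means and means["pain"] < means["discomfort"]:
        w, proj = -w, -proj
        means = {c: -m for c, m in means.items()}
    return DiscriminantAxis(
        loading=w, per_cry_projection=proj, class_means=means, conditions=cond
    )


def trajectory_correlation(
    amap: AcousticMap, axis_coords: pd.DataFrame, pc_index: int = 1
) -> TrajectoryStats:
    """Pearson correlation between per-baby discriminant-axis projections (x)
    and PC coordinates (y), per condition and for the pain-minus-discomfort
    differences.

    ``axis_coords`` needs columns baby_id, condition, projection.
    """
    pc_col = f"PC{pc_index}"
    if pc_col not in amap.coords.columns:
        raise SpaceError(f"map has no column {pc_col}")
    babies = sorted(set(amap.coords["baby_id"]) & set(axis_coords["baby_id"]))
    if len(babies) < 5:
        raise SpaceError("trajectory correlation requires at least 5 babies")
    xs, ys = {}, {}
    for cond in ("discomfort", "pain"):
        ax = axis_coords[axis_coords["condition"] == cond].set_index("baby_id")
        mp = amap.coords[amap.coords["condition"] == cond].set_index("baby_id")
        xs[cond] = ax.loc[babies, "projection"].to_numpy(dtype=float)
        ys[cond] = mp.loc[babies, pc_col].to_numpy(dtype=float)
    for cond in ("discomfort", "pain"):
        if np.std(xs[cond]) == 0 or np.std(ys[cond]) == 0:
            raise SpaceError("zero variance in a coordinate; correlation undefined")

    def _r(x, y):
        res = stats.pearsonr(x, y)
        return float(res.statistic), float(res.pvalue)

    rd, pd_ = _r(xs["discomfort"], ys["discomfort"])
    rp, pp = _r(xs["pain"], ys["pain"])
    rdiff, pdiff = _r(
        xs["discomfort"] - xs["pain"], ys["discomfort"] - ys["pain"]
    )
    arrows = pd.DataFrame(
        {
            "baby_id": babies,
            "x_discomfort": xs["discomfort"],
            "y_discomfort": ys["discomfort"],
            "x_pain": xs["pain"],
            "y_pain": ys["pain"],
        }
    )
    return TrajectoryStats(
        r_discomfort=rd,
        p_discomfort=pd_,
        r_pain=rp,
        p_pain=pp,
        r_difference=rdiff,
        p_difference=pdiff,
        arrows=arrows,
    )
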