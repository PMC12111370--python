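"""Stage-1 screening: PCA of the spectral matrix and statistical description
of the principal components by categorical clinical factors.

The spectral matrix holds one row per sample (portion-averaged by default)
and one column per retained wavenumber.  Components are described in the
style of the R multivariate ecosystem: one-way ANOVA of the scores on each
factor (F, R^2, p), per-level barycenter estimates with contrast t-tests,
v-test values linking factor levels to quantitative variables, and Euclidean
distances between level barycenters in the retained score space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .spectrum import Spectrum


@dataclass
class SpectralMatrix:
    """Samples x wavenumbers intensity matrix with row metadata."""

    values: pd.DataFrame  # rows: sample ids, columns: wavenumbers (float)
    factors: pd.DataFrame  # rows: sample ids, columns: categorical factors

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("spectral matrix contains missing values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.values.columns.to_numpy(dtype=float)


@dataclass
class PCAResult:
    """Eigen-decomposition of the (centered, optionally standardized) matrix."""

    eigenvalues: np.ndarray
    explained_pct: np.ndarray
    cumulative_pct: np.ndarray
    scores: pd.DataFrame  # samples x PCs
    loadings: pd.DataFrame  # wavenumbers x PCs
    scaled: bool
    column_means: np.ndarray
    column_scales: np.ndarray

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size


@dataclass
class FactorAssociation:
    """ANOVA and per-level descriptions of each PC by each factor."""

    anova: pd.DataFrame  # pc, factor, F, R2, p
    levels: pd.DataFrame  # pc, factor, level, estimate, t, p


@dataclass
class DistanceTable:
    """Level barycenter geometry in the retained score space."""

    to_center: dict[str, pd.Series]  # factor -> level -> distance to overall center
    between: dict[str, pd.DataFrame]  # factor -> level x level distance matrix
    n_pcs: int


def build_matrix(
    spectra: list[Spectrum],
    band: tuple[float, float] = (1185.0, 1330.0),
    average_portions: bool = True,
    factors: pd.DataFrame | None = None,
) -> SpectralMatrix:
    """Assemble the spectral matrix from preprocessed spectra.

    All spectra must share one grid.  With `average_portions` the portions of
    each sample are averaged into a single row (samples are characterized by
    their average spectral profile); otherwise each portion is a row indexed
    ``sample_id/portion_id``.
    """
    if not spectra:
        raise ValueError("no spectra given")
    grid = spectra[0].wavenumbers
    for s in spectra[1:]:
        if s.wavenumbers.shape != grid.shape or not np.allclose(s.wavenumbers, grid):
            raise ValueError("spectra are not on a common grid; preprocess first")
    mask = (grid >= band[0]) & (grid <= band[1])
    if not mask.any():
        raise ValueError("band does not overlap the common grid")
    cols = grid[mask]
    rows: dict[str, list[np.ndarray]] = {}
    order: list[str] = []
    for s in spectra:
        if average_portions:
            key = str(s.sample_id)
        else:
            key = f"{s.sample_id}/{s.portion_id}"
        if key not in rows:
            rows[key] = []
            order.append(key)
        rows[key].append(s.absorbance[mask])
    values = pd.DataFrame(
        [np.mean(rows[k], axis=0) for k in order], index=order, columns=cols
    )
    if factors is None:
        factors = pd.DataFrame(index=values.index)
    else:
        if average_portions:
            factors = factors.loc[values.index]
        else:
            base = [k.rsplit("/", 1)[0] for k in order]
            factors = factors.loc[base].set_index(values.index)
    return SpectralMatrix(values=values, factors=factors)


def run_pca(matrix: SpectralMatrix, scale_unit: bool = True) -> PCAResult:
    """PCA via SVD of the centered (and optionally standardized) matrix.

    With `scale_unit` the columns are divided by their sample standard
    deviation, making the eigenvalues those of the correlation matrix (the
    convention under which the Kaiser criterion applies).  Zero-variance
    columns are dropped with a warning in that case.
    """
    X = matrix.values.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 rows")
    cols = matrix.values.columns
    means = X.mean(axis=0)
    Xc = X - means
    if scale_unit:
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance columns before "
                "correlation-matrix PCA",
                RuntimeWarning,
                stacklevel=2,
            )
            Xc, sd, cols, means = Xc[:, keep], sd[keep], cols[keep], means[keep]
        scales = sd
        Xc = Xc / sd
    else:
        scales = np.ones(Xc.shape[1])
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    explained = 100.0 * eigenvalues / eigenvalues.sum()
    pcs = [f"PC{i + 1}" for i in range(eigenvalues.size)]
    scores = pd.DataFrame(U * s, index=matrix.values.index, columns=pcs)
    loadings = pd.DataFrame(Vt.T, index=cols, columns=pcs)
    return PCAResult(
        eigenvalues=eigenvalues,
        explained_pct=explained,
        cumulative_pct=np.cumsum(explained),
        scores=scores,
        loadings=loadings,
        scaled=scale_unit,
        column_means=means,
        column_scales=np.asarray(scales),
    )


def kaiser_retain(eigenvalues: np.ndarray, scale_unit: bool = True) -> int:
    """Number of components with eigenvalue > 1 (Kaiser criterion).

    The criterion is meaningful for correlation-matrix eigenvalues; a warning
    is emitted otherwise, and when no eigenvalue exceeds 1 (fall back to the
    scree elbow in that case).
    """
    if not scale_unit:
        warnings.warn(
            "Kaiser criterion applies to correlation-matrix eigenvalues; "
            "run PCA with scale_unit=True",
            RuntimeWarning,
            stacklevel=2,
        )
    k = int(np.sum(np.asarray(eigenvalues) > 1.0))
    if k == 0:
        warnings.warn(
            "no eigenvalue exceeds 1; fall back to the scree elbow",
            RuntimeWarning,
            stacklevel=2,
        )
    return k


def elbow_retain(explained_pct: np.ndarray) -> int:
    """Scree-elbow retention: keep components up to the sharpest bend.

    The bend is located at the maximum acceleration (second difference) of
    the explained-percentage profile, i.e. where the curve flattens onto the
    floor of negligible components.
    """
    e = np.asarray(explained_pct, dtype=float)
    if e.size < 3:
        return e.size
    accel = e[:-2] - 2.0 * e[1:-1] + e[2:]
    return int(np.argmax(accel)) + 2


def describe_dimension(
    pca: PCAResult,
    factors: pd.DataFrame,
    n_pcs: int | None = None,
) -> FactorAssociation:
    """Associate each principal component with each categorical factor.

    Per (PC, factor): one-way ANOVA of the scores on the factor levels
    (F statistic, R^2 = SS_between / SS_total, p).  Per level: estimate =
    level mean score - grand mean, with a contrast t-test using the ANOVA
    residual variance, se = sqrt(MSW * (1/n_level - 1/N)) and df = N - k.
    That contrast is computable even for single-observation levels.
    Factors with a single observed level are skipped with a warning.
    """
    n_pcs = n_pcs or min(5, pca.n_components)
    scores = pca.scores.iloc[:, :n_pcs]
    factors = factors.loc[scores.index]
    anova_rows, level_rows = [], []
    for pc in scores.columns:
        y = scores[pc].to_numpy()
        N = y.size
        grand = y.mean()
        sst = float(np.sum((y - grand) ** 2))
        for factor in factors.columns:
            labels = factors[factor].astype(str).to_numpy()
            levels, counts = np.unique(labels, return_counts=True)
            k = levels.size
            if k < 2:
                warnings.warn(
                    f"factor {factor!r} has a single level; skipped",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            if k >= N:
                warnings.warn(
                    f"factor {factor!r}: as many levels as samples; skipped",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            means = {lv: y[labels == lv].mean() for lv in levels}
            ssb = float(sum(c * (means[lv] - grand) ** 2 for lv, c in zip(levels, counts)))
            ssw = sst - ssb
            df1, df2 = k - 1, N - k
            msw = ssw / df2
            if msw <= 0 or sst <= 0:
                F = np.inf if ssb > 0 else 0.0
                p = 0.0 if ssb > 0 else 1.0
                r2 = 1.0 if sst > 0 and ssw <= 0 else 0.0
            else:
                F = (ssb / df1) / msw
                p = float(stats.f.sf(F, df1, df2))
                r2 = ssb / sst
            anova_rows.append(
                {"pc": pc, "factor": factor, "F": float(F), "R2": float(r2), "p": p}
            )
            for lv, c in zip(levels, counts):
                est = means[lv] - grand
                var = msw * (1.0 / c - 1.0 / N)
                if var > 0:
                    t = est / np.sqrt(var)
                    pt = float(2.0 * stats.t.sf(abs(t), df2))
                else:
                    t, pt = (0.0, 1.0) if est == 0 else (np.inf * np.sign(est), 0.0)
                level_rows.append(
                    {
                        "pc": pc, "factor": factor, "level": lv, "n": int(c),
                        "estimate": float(est), "t": float(t), "p": pt,
                    }
                )
    return FactorAssociation(
        anova=pd.DataFrame(anova_rows),
        levels=pd.DataFrame(level_rows),
    )


def v_test(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Standardized deviation of each level mean from the overall mean.

    v = (mean_level - mean) / sqrt((s^2 / n_level) * (N - n_level) / (N - 1))
    with s^2 the overall (population) variance; the two-sided p comes from
    the standard normal.  The sign gives the direction of the deviation.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.size != labels.size:
        raise ValueError("values and labels must be aligned")
    N = values.size
    if N < 2:
        raise ValueError("v-test needs at least 2 observations")
    mean = values.mean()
    var = values.var(ddof=0)
    if var <= 0:
        raise ValueError("v-test undefined: overall variance is zero")
    rows = []
    for lv in np.unique(labels):
        sel = values[labels == lv]
        n_l = sel.size
        if n_l == N:
            v, p = 0.0, 1.0
        else:
            se = np.sqrt((var / n_l) * (N - n_l) / (N - 1))
            v = float((sel.mean() - mean) / se)
            p = float(2.0 * stats.norm.sf(abs(v)))
        rows.append({"level": lv, "n": int(n_l), "v": v, "p": p})
    return pd.DataFrame(rows).set_index("level")


def level_distances(
    pca: PCAResult,
    factors: pd.DataFrame,
    n_pcs: int = 2,
) -> DistanceTable:
    """Euclidean geometry of factor-level barycenters in score space.

    For each factor: the barycenter of the scores of every non-empty level in
    the first `n_pcs` dimensions, its distance from the overall center (the
    origin, since scores are column-centered), and the full level x level
    distance matrix.
    """
    if n_pcs > pca.n_components:
        raise ValueError(f"n_pcs={n_pcs} exceeds available components {pca.n_components}")
    S = pca.scores.iloc[:, :n_pcs]
    factors = factors.loc[S.index]
    to_center: dict[str, pd.Series] = {}
    between: dict[str, pd.DataFrame] = {}
    for factor in factors.columns:
        labels = factors[factor].astype(str)
        bary = S.groupby(labels).mean()
        if bary.empty:
            continue
        to_center[factor] = pd.Series(
            np.linalg.norm(bary.to_numpy(), axis=1), index=bary.index, name="distance"
        )
        diff = bary.to_numpy()[:, None, :] - bary.to_numpy()[None, :, :]
        between[factor] = pd.DataFrame(
            np.linalg.norm(diff, axis=2), index=bary.index, columns=bary.index
        )
    return DistanceTable(to_center=to_center, between=between, n_pcs=n_pcs)
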