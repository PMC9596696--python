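"""Population-genetic statistics on a biallelic dosage panel.

Covers the structure/relatedness side of an association study: composite
linkage disequilibrium (r^2 between dosage vectors) with chi-square
significance, LD decay by tricube local-linear (LOESS) regression over cM
distance, the VanRaden genomic relationship matrix, its eigen-PCA, a
k-means clustering proxy for admixture grouping, and a Saitou-Nei
neighbor-joining tree from a pairwise distance matrix.

Distances live on the genetic map (cM) throughout; physical positions are
not modelled.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

__all__ = [
    "GenotypePanel",
    "pairwise_ld",
    "ld_summary",
    "percent_significant",
    "marker_genome_shares",
    "ld_decay_curve",
    "loess_curve",
    "kinship_vanraden",
    "kinship_distance",
    "pca_genotypes",
    "cluster_accessions",
    "nj_tree",
]


@dataclass
class GenotypePanel:
    """Accessions x biallelic markers with a genetic map.

    ``dosages`` counts copies of the alternate allele (0/1/2; -1 marks a
    missing call).  ``markers`` has columns ``id, chrom, genome, cm``;
    ``accessions`` has at least ``id``.
    """

    dosages: np.ndarray
    markers: pd.DataFrame
    accessions: pd.DataFrame

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages)
        n, m = self.dosages.shape
        if len(self.markers) != m:
            raise ValueError("marker metadata does not match dosage columns")
        if len(self.accessions) != n:
            raise ValueError("accession metadata does not match dosage rows")
        if self.markers["id"].duplicated().any():
            raise ValueError("duplicate marker ids")
        bad = ~np.isin(self.dosages, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} (-1 for missing)")
        for _, grp in self.markers.groupby("chrom", sort=False):
            if (np.diff(grp["cm"].to_numpy()) < 0).any():
                raise ValueError("cM positions must be non-decreasing per chromosome")

    @property
    def n_accessions(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per marker (missing calls excluded)."""
        d = np.ma.masked_equal(self.dosages, -1)
        return np.asarray(d.mean(axis=0) / 2.0)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)


def pairwise_ld(panel: GenotypePanel, scope: str = "within",
                alpha: float = 0.001) -> tuple[pd.DataFrame, int]:
    """Composite LD for marker pairs: r^2, cM distance and significance.

    r^2 is the squared Pearson correlation of the dosage vectors (the
    composite estimator appropriate for unphased genotypes); its p-value
    comes from chi^2 = n*r^2 with 1 df.  ``scope='within'`` pairs markers
    on the same chromosome; ``'all'`` adds cross-chromosome pairs (their
    distance is NaN).  Monomorphic markers cannot carry LD and are skipped;
    the second return value counts them.
    """
    if scope not in ("within", "all"):
        raise ValueError(f"unknown scope {scope!r}")
    if panel.n_markers < 2:
        raise ValueError("need at least 2 markers")
    X = panel.dosages.astype(float)
    X[X < 0] = np.nan
    poly = np.nanstd(X, axis=0) > 0
    n_skipped = int((~poly).sum())
    idx = np.flatnonzero(poly)
    meta = panel.markers.iloc[idx].reset_index(drop=True)
    X = X[:, idx]
    n = X.shape[0]

    frames = []
    if scope == "within":
        groups = [g.index.to_numpy() for _, g in meta.groupby("chrom", sort=False)]
    else:
        groups = [np.arange(len(meta))]
    for g in groups:
        if len(g) < 2:
            continue
        sub = X[:, g]
        with np.errstate(invalid="ignore"):
            R = np.corrcoef(sub, rowvar=False)
        iu, ju = np.triu_indices(len(g), k=1)
        r2 = R[iu, ju] ** 2
        mi, mj = meta.iloc[g[iu]], meta.iloc[g[ju]]
        same = (mi["chrom"].to_numpy() == mj["chrom"].to_numpy())
        dist = np.where(same, np.abs(mi["cm"].to_numpy() - mj["cm"].to_numpy()),
                        np.nan)
        frames.append(pd.DataFrame({
            "marker_i": mi["id"].to_numpy(),
            "marker_j": mj["id"].to_numpy(),
            "chrom": np.where(same, mi["chrom"].to_numpy(), "-"),
            "genome": np.where(same, mi["genome"].to_numpy(), "-"),
            "same_chrom": same,
            "dist_cm": dist,
            "r2": r2,
        }))
    rec = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["marker_i", "marker_j", "chrom", "genome", "same_chrom",
                 "dist_cm", "r2"])
    rec["p"] = stats.chi2.sf(n * rec["r2"].to_numpy(), df=1)
    rec["significant"] = rec["p"] < alpha
    return rec, n_skipped


def percent_significant(n_significant: int, n_total: int) -> float:
    """Share of significant pairs as a percentage, reported to 2 dp."""
    if n_total <= 0:
        raise ValueError("total pair count must be > 0")
    return round(100.0 * n_significant / n_total, 2)


def marker_genome_shares(counts: dict) -> dict:
    """Percent of markers per genome class (1 dp), e.g. A/B/D subgenomes."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("no markers")
    return {g: round(100.0 * c / total, 1) for g, c in counts.items()}


def ld_summary(records: pd.DataFrame, alpha: float = 0.001,
               near_threshold: float = 10.0) -> pd.DataFrame:
    """Per-genome and overall LD summary.

    For every genome class (and an ``all`` row): pair count, significant
    count at ``alpha``, percent significant (2 dp), mean r^2, and the
    percent of *significant* pairs closer than ``near_threshold`` cM.
    """
    if records.empty:
        raise ValueError("no LD records")
    sig = records["p"] < alpha

    def _row(label, sub, subsig):
        nsig = int(subsig.sum())
        close = sub.loc[subsig & (sub["dist_cm"] < near_threshold)]
        return {
            "genome": label,
            "n_pairs": len(sub),
            "n_significant": nsig,
            "pct_significant": percent_significant(nsig, len(sub)),
            "mean_r2": float(sub["r2"].mean()),
            "pct_significant_near": (round(100.0 * len(close) / nsig, 2)
                                     if nsig else np.nan),
        }

    rows = [_row("all", records, sig)]
    same = records[records["same_chrom"]]
    for genome, sub in same.groupby("genome", sort=True):
        rows.append(_row(genome, sub, sub["p"] < alpha))
    return pd.DataFrame(rows)


def loess_curve(x: np.ndarray, y: np.ndarray, grid: np.ndarray,
                frac: float = 0.3) -> np.ndarray:
    """Tricube-weighted local *linear* regression evaluated on ``grid``.

    At each grid point the bandwidth is the distance to the
    ceil(frac*n)-th nearest data point; a weighted degree-1 fit gives the
    smoothed value.  Globally linear data are reproduced exactly.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    if np.ptp(x) == 0:
        raise ValueError("all distances identical; cannot smooth")
    k = max(2, int(np.ceil(frac * len(x))))
    out = np.empty(len(grid))
    for i, x0 in enumerate(grid):
        d = np.abs(x - x0)
        h = np.partition(d, k - 1)[k - 1]
        if h == 0:
            h = np.min(d[d > 0], initial=1.0)
        w = (1 - np.clip(d / h, 0, 1) ** 3) ** 3
        use = w > 0
        X = np.column_stack([np.ones(use.sum()), x[use] - x0])
        W = w[use]
        beta, *_ = np.linalg.lstsq(X * np.sqrt(W)[:, None],
                                   y[use] * np.sqrt(W), rcond=None)
        out[i] = beta[0]
    return out


def ld_decay_curve(records: pd.DataFrame, frac: float = 0.3,
                   grid: np.ndarray | None = None,
                   r2_threshold: float = 0.1) -> tuple[pd.DataFrame, float]:
    """LOESS-smoothed r^2 as a function of cM distance plus decay distance.

    Uses same-chromosome records only.  The decay distance is the first
    grid point at which the smoothed curve drops below ``r2_threshold``
    (NaN if it never does).
    """
    same = records[records["same_chrom"] & records["dist_cm"].notna()]
    if len(same) < 20:
        raise ValueError("need >= 20 same-chromosome LD records")
    x = same["dist_cm"].to_numpy()
    y = same["r2"].to_numpy()
    if grid is None:
        grid = np.linspace(0.0, float(np.quantile(x, 0.99)), 200)
    fitted = loess_curve(x, y, grid, frac=frac)
    below = np.flatnonzero(fitted < r2_threshold)
    decay = float(grid[below[0]]) if len(below) else float("nan")
    return pd.DataFrame({"dist_cm": grid, "r2_smooth": fitted}), decay


def kinship_vanraden(panel: GenotypePanel) -> np.ndarray:
    """VanRaden genomic relationship matrix K = ZZ' / (2 sum p(1-p)).

    Z is the column-centred dosage matrix (missing calls imputed at the
    marker mean, i.e. centred to zero). Monomorphic markers are dropped
    with a warning; K is symmetric positive semidefinite by construction.
    """
    X = panel.dosages.astype(float)
    X[X < 0] = np.nan
    p = np.nanmean(X, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if (~poly).any():
        warnings.warn(f"dropping {int((~poly).sum())} monomorphic markers")
    X, p = X[:, poly], p[poly]
    if X.shape[1] < 10:
        warnings.warn("fewer than 10 markers; kinship will be unstable")
    Z = X - 2.0 * p
    Z[np.isnan(Z)] = 0.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    K = Z @ Z.T / denom
    return (K + K.T) / 2.0


def kinship_distance(K: np.ndarray, method: str = "kinship") -> np.ndarray:
    """Pairwise distance for tree building: 1 - K_ij / max(K) (default),
    or plain allele-sharing distance when ``method='allele'`` is requested
    on a dosage matrix elsewhere."""
    if method != "kinship":
        raise ValueError("only the kinship-derived distance lives here")
    D = 1.0 - K / float(K.max())
    np.fill_diagonal(D, 0.0)
    return np.maximum((D + D.T) / 2.0, 0.0)


def pca_genotypes(K: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigen-PCA of a kinship matrix.

    Returns (eigenvalues desc, scores, percent variance per PC); percents
    are eigenvalue / trace x 100 and sum to 100.  Scores are the
    eigenvectors scaled by sqrt(eigenvalue).
    """
    K = np.asarray(K, float)
    if K.ndim != 2 or K.shape[0] != K.shape[1] or not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kinship matrix must be symmetric")
    vals, vecs = np.linalg.eigh(K)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.clip(vals, 0.0, None)
    pct = 100.0 * vals / vals.sum()
    scores = vecs * np.sqrt(vals)
    return vals, scores, pct


def cluster_accessions(scores: np.ndarray, k: int, seed: int = 0,
                       n_pcs: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """k-means on leading PC scores as a labelled admixture proxy.

    Returns (labels, distances-to-centroid matrix). Deterministic for a
    given seed (``n_init=10`` restarts).
    """
    scores = np.asarray(scores, float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > scores.shape[0]:
        raise ValueError("k cannot exceed the number of accessions")
    sub = scores[:, :n_pcs]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(sub)
    dists = km.transform(sub)
    return km.labels_, dists


def nj_tree(D: np.ndarray, labels: list[str]) -> str:
    """Saitou-Nei neighbor-joining tree as a newick string.

    Negative branch lengths (possible for non-additive inputs) are clamped
    to zero.  The input must be a symmetric, zero-diagonal distance matrix
    over >= 3 taxa with no NaNs.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    D = np.asarray(D, float)
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if D.shape[0] < 3:
        raise ValueError("need >= 3 taxa")
    if not np.allclose(D, D.T, atol=1e-8) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    tree = nj(DistanceMatrix(D, ids=list(labels)))
    clamped = False
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped = True
    newick = str(tree).strip()
    if clamped:
        warnings.warn("negative NJ branch lengths clamped to zero")
    return newick


def natural_chrom_key(chrom: str):
    """Sort key putting 1A < 1B < 1D < 2A ... before any oddballs."""
    m = re.match(r"^(\d+)([A-Za-z]*)$", str(chrom))
    return (0, int(m.group(1)), m.group(2)) if m else (1, 0, str(chrom))
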