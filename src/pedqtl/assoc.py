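"""Population structure and kinship mixed-model association scan.

The scan fits, per marker,

    y = mu + beta_k * kernel + beta_m * x + u + eps,
    u ~ N(0, sigma_g^2 K),  eps ~ N(0, sigma_e^2 I)

where K is a marker-derived kinship matrix and the kernel-type indicator
(0 soft / 1 hard) is a fixed covariate. The variance ratio is estimated by
REML through a one-time spectral decomposition of K under the null model
and reused for every marker (the "population parameters previously
determined" shortcut); an exact per-marker refit is available behind a
flag. Lines are inbred, markers are coded x in {0, 1}, so the reported
effect is the full homozygote substitution effect of the code-1 (focal
line) allele.

Multiple testing uses Storey's q-values with the smoother pi0 estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import MISSING, ConfigError, GeneticMap, GenotypeMatrix


# ---------------------------------------------------------------------------
# marker filtering


def filter_markers(
    g: GenotypeMatrix,
    maf_min: float = 0.1,
    drop_redundant: bool = True,
    gmap: GeneticMap | None = None,
) -> GenotypeMatrix:
    """Remove low-MAF and redundant markers.

    MAF is computed over non-missing calls. Redundant markers have exactly
    identical call vectors including the missing pattern; the first marker
    in map order (input order when no map is given) is retained.
    """
    maf = g.maf()
    keep = [m for m, f in zip(g.marker_ids, maf) if np.isfinite(f) and f >= maf_min]
    if gmap is not None:
        in_map = [m for m in gmap.marker_ids if m in set(keep)]
        unmapped = [m for m in keep if m not in set(gmap.marker_ids)]
        keep = in_map + unmapped
    if drop_redundant:
        seen: dict[bytes, str] = {}
        unique = []
        for m in keep:
            sig = g.column(m).tobytes()
            if sig not in seen:
                seen[sig] = m
                unique.append(m)
        keep = unique
    if not keep:
        warnings.warn("no markers survive filtering")
    return g.subset_markers(keep)


# ---------------------------------------------------------------------------
# kNN imputation


def knn_impute(g: GenotypeMatrix, k: int = 3, min_freq: float = 0.8) -> GenotypeMatrix:
    """Nearest-neighbour imputation of missing calls.

    Accessions with less than ``min_freq`` non-missing data are dropped with
    a warning. Distances are mean absolute call differences over markers
    non-missing in both accessions (Manhattan distance normalised by
    overlap, so unequal missingness does not bias neighbour choice). Each
    missing call becomes the unweighted average over the k nearest
    accessions with data at that marker, rounded to the nearer code (0.5
    rounds up).
    """
    obs = g.calls != MISSING
    frac = obs.mean(axis=1)
    keep = frac >= min_freq
    if not keep.all():
        dropped = [a for a, kk in zip(g.accession_ids, keep) if not kk]
        warnings.warn(f"dropping accessions below {min_freq:.0%} data: {dropped}")
        g = g.subset_accessions([a for a, kk in zip(g.accession_ids, keep) if kk])
        obs = g.calls != MISSING
    n = g.n_accessions
    if k >= n:
        raise ConfigError(f"k={k} must be smaller than the number of accessions ({n})")

    calls = g.calls.astype(float)
    calls[~obs] = np.nan
    # pairwise mean |difference| over shared non-missing markers
    diff_sum = np.zeros((n, n))
    share = np.zeros((n, n))
    x = np.nan_to_num(calls)
    o = obs.astype(float)
    # |a-b| for 0/1 codes = a + b - 2ab on shared entries
    shared_ab = x @ x.T
    a_on_shared = (x * 1.0) @ o.T
    share = o @ o.T
    diff_sum = a_on_shared + a_on_shared.T - 2 * shared_ab
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(share > 0, diff_sum / share, np.inf)
    np.fill_diagonal(dist, np.inf)

    out = g.calls.copy()
    order = np.argsort(dist, axis=1, kind="stable")
    for i in range(n):
        missing_j = np.where(~obs[i])[0]
        if missing_j.size == 0:
            continue
        ranked = order[i]
        for j in missing_j:
            donors = ranked[obs[ranked, j]][:k]
            if donors.size == 0:
                # no accession has data here; fall back to 0 (rare, flagged)
                warnings.warn(f"marker {g.marker_ids[j]} has no observed calls; imputing 0")
                out[i, j] = 0
                continue
            avg = g.calls[donors, j].mean()
            out[i, j] = 1 if avg >= 0.5 else 0
    return GenotypeMatrix(list(g.accession_ids), list(g.marker_ids), out)


# ---------------------------------------------------------------------------
# PCA


def pca(g: GenotypeMatrix, n_components: int = 3) -> tuple[pd.DataFrame, np.ndarray]:
    """Correlation-based principal components of a complete genotype matrix.

    Markers are standardised to unit variance (so the decomposition is of
    the marker correlation matrix); zero-variance markers are excluded with
    a warning. Proportions of variance are reported for the requested
    components; component sign is fixed by making the largest-magnitude
    marker loading positive. Proportions are invariant to 0/1 allele-code
    flips, which only negate standardised columns.
    """
    if (g.calls == MISSING).any():
        raise ConfigError("PCA requires a complete matrix; impute first")
    if g.n_accessions < 2:
        raise ConfigError("need at least 2 accessions")
    X = g.calls.astype(float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} zero-variance markers from PCA")
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    eig = s**2
    proportions = eig / eig.sum()
    n_components = min(n_components, len(s))
    coords = u[:, :n_components] * s[:n_components]
    for c in range(n_components):
        j = np.argmax(np.abs(vt[c]))
        if vt[c, j] < 0:
            coords[:, c] = -coords[:, c]
    frame = pd.DataFrame(
        coords, index=g.accession_ids, columns=[f"PC{i + 1}" for i in range(n_components)]
    )
    return frame, proportions[:n_components]


# ---------------------------------------------------------------------------
# distances and UPGMA


def distance_matrix(g: GenotypeMatrix) -> pd.DataFrame:
    """1 - proportion of shared calls over mutually non-missing markers."""
    obs = (g.calls != MISSING).astype(float)
    x = np.where(g.calls == MISSING, 0, g.calls).astype(float)
    share = obs @ obs.T
    same0 = (1 - x) * obs  # indicator of call 0 (observed)
    match = x @ x.T + same0 @ same0.T
    if (share == 0).any():
        raise ConfigError("accession pair with no shared non-missing markers")
    d = 1.0 - match / share
    return pd.DataFrame(d, index=g.accession_ids, columns=g.accession_ids)


@dataclass
class TreeNode:
    """Node of an ultrametric (UPGMA) tree; ``height`` is distance/2 to leaves."""

    name: str
    height: float
    children: list["TreeNode"]
    members: list[str]

    @property
    def is_leaf(self) -> bool:
        return not self.children


def upgma(distances: pd.DataFrame) -> TreeNode:
    """Average-linkage (UPGMA) clustering with deterministic tie-breaks.

    Among equally close pairs the one whose lexicographically smallest
    member id sorts first (then the partner's) is merged, so repeated runs
    and reordered inputs give the same tree.
    """
    if distances.empty:
        raise ConfigError("empty distance matrix")
    d = distances.to_numpy(dtype=float)
    if not np.isfinite(d).all():
        raise ConfigError("non-finite distance")
    ids = list(distances.index)
    clusters: dict[int, TreeNode] = {
        i: TreeNode(name=ids[i], height=0.0, children=[], members=[ids[i]])
        for i in range(len(ids))
    }
    dist: dict[tuple[int, int], float] = {
        (i, j): d[i, j] for i in range(len(ids)) for j in range(i + 1, len(ids))
    }
    next_id = len(ids)
    while len(clusters) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (
                kv[1],
                min(clusters[kv[0][0]].members + clusters[kv[0][1]].members),
                max(
                    min(clusters[kv[0][0]].members),
                    min(clusters[kv[0][1]].members),
                ),
            ),
        )
        (a, b), dab = best
        na, nb = len(clusters[a].members), len(clusters[b].members)
        node = TreeNode(
            name="",
            height=dab / 2.0,
            children=sorted([clusters[a], clusters[b]], key=lambda n: min(n.members)),
            members=sorted(clusters[a].members + clusters[b].members),
        )
        for other in list(clusters):
            if other in (a, b):
                continue
            ka = (min(a, other), max(a, other))
            kb = (min(b, other), max(b, other))
            dnew = (na * dist[ka] + nb * dist[kb]) / (na + nb)
            del dist[ka], dist[kb]
            dist[(min(other, next_id), max(other, next_id))] = dnew
        del dist[(a, b)], clusters[a], clusters[b]
        clusters[next_id] = node
        next_id += 1
    return next(iter(clusters.values()))


# ---------------------------------------------------------------------------
# kinship


@dataclass
class KinshipMatrix:
    """Rescaled allele-sharing similarity: diagonal 1, minimum off-diagonal 0."""

    accession_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.accession_ids)
        if self.values.shape != (n, n):
            raise ConfigError("kinship matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ConfigError("kinship matrix not symmetric")

    def aligned(self, accession_ids: list[str]) -> np.ndarray:
        idx = [self.accession_ids.index(a) for a in accession_ids]
        return self.values[np.ix_(idx, idx)]


def kinship(g: GenotypeMatrix) -> KinshipMatrix:
    """Marker kinship as rescaled identity-by-state similarity.

    S_ij is the proportion of matching calls over mutually non-missing
    markers; K = (S - min_offdiag) / (1 - min_offdiag) puts the least
    related pair at 0 and the diagonal at 1.
    """
    sim = 1.0 - distance_matrix(g).to_numpy()
    n = sim.shape[0]
    if n < 2:
        return KinshipMatrix(list(g.accession_ids), np.ones((1, 1)))
    off = sim[~np.eye(n, dtype=bool)]
    m = off.min()
    if m >= 1.0:
        values = np.ones_like(sim)
    else:
        values = (sim - m) / (1.0 - m)
    np.fill_diagonal(values, 1.0)
    return KinshipMatrix(list(g.accession_ids), values)


# ---------------------------------------------------------------------------
# REML machinery


def _reml_neg_loglik(log_delta: float, eig: np.ndarray, Xr: np.ndarray, yr: np.ndarray) -> float:
    """-2 x restricted log-likelihood (up to a constant) for H = K + delta*I."""
    delta = np.exp(log_delta)
    w = 1.0 / (eig + delta)
    n, p = Xr.shape
    Xw = Xr * np.sqrt(w)[:, None]
    yw = yr * np.sqrt(w)
    xtx = Xw.T @ Xw
    beta = np.linalg.solve(xtx, Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2 = rss / (n - p)
    _, logdet_xtx = np.linalg.slogdet(xtx)
    return (n - p) * np.log(sigma2) + np.sum(np.log(eig + delta)) + logdet_xtx


def reml_variance_ratio(
    y: np.ndarray, X: np.ndarray, K: np.ndarray
) -> tuple[float, float, float]:
    """REML estimates (delta, sigma_g^2, sigma_e^2) for y = X beta + u + eps.

    delta = sigma_e^2 / sigma_g^2; optimised on log scale over
    delta in [1e-5, 1e5] by grid search plus bounded refinement.
    """
    eig, U = np.linalg.eigh(K)
    eig = np.clip(eig, 0.0, None)
    yr = U.T @ y
    Xr = U.T @ X
    grid = np.linspace(np.log(1e-5), np.log(1e5), 61)
    vals = [_reml_neg_loglik(ld, eig, Xr, yr) for ld in grid]
    i = int(np.argmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        _reml_neg_loglik, args=(eig, Xr, yr), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8},
    )
    delta = float(np.exp(res.x))
    w = 1.0 / (eig + delta)
    Xw = Xr * np.sqrt(w)[:, None]
    yw = yr * np.sqrt(w)
    beta = np.linalg.solve(Xw.T @ Xw, Xw.T @ yw)
    resid = yw - Xw @ beta
    n, p = Xr.shape
    sigma_g2 = float(resid @ resid) / (n - p)
    return delta, sigma_g2, sigma_g2 * delta


# ---------------------------------------------------------------------------
# MLM scan


def mlm_scan(
    g: GenotypeMatrix,
    phenotype: pd.Series,
    K: KinshipMatrix,
    covariates: pd.Series | pd.DataFrame | None = None,
    refit_per_marker: bool = False,
    delta: float | None = None,
) -> pd.DataFrame:
    """Kinship mixed-model association scan (see module docstring).

    ``phenotype`` holds per-accession genotypic values; ``covariates`` is
    typically the kernel-type indicator. ``delta`` pins the variance ratio
    sigma_e^2/sigma_g^2 (``numpy.inf`` collapses the model to ordinary
    least squares ANCOVA). Returns a frame with columns marker_id, maf,
    p_value, effect, r_squared, note; markers confounded with the fixed
    effects are skipped with a reason.
    """
    if (g.calls == MISSING).any():
        raise ConfigError("association scan requires complete genotypes; impute first")
    accs = g.accession_ids
    y = phenotype.reindex(accs)
    if y.isna().any():
        raise ConfigError("phenotype missing for some accessions")
    y = y.to_numpy(dtype=float)
    cols = [np.ones(len(accs))]
    if covariates is not None:
        cov = covariates.to_frame() if isinstance(covariates, pd.Series) else covariates
        cov = cov.reindex(accs)
        if cov.isna().any().any():
            raise ConfigError("covariates missing for some accessions")
        cols.extend(cov[c].to_numpy(dtype=float) for c in cov.columns)
    X0 = np.column_stack(cols)
    Kmat = K.aligned(accs)
    n, p0 = X0.shape

    markers = g.calls.astype(float)
    maf = g.maf()

    eig, U = np.linalg.eigh(Kmat)
    eig = np.clip(eig, 0.0, None)

    if delta is None:
        delta_hat, _, _ = reml_variance_ratio(y, X0, Kmat)
    else:
        delta_hat = float(delta)

    if np.isinf(delta_hat):
        yw, X0w, Mw = y, X0, markers
    else:
        w = np.sqrt(1.0 / (eig + delta_hat))
        yw = (U.T @ y) * w
        X0w = (U.T @ X0) * w[:, None]
        Mw = (U.T @ markers) * w[:, None]

    # residualise against the null fixed effects
    Q, _ = np.linalg.qr(X0w)
    yr = yw - Q @ (Q.T @ yw)
    sse0 = float(yr @ yr)
    Mr = Mw - Q @ (Q.T @ Mw)

    # total (intercept-corrected) SS on the whitened scale, for marker r^2
    ones_w = X0w[:, 0]
    y1 = yw - ones_w * (ones_w @ yw) / (ones_w @ ones_w)
    sst = float(y1 @ y1)

    xtx = np.einsum("ij,ij->j", Mr, Mr)
    xty = Mr.T @ yr
    df_err = n - p0 - 1
    records = []
    scale = np.einsum("ij,ij->j", Mw, Mw)
    for j, mid in enumerate(g.marker_ids):
        if xtx[j] <= 1e-10 * max(scale[j], 1.0):
            records.append((mid, maf[j], np.nan, np.nan, np.nan, "confounded with covariates"))
            continue
        if refit_per_marker and not np.isinf(delta_hat):
            Xj = np.column_stack([X0, markers[:, j]])
            dj, _, _ = reml_variance_ratio(y, Xj, Kmat)
            wj = np.sqrt(1.0 / (eig + dj))
            ywj = (U.T @ y) * wj
            X0wj = (U.T @ X0) * wj[:, None]
            xwj = (U.T @ markers[:, j]) * wj
            Qj, _ = np.linalg.qr(X0wj)
            yrj = ywj - Qj @ (Qj.T @ ywj)
            xrj = xwj - Qj @ (Qj.T @ xwj)
            num = (xrj @ yrj) ** 2 / (xrj @ xrj)
            sse1 = float(yrj @ yrj) - num
            beta = (xrj @ yrj) / (xrj @ xrj)
            onesj = X0wj[:, 0]
            y1j = ywj - onesj * (onesj @ ywj) / (onesj @ onesj)
            sstj = float(y1j @ y1j)
        else:
            num = xty[j] ** 2 / xtx[j]
            sse1 = sse0 - num
            beta = xty[j] / xtx[j]
            sstj = sst
        f = num / (sse1 / df_err) if sse1 > 0 else np.inf
        p = float(stats.f.sf(f, 1, df_err))
        r2 = num / sstj if sstj > 0 else np.nan
        records.append((mid, maf[j], p, float(beta), float(r2), ""))
    return pd.DataFrame(
        records, columns=["marker_id", "maf", "p_value", "effect", "r_squared", "note"]
    )


# ---------------------------------------------------------------------------
# Storey q-values


def storey_qvalues(
    p_values: np.ndarray, pi0: float | None = None
) -> tuple[np.ndarray, float]:
    """Storey q-values with the smoother pi0 estimate.

    pi0 is estimated by a cubic fit of pi0(lambda) = #{p > lambda} /
    (m (1 - lambda)) over lambda in {0, 0.05, ..., 0.90}, evaluated at
    0.90, falling back to 1 when the estimate leaves (0, 1]. q_i is the
    minimum over thresholds t >= p_i of pi0 * m * t / #{p <= t}, clipped to
    [0, 1]; q is monotone non-decreasing in p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ConfigError("empty p-value list")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ConfigError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        lambdas = np.arange(0.0, 0.9001, 0.05)
        pi0_l = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
        coeffs = np.polyfit(lambdas, pi0_l, deg=3)
        est = float(np.polyval(coeffs, 0.90))
        pi0 = est if 0.0 < est <= 1.0 else 1.0
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, float(pi0)


def mta_table(scan: pd.DataFrame, gmap: GeneticMap, q_threshold: float = 0.5) -> pd.DataFrame:
    """Significant marker-trait associations with map positions attached.

    Adds q-values if absent, joins (map source, linkage group, cM) for
    located markers — unlocated MTAs keep missing positions and are
    reported but excluded from QTL classification downstream — and filters
    at the q threshold. R^2 is reported as a percentage.
    """
    out = scan.copy()
    if "q_value" not in out.columns:
        valid = out["p_value"].notna()
        q = np.full(len(out), np.nan)
        q[valid.to_numpy()], _ = storey_qvalues(out.loc[valid, "p_value"].to_numpy())
        out["q_value"] = q
    pos = gmap.table.set_index("marker_id")[["map_source", "linkage_group", "position_cm"]]
    out = out.join(pos, on="marker_id")
    out["r_squared_pct"] = out["r_squared"] * 100.0
    sig = out[out["q_value"] < q_threshold].reset_index(drop=True)
    return sig
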