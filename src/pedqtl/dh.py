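"""Doubled-haploid QTL validation and marker-based prediction.

Each DH population segregates 1:1 at markers polymorphic between its
parents. A QTL is validated by a two-sided pooled-variance t-test between
the two allele-class means of the trait. Prediction uses ordinary least
squares of the trait on 0/1 marker codes (1 = focal parent's allele),
either per population ("each" models) or on the stacked populations with
population-specific intercepts to absorb their mean differences ("total"
model); accuracy is the Pearson correlation between predicted and actual
values over all lines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, ConfigError, DHPopulation


@dataclass
class AlleleMeanTest:
    """Allele-class means and pooled t-test for one marker in one population."""

    population: str
    marker_id: str
    focal_allele: int  # code of the focal parent's allele
    n_focal: int
    mean_focal: float
    n_other: int
    mean_other: float
    t: float  # NaN when the marker is monomorphic
    p: float


def _oriented_column(pop: DHPopulation, marker: str) -> np.ndarray:
    """Marker codes recoded so 1 = focal parent's allele (missing stays missing)."""
    j = pop.genotypes.marker_index(marker)
    col = pop.genotypes.calls[:, j].astype(int)
    if pop.focal_alleles is None:
        focal = 1
    else:
        focal = int(pop.focal_alleles[j])
    out = np.where(col == MISSING, MISSING, (col == focal).astype(int))
    return out


def allele_mean_test(pop: DHPopulation, marker: str) -> AlleleMeanTest:
    """Two-sided pooled-variance t-test between allele-class trait means.

    The focal parent's allele class is reported first. A marker
    monomorphic in the population yields a single-class result with a
    missing p (mirroring blank validation-table cells); classes need at
    least 2 lines each for the test.
    """
    if pop.phenotypes is None:
        raise ConfigError(f"population {pop.name} has no phenotypes")
    x = _oriented_column(pop, marker)
    y = pop.phenotypes.reindex(pop.genotypes.accession_ids).to_numpy(dtype=float)
    ok = (x != MISSING) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    focal_j = pop.genotypes.marker_index(marker)
    focal_allele = int(pop.focal_alleles[focal_j]) if pop.focal_alleles is not None else 1
    yf, yo = y[x == 1], y[x == 0]
    if len(yf) == 0 or len(yo) == 0:
        grp = yf if len(yf) else yo
        return AlleleMeanTest(
            pop.name, marker, focal_allele, len(yf), float(yf.mean()) if len(yf) else math.nan,
            len(yo), float(yo.mean()) if len(yo) else math.nan, math.nan, math.nan,
        )
    if len(yf) < 2 or len(yo) < 2:
        t = p = math.nan
    else:
        t, p = stats.ttest_ind(yf, yo, equal_var=True)
    return AlleleMeanTest(
        pop.name, marker, focal_allele, len(yf), float(yf.mean()),
        len(yo), float(yo.mean()), float(t), float(p),
    )


def validation_table(pops: list[DHPopulation], markers: list[str]) -> pd.DataFrame:
    """Marker x population table of allele means, counts and p-values."""
    rows = []
    for m in markers:
        for pop in pops:
            r = allele_mean_test(pop, m)
            rows.append(
                {
                    "marker": m,
                    "population": pop.name,
                    "n_focal": r.n_focal,
                    "mean_focal": r.mean_focal,
                    "n_other": r.n_other,
                    "mean_other": r.mean_other,
                    "p": r.p,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# multiple regression prediction


@dataclass
class MarkerRegressionModel:
    markers: list[str]  # markers retained in the fit
    coefficients: pd.Series  # per-marker effects, trait units
    intercepts: dict[str, float]  # population -> intercept
    r_squared: float
    n_obs: int
    populations: list[str]
    dropped_markers: list[str]


def _design(
    pops: list[DHPopulation], markers: list[str]
) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray]:
    """Stacked (X_markers, y, pop labels, complete-row mask); X oriented to focal."""
    xs, ys, labels = [], [], []
    for pop in pops:
        if pop.phenotypes is None:
            raise ConfigError(f"population {pop.name} has no phenotypes")
        cols = np.column_stack([_oriented_column(pop, m) for m in markers])
        y = pop.phenotypes.reindex(pop.genotypes.accession_ids).to_numpy(dtype=float)
        xs.append(cols)
        ys.append(y)
        labels.extend([pop.name] * len(y))
    X = np.vstack(xs).astype(float)
    y = np.concatenate(ys)
    labels = np.asarray(labels)
    complete = (X != MISSING).all(axis=1) & ~np.isnan(y)
    return X, y, list(labels), complete


def fit_marker_regression(
    pops: DHPopulation | list[DHPopulation],
    markers: list[str],
    population_intercepts: bool = True,
) -> MarkerRegressionModel:
    """Ordinary least squares of the trait on 0/1 marker codes.

    Combining populations adds population-specific intercepts (unless
    disabled). Markers without variation among the complete-data lines are
    excluded with a warning; a rank-deficient design afterwards raises an
    error naming the collinear markers. Lines missing any model genotype
    or the phenotype are dropped and reported.
    """
    pops = [pops] if isinstance(pops, DHPopulation) else list(pops)
    X, y, labels, complete = _design(pops, markers)
    n_dropped = int((~complete).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} lines with incomplete data from the fit")
    X, y = X[complete], y[complete]
    labels = [l for l, c in zip(labels, complete) if c]

    kept, dropped = [], []
    for i, m in enumerate(markers):
        if np.ptp(X[:, i]) == 0:
            dropped.append(m)
        else:
            kept.append(m)
    if dropped:
        warnings.warn(f"excluding monomorphic marker(s) from the fit: {dropped}")
    if not kept:
        raise ConfigError("no polymorphic markers to fit")
    Xm = X[:, [markers.index(m) for m in kept]]

    pop_names = list(dict.fromkeys(labels))
    if population_intercepts and len(pop_names) > 1:
        D = np.column_stack([(np.asarray(labels) == p).astype(float) for p in pop_names])
    else:
        D = np.ones((len(y), 1))
    design = np.column_stack([D, Xm])
    if len(y) < design.shape[1] + 1:
        raise ConfigError("fewer complete lines than model parameters")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        corr = np.corrcoef(Xm, rowvar=False)
        pairs = [
            (kept[i], kept[j])
            for i in range(len(kept))
            for j in range(i + 1, len(kept))
            if abs(corr[i, j]) > 0.999999
        ]
        raise ConfigError(f"rank-deficient design; collinear markers: {pairs or kept}")

    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan
    k = D.shape[1]
    if population_intercepts and len(pop_names) > 1:
        intercepts = {p: float(beta[i]) for i, p in enumerate(pop_names)}
    else:
        intercepts = {p: float(beta[0]) for p in pop_names}
    return MarkerRegressionModel(
        markers=kept,
        coefficients=pd.Series(beta[k:], index=kept, name="effect"),
        intercepts=intercepts,
        r_squared=r2,
        n_obs=len(y),
        populations=pop_names,
        dropped_markers=dropped,
    )


def predict_and_correlate(
    model: MarkerRegressionModel, pop: DHPopulation
) -> tuple[pd.Series, float]:
    """Per-line linear predictions and Pearson r against actual values.

    Lines with incomplete data get missing predictions; r is computed over
    complete lines and is missing when predictions have zero variance. A
    population unseen at training time uses the mean training intercept.
    """
    X = np.column_stack([_oriented_column(pop, m) for m in model.markers]).astype(float)
    complete = (X != MISSING).all(axis=1)
    intercept = model.intercepts.get(
        pop.name, float(np.mean(list(model.intercepts.values())))
    )
    pred = np.full(len(X), np.nan)
    pred[complete] = intercept + X[complete] @ model.coefficients.to_numpy()
    predictions = pd.Series(pred, index=pop.genotypes.accession_ids, name="predicted")
    actual = pop.phenotypes.reindex(predictions.index)
    ok = predictions.notna() & actual.notna()
    if ok.sum() < 3 or predictions[ok].std() == 0:
        warnings.warn("prediction correlation undefined (zero variance or too few lines)")
        return predictions, math.nan
    r = float(stats.pearsonr(predictions[ok], actual[ok])[0])
    return predictions, r


def pooled_prediction_accuracy(
    pops: list[DHPopulation], markers: list[str], per_population: bool
) -> tuple[pd.Series, float]:
    """The study's two prediction schemes over all DH lines pooled.

    ``per_population`` True fits one model per population ("each");
    False fits one combined model with population intercepts ("total").
    Returns pooled predictions and the overall Pearson r versus actual.
    """
    preds, actuals = [], []
    if per_population:
        for pop in pops:
            try:
                model = fit_marker_regression(pop, markers)
            except ConfigError as exc:
                warnings.warn(f"population {pop.name} skipped: {exc}")
                continue
            p, _ = predict_and_correlate(model, pop)
            preds.append(p)
            actuals.append(pop.phenotypes.reindex(p.index))
    else:
        model = fit_marker_regression(pops, markers, population_intercepts=True)
        for pop in pops:
            p, _ = predict_and_correlate(model, pop)
            preds.append(p)
            actuals.append(pop.phenotypes.reindex(p.index))
    if not preds:
        raise ConfigError("no population could be fitted")
    pred = pd.concat(preds)
    actual = pd.concat(actuals)
    ok = pred.notna() & actual.notna()
    r = float(stats.pearsonr(pred[ok], actual[ok])[0])
    return pred, r
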