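"""Sampling-effect analyses: divergence vs sampling depth, and species
resampling.

Two questions drive this module.  First, does the maximum intraspecific
divergence of a species grow with the number of specimens sampled?
(Scatter of n vs max-intra, Spearman rank correlation, LOESS trend.)
Second, how does the nearest-neighbor (NN) distance landscape change as
species coverage of a clade increases?  Random species subsets of
increasing size are drawn, the barcode-gap analysis re-run on each, and
the mean and minimum NN distance recorded per draw.

LOESS here is the classic locally weighted polynomial: a tricube-weighted
least-squares polynomial fit in a span-sized neighborhood of each
evaluation point, with pointwise 95% confidence intervals from the
weighted-least-squares variance of the fitted value.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .distances import DistanceMatrix, build_distance_matrix
from .gap_analysis import SpeciesGapSummary
from .io_formats import Library


@dataclass
class CorrelationResult:
    """Spearman rank correlation with its two-sided p-value."""

    rho: float
    p_value: float
    n: int
    undefined: bool = False


@dataclass
class LoessFit:
    """LOESS fit: fitted values and 95% CI half-widths at evaluation points."""

    x: np.ndarray
    fitted: np.ndarray
    ci_halfwidth: np.ndarray
    span: float
    degree: int


@dataclass
class ResamplingDesign:
    """Design of the species-resampling experiment.

    Defaults mirror a coverage ladder of 20, 40, ..., 180 species with 10
    independent replicate draws per size (90 analyses in total).  ``scope``
    optionally restricts the library to a set of species (e.g. one family)
    before sampling.  ``nested`` draws one species permutation per
    replicate and uses its prefixes, making NN distances exactly monotone
    in coverage within a replicate.
    """

    subset_sizes: Sequence[int] = tuple(range(20, 181, 20))
    replicates: int = 10
    seed: int = 0
    scope: Optional[Sequence[str]] = None
    nested: bool = False

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(s < 2 for s in self.subset_sizes):
            raise ValueError("subset sizes must be >= 2")


def spearman_correlation(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 10
) -> CorrelationResult:
    """Spearman's rho with ties handled by average ranks.

    Two-sided p-value: t-approximation for n > ``exact_max_n``, exact
    permutation enumeration otherwise.  Constant input flags the result as
    undefined (rho NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(rho=math.nan, p_value=math.nan, n=n,
                                 undefined=True)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n > exact_max_n:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    else:
        # exact: enumerate all permutations of one rank vector
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = math.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
        observed = abs((rx_c * ry_c).sum() / denom)
        count = total = 0
        for perm in itertools.permutations(range(n)):
            r = abs((rx_c[list(perm)] * ry_c).sum() / denom)
            total += 1
            if r >= observed - 1e-12:
                count += 1
        p = count / total
    return CorrelationResult(rho=rho, p_value=min(1.0, float(p)), n=n)


def loess_fit(
    x: Sequence[float],
    y: Sequence[float],
    span: float = 0.75,
    degree: int = 2,
    eval_x: Optional[Sequence[float]] = None,
) -> LoessFit:
    """Tricube-weighted local polynomial regression with pointwise 95% CI.

    At each evaluation point the ``span`` fraction of nearest observations
    receives tricube weights scaled by the neighborhood radius, and a
    weighted polynomial of ``degree`` is fit; the fitted value and its WLS
    standard error give the confidence band.  The residual variance is
    estimated globally from the fit at the data points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < degree + 2:
        raise ValueError("need at least degree + 2 observations")
    if np.ptp(x) == 0:
        raise ValueError("x values are all equal")
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    k = max(degree + 2, int(math.ceil(span * n)))
    k = min(k, n)

    def local_design(x0: float):
        d = np.abs(x - x0)
        order = np.argsort(d, kind="stable")
        idx = order[:k]
        h = d[idx].max()
        if h == 0:
            # all selected points coincide with x0; widen to any spread
            idx = order
            h = d[idx].max()
            if h == 0:
                raise ValueError("degenerate neighborhood: all x identical")
        w = (1.0 - np.clip(d[idx] / h, 0.0, 1.0) ** 3) ** 3
        if (w > 0).sum() < degree + 1:
            raise ValueError(
                "span too small: fewer than degree+1 points with positive weight"
            )
        X = np.vander(x[idx] - x0, N=degree + 1, increasing=True)
        return idx, X, w

    def fit_at(x0: float, sigma2: float | None):
        idx, X, w = local_design(x0)
        W = np.diag(w)
        XtW = X.T * w
        A = XtW @ X
        beta = np.linalg.solve(A, XtW @ y[idx])
        fitted = beta[0]
        if sigma2 is None:
            return fitted, 0.0
        Ainv = np.linalg.inv(A)
        # var(beta0) = sigma2 * [Ainv X'W^2 X Ainv]_{00}
        mid = XtW @ W @ X
        var0 = sigma2 * (Ainv @ mid @ Ainv)[0, 0]
        return fitted, math.sqrt(max(0.0, var0))

    # pass 1: fitted values at data points -> residual variance
    fitted_data = np.array([fit_at(xi, None)[0] for xi in x])
    dof = max(n - (degree + 1), 1)
    sigma2 = float(((y - fitted_data) ** 2).sum() / dof)

    if eval_x is None:
        eval_arr = np.unique(x)
    else:
        eval_arr = np.asarray(eval_x, dtype=float)
    out_fit = np.empty(eval_arr.size)
    out_se = np.empty(eval_arr.size)
    for i, x0 in enumerate(eval_arr):
        out_fit[i], out_se[i] = fit_at(float(x0), sigma2)
    tcrit = stats.t.ppf(0.975, df=dof)
    return LoessFit(
        x=eval_arr,
        fitted=out_fit,
        ci_halfwidth=tcrit * out_se,
        span=span,
        degree=degree,
    )


def divergence_vs_sample_size(
    summaries: Sequence[SpeciesGapSummary],
    exclusions: Sequence[str] = (),
    span: float = 0.75,
    degree: int = 2,
) -> tuple[pd.DataFrame, CorrelationResult, Optional[LoessFit]]:
    """Specimens-per-species vs maximum intraspecific divergence.

    Singletons (undefined max-intra) and explicitly excluded species are
    dropped; returns the scatter table, the Spearman correlation and a
    LOESS trend of max-intra on sample size (None when too few points
    remain for the requested degree).
    """
    drop = set(exclusions)
    rows = [
        {"species": s.species, "n_specimens": s.n_specimens,
         "max_intra": s.max_intra}
        for s in summaries
        if s.n_specimens > 1 and s.max_intra is not None and s.species not in drop
    ]
    if len(rows) < 3:
        raise ValueError(f"only {len(rows)} species remain after exclusions")
    df = pd.DataFrame(rows)
    corr = spearman_correlation(df["n_specimens"], df["max_intra"])
    try:
        fit = loess_fit(df["n_specimens"], df["max_intra"], span=span,
                        degree=degree)
    except ValueError:
        fit = None
    return df, corr, fit


def _per_species_nn(
    matrix: DistanceMatrix, species_of: np.ndarray, species: Sequence[str]
) -> dict[str, float]:
    """NN distance per species within the given species subset."""
    subset = set(species)
    cols = np.flatnonzero(np.isin(species_of, list(subset)))
    vals = matrix.values[np.ix_(cols, cols)]
    sp_cols = species_of[cols]
    out = {}
    for sp in species:
        own = sp_cols == sp
        cross = vals[np.ix_(own, ~own)]
        finite = ~np.isnan(cross)
        if not finite.any():
            raise ValueError(f"species {sp!r}: no defined heterospecific distance")
        out[sp] = float(np.nanmin(cross))
    return out


def species_resampling_experiment(
    library: Library,
    design: Optional[ResamplingDesign] = None,
    matrix: Optional[DistanceMatrix] = None,
    model: str = "K2P",
    span: float = 0.75,
    degree: int = 2,
) -> tuple[pd.DataFrame, CorrelationResult, Optional[LoessFit]]:
    """Species-coverage resampling of the barcode-gap analysis.

    For every (subset size, replicate) cell, draws that many species
    uniformly without replacement (deterministic substream per cell from
    the master seed), restricts the library to them, and records the mean
    and minimum per-species NN distance.  Returns the long-form result
    table plus the Spearman correlation and LOESS trend of mean NN on
    subset size.
    """
    if design is None:
        design = ResamplingDesign()
    if design.scope is not None:
        library = library.subset_species(design.scope)
    species = sorted({r.species for r in library if r.species})
    max_size = max(design.subset_sizes)
    if len(species) < max_size:
        raise ValueError(
            f"need at least {max_size} species in scope, found {len(species)}"
        )
    if matrix is None:
        matrix = build_distance_matrix(library, model=model)
    species_of = np.empty(len(matrix.ids), dtype=object)
    rec_species = {r.specimen_id: r.species for r in library}
    for i, sid in enumerate(matrix.ids):
        species_of[i] = rec_species[sid]

    species_arr = np.array(species, dtype=object)
    rows = []
    for rep in range(1, design.replicates + 1):
        if design.nested:
            rng = np.random.default_rng(
                np.random.SeedSequence([design.seed, 0, rep])
            )
            order = rng.permutation(len(species_arr))
        for size in design.subset_sizes:
            if design.nested:
                chosen = species_arr[order[:size]]
            else:
                rng = np.random.default_rng(
                    np.random.SeedSequence([design.seed, size, rep])
                )
                chosen = rng.choice(species_arr, size=size, replace=False)
            nn = _per_species_nn(matrix, species_of, list(chosen))
            vals = np.array(list(nn.values()))
            rows.append(
                {
                    "subset_size": size,
                    "replicate": rep,
                    "mean_nn": float(vals.mean()),
                    "min_nn": float(vals.min()),
                }
            )
    result = pd.DataFrame(rows).sort_values(
        ["subset_size", "replicate"], ignore_index=True
    )
    corr = spearman_correlation(result["subset_size"], result["mean_nn"])
    try:
        fit = loess_fit(result["subset_size"], result["mean_nn"], span=span,
                        degree=degree)
    except ValueError:
        # degenerate design (single subset size or too few cells): no trend
        fit = None
    return result, corr, fit
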