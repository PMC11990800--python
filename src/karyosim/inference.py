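"""Approximate Bayesian computation for selection and CNA-rate parameters.

Three inference tasks are supported, all sharing one engine:

* chromosome-arm selection rates ``lambda_r`` and the arm-missegregation
  probability, from a cohort's per-arm gain/loss frequencies;
* whole-genome duplication probability ``p_wgd`` and the WGD-aneuploidy rate
  ``alpha``, from the cohort's WGD proportion and WGD FGA difference;
* driver-gene selection rates ``lambda_d`` and the focal-deletion
  probability, from per-gene mutation/gain/loss frequencies.

The engine draws parameters from their priors, simulates one cohort per draw
(matched in size to the observed cohort), and regresses each parameter on the
summary statistics with a random forest; posterior weights follow the
random-forest ABC convention (training rows sharing the observed vector's
leaves, weighted inversely to leaf occupancy).  A classical
rejection/local-linear adjustment engine is available as a fallback.  Point
estimates are maximum a posteriori values: modes of weighted kernel density
estimates over the posterior draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Prior",
    "PriorSpec",
    "PosteriorTable",
    "build_reference_table",
    "abc_posterior",
    "infer_arm_selection",
    "infer_wgd",
    "infer_driver_selection",
    "label_driver_genes",
    "fit_beta_lengths",
]


@dataclass(frozen=True)
class Prior:
    """Uniform prior on ``[low, high]``; draws live on the stated scale.

    For log-scale parameters give bounds on the log10 scale and a name that
    says so (e.g. ``log10_p_wgd``).
    """

    name: str
    low: float
    high: float

    def __post_init__(self):
        if not np.isfinite(self.low) or not np.isfinite(self.high) or self.low >= self.high:
            raise ValueError(f"invalid prior bounds for {self.name}")

    def sample(self, rng, size=None):
        return rng.uniform(self.low, self.high, size=size)


@dataclass
class PriorSpec:
    """Free parameters (uniform priors) plus fixed parameters of a model."""

    priors: list
    fixed: dict = field(default_factory=dict)

    @property
    def names(self):
        return [p.name for p in self.priors]

    def sample(self, rng) -> dict:
        out = dict(self.fixed)
        for p in self.priors:
            out[p.name] = float(p.sample(rng))
        return out

    def bounds(self, name):
        for p in self.priors:
            if p.name == name:
                return p.low, p.high
        raise KeyError(name)


class PosteriorTable:
    """Per-parameter posterior draws with weights, MAP and mean estimates."""

    def __init__(self, draws: dict, priors: PriorSpec | None = None):
        # draws: name -> (values, weights); weights normalised to sum 1
        self.draws = {}
        for name, (v, w) in draws.items():
            v = np.asarray(v, dtype=float)
            w = np.asarray(w, dtype=float)
            if w.sum() <= 0:
                w = np.ones_like(w)
            self.draws[name] = (v, w / w.sum())
        self.priors = priors

    @property
    def names(self):
        return list(self.draws)

    def mean(self, name: str) -> float:
        v, w = self.draws[name]
        return float(v @ w)

    def quantile(self, name: str, q) -> np.ndarray:
        v, w = self.draws[name]
        order = np.argsort(v)
        cw = np.cumsum(w[order])
        return np.interp(np.atleast_1d(q), cw, v[order])

    def credible_interval(self, name: str, level: float = 0.9):
        lo, hi = self.quantile(name, [(1 - level) / 2, 1 - (1 - level) / 2])
        return float(lo), float(hi)

    def map_estimate(self, name: str) -> float:
        """Mode of the weighted kernel density over the posterior draws."""
        v, w = self.draws[name]
        if self.priors is not None and name in [p.name for p in self.priors.priors]:
            lo, hi = self.priors.bounds(name)
        else:
            lo, hi = float(v.min()), float(v.max())
        if np.ptp(v[w > 0]) < 1e-12 or np.count_nonzero(w) < 3:
            return float(v[np.argmax(w)])
        try:
            kde = stats.gaussian_kde(v, weights=w)
        except np.linalg.LinAlgError:
            return float(v[np.argmax(w)])
        grid = np.linspace(lo, hi, 512)
        return float(grid[np.argmax(kde(grid))])

    @property
    def map_estimates(self) -> dict:
        return {name: self.map_estimate(name) for name in self.draws}

    @property
    def means(self) -> dict:
        return {name: self.mean(name) for name in self.draws}


def build_reference_table(prior: PriorSpec, simulator, n_sims: int, rng):
    """Simulate the ABC reference table.

    ``simulator(params: dict, rng) -> 1d summary array``; one cohort per
    prior draw.  Returns ``(params DataFrame, summaries array)``.
    Deterministic given ``rng``.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    rows = []
    summaries = []
    for _ in range(n_sims):
        params = prior.sample(rng)
        s = np.asarray(simulator(params, rng), dtype=float)
        rows.append(params)
        summaries.append(s)
    return pd.DataFrame(rows), np.vstack(summaries)


def _rf_weights(X, y, observed, n_trees, min_samples_leaf, seed):
    from sklearn.ensemble import RandomForestRegressor

    rf = RandomForestRegressor(
        n_estimators=n_trees,
        min_samples_leaf=min_samples_leaf,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    leaves = rf.apply(X)  # (n, trees)
    leaf_obs = rf.apply(observed.reshape(1, -1))[0]
    match = leaves == leaf_obs[None, :]
    occupancy = match.sum(axis=0).astype(float)
    occupancy[occupancy == 0] = np.inf
    return (match / occupancy[None, :]).sum(axis=1) / match.shape[1]


def _rejection_weights(X, y, observed, accept_frac, bounds):
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    d = np.sqrt((((X - observed[None, :]) / sd) ** 2).sum(axis=1))
    n_keep = max(20, int(np.ceil(accept_frac * len(d))))
    idx = np.argsort(d)[:n_keep]
    dmax = d[idx].max() or 1.0
    w = 1.0 - (d[idx] / dmax) ** 2  # Epanechnikov
    w = np.clip(w, 1e-8, None)
    # local-linear adjustment of y toward the observed summary
    Z = (X[idx] - observed[None, :]) / sd
    A = np.hstack([np.ones((len(idx), 1)), Z])
    Aw = A * np.sqrt(w)[:, None]
    coef, *_ = np.linalg.lstsq(Aw, y[idx] * np.sqrt(w), rcond=None)
    y_adj = y[idx] - Z @ coef[1:]
    if bounds is not None:
        y_adj = np.clip(y_adj, bounds[0], bounds[1])
    return idx, y_adj, w


def abc_posterior(
    params: pd.DataFrame,
    summaries: np.ndarray,
    observed,
    prior: PriorSpec | None = None,
    engine: str = "rf",
    n_trees: int = 300,
    min_samples_leaf: int = 5,
    accept_frac: float = 0.1,
    seed: int = 0,
) -> PosteriorTable:
    """Per-parameter ABC posterior from a reference table.

    ``engine='rf'`` uses random-forest regression weights; ``'rejection'``
    keeps the nearest fraction of rows by normalised Euclidean distance with
    a weighted local-linear adjustment.
    """
    observed = np.asarray(observed, dtype=float).ravel()
    if observed.shape[0] != summaries.shape[1]:
        raise ValueError(
            f"observed summary has dimension {observed.shape[0]}, "
            f"reference table has {summaries.shape[1]}"
        )
    X = np.asarray(summaries, dtype=float)
    draws = {}
    for k, name in enumerate(params.columns):
        y = params[name].to_numpy(dtype=float)
        if engine == "rf":
            w = _rf_weights(X, y, observed, n_trees, min_samples_leaf, seed + k)
            draws[name] = (y, w)
        elif engine == "rejection":
            bounds = None
            if prior is not None:
                try:
                    bounds = prior.bounds(name)
                except KeyError:
                    bounds = None
            idx, y_adj, w = _rejection_weights(X, y, observed, accept_frac, bounds)
            draws[name] = (y_adj, w)
        else:
            raise ValueError(f"unknown ABC engine {engine!r}")
    return PosteriorTable(draws, priors=prior)


# ---------------------------------------------------------------------------
# task-level drivers
# ---------------------------------------------------------------------------

def infer_arm_selection(
    observed: pd.DataFrame,
    model,
    rng,
    n_sims: int = 2000,
    engine: str = "rf",
    freq_threshold: float = 0.1,
    use_abs: bool = True,
    min_cohort: int = 10,
    lam_bounds=(0.5, 1.5),
    p_arm_bounds=(0.004, 0.016),
    **abc_kwargs,
) -> dict:
    """Infer arm selection rates and the arm-missegregation probability.

    ``observed`` is the cohort frequency table (columns arm, fr_gain,
    fr_loss); ``model`` is a cohort simulator exposing ``cohort_size``,
    ``genome`` and ``cohort_arm_frequencies(rates, p_arm_misseg, rng)``.
    Arms whose frequency difference fails the filter are fixed at
    ``lambda = 1`` and excluded from inference.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if model.cohort_size < min_cohort:
        raise ValueError(
            f"cohort of {model.cohort_size} samples is below the minimum of {min_cohort}"
        )
    obs = observed.set_index("arm")
    arm_order = model.genome.arm_labels
    diffs = {a: float(obs.loc[a, "fr_gain"] - obs.loc[a, "fr_loss"]) for a in arm_order}
    if use_abs:
        inferred = [a for a in arm_order if abs(diffs[a]) >= freq_threshold]
    else:
        inferred = [a for a in arm_order if diffs[a] >= freq_threshold]
    result = {"inferred_arms": inferred, "posterior": None, "report": None,
              "warnings": []}
    if not inferred:
        result["warnings"].append(
            "no arm passes the gain/loss frequency filter; nothing to infer"
        )
        warnings.warn(result["warnings"][-1])
        return result

    priors = [Prior(f"lam_{a}", *lam_bounds) for a in inferred]
    priors.append(Prior("p_arm_misseg", *p_arm_bounds))
    spec = PriorSpec(priors)

    def simulator(params, rng_):
        rates = {a: params[f"lam_{a}"] for a in inferred}
        freq = model.cohort_arm_frequencies(rates, params["p_arm_misseg"], rng_)
        return np.concatenate([freq["fr_gain"].to_numpy(), freq["fr_loss"].to_numpy()])

    table_params, table_summ = build_reference_table(spec, simulator, n_sims, rng)
    obs_vec = np.concatenate(
        [
            np.array([obs.loc[a, "fr_gain"] for a in arm_order], dtype=float),
            np.array([obs.loc[a, "fr_loss"] for a in arm_order], dtype=float),
        ]
    )
    post = abc_posterior(table_params, table_summ, obs_vec, prior=spec,
                         engine=engine, **abc_kwargs)
    from .summaries import classify_arms

    means = {a: 1.0 for a in arm_order}
    means.update({a: post.mean(f"lam_{a}") for a in inferred})
    report = classify_arms(means, observed, freq_threshold=freq_threshold,
                           use_abs=use_abs)
    result["posterior"] = post
    result["report"] = report
    result["reference"] = (table_params, table_summ)
    return result


def infer_wgd(
    observed_stats,
    model,
    rng,
    rates: dict | None = None,
    n_sims: int = 1000,
    engine: str = "rf",
    min_wgd_proportion: float = 0.1,
    alpha_bounds=(1.0, 15.0),
    log10_p_wgd_bounds=(-2.0, -0.8),
    **abc_kwargs,
) -> PosteriorTable:
    """Infer the WGD probability and WGD-aneuploidy rate ``alpha``.

    ``observed_stats = (wgd_proportion, wgd_fga_difference)``.  Arm selection
    parameters are held fixed at ``rates`` (from a previous arm fit).
    Cohorts with WGD proportion at or below ``min_wgd_proportion`` are
    refused.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    prop = float(observed_stats[0])
    if prop <= min_wgd_proportion:
        raise ValueError(
            f"WGD proportion {prop:.3f} <= {min_wgd_proportion}; not analyzed"
        )
    rates = rates or {}
    spec = PriorSpec([
        Prior("log10_p_wgd", *log10_p_wgd_bounds),
        Prior("alpha", *alpha_bounds),
    ])

    def simulator(params, rng_):
        return model.cohort_wgd_stats(
            rates, 10.0 ** params["log10_p_wgd"], params["alpha"], rng_
        )

    table_params, table_summ = build_reference_table(spec, simulator, n_sims, rng)
    obs_vec = np.asarray(observed_stats, dtype=float)
    return abc_posterior(table_params, table_summ, obs_vec, prior=spec,
                         engine=engine, **abc_kwargs)


def infer_driver_selection(
    observed: pd.DataFrame,
    model,
    rng,
    n_sims: int = 800,
    engine: str = "rf",
    lam_bounds=(1.0, 1.4),
    p_focal_del_bounds=(0.001, 0.02),
    **abc_kwargs,
) -> dict:
    """Infer driver-gene selection rates and the focal-deletion probability.

    ``observed`` has columns gene, fr_mut, fr_gain, fr_loss.  The driver
    mutation rate is fixed in the model; genes absent from the observed
    table are excluded with a warning.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    obs = observed.set_index("gene")
    genes = [d.name for d in model.drivers]
    missing = [g for g in genes if g not in obs.index]
    warns = []
    if missing:
        warns.append(f"genes absent from observed summaries, excluded: {missing}")
        warnings.warn(warns[-1])
        genes = [g for g in genes if g not in missing]
    if not genes:
        raise ValueError("no driver gene overlaps the observed summaries")

    priors = [Prior(f"lam_{g}", *lam_bounds) for g in genes]
    priors.append(Prior("p_focal_del", *p_focal_del_bounds))
    spec = PriorSpec(priors)

    def simulator(params, rng_):
        lam = {g: params[f"lam_{g}"] for g in genes}
        freq = model.cohort_gene_frequencies(lam, params["p_focal_del"], rng_)
        freq = freq.set_index("gene").loc[genes]
        return np.concatenate(
            [freq["fr_mut"].to_numpy(), freq["fr_gain"].to_numpy(),
             freq["fr_loss"].to_numpy()]
        )

    table_params, table_summ = build_reference_table(spec, simulator, n_sims, rng)
    sub = obs.loc[genes]
    obs_vec = np.concatenate(
        [sub["fr_mut"].to_numpy(dtype=float), sub["fr_gain"].to_numpy(dtype=float),
         sub["fr_loss"].to_numpy(dtype=float)]
    )
    post = abc_posterior(table_params, table_summ, obs_vec, prior=spec,
                         engine=engine, **abc_kwargs)
    return {"posterior": post, "genes": genes, "warnings": warns,
            "reference": (table_params, table_summ)}


def label_driver_genes(frequencies: pd.DataFrame, fallback: dict | None = None) -> dict:
    """Label genes TSG or OG from cohort loss/gain frequencies.

    Loss > gain -> TSG; gain > loss -> OG; ties fall back to the annotation
    table; genes with a tie and no fallback are dropped with a warning.
    """
    fallback = fallback or {}
    roles = {}
    for _, row in frequencies.iterrows():
        gene = row["gene"]
        if row["fr_loss"] > row["fr_gain"]:
            roles[gene] = "TSG"
        elif row["fr_gain"] > row["fr_loss"]:
            roles[gene] = "OG"
        elif gene in fallback:
            roles[gene] = fallback[gene]
        else:
            warnings.warn(f"gene {gene}: tied gain/loss frequencies and no "
                          "fallback annotation; dropped")
    return roles


def fit_beta_lengths(ratios, eps: float = 1e-6):
    """Maximum-likelihood Beta fit to focal-length / arm-length ratios."""
    r = np.asarray(ratios, dtype=float)
    if r.size < 2:
        raise ValueError("need at least two ratios")
    if (r < 0).any() or (r > 1).any():
        raise ValueError("length ratios must lie in [0, 1]")
    if np.ptp(r) < 1e-12:
        raise ValueError("degenerate (constant) length ratios; cannot fit Beta")
    r = np.clip(r, eps, 1 - eps)
    a, b, _, _ = stats.beta.fit(r, floc=0, fscale=1)
    return float(a), float(b)
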