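"""Statistics matching neural frequency tuning to cue-map predictors.

For each neuron the smoothed rate-frequency tuning curve is compared
(Pearson) with a predictor profile — IPD reliability, gain, or
interaural correlation as a function of frequency at the neuron's
preferred direction.  At the population level: ordinary least-squares
regressions (BF vs best ITD, tuning edges vs map edges) and a Wilcoxon
rank-sum comparison of the correlation-coefficient distributions of two
competing predictors.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tuning import smooth_curve

__all__ = [
    "RegressionResult",
    "MatchResult",
    "tuning_vs_predictor",
    "population_regression",
    "compare_predictors",
    "edge_match",
    "match_population",
]

ALPHA_SIGNIFICANT = 0.05  # per-neuron two-sided significance threshold


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


@dataclass
class MatchResult:
    """Per-neuron correlations against each predictor plus the
    population-level regressions and predictor comparison."""

    per_neuron: pd.DataFrame  # columns: r_<predictor>, p_<predictor>, bf_hz, ...
    fraction_significant: dict
    bf_vs_best_itd: RegressionResult
    edge_regressions: dict
    ranksum_p: dict
    alpha: float = ALPHA_SIGNIFICANT

    def to_json(self, path=None) -> str:
        payload = {
            "fraction_significant": self.fraction_significant,
            "bf_vs_best_itd": asdict(self.bf_vs_best_itd),
            "edge_regressions": {k: asdict(v) for k, v in self.edge_regressions.items()},
            "ranksum_p": self.ranksum_p,
            "alpha": self.alpha,
            "n_neurons": int(len(self.per_neuron)),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text


def tuning_vs_predictor(
    freq_tuning_rates,
    predictor_profile,
    smoothing_window: int = 3,
) -> tuple[float, float]:
    """Pearson r and two-sided p between a smoothed frequency tuning
    curve and a predictor profile on the shared channel grid."""
    y = smooth_curve(np.asarray(freq_tuning_rates, dtype=float), smoothing_window)
    x = np.asarray(predictor_profile, dtype=float)
    if x.size != y.size:
        raise ValueError("curve and predictor must share the channel grid")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = stats.pearsonr(y, x)
    return float(r), float(p)


def population_regression(x, y) -> RegressionResult:
    """Ordinary least squares with a two-sided slope test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def compare_predictors(r_values_a, r_values_b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value between two
    samples of correlation coefficients."""
    a = np.asarray(r_values_a, dtype=float)
    b = np.asarray(r_values_b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("need at least 5 values per sample")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and a.size * b.size <= 2500) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def edge_match(neuron_edges, map_edges) -> dict:
    """Regress neuron frequency-tuning edges on cue-map band edges.

    Both arguments are ``(n, 2)`` arrays of ``(lower, upper)`` edges in
    Hz, paired by neuron.  Returns lower-vs-lower and upper-vs-upper
    `RegressionResult`s.
    """
    neuron_edges = np.asarray(neuron_edges, dtype=float)
    map_edges = np.asarray(map_edges, dtype=float)
    if neuron_edges.shape != map_edges.shape or neuron_edges.ndim != 2:
        raise ValueError("edge arrays must both be (n, 2)")
    return {
        "lower": population_regression(map_edges[:, 0], neuron_edges[:, 0]),
        "upper": population_regression(map_edges[:, 1], neuron_edges[:, 1]),
    }


def match_population(
    features: pd.DataFrame,
    predictors: dict,
    map_edges_by_neuron: np.ndarray | None = None,
    alpha: float = ALPHA_SIGNIFICANT,
    smoothing_window: int = 3,
) -> MatchResult:
    """Full matching analysis of an analysed population.

    ``features`` needs one row per neuron with columns ``bf_hz``,
    ``abs_best_itd_us``, ``f_low_hz``, ``f_high_hz`` and
    ``tuning_rates`` (array-like per row, on the channel grid).
    ``predictors`` maps predictor name to an ``(n_neurons, n_channels)``
    array of profiles at each neuron's preferred location.
    """
    records = {}
    for name, profiles in predictors.items():
        rs, ps = [], []
        for i, (_, row) in enumerate(features.iterrows()):
            try:
                r, p = tuning_vs_predictor(row["tuning_rates"], profiles[i], smoothing_window)
            except ValueError:
                r, p = np.nan, np.nan
            rs.append(r)
            ps.append(p)
        records[f"r_{name}"] = rs
        records[f"p_{name}"] = ps

    per_neuron = features.drop(columns=["tuning_rates"]).reset_index(drop=True)
    for col, vals in records.items():
        per_neuron[col] = vals

    fraction_significant = {
        name: float(
            np.mean(
                (per_neuron[f"p_{name}"] < alpha)
                & (per_neuron[f"r_{name}"] > 0)
            )
        )
        for name in predictors
    }

    bf_reg = population_regression(per_neuron["abs_best_itd_us"], per_neuron["bf_hz"])

    edge_regs = {}
    if map_edges_by_neuron is not None:
        neuron_edges = per_neuron[["f_low_hz", "f_high_hz"]].to_numpy()
        edge_regs = edge_match(neuron_edges, map_edges_by_neuron)

    names = list(predictors)
    ranksum_p = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = per_neuron[f"r_{names[i]}"].dropna()
            b = per_neuron[f"r_{names[j]}"].dropna()
            ranksum_p[f"{names[i]}_vs_{names[j]}"] = compare_predictors(a, b)

    return MatchResult(
        per_neuron=per_neuron,
        fraction_significant=fraction_significant,
        bf_vs_best_itd=bf_reg,
        edge_regressions=edge_regs,
        ranksum_p=ranksum_p,
        alpha=alpha,
    )
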