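"""Sloan neutral community model: occurrence frequency vs mean abundance.

The model predicts the probability that a taxon with metacommunity mean
relative abundance p is detected in a local community of size N under
migration rate m:

    freq(p) = 1 - BetaCDF(d; Nm*p, Nm*(1-p)),   Nm = N*m,  d = 1/N

where d is the detection limit (one read).  Nm is estimated by nonlinear
least squares of the observed occurrence frequencies against this curve,
goodness of fit is the coefficient of determination R^2, and each taxon is
partitioned as above / within / below the 95% band around its predicted
frequency (Wilson score interval by default, matching Burns-style
implementations; beta quantiles behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.proportion import proportion_confint

from .io import AsvTable


def occurrence_stats(table: AsvTable) -> pd.DataFrame:
    """Per-taxon mean relative abundance p and occurrence frequency.

    p is the mean over samples of the within-sample relative abundance;
    frequency is the fraction of samples where the taxon has a nonzero count.
    """
    x = table.values().astype(float)
    if x.size == 0:
        raise ValueError("empty table")
    totals = x.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("all-zero samples present")
    rel = x / totals
    return pd.DataFrame(
        {"p": rel.mean(axis=0), "frequency": (x > 0).mean(axis=0)},
        index=table.taxon_ids,
    )


def ncm_predict(p, Nm: float, N: float, d: float | None = None):
    """Predicted occurrence frequency 1 - BetaCDF(d; Nm*p, Nm*(1-p))."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie strictly in (0, 1)")
    if Nm <= 0 or N <= 0:
        raise ValueError("Nm and N must be positive")
    if d is None:
        d = 1.0 / N
    out = stats.beta.sf(d, Nm * p, Nm * (1.0 - p))
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


@dataclass
class NCMResults:
    """Fitted neutral-model parameters with the per-taxon partition."""

    Nm: float
    m: float
    N: float
    d: float
    r_squared: float
    taxa: pd.DataFrame  # p, frequency, predicted, lower, upper, partition
    fraction_within: float
    n_samples: int
    n_taxa_fit: int

    @property
    def fraction_above(self) -> float:
        return float((self.taxa["partition"] == "above").mean())

    @property
    def fraction_below(self) -> float:
        return float((self.taxa["partition"] == "below").mean())

    def summary(self) -> str:
        return "\n".join([
            "Sloan neutral community model fit",
            "=" * 40,
            f"samples                 {self.n_samples}",
            f"taxa in fit             {self.n_taxa_fit}",
            f"N (mean reads/sample)   {self.N:.1f}",
            f"Nm                      {self.Nm:.1f}",
            f"m = Nm/N                {self.m:.5f}",
            f"detection limit d       {self.d:.3g}",
            f"R^2                     {self.r_squared:.3f}",
            f"within 95% band         {100 * self.fraction_within:.2f}%",
            f"above band              {100 * self.fraction_above:.2f}%",
            f"below band              {100 * self.fraction_below:.2f}%",
        ])

    def plot(self, ax=None):
        """Occurrence-frequency vs log10(p) with the fitted curve and band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.taxa.sort_values("p")
        colors = t["partition"].map(
            {"within": "0.4", "above": "tab:green", "below": "tab:red"})
        ax.scatter(np.log10(t["p"]), t["frequency"], s=8, c=colors)
        ax.plot(np.log10(t["p"]), t["predicted"], color="tab:blue")
        ax.plot(np.log10(t["p"]), t["lower"], "--", color="tab:blue")
        ax.plot(np.log10(t["p"]), t["upper"], "--", color="tab:blue")
        ax.set_xlabel("log10 mean relative abundance")
        ax.set_ylabel("occurrence frequency")
        ax.set_title(f"NCM: Nm={self.Nm:.0f}, R²={self.r_squared:.3f}")
        return ax


class NeutralCommunityModel:
    """Sloan neutral model of occupancy-abundance structure.

    Parameters
    ----------
    table : AsvTable
        Count table (post filtering/rarefaction).  N is the mean sample
        depth; after rarefaction this equals the common depth.
    """

    def __init__(self, table: AsvTable, detection_limit: float | None = None):
        self.table = table
        self.N = float(table.values().sum(axis=1).mean())
        self.d = detection_limit if detection_limit is not None else 1.0 / self.N

    def fit(self, ci_method: str = "wilson", bounds: tuple = (1.0, 1e7)) -> NCMResults:
        """Estimate Nm by bounded least squares on occurrence frequencies.

        Taxa with p outside (0,1) (absent or fixed everywhere) are excluded
        from the SSE but reported.  R^2 = 1 - SSE/SST about the mean observed
        frequency; it is not clamped and can be negative.
        """
        occ = occurrence_stats(self.table)
        usable = occ[(occ["p"] > 0) & (occ["p"] < 1) & (occ["frequency"] > 0)]
        if len(usable) < 10:
            raise ValueError("need at least 10 taxa with p in (0,1) to fit")
        return fit_occupancy_curve(
            usable["p"], usable["frequency"], N=self.N, d=self.d,
            n_samples=self.table.shape[0], ci_method=ci_method, bounds=bounds,
        )


def fit_occupancy_curve(p, freq, N: float, d: float, n_samples: int,
                        ci_method: str = "wilson",
                        bounds: tuple = (1.0, 1e7)) -> NCMResults:
    """Least-squares Sloan fit of occurrence frequency vs mean abundance.

    The optimization is a bounded 1-D search over log(Nm).  Exposed
    separately from :class:`NeutralCommunityModel` so a frequency curve from
    any source (including one constructed to lie exactly on the model) can
    be fit directly.
    """
    index = p.index if isinstance(p, pd.Series) else None
    p = np.asarray(p, dtype=float)
    freq = np.asarray(freq, dtype=float)

    def sse(log_nm):
        pred = ncm_predict(p, np.exp(log_nm), N, d)
        return ((freq - pred) ** 2).sum()

    res = optimize.minimize_scalar(
        sse, bounds=(np.log(bounds[0]), np.log(bounds[1])), method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise RuntimeError(f"NCM fit failed to converge (last Nm={np.exp(res.x):.3g}, "
                           f"SSE={res.fun:.3g})")
    nm = float(np.exp(res.x))
    pred = ncm_predict(p, nm, N, d)
    sst = ((freq - freq.mean()) ** 2).sum()
    r2 = 1.0 - res.fun / sst if sst > 0 else float("nan")
    lower, upper = _ci_band(pred, n_samples, ci_method)
    partition = np.where(freq > upper, "above",
                         np.where(freq < lower, "below", "within"))
    taxa = pd.DataFrame({
        "p": p, "frequency": freq, "predicted": pred,
        "lower": lower, "upper": upper, "partition": partition,
    }, index=index)
    return NCMResults(
        Nm=nm, m=nm / N, N=N, d=d, r_squared=float(r2),
        taxa=taxa, fraction_within=float((partition == "within").mean()),
        n_samples=n_samples, n_taxa_fit=len(p),
    )


def _ci_band(pred: np.ndarray, n_samples: int, method: str):
    """95% band around predicted occurrence frequencies.

    ``wilson``: Wilson score interval for a binomial proportion at the
    predicted frequency with n = number of samples.  ``beta``: 2.5/97.5%
    quantiles of Binomial(n, pred)/n (Clopper-Pearson-style count band).
    """
    if method == "wilson":
        lower, upper = proportion_confint(pred * n_samples, n_samples, alpha=0.05,
                                          method="wilson")
    elif method == "beta":
        lower = stats.binom.ppf(0.025, n_samples, pred) / n_samples
        upper = stats.binom.ppf(0.975, n_samples, pred) / n_samples
    else:
        raise ValueError("ci_method must be 'wilson' or 'beta'")
    return np.asarray(lower), np.asarray(upper)


def ncm_fit(table: AsvTable, **kwargs) -> NCMResults:
    """Functional shorthand for ``NeutralCommunityModel(table).fit(**kwargs)``."""
    return NeutralCommunityModel(table).fit(**kwargs)
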