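"""Bayesian two-group relevance analysis by Gibbs sampling.

Per metabolite the model is y_ij = µ_i + e_ij with i ∈ {H, L} and
e ~ Normal(0, σ²), under flat (improper uniform) priors on both group means
and on σ².  The full conditionals are Normal for the means and scaled
inverse-chi-square for σ², so a Gibbs sampler applies; because they depend
on the data only through per-group means and the within-group sum of
squares, the sweep is vectorised over all metabolites and chains at once.

Posterior summaries per metabolite: the mean of D = µ_H − µ_L (in SD units
when fitted on autoscaled data), P0 (posterior probability that D exceeds 0
if its mean is positive, or is below 0 if negative), the 95% highest
posterior density interval, and the posterior error probability
PEP = (1 − P0)/0.5.  Relevance is declared with a Storey-style q-value
analogue: sort PEPs ascending, take running means (cumulative PEP), and flag
metabolites while the cumulative PEP stays at or below the target level.

Under the flat priors the marginal posterior of D has a closed form — a
location-scale t with n₁+n₂−4 degrees of freedom (uniform prior on σ² costs
two degrees relative to the Jeffreys posterior), location ȳ_H − ȳ_L and
scale sqrt(SSE/(n−4) · (1/n₁ + 1/n₂)) — which the test suite uses as an
independent oracle for the sampler.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import TransformedMatrix
from .errors import ConfigError, InputError


@dataclass
class GibbsConfig:
    """Gibbs sampler settings: chains, length, thinning lag, burn-in."""

    n_chains: int = 4
    n_iter: int = 50_000
    thin: int = 10
    burn_in: int = 1_000
    seed: int | None = None

    def validate(self) -> None:
        if self.n_chains < 1:
            raise ConfigError(f"n_chains must be >= 1, got {self.n_chains}")
        if self.thin < 1:
            raise ConfigError(f"thin must be >= 1, got {self.thin}")
        if not 0 <= self.burn_in < self.n_iter:
            raise ConfigError(
                f"burn_in must lie in [0, n_iter), got burn_in={self.burn_in}, "
                f"n_iter={self.n_iter}"
            )

    @property
    def kept_per_chain(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    @property
    def kept_total(self) -> int:
        return self.kept_per_chain * self.n_chains


@dataclass
class PosteriorSummary:
    """Per-metabolite posterior summary of the H − L contrast."""

    metabolite_id: str
    mean_diff: float
    p0: float
    hpd95_low: float
    hpd95_high: float
    pep: float
    cum_pep: float | None = None
    relevant: bool | None = None


# ---------------------------------------------------------------------------
# sampler core
# ---------------------------------------------------------------------------
def _suff_stats(values: np.ndarray, is_h: np.ndarray):
    """Per-column group means and pooled within-group sum of squares."""
    yh, yl = values[is_h], values[~is_h]
    ybar_h = yh.mean(axis=0)
    ybar_l = yl.mean(axis=0)
    ssw = ((yh - ybar_h) ** 2).sum(axis=0) + ((yl - ybar_l) ** 2).sum(axis=0)
    return ybar_h, ybar_l, ssw, yh.shape[0], yl.shape[0]


def _gibbs_sweep(
    ybar_h: np.ndarray,
    ybar_l: np.ndarray,
    ssw: np.ndarray,
    n_h: int,
    n_l: int,
    config: GibbsConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gibbs draws of D = µ_H − µ_L, vectorised over chains × metabolites.

    Full conditionals under flat priors:
      µ_i | σ², y  ~  Normal(ȳ_i, σ²/n_i)
      σ² | µ, y    ~  Inv-Gamma(n/2 − 1, SSE(µ)/2),
    with SSE(µ) = SSW + n_H(µ_H − ȳ_H)² + n_L(µ_L − ȳ_L)².  Returns a
    (kept_total, p) array of pooled post-burn-in, thinned draws.
    """
    n = n_h + n_l
    shape = n / 2.0 - 1.0
    if shape <= 0:
        raise InputError(f"too few samples for the flat-prior model (n={n})")
    p = ybar_h.shape[0]
    c = config.n_chains
    sig2 = np.full((c, p), ssw / max(n - 2, 1))  # start at the pooled variance
    kept = np.empty((config.kept_per_chain, c, p))
    k = 0
    for it in range(1, config.n_iter + 1):
        mu_h = ybar_h + np.sqrt(sig2 / n_h) * rng.standard_normal((c, p))
        mu_l = ybar_l + np.sqrt(sig2 / n_l) * rng.standard_normal((c, p))
        sse = ssw + n_h * (mu_h - ybar_h) ** 2 + n_l * (mu_l - ybar_l) ** 2
        sig2 = 0.5 * sse / rng.gamma(shape, 1.0, size=(c, p))
        if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
            kept[k] = mu_h - mu_l
            k += 1
    return kept[:k].reshape(-1, p)


def gibbs_two_group(
    y_metabolite, labels, config: GibbsConfig | None = None
) -> np.ndarray:
    """Posterior draws of D = µ_H − µ_L for one metabolite.

    ``y_metabolite`` holds per-sample abundances (SD units when taken from an
    autoscaled matrix); ``labels`` the matching H/L population labels.
    Returns the pooled 1-D array of post-burn-in, thinned draws from all
    chains; deterministic given ``config.seed``.
    """
    config = config or GibbsConfig()
    config.validate()
    y = np.asarray(y_metabolite, dtype=float)
    labels = np.asarray(labels)
    if y.ndim != 1 or y.shape[0] != labels.shape[0]:
        raise InputError("y_metabolite and labels must be 1-D and equally long")
    if not np.all(np.isfinite(y)):
        raise InputError("non-finite abundance values")
    for c in ("H", "L"):
        if (labels == c).sum() < 2:
            raise InputError(f"class {c!r} has fewer than 2 samples")
    is_h = labels == "H"
    ybar_h, ybar_l, ssw, n_h, n_l = _suff_stats(y[:, None], is_h)
    rng = np.random.default_rng(config.seed)
    return _gibbs_sweep(ybar_h, ybar_l, ssw, n_h, n_l, config, rng)[:, 0]


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------
def hpd_interval(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest interval containing ``mass`` of the draws (window scan over
    the sorted sample)."""
    d = np.sort(np.asarray(draws, dtype=float))
    n = d.shape[0]
    if n == 0:
        raise InputError("empty draw vector")
    m = int(np.ceil(mass * n))
    if m >= n:
        return float(d[0]), float(d[-1])
    widths = d[m - 1 :] - d[: n - m + 1]
    i = int(np.argmin(widths))
    return float(d[i]), float(d[i + m - 1])


def summarize(draws: np.ndarray, metabolite_id: str = "") -> PosteriorSummary:
    """Posterior summary of one metabolite's contrast draws.

    P0 is the larger of the posterior masses above and below zero (hence
    always ≥ 0.5 up to ties at exactly zero); PEP = (1 − P0)/0.5 rescales the
    complementary mass so a sign-certain contrast has PEP 0 and a symmetric
    one PEP 1.
    """
    d = np.asarray(draws, dtype=float).ravel()
    if d.size == 0:
        raise InputError("empty draw vector")
    mean_diff = float(d.mean())
    p0 = float(max((d > 0).mean(), (d < 0).mean()))
    pep = float(min(max((1.0 - p0) / 0.5, 0.0), 1.0))
    low, high = hpd_interval(d, 0.95)
    return PosteriorSummary(
        metabolite_id=metabolite_id, mean_diff=mean_diff, p0=p0,
        hpd95_low=low, hpd95_high=high, pep=pep,
    )


def fdr_select(
    summaries: list[PosteriorSummary], alpha: float = 0.05
) -> list[PosteriorSummary]:
    """Cumulative-PEP (q-value analogue) relevance selection.

    PEPs are sorted ascending; the cumulative PEP at rank i is the mean of
    the i smallest PEPs — an estimate of the FDR were the list cut there.
    Metabolites with cumulative PEP ≤ alpha are flagged relevant.  Tied PEPs
    share the cumulative PEP of the largest tied rank.  Input order is
    restored on return.
    """
    if not summaries:
        raise InputError("empty summary list")
    peps = np.array([s.pep for s in summaries])
    order = np.argsort(peps, kind="stable")
    sorted_peps = peps[order]
    running = np.cumsum(sorted_peps) / np.arange(1, len(peps) + 1)
    # ties take the running mean at the last index of their tie group
    cum = running.copy()
    j = len(sorted_peps) - 1
    while j > 0:
        if sorted_peps[j - 1] == sorted_peps[j]:
            cum[j - 1] = cum[j]
        j -= 1
    for rank, idx in enumerate(order):
        s = summaries[idx]
        s.cum_pep = float(cum[rank])
        s.relevant = bool(cum[rank] <= alpha)
    return summaries


# ---------------------------------------------------------------------------
# whole-matrix sweep
# ---------------------------------------------------------------------------
def run_bayes(
    matrix: TransformedMatrix | pd.DataFrame,
    config: GibbsConfig | None = None,
    alpha: float = 0.05,
    labels=None,
) -> pd.DataFrame:
    """Per-metabolite Gibbs analysis of a full (autoscaled) matrix.

    Returns one row per column: meanDiff, P0, HPD95 bounds, PEP, cumulative
    PEP and the relevance flag at level ``alpha``, in the input column order.
    """
    config = config or GibbsConfig()
    config.validate()
    if isinstance(matrix, TransformedMatrix):
        values_df = matrix.values
        labels = matrix.population.to_numpy() if labels is None else np.asarray(labels)
    else:
        values_df = matrix
        if labels is None:
            raise InputError("labels are required when passing a plain matrix")
        labels = np.asarray(labels)
    values = values_df.to_numpy(dtype=float)
    if values.shape[0] != labels.shape[0]:
        raise InputError("matrix rows and labels differ in length")
    if not np.all(np.isfinite(values)):
        raise InputError("non-finite abundance values")
    for c in ("H", "L"):
        if (labels == c).sum() < 2:
            raise InputError(f"class {c!r} has fewer than 2 samples")

    is_h = labels == "H"
    ybar_h, ybar_l, ssw, n_h, n_l = _suff_stats(values, is_h)
    rng = np.random.default_rng(config.seed)
    draws = _gibbs_sweep(ybar_h, ybar_l, ssw, n_h, n_l, config, rng)

    summaries = [
        summarize(draws[:, j], metabolite_id=str(col))
        for j, col in enumerate(values_df.columns)
    ]
    fdr_select(summaries, alpha=alpha)
    return pd.DataFrame(
        {
            "metabolite": [s.metabolite_id for s in summaries],
            "meanDiff": [s.mean_diff for s in summaries],
            "P0": [s.p0 for s in summaries],
            "HPD95_low": [s.hpd95_low for s in summaries],
            "HPD95_high": [s.hpd95_high for s in summaries],
            "PEP": [s.pep for s in summaries],
            "cumPEP": [s.cum_pep for s in summaries],
            "relevant": [s.relevant for s in summaries],
        }
    )
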