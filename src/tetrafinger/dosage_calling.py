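"""Tetraploid allele-dosage calling from two-channel endpoint fluorescence.

Competitive allele-specific PCR (KASP/PARMS) reads out one fluorophore
per allele (FAM, HEX).  In an autotetraploid the allele-B copy number
per sample is 0-4, so the per-marker signal ratio ``hex/(fam+hex)``
forms up to five clusters.  Calling proceeds per marker:

1. the raw ratio is arcsine-square-root transformed (variance
   stabilisation for proportions);
2. one-dimensional Gaussian mixtures with k = 1..5 tied-variance
   components are fitted by EM under an order constraint on the
   component means, and k is selected by BIC;
3. components are mapped to dosage classes by matching their means to
   the canonical class centres ``arcsin(sqrt(d/4))`` (an order-preserving
   one-to-one assignment, so markers showing fewer than five classes are
   handled naturally);
4. each sample receives the maximum-posterior dosage when that posterior
   reaches the posterior threshold (default 0.6), and a missing call
   otherwise.  If the largest component holds a sample fraction above
   the peak threshold the marker is flagged non-segregating (the default
   threshold of 1.0 disables the flag).

The fit is deterministic given the seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

#: transformed-scale centres of the five dosage classes (ratio d/4)
CLASS_CENTERS = np.arcsin(np.sqrt(np.arange(5) / 4.0))

_MIN_VAR = 1e-10


def signal_ratio(fam: float, hex: float) -> float:
    """Raw allele-B signal fraction ``hex/(fam+hex)``.

    Returns NaN (uncallable) when both channels are zero.
    """
    total = fam + hex
    if total <= 0:
        return math.nan
    return hex / total


def transform_ratio(ratio):
    """Arcsine-square-root transform used on the fitting scale."""
    return np.arcsin(np.sqrt(np.clip(ratio, 0.0, 1.0)))


@dataclass
class MarkerMixtureFit:
    """Fitted mixture for one marker."""

    marker: str
    n_components: int
    means: np.ndarray          # transformed scale, increasing
    variance: float            # tied across components
    weights: np.ndarray
    dosage_of_component: np.ndarray  # dosage class per component
    log_likelihood: float
    bic_by_k: dict[int, float]
    converged: bool
    flags: list[str] = field(default_factory=list)


def _em_1d(x: np.ndarray, k: int, rng: np.random.Generator,
           n_restarts: int = 5, max_iter: int = 500,
           tol: float = 1e-8) -> tuple[np.ndarray, float, np.ndarray, float, bool]:
    """Tied-variance 1-D Gaussian mixture EM with sorted means.

    Restart 0 initialises means at data quantiles, restart 1 at k-means
    centres (robust when class sizes are very unbalanced); later
    restarts jitter the quantile means with the seeded RNG.  Returns
    (means, variance, weights, log-likelihood, converged) for the best
    restart.
    """
    n = len(x)
    spread = float(np.std(x)) + 1e-6
    best = None
    for r in range(n_restarts):
        if r == 1 and k > 1 and len(np.unique(x)) >= k:
            km = KMeans(n_clusters=k, n_init=3,
                        random_state=int(rng.integers(2 ** 31)))
            means = km.fit(x[:, None]).cluster_centers_.ravel()
        else:
            means = np.quantile(x, (np.arange(k) + 0.5) / k)
            if r > 1:
                means = means + rng.normal(0.0, 0.2 * spread, size=k)
        means = np.sort(means)
        var = max(float(np.var(x)) / (k * k), _MIN_VAR)
        weights = np.full(k, 1.0 / k)
        prev_ll = -np.inf
        converged = False
        for _ in range(max_iter):
            log_comp = (np.log(weights)
                        - 0.5 * np.log(2 * np.pi * var)
                        - 0.5 * (x[:, None] - means) ** 2 / var)
            log_norm = logsumexp(log_comp, axis=1)
            ll = float(log_norm.sum())
            resp = np.exp(log_comp - log_norm[:, None])
            nk = resp.sum(axis=0) + 1e-300
            weights = nk / n
            means = (resp * x[:, None]).sum(axis=0) / nk
            order = np.argsort(means)
            means, weights = means[order], weights[order]
            resp = resp[:, order]
            var = max(float((resp * (x[:, None] - means) ** 2).sum() / n),
                      _MIN_VAR)
            if abs(ll - prev_ll) < tol:
                converged = True
                break
            prev_ll = ll
        if best is None or ll > best[3]:
            best = (means, var, weights, ll, converged)
    return best


#: minimum separation of adjacent component means on the transformed
#: scale: half the smallest gap between canonical class centres.  Models
#: whose fitted means sit closer describe sub-structure within one dosage
#: class, not distinct classes, and are excluded from selection.
MIN_COMPONENT_SEPARATION = float(np.diff(CLASS_CENTERS).min()) / 2.0


def fit_marker_mixture(marker: str, transformed: np.ndarray,
                       rng: np.random.Generator,
                       max_components: int = 5,
                       peak_threshold: float = 1.0,
                       min_separation: float = MIN_COMPONENT_SEPARATION,
                       ) -> MarkerMixtureFit:
    """Fit k = 1..max_components mixtures to one marker and select by BIC
    among models whose adjacent means are at least ``min_separation``
    apart (k = 1 is always admissible)."""
    n = len(transformed)
    bic_by_k: dict[int, float] = {}
    fits = {}
    admissible = []
    for k in range(1, max_components + 1):
        means, var, weights, ll, conv = _em_1d(transformed, k, rng)
        n_params = 2 * k  # k means + (k-1) weights + 1 tied variance
        bic_by_k[k] = -2.0 * ll + n_params * math.log(n)
        fits[k] = (means, var, weights, ll, conv)
        if k == 1 or float(np.diff(means).min()) >= min_separation:
            admissible.append(k)
    k_best = min(admissible, key=lambda k: (bic_by_k[k], k))
    means, var, weights, ll, conv = fits[k_best]
    # order-preserving one-to-one map of components to dosage classes:
    # L1 cost to the canonical centres; with sorted means and sorted
    # centres the optimal assignment is monotone
    cost = np.abs(means[:, None] - CLASS_CENTERS[None, :])
    rows, cols = linear_sum_assignment(cost)
    dosage_of_component = np.empty(k_best, dtype=int)
    dosage_of_component[rows] = cols
    flags = []
    if not conv:
        flags.append("em_not_converged")
    if float(weights.max()) > peak_threshold:
        flags.append("non_segregating")
    return MarkerMixtureFit(marker=marker, n_components=k_best, means=means,
                            variance=var, weights=weights,
                            dosage_of_component=dosage_of_component,
                            log_likelihood=ll, bic_by_k=bic_by_k,
                            converged=conv, flags=flags)


class DosageMixtureModel:
    """Mixture-model dosage caller over a long-format fluorescence table.

    Parameters
    ----------
    signals : pandas.DataFrame
        Columns ``sample``, ``marker``, ``fam``, ``hex``.
    orientation : {"fam-is-A", "hex-is-A"}
        Which fluorophore reports the A allele.  With the default
        ``fam-is-A``, HEX intensity grows with B dosage, so the lowest
        ratio cluster is dosage 0.  The MA statistic downstream depends
        on this; set it per assay design.
    """

    def __init__(self, signals: pd.DataFrame,
                 orientation: str = "fam-is-A") -> None:
        required = {"sample", "marker", "fam", "hex"}
        if not required <= set(signals.columns):
            raise ValueError(f"signals must carry columns {sorted(required)}")
        if orientation not in ("fam-is-A", "hex-is-A"):
            raise ValueError(f"unknown orientation {orientation!r}")
        self.signals = signals.reset_index(drop=True)
        self.orientation = orientation

    def fit(self, posterior_threshold: float = 0.6,
            peak_threshold: float = 1.0, max_components: int = 5,
            min_records: int = 10, seed: int = 0) -> "DosageCallingResults":
        """Fit every marker and assign dosage calls.

        Markers with fewer than ``min_records`` callable records are left
        uncalled and flagged.
        """
        rng = np.random.default_rng(seed)
        df = self.signals.copy()
        ratio = (df["hex"] / (df["fam"] + df["hex"])).where(
            df["fam"] + df["hex"] > 0)
        if self.orientation == "hex-is-A":
            ratio = 1.0 - ratio
        df["ratio"] = ratio
        df["transformed"] = transform_ratio(ratio)
        df["dosage"] = np.nan
        df["posterior"] = np.nan
        fits: dict[str, MarkerMixtureFit] = {}
        for marker, idx in df.groupby("marker", sort=False).groups.items():
            sub = df.loc[idx]
            callable_mask = sub["ratio"].notna()
            x = sub.loc[callable_mask, "transformed"].to_numpy()
            if len(x) < min_records:
                fits[marker] = MarkerMixtureFit(
                    marker=marker, n_components=0, means=np.empty(0),
                    variance=math.nan, weights=np.empty(0),
                    dosage_of_component=np.empty(0, dtype=int),
                    log_likelihood=math.nan, bic_by_k={}, converged=False,
                    flags=["too_few_records"])
                continue
            fit = fit_marker_mixture(marker, x, rng,
                                     max_components=max_components,
                                     peak_threshold=peak_threshold)
            fits[marker] = fit
            if "em_not_converged" in fit.flags:
                logger.warning("marker %s: EM did not converge; calls withheld",
                               marker)
                continue
            log_comp = (np.log(fit.weights)
                        - 0.5 * np.log(2 * np.pi * fit.variance)
                        - 0.5 * (x[:, None] - fit.means) ** 2 / fit.variance)
            resp = np.exp(log_comp - logsumexp(log_comp, axis=1)[:, None])
            best_comp = resp.argmax(axis=1)
            posterior = resp[np.arange(len(x)), best_comp]
            dosage = fit.dosage_of_component[best_comp].astype(float)
            dosage[posterior < posterior_threshold] = np.nan
            called_idx = sub.index[callable_mask]
            df.loc[called_idx, "posterior"] = posterior
            df.loc[called_idx, "dosage"] = dosage
        n_assigned = int(df["dosage"].notna().sum())
        logger.info("dosage calling: %d of %d records assigned",
                    n_assigned, len(df))
        return DosageCallingResults(model=self, calls=df, marker_fits=fits,
                                    posterior_threshold=posterior_threshold,
                                    peak_threshold=peak_threshold, seed=seed)


@dataclass
class DosageCallingResults:
    """Calls plus per-marker fitted mixtures from a :class:`DosageMixtureModel`."""

    model: DosageMixtureModel
    calls: pd.DataFrame
    marker_fits: dict[str, MarkerMixtureFit]
    posterior_threshold: float
    peak_threshold: float
    seed: int

    def to_matrix(self) -> pd.DataFrame:
        """Pivot calls into a samples x markers dosage matrix."""
        return calls_to_matrix(self.calls)

    def summary(self) -> pd.DataFrame:
        """Per-marker fit summary: components, call rate, variance, flags."""
        rows = []
        for marker, fit in self.marker_fits.items():
            sub = self.calls[self.calls["marker"] == marker]
            rows.append({
                "marker": marker,
                "n_records": len(sub),
                "n_called": int(sub["dosage"].notna().sum()),
                "n_components": fit.n_components,
                "dosages_modelled": ",".join(
                    str(d) for d in fit.dosage_of_component),
                "variance": fit.variance,
                "converged": fit.converged,
                "flags": ";".join(fit.flags),
            })
        return pd.DataFrame(rows).set_index("marker")

    def model_report(self) -> dict:
        """JSON-serialisable report of every marker fit."""
        out = {}
        for marker, fit in self.marker_fits.items():
            out[marker] = {
                "n_components": fit.n_components,
                "means": [float(m) for m in fit.means],
                "variance": None if math.isnan(fit.variance) else fit.variance,
                "weights": [float(w) for w in fit.weights],
                "dosage_of_component": [int(d) for d in fit.dosage_of_component],
                "bic_by_k": {str(k): v for k, v in fit.bic_by_k.items()},
                "converged": fit.converged,
                "flags": fit.flags,
            }
        return out


def calls_to_matrix(calls: pd.DataFrame) -> pd.DataFrame:
    """Pivot a calls table into a samples x markers dosage matrix.

    At most one call per (sample, marker) is allowed; combinations absent
    from the table come out missing.
    """
    dup = calls.duplicated(subset=["sample", "marker"])
    if dup.any():
        first = calls.loc[dup.idxmax()]
        raise ValueError(
            f"duplicate call for sample {first['sample']!r}, "
            f"marker {first['marker']!r}")
    matrix = calls.pivot(index="sample", columns="marker", values="dosage")
    # preserve first-appearance order of samples and markers
    matrix = matrix.reindex(index=pd.unique(calls["sample"]),
                            columns=pd.unique(calls["marker"]))
    matrix.columns.name = None
    matrix.index.name = None
    return matrix
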