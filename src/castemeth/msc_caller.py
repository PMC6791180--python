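"""Binary methylation-status calling via a two-component count mixture.

In a sparsely methylated genome, per-CpG methylated read counts are a
mixture of (i) an error component — truly unmethylated cytosines emitting
methylated reads at the bisulfite non-conversion rate ``p0`` — and (ii) a
methylated component whose level varies between sites.  The model fitted
here, per sample across sites, is

    P(k | n) = (1 - pi) * Binomial(k; n, p0) + pi * Comp1(k; n)

where ``Comp1`` is by default a beta-binomial (absorbing biological
variation in methylation level) or, optionally, a point binomial.  The EM
fit yields a posterior probability of methylation per site; binary calls
are made by ranking sites on posterior and choosing the largest call set
whose estimated false discovery rate (mean of 1 - posterior over called
sites) stays at or below the target.  The mean posterior over uncalled
sites — the non-discovery rate — is reported alongside.

The mixture is exposed statsmodels-style: :class:`BinomialMixture` is built
from the counts and ``fit()`` returns an :class:`MscModel` carrying the
estimates, the log-likelihood trace and posterior machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln, gammaln


def _log_binom_coeff(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _log_binom_pmf(k, n, p):
    p = min(max(p, 1e-12), 1 - 1e-12)
    return _log_binom_coeff(k, n) + k * np.log(p) + (n - k) * np.log1p(-p)


def _log_betabinom_pmf(k, n, a, b):
    return _log_binom_coeff(k, n) + betaln(k + a, n - k + b) - betaln(a, b)


@dataclass
class MscModel:
    """Fitted two-component methylation-status mixture for one sample.

    ``pi`` is the weight of the methylated component; ``p0`` the error
    (non-conversion) rate; the methylated component is Beta-binomial with
    ``(alpha1, beta1)`` or, for the point variant, Binomial with ``p1``.
    """

    pi: float
    p0: float
    component1: str                      # "betabinom" | "binomial"
    alpha1: float | None = None
    beta1: float | None = None
    p1: float | None = None
    loglik: float = float("-inf")
    n_iter: int = 0
    converged: bool = True
    degenerate: bool = False
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def component1_mean(self) -> float:
        if self.component1 == "binomial":
            return float(self.p1)
        return float(self.alpha1 / (self.alpha1 + self.beta1))

    def _log_f1(self, k: np.ndarray, n: np.ndarray) -> np.ndarray:
        if self.component1 == "binomial":
            return _log_binom_pmf(k, n, self.p1)
        return _log_betabinom_pmf(k, n, self.alpha1, self.beta1)

    def posterior(self, n_meth, n_total) -> np.ndarray:
        """Posterior probability that each site belongs to the methylated component."""
        k = np.asarray(n_meth, dtype=float)
        n = np.asarray(n_total, dtype=float)
        if self.pi <= 0.0:
            return np.zeros_like(k)
        if self.pi >= 1.0:
            return np.ones_like(k)
        log0 = np.log1p(-self.pi) + _log_binom_pmf(k, n, self.p0)
        log1 = np.log(self.pi) + self._log_f1(k, n)
        return np.exp(log1 - np.logaddexp(log0, log1))

    def summary(self) -> str:
        lines = [
            "Binomial mixture methylation-status model",
            f"  component 1      : {self.component1}",
            f"  pi (meth weight) : {self.pi:.6g}",
            f"  p0 (error rate)  : {self.p0:.6g}",
            f"  comp-1 mean      : {self.component1_mean if self.pi > 0 else float('nan'):.4g}",
            f"  log-likelihood   : {self.loglik:.6g}",
            f"  EM iterations    : {self.n_iter} (converged={self.converged})",
        ]
        if self.degenerate:
            lines.append("  [degenerate fit: no methylated signal]")
        return "\n".join(lines)


class BinomialMixture:
    """Two-component binomial mixture across all CpGs of one sample.

    Parameters
    ----------
    n_meth, n_total
        Per-site methylated and total read counts.
    p0
        Error-component success probability; by default the lambda-spike
        non-conversion estimate, held fixed during EM (``fix_p0=False``
        frees it).
    component1
        ``"betabinom"`` (default) or ``"binomial"`` for a point-mass level.
    """

    def __init__(
        self,
        n_meth,
        n_total,
        p0: float = 0.0045,
        component1: str = "betabinom",
        fix_p0: bool = True,
    ):
        self.k = np.asarray(n_meth, dtype=float)
        self.n = np.asarray(n_total, dtype=float)
        if self.k.shape != self.n.shape:
            raise ValueError("n_meth and n_total must have the same shape")
        if np.any(self.k < 0) or np.any(self.k > self.n):
            raise ValueError("counts must satisfy 0 <= n_meth <= n_total")
        if component1 not in ("betabinom", "binomial"):
            raise ValueError(f"unknown component1 {component1!r}")
        self.p0 = float(p0)
        self.component1 = component1
        self.fix_p0 = fix_p0

    def _loglik(self, pi, p0, theta) -> float:
        log0 = np.log1p(-pi) + _log_binom_pmf(self.k, self.n, p0)
        if self.component1 == "binomial":
            log1 = np.log(max(pi, 1e-300)) + _log_binom_pmf(self.k, self.n, theta)
        else:
            a, b = theta
            log1 = np.log(max(pi, 1e-300)) + _log_betabinom_pmf(self.k, self.n, a, b)
        return float(np.logaddexp(log0, log1).sum())

    def fit(self, tol: float = 1e-6, max_iter: int = 500) -> MscModel:
        """EM fit; the log-likelihood is non-decreasing across iterations.

        Initialization: ``pi`` from the fraction of sites with a majority of
        methylated reads, component-1 mean 0.8.  The beta-binomial M-step is
        a bounded Nelder–Mead refinement started from the current parameters
        (a generalized EM step, so monotonicity is preserved).
        """
        k, n = self.k, self.n
        if len(k) == 0 or not np.any(k > 0):
            # degenerate: nothing methylated at all
            model = MscModel(
                pi=0.0, p0=self.p0, component1=self.component1,
                alpha1=8.0, beta1=2.0, p1=0.8, loglik=0.0, degenerate=True,
            )
            model.loglik = self._loglik(0.0, self.p0, (8.0, 2.0) if
                                        self.component1 == "betabinom" else 0.8)
            return model

        pi = float(np.mean(k / np.maximum(n, 1) > 0.5))
        pi = min(max(pi, 1e-4), 1 - 1e-4)
        p0 = self.p0
        a, b = 8.0, 2.0          # beta-binomial start, mean 0.8
        p1 = 0.8

        theta = (a, b) if self.component1 == "betabinom" else p1
        loglik = self._loglik(pi, p0, theta)
        trace = [loglik]
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            # E-step
            log0 = np.log1p(-pi) + _log_binom_pmf(k, n, p0)
            if self.component1 == "binomial":
                log1 = np.log(pi) + _log_binom_pmf(k, n, p1)
            else:
                log1 = np.log(pi) + _log_betabinom_pmf(k, n, a, b)
            tau = np.exp(log1 - np.logaddexp(log0, log1))

            # M-step
            pi = float(np.clip(tau.mean(), 1e-8, 1 - 1e-8))
            if not self.fix_p0:
                w0 = 1.0 - tau
                p0 = float(np.clip((w0 * k).sum() / max((w0 * n).sum(), 1e-12),
                                   1e-8, 1 - 1e-8))
            if self.component1 == "binomial":
                denom = (tau * n).sum()
                if denom > 0:
                    p1 = float(np.clip((tau * k).sum() / denom, 1e-6, 1 - 1e-6))
            else:
                def neg_q(x):
                    aa, bb = np.exp(x)
                    return -float((tau * _log_betabinom_pmf(k, n, aa, bb)).sum())

                res = minimize(neg_q, np.log([a, b]), method="Nelder-Mead",
                               options={"maxiter": 60, "xatol": 1e-4, "fatol": 1e-8})
                cand = np.exp(res.x)
                # accept only if the weighted objective improved (GEM step)
                if neg_q(np.log(cand)) <= neg_q(np.log([a, b])):
                    a, b = float(cand[0]), float(cand[1])

            theta = (a, b) if self.component1 == "betabinom" else p1
            new_loglik = self._loglik(pi, p0, theta)
            trace.append(new_loglik)
            if abs(new_loglik - loglik) < tol:
                loglik = new_loglik
                converged = True
                break
            loglik = new_loglik

        if not converged:
            warnings.warn(
                f"EM did not converge in {max_iter} iterations "
                f"(last delta {trace[-1] - trace[-2]:.3g})",
                stacklevel=2,
            )
        return MscModel(
            pi=pi, p0=p0, component1=self.component1,
            alpha1=a if self.component1 == "betabinom" else None,
            beta1=b if self.component1 == "betabinom" else None,
            p1=p1 if self.component1 == "binomial" else None,
            loglik=loglik, n_iter=it, converged=converged, loglik_trace=trace,
        )


def fit_msc(
    n_meth,
    n_total,
    p0: float = 0.0045,
    component1: str = "betabinom",
    fix_p0: bool = True,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> MscModel:
    """Fit the methylation-status mixture for one sample (functional wrapper)."""
    return BinomialMixture(
        n_meth, n_total, p0=p0, component1=component1, fix_p0=fix_p0
    ).fit(tol=tol, max_iter=max_iter)


def fdr_call_mask(posterior: np.ndarray, fdr_target: float = 0.05) -> np.ndarray:
    """Boolean call mask: largest posterior-ranked set with estimated FDR <= target.

    The estimated FDR of a call set is the mean of (1 - posterior) over the
    called sites.
    """
    posterior = np.asarray(posterior, dtype=float)
    order = np.argsort(-posterior, kind="stable")
    sorted_post = posterior[order]
    called = np.zeros(len(posterior), dtype=bool)
    if len(sorted_post):
        cum_fdr = np.cumsum(1.0 - sorted_post) / np.arange(1, len(sorted_post) + 1)
        ok = np.flatnonzero(cum_fdr <= fdr_target)
        n_called = (ok[-1] + 1) if len(ok) else 0
        called[order[:n_called]] = True
    # a zero-posterior site is never a discovery
    called &= posterior > 0
    return called


def call_status(
    model: MscModel,
    counts: pd.DataFrame,
    fdr_target: float = 0.05,
) -> pd.DataFrame:
    """Binary methylated/unmethylated calls under posterior-based FDR control.

    Sites are ranked by posterior; the cutoff is the largest call set whose
    estimated FDR — the mean of (1 - posterior) over called sites — is at
    most ``fdr_target``.  Output adds ``posterior``, ``status`` and the
    non-discovery rate (mean posterior over uncalled sites) as metadata in
    ``df.attrs['non_discovery_rate']``.
    """
    posterior = model.posterior(counts["n_meth"].to_numpy(),
                                counts["n_total"].to_numpy())
    called = fdr_call_mask(posterior, fdr_target)

    out = counts.copy()
    out["posterior"] = posterior
    out["status"] = np.where(called, "methylated", "unmethylated")
    out.attrs["estimated_fdr"] = (
        float(np.mean(1.0 - posterior[called])) if called.any() else 0.0
    )
    out.attrs["non_discovery_rate"] = (
        float(np.mean(posterior[~called])) if (~called).any() else 0.0
    )
    return out


def filter_informative(calls: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Sites called methylated in at least one sample.

    Input maps sample id to a call table (``chrom, pos, strand, status``).
    Returns the unique (chrom, pos, strand) rows that were methylated
    somewhere, with ``n_samples_methylated``; reduction bookkeeping is in
    ``attrs['n_sites_removed']``.
    """
    stacked = pd.concat(
        [t[["chrom", "pos", "strand", "status"]] for t in calls.values()],
        ignore_index=True,
    )
    grouped = (
        stacked.assign(meth=stacked["status"] == "methylated")
        .groupby(["chrom", "pos", "strand"], sort=True)["meth"]
        .sum()
        .rename("n_samples_methylated")
        .reset_index()
    )
    kept = grouped[grouped["n_samples_methylated"] > 0].reset_index(drop=True)
    kept.attrs["n_sites_removed"] = int(len(grouped) - len(kept))
    return kept
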