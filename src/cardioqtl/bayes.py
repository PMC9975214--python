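"""Wakefield approximate Bayes factors, single-trait fine-mapping with 99%
credible sets, and five-hypothesis colocalization of two summary-statistic
vectors.

Under a normal prior b ~ N(0, W) on the true effect and a normal estimate
b_hat ~ N(b, V), the approximate Bayes factor for association at one
variant is

    ABF = sqrt(1 - r) * exp(r * z^2 / 2),  r = W / (V + W),  z = b_hat / se

(computed in log space throughout). Single-trait fine-mapping assumes one
causal variant per signal with a flat prior, so PPA_i is the softmax of the
log-ABFs. Colocalization enumerates the five standard hypotheses H0-H4 for
a pair of traits over a shared, identically ordered variant list with
per-hypothesis priors p1, p2, p12.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .types import ColocResult, CredibleSet

DEFAULT_W = 0.15**2


@dataclass
class ABFConfig:
    """Effect-size prior and colocalization priors (quantitative-trait defaults)."""

    w: float = DEFAULT_W
    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    pp_threshold: float = 0.8       # label cut for colocalized / distinct

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError("prior effect variance W must be positive")
        if not (0 < self.p12 <= min(self.p1, self.p2)):
            raise ValueError("require 0 < p12 <= min(p1, p2)")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("prior probabilities must sum below 1")


def wakefield_log_abf(
    beta: np.ndarray, se: np.ndarray, config: ABFConfig | None = None
) -> np.ndarray:
    """log approximate Bayes factor per variant; se <= 0 yields NaN with a warning."""
    config = config or ABFConfig()
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    bad = ~(se > 0)
    if np.any(bad):
        warnings.warn(f"excluding {int(bad.sum())} variant(s) with non-positive SE")
    v = np.where(bad, np.nan, se**2)
    r = config.w / (v + config.w)
    z2 = (beta / np.where(bad, np.nan, se)) ** 2
    return 0.5 * (np.log1p(-r) + r * z2)


def finemap_ppa(log_abfs: np.ndarray) -> np.ndarray:
    """Posterior probability of association under a single causal variant
    with a flat prior: softmax of the log-ABFs (NaN entries get PPA 0)."""
    la = np.asarray(log_abfs, dtype=float)
    if la.size == 0:
        raise ValueError("empty locus")
    ok = np.isfinite(la)
    if not ok.any():
        raise ValueError("no usable variants at locus")
    out = np.zeros_like(la)
    out[ok] = np.exp(la[ok] - logsumexp(la[ok]))
    return out


def credible_set_99(
    ppas: np.ndarray,
    variant_ids: np.ndarray,
    positions: np.ndarray | None = None,
    mass: float = 0.99,
) -> CredibleSet:
    """Shortest descending-PPA prefix whose cumulative mass is strictly > mass.

    PPA ties are broken by ascending position (when given) then variant id,
    so the set is deterministic.
    """
    ppas = np.asarray(ppas, dtype=float)
    variant_ids = np.asarray(variant_ids)
    if positions is None:
        positions = np.arange(len(ppas))
    order = np.lexsort((np.asarray(variant_ids, dtype=str), np.asarray(positions), -ppas))
    sorted_ppa = ppas[order]
    cum = np.cumsum(sorted_ppa)
    # strictly-greater rule with a tolerance so rounding in the cumsum cannot
    # flip the boundary case (e.g. 198 x 0.005 must not count as > 0.99)
    k = int(np.searchsorted(cum, mass + 1e-12, side="right")) + 1
    k = min(k, len(ppas))
    return CredibleSet(
        variant_ids=[str(v) for v in variant_ids[order[:k]]],
        ppas=sorted_ppa[:k],
        cumulative=cum[:k],
    )


def _log_diff_exp(log_a: float, log_b: float) -> float:
    """log(exp(log_a) - exp(log_b)), -inf if the difference is not positive."""
    if log_b >= log_a:
        return -np.inf
    return log_a + np.log1p(-np.exp(log_b - log_a))


def coloc_two_traits(
    log_abf1: np.ndarray,
    log_abf2: np.ndarray,
    config: ABFConfig | None = None,
) -> ColocResult:
    """Five-hypothesis colocalization for two traits over one shared,
    identically ordered variant list.

    Configuration sums (in log space):
      H1: sum_i ABF1_i             H2: sum_j ABF2_j
      H3: sum_{i != j} ABF1_i ABF2_j = S1*S2 - S12
      H4: sum_i ABF1_i ABF2_i (= S12)
    with priors 1, p1, p2, p1*p2, p12 per configuration class.
    """
    config = config or ABFConfig()
    l1 = np.asarray(log_abf1, dtype=float)
    l2 = np.asarray(log_abf2, dtype=float)
    if l1.shape != l2.shape:
        raise ValueError("traits must share an identical ordered variant list")
    ok = np.isfinite(l1) & np.isfinite(l2)
    l1, l2 = l1[ok], l2[ok]
    n = len(l1)
    if n < 2:
        warnings.warn("fewer than 2 shared variants: colocalization not resolved")
        if n == 0:
            return ColocResult(pp=np.full(5, np.nan), n_variants=0, label="not_resolved")
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    s3 = _log_diff_exp(s1 + s2, s12)
    log_terms = np.array(
        [
            0.0,
            np.log(config.p1) + s1,
            np.log(config.p2) + s2,
            np.log(config.p1) + np.log(config.p2) + s3,
            np.log(config.p12) + s12,
        ]
    )
    pp = np.exp(log_terms - logsumexp(log_terms[np.isfinite(log_terms)]))
    pp[~np.isfinite(log_terms)] = 0.0
    pp /= pp.sum()
    if n < 2:
        label = "not_resolved"
    elif pp[4] > config.pp_threshold:
        label = "colocalized"
    elif pp[3] > config.pp_threshold:
        label = "distinct"
    else:
        label = "not_resolved"
    h4 = np.exp((l1 + l2) - s12)
    return ColocResult(pp=pp, n_variants=n, label=label, h4_ppa=h4)


def coloc_summary_pair(
    beta1, se1, beta2, se2, variant_ids=None, config: ABFConfig | None = None
) -> ColocResult:
    """Convenience wrapper: ABFs from two (beta, se) vectors, then coloc."""
    config = config or ABFConfig()
    res = coloc_two_traits(
        wakefield_log_abf(beta1, se1, config),
        wakefield_log_abf(beta2, se2, config),
        config,
    )
    if variant_ids is not None:
        res.variant_ids = np.asarray(variant_ids)
    return res


def best_pair_coloc(signals1, signals2, config: ABFConfig | None = None) -> ColocResult:
    """Maximum PP-H4 colocalization over the cross product of two signal
    lists (primary + conditional ``EqtlSignal``s, each carrying per-variant
    conditioned summary statistics)."""
    config = config or ABFConfig()
    best: ColocResult | None = None
    for s1 in signals1:
        ids1 = {v: k for k, v in enumerate(s1.scan.variant_ids)}
        for s2 in signals2:
            common = [v for v in s2.scan.variant_ids if v in ids1]
            if len(common) == 0:
                continue
            i1 = np.array([ids1[v] for v in common])
            idx2 = {v: k for k, v in enumerate(s2.scan.variant_ids)}
            i2 = np.array([idx2[v] for v in common])
            res = coloc_summary_pair(
                s1.scan.beta[i1],
                s1.scan.se[i1],
                s2.scan.beta[i2],
                s2.scan.se[i2],
                variant_ids=np.asarray(common),
                config=config,
            )
            res.signal_pair = (
                (s1.feature_id, s1.signal_rank),
                (s2.feature_id, s2.signal_rank),
            )
            if best is None or (
                np.isfinite(res.pp_h4) and res.pp_h4 > (best.pp_h4 if np.isfinite(best.pp_h4) else -1)
            ):
                best = res
    if best is None:
        warnings.warn("no overlapping variants for any signal pair")
        return ColocResult(pp=np.full(5, np.nan), n_variants=0, label="not_resolved")
    return best
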