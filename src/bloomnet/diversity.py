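"""Hill-number diversity, sample coverage, and rarefaction.

The pooled specimens of each treatment form an abundance vector; Hill
numbers qD give the effective number of equally-common species at
diversity order q (q=0 richness, q=1 exponential Shannon, q=2 inverse
Simpson).  Sample coverage is the estimated probability that the next
specimen collected belongs to an already-observed species, computed from
singleton and doubleton counts.  Rarefaction interpolates the expected
Hill numbers of random subsamples of m specimens drawn without
replacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = ["AbundanceVector", "hill_number", "sample_coverage", "rarefaction_curve"]


@dataclass
class AbundanceVector:
    """Species abundance counts for one assemblage."""

    species: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.species) != len(self.counts):
            raise ValueError("species/counts length mismatch")
        if (self.counts <= 0).any():
            raise ValueError("abundances must be strictly positive")

    @classmethod
    def from_series(cls, series) -> "AbundanceVector":
        return cls(species=list(series.index), counts=series.to_numpy())

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def richness(self) -> int:
        return len(self.counts)

    def f(self, k: int) -> int:
        """Number of species with abundance exactly k."""
        return int((self.counts == k).sum())


def hill_number(v: AbundanceVector, q: float) -> float:
    """Effective species count of order q: (sum p_i^q)^(1/(1-q)).

    q=0 is observed richness, q=1 the Shannon limit exp(-sum p ln p),
    q=2 the inverse Simpson index.
    """
    if q < 0:
        raise ValueError("diversity order q must be >= 0")
    if v.n == 0:
        raise ValueError("empty abundance vector")
    p = v.counts / v.n
    if abs(q - 1.0) < 1e-9:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def sample_coverage(v: AbundanceVector) -> float:
    """Estimated sample coverage Chat in [0, 1].

    Chat = 1 - (f1/n) * [(n-1) f1 / ((n-1) f1 + 2 f2)], from singleton
    (f1) and doubleton (f2) frequencies.  Coverage 1 means no singletons:
    the sample is estimated to have captured essentially all common species.
    """
    n = v.n
    if n < 2:
        raise ValueError("sample coverage needs n >= 2")
    f1, f2 = v.f(1), v.f(2)
    if f1 == 0:
        return 1.0
    denom = (n - 1) * f1 + 2 * f2
    return float(1.0 - (f1 / n) * ((n - 1) * f1 / denom))


def _log_choose(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def _expected_fk(counts: np.ndarray, m: int) -> np.ndarray:
    """E[f_k(m)] for k = 1..m under hypergeometric subsampling of m
    specimens: sum_i C(x_i, k) C(n - x_i, m - k) / C(n, m)."""
    n = counts.sum()
    ks = np.arange(1, m + 1)
    ef = np.zeros(m)
    log_cnm = _log_choose(np.array([n]), np.array([m]))[0]
    for x in counts:
        kk = ks[(ks <= x) & (m - ks <= n - x)]
        if len(kk) == 0:
            continue
        lp = (
            _log_choose(np.full(len(kk), x), kk)
            + _log_choose(np.full(len(kk), n - x), m - kk)
            - log_cnm
        )
        ef[kk - 1] += np.exp(lp)
    return ef


def rarefaction_curve(
    v: AbundanceVector, sizes, q: float = 0
) -> np.ndarray:
    """Expected Hill number of order q at each subsample size m <= n.

    For q=0 this is the classical hypergeometric rarefaction
    E[S_m] = sum_i [1 - C(n - x_i, m) / C(n, m)]; for q>0 the Hill number
    of the expected abundance-frequency counts of the subsample.  The curve
    is monotone non-decreasing in m and equals the observed qD at m = n.
    """
    sizes = np.atleast_1d(np.asarray(sizes, dtype=int))
    n = v.n
    if (sizes <= 0).any():
        raise ValueError("subsample sizes must be positive")
    if (sizes > n).any():
        raise ValueError(
            f"subsample size exceeds n = {n}; extrapolation is not enabled"
        )
    out = np.empty(len(sizes), dtype=float)
    for idx, m in enumerate(sizes):
        if q == 0:
            # P(species i absent from the subsample)
            log_cnm = _log_choose(np.array([n]), np.array([m]))[0]
            absent = np.zeros(len(v.counts))
            ok = n - v.counts >= m
            absent[ok] = np.exp(
                _log_choose((n - v.counts[ok]).astype(float), float(m)) - log_cnm
            )
            out[idx] = float(np.sum(1.0 - absent))
        else:
            ef = _expected_fk(v.counts, int(m))
            ks = np.arange(1, m + 1) / m
            if abs(q - 1.0) < 1e-9:
                out[idx] = float(np.exp(-np.sum(ks * np.log(ks) * ef)))
            else:
                out[idx] = float(np.sum(ef * ks**q) ** (1.0 / (1.0 - q)))
    return out
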