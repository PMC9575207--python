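"""Maximum-likelihood inference of GC-biased gene conversion strength.

The population-scaled conversion strength B = 4·Ne·b acts on GC-changing
polymorphism like directional selection of strength B for the strong (G/C)
allele. Under the stationary diffusion approximation, the density of sites
at GC-allele population frequency x is proportional to

    phi(x; B) = (1 - exp(-B (1 - x))) / ((1 - exp(-B)) x (1 - x))

(the neutral limit 1/x as B -> 0). For a sample of n chromosomes, the
expected number of segregating sites with GC-allele count i (1 <= i <= n-1)
is

    E_i = theta_WS C(n,i) Int x^i (1-x)^(n-i) phi(x;  B) dx
        + theta_SW C(n,i) Int x^(n-i) (1-x)^i phi(x; -B) dx

with theta_WS and theta_SW the intensities of weak->strong (origin AT) and
strong->weak (origin GC) mutation. B and the two thetas are fit by
maximising an independent-Poisson likelihood over the untrimmed GC-frequency
categories; uncertainty comes from multinomial bootstrap of the AFS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, special

B_BOUND = 50.0
_B_EPS = 1e-8
N_BINS = 50  # frequency-range scheme used for large (human-scale) samples

#: AFS mutation-class selectors; `pooled` is every GC-changing site except
#: CpG transversions, the rest follow transition/transversion x CpG context.
CLASS_SELECTORS = ("pooled", "ts_noncpg", "ts_cpg", "tv_noncpg")


class DomainError(ValueError):
    pass


def _g(x: np.ndarray, B: float) -> np.ndarray:
    """(1 - e^{-B(1-x)}) / (1 - e^{-B}), the fixation-bias factor of
    phi(x;B)*x*(1-x); analytic limit (1-x) at B = 0. Stable for |B| <= 50."""
    if abs(B) < _B_EPS:
        return 1.0 - x
    return np.expm1(-B * (1.0 - x)) / np.expm1(-B)


def phi(x: np.ndarray, B: float) -> np.ndarray:
    """Stationary density (up to the mutation-rate constant) of segregating
    GC frequency x under conversion strength B."""
    x = np.asarray(x, dtype=float)
    return _g(x, B) / (x * (1.0 - x))


class _SpectrumKernel:
    """Precomputed Gauss-Legendre quadrature of the sampling integrals for a
    fixed sample size n; evaluation per B is two small mat-vecs."""

    def __init__(self, n: int, n_nodes: int | None = None):
        if n < 4:
            raise ValueError("need a sample of at least 4 chromosomes")
        self.n = n
        m = n_nodes or max(80, n + 40)
        z, w = np.polynomial.legendre.leggauss(m)
        self.x = 0.5 * (z + 1.0)          # nodes on (0, 1)
        self.w = 0.5 * w
        i = np.arange(1, n)
        logc = (special.gammaln(n + 1) - special.gammaln(i + 1)
                - special.gammaln(n - i + 1))
        lx, l1x = np.log(self.x), np.log1p(-self.x)
        # P[i-1, k] = C(n,i) x_k^{i-1} (1-x_k)^{n-i-1}
        logp = (logc[:, None] + np.outer(i - 1, lx)
                + np.outer(n - i - 1, l1x))
        self.P = np.exp(logp)

    def expected(self, B: float, theta_ws: float, theta_sw: float) -> np.ndarray:
        gws = self.w * _g(self.x, B)
        gsw = self.w * _g(self.x, -B)
        ws = self.P @ gws
        # the strong->weak integral is the weak->strong one at category n-i
        sw = (self.P @ gsw)[::-1]
        return theta_ws * ws + theta_sw * sw


_kernels: dict[int, _SpectrumKernel] = {}


def _kernel(n: int) -> _SpectrumKernel:
    if n not in _kernels:
        _kernels[n] = _SpectrumKernel(n)
    return _kernels[n]


def expected_gc_afs(B: float, n: int, theta_ws: float, theta_sw: float,
                    ) -> np.ndarray:
    """Expected per-category site intensities for GC counts i = 1..n-1."""
    if abs(B) > B_BOUND:
        raise DomainError(f"|B| exceeds the optimiser bound {B_BOUND}")
    if theta_ws < 0 or theta_sw < 0:
        raise ValueError("mutation intensities must be non-negative")
    return _kernel(n).expected(B, theta_ws, theta_sw)


def bin_of_frequency(freq: np.ndarray, n_bins: int = N_BINS) -> np.ndarray:
    """0-based bin index of GC relative frequencies on (0,1): half-open
    equal-width intervals, last bin closed at 1."""
    idx = np.floor(np.asarray(freq, dtype=float) * n_bins).astype(int)
    return np.minimum(idx, n_bins - 1)


@dataclass
class GCFrequencyAFS:
    """Counts of segregating sites per GC-frequency category.

    For `scheme == "counts"` the categories are GC-allele counts 1..n-1; for
    `scheme == "bins"` they are the equal-width frequency bins that carry at
    least one possible count category. Monomorphic categories (0 and n) are
    excluded by construction. `trimmed` marks categories dropped from the
    likelihood (the two most extreme ones, most exposed to mis-polarisation
    and mutation-process artefacts).
    """

    n: int
    counts: np.ndarray
    mut_class: str = "pooled"
    scheme: str = "counts"
    trimmed: np.ndarray = None

    def __post_init__(self):
        # float dtype so exact expected spectra can be used as noiseless input
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if np.any(self.counts < 0):
            raise ValueError("negative category counts")
        expected_len = self.n - 1 if self.scheme == "counts" else N_BINS
        if self.counts.size != expected_len:
            raise ValueError(f"expected {expected_len} categories for scheme "
                             f"{self.scheme!r}, got {self.counts.size}")
        if self.trimmed is None:
            self.trimmed = np.zeros(self.counts.size, dtype=bool)
        self.trimmed = np.asarray(self.trimmed, dtype=bool)

    @property
    def n_categories(self) -> int:
        return int(self.counts.size)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def category_map(self) -> np.ndarray:
        """Category index (into counts) of each GC count 1..n-1."""
        i = np.arange(1, self.n)
        if self.scheme == "counts":
            return i - 1
        return bin_of_frequency(i / self.n)

    def reversed(self) -> "GCFrequencyAFS":
        """Polarity-swapped spectrum (category vector reversed)."""
        return replace(self, counts=self.counts[::-1].copy(),
                       trimmed=self.trimmed[::-1].copy())


def build_gc_afs(sites, class_selector: str = "pooled",
                 scheme: str | None = None) -> GCFrequencyAFS:
    """GC-frequency AFS of the complete-data, biallelic, GC-changing
    segregating sites of a :class:`~parevo.diversity.SiteTable`.

    The category of a site is the count (or frequency bin) of its G/C allele
    among the 2N chromosomes. GC-conservative sites (A<->T, C<->G) are
    filtered with a warning; CpG transversions are excluded from the pooled
    class. `scheme` defaults to GC counts, or frequency bins when the count
    scheme would exceed 50 categories.
    """
    if class_selector not in CLASS_SELECTORS:
        raise ValueError(f"unknown class selector {class_selector!r}")
    strong = ("C", "G")
    is_strong_ref = np.isin(sites.ref, strong)
    is_strong_alt = np.isin(sites.alt, strong)
    gc_changing = is_strong_ref != is_strong_alt
    if np.any(~gc_changing):
        warnings.warn(f"{int((~gc_changing).sum())} GC-conservative sites "
                      "ignored in the GC-frequency AFS")
    transition = ((np.char.add(sites.ref.astype("<U1"), sites.alt) == "CT")
                  | (np.char.add(sites.ref.astype("<U1"), sites.alt) == "TC")
                  | (np.char.add(sites.ref.astype("<U1"), sites.alt) == "GA")
                  | (np.char.add(sites.ref.astype("<U1"), sites.alt) == "AG"))
    cpg = sites.cpg
    if class_selector == "pooled":
        keep_class = ~(~transition & cpg)        # drop CpG transversions
    elif class_selector == "ts_noncpg":
        keep_class = transition & ~cpg
    elif class_selector == "ts_cpg":
        keep_class = transition & cpg
    else:  # tv_noncpg
        keep_class = ~transition & ~cpg
    use = (gc_changing & keep_class & sites.complete_mask()
           & sites.segregating_mask())

    n = 2 * sites.n_samples
    ac = sites.gt[use].sum(axis=1)
    gc_count = np.where(is_strong_alt[use], ac, n - ac)
    if scheme is None:
        scheme = "counts" if n - 1 <= N_BINS else "bins"
    if scheme == "counts":
        counts = np.bincount(gc_count, minlength=n)[1:n]
    else:
        counts = np.bincount(bin_of_frequency(gc_count / n), minlength=N_BINS)
    return GCFrequencyAFS(n=n, counts=counts, mut_class=class_selector,
                          scheme=scheme)


def trim_extremes(afs: GCFrequencyAFS) -> GCFrequencyAFS:
    """Mark the two most extreme categories (lowest and highest) as excluded
    from the likelihood. Idempotent on the trimmed set."""
    if afs.n_categories < 5:
        raise ValueError("too few categories to trim")
    trimmed = np.zeros(afs.n_categories, dtype=bool)
    trimmed[0] = trimmed[-1] = True
    return replace(afs, trimmed=trimmed)


@dataclass
class GbgcFit:
    """MLE of the conversion strength with optional bootstrap uncertainty."""

    B: float
    theta_ws: float
    theta_sw: float
    loglik: float
    converged: bool
    mut_class: str = "pooled"
    replicates: np.ndarray | None = None
    ci: tuple[float, float] | None = None
    n_failed_replicates: int = 0


def _expected_for(afs: GCFrequencyAFS, B: float, tws: float, tsw: float,
                  ) -> np.ndarray:
    mu = expected_gc_afs(B, afs.n, tws, tsw)
    if afs.scheme == "counts":
        return mu
    out = np.zeros(afs.n_categories)
    np.add.at(out, afs.category_map(), mu)
    return out


def fit_B(afs: GCFrequencyAFS) -> GbgcFit:
    """Maximise the Poisson likelihood of the untrimmed AFS categories over
    (B, theta_WS, theta_SW), restarting from B in {-2, 0, 2}."""
    if afs.total == 0:
        raise ValueError("empty spectrum")
    obs = afs.counts[~afs.trimmed].astype(float)
    keep = ~afs.trimmed

    def nll(params: np.ndarray) -> float:
        B, lws, lsw = params
        mu = _expected_for(afs, B, np.exp(lws), np.exp(lsw))[keep]
        mu = np.maximum(mu, 1e-300)
        return float(np.sum(mu) - np.sum(obs * np.log(mu)))

    # scale-matched theta start: split the observed total evenly
    neutral = _expected_for(afs, 0.0, 1.0, 1.0)[keep].sum()
    t0 = np.log(max(obs.sum() / neutral / 2.0, 1e-12))
    best = None
    for b0 in (-2.0, 0.0, 2.0):
        res = optimize.minimize(
            nll, x0=np.array([b0, t0, t0]), method="L-BFGS-B",
            bounds=[(-B_BOUND, B_BOUND), (t0 - 25, t0 + 25), (t0 - 25, t0 + 25)],
            options={"ftol": 1e-13, "gtol": 1e-9, "maxiter": 500})
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("gBGC fit failed to converge from all restarts")
    B, lws, lsw = best.x
    return GbgcFit(B=float(B), theta_ws=float(np.exp(lws)),
                   theta_sw=float(np.exp(lsw)), loglik=float(-best.fun),
                   converged=bool(best.success), mut_class=afs.mut_class)


def bootstrap_B(afs: GCFrequencyAFS, n_reps: int = 100, seed: int = 0,
                ci_level: float = 0.95) -> GbgcFit:
    """Multinomial site bootstrap of the AFS (total held fixed), refitting B
    per replicate; returns the point fit with replicate values and the
    percentile confidence interval attached."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    point = fit_B(afs)
    rng = np.random.default_rng(seed)
    p = afs.counts / afs.total
    total = int(round(afs.total))
    reps, failed = [], 0
    for _ in range(n_reps):
        counts = rng.multinomial(total, p)
        try:
            reps.append(fit_B(replace(afs, counts=counts)).B)
        except (RuntimeError, ValueError):
            failed += 1
    reps = np.array(reps)
    alpha = (1.0 - ci_level) / 2.0
    ci = (float(np.quantile(reps, alpha)), float(np.quantile(reps, 1 - alpha)))
    return replace(point, replicates=reps, ci=ci, n_failed_replicates=failed)
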