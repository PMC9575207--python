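"""Equilibrium GC content (GC*) and its correlates.

GC* is the stationary GC proportion implied by the weak-to-strong (AT->GC)
and strong-to-weak (GC->AT) per-site substitution rates:

    GC* = r_WS / (r_WS + r_SW)

where r_WS is the AT->GC count per ancestral A/T site and r_SW the GC->AT
count per ancestral G/C site (CpG>TpG included among the strong-to-weak
classes). The deviation GC* - GC measures how far a sequence sits from its
compositional equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import (AncestralAlignment, SubstitutionTally, UndefinedRatioError,
                        count_branch_substitutions, divergence_rate, ts_tv_ratio)
from .trees import SpeciesTree


@dataclass
class GCSummary:
    """Per-(telomere, branch) GC-evolution summary."""

    telomere: str
    branch: str
    rate_ws: float
    rate_sw: float
    count_ws: int
    count_sw: int
    gc: float          # current GC proportion of the child-node sequence
    gc_star: float
    deviation: float   # GC* - GC
    tstv: float
    chrom_length: float  # bp

    def to_series(self) -> pd.Series:
        return pd.Series(vars(self))


def gc_star(rate_ws: float, rate_sw: float) -> float:
    """Stationary GC proportion from weak->strong and strong->weak rates."""
    if rate_ws < 0 or rate_sw < 0:
        raise ValueError("rates must be non-negative")
    total = rate_ws + rate_sw
    if total == 0:
        raise ValueError("GC* undefined when both rates are zero")
    return rate_ws / total


def ws_count_ratio(tally: SubstitutionTally) -> float:
    """AT->GC over GC->AT substitution counts; ~1 at compositional equilibrium."""
    if tally.count_sw == 0:
        raise UndefinedRatioError("no GC->AT substitutions")
    return tally.count_ws / tally.count_sw


def gc_summary(aln: AncestralAlignment, tree: SpeciesTree, branch: str,
               telomere: str = "PAR1", chrom_length: float = float("nan"),
               ) -> GCSummary:
    """Compute the GC summary of one branch from an (already filtered)
    ancestral alignment."""
    tally = count_branch_substitutions(aln, tree, branch)
    gstar = gc_star(tally.rate_ws, tally.rate_sw)
    gc = aln.gc_content(branch)
    return GCSummary(telomere=telomere, branch=branch,
                     rate_ws=tally.rate_ws, rate_sw=tally.rate_sw,
                     count_ws=tally.count_ws, count_sw=tally.count_sw,
                     gc=gc, gc_star=gstar, deviation=gstar - gc,
                     tstv=ts_tv_ratio(tally), chrom_length=chrom_length)


def bootstrap_gc_summary(aln: AncestralAlignment, tree: SpeciesTree, branch: str,
                         n_reps: int, seed: int, telomere: str = "PAR1",
                         chrom_length: float = float("nan")) -> pd.DataFrame:
    """Site bootstrap of the GC summary: resample alignment columns with
    replacement and recompute GC* and deviation per replicate."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if aln.n_columns == 0:
        raise ValueError("empty alignment")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_reps):
        idx = np.sort(rng.integers(0, aln.n_columns, size=aln.n_columns))
        # resampled columns get fresh consecutive coordinates: a bootstrap
        # column's CpG context is read from its sampled neighbours, which is
        # the standard site-bootstrap approximation
        boot = AncestralAlignment({k: v[idx] for k, v in aln.seqs.items()},
                                  np.arange(idx.size), aln.ref_name)
        s = gc_summary(boot, tree, branch, telomere=telomere,
                       chrom_length=chrom_length).to_series()
        s["replicate"] = rep
        rows.append(s)
    return pd.DataFrame(rows)


def equilibrium_regression(table: pd.DataFrame):
    """OLS of the equilibrium deviation on divergence rate, ts:tv and
    chromosome length (in Mb), with intercept.

    `table` needs columns deviation, rate_py (per site and year), tstv and
    chrom_length (bp). Returns the fitted statsmodels results object.
    """
    import statsmodels.api as sm

    required = {"deviation", "rate_py", "tstv", "chrom_length"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"regression table lacks columns {missing}")
    if len(table) < 5:
        raise ValueError("need at least 5 rows")
    if table[list(required)].isna().any().any():
        raise ValueError("regression table contains missing values")
    X = pd.DataFrame({
        "div_rate": table["rate_py"].astype(float),
        "tstv": table["tstv"].astype(float),
        "length_mb": table["chrom_length"].astype(float) / 1e6,
    })
    X = sm.add_constant(X)
    fit = sm.OLS(table["deviation"].astype(float), X).fit()
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient (collinear) design")
    return fit


def regression_report(fit) -> pd.DataFrame:
    """Coefficient table (estimate, standard error, p-value) plus R^2."""
    df = pd.DataFrame({"estimate": fit.params, "std_error": fit.bse,
                       "p_value": fit.pvalues})
    df.attrs["r_squared"] = float(fit.rsquared)
    return df


def partial_spearman(x, y, *controls) -> tuple[float, float]:
    """Spearman partial correlation of x and y given zero or more controls.

    All variables are rank-transformed (average ranks for ties); x and y
    ranks are residualised on the control ranks and the Pearson correlation
    of the residuals is returned with a t-approximation p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4 or y.size != n:
        raise ValueError("need >= 4 paired observations")
    mats = [x, y, *[np.asarray(c, dtype=float) for c in controls]]
    if any(np.unique(m).size == 1 for m in mats):
        raise ValueError("constant variable: correlation undefined")
    ranks = [stats.rankdata(m) for m in mats]
    rx, ry = ranks[0], ranks[1]
    k = len(ranks) - 2
    if k:
        Z = np.column_stack([np.ones(n), *ranks[2:]])
        rx = rx - Z @ np.linalg.lstsq(Z, rx, rcond=None)[0]
        ry = ry - Z @ np.linalg.lstsq(Z, ry, rcond=None)[0]
    else:
        rx, ry = rx - rx.mean(), ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    if denom == 0:
        raise ValueError("degenerate ranks: correlation undefined")
    r = float((rx * ry).sum() / denom)
    df = n - 2 - k
    r_clamped = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_clamped * np.sqrt(df / (1 - r_clamped ** 2))
    p = float(2 * stats.t.sf(abs(t), df))
    return r, p
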