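"""Windowed recombination maps: scaling, binning, averaging, correlation.

Maps live on a fixed 10-kb window grid. Population-scaled rates (ρ = 4·Ne·r
per window) are converted to cM/Mb by rescaling the map so its mean over
usable windows equals a target sex-averaged rate (default 9.01 cM/Mb, the
pedigree estimate for the human pseudoautosomal region). Windows are then
cut into low/medium/high terciles (defaults 4.25 and 11.29 cM/Mb).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_TARGET_MEAN = 9.01   # cM/Mb
DEFAULT_LOW_CUT = 4.25       # cM/Mb
DEFAULT_HIGH_CUT = 11.29     # cM/Mb


@dataclass
class RecombMap:
    """Per-window recombination rates for one population on a fixed grid."""

    population: str
    starts: np.ndarray          # window starts (grid must match across maps)
    rates: np.ndarray           # rho (4 Ne r) or cM/Mb
    usable: np.ndarray = None
    window: int = 10_000
    units: str = "rho"

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.usable is None:
            self.usable = np.ones(self.starts.size, dtype=bool)
        self.usable = np.asarray(self.usable, dtype=bool)
        if not (self.starts.size == self.rates.size == self.usable.size):
            raise ValueError("grid, rates and usable flags differ in length")
        if np.any(self.rates[self.usable] < 0):
            raise ValueError("negative recombination rate")

    @property
    def n_windows(self) -> int:
        return int(self.starts.size)

    def same_grid(self, other: "RecombMap") -> bool:
        return (self.window == other.window
                and np.array_equal(self.starts, other.starts))

    def to_frame(self, chrom: str = "PAR1") -> pd.DataFrame:
        return pd.DataFrame({"chrom": chrom, "start": self.starts,
                             "end": self.starts + self.window,
                             "rate": self.rates, "usable": self.usable})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, population: str = "pop",
                   units: str = "rho") -> "RecombMap":
        window = int((df["end"] - df["start"]).iloc[0])
        usable = df["usable"].to_numpy(bool) if "usable" in df else None
        return cls(population, df["start"].to_numpy(np.int64),
                   df["rate"].to_numpy(float), usable, window, units)


def scale_to_cmmb(rmap: RecombMap,
                  target_mean: float = DEFAULT_TARGET_MEAN) -> RecombMap:
    """Rescale a ρ map so the mean over usable windows is exactly
    `target_mean` cM/Mb; scale-invariant in the input units."""
    vals = rmap.rates[rmap.usable]
    if vals.size == 0 or vals.mean() == 0:
        raise ValueError("cannot scale an empty or all-zero map")
    scaled = rmap.rates * (target_mean / vals.mean())
    return replace(rmap, rates=scaled, units="cM/Mb")


def assign_bins(rmap: RecombMap, low_cut: float = DEFAULT_LOW_CUT,
                high_cut: float = DEFAULT_HIGH_CUT) -> np.ndarray:
    """Label each usable window low (rate <= low_cut), medium
    (low_cut < rate <= high_cut) or high (rate > high_cut)."""
    if low_cut >= high_cut:
        raise ValueError("low cut must be below high cut")
    bins = np.full(rmap.n_windows, "", dtype="<U6")
    r = rmap.rates
    bins[rmap.usable & (r <= low_cut)] = "low"
    bins[rmap.usable & (r > low_cut) & (r <= high_cut)] = "medium"
    bins[rmap.usable & (r > high_cut)] = "high"
    return bins


def pooled_tercile_cuts(maps: list[RecombMap]) -> tuple[float, float]:
    """Tercile cut points of the usable-window rates pooled across maps."""
    pooled = np.concatenate([m.rates[m.usable] for m in maps])
    lo, hi = np.quantile(pooled, [1 / 3, 2 / 3])
    return float(lo), float(hi)


def genus_mean_map(maps: list[RecombMap], population: str = "mean",
                   ) -> RecombMap:
    """Per-window arithmetic mean across maps, ignoring windows unusable in
    a given map; a window is unusable in the mean only if unusable in all."""
    if not maps:
        raise ValueError("need at least one map")
    first = maps[0]
    for m in maps[1:]:
        if not first.same_grid(m):
            raise ValueError("maps are not on a shared window grid")
    rates = np.stack([m.rates for m in maps])
    usable = np.stack([m.usable for m in maps])
    n_ok = usable.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n_ok > 0,
                        np.where(usable, rates, 0.0).sum(axis=0) / np.maximum(n_ok, 1),
                        0.0)
    return RecombMap(population, first.starts.copy(), mean, n_ok > 0,
                     first.window, first.units)


def window_correlation(a: np.ndarray, b: np.ndarray,
                       usable_a: np.ndarray | None = None,
                       usable_b: np.ndarray | None = None,
                       ) -> tuple[float, float]:
    """Spearman rank correlation over windows usable in both inputs."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if usable_a is not None:
        ok &= np.asarray(usable_a, dtype=bool)
    if usable_b is not None:
        ok &= np.asarray(usable_b, dtype=bool)
    if ok.sum() < 4:
        raise ValueError("need >= 4 shared usable windows")
    if np.unique(a[ok]).size == 1 or np.unique(b[ok]).size == 1:
        raise ValueError("constant input: correlation undefined")
    rho, p = stats.spearmanr(a[ok], b[ok])
    return float(rho), float(p)
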