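"""Population diversity statistics on per-site genotype tables.

Statistics are computed on a fixed 10-kb window grid and reported only for
windows with more than a minimum number of callable sites (default 2500).
π uses the unbiased n/(n-1) pairwise estimator with the site-specific number
of non-missing chromosomes; Watterson's θ and Tajima's D follow the standard
definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import CLASSES, classify_substitution
from .io import GenomicIntervals

WINDOW = 10_000
MIN_CALLABLE = 2_500

MISSING = -1


@dataclass
class SiteTable:
    """Per-site biallelic genotypes with ancestral state and class annotation.

    `gt` holds the alternate-allele dosage (0, 1, 2; -1 for missing) per site
    and sample. `mut_class` is one of the seven strand-symmetric classes
    (empty string where unannotated); `cpg` marks ancestral CpG context.
    """

    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    anc: np.ndarray
    gt: np.ndarray                 # (n_sites, n_samples) int8 dosage
    samples: list[str]
    sex: np.ndarray                # per-sample 'F'/'M'
    mut_class: np.ndarray = None   # per-site class or ''
    cpg: np.ndarray = None         # per-site ancestral CpG context flag
    chrom: str = "PAR1"

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype="<U1")
        self.alt = np.asarray(self.alt, dtype="<U1")
        self.anc = np.asarray(self.anc, dtype="<U1")
        self.gt = np.asarray(self.gt, dtype=np.int8)
        self.sex = np.asarray(self.sex, dtype="<U1")
        if self.mut_class is None:
            self.mut_class = np.full(self.pos.size, "", dtype="<U8")
        self.mut_class = np.asarray(self.mut_class, dtype="<U8")
        if self.cpg is None:
            self.cpg = np.zeros(self.pos.size, dtype=bool)
        self.cpg = np.asarray(self.cpg, dtype=bool)
        if self.gt.shape != (self.pos.size, len(self.samples)):
            raise ValueError("genotype matrix shape mismatch")
        if self.sex.size != len(self.samples):
            raise ValueError("sex labels do not match samples")

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset(self, index) -> "SiteTable":
        return SiteTable(self.pos[index], self.ref[index], self.alt[index],
                         self.anc[index], self.gt[index], list(self.samples),
                         self.sex, self.mut_class[index], self.cpg[index],
                         self.chrom)

    def alt_counts(self):
        """Per-site alternate-allele count and number of non-missing
        chromosomes."""
        observed = self.gt != MISSING
        ac = np.where(observed, self.gt, 0).sum(axis=1)
        an = 2 * observed.sum(axis=1)
        return ac, an

    def complete_mask(self) -> np.ndarray:
        return (self.gt != MISSING).all(axis=1)

    def segregating_mask(self) -> np.ndarray:
        ac, an = self.alt_counts()
        return (ac > 0) & (ac < an)

    def derived_counts(self):
        """Per-site derived-allele count (polarised by the ancestral allele)
        and non-missing chromosome count; sites where the ancestral allele
        matches neither allele get -1."""
        ac, an = self.alt_counts()
        dc = np.where(self.anc == self.ref, ac,
                      np.where(self.anc == self.alt, an - ac, -1))
        return dc, an


def annotate_classes(sites: SiteTable, ref_seq: np.ndarray) -> SiteTable:
    """Assign each site its strand-symmetric mutation class from the
    ancestral allele, derived allele, and the CpG context read from the
    reference sequence around the site."""
    ref_seq = np.asarray(ref_seq, dtype="<U1")
    classes = np.full(sites.n_sites, "", dtype="<U8")
    cpg = np.zeros(sites.n_sites, dtype=bool)
    for i in range(sites.n_sites):
        anc = sites.anc[i]
        derived = sites.alt[i] if anc == sites.ref[i] else (
            sites.ref[i] if anc == sites.alt[i] else None)
        if derived is None:
            continue
        p = int(sites.pos[i])
        left = ref_seq[p - 1] if p - 1 >= 0 else None
        right = ref_seq[p + 1] if p + 1 < ref_seq.size else None
        cls = classify_substitution(anc, derived, left, right)
        if cls and cls != "unscorable":
            classes[i] = cls
        # CpG context of the ancestral state, on either strand
        cpg[i] = ((anc == "C" and right == "G") or (anc == "G" and left == "C"))
    return SiteTable(sites.pos, sites.ref, sites.alt, sites.anc, sites.gt,
                     list(sites.samples), sites.sex, classes, cpg, sites.chrom)


@dataclass
class CallableMask:
    """Positions passing the depth-based callability rule, with per-window
    callable counts on the fixed 10-kb grid."""

    intervals: GenomicIntervals
    region_length: int
    window: int = WINDOW

    @property
    def n_windows(self) -> int:
        return -(-self.region_length // self.window)

    def window_callable(self) -> np.ndarray:
        return self.intervals.window_counts(self.window, self.n_windows)

    def contains(self, positions) -> np.ndarray:
        return self.intervals.contains(positions)

    @property
    def n_callable(self) -> int:
        return self.intervals.total_length


def callable_mask_from_depth(depth: np.ndarray, n: int, mean_cov: float,
                             chrom: str = "PAR1", window: int = WINDOW,
                             ) -> CallableMask:
    """Callability from a per-site depth track.

    A position is callable iff depth >= 1.5 * n and depth <= 2 * n * mean_cov,
    where `n` is the number of haploid genomes (ploidy) and `mean_cov` the
    mean coverage per haploid genome; both bounds are inclusive.
    """
    depth = np.asarray(depth, dtype=float)
    if np.any(depth < 0):
        raise ValueError("negative depth")
    if n < 1 or mean_cov < 0:
        raise ValueError("invalid ploidy or coverage")
    ok = (depth >= 1.5 * n) & (depth <= 2 * n * mean_cov)
    return CallableMask(GenomicIntervals.from_boolean(chrom, ok),
                        region_length=depth.size, window=window)


def nucleotide_diversity_pi(sites: SiteTable, mask: CallableMask,
                            window: tuple[int, int],
                            min_callable: int = MIN_CALLABLE) -> float:
    """Per-site π over one window: sum over sites of 2*p*(1-p)*n/(n-1)
    divided by the callable-site count. NaN where the window fails the
    callable filter."""
    start, end = window
    callable_sites = mask.intervals.window_counts(
        end - start, 1, offset=start)[0]
    if callable_sites <= min_callable:
        return float("nan")
    in_win = (sites.pos >= start) & (sites.pos < end) & mask.contains(sites.pos)
    sub = sites.subset(in_win)
    ac, an = sub.alt_counts()
    use = an >= 2
    ac, an = ac[use], an[use]
    p = np.divide(ac, an, out=np.zeros(ac.shape, dtype=float), where=an > 0)
    per_site = 2.0 * p * (1 - p) * an / np.maximum(an - 1, 1)
    return float(per_site.sum() / callable_sites)


def harmonic_number(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i."""
    return float(np.sum(1.0 / np.arange(1, n)))


def watterson_theta(S: int, n: int, callable_sites: int) -> float:
    """Watterson's per-site θ = S / (a_n * callable)."""
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    if callable_sites <= 0:
        raise ValueError("need positive callable-site count")
    return S / (harmonic_number(n) * callable_sites)


def tajimas_d(S: int, n: int, pi_total: float) -> float:
    """Tajima's D from the segregating-site count, sample size (chromosomes)
    and the window-total pairwise diversity (not per-site)."""
    if n < 4:
        raise ValueError("need at least 4 chromosomes")
    if S <= 0:
        raise ValueError("D undefined with no segregating sites")
    a1 = harmonic_number(n)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float((pi_total - S / a1) / np.sqrt(var))


def heterozygosity(gt: np.ndarray, pos: np.ndarray, mask: CallableMask,
                   window: tuple[int, int],
                   min_callable: int = MIN_CALLABLE) -> float:
    """Single-genome per-site heterozygosity over one window: heterozygous
    callable sites / callable sites."""
    gt = np.asarray(gt)
    if gt.ndim != 1:
        raise ValueError("expected a single sample's dosage vector")
    start, end = window
    callable_sites = mask.intervals.window_counts(end - start, 1, offset=start)[0]
    if callable_sites <= min_callable:
        return float("nan")
    in_win = (pos >= start) & (pos < end) & mask.contains(pos)
    n_het = int(np.sum(gt[in_win] == 1))
    return n_het / callable_sites


def window_statistics(sites: SiteTable, mask: CallableMask,
                      window: int = WINDOW,
                      min_callable: int = MIN_CALLABLE,
                      complete_only: bool = True) -> pd.DataFrame:
    """Per-window segregating count, π, Watterson's θ and Tajima's D.

    With `complete_only`, only segregating sites with no missing genotypes
    enter S, θ and D (π always uses the site-specific chromosome count).
    Windows failing the callable filter are flagged `pass_filter = False`
    with NaN statistics.
    """
    n_win = -(-mask.region_length // window)
    callable_per_win = mask.intervals.window_counts(window, n_win)
    seg = sites.segregating_mask() & mask.contains(sites.pos)
    seg_complete = seg & (sites.complete_mask() if complete_only else True)
    rows = []
    for w in range(n_win):
        start, end = w * window, (w + 1) * window
        cw = int(callable_per_win[w])
        ok = cw > min_callable
        row = {"start": start, "end": end, "callable": cw,
               "pass_filter": ok, "S": np.nan, "pi": np.nan,
               "theta_w": np.nan, "tajimas_d": np.nan}
        if ok:
            in_win = (sites.pos >= start) & (sites.pos < end)
            row["pi"] = nucleotide_diversity_pi(sites, mask, (start, end),
                                                min_callable)
            sel = in_win & seg_complete
            S = int(sel.sum())
            row["S"] = S
            n_chrom = 2 * sites.n_samples
            row["theta_w"] = watterson_theta(S, n_chrom, cw)
            if S > 0 and n_chrom >= 4:
                sub = sites.subset(sel)
                ac, an = sub.alt_counts()
                p = ac / an
                pi_total = float(np.sum(2 * p * (1 - p) * an / (an - 1)))
                row["tajimas_d"] = tajimas_d(S, n_chrom, pi_total)
        rows.append(row)
    return pd.DataFrame(rows)


def diversity_spectrum(sites: SiteTable) -> pd.Series:
    """Proportion of segregating sites per mutation class, among classified
    segregating sites."""
    seg = sites.segregating_mask()
    classified = seg & (sites.mut_class != "")
    if not classified.any():
        raise ValueError("no classified segregating sites")
    counts = pd.Series(sites.mut_class[classified]).value_counts()
    return pd.Series({c: counts.get(c, 0) / counts.sum() for c in CLASSES})


def write_vcf(path: str | Path, sites: SiteTable) -> None:
    """Write a biallelic VCF 4.2 with an AA (ancestral allele) INFO tag."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={sites.chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sites.samples) + "\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for i in range(sites.n_sites):
            gts = "\t".join(gt_str[int(g)] for g in sites.gt[i])
            fh.write(f"{sites.chrom}\t{sites.pos[i] + 1}\t.\t{sites.ref[i]}\t"
                     f"{sites.alt[i]}\t.\tPASS\tAA={sites.anc[i]}\tGT\t{gts}\n")


def write_sites_tsv(path: str | Path, sites: SiteTable) -> None:
    """Tabular SiteTable dump: site fields plus one dosage column per sample."""
    df = pd.DataFrame({"pos": sites.pos, "ref": sites.ref, "alt": sites.alt,
                       "anc": sites.anc, "mut_class": sites.mut_class,
                       "cpg": sites.cpg.astype(int)})
    for j, s in enumerate(sites.samples):
        df[f"gt:{s}:{sites.sex[j]}"] = sites.gt[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_sites_tsv(path: str | Path, chrom: str = "PAR1") -> SiteTable:
    df = pd.read_csv(path, sep="\t", dtype={"mut_class": str}, keep_default_na=False)
    gt_cols = [c for c in df.columns if c.startswith("gt:")]
    samples = [c.split(":")[1] for c in gt_cols]
    sex = np.array([c.split(":")[2] for c in gt_cols], dtype="<U1")
    gt = df[gt_cols].to_numpy(dtype=np.int8)
    return SiteTable(df["pos"].to_numpy(np.int64),
                     df["ref"].to_numpy(dtype="<U1"),
                     df["alt"].to_numpy(dtype="<U1"),
                     df["anc"].to_numpy(dtype="<U1"),
                     gt, samples, sex,
                     df["mut_class"].to_numpy(dtype="<U8"),
                     df["cpg"].to_numpy(dtype=bool), chrom)


def read_vcf(path: str | Path, sex: dict[str, str] | None = None) -> SiteTable:
    """Read a biallelic VCF into a SiteTable using cyvcf2; the ancestral
    allele is taken from the AA INFO tag (reference allele where absent).
    Multi-allelic and non-SNP records are skipped."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    sex_arr = np.array([(sex or {}).get(s, "F") for s in samples], dtype="<U1")
    pos, ref, alt, anc, gts = [], [], [], [], []
    chrom = "PAR1"
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            continue
        chrom = var.CHROM
        pos.append(var.POS - 1)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        anc.append(var.INFO.get("AA") or var.REF)
        g = var.genotype.array()[:, :2]
        dosage = np.where((g < 0).any(axis=1), MISSING, (g > 0).sum(axis=1))
        gts.append(dosage)
    vcf.close()
    gt = np.array(gts, dtype=np.int8) if gts else np.empty((0, len(samples)), np.int8)
    return SiteTable(np.array(pos, dtype=np.int64), np.array(ref, dtype="<U1"),
                     np.array(alt, dtype="<U1"), np.array(anc, dtype="<U1"),
                     gt, samples, sex_arr, chrom=chrom)


def sex_diff_scan(sites: SiteTable, fdr_level: float = 0.05) -> pd.DataFrame:
    """Fisher's exact test of allele counts by sex at every segregating site,
    with Benjamini–Hochberg control of the FDR.

    Returns a frame with per-site allele counts, p, q and discovery flags.
    """
    from statsmodels.stats.multitest import multipletests

    is_f = sites.sex == "F"
    is_m = sites.sex == "M"
    if not is_f.any() or not is_m.any():
        raise ValueError("both sexes must be represented")
    seg = np.flatnonzero(sites.segregating_mask())
    rows = []
    for i in seg:
        g = sites.gt[i]
        obs_f, obs_m = (g != MISSING) & is_f, (g != MISSING) & is_m
        alt_f = int(g[obs_f].sum())
        alt_m = int(g[obs_m].sum())
        ref_f = int(2 * obs_f.sum() - alt_f)
        ref_m = int(2 * obs_m.sum() - alt_m)
        _, p = stats.fisher_exact([[alt_f, ref_f], [alt_m, ref_m]])
        rows.append({"pos": int(sites.pos[i]), "alt_F": alt_f, "ref_F": ref_f,
                     "alt_M": alt_m, "ref_M": ref_m, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        reject, q, _, _ = multipletests(out["p"], alpha=fdr_level,
                                        method="fdr_bh")
        out["q"] = q
        out["discovery"] = reject
    else:
        out["q"] = []
        out["discovery"] = []
    return out
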