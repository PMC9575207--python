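"""Substitution counting on multi-species alignments with ancestral nodes.

Substitutions between a parent (ancestral) and child node are collapsed by
strand symmetry into seven classes:

    C>A, C>G, C>T (non-CpG), CpG>TpG, T>A, T>C, T>G

A purine-ancestral change is mapped to its reverse complement, so the
ancestral base is always a pyrimidine. A C>T whose ancestral 3' neighbour is
G (equivalently, a G>A whose ancestral 5' neighbour is C) is the hypermutable
CpG>TpG class. CpG context is read from the parent sequence only; where the
needed neighbour is undefined (block edge, non-contiguous coordinate, gap or
N) the column is excluded from CpG opportunity, and a C>T there is
unscorable — counted in no class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CoordinateSystemError, GenomicIntervals
from .trees import SpeciesTree

#: Canonical strand-symmetric substitution class order.
CLASSES = ("C>A", "C>G", "C>T", "CpG>TpG", "T>A", "T>C", "T>G")
TRANSITIONS = ("C>T", "CpG>TpG", "T>C")
TRANSVERSIONS = ("C>A", "C>G", "T>A", "T>G")
#: Weak-to-strong (AT -> GC) and strong-to-weak (GC -> AT) classes.
WS_CLASSES = ("T>C", "T>G")
SW_CLASSES = ("C>A", "C>T", "CpG>TpG")

UNSCORABLE = "unscorable"
NUCS = ("A", "C", "G", "T")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class InputError(ValueError):
    pass


class UndefinedRatioError(ZeroDivisionError):
    """Signals a ratio whose denominator count is zero."""


def _ctx(base) -> str | None:
    """Normalise a context base: anything but A/C/G/T is undefined."""
    if base is None:
        return None
    base = str(base).upper()
    return base if base in _COMP else None


def classify_substitution(parent: str, child: str,
                          parent_5prime: str | None = None,
                          parent_3prime: str | None = None) -> str | None:
    """Class of a parent->child change, or None if no change.

    Returns ``"unscorable"`` for a C>T (after strand collapse) whose required
    3' ancestral context is undefined.
    """
    parent, child = str(parent).upper(), str(child).upper()
    if parent not in _COMP or child not in _COMP:
        raise InputError(f"non-nucleotide input {parent!r}>{child!r}")
    if parent == child:
        return None
    p5, p3 = _ctx(parent_5prime), _ctx(parent_3prime)
    if parent in ("A", "G"):  # collapse to the pyrimidine-ancestral strand
        parent, child = _COMP[parent], _COMP[child]
        p5, p3 = (_COMP[p3] if p3 else None), (_COMP[p5] if p5 else None)
    if parent == "C" and child == "T":
        if p3 is None:
            return UNSCORABLE
        return "CpG>TpG" if p3 == "G" else "C>T"
    return f"{parent}>{child}"


@dataclass
class AncestralAlignment:
    """Columns of aligned bases for leaves and internal nodes of a fixed tree.

    `seqs` maps node label to a per-column base array over {A,C,G,T,-,N};
    `coords` gives each column's 0-based position on `ref_name`.
    """

    seqs: dict[str, np.ndarray]
    coords: np.ndarray
    ref_name: str = "ref"

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.int64)
        lengths = {len(s) for s in self.seqs.values()}
        if len(lengths) > 1:
            raise ValueError(f"node sequences have unequal lengths: {lengths}")
        if lengths and lengths.pop() != self.coords.size:
            raise ValueError("coordinate vector length differs from sequences")
        if self.coords.size and np.any(np.diff(self.coords) <= 0):
            raise ValueError("reference coordinates must be strictly increasing")
        self.seqs = {k: np.asarray(v, dtype="<U1") for k, v in self.seqs.items()}

    @classmethod
    def from_strings(cls, seqs: Mapping[str, str], coords=None,
                     ref_name: str = "ref") -> "AncestralAlignment":
        arr = {k: np.array(list(v.upper()), dtype="<U1") for k, v in seqs.items()}
        n = len(next(iter(arr.values()))) if arr else 0
        if coords is None:
            coords = np.arange(n)
        return cls(arr, coords, ref_name)

    @property
    def nodes(self) -> list[str]:
        return list(self.seqs)

    @property
    def n_columns(self) -> int:
        return int(self.coords.size)

    def subset(self, index: np.ndarray) -> "AncestralAlignment":
        return AncestralAlignment({k: v[index] for k, v in self.seqs.items()},
                                  self.coords[index], self.ref_name)

    def sequence(self, node: str) -> str:
        return "".join(self.seqs[node])

    def gap_free_columns(self) -> np.ndarray:
        """Boolean mask of columns with a plain base in every node."""
        ok = np.ones(self.n_columns, dtype=bool)
        for arr in self.seqs.values():
            ok &= np.isin(arr, NUCS)
        return ok

    def gc_content(self, node: str) -> float:
        arr = self.seqs[node]
        valid = np.isin(arr, NUCS)
        if not valid.any():
            raise ValueError("no scored bases")
        return float(np.isin(arr[valid], ("G", "C")).mean())


def read_fasta_alignment(path: str | Path, ref_name: str = "ref",
                         coords=None) -> AncestralAlignment:
    """Read a directory of per-node FASTA files, or one multi-FASTA, of equal
    length; record names are tree node labels."""
    from Bio import SeqIO

    path = Path(path)
    records: dict[str, str] = {}
    files = sorted(path.glob("*.fa*")) if path.is_dir() else [path]
    for f in files:
        for rec in SeqIO.parse(str(f), "fasta"):
            records[rec.id] = str(rec.seq).upper()
    if not records:
        raise InputError(f"no FASTA records under {path}")
    return AncestralAlignment.from_strings(records, coords=coords, ref_name=ref_name)


def write_fasta_alignment(path: str | Path, aln: AncestralAlignment) -> None:
    with open(path, "w") as fh:
        for node in aln.nodes:
            fh.write(f">{node}\n{aln.sequence(node)}\n")


def read_maf_alignment(path: str | Path, ref_node: str) -> AncestralAlignment:
    """Read a MAF whose rows (including ancestor rows) are named as tree nodes.

    Columns where the reference row has a gap are dropped so that every
    retained column has a reference coordinate; blocks are concatenated in
    reference order.
    """
    from Bio import AlignIO

    blocks = []
    for msa in AlignIO.parse(str(path), "maf"):
        rows = {}
        ref_rec = None
        for rec in msa:
            name = rec.id.split(".")[0]
            rows[name] = np.array(list(str(rec.seq).upper()), dtype="<U1")
            if name == ref_node:
                ref_rec = rec
        if ref_rec is None:
            raise InputError(f"MAF block lacks reference row {ref_node!r}")
        start = int(ref_rec.annotations.get("start", 0))
        ref_name = ref_rec.id.split(".", 1)[1] if "." in ref_rec.id else "ref"
        keep = rows[ref_node] != "-"
        coords = start + np.cumsum(keep) - 1
        blocks.append(({k: v[keep] for k, v in rows.items()}, coords[keep], ref_name))
    if not blocks:
        raise InputError(f"no alignment blocks in {path}")
    blocks.sort(key=lambda b: b[1][0] if b[1].size else -1)
    nodes = blocks[0][0].keys()
    seqs = {k: np.concatenate([b[0][k] for b in blocks]) for k in nodes}
    coords = np.concatenate([b[1] for b in blocks])
    return AncestralAlignment(seqs, coords, blocks[0][2])


def filter_neutral_sites(aln: AncestralAlignment,
                         masks: Mapping[str, GenomicIntervals] | Iterable[GenomicIntervals] = (),
                         ) -> AncestralAlignment:
    """Columns outside every mask interval and with no gap/N in any node.

    Masks are exclusion features (coding, CpG island, repeat, conserved ...)
    as 0-based half-open intervals on the alignment's reference sequence.
    Idempotent; an empty result is returned as an empty alignment.
    """
    if isinstance(masks, Mapping):
        masks = list(masks.values())
    keep = aln.gap_free_columns()
    for iv in masks:
        if iv.chrom != aln.ref_name:
            raise CoordinateSystemError(
                f"mask on {iv.chrom!r} but alignment on {aln.ref_name!r}")
        keep &= ~iv.contains(aln.coords)
    return aln.subset(keep)


@dataclass
class SubstitutionTally:
    """Per-branch substitution counts in the seven strand-symmetric classes,
    with the opportunity (site) counts needed to turn them into rates."""

    branch: str
    counts: dict[str, int]
    n_scored: int          # columns scored (plain bases in parent and child)
    n_strong: int          # ancestral G/C columns
    n_weak: int            # ancestral A/T columns
    n_cpg: int             # ancestral CpG-context C columns (both strands)
    n_unscorable: int = 0  # C>T changes with undefined CpG context

    def __post_init__(self):
        self.counts = {c: int(self.counts.get(c, 0)) for c in CLASSES}
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative substitution count")
        if self.total_substitutions > self.n_scored:
            raise ValueError("more substitutions than scored columns")
        if self.counts["CpG>TpG"] > self.n_cpg:
            raise ValueError("CpG>TpG count exceeds CpG-context opportunity")

    @property
    def total_substitutions(self) -> int:
        return sum(self.counts.values())

    @property
    def count_ws(self) -> int:
        return sum(self.counts[c] for c in WS_CLASSES)

    @property
    def count_sw(self) -> int:
        return sum(self.counts[c] for c in SW_CLASSES)

    @property
    def rate_ws(self) -> float:
        """AT->GC substitutions per ancestral weak (A/T) site."""
        return self.count_ws / self.n_weak

    @property
    def rate_sw(self) -> float:
        """GC->AT substitutions per ancestral strong (G/C) site."""
        return self.count_sw / self.n_strong

    def to_series(self) -> pd.Series:
        data = {"branch": self.branch, **self.counts,
                "n_scored": self.n_scored, "n_strong": self.n_strong,
                "n_weak": self.n_weak, "n_cpg": self.n_cpg,
                "n_unscorable": self.n_unscorable}
        return pd.Series(data)

    @classmethod
    def from_series(cls, row: Mapping) -> "SubstitutionTally":
        return cls(branch=str(row["branch"]),
                   counts={c: int(row[c]) for c in CLASSES},
                   n_scored=int(row["n_scored"]), n_strong=int(row["n_strong"]),
                   n_weak=int(row["n_weak"]), n_cpg=int(row["n_cpg"]),
                   n_unscorable=int(row.get("n_unscorable", 0)))


def tallies_to_frame(tallies: Iterable[SubstitutionTally]) -> pd.DataFrame:
    return pd.DataFrame([t.to_series() for t in tallies])


def _parent_context(parent: np.ndarray, coords: np.ndarray):
    """Left/right ancestral neighbours per column; undefined where the
    neighbouring column is absent, non-contiguous, or not a plain base."""
    n = parent.size
    left = np.full(n, "", dtype="<U1")
    right = np.full(n, "", dtype="<U1")
    if n > 1:
        adj = np.diff(coords) == 1
        ok = adj & np.isin(parent[:-1], NUCS)
        left[1:][ok] = parent[:-1][ok]
        ok = adj & np.isin(parent[1:], NUCS)
        right[:-1][ok] = parent[1:][ok]
    return left, right


def count_branch_substitutions(aln: AncestralAlignment, tree: SpeciesTree,
                               branch: str) -> SubstitutionTally:
    """Tally parent-vs-child differences along the branch leading to `branch`.

    Only columns where both parent and child carry a plain base are scored;
    run the alignment through :func:`filter_neutral_sites` first to score the
    identical column set for every branch.
    """
    if branch not in tree.parent:
        raise KeyError(f"unknown branch (child node) {branch!r}")
    parent_label = tree.parent[branch]
    try:
        p, c = aln.seqs[parent_label], aln.seqs[branch]
    except KeyError as e:
        raise InputError(f"alignment lacks node {e.args[0]!r}") from e

    valid = np.isin(p, NUCS) & np.isin(c, NUCS)
    left, right = _parent_context(p, aln.coords)

    # CpG context on the collapsed (pyrimidine-ancestral) strand:
    # C followed by G, or G preceded by C.
    is_cpg = ((p == "C") & (right == "G")) | ((p == "G") & (left == "C"))
    # context needed but undefined
    ambiguous = ((p == "C") & (right == "")) | ((p == "G") & (left == ""))

    strong = valid & np.isin(p, ("C", "G"))
    weak = valid & np.isin(p, ("A", "T"))
    n_cpg = int((valid & is_cpg & ~ambiguous).sum())

    # collapse purine-ancestral columns to their reverse complement
    purine = valid & np.isin(p, ("A", "G"))
    eff_p = p.copy()
    eff_c = c.copy()
    for base, cb in zip(NUCS, ("T", "G", "C", "A")):
        eff_p[purine & (p == base)] = cb
        eff_c[purine & (c == base)] = cb

    changed = valid & (p != c)
    counts = {cls: 0 for cls in CLASSES}
    n_unscorable = 0
    for cls in CLASSES:
        if cls == "C>T":
            sel = changed & (eff_p == "C") & (eff_c == "T") & ~is_cpg & ~ambiguous
        elif cls == "CpG>TpG":
            sel = changed & (eff_p == "C") & (eff_c == "T") & is_cpg & ~ambiguous
        else:
            a, b = cls.split(">")
            sel = changed & (eff_p == a) & (eff_c == b)
        counts[cls] = int(sel.sum())
    n_unscorable = int((changed & (eff_p == "C") & (eff_c == "T") & ambiguous).sum())

    return SubstitutionTally(branch=branch, counts=counts,
                             n_scored=int(valid.sum()),
                             n_strong=int(strong.sum()), n_weak=int(weak.sum()),
                             n_cpg=n_cpg, n_unscorable=n_unscorable)


def divergence_rate(tally: SubstitutionTally) -> float:
    """Per-site divergence: substitutions over scored columns."""
    if tally.n_scored <= 0:
        raise ValueError("no scored columns")
    return tally.total_substitutions / tally.n_scored


def per_year(divergence: float, branch_years: float) -> float:
    """Per-site-and-year rate from a per-site divergence and branch duration."""
    if branch_years <= 0:
        raise ValueError("branch duration must be positive")
    return divergence / branch_years


def ts_tv_ratio(tally: SubstitutionTally) -> float:
    """Transition:transversion count ratio (CpG>TpG counts as a transition)."""
    tv = sum(tally.counts[c] for c in TRANSVERSIONS)
    if tv == 0:
        raise UndefinedRatioError("no transversions observed")
    ts = sum(tally.counts[c] for c in TRANSITIONS)
    return ts / tv


def substitution_spectrum(tally: SubstitutionTally) -> pd.Series:
    """Proportion of substitutions in each of the seven classes (sums to 1)."""
    total = tally.total_substitutions
    if total == 0:
        raise ValueError("no substitutions to form a spectrum")
    return pd.Series({c: tally.counts[c] / total for c in CLASSES},
                     name=tally.branch)


def spectrum_zscores(spectra: pd.DataFrame) -> pd.DataFrame:
    """Z-score spectra across telomeres, per species and class.

    `spectra` is a tidy frame with columns (telomere, species, cls,
    proportion); the returned frame adds a `z` column where each value is
    standardised by the mean and sample SD over telomeres of the same
    (species, cls) cell. Cells with zero variance get NaN.
    """
    required = {"telomere", "species", "cls", "proportion"}
    if not required.issubset(spectra.columns):
        raise ValueError(f"spectra frame needs columns {required}")
    out = spectra.copy()

    def _z(group: pd.Series) -> pd.Series:
        if group.size < 3:
            raise ValueError("need >= 3 telomeres per (species, class) cell")
        sd = group.std(ddof=1)
        # identical proportions give sd ~ 1e-17 by round-off: zero-variance
        if not np.isfinite(sd) or sd <= 1e-12 * max(abs(group.mean()), 1e-300):
            return pd.Series(np.nan, index=group.index)
        return (group - group.mean()) / sd

    out["z"] = out.groupby(["species", "cls"], sort=False)["proportion"].transform(_z)
    return out
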