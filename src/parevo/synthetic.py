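"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates the study design end to end: a five-taxon great-ape
alignment with exact ancestral sequences and a per-branch event log
(context-dependent Gillespie simulation with CpG transition hypermutability),
per-population genotype tables whose GC-frequency spectra follow the
stationary distribution under a conversion strength B, per-site depth
tracks, and telomere-peaked 10-kb recombination maps. Polymorphic sites are
generated independently (no linkage): sufficient for every estimator here,
since map inference from LD is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment import CLASSES, AncestralAlignment, classify_substitution
from .diversity import MISSING, SiteTable
from .gbgc import B_BOUND, expected_gc_afs
from .recombination import RecombMap
from .trees import GREAT_APE_NEWICK, SpeciesTree

NUC = np.array(["A", "C", "G", "T"])
_IDX = {b: i for i, b in enumerate(NUC)}


def hky_matrix(kappa: float = 4.0, gc: float = 0.45) -> np.ndarray:
    """HKY rate generator (rows A,C,G,T summing to zero), scaled to one
    expected substitution per site per unit branch length at stationarity.

    kappa = 4 with stationary GC = 0.45 gives a transition:transversion
    flux near 2, matching pseudoautosomal telomere estimates.
    """
    pi = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    Q = np.tile(pi, (4, 1))
    for i, j in ((0, 2), (2, 0), (1, 3), (3, 1)):  # A<->G, C<->T transitions
        Q[i, j] *= kappa
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -np.dot(pi, np.diag(Q))
    return Q / scale


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Left null vector of the generator, normalised to a distribution."""
    w, v = np.linalg.eig(Q.T)
    k = np.argmin(np.abs(w))
    pi = np.real(v[:, k])
    return pi / pi.sum()


def validate_generator(Q: np.ndarray) -> None:
    Q = np.asarray(Q, dtype=float)
    if Q.shape != (4, 4):
        raise ValueError("generator must be 4x4")
    off = Q.copy()
    np.fill_diagonal(off, 0.0)
    if np.any(off < 0):
        raise ValueError("off-diagonal rates must be non-negative")
    if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-10):
        raise ValueError("generator rows must sum to zero")


@dataclass
class SimulationConfig:
    """Study-shaped defaults: a ~240 kb neutral alignment (the size of the
    filtered PAR1 alignment), populations of 13 diploids over a 2.7 Mb
    region with per-site diversity near 2.5e-3, conversion strength near
    0.7, CpG transitions ~10x hypermutable, and maps averaging 9 cM/Mb with
    a telomere-proximal peak."""

    seed: int = 0
    newick: str = GREAT_APE_NEWICK
    kappa: float = 4.0
    gc: float = 0.45
    Q: np.ndarray | None = None
    cpg_multiplier: float = 10.0
    length: int = 240_000
    # population block
    n_diploid: int = 13
    sex_ratio: float = 0.5
    region_length: int = 2_700_000
    theta_class: dict = None
    B_class: dict = None
    mean_coverage: float = 15.0
    # recombination profile
    recomb_peak: float = 30.0
    recomb_decay: float = 1.0e6
    recomb_noise_sigma: float = 0.5
    window: int = 10_000

    def __post_init__(self):
        if self.Q is None:
            self.Q = hky_matrix(self.kappa, self.gc)
        validate_generator(self.Q)
        if self.length <= 0 or self.region_length <= 0 or self.n_diploid <= 0:
            raise ValueError("lengths and counts must be positive")
        if self.theta_class is None:
            # per-class per-site theta summing to ~2.1e-3: CpG transitions
            # enriched as in observed diversity spectra, and strong->weak
            # intensity about twice weak->strong (AT-biased mutation, which
            # is also what renders B identifiable from the GC spectrum)
            self.theta_class = {"C>A": 2.0e-4, "C>G": 2.5e-4, "C>T": 6.0e-4,
                                "CpG>TpG": 5.0e-4, "T>A": 1.5e-4,
                                "T>C": 3.0e-4, "T>G": 1.0e-4}
        if self.B_class is None:
            self.B_class = {"C>A": 0.7, "C>T": 0.7, "CpG>TpG": 1.5,
                            "T>C": 0.7, "T>G": 0.7}
        for b in self.B_class.values():
            if abs(b) > B_BOUND:
                raise ValueError("B outside the supported domain")
        if any(t < 0 for t in self.theta_class.values()):
            raise ValueError("theta must be non-negative")
        if self.mean_coverage < 0:
            raise ValueError("coverage must be non-negative")

    def tree(self) -> SpeciesTree:
        return SpeciesTree.from_newick(self.newick)


def _evolve_branch(parent_idx: np.ndarray, t: float, Q: np.ndarray,
                   mult: float, rng: np.random.Generator):
    """Gillespie simulation of one branch; returns (child index array,
    event list of (column, from_base, to_base))."""
    child = parent_idx.copy()
    L = child.size
    events: list[tuple[int, str, str]] = []
    if t == 0 or L == 0:
        return child, events
    base_max = float(np.max(-np.diag(Q)))
    max_rate = base_max + (mult - 1.0) * max(Q[_IDX["C"], _IDX["T"]],
                                             Q[_IDX["G"], _IDX["A"]])
    clock = 0.0
    while True:
        clock += rng.exponential(1.0 / (L * max_rate))
        if clock >= t:
            break
        col = int(rng.integers(0, L))
        b = child[col]
        rates = Q[b].copy()
        rates[b] = 0.0
        if b == _IDX["C"] and col + 1 < L and child[col + 1] == _IDX["G"]:
            rates[_IDX["T"]] *= mult
        elif b == _IDX["G"] and col > 0 and child[col - 1] == _IDX["C"]:
            rates[_IDX["A"]] *= mult
        total = rates.sum()
        if rng.random() * max_rate >= total:
            continue  # thinning rejection
        to = int(rng.choice(4, p=rates / total))
        events.append((col, NUC[b], NUC[to]))
        child[col] = to
    return child, events


def simulate_alignment(cfg: SimulationConfig, seed: int | None = None,
                       ) -> tuple[AncestralAlignment, dict[str, list]]:
    """Evolve a root sequence down the species tree; returns the alignment
    (leaves and all internal nodes) and the per-branch event log."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    tree = cfg.tree()
    pi = stationary_distribution(cfg.Q)
    seqs_idx: dict[str, np.ndarray] = {
        tree.root: rng.choice(4, size=cfg.length, p=pi)}
    events: dict[str, list] = {}
    # parents before children: sort branches by depth
    def depth(node: str) -> int:
        d = 0
        while node != tree.root:
            node = tree.parent[node]
            d += 1
        return d
    for child in sorted(tree.parent, key=depth):
        parent = tree.parent[child]
        t = tree.lengths.get(child, 0.0)
        seqs_idx[child], events[child] = _evolve_branch(
            seqs_idx[parent], t, cfg.Q, cfg.cpg_multiplier, rng)
    aln = AncestralAlignment({k: NUC[v] for k, v in seqs_idx.items()},
                             np.arange(cfg.length), ref_name="PAR1_sim")
    return aln, events


def tally_event_log(events: list[tuple[int, str, str]],
                    parent_seq: np.ndarray) -> dict[str, int]:
    """Classify logged events by the parent sequence's context — the same
    convention the counting estimator uses — for oracle comparisons."""
    parent_seq = np.asarray(parent_seq, dtype="<U1")
    counts = {c: 0 for c in CLASSES}
    for col, frm, to in events:
        left = parent_seq[col - 1] if col > 0 else None
        right = parent_seq[col + 1] if col + 1 < parent_seq.size else None
        cls = classify_substitution(frm, to, left, right)
        if cls and cls != "unscorable":
            counts[cls] += 1
    return counts


_STRONG = ("C", "G")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
#: per-class (ancestral, derived) on the pyrimidine-ancestral strand
_CLASS_ALLELES = {"C>A": ("C", "A"), "C>G": ("C", "G"), "C>T": ("C", "T"),
                  "CpG>TpG": ("C", "T"), "T>A": ("T", "A"),
                  "T>C": ("T", "C"), "T>G": ("T", "G")}


def _class_intensities(cls: str, B: float, n: int) -> np.ndarray:
    """Unit-theta expected spectrum over derived-allele counts 1..n-1."""
    anc, der = _CLASS_ALLELES[cls]
    anc_strong, der_strong = anc in _STRONG, der in _STRONG
    if anc_strong == der_strong:            # GC-conservative: neutral 1/i
        return 1.0 / np.arange(1, n)
    if der_strong:                           # weak -> strong: derived is GC
        return expected_gc_afs(B, n, 1.0, 0.0)
    # strong -> weak: GC allele is ancestral at count n-i for derived count i
    return expected_gc_afs(B, n, 0.0, 1.0)[::-1]


def simulate_polymorphism(cfg: SimulationConfig, seed: int | None = None,
                          ) -> tuple[SiteTable, np.ndarray]:
    """Segregating sites for one population, plus the reference sequence
    their CpG-context annotation is consistent with.

    Per class, the segregating-site count is Poisson with intensity
    theta_class * L * (stationary sampling spectrum under +/-B conditioned
    on polymorphism); derived alleles are placed on chromosomes at the drawn
    count and paired into Hardy-Weinberg diploid genotypes.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    n = 2 * cfg.n_diploid
    L = cfg.region_length
    ref = NUC[rng.choice(4, size=L, p=stationary_distribution(cfg.Q))]

    # positions on a stride-3 grid so CpG-context edits never collide
    grid = np.arange(1, L - 2, 3)
    records = []
    for cls in CLASSES:
        theta = cfg.theta_class.get(cls, 0.0)
        if theta == 0.0:
            continue
        B = cfg.B_class.get(cls, 0.0)
        lam = theta * L * _class_intensities(cls, B, n)
        counts = rng.poisson(lam)
        for derived_count, n_sites in zip(np.arange(1, n), counts):
            for _ in range(int(n_sites)):
                records.append((cls, int(derived_count)))
    if len(records) > grid.size:
        raise ValueError("region too short for the requested theta")
    pos = rng.choice(grid, size=len(records), replace=False)

    order = np.argsort(pos)
    pos = pos[order]
    records = [records[i] for i in order]
    m = len(records)
    anc = np.empty(m, dtype="<U1")
    der = np.empty(m, dtype="<U1")
    cls_arr = np.empty(m, dtype="<U8")
    cpg_arr = np.zeros(m, dtype=bool)
    gt = np.zeros((m, cfg.n_diploid), dtype=np.int8)
    for i, (cls, derived_count) in enumerate(records):
        a, d = _CLASS_ALLELES[cls]
        if rng.random() < 0.5:  # place on the purine-ancestral strand
            a, d = _COMP[a], _COMP[d]
            flipped = True
        else:
            flipped = False
        p = int(pos[i])
        ref[p] = a
        # make reference context consistent with the class annotation
        if cls == "CpG>TpG":
            if flipped:
                ref[p - 1] = "C"
            else:
                ref[p + 1] = "G"
            cpg_arr[i] = True
        elif a == "C" and ref[p + 1] == "G":
            ref[p + 1] = NUC[rng.choice([0, 1, 3])]
        elif a == "G" and ref[p - 1] == "C":
            ref[p - 1] = NUC[rng.choice([0, 2, 3])]
        anc[i], der[i] = a, d
        cls_arr[i] = cls
        chroms = rng.permutation(n) < derived_count
        gt[i] = chroms.reshape(cfg.n_diploid, 2).sum(axis=1)

    n_f = int(round(cfg.n_diploid * cfg.sex_ratio))
    sex = np.array(["F"] * n_f + ["M"] * (cfg.n_diploid - n_f), dtype="<U1")
    rng.shuffle(sex)
    samples = [f"ind{i:02d}" for i in range(cfg.n_diploid)]
    sites = SiteTable(pos=pos, ref=anc.copy(), alt=der.copy(), anc=anc,
                      gt=gt, samples=samples, sex=sex, mut_class=cls_arr,
                      cpg=cpg_arr, chrom="PAR1_sim")
    return sites, ref


def simulate_recomb_map(cfg: SimulationConfig, population: str = "pop",
                        seed: int | None = None,
                        noise_sigma: float | None = None) -> RecombMap:
    """Telomere-peaked map: rate_w = peak * exp(-start_w / decay) *
    lognormal noise, on the fixed window grid."""
    if cfg.recomb_decay <= 0:
        raise ValueError("decay scale must be positive")
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    starts = np.arange(0, cfg.region_length, cfg.window, dtype=np.int64)
    profile = cfg.recomb_peak * np.exp(-starts / cfg.recomb_decay)
    sigma = cfg.recomb_noise_sigma if noise_sigma is None else noise_sigma
    noise = rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma,
                          size=starts.size) if sigma > 0 else 1.0
    return RecombMap(population, starts, profile * noise,
                     window=cfg.window, units="rho")


def simulate_depth(cfg: SimulationConfig, n_haploid: int | None = None,
                   seed: int | None = None) -> np.ndarray:
    """Per-site Poisson(n_haploid * mean_coverage) read depths."""
    rng = np.random.default_rng(cfg.seed + 3 if seed is None else seed)
    n_hap = 2 * cfg.n_diploid if n_haploid is None else n_haploid
    return rng.poisson(n_hap * cfg.mean_coverage,
                       size=cfg.region_length).astype(np.int64)


#: Hominin scaffold: branch lengths solve the observed pairwise divergences
#: (human-Neanderthal 0.0021, human-Denisovan 0.0022, Neanderthal-Denisovan
#: 0.0019) with a chimpanzee outgroup at human-chimpanzee distance 0.0225.
HOMININ_NEWICK = ("(((N:0.0009,D:0.0010)ND:0.0003,H:0.0009)HND:0.0104,"
                  "C:0.0112)root;")


def simulate_hominin_alignment(length: int = 250_000, seed: int = 0,
                               ) -> AncestralAlignment:
    """Alignment of H, N, D and C leaf sequences under the hominin scaffold
    (no CpG hypermutability; p-distances estimate the branch sums)."""
    cfg = SimulationConfig(seed=seed, newick=HOMININ_NEWICK, length=length,
                           cpg_multiplier=1.0)
    aln, _ = simulate_alignment(cfg)
    return aln
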