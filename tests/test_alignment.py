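"""Substitution classification, neutral-site filtering and branch counting."""

import numpy as np
import pandas as pd
import pytest

from parevo import alignment as al
from parevo.io import CoordinateSystemError, GenomicIntervals
from parevo.synthetic import SimulationConfig, simulate_alignment, tally_event_log
from parevo.trees import SpeciesTree, great_ape_tree


@pytest.mark.parametrize("parent,child,p5,p3,expected", [
    ("C", "T", None, "G", "CpG>TpG"),
    ("G", "A", "C", None, "CpG>TpG"),
    ("C", "T", None, "A", "C>T"),
    ("G", "A", "T", None, "C>T"),
    ("A", "C", None, None, "T>G"),
    ("A", "G", None, None, "T>C"),
    ("G", "C", None, None, "C>G"),
    ("T", "A", None, None, "T>A"),
    ("C", "C", None, None, None),
    ("C", "T", None, None, "unscorable"),
    ("C", "T", None, "N", "unscorable"),
    ("G", "A", "-", None, "unscorable"),
])
def test_classify_substitution(parent, child, p5, p3, expected):
    assert al.classify_substitution(parent, child, p5, p3) == expected


def test_classify_rejects_non_nucleotides():
    with pytest.raises(al.InputError):
        al.classify_substitution("N", "A")


def _toy_aln(**seqs):
    return al.AncestralAlignment.from_strings(seqs)


class TestFilterNeutralSites:
    def test_identity_with_no_masks(self):
        aln = _toy_aln(H="ACGTACGTAC", HC="ACGTACGTAC")
        assert al.filter_neutral_sites(aln).n_columns == 10

    def test_mask_interval_removes_covered_columns(self):
        aln = _toy_aln(H="ACGTACGTAC", HC="ACGTACGTAC")
        mask = GenomicIntervals("ref", [3], [6])
        kept = al.filter_neutral_sites(aln, [mask])
        # brute-force interval test per column
        expected = [c for c in range(10) if not (3 <= c < 6)]
        assert list(kept.coords) == expected

    def test_gap_or_n_column_removed(self):
        aln = _toy_aln(H="AC-TA", HC="ACGTN")
        kept = al.filter_neutral_sites(aln)
        assert list(kept.coords) == [0, 1, 3]

    def test_idempotent(self):
        aln = _toy_aln(H="ACGTACGTAC", HC="AC-TACGTAC")
        mask = GenomicIntervals("ref", [7], [9])
        once = al.filter_neutral_sites(aln, [mask])
        twice = al.filter_neutral_sites(once, [mask])
        assert list(once.coords) == list(twice.coords)

    def test_wrong_reference_raises(self):
        aln = _toy_aln(H="ACGT", HC="ACGT")
        with pytest.raises(CoordinateSystemError):
            al.filter_neutral_sites(aln, [GenomicIntervals("chrX", [0], [2])])


TWO_NODE_TREE = SpeciesTree(parent={"H": "HC"}, root="HC")


class TestCountBranchSubstitutions:
    def test_identical_sequences_scored_but_uncounted(self):
        aln = _toy_aln(HC="ACGT", H="ACGT")
        t = al.count_branch_substitutions(aln, TWO_NODE_TREE, "H")
        assert t.total_substitutions == 0
        assert t.n_scored == 4

    def test_hand_scored_cpg_column(self):
        # parent ACGA -> child ATGA: the C sits 5' of a G, so C>T is CpG>TpG
        aln = _toy_aln(HC="ACGA", H="ATGA")
        t = al.count_branch_substitutions(aln, TWO_NODE_TREE, "H")
        assert t.counts["CpG>TpG"] == 1
        assert t.total_substitutions == 1
        assert t.n_cpg == 2  # the C and the G of the CpG, both strands

    def test_unknown_branch(self):
        aln = _toy_aln(HC="ACGT", H="ACGT")
        with pytest.raises(KeyError):
            al.count_branch_substitutions(aln, TWO_NODE_TREE, "X")

    def test_counter_matches_per_column_brute_force(self, small_alignment,
                                                    small_cfg):
        """The vectorised counter agrees exactly with a per-column scan that
        classifies each parent/child difference with its parent context."""
        aln, _ = small_alignment
        tree = small_cfg.tree()
        for branch in ("H", "M"):
            p, c = aln.seqs[tree.parent[branch]], aln.seqs[branch]
            expected = {cls: 0 for cls in al.CLASSES}
            for j in range(aln.n_columns):
                if p[j] == c[j]:
                    continue
                left = p[j - 1] if j > 0 else None
                right = p[j + 1] if j + 1 < aln.n_columns else None
                cls = al.classify_substitution(p[j], c[j], left, right)
                if cls and cls != al.UNSCORABLE:
                    expected[cls] += 1
            t = al.count_branch_substitutions(aln, tree, branch)
            assert t.counts == expected

    def test_event_log_oracle_single_hit_columns(self, small_alignment,
                                                 small_cfg):
        """Wherever a branch-column carries exactly one simulated event, the
        end-state class equals the logged event's class (read from the
        parent context, as the estimator does)."""
        aln, events = small_alignment
        tree = small_cfg.tree()
        checked = 0
        for branch in ("H", "G", "O", "HC"):
            parent = aln.seqs[tree.parent[branch]]
            child = aln.seqs[branch]
            cols = [e[0] for e in events[branch]]
            multi = {c for c in cols if cols.count(c) > 1}
            for col, frm, to in events[branch]:
                if col in multi:
                    continue
                assert parent[col] == frm and child[col] == to
                left = parent[col - 1] if col > 0 else None
                right = parent[col + 1] if col + 1 < aln.n_columns else None
                assert (al.classify_substitution(parent[col], child[col],
                                                 left, right)
                        == al.classify_substitution(frm, to, left, right))
                checked += 1
        assert checked > 100

    def test_multiple_hits_only_reduce_counts(self, small_alignment, small_cfg):
        aln, events = small_alignment
        t = al.count_branch_substitutions(aln, small_cfg.tree(), "M")
        assert t.total_substitutions <= len(events["M"])

    def test_strand_symmetry_of_counts(self, small_alignment, small_cfg):
        """Reverse-complementing every sequence leaves class counts intact."""
        aln, _ = small_alignment
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = {k: np.array([comp[b] for b in v[::-1]], dtype="<U1")
              for k, v in aln.seqs.items()}
        flipped = al.AncestralAlignment(rc, aln.coords, aln.ref_name)
        t1 = al.count_branch_substitutions(aln, small_cfg.tree(), "H")
        t2 = al.count_branch_substitutions(flipped, small_cfg.tree(), "H")
        assert t1.counts == t2.counts


def _tally(counts, n_scored=10_000, n_strong=4_000, n_weak=6_000, n_cpg=500):
    full = dict(zip(al.CLASSES, counts))
    return al.SubstitutionTally("H", full, n_scored, n_strong, n_weak, n_cpg)


class TestRates:
    def test_divergence_arithmetic(self):
        t = _tally([2, 2, 2, 2, 2, 1, 1], n_scored=1200)
        assert al.divergence_rate(t) == pytest.approx(0.01)

    def test_zero_counts_zero_divergence(self):
        assert al.divergence_rate(_tally([0] * 7)) == 0.0

    def test_zero_scored_columns_error(self):
        t = _tally([0] * 7)
        t.n_scored = 0
        with pytest.raises(ValueError):
            al.divergence_rate(t)

    def test_per_year_consistency_with_published_branch(self):
        # human branch: 0.0105 total at 0.9652e-9 /site/year implies a
        # branch duration near 10.88 My; the division must invert exactly
        years = 0.0105 / 0.9652e-9
        assert al.per_year(0.0105, years) == pytest.approx(0.9652e-9)
        assert years == pytest.approx(1.088e7, rel=1e-3)

    def test_ts_tv_printed_format(self):
        # 192 transitions over 100 transversions -> 1.92, the region average
        t = _tally([40, 30, 100, 42, 20, 50, 10])
        assert al.ts_tv_ratio(t) == pytest.approx(1.92)

    def test_ts_tv_undefined_without_transversions(self):
        with pytest.raises(al.UndefinedRatioError):
            al.ts_tv_ratio(_tally([0, 0, 5, 5, 0, 5, 0]))

    def test_ts_tv_tracks_simulated_transition_bias(self):
        """A kappa = 2 generator yields a ts:tv ratio near 2x the flux share."""
        from parevo.synthetic import hky_matrix
        cfg = SimulationConfig(seed=5, length=60_000, cpg_multiplier=1.0,
                               kappa=2.0, newick="(H:0.05)HC;")
        aln, _ = simulate_alignment(cfg)
        t = al.count_branch_substitutions(aln, SpeciesTree({"H": "HC"}, "HC"), "H")
        # kappa=2, GC=0.45: expected ts:tv flux ratio = 2 * 0.495 = 0.99
        assert al.ts_tv_ratio(t) == pytest.approx(0.99, rel=0.15)


class TestSpectrum:
    def test_uniform_and_sparse_spectra(self):
        assert np.allclose(al.substitution_spectrum(_tally([1] * 7)), 1 / 7)
        s = al.substitution_spectrum(_tally([0, 0, 5, 0, 0, 0, 5]))
        assert list(s) == [0, 0, 0.5, 0, 0, 0, 0.5]
        assert s.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_tally_error(self):
        with pytest.raises(ValueError):
            al.substitution_spectrum(_tally([0] * 7))

    def test_proportions_track_generator_rate_shares(self, small_alignment,
                                                     small_cfg):
        t = al.count_branch_substitutions(small_alignment[0],
                                          small_cfg.tree(), "M")
        s = al.substitution_spectrum(t)
        assert s.sum() == pytest.approx(1.0, abs=1e-12)
        # transitions dominate under kappa=4 with CpG hypermutability
        assert s["CpG>TpG"] + s["C>T"] + s["T>C"] > 0.5


class TestSpectrumZscores:
    @staticmethod
    def _frame(props):
        return pd.DataFrame([
            {"telomere": f"t{i}", "species": "H", "cls": "C>G", "proportion": p}
            for i, p in enumerate(props)])

    def test_three_telomere_example(self):
        z = al.spectrum_zscores(self._frame([0.1, 0.2, 0.3]))["z"]
        assert np.allclose(z, [-1.0, 0.0, 1.0])

    def test_zero_variance_cell_flagged_nan(self):
        z = al.spectrum_zscores(self._frame([0.2, 0.2, 0.2]))["z"]
        assert z.isna().all()

    def test_standardisation_property(self):
        rng = np.random.default_rng(0)
        rows = [{"telomere": f"t{i}", "species": sp, "cls": c,
                 "proportion": rng.random()}
                for i in range(8) for sp in "HC" for c in ("C>A", "T>C")]
        out = al.spectrum_zscores(pd.DataFrame(rows))
        g = out.groupby(["species", "cls"])["z"]
        assert np.allclose(g.mean(), 0.0, atol=1e-12)
        assert np.allclose(g.std(ddof=1), 1.0, atol=1e-12)


def test_great_ape_tree_structure():
    tree = great_ape_tree()
    assert tree.leaves == {"H", "C", "G", "O", "M"}
    assert tree.parent["H"] == "HC" and tree.parent["HC"] == "HCG"
    assert tree.ages["H"] > 0
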