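"""Window diversity, bimodal thresholding and block calling."""
import numpy as np
import pandas as pd
import pytest

from pedtrace.ancestry import (DiversityProfile, InsufficientWindowsError,
                               WindowGrid, bimodal_threshold, call_blocks,
                               contribution_fractions, fit_thresholds,
                               make_window_grid, window_diversity)
from pedtrace.similarity import pair_diff_valid

from conftest import make_gm


def brute_force_profile(calls, grid, samples, descendant, ancestors, positions):
    """Exhaustive pair-count oracle for the per-window statistics."""
    out = {}
    n = len(samples)
    for (chrom, s, e) in grid.windows:
        in_w = [k for k, p in enumerate(positions) if s < p <= e]
        pis = {}
        for i in range(n):
            for j in range(i + 1, n):
                diff = comp = 0
                for k in in_w:
                    a, b = calls[i][k], calls[j][k]
                    if a in (0, 2) and b in (0, 2):
                        comp += 1
                        diff += a != b
                if comp:
                    pis[(i, j)] = diff / comp
        d_arv = np.mean(list(pis.values())) if pis else np.nan
        for anc in ancestors:
            pair = tuple(sorted((samples.index(descendant), samples.index(anc))))
            d_pair = pis.get(pair, np.nan)
            out[(chrom, s, anc)] = (d_pair, d_arv)
    return out


class TestWindowDiversity:
    def test_decrease_formula_values(self):
        # window with d_arv > 0 and descendant identical to ancestor A
        calls = np.array([
            [0, 0, 2, 2, 0],   # A
            [2, 2, 0, 0, 2],   # B
            [0, 2, 2, 0, 0],   # C
            [0, 0, 2, 2, 0],   # D = descendant, identical to A
        ], dtype=np.int8)
        gm = make_gm(calls, samples=["A", "B", "C", "D"])
        grid = make_window_grid({"chr1": 600}, window_bp=600, step_bp=600,
                                min_snps=1)
        prof = window_diversity(gm, grid, "D", ["A", "B"])
        t = prof.table.set_index("ancestor")
        assert t.loc["A", "decrease"] == pytest.approx(1.0)  # Dpair = 0
        # direct formula check for ancestor B
        d_arv = t.loc["B", "d_arv"]
        d_pair = t.loc["B", "d_pair"]
        assert t.loc["B", "decrease"] == pytest.approx((d_arv - d_pair) / d_arv)

    def test_direct_formula_evaluation(self):
        # decrease = (0.4 - 0.1)/0.4 = 0.75 — scalar identity on the formula path
        prof = DiversityProfile("x", ["a"], make_window_grid({"c": 10}, 10, 10, 1),
                                pd.DataFrame([dict(chrom="c", start=0, end=10,
                                                   ancestor="a", d_pair=0.1,
                                                   d_arv=0.4, decrease=(0.4 - 0.1) / 0.4,
                                                   n_snps=5, informative=True)]))
        assert prof.decreases("a")[0] == pytest.approx(0.75)

    def test_matches_exhaustive_pair_count_oracle(self):
        rng = np.random.default_rng(23)
        samples = ["A", "B", "C", "D"]
        calls = rng.choice([-1, 0, 1, 2], size=(4, 120), p=[0.05, 0.45, 0.1, 0.4])
        gm = make_gm(calls, samples=samples, spacing=50)
        positions = gm.sites["pos"].tolist()
        grid = make_window_grid({"chr1": 6000}, window_bp=1500, step_bp=750,
                                min_snps=1)
        prof = window_diversity(gm, grid, "D", ["A", "B"])
        oracle = brute_force_profile(calls, grid, samples, "D", ["A", "B"], positions)
        for _, r in prof.table.iterrows():
            d_pair, d_arv = oracle[(r["chrom"], r["start"], r["ancestor"])]
            np.testing.assert_allclose(r["d_pair"], d_pair, equal_nan=True)
            np.testing.assert_allclose(r["d_arv"], d_arv, equal_nan=True)

    def test_empty_window_uninformative_not_nan_propagating(self):
        gm = make_gm([[0, 2], [2, 0], [0, 0]], samples=["A", "B", "D"], spacing=10)
        grid = make_window_grid({"chr1": 1000}, window_bp=100, step_bp=100,
                                min_snps=1)
        prof = window_diversity(gm, grid, "D", ["A"])
        empty = prof.table[prof.table["start"] >= 100]
        assert not empty["informative"].any()
        assert (empty["n_snps"] == 0).all()

    def test_permuting_uninvolved_samples_invariant(self):
        rng = np.random.default_rng(3)
        calls = rng.choice([0, 2], size=(5, 80))
        samples = ["A", "B", "C", "D", "E"]
        gm1 = make_gm(calls, samples=samples, spacing=10)
        perm = [0, 4, 3, 2, 1]  # descendant A and ancestor? keep A first
        gm2 = make_gm(calls[perm], samples=[samples[i] for i in perm], spacing=10)
        grid = make_window_grid({"chr1": 800}, 200, 200, 1)
        p1 = window_diversity(gm1, grid, "A", ["B"]).table
        p2 = window_diversity(gm2, grid, "A", ["B"]).table
        np.testing.assert_allclose(p1["d_pair"], p2["d_pair"], equal_nan=True)
        np.testing.assert_allclose(p1["d_arv"], p2["d_arv"], equal_nan=True)


class TestBimodalThreshold:
    def test_separates_planted_mixture(self):
        rng = np.random.default_rng(7)
        lo = rng.normal(0.1, 0.02, 300)
        hi = rng.normal(0.85, 0.05, 300)
        vals = np.concatenate([lo, hi])
        fit = bimodal_threshold(vals, seed=0)
        assert not fit.unimodal
        assert 0.3 < fit.threshold < 0.6
        assert 0.4 < fit.weights[0] < 0.6
        # misassignment against the planted labels < 1%
        mis = np.sum(lo >= fit.threshold) + np.sum(hi < fit.threshold)
        assert mis / len(vals) < 0.01

    def test_identical_values_fall_back_unimodal(self):
        fit = bimodal_threshold(np.full(100, 0.37), fallback=0.5)
        assert fit.unimodal and fit.threshold == 0.5

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(8)
        vals = np.concatenate([rng.normal(0.2, 0.05, 100),
                               rng.normal(0.8, 0.05, 100)])
        f1 = bimodal_threshold(vals, seed=3)
        f2 = bimodal_threshold(vals.copy(), seed=3)
        assert f1.threshold == f2.threshold

    def test_too_few_windows_is_explicit_error(self):
        with pytest.raises(InsufficientWindowsError):
            bimodal_threshold(np.linspace(0, 1, 10))


def _profile_from_labels(labels, ancestors, window=10_000):
    """Build a single-chromosome profile whose windows favor given labels.

    label == ancestor name -> that ancestor has decrease 0.9, others 0.1;
    label None -> all ancestors 0.1 (no one passes a 0.5 threshold).
    """
    rows = []
    for w, lab in enumerate(labels):
        for anc in ancestors:
            dec = 0.9 if lab == anc else 0.1
            rows.append(dict(chrom="chr1", start=w * window, end=(w + 1) * window,
                             ancestor=anc, d_pair=np.nan, d_arv=0.4,
                             decrease=dec, n_snps=50, informative=True))
    grid = WindowGrid([(r["chrom"], r["start"], r["end"])
                       for r in rows if r["ancestor"] == ancestors[0]],
                      window, window, 1, {"chr1": len(labels) * window})
    return DiversityProfile("X", list(ancestors), grid, pd.DataFrame(rows))


class TestCallBlocks:
    def test_uniform_origin_single_block(self):
        prof = _profile_from_labels(["A"] * 10, ["A", "B"])
        mosaic = call_blocks(prof, {"A": 0.5, "B": 0.5})
        assert len(mosaic.blocks) == 1
        b = mosaic.blocks[0]
        assert (b.start, b.end, b.origin) == (0, 100_000, "A")
        rep = contribution_fractions(mosaic)
        assert rep.fractions == {"A": 1.0}

    def test_uncertain_run_split_at_midpoint(self):
        # A A A . . . . B B B -> boundary two windows into the uncertain run
        labels = ["A"] * 3 + [None] * 4 + ["B"] * 3
        prof = _profile_from_labels(labels, ["A", "B"])
        mosaic = call_blocks(prof, {"A": 0.5, "B": 0.5})
        assert [(b.start, b.end, b.origin) for b in mosaic.blocks] == [
            (0, 50_000, "A"), (50_000, 100_000, "B")]

    def test_uncertain_at_ends_attached_to_neighbor(self):
        labels = [None, None, "A", "A", None]
        prof = _profile_from_labels(labels, ["A", "B"])
        mosaic = call_blocks(prof, {"A": 0.5, "B": 0.5})
        assert [(b.start, b.end, b.origin) for b in mosaic.blocks] == [
            (0, 50_000, "A")]

    def test_entirely_uncertain_chromosome_unassigned(self):
        prof = _profile_from_labels([None] * 6, ["A", "B"])
        with pytest.warns(UserWarning):
            mosaic = call_blocks(prof, {"A": 0.5, "B": 0.5})
        assert mosaic.unassigned_chroms == ["chr1"]
        with pytest.raises(ValueError):
            contribution_fractions(mosaic)

    def test_missing_threshold_rejected(self):
        prof = _profile_from_labels(["A"] * 5, ["A", "B"])
        with pytest.raises(ValueError):
            call_blocks(prof, {"A": 0.5})

    def test_single_crossover_breakpoint_recovered_within_one_window(self):
        # homozygous mosaic: founder A up to X, founder B after
        rng = np.random.default_rng(31)
        n = 1000
        pos = np.sort(rng.choice(np.arange(1, 1_000_001), n, replace=False))
        A = rng.choice([0, 2], n)
        B = rng.choice([0, 2], n)
        X = 412_345
        off = np.where(pos <= X, A, B)
        from pedtrace.io import GenotypeMatrix
        sites = pd.DataFrame({"chrom": ["chr1"] * n, "pos": pos,
                              "ref": ["A"] * n, "alt": ["T"] * n})
        gm = GenotypeMatrix(["A", "B", "off"],
                            sites, np.stack([A, B, off]).astype(np.int8))
        grid = make_window_grid({"chr1": 1_000_000}, 100_000, 10_000, 10)
        prof = window_diversity(gm, grid, "off", ["A", "B"])
        mosaic = call_blocks(prof, fit_thresholds(prof, seed=0))
        switches = [(b.start, b.origin) for b in mosaic.blocks]
        assert [o for _, o in switches] == ["A", "B"]
        boundary = mosaic.blocks[1].start
        assert abs(boundary - X) <= grid.window_bp

    def test_contribution_fractions_sum_to_one(self):
        labels = ["A"] * 4 + ["B"] * 3 + [None] * 2 + ["A"] * 3
        prof = _profile_from_labels(labels, ["A", "B"])
        rep = contribution_fractions(call_blocks(prof, {"A": 0.5, "B": 0.5}))
        assert sum(rep.fractions.values()) == pytest.approx(1.0, abs=1e-9)
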