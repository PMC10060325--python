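"""Volcano filter, EASE enrichment against a combinatorial oracle,
estimation-plot z-scores, mtDNA ratio."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mitothermics.omics_enrichment import (
    AbundanceTable,
    PathwayDef,
    QpcrRecords,
    de_filter,
    ease_fisher,
    enrich_pathways,
    mtdna_ratio,
    pathway_zscores,
    read_gmt,
    write_gmt,
)


def hypergeom_upper_tail(k, N, K, n):
    """Exact P(X >= k) by rational arithmetic — independent of scipy."""
    total = comb(N, n)
    acc = Fraction(0)
    for x in range(k, min(n, K) + 1):
        acc += Fraction(comb(K, x) * comb(N - K, n - x), total)
    return float(acc)


def make_table(log2_matrix, groups):
    values = pd.DataFrame(
        2.0 ** np.asarray(log2_matrix, dtype=float),
        index=[f"P{i}" for i in range(len(log2_matrix))],
        columns=list(groups),
    )
    return AbundanceTable(values, pd.Series(list(groups.values()), index=list(groups)))


class TestEaseFisher:
    def test_zero_overlap_is_one(self):
        assert ease_fisher(0, 5, 5, 20) == 1.0

    def test_worked_example_against_oracle(self):
        p = ease_fisher(3, 5, 5, 20)
        assert p == pytest.approx(hypergeom_upper_tail(2, 20, 5, 5), abs=1e-12)
        assert p == pytest.approx(0.36608, abs=1e-4)

    def test_classic_equals_oracle_exhaustively(self):
        for N in range(1, 13):
            for K in range(0, N + 1):
                for n in range(0, N + 1):
                    for k in range(0, min(n, K) + 1):
                        got = ease_fisher(k, n, K, N, variant="classic")
                        want = hypergeom_upper_tail(k, N, K, n)
                        assert got == pytest.approx(want, abs=1e-12), (N, K, n, k)

    def test_ease_never_below_classic(self):
        for N in range(1, 13):
            for K in range(0, N + 1):
                for n in range(0, N + 1):
                    for k in range(1, min(n, K) + 1):
                        assert ease_fisher(k, n, K, N) >= ease_fisher(
                            k, n, K, N, variant="classic"
                        ) - 1e-15

    def test_inconsistent_margins_rejected(self):
        with pytest.raises(ValueError):
            ease_fisher(3, 2, 5, 20)
        with pytest.raises(ValueError):
            ease_fisher(1, 5, 30, 20)

    def test_enrich_pathways_applies_bh(self):
        universe = [f"P{i}" for i in range(40)]
        de = universe[:10]
        pws = [PathwayDef("hit", frozenset(universe[:8])),
               PathwayDef("miss", frozenset(universe[30:38]))]
        out = enrich_pathways(de, pws, universe)
        assert list(out["pathway"]) == ["hit", "miss"]
        assert out.loc[0, "p"] < out.loc[1, "p"]
        assert np.all(out["q"] >= out["p"] - 1e-15)


class TestDeFilter:
    def test_empty_table(self):
        table = AbundanceTable(
            pd.DataFrame(columns=["a1", "a2", "b1", "b2"], dtype=float),
            pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"}),
        )
        res = de_filter(table, "A", "B")
        assert (res.n_up, res.n_down, res.n_tested) == (0, 0, 0)

    def test_threshold_contract(self):
        """Ratio 1.6 with tiny p passes as 'up'; ratio 1.4 fails the fold
        gate regardless of p."""
        base = np.array([10.0, 10.1, 9.9, 10.0])
        rows = [
            np.concatenate([base, base + np.log2(1.6)]),
            np.concatenate([base, base + np.log2(1.4)]),
        ]
        groups = {f"a{i}": "A" for i in range(4)} | {f"b{i}": "B" for i in range(4)}
        res = de_filter(make_table(rows, groups), "A", "B")
        assert bool(res.table.loc["P0", "passed"]) is True
        assert res.table.loc["P0", "direction"] == "up"
        assert res.table.loc["P0", "p"] < 0.05
        assert bool(res.table.loc["P1", "passed"]) is False
        assert res.table.loc["P1", "p"] < 0.05  # fails on fold alone

    def test_zero_variance_excluded_with_reason(self):
        rows = [[10.0, 10.0, 10.0, 10.0, 10.0, 10.0],
                [10.0, 10.5, 9.5, 11.0, 11.5, 10.5]]
        groups = {f"a{i}": "A" for i in range(3)} | {f"b{i}": "B" for i in range(3)}
        res = de_filter(make_table(rows, groups), "A", "B")
        assert res.n_tested == 1
        assert "zero variance" in res.excluded["P0"]

    def test_matches_naive_double_loop(self):
        """Oracle equivalence on a 200 x 12 random table: per-protein pooled
        t statistic and p computed from first principles."""
        rng = np.random.default_rng(12)
        log2 = rng.normal(18, 1.5, size=(200, 12))
        log2[:15, 6:] += 1.1
        groups = {f"a{i}": "A" for i in range(6)} | {f"b{i}": "B" for i in range(6)}
        table = make_table(log2, groups)
        res = de_filter(table, "A", "B")

        for i, pid in enumerate(table.values.index):
            a, b = log2[i, :6], log2[i, 6:]
            na, nb = 6, 6
            sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
            t = (b.mean() - a.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
            p = 2 * stats.t.sf(abs(t), na + nb - 2)
            ratio = 2.0 ** (b.mean() - a.mean())
            passed = (p < 0.05) and (ratio >= 1.5 or ratio <= 1 / 1.5)
            assert res.table.loc[pid, "p"] == pytest.approx(p, rel=1e-9)
            assert res.table.loc[pid, "fold_change"] == pytest.approx(ratio, rel=1e-9)
            assert bool(res.table.loc[pid, "passed"]) == passed

    def test_counts_consistent(self):
        rng = np.random.default_rng(4)
        log2 = rng.normal(18, 1, size=(60, 10))
        groups = {f"a{i}": "A" for i in range(5)} | {f"b{i}": "B" for i in range(5)}
        res = de_filter(make_table(log2, groups), "A", "B")
        assert res.n_up + res.n_down <= res.n_tested
        assert res.n_up + res.n_down == int(res.table["passed"].sum())


class TestPathwayZscores:
    def test_standardization_identity(self):
        rng = np.random.default_rng(8)
        log2 = rng.normal(15, 2, size=(6, 10))
        groups = {f"a{i}": "A" for i in range(5)} | {f"b{i}": "B" for i in range(5)}
        table = make_table(log2, groups)
        pw = PathwayDef("all", frozenset(table.values.index))
        z = pathway_zscores(table, pw, "A", "B")
        # reconstruct the full z matrix the same way and check row moments
        sub = table.values
        zz = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=0), axis=0)
        np.testing.assert_allclose(zz.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(zz.var(axis=1, ddof=0), 1, atol=1e-12)
        # grand mean of z over all proteins and samples is zero
        assert zz.to_numpy().mean() == pytest.approx(0, abs=1e-12)
        # per-group means of z must average to ~0 weighted by group sizes
        assert (z.group_means["A"] + z.group_means["B"]) / 2 == pytest.approx(0, abs=1e-12)

    def test_identical_groups_no_shift(self):
        log2 = np.tile(np.array([[10.0, 11.0, 12.0, 10.0, 11.0, 12.0]]), (4, 1))
        log2 += np.arange(4)[:, None]
        groups = {f"a{i}": "A" for i in range(3)} | {f"b{i}": "B" for i in range(3)}
        z = pathway_zscores(make_table(log2, groups), PathwayDef("pw", frozenset(f"P{i}" for i in range(4))), "A", "B")
        assert z.mean_difference == pytest.approx(0, abs=1e-12)
        assert z.ci_low <= 0 <= z.ci_high

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(21)
        log2 = rng.normal(14, 1, size=(4, 10)) * 0.02 + 14
        log2[:, 5:] += 1.0  # +1 SD-scale shift in group B for all 4 members
        groups = {f"a{i}": "A" for i in range(5)} | {f"b{i}": "B" for i in range(5)}
        z = pathway_zscores(make_table(log2, groups), PathwayDef("pw", frozenset(f"P{i}" for i in range(4))), "A", "B")
        assert z.mean_difference > 0
        assert z.ci_low > 0  # CI excludes zero at low noise

    def test_singleton_pathway_flagged(self):
        rng = np.random.default_rng(2)
        log2 = rng.normal(14, 1, size=(3, 8))
        groups = {f"a{i}": "A" for i in range(4)} | {f"b{i}": "B" for i in range(4)}
        z = pathway_zscores(make_table(log2, groups), PathwayDef("one", frozenset({"P0"})), "A", "B")
        assert z.singleton
        assert np.isnan(z.ci_low)

    def test_disjoint_pathway_rejected(self):
        rng = np.random.default_rng(2)
        log2 = rng.normal(14, 1, size=(3, 8))
        groups = {f"a{i}": "A" for i in range(4)} | {f"b{i}": "B" for i in range(4)}
        with pytest.raises(ValueError, match="no proteins"):
            pathway_zscores(make_table(log2, groups), PathwayDef("x", frozenset({"Q1"})), "A", "B")


class TestGmtIO:
    def test_roundtrip(self, tmp_path):
        pws = [PathwayDef("glycolysis", frozenset({"Hk1", "Pfkm", "Pkm"})),
               PathwayDef("tca", frozenset({"Cs", "Idh2"}))]
        path = tmp_path / "sets.gmt"
        write_gmt(pws, path)
        back = read_gmt(path)
        assert {p.name: p.members for p in back} == {p.name: p.members for p in pws}

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("onlyname\tdesc\n")
        with pytest.raises(ValueError, match="malformed"):
            read_gmt(path)


class TestMtdnaRatio:
    def _records(self, rows):
        return QpcrRecords(pd.DataFrame(rows, columns=["animal_id", "group", "gene", "replicate", "ct"]))

    def test_equal_cts_unit_ratio(self):
        rec = self._records([("m1", "g", "Nd1", 1, 25.0), ("m1", "g", "Lpl", 1, 25.0)])
        assert mtdna_ratio(rec)["ratio"].iloc[0] == pytest.approx(1.0)

    def test_one_cycle_doubles(self):
        rec = self._records([("m1", "g", "Nd1", 1, 24.0), ("m1", "g", "Lpl", 1, 25.0)])
        assert mtdna_ratio(rec)["ratio"].iloc[0] == pytest.approx(2.0)

    def test_replicates_averaged_first(self):
        rec = self._records(
            [("m1", "g", "Nd1", r, 20.0) for r in (1, 2, 3)]
            + [("m1", "g", "Lpl", r, 21.0) for r in (1, 2, 3)]
        )
        assert mtdna_ratio(rec)["ratio"].iloc[0] == pytest.approx(2.0)

    def test_invariant_to_constant_ct_shift(self):
        base = [("m1", "g", "Nd1", 1, 23.4), ("m1", "g", "Lpl", 1, 24.9)]
        shifted = [(a, g, gene, r, ct + 3.3) for a, g, gene, r, ct in base]
        r1 = mtdna_ratio(self._records(base))["ratio"].iloc[0]
        r2 = mtdna_ratio(self._records(shifted))["ratio"].iloc[0]
        assert r1 == pytest.approx(r2)

    def test_missing_gene_names_animal(self):
        rec = self._records([("m1", "g", "Nd1", 1, 25.0), ("m1", "g", "Lpl", 1, 25.0),
                             ("m2", "g", "Nd1", 1, 25.0)])
        with pytest.raises(ValueError, match="m2"):
            mtdna_ratio(rec)

    def test_ct_range_enforced(self):
        with pytest.raises(ValueError, match="Ct"):
            self._records([("m1", "g", "Nd1", 1, 50.0)])
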