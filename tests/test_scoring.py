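"""PES arithmetic, ranking/standardization, aggregation, DEG filtering,
and pathway enrichment against direct-summation oracles."""

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest

from fluxtarget.perturbation import classify_flux_changes, gene_knockout
from fluxtarget.scoring import (
    DEGTable,
    PESCounts,
    aggregate_and_select,
    count_deg_flux_changes,
    load_degs,
    pathway_enrichment,
    pes,
    rank_pes,
    zscore_ranks,
)
from fluxtarget.solvers import fba


def deg_table(rows, disease="d"):
    df = pd.DataFrame(rows, columns=["gene_id", "log2fc", "direction", "p_adj"])
    return DEGTable(table=df.set_index("gene_id"), disease=disease)


class TestLoadDegs:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "log2fc", "p_adj"])

    def test_primary_cutoff_retains_strong_gene(self):
        df = self.frame([("gA", math.log2(2.5), 0.01)] * 12)
        out = load_degs(df, min_metabolic_degs=1)
        assert "gA" in out.table.index
        assert out.fc_cutoff == 2.0

    def test_filters_p_and_fc(self):
        df = self.frame(
            [("gA", 1.5, 0.01), ("gB", 0.5, 0.01), ("gC", 2.0, 0.2)]
        )
        out = load_degs(df, min_metabolic_degs=0)
        assert list(out.table.index) == ["gA"]

    def test_fallback_cutoff_applied_when_too_few(self):
        """3 metabolic DEGs at two-fold with min 10 -> refilter at 1.5-fold."""

        strong = [(f"s{i}", 1.2, 0.01) for i in range(3)]
        weak = [(f"w{i}", 0.7, 0.01) for i in range(10)]  # 1.5 < FC < 2
        out = load_degs(self.frame(strong + weak), min_metabolic_degs=10)
        assert out.fc_cutoff == 1.5
        assert len(out.table) == 13

    def test_direction_derived_from_sign(self):
        df = self.frame([("gA", 1.5, 0.01), ("gB", -1.5, 0.01)])
        out = load_degs(df, min_metabolic_degs=0)
        assert out.up_genes == {"gA"}
        assert out.down_genes == {"gB"}

    def test_retained_set_matches_filter_oracle(self):
        rng = np.random.default_rng(4)
        rows = [(f"g{i}", float(rng.normal(0, 1.5)), float(rng.uniform(0, 0.2)))
                for i in range(100)]
        out = load_degs(self.frame(rows), min_metabolic_degs=0)
        expected = {
            g for g, fc, p in rows if p < 0.05 and abs(fc) >= 1.0
        }
        assert set(out.table.index) == expected

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "degs.tsv"
        path.write_text("gene_id\tfold\n g1\t2.0\n")
        with pytest.raises(ValueError, match="missing columns"):
            load_degs(path)


class TestPes:
    def test_perfect_reversal_attains_upper_bound(self):
        assert pes(PESCounts(2, 0, 0, 0, 3, 0)) == pytest.approx(2.0)

    def test_all_zero_counts(self):
        assert pes(PESCounts()) == 0.0

    def test_derived_worked_value(self):
        # (3-1)/4 + (0-0)/2 = 0.5, evaluated independently
        assert pes(PESCounts(3, 1, 0, 0, 0, 2)) == pytest.approx(0.5)

    def test_zero_denominator_term_contributes_zero(self):
        assert pes(PESCounts(2, 0, 0, 0, 0, 0)) == pytest.approx(1.0)
        assert pes(PESCounts(0, 0, 0, 0, 3, 0)) == pytest.approx(1.0)

    def test_bounded_in_minus2_plus2(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            counts = PESCounts(*rng.integers(0, 6, size=6))
            assert -2.0 <= pes(counts) <= 2.0

    def test_maximum_characterization(self):
        """Over counts 0..4: PES = 2 iff UpInc=UpUnc=DownDec=DownUnc=0 with
        both numerator counts positive (exhaustive enumeration)."""

        for tup in itertools.product(range(5), repeat=6):
            counts = PESCounts(*tup)
            is_max = pes(counts) == pytest.approx(2.0)
            expected = (
                counts.up_dec > 0 and counts.down_inc > 0
                and counts.up_inc == counts.up_unc == 0
                and counts.down_dec == counts.down_unc == 0
            )
            assert is_max == expected

    def test_invariant_under_count_scaling(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            tup = tuple(int(x) for x in rng.integers(0, 5, size=6))
            base = pes(PESCounts(*tup))
            for k in (2, 3, 5):
                assert pes(PESCounts(*(k * x for x in tup))) == pytest.approx(base)

    def test_monotone_in_up_dec(self):
        """Swapping one unchanged reaction to decreased never lowers PES."""

        rng = np.random.default_rng(2)
        for _ in range(100):
            up_dec, up_inc, up_unc = (int(x) for x in rng.integers(0, 5, size=3))
            rest = tuple(int(x) for x in rng.integers(0, 5, size=3))
            if up_unc == 0:
                continue
            a = pes(PESCounts(up_dec, up_inc, up_unc, *rest))
            b = pes(PESCounts(up_dec + 1, up_inc, up_unc - 1, *rest))
            assert b >= a - 1e-12


class TestCounts:
    def test_no_mapped_degs_all_zero(self, template):
        wt = fba(template)
        ko = gene_knockout(template, "g_MPC1", wt)
        table = classify_flux_changes(wt, ko.v_ko)
        degs = deg_table([("g_unknown", 1.5, "up", 0.01)])
        counts = count_deg_flux_changes(table, degs, template)
        assert counts == PESCounts()

    def test_partition_fixture(self, template):
        """One up-DEG regulating three reactions classified down/down/up."""

        wt = fba(template)
        ko = gene_knockout(template, "g_MPC1", wt)
        table = classify_flux_changes(wt, ko.v_ko)
        table.table.loc["GLCt", "class"] = "down"
        table.table.loc["HEX1", "class"] = "down"
        table.table.loc["PGI", "class"] = "up"
        degs = deg_table(
            [("g_GLUT1", 2.0, "up", 0.01), ("g_HK1", 2.0, "up", 0.01),
             ("g_GPI", 2.0, "up", 0.01)]
        )
        counts = count_deg_flux_changes(table, degs, template)
        assert (counts.up_dec, counts.up_inc, counts.up_unc) == (2, 1, 0)

    def test_union_semantics_and_both_groups(self, template):
        """A reaction regulated by several same-direction DEGs counts once;
        a reaction with both an up- and a down-DEG counts in both groups."""

        wt = fba(template)
        ko = gene_knockout(template, "g_MPC1", wt)
        table = classify_flux_changes(wt, ko.v_ko)
        # g_LDHA and g_LDHB both regulate LDH_L
        degs = deg_table(
            [("g_LDHA", 2.0, "up", 0.01), ("g_LDHB", 2.0, "up", 0.01),
             ("g_GLUT1", -2.0, "down", 0.01), ("g_GLUT3", 2.0, "up", 0.01)]
        )
        counts = count_deg_flux_changes(table, degs, template)
        up_total = counts.up_dec + counts.up_inc + counts.up_unc
        assert up_total == 2  # LDH_L once + GLCt once
        down_total = counts.down_dec + counts.down_inc + counts.down_unc
        assert down_total == 1  # GLCt also in the down group

    def test_counts_match_set_union_oracle(self, template, scenario):
        wt = fba(template)
        ko = gene_knockout(template, "g_PDHA1", wt)
        table = classify_flux_changes(wt, ko.v_ko)
        degs = scenario.deg_truth
        counts = count_deg_flux_changes(table, degs, template)
        for direction, got in (("up", (counts.up_dec, counts.up_inc, counts.up_unc)),
                               ("down", (counts.down_dec, counts.down_inc,
                                         counts.down_unc))):
            deg_genes = degs.up_genes if direction == "up" else degs.down_genes
            rxns = set()
            for rxn in template.reactions:
                if rxn.gpr.genes & deg_genes:
                    rxns.add(rxn.id)
            dec = sum(table.class_of(r) == "down" for r in rxns)
            inc = sum(table.class_of(r) == "up" for r in rxns)
            unc = sum(table.class_of(r) == "unchanged" for r in rxns)
            assert got == (dec, inc, unc)


class TestRankZ:
    def test_rank_highest_is_one(self):
        ranks = rank_pes({"a": 2.0, "b": 0.0, "c": -1.0})
        assert ranks == {"a": 1.0, "b": 2.0, "c": 3.0}

    def test_ties_average(self):
        ranks = rank_pes({"a": 2.0, "b": 2.0, "c": 0.0})
        assert ranks["a"] == ranks["b"] == 1.5
        assert ranks["c"] == 3.0

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(6)
        scores = {f"g{i}": float(rng.normal()) for i in range(30)}
        ranks = rank_pes(scores)
        ordered = sorted(scores, key=scores.get, reverse=True)
        for idx, gene in enumerate(ordered, start=1):
            assert ranks[gene] == pytest.approx(idx)

    def test_zscore_closed_form(self):
        z = zscore_ranks({"a": 1.0, "b": 2.0, "c": 3.0}, ddof=1)
        assert z.loc["a", "z"] == pytest.approx(-1.0)
        assert z.loc["b", "z"] == pytest.approx(0.0)
        assert z.loc["c", "z"] == pytest.approx(1.0)
        zpop = zscore_ranks({"a": 1.0, "b": 2.0, "c": 3.0}, ddof=0)
        assert zpop.loc["c", "z"] == pytest.approx(math.sqrt(1.5))

    def test_zscore_normalization_identity(self):
        rng = np.random.default_rng(7)
        ranks = {f"g{i}": float(r) for i, r in
                 enumerate(rng.permutation(np.arange(1.0, 21.0)))}
        z = zscore_ranks(ranks)["z"]
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_all_tied_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="tied"):
            z = zscore_ranks({"a": 1.5, "b": 1.5})
        assert (z["z"] == 0).all()


class TestAggregate:
    def make_z(self, data):
        return {m: pd.Series(v) for m, v in data.items()}

    def test_best_in_all_models_selected(self):
        genes = [f"g{i}" for i in range(12)]
        per_model = {}
        for m in ("m1", "m2", "m3", "m4"):
            ranks = {g: float(i + 1) for i, g in enumerate(genes)}
            per_model[m] = zscore_ranks(ranks)["z"]
        out = aggregate_and_select(per_model, cutoff=-1.0)
        assert out.index[0] == "g0"
        assert bool(out.loc["g0", "selected"]) is True
        assert out.loc["g0", "rank"] == 1

    def test_mean_gene_not_selected(self):
        per_model = self.make_z(
            {"m1": {"a": -2.0, "b": 0.0, "c": 2.0, "d": 0.1, "e": -0.1},
             "m2": {"a": -2.0, "b": 0.0, "c": 2.0, "d": -0.1, "e": 0.1}}
        )
        out = aggregate_and_select(per_model)
        assert bool(out.loc["b", "selected"]) is False

    def test_selection_matches_threshold_oracle(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(25)]
        per_model = self.make_z(
            {m: {g: float(rng.normal()) for g in genes} for m in ("m1", "m2")}
        )
        out = aggregate_and_select(per_model, cutoff=-1.0)
        agg = pd.DataFrame(per_model).sum(axis=1)
        agg_z = (agg - agg.mean()) / agg.std(ddof=1)
        for gene in genes:
            assert out.loc[gene, "aggregate"] == pytest.approx(agg[gene])
            assert bool(out.loc[gene, "selected"]) == (agg_z[gene] <= -1.0)
        # ranks ascend with the aggregate
        assert (out["aggregate"].diff().dropna() >= -1e-12).all()

    def test_raw_sum_mode(self):
        per_model = self.make_z(
            {"m1": {"a": -1.0, "b": 1.0}, "m2": {"a": -0.5, "b": 0.5}}
        )
        out = aggregate_and_select(per_model, cutoff=-1.0, restandardize=False)
        assert bool(out.loc["a", "selected"]) is True  # raw sum -1.5 <= -1

    def test_missing_gene_excluded_with_warning(self):
        per_model = self.make_z(
            {"m1": {"a": -1.0, "b": 1.0, "c": 0.0},
             "m2": {"a": -0.5, "b": 0.5}}
        )
        with pytest.warns(UserWarning, match="missing"):
            out = aggregate_and_select(per_model)
        assert "c" not in out.index


class TestEnrichment:
    def test_saturated_pathway(self):
        background = {f"g{i}" for i in range(20)}
        out = pathway_enrichment(background, background,
                                 {"pw": set(background)})
        assert out.loc["pw", "fold_enrichment"] == pytest.approx(1.0)
        assert out.loc["pw", "p"] == pytest.approx(1.0)

    def test_fold_enrichment_arithmetic(self):
        background = {f"g{i}" for i in range(1000)}
        gene_set = {f"g{i}" for i in range(10)}
        pathway = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(500, 545)}
        out = pathway_enrichment(gene_set, background, {"pw": pathway})
        # (5/10) / (50/1000) = 10
        assert out.loc["pw", "fold_enrichment"] == pytest.approx(10.0)

    def test_p_matches_hypergeometric_summation(self):
        """Fisher tail equals direct summation of hypergeometric pmf terms
        computed with exact integer binomials."""

        rng = np.random.default_rng(13)
        for _ in range(50):
            N = int(rng.integers(20, 120))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            background = {f"g{i}" for i in range(N)}
            pathway = {f"g{i}" for i in range(K)}
            gene_set = set(rng.choice(sorted(background), size=n, replace=False))
            k = len(gene_set & pathway)
            out = pathway_enrichment(gene_set, background, {"pw": pathway})
            expected = sum(
                math.comb(K, i) * math.comb(N - K, n - i)
                for i in range(k, min(K, n) + 1)
            ) / math.comb(N, n)
            assert out.loc["pw", "p"] == pytest.approx(expected, rel=1e-9)

    def test_bh_monotone_in_p_order(self):
        rng = np.random.default_rng(14)
        background = {f"g{i}" for i in range(200)}
        gene_set = set(rng.choice(sorted(background), size=30, replace=False))
        pmap = {
            f"pw{j}": set(rng.choice(sorted(background),
                                     size=int(rng.integers(5, 60)),
                                     replace=False))
            for j in range(15)
        }
        out = pathway_enrichment(gene_set, background, pmap)
        ordered = out.sort_values("p")
        assert (ordered["fdr"].diff().dropna() >= -1e-12).all()
        assert (ordered["fdr"] >= ordered["p"] - 1e-12).all()

    def test_gene_set_outside_background_rejected(self):
        with pytest.raises(ValueError):
            pathway_enrichment({"gX"}, {"g1"}, {"pw": {"g1"}})

    def test_empty_background_pathway_skipped(self):
        background = {"g1", "g2"}
        with pytest.warns(UserWarning, match="skipped"):
            out = pathway_enrichment({"g1"}, background, {"pw": {"gZ"}})
        assert len(out) == 0
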