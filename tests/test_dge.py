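"""DEG filtering, direction summaries and term overrepresentation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import opsinpipe as op
from opsinpipe.dge import fisher_overrepresentation_p
from opsinpipe.simulate import simulate_dge_table


def hypergeom_tail_oracle(a: int, study: int, pop_hits: int, pop: int) -> float:
    """P(X >= a) for X ~ Hypergeometric(pop, pop_hits, study), by direct
    enumeration with binomial coefficients."""
    hi = min(study, pop_hits)
    total = math.comb(pop, study)
    return sum(
        math.comb(pop_hits, k) * math.comb(pop - pop_hits, study - k) for k in range(a, hi + 1)
    ) / total


def _table(rows):
    return pd.DataFrame(rows, columns=["transcript_id", "log2fc", "padj"])


class TestFilterDegs:
    def test_empty_table(self):
        assert op.filter_degs(_table([])).empty

    def test_alpha_boundary_inclusive(self):
        table = _table([("t1", 1.0, 0.05), ("t2", 1.0, 0.051)])
        kept = op.filter_degs(table)
        assert list(kept["transcript_id"]) == ["t1"]

    def test_missing_padj_dropped(self):
        table = _table([("t1", 1.0, 0.01), ("t2", 1.0, None)])
        assert list(op.filter_degs(table)["transcript_id"]) == ["t1"]

    def test_count_matches_direct_tally(self):
        rng = np.random.default_rng(0)
        table = _table([(f"t{i}", 1.0, p) for i, p in enumerate(rng.uniform(0, 1, 200))])
        kept = op.filter_degs(table, alpha=0.05)
        assert len(kept) == (table["padj"] <= 0.05).sum()

    def test_bad_padj_named(self):
        table = _table([("odd", 1.0, 1.5)])
        with pytest.raises(ValueError, match="odd"):
            op.filter_degs(table)


class TestSplitByDirection:
    def test_signs_partition(self):
        up, down = op.split_by_direction(_table([("a", 1.0, 0.01), ("b", -2.0, 0.01), ("c", 0.5, 0.01)]))
        assert len(up) == 2 and len(down) == 1

    def test_all_negative(self):
        up, down = op.split_by_direction(_table([("a", -1.0, 0.01)]))
        assert up.empty and len(down) == 1

    def test_zero_lfc_excluded_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            up, down = op.split_by_direction(
                _table([("a", 0.0, 0.01), ("b", 1.0, 0.01), ("c", -1.0, 0.01)])
            )
        assert len(up) == 1 and len(down) == 1
        assert "0" in caplog.text


class TestSummarizeDegs:
    def test_published_direction_percentages(self):
        """1,394 up and 3,243 down give the 30.1% / 69.9% split."""
        up = _table([(f"u{i}", 1.0, 0.01) for i in range(1394)])
        down = _table([(f"d{i}", -1.0, 0.01) for i in range(3243)])
        summary = op.summarize_degs(up, down)
        assert summary.n_deg_total == 4637
        assert summary.pct_up_a == 30.1
        assert summary.pct_up_b == 69.9

    def test_symmetric_split(self):
        summary = op.summarize_degs(
            _table([("a", 1.0, 0.01)]), _table([("b", -1.0, 0.01)])
        )
        assert summary.pct_up_a == 50.0 and summary.pct_up_b == 50.0

    def test_top_n_matches_full_sort(self):
        rng = np.random.default_rng(1)
        up = _table([(f"t{i}", lfc, 0.01) for i, lfc in enumerate(rng.normal(2, 3, 20))])
        up = up[up["log2fc"] > 0]
        summary = op.summarize_degs(up, _table([]), top_n=15)
        expected = up.reindex(
            up["log2fc"].abs().sort_values(ascending=False).index
        )["transcript_id"].tolist()[: min(15, len(up))]
        assert summary.top_a["transcript_id"].tolist() == expected

    def test_empty_inputs_no_division(self):
        summary = op.summarize_degs(_table([]), _table([]))
        assert summary.n_deg_total == 0
        assert summary.pct_up_a == 0.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 500), st.integers(0, 500))
    def test_percentages_sum_to_100(self, n_up, n_down):
        if n_up + n_down == 0:
            return
        up = _table([(f"u{i}", 1.0, 0.01) for i in range(n_up)])
        down = _table([(f"d{i}", -1.0, 0.01) for i in range(n_down)])
        summary = op.summarize_degs(up, down)
        assert summary.pct_up_a + summary.pct_up_b == pytest.approx(100.0, abs=0.1)

    def test_generator_truth_recovered(self):
        table, truth = simulate_dge_table(2000, 300, 0.25, seed=5)
        up, down = op.split_by_direction(op.filter_degs(table))
        assert len(up) == truth["n_up"]
        assert len(down) == truth["n_down"]


class TestFractionOfTranscriptome:
    def test_published_fraction(self):
        assert op.fraction_of_transcriptome(4637, 54094) == 8.6


class TestEnrichment:
    def _run(self, pop, ann, study, **kw):
        return op.enrichment_test(set(study), set(pop), ann, **kw)

    def test_no_enrichment_not_reported(self):
        pop = [f"g{i}" for i in range(100)]
        ann = {g: {"T"} for g in pop[:10]}
        study = pop[:1] + pop[50:59]  # 1/10 in study matches 10/100 in pop
        out = self._run(pop, ann, study)
        assert out.empty

    def test_fivefold_excluded_by_min_fold(self):
        pop = [f"g{i}" for i in range(100)]
        ann = {g: {"T"} for g in pop[:10]}
        study = pop[:5] + pop[50:55]  # 5/10 vs 10/100: fold 5.0
        out = self._run(pop, ann, study, fdr_alpha=1.0)
        assert out.empty  # fold 5 < 6
        p = fisher_overrepresentation_p(5, 10, 10, 100)
        assert p == pytest.approx(hypergeom_tail_oracle(5, 10, 10, 100))

    def test_fold_exactly_six_retained(self):
        pop = [f"g{i}" for i in range(120)]
        ann = {g: {"T"} for g in pop[:10]}
        study = pop[:5] + pop[50:55]  # 5/10 study vs 10/120 pop: fold = 6.0
        out = self._run(pop, ann, study)
        assert list(out["term_id"]) == ["T"]
        assert out["fold_enrichment"].iloc[0] == pytest.approx(6.0)
        assert out["fdr"].iloc[0] < 0.05

    def test_study_gene_outside_population_rejected(self):
        with pytest.raises(ValueError):
            self._run(["a"], {}, ["zzz"])

    def test_fisher_matches_enumeration_small_margins(self):
        for pop in range(2, 21):
            for hits in range(1, pop + 1):
                for study in range(1, pop + 1):
                    lo = max(0, study + hits - pop)
                    for a in range(lo, min(study, hits) + 1):
                        got = fisher_overrepresentation_p(a, study, hits, pop)
                        want = hypergeom_tail_oracle(a, study, hits, pop)
                        assert got == pytest.approx(want, rel=1e-9, abs=1e-12)

    def test_bh_fdr_monotone(self):
        rng = np.random.default_rng(3)
        pop = [f"g{i}" for i in range(400)]
        ann = {}
        for t in range(25):
            members = rng.choice(pop, size=12, replace=False)
            for g in members:
                ann.setdefault(g, set()).add(f"T{t}")
        study = set(rng.choice(pop, size=60, replace=False)) | set(pop[:12])
        out = op.enrichment_test(study, set(pop), ann, fdr_alpha=1.1, min_fold=0.0)
        by_p = out.sort_values("p_value")
        assert (by_p["fdr"].diff().dropna() >= -1e-12).all()
        assert (out["fdr"] >= out["p_value"] - 1e-12).all()
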