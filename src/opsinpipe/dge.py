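"""DEG filtering, direction split, summaries, and term overrepresentation.

Operates on a differential-expression table produced by any upstream
engine (columns: ``transcript_id``, ``log2fc``, ``padj``, optional
``annotation``). Significant genes (adjusted P ≤ α, inclusive) are split
by log-fold-change sign, summarised (counts, percentages of all DEGs,
top-N by absolute fold change), and tested for term overrepresentation
with a one-sided Fisher's exact test, Benjamini–Hochberg FDR < 0.05 and a
fold-enrichment ≥ 6 filter — the "highly overrepresented" regime.

Terms are flat labels here (no ontology-graph propagation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("transcript_id", "log2fc", "padj")


def read_dge_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    validate_dge_table(table)
    return table


def validate_dge_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"DE table is missing columns: {missing}")
    bad = table.loc[table["padj"].notna() & ~table["padj"].between(0, 1)]
    if not bad.empty:
        row = bad.iloc[0]
        raise ValueError(
            f"adjusted P outside [0, 1] for transcript {row['transcript_id']!r}"
        )


def filter_degs(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Rows with adjusted P ≤ alpha (inclusive); missing padj are dropped."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    validate_dge_table(table)
    return table.loc[table["padj"].notna() & (table["padj"] <= alpha)].copy()


def split_by_direction(degs: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Strictly positive log fold change up, strictly negative down.

    Rows with a log fold change of exactly zero belong to neither
    direction; they are excluded with a warning.
    """
    zero = degs.loc[degs["log2fc"] == 0]
    if not zero.empty:
        logger.warning(
            "%d DEG(s) with log fold change exactly 0 excluded from both directions",
            len(zero),
        )
    up = degs.loc[degs["log2fc"] > 0].copy()
    down = degs.loc[degs["log2fc"] < 0].copy()
    return up, down


@dataclass
class DGESummary:
    n_deg_total: int
    n_up_a: int
    n_up_b: int
    pct_up_a: float
    pct_up_b: float
    top_a: pd.DataFrame = field(repr=False, default=None)
    top_b: pd.DataFrame = field(repr=False, default=None)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            fh.write(f"n_deg_total\t{self.n_deg_total}\n")
            fh.write(f"n_up_a\t{self.n_up_a}\n")
            fh.write(f"n_up_b\t{self.n_up_b}\n")
            fh.write(f"pct_up_a\t{self.pct_up_a}\n")
            fh.write(f"pct_up_b\t{self.pct_up_b}\n")


def _top_by_abs_lfc(frame: pd.DataFrame, top_n: int) -> pd.DataFrame:
    """Top rows by |log2fc|, ties broken by transcript id."""
    ranked = frame.assign(_abs=frame["log2fc"].abs()).sort_values(
        ["_abs", "transcript_id"], ascending=[False, True], kind="mergesort"
    )
    return ranked.drop(columns="_abs").head(top_n).reset_index(drop=True)


def summarize_degs(
    up_list: pd.DataFrame, down_list: pd.DataFrame, top_n: int = 15
) -> DGESummary:
    """Counts, direction percentages (1 d.p.) and top-N per direction."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    n_up, n_down = len(up_list), len(down_list)
    total = n_up + n_down
    if total == 0:
        return DGESummary(0, 0, 0, 0.0, 0.0, up_list.head(0), down_list.head(0))
    return DGESummary(
        n_deg_total=total,
        n_up_a=n_up,
        n_up_b=n_down,
        pct_up_a=round(100.0 * n_up / total, 1),
        pct_up_b=round(100.0 * n_down / total, 1),
        top_a=_top_by_abs_lfc(up_list, top_n),
        top_b=_top_by_abs_lfc(down_list, top_n),
    )


def fraction_of_transcriptome(n_deg: int, n_transcripts: int) -> float:
    """Share of the transcriptome that is differentially expressed, in
    percent at one decimal place."""
    if n_transcripts <= 0:
        raise ValueError("n_transcripts must be positive")
    return round(100.0 * n_deg / n_transcripts, 1)


# ---------------------------------------------------------------------------
# Overrepresentation
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    term_id: str
    study_count: int
    study_size: int
    pop_count: int
    pop_size: int
    fold_enrichment: float
    p_value: float
    fdr: float


def fisher_overrepresentation_p(
    study_count: int, study_size: int, pop_count: int, pop_size: int
) -> float:
    """One-sided Fisher's exact P for overrepresentation of a term.

    2×2 table: study/non-study × in-term/not-in-term, tested with
    alternative "greater" on the study∩term cell.
    """
    a = study_count
    b = study_size - study_count
    c = pop_count - study_count
    d = (pop_size - study_size) - c
    if min(a, b, c, d) < 0:
        raise ValueError("inconsistent 2x2 table")
    return float(fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def enrichment_test(
    study_set: set[str],
    population: set[str],
    annotation_map: dict[str, set[str]],
    fdr_alpha: float = 0.05,
    min_fold: float = 6.0,
    universe: str = "study",
) -> pd.DataFrame:
    """Term overrepresentation in a study set relative to a population.

    Tests every term annotating ≥1 study gene (``universe="study"``, the
    default) or every annotated term (``universe="all"``); corrects with
    Benjamini–Hochberg across the tested terms; and returns the terms with
    FDR strictly below ``fdr_alpha`` and fold enrichment of at least
    ``min_fold`` (inclusive), sorted by FDR then term id. Genes without
    annotation simply contribute to the population size.
    """
    stray = study_set - population
    if stray:
        raise ValueError(f"study genes absent from population: {sorted(stray)[:5]}")
    if not study_set:
        return _enrichment_frame([])
    pop_size = len(population)
    study_size = len(study_set)
    term_to_pop: dict[str, int] = {}
    term_to_study: dict[str, int] = {}
    for gene in population:
        for term in annotation_map.get(gene, ()):
            term_to_pop[term] = term_to_pop.get(term, 0) + 1
            if gene in study_set:
                term_to_study[term] = term_to_study.get(term, 0) + 1
    if universe == "study":
        terms = sorted(term_to_study)
    elif universe == "all":
        terms = sorted(term_to_pop)
    else:
        raise ValueError("universe must be 'study' or 'all'")
    results: list[EnrichmentResult] = []
    for term in terms:
        pop_count = term_to_pop.get(term, 0)
        if pop_count == 0:
            continue  # fold enrichment undefined
        study_count = term_to_study.get(term, 0)
        fold = (study_count / study_size) / (pop_count / pop_size)
        p = fisher_overrepresentation_p(study_count, study_size, pop_count, pop_size)
        results.append(
            EnrichmentResult(term, study_count, study_size, pop_count, pop_size, fold, p, 1.0)
        )
    if not results:
        return _enrichment_frame([])
    _, fdrs, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
    for r, q in zip(results, fdrs):
        r.fdr = float(q)
    kept = [r for r in results if r.fdr < fdr_alpha and r.fold_enrichment >= min_fold]
    kept.sort(key=lambda r: (r.fdr, r.term_id))
    return _enrichment_frame(kept)


def _enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    cols = [
        "term_id",
        "study_count",
        "study_size",
        "pop_count",
        "pop_size",
        "fold_enrichment",
        "p_value",
        "fdr",
    ]
    return pd.DataFrame([vars(r) for r in results], columns=cols)


def read_annotation_map(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (gene_id, term_id) → gene→terms mapping."""
    mapping: dict[str, set[str]] = {}
    frame = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term_id"])
    for gene, term in zip(frame["gene_id"], frame["term_id"]):
        mapping.setdefault(str(gene), set()).add(str(term))
    return mapping
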