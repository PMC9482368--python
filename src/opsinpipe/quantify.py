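"""Competitive read-pair assignment and proportional opsin expression.

Read pairs are mapped back onto the complete extracted CDS of every
expressed opsin. A pair is credited to a gene only when *both* mates align
within that gene's paralog-derived mismatch threshold and within no other
gene's; pairs satisfying two or more thresholds are discarded outright so
that no read counts toward multiple paralogs. Counts are divided by gene
length, and the per-base rates summarised as:

* rod vs cone share — *rh1* rate over the total opsin rate;
* per-gene single-cone shares — each *sws1*/*sws2* copy over the
  single-cone total;
* per-gene double-cone shares — each *rh2*/*lws* copy over the
  double-cone total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .extract import (
    ExtractedCDS,
    ReadPairs,
    TolerantMapParams,
    align_read,
    build_index,
)
from .refpanel import (
    DOUBLE_CONE_CLASSES,
    MappingThresholds,
    ROD_CLASSES,
    SINGLE_CONE_CLASSES,
)


@dataclass
class GeneCounts:
    """Pairs assigned per gene plus the two discard tallies."""

    pair_count: dict[str, int] = field(default_factory=dict)
    discarded_multi: int = 0
    discarded_unmapped: int = 0

    @property
    def total(self) -> int:
        return sum(self.pair_count.values()) + self.discarded_multi + self.discarded_unmapped

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tpair_count\n")
            for g, c in self.pair_count.items():
                fh.write(f"{g}\t{c}\n")
            fh.write(f"__discarded_multi__\t{self.discarded_multi}\n")
            fh.write(f"__discarded_unmapped__\t{self.discarded_unmapped}\n")


@dataclass
class ProportionReport:
    """Length-adjusted proportional opsin expression."""

    prop_rod: float
    prop_cone: float
    single_cone_props: dict[str, float]
    double_cone_props: dict[str, float]
    normalized_rate: dict[str, float]

    def to_tsv(self, path: str | Path) -> None:
        """Tabular output with percentages at one decimal place."""
        with open(path, "w") as fh:
            fh.write("category\tgene_id\tpercent\n")
            fh.write(f"rod_vs_cone\trod\t{100 * self.prop_rod:.1f}\n")
            fh.write(f"rod_vs_cone\tcone\t{100 * self.prop_cone:.1f}\n")
            for g, v in self.single_cone_props.items():
                fh.write(f"single_cone\t{g}\t{100 * v:.1f}\n")
            for g, v in self.double_cone_props.items():
                fh.write(f"double_cone\t{g}\t{100 * v:.1f}\n")


def competitive_map_counts(
    pairs: ReadPairs,
    targets: Sequence[ExtractedCDS],
    thresholds: MappingThresholds,
    params: TolerantMapParams | None = None,
) -> GeneCounts:
    """Assign each read pair to at most one target gene.

    A pair satisfies gene ``g`` when both mates align to ``g`` with an
    alignment divergence (mismatch plus gap columns — the same measure the
    thresholds were derived from) at or below ``thresholds[g]``, within the
    tolerant-mapping ceilings. Pairs satisfying no gene are counted as
    unmapped; pairs satisfying several are discarded as multi-mapping.
    """
    if params is None:
        params = TolerantMapParams()
    missing = [t.gene_id for t in targets if t.gene_id not in thresholds.max_mismatch_pct]
    if missing:
        raise ValueError(f"no mismatch threshold for targets: {missing}")
    indexes = {t.gene_id: build_index(t.sequence, params) for t in targets}
    counts = GeneCounts(pair_count={t.gene_id: 0 for t in targets})
    for pid, m1, m2 in pairs:
        satisfied = []
        for t in targets:
            thr = thresholds[t.gene_id]
            a1 = align_read(m1, t.sequence, params, f"{pid}/1", t.gene_id, indexes[t.gene_id])
            if a1 is None or a1.divergence_pct > thr:
                continue
            a2 = align_read(m2, t.sequence, params, f"{pid}/2", t.gene_id, indexes[t.gene_id])
            if a2 is None or a2.divergence_pct > thr:
                continue
            satisfied.append(t.gene_id)
        if len(satisfied) == 1:
            counts.pair_count[satisfied[0]] += 1
        elif len(satisfied) > 1:
            counts.discarded_multi += 1
        else:
            counts.discarded_unmapped += 1
    return counts


def length_normalize(
    counts: GeneCounts, targets: Sequence[ExtractedCDS]
) -> dict[str, float]:
    """Per-base read-pair rate: pair_count / gene length."""
    lengths = {t.gene_id: t.length_bp for t in targets}
    rates: dict[str, float] = {}
    for g, c in counts.pair_count.items():
        L = lengths.get(g)
        if L is None:
            raise ValueError(f"counted gene {g!r} absent from targets")
        if L <= 0:
            raise ValueError(f"gene {g!r} has non-positive length")
        rates[g] = c / L
    return rates


def proportions(
    normalized_rate: dict[str, float], class_map: dict[str, str]
) -> ProportionReport:
    """Proportional expression from per-base rates and opsin classes.

    Cone categories with zero total rate are reported as absent (empty
    mapping), never as divisions by zero.
    """
    unknown = [g for g in normalized_rate if g not in class_map]
    if unknown:
        raise ValueError(f"genes without a class label: {unknown}")
    bad = {
        g: class_map[g]
        for g in normalized_rate
        if class_map[g] not in ROD_CLASSES | SINGLE_CONE_CLASSES | DOUBLE_CONE_CLASSES
    }
    if bad:
        raise ValueError(f"unknown opsin class labels: {bad}")
    total = sum(normalized_rate.values())
    if total <= 0:
        raise ValueError("no expression: all rates are zero")
    rod = sum(v for g, v in normalized_rate.items() if class_map[g] in ROD_CLASSES)
    prop_rod = rod / total
    single = {g: v for g, v in normalized_rate.items() if class_map[g] in SINGLE_CONE_CLASSES}
    double = {g: v for g, v in normalized_rate.items() if class_map[g] in DOUBLE_CONE_CLASSES}
    s_tot = sum(single.values())
    d_tot = sum(double.values())
    return ProportionReport(
        prop_rod=prop_rod,
        prop_cone=1.0 - prop_rod,
        single_cone_props={g: v / s_tot for g, v in single.items()} if s_tot > 0 else {},
        double_cone_props={g: v / d_tot for g, v in double.items()} if d_tot > 0 else {},
        normalized_rate=dict(normalized_rate),
    )
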