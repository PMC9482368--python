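"""Labelled opsin reference panels and paralog-similarity mismatch thresholds.

A reference panel is a small set of opsin coding sequences (CDS), each
annotated with its opsin class (RH1 rod opsin; RH2, SWS1, SWS2, LWS cone
opsins). Because teleost opsin paralogs — holocentrid *rh2* copies in
particular — can be >95% identical, reads must be assigned competitively.
The rule used here: each gene's maximum tolerated read mismatch percentage
is the smallest divergence to any paralog minus one percentage point, so an
error-free read from one paralog can never satisfy another paralog's
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Align import PairwiseAligner

OPSIN_CLASSES = ("RH1", "RH2", "SWS1", "SWS2", "LWS", "OTHER")

ROD_CLASSES = frozenset({"RH1"})
SINGLE_CONE_CLASSES = frozenset({"SWS1", "SWS2"})
DOUBLE_CONE_CLASSES = frozenset({"RH2", "LWS"})

_IUPAC_OK = frozenset("ACGTN")

# Fixed scoring scheme so identity percentages are reproducible:
# global alignment, match +1, mismatch -1, gap open/extend -2.
MATCH_SCORE = 1
MISMATCH_SCORE = -1
GAP_SCORE = -2


@dataclass(frozen=True)
class ReferenceOpsin:
    """One labelled opsin coding sequence."""

    gene_id: str
    opsin_class: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.gene_id!r}")
        if self.opsin_class not in OPSIN_CLASSES:
            raise ValueError(
                f"unknown opsin class {self.opsin_class!r} for {self.gene_id!r}"
            )
        bad = set(self.sequence) - _IUPAC_OK
        if bad:
            raise ValueError(
                f"non-IUPAC characters {sorted(bad)} in record {self.gene_id!r}"
            )

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass
class ReferencePanel:
    """Ordered collection of reference opsins with unique ids."""

    members: list[ReferenceOpsin] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("reference panel must contain at least one member")
        seen: set[str] = set()
        for m in self.members:
            if m.gene_id in seen:
                raise ValueError(f"duplicate gene_id {m.gene_id!r} in panel")
            seen.add(m.gene_id)

    def __iter__(self) -> Iterator[ReferenceOpsin]:
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __getitem__(self, gene_id: str) -> ReferenceOpsin:
        for m in self.members:
            if m.gene_id == gene_id:
                return m
        raise KeyError(gene_id)

    @property
    def gene_ids(self) -> list[str]:
        return [m.gene_id for m in self.members]

    @property
    def class_map(self) -> dict[str, str]:
        return {m.gene_id: m.opsin_class for m in self.members}


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of pairwise global-alignment identity percentages."""

    gene_ids: list[str]
    identity_pct: "list[list[float]]"

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if len(self.identity_pct) != n or any(len(r) != n for r in self.identity_pct):
            raise ValueError("identity matrix shape does not match gene ids")
        for i in range(n):
            if abs(self.identity_pct[i][i] - 100.0) > 1e-9:
                raise ValueError("diagonal of identity matrix must be 100")
            for j in range(n):
                v = self.identity_pct[i][j]
                if not 0.0 <= v <= 100.0:
                    raise ValueError("identity percentages must lie in [0, 100]")
                if abs(v - self.identity_pct[j][i]) > 1e-9:
                    raise ValueError("identity matrix must be symmetric")

    def get(self, a: str, b: str) -> float:
        i = self.gene_ids.index(a)
        j = self.gene_ids.index(b)
        return self.identity_pct[i][j]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\t" + "\t".join(self.gene_ids) + "\n")
            for gid, row in zip(self.gene_ids, self.identity_pct):
                fh.write(gid + "\t" + "\t".join(f"{v:.4f}" for v in row) + "\n")


@dataclass
class MappingThresholds:
    """Per-gene maximum mismatch percentage for competitive read assignment."""

    max_mismatch_pct: dict[str, float]
    solo_default_pct: float = 10.0

    def __post_init__(self) -> None:
        for g, t in self.max_mismatch_pct.items():
            if t < 0:
                raise ValueError(f"negative threshold for {g!r}")

    def __getitem__(self, gene_id: str) -> float:
        return self.max_mismatch_pct[gene_id]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tmax_mismatch_pct\n")
            for g, t in self.max_mismatch_pct.items():
                fh.write(f"{g}\t{t:.4f}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, solo_default_pct: float = 10.0) -> "MappingThresholds":
        thresholds: dict[str, float] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("gene_id"):
                raise ValueError(f"unexpected thresholds header in {path}")
            for line in fh:
                if not line.strip():
                    continue
                g, t = line.rstrip("\n").split("\t")
                thresholds[g] = float(t)
        return cls(thresholds, solo_default_pct=solo_default_pct)


def load_reference_panel(path: str | Path) -> ReferencePanel:
    """Load a labelled panel from FASTA.

    Headers follow the ``geneid|class`` convention, e.g. ``>rh2-1|RH2``.
    Records without a recognised class annotation fall back to ``OTHER``.
    Sequences are upper-cased and RNA ``U`` is converted to ``T``.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    members = []
    for rec in records:
        gene_id, _, klass = rec.id.partition("|")
        klass = klass.upper()
        if klass not in OPSIN_CLASSES:
            klass = "OTHER"
        seq = str(rec.seq).upper().replace("U", "T")
        members.append(ReferenceOpsin(gene_id=gene_id, opsin_class=klass, sequence=seq))
    return ReferencePanel(members)


_aligner: PairwiseAligner | None = None


def _global_aligner() -> PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = PairwiseAligner()
        a.mode = "global"
        a.match_score = MATCH_SCORE
        a.mismatch_score = MISMATCH_SCORE
        a.open_gap_score = GAP_SCORE
        a.extend_gap_score = GAP_SCORE
        _aligner = a
    return _aligner


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity of two nucleotide sequences, in percent.

    Identity is matched columns over all aligned columns (gap columns count
    as non-matches) under the fixed scoring scheme of this module. ``N``
    never counts as a match. Symmetric in its arguments.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    aln = _global_aligner().align(seq_a, seq_b)[0]
    qa, ta = str(aln[0]), str(aln[1])
    matches = sum(
        1 for x, y in zip(qa, ta) if x == y and x != "-" and x != "N"
    )
    return 100.0 * matches / len(qa)


def similarity_matrix(panel: ReferencePanel) -> SimilarityMatrix:
    """All-vs-all pairwise identity for a panel; diagonal fixed at 100."""
    ids = panel.gene_ids
    n = len(ids)
    mat = [[100.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            v = pairwise_identity(panel.members[i].sequence, panel.members[j].sequence)
            mat[i][j] = mat[j][i] = v
    return SimilarityMatrix(gene_ids=ids, identity_pct=mat)


def derive_mismatch_thresholds(
    matrix: SimilarityMatrix, solo_default_pct: float = 10.0
) -> MappingThresholds:
    """Derive per-gene maximum mismatch percentages from paralog similarity.

    For a gene with paralogs the threshold is the minimum divergence
    (100 − identity) to any paralog minus one percentage point, clamped at
    zero; a read diverging from a gene by no more than this can only have
    come from that gene. A solo gene, with no competitor, receives
    ``solo_default_pct`` (default 10%, tolerating polymorphism plus
    sequencing error).
    """
    ids = matrix.gene_ids
    thresholds: dict[str, float] = {}
    for i, g in enumerate(ids):
        others = [matrix.identity_pct[i][j] for j in range(len(ids)) if j != i]
        if not others:
            thresholds[g] = float(solo_default_pct)
        else:
            min_div = min(100.0 - v for v in others)
            thresholds[g] = max(0.0, min_div - 1.0)
    return MappingThresholds(thresholds, solo_default_pct=float(solo_default_pct))
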