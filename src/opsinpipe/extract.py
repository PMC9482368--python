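"""Targeted reconstruction of opsin CDS from paired-end reads.

Mirrors the manual two-step extraction workflow used for paralog-rich opsin
families:

1. *Tolerant mapping* — reads are seeded by exact k-mers and aligned to a
   published reference CDS under permissive ceilings (40% mismatches, 15%
   gapped columns, 50 bp maximum gap, both mates must map), so that reads
   from every paralog of the family are recruited.
2. *SNP partitioning* — recruited read pairs are split into per-paralog
   piles by the variant alleles they carry: pairs sharing an allele at a
   called variant site belong to the same pile. This formalises the manual
   practice of following linked SNPs across a read pile-up.
3. *Consensus and cyclic extension* — each pile's majority-rule consensus
   seeds an iterative cycle of 100%-identity re-mapping that grows the
   contig by read overhangs (recruiting mates to bridge gaps) until an
   in-frame start-to-stop ORF of the expected length emerges or growth
   stalls.

Coordinates are 0-based half-open throughout; FASTQ is assumed Phred+33.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import edlib
from Bio import SeqIO

from .refpanel import ReferenceOpsin, ReferencePanel
from .simulate import reverse_complement

logger = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([=XID])")

# Length tolerance when deciding a reconstructed ORF matches the reference
# model: +/- 3 codons of indel polymorphism.
COMPLETE_LENGTH_TOL_BP = 9

_STOPS = ("TAA", "TAG", "TGA")
_TIE_ORDER = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class TolerantMapParams:
    """Sensitivity settings for tolerant (read-recruiting) mapping.

    Defaults: no fine tuning; maximum gap per read 15%; word length 14;
    maximum mismatches per read 40%; maximum gap size 50 bp; index word
    length 12; paired reads must both map.
    """

    max_gap_per_read_pct: float = 15.0
    word_length: int = 14
    max_mismatch_per_read_pct: float = 40.0
    max_gap_size_bp: int = 50
    index_word_length: int = 12
    require_both_mates: bool = True

    def __post_init__(self) -> None:
        for name in ("max_gap_per_read_pct", "max_mismatch_per_read_pct"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must lie in [0, 100]")
        if self.word_length < 4 or self.index_word_length < 4:
            raise ValueError("word lengths must be >= 4")


@dataclass
class ReadAlignment:
    """An accepted read-to-reference alignment."""

    read_id: str
    gene_id: str
    reference_start: int  # 0-based inclusive
    reference_end: int  # 0-based exclusive
    strand: str  # '+' or '-'
    mismatch_pct: float
    gap_pct: float
    edit_distance: int = 0
    query_aligned: str = ""
    target_aligned: str = ""

    def __post_init__(self) -> None:
        if self.reference_start >= self.reference_end:
            raise ValueError("reference_start must be < reference_end")

    @property
    def divergence_pct(self) -> float:
        """Non-matching alignment columns (mismatches plus gaps) in percent
        — the same definition of divergence that paralog identity uses, so
        values are directly comparable to similarity-derived thresholds."""
        return self.mismatch_pct + self.gap_pct


@dataclass
class ExtractedCDS:
    """A reconstructed coding sequence and its provenance."""

    gene_id: str
    sequence: str
    complete: bool
    min_coverage: int = 0
    iterations_used: int = 0
    ambiguous: bool = False

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


ReadPairs = list[tuple[str, str, str]]  # (pair_id, mate1, mate2)


def load_paired_fastq(r1_path: str | Path, r2_path: str | Path) -> ReadPairs:
    """Read two FASTQ files into a list of (pair_id, mate1, mate2).

    Mate ids must match record-for-record once a trailing ``/1``/``/2``
    is stripped.
    """
    try:
        recs1 = list(SeqIO.parse(str(r1_path), "fastq"))
        recs2 = list(SeqIO.parse(str(r2_path), "fastq"))
    except (ValueError, FileNotFoundError) as exc:
        raise ValueError(f"unreadable FASTQ input: {exc}") from exc
    if len(recs1) != len(recs2):
        raise ValueError("R1 and R2 contain different numbers of reads")
    pairs: ReadPairs = []
    for a, b in zip(recs1, recs2):
        ida = re.sub(r"/[12]$", "", a.id)
        idb = re.sub(r"/[12]$", "", b.id)
        if ida != idb:
            raise ValueError(f"mismatched mate ids: {a.id!r} vs {b.id!r}")
        pairs.append((ida, str(a.seq).upper(), str(b.seq).upper()))
    return pairs


def _cigar_stats(cigar: str) -> tuple[int, int, int, int, int]:
    """(matches, mismatches, gap_columns, max_gap, aligned_columns)."""
    eq = x = gaps = max_gap = cols = 0
    for n_str, op in _CIGAR_RE.findall(cigar):
        n = int(n_str)
        cols += n
        if op == "=":
            eq += n
        elif op == "X":
            x += n
        else:  # I or D
            gaps += n
            max_gap = max(max_gap, n)
    return eq, x, gaps, max_gap, cols


def _aligned_strings(cigar: str, query: str, target: str, t_start: int) -> tuple[str, str]:
    """Expand an extended CIGAR into gapped query/target strings."""
    q_parts: list[str] = []
    t_parts: list[str] = []
    qi, ti = 0, t_start
    for n_str, op in _CIGAR_RE.findall(cigar):
        n = int(n_str)
        if op in "=X":
            q_parts.append(query[qi : qi + n])
            t_parts.append(target[ti : ti + n])
            qi += n
            ti += n
        elif op == "I":  # extra bases in the read
            q_parts.append(query[qi : qi + n])
            t_parts.append("-" * n)
            qi += n
        else:  # 'D': bases in reference absent from the read
            q_parts.append("-" * n)
            t_parts.append(target[ti : ti + n])
            ti += n
    return "".join(q_parts), "".join(t_parts)


class _KmerIndex:
    """Exact k-mer index of one reference strand."""

    def __init__(self, reference: str, k: int):
        self.k = k
        self.reference = reference
        self.index: dict[str, list[int]] = {}
        for i in range(len(reference) - k + 1):
            kmer = reference[i : i + k]
            if "N" in kmer:
                continue
            self.index.setdefault(kmer, []).append(i)

    def has_seed(self, query: str, word_length: int) -> bool:
        """True if some exact match of ``word_length`` anchors the query.

        Candidate positions come from the k-mer index; each candidate is
        verified by extending the shared k-mer to ``word_length``.
        """
        k = self.k
        need = max(word_length, k)
        ref = self.reference
        for qi in range(len(query) - k + 1):
            word = query[qi : qi + need]
            if len(word) < need:
                break
            for ti in self.index.get(query[qi : qi + k], ()):
                if word == ref[ti : ti + need]:
                    return True
        return False


def align_read(
    read_seq: str,
    reference: str,
    params: TolerantMapParams,
    read_id: str = "read",
    gene_id: str = "ref",
    index: tuple[_KmerIndex, _KmerIndex] | None = None,
) -> ReadAlignment | None:
    """Seed-and-extend a single read against one reference.

    Both orientations are tried; seeds are exact ``index_word_length``-mers
    verified out to ``word_length``. The seeded candidate is aligned
    semi-globally (read contained in reference) and accepted only when the
    mismatch, gapped-column and single-gap ceilings all hold. Returns the
    best accepted alignment or ``None``.
    """
    if not reference:
        raise ValueError("reference must be non-empty")
    if index is None:
        index = build_index(reference, params)
    fwd_index, _ = index
    best: ReadAlignment | None = None
    for strand, oriented in (("+", read_seq), ("-", reverse_complement(read_seq))):
        if not fwd_index.has_seed(oriented, params.word_length):
            continue
        res = edlib.align(oriented, reference, mode="HW", task="path")
        if res["editDistance"] < 0 or not res["locations"]:
            continue
        t_start, t_end = res["locations"][0]
        cigar = res["cigar"]
        _, x, gaps, max_gap, cols = _cigar_stats(cigar)
        mismatch_pct = 100.0 * x / cols
        gap_pct = 100.0 * gaps / cols
        if mismatch_pct > params.max_mismatch_per_read_pct:
            continue
        if gap_pct > params.max_gap_per_read_pct:
            continue
        if max_gap > params.max_gap_size_bp:
            continue
        qa, ta = _aligned_strings(cigar, oriented, reference, t_start)
        aln = ReadAlignment(
            read_id=read_id,
            gene_id=gene_id,
            reference_start=t_start,
            reference_end=t_end + 1,
            strand=strand,
            mismatch_pct=mismatch_pct,
            gap_pct=gap_pct,
            edit_distance=res["editDistance"],
            query_aligned=qa,
            target_aligned=ta,
        )
        if best is None or aln.edit_distance < best.edit_distance:
            best = aln
    return best


def build_index(reference: str, params: TolerantMapParams) -> tuple[_KmerIndex, _KmerIndex]:
    """Forward-strand k-mer index, built once per reference."""
    fwd = _KmerIndex(reference, params.index_word_length)
    return fwd, fwd


def tolerant_map(
    pairs: ReadPairs, reference: str, params: TolerantMapParams, gene_id: str = "ref"
) -> list[ReadAlignment]:
    """Map read pairs to one reference under tolerant sensitivity settings.

    When ``params.require_both_mates`` (the default) a pair contributes
    only if both mates individually pass every ceiling.
    """
    index = build_index(reference, params)
    out: list[ReadAlignment] = []
    for pid, m1, m2 in pairs:
        a1 = align_read(m1, reference, params, f"{pid}/1", gene_id, index)
        a2 = align_read(m2, reference, params, f"{pid}/2", gene_id, index)
        if params.require_both_mates:
            if a1 is not None and a2 is not None:
                out.extend((a1, a2))
        else:
            out.extend(a for a in (a1, a2) if a is not None)
    return out


def build_consensus(
    alignments: list[ReadAlignment],
    reference_length: int,
    trim_uncovered_ends: bool = True,
) -> str:
    """Per-column majority consensus of accepted alignments.

    Columns with zero coverage emit ``N``; by default uncovered runs at the
    two ends are trimmed so the result spans the covered reference region.
    Count ties resolve to the highest base under the fixed order A<C<G<T.
    """
    if not alignments:
        raise ValueError("cannot build a consensus from zero alignments")
    tallies: list[dict[str, int]] = [dict() for _ in range(reference_length)]
    for aln in alignments:
        col = aln.reference_start
        for qc, tc in zip(aln.query_aligned, aln.target_aligned):
            if tc == "-":
                continue  # read insertion: no reference column
            if qc != "-" and qc in _TIE_ORDER:
                t = tallies[col]
                t[qc] = t.get(qc, 0) + 1
            col += 1
    out = []
    for t in tallies:
        if not t:
            out.append("N")
        else:
            best_count = max(t.values())
            out.append(max((b for b, c in t.items() if c == best_count), key=_TIE_ORDER.get))
    consensus = "".join(out)
    if trim_uncovered_ends:
        consensus = consensus.strip("N")
    return consensus


# ---------------------------------------------------------------------------
# Cyclic 100%-identity extension
# ---------------------------------------------------------------------------

_EXTEND_K = 14
_MIN_OVERLAP = 20
_MATE_MIN_OVERLAP = 10


def _exact_placements(
    oriented: str, consensus: str, index: dict[str, list[int]], k: int, min_overlap: int
) -> list[int]:
    """Offsets at which ``oriented`` matches the consensus with zero
    mismatches over their overlap (consensus ``N`` matches anything)."""
    L = len(consensus)
    candidates: set[int] = set()
    for qi in range(0, len(oriented) - k + 1):
        for ti in index.get(oriented[qi : qi + k], ()):
            candidates.add(ti - qi)
    placements = []
    for off in candidates:
        overlap = 0
        ok = True
        for p, base in enumerate(oriented):
            col = off + p
            if 0 <= col < L:
                overlap += 1
                cc = consensus[col]
                if cc != "N" and cc != base:
                    ok = False
                    break
        if ok and overlap >= min_overlap:
            placements.append(off)
    return placements


def _place_read(
    read: str, consensus: str, index: dict[str, list[int]], min_overlap: int
) -> tuple[int, str, str] | None:
    """Unique exact placement of a read in either orientation, or None."""
    hits: list[tuple[int, str, str]] = []
    for strand, oriented in (("+", read), ("-", reverse_complement(read))):
        for off in _exact_placements(oriented, consensus, index, _EXTEND_K, min_overlap):
            hits.append((off, strand, oriented))
    distinct = {(off, oriented) for off, _, oriented in hits}
    if len(distinct) != 1:
        return None  # unplaced, or ambiguous between loci
    return hits[0]


def _consensus_kmer_index(consensus: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(consensus) - k + 1):
        kmer = consensus[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _find_orf(seq: str, expected_len: int, tol: int = COMPLETE_LENGTH_TOL_BP) -> str | None:
    """First in-frame ATG→stop ORF whose length matches the expected CDS
    length within tolerance; among candidates the closest length wins."""
    best: tuple[int, int, str] | None = None  # (|len diff|, start, orf)
    for start in range(len(seq) - 2):
        if seq[start : start + 3] != "ATG":
            continue
        for p in range(start, len(seq) - 2, 3):
            codon = seq[p : p + 3]
            if codon in _STOPS:
                orf = seq[start : p + 3]
                diff = abs(len(orf) - expected_len)
                if diff <= tol and "N" not in orf:
                    cand = (diff, start, orf)
                    if best is None or cand[:2] < best[:2]:
                        best = cand
                break
    return best[2] if best else None


def iterative_extend(
    pairs: ReadPairs,
    seed_cds: str,
    reference_cds_model: ReferenceOpsin,
    max_iterations: int = 30,
) -> ExtractedCDS:
    """Grow a partial CDS by cycles of 100%-identity mapping.

    Each cycle places reads that match the current consensus exactly over
    their overlap, recruits their mates at a relaxed minimum overlap to
    bridge gaps, rebuilds the per-column majority, and extends both ends by
    read overhangs. The cycle stops when an in-frame start-to-stop ORF of
    length compatible with ``reference_cds_model`` (±9 bp) appears, when an
    iteration adds no bases, or when two incompatible extensions have equal
    support (recorded as ambiguous).
    """
    if not seed_cds:
        raise ValueError("seed_cds must be non-empty")
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    consensus = seed_cds
    expected = reference_cds_model.length_bp
    iterations = 0
    min_coverage = 0
    ambiguous = False

    orf = _find_orf(consensus, expected)
    if orf is not None:
        return ExtractedCDS(
            gene_id=reference_cds_model.gene_id,
            sequence=orf,
            complete=True,
            min_coverage=0,
            iterations_used=0,
        )

    for _ in range(max_iterations):
        index = _consensus_kmer_index(consensus, _EXTEND_K)
        placed: list[tuple[int, str]] = []  # (offset, oriented read)
        for pid, m1, m2 in pairs:
            p1 = _place_read(m1, consensus, index, _MIN_OVERLAP)
            p2 = _place_read(m2, consensus, index, _MIN_OVERLAP)
            # mate recruitment: a placed read pulls in its unplaced mate
            # under a relaxed overlap requirement
            if p1 is not None and p2 is None:
                p2 = _place_read(m2, consensus, index, _MATE_MIN_OVERLAP)
            elif p2 is not None and p1 is None:
                p1 = _place_read(m1, consensus, index, _MATE_MIN_OVERLAP)
            for p in (p1, p2):
                if p is not None:
                    placed.append((p[0], p[2]))
        iterations += 1
        if not placed:
            break
        lo = min(0, min(off for off, _ in placed))
        hi = max(len(consensus), max(off + len(r) for off, r in placed))
        tallies: list[dict[str, int]] = [dict() for _ in range(hi - lo)]
        for off, oriented in placed:
            for p, base in enumerate(oriented):
                t = tallies[off + p - lo]
                t[base] = t.get(base, 0) + 1

        def _call(t: dict[str, int]) -> tuple[str, bool]:
            best_count = max(t.values())
            tied = [b for b, c in t.items() if c == best_count]
            return max(tied, key=_TIE_ORDER.get), len(tied) > 1

        # left extension, truncated at the first ambiguous column
        left_ext: list[str] = []
        for coord in range(-1, lo - 1, -1):
            t = tallies[coord - lo]
            if not t:
                break
            base, tie = _call(t)
            if tie:
                ambiguous = True
                break
            left_ext.append(base)
        left_ext.reverse()
        # right extension
        right_ext: list[str] = []
        for coord in range(len(consensus), hi):
            t = tallies[coord - lo]
            if not t:
                break
            base, tie = _call(t)
            if tie:
                ambiguous = True
                break
            right_ext.append(base)
        # interior update: majority where covered, old base otherwise
        interior: list[str] = []
        for coord in range(len(consensus)):
            t = tallies[coord - lo]
            if t:
                base, tie = _call(t)
                interior.append(consensus[coord] if tie and consensus[coord] != "N" else base)
            else:
                interior.append(consensus[coord])
        new_consensus = "".join(left_ext) + "".join(interior) + "".join(right_ext)
        min_coverage = min((sum(t.values()) for t in tallies), default=0)

        grew = len(new_consensus) > len(consensus)
        changed = new_consensus != consensus
        consensus = new_consensus
        orf = _find_orf(consensus, expected)
        if orf is not None:
            return ExtractedCDS(
                gene_id=reference_cds_model.gene_id,
                sequence=orf,
                complete=True,
                min_coverage=min_coverage,
                iterations_used=iterations,
                ambiguous=ambiguous,
            )
        if ambiguous or not (grew or changed):
            break
    return ExtractedCDS(
        gene_id=reference_cds_model.gene_id,
        sequence=consensus,
        complete=False,
        min_coverage=min_coverage,
        iterations_used=iterations,
        ambiguous=ambiguous,
    )


# ---------------------------------------------------------------------------
# SNP-consistent read partitioning
# ---------------------------------------------------------------------------


def _pair_id(read_id: str) -> str:
    return re.sub(r"/[12]$", "", read_id)


def snp_partition(
    alignments: list[ReadAlignment], reference: str
) -> list[ReadAlignment]:
    """Select the reference-consistent SNP pile of read pairs.

    Tolerant mapping recruits reads from every paralog of a family; this
    step keeps only the pile belonging to the reference's own gene.
    Variant sites are called wherever a non-reference allele is supported
    by at least ``max(2, 5% of coverage)`` reads — these are the linked
    SNPs that distinguish paralogs. A read pair stays in the pile only if
    it carries the reference allele at every called site it covers;
    pairs supporting a paralog's allele set are set aside. Sporadic
    sequencing errors fall below the calling floor and therefore do not
    eject a pair. If no pair is fully consistent (e.g. the sample's gene
    is uniformly diverged from the published reference) all alignments are
    kept and the downstream consensus resolves the divergence by majority.
    """
    if not alignments:
        return []
    counts: dict[int, dict[str, int]] = {}
    per_read_alleles: dict[str, dict[int, str]] = {}
    for aln in alignments:
        col = aln.reference_start
        alleles: dict[int, str] = per_read_alleles.setdefault(aln.read_id, {})
        for qc, tc in zip(aln.query_aligned, aln.target_aligned):
            if tc == "-":
                continue
            if qc != "-" and qc in _TIE_ORDER:
                counts.setdefault(col, {})[qc] = counts.get(col, {}).get(qc, 0) + 1
                alleles[col] = qc
            col += 1
    called: set[int] = set()
    for col, c in counts.items():
        cov = sum(c.values())
        floor = max(2, -(-cov // 20))  # ceil(5% of coverage)
        ref_base = reference[col]
        if any(base != ref_base and n >= floor for base, n in c.items()):
            called.add(col)
    consistent: dict[str, bool] = {}
    for read_id, alleles in per_read_alleles.items():
        pid = consistent.setdefault(_pair_id(read_id), True)
        if not pid:
            continue
        for col, base in alleles.items():
            if col in called and base != reference[col]:
                consistent[_pair_id(read_id)] = False
                break
    chosen = {pid for pid, ok in consistent.items() if ok}
    if not chosen:
        return alignments
    return [a for a in alignments if _pair_id(a.read_id) in chosen]


def extract_genes(
    pairs: ReadPairs,
    panel: ReferencePanel,
    params: TolerantMapParams | None = None,
    max_iterations: int = 30,
) -> list[ExtractedCDS]:
    """Reconstruct one CDS per panel gene from paired reads.

    Pipeline per gene: tolerant mapping → SNP-consistent partitioning →
    majority consensus → cyclic 100%-identity extension. Genes recruiting
    zero read pairs are omitted with a logged notice.
    """
    if params is None:
        params = TolerantMapParams()
    if not pairs:
        logger.warning("no read pairs supplied; nothing to extract")
        return []
    results: list[ExtractedCDS] = []
    for gene in panel:
        alns = tolerant_map(pairs, gene.sequence, params, gene.gene_id)
        if not alns:
            logger.warning("gene %s recruited no read pairs; omitted", gene.gene_id)
            continue
        pile = snp_partition(alns, gene.sequence)
        if not pile:
            logger.warning("gene %s: no SNP-consistent pile; omitted", gene.gene_id)
            continue
        seed = build_consensus(pile, gene.length_bp)
        if not seed:
            logger.warning("gene %s: empty consensus; omitted", gene.gene_id)
            continue
        results.append(iterative_extend(pairs, seed, gene, max_iterations=max_iterations))
    return results


def write_extraction_report(results: list[ExtractedCDS], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlength_bp\tcomplete\tmin_coverage\titerations_used\tambiguous\n")
        for r in results:
            fh.write(
                f"{r.gene_id}\t{r.length_bp}\t{str(r.complete).lower()}\t"
                f"{r.min_coverage}\t{r.iterations_used}\t{str(r.ambiguous).lower()}\n"
            )


def write_cds_fasta(results: list[ExtractedCDS], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in results:
            status = "complete" if r.complete else "partial"
            fh.write(f">{r.gene_id} {status}\n{r.sequence}\n")
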