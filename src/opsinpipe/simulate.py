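"""Synthetic data with known ground truth for every pipeline stage.

Emulates the study design this pipeline targets: a family of 2–8 highly
similar opsin paralogs (~1.0–1.1 kb CDS, 80–99% pairwise identity — the
extreme case being the eight genomic *rh2* copies of some holocentrids),
sequenced as 150 bp paired-end Illumina reads at user-set per-gene mixing
proportions (e.g. an rh1-dominated retina), plus a differential-expression
table with a known number of true positives.

The error model is substitution-only with uniform coverage; fragments fall
wholly within the CDS. This matches an idealised Illumina profile and keeps
read mismatch percentages directly comparable to the paralog-divergence
thresholds used downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .refpanel import ReferenceOpsin, ReferencePanel

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SimConfig:
    """Parameters of the synthetic paralog family and read set.

    Defaults reflect the study conditions the pipeline targets: ~1.1 kb
    opsin CDS, 150 bp paired-end reads, ~350 bp inserts, low substitution
    error.
    """

    base_length_bp: int = 1065
    n_paralogs: int = 2
    target_identity_pct: float = 90.0
    read_length_bp: int = 150
    insert_mean_bp: float = 350.0
    insert_sd_bp: float = 30.0
    error_rate: float = 0.001
    proportions: dict[str, float] = field(default_factory=dict)
    total_pairs: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_length_bp <= 0 or self.base_length_bp % 3:
            raise ValueError("base_length_bp must be a positive multiple of 3")
        if self.n_paralogs < 1:
            raise ValueError("n_paralogs must be >= 1")
        if not 0 < self.target_identity_pct <= 100:
            raise ValueError("target_identity_pct must lie in (0, 100]")
        if self.read_length_bp > self.base_length_bp:
            raise ValueError("read_length_bp must not exceed base_length_bp")
        if self.insert_mean_bp < self.read_length_bp:
            raise ValueError("insert_mean_bp must be >= read_length_bp")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must lie in [0, 1)")
        if self.proportions:
            total = sum(self.proportions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"proportions sum to {total}, expected 1")


@dataclass
class SimTruth:
    """Ground truth of a simulation run."""

    true_sequences: dict[str, str] = field(default_factory=dict)
    true_pair_counts: dict[str, int] = field(default_factory=dict)
    realized_identity_pct: dict[tuple[str, str], float] = field(default_factory=dict)
    per_read_origin: dict[str, str] = field(default_factory=dict)


def _random_cds(rng: np.random.Generator, length_bp: int) -> str:
    """Random CDS: ATG, no in-frame internal stop, terminal stop codon."""
    n_internal = length_bp // 3 - 2
    codons = ["ATG"]
    for _ in range(n_internal):
        while True:
            c = "".join(rng.choice(_BASES, size=3))
            if c not in _STOPS:
                break
        codons.append(c)
    codons.append(_STOPS[rng.integers(0, 3)])
    return "".join(codons)


def _mutate_to_identity(
    rng: np.random.Generator, base: str, target_identity_pct: float
) -> str:
    """Substitute positions so the result is ~target identity to ``base``.

    Start and stop codons are preserved and substitutions that would create
    an in-frame stop are redrawn, so every paralog stays a valid CDS.
    """
    L = len(base)
    n_sub = round(L * (100.0 - target_identity_pct) / 100.0)
    seq = list(base)
    # Stratified placement: one substitution drawn per equal-width stratum
    # of the eligible range, so divergence is spread evenly along the gene
    # and every read-length window diverges at close to the family-wide
    # rate — the regime paralog-similarity mismatch thresholds assume.
    eligible = np.arange(3, L - 3)
    n_sub = min(n_sub, len(eligible))
    positions = []
    if n_sub:
        edges = np.linspace(0, len(eligible), n_sub + 1)
        for i in range(n_sub):
            lo, hi = int(edges[i]), max(int(edges[i]) + 1, int(edges[i + 1]))
            positions.append(int(eligible[rng.integers(lo, hi)]))
    for pos in sorted(int(p) for p in positions):
        original = seq[pos]
        choices = [b for b in "ACGT" if b != original]
        order = rng.permutation(len(choices))
        placed = False
        for k in order:
            seq[pos] = choices[int(k)]
            codon_start = (pos // 3) * 3
            if "".join(seq[codon_start : codon_start + 3]) not in _STOPS:
                placed = True
                break
        if not placed:
            seq[pos] = original
    return "".join(seq)


def hamming_identity_pct(a: str, b: str) -> float:
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    matches = sum(1 for x, y in zip(a, b) if x == y)
    return 100.0 * matches / len(a)


def generate_paralog_family(config: SimConfig) -> tuple[ReferencePanel, SimTruth]:
    """Generate a labelled family of paralogous CDS at a target identity.

    Gene ids are ``gene1`` … ``geneN`` (``gene1`` is the unmutated base
    sequence) unless ``config.proportions`` names exactly ``n_paralogs``
    genes, in which case those ids are used in order. All members are
    labelled RH2, the class with the largest paralog expansions.
    """
    rng = np.random.default_rng(config.seed)
    base = _random_cds(rng, config.base_length_bp)
    if config.proportions and len(config.proportions) == config.n_paralogs:
        ids = list(config.proportions)
    else:
        ids = [f"gene{i + 1}" for i in range(config.n_paralogs)]
    seqs = [base]
    for _ in range(1, config.n_paralogs):
        seqs.append(_mutate_to_identity(rng, base, config.target_identity_pct))
    truth = SimTruth(true_sequences=dict(zip(ids, seqs)))
    for i in range(len(ids)):
        for j in range(len(ids)):
            truth.realized_identity_pct[(ids[i], ids[j])] = hamming_identity_pct(
                seqs[i], seqs[j]
            )
    panel = ReferencePanel(
        [ReferenceOpsin(gene_id=g, opsin_class="RH2", sequence=s) for g, s in zip(ids, seqs)]
    )
    return panel, truth


def _apply_errors(rng: np.random.Generator, read: str, error_rate: float) -> str:
    if error_rate == 0:
        return read
    arr = np.frombuffer(read.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for pos in hits:
        original = arr[pos].decode()
        alternatives = [b for b in "ACGT" if b != original]
        arr[pos] = alternatives[rng.integers(0, len(alternatives))].encode()
    return arr.tobytes().decode()


def simulate_reads(
    panel: ReferencePanel,
    config: SimConfig,
    r1_path: str | Path | None = None,
    r2_path: str | Path | None = None,
) -> tuple[list[tuple[str, str, str]], SimTruth]:
    """Simulate paired-end reads from a panel at known mixing proportions.

    Returns ``(pairs, truth)`` where ``pairs`` is a list of
    ``(read_id, mate1_seq, mate2_seq)``; mate 2 is the reverse complement
    of the fragment's far end. Per-gene pair counts are multinomial in
    ``config.proportions``; fragment starts are uniform; substitution
    errors occur independently per base at ``config.error_rate``. If
    ``r1_path``/``r2_path`` are given the pairs are also written as
    Phred+33 FASTQ (constant Q37 — no stage consumes qualities).
    """
    if not config.proportions:
        raise ValueError("config.proportions must be set")
    missing = set(config.proportions) - set(panel.gene_ids)
    if missing:
        raise ValueError(f"proportion keys absent from panel: {sorted(missing)}")
    if config.total_pairs < 1:
        raise ValueError("total_pairs must be >= 1")
    rng = np.random.default_rng(config.seed)
    genes = list(config.proportions)
    probs = np.array([config.proportions[g] for g in genes])
    counts = rng.multinomial(config.total_pairs, probs)

    truth = SimTruth(true_pair_counts=dict(zip(genes, (int(c) for c in counts))))
    truth.true_sequences = {g: panel[g].sequence for g in genes}
    pairs: list[tuple[str, str, str]] = []
    rl = config.read_length_bp
    idx = 0
    for gene, n_pairs in zip(genes, counts):
        seq = panel[gene].sequence
        L = len(seq)
        for _ in range(int(n_pairs)):
            frag_len = int(round(rng.normal(config.insert_mean_bp, config.insert_sd_bp)))
            frag_len = max(rl, min(frag_len, L))
            # Fragment windows are drawn from a range extending one
            # insert-minus-read beyond each CDS end and clipped at the
            # boundaries. Real cDNA fragments run into the UTRs, so read
            # coverage along the CDS is uniform; clipping (which shortens
            # inserts at the termini) reproduces that uniformity while
            # keeping every base inside the CDS.
            lo = rl - frag_len
            hi = L - rl
            start = int(rng.integers(lo, hi + 1))
            frag = seq[max(0, start) : min(L, start + frag_len)]
            m1 = _apply_errors(rng, frag[:rl], config.error_rate)
            m2 = _apply_errors(rng, reverse_complement(frag)[:rl], config.error_rate)
            rid = f"pair{idx:07d}"
            truth.per_read_origin[rid] = gene
            pairs.append((rid, m1, m2))
            idx += 1
    if r1_path is not None and r2_path is not None:
        write_paired_fastq(pairs, r1_path, r2_path)
    return pairs, truth


def write_paired_fastq(
    pairs: list[tuple[str, str, str]], r1_path: str | Path, r2_path: str | Path
) -> None:
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for rid, m1, m2 in pairs:
            f1.write(f"@{rid}/1\n{m1}\n+\n{'F' * len(m1)}\n")
            f2.write(f"@{rid}/2\n{m2}\n+\n{'F' * len(m2)}\n")


def write_truth_manifest(truth: SimTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\ttrue_pair_count\n")
        for g, c in truth.true_pair_counts.items():
            fh.write(f"{g}\t{c}\n")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def simulate_dge_table(
    n_transcripts: int, n_sig: int, frac_up: float, seed: int = 0
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Differential-expression table with a known number of true DEGs.

    Exactly ``n_sig`` rows receive an adjusted P ≤ 0.05, of which
    ``round(n_sig * frac_up)`` (half away from zero) get a positive log
    fold change and the rest a negative one; remaining rows draw adjusted P
    above 0.05. Returns the table and a truth dict with keys ``n_sig``,
    ``n_up``, ``n_down``.
    """
    if n_transcripts < 0 or n_sig < 0:
        raise ValueError("counts must be non-negative")
    if n_sig > n_transcripts:
        raise ValueError("n_sig must not exceed n_transcripts")
    if not 0 <= frac_up <= 1:
        raise ValueError("frac_up must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_up = _round_half_away(n_sig * frac_up)
    n_down = n_sig - n_up
    ids = [f"TRINITY_DN{i:06d}" for i in range(n_transcripts)]
    padj = np.empty(n_transcripts)
    lfc = rng.normal(0.0, 1.0, size=n_transcripts)
    padj[:n_sig] = rng.uniform(1e-6, 0.05, size=n_sig)
    padj[n_sig:] = rng.uniform(0.0501, 1.0, size=n_transcripts - n_sig)
    lfc[:n_up] = np.abs(rng.normal(2.0, 1.0, size=n_up)) + 0.05
    lfc[n_up:n_sig] = -(np.abs(rng.normal(2.0, 1.0, size=n_down)) + 0.05)
    table = pd.DataFrame(
        {"transcript_id": ids, "log2fc": lfc, "padj": padj}
    ).sample(frac=1.0, random_state=int(rng.integers(0, 2**31))).reset_index(drop=True)
    truth = {"n_sig": n_sig, "n_up": n_up, "n_down": n_down}
    return table, truth
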