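# opsinpipe

Paralog-aware opsin expression profiling from paired-end RNA-seq.

Visual opsin genes occur in families of highly similar paralogs — some
nocturnal reef fishes carry up to eight *rh2* copies exceeding 95%
nucleotide identity. Short reads from one copy readily map to several, so
naive quantification misattributes expression and de novo assemblers
produce chimeric transcripts. `opsinpipe` implements a targeted,
reproducible alternative for researchers studying visual-system gene
expression (and anyone quantifying close paralogs from bulk RNA-seq):

1. **Reference panel & thresholds** (`refpanel`) — load a labelled opsin
   CDS panel (classes RH1, RH2, SWS1, SWS2, LWS), score all-vs-all global
   alignment identity, and derive a per-gene maximum mismatch threshold

   *t(g) = min over paralogs p of [100 − identity(g, p)] − 1*   (percentage points, clamped at 0)

   so an error-free read from one paralog can never satisfy another's
   threshold.
2. **Synthetic ground truth** (`simulate`) — paralog families with
   controlled pairwise identity, 150 bp paired-end reads at chosen mixing
   proportions with substitution errors, and differential-expression
   tables with known truth, so every downstream stage is testable.
3. **Targeted CDS extraction** (`extract`) — tolerant k-mer-seeded mapping
   (≤40% mismatches, ≤15% gap columns, ≤50 bp gaps, both mates must map),
   SNP-consistent read partitioning to isolate each paralog's read pile,
   majority consensus, then cyclic 100%-identity re-mapping that extends
   the contig by read overhangs (recruiting mates to bridge gaps) until a
   complete in-frame CDS emerges.
4. **Classification** (`classify`) — nearest-reference opsin class by
   global identity, with the margin to the best other-class hit reported.
5. **Competitive quantification** (`quantify`) — a read pair is credited
   to a gene only if both mates fall within that gene's threshold and no
   other's; multi-satisfying pairs are discarded. Counts are divided by
   gene length and reported as rod-vs-cone, single-cone (*sws1*, *sws2*)
   and double-cone (*rh2*, *lws*) proportional expression:

   *P(rod) = r(rh1) / Σ r(g)*, with *r(g) = pairs(g) / length(g)*.

6. **DEG & overrepresentation** (`dge`) — filter on adjusted P ≤ 0.05,
   split by log-fold-change sign, summarise top genes, and test term
   overrepresentation with one-sided Fisher's exact tests,
   Benjamini–Hochberg FDR < 0.05 and fold enrichment ≥ 6.

## Worked example

Simulate an rh1-dominated retina (80% *rh1*, 10% *sws2a*, 10% *rh2-1*;
three 1,065 bp genes at ~90% pairwise identity; 5,000 pairs at 0.1%
substitution error), then run extraction and quantification:

```python
import opsinpipe as op

cfg = op.SimConfig(
    n_paralogs=3, target_identity_pct=90.0, error_rate=0.001,
    proportions={"rh1": 0.80, "sws2a": 0.10, "rh2-1": 0.10},
    total_pairs=5000, seed=1,
)
panel, truth = op.generate_paralog_family(cfg)
pairs, _ = op.simulate_reads(panel, cfg)

extracted = op.extract_genes(pairs, panel)
thresholds = op.derive_mismatch_thresholds(op.similarity_matrix(panel))
counts = op.competitive_map_counts(pairs, extracted, thresholds)
rates = op.length_normalize(counts, extracted)
report = op.proportions(rates, {"rh1": "RH1", "sws2a": "SWS2", "rh2-1": "RH2"})
```

Output (printing the intermediate objects as in the example script):

```
rh1: 1065 bp, complete=True, exact=True
sws2a: 1065 bp, complete=True, exact=True
rh2-1: 1065 bp, complete=True, exact=True
thresholds: {'rh1': 8.95, 'sws2a': 8.95, 'rh2-1': 8.95}
pair counts: {'rh1': 4014, 'sws2a': 517, 'rh2-1': 469} | multi: 0 unmapped: 0
rod share: 80.3%  cone share: 19.7%
single-cone: {'sws2a': '100.0%'}
double-cone: {'rh2-1': '100.0%'}
```

All three coding sequences are reconstructed byte-exactly from the reads
alone; the ~9% mismatch thresholds keep every pair on its gene of origin
(zero multi-mapped discards), and the recovered rod share (80.3%) matches
the simulated 80% within sampling noise.

The same stages are available as CLI subcommands (`opsinpipe panel`,
`simulate`, `extract`, `classify`, `quantify`, `dge`); see `--help`.

## Layout

- `src/opsinpipe/` — library modules (`refpanel`, `simulate`, `extract`,
  `classify`, `quantify`, `dge`, `cli`)
- `tests/` — pytest suite with independent oracles (Needleman–Wunsch DP,
  hypergeometric enumeration, simulator ground truth)
- `docs/methods.md` — models, parameter choices and limitations
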