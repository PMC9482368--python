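import pytest

import opsinpipe as op


@pytest.fixture(scope="session")
def family2():
    """Two-paralog family at ~90% identity with error-free reads, 60/40 mix."""
    cfg = op.SimConfig(
        n_paralogs=2,
        target_identity_pct=90.0,
        error_rate=0.0,
        proportions={"gene1": 0.6, "gene2": 0.4},
        total_pairs=2000,
        seed=7,
    )
    panel, fam_truth = op.generate_paralog_family(cfg)
    pairs, read_truth = op.simulate_reads(panel, cfg)
    return cfg, panel, fam_truth, pairs, read_truth


@pytest.fixture(scope="session")
def solo_reads():
    """Single 1,065 bp gene with error-free ~30x paired coverage."""
    cfg = op.SimConfig(
        n_paralogs=1,
        error_rate=0.0,
        proportions={"gene1": 1.0},
        total_pairs=107,
        seed=11,
    )
    panel, fam_truth = op.generate_paralog_family(cfg)
    pairs, read_truth = op.simulate_reads(panel, cfg)
    return cfg, panel, fam_truth, pairs, read_truth


@pytest.fixture()
def toy_panel():
    return op.ReferencePanel(
        [
            op.ReferenceOpsin("rh1", "RH1", "ATGACGTACGTACGTACGTTAA"),
            op.ReferenceOpsin("rh2-1", "RH2", "ATGACGTACCTACGAACGTTAA"),
            op.ReferenceOpsin("sws2a", "SWS2", "ATGAGGTTCCTAGGAACCTTAA"),
        ]
    )
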