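"""Shared fixtures: one standard planted simulation reused across modules."""
import pytest

from pipseq import CallerConfig, SimConfig, call_pps, simulate_annotation, simulate_libraries

STANDARD_SEED = 7


@pytest.fixture(scope="session")
def standard_sim():
    """Planted-truth experiment at the default study conditions
    (enrichment 8x, depletion 0.1, 30x control depth, 40+/-5 nt sites)."""
    cfg = SimConfig(n_transcripts=20, seed=STANDARD_SEED)
    transcripts, truth = simulate_annotation(cfg)
    fp, ctl = simulate_libraries(cfg, truth)
    return cfg, transcripts, truth, fp, ctl


@pytest.fixture(scope="session")
def standard_calls(standard_sim):
    cfg, transcripts, truth, fp, ctl = standard_sim
    calls, table = call_pps(fp, ctl, CallerConfig(seed=STANDARD_SEED + 100))
    return calls, table
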