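import logging

import numpy as np
import pytest

from fldskit.io import PipelineConfig
from fldskit.pipeline import evaluate_against_truth, run_pipeline
from fldskit.rdrp import load_motif_profiles
from fldskit.simulate import VirusSpec, random_terminal_words

logging.getLogger("fldskit").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def profiles():
    return load_motif_profiles()


def make_spec(
    virus_id="VX.S99",
    strain="S99",
    lengths=(1800, 1200),
    architecture="complete",
    polya_len=0,
    seed=11,
    genetic_code="standard",
):
    rng = np.random.default_rng(seed)
    w5, w3 = random_terminal_words(rng)
    return VirusSpec(
        virus_id=virus_id,
        host_strain=strain,
        n_segments=len(lengths),
        segment_lengths=list(lengths),
        terminal_word_5p=w5,
        terminal_word_3p=w3,
        polya_len=polya_len,
        rdrp_architecture=architecture,
        genetic_code=genetic_code,
        seed=seed,
    )


@pytest.fixture(scope="session")
def full_run():
    """One full pipeline run on the built-in 10-strain study (shared by
    end-to-end tests to keep the suite fast)."""
    config = PipelineConfig(seed=1)
    study, result = run_pipeline(config)
    metrics = evaluate_against_truth(study, result)
    return study, result, metrics
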