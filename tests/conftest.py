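import numpy as np
import pytest

from mirmod.simulate import (
    MiRNAReference,
    default_truth,
    generate_reference,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def toy_refs():
    refs, _ = generate_reference(8, (20, 23), None, seed=11)
    return refs


@pytest.fixture(scope="session")
def mini_experiment(tmp_path_factory):
    """Small but complete 3-donor x 3-compartment simulated experiment."""
    outdir = tmp_path_factory.mktemp("mini_sim")
    refs, fragment = generate_reference(
        15, (20, 23), {"motif": "GGAG", "n_carriers": 3}, seed=5
    )
    truth = default_truth(refs, seed=5, fragment=fragment, n_donors=3)
    out = simulate_experiment(refs, truth, 600, outdir)
    return {"refs": refs, "truth": truth, "out": out, "outdir": outdir}


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))
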