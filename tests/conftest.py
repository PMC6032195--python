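import numpy as np
import pytest

from groovekit import GrooveSimSpec, build_groove, groove_definition


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def default_spec():
    return GrooveSimSpec(seed=7)


@pytest.fixture
def groove(default_spec):
    return build_groove(default_spec), groove_definition(default_spec)


def make_pdb_text(records):
    """Minimal PDB text from (chain, resid, resname, name, x, y, z) tuples."""
    lines = []
    for i, (chain, resid, resname, name, x, y, z) in enumerate(records, start=1):
        lines.append(
            f"ATOM  {i:5d} {name:^4s}{resname:>4s} {chain}{resid:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
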