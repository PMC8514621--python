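import numpy as np
import pytest

from zernab.fixtures import make_toy_complex
from zernab.patches import native_epitope
from zernab.surface import assign_electrostatics, residue_sasa, sample_sas


@pytest.fixture(scope="session")
def toy():
    """Toy antibody-antigen complex with precomputed surfaces and epitope."""
    tc = make_toy_complex(seed=0)
    antigen = tc.antigen
    antibody = tc.antibody
    ag_cloud = assign_electrostatics(sample_sas(antigen), antigen)
    ab_cloud = assign_electrostatics(sample_sas(antibody), antibody)
    native = native_epitope(tc.structure, ag_cloud, cutoff=6.0)
    return {
        "complex": tc,
        "structure": tc.structure,
        "antigen": antigen,
        "antibody": antibody,
        "antigen_cloud": ag_cloud,
        "antibody_cloud": ab_cloud,
        "native": native,
        "antigen_sasa": residue_sasa(antigen),
    }


def single_atom_structure(radius=1.7, charge=0.0, name="CA", resname="ALA"):
    from zernab.structure_io import Atom, Structure
    return Structure(atoms=[Atom(serial=1, name=name, element="C",
                                 position=np.zeros(3), radius=radius,
                                 partial_charge=charge,
                                 residue_key=("A", 1, ""), residue_name=resname)])
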