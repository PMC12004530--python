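import numpy as np
import pytest

from plikit import synthetic as syn
from plikit.io import default_vocabularies
from plikit.model import JointTransformer, ModelConfig
from plikit.tokenization import PROTEIN, SELFIES, SMILES, build_vocabulary


@pytest.fixture(scope="session")
def protein_vocab():
    return build_vocabulary(PROTEIN)


@pytest.fixture(scope="session")
def smiles_vocab():
    return build_vocabulary(SMILES)


@pytest.fixture(scope="session")
def selfies_vocab():
    return build_vocabulary(SELFIES)


@pytest.fixture(scope="session")
def vocabs():
    return default_vocabularies()


@pytest.fixture(scope="session")
def tiny_cfg(vocabs):
    pv, lv = vocabs
    return ModelConfig.preset("tiny", protein_vocab_size=len(pv),
                              ligand_vocab_size=len(lv), seed=11)


@pytest.fixture()
def tiny_model(tiny_cfg):
    return JointTransformer(tiny_cfg)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but fully featured synthetic dataset shared across tests."""
    return syn.generate(syn.SyntheticConfig(n_records=160, master_seed=7))


def random_joint(rng, vocabs, protein_len=None, n_ligands=1):
    """A random but well-formed joint sequence for shape/contract tests."""
    from plikit.tokenization import assemble_joint, tokenize_ligand, tokenize_protein
    pv, lv = vocabs
    aa = [t for t in pv.tokens if len(t) == 1 and t.isalpha()]
    protein_len = protein_len or int(rng.integers(8, 30))
    protein = "".join(rng.choice(aa, size=protein_len))
    prot = tokenize_protein(protein, pv)
    ligs = []
    for _ in range(n_ligands):
        n = int(rng.integers(2, 8))
        smiles = "".join(rng.choice(list("CNO"), size=n))
        ligs.append(tokenize_ligand(smiles, SMILES, lv))
    return assemble_joint(prot, ligs, pv, lv)
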