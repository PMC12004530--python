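"""Tokenize a protein and two ligand notations, and build the joint input.

Shows the dual-vocabulary scheme: one token per protein residue, a greedy
scanner for SMILES (two-character halogens and bracket atoms are single
tokens), bracket-symbol splitting for SELFIES, and the joint layout
BOS protein EOS SEP ligand with its modality mask.
"""

from plikit import (
    PROTEIN, SELFIES, SMILES, assemble_joint, build_vocabulary,
    tokenize_ligand, tokenize_protein,
)

protein_vocab = build_vocabulary(PROTEIN)
smiles_vocab = build_vocabulary(SMILES)
selfies_vocab = build_vocabulary(SELFIES)
print(f"vocabulary sizes: protein={len(protein_vocab)} "
      f"smiles={len(smiles_vocab)} selfies={len(selfies_vocab)}")

prot = tokenize_protein("MKVLAWGH", protein_vocab)
print("protein tokens:", " ".join(prot.surface))

lig = tokenize_ligand("C(Cl)Br", SMILES, smiles_vocab)
print("SMILES tokens:", " ".join(lig.surface), "(halogens are single tokens)")

sel = tokenize_ligand("[C][Branch1][N][EndBranch1][O]", SELFIES, selfies_vocab)
print("SELFIES tokens:", " ".join(sel.surface))

joint = assemble_joint(prot, [lig], protein_vocab, smiles_vocab)
print(f"joint length {len(joint)} = 8 residues + 5 ligand tokens + BOS/EOS/SEP")
print("protein span:", joint.protein_span, "ligand span:", joint.ligand_span)
# The modality mask is what the pooling and site heads use to ignore
# special tokens and ligand positions respectively.
print("modality mask:", joint.modality_mask)
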