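"""Molecule-to-feature-vector encoders for the surrogate.

Two featurizers are shipped: a physicochemical descriptor vector computed
with RDKit (the realistic default), and a toolkit-free hash featurizer
that maps any string deterministically to a fixed-length Gaussian vector
(used by the synthetic benchmark objectives, which are smooth functions of
the same hash coordinates — so the surrogate has signal to learn).
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["descriptor_features", "hash_features", "featurize", "FEATURIZERS"]

_DESCRIPTOR_FNS = None


def _descriptor_fns():
    global _DESCRIPTOR_FNS
    if _DESCRIPTOR_FNS is None:
        from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

        _DESCRIPTOR_FNS = [
            Descriptors.MolWt,
            Crippen.MolLogP,
            rdMolDescriptors.CalcTPSA,
            Lipinski.NumHAcceptors,
            Lipinski.NumHDonors,
            Lipinski.NumRotatableBonds,
            rdMolDescriptors.CalcNumRings,
            rdMolDescriptors.CalcNumAromaticRings,
            rdMolDescriptors.CalcFractionCSP3,
            Descriptors.HeavyAtomCount,
        ]
    return _DESCRIPTOR_FNS


def descriptor_features(smiles_list) -> np.ndarray:
    """(n, 10) physicochemical descriptor matrix; raises on invalid SMILES."""
    from rdkit import Chem

    fns = _descriptor_fns()
    out = np.empty((len(smiles_list), len(fns)))
    for i, smi in enumerate(smiles_list):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"invalid SMILES in feature computation: {smi!r}")
        out[i] = [fn(mol) for fn in fns]
    return out


def hash_features(strings, dim: int = 6) -> np.ndarray:
    """Deterministic string → N(0, I_dim) embedding via a stable hash.

    Stable across processes and platforms (blake2b digest seeds a PCG64
    stream), so it can serve as both oracle input and surrogate feature.
    """
    out = np.empty((len(strings), dim))
    for i, s in enumerate(strings):
        digest = hashlib.blake2b(s.encode("utf-8"), digest_size=8).digest()
        rng = np.random.default_rng(int.from_bytes(digest, "big"))
        out[i] = rng.standard_normal(dim)
    return out


FEATURIZERS = {
    "descriptors": descriptor_features,
    "hash": hash_features,
}


def featurize(smiles_list, name: str) -> np.ndarray:
    try:
        fn = FEATURIZERS[name]
    except KeyError:
        raise ValueError(f"unknown featurizer {name!r}; options: {sorted(FEATURIZERS)}")
    return fn(smiles_list)
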