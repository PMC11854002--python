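"""Deterministic drug-like molecule libraries and toy latent datasets.

Real training corpora for molecular generative models are libraries of a few
hundred thousand drug-like compounds.  For development and testing this module
builds a miniature analogue: a seeded, purely deterministic library assembled
from curated aromatic/aliphatic scaffolds and substituents plus an enumerated
set of small alkanes, alcohols and amines.  The construction guarantees the
properties downstream experiments rely on — every molecule is valid, neutral,
token-encodable, within a heavy-atom budget, and the library spans several
ring counts and a wide logP range so property guidance has signal to work
with.

`generate_gaussian_latents` provides analytically known latent datasets used
to validate the diffusion model's moment recovery in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .codec import CodecError, canonical_smiles, tokenize_smiles

__all__ = ["FixtureSpec", "FixtureError", "generate_library", "generate_gaussian_latents"]


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic molecule library."""

    n_molecules: int = 500
    seed: int = 7
    heavy_atom_range: tuple[int, int] = (1, 25)
    element_set: frozenset[str] = field(
        default_factory=lambda: frozenset({"C", "N", "O", "S", "F", "Cl"}))

    def __post_init__(self):
        if self.n_molecules < 1:
            raise FixtureError("n_molecules must be >= 1")
        lo, hi = self.heavy_atom_range
        if lo > hi:
            raise FixtureError("heavy_atom_range min exceeds max")


# Enumerated small molecules: ring count 0, low-to-mid logP.
_BASE = [
    "C", "CC", "CCC", "CCCC", "CCCCC", "CCCCCC", "CCCCCCC", "CCCCCCCC",
    "CO", "CCO", "CCCO", "CC(C)O", "OCCO", "OCC(O)CO", "CCOC", "CCOCC",
    "CN", "CCN", "CCCN", "CC(C)N", "NCCO", "NCCN", "CNC", "CCNCC",
    "CCl", "CCCl", "ClCCCl", "CF", "FCCF", "CSC", "CCSC", "CC(C)(C)C",
    "CC(C)CC(C)C", "C=CC", "C=CCC", "CC#N", "CCC#N", "CC(=O)C", "CC(=O)OC",
    "CC(=O)N", "CC(=O)NC", "C=O", "CC=O", "CCC=O", "OCCOCCO", "NCC(=O)O",
]

# Scaffolds with substitution points; all fill-ins below keep them valid.
_SCAFFOLDS = [
    "c1ccc({0})cc1",
    "c1cc({1})ccc1{0}",
    "c1ccc2cc({0})ccc2c1",
    "c1cc({0})cnc1",
    "c1ccnc({0})c1",
    "c1cc({0})oc1",
    "c1cc({0})sc1",
    "c1cc({0})[nH]c1",
    "C1CCC({0})CC1",
    "C1CCN({0})CC1",
    "C1CC({0})OCC1",
    "c1ccc(-c2ccc({0})cc2)cc1",
    "c1ccc(C{0})cc1",
    "c1ccc(OC{0})cc1",
    "c1ccc(N{0})cc1",
    "C1CC1{0}",
    "C1CCC1{0}",
    "C1CCCCCC1{0}",
]

_SUBSTITUENTS = [
    "C", "CC", "CCC", "CCCC", "CCCCCC", "C(C)C", "C(C)(C)C",
    "O", "OC", "OCC", "N", "NC", "N(C)C", "Cl", "F",
    "C(=O)C", "C(=O)OC", "C(=O)N", "CO", "CCO", "CCN", "C#N", "C=C", "SC",
    "C(F)(F)F", "CCl", "OCCO", "NCC",
]


def _admissible(smiles: str, spec: FixtureSpec) -> str | None:
    """Canonicalise and validate one candidate; None if outside the spec."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    lo, hi = spec.heavy_atom_range
    if not lo <= mol.GetNumHeavyAtoms() <= hi:
        return None
    if any(a.GetSymbol() not in spec.element_set for a in mol.GetAtoms()):
        return None
    canon = Chem.MolToSmiles(mol)
    try:
        tokenize_smiles(canon)   # must be encodable by the robust grammar
    except CodecError:
        return None
    return canon


def generate_library(spec: FixtureSpec = FixtureSpec()) -> list[str]:
    """Build a deterministic drug-like library of ``spec.n_molecules`` SMILES.

    The enumerated base set is taken first (in fixed order), then scaffold +
    substituent assemblies are sampled with the seeded generator until the
    target count of distinct canonical SMILES is reached.
    """
    rng = np.random.default_rng(spec.seed)
    out: list[str] = []
    seen: set[str] = set()

    for smi in _BASE:
        canon = _admissible(smi, spec)
        if canon is not None and canon not in seen:
            seen.add(canon)
            out.append(canon)
        if len(out) == spec.n_molecules:
            return out

    attempts = 0
    max_attempts = 400 * spec.n_molecules
    while len(out) < spec.n_molecules:
        attempts += 1
        if attempts > max_attempts:
            raise FixtureError(
                f"could not assemble {spec.n_molecules} molecules under "
                f"heavy_atom_range={spec.heavy_atom_range}; spec may be unsatisfiable")
        scaffold = _SCAFFOLDS[rng.integers(len(_SCAFFOLDS))]
        n_slots = scaffold.count("{")
        subs = [_SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))] for _ in range(n_slots)]
        canon = _admissible(scaffold.format(*subs), spec)
        if canon is not None and canon not in seen:
            seen.add(canon)
            out.append(canon)
    return out


def generate_gaussian_latents(n: int, dim: int, mean=0.0, cov_scale: float = 1.0,
                              seed: int = 0) -> np.ndarray:
    """Draw ``n`` i.i.d. latent vectors from N(mean, cov_scale * I)."""
    if n < 2:
        raise FixtureError("n must be >= 2")
    if dim < 1:
        raise FixtureError("dim must be >= 1")
    if cov_scale <= 0:
        raise FixtureError("cov_scale must be positive")
    rng = np.random.default_rng(seed)
    mean = np.broadcast_to(np.asarray(mean, dtype=np.float64), (dim,))
    return mean + np.sqrt(cov_scale) * rng.standard_normal((n, dim))
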