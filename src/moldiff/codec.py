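"""Robust molecular string codec: SMILES <-> SELFIES-style tokens <-> one-hot.

Molecules are represented as sequences of tokens from a small derivation
grammar in the spirit of SELFIES: atom tokens carry the element and the order
of the bond to the current attachment point, ``[Branch]``/``[Pop]`` manage a
branch stack, and ``[Ring{k}]`` closes a ring to the atom created ``k`` steps
earlier.  The decoder clips every requested bond to the valences still
available, so *any* token sequence — including random ones — derives a valid
molecule.  This robustness-by-construction is what lets a generative model
emit relaxed one-hot matrices and still always obtain parseable chemistry.

Scope: neutral organic molecules over C, N, O, S, F, Cl without stereo
annotations, which covers the drug-like fixture libraries this package
trains on.  Aromatic systems are kekulised on encode and re-perceived on
decode, so round-trips compare equal as canonical SMILES.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "CodecError",
    "MoleculeRecord",
    "Vocabulary",
    "EMPTY_MOLECULE",
    "PAD_TOKEN",
    "canonical_smiles",
    "tokenize_smiles",
    "detokenize",
    "build_vocabulary",
    "encode",
    "decode",
    "to_onehot",
    "read_molecule_file",
    "write_molecule_file",
]

#: Sentinel returned when a token sequence derives no atoms (e.g. all padding).
#: The empty string parses to the empty molecule under RDKit.
EMPTY_MOLECULE = ""

PAD_TOKEN = "[nop]"

_MAX_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "F": 1, "Cl": 1}
_BOND_PREFIX = {1: "", 2: "=", 3: "#"}
_PREFIX_BOND = {"": 1, "=": 2, "#": 3}
_RDKIT_BOND = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
               3: Chem.BondType.TRIPLE}


class CodecError(ValueError):
    """Raised for molecules or encodings outside the codec's contract."""


def canonical_smiles(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise CodecError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


# ---------------------------------------------------------------------------
# tokenisation (SMILES -> tokens)
# ---------------------------------------------------------------------------

def tokenize_smiles(smiles: str) -> list[str]:
    """Tokenise a SMILES string into the robust grammar.

    The molecule is kekulised and traversed depth-first from atom 0 in RDKit
    canonical order; spanning-tree edges become atom tokens, back edges become
    ring tokens, and side chains are wrapped in ``[Branch]`` … ``[Pop]``.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise CodecError(f"unparseable SMILES: {smiles!r}")
    # re-parse the canonical form so atom order is reproducible
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
    Chem.Kekulize(mol, clearAromaticFlags=True)
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in _MAX_VALENCE:
            raise CodecError(f"unsupported element {sym!r} in {smiles!r}")
        if atom.GetFormalCharge() != 0:
            raise CodecError(f"charged atom in {smiles!r}: codec covers neutral molecules")
        if atom.GetNumRadicalElectrons() != 0:
            raise CodecError(f"radical in {smiles!r} not supported")

    tokens: list[str] = []
    creation: dict[int, int] = {}   # atom idx -> creation position
    used_bonds: set[int] = set()
    counter = 0

    def emit_atom(idx: int, bond_order: int) -> None:
        nonlocal counter
        tokens.append(f"[{_BOND_PREFIX[bond_order]}{mol.GetAtomWithIdx(idx).GetSymbol()}]")
        creation[idx] = counter
        counter += 1

    def visit(idx: int) -> None:
        atom = mol.GetAtomWithIdx(idx)
        # ring closures back to already-created atoms
        for bond in atom.GetBonds():
            other = bond.GetOtherAtomIdx(idx)
            if other in creation and bond.GetIdx() not in used_bonds:
                used_bonds.add(bond.GetIdx())
                delta = creation[idx] - creation[other]
                order = int(bond.GetBondTypeAsDouble())
                tokens.append(f"[{_BOND_PREFIX[order]}Ring{delta}]")
        children = []
        for bond in atom.GetBonds():
            other = bond.GetOtherAtomIdx(idx)
            if other not in creation and bond.GetIdx() not in used_bonds:
                children.append((other, bond))
        for i, (other, bond) in enumerate(children):
            if other in creation:      # closed meanwhile by a sibling branch
                continue
            used_bonds.add(bond.GetIdx())
            last = i == len(children) - 1
            if not last:
                tokens.append("[Branch]")
            emit_atom(other, int(bond.GetBondTypeAsDouble()))
            visit(other)
            if not last:
                tokens.append("[Pop]")

    if mol.GetNumAtoms() == 0:
        return []
    emit_atom(0, 1)
    visit(0)
    return tokens


# ---------------------------------------------------------------------------
# derivation (tokens -> SMILES)
# ---------------------------------------------------------------------------

def _parse_token(token: str) -> tuple[str, str, int]:
    """Return (kind, payload, bond_order); kind in {atom, branch, pop, ring, nop}."""
    if token == PAD_TOKEN:
        return "nop", "", 0
    if token == "[Branch]":
        return "branch", "", 0
    if token == "[Pop]":
        return "pop", "", 0
    if not (token.startswith("[") and token.endswith("]")):
        raise CodecError(f"malformed token {token!r}")
    body = token[1:-1]
    order = 1
    if body.startswith("="):
        order, body = 2, body[1:]
    elif body.startswith("#"):
        order, body = 3, body[1:]
    if body.startswith("Ring"):
        return "ring", body[4:], order
    if body in _MAX_VALENCE:
        return "atom", body, order
    raise CodecError(f"unknown token {token!r}")


def detokenize(tokens: Sequence[str]) -> str:
    """Derive a molecule from a token sequence; always returns parseable SMILES.

    Requested bonds are clipped to the free valence of both endpoints;
    unsatisfiable tokens (saturated attachment point, dangling ``[Pop]``,
    out-of-range ring references) are skipped.  Sequences that create no atom
    return :data:`EMPTY_MOLECULE`.
    """
    rw = Chem.RWMol()
    order_created: list[int] = []   # rdkit atom indices in creation order
    position: dict[int, int] = {}
    free: dict[int, int] = {}
    cur: int | None = None
    stack: list[int] = []

    def add_atom(elem: str) -> int:
        idx = rw.AddAtom(Chem.Atom(elem))
        position[idx] = len(order_created)
        order_created.append(idx)
        free[idx] = _MAX_VALENCE[elem]
        return idx

    for token in tokens:
        kind, payload, order = _parse_token(token)
        if kind == "nop":
            continue
        if kind == "atom":
            if cur is None:
                cur = add_atom(payload)
                continue
            b = min(order, free[cur], _MAX_VALENCE[payload])
            if b < 1:
                continue
            new = add_atom(payload)
            rw.AddBond(cur, new, _RDKIT_BOND[b])
            free[cur] -= b
            free[new] -= b
            cur = new
        elif kind == "branch":
            if cur is not None:
                stack.append(cur)
        elif kind == "pop":
            if stack:
                cur = stack.pop()
        elif kind == "ring":
            if cur is None:
                continue
            try:
                delta = int(payload)
            except ValueError as exc:
                raise CodecError(f"malformed ring token {token!r}") from exc
            tgt_pos = position[cur] - delta
            if tgt_pos < 0:
                continue
            tgt = order_created[tgt_pos]
            if tgt == cur or rw.GetBondBetweenAtoms(cur, tgt) is not None:
                continue
            b = min(order, free[cur], free[tgt])
            if b < 1:
                continue
            rw.AddBond(cur, tgt, _RDKIT_BOND[b])
            free[cur] -= b
            free[tgt] -= b

    if rw.GetNumAtoms() == 0:
        return EMPTY_MOLECULE
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


# ---------------------------------------------------------------------------
# vocabulary and records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Vocabulary:
    """Ordered token alphabet (lexicographic) plus the padding token."""

    tokens: tuple[str, ...]
    max_len: int
    index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if len(set(self.tokens)) != len(self.tokens):
            raise CodecError("duplicate tokens in vocabulary")
        if self.tokens.count(PAD_TOKEN) != 1:
            raise CodecError("vocabulary must contain the padding token exactly once")
        object.__setattr__(self, "index", {t: i for i, t in enumerate(self.tokens)})

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad_index(self) -> int:
        return self.index[PAD_TOKEN]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"tokens": list(self.tokens),
                                          "max_len": self.max_len}))

    @classmethod
    def from_json(cls, path: str | Path) -> "Vocabulary":
        d = json.loads(Path(path).read_text())
        return cls(tokens=tuple(d["tokens"]), max_len=int(d["max_len"]))


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule: canonical SMILES, token string, padded index sequence."""

    smiles: str
    selfies: str
    tokens: tuple[int, ...]


def build_vocabulary(molecules: Sequence[str]) -> Vocabulary:
    """Build the token alphabet covering a molecule library.

    ``max_len`` is the longest tokenisation observed; token order is
    lexicographic so identical libraries always yield identical vocabularies.
    """
    if not molecules:
        raise CodecError("empty molecule list")
    symbols: set[str] = set()
    max_len = 0
    for smi in molecules:
        toks = tokenize_smiles(smi)
        symbols.update(toks)
        max_len = max(max_len, len(toks))
    return Vocabulary(tokens=tuple(sorted(symbols) + [PAD_TOKEN]), max_len=max_len)


def encode(smiles: str, vocab: Vocabulary) -> MoleculeRecord:
    """Encode a SMILES string as a padded index sequence under ``vocab``."""
    canon = canonical_smiles(smiles)
    toks = tokenize_smiles(canon)
    missing = [t for t in toks if t not in vocab.index]
    if missing:
        raise CodecError(f"out-of-vocabulary symbols {sorted(set(missing))} for {smiles!r}")
    if len(toks) > vocab.max_len:
        raise CodecError(f"tokenisation of {smiles!r} exceeds max_len={vocab.max_len}")
    idx = [vocab.index[t] for t in toks]
    idx += [vocab.pad_index] * (vocab.max_len - len(idx))
    return MoleculeRecord(smiles=canon, selfies="".join(toks), tokens=tuple(idx))


def decode(encoding: np.ndarray, vocab: Vocabulary) -> str:
    """Decode a (relaxed) one-hot matrix to canonical SMILES via row argmax."""
    enc = np.asarray(encoding)
    if enc.shape != (vocab.max_len, len(vocab)):
        raise CodecError(
            f"encoding shape {enc.shape} does not match vocabulary "
            f"({vocab.max_len}, {len(vocab)})")
    toks = [vocab.tokens[i] for i in enc.argmax(axis=1)]
    return detokenize(toks)


def decode_indices(indices: Sequence[int], vocab: Vocabulary) -> str:
    """Decode a padded index sequence to canonical SMILES."""
    return detokenize([vocab.tokens[int(i)] for i in indices])


def to_onehot(record: MoleculeRecord, vocab: Vocabulary) -> np.ndarray:
    """Hard one-hot matrix (max_len x vocabulary size) for a record."""
    out = np.zeros((vocab.max_len, len(vocab)))
    out[np.arange(vocab.max_len), list(record.tokens)] = 1.0
    return out


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_molecule_file(path: str | Path) -> list[str]:
    """Read SMILES from ``.smi`` (one per line) or CSV with a ``smiles`` column."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        if "smiles" not in df.columns:
            raise CodecError(f"{path}: CSV missing required 'smiles' column")
        out = [str(s) for s in df["smiles"]]
    else:
        out = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    if not out:
        raise CodecError(f"{path}: no molecules found")
    return out


def write_molecule_file(smiles: Iterable[str], path: str | Path) -> None:
    path = Path(path)
    smiles = list(smiles)
    if path.suffix.lower() == ".csv":
        pd.DataFrame({"smiles": smiles}).to_csv(path, index=False)
    else:
        path.write_text("\n".join(smiles) + "\n")
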