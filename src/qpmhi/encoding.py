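"""Robust token encoding of molecules for string-level genetic edits.

SMILES is brittle under random edits: most point mutations of a SMILES
string do not parse.  This module provides a SELFIES-style robust
alternative: molecules are encoded as a linear token sequence (atoms with
bond-order prefixes, branch push/pop markers, and relative ring closures),
and the decoder tracks remaining valence so that *any* token sequence
decodes to a chemically valid molecule — tokens that cannot be realized
are capped or skipped rather than failing.  Random insertions, deletions
and substitutions therefore decode to valid structures essentially always,
which is what makes string-space genetic search practical.

The grammar is deliberately small (neutral organic subset: C, N, O, F, P,
S, Cl, Br; single/double/triple bonds; branches; rings closed by relative
back-reference).  Molecules outside the grammar (charges, isotopes,
radicals, exotic elements) fail to encode and are rejected upstream, which
is a normal outcome for a generator operating on drug-like space.
"""

from __future__ import annotations

import re

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = ["encode", "decode", "MUTATION_ALPHABET", "TOKEN_RE"]

_MAX_VALENCE = {"C": 4, "N": 3, "O": 2, "F": 1, "P": 5, "S": 6, "Cl": 1, "Br": 1}
_BOND_ORDER = {"": 1, "=": 2, "#": 3}
_BOND_TYPE = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
}
_ORDER_OF_TYPE = {v: k for k, v in _BOND_TYPE.items()}

#: longest ring back-reference the encoder may emit
_MAX_RING_BACK = 24

TOKEN_RE = re.compile(
    r"\[(?P<bond>[=#]?)(?:(?P<elem>C|N|O|F|P|S|Cl|Br)|Ring(?P<ring>\d+))\]|\[(?P<ctrl>Branch|Pop)\]"
)

#: alphabet used for random substitutions/insertions in the GA
MUTATION_ALPHABET = (
    ["[C]", "[C]", "[C]", "[N]", "[O]", "[F]", "[S]", "[Cl]", "[Br]", "[P]"]
    + ["[=C]", "[=N]", "[=O]", "[#C]", "[#N]", "[=S]"]
    + ["[Branch]", "[Pop]"]
    + [f"[Ring{k}]" for k in (2, 3, 4, 5)]
    + ["[=Ring2]", "[=Ring3]"]
)


def tokenize(s: str) -> list[str]:
    """Split an encoded string into tokens; raises on malformed input."""
    tokens, pos = [], 0
    for m in TOKEN_RE.finditer(s):
        if m.start() != pos:
            raise ValueError(f"malformed token stream at position {pos}: {s!r}")
        tokens.append(m.group(0))
        pos = m.end()
    if pos != len(s):
        raise ValueError(f"trailing garbage in token stream: {s[pos:]!r}")
    return tokens


def _parse_token(tok: str):
    m = TOKEN_RE.fullmatch(tok)
    if m is None:
        raise ValueError(f"bad token {tok!r}")
    if m.group("ctrl"):
        return ("ctrl", m.group("ctrl"), 0)
    order = _BOND_ORDER[m.group("bond") or ""]
    if m.group("ring"):
        return ("ring", int(m.group("ring")), order)
    return ("atom", m.group("elem"), order)


def decode(tokens) -> str | None:
    """Decode a token sequence to a canonical SMILES string.

    Valence is tracked while building the graph: bond orders are capped to
    the free valence of both endpoints, and unrealizable tokens are
    skipped, so arbitrary sequences decode to valid molecules.  Returns
    None only for sequences that produce no atoms at all or that fail
    RDKit sanitization (rare corner cases such as nitrogen hypervalence
    interactions are caught rather than propagated).
    """
    if isinstance(tokens, str):
        tokens = tokenize(tokens)
    mol = Chem.RWMol()
    free: dict[int, int] = {}
    emitted: list[int] = []  # atom indices in emission order
    stack: list[int] = []
    current: int | None = None

    for tok in tokens:
        kind, payload, order = _parse_token(tok)
        if kind == "ctrl":
            if payload == "Branch":
                if current is not None and free.get(current, 0) >= 2:
                    stack.append(current)
            else:  # Pop
                if stack:
                    current = stack.pop()
            continue
        if kind == "ring":
            k = payload
            if current is None or len(emitted) < k + 1 or k < 1:
                continue
            u = emitted[-1]
            v = emitted[-1 - k]
            if u == v or mol.GetBondBetweenAtoms(u, v) is not None:
                continue
            b = min(order, free.get(u, 0), free.get(v, 0))
            if b < 1:
                continue
            mol.AddBond(u, v, _BOND_TYPE[b])
            free[u] -= b
            free[v] -= b
            continue
        # atom token
        elem = payload
        maxval = _MAX_VALENCE[elem]
        if current is None:
            idx = mol.AddAtom(Chem.Atom(elem))
            free[idx] = maxval
            emitted.append(idx)
            current = idx
            continue
        if free.get(current, 0) < 1:
            # walk back up to an attachment point with free valence
            while stack and free.get(current, 0) < 1:
                current = stack.pop()
            if free.get(current, 0) < 1:
                break  # nothing left to grow from; ignore the rest
        b = min(order, free[current], maxval)
        idx = mol.AddAtom(Chem.Atom(elem))
        mol.AddBond(current, idx, _BOND_TYPE[b])
        free[current] -= b
        free[idx] = maxval - b
        emitted.append(idx)
        current = idx

    if mol.GetNumAtoms() == 0:
        return None
    try:
        out = mol.GetMol()
        Chem.SanitizeMol(out)
        return Chem.MolToSmiles(out)
    except Exception:
        return None


def encode(smiles: str) -> list[str] | None:
    """Encode a SMILES string into the robust token grammar.

    Returns None when the molecule is outside the grammar (charged atoms,
    isotopes, radicals, unsupported elements, disconnected fragments, or a
    ring closure reaching farther back than the grammar allows).
    Round-trips: ``decode(encode(s))`` is the canonical form of ``s``.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        return None
    if len(Chem.GetMolFrags(mol)) > 1:
        return None
    mol = Chem.Mol(mol)
    try:
        Chem.Kekulize(mol, clearAromaticFlags=True)
    except Exception:
        return None
    for atom in mol.GetAtoms():
        if (
            atom.GetSymbol() not in _MAX_VALENCE
            or atom.GetFormalCharge() != 0
            or atom.GetIsotope() != 0
            or atom.GetNumRadicalElectrons() != 0
        ):
            return None
    for bond in mol.GetBonds():
        if bond.GetBondType() not in _ORDER_OF_TYPE:
            return None

    tokens: list[str] = []
    emit_pos: dict[int, int] = {}
    visited: set[int] = set()
    ring_done: set[frozenset] = set()
    prefix = {1: "", 2: "=", 3: "#"}
    counter = [0]

    def dfs(u: int, bond_in: int) -> bool:
        visited.add(u)
        tokens.append(f"[{prefix[bond_in]}{mol.GetAtomWithIdx(u).GetSymbol()}]" if bond_in else f"[{mol.GetAtomWithIdx(u).GetSymbol()}]")
        emit_pos[u] = counter[0]
        counter[0] += 1
        # close any back edges from u to already-emitted atoms (tree edges
        # are in ring_done already, so only genuine ring closures remain)
        for bond in mol.GetAtomWithIdx(u).GetBonds():
            v = bond.GetOtherAtomIdx(u)
            key = frozenset((u, v))
            if v in visited and key not in ring_done:
                k = emit_pos[u] - emit_pos[v]
                if k > _MAX_RING_BACK:
                    return False
                order = _ORDER_OF_TYPE[bond.GetBondType()]
                tokens.append(f"[{prefix[order]}Ring{k}]")
                ring_done.add(key)
        children = [
            b.GetOtherAtomIdx(u)
            for b in mol.GetAtomWithIdx(u).GetBonds()
            if b.GetOtherAtomIdx(u) not in visited
        ]
        for i, v in enumerate(children):
            if v in visited:
                continue  # became visited via an intervening path? (acyclic DFS: no)
            order = _ORDER_OF_TYPE[mol.GetBondBetweenAtoms(u, v).GetBondType()]
            last = i == len(children) - 1
            if not last:
                tokens.append("[Branch]")
            ring_done.add(frozenset((u, v)))  # tree edge, not a ring closure
            if not dfs(v, order):
                return False
            if not last:
                tokens.append("[Pop]")
        return True

    if not dfs(0, 0):
        return None
    return tokens
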