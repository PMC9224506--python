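"""Molecular attribute extraction: the feature alphabet of the optimal descriptor.

Four attribute families are extracted from a molecule:

* **S / SS / SSS** — SMILES n-grams of one, two or three adjacent tokens.
  Two- and three-token windows are normalized against their reversal so a
  string and its mirror yield identical keys ("combination", not
  "sequence").
* **EC1–EC3** — element-tagged Morgan extended-connectivity values on the
  hydrogen-suppressed graph: EC0(v) = degree(v), ECk(v) = Σ_u∈N(v) ECk−1(u).
* **NNC** — nearest-neighbor codes: an atom's element plus the sorted
  multiset of its neighbors' elements.  The exact legacy code is not
  published; this element+sorted-neighborhood form is this package's
  definition.
* **APP** — atom-pair proportions over the alphabet
  {F, Cl, Br, N, O, S, P, =, #}: for a pair (A, B) present in the molecule,
  one key ``(A.B)..nA.nB`` encoding the joint counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import NamedTuple

from .chem_io import Molecule

__all__ = [
    "AttributeKey",
    "AttributeSet",
    "APP_ALPHABET",
    "GAMMA_PAIRS",
    "DELTA_PAIRS",
    "extract_sequence",
    "extract_ec",
    "extract_nnc",
    "extract_app",
    "extract_all",
]

APP_ALPHABET = ("F", "Cl", "Br", "N", "O", "S", "P", "=", "#")

#: the four chlorine pairs selectable individually (y1–y4 toggles)
GAMMA_PAIRS = (("Cl", "N"), ("Cl", "O"), ("Cl", "S"), ("Cl", "P"))

#: upper triangle of the full pair matrix over the APP alphabet
DELTA_PAIRS = tuple(
    (APP_ALPHABET[i], APP_ALPHABET[j])
    for i in range(len(APP_ALPHABET))
    for j in range(i + 1, len(APP_ALPHABET))
)

_SEQ_FAMILY = {1: "S", 2: "SS", 3: "SSS"}
_SEQ_SEP = "~"


class AttributeKey(NamedTuple):
    family: str  # S, SS, SSS, EC1, EC2, EC3, NNC, APP
    key: str

    def __str__(self) -> str:
        return f"{self.family}|{self.key}"

    @classmethod
    def parse(cls, text: str) -> "AttributeKey":
        family, _, key = text.partition("|")
        return cls(family, key)


@dataclass
class AttributeSet:
    """The multiset of attributes extracted from one molecule."""

    molecule_id: str
    counts: dict[AttributeKey, int]

    def __len__(self) -> int:
        return len(self.counts)

    def keys(self):
        return self.counts.keys()


def extract_sequence(molecule: Molecule, order: int) -> dict[AttributeKey, int]:
    """SMILES n-gram attributes of the given order (1, 2 or 3).

    Windows of two or three adjacent tokens are canonically oriented: the
    window is compared with its reversal and the lexicographically smaller
    kept, so "CCO" and "OCC" produce identical keys.
    """
    if order not in (1, 2, 3):
        raise ValueError(f"sequence order must be 1, 2 or 3, got {order}")
    fam = _SEQ_FAMILY[order]
    tokens = molecule.tokens
    counts: Counter[AttributeKey] = Counter()
    if order == 1:
        for tok in tokens:
            counts[AttributeKey(fam, tok)] += 1
    else:
        for i in range(len(tokens) - order + 1):
            window = tuple(tokens[i : i + order])
            window = min(window, tuple(reversed(window)))
            counts[AttributeKey(fam, _SEQ_SEP.join(window))] += 1
    return dict(counts)


def extract_ec(molecule: Molecule, order: int) -> dict[AttributeKey, int]:
    """Element-tagged Morgan extended-connectivity attributes of order 1–3."""
    if order not in (1, 2, 3):
        raise ValueError(f"EC order must be 1, 2 or 3, got {order}")
    adj = molecule.adjacency()
    ec = [len(nbrs) for nbrs in adj]  # EC0 = degree
    for _ in range(order):
        ec = [sum(ec[u] for u in adj[v]) for v in range(len(adj))]
    counts: Counter[AttributeKey] = Counter()
    for v, elem in enumerate(molecule.vertices):
        counts[AttributeKey(f"EC{order}", f"{elem}/EC{order}={ec[v]}")] += 1
    return dict(counts)


def extract_nnc(molecule: Molecule) -> dict[AttributeKey, int]:
    """Nearest-neighbor codes: element plus sorted neighbor-element multiset."""
    adj = molecule.adjacency()
    counts: Counter[AttributeKey] = Counter()
    for v, elem in enumerate(molecule.vertices):
        nbrs = ",".join(sorted(molecule.vertices[u] for u in adj[v]))
        counts[AttributeKey("NNC", f"{elem}/N[{nbrs}]")] += 1
    return dict(counts)


def extract_app(
    molecule: Molecule, pairs: tuple[tuple[str, str], ...]
) -> dict[AttributeKey, int]:
    """Atom-pair-proportion keys for the requested symbol pairs.

    For each pair (A, B) with both counts ≥ 1 exactly one key
    ``(A.B)..count(A).count(B)`` is emitted (multiplicity 1); pairs with
    either count zero emit nothing.
    """
    out: dict[AttributeKey, int] = {}
    for a, b in pairs:
        if a not in APP_ALPHABET or b not in APP_ALPHABET:
            raise ValueError(f"APP symbols must be in {APP_ALPHABET}, got ({a}, {b})")
        na = molecule.counts.get(a, 0)
        nb = molecule.counts.get(b, 0)
        if na >= 1 and nb >= 1:
            out[AttributeKey("APP", f"({a}.{b})..{na}.{nb}")] = 1
    return out


def extract_all(molecule: Molecule, config, molecule_id: str = "") -> AttributeSet:
    """Extract the union of attribute families enabled by a model config.

    α contributes S/SS/SSS per the x1–x3 toggles; β contributes EC1–EC3 and
    NNC; γ contributes the chlorine APP pairs per y1–y4; δ contributes APP
    over every unordered pair of the full alphabet.  A key produced by both
    γ and δ appears once here — its double weight is applied when the
    descriptor is summed.
    """
    counts: dict[AttributeKey, int] = {}
    if config.alpha:
        for order, toggle in ((1, config.x1), (2, config.x2), (3, config.x3)):
            if toggle and len(molecule.tokens) >= order:
                counts.update(extract_sequence(molecule, order))
    if config.beta:
        for order in (1, 2, 3):
            counts.update(extract_ec(molecule, order))
        counts.update(extract_nnc(molecule))
    app_pairs: list[tuple[str, str]] = []
    if config.gamma:
        toggles = (config.y1, config.y2, config.y3, config.y4)
        app_pairs.extend(p for p, t in zip(GAMMA_PAIRS, toggles) if t)
    if config.delta:
        app_pairs.extend(p for p in DELTA_PAIRS if p not in app_pairs)
    if app_pairs:
        counts.update(extract_app(molecule, tuple(app_pairs)))
    return AttributeSet(molecule_id=molecule_id, counts=counts)
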