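"""Synthetic SMILES libraries and planted-truth endpoint data.

The generator emulates the shape of curated sub-chronic oral-toxicity
datasets: a few hundred small organic molecules over the elements
{C, F, Cl, Br, N, O, S, P} with double and triple bonds and simple aromatic
rings, labeled on a log10 mg/kg bw/day scale spanning roughly −1 to 4.3.
Labels are planted: a known correlation-weight table is drawn, the true
descriptor computed, and the endpoint generated as an affine function of it
plus Gaussian noise — so training can be judged against a known ground
truth.

Molecules are built as random valence-respecting trees and serialized to
SMILES depth-first, which guarantees syntactic validity and chemical
plausibility without a chemistry toolkit; an occasional phenyl substituent
adds aromatic tokens and rings.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .attributes import AttributeKey, extract_all
from .chem_io import DatasetRecord, build_hsg
from .descriptor import CorrelationWeights, ModelConfig, compute_dcw

__all__ = [
    "PlantedModel",
    "generate_library",
    "plant_and_label",
    "make_ad_challenge",
]

_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 3, "F": 1, "Cl": 1, "Br": 1}
_DEFAULT_ELEMENTS = ("C", "N", "O", "S", "P", "F", "Cl", "Br")
_ELEMENT_WEIGHTS = {"C": 10, "N": 2, "O": 3, "S": 1, "P": 1, "F": 1, "Cl": 2, "Br": 1}
_PHENYL = "c1ccccc1"


@dataclass
class PlantedModel:
    """The ground truth behind a synthetic dataset."""

    true_weights: dict[AttributeKey, float]
    true_c0: float
    true_c1: float
    noise_sigma: float
    seed: int


class _TreeMol:
    def __init__(self):
        self.elements: list[str] = []
        self.children: list[list[tuple[int, int]]] = []  # (child index, bond order)
        self.free: list[int] = []
        self.phenyl: list[bool] = []

    def add_atom(self, elem: str, parent: int | None = None, order: int = 1) -> int:
        idx = len(self.elements)
        self.elements.append(elem)
        self.children.append([])
        self.phenyl.append(elem == "phenyl")
        valence = 1 if elem == "phenyl" else _VALENCE[elem]
        self.free.append(valence - (order if parent is not None else 0))
        if parent is not None:
            self.children[parent].append((idx, order))
            self.free[parent] -= order
        return idx

    def heavy_atoms(self) -> int:
        return sum(6 if p else 1 for p in self.phenyl)

    def serialize(self) -> str:
        bond_sym = {1: "", 2: "=", 3: "#"}

        def emit(idx: int) -> str:
            sym = _PHENYL if self.phenyl[idx] else self.elements[idx]
            parts = [sym]
            kids = self.children[idx]
            for pos, (child, order) in enumerate(kids):
                sub = bond_sym[order] + emit(child)
                if pos < len(kids) - 1:
                    parts.append(f"({sub})")
                else:
                    parts.append(sub)
            return "".join(parts)

        return emit(0)


def _random_molecule(
    rng: random.Random,
    elements: tuple[str, ...],
    target_heavy: int,
    require: str | None = None,
    allow_phenyl: bool = True,
) -> str:
    """Grow a random valence-respecting tree and serialize it.

    ``require`` forces the presence of one alphabet symbol: an element, or
    '=' / '#' to force a double / triple bond.
    """
    weights = [_ELEMENT_WEIGHTS.get(e, 1) for e in elements]
    mol = _TreeMol()
    mol.add_atom("C")
    forced_bond = require if require in ("=", "#") else None
    forced_elem = require if require not in (None, "=", "#") else None

    while mol.heavy_atoms() < target_heavy:
        open_atoms = [i for i, f in enumerate(mol.free) if f >= 1 and not mol.phenyl[i]]
        if not open_atoms:
            break
        parent = rng.choice(open_atoms)
        if forced_bond is not None:
            order = 2 if forced_bond == "=" else 3
            if mol.free[parent] < order:
                # extend with a carbon and retry from the new open atom
                mol.add_atom("C", parent, 1)
                continue
            child_elem = "C" if order == 3 and rng.random() < 0.5 else (
                "N" if order == 3 else rng.choice(["C", "O"])
            )
            mol.add_atom(child_elem, parent, order)
            forced_bond = None
            continue
        if forced_elem is not None:
            if forced_elem in _VALENCE:
                mol.add_atom(forced_elem, parent, 1)
                forced_elem = None
                continue
        if (
            allow_phenyl
            and mol.heavy_atoms() + 6 <= target_heavy + 2
            and rng.random() < 0.08
        ):
            mol.add_atom("phenyl", parent, 1)
            continue
        elem = rng.choices(elements, weights=weights)[0]
        order = 1
        if elem == "C" and mol.free[parent] >= 2 and rng.random() < 0.12:
            order = 2 if rng.random() < 0.8 else (3 if mol.free[parent] >= 3 else 2)
        elif elem == "O" and mol.free[parent] >= 2 and rng.random() < 0.25:
            order = 2
        elif elem == "N" and mol.free[parent] >= 3 and rng.random() < 0.08:
            order = 3
        mol.add_atom(elem, parent, order)

    if forced_bond is not None or forced_elem is not None:
        # target size reached before the requirement could be placed; force it
        open_atoms = [i for i, f in enumerate(mol.free) if f >= 1 and not mol.phenyl[i]]
        if forced_elem is not None and open_atoms:
            mol.add_atom(forced_elem, rng.choice(open_atoms), 1)
        elif forced_bond is not None:
            order = 2 if forced_bond == "=" else 3
            candidates = [i for i, f in enumerate(mol.free) if f >= order and not mol.phenyl[i]]
            parent = rng.choice(candidates) if candidates else mol.add_atom("C", None)
            if not candidates:
                parent = len(mol.elements) - 1
            mol.add_atom("N" if order == 3 else "O", parent, order)
    return mol.serialize()


def generate_library(
    n: int,
    seed: int = 0,
    elements: tuple[str, ...] = _DEFAULT_ELEMENTS,
    heavy_range: tuple[int, int] = (3, 14),
    max_heavy: int | None = None,
    allow_phenyl: bool = True,
    min_symbol_coverage: int = 5,
) -> list[str]:
    """Generate ``n`` unique, parseable SMILES strings.

    When the full default alphabet is enabled, every symbol of
    {F, Cl, Br, N, O, S, P, =, #} is guaranteed to occur in at least
    ``min_symbol_coverage`` molecules (template-forced in a first pass).
    """
    rng = random.Random(seed)
    lo, hi = heavy_range
    if max_heavy is not None:
        hi = min(hi, max_heavy)
        lo = min(lo, hi)
        allow_phenyl = allow_phenyl and max_heavy >= 7
    requirements: list[str | None] = []
    forced = [s for s in ("F", "Cl", "Br", "N", "O", "S", "P", "=", "#") if s in elements or s in ("=", "#")]
    if min_symbol_coverage > 0 and n >= len(forced) * min_symbol_coverage:
        for sym in forced:
            requirements.extend([sym] * min_symbol_coverage)
    while len(requirements) < n:
        requirements.append(None)
    requirements = requirements[:n]

    library: list[str] = []
    seen: set[str] = set()
    for require in requirements:
        for attempt in range(500):
            target = rng.randint(lo, hi)
            smi = _random_molecule(
                rng, elements, target, require=require, allow_phenyl=allow_phenyl
            )
            if max_heavy is not None and len(build_hsg(smi).vertices) > max_heavy:
                continue
            if smi not in seen:
                seen.add(smi)
                library.append(smi)
                break
        else:
            raise RuntimeError(
                f"could not generate a fresh molecule (n={n}, require={require})"
            )
    return library


def plant_and_label(
    library: list[str],
    config: ModelConfig,
    noise_sigma: float = 0.0,
    seed: int = 0,
    value_range: tuple[float, float] = (-1.0, 4.3),
    paired: bool = False,
    endpoint_label: str = "NOAEL",
) -> tuple[list[DatasetRecord], PlantedModel]:
    """Label a library with a planted linear model of a known descriptor.

    True correlation weights are drawn uniformly in [0.5, 2.5] for every
    feature present in the library; the affine scale (true_c0, true_c1) maps
    the true-descriptor range onto ``value_range`` (the span of curated
    log-scale endpoint tables); Gaussian noise with ``noise_sigma`` is
    added.  In paired mode a complementary LOAEL value ≥ the NOAEL is
    emitted as ``value2``.
    """
    rng = random.Random(seed)
    attr_sets = [extract_all(build_hsg(smi), config, molecule_id=str(i)) for i, smi in enumerate(library)]
    keys = sorted({k for attrs in attr_sets for k in attrs.counts}, key=lambda k: (k.family, k.key))
    if not keys:
        raise ValueError("the library yields no attributes under this config")
    true_weights = {k: rng.uniform(0.5, 2.5) for k in keys}
    cw = CorrelationWeights(weights=true_weights)
    dcw = [compute_dcw(attrs, cw, config) for attrs in attr_sets]
    dmin, dmax = min(dcw), max(dcw)
    if dmax <= dmin:
        raise ValueError("planted descriptor is constant on this library")
    lo, hi = value_range
    c1 = (hi - lo) / (dmax - dmin)
    c0 = lo - c1 * dmin
    records = []
    for i, (smi, d) in enumerate(zip(library, dcw)):
        value = c0 + c1 * d + rng.gauss(0.0, noise_sigma)
        value2 = value + rng.uniform(0.05, 0.5) if paired else None
        if paired and endpoint_label == "LOAEL":
            value, value2 = value2, value
        records.append(
            DatasetRecord(
                id=str(i),
                cas="",
                smiles=smi,
                value=value,
                endpoint_label=endpoint_label,
                value2=value2,
            )
        )
    planted = PlantedModel(
        true_weights=true_weights,
        true_c0=c0,
        true_c1=c1,
        noise_sigma=noise_sigma,
        seed=seed,
    )
    return records, planted


def make_ad_challenge(
    seed: int = 0, n_train: int = 120, n_challenge: int = 30
) -> tuple[list[str], list[str]]:
    """A domain-shift pair: halogen-free train-like set vs perhalogenated set.

    Every challenge molecule carries halogen features absent from the
    train-like set, so its statistical SMILES defect is guaranteed to see
    unseen attributes.
    """
    train_like = generate_library(
        n_train, seed=seed, elements=("C", "N", "O", "S", "P"), min_symbol_coverage=0
    )
    rng = random.Random(seed + 1)
    challenge: list[str] = []
    seen: set[str] = set()
    while len(challenge) < n_challenge:
        length = rng.randint(1, 4)
        atoms = []
        for i in range(length):
            backbone = 2 if 0 < i < length - 1 else (1 if length > 1 else 0)
            halos = [rng.choice(["F", "Cl", "Br"]) for _ in range(4 - backbone)]
            atoms.append(halos)
        parts = []
        for i, halos in enumerate(atoms):
            is_first = i == 0
            is_last = i == length - 1
            if is_first:
                prefix, rest = halos[0], halos[1:]
            else:
                prefix, rest = "", halos
            if is_last and rest:
                branches, tail = rest[:-1], rest[-1]
            else:
                branches, tail = rest, ""
            parts.append(prefix + "C" + "".join(f"({h})" for h in branches) + tail)
        smi = "".join(parts)
        if smi not in seen:
            try:
                build_hsg(smi)
            except ValueError:  # pragma: no cover - templates are valid
                continue
            seen.add(smi)
            challenge.append(smi)
    return train_like, challenge
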