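"""Dataset curation, SMILES tokenization and hydrogen-suppressed molecular graphs.

The models operate on two synchronized views of a chemical: the raw SMILES
token stream (string attributes) and the hydrogen-suppressed molecular graph
(HSG; graph attributes).  Both are built here without a chemistry toolkit —
the attribute alphabet is defined on tokens and adjacency, not on perceived
chemistry, so a light parser over a Daylight-style SMILES subset suffices.
Stereo markers (``/``, ``\\``, ``@``) are kept as tokens but carry no graph
semantics.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "MalformedSmilesError",
    "DatasetParseError",
    "DatasetRecord",
    "Molecule",
    "CurationPolicy",
    "tokenize_smiles",
    "build_hsg",
    "read_dataset",
    "curate",
    "write_dataset",
    "write_rejections",
]


class MalformedSmilesError(ValueError):
    """Raised for SMILES the parser cannot interpret; carries the position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


class DatasetParseError(ValueError):
    """Raised for unreadable dataset files; names the offending row."""


# --- SMILES tokenization -------------------------------------------------

_TWO_CHAR = ("Cl", "Br")
_UPPER_ATOMS = set("BCNOSPFI")
_LOWER_ATOMS = set("bcnosp")
_SINGLE_CHARS = set("()=#-:/\\.%") | set("0123456789")
_BRACKET_ELEMENT = re.compile(r"\[(?:\d+)?([A-Z][a-z]?|[a-z])")


def tokenize_smiles(smiles: str) -> list[str]:
    """Split a SMILES string into tokens.

    Two-character element symbols (Cl, Br) and complete bracket atoms
    ``[...]`` are single tokens; ring-closure digits (and ``%nn`` pairs),
    bond symbols and parentheses are their own tokens.  The concatenation of
    the returned tokens reproduces the input exactly.
    """
    if not smiles:
        raise MalformedSmilesError("empty SMILES", 0)
    tokens: list[str] = []
    i, n = 0, len(smiles)
    while i < n:
        ch = smiles[i]
        if ch == "[":
            j = smiles.find("]", i)
            if j < 0:
                raise MalformedSmilesError("unclosed '['", i)
            tokens.append(smiles[i : j + 1])
            i = j + 1
        elif ch == "]":
            raise MalformedSmilesError("unmatched ']'", i)
        elif smiles[i : i + 2] in _TWO_CHAR:
            tokens.append(smiles[i : i + 2])
            i += 2
        elif ch == "%":
            if i + 2 >= n or not smiles[i + 1 : i + 3].isdigit():
                raise MalformedSmilesError("'%' not followed by two digits", i)
            tokens.append(smiles[i : i + 3])
            i += 3
        elif ch in _UPPER_ATOMS or ch in _LOWER_ATOMS or ch in _SINGLE_CHARS:
            tokens.append(ch)
            i += 1
        elif ch == "H":
            # bare explicit hydrogen (rare outside brackets)
            tokens.append(ch)
            i += 1
        else:
            raise MalformedSmilesError(f"unrecognized character {ch!r}", i)
    depth = 0
    pos = 0
    for tok in tokens:
        if tok == "(":
            depth += 1
        elif tok == ")":
            depth -= 1
            if depth < 0:
                raise MalformedSmilesError("unmatched ')'", pos)
        pos += len(tok)
    if depth != 0:
        raise MalformedSmilesError("unclosed '('", len(smiles))
    return tokens


def is_atom_token(token: str) -> bool:
    if token.startswith("["):
        return True
    if token in _TWO_CHAR:
        return True
    return len(token) == 1 and (token in _UPPER_ATOMS or token in _LOWER_ATOMS or token == "H")


def element_of(token: str) -> str:
    """Element symbol of an atom token, case preserved (aromatic stays lowercase).

    For bracket atoms the isotope prefix, charge, chirality and H-count are
    stripped; only the element symbol remains.
    """
    if token.startswith("["):
        m = _BRACKET_ELEMENT.match(token)
        if m is None:
            raise MalformedSmilesError(f"no element in bracket atom {token}", 0)
        return m.group(1)
    return token


# --- Hydrogen-suppressed molecular graph ---------------------------------

_BOND_TOKENS = {"-": 1, "=": 2, "#": 3, ":": "aromatic", "/": 1, "\\": 1}

_APP_ELEMENTS = ("F", "Cl", "Br", "N", "O", "S", "P")


@dataclass
class Molecule:
    """A tokenized SMILES plus its hydrogen-suppressed graph.

    ``vertices`` lists element symbols of non-hydrogen atoms in token order
    (aromatic atoms keep their lowercase symbol).  ``edges`` are
    ``(i, j, order)`` with order in {1, 2, 3, "aromatic"}.  ``counts`` holds
    the occurrence counts of the atom-pair-proportion alphabet
    {F, Cl, Br, N, O, S, P, =, #} ('=' and '#' as bond tokens outside
    brackets; element counts are case-insensitive so aromatic n counts as N).
    """

    smiles: str
    tokens: list[str]
    vertices: list[str]
    edges: list[tuple[int, int, object]]
    counts: dict[str, int]

    @property
    def degrees(self) -> list[int]:
        deg = [0] * len(self.vertices)
        for i, j, _ in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.vertices]
        for i, j, _ in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        return adj


def build_hsg(smiles: str) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule`.

    Explicit hydrogens ([H], [2H]) are dropped.  Ring closures, branches and
    bond orders follow standard SMILES adjacency; a default bond between two
    aromatic atoms is recorded as aromatic.
    """
    tokens = tokenize_smiles(smiles)
    vertices: list[str] = []
    aromatic: list[bool] = []
    edges: list[tuple[int, int, object]] = []
    stack: list[int | None] = []
    ring_open: dict[int, tuple[int, object | None]] = {}
    prev: int | None = None
    pending: object | None = None
    pos = 0
    for tok in tokens:
        if is_atom_token(tok):
            elem = element_of(tok)
            if elem.upper() == "H":
                pending = None
                pos += len(tok)
                continue
            vertices.append(elem)
            aromatic.append(elem[0].islower())
            idx = len(vertices) - 1
            if prev is not None:
                order = pending
                if order is None:
                    order = "aromatic" if (aromatic[prev] and aromatic[idx]) else 1
                edges.append((prev, idx, order))
            prev = idx
            pending = None
        elif tok in _BOND_TOKENS:
            pending = _BOND_TOKENS[tok]
        elif tok == "(":
            stack.append(prev)
        elif tok == ")":
            prev = stack.pop()
            pending = None
        elif tok == ".":
            prev = None
            pending = None
        elif tok.isdigit() or tok.startswith("%"):
            if prev is None:
                raise MalformedSmilesError("ring closure before any atom", pos)
            num = int(tok.lstrip("%"))
            if num in ring_open:
                other, other_pending = ring_open.pop(num)
                if other == prev:
                    raise MalformedSmilesError(f"ring bond {num} closes on itself", pos)
                order = pending if pending is not None else other_pending
                if order is None:
                    order = "aromatic" if (aromatic[other] and aromatic[prev]) else 1
                edges.append((other, prev, order))
            else:
                ring_open[num] = (prev, pending)
            pending = None
        else:  # pragma: no cover - tokenizer admits nothing else
            raise MalformedSmilesError(f"unexpected token {tok!r}", pos)
        pos += len(tok)
    if ring_open:
        raise MalformedSmilesError(
            f"unmatched ring closure digit(s) {sorted(ring_open)}", len(smiles)
        )

    counts: dict[str, int] = {}
    for sym in _APP_ELEMENTS:
        c = sum(1 for v in vertices if v.capitalize() == sym)
        if c:
            counts[sym] = c
    for bond in ("=", "#"):
        c = sum(1 for t in tokens if t == bond)
        if c:
            counts[bond] = c
    return Molecule(smiles=smiles, tokens=tokens, vertices=vertices, edges=edges, counts=counts)


# --- Dataset records and curation ----------------------------------------


@dataclass
class DatasetRecord:
    """One chemical with its endpoint on the log10 mg/kg bw/day scale.

    ``value2`` optionally carries the paired complementary endpoint (the
    LOAEL when ``endpoint_label`` is NOAEL and vice versa), enabling the
    NOAEL ≤ LOAEL consistency filter during curation.
    """

    id: str
    cas: str
    smiles: str
    value: float
    endpoint_label: str = "NOAEL"
    value2: float | None = None


@dataclass
class CurationPolicy:
    """Options controlling :func:`curate`.

    ``value_range`` is the plausible log10 endpoint window (defaults bracket
    the −1 to 4.3 span of curated sub-chronic datasets with margin).
    ``tail_min_count`` > 0 enables the optional histogram-tail trim that
    drops records whose endpoint falls in sparsely populated extreme bins —
    a stand-in policy for removing low-frequency endpoint values, off by
    default.
    """

    element_whitelist: frozenset[str] = frozenset(
        {"C", "H", "O", "N", "S", "P", "F", "Cl", "Br", "I"}
    )
    value_range: tuple[float, float] = (-3.0, 5.0)
    enforce_noael_le_loael: bool = True
    tail_min_count: int = 0
    tail_bins: int = 10


def read_dataset(
    path,
    value_scale: str = "log10",
    endpoint_label: str = "NOAEL",
) -> list[DatasetRecord]:
    """Read a dataset CSV (columns id, cas, smiles, value[, value2]).

    With ``value_scale="linear"`` the endpoint values (mg/kg bw/day) are
    converted to log10; values must then be positive.
    """
    if value_scale not in ("log10", "linear"):
        raise ValueError(f"value_scale must be 'log10' or 'linear', got {value_scale!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["id", "cas", "smiles", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DatasetParseError(f"{path}: missing required column(s) {missing}")
    has_value2 = "value2" in df.columns

    records = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        d = row._asdict()

        def _num(col: str) -> float:
            raw = str(d[col]).strip()
            try:
                v = float(raw)
            except ValueError:
                raise DatasetParseError(
                    f"{path}: row {row_no}: non-numeric {col} {raw!r}"
                ) from None
            if value_scale == "linear":
                if v <= 0:
                    raise DatasetParseError(
                        f"{path}: row {row_no}: non-positive linear {col} {v}"
                    )
                v = math.log10(v)
            return v

        value2 = None
        if has_value2 and str(d["value2"]).strip() != "":
            value2 = _num("value2")
        records.append(
            DatasetRecord(
                id=str(d["id"]).strip(),
                cas=str(d["cas"]).strip(),
                smiles=str(d["smiles"]).strip(),
                value=_num("value"),
                endpoint_label=endpoint_label,
                value2=value2,
            )
        )
    return records


def _molecule_elements(smiles: str) -> set[str]:
    return {
        element_of(tok).capitalize()
        for tok in tokenize_smiles(smiles)
        if is_atom_token(tok)
    }


def curate(
    records: Sequence[DatasetRecord],
    policy: CurationPolicy | None = None,
) -> tuple[list[DatasetRecord], list[tuple[DatasetRecord, str]]]:
    """Apply the dataset curation rules.

    Rejects (with machine-readable reason codes): unparseable SMILES
    (``malformed_smiles``), multi-fragment SMILES — mixtures and salts —
    (``multi_fragment``), structures with elements outside the organic
    whitelist (``non_organic_element``), implausible endpoint values
    (``value_out_of_range``), paired rows violating NOAEL ≤ LOAEL
    (``noael_gt_loael``), and duplicates by CAS — or exact SMILES when CAS is
    empty — keeping the lowest (most conservative) value (``duplicate``).
    The optional histogram-tail trim rejects with ``low_frequency_value``.

    Returns ``(kept, rejected)``; every input record lands in exactly one.
    """
    policy = policy or CurationPolicy()
    rejected: list[tuple[DatasetRecord, str]] = []
    stage: list[DatasetRecord] = []
    for rec in records:
        if not rec.smiles:
            rejected.append((rec, "malformed_smiles"))
            continue
        try:
            tokens = tokenize_smiles(rec.smiles)
        except MalformedSmilesError:
            rejected.append((rec, "malformed_smiles"))
            continue
        if "." in tokens:
            rejected.append((rec, "multi_fragment"))
            continue
        try:
            elements = _molecule_elements(rec.smiles)
        except MalformedSmilesError:
            rejected.append((rec, "malformed_smiles"))
            continue
        whitelist = {e.capitalize() for e in policy.element_whitelist}
        if not elements <= whitelist:
            rejected.append((rec, "non_organic_element"))
            continue
        lo, hi = policy.value_range
        if not (math.isfinite(rec.value) and lo <= rec.value <= hi):
            rejected.append((rec, "value_out_of_range"))
            continue
        if policy.enforce_noael_le_loael and rec.value2 is not None:
            if rec.endpoint_label == "NOAEL":
                noael, loael = rec.value, rec.value2
            else:
                noael, loael = rec.value2, rec.value
            if noael > loael:
                rejected.append((rec, "noael_gt_loael"))
                continue
        stage.append(rec)

    # duplicate collapse: lowest value wins; ties keep the earliest record
    best: dict[str, int] = {}
    for idx, rec in enumerate(stage):
        key = rec.cas if rec.cas else rec.smiles
        if key not in best or rec.value < stage[best[key]].value:
            best[key] = idx
    keep_idx = set(best.values())
    kept = []
    for idx, rec in enumerate(stage):
        if idx in keep_idx:
            kept.append(rec)
        else:
            rejected.append((rec, "duplicate"))

    if policy.tail_min_count > 0 and kept:
        values = [r.value for r in kept]
        vmin, vmax = min(values), max(values)
        if vmax > vmin:
            nbins = policy.tail_bins
            width = (vmax - vmin) / nbins
            bins = [min(int((v - vmin) / width), nbins - 1) for v in values]
            counts = [0] * nbins
            for b in bins:
                counts[b] += 1
            lo_b = 0
            while lo_b < nbins and 0 < counts[lo_b] < policy.tail_min_count:
                lo_b += 1
            hi_b = nbins - 1
            while hi_b >= 0 and 0 < counts[hi_b] < policy.tail_min_count:
                hi_b -= 1
            trimmed = []
            for rec, b in zip(kept, bins):
                if b < lo_b or b > hi_b:
                    rejected.append((rec, "low_frequency_value"))
                else:
                    trimmed.append(rec)
            kept = trimmed
    return kept, rejected


def write_dataset(records: Iterable[DatasetRecord], path) -> None:
    rows = []
    for r in records:
        row = {"id": r.id, "cas": r.cas, "smiles": r.smiles, "value": r.value}
        if r.value2 is not None:
            row["value2"] = r.value2
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_rejections(rejections: Iterable[tuple[DatasetRecord, str]], path) -> None:
    pd.DataFrame(
        [{"id": r.id, "smiles": r.smiles, "reason": reason} for r, reason in rejections]
    ).to_csv(path, index=False)
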