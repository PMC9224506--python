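"""Correlation-weight storage, the DCW descriptor and the one-variable model.

The model is strictly one-variable:

    endpoint = C0 + C1 · DCW(T, N)

where DCW(T, N) is the sum of learned correlation weights over a molecule's
non-rare features,

    DCW = DCWα + DCWβ + DCWγ + DCWδ

with DCWα = x1·ΣCW(S_k) + x2·ΣCW(SS_k) + x3·ΣCW(SSS_k), DCWβ the EC1–EC3
and NNC sums, DCWγ the y-toggled chlorine atom-pair terms and DCWδ the full
atom-pair matrix.  T is the rare-feature threshold (features seen in fewer
than T active-training compounds are blocked and never contribute) and N the
number of Monte Carlo epochs used to optimize the weights.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .applicability import ADStatistics, in_domain, smiles_defect
from .attributes import AttributeKey, AttributeSet, GAMMA_PAIRS, extract_all
from .chem_io import build_hsg

__all__ = [
    "DegenerateDescriptorError",
    "ModelFileError",
    "ModelConfig",
    "CorrelationWeights",
    "Prediction",
    "TrainedModel",
    "block_rare",
    "key_multiplier",
    "compute_dcw",
    "fit_linear",
    "save_model",
    "load_model",
]

SCHEMA_VERSION = "1"


class DegenerateDescriptorError(ValueError):
    """Raised when the descriptor carries no usable variance."""


class ModelFileError(ValueError):
    """Raised for unreadable or incompatible model files."""


@dataclass(frozen=True)
class ModelConfig:
    """One model recipe: attribute-block toggles and optimizer settings.

    ``alpha``–``delta`` switch the four attribute blocks; ``x1``–``x3``
    select the SMILES n-gram orders inside α; ``y1``–``y4`` select the
    chlorine pairs inside γ.  ``threshold`` (T) is the rare-feature cutoff,
    ``n_epochs`` (N) the Monte Carlo epoch count, ``iic_weight`` /
    ``cii_weight`` the calibration-set correlation-index weights in the
    target function, and ``tf_balance`` the penalty on the active/passive
    correlation gap.  ``proposal_scale`` and ``init_weight`` govern the
    Monte Carlo proposals.
    """

    alpha: int = 1
    beta: int = 0
    gamma: int = 1
    delta: int = 0
    x1: int = 1
    x2: int = 1
    x3: int = 1
    y1: int = 1
    y2: int = 1
    y3: int = 1
    y4: int = 1
    threshold: int = 1
    n_epochs: int = 30
    iic_weight: float = 0.25
    cii_weight: float = 0.30
    tf_balance: float = 0.1
    proposal_scale: float = 0.1
    init_weight: float = 1.0

    def __post_init__(self):
        if not (self.alpha or self.beta or self.gamma or self.delta):
            raise ValueError("at least one attribute block (alpha..delta) must be enabled")
        if self.threshold < 1:
            raise ValueError("threshold T must be a positive integer")
        if self.n_epochs < 1:
            raise ValueError("n_epochs N must be a positive integer")
        for name in ("iic_weight", "cii_weight", "tf_balance", "proposal_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass
class CorrelationWeights:
    """Learned per-feature weights plus the blocked (rare) feature set."""

    weights: dict[AttributeKey, float]
    blocked: frozenset[AttributeKey] = frozenset()

    def __post_init__(self):
        overlap = set(self.weights) & set(self.blocked)
        if overlap:
            raise ValueError(f"blocked keys may not carry weights: {sorted(overlap)[:3]}")


def block_rare(frequency: dict[AttributeKey, int], threshold: int) -> set[AttributeKey]:
    """Features seen in fewer than ``threshold`` active-training compounds.

    Any key absent from the frequency table is additionally treated as
    blocked at prediction time (it cannot carry a weight).
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return {k for k, f in frequency.items() if f < threshold}


def key_multiplier(key: AttributeKey, config: ModelConfig) -> float:
    """Block multiplier of one feature under a config (the x/y toggle algebra).

    An APP pair selected by both γ and δ counts in both blocks, i.e. with
    multiplier 2.
    """
    fam = key.family
    if fam == "S":
        return float(config.alpha * config.x1)
    if fam == "SS":
        return float(config.alpha * config.x2)
    if fam == "SSS":
        return float(config.alpha * config.x3)
    if fam in ("EC1", "EC2", "EC3", "NNC"):
        return float(config.beta)
    if fam == "APP":
        pair = tuple(key.key[1:].split(")")[0].split("."))
        m = 0.0
        if config.gamma:
            toggles = (config.y1, config.y2, config.y3, config.y4)
            for gp, t in zip(GAMMA_PAIRS, toggles):
                if t and pair == gp:
                    m += 1.0
        if config.delta:
            m += 1.0
        return m
    raise ValueError(f"unknown attribute family {fam!r}")


def compute_dcw(
    attrs: AttributeSet, cw: CorrelationWeights, config: ModelConfig
) -> float:
    """Descriptor value: Σ multiplicity × CW × block multiplier over active keys.

    Blocked keys contribute exactly 0; unknown (never-trained) keys also
    contribute 0 — use :func:`dcw_components` to have them reported.
    """
    return dcw_components(attrs, cw, config)[0]


def dcw_components(
    attrs: AttributeSet, cw: CorrelationWeights, config: ModelConfig
) -> tuple[float, list[AttributeKey]]:
    """DCW value plus the list of unknown non-blocked keys (extrapolation signal)."""
    total = 0.0
    unknown: list[AttributeKey] = []
    for key, mult in attrs.counts.items():
        if key in cw.blocked:
            continue
        w = cw.weights.get(key)
        if w is None:
            unknown.append(key)
            continue
        total += mult * w * key_multiplier(key, config)
    return total, unknown


def fit_linear(dcw, y) -> tuple[float, float]:
    """Ordinary least squares of y on the descriptor; returns (c0, c1)."""
    dcw = np.asarray(dcw, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(dcw) < 3:
        raise DegenerateDescriptorError("need at least 3 points for the linear fit")
    xc = dcw - dcw.mean()
    sxx = float(xc @ xc)
    if sxx <= 0.0:
        raise DegenerateDescriptorError("descriptor is constant; cannot calibrate")
    c1 = float(xc @ (y - y.mean())) / sxx
    c0 = float(y.mean() - c1 * dcw.mean())
    return c0, c1


@dataclass
class Prediction:
    value: float
    in_domain: bool
    dcw: float
    defect: float
    unknown_keys: list[AttributeKey] = field(default_factory=list)


@dataclass
class TrainedModel:
    """A complete trained model: weights, calibration line and AD statistics."""

    config: ModelConfig
    cw: CorrelationWeights
    c0: float
    c1: float
    ad_stats: ADStatistics
    freq_active: dict[AttributeKey, int]
    freq_calib: dict[AttributeKey, int]
    seed: int
    provenance: dict = field(default_factory=dict)

    def describe(self, smiles: str) -> Prediction:
        """Predict one SMILES with full applicability-domain detail."""
        molecule = build_hsg(smiles)
        attrs = extract_all(molecule, self.config)
        dcw, unknown = dcw_components(attrs, self.cw, self.config)
        defect = smiles_defect(attrs, self.ad_stats, self.cw.blocked)
        return Prediction(
            value=self.c0 + self.c1 * dcw,
            in_domain=in_domain(attrs, self.ad_stats, self.cw.blocked),
            dcw=dcw,
            defect=defect,
            unknown_keys=unknown,
        )

    def predict(self, smiles: str) -> tuple[float, bool, float]:
        """Predict one SMILES; returns (value, in_domain, dcw)."""
        p = self.describe(smiles)
        return p.value, p.in_domain, p.dcw

    def dcw_of(self, smiles: str) -> float:
        molecule = build_hsg(smiles)
        attrs = extract_all(molecule, self.config)
        return compute_dcw(attrs, self.cw, self.config)


def _key_map_to_json(d: dict) -> dict:
    return {str(k): v for k, v in d.items()}


def _key_map_from_json(d: dict, cast=float) -> dict:
    return {AttributeKey.parse(k): cast(v) for k, v in d.items()}


def save_model(model: TrainedModel, path) -> None:
    """Serialize a trained model to JSON (schema-versioned)."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "config": model.config.as_dict(),
        "weights": _key_map_to_json(model.cw.weights),
        "blocked": sorted(str(k) for k in model.cw.blocked),
        "freq_active": _key_map_to_json(model.freq_active),
        "freq_calib": _key_map_to_json(model.freq_calib),
        "c0": model.c0,
        "c1": model.c1,
        "ad": {
            "p_active": _key_map_to_json(model.ad_stats.p_active),
            "p_calib": _key_map_to_json(model.ad_stats.p_calib),
            "n_active": _key_map_to_json(model.ad_stats.n_active),
            "n_calib": _key_map_to_json(model.ad_stats.n_calib),
            "d_bar": model.ad_stats.d_bar,
            "threshold": model.ad_stats.threshold,
        },
        "seed": model.seed,
        "provenance": model.provenance,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> TrainedModel:
    """Load a model saved by :func:`save_model`; round-trips bit-for-bit."""
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except (json.JSONDecodeError, OSError) as exc:
        raise ModelFileError(f"unreadable model file {path}: {exc}") from exc
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ModelFileError(
            f"model schema version {version!r} not supported (expected {SCHEMA_VERSION!r})"
        )
    try:
        ad = payload["ad"]
        return TrainedModel(
            config=ModelConfig.from_dict(payload["config"]),
            cw=CorrelationWeights(
                weights=_key_map_from_json(payload["weights"]),
                blocked=frozenset(AttributeKey.parse(k) for k in payload["blocked"]),
            ),
            c0=float(payload["c0"]),
            c1=float(payload["c1"]),
            ad_stats=ADStatistics(
                p_active=_key_map_from_json(ad["p_active"]),
                p_calib=_key_map_from_json(ad["p_calib"]),
                n_active=_key_map_from_json(ad["n_active"], int),
                n_calib=_key_map_from_json(ad["n_calib"], int),
                d_bar=float(ad["d_bar"]),
                threshold=float(ad["threshold"]),
            ),
            freq_active=_key_map_from_json(payload["freq_active"], int),
            freq_calib=_key_map_from_json(payload["freq_calib"], int),
            seed=int(payload["seed"]),
            provenance=payload.get("provenance", {}),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFileError(f"malformed model file {path}: {exc}") from exc
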