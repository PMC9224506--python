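"""Named model recipes for the eight published NOAEL/LOAEL endpoints.

Each preset encodes one endpoint's attribute-block toggles, target-function
weights and selected (T*, N*): the general systemic models, and the
organ-specific kidney, brain and liver models.
"""

from __future__ import annotations

from .descriptor import ModelConfig

__all__ = ["PRESETS", "get_preset"]

PRESETS: dict[str, ModelConfig] = {
    "general-noael": ModelConfig(
        alpha=1, beta=0, gamma=1, delta=0, x1=1, x2=1, x3=1,
        y1=1, y2=1, y3=1, y4=1, iic_weight=0.25, cii_weight=0.30,
        threshold=1, n_epochs=30,
    ),
    "general-loael": ModelConfig(
        alpha=1, beta=0, gamma=1, delta=0, x1=1, x2=1, x3=1,
        y1=1, y2=1, y3=1, y4=1, iic_weight=0.20, cii_weight=0.0,
        threshold=1, n_epochs=30,
    ),
    "kidney-noael": ModelConfig(
        alpha=1, beta=0, gamma=1, delta=0, x1=1, x2=1, x3=1,
        y1=1, y2=1, y3=0, y4=0, iic_weight=0.25, cii_weight=0.0,
        threshold=1, n_epochs=10,
    ),
    "kidney-loael": ModelConfig(
        alpha=1, beta=0, gamma=0, delta=0, x1=1, x2=1, x3=1,
        y1=0, y2=0, y3=0, y4=0, iic_weight=0.20, cii_weight=0.0,
        threshold=1, n_epochs=10,
    ),
    "brain-noael": ModelConfig(
        alpha=1, beta=0, gamma=0, delta=1, x1=1, x2=0, x3=0,
        y1=0, y2=0, y3=0, y4=0, iic_weight=0.50, cii_weight=0.0,
        threshold=1, n_epochs=33,
    ),
    "brain-loael": ModelConfig(
        alpha=1, beta=0, gamma=0, delta=0, x1=1, x2=1, x3=0,
        y1=0, y2=0, y3=0, y4=0, iic_weight=0.20, cii_weight=0.0,
        threshold=1, n_epochs=4,
    ),
    "liver-noael": ModelConfig(
        alpha=1, beta=1, gamma=0, delta=0, x1=1, x2=1, x3=1,
        y1=0, y2=0, y3=0, y4=0, iic_weight=0.15, cii_weight=0.0,
        threshold=2, n_epochs=15,
    ),
    "liver-loael": ModelConfig(
        alpha=1, beta=1, gamma=0, delta=0, x1=1, x2=1, x3=1,
        y1=0, y2=0, y3=0, y4=0, iic_weight=0.25, cii_weight=0.0,
        threshold=2, n_epochs=14,
    ),
}


def get_preset(name: str) -> ModelConfig:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
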