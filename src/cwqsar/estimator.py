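"""Scikit-learn style front end for the correlation-weight QSAR model."""

from __future__ import annotations

import numbers

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .chem_io import DatasetRecord
from .descriptor import ModelConfig
from .optimizer import split_dataset, train

__all__ = ["CorrelationWeightRegressor"]


class CorrelationWeightRegressor(RegressorMixin, BaseEstimator):
    """One-variable QSAR regressor on a Monte Carlo optimal descriptor.

    ``X`` is a sequence of SMILES strings; ``y`` the endpoint on a log10
    scale.  ``fit`` splits the data into active-training, passive-training,
    calibration and validation subsets, optimizes per-feature correlation
    weights by Monte Carlo against a target function combining the
    training-set correlations with the calibration-set index of ideality of
    correlation (IIC) and correlation intensity index (CII), and calibrates
    the final line ``endpoint = c0_ + c1_ · DCW``.

    Parameters mirror the model-recipe fields: the attribute-block toggles
    ``alpha``–``delta``, the SMILES n-gram orders ``x1``–``x3``, the
    chlorine-pair toggles ``y1``–``y4``, the rare-feature threshold ``T``,
    the epoch count ``n_epochs``, and the target-function weights.  The
    defaults correspond to a general systemic-toxicity recipe (α and γ
    blocks, all n-gram orders, IIC weight 0.25, CII weight 0.30, T=1,
    N=30).

    Attributes set by ``fit`` (trailing underscore): ``model_`` (the full
    trained model, serializable), ``c0_``, ``c1_``, ``weights_``,
    ``blocked_``, ``split_``, ``ad_threshold_``.
    """

    def __init__(
        self,
        alpha: int = 1,
        beta: int = 0,
        gamma: int = 1,
        delta: int = 0,
        x1: int = 1,
        x2: int = 1,
        x3: int = 1,
        y1: int = 1,
        y2: int = 1,
        y3: int = 1,
        y4: int = 1,
        T: int = 1,
        n_epochs: int = 30,
        iic_weight: float = 0.25,
        cii_weight: float = 0.30,
        tf_balance: float = 0.1,
        proposal_scale: float = 0.1,
        init_weight: float = 1.0,
        fractions: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
        random_state: int = 0,
    ):
        self.alpha = alpha
        self.beta = beta
        self.gamma = gamma
        self.delta = delta
        self.x1 = x1
        self.x2 = x2
        self.x3 = x3
        self.y1 = y1
        self.y2 = y2
        self.y3 = y3
        self.y4 = y4
        self.T = T
        self.n_epochs = n_epochs
        self.iic_weight = iic_weight
        self.cii_weight = cii_weight
        self.tf_balance = tf_balance
        self.proposal_scale = proposal_scale
        self.init_weight = init_weight
        self.fractions = fractions
        self.random_state = random_state

    def _config(self) -> ModelConfig:
        return ModelConfig(
            alpha=self.alpha,
            beta=self.beta,
            gamma=self.gamma,
            delta=self.delta,
            x1=self.x1,
            x2=self.x2,
            x3=self.x3,
            y1=self.y1,
            y2=self.y2,
            y3=self.y3,
            y4=self.y4,
            threshold=self.T,
            n_epochs=self.n_epochs,
            iic_weight=self.iic_weight,
            cii_weight=self.cii_weight,
            tf_balance=self.tf_balance,
            proposal_scale=self.proposal_scale,
            init_weight=self.init_weight,
        )

    @staticmethod
    def _validate_X(X) -> list[str]:
        smiles = list(X)
        if not smiles or not all(isinstance(s, str) and s for s in smiles):
            raise ValueError("X must be a non-empty sequence of SMILES strings")
        return smiles

    def fit(self, X, y):
        smiles = self._validate_X(X)
        y = np.asarray(y, dtype=float)
        if len(y) != len(smiles):
            raise ValueError(f"X has {len(smiles)} rows but y has {len(y)}")
        if not all(isinstance(v, numbers.Real) and np.isfinite(v) for v in y):
            raise ValueError("y must contain finite numbers")
        records = [
            DatasetRecord(id=str(i), cas="", smiles=s, value=float(v))
            for i, (s, v) in enumerate(zip(smiles, y))
        ]
        self.split_ = split_dataset(
            records, fractions=tuple(self.fractions), seed=self.random_state
        )
        self.model_ = train(self.split_, self._config(), seed=self.random_state)
        self.c0_ = self.model_.c0
        self.c1_ = self.model_.c1
        self.weights_ = dict(self.model_.cw.weights)
        self.blocked_ = set(self.model_.cw.blocked)
        self.ad_threshold_ = self.model_.ad_stats.threshold
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        smiles = self._validate_X(X)
        return np.array([self.model_.describe(s).value for s in smiles])

    def decision_path_frame(self, X) -> pd.DataFrame:
        """Per-molecule detail: dcw, prediction, defect, threshold, in_domain."""
        check_is_fitted(self, "model_")
        rows = []
        for s in self._validate_X(X):
            p = self.model_.describe(s)
            rows.append(
                {
                    "smiles": s,
                    "dcw": p.dcw,
                    "prediction": p.value,
                    "defect": p.defect,
                    "threshold": self.ad_threshold_,
                    "in_domain": p.in_domain,
                }
            )
        return pd.DataFrame(rows)
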