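"""Monte Carlo optimization of correlation weights.

The dataset is split into four disjoint subsets with distinct roles:

* **active training** — drives the weight updates (the target function
  rewards correlation between DCW and the endpoint here);
* **passive training** — monitors whether the weights generalize to
  similar compounds (enters the target function only through its
  correlation term);
* **calibration** — detects overtraining: the IIC and CII terms of the
  target function are computed here, and the per-epoch snapshot with the
  best calibration R² is the one kept;
* **validation** — never touched during training; used only for the final
  external evaluation.

The target function is

    TF = r_AT + r_PT − tf_balance·|r_AT − r_PT| + IIC_w·IIC_C + CII_w·CII_C

with r the Pearson correlation between DCW and the endpoint on the
active/passive training sets.  One epoch visits every active feature once
in seeded random order, proposing CW ← CW + u with u ~ U(−s, +s)
(s = ``proposal_scale``) and accepting only proposals that strictly
increase TF — so the accepted-move TF trace is non-decreasing by
construction, and a run is bit-reproducible from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .applicability import build_ad_statistics
from .attributes import AttributeKey, AttributeSet, extract_all
from .chem_io import DatasetRecord, build_hsg
from .descriptor import (
    CorrelationWeights,
    DegenerateDescriptorError,
    ModelConfig,
    TrainedModel,
    block_rare,
    fit_linear,
    key_multiplier,
)
from .metrics import cii as cii_metric
from .metrics import iic as iic_metric

__all__ = [
    "SplitDataset",
    "TargetFunctionReport",
    "split_dataset",
    "combine_tf",
    "target_function",
    "train",
    "select_hyperparams",
]


@dataclass
class SplitDataset:
    """The four disjoint subsets of one modeling run."""

    active_training: list[DatasetRecord]
    passive_training: list[DatasetRecord]
    calibration: list[DatasetRecord]
    validation: list[DatasetRecord]
    seed: int = 0

    @property
    def sizes(self) -> tuple[int, int, int, int]:
        return (
            len(self.active_training),
            len(self.passive_training),
            len(self.calibration),
            len(self.validation),
        )

    def subsets(self) -> dict[str, list[DatasetRecord]]:
        return {
            "active_training": self.active_training,
            "passive_training": self.passive_training,
            "calibration": self.calibration,
            "validation": self.validation,
        }


@dataclass
class TargetFunctionReport:
    r_at: float
    r_pt: float
    iic_c: float
    cii_c: float
    tf: float


def split_dataset(
    records: Sequence[DatasetRecord],
    fractions: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
) -> SplitDataset:
    """Uniform random four-way partition under a seed.

    The first three subset sizes are ⌊n·f⌋; the remainder goes to the
    validation set (so equal quarters of 561 records give 140/140/140/141).
    """
    if len(fractions) != 4:
        raise ValueError("exactly four fractions are required")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    n = len(records)
    if n < 12:
        raise ValueError(f"need at least 12 records to split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n1 = int(n * fractions[0])
    n2 = int(n * fractions[1])
    n3 = int(n * fractions[2])
    idx_at = order[:n1]
    idx_pt = order[n1 : n1 + n2]
    idx_c = order[n1 + n2 : n1 + n2 + n3]
    idx_v = order[n1 + n2 + n3 :]
    pick = lambda idx: [records[i] for i in idx]
    return SplitDataset(
        active_training=pick(idx_at),
        passive_training=pick(idx_pt),
        calibration=pick(idx_c),
        validation=pick(idx_v),
        seed=seed,
    )


def combine_tf(
    r_at: float, r_pt: float, iic_c: float, cii_c: float, config: ModelConfig
) -> float:
    """The target-function arithmetic, exposed for direct testing."""
    return (
        r_at
        + r_pt
        - config.tf_balance * abs(r_at - r_pt)
        + config.iic_weight * iic_c
        + config.cii_weight * cii_c
    )


def _pearson_or_nan(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx <= 0.0 or sy <= 0.0:
        return math.nan
    return float(xc @ yc) / math.sqrt(sx * sy)


class _Workspace:
    """Incidence structures for fast single-weight DCW updates.

    For each active feature j and subset s we precompute the molecules
    containing j and their effective coefficients (multiplicity × block
    multiplier), so a proposal ΔCW_j updates each subset's DCW vector with
    one fancy-indexed add.
    """

    SUBSETS = ("active_training", "passive_training", "calibration", "validation")

    def __init__(self, split: SplitDataset, config: ModelConfig):
        self.config = config
        self.attrs: dict[str, list[AttributeSet]] = {}
        self.y: dict[str, np.ndarray] = {}
        for name, records in split.subsets().items():
            self.attrs[name] = [
                extract_all(build_hsg(r.smiles), config, molecule_id=r.id)
                for r in records
            ]
            self.y[name] = np.array([r.value for r in records], dtype=float)

        freq: dict[AttributeKey, int] = {}
        for attrs in self.attrs["active_training"]:
            for key in attrs.counts:
                freq[key] = freq.get(key, 0) + 1
        self.freq_active = freq
        self.blocked = frozenset(block_rare(freq, config.threshold))
        self.keys = sorted(
            (k for k in freq if k not in self.blocked), key=lambda k: (k.family, k.key)
        )
        if not self.keys:
            raise DegenerateDescriptorError(
                "no active features after rare-feature blocking; lower the threshold T"
            )
        key_index = {k: j for j, k in enumerate(self.keys)}
        self.incidence: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
        for name in self.SUBSETS:
            per_key: list[list[tuple[int, float]]] = [[] for _ in self.keys]
            for mol_i, attrs in enumerate(self.attrs[name]):
                for key, mult in attrs.counts.items():
                    j = key_index.get(key)
                    if j is None:
                        continue
                    coeff = mult * key_multiplier(key, self.config)
                    if coeff != 0.0:
                        per_key[j].append((mol_i, coeff))
            self.incidence[name] = [
                (
                    np.array([i for i, _ in entries], dtype=np.intp),
                    np.array([c for _, c in entries], dtype=float),
                )
                for entries in per_key
            ]

    def dcw_vectors(self, w: np.ndarray) -> dict[str, np.ndarray]:
        out = {}
        for name in self.SUBSETS:
            vec = np.zeros(len(self.attrs[name]))
            for j, (idx, coeff) in enumerate(self.incidence[name]):
                if len(idx):
                    np.add.at(vec, idx, coeff * w[j])
            out[name] = vec
        return out

    # validation DCW is never consulted during optimization, so proposals
    # only touch the three subsets entering the target function
    SHIFT_SUBSETS = ("active_training", "passive_training", "calibration")

    def shift(self, dcw: dict[str, np.ndarray], j: int, delta: float) -> None:
        for name in self.SHIFT_SUBSETS:
            idx, coeff = self.incidence[name][j]
            if len(idx):
                dcw[name][idx] += coeff * delta


def _evaluate_tf(
    ws: _Workspace, dcw: dict[str, np.ndarray], config: ModelConfig, full: bool = False
) -> TargetFunctionReport:
    y_at = ws.y["active_training"]
    y_pt = ws.y["passive_training"]
    d_at = dcw["active_training"]
    d_pt = dcw["passive_training"]
    r_at = _pearson_or_nan(d_at, y_at)
    r_pt = _pearson_or_nan(d_pt, y_pt)
    if math.isnan(r_at) or math.isnan(r_pt):
        return TargetFunctionReport(r_at, r_pt, 0.0, 0.0, -math.inf)
    iic_c = 0.0
    cii_c = 0.0
    d_c = dcw["calibration"]
    y_c = ws.y["calibration"]
    if (config.iic_weight > 0 or full) and len(y_c) >= 3:
        c0, c1 = fit_linear(d_at, y_at)
        yhat_c = c0 + c1 * d_c
        try:
            iic_c = iic_metric(y_c, yhat_c)
        except ValueError:
            iic_c = 0.0
    if (config.cii_weight > 0 or full) and len(y_c) >= 5:
        try:
            cii_c = cii_metric(d_c, y_c)
        except ValueError:
            cii_c = 0.0
    return TargetFunctionReport(
        r_at, r_pt, iic_c, cii_c, combine_tf(r_at, r_pt, iic_c, cii_c, config)
    )


def target_function(
    weights: CorrelationWeights | dict[AttributeKey, float],
    split: SplitDataset,
    config: ModelConfig,
) -> TargetFunctionReport:
    """Evaluate the target function of a given weight table on a split."""
    if isinstance(weights, CorrelationWeights):
        cw = weights
    else:
        cw = CorrelationWeights(weights=dict(weights))
    ws = _Workspace(split, config)
    w = np.array([cw.weights.get(k, 0.0) for k in ws.keys])
    dcw = ws.dcw_vectors(w)
    for name in ("active_training", "passive_training"):
        if np.ptp(dcw[name]) == 0.0:
            raise DegenerateDescriptorError(f"zero-variance DCW on the {name} set")
    return _evaluate_tf(ws, dcw, config, full=True)


def train(split: SplitDataset, config: ModelConfig, seed: int = 0) -> TrainedModel:
    """Run the Monte Carlo weight optimization and calibrate the linear model.

    Weights start at ``config.init_weight`` for every active feature.  For
    ``config.n_epochs`` epochs, features are visited in seeded random order
    with uniform ±``proposal_scale`` proposals accepted only when the target
    function strictly increases.  After each epoch the calibration R² is
    recorded and the best snapshot kept; (C0, C1) are then fitted on the
    active training set with those weights, and the AD statistics attached.
    """
    ws = _Workspace(split, config)
    K = len(ws.keys)
    w = np.full(K, config.init_weight, dtype=float)
    dcw = ws.dcw_vectors(w)
    for name in ("active_training", "passive_training"):
        if np.ptp(dcw[name]) == 0.0:
            raise DegenerateDescriptorError(
                f"zero-variance DCW on the {name} set; enable more attribute "
                "blocks or lower the threshold T"
            )

    rng = np.random.default_rng(seed)
    report = _evaluate_tf(ws, dcw, config)
    tf_cur = report.tf
    accepted_tf: list[float] = [tf_cur]
    epoch_log: list[dict] = []
    best_cal_r2 = -math.inf
    best_w = w.copy()
    best_epoch = 0
    y_c = ws.y["calibration"]

    for epoch in range(1, config.n_epochs + 1):
        for j in rng.permutation(K):
            u = rng.uniform(-config.proposal_scale, config.proposal_scale)
            ws.shift(dcw, j, u)
            cand = _evaluate_tf(ws, dcw, config)
            if cand.tf > tf_cur:
                w[j] += u
                tf_cur = cand.tf
                accepted_tf.append(tf_cur)
            else:
                ws.shift(dcw, j, -u)
        full = _evaluate_tf(ws, dcw, config, full=True)
        r_c = _pearson_or_nan(dcw["calibration"], y_c)
        cal_r2 = r_c**2 if not math.isnan(r_c) else -math.inf
        epoch_log.append(
            {
                "epoch": epoch,
                "tf": full.tf,
                "r_at": full.r_at,
                "r_pt": full.r_pt,
                "iic_c": full.iic_c,
                "cii_c": full.cii_c,
                "cal_r2": cal_r2 if math.isfinite(cal_r2) else float("nan"),
            }
        )
        if cal_r2 > best_cal_r2:
            best_cal_r2 = cal_r2
            best_w = w.copy()
            best_epoch = epoch

    w = best_w
    dcw = ws.dcw_vectors(w)
    c0, c1 = fit_linear(dcw["active_training"], ws.y["active_training"])
    cw = CorrelationWeights(
        weights={k: float(w[j]) for j, k in enumerate(ws.keys)}, blocked=ws.blocked
    )
    freq_calib: dict[AttributeKey, int] = {}
    for attrs in ws.attrs["calibration"]:
        for key in attrs.counts:
            freq_calib[key] = freq_calib.get(key, 0) + 1
    ad_stats = build_ad_statistics(
        ws.attrs["active_training"], ws.attrs["calibration"], ws.blocked
    )
    final = _evaluate_tf(ws, dcw, config, full=True)
    return TrainedModel(
        config=config,
        cw=cw,
        c0=c0,
        c1=c1,
        ad_stats=ad_stats,
        freq_active=ws.freq_active,
        freq_calib=freq_calib,
        seed=seed,
        provenance={
            "subset_sizes": list(split.sizes),
            "n_active_features": K,
            "n_blocked_features": len(ws.blocked),
            "best_epoch": best_epoch,
            "best_calibration_r2": best_cal_r2,
            "final_tf": final.tf,
            "y_active_training": [float(v) for v in ws.y["active_training"]],
            "accepted_tf": accepted_tf,
            "epoch_log": epoch_log,
        },
    )


def calibration_r2(model: TrainedModel, split: SplitDataset) -> float:
    """Squared correlation between DCW and endpoint on the calibration set."""
    d = np.array([model.dcw_of(r.smiles) for r in split.calibration])
    y = np.array([r.value for r in split.calibration])
    r = _pearson_or_nan(d, y)
    return r**2 if not math.isnan(r) else -math.inf


def select_hyperparams(
    records: Sequence[DatasetRecord],
    config: ModelConfig,
    t_values: Sequence[int],
    n_values: Sequence[int],
    seed: int = 0,
    fractions: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> tuple[int, int, TrainedModel]:
    """Grid search for (T*, N*) maximizing calibration R².

    Ties break toward the smaller threshold, then the smaller epoch count.
    """
    if not t_values or not n_values:
        raise ValueError("T and N ranges must be non-empty")
    split = split_dataset(records, fractions=fractions, seed=seed)
    best: tuple[float, int, int, TrainedModel] | None = None
    for t in sorted(t_values):
        for n in sorted(n_values):
            cfg = replace(config, threshold=int(t), n_epochs=int(n))
            try:
                model = train(split, cfg, seed=seed)
            except DegenerateDescriptorError:
                continue
            score = model.provenance["best_calibration_r2"]
            if best is None or score > best[0]:
                best = (score, t, n, model)
    if best is None:
        raise DegenerateDescriptorError("every (T, N) grid cell was degenerate")
    _, t_star, n_star, model = best
    return t_star, n_star, model
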