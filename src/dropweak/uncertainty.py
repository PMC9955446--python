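"""Monte-Carlo predictive inference and uncertainty decomposition.

Keeping the stochastic masks active at test time and repeating the
forward pass T times treats each mask realization as one draw from an
approximate weight posterior. The T per-pass class distributions are
then summarized per sample as

* predictive entropy  H[mean_t p_t]          (total uncertainty),
* aleatoric term      mean_t H[p_t]          (expected per-pass entropy),
* epistemic term      MI = H[mean] - mean H  (mutual information between
  the prediction and the weight configuration; zero iff all passes agree).

All entropies are in nats by default (bounded by ln C); a bits toggle is
provided for reporting. The plug-in entropy of a T-pass average is
biased for small T; a jackknife (leave-one-pass-out) correction
``T*H - (T-1)*mean_j H_(-j)`` is applied to both terms to form the
bias-corrected mutual information.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .rng import substream

__all__ = [
    "MCPredictiveSet",
    "UncertaintyReport",
    "mc_predict",
    "predictive_mean",
    "entropy",
    "decompose_uncertainty",
    "jackknife_entropy",
    "bias_corrected_mi",
    "ph_values",
    "report_to_frame",
    "write_report",
]

_SIMPLEX_TOL = 1e-6


@dataclass
class MCPredictiveSet:
    """T x N x C per-pass class probabilities from T stochastic passes."""

    probs: np.ndarray
    seeds: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 3 or p.shape[0] < 1:
            raise ValueError("probs must be a T x N x C array with T >= 1")
        if np.any(p < -_SIMPLEX_TOL) or np.any(np.abs(p.sum(axis=2) - 1.0) > _SIMPLEX_TOL):
            raise ValueError("each (t, n) row must lie on the probability simplex")
        self.probs = p

    @property
    def n_samples(self) -> int:
        return self.probs.shape[0]


@dataclass
class UncertaintyReport:
    predictive_mean: np.ndarray  # N x C
    predictive_entropy: np.ndarray  # N, nats
    aleatoric: np.ndarray  # N, nats
    epistemic: np.ndarray  # N, nats (clipped at 0)
    epistemic_raw: np.ndarray  # N, unclipped MI (may be ~ -1e-16)
    epistemic_bias_corrected: np.ndarray | None  # N, nats; None when T < 3
    ph_value: np.ndarray  # N, max predictive-mean probability
    unit: str = "nats"


def mc_predict(model, batch: np.ndarray, T: int = 25, seed: int = 0) -> MCPredictiveSet:
    """T stochastic forward passes with independent masks.

    Each pass consumes its own named substream of ``seed``, so the set
    is reproducible pass-for-pass and T=1 equals a single stochastic
    forward on substream 0.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    slices, seeds = [], []
    for t in range(T):
        rng = substream(seed, "mc-pass", t)
        slices.append(model.forward(batch, stochastic=True, rng=rng))
        seeds.append(f"mc-pass[{t}]@{seed}")
    return MCPredictiveSet(np.stack(slices).astype(float), seeds)


def predictive_mean(mc: MCPredictiveSet) -> np.ndarray:
    """Arithmetic mean over passes; rows remain on the simplex."""
    return mc.probs.mean(axis=0)


def entropy(p: np.ndarray, base: str = "nats") -> np.ndarray | float:
    """Shannon entropy with the 0*ln 0 = 0 convention.

    Accepts a single distribution or an array whose last axis is the
    class axis; validates simplex membership.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < -_SIMPLEX_TOL) or np.any(np.abs(arr.sum(axis=-1) - 1.0) > _SIMPLEX_TOL):
        raise ValueError("input must lie on the probability simplex")
    h = -np.sum(np.where(arr > 0, arr * np.log(np.maximum(arr, 1e-300)), 0.0), axis=-1)
    if base == "bits":
        h = h / np.log(2.0)
    elif base != "nats":
        raise ValueError("base must be 'nats' or 'bits'")
    return float(h) if h.ndim == 0 else h


def ph_values(pred_mean: np.ndarray) -> np.ndarray:
    """Probability-of-hit: the maximum class probability per sample."""
    arr = np.asarray(pred_mean, dtype=float)
    if np.any(np.abs(arr.sum(axis=-1) - 1.0) > _SIMPLEX_TOL):
        raise ValueError("rows must lie on the probability simplex")
    return arr.max(axis=-1)


def decompose_uncertainty(mc: MCPredictiveSet, base: str = "nats") -> UncertaintyReport:
    """Split total predictive uncertainty into aleatoric and epistemic.

    The identity predictive_entropy = aleatoric + epistemic holds exactly
    before clipping; by Jensen's inequality the epistemic term is
    non-negative up to floating-point noise, and any tiny negative value
    is clipped to 0 with the raw value retained.
    """
    mean = predictive_mean(mc)
    pred_h = np.asarray(entropy(mean, base=base))
    alea = np.asarray(entropy(mc.probs, base=base)).mean(axis=0)
    raw = pred_h - alea
    bc = bias_corrected_mi(mc, base=base) if mc.n_samples >= 3 else None
    return UncertaintyReport(
        predictive_mean=mean,
        predictive_entropy=pred_h,
        aleatoric=alea,
        epistemic=np.maximum(raw, 0.0),
        epistemic_raw=raw,
        epistemic_bias_corrected=bc,
        ph_value=ph_values(mean),
        unit=base,
    )


def jackknife_entropy(mc: MCPredictiveSet, base: str = "nats") -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-pass-out corrected (predictive entropy, aleatoric term).

    For a statistic S computed on all T passes and S_(-j) on the T-1
    passes excluding pass j, the corrected value is
    T*S - (T-1)*mean_j S_(-j). Applied to H[mean of passes] this removes
    the leading finite-T bias; applied to the aleatoric term (a plain
    mean, hence a linear statistic) it returns the term unchanged.
    """
    if mc.n_samples < 3:
        raise ValueError("jackknife correction requires T >= 3")
    p = mc.probs
    T = mc.n_samples
    full_mean = p.mean(axis=0)
    h_full = np.asarray(entropy(full_mean, base=base))
    loo_means = (full_mean[None] * T - p) / (T - 1)  # T x N x C
    h_loo = np.asarray(entropy(loo_means, base=base))  # T x N
    pred_corrected = T * h_full - (T - 1) * h_loo.mean(axis=0)

    h_pass = np.asarray(entropy(p, base=base))  # T x N
    a_full = h_pass.mean(axis=0)
    a_loo = (a_full[None] * T - h_pass) / (T - 1)
    alea_corrected = T * a_full - (T - 1) * a_loo.mean(axis=0)
    return pred_corrected, alea_corrected


def bias_corrected_mi(mc: MCPredictiveSet, base: str = "nats") -> np.ndarray:
    """Jackknife-corrected mutual information per sample."""
    pred_c, alea_c = jackknife_entropy(mc, base=base)
    return pred_c - alea_c


def report_to_frame(report: UncertaintyReport, sample_ids=None) -> pd.DataFrame:
    n = len(report.predictive_entropy)
    bc = report.epistemic_bias_corrected
    return pd.DataFrame(
        {
            "sample_id": np.arange(n) if sample_ids is None else sample_ids,
            "pred_class": report.predictive_mean.argmax(axis=1),
            "ph": report.ph_value,
            "pred_entropy": report.predictive_entropy,
            "aleatoric": report.aleatoric,
            "epistemic": report.epistemic,
            "epistemic_bc": np.full(n, np.nan) if bc is None else bc,
        }
    )


def write_report(report: UncertaintyReport, out_dir: str | Path, sample_ids=None) -> Path:
    """Per-sample CSV plus a JSON summary with per-class means."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = report_to_frame(report, sample_ids)
    csv_path = out / "uncertainty.csv"
    frame.to_csv(csv_path, index=False)
    summary = {
        "unit": report.unit,
        "n_samples": len(frame),
        "per_class_means": {
            str(c): {
                col: float(frame.loc[frame.pred_class == c, col].mean())
                for col in ("ph", "pred_entropy", "aleatoric", "epistemic", "epistemic_bc")
            }
            for c in sorted(frame.pred_class.unique())
        },
    }
    (out / "uncertainty_summary.json").write_text(json.dumps(summary, indent=1))
    return csv_path
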