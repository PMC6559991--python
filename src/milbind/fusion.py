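"""Bag-level fusion of per-instance class probabilities.

Three fusion rules collapse the (n, 2) instance probability matrix of a
bag into a single two-class distribution:

* ``noisy_and`` — a differentiable MIL pooling that activates the bag
  once the mean instance probability p̄ of a class exceeds a learned
  soft threshold b, with fixed slope a:

      P = (sigma(a*(p̄ - b)) - sigma(-a*b)) / (sigma(a*(1 - b)) - sigma(-a*b))

  The subtraction and the denominator normalise P to [0, 1] for
  b in [0, 1] and a > 0.  b is learned per class; a defaults to 7.5.
* ``max`` — per-class maximum over instances (the classical MIL
  "at least one positive instance" reading).
* ``average`` — per-class mean over instances.

In every case the two per-class fused values are renormalised to a
probability simplex before the loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from . import nn
from .nn import Parameter, Tensor

FUSION_METHODS = ("noisy_and", "max", "average")
DEFAULT_SLOPE = 7.5
_EPS = 1e-8


@dataclass
class FusionParams:
    """Fusion rule plus the Noisy-and slope ``a`` and per-class soft
    thresholds ``b`` (each in [0, 1]; learned during training)."""

    method: str = "noisy_and"
    a: float = DEFAULT_SLOPE
    b: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.5]))

    def __post_init__(self):
        if self.method not in FUSION_METHODS:
            raise ValueError(
                f"unknown fusion method {self.method!r}; "
                f"choose from {FUSION_METHODS}"
            )
        if self.a <= 0:
            raise ValueError(f"noisy-and slope a must be > 0, got {self.a}")
        self.b = np.atleast_1d(np.asarray(self.b, dtype=np.float64))
        if np.any((self.b < 0) | (self.b > 1)):
            raise ValueError("thresholds b must lie in [0, 1]")


def noisy_and(p_bar, a: float = DEFAULT_SLOPE, b=0.5):
    """Noisy-and activation of a mean instance probability.

    Accepts scalars or arrays; strictly increasing in ``p_bar`` on
    [0, 1] with fixed points noisy_and(0)=0 and noisy_and(1)=1.
    """
    if a <= 0:
        raise ValueError(f"slope a must be > 0, got {a}")
    p_bar = np.asarray(p_bar, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    lo = expit(-a * b)
    hi = expit(a * (1.0 - b))
    return (expit(a * (p_bar - b)) - lo) / (hi - lo + _EPS)


def fuse_bag(scores: np.ndarray, params: FusionParams) -> np.ndarray:
    """Fuse an (n, 2) instance-probability matrix to a length-2 simplex
    vector (inference path, NumPy only)."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 2 or scores.shape[0] < 1:
        raise ValueError("scores must be a non-empty (n, 2) matrix")
    if params.method == "noisy_and":
        p_bar = scores.mean(axis=0)
        fused = noisy_and(p_bar, params.a, params.b)
    elif params.method == "max":
        fused = scores.max(axis=0)
    else:  # average
        fused = scores.mean(axis=0)
    return fused / (fused.sum() + _EPS)


class FusionLayer:
    """Differentiable fusion head over batched instance probabilities.

    For Noisy-and the per-class thresholds are stored as unconstrained
    parameters squashed through a logistic sigmoid, so the learned b
    always lies in [0, 1]; they are initialised at the midpoint 0.5 and
    excluded from weight decay.
    """

    def __init__(self, params: FusionParams, n_classes: int = 2):
        self.method = params.method
        self.a = params.a
        b0 = np.broadcast_to(params.b, (n_classes,)).astype(np.float64)
        # inverse-sigmoid parameterisation; clip away exact endpoints
        self.raw_b = Parameter(logit(np.clip(b0, 1e-6, 1 - 1e-6)),
                               decay=False)

    @property
    def b(self) -> np.ndarray:
        return expit(self.raw_b.data)

    def parameters(self) -> dict[str, Parameter]:
        if self.method == "noisy_and":
            return {"fusion.raw_b": self.raw_b}
        return {}

    def forward(self, instance_probs: Tensor) -> Tensor:
        """(B, n, 2) instance probabilities -> (B, 2) bag simplex."""
        if instance_probs.shape[1] < 1:
            raise ValueError("empty bag: at least one instance required")
        if self.method == "max":
            fused = instance_probs.max(axis=1)
        elif self.method == "average":
            fused = instance_probs.mean(axis=1)
        else:
            p_bar = instance_probs.mean(axis=1)          # (B, 2)
            b = nn.sigmoid(self.raw_b)                   # (2,)
            lo = nn.sigmoid(nn.mul(b, -self.a))
            hi = nn.sigmoid(nn.mul(nn.add(nn.mul(b, -1.0), 1.0), self.a))
            num = nn.sigmoid(nn.mul(nn.add(p_bar, nn.mul(b, -1.0)), self.a))
            fused = nn.div(nn.add(num, nn.mul(lo, -1.0)),
                           nn.add(nn.add(hi, nn.mul(lo, -1.0)), _EPS))
        total = nn.add(fused.sum(axis=1, keepdims=True), _EPS)
        return nn.div(fused, total)

    def to_params(self) -> FusionParams:
        return FusionParams(method=self.method, a=self.a, b=self.b)
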