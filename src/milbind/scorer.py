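"""Per-instance scoring networks with shared weights across a bag.

Four architectures are supported, all scoring each instance of a bag
independently (convolution and pooling act along the width axis only):

* ``WSCNNLSTM`` — the weakly supervised hybrid network: convolution
  (16 kernels of width 24) -> ReLU -> max-pool (1, 8) -> dropout ->
  bidirectional LSTM (32 units per direction, read out as the
  concatenated final states of the two directions, 64 features) ->
  dropout -> two-class softmax.  No fully connected layer between the
  recurrent layer and the softmax.
* ``DANQ_LIKE`` — the same stack applied in single-instance mode
  (the whole sequence is one instance; one-hot input).
* ``DEEPBIND_LIKE`` — convolution -> ReLU -> global max-pool -> fully
  connected layer (32) -> dropout -> softmax, single-instance mode.
* ``WSCNN_LIKE`` — the DEEPBIND_LIKE stack applied per instance of a
  bag, followed by a fusion layer.

Weights are initialised with the Glorot uniform scheme; LSTM forget-gate
biases start at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Union

import numpy as np

from . import nn
from .bagcode import BagLayout
from .nn import Parameter, Tensor

GLOBAL = "global"

VARIANTS = ("WSCNNLSTM", "DEEPBIND_LIKE", "DANQ_LIKE", "WSCNN_LIKE")
#: Variants that score bags of overlapping instances (MIL); the others
#: treat the whole sequence as a single instance (SIL).
MIL_VARIANTS = ("WSCNNLSTM", "WSCNN_LIKE")
#: Variants with a recurrent layer after the convolution.
RECURRENT_VARIANTS = ("WSCNNLSTM", "DANQ_LIKE")


class BuildError(ValueError):
    """Raised when a spec is internally inconsistent or incompatible
    with the bag geometry."""


@dataclass(frozen=True)
class ModelSpec:
    """Architecture and hyper-parameters of one scoring network."""

    variant: str = "WSCNNLSTM"
    conv_kernels: int = 16
    conv_width: int = 24
    pool_width: Union[int, str] = 8      # positions, or "global"
    lstm_units: int | None = 32          # per direction
    fc_units: int | None = None
    dropout_ratio: float = 0.5
    softmax_classes: int = 2
    k: int = 1
    weight_decay: float = 5e-4

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise BuildError(f"unknown variant {self.variant!r}")
        if self.variant in RECURRENT_VARIANTS:
            if self.lstm_units is None or self.fc_units is not None \
                    or self.pool_width == GLOBAL:
                raise BuildError(
                    f"{self.variant} requires local pooling + a recurrent "
                    "layer and no fully connected layer"
                )
        else:
            if self.lstm_units is not None or self.fc_units is None \
                    or self.pool_width != GLOBAL:
                raise BuildError(
                    f"{self.variant} requires global pooling + a fully "
                    "connected layer and no recurrent layer"
                )
        if not 0.0 <= self.dropout_ratio < 1.0:
            raise BuildError(
                f"dropout ratio must be in [0, 1), got {self.dropout_ratio}"
            )
        if self.softmax_classes != 2:
            raise BuildError("binary classification: softmax_classes must be 2")

    @classmethod
    def for_variant(cls, variant: str, k: int = 1,
                    dropout_ratio: float = 0.5) -> "ModelSpec":
        """Default hyper-parameters for a named architecture."""
        if variant in RECURRENT_VARIANTS:
            return cls(variant=variant, pool_width=8, lstm_units=32,
                       fc_units=None, k=k, dropout_ratio=dropout_ratio)
        if variant in VARIANTS:
            return cls(variant=variant, pool_width=GLOBAL, lstm_units=None,
                       fc_units=32, k=k, dropout_ratio=dropout_ratio)
        raise BuildError(f"unknown variant {variant!r}")

    @property
    def is_mil(self) -> bool:
        return self.variant in MIL_VARIANTS

    @property
    def is_recurrent(self) -> bool:
        return self.variant in RECURRENT_VARIANTS

    def to_dict(self) -> dict:
        return asdict(self)


class InstanceScorer:
    """The shared-weight network mapping one bag tensor
    (4**k, n, c-k+1) to an (n, 2) matrix of instance probabilities."""

    def __init__(self, spec: ModelSpec, instance_width: int,
                 rng: np.random.Generator):
        self.spec = spec
        self.instance_width = instance_width
        channels = 4 ** spec.k
        conv_out = instance_width - spec.conv_width + 1
        if conv_out < 1:
            raise BuildError(
                f"convolution kernel width {spec.conv_width} exceeds encoded "
                f"instance width {instance_width}"
            )
        p: dict[str, Parameter] = {}
        p["conv.w"] = Parameter(nn.glorot_uniform(
            rng, (spec.conv_kernels, channels, spec.conv_width)))
        p["conv.b"] = Parameter(np.zeros(spec.conv_kernels), decay=False)

        if spec.is_recurrent:
            self.n_steps = conv_out // spec.pool_width
            if self.n_steps < 1:
                raise BuildError(
                    f"pool width {spec.pool_width} exceeds convolution "
                    f"output width {conv_out}"
                )
            h = spec.lstm_units
            for d in ("fwd", "bwd"):
                p[f"lstm.{d}.wx"] = Parameter(nn.glorot_uniform(
                    rng, (spec.conv_kernels, 4 * h)))
                p[f"lstm.{d}.wh"] = Parameter(nn.glorot_uniform(
                    rng, (h, 4 * h)))
                bias = np.zeros(4 * h)
                bias[h: 2 * h] = 1.0  # forget gate opens at init
                p[f"lstm.{d}.b"] = Parameter(bias, decay=False)
            head_in = 2 * h
        else:
            p["fc.w"] = Parameter(nn.glorot_uniform(
                rng, (spec.conv_kernels, spec.fc_units)))
            p["fc.b"] = Parameter(np.zeros(spec.fc_units), decay=False)
            head_in = spec.fc_units

        p["out.w"] = Parameter(nn.glorot_uniform(
            rng, (head_in, spec.softmax_classes)))
        p["out.b"] = Parameter(np.zeros(spec.softmax_classes), decay=False)
        self.params = p

    # -- forward -------------------------------------------------------

    def _lstm_direction(self, steps: list[Tensor], direction: str,
                        n_rows: int) -> Tensor:
        """Run one LSTM direction over the step list; returns the final
        hidden state (n_rows, H)."""
        h_units = self.spec.lstm_units
        wx = self.params[f"lstm.{direction}.wx"]
        wh = self.params[f"lstm.{direction}.wh"]
        b = self.params[f"lstm.{direction}.b"]
        order = steps if direction == "fwd" else steps[::-1]
        h = Tensor(np.zeros((n_rows, h_units)))
        c = Tensor(np.zeros((n_rows, h_units)))
        for x_t in order:
            gates = nn.add(nn.add(nn.matmul(x_t, wx), nn.matmul(h, wh)), b)
            i_g = nn.sigmoid(gates[:, 0 * h_units: 1 * h_units])
            f_g = nn.sigmoid(gates[:, 1 * h_units: 2 * h_units])
            g_g = nn.tanh(gates[:, 2 * h_units: 3 * h_units])
            o_g = nn.sigmoid(gates[:, 3 * h_units: 4 * h_units])
            c = nn.add(nn.mul(f_g, c), nn.mul(i_g, g_g))
            h = nn.mul(o_g, nn.tanh(c))
        return h

    def forward(self, bags: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Score a batch of bags: (B, 4**k, n, w) -> probabilities
        (B, n, 2).  ``train`` enables dropout (requires ``rng``)."""
        if bags.ndim != 4:
            raise BuildError("expected a batched bag tensor (B, C, n, w)")
        batch, channels, n_inst, width = bags.shape
        if width != self.instance_width:
            raise BuildError(
                f"bag width {width} does not match the build-time "
                f"instance width {self.instance_width}"
            )
        if train and rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")
        spec = self.spec
        rows = batch * n_inst
        # (B, C, n, w) -> (B, n, C, w) -> (B*n, C, w): row b*n+j is
        # instance j of bag b
        x = Tensor(np.ascontiguousarray(bags.transpose(0, 2, 1, 3))
                   .reshape(rows, channels, width))
        x = nn.relu(nn.conv1d(x, self.params["conv.w"], self.params["conv.b"]))

        if spec.is_recurrent:
            x = nn.maxpool1d(x, spec.pool_width)          # (rows, F, T)
            x = nn.dropout(x, spec.dropout_ratio, rng, train)
            steps = [x[:, :, t] for t in range(self.n_steps)]
            h_fwd = self._lstm_direction(steps, "fwd", rows)
            h_bwd = self._lstm_direction(steps, "bwd", rows)
            feats = nn.concat([h_fwd, h_bwd], axis=1)     # (rows, 64)
            feats = nn.dropout(feats, spec.dropout_ratio, rng, train)
        else:
            x = nn.global_maxpool1d(x)                    # (rows, F)
            feats = nn.relu(nn.add(nn.matmul(x, self.params["fc.w"]),
                                   self.params["fc.b"]))
            feats = nn.dropout(feats, spec.dropout_ratio, rng, train)

        logits = nn.add(nn.matmul(feats, self.params["out.w"]),
                        self.params["out.b"])
        probs = nn.exp(nn.log_softmax(logits, axis=1))
        return probs.reshape((batch, n_inst, spec.softmax_classes))

    # -- utilities -----------------------------------------------------

    def parameters(self) -> dict[str, Parameter]:
        return dict(self.params)

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    @property
    def feature_dim(self) -> int:
        """Width of the feature vector feeding the softmax (64 for the
        bidirectional recurrent variants)."""
        if self.spec.is_recurrent:
            return 2 * self.spec.lstm_units
        return self.spec.fc_units


def build_scorer(spec: ModelSpec, layout: BagLayout,
                 rng: np.random.Generator | None = None) -> InstanceScorer:
    """Instantiate the scoring network for a bag layout.

    Single-instance variants are built against the whole-sequence
    layout regardless of the segmentation geometry passed in.
    """
    if spec.k != layout.k:
        raise BuildError(
            f"spec k={spec.k} does not match layout k={layout.k}"
        )
    if not spec.is_mil:
        layout = layout.single_instance()
    if rng is None:
        rng = np.random.default_rng()
    return InstanceScorer(spec, layout.instance_width, rng)


def score_instances(scorer: InstanceScorer, bag_tensor: np.ndarray
                    ) -> np.ndarray:
    """Inference-mode scores for one bag: (4**k, n, w) -> (n, 2)."""
    if bag_tensor.ndim != 3:
        raise BuildError("expected a single bag tensor (C, n, w)")
    out = scorer.forward(bag_tensor[None], train=False)
    return out.data[0]
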