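"""The end-to-end bag classifier: encoding layout + instance scorer +
fusion head, with cross-entropy loss, prediction and checkpointing."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import nn
from .bagcode import BagLayout, Sequence, encode_dataset
from .fusion import FusionLayer, FusionParams
from .nn import Parameter, Tensor
from .scorer import InstanceScorer, ModelSpec, build_scorer

_EPS = 1e-8


class BagClassifier:
    """Scores every instance of a bag with a shared network and fuses
    the instance probabilities into one bag-level distribution.

    Single-instance variants (DEEPBIND_LIKE, DANQ_LIKE) use the
    whole-sequence layout — one instance per bag — so the same code path
    covers weakly supervised and fully supervised training.
    """

    def __init__(self, spec: ModelSpec, layout: BagLayout,
                 fusion: FusionParams | None = None,
                 rng: np.random.Generator | None = None):
        if rng is None:
            rng = np.random.default_rng()
        self.spec = spec
        self.layout = layout if spec.is_mil else layout.single_instance()
        self.fusion_params = fusion or FusionParams()
        self.scorer: InstanceScorer = build_scorer(spec, layout, rng)
        self.fusion = FusionLayer(self.fusion_params,
                                  n_classes=spec.softmax_classes)

    # -- data ----------------------------------------------------------

    def encode(self, seqs: list[Sequence]
               ) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Encode sequences with this model's effective layout."""
        return encode_dataset(seqs, self.layout)

    # -- forward / inference -------------------------------------------

    def forward(self, bags: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """(B, 4**k, n, w) -> bag probabilities (B, 2)."""
        instance_probs = self.scorer.forward(bags, train=train, rng=rng)
        return self.fusion.forward(instance_probs)

    def loss(self, bags: np.ndarray, labels: np.ndarray,
             rng: np.random.Generator) -> Tensor:
        """Mean two-class cross-entropy on bag labels (training mode)."""
        probs = self.forward(bags, train=True, rng=rng)
        picked = probs[np.arange(len(labels)), labels]
        return nn.mul(nn.log(nn.add(picked, _EPS)).sum(), -1.0 / len(labels))

    def predict_proba(self, bags: np.ndarray, batch_size: int = 512
                      ) -> np.ndarray:
        """Inference-mode bag probabilities, batched for memory."""
        chunks = [
            self.forward(bags[i: i + batch_size], train=False).data
            for i in range(0, len(bags), batch_size)
        ]
        return np.concatenate(chunks, axis=0)

    def predict(self, bags: np.ndarray) -> np.ndarray:
        """Hard labels by argmax of the bag distribution."""
        return self.predict_proba(bags).argmax(axis=1)

    # -- parameters & checkpoints --------------------------------------

    def parameters(self) -> dict[str, Parameter]:
        params = self.scorer.parameters()
        params.update(self.fusion.parameters())
        return params

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.parameters().items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if set(state) != set(params):
            raise ValueError("checkpoint does not match model parameters")
        for k, p in params.items():
            p.data = state[k].copy()

    def save(self, path: str | Path) -> None:
        """Write weights (.npz) plus a JSON sidecar of the configuration."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.get_state())
        sidecar = {
            "spec": self.spec.to_dict(),
            "layout": {"l": self.layout.l, "c": self.layout.c,
                       "s": self.layout.s, "k": self.layout.k},
            "fusion": {"method": self.fusion.method, "a": self.fusion.a,
                       "b": self.fusion.b.tolist()},
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "BagClassifier":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        spec = ModelSpec(**sidecar["spec"])
        layout = BagLayout(**sidecar["layout"])
        fusion = FusionParams(method=sidecar["fusion"]["method"],
                              a=sidecar["fusion"]["a"],
                              b=np.array(sidecar["fusion"]["b"]))
        model = cls(spec, layout, fusion, rng=np.random.default_rng(0))
        with np.load(path.with_suffix(".npz")) as npz:
            model.set_state({k: npz[k] for k in npz.files})
        return model
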