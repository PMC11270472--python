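"""Trained-model handles and single-file checkpoints.

A handle bundles the network object with everything needed to reproduce its
predictions: the architecture/preprocessing config, the training seed, and the
per-epoch loss history.  Checkpoints are one ``.npz`` file holding every
parameter and batch-norm buffer plus the config as an embedded JSON string.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np

from . import nn


class UntrainedModelError(RuntimeError):
    pass


@dataclass
class ModelHandle:
    kind: str  # "classifier" | "segmenter"
    model: Any
    config: dict
    seed: int
    history: list = field(default_factory=list)
    class_weights: Any = None
    trained: bool = False

    def require_trained(self) -> None:
        if not self.trained:
            raise UntrainedModelError(f"{self.kind} handle has not been trained")

    def save(self, path: str | os.PathLike) -> None:
        leaves = nn.all_leaf_layers(self.model.layers)
        state = nn.save_state(leaves)
        meta = {
            "kind": self.kind,
            "config": self.config,
            "seed": self.seed,
            "history": self.history,
            "trained": self.trained,
            "class_weights": None
            if self.class_weights is None
            else list(map(float, np.asarray(self.class_weights.weights))),
        }
        np.savez(
            os.fspath(path),
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **{f"arr_{i}": a for i, a in enumerate(state)},
        )

    @staticmethod
    def load(path: str | os.PathLike, builder: Callable[[dict, int], Any]) -> "ModelHandle":
        """Rebuild a handle; ``builder(config, seed)`` constructs the bare model."""
        with np.load(os.fspath(path)) as z:
            meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
            n = len([k for k in z.files if k.startswith("arr_")])
            state = [z[f"arr_{i}"] for i in range(n)]
        model = builder(meta["config"], meta["seed"])
        nn.load_state(nn.all_leaf_layers(model.layers), state)
        h = ModelHandle(
            kind=meta["kind"], model=model, config=meta["config"], seed=meta["seed"],
            history=meta["history"], trained=meta["trained"],
        )
        if meta.get("class_weights"):
            h.class_weights = meta["class_weights"]
        return h

    def history_to_csv(self, path: str | os.PathLike) -> None:
        import pandas as pd

        pd.DataFrame({"epoch": range(1, len(self.history) + 1), "loss": self.history}).to_csv(
            path, index=False
        )
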