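"""The six parameter-matched sequence classifiers and the averaging base model.

Each trainable architecture stacks three blocks of its kind followed by a
single dense sigmoid head that emits all 24/tau next-day bin probabilities in
one forward pass (non-autoregressive).  To compare architectures fairly, the
per-architecture hidden widths are chosen by integer search so every trainable
parameter count sits as close as possible to an LSTM reference, with the
spread across the six kept within 3,000 parameters.

The base model is the untrained reference: its probability for a time slot is
the mean CPE indicator (binned NRS >= 4) at that same slot over the prior days
inside the input window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .nn.layers import (
    BiLSTMLayer,
    Conv1dLayer,
    GRULayer,
    LSTMLayer,
    Module,
    RecurrentClassifier,
    RNNLayer,
    TransformerClassifier,
)

TRAINABLE_ARCHITECTURES = ("RNN", "LSTM", "GRU", "BiLSTM", "CNN-LSTM", "Transformer")
ARCHITECTURES = TRAINABLE_ARCHITECTURES + ("Base",)

CPE_THRESHOLD = 4
N_BLOCKS = 3
PARAM_SPREAD_BUDGET = 3000


@dataclass(frozen=True)
class ModelSpec:
    """Identity of one classifier in one experiment cell."""

    architecture: str
    hidden_width: int
    input_bins: int
    output_bins: int
    n_blocks: int = N_BLOCKS
    param_count: int = field(default=0)

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.architecture != "Base" and self.hidden_width <= 0:
            raise ValueError("hidden_width must be positive")


class BaseModel:
    """Same-time-of-day averaging predictor; no trainable state.

    For an input window of L hours binned at tau, the probability emitted for
    output slot s is the fraction of the window's L/24 prior days whose bin at
    slot s was a CPE (NRS >= 4).
    """

    def __init__(self, input_bins: int, output_bins: int):
        if input_bins % output_bins:
            raise ValueError("input window must cover whole days")
        self.input_bins = input_bins
        self.output_bins = output_bins

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            return self.predict_proba(x[None, :])[0]
        n_days = self.input_bins // self.output_bins
        days = (x >= CPE_THRESHOLD).reshape(x.shape[0], n_days, self.output_bins)
        return days.mean(axis=1)

    def n_parameters(self) -> int:
        return 0


def base_model_predict(x: np.ndarray, L: int, tau: int) -> np.ndarray:
    """Functional form of the base model for a single window.

    ``x`` holds the L/tau binned NRS values of the window (most recent last);
    the result is the 24/tau probability vector for the forecast day.
    """
    if L < 24:
        raise ValueError("base model needs at least one complete prior day (L >= 24)")
    if L % 24:
        raise ValueError("L must be a multiple of 24")
    if 24 % tau:
        raise ValueError("tau must divide 24")
    model = BaseModel(input_bins=L // tau, output_bins=24 // tau)
    return model.predict_proba(np.asarray(x, dtype=float))


def build_model(spec: ModelSpec, seed: int = 0):
    """Instantiate the network a spec describes, weights drawn from ``seed``."""
    rng = np.random.default_rng(seed)
    arch, w = spec.architecture, spec.hidden_width
    ib, ob = spec.input_bins, spec.output_bins
    if arch == "Base":
        return BaseModel(ib, ob)
    if arch == "RNN":
        blocks = [RNNLayer(1, w, rng)] + [RNNLayer(w, w, rng) for _ in range(2)]
        return RecurrentClassifier(blocks, w, ob, rng)
    if arch == "LSTM":
        blocks = [LSTMLayer(1, w, rng)] + [LSTMLayer(w, w, rng) for _ in range(2)]
        return RecurrentClassifier(blocks, w, ob, rng)
    if arch == "GRU":
        blocks = [GRULayer(1, w, rng)] + [GRULayer(w, w, rng) for _ in range(2)]
        return RecurrentClassifier(blocks, w, ob, rng)
    if arch == "BiLSTM":
        # total width w split across the two directions before budget matching
        half = max(1, w // 2)
        blocks = [BiLSTMLayer(1, half, rng)] + \
                 [BiLSTMLayer(2 * half, half, rng) for _ in range(2)]
        return RecurrentClassifier(blocks, 2 * half, ob, rng)
    if arch == "CNN-LSTM":
        blocks = [Conv1dLayer(1, w, rng), LSTMLayer(w, w, rng), LSTMLayer(w, w, rng)]
        return RecurrentClassifier(blocks, w, ob, rng)
    if arch == "Transformer":
        d = w if w % 2 == 0 else w + 1  # 2 heads need an even model dimension
        return TransformerClassifier(d, 2, N_BLOCKS, ob, max_len=ib, rng=rng)
    raise ValueError(f"unknown architecture {arch!r}")  # pragma: no cover


def count_parameters(model) -> int:
    """Exact count of trainable scalar weights."""
    if isinstance(model, Module):
        return model.n_parameters()
    if isinstance(model, BaseModel):
        return 0
    raise TypeError(f"cannot count parameters of {type(model)!r}")


def spec_with_count(spec: ModelSpec) -> ModelSpec:
    """Fill in the derived param_count field by building the model."""
    return replace(spec, param_count=count_parameters(build_model(spec)))


def match_budgets(
    architectures: tuple[str, ...],
    reference_width: int,
    L: int,
    tau: int,
    width_range: tuple[int, int] = (2, 64),
) -> dict[str, ModelSpec]:
    """Choose per-architecture widths so parameter counts nearly agree.

    The LSTM at ``reference_width`` anchors the budget; every other trainable
    architecture's width is picked by exhaustive integer search to minimize the
    absolute count difference to that anchor.  Raises if the resulting spread
    exceeds the 3,000-parameter fairness budget.
    """
    input_bins, output_bins = L // tau, 24 // tau
    ref = spec_with_count(ModelSpec("LSTM", reference_width, input_bins, output_bins))
    specs: dict[str, ModelSpec] = {}
    for arch in architectures:
        if arch == "Base":
            specs[arch] = ModelSpec("Base", 0, input_bins, output_bins, n_blocks=0)
            continue
        if arch == "LSTM":
            specs[arch] = ref
            continue
        best: ModelSpec | None = None
        for w in range(width_range[0], width_range[1] + 1):
            cand = spec_with_count(ModelSpec(arch, w, input_bins, output_bins))
            if best is None or abs(cand.param_count - ref.param_count) < \
                    abs(best.param_count - ref.param_count):
                best = cand
        assert best is not None
        specs[arch] = best
    counts = [s.param_count for s in specs.values() if s.architecture != "Base"]
    if counts and max(counts) - min(counts) > PARAM_SPREAD_BUDGET:
        raise ValueError(
            f"no widths in {width_range} keep the parameter spread within "
            f"{PARAM_SPREAD_BUDGET}: got {max(counts) - min(counts)}"
        )
    return specs
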