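"""The relation-classification model.

Per-token feature combination (word + position encoding | POS |
entity type | distance-to-entity-1 | distance-to-entity-2) feeds a
sentence encoder — multi-head self-attention by default, with plain
CNN, BiLSTM and additive-attention variants for ablation — while the
shortest-dependency-path channel (path word | dependency type) feeds a
multi-filter CNN (or BiLSTM, or nothing).  The two pooled feature
vectors are concatenated, passed through dropout, and classified with
a linear softmax layer over the relation categories (including
``none``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .encoding import EncodedInstance, FeatureSpace, positional_encoding
from .nn.autograd import Tensor, concat
from .nn.layers import (
    AdditiveAttentionPooling,
    BiLstmEncoder,
    CnnEncoder,
    Linear,
    MultiHeadAttentionEncoder,
)

SENTENCE_ENCODERS = ("mha", "cnn", "bilstm", "cnn_attn", "bilstm_attn")
SDP_ENCODERS = ("cnn", "lstm", "none")


@dataclass
class ModelConfig:
    """Architecture hyperparameters (defaults follow the study settings)."""

    encoder: str = "mha"
    sdp_encoder: str = "cnn"
    heads: int = 8
    d_ff: Optional[int] = None          # FFN hidden width; None -> model dim
    attention_scale: str = "head"       # softmax scale sqrt(d_head) | sqrt(d)
    dropout: float = 0.5
    sdp_windows: tuple = (2, 3, 4)
    sdp_filters: int = 128
    lstm_hidden: int = 128
    use_positional_encoding: bool = True

    def __post_init__(self):
        if self.encoder not in SENTENCE_ENCODERS:
            raise ValueError(f"unknown sentence encoder {self.encoder!r}")
        if self.sdp_encoder not in SDP_ENCODERS:
            raise ValueError(f"unknown SDP encoder {self.sdp_encoder!r}")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")


class RelationModel:
    """All trainable state for one run (one random initialisation)."""

    def __init__(
        self,
        space: FeatureSpace,
        categories: Sequence[str],
        config: ModelConfig | None = None,
        seed: int = 0,
    ):
        self.space = space
        self.categories = list(categories)
        self.config = config or ModelConfig()
        self.seed = seed
        rng = np.random.default_rng(seed)
        dims = space.dims
        sizes = space.table_sizes()

        def table(name, d):
            t = rng.uniform(-0.05, 0.05, size=(sizes[name], d)).astype(np.float32)
            t[0] = 0.0  # PAD row, frozen
            return Tensor(t, requires_grad=True)

        if space.word_table is not None:
            wt = space.word_table.astype(np.float32).copy()
            wt[0] = 0.0
            self.word_table = Tensor(wt, requires_grad=True)
        else:
            self.word_table = table("word", dims["word"])
        self.pos_table = table("pos", dims["pos"])
        self.etype_table = table("etype", dims["etype"])
        self.dist_table = table("dist", dims["dist"])  # shared by both chains
        self.deptype_table = table("deptype", dims["deptype"])

        self.d_token = (
            dims["word"] + dims["pos"] + dims["etype"] + 2 * dims["dist"]
        )
        self.d_sdp = dims["word"] + dims["deptype"]

        enc = self.config.encoder
        if enc == "mha":
            self.encoder = MultiHeadAttentionEncoder(
                rng, self.d_token, heads=self.config.heads,
                d_ff=self.config.d_ff, scale_dim=self.config.attention_scale,
            )
            self._attn_pool = None
        elif enc in ("cnn", "cnn_attn"):
            self.encoder = CnnEncoder(
                rng, self.d_token, windows=self.config.sdp_windows,
                filters=self.config.sdp_filters,
            )
            self._attn_pool = (
                AdditiveAttentionPooling(rng, self.config.sdp_filters)
                if enc == "cnn_attn" else None
            )
        else:  # bilstm / bilstm_attn
            self.encoder = BiLstmEncoder(rng, self.d_token, self.config.lstm_hidden)
            self._attn_pool = (
                AdditiveAttentionPooling(rng, 2 * self.config.lstm_hidden)
                if enc == "bilstm_attn" else None
            )
        if self._attn_pool is not None:
            self.sent_dim = self._attn_pool.out_dim
        else:
            self.sent_dim = self.encoder.out_dim

        sdp = self.config.sdp_encoder
        if sdp == "cnn":
            self.sdp_enc = CnnEncoder(
                rng, self.d_sdp, windows=self.config.sdp_windows,
                filters=self.config.sdp_filters,
            )
            self.sdp_dim = self.sdp_enc.out_dim
        elif sdp == "lstm":
            self.sdp_enc = BiLstmEncoder(rng, self.d_sdp, self.config.lstm_hidden)
            self.sdp_dim = self.sdp_enc.out_dim
        else:
            self.sdp_enc = None
            self.sdp_dim = 0

        self.classifier = Linear(rng, self.sent_dim + self.sdp_dim, len(self.categories))
        self._pe_cache: dict[int, Tensor] = {}
        self._drop_rng = np.random.default_rng(rng.integers(2**31))

    # -- forward -----------------------------------------------------------

    def _pe(self, n: int) -> Tensor:
        t = self._pe_cache.get(n)
        if t is None:
            t = Tensor(
                positional_encoding(n, self.space.dims["word"]).astype(np.float32)
            )
            self._pe_cache[n] = t
        return t

    def token_features(self, enc: EncodedInstance) -> Tensor:
        """The (n, d) per-token feature-combination matrix."""
        W = self.word_table.take_rows(enc.word_idx)
        if self.config.use_positional_encoding:
            W = W + self._pe(enc.n)
        return concat(
            [
                W,
                self.pos_table.take_rows(enc.pos_idx),
                self.etype_table.take_rows(enc.etype_idx),
                self.dist_table.take_rows(enc.dist1_idx),
                self.dist_table.take_rows(enc.dist2_idx),
            ],
            axis=-1,
        )

    def _sentence_vector(self, X: Tensor) -> Tensor:
        if self._attn_pool is not None:
            if isinstance(self.encoder, CnnEncoder):
                H = self.encoder.feature_map(X, w_index=1)  # window 3
            else:
                H = self.encoder.outputs(X)
            return self._attn_pool.encode(H)
        return self.encoder.encode(X)

    def _sdp_vector(self, enc: EncodedInstance) -> Optional[Tensor]:
        if self.sdp_enc is None:
            return None
        S = concat(
            [
                self.word_table.take_rows(enc.sdp_word_idx),
                self.deptype_table.take_rows(enc.sdp_deptype_idx),
            ],
            axis=-1,
        )
        if isinstance(self.sdp_enc, BiLstmEncoder):
            return self.sdp_enc.final_states(S)
        return self.sdp_enc.encode(S)

    def logits(self, enc: EncodedInstance, train: bool = False) -> Tensor:
        sv = self._sentence_vector(self.token_features(enc))
        pv = self._sdp_vector(enc)
        feat = sv if pv is None else concat([sv, pv], axis=-1)
        feat = feat.dropout(self.config.dropout, self._drop_rng, train)
        return self.classifier(feat)

    def loss(self, batch: Sequence[EncodedInstance], train: bool = True) -> Tensor:
        if not batch:
            raise ValueError("empty batch")
        total = None
        for enc in batch:
            li = self.logits(enc, train=train).cross_entropy(enc.label_idx)
            total = li if total is None else total + li
        return total / len(batch)

    def predict_proba(self, batch: Sequence[EncodedInstance]) -> np.ndarray:
        out = np.empty((len(batch), len(self.categories)))
        for i, enc in enumerate(batch):
            z = self.logits(enc, train=False).data.astype(np.float64)
            z = z - z.max()
            e = np.exp(z)
            out[i] = e / e.sum()
        return out

    def predict_labels(self, batch: Sequence[EncodedInstance]) -> list[str]:
        p = self.predict_proba(batch)
        return [self.categories[int(i)] for i in p.argmax(axis=1)]

    # -- parameter plumbing --------------------------------------------------

    def parameters(self) -> list[Tensor]:
        params = [
            self.word_table, self.pos_table, self.etype_table,
            self.dist_table, self.deptype_table,
        ]
        params += self.encoder.parameters()
        if self._attn_pool is not None:
            params += self._attn_pool.parameters()
        if self.sdp_enc is not None:
            params += self.sdp_enc.parameters()
        params += self.classifier.parameters()
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def freeze_pad_rows(self) -> None:
        """Zero the PAD-row gradient of every embedding table."""
        for t in (
            self.word_table, self.pos_table, self.etype_table,
            self.dist_table, self.deptype_table,
        ):
            if t.grad is not None:
                t.grad[0] = 0.0

    def state_copy(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p.data[...] = s
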