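"""Model/Results facade over the library modules.

:class:`LeftCornerSurprisalModel` is built from an annotated treebank (or
pre-extracted decision sequences); ``fit`` returns a
:class:`SurprisalResults` object carrying the trained parameters, training
diagnostics, and the estimation methods (per-word surprisal, corpus
perplexity, sentence simulation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .categories import Inventories
from .inference import beam_forward, corpus_perplexity, exact_forward, \
    score_sentences
from .morph import RuleInventory
from .neural import NeuralParameters
from .synth import sample_decisions
from .training import (
    TrainConfig,
    TrainingHistory,
    _InvProbe,
    build_inventories_from_trees,
    fit_model,
    make_ablation,
    resolve_tree,
    tree_to_decisions,
)
from .transition import TransitionModel
from .treebank import read_treebank


class LeftCornerSurprisalModel:
    """Incremental left-corner surprisal estimator.

    Parameters
    ----------
    sequences : list of decision sequences
        Oracle decision sequences, one per sentence.
    inv : Inventories
        Frozen category/predicate/rule/character inventories.
    config : TrainConfig, optional
        Optimizer and architecture settings.
    """

    def __init__(self, sequences, inv: Inventories,
                 config: TrainConfig | None = None):
        self.sequences = sequences
        self.inv = inv
        self.config = config or TrainConfig()

    @classmethod
    def from_treebank(cls, trees, header, rules: RuleInventory,
                      config: TrainConfig | None = None, D: int | None = None
                      ) -> "LeftCornerSurprisalModel":
        """Build from string-level trees plus their header."""
        inv = build_inventories_from_trees(trees, header, rules, D=D)
        probe = _InvProbe(inv)
        sequences = [
            tree_to_decisions(resolve_tree(t, inv), probe) for t in trees
        ]
        return cls(sequences, inv, config)

    @classmethod
    def from_file(cls, path, rules: RuleInventory,
                  config: TrainConfig | None = None) -> "LeftCornerSurprisalModel":
        trees, header, _ = read_treebank(path, rules)
        return cls.from_treebank(trees, header, rules, config)

    def fit(self, seed: int = 0) -> "SurprisalResults":
        params, history = fit_model(self.sequences, self.inv, self.config,
                                    seed=seed)
        return SurprisalResults(self, params, history)

    def fit_ablation(self, which: str, seed: int = 0) -> "SurprisalResults":
        """Retrain the -cat or -morph variant from scratch."""
        params, history = make_ablation(which, self.sequences, self.inv,
                                        self.config, seed=seed)
        return SurprisalResults(self, params, history, ablation=which)


@dataclass
class SurprisalResults:
    model: LeftCornerSurprisalModel | None
    params: NeuralParameters
    history: TrainingHistory | None = None
    ablation: str | None = None

    def __post_init__(self):
        self._tm = TransitionModel(self.params)

    # -- estimation ---------------------------------------------------------

    def surprisal(self, sentences, beam_size: int | None = 5000,
                  floor_nats: float = 25.0) -> pd.DataFrame:
        """Per-word surprisal table for tokenized sentences.

        Columns: sentence_id, token_id, word, prefix_logprob_nats,
        surprisal_nats, surprisal_bits, parse_failed.
        """
        records = score_sentences(sentences, self._tm, beam_size=beam_size,
                                  floor_nats=floor_nats)
        return pd.DataFrame(
            {
                "sentence_id": [r.sentence_index for r in records],
                "token_id": [r.token_index for r in records],
                "word": [r.word for r in records],
                "prefix_logprob_nats": [r.prefix_logprob for r in records],
                "surprisal_nats": [r.surprisal_nats for r in records],
                "surprisal_bits": [r.surprisal_bits for r in records],
                "parse_failed": [r.parse_failed for r in records],
            }
        )

    def perplexity(self, sentences, beam_size: int | None = 5000
                   ) -> tuple[float, int]:
        """Corpus perplexity: exp(mean per-token surprisal in nats)."""
        records = score_sentences(sentences, self._tm, beam_size=beam_size)
        return corpus_perplexity(records)

    def prefix_logprobs(self, words, exact: bool = False,
                        beam_size: int = 5000):
        res = (exact_forward(words, self._tm) if exact
               else beam_forward(words, self._tm, beam_size))
        return res

    def simulate(self, n_sentences: int, seed: int = 0, max_len: int = 12):
        """Sample sentences from the fitted transition model."""
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n_sentences):
            steps, logp, _ = sample_decisions(self.params, rng,
                                              max_len=max_len)
            out.append(([s.word for s in steps], logp))
        return out

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        inv = self.params.inv
        lines = [
            "Left-corner surprisal model",
            "=" * 40,
            f"variant:             {self.ablation or 'full'}",
            f"categories:          {inv.n_real_cats} (+2 reserved)",
            f"predicate contexts:  K={inv.space.K} V={inv.space.V} "
            f"E={inv.space.E} (H={inv.space.H})",
            f"operators:           {len(self.params.operators)}",
            f"morph rules:         {len(inv.rules)}",
            f"lexical contexts:    {inv.n_lex_contexts}",
            f"depth bound D:       {inv.D}",
        ]
        if self.history is not None:
            lines.append(f"training examples:   {self.history.n_examples}")
            if self.history.epoch_nll:
                lines.append(
                    f"mean NLL by epoch:   "
                    + " ".join(f"{x:.3f}" for x in self.history.epoch_nll)
                )
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        self.params.save(path)

    @classmethod
    def load(cls, path) -> "SurprisalResults":
        return cls(None, NeuralParameters.load(path))
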