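"""Rank-value encoding of single-cell transcriptomes.

Each cell becomes an ordered sequence of gene tokens, highest-priority first.
A gene's priority in a cell is its depth-normalized expression divided by the
gene's corpus-wide normalization factor (the median of its nonzero
depth-normalized values across the reference corpus). Dividing by the nonzero
median deprioritizes ubiquitously high housekeeping genes so that the front
of the sequence carries cell-state-specific signal.

Token ids 0 and 1 are reserved (PAD, MASK); gene tokens start at 2 and are
assigned in lexicographic order of gene id. Ties in priority are broken by
ascending token id so encodings are fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import ExpressionCorpus

PAD_TOKEN = 0
MASK_TOKEN = 1
FIRST_GENE_TOKEN = 2

DEFAULT_CONTEXT_LENGTH = 128


class UnencodableCellError(ValueError):
    """Cell expresses no vocabulary gene and has no rank encoding."""


@dataclass(frozen=True)
class RankEncoding:
    """Ordered gene-token sequence for one cell (highest priority first)."""

    cell_id: str
    tokens: tuple[int, ...]
    context_length: int

    def __post_init__(self) -> None:
        if len(self.tokens) > self.context_length:
            raise ValueError(
                f"{self.cell_id}: {len(self.tokens)} tokens exceed context length "
                f"{self.context_length}"
            )
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError(f"{self.cell_id}: duplicate tokens in encoding")
        if any(t < FIRST_GENE_TOKEN for t in self.tokens):
            raise ValueError(f"{self.cell_id}: reserved token in encoding")

    def __len__(self) -> int:
        return len(self.tokens)


class GeneVocabulary:
    """Gene -> token map plus per-gene normalization factors."""

    def __init__(self, gene_ids: list[str], factors: np.ndarray):
        self.gene_ids = list(gene_ids)
        self.factors = np.asarray(factors, dtype=np.float64)
        if len(self.gene_ids) != len(self.factors):
            raise ValueError("one factor per gene required")
        if not (self.factors > 0).all():
            raise ValueError("every normalization factor must be > 0")
        self.token_of = {
            g: FIRST_GENE_TOKEN + i for i, g in enumerate(self.gene_ids)
        }
        self.gene_of = {t: g for g, t in self.token_of.items()}

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.token_of

    @property
    def size(self) -> int:
        """Total token-table size including PAD and MASK."""
        return FIRST_GENE_TOKEN + len(self.gene_ids)

    def to_tsv(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(
                f"{g}\t{self.token_of[g]}\t{f:.10g}\n"
                for g, f in zip(self.gene_ids, self.factors)
            ),
            encoding="utf-8",
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneVocabulary":
        gene_ids, factors = [], []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            g, tok, f = line.split("\t")
            gene_ids.append(g)
            factors.append(float(f))
            if int(tok) != FIRST_GENE_TOKEN + len(gene_ids) - 1:
                raise ValueError(f"{path}: token ids out of order at gene {g}")
        return cls(gene_ids, np.array(factors))


def build_vocabulary(corpus: ExpressionCorpus) -> GeneVocabulary:
    """Compute the token map and nonzero-median normalization factors.

    Depth normalization divides each count by its cell's total counts. Genes
    never expressed in the reference corpus are excluded from the vocabulary.
    """
    counts = corpus.counts
    totals = counts.sum(axis=1, keepdims=True).astype(np.float64)
    if (totals == 0).all():
        raise ValueError("no expressed genes: corpus count matrix is all zero")
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(totals > 0, counts / totals, 0.0)

    order = np.argsort(np.asarray(corpus.gene_ids, dtype=str), kind="stable")
    gene_ids, factors = [], []
    for j in order:
        nz = norm[counts[:, j] > 0, j]
        if nz.size == 0:
            continue
        gene_ids.append(str(corpus.gene_ids[j]))
        factors.append(float(np.median(nz)))
    if not gene_ids:
        raise ValueError("no expressed genes: corpus count matrix is all zero")
    return GeneVocabulary(gene_ids, np.array(factors))


def rank_encode(
    cell_counts: np.ndarray,
    gene_ids: np.ndarray,
    vocabulary: GeneVocabulary,
    context_length: int = DEFAULT_CONTEXT_LENGTH,
    cell_id: str = "",
) -> RankEncoding:
    """Encode one cell: tokens sorted by score descending, ties by token id.

    score(gene) = (count / cell_total_counts) / normalization_factor. The cell
    total includes all genes, also those outside the vocabulary; genes absent
    from the vocabulary are dropped from the ranking.
    """
    if context_length < 1:
        raise ValueError("context_length must be >= 1")
    cell_counts = np.asarray(cell_counts)
    total = float(cell_counts.sum())
    tokens_scores = []
    for j, g in enumerate(gene_ids):
        c = cell_counts[j]
        if c > 0 and g in vocabulary:
            tok = vocabulary.token_of[g]
            score = (c / total) / vocabulary.factors[tok - FIRST_GENE_TOKEN]
            tokens_scores.append((tok, score))
    if not tokens_scores:
        raise UnencodableCellError(
            f"cell {cell_id!r} expresses no vocabulary gene and cannot be encoded"
        )
    toks = np.array([t for t, _ in tokens_scores])
    scores = np.array([s for _, s in tokens_scores])
    order = np.lexsort((toks, -scores))  # score desc, then token id asc
    ranked = toks[order][:context_length]
    return RankEncoding(cell_id=cell_id, tokens=tuple(int(t) for t in ranked),
                        context_length=context_length)


class RankEncoder(BaseEstimator, TransformerMixin):
    """Corpus -> list of rank encodings, with a vocabulary frozen at fit time.

    The vocabulary (token map and normalization factors) is built on the
    corpus passed to :meth:`fit` and then frozen; cells transformed later use
    that vocabulary, dropping genes it does not contain. Cells that express no
    vocabulary gene are skipped and listed in ``dropped_cells_``.

    Parameters
    ----------
    context_length : int, default 128
        Maximum encoding length L; sequences are truncated to the L
        highest-priority genes.
    """

    def __init__(self, context_length: int = DEFAULT_CONTEXT_LENGTH):
        self.context_length = context_length

    def fit(self, corpus: ExpressionCorpus, y=None) -> "RankEncoder":
        self.vocabulary_ = build_vocabulary(corpus)
        return self

    def transform(self, corpus: ExpressionCorpus) -> list[RankEncoding]:
        if not hasattr(self, "vocabulary_"):
            raise RuntimeError("RankEncoder must be fit before transform")
        vocab = self.vocabulary_
        counts = corpus.counts
        totals = counts.sum(axis=1).astype(np.float64)
        gene_ids = np.asarray(corpus.gene_ids, dtype=str)

        # vectorized scoring over the vocabulary columns present in this corpus
        col_of = {g: j for j, g in enumerate(gene_ids)}
        vocab_cols = np.array([col_of[g] for g in vocab.gene_ids if g in col_of])
        vocab_toks = np.array(
            [vocab.token_of[g] for g in vocab.gene_ids if g in col_of]
        )
        vocab_factors = np.array(
            [vocab.factors[vocab.token_of[g] - FIRST_GENE_TOKEN]
             for g in vocab.gene_ids if g in col_of]
        )

        encodings: list[RankEncoding] = []
        self.dropped_cells_: list[str] = []
        L = self.context_length
        if vocab_cols.size == 0:
            self.dropped_cells_ = [str(c) for c in corpus.cell_ids]
            return encodings
        sub = counts[:, vocab_cols]
        for i in range(corpus.n_cells):
            row = sub[i]
            nz = row > 0
            if totals[i] == 0 or not nz.any():
                self.dropped_cells_.append(str(corpus.cell_ids[i]))
                continue
            scores = (row[nz] / totals[i]) / vocab_factors[nz]
            toks = vocab_toks[nz]
            order = np.lexsort((toks, -scores))
            ranked = toks[order][:L]
            encodings.append(
                RankEncoding(
                    cell_id=str(corpus.cell_ids[i]),
                    tokens=tuple(int(t) for t in ranked),
                    context_length=L,
                )
            )
        return encodings
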