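"""In-silico perturbation of rank encodings and cosine-shift statistics.

Deleting a gene removes its token from a cell's rank encoding (simulated
knockdown); overexpressing a gene moves or inserts its token at the front
(simulated activation). The effect of a perturbation on a cell is the change
in cosine similarity between the cell's embedding and the centroid of the
goal condition's embeddings ("shift to goal end"): positive shifts move the
cell toward the goal state.

Per-gene significance uses a two-sided Wilcoxon rank-sum test of the gene's
per-cell shifts against the aggregate null — the pooled per-cell shifts of
all tested genes (the gene's own cells included) — with Benjamini-Hochberg
adjustment across tested genes. Candidates are genes with a positive mean
shift and FDR below alpha, ranked by shift descending with FDR ascending as
the tie-break.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .encoding import FIRST_GENE_TOKEN, GeneVocabulary, RankEncoding

#: returned by delete/overexpress when the cell is ineligible for the gene
SKIP = None

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_CELLS = 5


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def _token_for(gene_id: str, vocabulary: GeneVocabulary) -> int:
    try:
        return vocabulary.token_of[gene_id]
    except KeyError:
        raise ValueError(f"gene {gene_id!r} is not in the vocabulary") from None


def delete_gene(
    encoding: RankEncoding, gene_id: str, vocabulary: GeneVocabulary
) -> RankEncoding | None:
    """Remove the gene's token, preserving the order of all other tokens.

    Returns ``SKIP`` (None) when the gene is absent from the encoding — the
    cell is ineligible for this deletion. A gene missing from the vocabulary
    is an error, distinct from a skip.
    """
    token = _token_for(gene_id, vocabulary)
    if token not in encoding.tokens:
        return SKIP
    return RankEncoding(
        cell_id=encoding.cell_id,
        tokens=tuple(t for t in encoding.tokens if t != token),
        context_length=encoding.context_length,
    )


def overexpress_gene(
    encoding: RankEncoding, gene_id: str, vocabulary: GeneVocabulary
) -> RankEncoding:
    """Move (or insert) the gene's token to the front of the encoding.

    Present genes are moved to position 0 with all other relative order kept;
    absent genes are inserted at the front and the sequence truncated back to
    the context length. The result never contains duplicates.
    """
    token = _token_for(gene_id, vocabulary)
    rest = tuple(t for t in encoding.tokens if t != token)
    tokens = ((token,) + rest)[: encoding.context_length]
    return RankEncoding(
        cell_id=encoding.cell_id, tokens=tokens, context_length=encoding.context_length
    )


@dataclass
class GoalState:
    """Embedding centroid of the target condition's cells."""

    label: str
    centroid: np.ndarray
    n_cells: int

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=np.float64)
        if self.n_cells < 1:
            raise ValueError("goal state needs at least one cell")


def compute_goal_state(embeddings: np.ndarray, label: str) -> GoalState:
    embeddings = np.asarray(embeddings, dtype=np.float64)
    if embeddings.ndim != 2 or embeddings.shape[0] == 0:
        raise ValueError("need a non-empty (n_cells, d) embedding array")
    return GoalState(
        label=label, centroid=embeddings.mean(0), n_cells=embeddings.shape[0]
    )


def _cosine(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("cosine similarity undefined for zero-norm vectors")
    return (a * b).sum(-1) / (na * nb)


def shift_to_goal(
    original_emb: np.ndarray, perturbed_emb: np.ndarray, goal: GoalState
) -> float:
    """cos(perturbed, goal centroid) - cos(original, goal centroid); in [-2, 2]."""
    return float(
        _cosine(perturbed_emb, goal.centroid) - _cosine(original_emb, goal.centroid)
    )


@dataclass
class PerturbationRecord:
    gene_id: str
    mode: str  # "delete" | "overexpress"
    direction: str  # e.g. "control->disease"
    n_cells: int
    shift_to_goal_end: float
    cell_shifts: np.ndarray = field(repr=False)
    p_value: float = float("nan")
    fdr: float = float("nan")


@dataclass
class CandidateTable:
    """Filtered, ranked candidate genes plus the full per-gene statistics."""

    table: pd.DataFrame  # passing records, ranked
    all_records: pd.DataFrame  # every tested gene with p/fdr
    excluded: pd.DataFrame  # genes with n_cells < min_cells
    alpha: float
    min_cells: int
    metadata: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        self.table.to_csv(path, sep="\t", index=False)
        meta = dict(self.metadata)
        meta.update(
            alpha=self.alpha,
            min_cells=self.min_cells,
            n_tested=len(self.all_records),
            n_candidates=len(self.table),
            n_excluded=len(self.excluded),
        )
        path.with_suffix(".meta.json").write_text(
            json.dumps(meta, indent=2), encoding="utf-8"
        )


def perturb_corpus(
    model,
    encodings: list[RankEncoding],
    gene_ids: list[str],
    mode: str,
    goal: GoalState,
    vocabulary: GeneVocabulary,
    direction: str = "",
    batch_size: int = 128,
) -> list[PerturbationRecord]:
    """Per-gene cosine shifts of start-condition cells toward the goal state.

    For deletion only cells expressing the gene are eligible; overexpression
    applies to every cell. Genes with zero eligible cells are returned with
    ``n_cells=0`` and no shifts (excluded downstream). ``model`` must expose
    ``embed(list_of_encodings) -> (n, d)``.
    """
    if mode not in ("delete", "overexpress"):
        raise ValueError(f"unknown perturbation mode {mode!r}")
    if not gene_ids:
        raise ValueError("empty gene list")
    if not encodings:
        raise ValueError("no encodable start-condition cells")

    original_emb = np.asarray(model.embed(encodings), dtype=np.float64)
    cos_orig = _cosine(original_emb, goal.centroid[None, :])

    # build all perturbed encodings, tagged by (gene index, cell index)
    perturbed: list[RankEncoding] = []
    owner_gene: list[int] = []
    owner_cell: list[int] = []
    for gi, gene in enumerate(gene_ids):
        for ci, enc in enumerate(encodings):
            if mode == "delete":
                new = delete_gene(enc, gene, vocabulary)
                if new is SKIP:
                    continue
            else:
                new = overexpress_gene(enc, gene, vocabulary)
            perturbed.append(new)
            owner_gene.append(gi)
            owner_cell.append(ci)

    shifts_by_gene: dict[int, list[float]] = {gi: [] for gi in range(len(gene_ids))}
    for start in range(0, len(perturbed), batch_size):
        chunk = perturbed[start : start + batch_size]
        emb = np.asarray(model.embed(chunk), dtype=np.float64)
        cos_pert = _cosine(emb, goal.centroid[None, :])
        for j, cp in enumerate(cos_pert):
            idx = start + j
            shifts_by_gene[owner_gene[idx]].append(cp - cos_orig[owner_cell[idx]])

    records = []
    for gi, gene in enumerate(gene_ids):
        shifts = np.array(shifts_by_gene[gi], dtype=np.float64)
        records.append(
            PerturbationRecord(
                gene_id=gene,
                mode=mode,
                direction=direction,
                n_cells=len(shifts),
                shift_to_goal_end=float(shifts.mean()) if len(shifts) else float("nan"),
                cell_shifts=shifts,
            )
        )
    return records


def expressed_in_both_conditions(corpus) -> list[str]:
    """Genes expressed in at least one cell of each condition — the standard
    target universe for perturbation screens."""
    from .simulate import CONTROL, DISEASE

    ctrl = corpus.counts[corpus.mask(CONTROL)].sum(0) > 0
    dis = corpus.counts[corpus.mask(DISEASE)].sum(0) > 0
    return [str(g) for g, a, b in zip(corpus.gene_ids, ctrl, dis) if a and b]


def rank_candidates(
    records: list[PerturbationRecord],
    alpha: float = DEFAULT_ALPHA,
    min_cells: int = DEFAULT_MIN_CELLS,
    ground_truth: dict | None = None,
) -> CandidateTable:
    """Wilcoxon rank-sum vs the aggregate null, BH-FDR, filter and rank.

    Tested genes need at least ``min_cells`` eligible cells; the null pools
    the per-cell shifts of all tested genes. Candidates satisfy
    ``shift_to_goal_end > 0`` and ``fdr < alpha`` and are sorted by shift
    descending, ties broken by FDR ascending.
    """
    tested = [r for r in records if r.n_cells >= min_cells]
    excluded = [r for r in records if r.n_cells < min_cells]
    if len(tested) < 2:
        raise ValueError(
            f"need >= 2 genes with >= {min_cells} eligible cells to form an "
            f"aggregate null, got {len(tested)}"
        )
    pooled = np.concatenate([r.cell_shifts for r in tested])
    pvals = np.empty(len(tested))
    for i, r in enumerate(tested):
        combined_min = min(r.cell_shifts.min(), pooled.min())
        combined_max = max(r.cell_shifts.max(), pooled.max())
        if combined_min == combined_max:  # degenerate: no variation anywhere
            pvals[i] = 1.0
            continue
        pvals[i] = mannwhitneyu(
            r.cell_shifts, pooled, alternative="two-sided", method="asymptotic"
        ).pvalue
    fdrs = bh_adjust(pvals)
    for r, p, q in zip(tested, pvals, fdrs):
        r.p_value = float(p)
        r.fdr = float(q)

    def _frame(rs):
        df = pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in rs],
                "mode": [r.mode for r in rs],
                "direction": [r.direction for r in rs],
                "n_cells": [r.n_cells for r in rs],
                "shift_to_goal_end": [r.shift_to_goal_end for r in rs],
                "p_value": [r.p_value for r in rs],
                "fdr": [r.fdr for r in rs],
            }
        )
        if ground_truth is not None:
            df["is_planted_driver"] = df["gene_id"].isin(set(ground_truth))
        return df

    all_df = _frame(tested)
    passing = all_df[(all_df.shift_to_goal_end > 0) & (all_df.fdr < alpha)]
    ranked = passing.sort_values(
        ["shift_to_goal_end", "fdr"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return CandidateTable(
        table=ranked,
        all_records=all_df,
        excluded=_frame(excluded),
        alpha=alpha,
        min_cells=min_cells,
    )
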