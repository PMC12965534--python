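"""Permutation-based natural-fluctuation threshold for log2 fold changes.

Random equal splits of a homogeneous control population produce nonzero
per-gene log2 fold changes purely from sampling noise. Repeating the split
many times yields a background distribution; the "natural fluctuation zone"
is the symmetric interval +-T where T is a high percentile (default the
95th) of the pooled absolute background log2FC across all genes and
iterations. An observed disease-vs-control log2FC whose magnitude strictly
exceeds T is a robust change beyond natural variance, and its fold-excess
|observed| / T quantifies by how much.

Expression is depth-normalized to counts per 10,000 per cell before group
means are taken; a pseudocount (default 1) is added to both group means
inside the log ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

DEFAULT_ITERATIONS = 100
DEFAULT_PERCENTILE = 95.0
DEFAULT_PSEUDOCOUNT = 1.0
CP10K = 1e4


def _cp10k(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, dtype=np.float64)
    totals = counts.sum(1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("cell with zero total counts cannot be depth-normalized")
    return counts / totals * CP10K


def log2fc(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """Per-gene log2((mean CP10K in A + pc) / (mean CP10K in B + pc))."""
    counts_a = np.atleast_2d(counts_a)
    counts_b = np.atleast_2d(counts_b)
    if counts_a.shape[0] == 0 or counts_b.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    mean_a = _cp10k(counts_a).mean(0)
    mean_b = _cp10k(counts_b).mean(0)
    return np.log2((mean_a + pseudocount) / (mean_b + pseudocount))


def permute_background(
    control_counts: np.ndarray,
    n_iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """Background log2FC matrix (n_iterations, n_genes) from random equal splits.

    Each iteration shuffles the control cells and splits them into halves
    (sizes floor(n/2) and ceil(n/2) for odd n); the per-gene log2FC between
    the halves is one background sample.
    """
    control_counts = np.asarray(control_counts)
    n = control_counts.shape[0]
    if n < 4:
        raise ValueError(f"need at least 4 control cells, got {n}")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    half = n // 2
    out = np.empty((n_iterations, control_counts.shape[1]))
    for i in range(n_iterations):
        perm = rng.permutation(n)
        out[i] = log2fc(
            control_counts[perm[:half]], control_counts[perm[half:]], pseudocount
        )
    return out


def estimate_threshold(
    background: np.ndarray, percentile: float = DEFAULT_PERCENTILE
) -> float:
    """Percentile of pooled |log2FC| (linear interpolation convention)."""
    background = np.asarray(background)
    if background.size == 0:
        raise ValueError("background is empty")
    if not 0 < percentile < 100:
        raise ValueError(f"percentile must be in (0, 100), got {percentile}")
    return float(
        np.percentile(np.abs(background).ravel(), percentile, method="linear")
    )


def assess_gene(observed_log2fc, threshold: float):
    """Exceedance (|observed| strictly > threshold) and fold-excess
    |observed| / threshold. Scalar in, scalar out; array in, array out."""
    if not threshold > 0:
        raise ValueError(
            "degenerate background: fluctuation threshold must be > 0"
        )
    observed = np.asarray(observed_log2fc, dtype=np.float64)
    exceeds = np.abs(observed) > threshold
    fold_excess = np.abs(observed) / threshold
    if observed.ndim == 0:
        return bool(exceeds), float(fold_excess)
    return exceeds, fold_excess


@dataclass
class FluctuationResult:
    n_iterations: int
    background: np.ndarray = field(repr=False)
    threshold: float
    percentile: float
    convention: str
    seed: int
    pseudocount: float
    observed: pd.DataFrame | None = None  # gene_id, observed_log2fc, exceeds, fold_excess

    def write(self, directory: str | Path, prefix: str = "fluctuation") -> None:
        directory = Path(directory)
        payload = {
            "threshold": self.threshold,
            "percentile": self.percentile,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "pseudocount": self.pseudocount,
            "convention": self.convention,
        }
        (directory / f"{prefix}.json").write_text(
            json.dumps(payload, indent=2), encoding="utf-8"
        )
        if self.observed is not None:
            self.observed.to_csv(directory / f"{prefix}_genes.tsv", sep="\t", index=False)


class FluctuationThreshold(BaseEstimator):
    """Estimator for the natural-fluctuation zone of per-gene log2FC.

    ``fit`` takes control-cell counts (cells x genes) and estimates the
    threshold from ``n_iterations`` random equal splits; ``assess`` flags
    observed log2 fold changes that exceed it.

    Parameters
    ----------
    n_iterations : int, default 100
        Number of random equal splits.
    percentile : float, default 95
        Background percentile defining the zone.
    pseudocount : float, default 1.0
        Added to both CP10K group means inside the log ratio.
    convention : {"absolute", "signed"}
        "absolute" takes the percentile of pooled |log2FC| (symmetric +-T);
        "signed" uses the (100-p)/2 and 100-(100-p)/2 signed percentiles and
        takes T as the larger magnitude of the two bounds.
    seed : int
        Split randomness.
    """

    def __init__(
        self,
        n_iterations: int = DEFAULT_ITERATIONS,
        percentile: float = DEFAULT_PERCENTILE,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        convention: str = "absolute",
        seed: int = 0,
    ):
        self.n_iterations = n_iterations
        self.percentile = percentile
        self.pseudocount = pseudocount
        self.convention = convention
        self.seed = seed

    def fit(self, control_counts: np.ndarray, y=None) -> "FluctuationThreshold":
        if self.convention not in ("absolute", "signed"):
            raise ValueError(f"unknown convention {self.convention!r}")
        self.background_ = permute_background(
            control_counts, self.n_iterations, self.seed, self.pseudocount
        )
        if self.convention == "absolute":
            self.threshold_ = estimate_threshold(self.background_, self.percentile)
        else:
            tail = (100.0 - self.percentile) / 2.0
            lo, hi = np.percentile(
                self.background_.ravel(), [tail, 100.0 - tail], method="linear"
            )
            self.lower_, self.upper_ = float(lo), float(hi)
            self.threshold_ = float(max(abs(lo), abs(hi)))
        return self

    def assess(
        self, observed_log2fc: np.ndarray, gene_ids=None
    ) -> FluctuationResult:
        if not hasattr(self, "threshold_"):
            raise RuntimeError("FluctuationThreshold must be fit before assess")
        observed = np.asarray(observed_log2fc, dtype=np.float64)
        exceeds, fold_excess = assess_gene(observed, self.threshold_)
        if gene_ids is None:
            gene_ids = [f"g{i}" for i in range(observed.size)]
        table = pd.DataFrame(
            {
                "gene_id": list(gene_ids),
                "observed_log2fc": np.atleast_1d(observed),
                "exceeds": np.atleast_1d(exceeds),
                "fold_excess": np.atleast_1d(fold_excess),
            }
        )
        return FluctuationResult(
            n_iterations=self.n_iterations,
            background=self.background_,
            threshold=self.threshold_,
            percentile=self.percentile,
            convention=self.convention,
            seed=self.seed,
            pseudocount=self.pseudocount,
            observed=table,
        )
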