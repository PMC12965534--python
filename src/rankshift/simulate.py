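"""Synthetic two-condition single-cell count corpora with planted driver genes.

The generator emulates a droplet scRNA-seq experiment on a single cell type:
per-gene baseline means are log-normal across genes, per-cell sequencing depth
is a log-normal multiplicative factor, and counts are negative-binomial.
A chosen subset of "driver" genes is expressed higher in the control
condition than in the disease condition by a programmed log2 effect size, so
that removing a driver from a control cell's rank encoding is expected to push
its embedding toward the disease state.

Negative-binomial parameterization (used consistently package-wide):
mean ``mu`` and size (dispersion) ``theta`` with ``var = mu + mu**2 / theta``;
larger ``theta`` means closer to Poisson.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

CONTROL = "control"
DISEASE = "disease"
CONDITIONS = (CONTROL, DISEASE)


class SimulationError(ValueError):
    """Raised when a SimulationSpec field is invalid; names the field."""


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the synthetic corpus.

    Defaults are the package's standard study conditions: 1000 cells per
    condition, 300 genes, 10 drivers at log2FC = 2 (drivers higher in
    control), log-normal(0, 1) baseline means, NB size 2.0, log-normal(0, 0.3)
    library-size factors.
    """

    n_cells_control: int = 1000
    n_cells_disease: int = 1000
    n_genes: int = 300
    n_driver_genes: int = 10
    driver_log2fc: float = 2.0
    baseline_mean_log_params: tuple[float, float] = (0.0, 1.0)
    nb_dispersion: float = 2.0
    library_size_log_params: tuple[float, float] = (0.0, 0.3)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cells_control", "n_cells_disease", "n_genes"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise SimulationError(f"{name} must be an integer >= 1, got {v!r}")
        if not isinstance(self.n_driver_genes, (int, np.integer)) or self.n_driver_genes < 0:
            raise SimulationError(
                f"n_driver_genes must be an integer >= 0, got {self.n_driver_genes!r}"
            )
        if self.n_driver_genes > self.n_genes:
            raise SimulationError(
                f"n_driver_genes ({self.n_driver_genes}) exceeds n_genes ({self.n_genes})"
            )
        if not math.isfinite(self.driver_log2fc):
            raise SimulationError(f"driver_log2fc must be finite, got {self.driver_log2fc!r}")
        if not self.nb_dispersion > 0:
            raise SimulationError(f"nb_dispersion must be > 0, got {self.nb_dispersion!r}")
        for name in ("baseline_mean_log_params", "library_size_log_params"):
            v = getattr(self, name)
            if len(v) != 2 or v[1] < 0:
                raise SimulationError(f"{name} must be (mean, sd>=0), got {v!r}")

    def with_seed(self, seed: int) -> "SimulationSpec":
        return replace(self, seed=int(seed))


@dataclass
class ExpressionCorpus:
    """A cells x genes integer count matrix with two-state condition labels.

    ``ground_truth`` maps planted driver gene ids to their programmed log2
    effect size (control over disease); empty when no drivers were planted or
    the corpus came from outside the simulator.
    """

    gene_ids: np.ndarray
    cell_ids: np.ndarray
    counts: np.ndarray  # (n_cells, n_genes) non-negative integers
    condition: np.ndarray  # per-cell label in {"control", "disease"}
    ground_truth: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.counts = np.asarray(self.counts)
        self.condition = np.asarray(self.condition, dtype=object)
        self.validate()

    def validate(self) -> None:
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"cell_ids length {len(self.cell_ids)} != counts rows {n_cells}"
            )
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"gene_ids length {len(self.gene_ids)} != counts columns {n_genes}"
            )
        if len(self.condition) != n_cells:
            raise ValueError("condition labels must have one entry per cell")
        bad = set(self.condition) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition label(s): {sorted(bad)}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError(f"counts must be integer, got dtype {self.counts.dtype}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        unknown = set(self.ground_truth) - set(self.gene_ids)
        if unknown:
            raise ValueError(f"ground_truth genes not in gene_ids: {sorted(unknown)}")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def mask(self, condition: str) -> np.ndarray:
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        return self.condition == condition

    def subset_cells(self, index: np.ndarray) -> "ExpressionCorpus":
        index = np.asarray(index)
        return ExpressionCorpus(
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[index],
            counts=self.counts[index],
            condition=self.condition[index],
            ground_truth=dict(self.ground_truth),
        )


def simulate_corpus(spec: SimulationSpec) -> ExpressionCorpus:
    """Draw a two-condition corpus from the negative-binomial model.

    Driver genes have expected mean ``2**driver_log2fc`` times higher in
    control than in disease (before library-size scaling); all other genes are
    identically distributed across conditions. Bit-identical for a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n_cells = spec.n_cells_control + spec.n_cells_disease
    width = max(4, len(str(spec.n_genes)))
    gene_ids = np.array([f"G{i:0{width}d}" for i in range(spec.n_genes)], dtype=object)
    cell_ids = np.array([f"cell{i:05d}" for i in range(n_cells)], dtype=object)
    condition = np.array(
        [CONTROL] * spec.n_cells_control + [DISEASE] * spec.n_cells_disease, dtype=object
    )

    mu_log, sd_log = spec.baseline_mean_log_params
    base_mean = rng.lognormal(mean=mu_log, sigma=sd_log, size=spec.n_genes)
    driver_idx = rng.choice(spec.n_genes, size=spec.n_driver_genes, replace=False)
    driver_idx = np.sort(driver_idx)

    # disease means are the baseline; control drivers are scaled up
    mean_control = base_mean.copy()
    mean_control[driver_idx] *= 2.0 ** spec.driver_log2fc
    mean_disease = base_mean

    lib_mu, lib_sd = spec.library_size_log_params
    lib = rng.lognormal(mean=lib_mu, sigma=lib_sd, size=n_cells)

    per_cell_mean = np.where(
        (condition == CONTROL)[:, None], mean_control[None, :], mean_disease[None, :]
    )
    mu = lib[:, None] * per_cell_mean
    theta = spec.nb_dispersion
    p = theta / (theta + mu)
    counts = rng.negative_binomial(theta, p).astype(np.int64)

    ground_truth = {str(gene_ids[i]): float(spec.driver_log2fc) for i in driver_idx}
    return ExpressionCorpus(
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        counts=counts,
        condition=condition,
        ground_truth=ground_truth,
    )
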