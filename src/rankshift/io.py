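"""Reading and writing corpora on disk.

Layout follows the 10x Genomics convention: ``matrix.mtx`` is a Matrix Market
coordinate file with genes as rows and cells as columns, next to
``barcodes.tsv`` (one cell id per line), ``features.tsv`` (gene id TAB gene
name) and ``labels.tsv`` (cell id TAB condition). ``ground_truth.tsv``
(gene id TAB planted log2FC) is written when the corpus carries planted
drivers and read back when present. All files UTF-8, no header.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse

from .simulate import CONDITIONS, ExpressionCorpus


class CorpusFormatError(ValueError):
    """Malformed or mutually inconsistent corpus files."""


MATRIX_FILE = "matrix.mtx"
BARCODES_FILE = "barcodes.tsv"
FEATURES_FILE = "features.tsv"
LABELS_FILE = "labels.tsv"
GROUND_TRUTH_FILE = "ground_truth.tsv"


def write_corpus(corpus: ExpressionCorpus, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    sparse = scipy.sparse.coo_matrix(corpus.counts.T)  # genes x cells
    scipy.io.mmwrite(directory / MATRIX_FILE, sparse, field="integer")

    (directory / BARCODES_FILE).write_text(
        "".join(f"{c}\n" for c in corpus.cell_ids), encoding="utf-8"
    )
    (directory / FEATURES_FILE).write_text(
        "".join(f"{g}\t{g}\n" for g in corpus.gene_ids), encoding="utf-8"
    )
    (directory / LABELS_FILE).write_text(
        "".join(f"{c}\t{lab}\n" for c, lab in zip(corpus.cell_ids, corpus.condition)),
        encoding="utf-8",
    )
    if corpus.ground_truth:
        (directory / GROUND_TRUTH_FILE).write_text(
            "".join(f"{g}\t{fc}\n" for g, fc in sorted(corpus.ground_truth.items())),
            encoding="utf-8",
        )
    return directory


def _read_single_column(path: Path) -> list[str]:
    lines = path.read_text(encoding="utf-8").splitlines()
    out = []
    for i, line in enumerate(lines, start=1):
        v = line.split("\t")[0].strip()
        if not v:
            raise CorpusFormatError(f"{path}: empty id on line {i}")
        out.append(v)
    return out


def read_corpus(directory: str | Path) -> ExpressionCorpus:
    directory = Path(directory)
    mtx_path = directory / MATRIX_FILE
    try:
        matrix = scipy.io.mmread(mtx_path)
    except Exception as exc:  # malformed header / body
        raise CorpusFormatError(f"{mtx_path}: cannot parse Matrix Market file: {exc}") from exc
    counts = np.asarray(scipy.sparse.coo_matrix(matrix).todense()).T  # cells x genes
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise CorpusFormatError(f"{mtx_path}: non-integer entries in count matrix")
        counts = counts.astype(np.int64)

    gene_lines = (directory / FEATURES_FILE).read_text(encoding="utf-8").splitlines()
    gene_ids = []
    for i, line in enumerate(gene_lines, start=1):
        fields = line.split("\t")
        if not fields or not fields[0].strip():
            raise CorpusFormatError(f"{directory / FEATURES_FILE}: empty gene id on line {i}")
        gene_ids.append(fields[0].strip())
    cell_ids = _read_single_column(directory / BARCODES_FILE)

    n_cells, n_genes = counts.shape
    if len(gene_ids) != n_genes:
        raise CorpusFormatError(
            f"{directory / FEATURES_FILE}: {len(gene_ids)} features but "
            f"{mtx_path} declares {n_genes} genes"
        )
    if len(cell_ids) != n_cells:
        raise CorpusFormatError(
            f"{directory / BARCODES_FILE}: {len(cell_ids)} barcodes but "
            f"{mtx_path} declares {n_cells} cells"
        )

    labels_path = directory / LABELS_FILE
    label_by_cell: dict[str, str] = {}
    for i, line in enumerate(labels_path.read_text(encoding="utf-8").splitlines(), start=1):
        fields = line.split("\t")
        if len(fields) != 2:
            raise CorpusFormatError(f"{labels_path}: expected 'cell<TAB>label' on line {i}")
        cell, label = fields[0].strip(), fields[1].strip()
        if label not in CONDITIONS:
            raise CorpusFormatError(
                f"{labels_path}: unknown label {label!r} on line {i} "
                f"(expected one of {CONDITIONS})"
            )
        label_by_cell[cell] = label
    missing = [c for c in cell_ids if c not in label_by_cell]
    if missing:
        raise CorpusFormatError(f"{labels_path}: no label for cell(s) {missing[:5]}")
    condition = np.array([label_by_cell[c] for c in cell_ids], dtype=object)

    ground_truth: dict[str, float] = {}
    gt_path = directory / GROUND_TRUTH_FILE
    if gt_path.exists():
        for i, line in enumerate(gt_path.read_text(encoding="utf-8").splitlines(), start=1):
            fields = line.split("\t")
            if len(fields) != 2:
                raise CorpusFormatError(f"{gt_path}: expected 'gene<TAB>log2fc' on line {i}")
            ground_truth[fields[0].strip()] = float(fields[1])

    return ExpressionCorpus(
        gene_ids=np.array(gene_ids, dtype=object),
        cell_ids=np.array(cell_ids, dtype=object),
        counts=counts,
        condition=condition,
        ground_truth=ground_truth,
    )
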