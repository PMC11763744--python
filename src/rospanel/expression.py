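"""Expression matrix preparation: replicate averaging, housekeeping
normalization and annotation filtering.

Input is a gene x sample matrix of log2 expression values (already
summarized per gene upstream; no probe-level processing happens here)
plus a sample sheet mapping samples to cell lines. Replicates are
averaged per line, then every gene is normalized to a housekeeping gene
(default RPL13A) by subtraction on the log2 scale — the log-space
equivalent of the ratio-to-reference normalization. Because the
housekeeping value generally varies (if only by noise) across lines,
normalization subtracts a line-varying constant and can therefore change
downstream cross-line correlations; this is intended, documented
behaviour, not an invariance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pandas as pd

from rospanel.errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Log2 gene x cell-line matrix with processing provenance flags."""

    values: pd.DataFrame  # index: gene ids, columns: cell lines
    normalized: bool = False
    annotation_filtered: bool = False

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def cell_lines(self) -> pd.Index:
        return self.values.columns


def average_replicates(samples: pd.DataFrame, sample_sheet: pd.DataFrame) -> ExpressionMatrix:
    """Average log2 expression over each cell line's replicate samples.

    ``samples`` is genes x sample-ids; ``sample_sheet`` has columns
    sample_id, cell_line (replicate column optional). Every sample
    column must be mapped, every referenced sample must exist, and each
    cell line needs at least one replicate. Duplicate gene identifiers
    are rejected (ambiguous, not averaged).
    """
    if samples.index.duplicated().any():
        dupes = samples.index[samples.index.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate gene identifiers in expression input: {dupes}")
    for col in ("sample_id", "cell_line"):
        if col not in sample_sheet.columns:
            raise ValidationError(f"sample sheet missing column {col!r}")
    mapping = sample_sheet.set_index("sample_id")["cell_line"]
    unmapped = [c for c in samples.columns if c not in mapping.index]
    if unmapped:
        raise ValidationError(f"sample columns not in sample sheet: {unmapped[:5]}")
    absent = [s for s in mapping.index if s not in samples.columns]
    if absent:
        raise ValidationError(f"sample sheet references absent samples: {absent[:5]}")
    grouped = samples.T.groupby(mapping).mean().T
    # preserve first-appearance order of cell lines
    order = list(dict.fromkeys(mapping[samples.columns]))
    return ExpressionMatrix(values=grouped[order])


def housekeeping_normalize(matrix: ExpressionMatrix, hk_gene: str) -> ExpressionMatrix:
    """Subtract the housekeeping gene's log2 value from every gene, per line.

    The housekeeping row itself becomes identically zero, which also
    makes the operation idempotent.
    """
    if hk_gene not in matrix.values.index:
        raise ValidationError(f"housekeeping gene {hk_gene!r} absent from matrix")
    values = matrix.values.sub(matrix.values.loc[hk_gene], axis=1)
    return replace(matrix, values=values, normalized=True)


def filter_annotated(matrix: ExpressionMatrix, annotation: pd.DataFrame) -> ExpressionMatrix:
    """Drop genes whose annotation symbol is empty or absent.

    ``annotation`` has columns gene_id, symbol; an empty symbol marks an
    uncharacterized gene. Genes missing from the table entirely are also
    dropped (the coverage gap is logged).
    """
    for col in ("gene_id", "symbol"):
        if col not in annotation.columns:
            raise ValidationError(f"annotation table missing column {col!r}")
    symbols = annotation.set_index("gene_id")["symbol"].fillna("")
    uncovered = matrix.values.index.difference(symbols.index)
    if not uncovered.empty:
        logger.info("filter_annotated: %d genes absent from annotation table", len(uncovered))
    annotated = [
        g for g in matrix.values.index
        if g in symbols.index and str(symbols[g]).strip() != ""
    ]
    n_removed = len(matrix.values.index) - len(annotated)
    logger.info("filter_annotated: removed %d unannotated genes", n_removed)
    return replace(matrix, values=matrix.values.loc[annotated], annotation_filtered=True)
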