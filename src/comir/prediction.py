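"""End-to-end miRNA-target calls from shared promoter cis-elements.

For a mature miRNA, each assigned pre-miRNA contributes one promoter; a
candidate gene is predicted as a target when the common-element spectrum
between the gene promoter and at least one of those pre-miRNA promoters is
significant against the background null (union over pre-miRNAs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .annotations import MatureMirna
from .common_elements import pair_spectrum
from .conservation import MIN_ELEMENT_LENGTH, PutativeCisElement
from .significance import DEFAULT_ALPHA, NullDistribution, SignificanceResult, test_significance

Elements = Sequence[PutativeCisElement]
NullLookup = Union[NullDistribution, Callable[[str, str], NullDistribution]]


@dataclass(frozen=True)
class PredictionRecord:
    """Target call for one (mature miRNA, gene): significance per pre-miRNA,
    predicted iff significant for at least one assigned pre-miRNA."""

    mature_id: str
    gene_id: str
    per_pre: tuple[tuple[str, SignificanceResult], ...]
    predicted: bool

    @property
    def best_corrected_p(self) -> float:
        return min((r.min_corrected_p for _, r in self.per_pre), default=1.0)

    @property
    def supporting_pres(self) -> tuple[str, ...]:
        return tuple(pre_id for pre_id, r in self.per_pre if r.significant)


@dataclass
class PredictionResources:
    """Precomputed inputs for a prediction scan.

    ``null`` may be a single shared NullDistribution or a callable
    ``(pre_id, gene_id) -> NullDistribution`` for stratum-matched nulls.
    """

    pre_elements: Mapping[str, Elements]
    gene_elements: Mapping[str, Elements]
    null: NullLookup
    alpha: float = DEFAULT_ALPHA
    min_len: int = MIN_ELEMENT_LENGTH

    def null_for(self, pre_id: str, gene_id: str) -> NullDistribution:
        if callable(self.null):
            return self.null(pre_id, gene_id)
        return self.null


def predict_targets(
    mature: MatureMirna,
    gene_ids: Iterable[str],
    resources: PredictionResources,
) -> tuple[PredictionRecord, ...]:
    """Scan candidate genes for one mature miRNA.

    Each assigned pre-miRNA's promoter elements are compared against every
    gene promoter's elements; the gene is predicted when the spectrum is
    significant for any pre-miRNA. Genes whose promoters yielded no elements
    produce non-predicted records, not errors. A mature miRNA with no
    assigned pre-miRNA cannot be evaluated and is an error (such matures are
    discarded upstream).
    """
    pre_ids = sorted(mature.assigned_pre)
    if not pre_ids:
        raise ValueError(f"mature miRNA {mature.mature_id} has no assigned pre-miRNA")
    missing = [p for p in pre_ids if p not in resources.pre_elements]
    if missing:
        raise KeyError(f"no promoter elements for pre-miRNA(s): {missing}")

    records = []
    for gene_id in sorted(set(gene_ids)):
        per_pre = []
        for pre_id in pre_ids:
            spectrum = pair_spectrum(
                resources.pre_elements[pre_id],
                resources.gene_elements.get(gene_id, ()),
                min_len=resources.min_len,
            )
            result = test_significance(
                spectrum, resources.null_for(pre_id, gene_id), alpha=resources.alpha
            )
            per_pre.append((pre_id, result))
        predicted = any(r.significant for _, r in per_pre)
        records.append(
            PredictionRecord(
                mature_id=mature.mature_id,
                gene_id=gene_id,
                per_pre=tuple(per_pre),
                predicted=predicted,
            )
        )
    return tuple(records)


def intersect_predictions(p: Iterable[str], q: Iterable[str]) -> frozenset[str]:
    """Combine two methods' target lists by set intersection."""
    return frozenset(p) & frozenset(q)


def predictions_frame(records: Iterable[PredictionRecord]) -> pd.DataFrame:
    """Tabular view of prediction records, sorted for stable output files."""
    rows = [
        {
            "mature_id": r.mature_id,
            "gene_id": r.gene_id,
            "best_corrected_p": r.best_corrected_p,
            "supporting_pres": ",".join(r.supporting_pres),
            "predicted": r.predicted,
        }
        for r in records
    ]
    frame = pd.DataFrame(
        rows, columns=["mature_id", "gene_id", "best_corrected_p", "supporting_pres", "predicted"]
    )
    return frame.sort_values(["mature_id", "gene_id"], kind="mergesort").reset_index(drop=True)


def evaluate_against_pairs(
    predictions: Mapping[str, Iterable[str]],
    known_pairs: Iterable[tuple[str, str]],
) -> tuple[int, pd.DataFrame]:
    """Score predictions against experimentally supported (miRNA, gene) pairs.

    Returns the true-positive count and a per-pair hit table (miRNA, target
    gene, prediction mark).
    """
    predicted_sets = {m: frozenset(genes) for m, genes in predictions.items()}
    rows = []
    hits = 0
    for mature_id, gene_id in sorted(set(known_pairs)):
        hit = gene_id in predicted_sets.get(mature_id, frozenset())
        hits += int(hit)
        rows.append({"mirna": mature_id, "target_gene": gene_id, "prediction": "o" if hit else "x"})
    table = pd.DataFrame(rows, columns=["mirna", "target_gene", "prediction"])
    return hits, table
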