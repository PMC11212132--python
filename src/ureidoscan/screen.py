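"""Evaluation of the ureido signature against labels, and neighborhood rules.

``evaluate_signature`` scores the exact-match EHHXXHDG rule on a labeled
domain set as a binary classifier (positive = ureido-forming), reporting a
confusion matrix with sensitivity and specificity.

``neighborhood_call`` applies the genome-neighborhood rule separating
PEARL-like glutamylation enzymes from class I lantibiotic dehydratases:
a gene carrying the glutamylation family PF04738 is dehydratase-like when
the elimination family PF14028 co-occurs anywhere in the same cluster, and
PEARL-like otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .classify import C_UREA
from .records import BgcRecord, LabelTable

GLUTAMYLATION_FAMILY = "PF04738"
ELIMINATION_FAMILY = "PF14028"

PEARL_LIKE = "pearl_like"
DEHYDRATASE_LIKE = "dehydratase_like"
NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class ScreenResult:
    """Confusion matrix of the signature rule on a labeled set.

    Positive = labeled ``urea``; predicted positive = classified C_urea.
    Rates are None (reported as NA) when their denominator is 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    misclassified: tuple[str, ...] = ()

    @property
    def n_labeled(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float | None:
        denom = self.tp + self.fn
        return self.tp / denom if denom else None

    @property
    def specificity(self) -> float | None:
        denom = self.tn + self.fp
        return self.tn / denom if denom else None

    def summary(self) -> str:
        fmt = lambda x: "NA" if x is None else f"{x:.3f}"
        return (
            f"TP={self.tp} FP={self.fp} TN={self.tn} FN={self.fn} "
            f"sensitivity={fmt(self.sensitivity)} specificity={fmt(self.specificity)}"
        )


def evaluate_signature(
    classified: Mapping[str, str], labels: LabelTable
) -> ScreenResult:
    """Score classified octamer labels against function labels.

    ``classified`` maps each domain id to its motif class (``C_urea``,
    ``canonical_C`` or ``noncanonical``). Every labeled id must be present;
    missing ids raise :class:`ValueError` listing them.
    """
    missing = [did for did in labels if did not in classified]
    if missing:
        raise ValueError(f"labeled ids without a classified hit: {sorted(missing)}")
    tp = fp = tn = fn = 0
    bad: list[str] = []
    for did, function in labels.items():
        predicted_positive = classified[did] == C_UREA
        truly_positive = function == "urea"
        if predicted_positive and truly_positive:
            tp += 1
        elif predicted_positive and not truly_positive:
            fp += 1
            bad.append(did)
        elif not predicted_positive and truly_positive:
            fn += 1
            bad.append(did)
        else:
            tn += 1
    return ScreenResult(tp, fp, tn, fn, tuple(sorted(bad)))


@dataclass(frozen=True)
class NeighborhoodCall:
    """Classification of one gene under the PF04738/PF14028 co-occurrence rule."""

    gene_id: str
    call: str
    evidence: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.call in (PEARL_LIKE, DEHYDRATASE_LIKE) and GLUTAMYLATION_FAMILY not in self.evidence:
            raise ValueError(f"{self.call} call requires {GLUTAMYLATION_FAMILY} evidence")


def neighborhood_call(record: BgcRecord) -> list[NeighborhoodCall]:
    """Apply the PEARL-vs-dehydratase rule to each gene of a BGC record.

    A gene with the glutamylation family PF04738 is called
    ``dehydratase_like`` if the elimination family PF14028 occurs on the
    same gene or any other gene in the record, else ``pearl_like``. Genes
    without PF04738 are ``not_applicable``.
    """
    record_has_elimination = ELIMINATION_FAMILY in record.all_families()
    calls = []
    for gene in record.genes:
        fams = set(gene.family_annotations)
        if GLUTAMYLATION_FAMILY not in fams:
            calls.append(NeighborhoodCall(gene.gene_id, NOT_APPLICABLE, ()))
            continue
        evidence = {GLUTAMYLATION_FAMILY}
        if record_has_elimination:
            evidence.add(ELIMINATION_FAMILY)
            call = DEHYDRATASE_LIKE
        else:
            call = PEARL_LIKE
        calls.append(NeighborhoodCall(gene.gene_id, call, tuple(sorted(evidence))))
    return calls
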