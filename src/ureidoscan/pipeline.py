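"""End-to-end drivers wiring scan -> classify -> screen.

These are the functions the CLI, the analysis scripts and the acceptance
checks share. Strategy: every protein is scanned strictly first; proteins
with no strict anchor fall back to relaxed candidates (which can never be
classified ureido-forming), so a classified call exists for every labeled
protein, including motif-free negatives.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

from .classify import NONCANONICAL, ActiveSiteMotif, map_motif_coords
from .records import LabelTable, ProteinRecord
from .scanner import DomainHit, Profile, scan_protein
from .screen import ScreenResult, evaluate_signature

log = logging.getLogger(__name__)


def classify_proteins(
    records: Sequence[ProteinRecord],
    profile: Profile | None = None,
    *,
    relaxed_fallback: bool = True,
    upstream: int = 150,
    downstream: int = 300,
) -> tuple[dict[str, str], dict[str, DomainHit], dict[str, ActiveSiteMotif]]:
    """Scan and classify each protein's best active-site candidate.

    Returns (labels by protein id, best hit by id, motif report by id).
    Proteins with no candidate anchor at all are labeled noncanonical and
    have no hit entry.
    """
    labels: dict[str, str] = {}
    hits: dict[str, DomainHit] = {}
    motifs: dict[str, ActiveSiteMotif] = {}
    for rec in records:
        found = scan_protein(rec, profile=profile, upstream=upstream, downstream=downstream)
        if not found and relaxed_fallback:
            found = scan_protein(
                rec, profile=profile, relaxed=True, upstream=upstream, downstream=downstream
            )
        if not found:
            labels[rec.id] = NONCANONICAL
            continue
        top = found[0]
        motif = map_motif_coords(top)
        # relaxed anchors are degraded cores and are never called ureido
        labels[rec.id] = NONCANONICAL if top.relaxed else motif.label
        hits[rec.id] = top
        motifs[rec.id] = motif
    return labels, hits, motifs


def run_screen(
    records: Sequence[ProteinRecord],
    labels: LabelTable,
    profile: Profile | None = None,
) -> tuple[ScreenResult, dict[str, str]]:
    """Scan, classify and evaluate the ureido signature against labels."""
    classified, _, _ = classify_proteins(records, profile=profile)
    result = evaluate_signature(classified, labels)
    log.info("signature screen: %s", result.summary())
    return result, classified
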