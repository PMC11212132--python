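"""Classification of condensation-domain active-site octamers.

The 8-residue active-site window M1..M8 is classified against two exact
patterns:

* ``C_urea`` — the ureido-forming signature EHHXXHDG
  (M1=E, M2=H, M3=H, M6=H, M7=D, M8=G);
* ``canonical_C`` — the canonical amide-forming core XHHXXXDG
  (M2=H, M3=H, M7=D, M8=G) when the window is not ``C_urea``;
* ``noncanonical`` — everything else.

The ureido pattern is a strict specialization of the canonical one: the
extra conserved glutamate (M1) and histidine (M6) mark ureido-forming
activity. Matching is exact; X never satisfies a constrained position.
"""

from __future__ import annotations

from dataclasses import dataclass

from .msa import Alignment
from .records import ALPHABET
from .scanner import DomainHit

#: Constraints of the ureido-forming signature EHHXXHDG (offset from M1).
UREA_POSITIONS: dict[int, str] = {0: "E", 1: "H", 2: "H", 5: "H", 6: "D", 7: "G"}
#: Constraints of the canonical core XHHXXXDG (offset from M1).
CANONICAL_POSITIONS: dict[int, str] = {1: "H", 2: "H", 6: "D", 7: "G"}

C_UREA = "C_urea"
CANONICAL_C = "canonical_C"
NONCANONICAL = "noncanonical"


def classify_active_site(octamer: str) -> str:
    """Classify an M1..M8 octamer as C_urea, canonical_C or noncanonical."""
    if len(octamer) != 8:
        raise ValueError(f"active-site octamer must have 8 residues, got {len(octamer)}")
    bad = set(octamer) - ALPHABET
    if bad:
        raise ValueError(f"octamer contains illegal residues: {sorted(bad)}")
    if all(octamer[k] == aa for k, aa in UREA_POSITIONS.items()):
        return C_UREA
    if all(octamer[k] == aa for k, aa in CANONICAL_POSITIONS.items()):
        return CANONICAL_C
    return NONCANONICAL


@dataclass(frozen=True)
class ActiveSiteMotif:
    """A classified octamer with 1-based protein coordinates of M1..M8."""

    octamer: str
    label: str
    coords: dict[str, int]

    def __post_init__(self) -> None:
        if len(self.octamer) != 8:
            raise ValueError("octamer must have 8 residues")
        if self.coords["M8"] - self.coords["M1"] != 7:
            raise ValueError("M1..M8 coordinates must span exactly 8 residues")


def map_motif_coords(hit: DomainHit) -> ActiveSiteMotif:
    """Map a hit's motif positions to 1-based protein residue numbers.

    ``coords['Mk']`` is ``motif_start + k`` in 1-based numbering, so e.g.
    a hit with 0-based ``motif_start = 743`` reports the catalytic
    glutamate M1 at residue 744.
    """
    coords = {f"M{k}": hit.motif_start + k for k in range(1, 9)}
    return ActiveSiteMotif(hit.octamer, classify_active_site(hit.octamer), coords)


@dataclass(frozen=True)
class ConservedSerReport:
    """A conserved downstream serine mapped onto one protein."""

    protein_id: str
    ser_index: int  # 1-based protein residue index
    offset_from_M8: int  # in ungapped residues of this protein


def find_conserved_ser(
    alignment: Alignment,
    hits: list[DomainHit],
    *,
    max_columns_downstream: int = 30,
    min_occupancy: float = 0.9,
) -> list[ConservedSerReport]:
    """Locate the fully conserved serine downstream of the active site.

    ``alignment`` holds the extracted domain regions keyed by protein id;
    each hit provides the coordinate back-mapping. The nearest alignment
    column strictly downstream of the M8 column in which every ungapped
    residue is S and at least ``min_occupancy`` of rows are ungapped is
    mapped to each protein's 1-based coordinate. Returns an empty list if
    no such column exists within ``max_columns_downstream`` columns.
    """
    by_id = {h.protein_id: h for h in hits}
    missing = [pid for pid in by_id if pid not in alignment.rows]
    if missing:
        raise ValueError(f"hits not present in alignment: {sorted(missing)}")

    # the M8 column, from each row's hit; the register must agree
    m8_cols = set()
    for pid, hit in by_id.items():
        m8_residue = hit.motif_start - hit.domain_start + 7
        m8_cols.add(alignment.column_of_residue(pid, m8_residue))
    if len(m8_cols) != 1:
        raise ValueError(
            f"active-site register is not aligned: M8 falls in columns {sorted(m8_cols)}"
        )
    m8_col = m8_cols.pop()

    n_rows = len(alignment.rows)
    limit = min(alignment.length, m8_col + 1 + max_columns_downstream)
    for c in range(m8_col + 1, limit):
        col = alignment.column(c)
        residues = [ch for ch in col if ch != "-"]
        if not residues or len(residues) / n_rows < min_occupancy:
            continue
        if any(ch != "S" for ch in residues):
            continue
        reports = []
        for pid, hit in by_id.items():
            cmap = alignment.column_map(pid)
            if cmap[c] is None:
                continue
            ser_residue = cmap[c]  # 0-based within the extracted domain
            m8_residue = hit.motif_start - hit.domain_start + 7
            reports.append(
                ConservedSerReport(
                    protein_id=pid,
                    ser_index=hit.domain_start + ser_residue + 1,
                    offset_from_M8=ser_residue - m8_residue,
                )
            )
        return reports
    return []
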