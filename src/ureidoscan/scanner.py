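"""Active-site anchoring and profile scoring for condensation domains.

NRPS condensation (C) domains carry an 8-residue active-site register,
written here M1..M8. The canonical amide-forming motif is XHHXXXDG: only
M2=H, M3=H, M7=D and M8=G are fixed. Anchoring therefore scans for those
four fixed positions exactly (an auditable, exhaustive operation), and all
discrimination between candidate anchors is delegated to a position-specific
scoring matrix (PSSM) built from an alignment of known active-site regions.

A "relaxed" scan additionally admits windows matching 3 of the 4 fixed
positions; such hits are flagged and are never classified as ureido-forming
downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .records import STANDARD_AA, ProteinRecord

log = logging.getLogger(__name__)

#: Fixed positions of the canonical core motif, as offsets from M1:
#: M2=H, M3=H, M7=D, M8=G.
CORE_POSITIONS: dict[int, str] = {1: "H", 2: "H", 6: "D", 7: "G"}

_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}


class CoreMatch(NamedTuple):
    """A candidate M1 index; ``relaxed`` marks a 3-of-4 fixed-position match."""

    start: int
    relaxed: bool


def _sequence_of(record) -> str:
    return record.sequence if isinstance(record, ProteinRecord) else str(record)


def core_match_count(sequence: str, start: int) -> int:
    """Number of the 4 fixed core positions satisfied by the window at ``start``."""
    return sum(
        1
        for off, aa in CORE_POSITIONS.items()
        if sequence[start + off] == aa
    )


def find_core_motifs(record, relaxed: bool = False) -> list[CoreMatch]:
    """Scan for active-site anchor candidates.

    Strict mode returns every 0-based index ``i`` with ``seq[i+1] == 'H'``,
    ``seq[i+2] == 'H'``, ``seq[i+6] == 'D'`` and ``seq[i+7] == 'G'``, in
    ascending order. Relaxed mode additionally returns windows satisfying
    exactly 3 of the 4 fixed positions, flagged ``relaxed=True``. X never
    satisfies a fixed position. Sequences shorter than 8 yield an empty list.
    """
    seq = _sequence_of(record)
    out: list[CoreMatch] = []
    for i in range(len(seq) - 7):
        n = core_match_count(seq, i)
        if n == 4:
            out.append(CoreMatch(i, False))
        elif relaxed and n == 3:
            out.append(CoreMatch(i, True))
    return out


# ---------------------------------------------------------------------------
# Profile (PSSM)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Profile:
    """A per-column amino-acid frequency model with log-odds scores.

    ``frequencies`` and ``logodds`` are ``(n_columns, 20)`` arrays over the
    standard amino acids (alphabetical one-letter order); ``logodds`` is in
    bits: ``log2(freq / background)``. ``window_offsets = (upstream,
    downstream)`` places the profile relative to an anchor: column ``c``
    scores sequence position ``motif_start - upstream + c``, so
    ``upstream + downstream`` must equal ``n_columns``.
    """

    frequencies: np.ndarray
    background: np.ndarray
    logodds: np.ndarray
    pseudocount: float
    window_offsets: tuple[int, int]

    @property
    def n_columns(self) -> int:
        return self.frequencies.shape[0]

    def __post_init__(self) -> None:
        up, down = self.window_offsets
        if up + down != self.frequencies.shape[0]:
            raise ValueError(
                f"window_offsets {self.window_offsets} inconsistent with "
                f"{self.frequencies.shape[0]} profile columns"
            )
        if not np.allclose(self.frequencies.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("profile frequency columns must each sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background frequencies must sum to 1")


def build_profile(
    alignment: Sequence[str],
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
    window_offsets: tuple[int, int] = (30, 10),
) -> Profile:
    """Build a :class:`Profile` from equal-length aligned rows.

    Per column, ``freq[a] = (count[a] + pseudocount) / (n_ungapped +
    20 * pseudocount)``; gap characters and X are excluded from counts.
    A column with no countable residues falls back to the background
    (logged). ``background`` defaults to uniform 1/20.
    """
    if not alignment:
        raise ValueError("alignment must be nonempty")
    length = len(alignment[0])
    if any(len(row) != length for row in alignment):
        raise ValueError("ragged alignment: rows differ in length")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if background is None:
        background = np.full(20, 1.0 / 20.0)
    background = np.asarray(background, dtype=float)
    if background.shape != (20,) or not math.isclose(float(background.sum()), 1.0, abs_tol=1e-6):
        raise ValueError("background must be a 20-vector summing to 1")
    background = background / background.sum()

    freqs = np.empty((length, 20), dtype=float)
    for c in range(length):
        counts = np.zeros(20, dtype=float)
        n_ungapped = 0
        for row in alignment:
            idx = _AA_INDEX.get(row[c])
            if idx is not None:
                counts[idx] += 1.0
                n_ungapped += 1
        if n_ungapped == 0:
            log.warning("profile column %d has no countable residues; using background", c)
            freqs[c] = background
        else:
            freqs[c] = (counts + pseudocount) / (n_ungapped + 20.0 * pseudocount)
            freqs[c] /= freqs[c].sum()
    logodds = np.log2(freqs / background)
    return Profile(freqs, background, logodds, pseudocount, tuple(window_offsets))


def score_anchor(profile: Profile, record, motif_start: int) -> float:
    """Profile log-odds score (bits) for the anchor at ``motif_start``.

    Column ``c`` scores the residue at ``motif_start - upstream + c``;
    positions clipped off the sequence, and X residues, contribute 0.
    """
    seq = _sequence_of(record)
    if not (0 <= motif_start <= len(seq) - 8):
        raise ValueError(
            f"motif_start {motif_start} out of range for sequence of length {len(seq)}"
        )
    upstream, _ = profile.window_offsets
    total = 0.0
    for c in range(profile.n_columns):
        pos = motif_start - upstream + c
        if 0 <= pos < len(seq):
            idx = _AA_INDEX.get(seq[pos])
            if idx is not None:
                total += float(profile.logodds[c, idx])
    return total


# ---------------------------------------------------------------------------
# Domain excision
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainHit:
    """A located condensation-domain region with its active-site anchor.

    Coordinates are 0-based half-open over the parent protein; ``octamer``
    is the M1..M8 window, ``score`` the anchor's profile log-odds in bits,
    and ``relaxed`` marks anchors admitted with one fixed-position mismatch.
    """

    protein_id: str
    domain_start: int
    domain_end: int
    motif_start: int
    octamer: str
    score: float = 0.0
    relaxed: bool = False

    def __post_init__(self) -> None:
        if len(self.octamer) != 8:
            raise ValueError("octamer must have exactly 8 residues")
        if not (self.domain_start <= self.motif_start and self.motif_start + 8 <= self.domain_end):
            raise ValueError(
                f"inconsistent hit coordinates for {self.protein_id!r}: "
                f"domain [{self.domain_start}, {self.domain_end}), motif_start {self.motif_start}"
            )


def extract_cdomain(
    record: ProteinRecord,
    motif_start: int,
    upstream: int = 150,
    downstream: int = 300,
    *,
    score: float = 0.0,
    relaxed: bool = False,
) -> DomainHit:
    """Excise the domain region around an anchor, clipped to the sequence.

    ``domain_start = max(0, motif_start - upstream)``;
    ``domain_end = min(L, motif_start + downstream)``. Defaults bracket a
    typical ~450-residue condensation domain.
    """
    L = len(record.sequence)
    if not (0 <= motif_start <= L - 8):
        raise ValueError(f"motif_start {motif_start} out of range for {record.id!r}")
    start = max(0, motif_start - upstream)
    end = min(L, motif_start + downstream)
    end = max(end, motif_start + 8)
    octamer = record.sequence[motif_start : motif_start + 8]
    return DomainHit(record.id, start, end, motif_start, octamer, score=score, relaxed=relaxed)


def scan_protein(
    record: ProteinRecord,
    profile: Profile | None = None,
    relaxed: bool = False,
    min_score: float | None = None,
    upstream: int = 150,
    downstream: int = 300,
) -> list[DomainHit]:
    """Scan a protein and return ranked :class:`DomainHit` candidates.

    Candidates are anchored with :func:`find_core_motifs`, scored with the
    profile when one is given (score 0 otherwise), and ranked by descending
    score; score ties prefer exact-core over relaxed anchors, then the
    leftmost anchor. ``min_score`` (bits) filters hits when a profile is
    supplied.
    """
    hits = []
    for match in find_core_motifs(record, relaxed=relaxed):
        s = score_anchor(profile, record, match.start) if profile is not None else 0.0
        if profile is not None and min_score is not None and s < min_score:
            continue
        hits.append(
            extract_cdomain(
                record, match.start, upstream, downstream, score=s, relaxed=match.relaxed
            )
        )
    hits.sort(key=lambda h: (-h.score, h.relaxed, h.motif_start))
    return hits


def best_hit(
    record: ProteinRecord,
    profile: Profile | None = None,
    relaxed: bool = False,
    **kwargs,
) -> DomainHit | None:
    """Top-ranked hit for a protein, or None if no candidate anchor exists."""
    hits = scan_protein(record, profile=profile, relaxed=relaxed, **kwargs)
    return hits[0] if hits else None
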