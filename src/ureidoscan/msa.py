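"""Pairwise and progressive multiple alignment, and column conservation.

Pairwise alignment is global (Needleman–Wunsch) with affine gap costs under
the three-state Gotoh recurrence: a gap run of length ``k`` costs
``gap_open + (k - 1) * gap_extend``. Traceback is deterministic with tie
order diagonal > up > left ("up" consumes a residue of the first sequence
against a gap). The default substitution table is BLOSUM62 with
``gap_open=11, gap_extend=1``.

Progressive alignment merges profiles in guide-tree postorder with the same
affine scheme; gaps, once introduced into a group, are never removed
("once a gap, always a gap"). The guide tree is a neighbor-joining tree on
pairwise identity distances unless one is supplied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .records import STANDARD_AA, ProteinRecord

log = logging.getLogger(__name__)

GAP = "-"

#: Symbol order used for numeric encoding: 20 amino acids, then X, then gap.
_SYMBOLS = STANDARD_AA + "X" + GAP
_SYM_INDEX = {s: i for i, s in enumerate(_SYMBOLS)}
_X_IDX = 20
_GAP_IDX = 21

_BLOSUM62_CACHE: np.ndarray | None = None


def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 as a (22, 22) array over ``STANDARD_AA + 'X' + '-'``.

    X rows/columns carry the BLOSUM62 X scores; anything against a gap
    scores 0 here (gap costs are handled by the affine penalties).
    """
    global _BLOSUM62_CACHE
    if _BLOSUM62_CACHE is None:
        raw = substitution_matrices.load("BLOSUM62")
        M = np.zeros((22, 22), dtype=float)
        for i, a in enumerate(_SYMBOLS[:21]):
            for j, b in enumerate(_SYMBOLS[:21]):
                M[i, j] = raw[a, b]
        _BLOSUM62_CACHE = M
    return _BLOSUM62_CACHE


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_SYM_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"illegal symbol {exc.args[0]!r} in sequence") from exc


class PairwiseAlignment(NamedTuple):
    aligned_a: str
    aligned_b: str
    score: float


_NEG_INF = float("-inf")


def global_align(
    a: str,
    b: str,
    substitution: np.ndarray | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> PairwiseAlignment:
    """Optimal affine-gap global alignment of two sequences.

    Returns the aligned rows and the optimal score. An empty sequence
    aligns all-gap with score ``-(gap_open + gap_extend * (n - 1))``.
    """
    if gap_open < gap_extend or gap_extend < 0:
        raise ValueError("require gap_open >= gap_extend >= 0")
    if substitution is None:
        substitution = blosum62_matrix()
    if not a and not b:
        return PairwiseAlignment("", "", 0.0)
    if not a or not b:
        n = max(len(a), len(b))
        score = -(gap_open + gap_extend * (n - 1))
        return PairwiseAlignment(a or GAP * n, b or GAP * n, score)

    ea, eb = _encode(a), _encode(b)
    S = substitution[np.ix_(ea, eb)]
    aligned = _affine_dp(S, gap_open, gap_extend)
    ra, rb = [], []
    for i, j in aligned.path:
        ra.append(a[i] if i >= 0 else GAP)
        rb.append(b[j] if j >= 0 else GAP)
    return PairwiseAlignment("".join(ra), "".join(rb), aligned.score)


class _DpResult(NamedTuple):
    score: float
    # path entries: (i, j) with -1 for a gap on that side
    path: list[tuple[int, int]]


def _affine_dp(S: np.ndarray, gap_open: float, gap_extend: float) -> _DpResult:
    """Three-state Gotoh DP over a precomputed column-score matrix ``S``.

    States: M (diagonal), X (gap in the second sequence; "up"), Y (gap in
    the first; "left"). Ties prefer M > X > Y everywhere, which realizes
    the diagonal > up > left traceback order.
    """
    n, m = S.shape
    M = np.full((n + 1, m + 1), _NEG_INF)
    X = np.full((n + 1, m + 1), _NEG_INF)
    Y = np.full((n + 1, m + 1), _NEG_INF)
    # backpointers: state entered from (0=M, 1=X, 2=Y)
    bM = np.zeros((n + 1, m + 1), dtype=np.int8)
    bX = np.zeros((n + 1, m + 1), dtype=np.int8)
    bY = np.zeros((n + 1, m + 1), dtype=np.int8)

    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + gap_extend * (i - 1))
        bX[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + gap_extend * (j - 1))
        bY[0, j] = 0 if j == 1 else 2

    for i in range(1, n + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        bMi, bXi, bYi = bM[i], bX[i], bY[i]
        Si = S[i - 1]
        for j in range(1, m + 1):
            # M: consume a[i-1], b[j-1]
            pm, px, py = Mi1[j - 1], Xi1[j - 1], Yi1[j - 1]
            if pm >= px and pm >= py:
                Mi[j], bMi[j] = pm + Si[j - 1], 0
            elif px >= py:
                Mi[j], bMi[j] = px + Si[j - 1], 1
            else:
                Mi[j], bMi[j] = py + Si[j - 1], 2
            # X: consume a[i-1] against a gap ("up")
            om, ox, oy = Mi1[j] - gap_open, Xi1[j] - gap_extend, Yi1[j] - gap_open
            if om >= ox and om >= oy:
                Xi[j], bXi[j] = om, 0
            elif ox >= oy:
                Xi[j], bXi[j] = ox, 1
            else:
                Xi[j], bXi[j] = oy, 2
            # Y: consume b[j-1] against a gap ("left")
            om, ox, oy = Mi[j - 1] - gap_open, Xi[j - 1] - gap_open, Yi[j - 1] - gap_extend
            if om >= ox and om >= oy:
                Yi[j], bYi[j] = om, 0
            elif ox >= oy:
                Yi[j], bYi[j] = ox, 1
            else:
                Yi[j], bYi[j] = oy, 2

    finals = (M[n, m], X[n, m], Y[n, m])
    state = int(np.argmax([finals[0], finals[1], finals[2]]))
    # argmax returns the first maximum, realizing the M > X > Y preference
    score = finals[state]

    path: list[tuple[int, int]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            prev = bM[i, j]
            i, j = i - 1, j - 1
            path.append((i, j))
        elif state == 1:
            prev = bX[i, j]
            i = i - 1
            path.append((i, -1))
        else:
            prev = bY[i, j]
            j = j - 1
            path.append((-1, j))
        state = int(prev)
    path.reverse()
    return _DpResult(float(score), path)


def pairwise_distance(aligned_a: str, aligned_b: str) -> float:
    """1 - (identities / aligned columns), excluding dual-gap columns."""
    ident = 0
    comparable = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == GAP and y == GAP:
            continue
        comparable += 1
        if x == y and x != GAP:
            ident += 1
    if comparable == 0:
        log.warning("no comparable columns in aligned pair; distance set to 1")
        return 1.0
    return 1.0 - ident / comparable


# ---------------------------------------------------------------------------
# Alignment container
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """A columnar multiple sequence alignment keyed by row id."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must have at least one row")
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError("alignment rows differ in length")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def degapped(self, row_id: str) -> str:
        return self.rows[row_id].replace(GAP, "")

    def column_map(self, row_id: str) -> list[int | None]:
        """Per column: 0-based ungapped residue index, or None at a gap."""
        out: list[int | None] = []
        k = 0
        for ch in self.rows[row_id]:
            if ch == GAP:
                out.append(None)
            else:
                out.append(k)
                k += 1
        return out

    def column(self, c: int) -> list[str]:
        return [row[c] for row in self.rows.values()]

    def column_of_residue(self, row_id: str, residue_index: int) -> int:
        """Alignment column holding the row's 0-based ungapped residue."""
        k = 0
        for c, ch in enumerate(self.rows[row_id]):
            if ch != GAP:
                if k == residue_index:
                    return c
                k += 1
        raise IndexError(f"residue index {residue_index} beyond row {row_id!r}")


# ---------------------------------------------------------------------------
# Progressive MSA
# ---------------------------------------------------------------------------

def _profile_counts(rows: Sequence[str]) -> np.ndarray:
    """(L, 21) per-column counts over amino acids + X (gaps excluded)."""
    L = len(rows[0])
    counts = np.zeros((L, 21), dtype=float)
    for row in rows:
        for c, ch in enumerate(row):
            idx = _SYM_INDEX[ch]
            if idx != _GAP_IDX:
                counts[c, idx] += 1.0
    return counts


def _merge_groups(
    rows_a: list[str],
    rows_b: list[str],
    substitution: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> tuple[list[str], list[str]]:
    """Profile–profile alignment of two gapped row groups."""
    ca = _profile_counts(rows_a)
    cb = _profile_counts(rows_b)
    S21 = substitution[:21, :21]
    # average substitution score over all residue pairs of the two columns
    denom = len(rows_a) * len(rows_b)
    S = (ca @ S21 @ cb.T) / denom
    result = _affine_dp(S, gap_open, gap_extend)
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    for i, j in result.path:
        for k, row in enumerate(rows_a):
            out_a[k] += row[i] if i >= 0 else GAP
        for k, row in enumerate(rows_b):
            out_b[k] += row[j] if j >= 0 else GAP
    return out_a, out_b


def distance_matrix(records: Sequence[ProteinRecord], **align_kwargs):
    """Pairwise identity distances from affine global alignments."""
    from skbio import DistanceMatrix

    n = len(records)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(records[i].sequence, records[j].sequence, **align_kwargs)
            D[i, j] = D[j, i] = pairwise_distance(aln.aligned_a, aln.aligned_b)
    return DistanceMatrix(D, [r.id for r in records])


def progressive_msa(
    records: Sequence[ProteinRecord],
    guide=None,
    substitution: np.ndarray | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> Alignment:
    """Progressive multiple alignment over a guide tree.

    ``guide`` is a scikit-bio ``TreeNode`` whose tip names are exactly the
    record ids; when omitted, a neighbor-joining tree on pairwise identity
    distances is used. Groups are merged by profile–profile affine
    alignment in postorder.
    """
    if substitution is None:
        substitution = blosum62_matrix()
    by_id = {r.id: r for r in records}
    if len(by_id) != len(records):
        raise ValueError("duplicate record ids")
    if len(records) == 1:
        rec = records[0]
        return Alignment({rec.id: rec.sequence})
    if len(records) == 2:
        aln = global_align(
            records[0].sequence, records[1].sequence, substitution, gap_open, gap_extend
        )
        return Alignment({records[0].id: aln.aligned_a, records[1].id: aln.aligned_b})

    if guide is None:
        from .phylo import nj_tree

        guide = nj_tree(distance_matrix(records, substitution=substitution,
                                        gap_open=gap_open, gap_extend=gap_extend))
    tip_names = {t.name for t in guide.tips()}
    if tip_names != set(by_id):
        raise ValueError(
            f"guide tree leaves {sorted(tip_names)} do not match record ids "
            f"{sorted(by_id)}"
        )

    def merge_node(node) -> tuple[list[str], list[str]]:
        if node.is_tip():
            return [node.name], [by_id[node.name].sequence]
        child_groups = [merge_node(c) for c in node.children]
        ids, rows = child_groups[0]
        for more_ids, more_rows in child_groups[1:]:
            rows, more_rows = _merge_groups(rows, more_rows, substitution, gap_open, gap_extend)
            ids = ids + more_ids
            rows = rows + more_rows
        return ids, rows

    ids, rows = merge_node(guide)
    merged = dict(zip(ids, rows))
    # present rows in the input record order
    ordered = {r.id: merged[r.id] for r in records}
    aln = Alignment(ordered)
    for r in records:
        if aln.degapped(r.id) != r.sequence:
            raise AssertionError(f"alignment row {r.id!r} does not degap to its input")
    return aln


# ---------------------------------------------------------------------------
# Conservation
# ---------------------------------------------------------------------------

MAX_IC_BITS = math.log2(20.0)


def column_conservation(alignment: Alignment) -> pd.DataFrame:
    """Per-column residue frequencies and information content in bits.

    IC = log2(20) - H(column) with gaps and X excluded from the frequency
    estimate; an all-gap column has IC = 0 (logged). No small-sample
    correction is applied. Output columns: ``column`` (1-based), the 20
    amino-acid frequencies, ``occupancy`` and ``information_bits``.
    """
    n_rows = len(alignment.rows)
    rows_out = []
    for c in range(alignment.length):
        col = alignment.column(c)
        counts = np.zeros(20)
        for ch in col:
            idx = _SYM_INDEX.get(ch)
            if idx is not None and idx < 20:
                counts[idx] += 1
        total = counts.sum()
        rec: dict[str, float] = {"column": c + 1}
        if total == 0:
            log.warning("column %d has no countable residues; IC set to 0", c + 1)
            freqs = np.zeros(20)
            ic = 0.0
        else:
            freqs = counts / total
            nz = freqs[freqs > 0]
            entropy = float(-(nz * np.log2(nz)).sum())
            ic = min(max(MAX_IC_BITS - entropy, 0.0), MAX_IC_BITS)
        for aa, f in zip(STANDARD_AA, freqs):
            rec[aa] = float(f)
        rec["occupancy"] = float(total) / n_rows
        rec["information_bits"] = ic
        rows_out.append(rec)
    return pd.DataFrame(rows_out)


def sum_of_pairs_score(
    alignment: Alignment,
    substitution: np.ndarray | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> float:
    """Sum over row pairs of the induced pairwise alignment scores.

    Each induced pair drops dual-gap columns; residue pairs score by the
    substitution table and gap runs cost ``gap_open + (k-1)*gap_extend``.
    """
    if substitution is None:
        substitution = blosum62_matrix()
    ids = alignment.ids
    total = 0.0
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            ra, rb = alignment.rows[ids[i]], alignment.rows[ids[j]]
            pa = [(x, y) for x, y in zip(ra, rb) if not (x == GAP and y == GAP)]
            in_gap = False
            for x, y in pa:
                if x == GAP or y == GAP:
                    total -= gap_extend if in_gap else gap_open
                    in_gap = True
                else:
                    total += substitution[_SYM_INDEX[x], _SYM_INDEX[y]]
                    in_gap = False
    return total
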