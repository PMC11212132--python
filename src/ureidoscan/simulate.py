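"""Synthetic condensation-domain families and NRPS-like benchmark proteins.

The generator emulates the statistical structure of an aligned family of
~450-residue condensation domains: a column-wise conservation profile at a
controlled mean pairwise identity, with the 8-residue active-site octamer
embedded exactly at a known position. Each function class (ureido-forming,
canonical amide-forming) gets its own random consensus, mimicking distinct
subfamilies. A column is conserved with probability ``identity``; in a
variable column every member independently draws a uniformly random
non-consensus residue, giving a mean pairwise per-site match probability of
``identity + (1 - identity) / 19`` (two variable draws coincide with
probability 1/19).

Ureido-forming members carry EHH??HDG (?? uniform); canonical members carry
?HH???DG with (M1 = E and M6 = H) explicitly excluded, so class labels and
octamer classification agree by construction. Both classes conserve a
serine two residues downstream of M8, emulating the fully conserved serine
observed next to condensation-domain active sites.

Domains can be embedded in longer multi-domain-like proteins between
uniform-random flanks carrying "decoy" near-motifs (exactly 3 of the 4
fixed core positions). Flanks are scrubbed of accidental windows matching
3 or more core positions, so strict scans find exactly the embedded motif
and relaxed scans find exactly the motif plus the planted decoys.

All outputs are pure functions of :class:`SynthConfig` (seeded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .records import STANDARD_AA, LabelTable, ProteinRecord, write_fasta, write_table
from .scanner import CORE_POSITIONS, core_match_count

log = logging.getLogger(__name__)

_AA = np.array(list(STANDARD_AA))
_AA_TO_IDX = {aa: i for i, aa in enumerate(STANDARD_AA)}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of a synthetic benchmark family set.

    ``identity`` is the probability that a non-motif column is held fixed
    across the family (the target mean pairwise identity, up to the 1/19
    coincidence correction). ``motif_position`` is the 0-based index of M1
    within the domain. ``decoys_per_protein`` near-motifs (3 of 4 fixed
    positions) are written into the flanks of each embedded protein.
    """

    n_urea: int = 5
    n_canonical: int = 20
    n_decoy_only: int = 5
    domain_length: int = 450
    identity: float = 0.7
    motif_position: int = 300
    decoys_per_protein: int = 2
    flank_length: int = 150
    conserved_ser_offset: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_urea, self.n_canonical, self.n_decoy_only) < 0:
            raise ValueError("family counts must be >= 0")
        if not (0.0 < self.identity <= 1.0):
            raise ValueError("identity must be in (0, 1]")
        if self.motif_position < 0 or self.motif_position + 8 > self.domain_length:
            raise ValueError("motif_position + 8 must fit in domain_length")
        if self.conserved_ser_offset is not None and self.conserved_ser_offset > 0:
            ser = self.motif_position + 7 + self.conserved_ser_offset
            if ser >= self.domain_length:
                raise ValueError("conserved serine falls outside the domain")
        if self.decoys_per_protein < 0 or self.flank_length < 0:
            raise ValueError("decoys_per_protein and flank_length must be >= 0")


@dataclass(frozen=True)
class TruthRow:
    """Ground truth for one emitted protein.

    ``true_motif_start`` is 0-based; -1 marks a protein with no embedded
    motif (decoy-only negatives), with an empty octamer.
    """

    protein_id: str
    true_motif_start: int
    octamer: str
    function_label: str


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 20, size=length)


def _draw_octamer(rng: np.random.Generator, label: str) -> str:
    if label == "urea":
        m4, m5 = _AA[rng.integers(0, 20, size=2)]
        return f"EHH{m4}{m5}HDG"
    # canonical: ?HH???DG with the ureido specialization excluded
    while True:
        m1, m4, m5, m6 = _AA[rng.integers(0, 20, size=4)]
        if not (m1 == "E" and m6 == "H"):
            return f"{m1}HH{m4}{m5}{m6}DG"


def sample_family(
    config: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[list[ProteinRecord], list[TruthRow]]:
    """Sample labeled condensation-domain-like sequences (domains only).

    Each function class draws its own consensus and its own column-wise
    conservation mask. Motif columns (and the conserved-serine column,
    when configured) are exempt from variation. Accidental windows
    matching 3+ fixed core positions elsewhere in a domain are scrubbed,
    so every emitted domain carries exactly one anchor candidate.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.domain_length
    m = config.motif_position
    protected = set(range(m, m + 8))
    ser_col = None
    if config.conserved_ser_offset and config.conserved_ser_offset > 0:
        ser_col = m + 7 + config.conserved_ser_offset
        protected.add(ser_col)

    records: list[ProteinRecord] = []
    truth: list[TruthRow] = []
    classes = (("urea", config.n_urea), ("amide", config.n_canonical))
    for label, count in classes:
        if count == 0:
            continue
        consensus = _random_sequence(rng, L)
        variable = rng.random(L) < (1.0 - config.identity)
        for col in protected:
            variable[col] = False
        var_cols = np.flatnonzero(variable)
        prefix = "urea" if label == "urea" else "can"
        for k in range(count):
            member = consensus.copy()
            if var_cols.size:
                # uniform over the 19 non-consensus residues per column
                shifts = rng.integers(1, 20, size=var_cols.size)
                member[var_cols] = (member[var_cols] + shifts) % 20
            base = list(_AA[member])
            if ser_col is not None:
                base[ser_col] = "S"
            # domains carry exactly one near-motif window: the real one.
            # an octamer whose free positions recreate an overlapping,
            # unremovable near-motif is redrawn (logged).
            for attempt in range(100):
                seq = base.copy()
                octamer = _draw_octamer(rng, label)
                seq[m : m + 8] = list(octamer)
                try:
                    _scrub_near_motifs(seq, {m}, protected)
                    break
                except RuntimeError:
                    log.info("octamer %s creates an unremovable near-motif; redrawn", octamer)
            else:
                raise RuntimeError("could not draw a scrub-compatible octamer")
            pid = f"{prefix}_{k + 1:03d}"
            records.append(
                ProteinRecord(pid, "".join(seq), source="synthetic")
            )
            truth.append(TruthRow(pid, m, octamer, label))
    return records, truth


# ---------------------------------------------------------------------------
# Embedding in multi-domain-like proteins
# ---------------------------------------------------------------------------

def _place_decoys(
    seq: list[str],
    slots: list[int],
    n_decoys: int,
    rng: np.random.Generator,
) -> list[int]:
    """Write near-motif windows (exactly 3/4 core positions) at non-
    overlapping positions drawn from ``slots``; returns their starts."""
    order = list(slots)
    rng.shuffle(order)
    chosen: list[int] = []
    for p in order:
        if len(chosen) == n_decoys:
            break
        if all(abs(p - q) >= 8 for q in chosen):
            chosen.append(p)
    if len(chosen) < n_decoys:
        raise ValueError(
            f"flanks too short to place {n_decoys} non-overlapping decoys"
        )
    for p in chosen:
        violated = int(rng.choice(list(CORE_POSITIONS)))
        for off in range(8):
            if off in CORE_POSITIONS and off != violated:
                seq[p + off] = CORE_POSITIONS[off]
            elif off == violated:
                correct = CORE_POSITIONS[off]
                choices = [aa for aa in STANDARD_AA if aa != correct]
                seq[p + off] = choices[int(rng.integers(0, len(choices)))]
            else:
                seq[p + off] = _AA[int(rng.integers(0, 20))]
    return sorted(chosen)


def _scrub_near_motifs(
    seq: list[str],
    allowed_starts: set[int],
    protected_positions: set[int],
) -> None:
    """Destroy accidental windows with >= 3 matching core positions.

    Any window not in ``allowed_starts`` matching 3 or 4 of the fixed core
    positions gets one of its matching core positions (outside
    ``protected_positions``) overwritten with alanine, which satisfies no
    core constraint. Deterministic; raises if a window cannot be broken.
    """
    s = "".join(seq)
    for _ in range(10 * len(seq)):
        offender = None
        for i in range(len(s) - 7):
            if i in allowed_starts:
                continue
            if core_match_count(s, i) >= 3:
                offender = i
                break
        if offender is None:
            break
        fixed = False
        for off, aa in CORE_POSITIONS.items():
            pos = offender + off
            if s[pos] == aa and pos not in protected_positions:
                seq[pos] = "A"
                s = "".join(seq)
                fixed = True
                break
        if not fixed:
            raise RuntimeError(
                f"cannot scrub accidental near-motif at position {offender}"
            )
    else:
        raise RuntimeError("near-motif scrubbing did not converge")


def embed_in_protein(
    domain_record: ProteinRecord,
    flank_length: int,
    decoys_per_protein: int,
    rng: np.random.Generator | int,
    *,
    true_motif_start: int,
    upstream: int | None = None,
    downstream: int | None = None,
    conserved_ser_offset: int | None = 2,
) -> tuple[ProteinRecord, int, list[int]]:
    """Place a domain between uniform-random flanks with planted decoys.

    Returns the embedded protein, the shifted 0-based motif start, and the
    decoy window starts. With ``flank_length`` 0 (and no overrides),
    coordinates are unchanged.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    up = flank_length if upstream is None else upstream
    down = flank_length if downstream is None else downstream
    if up < 0 or down < 0:
        raise ValueError("flank lengths must be >= 0")
    seq = (
        list(_AA[_random_sequence(rng, up)])
        + list(domain_record.sequence)
        + list(_AA[_random_sequence(rng, down)])
    )
    new_start = up + true_motif_start
    L_dom = len(domain_record.sequence)
    slots = list(range(0, up - 7)) + list(
        range(up + L_dom, len(seq) - 7)
    )
    decoy_starts = (
        _place_decoys(seq, slots, decoys_per_protein, rng)
        if decoys_per_protein > 0
        else []
    )
    protected = set(range(new_start, new_start + 8))
    if conserved_ser_offset and conserved_ser_offset > 0:
        protected.add(new_start + 7 + conserved_ser_offset)
    for p in decoy_starts:
        # only a decoy's core positions define its 3/4 status; its random
        # positions may be scrubbed without breaking the contract
        protected.update(p + off for off in CORE_POSITIONS)
    _scrub_near_motifs(seq, {new_start} | set(decoy_starts), protected)
    record = ProteinRecord(
        domain_record.id, "".join(seq), description=domain_record.description,
        source="synthetic",
    )
    return record, new_start, decoy_starts


def _decoy_only_protein(
    pid: str, config: SynthConfig, rng: np.random.Generator
) -> ProteinRecord:
    """A protein with no true motif, only planted near-motifs."""
    length = config.domain_length + 2 * config.flank_length
    seq = list(_AA[_random_sequence(rng, length)])
    n_decoys = max(1, config.decoys_per_protein)
    starts = _place_decoys(seq, list(range(0, length - 7)), n_decoys, rng)
    protected = set()
    for p in starts:
        protected.update(p + off for off in CORE_POSITIONS)
    _scrub_near_motifs(seq, set(starts), protected)
    return ProteinRecord(pid, "".join(seq), source="synthetic")


# ---------------------------------------------------------------------------
# Benchmark assembly
# ---------------------------------------------------------------------------

def generate_benchmark(
    config: SynthConfig,
) -> tuple[list[ProteinRecord], list[TruthRow], LabelTable]:
    """Build the full labeled benchmark in memory.

    Embedded urea/canonical proteins plus decoy-only negatives (label
    ``other``); every protein has exactly one truth row.
    """
    rng = np.random.default_rng(config.seed)
    domains, truth = sample_family(config, rng)
    records: list[ProteinRecord] = []
    out_truth: list[TruthRow] = []
    labels: dict[str, str] = {}
    for rec, row in zip(domains, truth):
        embedded, start, _ = embed_in_protein(
            rec,
            config.flank_length,
            config.decoys_per_protein,
            rng,
            true_motif_start=row.true_motif_start,
            conserved_ser_offset=config.conserved_ser_offset,
        )
        records.append(embedded)
        out_truth.append(replace(row, true_motif_start=start))
        labels[rec.id] = row.function_label
    for k in range(config.n_decoy_only):
        pid = f"decoy_{k + 1:03d}"
        records.append(_decoy_only_protein(pid, config, rng))
        out_truth.append(TruthRow(pid, -1, "", "other"))
        labels[pid] = "other"
    return records, out_truth, LabelTable(labels)


def make_benchmark(config: SynthConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write benchmark.fasta, truth.tsv and labels.tsv under ``out_dir``.

    Identical configs (including seed) produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, truth, labels = generate_benchmark(config)
    fasta = out_dir / "benchmark.fasta"
    truth_tsv = out_dir / "truth.tsv"
    labels_tsv = out_dir / "labels.tsv"
    write_fasta(records, fasta)
    write_table(
        [
            {
                "protein_id": t.protein_id,
                "true_motif_start": t.true_motif_start,
                "octamer": t.octamer,
                "function_label": t.function_label,
            }
            for t in truth
        ],
        truth_tsv,
    )
    labels.to_tsv(labels_tsv)
    return {"fasta": fasta, "truth": truth_tsv, "labels": labels_tsv}


def snaa_like_benchmark(
    seed: int = 0, n_family: int = 8, identity: float = 0.75
) -> tuple[list[ProteinRecord], list[TruthRow]]:
    """A synthetic family laid out on the SnaA active-site register.

    This is a synthetic stand-in for a ureido-forming condensation-domain
    family in SnaA coordinates (the NRPS whose C_urea active site is
    E744-H746-H749): domains of 300 residues with M1 at domain position
    144 (1-based) and the conserved serine at 153. The member
    named ``SnaA_like`` carries the octamer EHHLVHDG and is embedded after
    a 600-residue upstream flank, so its catalytic glutamate falls at
    protein residue 744, the catalytic-base histidine at 746, the third
    conserved histidine at 749 and the serine at 753. No real SnaA
    sequence is used; only the register geometry is reproduced.
    """
    config = SynthConfig(
        n_urea=n_family,
        n_canonical=0,
        n_decoy_only=0,
        domain_length=300,
        identity=identity,
        motif_position=143,
        conserved_ser_offset=2,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    records, truth = sample_family(config, rng)
    first = records[0]
    seq = list(first.sequence)
    m = config.motif_position
    seq[m + 3], seq[m + 4] = "L", "V"  # M4/M5 of EHHLVHDG
    octamer = "".join(seq[m : m + 8])
    domain = ProteinRecord("SnaA_like", "".join(seq), source="synthetic")
    embedded, start, _ = embed_in_protein(
        domain,
        150,
        2,
        rng,
        true_motif_start=m,
        upstream=600,
        conserved_ser_offset=config.conserved_ser_offset,
    )
    out_records = [embedded] + records[1:]
    out_truth = [TruthRow("SnaA_like", start, octamer, "urea")] + truth[1:]
    return out_records, out_truth


def perturb_m1(
    records: Sequence[ProteinRecord],
    truth: Sequence[TruthRow],
    replacement: str = "A",
) -> list[ProteinRecord]:
    """Mutate M1 of every urea-labeled motif (E -> ``replacement``).

    Used to probe the necessity of the conserved glutamate: the mutated
    positives match the canonical core but no longer the ureido signature.
    """
    by_id = {t.protein_id: t for t in truth}
    out = []
    for rec in records:
        t = by_id.get(rec.id)
        if t is not None and t.function_label == "urea" and t.true_motif_start >= 0:
            seq = list(rec.sequence)
            seq[t.true_motif_start] = replacement
            out.append(ProteinRecord(rec.id, "".join(seq), rec.description, rec.source))
        else:
            out.append(rec)
    return out
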