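"""Sequence records and file input/output.

This module defines the in-memory record model shared by every pipeline
stage (:class:`ProteinRecord`, :class:`BgcRecord`, :class:`LabelTable`) and
the readers/writers for the external formats the pipeline touches: protein
FASTA, biosynthetic-gene-cluster (BGC) JSON records carrying per-gene
protein-family annotations, TSV tables, and Newick trees.

Coordinate convention: everything internal is 0-based half-open; anything
written for a user (tables, reports) is 1-based inclusive, matching the
residue numbering used in the enzymology literature (e.g. "E744").
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical by one-letter code.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Accepted residue alphabet: standard amino acids plus the unknown code X.
ALPHABET = frozenset(STANDARD_AA + "X")
#: Ambiguity / rare codes tolerated on input and mapped to X with a warning.
AMBIGUOUS_AA = frozenset("BZJUO")

_PFAM_RE = re.compile(r"^PF\d+$")


def clean_sequence(raw: str, *, context: str = "") -> str:
    """Uppercase ``raw`` and validate it against the protein alphabet.

    Ambiguity codes (B, Z, J, U, O) are mapped to X with a logged warning;
    any other character raises :class:`ValueError` naming its 1-based
    position.
    """
    out = []
    for pos, ch in enumerate(raw.upper(), start=1):
        if ch in ALPHABET:
            out.append(ch)
        elif ch in AMBIGUOUS_AA:
            log.warning("ambiguous residue %r at position %d%s mapped to X", ch, pos, context)
            out.append("X")
        else:
            raise ValueError(f"illegal residue {ch!r} at position {pos}{context}")
    return "".join(out)


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence.

    Parameters
    ----------
    id : str
        Unique identifier within a run.
    sequence : str
        Uppercase residues over the 20 standard amino acids plus X.
    description : str
        Free-text description (FASTA header remainder).
    source : str, optional
        Provenance tag: ``fasta``, ``bgc_record`` or ``synthetic``.
    """

    id: str
    sequence: str
    description: str = ""
    source: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record id must be nonempty")
        if not self.sequence:
            raise ValueError(f"protein record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValueError(
                f"protein record {self.id!r} contains characters outside the "
                f"amino-acid alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BgcGene:
    """One gene of a BGC record: a protein plus its family annotations."""

    gene_id: str
    protein: ProteinRecord
    family_annotations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for fam in self.family_annotations:
            if fam != fam.upper():
                raise ValueError(f"family annotation {fam!r} must be uppercase")
            if fam.startswith("PF") and not _PFAM_RE.match(fam):
                raise ValueError(f"malformed Pfam-style identifier {fam!r}")


@dataclass(frozen=True)
class BgcRecord:
    """A biosynthetic gene cluster: an id plus annotated genes."""

    bgc_id: str
    genes: tuple[BgcGene, ...]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene_ids in BGC {self.bgc_id!r}: {dupes}")

    def all_families(self) -> frozenset[str]:
        """Union of family annotations over every gene in the record."""
        return frozenset(f for g in self.genes for f in g.family_annotations)


#: Allowed function labels for condensation domains.
FUNCTION_LABELS = ("urea", "amide", "other")


class LabelTable:
    """Mapping from domain/protein ids to function labels.

    Labels are restricted to ``urea`` (ureido-forming), ``amide``
    (canonical peptide-bond-forming) and ``other``.
    """

    def __init__(self, labels: Mapping[str, str]):
        for did, lab in labels.items():
            if lab not in FUNCTION_LABELS:
                raise ValueError(
                    f"label {lab!r} for {did!r} not in {FUNCTION_LABELS}"
                )
        self._labels = dict(labels)

    def __getitem__(self, domain_id: str) -> str:
        return self._labels[domain_id]

    def __contains__(self, domain_id: str) -> bool:
        return domain_id in self._labels

    def __len__(self) -> int:
        return len(self._labels)

    def __iter__(self):
        return iter(self._labels)

    def items(self):
        return self._labels.items()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LabelTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("domain_id", "function_label"):
            if col not in df.columns:
                raise ValueError(f"label table {path} lacks required column {col!r}")
        if df["domain_id"].duplicated().any():
            dupes = sorted(df.loc[df["domain_id"].duplicated(), "domain_id"])
            raise ValueError(f"duplicate domain_ids in label table: {dupes}")
        return cls(dict(zip(df["domain_id"], df["function_label"])))

    def to_tsv(self, path: str | Path) -> None:
        write_table(
            [{"domain_id": d, "function_label": l} for d, l in self._labels.items()],
            path,
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, *, source: str = "fasta") -> list[ProteinRecord]:
    """Read a protein FASTA file into a list of :class:`ProteinRecord`.

    Order is preserved, wrapped lines are joined, sequences are uppercased
    and validated. Duplicate ids and illegal residues are errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = clean_sequence(str(rec.seq), context=f" of record {rec.id!r}")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(ProteinRecord(rec.id, seq, description=desc, source=source))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, *, wrap: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``wrap`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), wrap):
                fh.write(rec.sequence[i : i + wrap] + "\n")


def read_alignment_fasta(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA (gap characters allowed) as id -> gapped row."""
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        row = str(rec.seq).upper()
        bad = set(row) - ALPHABET - {"-", "."}
        if bad:
            raise ValueError(f"illegal characters {sorted(bad)} in aligned row {rec.id!r}")
        rows[rec.id] = row.replace(".", "-")
    if not rows:
        raise ValueError(f"no FASTA records found in {path}")
    return rows


def write_alignment_fasta(rows: Mapping[str, str], path: str | Path, *, wrap: int = 60) -> None:
    """Write gapped alignment rows as FASTA."""
    with open(path, "w") as fh:
        for rid, row in rows.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(row), wrap):
                fh.write(row[i : i + wrap] + "\n")


# ---------------------------------------------------------------------------
# BGC JSON records
# ---------------------------------------------------------------------------

def read_bgc_record(path: str | Path) -> BgcRecord:
    """Parse a BGC JSON record.

    Schema::

        {"bgc_id": str,
         "genes": [{"gene_id": str,
                    "protein": {"id": str, "sequence": str},
                    "family_annotations": [str]}]}

    Family annotations are normalized to uppercase. Schema violations raise
    :class:`ValueError` naming the offending key.
    """
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise ValueError("BGC record must be a JSON object")
    for key in ("bgc_id", "genes"):
        if key not in data:
            raise ValueError(f"BGC record missing required key {key!r}")
    if not isinstance(data["genes"], list):
        raise ValueError("BGC record key 'genes' must be a list")
    genes = []
    for i, g in enumerate(data["genes"]):
        where = f"genes[{i}]"
        if not isinstance(g, dict):
            raise ValueError(f"{where} must be an object")
        for key in ("gene_id", "protein"):
            if key not in g:
                raise ValueError(f"{where} missing required key {key!r}")
        prot = g["protein"]
        if not isinstance(prot, dict):
            raise ValueError(f"{where}.protein must be an object")
        for key in ("id", "sequence"):
            if key not in prot:
                raise ValueError(f"{where}.protein missing required key {key!r}")
        seq = clean_sequence(str(prot["sequence"]), context=f" of {where}.protein")
        record = ProteinRecord(str(prot["id"]), seq, source="bgc_record")
        fams = tuple(str(f).upper() for f in g.get("family_annotations", []))
        genes.append(BgcGene(str(g["gene_id"]), record, fams))
    return BgcRecord(str(data["bgc_id"]), tuple(genes))


# ---------------------------------------------------------------------------
# Tables and trees
# ---------------------------------------------------------------------------

def write_table(rows: Iterable[Mapping] | pd.DataFrame, path: str | Path) -> None:
    """Write rows as a TSV table with a mandatory header row."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False)


_NEWICK_UNSAFE = re.compile(r"[\s(),:;\[\]']")


def _format_length(length: float) -> str:
    s = f"{float(length):.12g}"
    if "." not in s and "e" not in s and "E" not in s:
        s += ".0"
    return s


def newick_string(tree) -> str:
    """Serialize a scikit-bio ``TreeNode`` as Newick with branch lengths."""
    if tree is None or (not tree.children and not tree.name):
        raise ValueError("cannot serialize an empty tree")

    def render(node) -> str:
        if node.is_tip():
            if not node.name:
                raise ValueError("tree has an unlabeled leaf")
            if _NEWICK_UNSAFE.search(node.name):
                raise ValueError(f"leaf name {node.name!r} unsafe for Newick output")
            length = 0.0 if node.length is None else node.length
            if length < 0:
                raise ValueError(f"negative branch length at leaf {node.name!r}")
            return f"{node.name}:{_format_length(length)}"
        inner = ",".join(render(c) for c in node.children)
        if node.parent is None:
            return f"({inner})"
        length = 0.0 if node.length is None else node.length
        if length < 0:
            raise ValueError("negative internal branch length")
        return f"({inner}):{_format_length(length)}"

    return render(tree) + ";"


def write_newick(tree, path: str | Path) -> None:
    """Write a tree (scikit-bio ``TreeNode``) to ``path`` in Newick format."""
    with open(path, "w") as fh:
        fh.write(newick_string(tree) + "\n")


def read_newick(path_or_str: str | Path):
    """Read a Newick tree into a scikit-bio ``TreeNode``."""
    import io as _io

    from skbio import TreeNode

    text = str(path_or_str)
    if text.strip().endswith(";") and "(" in text:
        return TreeNode.read(_io.StringIO(text))
    return TreeNode.read(str(path_or_str))
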