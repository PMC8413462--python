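"""Sequence and table I/O for snoRNA records.

All sequences are normalised to the uppercase RNA alphabet {A, C, G, U, N}.
Internally every coordinate is 0-based half-open; user-facing reports are
1-based inclusive (each writer states this in its header).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGUN")
STRICT_ALPHABET = frozenset("ACGU")

BoxKind = Literal["D", "Dprime"]


def _normalise_box_kind(raw: str) -> str:
    """Map the spellings D / D' / Dprime / d' onto {"D", "Dprime"}."""
    k = raw.strip().replace("'", "prime").replace("’", "prime")
    k = k[0].upper() + k[1:]
    if k not in ("D", "Dprime"):
        raise ValueError(f"unknown box kind {raw!r}; expected D or D'")
    return k


@dataclass
class KnownTarget:
    """An experimentally verified methylation target of one guide region."""

    substrate_id: str
    position: int  # 1-based position on the substrate
    box_kind: str  # "D" or "Dprime"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"known target position must be >= 1, got {self.position}")
        self.box_kind = _normalise_box_kind(self.box_kind)


@dataclass
class SnoRNARecord:
    """One snoRNA sequence with identifier and optional target metadata."""

    id: str
    seq: str
    known_targets: Optional[list[KnownTarget]] = None
    source: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - RNA_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.seq) if c in bad)
            raise ValueError(
                f"record {self.id!r}: illegal character {self.seq[pos]!r} "
                f"at position {pos + 1} (1-based)"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _normalise_seq(rec_id: str, raw: str, alphabet_policy: str) -> str:
    if alphabet_policy not in ("strict", "coerce"):
        raise ValueError(f"alphabet_policy must be 'strict' or 'coerce', got {alphabet_policy!r}")
    if alphabet_policy == "coerce":
        seq = raw.upper().replace("T", "U")
    else:
        seq = raw
        for i, c in enumerate(seq):
            if c not in STRICT_ALPHABET:
                raise ValueError(
                    f"record {rec_id!r}: illegal character {c!r} at position "
                    f"{i + 1} (1-based) under strict alphabet policy"
                )
    return seq


def load_rna_records(path: str | Path, alphabet_policy: str = "coerce") -> list[SnoRNARecord]:
    """Read a FASTA file into :class:`SnoRNARecord` objects.

    With ``coerce`` (default), lowercase letters are uppercased and T→U; with
    ``strict`` any character outside {A,C,G,U} raises, naming the record and
    the offending 1-based position.  Multi-line FASTA is accepted; the
    description after the first whitespace is kept as provenance but ignored
    by all downstream logic.  An empty file is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for sr in SeqIO.parse(str(path), "fasta"):
        seq = _normalise_seq(sr.id, str(sr.seq), alphabet_policy)
        records.append(SnoRNARecord(id=sr.id, seq=seq, source=sr.description))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_rna_records(records: Iterable[SnoRNARecord], path: str | Path) -> None:
    """Write records as FASTA, preserving input order and identifiers."""
    seqrecs = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.source or "")
        for r in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def load_known_targets(path: str | Path) -> dict[str, list[KnownTarget]]:
    """Read a known-targets TSV (snoRNA_id, substrate_id, position, box_kind).

    Positions are 1-based on the substrate sequence.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"snoRNA_id": str, "substrate_id": str})
    required = {"snoRNA_id", "substrate_id", "position", "box_kind"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, list[KnownTarget]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.snoRNA_id, []).append(
            KnownTarget(
                substrate_id=row.substrate_id,
                position=int(row.position),
                box_kind=str(row.box_kind),
            )
        )
    return out


def attach_known_targets(records: list[SnoRNARecord], targets: dict[str, list[KnownTarget]]) -> None:
    """Attach parsed known-target entries to their records in place."""
    for rec in records:
        if rec.id in targets:
            rec.known_targets = targets[rec.id]
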