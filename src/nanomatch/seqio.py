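"""Readers and writers for the pipeline's external formats.

All other modules consume only the in-memory domain types defined here and
in their own namespaces: FASTA/FASTQ parsing is delegated to Biopython,
tabular formats to pandas. Every reader validates its input and reports
dropped rows; nothing is discarded silently.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("nanomatch")

DNA_BASES = set("ACGTN")
#: IUPAC degenerate DNA codes and the concrete bases each stands for.
IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
AA_STANDARD = set("ACDEFGHIKLMNPQRSTVWY")

PROTEASE_LABELS = ("trypsin", "chymotrypsin_high", "chymotrypsin_low")

DEFAULT_MIN_PEPTIDE_LEN = 6


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclasses.dataclass(frozen=True)
class SequenceRecord:
    """A named sequence with optional Phred qualities.

    ``qual`` must be absent or exactly as long as ``seq``.
    """

    id: str
    seq: str
    qual: Optional[tuple[int, ...]] = None
    description: str = ""

    def __post_init__(self):
        if not self.seq:
            raise ParseError(f"record {self.id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ParseError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclasses.dataclass(frozen=True)
class PeptideObservation:
    """One MS-identified peptide with its protease and sample labels."""

    peptide: str
    protease: str
    sample_id: str
    score: Optional[float] = None

    def __post_init__(self):
        if self.protease not in PROTEASE_LABELS:
            raise ValueError(
                f"unknown protease {self.protease!r}; "
                f"allowed: {', '.join(PROTEASE_LABELS)}"
            )
        bad = set(self.peptide) - AA_STANDARD
        if bad:
            raise ValueError(
                f"peptide {self.peptide!r} contains non-standard residues "
                f"{sorted(bad)}"
            )


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file, preserving record order and joining wrapped lines.

    The full header line is kept: the first token becomes ``id``, the
    remainder ``description``. Structural problems raise :class:`ParseError`
    naming the offending line number.
    """
    path = Path(path)
    _prevalidate_fasta(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq).upper(), description=desc))
    return records


def _prevalidate_fasta(path: Path) -> None:
    in_record = False
    has_body = False
    header_line = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if in_record and not has_body:
                    raise ParseError(
                        f"{path}: record starting at line {header_line} has an empty sequence"
                    )
                if len(line) == 1:
                    raise ParseError(f"{path}: malformed header at line {lineno}")
                in_record, has_body, header_line = True, False, lineno
            else:
                if not in_record:
                    raise ParseError(
                        f"{path}: sequence data before any header at line {lineno}"
                    )
                has_body = True
    if in_record and not has_body:
        raise ParseError(
            f"{path}: record starting at line {header_line} has an empty sequence"
        )


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def _strip_pair_suffix(name: str) -> str:
    for suffix in ("/1", "/2"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return name


def read_fastq(path) -> list[SequenceRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fastq"):
        records.append(
            SequenceRecord(
                id=rec.id,
                seq=str(rec.seq).upper(),
                qual=tuple(rec.letter_annotations["phred_quality"]),
            )
        )
    return records


def read_fastq_pairs(path_r1, path_r2) -> list[tuple[SequenceRecord, SequenceRecord]]:
    """Read record-aligned paired FASTQ files (Phred+33).

    Raises :class:`ParseError` on a record-count mismatch (stating both
    counts) or a read-name mismatch (ignoring ``/1``/``/2`` suffixes).
    """
    r1 = read_fastq(path_r1)
    r2 = read_fastq(path_r2)
    if len(r1) != len(r2):
        raise ParseError(
            f"paired FASTQ record counts differ: {len(r1)} vs {len(r2)}"
        )
    for a, b in zip(r1, r2):
        if _strip_pair_suffix(a.id) != _strip_pair_suffix(b.id):
            raise ParseError(f"paired read id mismatch: {a.id!r} vs {b.id!r}")
    return list(zip(r1, r2))


def write_fastq_pairs(pairs, path_r1, path_r2) -> None:
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for a, b in pairs:
            for rec, fh in ((a, f1), (b, f2)):
                qual = "".join(chr(q + 33) for q in rec.qual)
                fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")


def read_peptide_table(path, min_peptide_len: int = DEFAULT_MIN_PEPTIDE_LEN) -> list[PeptideObservation]:
    """Read a peptide TSV (columns: peptide, protease, sample_id, [score]).

    Rows shorter than ``min_peptide_len`` are dropped and the dropped count
    is logged — never silently discarded. Unknown protease labels raise.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"peptide", "protease", "sample_id"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")
    observations, dropped = [], 0
    for row in df.itertuples(index=False):
        pep = str(row.peptide).strip().upper()
        if len(pep) < min_peptide_len:
            dropped += 1
            continue
        score = None
        if "score" in df.columns:
            raw = getattr(row, "score")
            if raw is not None and not pd.isna(raw) and str(raw) != "":
                score = float(raw)
        observations.append(
            PeptideObservation(
                peptide=pep,
                protease=str(row.protease).strip(),
                sample_id=str(row.sample_id).strip(),
                score=score,
            )
        )
    if dropped:
        logger.warning(
            "%s: dropped %d peptide row(s) shorter than %d residues",
            path, dropped, min_peptide_len,
        )
    return observations


def write_peptide_table(observations: Iterable[PeptideObservation], path) -> None:
    df = pd.DataFrame(
        [
            {
                "peptide": o.peptide,
                "protease": o.protease,
                "sample_id": o.sample_id,
                "score": o.score,
            }
            for o in observations
        ],
        columns=["peptide", "protease", "sample_id", "score"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Candidate report serialization

REPORT_COLUMNS = [
    "group_rank", "group_id", "cdr3", "group_score",
    "member_rank", "member_id", "count", "coverage_score", "cdr3_covered",
    "hinge", "cross_antigen_hit", "glew_hit", "no_unique_peptide", "selected",
    "best_uniqueness", "n_peptides",
]


def write_candidate_report(report, path, format: str = "tsv") -> None:
    """Serialize a :class:`~nanomatch.match_score.CandidateReport`.

    Column order is fixed and both dialects are byte-stable for identical
    inputs. ``format`` is ``"tsv"`` (flat member table) or ``"json"``
    (full nested structure including per-peptide uniqueness evidence).
    """
    if format == "json":
        with open(path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=False)
            fh.write("\n")
    elif format == "tsv":
        rows = []
        for grank, group in enumerate(report.groups, start=1):
            for mrank, member in enumerate(group.members, start=1):
                uniq = [p["uniqueness"] for p in member.peptides]
                rows.append({
                    "group_rank": grank,
                    "group_id": group.group_id,
                    "cdr3": group.cdr3,
                    "group_score": round(group.group_score, 4),
                    "member_rank": mrank,
                    "member_id": member.member_id,
                    "count": member.count,
                    "coverage_score": round(member.coverage_score, 4),
                    "cdr3_covered": member.cdr3_covered,
                    "hinge": member.hinge,
                    "cross_antigen_hit": member.cross_antigen_hit,
                    "glew_hit": member.glew_hit,
                    "no_unique_peptide": member.no_unique_peptide,
                    "selected": member.selected,
                    "best_uniqueness": round(max(uniq), 2) if uniq else "",
                    "n_peptides": len(member.peptides),
                })
        pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_candidate_report_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
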