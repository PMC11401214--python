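"""In silico protease digestion under Expasy-style cleavage rules.

Supported enzymes: trypsin (cleave after K/R, not before P),
chymotrypsin high specificity (after F/Y/W, not before P) and
chymotrypsin low specificity (after F/Y/W/M/L/H, not before P). With
zero missed cleavages the emitted peptides tile the protein exactly;
with ``missed_cleavages = k`` every union of up to k+1 adjacent
fragments is emitted as well.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Sequence

from .annotate import CdrAnnotation
from .amplicon import VhhSequence
from .seqio import SequenceRecord


@dataclasses.dataclass(frozen=True)
class ProteaseRule:
    name: str
    cleave_after: frozenset
    blocked_before: frozenset


EXPASY_RULES = {
    "trypsin": ProteaseRule("trypsin", frozenset("KR"), frozenset("P")),
    "chymotrypsin_high": ProteaseRule("chymotrypsin_high", frozenset("FYW"), frozenset("P")),
    "chymotrypsin_low": ProteaseRule("chymotrypsin_low", frozenset("FYWMLH"), frozenset("P")),
}


@dataclasses.dataclass(frozen=True)
class DigestPeptide:
    peptide: str
    start: int  # 0-based, half-open span in the source protein
    end: int
    missed_cleavages: int


@dataclasses.dataclass(frozen=True)
class DigestResult:
    source_id: str
    peptides: tuple[DigestPeptide, ...]

    def peptide_strings(self, max_missed: int | None = None) -> list[str]:
        return [
            p.peptide
            for p in self.peptides
            if max_missed is None or p.missed_cleavages <= max_missed
        ]


def cleavage_sites(protein: str, rule: ProteaseRule) -> list[int]:
    """Positions i such that cleavage occurs after residue i.

    A site requires protein[i] in the cleave-after set and protein[i+1]
    outside the blocked set; the final residue never yields a site
    (there is nothing to cleave off).
    """
    return [
        i
        for i in range(len(protein) - 1)
        if protein[i] in rule.cleave_after and protein[i + 1] not in rule.blocked_before
    ]


def digest(protein: str, rule: ProteaseRule, missed_cleavages: int = 0, source_id: str = "") -> DigestResult:
    """Digest a protein, emitting peptides with spans and missed-site counts."""
    if not protein:
        raise ValueError("empty protein")
    sites = cleavage_sites(protein, rule)
    bounds = [0] + [s + 1 for s in sites] + [len(protein)]
    peptides = []
    nfrag = len(bounds) - 1
    for i in range(nfrag):
        for k in range(missed_cleavages + 1):
            j = i + k + 1
            if j >= len(bounds):
                break
            start, end = bounds[i], bounds[j]
            peptides.append(
                DigestPeptide(peptide=protein[start:end], start=start, end=end, missed_cleavages=k)
            )
    return DigestResult(source_id=source_id, peptides=tuple(peptides))


def unique_peptides(
    db: Sequence[VhhSequence],
    rule: ProteaseRule,
    min_len: int = 6,
    missed_cleavages: int = 0,
) -> list[tuple[str, frozenset]]:
    """The union of digest peptides across a deduplicated database.

    Each peptide of length >= ``min_len`` is paired with the complete
    set of source sequence ids; output is sorted lexicographically.
    Duplicate proteins in the input violate the dedup precondition and
    raise.
    """
    seen_proteins = set()
    for v in db:
        if v.protein in seen_proteins:
            raise ValueError(f"database is not deduplicated: protein of {v.id} occurs twice")
        seen_proteins.add(v.protein)
    sources: dict[str, set] = {}
    for v in db:
        for p in digest(v.protein, rule, missed_cleavages, source_id=v.id).peptides:
            if len(p.peptide) >= min_len:
                sources.setdefault(p.peptide, set()).add(v.id)
    return [(pep, frozenset(ids)) for pep, ids in sorted(sources.items())]


def peptides_to_fasta_records(peptides: Sequence[tuple[str, frozenset]]) -> list[SequenceRecord]:
    """Peptide list as FASTA records, source count encoded in the header."""
    return [
        SequenceRecord(id=f"pep_{i}", seq=pep, description=f"sources={len(ids)}")
        for i, (pep, ids) in enumerate(peptides)
    ]


def cleavage_histogram(
    db: Sequence[VhhSequence],
    rule: ProteaseRule,
    annotations: dict[str, CdrAnnotation],
) -> tuple[Counter, int]:
    """Counts of cleavage events per IMGT position across a database.

    For every cleavage site the IMGT position of the residue after which
    cleavage occurs is incremented; sites at residues absent from a
    sequence's position map are tallied separately and returned as the
    second element. Mapped + unmapped = total cleavage events.
    """
    hist: Counter = Counter()
    unmapped = 0
    for v in db:
        ann = annotations.get(v.id)
        imgt = ann.imgt_map if ann is not None else {}
        for site in cleavage_sites(v.protein, rule):
            pos = imgt.get(site)
            if pos is None:
                unmapped += 1
            else:
                hist[pos] += 1
    return hist, unmapped
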