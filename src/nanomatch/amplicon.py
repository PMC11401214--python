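"""From paired amplicon reads to a counted, translated VHH protein database.

The stages here mirror single-step PCR amplification of camelid VHH
domains with a leader-region forward primer and hinge-region reverse
primers: merge each read pair on its overlap, locate primer annealing
sites with a fractional mismatch budget, classify the hinge variant
(long hinge = IgG2, short hinge = IgG3) from the reverse primer that
matched, translate the open reading frame between the primers, and
collapse identical proteins while conserving read support.

All primer matching is substitution-only (Hamming); degenerate IUPAC
codes in primers match by set membership. The allowed mismatch count for
a primer of length L at fractional tolerance f is ``ceil(f * L)`` — a
23-base primer at 20% tolerance allows 5 mismatches.
"""

from __future__ import annotations

import dataclasses
import enum
import hashlib
import math
from collections import Counter
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from .seqio import IUPAC_DNA, SequenceRecord

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Hinge(str, enum.Enum):
    LONG_IGG2 = "long_hinge_IgG2"
    SHORT_IGG3 = "short_hinge_IgG3"
    UNKNOWN = "unknown"


class RejectReason(str, enum.Enum):
    NO_FORWARD = "no_forward"
    NO_REVERSE = "no_reverse"
    INTERNAL_STOP = "internal_stop"
    BAD_LENGTH = "bad_length"
    EMPTY_ORF = "empty_orf"


@dataclasses.dataclass(frozen=True)
class PrimerDef:
    """A PCR primer: annealing sequence only; 5' tail bases (e.g. the
    NNNNNN diversity hexamer) are declared as ``tail_len`` and never
    participate in matching or length accounting."""

    name: str
    annealing_seq: str
    orientation: str  # "forward" | "reverse"
    tail_len: int = 0
    hinge: Optional[Hinge] = None  # for reverse primers: hinge class they imply

    def __post_init__(self):
        if not self.annealing_seq:
            raise ValueError(f"primer {self.name!r}: empty annealing sequence")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"primer {self.name!r}: bad orientation {self.orientation!r}")
        bad = set(self.annealing_seq) - set(IUPAC_DNA)
        if bad:
            raise ValueError(f"primer {self.name!r}: non-IUPAC bases {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.annealing_seq)


def allowed_mismatches(primer: PrimerDef, max_mismatch_frac: float) -> int:
    """Mismatch budget: ceiling of tolerance x annealing length."""
    return math.ceil(max_mismatch_frac * len(primer.annealing_seq))


@dataclasses.dataclass(frozen=True)
class PrimerHit:
    primer_name: str
    position: int  # 0-based start on the + strand of the target
    strand: str    # "+" | "-"
    mismatches: int
    max_allowed: int
    length: int    # annealing length, for span arithmetic

    @property
    def end(self) -> int:
        return self.position + self.length


@dataclasses.dataclass(frozen=True)
class MergedAmplicon:
    id: str
    seq: str
    overlap_len: int
    conflict_count: int
    qual: Optional[tuple[int, ...]] = None


@dataclasses.dataclass(frozen=True)
class MergeFailure:
    id: str
    reason: str


@dataclasses.dataclass(frozen=True)
class VhhSequence:
    """One unique translated VHH candidate with its read support."""

    id: str
    protein: str
    dna: str
    count: int
    hinge: Hinge

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("count must be >= 1")


def _stable_id(protein: str) -> str:
    return "vhh_" + hashlib.sha1(protein.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Read-pair merging

_BASE_CODE = {b: i for i, b in enumerate("ACGTN")}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def merge_read_pair(
    r1: SequenceRecord,
    r2: SequenceRecord,
    min_overlap: int = 20,
    max_overlap_mismatch_frac: float = 0.05,
) -> MergedAmplicon | MergeFailure:
    """Merge a read pair on the longest acceptable ungapped overlap.

    ``r2`` is reverse-complemented first; candidate overlaps are the
    suffix-of-r1 / prefix-of-rc(r2) alignments. Among overlaps of length
    >= ``min_overlap`` whose mismatch fraction is within budget, the
    longest wins. Conflicting positions take the base with the higher
    Phred quality (tie: r1's base); each disagreement increments
    ``conflict_count``.
    """
    if r1.qual is None or r2.qual is None:
        raise ValueError("merge_read_pair requires quality scores on both reads")
    s2 = reverse_complement(r2.seq)
    q2 = np.asarray(r2.qual[::-1], dtype=np.int16)
    a = _encode(r1.seq)
    b = _encode(s2)
    n, m = len(a), len(b)
    max_l = min(n, m)
    if max_l < min_overlap:
        return MergeFailure(id=r1.id, reason=f"reads shorter than min_overlap {min_overlap}")
    # Mismatches for every candidate offset at once: slide windows of r1
    # (zero-padded; the pad never equals a base) against the prefix of
    # rc(r2). Padded positions register as mismatches and are subtracted.
    o_start = n - max_l
    o_end = n - min_overlap  # inclusive
    a_ext = np.concatenate([a, np.zeros(m, dtype=np.uint8)])
    windows = np.lib.stride_tricks.sliding_window_view(a_ext, m)[o_start:o_end + 1]
    mism_full = np.count_nonzero(windows != b, axis=1)
    offsets = np.arange(o_start, o_end + 1)
    lengths = n - offsets
    mism = mism_full - (m - lengths)
    ok = mism <= max_overlap_mismatch_frac * lengths
    if not ok.any():
        return MergeFailure(id=r1.id, reason=f"no overlap >= {min_overlap} within mismatch budget")
    idx = int(np.argmax(ok))  # smallest offset = longest acceptable overlap
    off, length = int(offsets[idx]), int(lengths[idx])

    ov_a, ov_b = a[off:], b[:length]
    q1 = np.asarray(r1.qual[off:], dtype=np.int16)
    q2o = q2[:length]
    diff = ov_a != ov_b
    use_b = diff & (q2o > q1)  # quality tie keeps the r1 base
    overlap_codes = np.where(use_b, ov_b, ov_a)
    overlap_qual = np.where(diff, np.where(use_b, q2o, q1), np.maximum(q1, q2o))
    merged_seq = r1.seq[:off] + overlap_codes.tobytes().decode() + s2[length:]
    qual_full = tuple(r1.qual[:off]) + tuple(int(q) for q in overlap_qual) + r2.qual[::-1][length:]
    return MergedAmplicon(
        id=r1.id,
        seq=merged_seq,
        overlap_len=length,
        conflict_count=int(diff.sum()),
        qual=qual_full,
    )


# ---------------------------------------------------------------------------
# Primer search

def _iupac_mismatches(primer_seq: str, window: str) -> int:
    n = 0
    for p, t in zip(primer_seq, window):
        if t not in IUPAC_DNA[p]:
            n += 1
    return n


_ALLOWED_TABLES: dict[str, np.ndarray] = {}


def _allowed_table(annealing_seq: str) -> np.ndarray:
    """(primer length x 256) lookup: does target byte match primer position."""
    table = _ALLOWED_TABLES.get(annealing_seq)
    if table is None:
        table = np.zeros((len(annealing_seq), 256), dtype=bool)
        for j, code in enumerate(annealing_seq):
            for base in IUPAC_DNA[code]:
                table[j, ord(base)] = True
        _ALLOWED_TABLES[annealing_seq] = table
    return table


def _mismatch_profile(target: str, annealing_seq: str) -> np.ndarray:
    """IUPAC-aware Hamming mismatch count at every target position."""
    plen = len(annealing_seq)
    t = np.frombuffer(target.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(t, plen)
    match = _allowed_table(annealing_seq)[np.arange(plen)[None, :], windows]
    return plen - match.sum(axis=1)


class NoHit:
    """Sentinel value: the primer found no site within tolerance."""

    def __bool__(self) -> bool:
        return False

    def __repr__(self) -> str:
        return "NoHit()"


NO_HIT = NoHit()


def find_primer(
    target: str,
    primer: PrimerDef,
    max_mismatch_frac: float = 0.2,
) -> PrimerHit | NoHit:
    """Best Hamming match of a primer's annealing sequence in a target.

    Reverse-orientation primers are matched against the reverse
    complement of the target; the hit position is reported on the
    + strand (0-based start of the occupied region). The best hit has
    the fewest mismatches; ties go to the smallest + strand position.
    """
    plen = len(primer.annealing_seq)
    if plen > len(target):
        return NO_HIT
    budget = allowed_mismatches(primer, max_mismatch_frac)
    strand = "+" if primer.orientation == "forward" else "-"
    search_target = target if strand == "+" else reverse_complement(target)
    mism = _mismatch_profile(search_target, primer.annealing_seq)
    in_budget = np.flatnonzero(mism <= budget)
    if in_budget.size == 0:
        return NO_HIT
    best_m = int(mism[in_budget].min())
    candidates = in_budget[mism[in_budget] == best_m]
    # tie-break on the smallest + strand position
    pos = int(candidates[0]) if strand == "+" else int(candidates[-1])
    plus_pos = pos if strand == "+" else len(target) - pos - plen
    return PrimerHit(
        primer_name=primer.name,
        position=plus_pos,
        strand=strand,
        mismatches=best_m,
        max_allowed=budget,
        length=plen,
    )


# ---------------------------------------------------------------------------
# ORF extraction and translation

TRANSLATED_LEN_RANGE = (90, 180)


def extract_and_translate(
    amplicon: MergedAmplicon,
    fwd_primers: Sequence[PrimerDef],
    rev_primers: Sequence[PrimerDef],
    frame_offset: int = 0,
    max_mismatch_frac: float = 0.2,
    fallback_rev: Optional[PrimerDef] = None,
    translated_len_range: tuple[int, int] = TRANSLATED_LEN_RANGE,
) -> VhhSequence | RejectReason:
    """Select and translate the ORF between the forward and reverse primers.

    The coding region starts at (forward annealing end + ``frame_offset``)
    and runs to the + strand start of the reverse primer site, truncated
    to whole codons. The identity of the matching reverse primer assigns
    the hinge class; if none matches but ``fallback_rev`` does, the hinge
    is ``unknown``. Draft records carry count 1 for later deduplication.
    """
    fwd_hit = _best_hit(amplicon.seq, fwd_primers, max_mismatch_frac)
    if fwd_hit is None:
        return RejectReason.NO_FORWARD
    rev_hit, hinge = None, Hinge.UNKNOWN
    best_rev = _best_hit(amplicon.seq, rev_primers, max_mismatch_frac)
    if best_rev is not None:
        rev_hit = best_rev
        matched = next(p for p in rev_primers if p.name == best_rev.primer_name)
        hinge = matched.hinge or Hinge.UNKNOWN
    elif fallback_rev is not None:
        fb = find_primer(amplicon.seq, fallback_rev, max_mismatch_frac)
        if fb:
            rev_hit, hinge = fb, Hinge.UNKNOWN
    if rev_hit is None:
        return RejectReason.NO_REVERSE

    start = fwd_hit.end + frame_offset
    end = rev_hit.position
    if end <= start:
        return RejectReason.EMPTY_ORF
    coding = amplicon.seq[start:end]
    coding = coding[: len(coding) - len(coding) % 3]
    if not coding:
        return RejectReason.EMPTY_ORF
    protein = str(Seq(coding).translate())
    if "*" in protein:
        return RejectReason.INTERNAL_STOP
    lo, hi = translated_len_range
    if not (lo <= len(protein) <= hi):
        return RejectReason.BAD_LENGTH
    return VhhSequence(
        id=_stable_id(protein), protein=protein, dna=coding, count=1, hinge=hinge
    )


def _best_hit(target, primers, max_mismatch_frac):
    best, best_key = None, None
    for p in primers:
        hit = find_primer(target, p, max_mismatch_frac)
        if hit:
            key = (hit.mismatches, hit.position, p.name)
            if best is None or key < best_key:
                best, best_key = hit, key
    return best


def dedup_and_count(drafts: Sequence[VhhSequence]) -> list[VhhSequence]:
    """Collapse exact protein duplicates, summing read support.

    The representative DNA is the most frequent exact DNA variant (ties:
    lexicographically smallest). Output sorted by count descending, then
    protein ascending. Total count is conserved.
    """
    by_protein: dict[str, list[VhhSequence]] = {}
    for d in drafts:
        by_protein.setdefault(d.protein, []).append(d)
    out = []
    for protein, group in by_protein.items():
        dna_votes = Counter()
        total = 0
        hinge_votes = Counter()
        for d in group:
            dna_votes[d.dna] += d.count
            total += d.count
            hinge_votes[d.hinge] += d.count
        best_dna = min(dna_votes, key=lambda s: (-dna_votes[s], s))
        hinge = min(hinge_votes, key=lambda h: (-hinge_votes[h], h.value))
        out.append(
            VhhSequence(
                id=_stable_id(protein), protein=protein, dna=best_dna,
                count=total, hinge=hinge,
            )
        )
    out.sort(key=lambda v: (-v.count, v.protein))
    return out


def build_database(
    pairs: Sequence[tuple[SequenceRecord, SequenceRecord]],
    fwd_primers: Sequence[PrimerDef],
    rev_primers: Sequence[PrimerDef],
    min_overlap: int = 20,
    max_overlap_mismatch_frac: float = 0.05,
    max_mismatch_frac: float = 0.2,
    frame_offset: int = 0,
    fallback_rev: Optional[PrimerDef] = None,
) -> tuple[list[VhhSequence], Counter]:
    """Merge, extract, translate and deduplicate a batch of read pairs.

    Returns the counted protein database plus a tally of merge failures
    and per-reason rejections (nothing is dropped silently).
    """
    tally: Counter = Counter()
    drafts = []
    for r1, r2 in pairs:
        merged = merge_read_pair(r1, r2, min_overlap, max_overlap_mismatch_frac)
        if isinstance(merged, MergeFailure):
            tally["merge_failure"] += 1
            continue
        result = extract_and_translate(
            merged, fwd_primers, rev_primers,
            frame_offset=frame_offset,
            max_mismatch_frac=max_mismatch_frac,
            fallback_rev=fallback_rev,
        )
        if isinstance(result, RejectReason):
            tally[f"reject_{result.value}"] += 1
            continue
        tally["translated"] += 1
        drafts.append(result)
    return dedup_and_count(drafts), tally


# ---------------------------------------------------------------------------
# Primer coverage survey and flank diversity

@dataclasses.dataclass(frozen=True)
class SurveyVariant:
    seq: str
    abundance: int
    mean_mismatches: float


@dataclasses.dataclass(frozen=True)
class SurveyResult:
    variants: tuple[SurveyVariant, ...]
    coverage: Optional[float]  # fraction in [0,1]; None if no target had a site
    n_targets: int
    n_with_site: int

    @property
    def coverage_pct(self) -> Optional[float]:
        return None if self.coverage is None else 100.0 * self.coverage


def primer_coverage_survey(
    targets: Sequence[str],
    probe: PrimerDef,
    max_mismatch_frac: float = 0.2,
    top_n: int = 10,
    merge_radius: int = 1,
) -> SurveyResult:
    """Survey how well a primer's annealing site covers a repertoire.

    For each target the best within-tolerance site is extracted as its
    annealing-site variant. The ``top_n`` most abundant variants are
    selected; every less abundant variant is then merged, in descending
    abundance, into the most abundant selected variant within Hamming
    distance ``merge_radius`` (accounting for sequencing errors and
    point mutations), else dropped. Coverage = kept abundance / targets
    with any within-tolerance site.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if merge_radius < 0:
        raise ValueError("merge_radius must be >= 0")
    variant_counts: Counter[str] = Counter()
    variant_mism: dict[str, int] = {}
    n_with_site = 0
    for t in targets:
        hit = find_primer(t, probe, max_mismatch_frac)
        if not hit:
            continue
        n_with_site += 1
        site = t[hit.position:hit.end]
        if probe.orientation == "reverse":
            site = reverse_complement(site)
        variant_counts[site] += 1
        variant_mism[site] = hit.mismatches
    if n_with_site == 0:
        return SurveyResult(variants=(), coverage=None, n_targets=len(targets), n_with_site=0)

    ordered = sorted(variant_counts, key=lambda v: (-variant_counts[v], v))
    kept = ordered[:top_n]
    merged_counts: dict[str, int] = {k: variant_counts[k] for k in kept}
    merged_mism: dict[str, list[tuple[int, int]]] = {
        k: [(variant_mism[k], variant_counts[k])] for k in kept
    }
    for v in ordered[top_n:]:
        cnt = variant_counts[v]
        home = None
        for k in sorted(kept, key=lambda k: (-merged_counts[k], k)):
            if len(k) == len(v) and _hamming(k, v) <= merge_radius:
                home = k
                break
        if home is not None:
            merged_counts[home] += cnt
            merged_mism[home].append((variant_mism[v], cnt))
        # else dropped: outside the kept set entirely
    variants = tuple(
        SurveyVariant(
            seq=k,
            abundance=merged_counts[k],
            mean_mismatches=sum(m * w for m, w in merged_mism[k]) / merged_counts[k],
        )
        for k in sorted(kept, key=lambda k: (-merged_counts[k], k))
    )
    coverage = sum(merged_counts.values()) / n_with_site
    return SurveyResult(
        variants=variants, coverage=coverage,
        n_targets=len(targets), n_with_site=n_with_site,
    )


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def flanking_region_diversity(
    targets: Sequence[str],
    anchor_hits: Sequence[PrimerHit],
    window: int,
    side: str,
) -> tuple[Counter, int]:
    """Unique flanking sequences adjacent to an anchor site, with counts.

    ``side`` is ``"upstream"`` (5' of the anchor on the + strand) or
    ``"downstream"``. Targets whose window would run off the end are
    skipped; the skip tally is returned alongside the counter.
    """
    if side not in ("upstream", "downstream"):
        raise ValueError(f"side must be 'upstream' or 'downstream', got {side!r}")
    flanks: Counter[str] = Counter()
    skipped = 0
    for target, hit in zip(targets, anchor_hits):
        if side == "upstream":
            start, end = hit.position - window, hit.position
        else:
            start, end = hit.end, hit.end + window
        if start < 0 or end > len(target):
            skipped += 1
            continue
        flanks[target[start:end]] += 1
    return flanks, skipped
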