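"""Peptide-to-sequence matching, CDR-weighted scoring, and candidate ranking.

The candidate-selection logic works as follows. MS-identified peptides
are mapped back onto the translated sequence database by substring
containment, with leucine and isoleucine treated as identical (they are
isobaric and indistinguishable by standard fragmentation). Each sequence
receives a coverage score — the weighted fraction of its residues
covered by at least one matched peptide, with CDR residues up-weighted
and CDR3 weighted most. Sequences are partitioned into clonotype groups
by CDR3; each group is ranked by its top-scoring member, and members
within a group by their sequencing read counts (higher-count sequences
are more likely to come from bona fide transcripts). Every matched
peptide gets a uniqueness score per group:

    100 x (sequences in the group containing the peptide)
        / (sequences in the whole database containing the peptide)

i.e. the probability the peptide originated from that clonotype.
Selection requires at least one peptide with uniqueness strictly above
the threshold (default 80), no cross-antigen peptide evidence, and no
VH-hallmark (GLEW) flag.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from typing import Optional, Sequence

from .amplicon import VhhSequence
from .annotate import CdrAnnotation, Confidence, has_vh_hallmark
from .seqio import PeptideObservation

logger = logging.getLogger("nanomatch")

DEFAULT_WEIGHTS = {"FR": 1.0, "CDR1": 3.0, "CDR2": 3.0, "CDR3": 10.0}
DEFAULT_UNIQUENESS_THRESHOLD = 80.0


def il_collapse(seq: str) -> str:
    """Collapse the isobaric leucine/isoleucine pair onto one symbol."""
    return seq.replace("I", "L")


def _contains(haystack: str, needle: str, il_equivalent: bool) -> bool:
    if il_equivalent:
        return il_collapse(needle) in il_collapse(haystack)
    return needle in haystack


def _find_spans(haystack: str, needle: str, il_equivalent: bool) -> tuple[tuple[int, int], ...]:
    h = il_collapse(haystack) if il_equivalent else haystack
    n = il_collapse(needle) if il_equivalent else needle
    spans = []
    start = h.find(n)
    while start != -1:
        spans.append((start, start + len(n)))
        start = h.find(n, start + 1)
    return tuple(spans)


@dataclasses.dataclass(frozen=True)
class PeptideMatch:
    peptide: str
    protease: str
    matched_ids: frozenset
    spans: dict  # sequence id -> tuple of (start, end) spans

    @property
    def unmatched(self) -> bool:
        return not self.matched_ids


def map_peptides(
    observations: Sequence[PeptideObservation],
    db: Sequence[VhhSequence],
    il_equivalent: bool = True,
) -> list[PeptideMatch]:
    """Map observed peptides onto database sequences by containment.

    One match record per distinct (peptide, protease) pair, in first-seen
    order; peptides matching nothing are retained with empty
    ``matched_ids`` so unmatched evidence is never silently lost.
    """
    seen = set()
    matches = []
    for obs in observations:
        key = (obs.peptide, obs.protease)
        if key in seen:
            continue
        seen.add(key)
        spans = {}
        for v in db:
            s = _find_spans(v.protein, obs.peptide, il_equivalent)
            if s:
                spans[v.id] = s
        matches.append(
            PeptideMatch(
                peptide=obs.peptide,
                protease=obs.protease,
                matched_ids=frozenset(spans),
                spans=spans,
            )
        )
    return matches


# ---------------------------------------------------------------------------
# Coverage scoring

@dataclasses.dataclass(frozen=True)
class CoverageScore:
    sequence_id: str
    score: float  # in [0, 100]
    region_covered: dict  # region -> (covered residues, region length)
    cdr3_covered: bool
    uniform_weights: bool = False
    cdr3_fragmentation_ok: Optional[bool] = None


def coverage_score(
    sequence: VhhSequence,
    annotation: CdrAnnotation,
    spans: Sequence[tuple[int, int]],
    weights: Optional[dict] = None,
) -> CoverageScore:
    """Weighted peptide-coverage score of one sequence.

    score = 100 x sum_r w_r c_r / sum_r w_r n_r over resolved regions,
    where c_r is the number of region-r residues covered by >= 1 matched
    peptide and n_r the region length. Unresolved regions carry zero
    weight. A failed annotation falls back to uniform weights over the
    whole sequence and is flagged.
    """
    weights = dict(DEFAULT_WEIGHTS if weights is None else weights)
    n = len(sequence.protein)
    covered = bytearray(n)
    for s, e in spans:
        for i in range(max(s, 0), min(e, n)):
            covered[i] = 1

    region_covered = {}
    if annotation.confidence == Confidence.FAILED:
        score = 100.0 * sum(covered) / n if n else 0.0
        return CoverageScore(
            sequence_id=sequence.id, score=score, region_covered={},
            cdr3_covered=False, uniform_weights=True,
        )

    num = den = 0.0
    for region, span in annotation.regions.items():
        if span is None:
            continue
        s, e = span
        w = weights.get(region, weights.get("FR", 1.0))
        c = sum(covered[s:e])
        region_covered[region] = (c, e - s)
        num += w * c
        den += w * (e - s)
    score = 100.0 * num / den if den else 0.0
    cdr3_span = annotation.regions.get("CDR3")
    cdr3_cov = bool(cdr3_span and sum(covered[cdr3_span[0]:cdr3_span[1]]) > 0)
    return CoverageScore(
        sequence_id=sequence.id, score=score,
        region_covered=region_covered, cdr3_covered=cdr3_cov,
    )


# ---------------------------------------------------------------------------
# CDR3 clonotype grouping

@dataclasses.dataclass(frozen=True)
class Cdr3Group:
    group_id: str
    cdr3: str  # representative CDR3 (I/L-collapsed key for exact groups)
    member_ids: tuple
    unresolved: bool = False


def _group_id(key: str) -> str:
    return "grp_" + hashlib.sha1(key.encode()).hexdigest()[:10]


def _cdr3_identity(a: str, b: str) -> float:
    """Ungapped identity between two CDR3s of length difference <= 1:
    best sliding alignment matches / longer length."""
    if len(a) > len(b):
        a, b = b, a
    if len(b) - len(a) > 1:
        return 0.0
    best = 0
    for off in range(len(b) - len(a) + 1):
        best = max(best, sum(x == y for x, y in zip(a, b[off:])))
    return best / len(b)


def group_by_cdr3(
    db: Sequence[VhhSequence],
    annotations: dict,
    mode: str = "exact",
    similarity_threshold: float = 0.8,
) -> list[Cdr3Group]:
    """Partition the database into CDR3 clonotype groups.

    Exact mode keys groups by the I/L-collapsed CDR3 string. Cluster
    mode additionally single-linkage-merges exact groups whose CDR3s
    have identity >= ``similarity_threshold`` (lengths within 1).
    Sequences with unresolved CDR3 become flagged singletons. The
    result is a partition of all input sequences.
    """
    if mode not in ("exact", "cluster"):
        raise ValueError(f"mode must be 'exact' or 'cluster', got {mode!r}")
    exact: dict[str, list[str]] = {}
    singletons = []
    for v in db:
        ann = annotations.get(v.id)
        cdr3 = ann.cdr3(v.protein) if ann is not None else None
        if not cdr3:
            singletons.append(v.id)
            continue
        exact.setdefault(il_collapse(cdr3), []).append(v.id)

    keys = sorted(exact)
    if mode == "cluster" and len(keys) > 1:
        parent = list(range(len(keys)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                if _cdr3_identity(keys[i], keys[j]) >= similarity_threshold:
                    parent[find(i)] = find(j)
        clusters: dict[int, list[str]] = {}
        for i in range(len(keys)):
            clusters.setdefault(find(i), []).append(keys[i])
        merged = {}
        counts = {v.id: v.count for v in db}
        for members in clusters.values():
            # representative CDR3: highest total read support, tie smallest
            rep = min(
                members,
                key=lambda k: (-sum(counts[m] for m in exact[k]), k),
            )
            merged[rep] = sorted(m for k in members for m in exact[k])
        exact = merged

    groups = [
        Cdr3Group(group_id=_group_id(key), cdr3=key, member_ids=tuple(sorted(ids)))
        for key, ids in sorted(exact.items())
    ]
    groups.extend(
        Cdr3Group(
            group_id=_group_id("__unresolved__" + sid), cdr3="",
            member_ids=(sid,), unresolved=True,
        )
        for sid in sorted(singletons)
    )
    return groups


# ---------------------------------------------------------------------------
# Uniqueness score

def uniqueness_score(
    peptide: str,
    group_member_ids: Sequence[str],
    db: Sequence[VhhSequence],
    il_equivalent: bool = True,
) -> float:
    """100 x (group sequences containing the peptide) / (database
    sequences containing the peptide); the probability the peptide
    originated from this clonotype. Undefined (raises) for a peptide
    contained in no database sequence."""
    members = set(group_member_ids)
    n_db = n_group = 0
    for v in db:
        if _contains(v.protein, peptide, il_equivalent):
            n_db += 1
            if v.id in members:
                n_group += 1
    if n_db == 0:
        raise ValueError(f"peptide {peptide!r} matches no database sequence")
    return 100.0 * n_group / n_db


# ---------------------------------------------------------------------------
# Report assembly: ranking, filters, evidence

@dataclasses.dataclass
class MemberResult:
    member_id: str
    count: int
    coverage_score: float
    cdr3_covered: bool
    hinge: str
    peptides: list  # dicts: peptide, protease, uniqueness, spans, covers_cdr3
    cross_antigen_hit: bool = False
    glew_hit: bool = False
    no_unique_peptide: bool = False
    selected: bool = False


@dataclasses.dataclass
class RankedGroup:
    group_id: str
    cdr3: str
    group_score: float
    total_count: int
    members: list
    unresolved_cdr3: bool = False


@dataclasses.dataclass
class CandidateReport:
    groups: list

    def to_dict(self) -> dict:
        return {
            "groups": [
                {
                    "group_id": g.group_id,
                    "cdr3": g.cdr3,
                    "group_score": round(g.group_score, 6),
                    "total_count": g.total_count,
                    "unresolved_cdr3": g.unresolved_cdr3,
                    "members": [
                        {
                            "member_id": m.member_id,
                            "count": m.count,
                            "coverage_score": round(m.coverage_score, 6),
                            "cdr3_covered": m.cdr3_covered,
                            "hinge": m.hinge,
                            "cross_antigen_hit": m.cross_antigen_hit,
                            "glew_hit": m.glew_hit,
                            "no_unique_peptide": m.no_unique_peptide,
                            "selected": m.selected,
                            "peptides": [
                                {
                                    "peptide": p["peptide"],
                                    "protease": p["protease"],
                                    "uniqueness": round(p["uniqueness"], 6),
                                    "spans": [list(s) for s in p["spans"]],
                                    "covers_cdr3": p["covers_cdr3"],
                                }
                                for p in m.peptides
                            ],
                        }
                        for m in g.members
                    ],
                }
                for g in self.groups
            ]
        }

    def selected_members(self) -> list:
        return [m for g in self.groups for m in g.members if m.selected]

    def candidate_shortlist(self) -> list:
        """The post-elimination candidate list: groups that retain at
        least one selected member, in rank order. Groups whose every
        member was flagged (cross-antigen evidence, VH hallmark, or no
        sufficiently unique peptide) are eliminated, mirroring how
        flagged sequences are struck from the candidate list before
        synthesis."""
        return [g for g in self.groups if any(m.selected for m in g.members)]


def rank_candidates(
    groups: Sequence[Cdr3Group],
    scores: dict,
    counts: dict,
) -> CandidateReport:
    """Assemble the ranked report skeleton (no filters applied yet).

    Groups are ordered by descending group score (max member coverage
    score), ties by descending total group read count then group id;
    members within a group by descending count, ties by descending
    coverage score then id. The ordering is total and deterministic.
    """
    ranked = []
    for g in groups:
        members = sorted(
            g.member_ids,
            key=lambda sid: (-counts[sid], -scores[sid].score, sid),
        )
        group_score = max(scores[sid].score for sid in g.member_ids)
        total_count = sum(counts[sid] for sid in g.member_ids)
        ranked.append((g, members, group_score, total_count))
    ranked.sort(key=lambda t: (-t[2], -t[3], t[0].group_id))
    report_groups = [
        RankedGroup(
            group_id=g.group_id,
            cdr3=g.cdr3,
            group_score=group_score,
            total_count=total_count,
            unresolved_cdr3=g.unresolved,
            members=[
                MemberResult(
                    member_id=sid,
                    count=counts[sid],
                    coverage_score=scores[sid].score,
                    cdr3_covered=scores[sid].cdr3_covered,
                    hinge="",
                    peptides=[],
                )
                for sid in members
            ],
        )
        for g, members, group_score, total_count in ranked
    ]
    return CandidateReport(groups=report_groups)


def attach_peptide_evidence(
    report: CandidateReport,
    matches: Sequence[PeptideMatch],
    annotations: dict,
    db: Sequence[VhhSequence],
) -> None:
    """Attach per-member peptide evidence with group-relative uniqueness.

    Uniqueness uses the match sets already computed (same containment
    relation as :func:`map_peptides`): denominator = database sequences
    containing the peptide, numerator = group members containing it.
    """
    hinge = {v.id: v.hinge.value for v in db}
    for group in report.groups:
        member_set = {m.member_id for m in group.members}
        for match in matches:
            if not match.matched_ids:
                continue
            in_group = match.matched_ids & member_set
            if not in_group:
                continue
            uniq = 100.0 * len(in_group) / len(match.matched_ids)
            for m in group.members:
                if m.member_id not in match.matched_ids:
                    continue
                spans = match.spans[m.member_id]
                ann = annotations.get(m.member_id)
                cdr3_span = ann.cdr3_span() if ann is not None else None
                covers = bool(cdr3_span) and any(
                    s < cdr3_span[1] and e > cdr3_span[0] for s, e in spans
                )
                m.peptides.append(
                    {
                        "peptide": match.peptide,
                        "protease": match.protease,
                        "uniqueness": uniq,
                        "spans": spans,
                        "covers_cdr3": covers,
                    }
                )
        for m in group.members:
            m.hinge = hinge.get(m.member_id, "")
            m.peptides.sort(key=lambda p: (-p["uniqueness"], p["peptide"], p["protease"]))


def apply_filters(
    report: CandidateReport,
    cross_antigen_peptides: Optional[dict] = None,
    uniqueness_threshold: float = DEFAULT_UNIQUENESS_THRESHOLD,
    glew_flags: Optional[dict] = None,
    il_equivalent: bool = True,
) -> CandidateReport:
    """Apply the selection filters in place and return the report.

    Flags per member: ``cross_antigen_hit`` if any CDR3-covering matched
    peptide with uniqueness strictly above the threshold also appears in
    an unrelated antigen's observed peptide set (I/L-equivalent) —
    evidence of nonspecific binding; ``glew_hit`` from the annotation's
    VH-hallmark check (indeterminate annotations do not flag);
    ``no_unique_peptide`` if no matched peptide exceeds the threshold.
    ``selected`` = no flag set.
    """
    cross_sets = {}
    for label, peps in (cross_antigen_peptides or {}).items():
        cross_sets[label] = {
            il_collapse(p) if il_equivalent else p for p in peps
        }
    glew_flags = glew_flags or {}
    for group in report.groups:
        for m in group.members:
            uniq_ok = [p for p in m.peptides if p["uniqueness"] > uniqueness_threshold]
            m.no_unique_peptide = not uniq_ok
            m.glew_hit = glew_flags.get(m.member_id) is True
            m.cross_antigen_hit = any(
                p["covers_cdr3"]
                and any(
                    (il_collapse(p["peptide"]) if il_equivalent else p["peptide"]) in s
                    for s in cross_sets.values()
                )
                for p in uniq_ok
            )
            m.selected = not (m.cross_antigen_hit or m.glew_hit or m.no_unique_peptide)
    return report


def evidence_summary(report: CandidateReport, annotations: dict) -> list[dict]:
    """Evidence rows for manual spectral review of selected candidates.

    For each selected candidate, every CDR3-spanning matched peptide is
    listed with its uniqueness and spans so its MS/MS spectrum can be
    examined for fragmentation within the CDR3. Candidates selected with
    no CDR3-spanning peptide produce a warning row.
    """
    rows = []
    for group in report.groups:
        for m in group.members:
            if not m.selected:
                continue
            cdr3_peps = [p for p in m.peptides if p["covers_cdr3"]]
            if not cdr3_peps:
                logger.warning(
                    "selected candidate %s has no CDR3-spanning peptide evidence",
                    m.member_id,
                )
            for p in cdr3_peps:
                rows.append(
                    {
                        "group_id": group.group_id,
                        "member_id": m.member_id,
                        "peptide": p["peptide"],
                        "protease": p["protease"],
                        "uniqueness": p["uniqueness"],
                        "spans": p["spans"],
                    }
                )
    return rows


def score_and_rank(
    db: Sequence[VhhSequence],
    annotations: dict,
    observations: Sequence[PeptideObservation],
    cross_antigen_peptides: Optional[dict] = None,
    weights: Optional[dict] = None,
    uniqueness_threshold: float = DEFAULT_UNIQUENESS_THRESHOLD,
    group_mode: str = "exact",
    similarity_threshold: float = 0.8,
    il_equivalent: bool = True,
) -> CandidateReport:
    """Run the full matching/scoring/ranking/filtering stage end to end."""
    matches = map_peptides(observations, db, il_equivalent)
    scores = {}
    for v in db:
        spans = [s for match in matches for s in match.spans.get(v.id, ())]
        scores[v.id] = coverage_score(v, annotations[v.id], spans, weights)
    groups = group_by_cdr3(db, annotations, group_mode, similarity_threshold)
    counts = {v.id: v.count for v in db}
    report = rank_candidates(groups, scores, counts)
    attach_peptide_evidence(report, matches, annotations, db)
    glew = {}
    for v in db:
        ann = annotations[v.id]
        glew[v.id] = (
            None
            if ann.confidence == Confidence.FAILED
            else has_vh_hallmark(v.protein, ann.imgt_map)
        )
    apply_filters(report, cross_antigen_peptides, uniqueness_threshold, glew, il_equivalent)
    return report
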